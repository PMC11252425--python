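import numpy as np
import pytest

from coop_punish import CategoryCounts, ParameterSet, SimulationDesign, simulate_experiment


@pytest.fixture(scope="session")
def exp1_like_design() -> SimulationDesign:
    """Two-condition design at the first experiment's sample size.

    Generating values are illustrative: moral punishment reduced and the
    bias elevated under time pressure, cooperation near one half.
    """
    return SimulationDesign(
        parameters={
            "no_pressure": ParameterSet(0.50, 0.60, 0.25, 0.10, 0.05),
            "pressure": ParameterSet(0.50, 0.45, 0.25, 0.15, 0.10),
        },
        n_participants={"no_pressure": 102, "pressure": 104},
        seed=20260101,
    )


@pytest.fixture(scope="session")
def exp1_like_trials(exp1_like_design):
    return simulate_experiment(exp1_like_design)


@pytest.fixture
def small_counts() -> CategoryCounts:
    """Hand-sized counts (≤30 per tree) for oracle comparisons."""
    return CategoryCounts(np.array([9, 5, 4, 10, 2, 12, 5, 8]))


def profile_grid_g2(counts: CategoryCounts, step: float = 0.001) -> float:
    """Independent G² oracle: brute-force grid over b with closed-form profiling.

    Given b, the product-multinomial likelihood separates: C has the
    closed-form MLE k_coop/N, and each outcome-contingent punishment
    probability q = P + (1-P)b ranges freely over [b, 1], so its optimum
    is the observed punish fraction clipped to [b, 1].  Scanning b on a
    0.001-step grid therefore evaluates the global profile likelihood by
    brute force, independently of the package optimizer.
    """
    n = counts.values.astype(float)
    k_coop = n[0] + n[1] + n[4] + n[5]
    k_def = n[2] + n[3] + n[6] + n[7]
    N = k_coop + k_def

    def xlogy(x, y):
        return x * np.log(np.clip(y, 1e-300, None)) if x > 0 else 0.0

    ll_c = 0.0
    if N > 0:
        c_hat = k_coop / N
        ll_c = xlogy(k_coop, c_hat) + xlogy(k_def, 1 - c_hat)

    # punish / no-punish pairs: (moral, hypocritical, antisocial) are
    # process cells with q in [b, 1]; the mutual-cooperation pair is pure bias.
    process_pairs = [(n[0], n[1]), (n[2], n[3]), (n[6], n[7])]
    bias_pair = (n[4], n[5])

    best = -np.inf
    for b in np.arange(0.0, 1.0 + step / 2, step):
        ll = ll_c + xlogy(bias_pair[0], b) + xlogy(bias_pair[1], 1 - b)
        for n_p, n_n in process_pairs:
            tot = n_p + n_n
            if tot == 0:
                continue
            q = min(max(n_p / tot, b), 1.0)
            ll += xlogy(n_p, q) + xlogy(n_n, 1 - q)
        best = max(best, ll)

    sat = 0.0
    for tree in (n[:4], n[4:]):
        tot = tree.sum()
        if tot > 0:
            for cell in tree:
                sat += xlogy(cell, cell / tot)
    return 2.0 * (sat - best)
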