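"""Maximum-likelihood estimation and nested-model testing.

Fits a :class:`~coop_punish.model.ModelSpec` to per-stratum category
counts under the product-multinomial likelihood, computes the G²
goodness-of-fit statistic, Wald standard errors from the observed
information, likelihood-ratio (ΔG²) tests of nested parameter
restrictions, and Cohen's w effect sizes.

Optimization runs on logit-transformed parameters with the analytic
gradient of the log-likelihood; multiple restarts from a seeded Sobol
draw guard against local optima under heavy parameter tying.  Strata
that share no free parameter are fitted as independent blocks, which
leaves the optimum unchanged but keeps large stratifications (e.g.
condition × round) fast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.stats import qmc
from scipy.special import expit, logit

from .model import (
    PARAMETER_NAMES,
    CategoryCounts,
    ModelSpec,
    _probabilities_array,
    category_probability_jacobian,
    degrees_of_freedom,
)

__all__ = [
    "FitResult",
    "TestResult",
    "g_squared",
    "fit",
    "wald_standard_errors",
    "delta_g2_test",
    "effect_size_w",
]

# fitted probabilities are clamped to this interval; keeps G² finite
# while perturbing probabilities by less than 1e-5
PARAM_EPS = 1e-6
_LOGIT_BOUND = float(logit(1 - PARAM_EPS))


@dataclass(frozen=True)
class FitResult:
    """Outcome of a maximum-likelihood fit."""

    estimates: Mapping[str, float]
    standard_errors: Mapping[str, float]
    g_squared: float
    df: int
    p_value: float
    log_likelihood: float
    converged: bool
    n_restarts_used: int
    spec: ModelSpec
    unidentified: tuple = ()

    def estimate_array(self) -> np.ndarray:
        return np.array([self.estimates[k] for k in self.spec.free_parameters])


@dataclass(frozen=True)
class TestResult:
    """Likelihood-ratio comparison of a restricted model against a base model."""

    delta_g_squared: float
    df: int
    p_value: float
    w: float
    restricted_fit: FitResult
    base_fit: FitResult


def g_squared(observed: np.ndarray | CategoryCounts, expected: np.ndarray) -> float:
    """Likelihood-ratio goodness-of-fit statistic 2·Σ nᵢ·ln(nᵢ/mᵢ).

    Cells with zero observed count contribute 0.  A zero expected count
    facing a positive observed count yields ``inf``.
    """
    if isinstance(observed, CategoryCounts):
        observed = observed.values
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if observed.shape != expected.shape:
        raise ValueError("observed and expected must share their shape")
    pos = observed > 0
    if np.any(expected[pos] <= 0):
        return float("inf")
    return float(2.0 * np.sum(observed[pos] * np.log(observed[pos] / expected[pos])))


def _saturated_loglik(counts: np.ndarray) -> float:
    """Log-likelihood of the saturated product-multinomial model."""
    total = 0.0
    for tree in (counts[:4], counts[4:]):
        n = tree.sum()
        if n > 0:
            pos = tree > 0
            total += float(np.sum(tree[pos] * np.log(tree[pos] / n)))
    return total


class _FitProblem:
    """Index bookkeeping for one connected block of strata."""

    def __init__(self, spec: ModelSpec, counts: Mapping, strata: Sequence):
        self.strata = tuple(strata)
        self.free_ids = []
        seen = {}
        for stratum in self.strata:
            for name in PARAMETER_NAMES:
                v = spec.assignments[(stratum, name)]
                if isinstance(v, str) and v not in seen:
                    seen[v] = len(self.free_ids)
                    self.free_ids.append(v)
        # slot_index[s, j] = index into free vector, or -1 for constants
        S = len(self.strata)
        self.slot_index = np.full((S, 5), -1, dtype=int)
        self.constants = np.zeros((S, 5), dtype=float)
        for i, stratum in enumerate(self.strata):
            for j, name in enumerate(PARAMETER_NAMES):
                v = spec.assignments[(stratum, name)]
                if isinstance(v, str):
                    self.slot_index[i, j] = seen[v]
                else:
                    self.constants[i, j] = v
        self.counts = np.stack(
            [np.asarray(counts[s].values, dtype=float) for s in self.strata]
        )  # (S, 8)
        self.sat_loglik = sum(_saturated_loglik(row) for row in self.counts)

    @property
    def k(self) -> int:
        return len(self.free_ids)

    def theta_matrix(self, free: np.ndarray) -> np.ndarray:
        theta = self.constants.copy()
        mask = self.slot_index >= 0
        theta[mask] = free[self.slot_index[mask]]
        return theta

    def negloglik_and_grad(self, z: np.ndarray) -> tuple[float, np.ndarray]:
        free = np.clip(expit(z), PARAM_EPS, 1 - PARAM_EPS)
        theta = self.theta_matrix(free)
        probs = _probabilities_array(theta)  # (S, 8)
        probs = np.clip(probs, 1e-300, None)
        ll = float(np.sum(self.counts * np.log(probs)))
        # d ll / d theta_{s,j} = sum_cells n/p * dp/dtheta
        jac = category_probability_jacobian(theta)  # (S, 8, 5)
        weights = self.counts / probs  # (S, 8)
        dll_dtheta = np.einsum("sc,scj->sj", weights, jac)  # (S, 5)
        grad = np.zeros(self.k)
        mask = self.slot_index >= 0
        np.add.at(grad, self.slot_index[mask], dll_dtheta[mask])
        grad *= free * (1 - free)  # chain rule through the logit
        return -ll, -grad

    def loglik_free(self, free: np.ndarray) -> float:
        theta = self.theta_matrix(np.clip(free, PARAM_EPS, 1 - PARAM_EPS))
        probs = np.clip(_probabilities_array(theta), 1e-300, None)
        return float(np.sum(self.counts * np.log(probs)))


def _connected_blocks(spec: ModelSpec) -> list:
    """Partition strata into blocks connected by shared free identifiers."""
    parent = {s: s for s in spec.strata}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    owner: dict = {}
    for stratum in spec.strata:
        for name in PARAMETER_NAMES:
            v = spec.assignments[(stratum, name)]
            if isinstance(v, str):
                if v in owner:
                    ra, rb = find(owner[v]), find(stratum)
                    if ra != rb:
                        parent[ra] = rb
                else:
                    owner[v] = stratum
    blocks: dict = {}
    for stratum in spec.strata:
        blocks.setdefault(find(stratum), []).append(stratum)
    return list(blocks.values())


def _starts(problem: _FitProblem, seed: int, n_restarts: int) -> np.ndarray:
    """First start at 0.5 everywhere, remainder from a scrambled Sobol draw."""
    starts = [np.full(problem.k, 0.5)]
    if n_restarts > 1:
        sob = qmc.Sobol(d=problem.k, scramble=True, rng=np.random.default_rng(seed))
        m = max(1, int(np.ceil(np.log2(n_restarts - 1))))
        draw = sob.random_base2(m)[: n_restarts - 1]
        starts.extend(0.02 + 0.96 * draw)
    return np.asarray(starts)


def fit(
    counts: Mapping,
    spec: ModelSpec,
    seed: int = 0,
    n_restarts: int = 20,
    compute_se: bool = True,
) -> FitResult:
    """Fit ``spec`` to per-stratum counts by maximum likelihood.

    Parameters
    ----------
    counts
        Mapping from stratum label to :class:`CategoryCounts`; every
        stratum of the spec must be present.
    seed
        Seeds the restart draw; identical inputs give identical results.
    n_restarts
        Optimizer starts per connected block.  The best (highest
        likelihood) solution is kept; exact ties break to the
        lexicographically smallest parameter vector.
    """
    missing = [s for s in spec.strata if s not in counts]
    if missing:
        raise ValueError(f"counts missing for strata: {missing}")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")

    estimates: dict = {}
    loglik = 0.0
    sat = 0.0
    converged = True
    unidentified: list = []
    rng_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=1000)

    for bi, block in enumerate(sorted(_connected_blocks(spec), key=str)):
        problem = _FitProblem(spec, counts, block)
        sat += problem.sat_loglik
        if problem.k == 0:
            loglik += problem.loglik_free(np.empty(0))
            continue
        unidentified.extend(_unidentified_ids(problem))
        best_ll, best_free, any_ok = -np.inf, None, False
        for start in _starts(problem, int(rng_seeds[bi % 1000]), n_restarts):
            res = optimize.minimize(
                problem.negloglik_and_grad,
                logit(start),
                jac=True,
                method="L-BFGS-B",
                bounds=[(-_LOGIT_BOUND, _LOGIT_BOUND)] * problem.k,
                options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-9},
            )
            free = np.clip(expit(res.x), PARAM_EPS, 1 - PARAM_EPS)
            ll = -res.fun
            any_ok = any_ok or res.success
            if ll > best_ll + 1e-8 or (
                abs(ll - best_ll) <= 1e-8
                and best_free is not None
                and tuple(free) < tuple(best_free)
            ):
                best_ll, best_free = ll, free
        converged = converged and any_ok
        loglik += best_ll
        estimates.update(zip(problem.free_ids, best_free))

    g2 = max(0.0, 2.0 * (sat - loglik))
    df = degrees_of_freedom(spec)
    p = float(stats.chi2.sf(g2, df)) if df > 0 else 1.0
    ses: dict = {k: float("nan") for k in spec.free_parameters}
    result = FitResult(
        estimates={k: float(estimates[k]) for k in spec.free_parameters},
        standard_errors=ses,
        g_squared=g2,
        df=df,
        p_value=p,
        log_likelihood=loglik,
        converged=converged,
        n_restarts_used=n_restarts,
        spec=spec,
        unidentified=tuple(unidentified),
    )
    if compute_se:
        result = FitResult(
            estimates=result.estimates,
            standard_errors=wald_standard_errors(result, counts),
            g_squared=g2,
            df=df,
            p_value=p,
            log_likelihood=loglik,
            converged=converged,
            n_restarts_used=n_restarts,
            spec=spec,
            unidentified=tuple(unidentified),
        )
    return result


# which trees each parameter influences: 0 = defector-partner, 1 = cooperator-partner
_PARAM_TREES = {
    "C": (0, 1),
    "P_Moral": (0,),
    "P_Hypocritical": (0,),
    "P_Antisocial": (1,),
    "b": (0, 1),
}


def _unidentified_ids(problem: _FitProblem) -> list:
    """Free identifiers whose every touching tree has zero observations."""
    tree_n = np.stack(
        [problem.counts[:, :4].sum(axis=1), problem.counts[:, 4:].sum(axis=1)], axis=1
    )  # (S, 2)
    out = []
    for idx, free_id in enumerate(problem.free_ids):
        touched = False
        for i in range(len(problem.strata)):
            for j, name in enumerate(PARAMETER_NAMES):
                if problem.slot_index[i, j] == idx:
                    if any(tree_n[i, t] > 0 for t in _PARAM_TREES[name]):
                        touched = True
        if not touched:
            out.append(free_id)
    return out


def wald_standard_errors(fit_result: FitResult, counts: Mapping) -> dict:
    """Square roots of the diagonal of the inverse observed information.

    The information is the negative Hessian of the product-multinomial
    log-likelihood at the MLE, evaluated on the probability scale by
    central differences of the analytic gradient.  Parameters at the
    boundary or with a singular information block are reported as NaN
    rather than fabricated.
    """
    spec = fit_result.spec
    ses = {k: float("nan") for k in spec.free_parameters}
    for block in _connected_blocks(spec):
        problem = _FitProblem(spec, counts, block)
        if problem.k == 0:
            continue
        free = np.array([fit_result.estimates[k] for k in problem.free_ids])
        at_boundary = (free <= PARAM_EPS * 2) | (free >= 1 - PARAM_EPS * 2)

        def grad_free(x: np.ndarray) -> np.ndarray:
            theta = problem.theta_matrix(x)
            probs = np.clip(_probabilities_array(theta), 1e-300, None)
            jac = category_probability_jacobian(theta)
            dll = np.einsum("sc,scj->sj", problem.counts / probs, jac)
            g = np.zeros(problem.k)
            mask = problem.slot_index >= 0
            np.add.at(g, problem.slot_index[mask], dll[mask])
            return g

        h = 1e-5
        hessian = np.zeros((problem.k, problem.k))
        for j in range(problem.k):
            step = np.zeros(problem.k)
            step[j] = h
            hessian[:, j] = (grad_free(free + step) - grad_free(free - step)) / (2 * h)
        info = -(hessian + hessian.T) / 2.0
        try:
            cov = np.linalg.inv(info)
            diag = np.diag(cov)
        except np.linalg.LinAlgError:
            continue
        for j, free_id in enumerate(problem.free_ids):
            if at_boundary[j] or diag[j] <= 0:
                continue
            ses[free_id] = float(math.sqrt(diag[j]))
    return ses


def effect_size_w(delta_g_squared: float, n_total: int) -> float:
    """Cohen's w for a chi-square statistic: sqrt(ΔG² / N_total).

    ``n_total`` is the total number of game trials entering the analysis
    (participants × rounds, summed over groups).
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if delta_g_squared < 0:
        raise ValueError("delta_g_squared must be non-negative")
    return math.sqrt(delta_g_squared / n_total)


def delta_g2_test(
    counts: Mapping,
    base: ModelSpec,
    restricted: ModelSpec,
    n_total: int,
    seed: int = 0,
    n_restarts: int = 20,
    base_fit: FitResult | None = None,
) -> TestResult:
    """ΔG² likelihood-ratio test of ``restricted`` against ``base``.

    ``restricted`` must be nested in ``base`` (its tying map refines the
    base map).  The statistic is the difference in G², chi-square
    distributed with df equal to the difference in free-parameter
    counts; ``w`` converts it to Cohen's effect-size metric using
    ``n_total`` game trials.
    """
    if not restricted.is_nested_in(base):
        raise ValueError("restricted model is not nested in the base model")
    if base_fit is None:
        base_fit = fit(counts, base, seed=seed, n_restarts=n_restarts,
                       compute_se=False)
    restricted_fit = fit(counts, restricted, seed=seed, n_restarts=n_restarts,
                         compute_se=False)
    delta = restricted_fit.g_squared - base_fit.g_squared
    if delta < -1e-6:
        raise RuntimeError(
            f"restricted fit beat the base fit by {-delta:.3g}; "
            "increase n_restarts"
        )
    delta = max(0.0, delta)
    df = base_fit.spec.n_free - restricted_fit.spec.n_free
    p = float(stats.chi2.sf(delta, df)) if df > 0 else 1.0
    return TestResult(
        delta_g_squared=delta,
        df=df,
        p_value=p,
        w=effect_size_w(delta, n_total),
        restricted_fit=restricted_fit,
        base_fit=base_fit,
    )
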