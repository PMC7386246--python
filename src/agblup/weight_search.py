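"""Kinship-weight hyperparameter search: grid, then bisection refinement.

The two weighting parameters — log base alpha and weighted top fraction
beta — are tuned against cross-validation accuracy.  A 4 x 4 grid
(alpha in (1.01, 1.11, e, 10), beta in (1e-4, 1e-3, 1e-2, 1e-1)) locates
a promising region; a seeded bisection-style refinement then repeatedly
redraws two levels per axis uniformly from the midpoint intervals
flanking the current best level, evaluates the four cross combinations,
and keeps the best point.  Both axes are searched on logarithmic scales
(log10 of ln(alpha), log10 of beta) because the grids span orders of
magnitude; midpoints on the raw scale would collapse the search into the
top decade.  Iteration stops at a budget or when the accuracy
improvement falls below a tolerance (default 1e-5).

If the best weighted accuracy never beats the plain-kinship baseline,
the weighting is abandoned and the standard kinship is kept — the
returned model's tuning accuracy therefore never falls below the
baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .cross_validation import CvPlan, cv_accuracy
from .genotype_io import GenotypeMatrix
from .kinship import WeightParams, weighted_kinship
from .mixed_model import GwasResult
from .qtn_selection import ModelSpec

__all__ = [
    "DEFAULT_ALPHA_GRID",
    "DEFAULT_BETA_GRID",
    "BisectionState",
    "make_weighted_objective",
    "grid_search",
    "bisection_refine",
    "optimize_weights",
]

DEFAULT_ALPHA_GRID = (1.01, 1.11, float(np.e), 10.0)
DEFAULT_BETA_GRID = (0.0001, 0.001, 0.01, 0.1)


def make_weighted_objective(
    plan: CvPlan,
    scans: Sequence[GwasResult | None],
    y: np.ndarray,
    g_pheno: GenotypeMatrix,
    base_K: np.ndarray,
    qtn_idx: Sequence[int] = (),
    covariates: np.ndarray | None = None,
    freq: np.ndarray | None = None,
) -> Callable[[float, float], float]:
    """CV-accuracy objective over (alpha, beta).

    Each fold's kinship is reweighted with that fold's cached scan
    p-values through the incremental top-fraction update, so only the
    top m*beta markers are touched.  Results are memoised on the
    weighted-count/alpha pair (a beta whose rounded count c is 0 always
    reproduces the baseline kinship).
    """
    from .kinship import KinshipMatrix

    cache: dict[tuple[float, int], float] = {}
    m = g_pheno.n_markers
    base_km = KinshipMatrix(base_K, list(g_pheno.individual_ids))

    def objective(alpha: float, beta: float) -> float:
        w = WeightParams(alpha=float(alpha), beta=float(beta))
        c = w.weighted_count(m)
        key = (round(float(alpha), 12), c)
        if key in cache:
            return cache[key]

        def fold_kinship(fi: int) -> np.ndarray:
            scan = scans[fi]
            if scan is None:
                raise ValueError("missing fold scan")
            return weighted_kinship(
                g_pheno, scan.p_values, w, base=base_km, route="incremental", freq=freq
            ).values

        if c == 0:
            acc = cv_accuracy(
                plan, y, base_K, G=g_pheno.values, qtn_idx=qtn_idx,
                covariates=covariates, use_kinship=True, cache_key="base",
            )
        else:
            acc = cv_accuracy(
                plan, y, fold_kinship, G=g_pheno.values, qtn_idx=qtn_idx,
                covariates=covariates, use_kinship=True,
            )
        cache[key] = acc
        return acc

    return objective


def grid_search(
    objective: Callable[[float, float], float],
    alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
    beta_grid: Sequence[float] = DEFAULT_BETA_GRID,
) -> tuple[float, float, float, pd.DataFrame]:
    """Evaluate every (alpha, beta) combination; return argmax and table."""
    records = []
    best = (-np.inf, None, None)
    for a in alpha_grid:
        for b in beta_grid:
            acc = objective(a, b)
            records.append({"alpha": a, "beta": b, "accuracy": acc})
            if np.isfinite(acc) and acc > best[0]:
                best = (acc, a, b)
    table = pd.DataFrame(records)
    if best[1] is None:
        raise ValueError("every grid combination was invalid")
    return best[1], best[2], best[0], table


@dataclass
class BisectionState:
    """Running state of the bisection refinement."""

    alpha: float
    beta: float
    accuracy: float
    alpha_levels: np.ndarray  # transformed-axis levels, sorted
    beta_levels: np.ndarray
    iteration: int = 0
    history: list[float] = field(default_factory=list)
    converged: bool = False


def _t_alpha(alpha: np.ndarray | float) -> np.ndarray | float:
    return np.log10(np.log(alpha))


def _alpha_of(t: np.ndarray | float) -> np.ndarray | float:
    return np.exp(10.0**t)


def _t_beta(beta: np.ndarray | float) -> np.ndarray | float:
    return np.log10(beta)


def _beta_of(t: np.ndarray | float) -> np.ndarray | float:
    return np.minimum(10.0**t, 1.0)


def _midpoint_interval(levels: np.ndarray, i: int) -> tuple[float, float]:
    """Uniform-draw interval flanking level i of a sorted level array.

    Interior levels get the midpoints to both neighbours; edge levels
    extend half the adjacent spacing beyond the edge (the axes are
    already log-transformed, so a half-spacing extension is the natural
    edge analogue of the midpoint rule).
    """
    n = levels.size
    if n == 1:
        return float(levels[0] - 0.5), float(levels[0] + 0.5)
    if i == 0:
        lo = (3 * levels[0] - levels[1]) / 2.0
        hi = (levels[0] + levels[1]) / 2.0
    elif i == n - 1:
        lo = (levels[-2] + levels[-1]) / 2.0
        hi = (3 * levels[-1] - levels[-2]) / 2.0
    else:
        lo = (levels[i - 1] + levels[i]) / 2.0
        hi = (levels[i] + levels[i + 1]) / 2.0
    return (float(lo), float(hi)) if lo <= hi else (float(hi), float(lo))


def bisection_refine(
    objective: Callable[[float, float], float],
    start_alpha: float,
    start_beta: float,
    start_accuracy: float,
    alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
    beta_grid: Sequence[float] = DEFAULT_BETA_GRID,
    seed: int = 0,
    max_iter: int = 10,
    tol: float = 1e-5,
) -> BisectionState:
    """Seeded uniform-midpoint refinement around the grid-search optimum.

    Per iteration, two fresh levels per axis are drawn uniformly from
    the midpoint intervals around the current best level; the four cross
    combinations are scored and the best point updated (never
    decreasing).  Stops on the iteration budget, on an accuracy
    improvement below ``tol``, or when the brackets collapse.
    """
    rng = np.random.default_rng(seed)
    ta = np.sort(_t_alpha(np.asarray(alpha_grid, dtype=float)))
    tb = np.sort(_t_beta(np.asarray(beta_grid, dtype=float)))
    state = BisectionState(
        alpha=float(start_alpha),
        beta=float(start_beta),
        accuracy=float(start_accuracy),
        alpha_levels=ta,
        beta_levels=tb,
        history=[float(start_accuracy)],
    )
    ia = int(np.argmin(np.abs(ta - _t_alpha(start_alpha))))
    ib = int(np.argmin(np.abs(tb - _t_beta(start_beta))))
    lo_a, hi_a = _midpoint_interval(ta, ia)
    lo_b, hi_b = _midpoint_interval(tb, ib)
    for it in range(1, max_iter + 1):
        if hi_a - lo_a < 1e-12 and hi_b - lo_b < 1e-12:
            state.converged = True
            break
        # one reset level on each flank of the current best level, so the
        # evaluated cross combinations always straddle it
        ca = float(np.clip(_t_alpha(state.alpha), lo_a, hi_a))
        cb = float(np.clip(_t_beta(state.beta), lo_b, hi_b))
        draws_a = np.array([rng.uniform(lo_a, ca), rng.uniform(ca, hi_a)])
        draws_b = np.minimum(
            np.array([rng.uniform(lo_b, cb), rng.uniform(cb, hi_b)]), 0.0
        )  # beta <= 1
        best_here = state.accuracy
        best_pt = (state.alpha, state.beta)
        for da in draws_a:
            for db in draws_b:
                a, b = float(_alpha_of(da)), float(_beta_of(db))
                acc = objective(a, b)
                if np.isfinite(acc) and acc > best_here:
                    best_here, best_pt = acc, (a, b)
        improvement = best_here - state.accuracy
        state.alpha, state.beta = best_pt
        state.accuracy = best_here
        state.iteration = it
        state.history.append(best_here)
        # contract the brackets to half width, re-centred on the best point
        wa = (hi_a - lo_a) / 2.5
        wb = (hi_b - lo_b) / 2.5
        ca = float(_t_alpha(state.alpha))
        cb = float(_t_beta(state.beta))
        lo_a, hi_a = ca - wa, ca + wa
        lo_b, hi_b = cb - wb, cb + wb
        state.alpha_levels = np.array([lo_a, ca, hi_a])
        state.beta_levels = np.array([lo_b, cb, hi_b])
        if improvement < tol:
            state.converged = True
            break
    return state


def optimize_weights(
    plan: CvPlan,
    scans: Sequence[GwasResult | None],
    y: np.ndarray,
    g_pheno: GenotypeMatrix,
    base_K: np.ndarray,
    model: ModelSpec,
    reference_accuracy: float,
    covariates: np.ndarray | None = None,
    freq: np.ndarray | None = None,
    alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
    beta_grid: Sequence[float] = DEFAULT_BETA_GRID,
    seed: int = 0,
    max_iter: int = 10,
    tol: float = 1e-5,
    objective: Callable[[float, float], float] | None = None,
) -> ModelSpec:
    """Tune (alpha, beta) for the selected family; fall back when futile.

    The baseline for the fallback comparison is the plain-LMM CV
    accuracy: weighting is kept only when the tuned accuracy strictly
    beats it, otherwise the standard kinship stands.
    """
    if model.model_type == "pQ":
        raise ValueError("the plain fixed-effect family has no kinship to weight")
    if objective is None:
        objective = make_weighted_objective(
            plan, scans, y, g_pheno, base_K,
            qtn_idx=model.pseudo_qtn_idx, covariates=covariates, freq=freq,
        )
    a_best, b_best, acc, table = grid_search(objective, alpha_grid, beta_grid)
    state = bisection_refine(
        objective, a_best, b_best, acc,
        alpha_grid=alpha_grid, beta_grid=beta_grid,
        seed=seed, max_iter=max_iter, tol=tol,
    )
    # the bar to clear: the selected family's own unweighted accuracy (which
    # is itself never below the plain-LMM baseline)
    unweighted = (
        model.cv_accuracy if np.isfinite(model.cv_accuracy) else reference_accuracy
    )
    bar = max(float(reference_accuracy), float(unweighted))
    trace = model.trace + [
        {
            "family": "weight_search",
            "candidate": -1,
            "accuracy": state.accuracy,
            "running_best": acc,
            "baseline": bar,
            "accepted": bool(state.accuracy > bar),
        }
    ]
    if not np.isfinite(state.accuracy) or state.accuracy <= bar:
        # weighting does not beat the plain baseline: keep the standard kinship
        return ModelSpec(
            model_type=model.model_type,
            pseudo_qtn_idx=model.pseudo_qtn_idx,
            pseudo_qtn_ids=model.pseudo_qtn_ids,
            weight_params=None,
            reference_accuracy=reference_accuracy,
            cv_accuracy=model.cv_accuracy,
            trace=trace,
            scan_kind=model.scan_kind,
            seed=model.seed,
        )
    new_type = "Kw" if model.model_type == "Ks" else "pQ+Kw"
    return ModelSpec(
        model_type=new_type,
        pseudo_qtn_idx=model.pseudo_qtn_idx,
        pseudo_qtn_ids=model.pseudo_qtn_ids,
        weight_params=WeightParams(alpha=state.alpha, beta=state.beta),
        reference_accuracy=reference_accuracy,
        cv_accuracy=float(state.accuracy),
        trace=trace,
        scan_kind=model.scan_kind,
        seed=model.seed,
    )
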