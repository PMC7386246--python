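"""Pseudo-QTN derivation and stepwise model-family selection.

Large-effect markers ("pseudo QTNs") are promoted to fixed covariates
cautiously, because a false positive hurts prediction badly.  The
pipeline is: per cross-validation fold, rank markers by ascending
p-value, prune the ranking by pairwise linkage disequilibrium (greedy,
r^2 threshold 0.3 against everything already retained), and keep the top
n (default 15).  A marker must recur in more than 90% of the s*v fold
lists to become a candidate — a bootstrap-style robustness filter
against population-specific LD.

Candidates are then auditioned one at a time, ordered by mean ascending
p-value rank across folds, under three model families: "K" (kinship
only), "pQ+K" (candidates as covariates plus kinship) and "pQ"
(candidates in a plain linear model).  A candidate is kept only when it
raises the family's running cross-validation accuracy AND beats the
plain-LMM baseline.  The family with the best final accuracy wins; ties
prefer fewer covariates, then the simpler kinship-only family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .cross_validation import CvPlan, cv_accuracy
from .kinship import WeightParams
from .mixed_model import GwasResult

__all__ = ["ModelSpec", "ld_filter", "select_candidate_qtns", "stepwise_model_select"]

MODEL_TYPES = ("Ks", "Kw", "pQ+Ks", "pQ+Kw", "pQ")


@dataclass
class ModelSpec:
    """Learned model state: family, pseudo-QTNs and kinship weights."""

    model_type: str
    pseudo_qtn_idx: list[int] = field(default_factory=list)
    pseudo_qtn_ids: list[str] = field(default_factory=list)
    weight_params: WeightParams | None = None
    reference_accuracy: float = np.nan  # plain-LMM CV baseline
    cv_accuracy: float = np.nan  # CV accuracy of the selected model
    trace: list[dict] = field(default_factory=list)
    scan_kind: str = "GLM"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.model_type not in MODEL_TYPES:
            raise ValueError(f"model_type must be one of {MODEL_TYPES}")
        if not (self.pseudo_qtn_ids or self.pseudo_qtn_idx) and self.model_type.startswith("pQ"):
            raise ValueError("pQ model families need at least one pseudo QTN")
        if self.weight_params is not None and self.model_type not in ("Kw", "pQ+Kw"):
            raise ValueError("weight_params only belong to weighted-kinship families")

    def trace_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.trace)


def ld_filter(
    candidates: Sequence[int],
    dosages: np.ndarray,
    r2_max: float = 0.3,
    max_keep: int | None = None,
) -> list[int]:
    """Greedy LD pruning of a ranked candidate list.

    Walks the candidates in rank order and drops any whose squared
    Pearson correlation of dosages with an already-retained candidate
    exceeds ``r2_max``.  Zero-variance columns are dropped outright.
    """
    kept: list[int] = []
    kept_cols: list[np.ndarray] = []
    n = dosages.shape[0]
    for j in candidates:
        col = dosages[:, j]
        cc = col - col.mean()
        ss = float(cc @ cc)
        if ss <= 0:
            continue
        ok = True
        for kc in kept_cols:
            r = float(cc @ kc[0]) / np.sqrt(ss * kc[1])
            if r * r > r2_max:
                ok = False
                break
        if ok:
            kept.append(int(j))
            kept_cols.append((cc, ss))
            if max_keep is not None and len(kept) >= max_keep:
                break
    return kept


def select_candidate_qtns(
    plan: CvPlan,
    scans: Sequence[GwasResult | None],
    G: np.ndarray,
    n_top: int = 15,
    r2_max: float = 0.3,
    count_fraction: float = 0.9,
) -> tuple[list[int], pd.DataFrame]:
    """Candidate pseudo-QTNs by fold-wise top lists and recurrence counting.

    Per fold: ascending-p ranking, greedy LD pruning at ``r2_max`` on the
    fold's *training* dosages, keep the first ``n_top`` survivors.  A
    marker counted in strictly more than ``s*v*count_fraction`` folds
    becomes a candidate; candidates are ordered by mean ascending-p rank
    across folds.  Returns (candidate indices, per-marker count table).
    """
    m = G.shape[1]
    counts = np.zeros(m, dtype=int)
    rank_sum = np.zeros(m, dtype=float)
    n_valid = 0
    for fd, scan in zip(plan.folds, scans):
        if scan is None:
            continue
        n_valid += 1
        order = np.argsort(scan.p_values, kind="stable")
        ranks = np.empty(m)
        ranks[order] = np.arange(m)
        rank_sum += ranks
        top = ld_filter(order, G[fd.train], r2_max=r2_max, max_keep=n_top)
        counts[top] += 1
    if n_valid == 0:
        raise ValueError("no valid fold scans")
    threshold = plan.n_folds * count_fraction
    chosen = np.flatnonzero(counts > threshold)
    mean_rank = rank_sum / n_valid
    chosen = chosen[np.argsort(mean_rank[chosen], kind="stable")]
    table = pd.DataFrame(
        {"marker": np.arange(m), "count": counts, "mean_rank": mean_rank}
    ).sort_values("count", ascending=False)
    return [int(j) for j in chosen], table


def stepwise_model_select(
    candidates: Sequence[int],
    plan: CvPlan,
    y: np.ndarray,
    G: np.ndarray,
    K: np.ndarray,
    reference_accuracy: float,
    covariates: np.ndarray | None = None,
    marker_ids: Sequence[str] | None = None,
) -> ModelSpec:
    """Stepwise forward audition of candidates under three model families.

    ``reference_accuracy`` is the plain-LMM CV baseline on the same
    plan.  The returned spec carries the winning family (weighting of
    the kinship is decided later), the accepted pseudo-QTNs, and the
    full audition trace.
    """
    a0 = float(reference_accuracy)
    trace: list[dict] = []
    results: dict[str, tuple[float, list[int]]] = {"K": (a0, [])}

    for family, use_k in (("pQ+K", True), ("pQ", False)):
        accepted: list[int] = []
        best = a0 if use_k else -np.inf
        for cand in candidates:
            try:
                acc = cv_accuracy(
                    plan,
                    y,
                    K if use_k else None,
                    G=G,
                    qtn_idx=accepted + [int(cand)],
                    covariates=covariates,
                    use_kinship=use_k,
                    cache_key="base",
                )
            except ValueError:
                acc = np.nan
            keep = np.isfinite(acc) and acc > best and acc > a0
            trace.append(
                {
                    "family": family,
                    "candidate": int(cand),
                    "accuracy": acc,
                    "running_best": best,
                    "baseline": a0,
                    "accepted": bool(keep),
                }
            )
            if keep:
                accepted.append(int(cand))
                best = acc
        if family == "pQ+K":
            results[family] = (best if accepted else a0, accepted)
        else:
            results[family] = (best, accepted) if accepted else (-np.inf, [])

    # pick the family: highest accuracy, ties -> fewer covariates, then
    # the simpler variance structure (K before pQ)
    prefer = {"K": 0, "pQ+K": 1, "pQ": 2}
    family = min(
        results, key=lambda f: (-results[f][0], len(results[f][1]), prefer[f])
    )
    acc, qtns = results[family]
    model_type = {"K": "Ks", "pQ+K": "pQ+Ks", "pQ": "pQ"}[family]
    ids = (
        [str(marker_ids[j]) for j in qtns] if marker_ids is not None else [str(j) for j in qtns]
    )
    return ModelSpec(
        model_type=model_type,
        pseudo_qtn_idx=qtns,
        pseudo_qtn_ids=ids,
        reference_accuracy=a0,
        cv_accuracy=float(acc),
        trace=trace,
    )
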