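"""Repeated k-fold cross-validation: partitions, per-fold scans, scoring.

The tuning loop of the adaptive model is built on an s-repeats x v-folds
partition of the phenotyped individuals.  Within each repeat the folds
are disjoint, cover everyone, and differ in size by at most one; binary
traits are stratified by class so no fold is single-class.  All
randomness flows from one seed.

Each of the s*v folds gets its own association scan on the v-1 training
groups — the left-out group's phenotypes never enter any quantity
computed for that fold — and the scans are cached for reuse by
pseudo-QTN selection and kinship-weight search.  ``cv_accuracy`` is the
shared objective: it fits the requested model family on each training
set, predicts the left-out group, scores it (Pearson or AUROC,
automatically), and averages over folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .metrics import accuracy_auto
from .mixed_model import (
    GwasResult,
    KinshipEig,
    blup_predict,
    fit_variance_components,
    glm_scan,
    mlm_scan,
)

__all__ = ["CvPlan", "make_cv_plan", "run_fold_scans", "aggregate_accuracy", "cv_accuracy"]


@dataclass
class Fold:
    repeat: int
    fold: int
    train: np.ndarray  # indices into the phenotyped-individual array
    val: np.ndarray


@dataclass
class CvPlan:
    s: int
    v: int
    seed: int
    n: int
    folds: list[Fold]
    scans: list[GwasResult | None] = field(default_factory=list)
    eig_cache: dict = field(default_factory=dict)

    @property
    def n_folds(self) -> int:
        return len(self.folds)


def make_cv_plan(
    n: int,
    s: int = 1,
    v: int = 5,
    seed: int = 0,
    stratify: np.ndarray | None = None,
) -> CvPlan:
    """Reproducible s x v partition of ``n`` phenotyped individuals.

    ``stratify``, when given (e.g. 0/1 case status), balances classes
    across folds while keeping overall fold sizes within one of each
    other.
    """
    if s < 1 or v < 2:
        raise ValueError("need s >= 1 repeats and v >= 2 folds")
    if v > n:
        raise ValueError(f"cannot split {n} individuals into {v} folds")
    rng = np.random.default_rng(seed)
    folds: list[Fold] = []
    for rep in range(s):
        fold_id = np.empty(n, dtype=int)
        if stratify is None:
            perm = rng.permutation(n)
            counter = 0
            for i in perm:
                fold_id[i] = counter % v
                counter += 1
        else:
            labels = np.asarray(stratify)
            counter = 0
            for lab in np.unique(labels):
                members = rng.permutation(np.flatnonzero(labels == lab))
                for i in members:
                    fold_id[i] = counter % v
                    counter += 1
        for f in range(v):
            folds.append(
                Fold(
                    repeat=rep,
                    fold=f,
                    train=np.flatnonzero(fold_id != f),
                    val=np.flatnonzero(fold_id == f),
                )
            )
    return CvPlan(s=s, v=v, seed=seed, n=n, folds=folds)


def run_fold_scans(
    plan: CvPlan,
    y: np.ndarray,
    G: np.ndarray,
    scan_kind: str = "GLM",
    K: np.ndarray | None = None,
    covariates: np.ndarray | None = None,
) -> list[GwasResult | None]:
    """One association scan per fold, on that fold's training individuals only.

    A fold whose training phenotypes are constant is flagged invalid
    (``None``).  Results are cached on the plan.
    """
    y = np.asarray(y, dtype=float).ravel()
    if y.size != plan.n:
        raise ValueError("plan was built for a different number of individuals")
    scans: list[GwasResult | None] = []
    for fd in plan.folds:
        yt = y[fd.train]
        if np.ptp(yt) == 0:
            warnings.warn(f"fold ({fd.repeat},{fd.fold}) has constant training phenotype")
            scans.append(None)
            continue
        cov = covariates[fd.train] if covariates is not None else None
        if scan_kind.upper() == "GLM":
            res = glm_scan(yt, G[fd.train], covariates=cov)
        elif scan_kind.upper() == "MLM":
            if K is None:
                raise ValueError("MLM scans need a kinship matrix")
            res = mlm_scan(yt, G[fd.train], K[np.ix_(fd.train, fd.train)], covariates=cov)
        else:
            raise ValueError(f"unknown scan kind {scan_kind!r}")
        res.fold = (fd.repeat, fd.fold)
        scans.append(res)
    plan.scans = scans
    return scans


def aggregate_accuracy(per_fold: Sequence[float]) -> float:
    """Mean over valid (finite) fold accuracies; raises when none is valid."""
    vals = np.asarray(list(per_fold), dtype=float)
    ok = np.isfinite(vals)
    if not ok.any():
        raise ValueError("no valid folds to aggregate")
    n_bad = int((~ok).sum())
    if n_bad:
        warnings.warn(f"excluding {n_bad} invalid fold(s) from the accuracy mean")
    return float(vals[ok].mean())


def cv_accuracy(
    plan: CvPlan,
    y: np.ndarray,
    K: np.ndarray | Callable[[int], np.ndarray] | None,
    G: np.ndarray | None = None,
    qtn_idx: Sequence[int] = (),
    covariates: np.ndarray | None = None,
    use_kinship: bool = True,
    cache_key: str | None = None,
) -> float:
    """Mean CV accuracy of one model family on the plan's folds.

    ``K`` is the kinship over *all* phenotyped individuals (so
    training-to-validation covariances are available), or a callable
    ``fold_index -> K`` when the kinship differs per fold (SNP
    weighting).  ``qtn_idx`` columns of ``G`` enter as fixed covariates;
    ``use_kinship=False`` gives the plain fixed-effect family (no random
    term).  Folds where the score is undefined contribute NaN and are
    excluded from the mean.
    """
    y = np.asarray(y, dtype=float).ravel()
    qtn_idx = list(qtn_idx)
    Q_all = G[:, qtn_idx] if qtn_idx else None
    accs: list[float] = []
    for fi, fd in enumerate(plan.folds):
        yt = y[fd.train]
        if np.ptp(yt) == 0:
            accs.append(np.nan)
            continue
        cov_all = covariates
        try:
            if use_kinship:
                Kf = K(fi) if callable(K) else K
                Ksub = Kf[np.ix_(fd.train, fd.train)]
                fixed_parts = []
                if cov_all is not None:
                    fixed_parts.append(np.atleast_2d(cov_all)[fd.train])
                if Q_all is not None:
                    fixed_parts.append(Q_all[fd.train])
                X_train = np.hstack(fixed_parts) if fixed_parts else None
                if not callable(K) and cache_key is not None:
                    key = (cache_key, fi)
                    eig = plan.eig_cache.get(key)
                    if eig is None:
                        eig = KinshipEig(Ksub)
                        plan.eig_cache[key] = eig
                else:
                    eig = KinshipEig(Ksub)
                vc = fit_variance_components(yt, Ksub, X=X_train, eig=eig)
                res = blup_predict(
                    yt,
                    Kf,
                    fd.train,
                    vc,
                    X=cov_all,
                    Q=Q_all,
                    eig=eig,
                )
                pred = res.mu[fd.val]
            else:
                cols = [np.ones((plan.n, 1))]
                if cov_all is not None:
                    cols.append(np.atleast_2d(cov_all).reshape(plan.n, -1))
                if Q_all is not None:
                    cols.append(Q_all)
                F = np.hstack(cols)
                coef, *_ = np.linalg.lstsq(F[fd.train], yt, rcond=None)
                pred = F[fd.val] @ coef
            accs.append(accuracy_auto(pred, y[fd.val]))
        except (ValueError, np.linalg.LinAlgError):
            accs.append(np.nan)
    return aggregate_accuracy(accs)
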