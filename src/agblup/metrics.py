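"""Prediction-accuracy measures.

Continuous traits are scored with the Pearson correlation between
predicted and observed values; 0/1 case-control traits with the area
under the ROC curve, computed from the mean rank of cases:

    AUROC = (r_bar_d - N_d/2 - 1/2) / N_d'

where N_d and N_d' are the case and control counts and r_bar_d the mean
rank (ascending, midranks for ties) of the cases.  With midranks this is
exactly the Mann-Whitney U statistic divided by N_d * N_d'.
``accuracy_auto`` dispatches on whether the observed vector is 0/1.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["pearson", "auroc", "accuracy_auto"]


def pearson(pred: np.ndarray, obs: np.ndarray) -> float:
    """Pearson product-moment correlation between predictions and observations."""
    pred = np.asarray(pred, dtype=float).ravel()
    obs = np.asarray(obs, dtype=float).ravel()
    if pred.shape != obs.shape:
        raise ValueError("pred and obs must have equal length")
    if pred.size < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    if np.ptp(pred) == 0 or np.ptp(obs) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(np.corrcoef(pred, obs)[0, 1])


def auroc(pred: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve from mean case ranks (midranks for ties)."""
    pred = np.asarray(pred, dtype=float).ravel()
    labels = np.asarray(labels, dtype=float).ravel()
    if pred.shape != labels.shape:
        raise ValueError("pred and labels must have equal length")
    if not np.isin(labels, (0.0, 1.0)).all():
        raise ValueError("labels must be 0/1")
    n_case = int(labels.sum())
    n_ctrl = labels.size - n_case
    if n_case == 0 or n_ctrl == 0:
        raise ValueError("both classes must be present to compute AUROC")
    ranks = stats.rankdata(pred)  # ascending, midranks for ties
    mean_case_rank = ranks[labels == 1.0].mean()
    return float((mean_case_rank - n_case / 2.0 - 0.5) / n_ctrl)


def accuracy_auto(pred: np.ndarray, obs: np.ndarray) -> float:
    """AUROC for 0/1 observations, Pearson correlation otherwise.

    A trait coded on more than two levels (e.g. 1..4 categories) is
    treated as continuous.
    """
    obs = np.asarray(obs, dtype=float).ravel()
    ok = obs[~np.isnan(obs)]
    if ok.size and np.isin(ok, (0.0, 1.0)).all():
        return auroc(pred, obs)
    return pearson(pred, obs)
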