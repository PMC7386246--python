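"""Genomic relationship matrices: standard and SNP-weighted.

The standard (VanRaden-style, per-marker standardised) genomic
relationship between individuals i and j over m markers is

    K_ij = (1/m) sum_k (M_ik - 2 p_k)(M_jk - 2 p_k) / (2 p_k (1 - p_k))

The weighted variant scales each marker's contribution by a weight
derived from its association p-value.  With the top fraction beta of
markers (by ascending p) weighted through a logarithm of base alpha,

    xi_k = 1 + log_alpha(P_c) - log_alpha(P_k)   for rank k <= c = round(m*beta)
    xi_k = 1                                     otherwise

so every weight is >= 1, the rank-c marker gets exactly 1, and the
weighted matrix collapses to the standard one at beta = 0.  The weighted
matrix can be formed either from the full weight vector or incrementally
as the standard matrix plus the contribution of the top-c markers only;
both routes are algebraically identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix

__all__ = [
    "KinshipMatrix",
    "WeightParams",
    "standard_kinship",
    "snp_weights",
    "weighted_kinship",
    "centered_scaled_dosages",
    "write_kinship",
]


@dataclass
class KinshipMatrix:
    """Symmetric individual-by-individual relationship matrix."""

    values: np.ndarray
    individual_ids: list[str]
    kind: str = "standard"  # "standard" | "weighted"
    weight_params: "WeightParams | None" = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("kinship must be square")
        if not np.isfinite(self.values).all():
            raise ValueError("kinship has non-finite entries")
        if np.abs(self.values - self.values.T).max() > 1e-10:
            raise ValueError("kinship not symmetric to 1e-10")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class WeightParams:
    """Kinship weighting parameters: log base alpha > 1, top fraction beta."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not self.alpha > 1.0:
            raise ValueError("alpha must exceed 1 (monotone increasing log)")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")

    def weighted_count(self, m: int) -> int:
        """Number of top markers weighted: m*beta rounded half-up."""
        return int(np.floor(m * self.beta + 0.5))


def centered_scaled_dosages(g: GenotypeMatrix | np.ndarray, freq: np.ndarray | None = None) -> np.ndarray:
    """Return W with W_ik = (M_ik - 2 p_k) / sqrt(2 p_k (1 - p_k)).

    Monomorphic markers (p in {0, 1}) make the scale zero and raise.
    """
    if isinstance(g, GenotypeMatrix):
        if g.missing.any():
            raise ValueError("kinship requires complete dosages; impute first")
        M = g.values
        p = g.allele_freq if freq is None else np.asarray(freq, float)
    else:
        M = np.asarray(g, dtype=float)
        p = M.mean(axis=0) / 2.0 if freq is None else np.asarray(freq, float)
    mono = (p <= 0.0) | (p >= 1.0)
    if mono.any():
        k = int(np.flatnonzero(mono)[0])
        name = g.markers["id"].iloc[k] if isinstance(g, GenotypeMatrix) else str(k)
        raise ZeroDivisionError(f"monomorphic marker {name!r} (p_k = {p[k]:g}) in kinship")
    return (M - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))


def standard_kinship(g: GenotypeMatrix, freq: np.ndarray | None = None) -> KinshipMatrix:
    """Standard genomic relationship matrix over all markers."""
    W = centered_scaled_dosages(g, freq)
    K = W @ W.T / W.shape[1]
    K = (K + K.T) / 2.0
    return KinshipMatrix(K, list(g.individual_ids), kind="standard")


def _rank_order(p_values: np.ndarray) -> np.ndarray:
    """Ascending p-value order; ties broken by marker position (stable sort)."""
    p = np.asarray(p_values, dtype=float)
    if np.isnan(p).any():
        raise ValueError("p-values contain NaN")
    if (p > 1.0).any():
        raise ValueError("p-values exceed 1")
    return np.argsort(p, kind="stable")


def _clamp_zeros(p: np.ndarray) -> np.ndarray:
    """Clamp non-positive p-values below the smallest positive one (logs need p > 0)."""
    p = np.asarray(p, dtype=float).copy()
    bad = p <= 0.0
    if bad.any():
        pos = p[~bad]
        if pos.size == 0:
            raise ValueError("all p-values are non-positive")
        p[bad] = pos.min() * 1e-2
    return p


def snp_weights(p_values: np.ndarray, w: WeightParams) -> np.ndarray:
    """Per-marker kinship weights xi (aligned to marker order, not rank)."""
    p = _clamp_zeros(p_values)
    m = p.size
    c = w.weighted_count(m)
    xi = np.ones(m)
    if c == 0:
        return xi
    order = _rank_order(p)
    top = order[:c]
    log_pc = np.log(p[order[c - 1]]) / np.log(w.alpha)
    xi[top] = 1.0 + log_pc - np.log(p[top]) / np.log(w.alpha)
    return xi


def weighted_kinship(
    g: GenotypeMatrix,
    p_values: np.ndarray,
    w: WeightParams,
    base: KinshipMatrix | None = None,
    route: str = "incremental",
    freq: np.ndarray | None = None,
) -> KinshipMatrix:
    """SNP-weighted genomic relationship matrix.

    ``route='incremental'`` adds the top-c markers' extra weighted
    contribution to the standard matrix (cheap when ``base`` is cached);
    ``route='full'`` rebuilds from the full weight vector.  The two are
    algebraically identical.
    """
    p = _clamp_zeros(p_values)
    if p.size != g.n_markers:
        raise ValueError("p-values not aligned to markers")
    if route == "full":
        W = centered_scaled_dosages(g, freq)
        xi = snp_weights(p, w)
        K = (W * xi) @ W.T / W.shape[1]
    elif route == "incremental":
        K = (base.values if base is not None else standard_kinship(g, freq).values).copy()
        c = w.weighted_count(p.size)
        if c > 0:
            order = _rank_order(p)
            top = order[:c]
            Wtop = centered_scaled_dosages(
                g.values[:, top] if not isinstance(g, np.ndarray) else g[:, top],
                freq=(g.allele_freq[top] if freq is None else np.asarray(freq)[top]),
            )
            lam = (np.log(p[order[c - 1]]) - np.log(p[top])) / np.log(w.alpha)
            K = K + (Wtop * lam) @ Wtop.T / p.size
    else:
        raise ValueError(f"unknown route {route!r}")
    K = (K + K.T) / 2.0
    return KinshipMatrix(K, list(g.individual_ids), kind="weighted", weight_params=w)


def write_kinship(k: KinshipMatrix, path) -> None:
    """Export as a square table with individual ids on header row and column."""
    pd.DataFrame(k.values, index=k.individual_ids, columns=k.individual_ids).to_csv(
        path, sep="\t"
    )
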