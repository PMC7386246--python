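"""Single-step evaluation: pedigree relationships, H matrix, prediction.

When only part of a population is genotyped, the pedigree numerator
relationship matrix A (Wright, via the exact tabular method with
inbreeding) and the genomic relationship G of the genotyped subset are
merged into one matrix H so that phenotypes of non-genotyped relatives
inform the predictions of everyone jointly.  Before merging, G is
rescaled so its diagonal and off-diagonal means match those of the
pedigree block A22 of the genotyped individuals, and a small fraction of
A22 (default 5%) is blended in to guarantee invertibility:

    G* = a + b G,   G_adj = (1 - w) G* + w A22

The single-step identity gives the inverse directly:

    H^-1 = A^-1 + [0 0; 0 G_adj^-1 - A22^-1]

The genomic matrix can be the SNP-weighted kinship of a tuned model
(weighted single-step), but pseudo-QTN covariates are never fitted here:
their dosages do not exist for non-genotyped individuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotype_io import GenotypeMatrix, Pedigree, PhenotypeVector, UNKNOWN_PARENT
from .kinship import KinshipMatrix, standard_kinship, weighted_kinship
from .mixed_model import blup_predict, fit_variance_components, glm_scan
from .qtn_selection import ModelSpec

__all__ = [
    "HMatrixConfig",
    "pedigree_a_matrix",
    "blend_scale_g",
    "h_matrix",
    "h_matrix_inverse",
    "ss_predict",
    "pedigree_blup",
]


@dataclass
class HMatrixConfig:
    """Blending/scaling settings for merging G with the pedigree block."""

    blend_weight: float = 0.05
    scale_adjust: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.blend_weight <= 1.0:
            raise ValueError("blend_weight must lie in [0, 1]")


def pedigree_a_matrix(ped: Pedigree) -> np.ndarray:
    """Wright's numerator relationship matrix by the tabular method.

    Exact, including inbreeding: A_ii = 1 + F_i with F_i half the
    relationship of the parents; off-diagonals are parent averages.
    Rows/columns follow the pedigree's own individual order.
    """
    order = ped.topological_order()  # raises on cycles
    n = len(ped)
    index = {ind: i for i, ind in enumerate(ped.individuals)}
    A = np.zeros((n, n))
    done: list[int] = []
    for i in order:
        s = index.get(ped.sires[i]) if ped.sires[i] != UNKNOWN_PARENT else None
        d = index.get(ped.dams[i]) if ped.dams[i] != UNKNOWN_PARENT else None
        if done:
            j = np.array(done)
            row = np.zeros(len(done))
            if s is not None:
                row += 0.5 * A[s, j]
            if d is not None:
                row += 0.5 * A[d, j]
            A[i, j] = row
            A[j, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if s is not None and d is not None else 0.0)
        done.append(i)
    return A


def blend_scale_g(
    G: KinshipMatrix | np.ndarray, A22: np.ndarray, cfg: HMatrixConfig | None = None
) -> np.ndarray:
    """Match G to the scale of A22, then blend a fraction of A22 into it.

    The scale step solves G* = a + b G so that the diagonal and
    off-diagonal means of G* equal those of A22 (the two-moment matching
    convention); the blend step returns (1-w) G* + w A22.
    """
    cfg = cfg or HMatrixConfig()
    G = G.values if isinstance(G, KinshipMatrix) else np.asarray(G, dtype=float)
    A22 = np.asarray(A22, dtype=float)
    if G.shape != A22.shape:
        raise ValueError("G and A22 must be conformable over the genotyped individuals")
    n = G.shape[0]
    out = G
    if cfg.scale_adjust:
        off = ~np.eye(n, dtype=bool)
        dG, oG = float(np.diag(G).mean()), float(G[off].mean()) if n > 1 else 0.0
        dA, oA = float(np.diag(A22).mean()), float(A22[off].mean()) if n > 1 else 0.0
        if abs(dG - oG) < 1e-12:
            raise ValueError("constant G: scale adjustment is unsolvable")
        b = (dA - oA) / (dG - oG)
        a = dA - b * dG
        out = a + b * G
    return (1.0 - cfg.blend_weight) * out + cfg.blend_weight * A22


def h_matrix_inverse(
    A: np.ndarray, A22: np.ndarray, G_adj: np.ndarray, genotyped: np.ndarray
) -> np.ndarray:
    """H^-1 = A^-1 + [0; G_adj^-1 - A22^-1] on the genotyped block."""
    genotyped = np.asarray(genotyped)
    if genotyped.dtype == bool:
        genotyped = np.flatnonzero(genotyped)
    try:
        Hinv = np.linalg.inv(A)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(f"singular A: {err}") from err
    if genotyped.size:
        try:
            delta = np.linalg.inv(G_adj) - np.linalg.inv(A22)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "singular genotyped block; consider blending more of A22 into G "
                f"(ridge): {err}"
            ) from err
        Hinv[np.ix_(genotyped, genotyped)] += delta
    return Hinv


def h_matrix(
    A: np.ndarray, A22: np.ndarray, G_adj: np.ndarray, genotyped: np.ndarray
) -> np.ndarray:
    """Direct H: A with its genotyped block replaced by G_adj and the
    cross blocks propagated through the conditional (joint-normal)
    formula.  Used as the forward construction; its inverse must match
    :func:`h_matrix_inverse`.
    """
    genotyped = np.asarray(genotyped)
    if genotyped.dtype == bool:
        genotyped = np.flatnonzero(genotyped)
    n = A.shape[0]
    rest = np.setdiff1d(np.arange(n), genotyped)
    if genotyped.size == 0:
        return A.copy()
    H = A.copy()
    A12 = A[np.ix_(rest, genotyped)]
    X = np.linalg.solve(A22, A12.T).T  # A12 A22^-1
    H[np.ix_(rest, genotyped)] = X @ G_adj
    H[np.ix_(genotyped, rest)] = (X @ G_adj).T
    H[np.ix_(rest, rest)] = A[np.ix_(rest, rest)] + X @ (G_adj - A22) @ X.T
    H[np.ix_(genotyped, genotyped)] = G_adj
    return (H + H.T) / 2.0


def pedigree_blup(y: PhenotypeVector, ped: Pedigree):
    """Plain pedigree BLUP (A-matrix relationship only)."""
    A = pedigree_a_matrix(ped)
    obs = np.flatnonzero(y.observed)
    vc = fit_variance_components(y.values[obs], A[np.ix_(obs, obs)])
    return blup_predict(y.values[obs], A, obs, vc)


def ss_predict(
    y: PhenotypeVector,
    ped: Pedigree,
    g: GenotypeMatrix | None,
    model: ModelSpec | None = None,
    cfg: HMatrixConfig | None = None,
    scan_kind: str = "GLM",
):
    """Single-step genetic values for every pedigree individual.

    ``y`` is aligned to the pedigree rows; ``g`` holds the genotyped
    subset (matched to the pedigree by individual id; ``None`` reduces
    to pedigree BLUP).  When ``model`` carries weight parameters the
    genomic matrix is the SNP-weighted kinship, its weights computed
    from a fresh association scan of the genotyped-and-phenotyped
    individuals; pseudo-QTN covariates are not fitted.
    """
    cfg = cfg or HMatrixConfig()
    if y.values.size != len(ped):
        raise ValueError("phenotype must be aligned to the pedigree rows")
    if g is None or g.n_individuals == 0:
        return pedigree_blup(y, ped)

    A = pedigree_a_matrix(ped)
    pos = {ind: i for i, ind in enumerate(ped.individuals)}
    try:
        geno_rows = np.array([pos[i] for i in g.individual_ids])
    except KeyError as err:
        raise ValueError(f"genotyped individual {err} missing from the pedigree") from err
    A22 = A[np.ix_(geno_rows, geno_rows)]

    # markers monomorphic within the genotyped subset carry no relationship
    # information and would break the per-marker scaling
    freq = g.allele_freq
    poly = (freq > 0.0) & (freq < 1.0)
    if not poly.all():
        g = g.subset_markers(np.flatnonzero(poly))

    if model is not None and model.weight_params is not None:
        geno_obs = np.flatnonzero(y.observed[geno_rows])
        scan = glm_scan(
            y.values[geno_rows][geno_obs], g.values[geno_obs]
        ) if scan_kind.upper() == "GLM" else None
        if scan is None:
            from .mixed_model import mlm_scan

            Kg = standard_kinship(g)
            scan = mlm_scan(
                y.values[geno_rows][geno_obs],
                g.values[geno_obs],
                Kg.values[np.ix_(geno_obs, geno_obs)],
            )
        G = weighted_kinship(g, scan.p_values, model.weight_params).values
    else:
        G = standard_kinship(g).values

    G_adj = blend_scale_g(G, A22, cfg)
    H = h_matrix(A, A22, G_adj, geno_rows)
    obs = np.flatnonzero(y.observed)
    vc = fit_variance_components(y.values[obs], H[np.ix_(obs, obs)])
    return blup_predict(y.values[obs], H, obs, vc)
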