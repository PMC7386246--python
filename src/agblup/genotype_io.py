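"""Genotype, phenotype, covariate and pedigree file handling.

Reads and writes PLINK binary filesets (bed/bim/fam, SNP-major bed v1),
whitespace-delimited phenotype/covariate tables and three-column pedigrees,
and applies the standard marker quality-control filters (minor allele
frequency, call rate, Hardy-Weinberg equilibrium).

Dosages count copies of the coded allele (the first allele column of the
bim file, PLINK's A1), so a homozygote for the coded allele is 2.  Missing
genotypes are carried as an explicit boolean mask alongside NaN in the
value array so that no arithmetic silently treats a missing call as a
number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeMatrix",
    "PhenotypeVector",
    "Pedigree",
    "read_plink",
    "write_plink",
    "qc_filter",
    "impute_missing",
    "read_phenotype",
    "read_covariates",
    "read_pedigree",
]

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

#: sentinel for an unknown parent in pedigree files
UNKNOWN_PARENT = "0"


class FormatError(ValueError):
    """Raised when a genotype file does not match its declared format."""


class EmptyPanelError(ValueError):
    """Raised when a filter removes every marker."""


@dataclass
class GenotypeMatrix:
    """Individuals x markers allele-dosage matrix with marker metadata.

    ``values`` holds dosages in {0, 1, 2} as float64 with NaN at missing
    entries; ``missing`` is the matching boolean mask.  ``markers`` is a
    DataFrame with columns (id, chrom, pos, allele_coded, allele_other).
    """

    values: np.ndarray
    individual_ids: list[str]
    markers: pd.DataFrame
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be 2-D (individuals x markers)")
        if self.missing is None:
            self.missing = np.isnan(self.values)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.values.shape != self.missing.shape:
            raise ValueError("missing mask shape mismatch")
        if len(self.individual_ids) != self.values.shape[0]:
            raise ValueError("individual id count does not match row count")
        if len(self.markers) != self.values.shape[1]:
            raise ValueError("marker table length does not match column count")
        ok = self.values[~self.missing]
        if ok.size and not np.isin(ok, (0.0, 1.0, 2.0)).all():
            raise ValueError("non-missing dosages must lie in {0,1,2}")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    @property
    def allele_freq(self) -> np.ndarray:
        """Frequency p_k of the coded allele; NaN where every call is missing."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(np.where(self.missing, np.nan, self.values), axis=0) / 2.0

    @property
    def call_rate(self) -> np.ndarray:
        return 1.0 - self.missing.mean(axis=0)

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            values=self.values[:, keep],
            individual_ids=list(self.individual_ids),
            markers=self.markers.iloc[keep].reset_index(drop=True),
            missing=self.missing[:, keep],
        )

    def subset_individuals(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(
            values=self.values[keep],
            individual_ids=[self.individual_ids[i] for i in np.arange(self.n_individuals)[keep]]
            if keep.dtype == bool
            else [self.individual_ids[i] for i in keep],
            markers=self.markers.copy(),
            missing=self.missing[keep],
        )


@dataclass
class PhenotypeVector:
    """Per-individual trait values; NaN marks a missing record."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()

    @property
    def is_binary(self) -> bool:
        ok = self.values[~np.isnan(self.values)]
        return ok.size > 0 and bool(np.isin(ok, (0.0, 1.0)).all())

    @property
    def observed(self) -> np.ndarray:
        """Boolean mask of non-missing records."""
        return ~np.isnan(self.values)


@dataclass
class Pedigree:
    """Rows of (individual, sire, dam); unknown parent is ``UNKNOWN_PARENT``."""

    individuals: list[str]
    sires: list[str]
    dams: list[str]

    def __post_init__(self) -> None:
        if not (len(self.individuals) == len(self.sires) == len(self.dams)):
            raise ValueError("pedigree columns must have equal length")

    def __len__(self) -> int:
        return len(self.individuals)

    def topological_order(self) -> list[int]:
        """Row order in which every parent precedes its offspring.

        Raises ``ValueError`` on a cyclic pedigree (an individual that is
        its own ancestor).
        """
        index = {ind: i for i, ind in enumerate(self.individuals)}
        state = [0] * len(self)  # 0 unvisited, 1 in progress, 2 done
        order: list[int] = []

        def visit(i: int) -> None:
            if state[i] == 2:
                return
            if state[i] == 1:
                raise ValueError(f"cyclic pedigree at individual {self.individuals[i]}")
            state[i] = 1
            for parent in (self.sires[i], self.dams[i]):
                if parent != UNKNOWN_PARENT and parent in index:
                    visit(index[parent])
            state[i] = 2
            order.append(i)

        for i in range(len(self)):
            visit(i)
        return order


# ---------------------------------------------------------------------------
# PLINK binary fileset


def _decode_table() -> np.ndarray:
    # byte value -> 4 dosages of the coded (A1) allele; 0b01 is missing
    table = np.empty((256, 4), dtype=np.float64)
    code = {0b00: 2.0, 0b01: np.nan, 0b10: 1.0, 0b11: 0.0}
    for byte in range(256):
        for pos in range(4):
            table[byte, pos] = code[(byte >> (2 * pos)) & 0b11]
    return table


_DECODE = _decode_table()


def read_plink(prefix: str | Path) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read a PLINK bed/bim/fam fileset into a :class:`GenotypeMatrix`.

    Returns the genotype matrix and the fam sample table.  Individual and
    marker order follow the fam/bim files; dosages count the bim A1 allele.
    """
    prefix = Path(prefix)
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "phenotype"],
        dtype={"fid": str, "iid": str, "father": str, "mother": str},
    )
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos", "allele_coded", "allele_other"],
        dtype={"chrom": str, "id": str, "allele_coded": str, "allele_other": str},
    )
    n, m = len(fam), len(bim)
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise FormatError(f"{prefix}.bed: bad magic bytes (not a SNP-major bed v1 file)")
    bytes_per_marker = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != bytes_per_marker * m:
        raise FormatError(
            f"{prefix}.bed: expected {bytes_per_marker * m} data bytes for "
            f"{n} individuals x {m} markers, found {body.size} (truncated?)"
        )
    decoded = _DECODE[body.reshape(m, bytes_per_marker)].reshape(m, -1)[:, :n]
    values = np.ascontiguousarray(decoded.T)
    markers = bim[["id", "chrom", "pos", "allele_coded", "allele_other"]].copy()
    return GenotypeMatrix(values, list(fam["iid"]), markers), fam


def write_plink(g: GenotypeMatrix, prefix: str | Path, fam: pd.DataFrame | None = None) -> None:
    """Write a :class:`GenotypeMatrix` as a PLINK bed/bim/fam fileset."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if fam is None:
        fam = pd.DataFrame(
            {
                "fid": g.individual_ids,
                "iid": g.individual_ids,
                "father": "0",
                "mother": "0",
                "sex": 0,
                "phenotype": -9,
            }
        )
    fam.to_csv(prefix.with_suffix(".fam"), sep=" ", header=False, index=False)
    bim = pd.DataFrame(
        {
            "chrom": g.markers["chrom"],
            "id": g.markers["id"],
            "cm": 0,
            "pos": g.markers["pos"],
            "allele_coded": g.markers["allele_coded"],
            "allele_other": g.markers["allele_other"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    n, m = g.values.shape
    # dosage -> 2-bit code: 2 -> 00, 1 -> 10, 0 -> 11, missing -> 01
    code = np.full((n, m), 0b01, dtype=np.uint8)
    code[g.values == 2.0] = 0b00
    code[g.values == 1.0] = 0b10
    code[g.values == 0.0] = 0b11
    code[g.missing] = 0b01
    pad = (-n) % 4
    if pad:
        # pad with 0b00 (decodes as dosage 2 but is sliced off on read)
        code = np.vstack([code, np.zeros((pad, m), dtype=np.uint8)])
    quads = code.T.reshape(m, -1, 4)
    packed = (
        quads[:, :, 0]
        | (quads[:, :, 1] << 2)
        | (quads[:, :, 2] << 4)
        | (quads[:, :, 3] << 6)
    ).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# Quality control


def hwe_pvalues(g: GenotypeMatrix) -> np.ndarray:
    """Per-marker Hardy-Weinberg chi-square (1 df) p-values on genotype counts."""
    vals = np.where(g.missing, np.nan, g.values)
    n0 = np.nansum(vals == 0.0, axis=0).astype(float)
    n1 = np.nansum(vals == 1.0, axis=0).astype(float)
    n2 = np.nansum(vals == 2.0, axis=0).astype(float)
    n = n0 + n1 + n2
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (2 * n2 + n1) / (2 * n)
        q = 1.0 - p
        exp = np.stack([n * q**2, 2 * n * p * q, n * p**2])
        obs = np.stack([n0, n1, n2])
        chi2 = np.where(exp > 0, (obs - exp) ** 2 / np.where(exp > 0, exp, 1.0), 0.0).sum(axis=0)
    pvals = stats.chi2.sf(chi2, df=1)
    # monomorphic markers (p in {0,1}) carry no HWE information
    pvals = np.where((p <= 0) | (p >= 1) | (n == 0), 1.0, pvals)
    return pvals


def qc_filter(
    g: GenotypeMatrix,
    maf_min: float = 0.01,
    cr_min: float = 0.95,
    hwe_p_min: float = 0.05,
) -> GenotypeMatrix:
    """Drop markers failing MAF, call-rate or Hardy-Weinberg thresholds.

    Defaults (MAF < 0.01, CR < 0.95, HWE p < 0.05) match common
    case-control panel filtering.  Survivor order is preserved.
    """
    for name, val in (("maf_min", maf_min), ("cr_min", cr_min), ("hwe_p_min", hwe_p_min)):
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {val}")
    freq = g.allele_freq
    with np.errstate(invalid="ignore"):
        maf = np.minimum(freq, 1.0 - freq)
    keep = (
        ~np.isnan(maf)
        & (maf >= maf_min)
        & (g.call_rate >= cr_min)
        & (hwe_pvalues(g) >= hwe_p_min)
    )
    if not keep.any():
        raise EmptyPanelError("QC removed every marker")
    return g.subset_markers(np.flatnonzero(keep))


def impute_missing(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each missing dosage with its marker mean 2*p_k.

    Leaves non-missing entries untouched and preserves every marker's
    allele frequency exactly.  A marker with no non-missing call has an
    undefined frequency and raises.
    """
    if not g.missing.any():
        return g
    freq = g.allele_freq
    if np.isnan(freq).any():
        bad = g.markers["id"].iloc[np.flatnonzero(np.isnan(freq))].tolist()
        raise ValueError(f"markers with all calls missing cannot be imputed: {bad[:5]}")
    values = np.where(g.missing, 2.0 * freq[None, :], g.values)
    out = GenotypeMatrix.__new__(GenotypeMatrix)
    out.values = values
    out.individual_ids = list(g.individual_ids)
    out.markers = g.markers.copy()
    out.missing = np.zeros_like(g.missing)
    return out


# ---------------------------------------------------------------------------
# Delimited tables


def read_phenotype(
    path: str | Path, individual_ids: list[str] | None = None, column: int | str = -1
) -> PhenotypeVector:
    """Read a whitespace/tab-delimited phenotype table.

    The first column holds individual ids; ``column`` picks the trait
    column (default: last).  A header row is detected automatically (the
    trait cell fails float conversion).  Missing is 'NA' or empty.  When
    ``individual_ids`` is given the values are reordered to match, with
    NaN for absent individuals.
    """
    df = pd.read_csv(Path(path), sep=r"\s+", header=None, dtype=str, na_values=["NA", "na", "NaN"])
    first_trait = df.iloc[0, column if isinstance(column, int) else df.columns.get_loc(column)]
    try:
        float(first_trait)
    except (TypeError, ValueError):
        df = df.iloc[1:].reset_index(drop=True)
    ids = df.iloc[:, 0].astype(str)
    vals = pd.to_numeric(df.iloc[:, column], errors="coerce").to_numpy()
    if individual_ids is None:
        return PhenotypeVector(vals)
    lookup = dict(zip(ids, vals))
    return PhenotypeVector(np.array([lookup.get(str(i), np.nan) for i in individual_ids]))


def read_covariates(path: str | Path, individual_ids: list[str]) -> np.ndarray:
    """Read covariate columns keyed by individual id, reordered to match."""
    df = pd.read_csv(Path(path), sep=r"\s+", header=None, dtype=str, na_values=["NA"])
    try:
        df.iloc[0, 1:].astype(float)
    except (TypeError, ValueError):
        df = df.iloc[1:].reset_index(drop=True)
    df = df.set_index(df.columns[0])
    block = df.astype(float)
    out = np.full((len(individual_ids), block.shape[1]), np.nan)
    for row, iid in enumerate(individual_ids):
        if str(iid) in block.index:
            out[row] = block.loc[str(iid)].to_numpy()
    return out


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a three-column (individual, sire, dam) pedigree file."""
    df = pd.read_csv(Path(path), sep=r"\s+", header=None, dtype=str).fillna(UNKNOWN_PARENT)
    if df.shape[1] < 3:
        raise FormatError("pedigree file must have three columns: individual, sire, dam")
    return Pedigree(
        individuals=df.iloc[:, 0].tolist(),
        sires=df.iloc[:, 1].tolist(),
        dams=df.iloc[:, 2].tolist(),
    )
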