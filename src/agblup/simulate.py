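"""Synthetic genotypes, traits and pedigreed populations.

Genotypes are drawn as two haplotypes per individual under
Hardy-Weinberg equilibrium, with marker frequencies uniform on a
configurable MAF range.  Linkage disequilibrium between adjacent markers
is induced by a first-order latent-Gaussian copying process: each
haplotype carries an AR(1) Gaussian track with lag-one correlation
``ld_decay`` that is thresholded at the per-marker frequency quantile, so
marginal allele frequencies are exact and adjacent-marker correlation
decays geometrically.

Trait architectures mirror the standard benchmarking scenarios for
genomic prediction:

* polygenic — a large block of small effects, N(0, 0.005) per SNP;
* polygenic + major — the polygenic block plus 10 large effects
  N(0, 0.1), with the two blocks rescaled post hoc to contribute equally
  to the genetic variance;
* major genes only — the 10 large effects alone;
* mixed — 10 large N(0, 0.1) + 1000 moderate N(0, 0.01) + the polygenic
  block;
* gamma QTL — 50 causal loci with gamma(shape 0.42, scale 5.4) effect
  sizes and random signs, the architecture of the 16th QTL-MAS Workshop
  trait.

The residual variance is set from the *realized* genetic variance so
each simulated dataset hits its nominal heritability exactly in
expectation; true breeding values and causal marker indices are returned
for scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import GenotypeMatrix, Pedigree, PhenotypeVector, UNKNOWN_PARENT

__all__ = [
    "SimScenario",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_pedigree_population",
    "PedigreePopulation",
]


@dataclass
class SimScenario:
    """Trait-architecture specification.

    ``blocks`` lists (marker count, per-SNP effect variance) pairs;
    ``gamma_qtl`` is an alternative (count, shape, scale) triple for
    gamma-distributed QTL effects with random signs.  When
    ``equalize_blocks`` is set, each block's realized genetic-value
    vector is rescaled so all blocks contribute equal genetic variance.
    """

    h2: float
    blocks: list[tuple[int, float]] = field(default_factory=list)
    gamma_qtl: tuple[int, float, float] | None = None
    equalize_blocks: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.h2 <= 1.0:
            raise ValueError("h2 must lie in (0, 1]")

    # -- the benchmark architectures ------------------------------------
    @classmethod
    def polygenic(cls, h2: float, n_polygenes: int = 10_000) -> "SimScenario":
        return cls(h2=h2, blocks=[(n_polygenes, 0.005)])

    @classmethod
    def polygenic_plus_major(
        cls, h2: float, n_polygenes: int = 10_000, n_major: int = 10
    ) -> "SimScenario":
        return cls(
            h2=h2,
            blocks=[(n_polygenes, 0.005), (n_major, 0.1)],
            equalize_blocks=True,
        )

    @classmethod
    def major_genes(cls, h2: float, n_major: int = 10) -> "SimScenario":
        return cls(h2=h2, blocks=[(n_major, 0.1)])

    @classmethod
    def mixed(
        cls, h2: float, n_polygenes: int = 10_000, n_moderate: int = 1000, n_major: int = 10
    ) -> "SimScenario":
        return cls(h2=h2, blocks=[(n_major, 0.1), (n_moderate, 0.01), (n_polygenes, 0.005)])

    @classmethod
    def gamma_qtl_trait(
        cls, h2: float, n_qtl: int = 50, shape: float = 0.42, scale: float = 5.4
    ) -> "SimScenario":
        return cls(h2=h2, gamma_qtl=(n_qtl, shape, scale))


def _marker_table(m: int, markers_per_chrom: int | None = None) -> pd.DataFrame:
    per = markers_per_chrom or m
    return pd.DataFrame(
        {
            "id": [f"M{k:06d}" for k in range(m)],
            "chrom": [str(k // per + 1) for k in range(m)],
            "pos": [(k % per + 1) * 1000 for k in range(m)],
            "allele_coded": "A",
            "allele_other": "B",
        }
    )


def _simulate_haplotypes(
    n_hap: int, freq: np.ndarray, ld_decay: float, rng: np.random.Generator
) -> np.ndarray:
    """Boolean haplotype array via a thresholded AR(1) latent Gaussian."""
    m = freq.size
    if not 0.0 <= ld_decay < 1.0:
        raise ValueError("ld_decay must lie in [0, 1)")
    x = np.empty((n_hap, m))
    x[:, 0] = rng.standard_normal(n_hap)
    if m > 1:
        innov = rng.standard_normal((n_hap, m - 1)) * np.sqrt(1.0 - ld_decay**2)
        for k in range(1, m):
            x[:, k] = ld_decay * x[:, k - 1] + innov[:, k - 1]
    thresh = stats.norm.ppf(freq)
    return x < thresh[None, :]


def simulate_genotypes(
    n: int,
    m: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    ld_decay: float = 0.0,
    seed: int = 0,
    markers_per_chrom: int | None = None,
    return_haplotypes: bool = False,
):
    """HWE genotypes with uniform MAF spectrum and first-order LD."""
    if n < 1 or m < 1:
        raise ValueError("n and m must be positive")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    rng = np.random.default_rng(seed)
    freq = rng.uniform(lo, hi, size=m)
    haps = _simulate_haplotypes(2 * n, freq, ld_decay, rng)
    values = (haps[0::2].astype(np.float64) + haps[1::2].astype(np.float64))
    g = GenotypeMatrix(
        values=values,
        individual_ids=[f"I{i:05d}" for i in range(n)],
        markers=_marker_table(m, markers_per_chrom),
    )
    return (g, haps) if return_haplotypes else g


def simulate_phenotypes(
    g: GenotypeMatrix, scenario: SimScenario, seed: int = 0
) -> tuple[PhenotypeVector, np.ndarray, np.ndarray]:
    """Simulate a trait on an existing genotype panel.

    Returns (phenotype, true breeding values, causal marker indices).
    Phenotype = genetic value + Gaussian residual whose variance is set
    from the realized var(g) so the sample heritability matches
    ``scenario.h2``.
    """
    rng = np.random.default_rng(seed)
    m = g.n_markers
    dosage = np.where(g.missing, np.nan, g.values)
    if np.isnan(dosage).any():
        raise ValueError("impute missing genotypes before simulating phenotypes")

    if scenario.gamma_qtl is not None:
        count, shape, scale = scenario.gamma_qtl
        specs = [(count, ("gamma", shape, scale))]
    else:
        specs = [(count, ("normal", var)) for count, var in scenario.blocks]
    total = sum(c for c, _ in specs)
    if total > m:
        raise ValueError(f"requested {total} causal markers but panel has {m}")

    causal = rng.choice(m, size=total, replace=False)
    parts = []
    start = 0
    causal_blocks = []
    for count, dist in specs:
        idx = causal[start : start + count]
        start += count
        if dist[0] == "normal":
            eff = rng.normal(0.0, np.sqrt(dist[1]), size=count)
        else:
            eff = rng.gamma(dist[1], dist[2], size=count) * rng.choice((-1.0, 1.0), size=count)
        parts.append(dosage[:, idx] @ eff)
        causal_blocks.append(idx)

    if scenario.equalize_blocks and len(parts) > 1:
        # rescale each block's genetic-value vector to equal variance share
        target = float(np.mean([np.var(p) for p in parts]))
        parts = [
            p * np.sqrt(target / np.var(p)) if np.var(p) > 0 else p for p in parts
        ]
    gvals = np.sum(parts, axis=0)
    var_g = float(np.var(gvals))
    if var_g == 0.0:
        y = rng.standard_normal(g.n_individuals)
    elif scenario.h2 >= 1.0:
        y = gvals.copy()
    else:
        sigma_e = np.sqrt(var_g * (1.0 - scenario.h2) / scenario.h2)
        y = gvals + rng.normal(0.0, sigma_e, size=g.n_individuals)
    return PhenotypeVector(y), gvals, np.concatenate(causal_blocks)


@dataclass
class PedigreePopulation:
    """A multi-generation pedigreed population with tracked truth."""

    pedigree: Pedigree
    genotypes: GenotypeMatrix
    phenotype: PhenotypeVector
    breeding_values: np.ndarray
    causal_idx: np.ndarray
    generation: np.ndarray  # generation number per individual (0 = founder)


def _mendelian_gamete(
    hap_a: np.ndarray, hap_b: np.ndarray, recomb_rate: float, rng: np.random.Generator
) -> np.ndarray:
    m = hap_a.size
    if recomb_rate <= 0:
        return (hap_a if rng.random() < 0.5 else hap_b).copy()
    cross = rng.random(m - 1) < recomb_rate
    track = np.empty(m, dtype=bool)
    track[0] = rng.random() < 0.5
    track[1:] = track[0] ^ (np.cumsum(cross) % 2).astype(bool)
    return np.where(track, hap_a, hap_b)


def simulate_pedigree_population(
    founders: int,
    generations: int,
    offspring_per_mating: int,
    m: int = 2000,
    maf_range: tuple[float, float] = (0.05, 0.5),
    ld_decay: float = 0.0,
    recomb_rate: float = 0.01,
    scenario: SimScenario | None = None,
    seed: int = 0,
    g_founders: GenotypeMatrix | None = None,
) -> PedigreePopulation:
    """Non-overlapping-generation population with Mendelian inheritance.

    Founders are unrelated HWE draws (or supplied via ``g_founders``, in
    which case heterozygotes are phased at random); each later generation
    mates random disjoint pairs of the previous one, every pair producing
    ``offspring_per_mating`` offspring with recombination between
    adjacent markers.  The trait (default: the gamma-QTL architecture at
    h2 = 0.5) is simulated on the full genotype matrix.
    """
    if founders < 2:
        raise ValueError("need at least 2 founders")
    rng = np.random.default_rng(seed)
    if g_founders is not None:
        m = g_founders.n_markers
        dos = np.where(g_founders.missing, np.nan, g_founders.values)
        if np.isnan(dos).any():
            raise ValueError("founder genotypes must be complete")
        founders = g_founders.n_individuals
        haps = np.zeros((2 * founders, m), dtype=bool)
        haps[0::2] = dos >= 1.5
        haps[1::2] = dos >= 0.5
        het = dos == 1.0
        flip = het & (rng.random(dos.shape) < 0.5)
        haps[0::2] ^= flip
        haps[1::2] ^= flip
        markers = g_founders.markers.copy()
    else:
        freq = rng.uniform(maf_range[0], maf_range[1], size=m)
        haps = _simulate_haplotypes(2 * founders, freq, ld_decay, rng)
        markers = _marker_table(m)

    hap_list = [haps[2 * i : 2 * i + 2] for i in range(founders)]
    ids = [f"G0_{i:04d}" for i in range(founders)]
    sires = [UNKNOWN_PARENT] * founders
    dams = [UNKNOWN_PARENT] * founders
    gen_of = [0] * founders
    prev = list(range(founders))

    counter = founders
    for gen in range(1, generations):
        order = rng.permutation(prev)
        pairs = [(order[2 * i], order[2 * i + 1]) for i in range(len(order) // 2)]
        new: list[int] = []
        for sire, dam in pairs:
            for _ in range(offspring_per_mating):
                gam_s = _mendelian_gamete(*hap_list[sire], recomb_rate, rng)
                gam_d = _mendelian_gamete(*hap_list[dam], recomb_rate, rng)
                hap_list.append(np.stack([gam_s, gam_d]))
                ids.append(f"G{gen}_{counter:04d}")
                sires.append(ids[sire])
                dams.append(ids[dam])
                gen_of.append(gen)
                new.append(counter)
                counter += 1
        prev = new

    values = np.stack([h[0].astype(np.float64) + h[1] for h in hap_list])
    g_all = GenotypeMatrix(values, ids, markers)
    scen = scenario or SimScenario.gamma_qtl_trait(h2=0.5)
    y, tbv, causal = simulate_phenotypes(g_all, scen, seed=int(rng.integers(2**31 - 1)))
    return PedigreePopulation(
        pedigree=Pedigree(ids, sires, dams),
        genotypes=g_all,
        phenotype=y,
        breeding_values=tbv,
        causal_idx=causal,
        generation=np.array(gen_of),
    )
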