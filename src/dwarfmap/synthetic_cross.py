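"""Simulate F2 crosses and bulk sequencing counts for BSA-Seq.

The simulator emulates the data-generating process that bulked-segregant
analysis assumes: two inbred parents differing at a set of homozygous
variant sites, an F1 selfed to give an F2 population, a fully penetrant
recessive phenotype at one causal locus, phenotype-based pooling of
individuals into two bulks, and shotgun sequencing of each pool with
Poisson depth, binomial allele sampling and a symmetric per-read error.

Allele coding: ``A`` is the recessive (dwarf) parent allele and is emitted
as ALT in downstream tables; ``B`` is the vine-parent/reference allele.
Genotypes are stored as A-allele dosage (0, 1 or 2) per marker.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SITE_COLUMNS = ["chrom", "pos", "n_ref_D", "n_alt_D", "n_ref_V", "n_alt_V", "variant_kind"]

#: default genetic map density: 1 cM per 250 kb
DEFAULT_CM_PER_MB = 4.0


class ConfigurationError(ValueError):
    """Raised when a genome/bulk specification violates its invariants."""


@dataclass(frozen=True)
class GenomeSpec:
    """Genome layout for the simulated cross.

    Parameters
    ----------
    chromosomes:
        ``[(name, length_bp), ...]``.
    marker_positions:
        per-chromosome sorted, strictly increasing 1-based positions of
        sites at which the two parents are homozygous for different
        alleles.
    locus:
        ``(chromosome, position)`` of the causal recessive locus.  The
        locus need not coincide with a marker.
    cm_per_mb:
        genetic map density used by the Haldane crossover model.
    """

    chromosomes: tuple[tuple[str, int], ...]
    marker_positions: dict[str, np.ndarray]
    locus: tuple[str, int]
    cm_per_mb: float = DEFAULT_CM_PER_MB

    def __post_init__(self):
        object.__setattr__(self, "chromosomes", tuple((str(n), int(l)) for n, l in self.chromosomes))
        lengths = dict(self.chromosomes)
        markers = {}
        for chrom, pos in self.marker_positions.items():
            if chrom not in lengths:
                raise ConfigurationError(f"marker chromosome {chrom!r} not declared")
            arr = np.asarray(pos, dtype=np.int64)
            if arr.size and (np.any(np.diff(arr) <= 0)):
                raise ConfigurationError(f"marker positions on {chrom} must be strictly increasing")
            if arr.size and (arr[0] < 1 or arr[-1] > lengths[chrom]):
                raise ConfigurationError(f"marker positions on {chrom} outside [1, {lengths[chrom]}]")
            markers[chrom] = arr
        object.__setattr__(self, "marker_positions", markers)
        lc, lp = self.locus
        if lc not in lengths:
            raise ConfigurationError(f"locus chromosome {lc!r} not among chromosomes")
        if not (1 <= int(lp) <= lengths[lc]):
            raise ConfigurationError(f"locus position {lp} outside chromosome {lc}")
        if self.cm_per_mb <= 0:
            raise ConfigurationError("cm_per_mb must be positive")

    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)


@dataclass
class F2Individual:
    """One simulated F2 plant.

    ``genotypes[chrom]`` is the A-allele dosage at each marker of that
    chromosome (same order as ``GenomeSpec.marker_positions``);
    ``locus_dosage`` is the dosage at the causal locus itself.
    """

    genotypes: dict[str, np.ndarray]
    locus_dosage: int
    phenotype: str  # "dwarf" | "vine"


@dataclass(frozen=True)
class BulkDesign:
    """Pooling and sequencing design for the two bulks."""

    n_dwarf: int = 25
    n_vine: int = 25
    depth_mean: float = 50.0
    error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self):
        if self.n_dwarf < 1 or self.n_vine < 1:
            raise ConfigurationError("bulk sizes must be >= 1")
        if self.depth_mean < 0:
            raise ConfigurationError("depth_mean must be >= 0")
        if not (0 <= self.error_rate < 0.5):
            raise ConfigurationError("error_rate must be in [0, 0.5)")


def _merged_positions(spec: GenomeSpec, chrom: str) -> tuple[np.ndarray, np.ndarray, int | None]:
    """Marker positions with the causal locus inserted.

    Returns (positions, marker_mask, locus_index); locus_index is None when
    the locus is on another chromosome.
    """
    pos = spec.marker_positions.get(chrom, np.empty(0, dtype=np.int64))
    lc, lp = spec.locus
    if chrom != lc:
        return pos, np.ones(pos.size, dtype=bool), None
    i = int(np.searchsorted(pos, lp))
    if i < pos.size and pos[i] == lp:
        return pos, np.ones(pos.size, dtype=bool), i
    merged = np.insert(pos, i, lp)
    mask = np.ones(merged.size, dtype=bool)
    mask[i] = False
    return merged, mask, i


def _simulate_gametes(rng: np.random.Generator, positions: np.ndarray, n_gametes: int,
                      cm_per_mb: float) -> np.ndarray:
    """Haldane (no-interference) gametes over ``positions``.

    Crossovers form a Poisson process on genetic distance, so the parity of
    crossover counts between adjacent sites is obtained from independent
    Poisson draws per interval; the haplotype at the first site is a fair
    coin.  Returns an (n_gametes, n_sites) 0/1 array (1 = A allele).
    """
    m = positions.size
    start = rng.integers(0, 2, size=(n_gametes, 1), dtype=np.int8)
    if m == 0:
        return np.empty((n_gametes, 0), dtype=np.int8)
    if m == 1:
        return start.astype(np.int8)
    morgans = np.diff(positions) * cm_per_mb / 1e6 / 100.0
    flips = rng.poisson(morgans, size=(n_gametes, m - 1))
    parity = np.cumsum(flips, axis=1) % 2
    hap = np.concatenate([start, start ^ parity.astype(np.int8)], axis=1)
    return hap.astype(np.int8)


def simulate_f2(spec: GenomeSpec, n: int, seed: int) -> list[F2Individual]:
    """Simulate ``n`` F2 individuals from the selfed F1 of two inbred parents.

    Each individual is the union of two independent gametes; each gamete is
    a mosaic of the two parental haplotypes under the Haldane model at
    ``spec.cm_per_mb``.  The phenotype is dwarf iff the individual is
    homozygous for the A allele at the causal locus (full penetrance).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    dosages: dict[str, np.ndarray] = {}
    locus_dosage = None
    for chrom, _length in spec.chromosomes:
        positions, marker_mask, locus_idx = _merged_positions(spec, chrom)
        gametes = _simulate_gametes(rng, positions, 2 * n, spec.cm_per_mb)
        dose = gametes[0::2] + gametes[1::2]  # (n, n_sites)
        if locus_idx is not None:
            locus_dosage = dose[:, locus_idx].copy()
        dosages[chrom] = dose[:, marker_mask]
    assert locus_dosage is not None  # guaranteed by GenomeSpec validation
    individuals = []
    for i in range(n):
        individuals.append(
            F2Individual(
                genotypes={c: dosages[c][i] for c, _ in spec.chromosomes},
                locus_dosage=int(locus_dosage[i]),
                phenotype="dwarf" if locus_dosage[i] == 2 else "vine",
            )
        )
    return individuals


def _pooled_frequencies(spec: GenomeSpec, members: list[F2Individual]) -> dict[str, np.ndarray]:
    """Mean A-allele frequency per marker over the pooled individuals."""
    out = {}
    for chrom, _ in spec.chromosomes:
        if members:
            out[chrom] = np.mean([ind.genotypes[chrom] for ind in members], axis=0) / 2.0
        else:
            out[chrom] = np.empty(0)
    return out


def _select_bulks(population: list[F2Individual], design: BulkDesign):
    dwarfs = [ind for ind in population if ind.phenotype == "dwarf"]
    vines = [ind for ind in population if ind.phenotype == "vine"]
    if len(dwarfs) < design.n_dwarf:
        raise ValueError(f"population has {len(dwarfs)} dwarf individuals, need {design.n_dwarf}")
    if len(vines) < design.n_vine:
        raise ValueError(f"population has {len(vines)} vine individuals, need {design.n_vine}")
    return dwarfs[: design.n_dwarf], vines[: design.n_vine]


def make_bulk_counts(population: list[F2Individual], design: BulkDesign, spec: GenomeSpec,
                     variant_kind: str = "SNP") -> pd.DataFrame:
    """Pool phenotype classes and sequence each bulk at every marker.

    For each marker and bulk, the pooled ALT(=A) frequency is the mean
    allele dosage of the pooled individuals; read depth is
    Poisson(``depth_mean``) and ALT reads are Binomial(depth, frequency
    adjusted by the symmetric error rate).  Returns a SiteCounts table.
    """
    d_bulk, v_bulk = _select_bulks(population, design)
    rng = np.random.default_rng(design.seed)
    freq_d = _pooled_frequencies(spec, d_bulk)
    freq_v = _pooled_frequencies(spec, v_bulk)
    e = design.error_rate
    rows = []
    for chrom, _ in spec.chromosomes:
        positions = spec.marker_positions.get(chrom, np.empty(0, dtype=np.int64))
        m = positions.size
        if m == 0:
            continue
        depth_d = rng.poisson(design.depth_mean, size=m)
        depth_v = rng.poisson(design.depth_mean, size=m)
        p_d = freq_d[chrom] * (1 - e) + (1 - freq_d[chrom]) * e
        p_v = freq_v[chrom] * (1 - e) + (1 - freq_v[chrom]) * e
        alt_d = rng.binomial(depth_d, p_d)
        alt_v = rng.binomial(depth_v, p_v)
        rows.append(pd.DataFrame({
            "chrom": chrom,
            "pos": positions,
            "n_ref_D": depth_d - alt_d,
            "n_alt_D": alt_d,
            "n_ref_V": depth_v - alt_v,
            "n_alt_V": alt_v,
            "variant_kind": variant_kind,
        }))
    if not rows:
        return pd.DataFrame(columns=SITE_COLUMNS)
    return pd.concat(rows, ignore_index=True)[SITE_COLUMNS]


def truth_table(population: list[F2Individual], design: BulkDesign, spec: GenomeSpec) -> pd.DataFrame:
    """Noise-free pooled allele frequencies per marker plus a causal flag."""
    d_bulk, v_bulk = _select_bulks(population, design)
    freq_d = _pooled_frequencies(spec, d_bulk)
    freq_v = _pooled_frequencies(spec, v_bulk)
    lc, lp = spec.locus
    rows = []
    for chrom, _ in spec.chromosomes:
        positions = spec.marker_positions.get(chrom, np.empty(0, dtype=np.int64))
        if positions.size == 0:
            continue
        rows.append(pd.DataFrame({
            "chrom": chrom,
            "pos": positions,
            "freq_alt_D": freq_d[chrom],
            "freq_alt_V": freq_v[chrom],
            "is_causal": (chrom == lc) & (positions == lp),
        }))
    if not rows:
        return pd.DataFrame(columns=["chrom", "pos", "freq_alt_D", "freq_alt_V", "is_causal"])
    return pd.concat(rows, ignore_index=True)


def uniform_genome(n_chrom: int = 1, length_bp: int = 8_000_000, n_markers: int = 500,
                   locus: tuple[str, int] | None = None, seed: int = 0,
                   cm_per_mb: float = DEFAULT_CM_PER_MB) -> GenomeSpec:
    """Convenience builder: equal-length chromosomes with uniform random markers."""
    rng = np.random.default_rng(seed)
    chroms = [(f"chr{i + 1}", length_bp) for i in range(n_chrom)]
    markers = {}
    for name, _ in chroms:
        pos = np.sort(rng.choice(np.arange(1, length_bp + 1), size=n_markers, replace=False))
        markers[name] = pos
    if locus is None:
        locus = (chroms[0][0], length_bp // 4)
    return GenomeSpec(chromosomes=tuple(chroms), marker_positions=markers, locus=locus,
                      cm_per_mb=cm_per_mb)
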