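"""Fine mapping by recombinant screening in recessive-class individuals.

Every individual in the panel is phenotypically recessive, hence homozygous
for the recessive-parent allele (call ``A``) at the causal locus.  A marker
call of ``H`` (heterozygous) or ``B`` (dominant-parent homozygote) in such
an individual evidences a crossover between the marker and the locus, so
per-marker recombinant counts decrease toward the locus; the interval is
delimited by the nearest flanking markers with at least one recombinant on
each side of the zero-recombinant core.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

RECOMBINANT_CALLS = frozenset({"H", "B"})
VALID_CALLS = frozenset({"A", "H", "B"})


@dataclass
class MarkerPanel:
    """Markers plus genotype calls of recessive-class individuals.

    ``markers`` has columns name/chrom/pos (positions sorted); ``genotypes``
    is individuals x markers with values in {A, H, B} or missing (NaN/"-").
    """

    markers: pd.DataFrame
    genotypes: pd.DataFrame

    def __post_init__(self):
        if list(self.genotypes.columns) != list(self.markers["name"]):
            raise ValueError("genotype columns must match marker names, in marker order")
        if np.any(np.diff(self.markers["pos"].to_numpy()) < 0):
            raise ValueError("marker positions must be sorted")
        vals = self.genotypes.to_numpy(dtype=object).ravel()
        bad = {v for v in vals if isinstance(v, str) and v not in VALID_CALLS | {"-", ""}}
        if bad:
            raise ValueError(f"unknown genotype calls: {sorted(bad)}")


def count_recombinants(panel: MarkerPanel) -> pd.Series:
    """Per-marker count of individuals with an H or B call (missing ignored)."""
    counts = {}
    for name in panel.genotypes.columns:
        col = panel.genotypes[name]
        counts[name] = int(col.isin(RECOMBINANT_CALLS).sum())
    return pd.Series(counts, name="recombinants")


@dataclass(frozen=True)
class Interval:
    left_pos: int
    right_pos: int
    ambiguous: bool = False

    @property
    def length_bp(self) -> int:
        return self.right_pos - self.left_pos

    @property
    def length_kb(self) -> int:
        """Interval span truncated (floored) to integer kilobases."""
        return self.length_bp // 1000


def delimit_interval(counts, positions) -> Interval:
    """Flanking-marker interval around the zero-recombinant core.

    ``counts`` and ``positions`` are parallel per-marker sequences (positions
    ascending).  Returns the positions of the nearest marker with >= 1
    recombinant on each side of the zero-recombinant markers; when a side
    has no such marker the outermost marker is used, and when no marker has
    zero recombinants the widest bracket is returned with a warning.
    """
    counts = np.asarray(counts, dtype=int)
    positions = np.asarray(positions, dtype=np.int64)
    if counts.size != positions.size or counts.size < 2:
        raise ValueError("need >= 2 markers with parallel counts and positions")
    if np.any(np.diff(positions) <= 0):
        raise ValueError("positions must be strictly increasing")
    zeros = np.flatnonzero(counts == 0)
    if zeros.size == 0:
        warnings.warn("no zero-recombinant marker: locus position ambiguous, "
                      "returning the widest marker bracket")
        return Interval(int(positions[0]), int(positions[-1]), ambiguous=True)
    left_candidates = np.flatnonzero(counts[: zeros[0]] > 0)
    right_candidates = zeros[-1] + 1 + np.flatnonzero(counts[zeros[-1] + 1:] > 0)
    ambiguous = False
    if left_candidates.size:
        left = int(positions[left_candidates[-1]])
    else:
        left = int(positions[0])
        ambiguous = True
        warnings.warn("no recombinant marker left of the zero-recombinant core")
    if right_candidates.size:
        right = int(positions[right_candidates[0]])
    else:
        right = int(positions[-1])
        ambiguous = True
        warnings.warn("no recombinant marker right of the zero-recombinant core")
    return Interval(left, right, ambiguous=ambiguous)


def panel_from_simulation(individuals, spec, chrom: str, marker_names=None) -> MarkerPanel:
    """Build a recessive-class marker panel from simulated F2 individuals.

    Keeps only dwarf (recessive) individuals and encodes dosage 2/1/0 of the
    recessive-parent allele as A/H/B, mirroring an SSR genotyping panel.
    """
    positions = spec.marker_positions[chrom]
    if marker_names is None:
        marker_names = [f"m{p}" for p in positions]
    dwarfs = [ind for ind in individuals if ind.phenotype == "dwarf"]
    code = {2: "A", 1: "H", 0: "B"}
    rows = [[code[int(d)] for d in ind.genotypes[chrom]] for ind in dwarfs]
    markers = pd.DataFrame({"name": marker_names, "chrom": chrom, "pos": positions})
    genotypes = pd.DataFrame(rows, columns=marker_names)
    return MarkerPanel(markers=markers, genotypes=genotypes)
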