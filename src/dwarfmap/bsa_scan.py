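"""SNP/InDel-index and Euclidean-distance QTL scanning for two bulks.

Per site, with ALT/REF read counts in a dwarf bulk (D) and a vine bulk (V):

    index_alt(bulk) = N_alt / (N_alt + N_ref)
    delta_alt       = index_alt(V) - index_alt(D)          in [-1, 1]
    delta_ref       = index_ref(V) - index_ref(D) = -delta_alt
    ED              = sqrt(delta_ref^2 + delta_alt^2)       in [0, sqrt(2)]

Sites are depth-filtered (default: total depth >= 5 in each bulk),
statistics are averaged in sliding windows (default 1-Mb window advanced by
1 kb), a per-window 99% significance threshold is calibrated against an
empirical no-linkage null, and above-threshold windows are merged into
candidate regions.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

SQRT2 = math.sqrt(2.0)

STAT_COLUMNS = [
    "index_alt_D", "index_alt_V", "index_ref_D", "index_ref_V",
    "delta_alt", "delta_ref", "ed",
]
WINDOW_COLUMNS = ["chrom", "window_start", "window_end", "n_sites", "mean_delta", "mean_ed"]

Region = tuple[str, int, int]


def snp_index(n_alt: int | np.ndarray, n_ref: int | np.ndarray) -> float | np.ndarray:
    """Fraction of reads carrying the allele: ``n_alt / (n_alt + n_ref)``."""
    n_alt = np.asarray(n_alt, dtype=float)
    n_ref = np.asarray(n_ref, dtype=float)
    total = n_alt + n_ref
    if np.any(total <= 0):
        raise ValueError("snp_index undefined at zero total depth; apply depth_filter first")
    out = n_alt / total
    return float(out) if out.ndim == 0 else out


def site_stats(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-site index, Δ-index and ED statistics for a SiteCounts table.

    Both bulks must pass the depth filter at every site (positive total
    depth); the returned frame carries the input columns plus
    ``STAT_COLUMNS``.
    """
    out = counts.copy()
    out["index_alt_D"] = snp_index(counts["n_alt_D"].to_numpy(), counts["n_ref_D"].to_numpy())
    out["index_alt_V"] = snp_index(counts["n_alt_V"].to_numpy(), counts["n_ref_V"].to_numpy())
    out["index_ref_D"] = 1.0 - out["index_alt_D"]
    out["index_ref_V"] = 1.0 - out["index_alt_V"]
    out["delta_alt"] = out["index_alt_V"] - out["index_alt_D"]
    out["delta_ref"] = out["index_ref_V"] - out["index_ref_D"]
    out["ed"] = np.sqrt(out["delta_ref"] ** 2 + out["delta_alt"] ** 2)
    return out


def depth_filter(sites: pd.DataFrame, min_reads: int = 5) -> pd.DataFrame:
    """Retain sites with total depth >= ``min_reads`` in EACH bulk (order kept)."""
    keep = ((sites["n_ref_D"] + sites["n_alt_D"] >= min_reads)
            & (sites["n_ref_V"] + sites["n_alt_V"] >= min_reads))
    return sites.loc[keep].reset_index(drop=True)


def _check_sorted(stats: pd.DataFrame) -> None:
    for _, grp in stats.groupby("chrom", sort=False):
        if np.any(np.diff(grp["pos"].to_numpy()) < 0):
            raise ValueError("site table must be sorted by (chrom, pos)")


def sliding_windows(stats: pd.DataFrame, window_bp: int = 1_000_000, step_bp: int = 1_000,
                    chrom_lengths: dict[str, int] | None = None) -> pd.DataFrame:
    """Average Δ-index and ED in windows of ``window_bp`` advanced by ``step_bp``.

    Windows start at 1, 1+step, ... on each chromosome (1-based inclusive
    ends, clipped at the chromosome end).  Empty windows are emitted with
    ``n_sites`` 0 and missing means.  Input must be sorted by (chrom, pos).
    """
    _check_sorted(stats)
    lengths = dict(chrom_lengths or {})
    frames = []
    chroms = lengths.keys() if lengths else pd.unique(stats["chrom"])
    for chrom in chroms:
        grp = stats.loc[stats["chrom"] == chrom]
        pos = grp["pos"].to_numpy()
        length = lengths.get(chrom, int(pos.max()) if pos.size else window_bp)
        starts = np.arange(1, length + 1, step_bp, dtype=np.int64)
        ends = np.minimum(starts + window_bp - 1, length)
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="right")
        n = hi - lo
        csum_d = np.concatenate([[0.0], np.cumsum(grp["delta_alt"].to_numpy())])
        csum_e = np.concatenate([[0.0], np.cumsum(grp["ed"].to_numpy())])
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_delta = np.where(n > 0, (csum_d[hi] - csum_d[lo]) / np.maximum(n, 1), np.nan)
            mean_ed = np.where(n > 0, (csum_e[hi] - csum_e[lo]) / np.maximum(n, 1), np.nan)
        frames.append(pd.DataFrame({
            "chrom": chrom, "window_start": starts, "window_end": ends,
            "n_sites": n, "mean_delta": mean_delta, "mean_ed": mean_ed,
        }))
    if not frames:
        return pd.DataFrame(columns=WINDOW_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def _null_window_means(rng: np.random.Generator, depths_d: np.ndarray, depths_v: np.ndarray,
                       n_sites: int, n_null: int, stat: str) -> np.ndarray:
    """Window-mean statistics under the no-linkage null (freq 0.5 both bulks)."""
    dd = rng.choice(depths_d, size=(n_null, n_sites), replace=True)
    dv = rng.choice(depths_v, size=(n_null, n_sites), replace=True)
    alt_d = rng.binomial(dd, 0.5)
    alt_v = rng.binomial(dv, 0.5)
    delta = alt_v / dv - alt_d / dd
    vals = SQRT2 * np.abs(delta) if stat == "ed" else delta
    return vals.mean(axis=1)


def threshold_99(windows: pd.DataFrame, site_counts: pd.DataFrame, n_null: int = 2_000,
                 seed: int = 0, stat: str = "ed", q: float = 0.99) -> pd.DataFrame:
    """Fill ``threshold_99`` and ``above`` by empirical null simulation.

    For each window the threshold is the ``q`` quantile of the window-mean
    statistic under a no-linkage null: ``n_sites`` sites with per-bulk
    depths resampled from the observed (filtered) depth distribution and
    pooled allele frequency 0.5 in both bulks.  Windows with the same site
    count share one null distribution.  ``above`` uses strict ``>``; empty
    windows get an undefined threshold and ``above`` False.
    """
    if n_null < 100:
        raise ValueError("n_null must be >= 100")
    if stat not in ("ed", "delta"):
        raise ValueError("stat must be 'ed' or 'delta'")
    depths_d = (site_counts["n_ref_D"] + site_counts["n_alt_D"]).to_numpy()
    depths_v = (site_counts["n_ref_V"] + site_counts["n_alt_V"]).to_numpy()
    if np.any(depths_d <= 0) or np.any(depths_v <= 0):
        raise ValueError("site_counts must be depth-filtered before null calibration")
    rng = np.random.default_rng(seed)
    out = windows.copy()
    out["threshold_99"] = np.nan
    thresholds = {}
    for n_sites in sorted(set(out.loc[out["n_sites"] > 0, "n_sites"])):
        means = _null_window_means(rng, depths_d, depths_v, int(n_sites), n_null, stat)
        thresholds[int(n_sites)] = float(np.quantile(means, q))
    mask = out["n_sites"] > 0
    out.loc[mask, "threshold_99"] = out.loc[mask, "n_sites"].map(thresholds)
    observed = out["mean_ed"] if stat == "ed" else out["mean_delta"]
    out["above"] = mask & (observed > out["threshold_99"])
    return out


def call_regions(windows: pd.DataFrame, merge_gap_bp: int = 0) -> list[Region]:
    """Merge runs of above-threshold windows into candidate intervals.

    Windows whose gap is at most ``merge_gap_bp`` are joined; each region is
    reported as (chrom, first window start, last window end), sorted.
    """
    if "above" not in windows.columns:
        raise ValueError("windows must carry 'above'; run threshold_99 first")
    regions: list[Region] = []
    flagged = windows.loc[windows["above"]].sort_values(["chrom", "window_start"])
    for chrom, grp in flagged.groupby("chrom", sort=True):
        cur_start = cur_end = None
        for start, end in zip(grp["window_start"], grp["window_end"]):
            if cur_start is None:
                cur_start, cur_end = int(start), int(end)
            elif int(start) - cur_end - 1 <= merge_gap_bp:
                cur_end = max(cur_end, int(end))
            else:
                regions.append((chrom, cur_start, cur_end))
                cur_start, cur_end = int(start), int(end)
        if cur_start is not None:
            regions.append((chrom, cur_start, cur_end))
    return sorted(regions)


def intersect_regions(a: Region, b: Region) -> Region | None:
    """Intersection of two 1-based inclusive regions; None when empty."""
    if a[0] != b[0]:
        warnings.warn(f"regions on different chromosomes ({a[0]} vs {b[0]}): empty intersection")
        return None
    start = max(a[1], b[1])
    end = min(a[2], b[2])
    if start > end:
        return None
    return (a[0], start, end)


def scan(counts: pd.DataFrame, min_reads: int = 5, window_bp: int = 1_000_000,
         step_bp: int = 1_000, n_null: int = 2_000, seed: int = 0,
         merge_gap_bp: int = 0, chrom_lengths: dict[str, int] | None = None,
         stat: str = "ed") -> tuple[pd.DataFrame, pd.DataFrame, list[Region]]:
    """Full scan: filter -> per-site stats -> windows -> threshold -> regions."""
    filtered = depth_filter(counts, min_reads=min_reads)
    stats = site_stats(filtered)
    windows = sliding_windows(stats, window_bp=window_bp, step_bp=step_bp,
                              chrom_lengths=chrom_lengths)
    windows = threshold_99(windows, filtered, n_null=n_null, seed=seed, stat=stat)
    regions = call_regions(windows, merge_gap_bp=merge_gap_bp)
    return stats, windows, regions
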