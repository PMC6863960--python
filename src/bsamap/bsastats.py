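"""Per-site and windowed bulk-segregant association statistics.

Two complementary statistics compare allele-frequency differences
between the phenotypic-extreme bulks at every informative SNP:

* the SNP-index — within a bulk, the fraction of reads carrying the
  mutant-parent (dwarf) allele; its between-bulk difference, the
  delta SNP-index, has a theoretical value of 2/3 (printed 0.67) at a
  fully penetrant recessive causal locus in an F2 design (mutant bulk
  fixed at 1, non-mutant bulk at the 1 DD : 2 Dd expectation of 1/3);
* the Euclidean distance (ED) between the bulks' allele-frequency
  vectors, raised to a power (default 5) to suppress background noise.

Sites are depth-filtered, per-site statistics are smoothed in sliding
windows along each chromosome, and candidate regions are called where
the smoothed track exceeds a threshold (a fixed theoretical value for
the delta SNP-index; a descriptive mean + 3 SD rule for ED^k).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScanConfig",
    "CandidateRegion",
    "BsaScan",
    "filter_sites",
    "snp_index",
    "euclidean_distance",
    "site_stats",
    "smooth_genome",
    "ed_threshold",
    "call_regions",
    "scan",
]


@dataclass(frozen=True)
class ScanConfig:
    """Tuning of the genome scan; defaults are recorded in output headers."""

    min_depth: int = 5
    window_bp: int = 1_000_000
    step_bp: int = 10_000
    ed_power: float = 5.0
    delta_threshold: float = 0.67
    ed_rule: str = "mean_sd"       # or "quantile"
    ed_n_sd: float = 3.0
    ed_quantile: float = 0.999
    gap_bp: int = 1_000_000
    top_n_peaks: int = 0           # >0: also report sub-threshold peaks

    def __post_init__(self) -> None:
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")
        if self.step_bp > self.window_bp:
            raise ValueError("step_bp must not exceed window_bp")
        if self.ed_power < 1:
            raise ValueError("ed_power must be >= 1")


@dataclass(frozen=True)
class CandidateRegion:
    """A called association region (1-based inclusive bp coordinates)."""

    chrom: str
    start_bp: int
    end_bp: int
    peak_value: float
    peak_pos: int
    n_sites: int
    statistic: str

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("region start exceeds end")
        if self.n_sites < 1:
            raise ValueError("a region needs at least one supporting site")

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start_bp <= pos <= self.end_bp


def filter_sites(sites: pd.DataFrame, min_depth: int) -> pd.DataFrame:
    """Keep sites with total read depth >= min_depth in *both* bulks.

    A site failing depth in either bulk is dropped entirely: both bulk
    indices are needed for the difference statistics.  Order preserved.
    """
    total_d = sites["d_ref"] + sites["d_alt"]
    total_n = sites["n_ref"] + sites["n_alt"]
    return sites.loc[(total_d >= min_depth) & (total_n >= min_depth)].copy()


def _dwarf_read_counts(sites: pd.DataFrame) -> tuple[np.ndarray, ...]:
    """Reads carrying the dwarf-parent allele (rho_x) and totals per bulk."""
    dw_is_alt = (sites["parent_dw"] == sites["alt"]).to_numpy()
    d_dw = np.where(dw_is_alt, sites["d_alt"], sites["d_ref"]).astype(float)
    n_dw = np.where(dw_is_alt, sites["n_alt"], sites["n_ref"]).astype(float)
    d_tot = (sites["d_ref"] + sites["d_alt"]).to_numpy(dtype=float)
    n_tot = (sites["n_ref"] + sites["n_alt"]).to_numpy(dtype=float)
    return d_dw, d_tot, n_dw, n_tot


def snp_index(sites: pd.DataFrame) -> pd.DataFrame:
    """SNP-index per bulk and their difference, per site.

    SNP-index(bulk) = rho_x / (rho_X + rho_x), where rho_x counts reads
    carrying the dwarf-parent allele and rho_X reads carrying the
    normal-parent allele, within that bulk.  Sites with zero total depth
    in either bulk get NaN (undefined; excluded from windows).
    """
    d_dw, d_tot, n_dw, n_tot = _dwarf_read_counts(sites)
    with np.errstate(invalid="ignore", divide="ignore"):
        idx_d = np.where(d_tot > 0, d_dw / d_tot, np.nan)
        idx_n = np.where(n_tot > 0, n_dw / n_tot, np.nan)
    out = sites.copy()
    out["snp_index_d"] = idx_d
    out["snp_index_n"] = idx_n
    out["delta_snp_index"] = idx_d - idx_n
    return out


def euclidean_distance(sites: pd.DataFrame, k: float = 5.0) -> pd.DataFrame:
    """Euclidean distance between bulk allele-frequency vectors, and ED^k.

    Over the two observed alleles of a biallelic site this collapses to
    sqrt(2) * |freq difference|, bounded by sqrt(2).
    """
    d_dw, d_tot, n_dw, n_tot = _dwarf_read_counts(sites)
    with np.errstate(invalid="ignore", divide="ignore"):
        fd = np.where(d_tot > 0, d_dw / d_tot, np.nan)
        fn = np.where(n_tot > 0, n_dw / n_tot, np.nan)
    ed = np.sqrt(2.0) * np.abs(fd - fn)
    out = sites.copy()
    out["ed"] = ed
    out["ed_k"] = ed ** k
    return out


def site_stats(sites: pd.DataFrame, ed_power: float = 5.0) -> pd.DataFrame:
    """All per-site statistics in one table (SNP-indices, delta, ED, ED^k)."""
    out = snp_index(sites)
    d_dw, d_tot, n_dw, n_tot = _dwarf_read_counts(sites)
    ed = np.sqrt(2.0) * np.abs(out["snp_index_d"] - out["snp_index_n"])
    out["ed"] = ed
    out["ed_k"] = ed ** ed_power
    return out


def smooth_genome(
    stats: pd.DataFrame,
    window_bp: int,
    step_bp: int,
    statistic: str,
) -> pd.DataFrame:
    """Sliding-window mean of a per-site statistic along each chromosome.

    Anchors are placed every ``step_bp`` spanning the observed sites of
    each chromosome; a window is ``window_bp`` wide, centered on its
    anchor.  Windows with no (defined) sites emit NaN.  Input must be
    sorted by (chrom, pos).
    """
    for chrom, sub in stats.groupby("chrom", sort=False):
        if not sub["pos"].is_monotonic_increasing:
            raise ValueError(f"sites not sorted by position on {chrom}")
    half = window_bp / 2.0
    frames = []
    for chrom, sub in stats.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy(dtype=float)
        val = sub[statistic].to_numpy(dtype=float)
        ok = ~np.isnan(val)
        pos_ok, val_ok = pos[ok], val[ok]
        lo = int(pos.min()) if pos.size else 0
        hi = int(pos.max()) if pos.size else 0
        anchors = np.arange(lo, hi + step_bp, step_bp, dtype=float)
        if pos_ok.size:
            csum = np.concatenate([[0.0], np.cumsum(val_ok)])
            left = np.searchsorted(pos_ok, anchors - half, side="left")
            right = np.searchsorted(pos_ok, anchors + half, side="right")
            n = right - left
            with np.errstate(invalid="ignore", divide="ignore"):
                mean = np.where(n > 0, (csum[right] - csum[left]) / n, np.nan)
        else:
            n = np.zeros(anchors.size, dtype=int)
            mean = np.full(anchors.size, np.nan)
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": anchors.astype(np.int64),
            "value": mean, "n_sites": n,
        }))
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chrom", "pos", "value", "n_sites"]
    )


def ed_threshold(
    track: pd.DataFrame | Sequence[float],
    rule: str = "mean_sd",
    n_sd: float = 3.0,
    q: float = 0.999,
) -> float:
    """Descriptive significance line for a smoothed ED^k track.

    ``mean_sd``: mean + n_sd * SD over all defined windows (default 3 SD);
    ``quantile``: the q-quantile of the defined windows.  This is a
    descriptive rule, not a formal test.
    """
    values = track["value"].to_numpy(dtype=float) if isinstance(track, pd.DataFrame) \
        else np.asarray(track, dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise ValueError("empty track: no defined windows")
    if rule == "mean_sd":
        return float(values.mean() + n_sd * values.std(ddof=0))
    if rule == "quantile":
        return float(np.quantile(values, q))
    raise ValueError(f"unknown threshold rule {rule!r}")


def _runs_to_regions(
    track: pd.DataFrame,
    above: np.ndarray,
    gap_bp: int,
    statistic: str,
    sites: pd.DataFrame | None,
    support_halfwidth: float = 0.0,
) -> list[CandidateRegion]:
    regions: list[CandidateRegion] = []
    for chrom, sub in track.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        mask = above[idx]
        if not mask.any():
            continue
        pos = sub["pos"].to_numpy()
        val = sub["value"].to_numpy()
        # maximal runs of above-threshold windows
        edges = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
        runs = [(pos[s], pos[e - 1], val[s:e]) for s, e in zip(edges[::2], edges[1::2])]
        # merge runs separated by <= gap_bp
        merged: list[list] = []
        for s, e, v in runs:
            if merged and s - merged[-1][1] <= gap_bp:
                merged[-1][1] = e
                merged[-1][2] = np.concatenate([merged[-1][2], v])
            else:
                merged.append([s, e, v])
        for s, e, v in merged:
            in_span = (pos >= s) & (pos <= e)
            span_vals = np.where(np.isnan(val), -np.inf, val)[in_span]
            peak_pos = int(pos[in_span][int(np.argmax(span_vals))])
            peak = float(np.max(span_vals))
            span_lo, span_hi = int(s), int(e)
            n_sites = 1
            if sites is not None:
                # region bounds come from the sites supporting the run's
                # windows (anchor span widened by the half window width)
                in_run = sites[
                    (sites["chrom"] == chrom)
                    & (sites["pos"] >= span_lo - support_halfwidth)
                    & (sites["pos"] <= span_hi + support_halfwidth)
                ]
                if len(in_run):
                    span_lo = int(in_run["pos"].min())
                    span_hi = int(in_run["pos"].max())
                    n_sites = len(in_run)
            regions.append(CandidateRegion(
                chrom=str(chrom), start_bp=span_lo, end_bp=span_hi,
                peak_value=peak, peak_pos=peak_pos, n_sites=n_sites,
                statistic=statistic,
            ))
    return regions


def call_regions(
    track: pd.DataFrame,
    threshold: float,
    gap_bp: int = 1_000_000,
    statistic: str = "delta_snp_index",
    sites: pd.DataFrame | None = None,
    top_n: int = 0,
    support_halfwidth: float = 0.0,
) -> list[CandidateRegion]:
    """Call candidate regions where the smoothed track reaches a threshold.

    Maximal runs of windows with value >= threshold are found per
    chromosome; same-chromosome runs separated by <= gap_bp are merged.
    When ``sites`` is given, region bounds are tightened to the outermost
    supporting sites and the supporting-site count is reported.

    ``top_n`` > 0 additionally reports the highest local track maxima as
    single-window "peak" regions even when sub-threshold — the situation
    where an underpowered scan still shows obvious peaks below the
    theoretical significance line.
    """
    track = track.reset_index(drop=True)
    values = track["value"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        above = (values >= threshold) & ~np.isnan(values)
    regions = _runs_to_regions(track, above, gap_bp, statistic, sites, support_halfwidth)
    if top_n > 0:
        defined = track.dropna(subset=["value"])
        order = defined.sort_values("value", ascending=False)
        taken: list[tuple[str, int]] = []
        for _, row in order.iterrows():
            if len(taken) >= top_n:
                break
            if any(c == row["chrom"] and abs(int(row["pos"]) - p) <= gap_bp
                   for c, p in taken):
                continue
            taken.append((row["chrom"], int(row["pos"])))
            if not any(r.contains(row["chrom"], int(row["pos"])) for r in regions):
                regions.append(CandidateRegion(
                    chrom=str(row["chrom"]), start_bp=int(row["pos"]),
                    end_bp=int(row["pos"]), peak_value=float(row["value"]),
                    peak_pos=int(row["pos"]), n_sites=max(int(row["n_sites"]), 1),
                    statistic=statistic + "_peak",
                ))
    return regions


@dataclass
class BsaScan:
    """Result bundle of a genome scan."""

    config: ScanConfig
    sites: pd.DataFrame               # filtered, with per-site statistics
    delta_track: pd.DataFrame
    ed_track: pd.DataFrame
    ed_threshold_value: float
    delta_regions: list[CandidateRegion] = field(default_factory=list)
    ed_regions: list[CandidateRegion] = field(default_factory=list)


def scan(sites: pd.DataFrame, config: ScanConfig | None = None) -> BsaScan:
    """Depth-filter, compute per-site statistics, smooth, and call regions."""
    cfg = config or ScanConfig()
    kept = filter_sites(sites, cfg.min_depth)
    kept = kept.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    stats = site_stats(kept, ed_power=cfg.ed_power)
    delta_track = smooth_genome(stats, cfg.window_bp, cfg.step_bp, "delta_snp_index")
    ed_track = smooth_genome(stats, cfg.window_bp, cfg.step_bp, "ed_k")
    ed_thr = ed_threshold(ed_track, rule=cfg.ed_rule, n_sd=cfg.ed_n_sd, q=cfg.ed_quantile)
    half = cfg.window_bp / 2.0
    delta_regions = call_regions(
        delta_track, cfg.delta_threshold, cfg.gap_bp,
        statistic="delta_snp_index", sites=stats, top_n=cfg.top_n_peaks,
        support_halfwidth=half,
    )
    ed_regions = call_regions(
        ed_track, ed_thr, cfg.gap_bp, statistic="ed_k", sites=stats,
        top_n=cfg.top_n_peaks, support_halfwidth=half,
    )
    return BsaScan(
        config=cfg, sites=stats, delta_track=delta_track, ed_track=ed_track,
        ed_threshold_value=ed_thr, delta_regions=delta_regions, ed_regions=ed_regions,
    )
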