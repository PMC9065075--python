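"""Sliding-window aggregation, z-standardization and RDD calling.

The scan averages per-site theta in 50-kbp windows advanced by 25 kbp
(defaults), keeps windows with at least ten scored SNPs, and expresses each
window's mean as a z-score relative to the genome-wide distribution of
window means for that contrast — with X-class contigs standardized
separately from the autosomes, since hemizygosity gives the X its own
drift scale.

A region of distinct differentiation (RDD) is a window in the top quantile
(default 15%) of the focal contrast's z-Fst that simultaneously sits in the
bottom quantile (default 25%) of every retained comparison contrast.
Passing windows are merged into maximal regions when they overlap or abut.

Coordinate convention: windows are 1-based inclusive internally; merged
regions are exported as BED (0-based half-open) by the pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variant_io import ContigLengths

logger = logging.getLogger(__name__)

__all__ = [
    "WindowGrid",
    "make_windows",
    "window_mean_fst",
    "zstandardize",
    "call_rdd",
    "merge_windows",
]

WINDOW_KEY = ["CHROM", "BIN_START", "BIN_END"]


@dataclass
class WindowGrid:
    """Ordered windows (1-based inclusive) plus generation parameters."""

    df: pd.DataFrame  # CHROM, BIN_START, BIN_END, CHROM_CLASS
    size: int
    step: int

    def __len__(self) -> int:
        return len(self.df)


def make_windows(contigs: ContigLengths, size: int = 50_000, step: int = 25_000) -> WindowGrid:
    """Sliding windows per contig: starts 1, 1+step, ... while start <= L.

    Window ends are clipped to the contig length; trailing truncated windows
    are kept (they may still hold >= min_snps sites).
    """
    if not (1 <= step <= size):
        raise ValueError("require size >= step >= 1")
    if not contigs.lengths:
        raise ValueError("empty contig table")
    rows = []
    for contig, length in contigs.lengths.items():
        cls = contigs.chrom_class(contig)
        start = 1
        while start <= length:
            rows.append((contig, start, min(start + size - 1, length), cls))
            start += step
    return WindowGrid(
        df=pd.DataFrame(rows, columns=WINDOW_KEY + ["CHROM_CLASS"]),
        size=size,
        step=step,
    )


def window_mean_fst(
    thetas: pd.DataFrame,
    grid: WindowGrid,
    min_snps: int = 10,
    weighted: bool = False,
) -> pd.DataFrame:
    """Per-window Fst for one contrast.

    ``thetas`` is the per-site table from :func:`rddscan.fst.contrast_site_fst`
    (CHROM, POS, WEIR_AND_COCKERHAM_FST, and A/ABC when ``weighted``).
    Membership is 1-based inclusive, so a site in the overlap of two windows
    contributes to both. The window statistic is the unweighted arithmetic
    mean of per-site theta (vcftools MEAN_FST); with ``weighted`` it is the
    ratio of sums sum(a)/sum(a+b+c) instead. Windows with fewer than
    ``min_snps`` scored sites are dropped.
    """
    thetas = thetas.reset_index(drop=True)
    rows = []
    theta_col = thetas["WEIR_AND_COCKERHAM_FST"].to_numpy(float)
    by_contig = {
        contig: sub.index.to_numpy()
        for contig, sub in thetas.groupby("CHROM", sort=False)
    }
    pos_all = thetas["POS"].to_numpy(int)
    for win in grid.df.itertuples(index=False):
        idx = by_contig.get(win.CHROM)
        if idx is None:
            continue
        pos = pos_all[idx]
        lo = np.searchsorted(pos, win.BIN_START, side="left")
        hi = np.searchsorted(pos, win.BIN_END, side="right")
        member = idx[lo:hi]
        n = hi - lo
        if n < min_snps:
            continue
        if weighted:
            num = thetas["A"].to_numpy(float)[member].sum()
            den = thetas["ABC"].to_numpy(float)[member].sum()
            stat = num / den if den != 0 else np.nan
            if not np.isfinite(stat):
                continue
        else:
            stat = float(theta_col[member].mean())
        rows.append((win.CHROM, win.BIN_START, win.BIN_END, n, stat, win.CHROM_CLASS))
    if not rows:
        logger.warning("no windows passed the min-SNP filter (min_snps=%d)", min_snps)
    return pd.DataFrame(
        rows, columns=WINDOW_KEY + ["N_VARIANTS", "MEAN_FST", "CHROM_CLASS"]
    )


def zstandardize(stats: pd.DataFrame) -> pd.DataFrame:
    """z-Fst per chromosome class: z = (mean_fst - m) / sd within class.

    ``m`` is the class mean and ``sd`` the class sample standard deviation
    (denominator n - 1); the X class is standardized separately from the
    pooled autosomes. A class with fewer than two windows or zero variance
    is a hard error — no meaningful deviation scale exists.
    """
    out = stats.copy()
    out["Z_FST"] = np.nan
    for cls, sub in stats.groupby("CHROM_CLASS", sort=False):
        if len(sub) < 2:
            raise ValueError(
                f"chromosome class {cls!r} has {len(sub)} window(s); "
                "need >= 2 to standardize"
            )
        m = sub["MEAN_FST"].mean()
        sd = sub["MEAN_FST"].std(ddof=1)
        if sd == 0:
            raise ValueError(f"chromosome class {cls!r} has zero variance")
        out.loc[sub.index, "Z_FST"] = (sub["MEAN_FST"] - m) / sd
    return out


def merge_windows(windows: pd.DataFrame) -> pd.DataFrame:
    """Merge 1-based inclusive windows that overlap or abut into maximal
    regions; returns CHROM, START, END, REGION_ID plus a window->region map
    column on the input order."""
    if windows.empty:
        return pd.DataFrame(columns=["CHROM", "START", "END", "REGION_ID"])
    w = windows.sort_values(WINDOW_KEY, kind="mergesort")
    regions = []
    cur = None
    for row in w.itertuples(index=False):
        if (
            cur is not None
            and row.CHROM == cur[0]
            and row.BIN_START <= cur[2] + 1
        ):
            cur[2] = max(cur[2], row.BIN_END)
        else:
            if cur is not None:
                regions.append(tuple(cur))
            cur = [row.CHROM, row.BIN_START, row.BIN_END]
    regions.append(tuple(cur))
    return pd.DataFrame(
        [
            (chrom, start, end, f"RDD{i + 1:04d}")
            for i, (chrom, start, end) in enumerate(regions)
        ],
        columns=["CHROM", "START", "END", "REGION_ID"],
    )


def _assign_regions(calls: pd.DataFrame, regions: pd.DataFrame) -> pd.Series:
    region_id = pd.Series("", index=calls.index, dtype=object)
    for reg in regions.itertuples(index=False):
        inside = (
            (calls["CHROM"] == reg.CHROM)
            & (calls["BIN_START"] >= reg.START)
            & (calls["BIN_END"] <= reg.END)
        )
        region_id[inside & calls["PASS"]] = reg.REGION_ID
    return region_id


def call_rdd(
    focal: pd.DataFrame,
    comparisons: dict[str, pd.DataFrame],
    top_fraction: float = 0.15,
    bottom_fraction: float = 0.25,
    exclude: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Line-specific RDD calls by quantile intersection.

    A window is eligible when it survived the min-SNP filter in the focal
    table and in every retained comparison table. Over the eligible windows,
    per table, the focal threshold is the (1 - top_fraction) quantile of
    Z_FST and each comparison threshold the bottom_fraction quantile
    (type-7 linear interpolation, ties inclusive: >= for high, <= for low).
    A window passes when the focal flag and all comparison flags hold;
    passing windows are merged into maximal regions.

    Returns (calls, regions): the per-window audit table with flags and the
    merged regions (1-based inclusive).
    """
    if not (0 < top_fraction < 1) or not (0 < bottom_fraction < 1):
        raise ValueError("fractions must lie in (0, 1)")
    exclude = list(exclude or [])
    retained = {k: v for k, v in comparisons.items() if k not in exclude}
    if not retained:
        raise ValueError("empty comparison set after exclusions")

    merged = focal[WINDOW_KEY + ["Z_FST"]].rename(columns={"Z_FST": "Z_FST_FOCAL"})
    for line, table in retained.items():
        sub = table[WINDOW_KEY + ["Z_FST"]].rename(columns={"Z_FST": f"Z_FST_{line}"})
        merged = merged.merge(sub, on=WINDOW_KEY, how="inner")
    if merged.empty:
        raise ValueError("no windows shared by the focal and comparison tables")

    hi_thr = float(np.quantile(merged["Z_FST_FOCAL"], 1.0 - top_fraction))
    merged["HIGH_FOCAL"] = merged["Z_FST_FOCAL"] >= hi_thr
    passing = merged["HIGH_FOCAL"].copy()
    for line in retained:
        lo_thr = float(np.quantile(merged[f"Z_FST_{line}"], bottom_fraction))
        merged[f"LOW_{line}"] = merged[f"Z_FST_{line}"] <= lo_thr
        passing &= merged[f"LOW_{line}"]
    merged["PASS"] = passing

    regions = merge_windows(merged.loc[merged["PASS"], WINDOW_KEY])
    merged["REGION_ID"] = _assign_regions(merged, regions)
    logger.info(
        "RDD calling: %d eligible windows, %d passing, %d merged regions",
        len(merged),
        int(passing.sum()),
        len(regions),
    )
    return merged, regions
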