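"""Weir & Cockerham (1984) per-site Fst.

The estimator decomposes allele-frequency variance at a biallelic site into
three components — ``a`` (among populations), ``b`` (among individuals within
populations) and ``c`` (within individuals) — and reports

    theta = a / (a + b + c)

the moment estimator of Wright's Fst. This is the estimator behind
``vcftools --weir-fst-pop``, computed here directly from per-population
counts: ``n_i`` called diploid individuals, ``p_i`` alt-allele frequency and
``h_i`` observed heterozygote frequency.

Per-site theta may be negative (sampling noise around 0); negative values are
retained by default because downstream window averages are taken over the raw
per-site values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PopSiteCounts",
    "FstComponents",
    "weir_cockerham_site",
    "weir_cockerham_components",
    "contrast_site_fst",
]


@dataclass(frozen=True)
class PopSiteCounts:
    """One population's summary at one site.

    n : called diploid individuals (>= 0)
    p : alt-allele frequency in [0, 1]
    h : observed heterozygote frequency in [0, 1]
    """

    n: float
    p: float
    h: float

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p must lie in [0, 1]")
        if not (0.0 <= self.h <= 1.0):
            raise ValueError("h must lie in [0, 1]")


@dataclass(frozen=True)
class FstComponents:
    """Variance components and intermediates for one site.

    ``theta`` is NaN and ``defined`` False when the site is uncomputable:
    some population has no called individuals, the mean sample size is 1
    (the within-population term divides by n_bar - 1), or a + b + c == 0
    (site monomorphic across all populations).
    """

    n_bar: float
    n_c: float
    p_bar: float
    s2: float
    h_bar: float
    a: float
    b: float
    c: float
    theta: float
    defined: bool


def weir_cockerham_components(
    n: np.ndarray, p: np.ndarray, h: np.ndarray
) -> dict[str, np.ndarray]:
    """Vectorized variance components over sites.

    Parameters
    ----------
    n, p, h : arrays of shape (n_sites, r)
        Called individuals, alt frequency and heterozygote frequency for each
        of the r populations at each site.

    Returns
    -------
    dict with per-site arrays ``a``, ``b``, ``c``, ``theta``, ``defined`` and
    the intermediates ``n_bar``, ``n_c``, ``p_bar``, ``s2``, ``h_bar``.
    Uncomputable sites carry NaN components and ``defined`` False.
    """
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    h = np.asarray(h, dtype=float)
    if n.ndim != 2 or n.shape != p.shape or n.shape != h.shape:
        raise ValueError("n, p, h must share shape (n_sites, r)")
    r = n.shape[1]
    if r < 2:
        raise ValueError("at least two populations required")

    ok = (n >= 1).all(axis=1)
    # avoid divide warnings on bad sites; they are masked out below
    n_safe = np.where(ok[:, None], n, 1.0)

    n_sum = n_safe.sum(axis=1)
    n_bar = n_sum / r
    n_c = (n_sum - (n_safe**2).sum(axis=1) / n_sum) / (r - 1)
    p_bar = (n_safe * p).sum(axis=1) / n_sum
    s2 = (n_safe * (p - p_bar[:, None]) ** 2).sum(axis=1) / ((r - 1) * n_bar)
    h_bar = (n_safe * h).sum(axis=1) / n_sum

    ok &= n_bar > 1  # n_bar == 1 -> division by zero in a and b
    with np.errstate(divide="ignore", invalid="ignore"):
        inner = p_bar * (1.0 - p_bar) - ((r - 1) / r) * s2
        a = (n_bar / n_c) * (s2 - (inner - h_bar / 4.0) / (n_bar - 1.0))
        b = (n_bar / (n_bar - 1.0)) * (
            inner - ((2.0 * n_bar - 1.0) / (4.0 * n_bar)) * h_bar
        )
    c = h_bar / 2.0

    with np.errstate(divide="ignore", invalid="ignore"):
        denom = a + b + c
        defined = ok & (denom != 0.0) & np.isfinite(denom)
        theta = np.where(defined, a / np.where(denom == 0.0, np.nan, denom), np.nan)

    nanify = lambda x: np.where(ok, x, np.nan)
    return {
        "n_bar": nanify(n_bar),
        "n_c": nanify(n_c),
        "p_bar": nanify(p_bar),
        "s2": nanify(s2),
        "h_bar": nanify(h_bar),
        "a": nanify(a),
        "b": nanify(b),
        "c": nanify(c),
        "theta": theta,
        "defined": defined,
    }


def weir_cockerham_site(counts: Sequence[PopSiteCounts]) -> FstComponents:
    """Compute the components for a single site from r >= 2 populations."""
    if len(counts) < 2:
        raise ValueError("at least two populations required")
    n = np.array([[c.n for c in counts]])
    p = np.array([[c.p for c in counts]])
    h = np.array([[c.h for c in counts]])
    comp = weir_cockerham_components(n, p, h)
    return FstComponents(
        n_bar=float(comp["n_bar"][0]),
        n_c=float(comp["n_c"][0]),
        p_bar=float(comp["p_bar"][0]),
        s2=float(comp["s2"][0]),
        h_bar=float(comp["h_bar"][0]),
        a=float(comp["a"][0]),
        b=float(comp["b"][0]),
        c=float(comp["c"][0]),
        theta=float(comp["theta"][0]),
        defined=bool(comp["defined"][0]),
    )


def contrast_site_fst(
    sites, line_a: str, line_b: str, clamp_negative: bool = False
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-site theta for a two-line contrast.

    Parameters
    ----------
    sites : SiteTable
        Per-line counts (see :mod:`rddscan.variant_io`).
    line_a, line_b : str
        The two line labels; symmetric.
    clamp_negative : bool
        Clamp negative theta to 0 (off by default; raw values mirror what
        vcftools prints and what the window average consumes).

    Returns
    -------
    (table, excluded) where table has columns CHROM, POS,
    WEIR_AND_COCKERHAM_FST plus the components A and ABC (for the optional
    ratio-of-sums window statistic), restricted to sites with defined theta,
    and excluded counts the dropped sites by reason.
    """
    for line in (line_a, line_b):
        if line not in sites.lines:
            raise KeyError(f"unknown line label: {line!r}")

    df = sites.df
    n = np.column_stack(
        [df[f"{line}:n_called"].to_numpy(float) for line in (line_a, line_b)]
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.column_stack(
            [
                df[f"{line}:alt_count"].to_numpy(float)
                / (2.0 * df[f"{line}:n_called"].to_numpy(float))
                for line in (line_a, line_b)
            ]
        )
        h = np.column_stack(
            [
                df[f"{line}:het_count"].to_numpy(float)
                / df[f"{line}:n_called"].to_numpy(float)
                for line in (line_a, line_b)
            ]
        )
    p = np.nan_to_num(p)
    h = np.nan_to_num(h)

    comp = weir_cockerham_components(n, p, h)
    defined = comp["defined"]

    no_samples = (n < 1).any(axis=1)
    excluded = {
        "no_called_samples": int(no_samples.sum()),
        "monomorphic_or_degenerate": int((~defined & ~no_samples).sum()),
    }

    theta = comp["theta"][defined]
    if clamp_negative:
        theta = np.maximum(theta, 0.0)
    out = pd.DataFrame(
        {
            "CHROM": df["CHROM"].to_numpy()[defined],
            "POS": df["POS"].to_numpy()[defined],
            "WEIR_AND_COCKERHAM_FST": theta,
            "A": comp["a"][defined],
            "ABC": (comp["a"] + comp["b"] + comp["c"])[defined],
        }
    )
    return out, excluded
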