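"""Gene overlap and over-representation analysis for RDD regions.

Genes are taken from a GFF3 (type ``gene`` features only), overlap with the
called regions is 1-based inclusive interval intersection (>= 1 bp), and
over-representation of gene-set terms in the overlapping gene list is the
one-sided hypergeometric tail with Benjamini-Hochberg FDR across terms —
the same statistic WebGestaltR-style ORA tools report, with

    enrichment_ratio = (k / n) / (K / N)

for k list genes in the term, n list genes in the universe, K universe
genes in the term and N the universe size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "TermMap",
    "read_gff3_genes",
    "read_gmt",
    "genes_in_regions",
    "overrepresentation",
    "benjamini_hochberg",
]

NONCODING_AS = "unknown"  # biotype assigned when the GFF3 carries none


@dataclass
class TermMap:
    """Gene-set annotation: term_id -> (name, member gene ids) plus universe.

    The universe defaults to the union of all member lists when not given;
    every term's members must be a subset of it.
    """

    terms: dict[str, tuple[str, list[str]]]
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.universe:
            self.universe = set().union(
                *(set(m) for _, m in self.terms.values())
            ) if self.terms else set()
        for term_id, (_, members) in self.terms.items():
            extra = set(members) - self.universe
            if extra:
                raise ValueError(
                    f"term {term_id!r} annotates genes outside the universe: "
                    f"{sorted(extra)[:5]}"
                )


def read_gmt(path: str | Path, universe: set[str] | None = None) -> TermMap:
    """GMT: one term per line — id, description, then member gene ids."""
    terms: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for ln in fh:
            parts = ln.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            terms[parts[0]] = (parts[1], [g for g in parts[2:] if g])
    if not terms:
        raise ValueError(f"no terms parsed from {path}")
    return TermMap(terms=terms, universe=set(universe) if universe else set())


def read_gff3_genes(path: str | Path) -> pd.DataFrame:
    """Gene models from GFF3: type ``gene`` features only.

    Biotype comes from the ``gene_biotype`` attribute, falling back to
    ``biotype``, else "unknown" (counted as non-coding downstream). Returns
    a DataFrame (gene_id, symbol, CHROM, start, end, strand, biotype).
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    rows = []
    skipped = 0
    for feat in db.features_of_type("gene"):
        try:
            start, end = int(feat.start), int(feat.end)
        except (TypeError, ValueError):
            skipped += 1
            continue
        if start > end:
            skipped += 1
            continue
        biotype = (
            feat.attributes.get("gene_biotype")
            or feat.attributes.get("biotype")
            or [NONCODING_AS]
        )[0]
        name = (feat.attributes.get("Name") or [feat.id])[0]
        rows.append(
            {
                "gene_id": feat.id,
                "symbol": name,
                "CHROM": feat.seqid,
                "start": start,
                "end": end,
                "strand": feat.strand or ".",
                "biotype": biotype,
            }
        )
    if skipped:
        logger.warning("skipped %d gene records with malformed coordinates", skipped)
    if not rows:
        raise ValueError(f"no gene features found in {path}")
    return pd.DataFrame(rows)


def genes_in_regions(
    regions: pd.DataFrame, genes: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Genes overlapping any region by >= 1 bp (1-based inclusive).

    ``regions`` needs CHROM, START, END columns (inclusive); ``genes`` is the
    table from :func:`read_gff3_genes`. Genes are deduplicated across
    regions; each reported row lists the first overlapping region. The
    summary counts total, protein-coding and non-coding genes.
    """
    trees: dict[str, IntervalTree] = {}
    for i, g in enumerate(genes.itertuples(index=False)):
        # inclusive [start, end] -> half-open [start, end + 1)
        trees.setdefault(g.CHROM, IntervalTree()).addi(g.start, g.end + 1, i)
    hit: dict[int, str] = {}
    for reg in regions.itertuples(index=False):
        tree = trees.get(reg.CHROM)
        if tree is None:
            continue
        label = getattr(reg, "REGION_ID", f"{reg.CHROM}:{reg.START}-{reg.END}")
        for iv in sorted(tree.overlap(reg.START, reg.END + 1)):
            hit.setdefault(iv.data, label)
    out = genes.iloc[sorted(hit)].copy()
    out["region"] = [hit[i] for i in sorted(hit)]
    n_coding = int((out["biotype"] == "protein_coding").sum())
    summary = {
        "total_genes": len(out),
        "protein_coding": n_coding,
        "non_coding": len(out) - n_coding,
    }
    return out.reset_index(drop=True), summary


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Step-up BH adjustment; input order preserved; p must lie in (0, 1]."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def overrepresentation(gene_list, terms: TermMap) -> pd.DataFrame:
    """One-sided hypergeometric over-representation across terms.

    List genes outside the universe are dropped (logged). For each term
    with k >= 1 list members: the enrichment ratio (k/n)/(K/N) and the
    upper-tail probability P[X >= k], X ~ Hypergeom(N, K, n). Rows are
    ordered by p; FDR is BH across the tested terms.
    """
    genes = list(dict.fromkeys(gene_list))
    inside = [g for g in genes if g in terms.universe]
    dropped = len(genes) - len(inside)
    if dropped:
        logger.info("dropped %d list genes absent from the universe", dropped)
    if not inside:
        raise ValueError("no list genes inside the annotation universe")
    n = len(inside)
    N = len(terms.universe)
    listed = set(inside)

    rows = []
    for term_id, (name, members) in terms.terms.items():
        K = len(set(members))
        overlap = sorted(listed & set(members))
        k = len(overlap)
        if k < 1:
            continue
        ratio = (k / n) / (K / N)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term_id": term_id,
                "term_name": name,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "enrichment_ratio": ratio,
                "p": min(p, 1.0),
                "genes": ";".join(overlap),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "term_id", "term_name", "k", "n", "K", "N",
            "enrichment_ratio", "p", "genes",
        ],
    )
    if not out.empty:
        out["fdr"] = benjamini_hochberg(out["p"].to_numpy())
        out = out.sort_values(["p", "term_id"], kind="mergesort").reset_index(drop=True)
        out = out[
            ["term_id", "term_name", "k", "n", "K", "N",
             "enrichment_ratio", "p", "fdr", "genes"]
        ]
    return out
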