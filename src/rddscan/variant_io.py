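"""Multi-sample VCF ingestion into per-site, per-line counts.

The scan never needs individual genotypes downstream of this module — only,
for each biallelic SNP and each line, the number of called diploid
individuals, the alt-allele copy count and the heterozygote count. Records
that are not biallelic SNPs are skipped and counted. Phased separators are
treated like unphased; half-missing genotypes ("0/.") count as missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

__all__ = [
    "SampleMap",
    "SiteTable",
    "ContigLengths",
    "read_sample_map",
    "read_vcf_counts",
    "read_contig_lengths",
]


@dataclass
class SampleMap:
    """sample_id -> line label; every sample maps to exactly one line."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.lines) < 2:
            raise ValueError("sample map must cover at least two lines")

    @property
    def lines(self) -> list[str]:
        """Line labels in first-appearance order."""
        seen: dict[str, None] = {}
        for line in self.mapping.values():
            seen.setdefault(line, None)
        return list(seen)

    def samples_of(self, line: str) -> list[str]:
        return [s for s, l in self.mapping.items() if l == line]


def read_sample_map(path: str | Path) -> SampleMap:
    """Two-column TSV (sample_id, line_label); '#' lines ignored."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for ln in fh:
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            parts = ln.split("\t")
            if len(parts) != 2:
                raise ValueError(f"malformed sample-map line: {ln!r}")
            sample, line = parts
            if sample in mapping:
                raise ValueError(f"sample {sample!r} listed twice")
            mapping[sample] = line
    return SampleMap(mapping)


@dataclass
class SiteTable:
    """Per-site, per-line counts over the retained biallelic SNPs.

    df columns: CHROM, POS (1-based), REF, ALT, then for each line
    ``{line}:n_called``, ``{line}:alt_count``, ``{line}:het_count``.
    ``skipped`` counts excluded records by reason.
    """

    df: pd.DataFrame
    lines: list[str]
    skipped: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    def to_tsv(self, path: str | Path) -> None:
        out = self.df.rename(
            columns={
                c: c.replace(":n_called", ":N_CALLED")
                .replace(":alt_count", ":ALT_COUNT")
                .replace(":het_count", ":HET_COUNT")
                for c in self.df.columns
            }
        )
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SiteTable":
        df = pd.read_csv(path, sep="\t")
        df = df.rename(
            columns={
                c: c.replace(":N_CALLED", ":n_called")
                .replace(":ALT_COUNT", ":alt_count")
                .replace(":HET_COUNT", ":het_count")
                for c in df.columns
            }
        )
        lines: list[str] = []
        for c in df.columns:
            if c.endswith(":n_called"):
                lines.append(c[: -len(":n_called")])
        return cls(df=df, lines=lines)


@dataclass
class ContigLengths:
    """contig -> length in bp, with a flagged X class."""

    lengths: dict[str, int]
    x_contigs: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for contig, length in self.lengths.items():
            if length < 1:
                raise ValueError(f"contig {contig!r} has non-positive length")
        unknown = set(self.x_contigs) - set(self.lengths)
        if unknown:
            raise ValueError(f"X-class contigs not in table: {sorted(unknown)}")

    def chrom_class(self, contig: str) -> str:
        return "X" if contig in self.x_contigs else "autosome"

    def validate_sites(self, sites: SiteTable) -> None:
        """Every contig carrying sites must be declared with a sufficient length."""
        maxima = sites.df.groupby("CHROM", sort=False)["POS"].max()
        for contig, max_pos in maxima.items():
            if contig not in self.lengths:
                raise ValueError(f"contig {contig!r} carries sites but has no length")
            if max_pos > self.lengths[contig]:
                raise ValueError(
                    f"site at {contig}:{int(max_pos)} exceeds declared length "
                    f"{self.lengths[contig]}"
                )


def read_contig_lengths(
    path: str | Path, x_names: list[str] | None = None
) -> ContigLengths:
    """Contig lengths from VCF ##contig headers or a .fai index."""
    path = Path(path)
    x_names = list(x_names or [])
    lengths: dict[str, int] = {}
    if path.suffix == ".fai":
        with open(path) as fh:
            for ln in fh:
                parts = ln.rstrip("\n").split("\t")
                if len(parts) >= 2:
                    lengths[parts[0]] = int(parts[1])
    else:
        with pysam.VariantFile(str(path)) as vcf:
            for contig in vcf.header.contigs.values():
                if contig.length is None:
                    raise ValueError(f"contig {contig.name!r} declared without length")
                lengths[contig.name] = int(contig.length)
    if not lengths:
        raise ValueError(f"no contig lengths found in {path}")
    x_names = [x for x in x_names if x in lengths]
    return ContigLengths(lengths=lengths, x_contigs=x_names)


def read_vcf_counts(
    vcf_path: str | Path,
    sample_map: SampleMap,
    pass_only: bool = False,
) -> SiteTable:
    """Count alleles per line over the biallelic SNPs of a VCF.

    Multi-allelic and non-SNP records are skipped (counted in
    ``SiteTable.skipped``); missing and half-missing genotypes reduce a
    line's ``n_called``. With ``pass_only``, records whose FILTER is set and
    not PASS are skipped too; by default FILTER is ignored.
    """
    lines = sample_map.lines
    skipped = {"multiallelic": 0, "not_snp": 0, "filtered": 0}
    rows: list[list] = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        header_samples = set(vcf.header.samples)
        missing = [s for s in sample_map.mapping if s not in header_samples]
        if missing:
            raise ValueError(
                f"samples in map absent from VCF: {', '.join(sorted(missing))}"
            )
        by_line = {
            line: [s for s in vcf.header.samples if sample_map.mapping.get(s) == line]
            for line in lines
        }
        for rec in vcf:
            alts = rec.alts or ()
            if len(alts) != 1:
                skipped["multiallelic"] += 1
                continue
            if len(rec.ref) != 1 or len(alts[0]) != 1 or alts[0] not in "ACGT":
                skipped["not_snp"] += 1
                continue
            if pass_only:
                filters = list(rec.filter.keys())
                if filters and filters != ["PASS"]:
                    skipped["filtered"] += 1
                    continue
            row: list = [rec.contig, rec.pos, rec.ref, alts[0]]
            for line in lines:
                n_called = alt_count = het_count = 0
                for sample in by_line[line]:
                    gt = rec.samples[sample]["GT"]
                    if gt is None or len(gt) != 2 or None in gt:
                        continue
                    n_called += 1
                    alt_count += gt[0] + gt[1]
                    if gt[0] != gt[1]:
                        het_count += 1
                row.extend((n_called, alt_count, het_count))
            rows.append(row)
    if not rows:
        raise ValueError(f"no usable biallelic SNP records in {vcf_path}")
    for reason, count in skipped.items():
        if count:
            logger.info("skipped %d records (%s)", count, reason)

    columns = ["CHROM", "POS", "REF", "ALT"]
    for line in lines:
        columns += [f"{line}:n_called", f"{line}:alt_count", f"{line}:het_count"]
    df = pd.DataFrame(rows, columns=columns)
    # canonical order: contig name, then position
    df = df.sort_values(["CHROM", "POS"], kind="mergesort").reset_index(drop=True)
    dup = df.duplicated(["CHROM", "POS"])
    if dup.any():
        raise ValueError("duplicate site positions within a contig")
    for line in lines:
        n2 = 2 * df[f"{line}:n_called"]
        if (df[f"{line}:alt_count"] > n2).any() or (
            df[f"{line}:het_count"] > df[f"{line}:n_called"]
        ).any():
            raise AssertionError("count invariant violated")  # pragma: no cover
    return SiteTable(df=df, lines=lines, skipped=skipped)
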