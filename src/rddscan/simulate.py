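"""Synthetic multi-line cohorts with planted selective sweeps.

Emulates the structure of a long-term livestock selection experiment: one
unselected control line and several selected lines all descend from a shared
founder population, then diverge by drift for G discrete generations under
the Wright-Fisher model. Directional selection is applied only inside
"planted" genomic regions and only in one focal line (optionally a second,
correlated line at half the selection coefficient, to mimic two lines
selected for overlapping traits).

The model is deliberately minimal: sites are independent (no linkage, no
recombination), there is no mutation (0 and 1 are absorbing), and selection
is genic, updating the alt-allele frequency each generation as

    p' = p (1 + s) / (1 + s p)

before binomial resampling of 2N gene copies. Window-scale differentiation
arises because planted sites are clustered into contiguous regions.

Genotypes are Hardy-Weinberg samples from each line's final frequencies:
per individual, dosage ~ Binomial(2, p). All randomness flows from a single
seed through named substreams, so e.g. the annotation draw cannot perturb
the cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "TruthSet",
    "Cohort",
    "default_config",
    "draw_founders",
    "evolve_line",
    "simulate_cohort",
    "synthesize_annotation",
    "write_cohort",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Parameters of one simulated cohort.

    line_names
        All line labels; must contain ``control`` and ``focal``.
    control, focal
        The unselected control line and the line carrying the planted
        sweeps. ``correlated_line``, if set, reuses the focal line's
        selected-site mask at half the selection coefficient.
    contig_lengths
        Mapping contig -> length in bp. ``x_contigs`` flags the X class
        (used downstream only for separate standardization; no sex-specific
        genetics is simulated).
    sites_per_contig
        Segregating-site count per contig (int applied to all, or a dict).
    founder_freq_alpha, founder_freq_beta
        Beta shape parameters of the founder allele-frequency distribution.
    effective_size, generations, selection_coefficient
        N diploid individuals per line per generation, G generations, and
        the genic selection coefficient s >= 0 at planted sites.
    planted_regions
        (contig, start, end) 1-based inclusive; non-overlapping, within
        contig bounds. All sites inside are selected in the focal line.
    samples_per_line
        Diploid individuals genotyped per line.
    missing_rate
        Per-genotype missingness probability (default 0).
    """

    line_names: list[str]
    control: str
    focal: str
    contig_lengths: dict[str, int]
    sites_per_contig: int | dict[str, int]
    correlated_line: str | None = None
    x_contigs: list[str] = field(default_factory=list)
    founder_freq_alpha: float = 1.0
    founder_freq_beta: float = 1.0
    effective_size: int = 50
    generations: int = 40
    selection_coefficient: float = 0.5
    planted_regions: list[tuple[str, int, int]] = field(default_factory=list)
    samples_per_line: int = 10
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.control not in self.line_names:
            raise ValueError(f"control line {self.control!r} not in line_names")
        if self.focal not in self.line_names:
            raise ValueError(f"focal line {self.focal!r} not in line_names")
        if self.focal == self.control:
            raise ValueError("focal line must differ from the control line")
        if self.correlated_line is not None:
            if self.correlated_line not in self.line_names:
                raise ValueError("correlated_line not in line_names")
            if self.correlated_line in (self.focal, self.control):
                raise ValueError("correlated_line must differ from focal and control")
        if len(set(self.line_names)) != len(self.line_names):
            raise ValueError("duplicate line names")
        if self.founder_freq_alpha <= 0 or self.founder_freq_beta <= 0:
            raise ValueError("Beta shape parameters must be positive")
        if self.effective_size < 1:
            raise ValueError("effective_size must be >= 1")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if self.selection_coefficient < 0:
            raise ValueError("selection_coefficient must be >= 0 (directional only)")
        if self.samples_per_line < 1:
            raise ValueError("samples_per_line must be >= 1")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        for name in self.x_contigs:
            if name not in self.contig_lengths:
                raise ValueError(f"X contig {name!r} not in contig_lengths")
        for contig, length in self.contig_lengths.items():
            if length < 1:
                raise ValueError(f"contig {contig!r} has non-positive length")
        by_contig: dict[str, list[tuple[int, int]]] = {}
        for contig, start, end in self.planted_regions:
            if contig not in self.contig_lengths:
                raise ValueError(f"planted region on unknown contig {contig!r}")
            if not (1 <= start <= end <= self.contig_lengths[contig]):
                raise ValueError(
                    f"planted region {contig}:{start}-{end} outside contig bounds"
                )
            by_contig.setdefault(contig, []).append((start, end))
        for contig, regions in by_contig.items():
            regions.sort()
            for (s1, e1), (s2, e2) in zip(regions, regions[1:]):
                if s2 <= e1:
                    raise ValueError(f"overlapping planted regions on {contig}")

    def n_sites(self, contig: str) -> int:
        if isinstance(self.sites_per_contig, dict):
            return int(self.sites_per_contig[contig])
        return int(self.sites_per_contig)

    @property
    def comparison_lines(self) -> list[str]:
        return [l for l in self.line_names if l not in (self.control, self.focal)]


@dataclass
class TruthSet:
    """What the simulator planted, for recovery scoring.

    planted_regions : (contig, start, end, s), 1-based inclusive
    founder_freqs : per-site founder alt frequency
    per_line_final_freqs : line -> per-site final alt frequency
    """

    planted_regions: list[tuple[str, int, int, float]]
    founder_freqs: np.ndarray
    per_line_final_freqs: dict[str, np.ndarray]


@dataclass
class Cohort:
    """Genotyped individuals per line over a shared site registry.

    sites : DataFrame with CHROM, POS (1-based), REF, ALT
    genotypes : line -> int8 array (samples_per_line, n_sites) of alt-allele
        dosage in {0, 1, 2}, -1 for missing.
    """

    sites: pd.DataFrame
    genotypes: dict[str, np.ndarray]

    def sample_names(self) -> list[tuple[str, str]]:
        """(sample_id, line) pairs, in VCF column order."""
        out = []
        for line, mat in self.genotypes.items():
            for i in range(mat.shape[0]):
                out.append((f"{line}_{i + 1}", line))
        return out


def default_config(seed: int = 0) -> SimConfig:
    """The reference simulation: six lines, three planted 100-kbp sweeps.

    One control, one focal sweep line, four neutral comparison lines;
    N = 50, G = 40, s = 0.5; two 2-Mbp autosomes plus a 1-Mbp X-class
    contig at one segregating site per kbp. Planted regions are aligned to
    the default 25-kbp window step.
    """
    return SimConfig(
        line_names=["FZTDU", "DU6", "DU6P", "DUK", "DUC", "DUhLB"],
        control="FZTDU",
        focal="DU6",
        contig_lengths={"chr1": 2_000_000, "chr2": 2_000_000, "chrX": 1_000_000},
        sites_per_contig={"chr1": 2000, "chr2": 2000, "chrX": 1000},
        x_contigs=["chrX"],
        planted_regions=[
            ("chr1", 400_001, 500_000),
            ("chr1", 1_200_001, 1_300_000),
            ("chr2", 700_001, 800_000),
        ],
        effective_size=50,
        generations=40,
        selection_coefficient=0.5,
        samples_per_line=10,
        seed=seed,
    )


def _substreams(seed: int, labels: list[str]) -> dict[str, np.random.Generator]:
    """Named, order-independent child generators from one root seed."""
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(labels))
    return {lab: np.random.default_rng(ss) for lab, ss in zip(labels, children)}


def draw_sites(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Site registry: strictly increasing positions plus ref/alt bases."""
    frames = []
    for contig in config.contig_lengths:
        length = config.contig_lengths[contig]
        k = config.n_sites(contig)
        if k > length:
            raise ValueError(f"more sites than positions on {contig}")
        pos = np.sort(rng.choice(length, size=k, replace=False) + 1)
        ref_idx = rng.integers(0, 4, size=k)
        alt_idx = (ref_idx + rng.integers(1, 4, size=k)) % 4
        frames.append(
            pd.DataFrame(
                {
                    "CHROM": contig,
                    "POS": pos,
                    "REF": _BASES[ref_idx],
                    "ALT": _BASES[alt_idx],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def draw_founders(
    config: SimConfig, rng: np.random.Generator | None = None, n_sites: int | None = None
) -> np.ndarray:
    """Founder alt-allele frequencies, i.i.d. Beta(alpha, beta) per site."""
    if rng is None:
        rng = _substreams(config.seed, ["sites", "founders"])["founders"]
    if n_sites is None:
        n_sites = sum(config.n_sites(c) for c in config.contig_lengths)
    return rng.beta(config.founder_freq_alpha, config.founder_freq_beta, size=n_sites)


def evolve_line(
    founder_freqs: np.ndarray,
    N: int,
    G: int,
    selected_site_mask: np.ndarray | None,
    s: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Wright-Fisher evolution of per-site frequencies over G generations.

    Each generation, selected sites are first pushed deterministically by
    p' = p(1+s)/(1+sp), then every site is resampled as Binomial(2N, p')/2N.
    No mutation: frequencies 0 and 1 are absorbing.
    """
    p = np.asarray(founder_freqs, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("founder frequencies must lie in [0, 1]")
    if N < 1:
        raise ValueError("N must be >= 1")
    if G < 0:
        raise ValueError("G must be >= 0")
    if s < 0:
        raise ValueError("s must be >= 0 (directional selection only)")
    p = p.copy()
    if selected_site_mask is None:
        selected_site_mask = np.zeros(p.shape, dtype=bool)
    sel = np.asarray(selected_site_mask, dtype=bool)
    two_n = 2 * N
    for _ in range(G):
        if s > 0 and sel.any():
            ps = p[sel]
            p[sel] = ps * (1.0 + s) / (1.0 + s * ps)
        p = rng.binomial(two_n, p) / two_n
    return p


def _region_mask(sites: pd.DataFrame, regions) -> np.ndarray:
    mask = np.zeros(len(sites), dtype=bool)
    chrom = sites["CHROM"].to_numpy()
    pos = sites["POS"].to_numpy()
    for region in regions:
        contig, start, end = region[0], region[1], region[2]
        mask |= (chrom == contig) & (pos >= start) & (pos <= end)
    return mask


def simulate_cohort(config: SimConfig) -> tuple[Cohort, TruthSet]:
    """Evolve every line independently from shared founders and genotype it."""
    labels = ["sites", "founders", "missing"]
    labels += [f"evolve:{l}" for l in config.line_names]
    labels += [f"genotype:{l}" for l in config.line_names]
    rngs = _substreams(config.seed, labels)

    sites = draw_sites(config, rngs["sites"])
    founders = draw_founders(config, rngs["founders"], n_sites=len(sites))

    planted_mask = _region_mask(sites, config.planted_regions)
    for contig, start, end in config.planted_regions:
        n_in = int(
            (
                (sites["CHROM"] == contig)
                & (sites["POS"] >= start)
                & (sites["POS"] <= end)
            ).sum()
        )
        if n_in == 0:
            logger.warning(
                "planted region %s:%d-%d contains zero sites (kept in truth set)",
                contig,
                start,
                end,
            )

    s = config.selection_coefficient
    final: dict[str, np.ndarray] = {}
    genotypes: dict[str, np.ndarray] = {}
    for line in config.line_names:
        if line == config.focal:
            mask, s_line = planted_mask, s
        elif line == config.correlated_line:
            mask, s_line = planted_mask, s / 2.0
        else:
            mask, s_line = None, 0.0
        freqs = evolve_line(
            founders,
            config.effective_size,
            config.generations,
            mask,
            s_line,
            rngs[f"evolve:{line}"],
        )
        final[line] = freqs
        dosage = rngs[f"genotype:{line}"].binomial(
            2, freqs, size=(config.samples_per_line, len(sites))
        )
        genotypes[line] = dosage.astype(np.int8)

    if config.missing_rate > 0:
        rng_m = rngs["missing"]
        for line in config.line_names:
            miss = rng_m.random(genotypes[line].shape) < config.missing_rate
            genotypes[line][miss] = -1

    truth = TruthSet(
        planted_regions=[
            (contig, start, end, s) for contig, start, end in config.planted_regions
        ],
        founder_freqs=founders,
        per_line_final_freqs=final,
    )
    return Cohort(sites=sites, genotypes=genotypes), truth


def synthesize_annotation(
    config: SimConfig,
    genes_per_contig: int | None = None,
    n_terms: int = 20,
    rng: np.random.Generator | None = None,
    coding_probability: float = 0.8,
    term_size_range: tuple[int, int] = (5, 30),
    sweep_biased_terms: int = 2,
) -> tuple[pd.DataFrame, dict[str, tuple[str, list[str]]]]:
    """Random gene models plus a gene-set (GO-style) term map.

    Genes are non-overlapping intervals tiled along each contig with
    randomized gaps; each gets a biotype (protein_coding with probability
    ``coding_probability``, else "lncRNA") and membership in zero or more
    terms. When ``genes_per_contig`` is None the count scales with contig
    length (one gene per 25 kbp, at most 40 per contig). ``sweep_biased_terms`` terms are seeded with every gene that
    overlaps a planted region, so an end-to-end run has real enrichment
    signal to detect; the remaining terms draw uniformly from the universe.

    Returns (genes, terms): genes as a DataFrame (gene_id, symbol, CHROM,
    start, end, strand, biotype) and terms as term_id -> (name, gene_ids).
    """
    if genes_per_contig is not None and genes_per_contig < 1:
        raise ValueError("genes_per_contig must be >= 1")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(64)[-1])

    rows = []
    idx = 0
    for contig, length in config.contig_lengths.items():
        k = genes_per_contig
        if k is None:
            k = max(1, min(40, length // 25_000))
        lengths = rng.integers(2_000, 20_001, size=k)
        total = int(lengths.sum())
        if total > length:
            raise ValueError(
                f"{k} genes (total {total} bp) cannot fit on "
                f"{contig} (length {length})"
            )
        slack = length - total
        # random gaps before each gene: order statistics of uniform draws
        cuts = np.sort(rng.integers(0, slack + 1, size=k))
        gaps = np.diff(np.concatenate([[0], cuts]))
        start = 1
        for gene_len, gap in zip(lengths, gaps):
            start += int(gap)
            end = start + int(gene_len) - 1
            idx += 1
            rows.append(
                {
                    "gene_id": f"SYNG{idx:05d}",
                    "symbol": f"Syng{idx}",
                    "CHROM": contig,
                    "start": start,
                    "end": end,
                    "strand": "+" if rng.random() < 0.5 else "-",
                    "biotype": "protein_coding"
                    if rng.random() < coding_probability
                    else "lncRNA",
                }
            )
            start = end + 1
    genes = pd.DataFrame(rows)

    universe = genes["gene_id"].to_list()
    overlap = np.zeros(len(genes), dtype=bool)
    for contig, r_start, r_end in config.planted_regions:
        overlap |= (
            (genes["CHROM"] == contig)
            & (genes["start"] <= r_end)
            & (genes["end"] >= r_start)
        ).to_numpy()
    swept = genes.loc[overlap, "gene_id"].to_list()

    lo, hi = term_size_range
    terms: dict[str, tuple[str, list[str]]] = {}
    for t in range(n_terms):
        term_id = f"SYNT:{t + 1:04d}"
        size = int(rng.integers(lo, hi + 1))
        if t < sweep_biased_terms and swept:
            members = list(swept)
            extra = [g for g in universe if g not in members]
            pad = max(0, size - len(members))
            if pad and extra:
                members += list(rng.choice(extra, size=min(pad, len(extra)), replace=False))
        else:
            members = list(rng.choice(universe, size=min(size, len(universe)), replace=False))
        terms[term_id] = (f"synthetic process {t + 1}", sorted(members))
    return genes, terms


_GT = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_cohort(
    cohort: Cohort,
    annotation: tuple[pd.DataFrame, dict[str, tuple[str, list[str]]]] | None,
    truth: TruthSet | None,
    outdir: str | Path,
    config: SimConfig | None = None,
) -> dict[str, Path]:
    """Write the cohort and its companions as standard text formats.

    Emits VCF v4.2 (GT-only, with ##contig header lines), a two-column
    sample map TSV, GFF3 gene models, a GMT term map, the truth regions as
    BED (0-based half-open) and the truth frequencies as TSV. Returns the
    mapping of logical names to paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    samples = cohort.sample_names()
    contig_lengths: dict[str, int]
    if config is not None:
        contig_lengths = dict(config.contig_lengths)
    else:
        contig_lengths = (
            cohort.sites.groupby("CHROM", sort=False)["POS"].max().astype(int).to_dict()
        )

    vcf_path = outdir / "cohort.vcf"
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=rddscan-simulate\n")
        for contig, length in contig_lengths.items():
            fh.write(f"##contig=<ID={contig},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(s for s, _ in samples)
            + "\n"
        )
        mats = [cohort.genotypes[line] for line in cohort.genotypes]
        all_gt = np.concatenate(mats, axis=0)  # (total_samples, n_sites)
        rows = cohort.sites.itertuples(index=False)
        for j, row in enumerate(rows):
            gt = "\t".join(_GT[int(d)] for d in all_gt[:, j])
            fh.write(
                f"{row.CHROM}\t{row.POS}\t.\t{row.REF}\t{row.ALT}\t.\t.\t.\tGT\t{gt}\n"
            )
    paths["vcf"] = vcf_path

    map_path = outdir / "samples.tsv"
    with open(map_path, "w") as fh:
        for sample, line in samples:
            fh.write(f"{sample}\t{line}\n")
    paths["sample_map"] = map_path

    if annotation is not None:
        genes, terms = annotation
        gff_path = outdir / "genes.gff3"
        with open(gff_path, "w") as fh:
            fh.write("##gff-version 3\n")
            for contig, length in contig_lengths.items():
                fh.write(f"##sequence-region {contig} 1 {length}\n")
            for row in genes.itertuples(index=False):
                attrs = (
                    f"ID={row.gene_id};Name={row.symbol};gene_biotype={row.biotype}"
                )
                fh.write(
                    f"{row.CHROM}\trddscan\tgene\t{row.start}\t{row.end}\t.\t"
                    f"{row.strand}\t.\t{attrs}\n"
                )
        paths["gff3"] = gff_path

        gmt_path = outdir / "terms.gmt"
        with open(gmt_path, "w") as fh:
            for term_id, (name, members) in terms.items():
                fh.write(term_id + "\t" + name + "\t" + "\t".join(members) + "\n")
        paths["gmt"] = gmt_path

    if truth is not None:
        bed_path = outdir / "truth_regions.bed"
        with open(bed_path, "w") as fh:
            for contig, start, end, s in truth.planted_regions:
                # 1-based inclusive -> 0-based half-open
                fh.write(f"{contig}\t{start - 1}\t{end}\ts={s}\n")
        paths["truth_bed"] = bed_path

        freq_path = outdir / "truth_freqs.tsv"
        freq_df = cohort.sites[["CHROM", "POS"]].copy()
        freq_df["FOUNDER"] = truth.founder_freqs
        for line, freqs in truth.per_line_final_freqs.items():
            freq_df[line] = freqs
        freq_df.to_csv(freq_path, sep="\t", index=False, float_format="%.6g")
        paths["truth_freqs"] = freq_path

    return paths
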