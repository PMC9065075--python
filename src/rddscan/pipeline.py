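"""End-to-end orchestration: simulate -> ingest -> Fst -> scan -> annotate.

One declarative TOML config drives a full run into a single output
directory with fixed file names, a structured log and a JSON manifest of
per-stage counts and output checksums. Reruns with the same config and seed
are byte-identical (log format carries no timestamps; all randomness flows
from the config seed through named substreams).
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .annotate import genes_in_regions, overrepresentation, read_gff3_genes, read_gmt
from .fst import contrast_site_fst
from .simulate import SimConfig, simulate_cohort, synthesize_annotation, write_cohort
from .variant_io import (
    ContigLengths,
    SiteTable,
    read_contig_lengths,
    read_sample_map,
    read_vcf_counts,
)
from .windows import call_rdd, make_windows, window_mean_fst, zstandardize

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "load_config"]

FLOAT_FMT = "%.17g"  # exact double round-trip: composed stage runs stay byte-identical


@dataclass
class PipelineConfig:
    """Resolved parameters of one pipeline run.

    Either the four input paths (vcf, sample_map, gff3, gmt) are given, or a
    ``simulate`` block generates them into the run directory. Defaults
    mirror the standard scan: 50-kbp windows, 25-kbp step, >= 10 SNPs,
    top 15% / bottom 25% quantiles.
    """

    outdir: str
    focal: str
    control: str
    comparisons: list[str] = field(default_factory=list)
    exclude: list[str] = field(default_factory=list)
    vcf: str | None = None
    sample_map: str | None = None
    gff3: str | None = None
    gmt: str | None = None
    contig_lengths: str | None = None  # .fai path; default: VCF header
    x_contigs: list[str] = field(default_factory=list)
    window_size: int = 50_000
    window_step: int = 25_000
    min_snps: int = 10
    top_fraction: float = 0.15
    bottom_fraction: float = 0.25
    weighted: bool = False
    seed: int = 0
    simulate: SimConfig | None = None

    def __post_init__(self) -> None:
        if not (0 < self.top_fraction < 1) or not (0 < self.bottom_fraction < 1):
            raise ValueError("quantile fractions must lie in (0, 1)")
        if self.focal == self.control:
            raise ValueError("focal and control lines must differ")
        if self.focal in self.comparisons:
            raise ValueError("focal line listed among comparisons")
        if self.control in self.comparisons:
            raise ValueError("control line listed among comparisons")
        unknown = set(self.exclude) - set(self.comparisons)
        if unknown:
            raise ValueError(f"exclude lines not among comparisons: {sorted(unknown)}")
        if self.simulate is None:
            for name in ("vcf", "sample_map"):
                if getattr(self, name) is None:
                    raise ValueError(f"missing input path {name!r} (no simulate block)")


@dataclass
class RunManifest:
    """Per-stage record counts, resolved config echo and output checksums."""

    config: dict
    version: str
    counts: dict
    checksums: dict[str, str]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def load_config(path: str | Path, outdir: str | None = None) -> PipelineConfig:
    """Read a TOML run config; an optional [simulate] table becomes a SimConfig."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    sim = None
    if "simulate" in raw:
        s = dict(raw["simulate"])
        s["planted_regions"] = [
            (r[0], int(r[1]), int(r[2])) for r in s.get("planted_regions", [])
        ]
        if "contig_lengths" in s:
            s["contig_lengths"] = {k: int(v) for k, v in s["contig_lengths"].items()}
        if "sites_per_contig" in s and isinstance(s["sites_per_contig"], dict):
            s["sites_per_contig"] = {
                k: int(v) for k, v in s["sites_per_contig"].items()
            }
        sim = SimConfig(**s)
    run = dict(raw.get("run", {}))
    if outdir is not None:
        run["outdir"] = outdir
    if sim is not None:
        run.setdefault("seed", sim.seed)
        run.setdefault("focal", sim.focal)
        run.setdefault("control", sim.control)
        run.setdefault("comparisons", sim.comparison_lines)
        run.setdefault("x_contigs", list(sim.x_contigs))
    return PipelineConfig(simulate=sim, **run)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _setup_log(outdir: Path) -> logging.Handler:
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    # no timestamps: reruns must be byte-identical
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("rddscan")
    root.setLevel(logging.INFO)
    root.addHandler(handler)
    return handler


def stage_simulate(sim: SimConfig, outdir: Path) -> dict[str, Path]:
    """Generate the cohort plus annotation and write all input files."""
    cohort, truth = simulate_cohort(sim)
    annotation = synthesize_annotation(sim)
    return write_cohort(cohort, annotation, truth, outdir, config=sim)


def stage_fst(
    config: PipelineConfig, outdir: Path
) -> tuple[SiteTable, ContigLengths, dict[str, pd.DataFrame], dict]:
    """Ingest the VCF and compute per-site theta for every line vs control."""
    sample_map = read_sample_map(config.sample_map)
    sites = read_vcf_counts(config.vcf, sample_map)
    contigs = read_contig_lengths(
        config.contig_lengths or config.vcf, x_names=config.x_contigs
    )
    contigs.validate_sites(sites)
    sites.to_tsv(outdir / "sites.tsv")

    contrasts: dict[str, pd.DataFrame] = {}
    excluded: dict[str, dict] = {}
    for line in [config.focal] + list(config.comparisons):
        table, dropped = contrast_site_fst(sites, line, config.control)
        contrasts[line] = table
        excluded[line] = dropped
        table[["CHROM", "POS", "WEIR_AND_COCKERHAM_FST"]].to_csv(
            outdir / f"fst.{line}.tsv", sep="\t", index=False, float_format=FLOAT_FMT
        )
    counts = {
        "sites_read": len(sites),
        "sites_skipped": dict(sites.skipped),
        "sites_excluded_per_contrast": excluded,
    }
    return sites, contigs, contrasts, counts


def stage_scan(
    config: PipelineConfig,
    contigs: ContigLengths,
    contrasts: dict[str, pd.DataFrame],
    outdir: Path,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Window the contrasts, z-standardize and call RDD."""
    grid = make_windows(contigs, size=config.window_size, step=config.window_step)
    tables: dict[str, pd.DataFrame] = {}
    for line, thetas in contrasts.items():
        stats = window_mean_fst(
            thetas, grid, min_snps=config.min_snps, weighted=config.weighted
        )
        tables[line] = zstandardize(stats)
        tables[line].to_csv(
            outdir / f"windows.{line}.tsv",
            sep="\t",
            index=False,
            float_format=FLOAT_FMT,
        )
    calls, regions = call_rdd(
        tables[config.focal],
        {l: tables[l] for l in config.comparisons},
        top_fraction=config.top_fraction,
        bottom_fraction=config.bottom_fraction,
        exclude=config.exclude,
    )
    calls.to_csv(
        outdir / "rdd_windows.tsv", sep="\t", index=False, float_format=FLOAT_FMT
    )
    with open(outdir / "rdd_regions.bed", "w") as fh:
        for reg in regions.itertuples(index=False):
            fh.write(f"{reg.CHROM}\t{reg.START - 1}\t{reg.END}\t{reg.REGION_ID}\n")
    counts = {
        "windows_built": len(grid),
        "windows_retained_per_contrast": {l: len(t) for l, t in tables.items()},
        "eligible_windows": len(calls),
        "rdd_windows": int(calls["PASS"].sum()),
        "merged_regions": len(regions),
    }
    return calls, regions, counts


def stage_annotate(
    config: PipelineConfig, regions: pd.DataFrame, outdir: Path
) -> dict:
    """Overlap genes with the called regions and test term enrichment."""
    genes = read_gff3_genes(config.gff3)
    hits, summary = genes_in_regions(regions, genes)
    hits.to_csv(outdir / "rdd_genes.tsv", sep="\t", index=False)

    counts = {"genes_overlapping": summary}
    if config.gmt and len(hits):
        terms = read_gmt(config.gmt, universe=set(genes["gene_id"]))
        enrich = overrepresentation(hits["gene_id"].to_list(), terms)
        enrich.to_csv(
            outdir / "enrichment.tsv", sep="\t", index=False, float_format=FLOAT_FMT
        )
        counts["terms_tested"] = len(enrich)
    else:
        counts["terms_tested"] = 0
    return counts


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute every stage into ``config.outdir`` and write manifest.json."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = _setup_log(outdir)
    try:
        cfg = config
        if config.simulate is not None:
            paths = stage_simulate(config.simulate, outdir)
            cfg = PipelineConfig(
                **{
                    **{k: v for k, v in asdict(config).items() if k != "simulate"},
                    "vcf": str(paths["vcf"]),
                    "sample_map": str(paths["sample_map"]),
                    "gff3": str(paths.get("gff3")) if "gff3" in paths else None,
                    "gmt": str(paths.get("gmt")) if "gmt" in paths else None,
                }
            )
        sites, contigs, contrasts, fst_counts = stage_fst(cfg, outdir)
        calls, regions, scan_counts = stage_scan(cfg, contigs, contrasts, outdir)
        if cfg.gff3:
            ann_counts = stage_annotate(cfg, regions, outdir)
        else:
            ann_counts = {"genes_overlapping": None, "terms_tested": 0}

        counts = {**fst_counts, **scan_counts, **ann_counts}
        assert counts["rdd_windows"] <= counts["eligible_windows"]
        assert counts["eligible_windows"] <= counts["windows_built"]

        checksums = {
            p.name: _sha256(p)
            for p in sorted(outdir.iterdir())
            if p.is_file() and p.name not in ("manifest.json", "run.log")
        }
        echo = asdict(config)
        manifest = RunManifest(
            config=echo, version=__version__, counts=counts, checksums=checksums
        )
        manifest.to_json(outdir / "manifest.json")
        logger.info("run complete: %d RDD windows in %d regions",
                    counts["rdd_windows"], counts["merged_regions"])
        return manifest
    finally:
        logging.getLogger("rddscan").removeHandler(handler)
        handler.close()
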