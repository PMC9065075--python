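"""Shared fixtures: a small simulated cohort written once per session."""

from __future__ import annotations

from pathlib import Path

import pytest

from rddscan.simulate import SimConfig, simulate_cohort, synthesize_annotation, write_cohort


def tiny_sim_config(seed: int = 7, **overrides) -> SimConfig:
    """Three lines, two contigs, one planted 50-kbp sweep; runs in ~100 ms."""
    kwargs = dict(
        line_names=["CTL", "SEL", "CMP"],
        control="CTL",
        focal="SEL",
        contig_lengths={"chr1": 500_000, "chrX": 300_000},
        sites_per_contig={"chr1": 500, "chrX": 300},
        x_contigs=["chrX"],
        planted_regions=[("chr1", 100_001, 150_000)],
        effective_size=50,
        generations=20,
        selection_coefficient=0.5,
        samples_per_line=10,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


@pytest.fixture(scope="session")
def tiny_config() -> SimConfig:
    return tiny_sim_config()


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return simulate_cohort(tiny_config)


@pytest.fixture(scope="session")
def tiny_run_dir(tiny_config, tiny_cohort, tmp_path_factory) -> Path:
    """The tiny cohort written to disk as VCF/GFF3/GMT/BED/TSV."""
    cohort, truth = tiny_cohort
    annotation = synthesize_annotation(tiny_config, genes_per_contig=20, n_terms=8)
    outdir = tmp_path_factory.mktemp("tiny_cohort")
    write_cohort(cohort, annotation, truth, outdir, config=tiny_config)
    return outdir
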