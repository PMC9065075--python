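"""Wright-Fisher simulator: moments, determinism, absorption, file output."""

from __future__ import annotations

import numpy as np
import pysam
import pytest

from rddscan.simulate import (
    SimConfig,
    draw_founders,
    evolve_line,
    simulate_cohort,
    synthesize_annotation,
    write_cohort,
)
from rddscan.variant_io import read_sample_map, read_vcf_counts

from .conftest import tiny_sim_config


class TestFounders:
    def test_uniform_founders_have_mean_half(self):
        cfg = tiny_sim_config(
            founder_freq_alpha=1.0,
            founder_freq_beta=1.0,
            sites_per_contig={"chr1": 8000, "chrX": 2000},
        )
        freqs = draw_founders(cfg)
        se = np.sqrt(1.0 / 12.0 / freqs.size)
        assert abs(freqs.mean() - 0.5) < 3 * se
        assert freqs.min() >= 0 and freqs.max() <= 1

    def test_beta_2_2_moments(self):
        """Beta(2,2): mean 1/2, variance 1/20; Monte-Carlo at 10,000 sites."""
        cfg = tiny_sim_config(
            founder_freq_alpha=2.0,
            founder_freq_beta=2.0,
            sites_per_contig={"chr1": 8000, "chrX": 2000},
        )
        freqs = draw_founders(cfg)
        m = freqs.size
        var = 0.05
        # SE of the sample variance of a Beta(2,2): sqrt((mu4 - var^2)/m),
        # mu4 = 3/560 for Beta(2,2)
        se_mean = np.sqrt(var / m)
        se_var = np.sqrt((3.0 / 560.0 - var**2) / m)
        assert abs(freqs.mean() - 0.5) < 3 * se_mean
        assert abs(freqs.var(ddof=1) - var) < 3 * se_var

    def test_same_seed_same_draw(self):
        cfg = tiny_sim_config(seed=123)
        np.testing.assert_array_equal(draw_founders(cfg), draw_founders(cfg))

    def test_nonpositive_shape_rejected(self):
        with pytest.raises(ValueError):
            tiny_sim_config(founder_freq_alpha=0.0)


class TestEvolve:
    def test_zero_frequency_is_absorbing(self):
        rng = np.random.default_rng(0)
        p = evolve_line(np.zeros(50), N=20, G=100, selected_site_mask=None, s=0.0, rng=rng)
        assert (p == 0).all()
        p1 = evolve_line(np.ones(50), N=20, G=100, selected_site_mask=None, s=0.0, rng=rng)
        assert (p1 == 1).all()

    def test_zero_generations_is_identity(self):
        rng = np.random.default_rng(0)
        founders = np.linspace(0, 1, 11)
        out = evolve_line(founders, N=10, G=0, selected_site_mask=None, s=0.0, rng=rng)
        np.testing.assert_array_equal(out, founders)

    def test_neutral_drift_is_a_martingale(self):
        """Mean over replicate sites stays at the founder frequency."""
        rng = np.random.default_rng(42)
        m, p0 = 10_000, 0.3
        final = evolve_line(np.full(m, p0), N=100, G=20, selected_site_mask=None, s=0.0, rng=rng)
        # drift variance after G generations: p(1-p)(1 - (1-1/2N)^G)
        var = p0 * (1 - p0) * (1.0 - (1.0 - 1.0 / 200.0) ** 20)
        assert abs(final.mean() - p0) < 3 * np.sqrt(var / m)

    def test_selection_pushes_frequency_up(self):
        rng = np.random.default_rng(1)
        m = 2000
        sel = np.ones(m, dtype=bool)
        up = evolve_line(np.full(m, 0.2), N=500, G=30, selected_site_mask=sel, s=0.5, rng=rng)
        assert up.mean() > 0.9  # deterministic update alone reaches ~0.99

    def test_negative_selection_rejected(self):
        with pytest.raises(ValueError):
            evolve_line(np.array([0.5]), N=10, G=1, selected_site_mask=None, s=-0.1,
                        rng=np.random.default_rng(0))


class TestCohort:
    def test_fixed_seed_reproduces_cohort(self, tiny_config, tiny_cohort):
        cohort, truth = tiny_cohort
        cohort2, truth2 = simulate_cohort(tiny_config)
        assert cohort.sites.equals(cohort2.sites)
        for line in cohort.genotypes:
            np.testing.assert_array_equal(cohort.genotypes[line], cohort2.genotypes[line])
        np.testing.assert_array_equal(truth.founder_freqs, truth2.founder_freqs)

    def test_truth_set_mirrors_config(self, tiny_config, tiny_cohort):
        _, truth = tiny_cohort
        assert [(c, s, e) for c, s, e, _ in truth.planted_regions] == list(
            tiny_config.planted_regions
        )
        for freqs in truth.per_line_final_freqs.values():
            assert freqs.min() >= 0 and freqs.max() <= 1

    def test_planted_sites_diverge_more_than_neutral(self):
        """|p_focal - p_control| is larger inside planted regions."""
        gaps_planted, gaps_neutral = [], []
        for rep in range(5):
            cfg = tiny_sim_config(seed=100 + rep)
            cohort, truth = simulate_cohort(cfg)
            pf = truth.per_line_final_freqs[cfg.focal]
            pc = truth.per_line_final_freqs[cfg.control]
            chrom = cohort.sites["CHROM"].to_numpy()
            pos = cohort.sites["POS"].to_numpy()
            mask = np.zeros(len(pos), dtype=bool)
            for c, s, e, _ in truth.planted_regions:
                mask |= (chrom == c) & (pos >= s) & (pos <= e)
            gaps_planted.append(np.abs(pf - pc)[mask].mean())
            gaps_neutral.append(np.abs(pf - pc)[~mask].mean())
        assert np.mean(gaps_planted) > np.mean(gaps_neutral)

    def test_no_divergence_without_drift_or_selection(self):
        cfg = tiny_sim_config(generations=0, selection_coefficient=0.0)
        _, truth = simulate_cohort(cfg)
        lines = list(truth.per_line_final_freqs)
        for line in lines[1:]:
            np.testing.assert_array_equal(
                truth.per_line_final_freqs[lines[0]], truth.per_line_final_freqs[line]
            )

    def test_hardy_weinberg_heterozygote_fraction(self):
        """At p = 0.5 the expected heterozygote fraction is 1/2."""
        cfg = tiny_sim_config(
            generations=0,
            founder_freq_alpha=1e6,  # founders concentrated at 0.5
            founder_freq_beta=1e6,
            samples_per_line=200,
            sites_per_contig={"chr1": 30, "chrX": 20},
        )
        cohort, _ = simulate_cohort(cfg)
        dosage = np.concatenate([g.ravel() for g in cohort.genotypes.values()])
        het = (dosage == 1).mean()
        se = np.sqrt(0.25 / dosage.size)
        assert abs(het - 0.5) < 3 * se

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="focal"):
            tiny_sim_config(focal="CTL")
        with pytest.raises(ValueError, match="outside contig bounds"):
            tiny_sim_config(planted_regions=[("chr1", 1, 600_000)])
        with pytest.raises(ValueError, match="overlapping"):
            tiny_sim_config(
                planted_regions=[("chr1", 1000, 2000), ("chr1", 1500, 2500)]
            )


class TestAnnotation:
    def test_single_gene_fits_contig(self):
        cfg = tiny_sim_config()
        rng = np.random.default_rng(3)
        genes, _ = synthesize_annotation(cfg, genes_per_contig=1, n_terms=2, rng=rng)
        assert len(genes) == len(cfg.contig_lengths)
        for row in genes.itertuples(index=False):
            assert 1 <= row.start <= row.end <= cfg.contig_lengths[row.CHROM]

    def test_degenerate_coding_probability(self):
        cfg = tiny_sim_config()
        genes, _ = synthesize_annotation(
            cfg, genes_per_contig=10, n_terms=2,
            rng=np.random.default_rng(4), coding_probability=1.0,
        )
        assert (genes["biotype"] == "protein_coding").all()

    def test_term_lists_are_subsets_of_universe(self):
        cfg = tiny_sim_config()
        genes, terms = synthesize_annotation(
            cfg, genes_per_contig=12, n_terms=5, rng=np.random.default_rng(5)
        )
        universe = set(genes["gene_id"])
        assert len(universe) == 24
        for _, members in terms.values():
            assert set(members) <= universe

    def test_too_many_genes_rejected(self):
        cfg = tiny_sim_config(contig_lengths={"chr1": 10_000, "chrX": 10_000},
                              sites_per_contig=5, x_contigs=["chrX"],
                              planted_regions=[])
        with pytest.raises(ValueError, match="cannot fit"):
            synthesize_annotation(cfg, genes_per_contig=10, rng=np.random.default_rng(6))


class TestWriteCohort:
    def test_round_trip_counts_exactly(self, tiny_cohort, tiny_run_dir):
        cohort, _ = tiny_cohort
        sample_map = read_sample_map(tiny_run_dir / "samples.tsv")
        sites = read_vcf_counts(tiny_run_dir / "cohort.vcf", sample_map)
        assert len(sites) == len(cohort.sites)
        for line, mat in cohort.genotypes.items():
            called = (mat >= 0).sum(axis=0)
            alt = np.where(mat > 0, mat, 0).sum(axis=0)
            het = (mat == 1).sum(axis=0)
            np.testing.assert_array_equal(sites.df[f"{line}:n_called"], called)
            np.testing.assert_array_equal(sites.df[f"{line}:alt_count"], alt)
            np.testing.assert_array_equal(sites.df[f"{line}:het_count"], het)

    def test_vcf_encodes_dosage_as_genotype(self, tiny_run_dir):
        """Dosage 1 appears as 0/1 in the VCF body; pysam parses the file."""
        with pysam.VariantFile(str(tiny_run_dir / "cohort.vcf")) as vcf:
            rec = next(iter(vcf))
            gts = {vcf_sample: rec.samples[vcf_sample]["GT"] for vcf_sample in rec.samples}
        assert all(gt in [(0, 0), (0, 1), (1, 1), (None, None)] for gt in gts.values())

    def test_truth_bed_is_zero_based_half_open(self, tiny_config, tiny_run_dir):
        lines = (tiny_run_dir / "truth_regions.bed").read_text().splitlines()
        contig, start, end = tiny_config.planted_regions[0]
        fields = lines[0].split("\t")
        assert fields[:3] == [contig, str(start - 1), str(end)]

    def test_written_files_are_byte_stable(self, tiny_config, tiny_cohort, tmp_path):
        cohort, truth = tiny_cohort
        a, b = tmp_path / "a", tmp_path / "b"
        for out in (a, b):
            write_cohort(cohort, None, truth, out, config=tiny_config)
        assert (a / "cohort.vcf").read_bytes() == (b / "cohort.vcf").read_bytes()
        assert (a / "truth_freqs.tsv").read_bytes() == (b / "truth_freqs.tsv").read_bytes()

    def test_missing_genotypes_written_and_counted(self, tmp_path):
        cfg = tiny_sim_config(missing_rate=0.3, sites_per_contig={"chr1": 50, "chrX": 30})
        cohort, truth = simulate_cohort(cfg)
        assert (np.concatenate([g.ravel() for g in cohort.genotypes.values()]) == -1).any()
        paths = write_cohort(cohort, None, truth, tmp_path, config=cfg)
        sample_map = read_sample_map(paths["sample_map"])
        sites = read_vcf_counts(paths["vcf"], sample_map)
        n_called = sites.df[[f"{l}:n_called" for l in sites.lines]].to_numpy()
        assert (n_called < cfg.samples_per_line).any()
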