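"""Generative screen model: conservation, closed forms, determinism."""

import numpy as np
import pytest

import sortscreen as ss
from sortscreen.simulate import ANCHOR_FULL, ConfigError


def _neutral_truth(cfg, lib, eps=1.0):
    truth = ss.make_truth(cfg, lib)
    truth.efficiency[:] = eps
    return truth


class TestConfig:
    def test_read_too_short_for_amplicon(self):
        with pytest.raises(ConfigError, match="read_length"):
            ss.ScreenConfig(n_genes=10, read_length=50)

    @pytest.mark.parametrize("field,value", [
        ("n_genes", 0), ("gate_fraction", 1.0), ("seq_error_rate", 1.5),
        ("moi", 0.0), ("library_skew_sd", -0.1), ("sort_rounds", 0),
    ])
    def test_invalid_values_rejected(self, field, value):
        with pytest.raises(ConfigError):
            ss.ScreenConfig(**{field: value})


class TestInitialPopulation:
    def test_total_cells_is_coverage_times_library(self, rng):
        cfg = ss.ScreenConfig(n_genes=20, seed=5)
        lib = ss.make_library(cfg)
        state = ss.simulate_initial_population(cfg, lib, rng)
        assert state.abundance.sum() == cfg.coverage * len(lib)

    def test_zero_skew_gives_uniform_expectation(self):
        cfg = ss.ScreenConfig(n_genes=50, library_skew_sd=0.0, coverage=1000, seed=5)
        lib = ss.make_library(cfg)
        state = ss.simulate_initial_population(cfg, lib, np.random.default_rng(5))
        # counts ~ Multinomial(n, uniform): each within 6 sigma of the mean
        mean = cfg.coverage
        sigma = np.sqrt(mean * (1 - 1 / len(lib)))
        assert np.abs(state.abundance - mean).max() < 6 * sigma

    def test_deterministic_under_seed(self):
        cfg = ss.ScreenConfig(n_genes=20, seed=9)
        lib = ss.make_library(cfg)
        a = ss.simulate_initial_population(cfg, lib, np.random.default_rng(3))
        b = ss.simulate_initial_population(cfg, lib, np.random.default_rng(3))
        np.testing.assert_array_equal(a.abundance, b.abundance)


class TestSortRound:
    def test_all_neutral_full_efficiency_preserves_proportions(self):
        """With phi_g == phi0 everywhere the gate cancels out of the sort."""
        cfg = ss.ScreenConfig(n_genes=30, seed=1)
        lib = ss.make_library(cfg)
        truth = _neutral_truth(cfg, lib, eps=1.0)
        state = ss.simulate_initial_population(cfg, lib, np.random.default_rng(1))
        after = ss.simulate_sort_round(state, truth, cfg, lib, round_index=1, expectation=True)
        np.testing.assert_allclose(after.proportions(), state.proportions(), rtol=1e-12)

    def test_single_hit_tenfold_gate_enrichment(self):
        """phi_g = 10*phi0 at eps=1: closed-form expected share is
        n_i*phi_g / sum_j n_j*phi_j, a ~10x relative gain for the hit."""
        cfg = ss.ScreenConfig(n_genes=40, library_skew_sd=0.0, seed=2)
        lib = ss.make_library(cfg)
        truth = _neutral_truth(cfg, lib, eps=1.0)
        hit = lib.genes()[0]
        truth.genes.loc[hit, ["phi", "label"]] = [10 * cfg.gate_fraction, "hit"]
        state = ss.simulate_initial_population(cfg, lib, np.random.default_rng(2))
        after = ss.simulate_sort_round(state, truth, cfg, lib, round_index=1, expectation=True)
        phi = np.where([sg.gene == hit for sg in lib], 10 * cfg.gate_fraction, cfg.gate_fraction)
        expected = state.abundance * phi
        expected /= expected.sum()
        np.testing.assert_allclose(after.proportions(), expected, rtol=1e-12)
        is_hit = np.array([sg.gene == hit for sg in lib])
        gain = (after.proportions()[is_hit] / state.proportions()[is_hit]).mean()
        ref = (after.proportions()[~is_hit] / state.proportions()[~is_hit]).mean()
        assert gain / ref == pytest.approx(10.0, rel=1e-9)

    def test_closed_form_matches_large_multinomial(self):
        """Stochastic one-round sort converges on the expectation at large
        sorted cell numbers (partial efficiencies included)."""
        cfg = ss.ScreenConfig(n_genes=20, sorted_cells_per_round=100_000_000,
                              library_skew_sd=0.0, seed=3)
        lib = ss.make_library(cfg)
        truth = ss.make_truth(cfg, lib, n_hits=2, hit_phi=0.1,
                              rng=np.random.default_rng(3))
        state = ss.simulate_initial_population(cfg, lib, np.random.default_rng(3))
        exp = ss.simulate_sort_round(state, truth, cfg, lib, expectation=True)
        obs = ss.simulate_sort_round(state, truth, cfg, lib, np.random.default_rng(4))
        np.testing.assert_allclose(obs.proportions(), exp.proportions(),
                                   atol=2e-3)

    def test_essential_gene_fitness_compounds_over_rounds(self):
        """w_g = 0.5 over two growth phases with neutral sorting leaves the
        essential gene at 0.25x a neutral gene's share (up to renormalization)."""
        cfg = ss.ScreenConfig(n_genes=10, library_skew_sd=0.0, seed=4)
        lib = ss.make_library(cfg)
        truth = _neutral_truth(cfg, lib, eps=1.0)
        ess = lib.genes()[0]
        truth.genes.loc[ess, ["fitness", "label"]] = [0.5, "essential"]
        state = ss.simulate_initial_population(cfg, lib, np.random.default_rng(4))
        p0 = state.proportions()
        for r in (1, 2):
            state = ss.simulate_sort_round(state, truth, cfg, lib, round_index=r,
                                           expectation=True)
        is_ess = np.array([sg.gene == ess for sg in lib])
        ratio = (state.proportions()[is_ess] / p0[is_ess]).mean()
        ref = (state.proportions()[~is_ess] / p0[~is_ess]).mean()
        assert ratio / ref == pytest.approx(0.25, rel=1e-9)

    def test_monotone_in_phi(self):
        """Raising phi_g never lowers the gene's expected sorted share."""
        cfg = ss.ScreenConfig(n_genes=15, seed=6)
        lib = ss.make_library(cfg)
        state = ss.simulate_initial_population(cfg, lib, np.random.default_rng(6))
        gene = lib.genes()[3]
        is_g = np.array([sg.gene == gene for sg in lib])
        shares = []
        for phi in (0.005, 0.01, 0.05, 0.2, 0.6):
            truth = _neutral_truth(cfg, lib, eps=0.8)
            if phi > cfg.gate_fraction:
                truth.genes.loc[gene, ["phi", "label"]] = [phi, "hit"]
            after = ss.simulate_sort_round(state, truth, cfg, lib, expectation=True)
            shares.append(after.proportions()[is_g].sum())
        assert np.all(np.diff(shares) >= 0)

    def test_empty_gate_raises(self):
        cfg = ss.ScreenConfig(n_genes=5, gate_fraction=0.0, seed=1)
        lib = ss.make_library(cfg)
        truth = _neutral_truth(cfg, lib, eps=0.0)
        # phi0 = 0 and no editing: nothing can pass the gate
        truth.genes["phi"] = 0.0
        state = ss.simulate_initial_population(cfg, lib, np.random.default_rng(1))
        with pytest.raises(ValueError, match="gate"):
            ss.simulate_sort_round(state, truth, cfg, lib, np.random.default_rng(1))


class TestSequencing:
    def test_tally_sums_to_reads_per_sample(self, small_cfg, small_lib, rng):
        state = ss.simulate_initial_population(small_cfg, small_lib, rng)
        tally = ss.simulate_sequencing(state, small_lib, small_cfg, "s", rng)
        assert tally.assigned("s") == small_cfg.reads_per_sample

    def test_zero_reads_gives_empty_fastq(self, tmp_path, small_lib):
        cfg = ss.ScreenConfig(n_genes=100, reads_per_sample=0, seed=1)
        state = ss.simulate_initial_population(cfg, small_lib, np.random.default_rng(1))
        fq = tmp_path / "empty.fastq"
        tally = ss.simulate_sequencing(state, small_lib, cfg, "s", fastq_path=fq)
        assert fq.read_text() == ""
        assert tally.assigned("s") == 0

    def test_read_layout(self, tmp_path, small_cfg, small_lib):
        cfg = ss.ScreenConfig(n_genes=100, reads_per_sample=200, seed=8)
        state = ss.simulate_initial_population(cfg, small_lib, np.random.default_rng(8))
        fq = tmp_path / "layout.fastq"
        ss.simulate_sequencing(state, small_lib, cfg, "s", np.random.default_rng(8), fastq_path=fq)
        spacers = set(small_lib.spacers)
        lines = fq.read_text().splitlines()
        assert len(lines) == 4 * 200
        for i in range(0, len(lines), 4):
            seq = lines[i + 1]
            assert len(seq) == cfg.read_length
            pos = seq.find(ANCHOR_FULL)
            assert 0 <= pos <= cfg.stagger_max
            assert seq[pos + len(ANCHOR_FULL):pos + len(ANCHOR_FULL) + 20] in spacers

    def test_identical_seed_byte_identical_fastq(self, tmp_path):
        cfg = ss.ScreenConfig(n_genes=30, reads_per_sample=500, seed=12)
        outs = []
        for tag in ("a", "b"):
            res = ss.simulate_screen(cfg, outdir=tmp_path / tag, write_fastq=True)
            outs.append((tmp_path / tag / "sorted_rep1.fastq").read_bytes())
        assert outs[0] == outs[1]


class TestFullScreen:
    def test_replicates_share_truth_not_draws(self, null_screen):
        c = null_screen.counts
        assert c.samples == ["unsorted_rep1", "sorted_rep1", "unsorted_rep2", "sorted_rep2"]
        assert not np.array_equal(c.column("unsorted_rep1"), c.column("unsorted_rep2"))

    def test_neutral_truth_invariants(self, null_screen):
        null_screen.truth.validate(null_screen.config.gate_fraction)
        assert (null_screen.truth.genes["label"] == "neutral").all()

    def test_bulk_depleted_minority_dominates(self, null_screen):
        """The qualitative outcome of iterated tight-gate sorting: most
        guides fall out of the pool and a small minority takes it over."""
        sorted_counts = null_screen.counts.column("sorted_rep1").to_numpy()
        assert (sorted_counts == 0).mean() > 0.5
        n_top = len(sorted_counts) // 50  # top 2% of guides
        top_share = np.sort(sorted_counts)[-n_top:].sum() / sorted_counts.sum()
        assert top_share > 0.5

    def test_neutral_null_lfc_mean_near_zero(self):
        """With no sorting (0 rounds are not allowed; use 1 gentle round at
        high sorted-cell numbers) the per-guide lfc has mean ~ 0."""
        cfg = ss.ScreenConfig(n_genes=200, sort_rounds=1,
                              sorted_cells_per_round=200_000_000, seed=21)
        res = ss.simulate_screen(cfg)
        enr = ss.compute_enrichment(res.counts, ss.replicate_pairs(res.counts))
        lfc = np.concatenate([enr["lfc_rep1"], enr["lfc_rep2"]])
        se = lfc.std(ddof=1) / np.sqrt(lfc.size)
        assert abs(lfc.mean()) < 3 * se

    def test_truth_files_roundtrip(self, tmp_path, hit_screen):
        hit_screen.truth.to_files(tmp_path / "g.tsv", tmp_path / "s.tsv")
        back = ss.ScreenTruth.from_files(tmp_path / "g.tsv", tmp_path / "s.tsv")
        assert back.hit_genes() == hit_screen.truth.hit_genes()
        np.testing.assert_allclose(back.efficiency, hit_screen.truth.efficiency)
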