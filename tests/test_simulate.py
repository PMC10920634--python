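"""Synthetic-data generator: panels, genotypes, fragmentation, damage,
libraries, methylxanthine tables."""

import numpy as np
import pandas as pd
import pytest

from paleocacao import simulate as sim
from paleocacao.simulate import (
    DamageModel,
    ItemConfig,
    build_panel,
    apply_damage,
    fragment_genome,
    revcomp,
    sample_admixed_genotype,
    simulate_library,
    simulate_methylxanthine,
    synthetic_genome,
)


class TestPanel:
    def test_default_collection_shape(self):
        panel = build_panel(seed=5)
        assert panel.n_groups == 11
        assert list(panel.group_sizes) == [8, 8, 8, 8, 7, 4, 7, 7, 4, 8, 7]
        assert panel.group_sizes.sum() == 76
        assert panel.groups[0] == "Criollo"

    def test_seed_determinism(self):
        a = build_panel(n_groups=4, n_loci=50, divergence=0.1, seed=7)
        b = build_panel(n_groups=4, n_loci=50, divergence=0.1, seed=7)
        assert np.array_equal(a.freqs, b.freqs)
        assert np.array_equal(a.genotypes, b.genotypes)
        assert [l.id for l in a.loci] == [l.id for l in b.loci]
        c = build_panel(n_groups=4, n_loci=50, divergence=0.1, seed=8)
        assert not np.array_equal(a.freqs, c.freqs)

    def test_no_divergence_limit_collapses_groups(self):
        panel = build_panel(n_groups=3, n_loci=200, divergence=1e-4, seed=3)
        spread = panel.freqs.max(axis=1) - panel.freqs.min(axis=1)
        assert spread.mean() < 0.02
        from paleocacao.popgen import nei_distance

        d = nei_distance(panel.freqs[:, 0], panel.freqs[:, 1], 10**6, 10**6)
        assert d < 1e-3

    def test_frequency_conservation_in_accessions(self):
        panel = build_panel(n_groups=11, n_loci=100, divergence=0.15, seed=9)
        emp = panel.sample_freqs()
        sizes = panel.group_sizes
        sd = np.sqrt(panel.freqs * (1 - panel.freqs) / (2 * sizes)[None, :])
        violations = np.abs(emp - panel.freqs) > 3 * np.maximum(sd, 1e-12)
        assert violations.mean() < 0.01

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            build_panel(n_groups=1)
        with pytest.raises(ValueError):
            build_panel(n_loci=5)
        with pytest.raises(ValueError):
            build_panel(divergence=0.0)
        with pytest.raises(ValueError):
            build_panel(n_groups=2, group_sizes=[3, 0])

    def test_tsv_round_trip(self, tmp_path, small_panel):
        path = tmp_path / "panel.tsv"
        small_panel.to_tsv(path)
        back = sim.ReferencePanel.from_tsv(path)
        assert back.groups == small_panel.groups
        assert np.allclose(back.freqs, small_panel.freqs)
        assert np.array_equal(back.genotypes, small_panel.genotypes)
        assert [l.pos for l in back.loci] == [l.pos for l in small_panel.loci]


class TestAdmixedGenotype:
    def test_one_hot_with_fixed_alt_gives_all_dosage_two(self):
        panel = build_panel(n_groups=2, n_loci=40, divergence=0.2, seed=1)
        panel.freqs[:, 0] = 1.0
        g = sample_admixed_genotype(panel, [1.0, 0.0], seed=2)
        assert (g == 2).all()

    def test_mean_dosage_matches_mixture_expectation(self):
        panel = build_panel(n_groups=3, n_loci=10000, divergence=0.2, seed=4)
        q = np.array([0.5, 0.3, 0.2])
        g = sample_admixed_genotype(panel, q, seed=5)
        expected = float(panel.freqs.mean(axis=0) @ q)
        # dosage/2 per locus lies in [0,1]; 3 conservative SDs of the mean
        tol = 3 * np.sqrt(0.25 / panel.n_loci)
        assert abs(g.mean() / 2 - expected) < tol

    def test_opposite_fixed_groups_give_binomial_half(self):
        panel = build_panel(n_groups=2, n_loci=3000, divergence=0.2, seed=6)
        panel.freqs[:, 0] = 0.0
        panel.freqs[:, 1] = 1.0
        g = sample_admixed_genotype(panel, [0.5, 0.5], seed=7)
        # per locus each copy is alt w.p. 1/2 -> dosage ~ Binomial(2, 1/2)
        frac = np.bincount(g, minlength=3) / len(g)
        sd = np.sqrt(np.array([0.25, 0.5, 0.25]) * 0.75 / len(g))
        assert np.all(np.abs(frac - [0.25, 0.5, 0.25]) < 4 * sd)

    def test_off_simplex_rejected(self, small_panel):
        with pytest.raises(ValueError):
            sample_admixed_genotype(small_panel, [0.7, 0.7, -0.4])
        with pytest.raises(ValueError):
            sample_admixed_genotype(small_panel, [0.5, 0.4])


class TestFragmentation:
    def test_no_fragment_shorter_than_30(self):
        gen = synthetic_genome(5000, seed=1)
        frags = fragment_genome(gen, DamageModel(), 2000, seed=2)
        lengths = np.array([e - s for s, e in frags])
        assert lengths.min() >= 30
        assert all(0 <= s < e <= len(gen) for s, e in frags)

    def test_mean_length_calibrated(self):
        gen = synthetic_genome(50000, seed=3)
        frags = fragment_genome(gen, DamageModel(), 20000, seed=4)
        L = np.array([e - s for s, e in frags], float)
        se = L.std() / np.sqrt(len(L))
        assert abs(L.mean() - 81.65) < 2 * se

    def test_unbiased_break_points_match_genome_composition(self):
        gen = synthetic_genome(30000, gc=0.5, seed=5)
        model = DamageModel(depurination_bias=1.0)
        frags = fragment_genome(gen, model, 3000, seed=6)
        pur = [gen[s - 1] in "AG" for s, _ in frags if s > 0]
        p = np.mean(pur)
        assert abs(p - 0.5) < 3 * np.sqrt(0.25 / len(pur))

    def test_depurination_bias_odds_closed_form(self):
        gen = synthetic_genome(30000, gc=0.5, seed=7)
        model = DamageModel(depurination_bias=4.0)
        frags = fragment_genome(gen, model, 3000, seed=8)
        pur = [gen[s - 1] in "AG" for s, _ in frags if s > 0]
        p = np.mean(pur)
        assert abs(p - 0.8) < 3 * np.sqrt(0.8 * 0.2 / len(pur))

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            fragment_genome("ACGT" * 5, DamageModel(), 1)


class TestDamage:
    def test_zero_rate_is_identity(self):
        gen = synthetic_genome(500, seed=1)
        out, truth = apply_damage(gen, DamageModel(delta0=0.0), seed=2)
        assert out == gen and truth == []

    def test_damage_closure(self):
        """Every difference is C->T (5'-weighted) or G->A (3'-weighted) and
        is listed in the truth; counts match exactly."""
        gen = synthetic_genome(400, seed=3)
        model = DamageModel(delta0=0.3, decay_lambda=0.9)
        out, truth = apply_damage(gen, model, seed=4)
        diffs = [(i, a, b) for i, (a, b) in enumerate(zip(gen, out)) if a != b]
        assert diffs == truth
        for _, orig, obs in truth:
            assert (orig, obs) in {("C", "T"), ("G", "A")}

    def test_terminal_rate_recovered(self):
        model = DamageModel(delta0=0.05)
        rng = np.random.default_rng(5)
        n = c_at_0 = ct_at_0 = 0
        for _ in range(20000):
            frag = synthetic_genome(60, seed=rng)
            out, _ = apply_damage(frag, model, seed=rng)
            if frag[0] == "C":
                c_at_0 += 1
                ct_at_0 += out[0] == "T"
        assert abs(ct_at_0 / c_at_0 - 0.05) < 0.01

    def test_geometric_decay_ratio(self):
        model = DamageModel(delta0=0.4, decay_lambda=0.5)
        rng = np.random.default_rng(6)
        num = np.zeros(2)
        den = np.zeros(2)
        for _ in range(30000):
            frag = synthetic_genome(40, seed=rng)
            out, _ = apply_damage(frag, model, seed=rng)
            for i in (0, 1):
                if frag[i] == "C":
                    den[i] += 1
                    num[i] += out[i] == "T"
        r0, r1 = num / den
        assert r0 / r1 == pytest.approx(1 / model.decay_lambda, rel=0.15)


class TestLibrary:
    def test_contamination_zero_all_target(self, small_panel, taxa_genomes):
        cfg = ItemConfig("it0", 100, genotype=None)
        lib = simulate_library(small_panel, taxa_genomes, DamageModel(), cfg, seed=1)
        assert set(lib.truth.taxon) == {"Theobroma_cacao"}

    def test_contaminant_fraction_binomial(self, small_panel, taxa_genomes):
        model = DamageModel(contamination_fraction=0.3)
        cfg = ItemConfig("it1", 10000, contaminant_taxa=("Zea_mays", "Musa"))
        lib = simulate_library(small_panel, taxa_genomes, model, cfg, seed=2)
        n_contam = (lib.truth.taxon != "Theobroma_cacao").sum()
        assert abs(n_contam - 3000) < 3 * np.sqrt(10000 * 0.3 * 0.7)

    def test_contamination_requires_taxa(self, small_panel, taxa_genomes):
        model = DamageModel(contamination_fraction=0.2)
        with pytest.raises(ValueError):
            simulate_library(small_panel, taxa_genomes, model, ItemConfig("x", 10), seed=3)

    def test_seed_determinism(self, small_panel, taxa_genomes):
        cfg = ItemConfig("it2", 50, contaminant_taxa=("Musa",))
        model = DamageModel(contamination_fraction=0.4)
        a = simulate_library(small_panel, taxa_genomes, model, cfg, seed=9)
        b = simulate_library(small_panel, taxa_genomes, model, cfg, seed=9)
        assert a.r1 == b.r1 and a.r2 == b.r2
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_read_through_geometry(self, small_panel, taxa_genomes):
        """A fragment shorter than the read length reappears, after adapter
        trimming and merging, at exactly its original length."""
        from paleocacao.readproc import run_readproc

        cfg = ItemConfig("it3", 60, genotype=None)
        lib = simulate_library(small_panel, taxa_genomes, DamageModel(), cfg, seed=4)
        reads, _ = run_readproc(lib.r1, lib.r2)
        truth_len = dict(zip(lib.truth.read_id, lib.truth.length))
        merged = [r for r in reads if r.merged]
        assert merged, "expected merged reads from short fragments"
        assert all(len(r.seq) == truth_len[r.id] for r in merged)

    def test_fragment_truth_consistency(self, small_panel, taxa_genomes):
        lib = simulate_library(
            small_panel, taxa_genomes, DamageModel(), ItemConfig("it4", 30), seed=5
        )
        for frag in lib.fragments:
            assert frag.end - frag.start == len(frag.sequence)
            genome = taxa_genomes[frag.taxon][frag.chrom]
            src = genome[frag.start:frag.end]
            oriented = src if frag.strand == "+" else revcomp(src)
            # non-damaged positions must match a personal haplotype of the
            # source; with no genotype, they match the reference exactly
            damaged_pos = {p for p, _, _ in frag.damage}
            for i, (a, b) in enumerate(zip(oriented, frag.sequence)):
                if i not in damaged_pos:
                    assert a == b


class TestMethylxanthine:
    def test_no_positives_stay_below_threshold(self):
        df = simulate_methylxanthine(100, positive_fraction=0.0, seed=1)
        assert (df[list(sim.ANALYTES)] < 700).all().all()

    def test_separated_modes_recovered_exactly(self):
        from paleocacao.chem import call_positive

        df = simulate_methylxanthine(
            326, positive_fraction=0.4, background_scale=50, positive_scale=8000, seed=2
        )
        flags = call_positive(df, threshold=700)
        assert (flags["theobromine"].to_numpy() == df.true_positive.to_numpy()).all()

    def test_overlapping_scales_warn(self):
        with pytest.warns(UserWarning):
            simulate_methylxanthine(50, 0.3, background_scale=150, positive_scale=900, seed=3)

    def test_invalid_scales_rejected(self):
        with pytest.raises(ValueError):
            simulate_methylxanthine(50, 0.3, background_scale=300, positive_scale=8000)
        with pytest.raises(ValueError):
            simulate_methylxanthine(50, 0.3, background_scale=50, positive_scale=500)
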