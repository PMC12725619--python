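"""Window densities, the 5' deficit inputs, context mutabilities."""

import math

import numpy as np
import pytest

from fpm.mutation_analysis import (
    TRINUCS,
    MutationRecord,
    expected_positional_rate,
    five_prime_deficit_inputs,
    genic_intergenic_profiles,
    mononuc_mutability,
    read_catalog,
    trinuc_mutability,
    trinuc_occurrences,
    weak_trinuc_content_by_position,
    window_density,
    window_deviation,
    write_catalog,
)
from fpm.sequence_io import CdsRecord, GenomicInterval, intergenic_intervals
from fpm.stats_tests import chi2_gof_two_cell
from fpm.synthetic_data import (
    GeneratorSpec,
    build_toy_genome,
    gen_cds_set,
    simulate_mutations,
)


@pytest.fixture(scope="module")
def uniform_world():
    """Fixed-length genes in a toy genome plus a uniform mutation catalog."""
    spec = GeneratorSpec(seed=50, n_genes=150, gene_length_codons=(120, 120),
                         n_mutations=20000)
    records = gen_cds_set(spec)
    genome, placed = build_toy_genome(records, seed=51, minus_fraction=0.5)
    catalog = simulate_mutations(genome, spec, placed)
    return genome, placed, catalog


class TestWindowDensity:
    def test_bp_conservation(self, uniform_world):
        _, placed, catalog = uniform_world
        ws = window_density(catalog, placed)
        total_bp = sum(w.bp for w in ws)
        # all windows together tile every codon after the start codon
        expected = sum(len(r.sequence) - 3 for r in placed)
        assert total_bp == expected
        for w in ws:
            assert w.density_per_kb == pytest.approx(1000 * w.mutations / w.bp)

    def test_uniform_catalog_flat_within_noise(self, uniform_world):
        _, placed, catalog = uniform_world
        ws = window_density(catalog, placed)
        dens = np.array([w.density_per_kb for w in ws])
        assert dens.std() / dens.mean() < 0.1

    def test_empty_catalog_zero(self, uniform_world):
        _, placed, _ = uniform_world
        assert all(w.mutations == 0 for w in window_density([], placed))

    def test_half_rate_first_window(self):
        spec = GeneratorSpec(
            seed=52, n_genes=150, gene_length_codons=(120, 120), n_mutations=30000,
            positional_subst_multiplier={p: 0.5 for p in range(2, 12)},
        )
        records = gen_cds_set(spec)
        genome, placed = build_toy_genome(records, seed=53, spacer_bp=30)
        catalog = simulate_mutations(genome, spec, placed)
        ws = window_density(catalog, placed)
        first = ws[0].density_per_kb
        deep = np.mean([w.density_per_kb for w in ws if w.start_codon > 70])
        assert first / deep == pytest.approx(0.5, abs=0.08)


class TestWindowDeviation:
    def test_uniform_near_zero(self, uniform_world):
        _, placed, catalog = uniform_world
        ws = window_deviation(catalog, placed)
        assert max(abs(w.o_minus_e_over_e) for w in ws) < 0.1

    def test_all_mutations_in_first_window_forced(self):
        recs = [CdsRecord("g0", "ATG" + "GGC" * 39, GenomicInterval("c", 0, 120, "+"))]
        genome = {"c": recs[0].sequence}
        catalog = [MutationRecord("c", 5, recs[0].sequence[5], "A" if recs[0].sequence[5] != "A" else "C")]
        ws = window_deviation(catalog, recs)
        n, e1 = 1, 1 * ws[0].bp / sum(w.bp for w in ws)
        assert ws[0].o_minus_e_over_e == pytest.approx((n - e1) / e1)
        assert all(w.o_minus_e_over_e == pytest.approx(-1.0) for w in ws[1:])

    def test_invariant_under_catalog_duplication(self, uniform_world):
        _, placed, catalog = uniform_world
        a = window_deviation(catalog, placed)
        b = window_deviation(list(catalog) + list(catalog), placed)
        assert [w.o_minus_e_over_e for w in a] == pytest.approx(
            [w.o_minus_e_over_e for w in b]
        )


class TestFivePrimeDeficit:
    def test_uniform_observed_near_expected(self, uniform_world):
        _, placed, catalog = uniform_world
        obs, exp, total = five_prime_deficit_inputs(catalog, placed)
        res = chi2_gof_two_cell(obs, exp, total)
        assert abs(obs - exp) / exp < 0.15
        assert res.p_value > 1e-4

    def test_half_rate_five_prime_detected(self):
        spec = GeneratorSpec(
            seed=54, n_genes=120, gene_length_codons=(120, 120), n_mutations=30000,
            positional_subst_multiplier={p: 0.5 for p in range(2, 12)},
        )
        records = gen_cds_set(spec)
        genome, placed = build_toy_genome(records, seed=55, spacer_bp=30)
        catalog = simulate_mutations(genome, spec, placed)
        obs, exp, total = five_prime_deficit_inputs(catalog, placed)
        assert obs < exp
        assert chi2_gof_two_cell(obs, exp, total).p_value < 1e-6


class TestContextMutability:
    def test_occurrence_counting_slides_by_one(self):
        occ = trinuc_occurrences({"c": "AAAA"})
        assert occ["AAA"] == 2

    def test_enriched_context_ranks_first(self):
        mut = {t: (10.0 if t == "GCC" else 1.0) for t in TRINUCS}
        spec = GeneratorSpec(seed=56, n_mutations=30000, trinuc_mutability=mut)
        from fpm.synthetic_data import gen_random_genome

        genome = gen_random_genome(60000, at=0.5, seed=57)
        catalog = simulate_mutations(genome, spec)
        prof = trinuc_mutability(catalog, genome)
        assert prof.rank_order()[0] == "GCC"

    def test_uniform_mutability_flat(self):
        from fpm.synthetic_data import gen_random_genome

        spec = GeneratorSpec(seed=58, n_mutations=60000)
        genome = gen_random_genome(50000, at=0.5, seed=59)
        catalog = simulate_mutations(genome, spec)
        prof = trinuc_mutability(catalog, genome)
        freqs = np.array([v[2] for v in prof.entries.values()])
        assert freqs.std() / freqs.mean() < 0.15

    def test_trinuc_collapse_to_mononucleotide(self, uniform_world):
        genome, _, catalog = uniform_world
        tri = trinuc_mutability(catalog, genome)
        mono = mononuc_mutability(catalog, genome)
        for b in "ACGT":
            tri_counts = sum(v[0] for t, v in tri.entries.items() if t[1] == b)
            tri_occ = sum(v[1] for t, v in tri.entries.items() if t[1] == b)
            # occurrence-weighted average of the 16 contexts sharing a
            # central base equals the mononucleotide frequency (edge bases
            # lack a full context on exactly one side, hence the tolerance)
            assert tri_counts / tri_occ == pytest.approx(mono[b][2], rel=0.01)

    def test_mono_count_conservation(self, uniform_world):
        genome, _, catalog = uniform_world
        mono = mononuc_mutability(catalog, genome)
        assert sum(v[0] for v in mono.values()) == len(catalog)

    def test_region_smaller_than_context_rejected(self):
        with pytest.raises(ValueError):
            trinuc_mutability([], {"c": "ACGT"}, [GenomicInterval("c", 0, 2)])


class TestExpectedPositionalRate:
    def test_uniform_profile_flat(self, uniform_world):
        _, placed, catalog = uniform_world
        mut = {t: 0.001 for t in TRINUCS}
        from fpm.mutation_analysis import TrinucProfile

        prof = expected_positional_rate(
            placed, TrinucProfile({t: (0, 1, 0.001) for t in TRINUCS}), "all_sites", 40
        )
        # codon 1's first base has no left flank, so only interior codons
        # carry the full three contexts
        interior = prof.values[(prof.positions >= 2) & (prof.positions < 40)]
        assert np.allclose(interior, 3 * 0.001)

    def test_gc_mutable_at_rich_5prime_low(self):
        # GC-context-mutable process + AT-rich 5' composition -> expected
        # rate low at 5', rising to a plateau (the substitution-rate shape)
        mut = {t: (0.004 if (t.count("G") + t.count("C")) >= 2 else 0.001) for t in TRINUCS}
        from fpm.mutation_analysis import TrinucProfile

        spec = GeneratorSpec(seed=60, n_genes=600, gene_length_codons=(100, 120),
                             at5=0.8, at_core=0.35, ramp_end_codon=30)
        records = gen_cds_set(spec)
        prof = expected_positional_rate(
            records, TrinucProfile({t: (0, 1, mut[t]) for t in TRINUCS}),
            "fourfold_third_central", 80,
        )
        d = prof.as_dict()
        five = np.mean([d[p] for p in range(2, 12)])
        deep = np.mean([d[p] for p in range(40, 80)])
        assert five < deep

    def test_predicts_realized_positional_density(self):
        # self-consistency: expected profile correlates with the realized
        # mutation density per window under the same context process
        mut = {t: (0.005 if t[1] in "GC" else 0.001) for t in TRINUCS}
        spec = GeneratorSpec(seed=61, n_genes=200, gene_length_codons=(90, 90),
                             n_mutations=40000, trinuc_mutability=mut,
                             at5=0.75, at_core=0.4, ramp_end_codon=25)
        records = gen_cds_set(spec)
        genome, placed = build_toy_genome(records, seed=62, spacer_bp=30)
        catalog = simulate_mutations(genome, spec, placed)
        from fpm.mutation_analysis import TrinucProfile

        exp_prof = expected_positional_rate(
            placed, TrinucProfile({t: (0, 1, mut[t]) for t in TRINUCS}), "all_sites", 85
        )
        ws = window_density(catalog, placed, window_codons=5)
        # average the expected profile into the same windows
        d = exp_prof.as_dict()
        exp_w, obs_w = [], []
        for w in ws:
            vals = [d[p] for p in range(w.start_codon, w.end_codon + 1) if p in d]
            if vals:
                exp_w.append(np.mean(vals))
                obs_w.append(w.density_per_kb)
        r = np.corrcoef(exp_w, obs_w)[0, 1]
        assert r > 0.9


class TestGenicIntergenic:
    def test_identical_process_t_near_zero(self, uniform_world):
        genome, placed, catalog = uniform_world
        feats = [r.interval for r in placed]
        inter = intergenic_intervals(feats, {c: len(s) for c, s in genome.items()})
        genic, interp, stat = genic_intergenic_profiles(catalog, feats, inter, genome)
        assert abs(stat["t"]) < 3
        assert stat["n_pairs"] > 40

    def test_doubled_intergenic_rate_detected(self):
        spec = GeneratorSpec(seed=63, n_genes=100, gene_length_codons=(100, 100),
                             n_mutations=30000)
        records = gen_cds_set(spec)
        genome, placed = build_toy_genome(records, seed=64, spacer_bp=300)
        feats = [r.interval for r in placed]
        inter = intergenic_intervals(feats, {c: len(s) for c, s in genome.items()})
        # double the weight of intergenic sites via positional multiplier of
        # genes at 0.5 (equivalently intergenic at 2x)
        spec2 = GeneratorSpec(seed=63, n_genes=100, gene_length_codons=(100, 100),
                              n_mutations=30000,
                              positional_subst_multiplier={p: 0.5 for p in range(1, 101)})
        catalog = simulate_mutations(genome, spec2, placed)
        genic, interp, stat = genic_intergenic_profiles(catalog, feats, inter, genome)
        assert stat["t"] > 5  # intergenic minus genic strongly positive
        assert stat["p_value"] < 1e-5


class TestWeakTrinucContent:
    def test_all_at_genes_full(self):
        recs = [CdsRecord("g", "ATG" + "AAA" * 20 + "TAA")]
        prof = weak_trinuc_content_by_position(recs, 15)
        assert np.all(prof.values[prof.positions >= 2] == 1.0)

    def test_gc_flanks_zero(self):
        recs = [CdsRecord("g", "ATG" + "GGC" * 20 + "TAA")]
        prof = weak_trinuc_content_by_position(recs, 15)
        assert np.all(prof.values[prof.positions >= 2] == 0.0)

    def test_at_rich_5prime_elevated(self):
        spec = GeneratorSpec(seed=65, n_genes=800, gene_length_codons=(80, 100),
                             at5=0.8, at_core=0.35, ramp_end_codon=20)
        prof = weak_trinuc_content_by_position(gen_cds_set(spec), 70)
        d = prof.as_dict()
        assert np.mean([d[p] for p in range(3, 11)]) > np.mean([d[p] for p in range(40, 70)])


class TestCatalogIO:
    def test_round_trip_and_reference_check(self, tmp_path, uniform_world):
        genome, _, catalog = uniform_world
        path = tmp_path / "cat.tsv"
        write_catalog(catalog[:100], path)
        back = read_catalog(path, genome)
        assert [(m.contig, m.position, m.ancestral, m.derived) for m in back] == [
            (m.contig, m.position, m.ancestral, m.derived) for m in catalog[:100]
        ]

    def test_mismatching_reference_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("contig\tposition\tancestral\tderived\nc\t1\tG\tT\n")
        with pytest.raises(ValueError):
            read_catalog(path, {"c": "AAAA"})
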