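"""Generator contracts: base composition, exact SNP injection, cohort
structure, read mixtures and sample QC."""

import numpy as np
import pytest
from scipy import stats

from straindyad import (
    CohortConfig,
    derive_strain,
    generate_ancestral_genome,
    qc_filter_samples,
    simulate_cohort,
    simulate_reads,
)
from straindyad.errors import ParameterError
from straindyad.simcohort import transmission_probability

from conftest import hamming


class TestAncestralGenome:
    @pytest.mark.parametrize(
        "length,gc",
        [(100_000, 0.5941), (10_000, 0.25), (1000, 0.5)],
    )
    def test_length_and_gc(self, length, gc):
        g = generate_ancestral_genome(length, gc, seed=1)
        assert len(g) == length
        counts = np.bincount(g.codes, minlength=4)
        realized_gc = (counts[1] + counts[2]) / length
        assert abs(realized_gc - gc) <= 0.01
        assert set(g.sequence) <= set("ACGT")

    def test_deterministic(self):
        a = generate_ancestral_genome(1000, 0.5, seed=1)
        b = generate_ancestral_genome(1000, 0.5, seed=1)
        assert a.sequence == b.sequence
        c = generate_ancestral_genome(1000, 0.5, seed=2)
        assert c.sequence != a.sequence

    @pytest.mark.parametrize("length,gc", [(0, 0.5), (999, 0.5), (1000, 0.0), (1000, 1.0)])
    def test_parameter_errors(self, length, gc):
        with pytest.raises(ParameterError):
            generate_ancestral_genome(length, gc, seed=1)


class TestDeriveStrain:
    def test_exact_hamming(self, genome_100k):
        child, positions = derive_strain(genome_100k, 20, seed=2)
        assert hamming(genome_100k, child) == 20
        assert positions == sorted(positions)
        assert len(set(positions)) == 20
        assert child.lineage_id == genome_100k.lineage_id
        diff = sorted(np.flatnonzero(genome_100k.codes != child.codes).tolist())
        assert diff == positions

    def test_zero_snps(self, genome_100k):
        child, positions = derive_strain(genome_100k, 0, seed=5)
        assert child.sequence == genome_100k.sequence
        assert positions == []

    def test_exact_ani_arithmetic(self, genome_50k):
        from straindyad import exact_ani_oracle

        child, _ = derive_strain(genome_50k, 61, seed=9)
        assert exact_ani_oracle(genome_50k, child) == pytest.approx(
            100 * (1 - 61 / 50_000), abs=1e-9
        )

    def test_too_many_snps(self, genome_50k):
        with pytest.raises(ParameterError):
            derive_strain(genome_50k, 50_001, seed=1)

    def test_composition_at_disjoint_positions(self, genome_100k):
        """Two derivation steps at disjoint positions add their distances."""
        child, p1 = derive_strain(genome_100k, 30, seed=11)
        grandchild, p2 = derive_strain(child, 40, seed=12)
        assert not (set(p1) & set(p2))  # w.h.p. on 100 kb; fixed seeds
        assert hamming(genome_100k, grandchild) == 70


class TestSimulateCohort:
    def test_transmitted_pairs_within_range(self, small_cohort):
        by_id = {g.genome_id: g for g in small_cohort.strains}
        lo, hi = small_cohort.config.transmitted_snp_range
        assert small_cohort.true_transmissions
        for t in small_cohort.true_transmissions:
            d = hamming(by_id[t.mother_genome_id], by_id[t.infant_genome_id])
            assert lo <= d <= hi
            assert d == t.n_snps
            assert by_id[t.mother_genome_id].lineage_id == by_id[t.infant_genome_id].lineage_id

    def test_non_transmitted_are_distant(self, small_cohort):
        by_indiv = {}
        for g in small_cohort.strains:
            by_indiv.setdefault(g.individual_id, []).append(g)
        for dyad in small_cohort.dyads:
            if small_cohort.is_transmitted(dyad.dyad_id, "sp1"):
                continue
            m = by_indiv[dyad.mother_id][0]
            i = by_indiv[dyad.infant_id][0]
            assert hamming(m, i) >= 1000
            assert m.lineage_id != i.lineage_id

    def test_deterministic_and_seed_sensitivity(self):
        cfg = dict(n_dyads=2, species=("sp1",), genome_length=20_000)
        a = simulate_cohort(CohortConfig(seed=7, **cfg))
        b = simulate_cohort(CohortConfig(seed=7, **cfg))
        c = simulate_cohort(CohortConfig(seed=8, **cfg))
        assert [g.sequence for g in a.strains] == [g.sequence for g in b.strains]
        assert a.abundances == b.abundances
        assert any(
            x.sequence != y.sequence for x, y in zip(a.strains, c.strains)
        )

    def test_forced_transmission(self):
        truth = simulate_cohort(
            CohortConfig(n_dyads=1, species=("sp1",), transmitted_fraction=1.0, seed=4)
        )
        assert len(truth.true_transmissions) == 1

    def test_overlapping_ranges_rejected(self):
        with pytest.raises(ParameterError):
            CohortConfig(transmitted_snp_range=(3, 5000), distinct_snp_range=(3000, 10000))

    def test_covariate_conditioned_rates(self):
        effects = {"delivery_mode": {"vaginal": 0.6, "caesarean": 0.05}}
        truth = simulate_cohort(
            CohortConfig(n_dyads=50, species=("sp1",), covariate_effects=effects, seed=11)
        )
        by_mode = {"vaginal": [0, 0], "caesarean": [0, 0]}
        for d in truth.dyads:
            mode = d.covariates["delivery_mode"]
            by_mode[mode][1] += 1
            by_mode[mode][0] += truth.is_transmitted(d.dyad_id, "sp1")
        for mode, p in (("vaginal", 0.6), ("caesarean", 0.05)):
            k, n = by_mode[mode]
            if n == 0:
                continue
            lo, hi = stats.binom.interval(0.95, n, p)
            assert lo <= k <= hi, f"{mode}: {k}/{n} outside 95% CI of p={p}"

    def test_effect_table_probability(self):
        cfg = CohortConfig(
            covariate_effects={"delivery_mode": {"vaginal": 0.6, "caesarean": 0.05}}
        )
        assert transmission_probability(cfg, {"delivery_mode": "vaginal"}) == 0.6
        assert transmission_probability(cfg, {"delivery_mode": "caesarean"}) == 0.05

    def test_abundances_valid(self, small_cohort):
        for sample, profile in small_cohort.abundances.items():
            assert all(0 <= v <= 1 for v in profile.values())
            assert sum(profile.values()) <= 1 + 1e-9


class TestSimulateReads:
    def test_error_free_reads_are_substrings(self, genome_100k):
        rs = simulate_reads({genome_100k: 1.0}, 100, read_length=150, error_rate=0.0, seed=1)
        assert len(rs) == 100
        for _rid, seq, qual in rs.reads:
            assert len(seq) == len(qual) == 150
            assert seq in genome_100k.sequence
        assert sum(rs.truth_composition.values()) == pytest.approx(1.0)

    def test_multinomial_proportions(self, genome_100k, genome_50k):
        rs = simulate_reads({genome_100k: 0.9, genome_50k: 0.1}, 10_000,
                            read_length=100, seed=2)
        # expected fraction weights abundance by genome length
        w100 = 0.9 * 100_000
        p100 = w100 / (w100 + 0.1 * 50_000)
        counts = {}
        for rid, seq, _ in rs.reads:
            counts[seq in genome_100k.sequence] = counts.get(seq in genome_100k.sequence, 0) + 1
        lo, hi = stats.binom.interval(0.99, 10_000, p100)
        assert lo <= counts[True] <= hi
        assert rs.truth_composition["ref100k"] == pytest.approx(p100)

    def test_empty_cases(self, genome_100k):
        assert len(simulate_reads({genome_100k: 1.0}, 0)) == 0
        with pytest.raises(ParameterError):
            simulate_reads({}, 10)
        with pytest.raises(ParameterError):
            simulate_reads({genome_100k: 0.0}, 10)

    def test_deterministic(self, genome_100k):
        a = simulate_reads({genome_100k: 1.0}, 50, seed=3)
        b = simulate_reads({genome_100k: 1.0}, 50, seed=3)
        assert a.reads == b.reads


class TestDeriveStrainProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(n_snps=st.integers(0, 200), seed=st.integers(0, 2**20))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_hamming_always_exact(self, n_snps, seed):
        g = generate_ancestral_genome(2000, 0.5941, 77)
        child, positions = derive_strain(g, n_snps, seed)
        assert hamming(g, child) == n_snps
        assert len(positions) == n_snps
        assert positions == sorted(set(positions))

    @given(gc=st.floats(0.05, 0.95), seed=st.integers(0, 2**20))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_gc_always_within_tolerance(self, gc, seed):
        g = generate_ancestral_genome(1000, gc, seed)
        assert abs(g.gc_content() - gc) <= 0.01


class TestQCFilter:
    def test_threshold_boundary(self):
        assert qc_filter_samples({"A": 99_999, "B": 100_000}) == {"B"}

    def test_all_zero(self):
        assert qc_filter_samples({"A": 0, "B": 0}) == set()

    def test_singleton_rule(self):
        counts = {"mother": 150_000, "infant": 50_000, "m2": 120_000, "i2": 130_000}
        retained = qc_filter_samples(counts, dyad_pairs=[("mother", "infant"), ("m2", "i2")])
        assert retained == {"m2", "i2"}
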