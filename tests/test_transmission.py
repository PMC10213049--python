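"""Per-method call rules, OR-integration, overlap tables, dominance and
cohort summaries."""

import numpy as np
import pytest
from skbio import TreeNode

from straindyad import (
    CohortConfig,
    DistanceMatrix,
    call_isolate_transmission,
    call_npd_transmission,
    call_popani_transmission,
    classify_dominance,
    integrate_calls,
    method_overlap,
    simulate_cohort,
    summarize_cohort,
)
from straindyad.errors import InputError
from straindyad.popani import PopANIResult
from straindyad.simcohort import Genome
from straindyad.transmission import TransmissionCall, detection_limit_summary


def _matrix(taxa, pairs, kind, diag):
    n = len(taxa)
    values = np.full((n, n), diag, dtype=float)
    np.fill_diagonal(values, 100.0 if kind == "ani_percent" else 0.0)
    idx = {t: i for i, t in enumerate(taxa)}
    for (a, b), v in pairs.items():
        values[idx[a], idx[b]] = values[idx[b], idx[a]] = v
    return DistanceMatrix(taxa, values, kind)


@pytest.fixture()
def dyad_setting():
    """Mother M and infant I as a cherry; outgroup pair X, Y."""
    tree = TreeNode.read(["((M:10,I:12):3000,(X:8,Y:9):3000);"])
    snp = _matrix(["M", "I", "X", "Y"],
                  {("M", "I"): 22, ("M", "X"): 7000, ("M", "Y"): 7000,
                   ("I", "X"): 7000, ("I", "Y"): 7000, ("X", "Y"): 17},
                  "snp_count", 7000.0)
    return tree, snp


class TestIsolateCall:
    def _ani(self, value):
        return _matrix(["M", "I", "X", "Y"], {("M", "I"): value}, "ani_percent", 91.0)

    def test_transmitted_pair(self, dyad_setting):
        tree, snp = dyad_setting
        flag, support = call_isolate_transmission(["M"], ["I"], self._ani(99.96), snp, tree)
        assert flag is True
        assert support["ani"] == 99.96
        assert support["snp"] == 22
        assert support["monophyletic"] is True

    def test_snp_boundary_strict(self, dyad_setting):
        tree, _ = dyad_setting
        snp = _matrix(["M", "I", "X", "Y"], {("M", "I"): 200}, "snp_count", 7000.0)
        flag, support = call_isolate_transmission(["M"], ["I"], self._ani(99.95), snp, tree)
        assert flag is False
        snp199 = _matrix(["M", "I", "X", "Y"], {("M", "I"): 199}, "snp_count", 7000.0)
        flag, _ = call_isolate_transmission(["M"], ["I"], self._ani(99.95), snp199, tree)
        assert flag is True

    def test_distinct_lineage_fails_before_tree(self, dyad_setting):
        tree, _ = dyad_setting
        snp = _matrix(["M", "I", "X", "Y"], {("M", "I"): 7828}, "snp_count", 7000.0)
        flag, support = call_isolate_transmission(["M"], ["I"], self._ani(98.7), snp, tree)
        assert flag is False
        assert support["monophyletic"] is None  # tree never consulted

    def test_non_monophyletic_pair_fails(self, dyad_setting):
        tree, snp = dyad_setting
        # M with Y: high ANI but not a clade on the tree
        ani = _matrix(["M", "I", "X", "Y"], {("M", "Y"): 99.95}, "ani_percent", 91.0)
        snp_my = _matrix(["M", "I", "X", "Y"], {("M", "Y"): 30}, "snp_count", 7000.0)
        flag, support = call_isolate_transmission(["M"], ["Y"], ani, snp_my, tree)
        assert flag is False
        assert support["monophyletic"] is False

    def test_missing_isolate_absent(self, dyad_setting):
        tree, snp = dyad_setting
        flag, support = call_isolate_transmission([], ["I"], self._ani(99.9), snp, tree)
        assert flag is None
        assert support == {}


class TestNpdCall:
    def _npd(self, value):
        return _matrix(["Ms", "Is"], {("Ms", "Is"): value}, "npd", 0.5)

    def test_share(self):
        flag, support = call_npd_transmission(["Ms"], ["Is"], self._npd(0.0004))
        assert flag is True
        assert support["npd"] == 0.0004

    def test_above_threshold(self):
        flag, _ = call_npd_transmission(["Ms"], ["Is"], self._npd(0.002))
        assert flag is False

    def test_missing_leaf_absent(self):
        flag, support = call_npd_transmission(["Ms"], ["missing"], self._npd(0.0004))
        assert flag is None and support == {}

    def test_unprofiled_absent(self):
        flag, _ = call_npd_transmission(["Ms"], ["Is"], None)
        assert flag is None


class TestPopaniCall:
    def test_passing_pair_with_direction(self):
        res = PopANIResult("V01_vag", "I01_stool", "ref", 99.9997, 1_000_000, 3, 80.0, 75.0)
        flag, support = call_popani_transmission(
            [res], sample_types={"V01_vag": "vaginal", "I01_stool": "infant_stool"})
        assert flag is True
        assert support["source_sample_type"] == "vaginal"

    def test_low_breadth_fails(self):
        res = PopANIResult("M", "I", "ref", 100.0, 60_000, 0, 45.0, 48.0)
        flag, _ = call_popani_transmission([res])
        assert flag is False

    def test_no_profiled_pair_absent(self):
        flag, support = call_popani_transmission([])
        assert flag is None and support == {}


class TestIntegration:
    def _evidence(self, isolate, popani, npd):
        return {
            "isolate": (isolate, {"ani": 99.9} if isolate is not None else {}),
            "popani": (popani, {"popani": 99.9999} if popani is not None else {}),
            "npd": (npd, {"npd": 0.0005} if npd is not None else {}),
        }

    def test_or_semantics(self):
        calls = integrate_calls({("D1", "sp"): self._evidence(True, None, False)})
        assert len(calls) == 1
        assert calls[0].transmitted is True
        assert calls[0].evidence == {"isolate": True, "popani": None, "npd": False}

    def test_all_absent_emits_nothing(self):
        calls = integrate_calls({("D1", "sp"): self._evidence(None, None, None)})
        assert calls == []

    def test_transmitted_equals_or_invariant(self):
        with pytest.raises(InputError):
            TransmissionCall("D1", "sp", {"isolate": False, "popani": None, "npd": None},
                             transmitted=True)


class TestMethodOverlap:
    def _call(self, dyad, methods):
        evidence = {m: (m in methods) for m in ("isolate", "popani", "npd")}
        return TransmissionCall(dyad, "sp", evidence, any(evidence.values()))

    def test_disjoint_single_methods(self):
        calls = [self._call("D1", {"isolate"}), self._call("D2", {"popani"}),
                 self._call("D3", {"npd"})]
        o = method_overlap(calls)
        assert o["marginals"] == {"isolate": 1, "popani": 1, "npd": 1}
        assert o["subset_counts"]["isolate+popani+npd"] == 0
        assert o["total"] == 3

    def test_mixed_subsets(self):
        calls = [self._call("D1", {"isolate", "popani"}),
                 self._call("D2", {"isolate"}),
                 self._call("D3", {"isolate", "popani", "npd"})]
        o = method_overlap(calls)
        assert o["marginals"]["isolate"] == 3
        assert o["subset_counts"]["isolate+popani"] == 1
        assert sum(o["subset_counts"].values()) == o["total"] == 3

    def test_marginal_dominates_subsets(self):
        calls = [self._call(f"D{i}", s) for i, s in
                 enumerate([{"isolate"}, {"isolate", "npd"}, {"npd"}, {"popani", "npd"}])]
        o = method_overlap(calls)
        for key, count in o["subset_counts"].items():
            for m in key.split("+"):
                assert o["marginals"][m] >= count


class TestDominance:
    def _isolate(self, species="sp1"):
        return Genome("g1", "ACGT" * 300, "M01", "maternal_stool", species, "L1")

    def test_dominant(self):
        label = classify_dominance(self._isolate(), {"sp1": 0.05, "sp2": 0.02})
        assert label.label == "dominant"

    def test_non_dominant(self):
        label = classify_dominance(self._isolate(), {"sp1": 0.001, "sp2": 0.02})
        assert label.label == "non_dominant"

    def test_not_detected(self):
        label = classify_dominance(self._isolate(), {"sp1": 0.0, "sp2": 0.0})
        assert label.label == "not_detected"

    def test_tie_is_dominant(self):
        label = classify_dominance(self._isolate(), {"sp1": 0.02, "sp2": 0.02})
        assert label.label == "dominant"

    def test_missing_profile_absent(self):
        assert classify_dominance(self._isolate(), None) is None


class TestSummaries:
    def test_empty(self):
        s = summarize_cohort([], n_dyads=10)
        assert s["n_events"] == 0
        assert s["pct_dyads_with_event"] == 0.0

    def test_dyad_fraction(self):
        calls = [
            TransmissionCall(f"D{i:03d}", "sp",
                             {"isolate": True, "popani": None, "npd": None}, True)
            for i in range(66)
        ]
        s = summarize_cohort(calls, n_dyads=135)
        assert s["n_dyads_with_event"] == 66
        assert s["pct_dyads_with_event"] == pytest.approx(48.888, abs=0.01)

    def test_detection_limits_monotone(self):
        truth = simulate_cohort(CohortConfig(n_dyads=4, species=("sp1",),
                                             transmitted_fraction=1.0, seed=21))
        calls = []
        for t in truth.true_transmissions:
            calls.append(TransmissionCall(
                t.dyad_id, t.species,
                {"isolate": True, "popani": False, "npd": None}, True))
        table = detection_limit_summary(truth, calls)
        iso = table.set_index("method").loc["isolate"]
        assert iso["n_detected"] == 4
        # isolate detection is abundance-independent: its minimum equals the
        # smallest simulated abundance among true events
        abundances = [
            min(truth.abundances[f"M{d:03d}_stool"]["sp1"],
                truth.abundances[f"I{d:03d}_stool"]["sp1"])
            for d in range(4)
        ]
        assert iso["min_abundance_detected"] == pytest.approx(min(abundances))
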