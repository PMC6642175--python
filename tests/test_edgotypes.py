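"""Edgotype calls, gamma estimation and the comparative statistics."""

import math

import numpy as np
import pytest
from scipy.special import comb

from edgotype.edgotypes import (
    DDGRecord,
    EdgeticCounts,
    call_edgotypes,
    compare_scores,
    estimate_gamma,
    fisher_edgetic_comparison,
    geometry_edgotype,
    pam30_score,
    physics_edgotype,
    tally_counts,
)
from edgotype.interactome import StructuralPPI
from edgotype.mutations import MappedMutation, MutationRecord


def _mapped(mid="M1", pid="P1", pos=5, cls="disease"):
    seq = "A" * 20
    rec = MutationRecord(mid, pid, seq, pos, "A", "G", cls)
    return MappedMutation(rec, pos)


def _ppi(pa, pb, iface_a, iface_b):
    return StructuralPPI(pa, pb, frozenset(iface_a), frozenset(iface_b))


SI = [
    _ppi("P1", "P2", {5, 6}, {1}),
    _ppi("P1", "P3", {5, 9}, {2}),
    _ppi("P1", "P4", {12}, {3}),
]


class TestGeometryCall:
    def test_multi_interface_membership(self):
        call = geometry_edgotype(_mapped(pos=5), SI)
        assert call.is_edgetic
        assert call.disrupted_ppis == {("P1", "P2"), ("P1", "P3")}
        assert not call.mono_edgetic

    def test_off_interface(self):
        call = geometry_edgotype(_mapped(pos=7), SI)
        assert not call.is_edgetic and call.label == "non_edgetic"

    def test_mono_edgetic_flag(self):
        call = geometry_edgotype(_mapped(pos=12), SI)
        assert call.mono_edgetic

    def test_invariant_to_ppi_order(self):
        fwd = geometry_edgotype(_mapped(pos=5), SI)
        rev = geometry_edgotype(_mapped(pos=5), SI[::-1])
        assert fwd.disrupted_ppis == rev.disrupted_ppis

    def test_full_agreement_with_generator_truth(self, small_world):
        from edgotype.pipeline import analyze_world

        analysis = analyze_world(small_world, method="geometry")
        for call in analysis.calls:
            truth = small_world.truth[call.mutation.record.mutation_id]
            assert call.is_edgetic == truth["interfacial"]
            assert call.disrupted_ppis == {tuple(k) for k in truth["ppis"]}


class TestPhysicsCall:
    def test_threshold_is_strict(self):
        ddg = [DDGRecord("M1", "P1", "P2", 0.5)]
        call = physics_edgotype(_mapped(pos=5), SI, ddg)
        assert not call.is_edgetic

    def test_mixed_records_mono_edgetic(self):
        ddg = [DDGRecord("M1", "P1", "P2", 0.3), DDGRecord("M1", "P1", "P3", 0.9)]
        call = physics_edgotype(_mapped(pos=5), SI, ddg)
        assert call.is_edgetic and call.mono_edgetic

    def test_missing_ddg_excluded_from_denominator(self):
        calls = call_edgotypes([_mapped(pos=5)], SI, method="physics", ddg_table=[])
        assert calls == []  # interfacial but no ΔΔG: dropped from physics counts

    def test_noninterfacial_kept_as_non_edgetic(self):
        calls = call_edgotypes([_mapped(pos=7)], SI, method="physics", ddg_table=[])
        assert len(calls) == 1 and not calls[0].is_edgetic

    def test_nonconsistent_record_rejected(self):
        ddg = [DDGRecord("M1", "P1", "P4", 2.0)]  # position 5 not on P1-P4 interface
        with pytest.raises(ValueError):
            physics_edgotype(_mapped(pos=5), SI, ddg)

    def test_physics_subset_of_geometry(self, small_world):
        from edgotype.pipeline import analyze_world

        geo = {
            c.mutation.record.mutation_id: c.disrupted_ppis
            for c in analyze_world(small_world, method="geometry").calls
        }
        for call in analyze_world(small_world, method="physics").calls:
            assert call.disrupted_ppis <= geo[call.mutation.record.mutation_id]

    def test_counts_match_direct_tally(self, small_world):
        from edgotype.pipeline import analyze_world

        analysis = analyze_world(small_world, method="geometry")
        k_M = sum(
            1
            for c in analysis.calls
            if c.mutation.mutation_class == "disease" and c.is_edgetic
        )
        assert analysis.counts.k_M == k_M


class TestEstimateGamma:
    def test_fraction_and_binomial_se(self):
        muts = [_mapped(mid=f"M{i}", cls="disease") for i in range(10)]
        ddg = [
            DDGRecord(f"M{i}", "P1", "P2", 1.0 if i < 6 else 0.0) for i in range(10)
        ]
        gamma, se = estimate_gamma(ddg, muts, "disease")
        assert gamma == pytest.approx(0.6)
        assert se == pytest.approx(math.sqrt(0.6 * 0.4 / 10))

    def test_all_below_threshold(self):
        muts = [_mapped(mid="M1", cls="non_disease")]
        ddg = [DDGRecord("M1", "P1", "P2", 0.1)]
        gamma, _ = estimate_gamma(ddg, muts, "non_disease")
        assert gamma == 0.0

    def test_empty_class_raises(self):
        with pytest.raises(ValueError):
            estimate_gamma([], [_mapped()], "disease")


class TestPAM30:
    @pytest.mark.parametrize(
        "pair,score",
        [(("A", "A"), 6), (("W", "W"), 13), (("C", "C"), 10), (("A", "R"), -7),
         (("R", "K"), 0)],
    )
    def test_canonical_matrix_entries(self, pair, score):
        assert pam30_score(*pair) == score

    def test_symmetry(self):
        for a, b in [("A", "W"), ("D", "K"), ("F", "Y")]:
            assert pam30_score(a, b) == pam30_score(b, a)

    def test_ambiguous_codes_rejected(self):
        with pytest.raises(KeyError):
            pam30_score("B", "A")


class TestBootstrapComparison:
    def test_identical_groups_give_p_one(self):
        scores = [1.0, 2.0, 3.0, 4.0]
        p = compare_scores(scores, scores, n_resamples=2000, seed=0)
        assert p == pytest.approx(1.0, abs=0.01)

    def test_separated_gaussians_detected(self):
        rng = np.random.default_rng(42)
        a = rng.normal(0.0, 1.0, size=500)
        b = rng.normal(3.0, 1.0, size=500)  # 3 SD shift
        p = compare_scores(a, b, n_resamples=100_000, seed=1)
        assert p < 1e-4

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(size=50), rng.normal(0.5, 1, size=60)
        p1 = compare_scores(a, b, n_resamples=5000, seed=3)
        p2 = compare_scores(a, b, n_resamples=5000, seed=3)
        assert p1 == p2


class TestFisher:
    def test_identical_margins(self):
        assert fisher_edgetic_comparison(EdgeticCounts(0, 10, 0, 10)) == 1.0

    def test_published_counts_significant(self):
        assert fisher_edgetic_comparison(EdgeticCounts(19, 376, 27, 145)) < 1e-4

    def test_matches_hypergeometric_enumeration(self):
        counts = EdgeticCounts(1, 5, 4, 5)
        # enumerate the hypergeometric support of the 2x2 table directly
        n1, n2 = counts.n_N, counts.n_M
        k_total = counts.k_N + counts.k_M
        denom = comb(n1 + n2, k_total)
        probs = {
            a: comb(n1, a) * comb(n2, k_total - a) / denom
            for a in range(max(0, k_total - n2), min(n1, k_total) + 1)
        }
        p_obs = probs[counts.k_N]
        expected = sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))
        assert fisher_edgetic_comparison(counts) == pytest.approx(expected)


def test_counts_validation():
    with pytest.raises(ValueError):
        EdgeticCounts(5, 4, 0, 10)
    with pytest.raises(ValueError):
        EdgeticCounts(0, 0, 1, 10)


def test_tally_mono_only():
    calls = [
        geometry_edgotype(_mapped(mid="A", pos=5), SI),   # disrupts 2
        geometry_edgotype(_mapped(mid="B", pos=12), SI),  # disrupts 1
        geometry_edgotype(_mapped(mid="C", pos=7), SI),   # disrupts 0
        geometry_edgotype(_mapped(mid="D", pos=9, cls="non_disease"), SI),
    ]
    full = tally_counts(calls)
    mono = tally_counts(calls, mono_only=True)
    assert (full.k_M, full.n_M) == (2, 3)
    assert (mono.k_M, mono.n_M) == (1, 3)
    assert (full.k_N, full.n_N) == (1, 1)
    assert (mono.k_N, mono.n_N) == (1, 1)
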