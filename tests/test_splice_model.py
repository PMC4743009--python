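import math

import numpy as np
import pytest

from bpshift import splice_model as sm
from bpshift.branchpoint import BranchpointCandidate


def bp_at(offset, score):
    return BranchpointCandidate(offset, "NNNNNAN", score, 0.5)


def two_acceptor_event():
    """Canonical AG (+1=G, ppt 0.8, BP 5.0 at -25) versus a cryptic AG' at
    -16 (+1=C, ppt 0.8, BP' 6.0 at -13)."""
    ag = sm.AcceptorCandidate(0, "G", 0.8, (bp_at(-25, 5.0),))
    agp = sm.AcceptorCandidate(-16, "C", 0.8, (bp_at(-13, 6.0),))
    return [ag, agp]


class TestU2afAffinity:
    @pytest.mark.parametrize(
        "ppt,plus_one,expected",
        [(1.0, "G", 1.5), (1.0, "C", 1.0), (0.0, "G", 0.0), (0.0, "T", 0.0)],
    )
    def test_formula(self, ppt, plus_one, expected):
        c = sm.AcceptorCandidate(0, plus_one, ppt)
        assert sm.u2af_affinity(c) == expected


class TestPredictUsage:
    def test_f_zero_equals_wt_mode(self):
        pred = sm.predict_usage(two_acceptor_event(), 0.0)
        assert pred.usage == pred.wt_usage

    def test_mixture_linearity_per_acceptor(self):
        accs = two_acceptor_event()
        p0 = sm.predict_usage(accs, 0.0)
        p1 = sm.predict_usage(accs, 1.0)
        for f in (0.1, 0.37, 0.8):
            pf = sm.predict_usage(accs, f)
            for u, u0, u1 in zip(pf.usage, p0.usage, p1.usage):
                assert u == pytest.approx((1 - f) * u0 + f * u1)

    def test_usage_sums_to_one(self):
        for f in (0.0, 0.5, 1.0):
            pred = sm.predict_usage(two_acceptor_event(), f)
            assert sum(pred.usage) == pytest.approx(1.0)

    def test_index_strictly_increasing_in_mutant_fraction(self):
        """The AG'/AG index rises through f = 0, 0.14, 0.30, 1 — the dose
        ordering seen across cell lines with increasing mutant expression."""
        accs = two_acceptor_event()
        indices = [sm.predict_usage(accs, f).agprime_index for f in (0, 0.14, 0.30, 1.0)]
        assert all(b > a for a, b in zip(indices, indices[1:]))
        assert indices[-1] == math.inf  # AG has no MUT-valid branchpoint

    def test_equal_scores_give_equal_usage(self):
        a = sm.AcceptorCandidate(0, "C", 0.5, (bp_at(-13, 5.0),))
        b = sm.AcceptorCandidate(-16, "C", 0.5, (bp_at(-13, 5.0),))
        for f in (0.0, 1.0):
            pred = sm.predict_usage([a, b], f)
            assert pred.usage == pytest.approx((0.5, 0.5))

    def test_monotone_in_bp_prime_strength(self):
        """Raising the BP' pairing score never lowers AG' usage at f>0."""
        last = -1.0
        for s in (3.0, 4.0, 4.5, 5.0, 6.0):
            ag = sm.AcceptorCandidate(0, "G", 0.8, (bp_at(-13, 5.0),))
            agp = sm.AcceptorCandidate(-16, "C", 0.8, (bp_at(-13, s),))
            u = sm.predict_usage([ag, agp], 0.6).usage_of(-16)
            assert u >= last - 1e-12
            last = u

    def test_monotone_in_canonical_bp_strength(self):
        last = 2.0
        for s in (3.0, 4.0, 5.0, 6.0):
            ag = sm.AcceptorCandidate(0, "G", 0.8, (bp_at(-13, s),))
            agp = sm.AcceptorCandidate(-16, "C", 0.8, (bp_at(-13, 5.0),))
            u = sm.predict_usage([ag, agp], 0.6).usage_of(-16)
            assert u <= last + 1e-12
            last = u

    def test_monotone_in_ag_u2af_affinity(self):
        last = 2.0
        for ppt in (0.2, 0.5, 0.8, 1.0):
            ag = sm.AcceptorCandidate(0, "G", ppt, (bp_at(-13, 5.0),))
            agp = sm.AcceptorCandidate(-16, "C", 0.8, (bp_at(-13, 5.0),))
            u = sm.predict_usage([ag, agp], 0.4).usage_of(-16)
            assert u <= last + 1e-12
            last = u

    def test_no_usable_acceptor_is_error(self):
        ag = sm.AcceptorCandidate(0, "G", 0.8, ())
        with pytest.raises(sm.ModelError):
            sm.predict_usage([ag], 0.5)

    def test_invalid_f_rejected(self):
        with pytest.raises(ValueError):
            sm.predict_usage(two_acceptor_event(), 1.2)


class TestAgprimeIndex:
    def test_ratio(self):
        assert sm.agprime_index(60, 100) == pytest.approx(0.6)

    def test_zero_agprime(self):
        assert sm.agprime_index(0, 100) == 0.0

    def test_zero_ag_flagged_absent(self):
        assert sm.agprime_index(10, 0) is None
        assert sm.agprime_index(10, 0, infinite=True) == math.inf

    def test_both_zero_absent(self):
        assert sm.agprime_index(0, 0) is None

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            sm.agprime_index(-1, 5)


class TestApplyMutations:
    def test_reference_mismatch_names_position(self):
        c, _ = sm.tmem14c_like_construct()
        with pytest.raises(sm.ModelError, match="-22"):
            sm.apply_mutations(c, [sm.Mutation(-22, "C", "G")])

    def test_destroying_ag_prime_dinucleotide_removes_candidate(self):
        c, _ = sm.tmem14c_like_construct()
        before = {a.offset for a in sm.derive_acceptors(c, sm.CONSTRUCT_PARAMS)}
        mutated = sm.apply_mutations(c, [sm.Mutation(-18, "A", "G")])
        after = {a.offset for a in sm.derive_acceptors(mutated, sm.CONSTRUCT_PARAMS)}
        assert before == {0, -16}
        assert after == {0}

    def test_neutral_adenosine_changes_nothing(self):
        c, _ = sm.tmem14c_like_construct()
        mutated = sm.apply_mutations(c, [sm.Mutation(-22, "A", "G")])
        p0 = sm.predict_usage(
            sm.derive_acceptors(c, sm.CONSTRUCT_PARAMS), 0.3, sm.CONSTRUCT_PARAMS
        )
        p1 = sm.predict_usage(
            sm.derive_acceptors(mutated, sm.CONSTRUCT_PARAMS), 0.3, sm.CONSTRUCT_PARAMS
        )
        assert p0.usage == pytest.approx(p1.usage)

    def test_created_ag_adds_candidate(self):
        c, series = sm.enosf1_like_construct()
        mutated = sm.apply_mutations(c, series["ag_prime_shifted"])
        offsets = {a.offset for a in sm.derive_acceptors(mutated, sm.CONSTRUCT_PARAMS)}
        assert -17 in offsets  # AAG > AGG creates an acceptor one base upstream
        assert -16 not in offsets


@pytest.fixture(scope="module")
def table():
    construct, series = sm.tmem14c_like_construct()
    return sm.mutagenesis_truth_table(construct, series, params=sm.CONSTRUCT_PARAMS)


class TestTruthTable:

    def test_bp_prime_destruction_abolishes_ag_prime_at_all_f(self, table):
        res = table["bp_prime_destroyed"]
        assert res["labels"][-16] == "abolished"
        assert res["usage_low_f"][-16] == 0.0
        assert res["usage_high_f"][-16] == 0.0

    def test_bp_destruction_abolishes_ag_and_shifts_flux(self, table):
        res = table["bp_destroyed"]
        assert res["labels"][0] == "abolished"
        assert res["usage_high_f"][-16] == pytest.approx(1.0)
        assert res["usage_low_f"][-16] == pytest.approx(1.0)

    def test_ag_prime_dinucleotide_destruction(self, table):
        assert table["ag_prime_destroyed"]["labels"][-16] == "abolished"

    def test_neutral_adenosine_unchanged(self, table):
        labels = table["neutral_a"]["labels"]
        assert labels == {0: "unchanged", -16: "unchanged"}

    def test_plus_one_g_strengthens_ag_prime(self, table):
        res = table["ag_prime_plus_one_g"]
        assert res["labels"][-16] == "strengthened"
        assert res["usage_low_f"][-16] > res["baseline_low_f"][-16]
        assert res["usage_high_f"][-16] > res["baseline_high_f"][-16]

    def test_perfect_canonical_bp_extinguishes_ag_prime(self, table):
        res = table["bp_perfect"]
        assert res["labels"][-16] == "abolished"
        assert res["usage_low_f"][-16] <= 0.01
        assert res["usage_high_f"][-16] <= 0.01

    def test_suboptimal_bp_reinforces_ag_prime(self, table):
        res = table["bp_suboptimal"]
        assert res["usage_high_f"][-16] > res["baseline_high_f"][-16]

    def test_swap_decreases_ag_prime_usage(self, table):
        res = table["bp_swap"]
        assert res["usage_high_f"][-16] < res["baseline_high_f"][-16]

    def test_index_increases_with_f_on_baseline_construct(self):
        construct, _ = sm.tmem14c_like_construct()
        accs = sm.derive_acceptors(construct, sm.CONSTRUCT_PARAMS)
        idx = [
            sm.predict_usage(accs, f, sm.CONSTRUCT_PARAMS).agprime_index
            for f in (0.0, 0.14, 0.30, 1.0)
        ]
        assert all(b > a for a, b in zip(idx, idx[1:]))
        assert all(math.isfinite(i) for i in idx)

    def test_new_site_label_on_aag_architecture(self):
        construct, series = sm.enosf1_like_construct()
        table = sm.mutagenesis_truth_table(
            construct, series, params=sm.CONSTRUCT_PARAMS
        )
        labels = table["ag_prime_shifted"]["labels"]
        assert labels[-17] == "new_site"
        assert labels[-16] == "abolished"
        assert table["ag_prime_shifted"]["usage_high_f"][-17] > 0.1


class TestSwapScoreExchange:
    def test_swap_exchanges_pairing_scores_exactly(self):
        from bpshift.branchpoint import pairing_score

        construct, series = sm.tmem14c_like_construct()
        accs = sm.derive_acceptors(construct, sm.CONSTRUCT_PARAMS)
        by_off = {a.offset: a for a in accs}
        s_bp = by_off[0].best_bp(sm.CONSTRUCT_PARAMS.wt_bp_window, 0.0).pairing_score
        s_bpp = by_off[-16].best_bp(sm.CONSTRUCT_PARAMS.wt_bp_window, 0.0).pairing_score
        swapped = sm.apply_mutations(construct, series["bp_swap"])
        accs2 = sm.derive_acceptors(swapped, sm.CONSTRUCT_PARAMS)
        by_off2 = {a.offset: a for a in accs2}
        assert by_off2[0].best_bp(sm.CONSTRUCT_PARAMS.wt_bp_window, 0.0).pairing_score == s_bpp
        assert by_off2[-16].best_bp(sm.CONSTRUCT_PARAMS.wt_bp_window, 0.0).pairing_score == s_bp
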