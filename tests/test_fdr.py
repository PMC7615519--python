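import math

import numpy as np
import pytest

from streamfdr.fdr import (
    Addis,
    AlphaSpending,
    LordOriginal,
    LordPlusPlus,
    MonotoneAlphaInvesting,
    Saffron,
    Uncorrected,
    make_policy,
    run_stream,
)
from streamfdr.spending import (
    lord_default_sequence,
    power_law_sequence,
    uniform_sequence,
)

ALPHA = 0.05

# frozen oracle values for the 7-p-value platform-trial fixture, M=20
SAFFRON_ALPHA2 = 0.0062076359500721505   # 0.5 * 0.025 * gamma_1(power 1.6, M=20)
SAFFRON_NEXT = 0.016510784271803504
ADDIS_ALPHA1 = 0.003103817975036075      # 0.25 * 0.025 * gamma_0(power+1 1.6, M=20)
ADDIS_ALPHA6 = 0.0010238780929147891     # 0.25 * 0.025 * gamma_1
ADDIS_NEXT = 0.001559061002559098
LORDPP_NEXT = 0.00016769339756683727     # w0 * gamma_8(lord-default, M=20)


class TestConfigInvariants:
    def test_lord_original_budget(self):
        with pytest.raises(ValueError):
            LordOriginal(ALPHA, w0=0.03, b0=0.03)
        LordOriginal(ALPHA, w0=0.025, b0=0.025)

    def test_lordpp_w0_range(self):
        with pytest.raises(ValueError):
            LordPlusPlus(ALPHA, w0=0.06)
        with pytest.raises(ValueError):
            LordPlusPlus(ALPHA, w0=-0.01)

    def test_addis_thresholds(self):
        with pytest.raises(ValueError):
            Addis(ALPHA, lam=0.5, eta=0.5)
        with pytest.raises(ValueError):
            Addis(ALPHA, lam=0.6, eta=0.5)

    def test_saffron_lambda(self):
        with pytest.raises(ValueError):
            Saffron(ALPHA, lam=0.0)
        with pytest.raises(ValueError):
            Saffron(ALPHA, lam=1.0)

    def test_alpha_range(self):
        with pytest.raises(ValueError):
            Uncorrected(0.0)


class TestAlphaSpending:
    def test_uniform_level(self):
        policy = AlphaSpending(ALPHA, sequence=uniform_sequence(20))
        state = policy.start()
        for _ in range(20):
            assert policy.level(state) == pytest.approx(0.0025)
            policy.observe(state, 0.9)
        # past the bound the level is zero
        assert policy.level(state) == 0.0

    def test_levels_sum_to_alpha(self):
        policy = AlphaSpending(ALPHA, sequence=uniform_sequence(20))
        log = policy.run([0.9] * 25)
        assert sum(r.alpha for r in log.records) == pytest.approx(ALPHA)


class TestLordOriginal:
    def test_no_rejections_spends_w0_only(self):
        seq = uniform_sequence(20)
        policy = LordOriginal(ALPHA, w0=0.025, b0=0.025, sequence=seq)
        log = policy.run([0.9] * 5)
        for t, rec in enumerate(log.records, 1):
            assert rec.alpha == pytest.approx(0.025 * seq.weight(t))

    def test_level_after_first_rejection(self):
        # rejection at tau_1 = 1, then alpha_3 = w0*g3 + b0*g2 = 0.0025
        policy = LordOriginal(ALPHA, w0=0.025, b0=0.025, sequence=uniform_sequence(20))
        log = policy.run([0.001, 0.9, 0.9])
        assert log.records[0].reject == 1
        assert log.records[2].alpha == pytest.approx(0.025 * 0.05 + 0.025 * 0.05)

    def test_monotone_in_added_rejections(self):
        policy = LordOriginal(ALPHA, w0=0.025, b0=0.025, sequence=uniform_sequence(20))
        base = policy.run([0.9, 0.9, 0.9, 0.9])
        more = policy.run([0.0001, 0.9, 0.9, 0.9])
        for a, b in zip(more.records[1:], base.records[1:]):
            assert a.alpha >= b.alpha - 1e-15


class TestLordPlusPlus:
    def test_reduces_to_alpha_spending_at_rate_w0(self):
        seq = lord_default_sequence(bound=50)
        policy = LordPlusPlus(ALPHA, w0=0.005, sequence=seq)
        log = policy.run([0.9] * 30)
        for t, rec in enumerate(log.records, 1):
            assert rec.alpha == pytest.approx(0.005 * seq.weight(t), rel=1e-12)

    def test_fixture_next_level(self, stampede):
        policy = make_policy("lordpp", alpha=ALPHA, bound=20)
        log = policy.run(stampede.pvals, ids=stampede.ids)
        assert log.n_rejections == 0
        assert log.next_level == pytest.approx(LORDPP_NEXT, rel=1e-12)
        assert round(log.next_level, 4) == 0.0002

    def test_level_after_one_rejection(self):
        seq = uniform_sequence(20)
        policy = LordPlusPlus(ALPHA, w0=0.005, sequence=seq)
        log = policy.run([1e-6, 0.9, 0.9])
        w0 = 0.005
        expected = w0 * seq.weight(3) + (ALPHA - w0) * seq.weight(2)
        assert log.records[2].alpha == pytest.approx(expected, rel=1e-12)


class TestSaffron:
    def test_first_level(self):
        policy = Saffron(ALPHA, w0=0.025, lam=0.5, sequence=power_law_sequence(1.6, bound=20))
        state = policy.start()
        g1 = power_law_sequence(1.6, bound=20).weight(1)
        assert policy.level(state) == pytest.approx(0.5 * 0.025 * g1, rel=1e-12)

    def test_fixture_trace(self, stampede):
        policy = make_policy("saffron", alpha=ALPHA, bound=20)
        log = policy.run(stampede.pvals, ids=stampede.ids)
        assert log.rejected_ids == ["C", "G"]
        assert log.records[1].alpha == pytest.approx(SAFFRON_ALPHA2, rel=1e-12)
        assert log.next_level == pytest.approx(SAFFRON_NEXT, rel=1e-12)
        assert round(log.next_level, 4) == 0.0165

    def test_levels_capped_at_lambda(self, stream_factory):
        policy = Saffron(ALPHA, lam=0.3)
        log = policy.run(stream_factory(200))
        assert all(0.0 <= r.alpha <= 0.3 for r in log.records)

    def test_all_noncandidates_track_lordpp_skeleton(self):
        # when every p-value is a non-candidate and the lambda cap is never
        # active, levels equal (1 - lambda) * the LORD++ levels
        lam = 0.35
        seq = lord_default_sequence(bound=50)
        pvals = [0.4, 0.6, 0.45, 0.8, 0.5] * 4
        saff = Saffron(ALPHA, w0=0.01, lam=lam, sequence=seq).run(pvals)
        lpp = LordPlusPlus(ALPHA, w0=0.01, sequence=seq).run(pvals)
        for a, b in zip(saff.records, lpp.records):
            assert a.alpha == pytest.approx((1 - lam) * b.alpha, rel=1e-12)


class TestAddis:
    def test_fixture_trace(self, stampede):
        policy = make_policy("addis", alpha=ALPHA, bound=20)
        log = policy.run(stampede.pvals, ids=stampede.ids)
        assert log.rejected_ids == ["G"]
        assert log.records[0].alpha == pytest.approx(ADDIS_ALPHA1, rel=1e-12)
        assert log.records[5].alpha == pytest.approx(ADDIS_ALPHA6, rel=1e-12)
        assert log.next_level == pytest.approx(ADDIS_NEXT, rel=1e-12)
        assert round(log.next_level, 4) == 0.0016

    def test_discard_invariance(self, stampede):
        policy = make_policy("addis", alpha=ALPHA, bound=20)
        base = policy.run(stampede.pvals)
        pvals = list(stampede.pvals)
        pvals.insert(3, 0.9)  # discarded: above eta = 0.5
        padded = policy.run(pvals)
        kept = [r.alpha for i, r in enumerate(padded.records) if i != 3]
        for a, b in zip(kept, [r.alpha for r in base.records]):
            assert a == pytest.approx(b, rel=1e-14)
        assert padded.next_level == pytest.approx(base.next_level, rel=1e-14)

    def test_eta_one_matches_saffron_when_nothing_discarded(self, stream_factory):
        # with eta = 1 nothing is discarded; ADDIS with matching lambda and a
        # 0-indexed copy of SAFFRON's sequence reproduces SAFFRON levels
        pvals = stream_factory(100)
        lam = 0.5
        saff = Saffron(ALPHA, lam=lam, sequence=power_law_sequence(1.6, bound=50))
        addis = Addis(
            ALPHA, lam=lam, eta=1.0, sequence=power_law_sequence(1.6, offset=1, bound=50)
        )
        la = saff.run(pvals)
        lb = addis.run(pvals)
        scale = (1.0 - lam) / (1.0 - lam)  # (1-lam) vs (eta-lam) with eta=1
        for a, b in zip(la.records, lb.records):
            assert b.alpha == pytest.approx(scale * a.alpha, rel=1e-10)

    def test_levels_capped_at_lambda(self, stream_factory):
        log = Addis(ALPHA).run(stream_factory(200))
        assert all(0.0 <= r.alpha <= 0.25 for r in log.records)


class TestMonotoneAlphaInvesting:
    def test_first_level_fixed_point_by_bisection(self):
        policy = MonotoneAlphaInvesting(ALPHA, w0=0.025)
        state = policy.start()
        level = policy.level(state)
        g1 = power_law_sequence(1.6).weight(1)
        b = 0.025 * g1
        lo, hi = 0.0, 1.0
        for _ in range(80):  # bisection on x - (1 - x) * b = 0
            mid = (lo + hi) / 2
            if mid - (1 - mid) * b < 0:
                lo = mid
            else:
                hi = mid
        assert level == pytest.approx(lo, abs=1e-12)

    def test_wealth_nonnegative(self, stream_factory):
        log = MonotoneAlphaInvesting(ALPHA).run(stream_factory(500))
        assert all(r.wealth >= -1e-12 for r in log.records)

    def test_levels_in_unit_interval(self, stream_factory):
        log = MonotoneAlphaInvesting(ALPHA).run(stream_factory(300))
        assert all(0.0 <= r.alpha < 1.0 for r in log.records)


class TestRunStream:
    def test_uncorrected_fixture(self, stampede):
        log = run_stream(stampede.pvals, Uncorrected(ALPHA), ids=stampede.ids)
        assert log.rejected_ids == ["C", "E", "G"]
        assert log.next_level == pytest.approx(0.05)
        assert len(log) == 7

    def test_empty_stream(self):
        policy = make_policy("saffron", alpha=ALPHA, bound=20)
        log = run_stream([], policy)
        assert len(log) == 0
        g1 = power_law_sequence(1.6, bound=20).weight(1)
        assert log.next_level == pytest.approx(0.5 * 0.025 * g1, rel=1e-12)

    def test_invalid_pvalue_names_index(self):
        with pytest.raises(ValueError, match="index 3"):
            run_stream([0.1, 0.2, 1.5], Uncorrected(ALPHA))

    def test_log_length_matches_input(self, stream_factory):
        pvals = stream_factory(40)
        log = run_stream(pvals, make_policy("lordpp"))
        assert len(log) == 40

    def test_batches_carried_through(self, stampede):
        policy = make_policy("addis", bound=20)
        log = policy.run(stampede.pvals, ids=stampede.ids, batches=stampede.batches)
        frame = log.to_frame()
        assert list(frame["batch"]) == list(stampede.batches)


class TestMakePolicy:
    def test_unknown_name(self):
        with pytest.raises(ValueError):
            make_policy("mystery")

    @pytest.mark.parametrize(
        "name", ["uncorrected", "alpha-spending", "lord", "lordpp", "saffron", "addis", "ai", "sidak"]
    )
    def test_all_names_construct_and_run(self, name, stream_factory):
        policy = make_policy(name, alpha=ALPHA, bound=30)
        log = policy.run(stream_factory(10))
        assert len(log) == 10
        assert math.isfinite(log.next_level)
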