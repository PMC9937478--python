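import numpy as np
import pytest
from hypothesis import given, strategies as st

from saltcost.exposure import (BinScheme, ExposurePrevalence, IntakeDistribution,
                               discretize, sbp_shift)
from saltcost.risk import (ProtectiveExposureWarning, RRRecord, combined_rr,
                           paf_for_stratum, par, rr_at_bin)
from saltcost.strata import Stratum

S = Stratum(sex="male", age_group="45-49")


class TestRRRecord:
    def test_nonpositive_rr_rejected(self):
        with pytest.raises(ValueError):
            RRRecord(outcome="CHD", stratum=S, rr_per_mmHg=0.0)


class TestRRAtBin:
    def test_null_risk_stays_one_everywhere(self):
        rec = RRRecord("CHD", S, 1.0)
        for mid in (5.0, 8.5, 12.5):
            assert rr_at_bin(rec, mid, reference=5.0) == 1.0

    def test_reference_bin_is_exactly_one(self):
        rec = RRRecord("CHD", S, 1.03)
        assert rr_at_bin(rec, 5.0, reference=5.0) == 1.0

    def test_log_linear_exponentiation_oracle(self):
        # 11 g vs 5 g reference: SBP shift = 5.8 mmHg, so RR = 1.02^5.8
        rec = RRRecord("stroke", S, 1.02)
        assert rr_at_bin(rec, 11.0, reference=5.0) == pytest.approx(
            1.02 ** 5.8, rel=1e-12)
        assert rr_at_bin(rec, 11.0, reference=5.0) == pytest.approx(1.1217, abs=5e-5)


class TestCombinedRR:
    def test_unexposed_population_returns_null_pair(self):
        prev = ExposurePrevalence(masses=(1.0, 0.0, 0.0))
        assert combined_rr(prev, [1.0, 1.2, 1.4]) == (0.0, 1.0)

    def test_weighted_mean_by_hand(self):
        prev = ExposurePrevalence(masses=(0.5, 0.25, 0.25))
        P, RR = combined_rr(prev, [1.0, 1.2, 1.4])
        assert P == pytest.approx(0.5)
        assert RR == pytest.approx(1.3)

    @given(m1=st.floats(0.01, 0.98), r=st.floats(1.0, 2.0))
    def test_uniform_rr_aggregates_to_itself(self, m1, r):
        m2 = (1.0 - m1) / 2
        prev = ExposurePrevalence(masses=(m2, m1, m2))
        _, RR = combined_rr(prev, [1.0, r, r])
        assert RR == pytest.approx(r, rel=1e-12)

    def test_length_mismatch_raises(self):
        prev = ExposurePrevalence(masses=(0.5, 0.5))
        with pytest.raises(ValueError):
            combined_rr(prev, [1.0, 1.2, 1.4])

    def test_reference_bin_must_be_null(self):
        prev = ExposurePrevalence(masses=(0.5, 0.5))
        with pytest.raises(ValueError):
            combined_rr(prev, [1.1, 1.2])


class TestPAR:
    @pytest.mark.parametrize("P", [0.0, 0.3, 1.0])
    def test_null_association_gives_zero(self, P):
        assert par(P, 1.0) == 0.0

    @pytest.mark.parametrize("P,RR,expected", [
        (1.0, 2.0, 50.0),             # 100*1/(1+1)
        (0.5, 3.0, 50.0),             # 100*1/(1+1)
        (0.25, 5.0, 50.0),            # 100*1/(1+1)
    ])
    def test_formula_oracle(self, P, RR, expected):
        assert par(P, RR) == pytest.approx(expected, rel=1e-12)

    def test_bounds_checks(self):
        with pytest.raises(ValueError):
            par(-0.1, 1.5)
        with pytest.raises(ValueError):
            par(0.5, 0.0)

    def test_singularity_when_excess_hits_minus_one(self):
        # P(RR-1) = -1 exactly (RR below float resolution of 1) is undefined
        with pytest.raises(ZeroDivisionError):
            par(1.0, 1e-17)

    def test_protective_exposure_warns_and_passes_through(self):
        with pytest.warns(ProtectiveExposureWarning):
            value = par(0.5, 0.5)
        assert value < 0

    @given(P=st.floats(0.05, 1.0),
           rr_pair=st.tuples(st.floats(1.01, 5.0), st.floats(1.01, 5.0)))
    def test_strictly_increasing_in_rr_at_fixed_positive_p(self, P, rr_pair):
        lo, hi = sorted(rr_pair)
        if hi - lo < 1e-9:
            return
        assert par(P, hi) > par(P, lo)

    @given(RR=st.floats(1.01, 5.0),
           p_pair=st.tuples(st.floats(0.0, 1.0), st.floats(0.0, 1.0)))
    def test_strictly_increasing_in_p_at_fixed_rr_above_one(self, RR, p_pair):
        lo, hi = sorted(p_pair)
        if hi - lo < 1e-9:
            return
        assert par(hi, RR) > par(lo, RR)


class TestMultiCategoryEquivalence:
    """The binary PAR with prevalence-weighted combined RR equals the
    multi-category attributable fraction 100*sum(p_i(RR_i-1))/(sum+1)."""

    @given(
        masses=st.tuples(st.floats(0.05, 0.9), st.floats(0.05, 0.9),
                         st.floats(0.05, 0.9)),
        rrs=st.tuples(st.floats(1.0, 3.0), st.floats(1.0, 3.0)),
    )
    def test_three_bin_toys_match_brute_force(self, masses, rrs):
        m = np.asarray(masses) / np.sum(masses)
        prev = ExposurePrevalence(masses=tuple(m))
        per_bin = [1.0, rrs[0], rrs[1]]
        P, RR = combined_rr(prev, per_bin)
        via_binary = par(P, RR)
        excess = sum(p * (r - 1.0) for p, r in zip(m[1:], per_bin[1:]))
        brute = 100.0 * excess / (excess + 1.0)
        assert via_binary == pytest.approx(brute, abs=1e-12)


class TestEndToEndMonotonicity:
    def test_par_never_decreases_with_baseline_mean(self):
        """Raising mean intake (fixed SD, RR > 1/mmHg) never lowers the PAR."""
        bins = BinScheme()
        rec = RRRecord("CHD", S, 1.025)
        pars = []
        for mean in (6.0, 8.0, 10.0, 12.0, 14.0):
            prev = discretize(IntakeDistribution(mean=mean, sd=4.0), bins)
            pars.append(paf_for_stratum(rec, prev, bins).PAR)
        assert all(b >= a for a, b in zip(pars, pars[1:]))
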