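import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from myelosim import kinetics
from myelosim.model_core import (
    COMMITTED_LINEAGES,
    GrowthFactors,
    Lineage,
    ValidationError,
    ZERO_CONCENTRATIONS,
)

C0 = ZERO_CONCENTRATIONS


class TestBindingProbability:
    def test_logistic_at_zero_sensitivity(self, params):
        # a*j + b + c = 0 at j = 0 when the offset is cancelled by c
        c = GrowthFactors(c_E=-params.b)
        assert kinetics.binding_probability(Lineage.E, 0, c, params) == pytest.approx(0.5)

    def test_stem_occupancy_matches_cube_root_inversion(self, params):
        # independent closed form: r_S = r_max*(1-(1-p)^3) at c = 0
        p_stem = 1.0 - (1.0 - (1.0 / 365.0) / params.r_max) ** (1.0 / 3.0)
        for x in COMMITTED_LINEAGES:
            got = kinetics.binding_probability(x, 0, C0, params)
            assert got == pytest.approx(p_stem, rel=1e-12)
        assert p_stem == pytest.approx(1.827e-4, rel=1e-3)

    @given(j=st.integers(0, 40), dc=st.floats(0.1, 5.0))
    @settings(deadline=None, max_examples=50)
    def test_strictly_increasing_in_concentration(self, params, j, dc):
        lo = kinetics.binding_probability(Lineage.E, j, C0, params)
        hi = kinetics.binding_probability(Lineage.E, j, GrowthFactors(c_E=dc), params)
        assert 0.0 < lo < hi < 1.0

    def test_strictly_increasing_in_stage(self, params):
        for x in COMMITTED_LINEAGES:
            js = np.arange(params.K_C + params.K(x))
            p = kinetics.binding_probability(x, js, C0, params)
            assert (np.diff(p) > 0).all()

    def test_stage_out_of_range(self, params):
        with pytest.raises(IndexError):
            kinetics.binding_probability(Lineage.E, params.K_C + params.K_E, C0, params)


class TestRates:
    def test_common_rate_bounds(self, params):
        rates = kinetics.common_rates(C0, params)
        ps = np.stack([
            kinetics.binding_probability(x, np.arange(params.K_C + 1), C0, params)
            for x in COMMITTED_LINEAGES
        ])
        # at least the strongest single receptor, at most the cap
        assert (rates >= params.r_max * ps.max(axis=0) - 1e-12).all()
        assert (rates <= params.r_max + 1e-12).all()

    def test_stem_rate_is_once_a_year_at_target(self, params):
        # b was constructed so that the stem compartment divides at 1/365
        assert kinetics.common_precursor_rate(0, C0, params) == pytest.approx(
            1.0 / 365.0, rel=1e-12
        )

    def test_blood_stage_rate_is_death_rate_for_any_c(self, params):
        for c in (C0, GrowthFactors(3.0, -2.0, 1.0)):
            for x in COMMITTED_LINEAGES:
                assert kinetics.committed_rate(x, params.K(x), c, params) == \
                    params.r_blood_death(x)

    def test_last_marrow_stage_rate_is_blood_output_rate(self, params):
        # the slopes were fitted so the previous-to-last stage divides 4x/day
        for x in COMMITTED_LINEAGES:
            r = kinetics.committed_rate(x, params.K(x) - 1, C0, params)
            assert r == pytest.approx(4.0, rel=1e-9)

    def test_rate_profile_shape(self, params):
        """Monotone rise along the common chain, a discontinuous drop on
        commitment (three receptors down to one), and a drop to the death
        rate at the blood stage."""
        common = kinetics.common_rates(C0, params)
        assert (np.diff(common) > 0).all()
        for x in COMMITTED_LINEAGES:
            committed = kinetics.committed_rates(x, C0, params)
            assert committed[0] < common[-1]
            assert (np.diff(committed[:-1]) > 0).all()
            assert committed[-1] < committed[-2]

    def test_stage_range_errors(self, params):
        with pytest.raises(IndexError):
            kinetics.common_precursor_rate(params.K_C + 1, C0, params)
        with pytest.raises(IndexError):
            kinetics.committed_rate(Lineage.G, 0, C0, params)


class TestCommitment:
    def test_symmetric_occupancies_give_equal_split(self, params):
        # make the three occupancies identical by compensating the slopes
        # via concentrations: c_x = -(a_x - a_E) * K_C
        c = GrowthFactors(
            c_E=0.0,
            c_G=-(params.a_G - params.a_E) * params.K_C,
            c_T=-(params.a_T - params.a_E) * params.K_C,
        )
        q = kinetics.commitment_probabilities(c, params)
        assert q == pytest.approx([1 / 3] * 3, rel=1e-12)

    @given(st.floats(-6, 6), st.floats(-6, 6), st.floats(-6, 6))
    @settings(deadline=None, max_examples=50)
    def test_normalization(self, params, ce, cg, ct):
        q = kinetics.commitment_probabilities(GrowthFactors(ce, cg, ct), params)
        assert q.sum() == pytest.approx(1.0, abs=1e-12)
        assert (q > 0).all()

    def test_calibrated_split_at_target(self, params):
        q = kinetics.commitment_probabilities(C0, params)
        assert q == pytest.approx([0.199, 0.327, 0.474], abs=5e-4)
        # cross-check: these q reproduce the adjusted death rates through
        # the steady-state blood constraint
        for qi, x in zip(q, COMMITTED_LINEAGES):
            r = params.N_S * (1 / 365) * 2 ** (params.K_C + params.K(x) - 1) \
                * qi * params.m(x) / params.N(x)
            assert r == pytest.approx(params.r_blood_death(x), rel=1e-9)


class TestFeedback:
    def test_targets_give_zero(self, params):
        counts = {x: int(params.N(x)) for x in COMMITTED_LINEAGES}
        c = kinetics.feedback_concentrations(counts, params)
        assert c.as_array() == pytest.approx([0.0, 0.0, 0.0])

    def test_depleted_lineage_gives_delta(self, params):
        counts = {x: int(params.N(x)) for x in COMMITTED_LINEAGES}
        counts[Lineage.G] = 0
        c = kinetics.feedback_concentrations(counts, params)
        assert c.c_G == pytest.approx(params.delta)

    def test_double_count_gives_minus_delta(self, params):
        counts = {x: 2 * int(params.N(x)) for x in COMMITTED_LINEAGES}
        c = kinetics.feedback_concentrations(counts, params)
        assert c.as_array() == pytest.approx([-params.delta] * 3, rel=1e-9)

    def test_negative_count_rejected(self, params):
        counts = {x: int(params.N(x)) for x in COMMITTED_LINEAGES}
        counts[Lineage.E] = -1
        with pytest.raises(ValidationError):
            kinetics.feedback_concentrations(counts, params)
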