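import math

import numpy as np
import pytest

from myelosim import engine, mutations, scenarios, steady_state
from myelosim.model_core import Lineage, ValidationError
from myelosim.mutations import (
    MutantCohortState,
    MutationConfig,
    MutationEvent,
    MutationType,
    _remove_uniform,
    expected_mutant_growth,
    rate_at_global_stage,
    time_diagnosis_to_breakdown,
    time_to_diagnosis,
)


class TestConfigValidation:
    def test_blood_stage_event_rejected(self, params):
        cfg = MutationConfig(events=(
            MutationEvent(0.0, Lineage.G, params.K_G, MutationType.BLOCK),
        ))
        with pytest.raises(ValidationError):
            cfg.check(params)

    def test_flagless_event_rejected(self, params):
        cfg = MutationConfig(events=(
            MutationEvent(0.0, Lineage.G, 5, MutationType(0)),
        ))
        with pytest.raises(ValidationError):
            cfg.check(params)

    def test_hayflick_limit_must_cover_erythrocyte_chain(self, params):
        cfg = MutationConfig(hayflick_limit=params.K_C + params.K_E)
        with pytest.raises(ValidationError):
            cfg.check(params)

    def test_default_config_valid(self, params):
        MutationConfig().check(params)


class TestNoMutationEquivalence:
    def test_trajectory_identical_to_base_engine(self, params):
        """With no mutation events the extended stepper consumes the same
        random draws as the base engine and produces the same trajectory."""
        initial = engine.initial_steady_state(params)
        base = engine.simulate(initial, params, 2.0, np.random.default_rng(5))
        ext = mutations.simulate_with_mutants(
            params, MutationConfig(), 2.0, np.random.default_rng(5),
            initial=initial,
        )
        for col in ("E_blood", "G_blood", "T_blood", "marrow_total"):
            np.testing.assert_array_equal(base.series(col), ext.series(col))
        assert (ext.series("mutant_total") == 0).all()
        assert (ext.series("blast_outflow") == 0).all()


class TestCloneDynamics:
    def test_block_only_clone_bounded_and_extinct(self, params):
        """A blocked clone founded with remaining capacity rho can never
        exceed 2^rho cells (each division doubles the newest generation and
        burns one capacity unit) and dies out once capacity is exhausted."""
        stage = params.K_G - 1  # late stage: small remaining capacity
        rho = 60 - (params.K_C + stage)
        spec = scenarios.block_only_scenario(seed=9, stage=stage)
        rec = scenarios.run_scenario(spec, params, stop_on_extinction=True)
        clone = rec.series("mutant_total")
        assert clone.max() <= 2**rho
        assert clone[-1] == 0

    def test_immortal_only_clone_extinct_within_a_year(self, params):
        """Unlimited replicative capacity alone washes out: the daughters
        keep differentiating into mature granulocytes and die."""
        for seed in (1, 2, 3):
            spec = scenarios.immortal_only_scenario(seed=seed)
            rec = scenarios.run_scenario(spec, params, stop_on_extinction=True)
            assert rec.series("mutant_total")[-1] == 0
            assert rec.time[-1] < 365.0

    def test_double_mutant_early_growth_matches_exponential(self, params):
        """While the clone is small the blood counts are unperturbed, so a
        block+immortal cohort grows like exp(r*t) at the stage's c=0 rate."""
        stage = 10
        r = rate_at_global_stage(params.K_C + stage, params, Lineage.G)
        founders = 2000
        cfg = MutationConfig(events=(
            MutationEvent(0.0, Lineage.G, stage,
                          MutationType.BLOCK | MutationType.IMMORTAL,
                          count=founders),
        ))
        rec = mutations.simulate_with_mutants(
            params, cfg, 8.0, np.random.default_rng(21),
        )
        clone = rec.series("mutant_total").astype(float)
        t = rec.time
        slope = np.polyfit(t, np.log(clone), 1)[0]
        assert slope == pytest.approx(r, rel=0.1)


class TestMarrowOverflow:
    def test_no_blasts_below_capacity(self, params):
        cfg = MutationConfig()
        rec = mutations.simulate_with_mutants(
            params, cfg, 1.0, np.random.default_rng(3),
        )
        assert (rec.series("blast_outflow") == 0).all()

    def test_remove_uniform_conserves_mass(self, rng):
        pools = [10**12, 5 * 10**11, 3, 10**7]
        removed = _remove_uniform(pools, 10**11, rng)
        assert sum(removed) == 10**11
        assert all(0 <= r <= n for r, n in zip(removed, pools))

    def test_remove_uniform_is_proportional(self, rng):
        pools = [2 * 10**10, 10**10]
        removed = _remove_uniform(pools, 3 * 10**9, rng)
        assert removed[0] / sum(removed) == pytest.approx(2 / 3, rel=0.01)

    def test_remove_more_than_present_rejected(self, rng):
        with pytest.raises(ValidationError):
            _remove_uniform([10, 10], 100, rng)


class TestAnalyticTimeline:
    def test_growth_multiplier_at_time_zero(self, params):
        assert expected_mutant_growth(1, 0.0, params) == 1.0

    def test_growth_increases_with_stage(self, params):
        g = [expected_mutant_growth(j, 10.0, params)
             for j in range(1, params.K_C + 1)]
        assert g == sorted(g)
        assert g[0] < g[-1]

    def test_diagnosis_time_decreasing_in_stage(self, params):
        times = [time_to_diagnosis(j, params) for j in range(1, params.K_C + 1)]
        assert times == sorted(times, reverse=True)

    def test_first_stage_diagnosis_under_twenty_years(self, params):
        assert time_to_diagnosis(1, params) < 20.0

    def test_doubling_founders_shortens_diagnosis_by_log_two(self, params):
        r = rate_at_global_stage(3, params)
        d1 = time_to_diagnosis(3, params, founders=1)
        d2 = time_to_diagnosis(3, params, founders=2)
        assert d1 - d2 == pytest.approx(math.log(2) / r / 365.0, rel=1e-9)

    def test_breakdown_is_two_log_two_over_rate(self, params):
        for j in (1, 5, 10):
            r = rate_at_global_stage(j, params)
            assert time_diagnosis_to_breakdown(j, params) == pytest.approx(
                2 * math.log(2) / r / 365.0, rel=1e-12
            )

    def test_breakdown_about_one_year_at_first_stage(self, params):
        assert time_diagnosis_to_breakdown(1, params) == pytest.approx(1.0, rel=0.2)

    def test_committed_stage_requires_lineage(self, params):
        with pytest.raises(ValidationError):
            rate_at_global_stage(params.K_C + 3, params)


class TestCohortState:
    def test_seeding_uses_stage_implied_capacity(self, params):
        mut = MutantCohortState(60)
        ev = MutationEvent(0.0, Lineage.G, 10, MutationType.BLOCK)
        mut.seed_event(ev, params)
        rho = 60 - (params.K_C + 10)
        key = (Lineage.G, 10, MutationType.BLOCK)
        assert mut.cohorts[key][rho] == 1
        assert mut.total() == 1
        assert mut.marrow_total(params) == 1

    def test_capacity_out_of_range_rejected(self, params):
        mut = MutantCohortState(60)
        with pytest.raises(ValidationError):
            mut.add(Lineage.G, 10, MutationType.BLOCK, 61, 1)
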