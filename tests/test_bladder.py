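"""Dynamic bladder: voiding schedule, activity bookkeeping, wall dose."""

import numpy as np
import pytest

from fdgdose import (
    BladderConfig,
    CompartmentalSystem,
    bladder_tiac,
    bladder_wall_dose,
    no_void_activity,
    simulate_bladder,
)
from fdgdose.nuclide import Emission, NuclideData

from conftest import make_volume_saf


@pytest.fixture(scope="module")
def male_traj(default_system, f18):
    return simulate_bladder(default_system, f18, BladderConfig.male())


@pytest.fixture(scope="module")
def female_traj(default_system, f18):
    return simulate_bladder(default_system, f18, BladderConfig.female())


class TestConfig:
    def test_steady_state_intervals(self):
        """Refill from residual to threshold: 250 ml at 66.67 ml/h = 3.75 h
        (male); 200 ml at 50 ml/h = 4 h (female)."""
        assert BladderConfig.male().steady_state_interval_h == pytest.approx(3.75)
        assert BladderConfig.female().steady_state_interval_h == pytest.approx(4.0)

    def test_thresholds(self):
        assert BladderConfig.male().void_threshold_ml == 260.0
        assert BladderConfig.female().void_threshold_ml == 210.0

    @pytest.mark.parametrize(
        "overrides",
        [
            dict(urine_production_ml_per_day=-1.0),
            dict(residual_volume_ml=400.0),
            dict(initial_volume_ml=5.0),
            dict(forced_void_times_h=(-0.5,)),
            dict(forced_void_times_h=(2.0,), max_time_h=1.0),
            dict(mixing="stirred"),
        ],
    )
    def test_invalid_configs(self, overrides):
        with pytest.raises(ValueError):
            BladderConfig.male(**overrides)


class TestSchedule:
    def test_male_void_times(self, male_traj):
        """Forced void at 45 min, then threshold refills of 250 ml at
        66.67 ml/h: voids at 0.75, 4.5, 8.25, 12.0 h."""
        times = [ev.time_h for ev in male_traj.void_events[:4]]
        assert times == pytest.approx([0.75, 4.5, 8.25, 12.0], abs=1e-9)
        assert male_traj.void_events[0].forced
        assert not male_traj.void_events[1].forced

    def test_female_void_times(self, female_traj):
        times = [ev.time_h for ev in female_traj.void_events[:4]]
        assert times == pytest.approx([0.75, 4.75, 8.75, 12.75], abs=1e-9)

    def test_volume_trajectory_piecewise_linear(self, male_traj):
        cfg = male_traj.config
        r = cfg.production_rate_ml_per_h
        t = np.array([0.0, 0.5, 0.75 + 1e-9, 2.0, 4.5 + 1e-9])
        v = male_traj.volume_ml(t)
        assert v[0] == pytest.approx(100.0)
        assert v[1] == pytest.approx(100.0 + 0.5 * r)
        assert v[2] == pytest.approx(10.0, abs=1e-5)
        assert v[3] == pytest.approx(10.0 + 1.25 * r)
        assert v[4] == pytest.approx(10.0, abs=1e-5)

    def test_volume_stays_within_bounds(self, male_traj):
        tt = np.linspace(0.0, 40.0, 4001)
        v = male_traj.volume_ml(tt)
        cfg = male_traj.config
        assert (v >= cfg.residual_volume_ml - 1e-9).all()
        assert (v <= cfg.void_threshold_ml + 1e-9).all()

    def test_zero_inflow_still_cycles(self, default_system, f18):
        """No kidneys->bladder pathway: activity is identically zero but the
        volume keeps cycling on the urine production rate."""
        sys0 = default_system.with_rates({("Kidneys", "UB contents"): 0.0})
        traj = simulate_bladder(sys0, f18, BladderConfig.male())
        tt = np.linspace(0, 12, 200)
        assert np.abs(traj.activity(tt)).max() < 1e-15
        assert len(traj.void_events) >= 3
        assert bladder_tiac(traj) == pytest.approx(0.0, abs=1e-15)


class TestActivity:
    def test_bookkeeping_reconstructs_physical_decay(self, default_system, f18, male_traj):
        """Body activity + bladder content + voided urine (each decaying from
        its void time) reconstructs e^(-lambda t) to 0.1%."""
        lam = f18.decay_constant
        for t in (0.5, 1.0, 3.0, 6.0, 10.0):
            tacs = default_system.solve([t]).apply_physical_decay(f18)
            body = tacs.total_body_activity().iloc[-1] - tacs.activity("UB contents")[-1]
            bladder = male_traj.activity(t)[0]
            voided = sum(
                ev.activity_removed * np.exp(-lam * (t - ev.time_h))
                for ev in male_traj.void_events
                if ev.time_h <= t
            )
            assert body + bladder + voided == pytest.approx(np.exp(-lam * t), rel=1e-3)

    def test_voiding_reduces_tiac(self, default_system, f18, male_traj):
        from fdgdose.tiac import compute_tiacs

        tiac_no_void = compute_tiacs(default_system, f18)["UB contents"]
        assert bladder_tiac(male_traj) < tiac_no_void

    def test_removing_forced_void_increases_tiac(self, default_system, f18, male_traj):
        cfg = BladderConfig.male(forced_void_times_h=())
        traj = simulate_bladder(default_system, f18, cfg)
        assert bladder_tiac(traj) > bladder_tiac(male_traj)

    def test_initial_volume_does_not_change_tiac(self, default_system, f18, male_traj):
        """Pre-injection urine carries no activity: starting from an emptied
        (10 ml) instead of half-full (100 ml) bladder leaves the content TIAC
        unchanged (it only matters for the volume-dependent wall SAFs)."""
        cfg = BladderConfig.male(initial_volume_ml=10.0)
        traj = simulate_bladder(default_system, f18, cfg)
        assert bladder_tiac(traj) == pytest.approx(bladder_tiac(male_traj), rel=1e-9)

    def test_whole_bladder_mixing_void_invariant(self, default_system, f18):
        """Well-mixed whole-bladder option: activity scales by the total
        volume ratio at each void."""
        cfg = BladderConfig.male(mixing="whole-bladder")
        traj = simulate_bladder(default_system, f18, cfg)
        ev = traj.void_events[0]
        before = traj.decay_corrected_activity(ev.time_h - 1e-12)[0]
        after = traj.decay_corrected_activity(ev.time_h + 1e-12)[0]
        assert after / before == pytest.approx(
            ev.volume_after_ml / ev.volume_before_ml, rel=1e-6
        )

    def test_fresh_urine_retention_uses_active_volume(self, male_traj):
        """Default bookkeeping: at the 45-min void the retained share is
        residual / urine-produced-since-injection (10/50), not 10/150."""
        ev = male_traj.void_events[0]
        before = male_traj.decay_corrected_activity(ev.time_h - 1e-12)[0]
        after = male_traj.decay_corrected_activity(ev.time_h + 1e-12)[0]
        produced = male_traj.config.production_rate_ml_per_h * 0.75
        assert after / before == pytest.approx(10.0 / produced, rel=1e-6)

    def test_tiac_matches_dense_quadrature(self, male_traj):
        """Closed-form per-segment TIAC vs trapezoid on a dense grid (0.1%)."""
        total = 0.0
        for i, seg in enumerate(male_traj.segments):
            tt = np.linspace(seg.t_start, seg.t_end, 6001)
            total += np.trapezoid(male_traj.segment_activity(i, tt), tt)
        assert bladder_tiac(male_traj) == pytest.approx(total, rel=1e-3)

    def test_short_horizon_warns(self, default_system, f18):
        cfg = BladderConfig.male(max_time_h=1.5)
        traj = simulate_bladder(default_system, f18, cfg)
        with pytest.warns(UserWarning, match="truncated horizon"):
            bladder_tiac(traj)

    def test_no_void_curve(self, default_system, f18):
        """Cumulative excretion with voiding disabled: ~9.7 %IA at 1 h."""
        assert 100 * no_void_activity(default_system, f18, 1.0) == pytest.approx(9.7, abs=0.1)


class TestWallDose:
    def test_constant_saf_makes_dynamic_equal_static(self, male_traj, f18):
        """SAF independent of volume degenerates the dynamic integral to
        SAF x TIAC, i.e. exactly the static-bladder dose."""
        table = make_volume_saf(const=1.0)
        dose = bladder_wall_dose(male_traj, table, f18)
        assert dose.photon_mgy_per_mbq == pytest.approx(dose.static_photon_mgy_per_mbq, rel=1e-4)
        assert dose.beta_mgy_per_mbq == pytest.approx(dose.static_beta_mgy_per_mbq, rel=1e-4)

    def test_inverse_volume_saf_dynamic_exceeds_static(self, male_traj, f18):
        """SAF ~ 1/volume and most of the activity-time spent below the 200 ml
        static reference: the dynamic dose must exceed the static one.
        Cross-checked against an independent quadrature oracle."""
        table = make_volume_saf()
        dose = bladder_wall_dose(male_traj, table, f18)
        assert dose.total_mgy_per_mbq > dose.static_total_mgy_per_mbq
        # independent oracle: brute-force quadrature, segment by segment
        oracle = 0.0
        for em in f18.emissions:
            kind = "photon" if em.particle_type == "photon" else "beta"
            for i, seg in enumerate(male_traj.segments):
                tt = np.linspace(seg.t_start, seg.t_end, 4001)
                a = male_traj.segment_activity(i, tt)
                r = male_traj.config.production_rate_ml_per_h
                v = seg.volume_start_ml + r * (tt - seg.t_start)
                saf = table.saf(kind, em.energy_mev, v)
                oracle += em.yield_per_decay * em.energy_mev * np.trapezoid(a * saf, tt)
        oracle *= 3.6e9 * 1.602176634e-13 * 1e3
        assert dose.total_mgy_per_mbq == pytest.approx(oracle, rel=1e-3)

    def test_zero_yield_spectrum_gives_zero_dose(self, male_traj):
        silent = NuclideData("silent", half_life_h=109.77 / 60.0, emissions=())
        dose = bladder_wall_dose(male_traj, make_volume_saf(), silent)
        assert dose.total_mgy_per_mbq == 0.0

    def test_volume_outside_table_refused(self, male_traj, f18):
        import pandas as pd

        from fdgdose.bladder import VolumeSAFTable

        rows = [
            {"volume_ml": v, "particle_type": p, "energy_MeV": 0.511, "saf_per_kg": 200.0 / v}
            for v in (50.0, 150.0)
            for p in ("photon", "beta")
        ]
        narrow = VolumeSAFTable(pd.DataFrame(rows))
        with pytest.raises(ValueError, match="extrapolate"):
            bladder_wall_dose(male_traj, narrow, f18)

    def test_saf_table_validation(self):
        import pandas as pd

        from fdgdose.bladder import VolumeSAFTable

        increasing = pd.DataFrame(
            {
                "volume_ml": [50.0, 100.0],
                "particle_type": ["photon", "photon"],
                "energy_MeV": [0.511, 0.511],
                "saf_per_kg": [0.1, 0.2],
            }
        )
        with pytest.raises(ValueError, match="non-increasing"):
            VolumeSAFTable(increasing)
        negative = increasing.assign(saf_per_kg=[-0.1, -0.2])
        with pytest.raises(ValueError, match="> 0"):
            VolumeSAFTable(negative)
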