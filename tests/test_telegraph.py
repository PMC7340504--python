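"""Two-state transcription model: SSA, nascent weighting, pairing."""

import numpy as np
import pytest

from burstfish import telegraph as tg


@pytest.fixture(scope="module")
def bursty_params():
    return tg.TelegraphParams(k_on=0.2, k_off=1.0, k_ini=4.0)


class TestParams:
    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            tg.TelegraphParams(k_on=-1.0, k_off=1.0, k_ini=1.0)

    def test_burst_descriptors(self):
        p = tg.TelegraphParams(k_on=0.5, k_off=2.0, k_ini=8.0)
        assert p.burst_size == pytest.approx(4.0)
        assert p.burst_frequency == pytest.approx(1 / (2.0 + 0.5))
        d = tg.burst_descriptors(p)
        assert (d.size, d.frequency) == (p.burst_size, p.burst_frequency)

    def test_fig_style_burst_sizes(self):
        # k_ini/k_off pairs chosen to set burst size to 1, 4 and 20
        sizes = [tg.TelegraphParams(0.1, k_off, k_ini).burst_size
                 for k_ini, k_off in [(1.0, 1.0), (4.0, 1.0), (20.0, 1.0)]]
        assert sizes == [1.0, 4.0, 20.0]

    def test_timing_defaults_and_validation(self):
        t = tg.NascentTiming.from_gene("brk")
        assert t.tau_elong == 1.35
        assert t.tau_probe == pytest.approx(0.8 * 1.35)
        with pytest.raises(KeyError):
            tg.NascentTiming.from_gene("nonexistent")
        with pytest.raises(ValueError):
            tg.NascentTiming("x", tau_elong=1.0, tau_probe=2.0)

    def test_elongation_table_matches_rate(self):
        # tau_elong = nt / (1100 nt/min): the table is in minutes
        assert tg.TAU_ELONG_MIN["sens"] == 5.15
        assert tg.ELONGATION_RATE_NT_PER_MIN == 1100.0


class TestGillespie:
    def test_absorbing_off_state_terminates_with_warning(self):
        p = tg.TelegraphParams(k_on=0.0, k_off=1.0, k_ini=5.0)
        with pytest.warns(UserWarning, match="absorbing"):
            traj = tg.gillespie_run(p, n_events=100, seed=1)
        assert traj.absorbed
        assert traj.n_events == 0
        assert traj.final_mrna == 0

    def test_trajectory_bookkeeping_consistent(self, bursty_params):
        traj = tg.gillespie_run(bursty_params, n_events=5000, seed=3)
        assert traj.n_events == 5000
        assert np.all(np.diff(traj.times) > 0)
        assert traj.mrna_trace()[-1] == traj.final_mrna
        n_init = (traj.events == tg.EVENT_INIT).sum()
        n_deg = (traj.events == tg.EVENT_DEG).sum()
        assert n_init - n_deg == traj.final_mrna

    def test_constitutive_limit_is_poisson(self):
        # promoter locks ON: mRNA count converges to Poisson(k_ini/k_deg)
        p = tg.TelegraphParams(k_on=10.0, k_off=0.0, k_ini=2.0)
        batch = tg.simulate_batch(p, n_sims=400, n_events=8000, seed=5)
        lam = 2.0 / 0.04
        assert batch.mature.mean() == pytest.approx(lam, rel=0.05)
        fano = batch.mature.var() / batch.mature.mean()
        assert fano == pytest.approx(1.0, abs=0.2)

    def test_mean_matches_closed_form_within_3_se(self, bursty_params):
        batch = tg.simulate_batch(bursty_params, n_sims=1000,
                                  n_events=10_000, seed=9)
        expected = tg.telegraph_mean(bursty_params)
        se = batch.mature.std(ddof=1) / np.sqrt(len(batch.mature))
        assert abs(batch.mature.mean() - expected) <= 3 * se

    def test_batch_matches_single_runs_at_end_convention(
            self, bursty_params):
        """The batch core and the trajectory route must produce
        identical outcomes for identical derived seeds."""
        timing = tg.NascentTiming.from_gene("dad")
        batch = tg.simulate_batch(bursty_params, timing, n_sims=8,
                                  n_events=2000, seed=31, record="end")
        seeds = tg._derive_seeds(31, 8)
        for i, s in enumerate(seeds):
            traj = tg.gillespie_run(bursty_params, n_events=2000,
                                    seed=int(s))
            assert batch.mature[i] == traj.final_mrna
            assert batch.nascent[i] == pytest.approx(
                tg.count_nascent(traj, timing))

    def test_stationary_record_reproducible(self, bursty_params):
        a = tg.simulate_batch(bursty_params, n_sims=50, seed=4)
        b = tg.simulate_batch(bursty_params, n_sims=50, seed=4)
        np.testing.assert_array_equal(a.mature, b.mature)


class TestMasterEquation:
    def test_closed_form_moments_verified_against_master_equation(self):
        """The mean and Fano formulas are independently confirmed by
        the truncated master-equation solution before being used as
        oracles elsewhere."""
        for p in [tg.TelegraphParams(0.05, 0.1, 1.0),
                  tg.TelegraphParams(2.0, 2.0, 8.0),
                  tg.TelegraphParams(0.5, 5.0, 30.0)]:
            pi = tg.master_equation_stationary(p)
            n = np.arange(len(pi))
            mean = float((n * pi).sum())
            var = float(((n - mean) ** 2 * pi).sum())
            assert mean == pytest.approx(tg.telegraph_mean(p), rel=1e-6)
            assert var / mean == pytest.approx(tg.telegraph_fano(p),
                                               rel=1e-5)

    def test_ssa_occupation_matches_master_equation(self, bursty_params):
        emp = tg.occupation_distribution(bursty_params, n_runs=500,
                                         n_events=10_000, seed=2)
        pi = tg.master_equation_stationary(bursty_params,
                                           n_max=len(emp) - 1)
        assert tg.total_variation(emp, pi) < 0.02

    def test_two_gene_copies_double_the_mean(self):
        p1 = tg.TelegraphParams(0.5, 1.0, 2.0, n_g_tot=1)
        p2 = p1.replace(n_g_tot=2)
        assert tg.telegraph_mean(p2) == pytest.approx(
            2 * tg.telegraph_mean(p1))
        pi2 = tg.master_equation_stationary(p2)
        n = np.arange(len(pi2))
        assert float((n * pi2).sum()) == pytest.approx(
            tg.telegraph_mean(p2), rel=1e-6)


class TestNascentCounting:
    def test_piecewise_weights_by_initiation_age(self):
        # ages 0.1 (inside probe region), 1.0 (fully probed), 10
        # (mature) with brk-like timing
        timing = tg.NascentTiming("brk", tau_elong=1.35,
                                  tau_probe=0.675)
        T = 20.0
        times = np.array([T - 10.0, T - 1.0, T - 0.1])
        events = np.full(3, tg.EVENT_INIT, dtype=np.int8)
        traj = tg.Trajectory(
            params=tg.TelegraphParams(1, 1, 1), times=times,
            events=events, final_time=T, final_mrna=3, final_active=1,
            seed=0)
        assert tg.count_nascent(traj, timing) == pytest.approx(1.5)

    def test_no_recent_initiation_gives_zero_units(self):
        timing = tg.NascentTiming.from_gene("dad")
        traj = tg.Trajectory(
            params=tg.TelegraphParams(1, 1, 1),
            times=np.array([1.0]),
            events=np.array([tg.EVENT_INIT], dtype=np.int8),
            final_time=100.0, final_mrna=1, final_active=1, seed=0)
        assert tg.count_nascent(traj, timing) == 0.0

    def test_probe_site_normalization_worked_example(self):
        # 12 transcribed probe-binding sites at 6 sites per mRNA
        assert tg.normalized_site_signal(12, 6) == pytest.approx(2.0)
        assert tg.normalized_site_signal(12, 6) >= tg.DETECTION_UNITS


class TestPairing:
    def make_batch(self, nascent):
        nascent = np.asarray(nascent, dtype=float)
        return tg.SimBatch(params=tg.TelegraphParams(1, 1, 1),
                           timing=None,
                           mature=np.arange(len(nascent)),
                           nascent=nascent, seed=0)

    def test_detection_boundary_is_inclusive(self):
        paired = tg.pair_alleles(self.make_batch([1.0, 1.0]), seed=0)
        assert paired.nascent[0] == 2.0
        assert paired.detected[0]

    def test_below_cutoff_not_detected(self):
        paired = tg.pair_alleles(self.make_batch([1.0, 0.5]), seed=0)
        assert not paired.detected[0]

    def test_pairing_conserves_totals(self, bursty_params):
        batch = tg.simulate_batch(bursty_params, n_sims=200, seed=6)
        paired = tg.pair_alleles(batch, seed=7)
        assert paired.mature.sum() == batch.mature.sum()
        assert paired.nascent.sum() == pytest.approx(batch.nascent.sum())

    def test_odd_count_drops_one_with_warning(self):
        with pytest.warns(UserWarning, match="odd"):
            paired = tg.pair_alleles(self.make_batch([1.0, 1.0, 3.0]),
                                     seed=0)
        assert paired.n_pairs == 1

    def test_detection_fraction_stable_across_pairing_orders(
            self, bursty_params):
        timing = tg.NascentTiming.from_gene("dad")
        batch = tg.simulate_batch(bursty_params, timing, n_sims=2000,
                                  seed=8)
        fracs = [tg.pair_alleles(batch, seed=s).fraction_detected
                 for s in range(10)]
        # exchangeable pairings: spread stays within binomial noise
        assert np.ptp(fracs) <= 4 * np.sqrt(0.25 / 1000)


class TestSweeps:
    def test_sweep_outside_literature_bounds_rejected(self,
                                                      bursty_params):
        timing = tg.NascentTiming.from_gene("dad")
        with pytest.raises(ValueError, match="range"):
            tg.sweep("k_ini", [0.01], bursty_params, timing,
                     n_pairs=100)
        with pytest.raises(ValueError, match="n_pairs"):
            tg.sweep("k_ini", [1.0], bursty_params, timing, n_pairs=10)

    def test_rates_for_burst_roundtrip(self):
        p = tg.rates_for_burst(size=4.0, frequency=0.2)
        assert p.burst_size == pytest.approx(4.0)
        assert p.burst_frequency == pytest.approx(0.2)

    def test_phase_diagram_limits(self):
        timing = tg.NascentTiming.from_gene("dad")
        df = tg.phase_diagram([1.0, 20.0], [0.1, 1.0], timing,
                              n_pairs=150, n_events=4000, seed=3)
        small = df[(df.burst_size == 1.0)
                   & (df.burst_frequency == 0.1)].iloc[0]
        big = df[(df.burst_size == 20.0)
                 & (df.burst_frequency == 1.0)].iloc[0]
        assert small.fraction_detected < 0.2
        assert big.fraction_detected > 0.8

    def test_infeasible_grid_points_marked(self):
        timing = tg.NascentTiming.from_gene("dad")
        # frequency 5/min implies k_off = 10 and k_ini = 400 for size
        # 40: outside every literature bound
        df = tg.phase_diagram([40.0], [5.0], timing, n_pairs=150,
                              n_events=1000, seed=1)
        assert not df.feasible.iloc[0]
        assert np.isnan(df.fraction_detected.iloc[0])

    def test_n_events_doubling_leaves_mean_unchanged(self,
                                                     bursty_params):
        a = tg.simulate_batch(bursty_params, n_sims=800,
                              n_events=10_000, seed=12)
        b = tg.simulate_batch(bursty_params, n_sims=800,
                              n_events=20_000, seed=13)
        se = np.hypot(a.mature.std(ddof=1) / np.sqrt(800),
                      b.mature.std(ddof=1) / np.sqrt(800))
        assert abs(a.mature.mean() - b.mature.mean()) <= 3 * se
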