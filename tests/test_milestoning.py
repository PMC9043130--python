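"""Markovian milestoning: event detection, balance equation, rate matrix, MFPT."""

import warnings

import numpy as np
import pytest

from permeakit.isd import ChannelBounds, smoluchowski_mfpt
from permeakit.milestoning import (CellPartition, CellSampling, CellStats,
                                   IrreducibilityError, MilestoningModel,
                                   build_rate_matrix, convergence_trace,
                                   detect_events, diagnostics, free_energy,
                                   merge_stats, mfpt_profile, mfpt_uncertainty,
                                   run_milestoning, solve_equilibrium,
                                   stride_sensitivity)
from permeakit.pmf import DiffusionProfile, PMFProfile
from permeakit.trajectory import from_values

from conftest import KT300, make_cell_samplings

PART3 = CellPartition((-3.0, -1.0, 1.0, 3.0))  # middle cell spans [-1, 1]


def stats_with(cell, escapes_left=0, escapes_right=0, incell_time=1.0, **kw):
    s = CellStats(cell=cell, incell_time=incell_time, total_time=incell_time,
                  assigned_time=kw.pop("assigned_time", incell_time))
    s.escapes["left"] = escapes_left
    s.escapes["right"] = escapes_right
    for k, v in kw.items():
        setattr(s, k, v)
    return s


class TestDetectEvents:
    def test_first_crossing_starts_the_clock(self):
        # path enters through the left edge, leaves through the right one:
        # the left-edge crossing is the first hit, the right-edge crossing
        # completes one left->right transition
        path = [-1.2, -0.4, 0.3, -0.2, 1.1]
        s = CellSampling(1, from_values(path, 0.5))
        st = detect_events(s, PART3)
        assert st.counts == {(0, 1): 1}
        assert st.residence.keys() == {0, 1}

    def test_residence_assigned_to_last_hit_milestone(self):
        # cross left edge at i=1, right edge at i=4: the 3 strides in between
        # belong to the left milestone (minus the out-of-cell first sample)
        path = [-1.2, -0.4, 0.3, 0.5, 1.1]
        st = detect_events(CellSampling(1, from_values(path, 0.5)), PART3)
        assert st.counts[(0, 1)] == 1
        assert st.residence[0] == pytest.approx(3 * 0.5)

    def test_landing_exactly_on_edge_counts_as_hit(self):
        path = [0.0, 1.0, 0.5, 0.2]
        st = detect_events(CellSampling(1, from_values(path, 0.5)), PART3)
        assert st.residence.keys() == {1}

    def test_double_crossing_in_one_frame_ordered_spatially(self):
        # one frame jumps across both edges: hits registered in spatial order
        path = [-0.5, -1.5, 1.5, 0.0]
        st = detect_events(CellSampling(1, from_values(path, 0.5)), PART3)
        assert st.counts == {(0, 1): 1}

    def test_no_hit_warns_and_contributes_nothing(self):
        path = [0.0, 0.1, -0.1, 0.2]
        with pytest.warns(UserWarning, match="no milestone"):
            st = detect_events(CellSampling(1, from_values(path, 0.5)), PART3)
        assert st.counts == {} and st.residence == {}

    def test_escape_counting_one_per_excursion(self):
        # two left excursions (one lasting two samples) and one right
        path = [0.0, -1.2, -1.4, 0.0, -1.1, 0.0, 1.3, 0.5]
        st = detect_events(CellSampling(1, from_values(path, 0.5)), PART3)
        assert st.escapes == {"left": 2, "right": 1}

    def test_brute_force_rescan_agrees(self, milestoning_samplings,
                                       milestoning_partition):
        """Counts and residence match an independent sample-by-sample scan."""
        s = milestoning_samplings[4]
        sub = CellSampling(s.cell, from_values(s.series.values[:200_000],
                                               s.series.stride))
        st = detect_events(sub, milestoning_partition)
        edges = milestoning_partition.edges
        lo, hi = edges[s.cell], edges[s.cell + 1]
        lm, rm = s.cell - 1, s.cell
        v = sub.series.values
        h = sub.series.stride
        label, t0 = None, None
        res = {lm: 0.0, rm: 0.0}
        cnt = {}
        incell = (v >= lo) & (v <= hi)
        cs = np.concatenate(([0], np.cumsum(incell)))
        for i in range(1, len(v)):
            prev, cur = v[i - 1], v[i]
            hits = []
            for m, pos in ((lm, lo), (rm, hi)):
                if (min(prev, cur) < pos < max(prev, cur)) or (cur == pos != prev):
                    hits.append((m, pos))
            hits.sort(key=lambda t: t[1], reverse=bool(prev > cur))
            for m, _ in hits:
                if label is None:
                    label, t0 = m, i
                elif m != label:
                    res[label] += h * (cs[i] - cs[t0])
                    cnt[(label, m)] = cnt.get((label, m), 0) + 1
                    label, t0 = m, i
        assert st.counts == cnt
        assert st.residence[lm] == pytest.approx(res[lm] + (0 if label != lm else
                                                 h * (cs[len(v)] - cs[t0])), rel=1e-9)
        assert st.residence_fraction(lm) + st.residence_fraction(rm) == pytest.approx(1.0)


class TestSolveEquilibrium:
    def test_two_cells_equal_rates(self):
        part = CellPartition((0.0, 1.0, 2.0))
        stats = [stats_with(0, escapes_right=5), stats_with(1, escapes_left=5)]
        np.testing.assert_allclose(solve_equilibrium(stats, part), [0.5, 0.5])

    def test_three_cell_master_equation(self):
        # k12=2, k21=1, k23=1, k32=2 -> pi = (0.25, 0.5, 0.25)
        part = CellPartition((0.0, 1.0, 2.0, 3.0))
        stats = [stats_with(0, escapes_right=2),
                 stats_with(1, escapes_left=1, escapes_right=1),
                 stats_with(2, escapes_left=2)]
        pi = solve_equilibrium(stats, part)
        np.testing.assert_allclose(pi, [0.25, 0.5, 0.25], atol=1e-12)
        assert pi.sum() == pytest.approx(1.0, abs=1e-14)

    def test_disconnected_graph_raises(self):
        part = CellPartition((0.0, 1.0, 2.0, 3.0))
        stats = [stats_with(0, escapes_right=2),
                 stats_with(1, escapes_left=1, escapes_right=0),
                 stats_with(2, escapes_left=2)]
        with pytest.raises(IrreducibilityError, match="cells 1 and 2"):
            solve_equilibrium(stats, part)

    def test_missing_cell_raises(self):
        part = CellPartition((0.0, 1.0, 2.0))
        with pytest.raises(ValueError, match="missing"):
            solve_equilibrium([stats_with(0, escapes_right=1)], part)


class TestFreeEnergy:
    def test_uniform_is_flat_zero(self):
        F = free_energy(np.full(5, 0.2), reference_cells=range(5))
        np.testing.assert_allclose(F, 0.0, atol=1e-12)

    def test_double_probability_is_kT_ln2(self):
        F = free_energy(np.array([0.25, 0.5, 0.25]), reference_cells=[1])
        assert F[0] == pytest.approx(KT300 * np.log(2), rel=1e-9)
        assert F[0] == pytest.approx(0.413, abs=0.001)
        assert F[1] == 0.0

    def test_zero_probability_rejected(self):
        with pytest.raises(ValueError):
            free_energy(np.array([0.5, 0.0, 0.5]), [0])


class TestRateMatrix:
    def test_direct_substitution(self):
        # q = pi_1 n_1 / (pi_1 r_1 + pi_0 r_0) = 0.25*0.005/(0.25*0.5+0.25*0.3)
        part = CellPartition((0.0, 1.0, 2.0, 3.0))
        s0 = stats_with(0, incell_time=1000.0, assigned_time=1000.0)
        s0.residence[0] = 300.0  # r_0(S01) = 0.3
        s1 = stats_with(1, incell_time=1000.0, assigned_time=1000.0)
        s1.residence[0] = 500.0  # r_1(S01) = 0.5
        s1.residence[1] = 500.0
        s1.counts[(0, 1)] = 5    # n_1(S01->S12) = 0.005 /ps
        s2 = stats_with(2, incell_time=1000.0, assigned_time=1000.0)
        s2.residence[1] = 500.0
        pi = np.array([0.25, 0.25, 0.5])
        model = build_rate_matrix([s0, s1, s2], pi, part)
        assert model.Q[0, 1] == pytest.approx(0.00625, rel=1e-12)

    def test_all_zero_counts_warn(self):
        part = CellPartition((0.0, 1.0, 2.0, 3.0))
        stats = [stats_with(c) for c in range(3)]
        with pytest.warns(UserWarning, match="never-hit"):
            model = build_rate_matrix(stats, np.full(3, 1 / 3), part)
        assert model.Q.size == 0

    def test_model_invariants_enforced(self):
        with pytest.raises(ValueError):
            MilestoningModel(np.array([0.6, 0.6]), np.zeros((1, 1)), np.array([1.0]))
        with pytest.raises(ValueError):
            MilestoningModel(np.array([0.5, 0.5]),
                             np.array([[0.1, -0.1], [0.0, 0.0]]), np.arange(2.0))


class TestMFPTProfile:
    def test_two_milestones_one_way(self):
        model = MilestoningModel(np.array([0.5, 0.3, 0.2]),
                                 np.array([[-0.01, 0.01], [0.02, -0.02]]),
                                 np.array([1.0, 2.0]))
        prof = mfpt_profile(model, "outward")
        assert prof.mfpt[1] == pytest.approx(100.0)
        assert prof.end_to_end == pytest.approx(100.0)

    def test_birth_death_chain_closed_form_and_gillespie(self):
        """Matrix MFPT equals the nearest-neighbor recursion and a direct
        stochastic simulation of the jump process."""
        rng = np.random.default_rng(5)
        n = 6
        up = rng.uniform(0.5, 2.0, n - 1)
        down = rng.uniform(0.5, 2.0, n - 1)  # down[i]: rate i+1 -> i
        Q = np.zeros((n, n))
        for i in range(n - 1):
            Q[i, i + 1] = up[i]
            Q[i + 1, i] = down[i]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        model = MilestoningModel(np.full(n + 1, 1 / (n + 1)), Q, np.arange(float(n)))
        got = mfpt_profile(model, "outward").end_to_end

        # oracle 1: the standard hop-time recursion T_i = 1/u_i + d_i/u_i T_{i-1}
        T = np.zeros(n - 1)
        T[0] = 1.0 / up[0]
        for i in range(1, n - 1):
            T[i] = 1.0 / up[i] + down[i - 1] / up[i] * T[i - 1]
        assert got == pytest.approx(T.sum(), rel=1e-10)

        # oracle 2: Gillespie simulation of the same chain
        times = []
        for _ in range(3000):
            state, t = 0, 0.0
            while state < n - 1:
                rates = Q[state].copy()
                rates[state] = 0.0
                total = rates.sum()
                t += rng.exponential(1.0 / total)
                state = rng.choice(n, p=rates / total)
            times.append(t)
        mc = np.mean(times)
        se = np.std(times, ddof=1) / np.sqrt(len(times))
        assert abs(mc - got) < 3 * se

    def test_unreachable_target_raises(self):
        Q = np.array([[-0.01, 0.01, 0.0],
                      [0.0, 0.0, 0.0],
                      [0.0, 0.02, -0.02]])
        model = MilestoningModel(np.full(4, 0.25), Q, np.arange(3.0))
        with pytest.raises(IrreducibilityError):
            mfpt_profile(model, "inward")


class TestEndToEnd:
    def test_mfpt_matches_smoluchowski_quadrature(self, barrier,
                                                  milestoning_samplings,
                                                  milestoning_partition):
        """Full pipeline on the barrier fixture agrees with the PMF/D
        quadrature (reflecting wall at the bulk edge) within 15%."""
        model, _ = run_milestoning(milestoning_samplings, milestoning_partition)
        out = mfpt_profile(model, "outward").end_to_end
        zg = np.linspace(-12, 12, 4801)
        pmf = PMFProfile(zg, barrier.energy(zg), bulk_region=(-12, -11.5))
        d = DiffusionProfile(zg, np.full_like(zg, 0.02))
        pred = smoluchowski_mfpt(pmf, d, ChannelBounds(-10.0, 10.0),
                                 reflecting_at=-12.0)
        assert abs(out - pred) / pred < 0.15

    def test_inward_outward_mirror_symmetry(self, milestoning_samplings,
                                            milestoning_partition):
        """On a symmetric channel the inward and outward MFPTs agree within
        two combined bootstrap standard errors."""
        boot = mfpt_uncertainty(milestoning_samplings, milestoning_partition,
                                n_blocks=5, n_boot=40, seed=1)
        out, se_out = boot["outward"]
        inw, se_in = boot["inward"]
        assert abs(out - inw) < 2 * np.hypot(se_out, se_in)

    def test_wider_bulk_scales_mfpt_with_concentration(self):
        """Extending the bulk region scales the MFPT by the inverse
        effective-concentration ratio (the argument that reconciles
        cylindrical and spherical bulk boundaries), here within 15%.

        The extended partition reuses the narrow partition's trajectories
        for the shared cells, so the comparison is paired and only the
        extra bulk cells add statistical noise.
        """
        import permeakit as pk
        from scipy.integrate import quad
        pot = pk.GaussianBarrier(4.0, 0.0, 1.2)
        part_a = CellPartition(tuple(np.arange(-10.0, 6.01, 2.0)))
        samp_a = make_cell_samplings(pot, part_a, n_steps=15_000_000,
                                     output_stride=20, seed0=900, D=0.05)
        part_b = CellPartition(tuple(np.arange(-18.0, 6.01, 2.0)))
        extra = make_cell_samplings(
            pk.FlatPotential(),  # bulk extension is flat to within 1e-10
            CellPartition(tuple(np.arange(-18.0, -9.99, 2.0))),
            n_steps=15_000_000, output_stride=20, seed0=950, D=0.05)
        samp_b = extra + [CellSampling(s.cell + 4, s.series) for s in samp_a]
        t = {}
        for part, samp, tag in ((part_a, samp_a, "a"), (part_b, samp_b, "b")):
            model, _ = run_milestoning(samp, part)
            t[tag] = mfpt_profile(model, "outward").end_to_end
        # effective bulk length: Boltzmann-weighted distance wall -> barrier
        beta = 1.0 / KT300
        weight = lambda lo: quad(
            lambda z: np.exp(-beta * pot.energy(np.array([z]))[0]), lo, 0.0)[0]
        conc_ratio = weight(-18.0) / weight(-10.0)
        assert abs(t["b"] / t["a"] / conc_ratio - 1) < 0.15


class TestDiagnostics:
    def test_waiting_times_and_decorrelation(self, milestoning_samplings,
                                             milestoning_partition):
        model, stats = run_milestoning(milestoning_samplings, milestoning_partition)
        diag = diagnostics(stats, milestoning_samplings)
        interior = diag[(diag.cell > 0) & (diag.cell < 11)]
        stride = milestoning_samplings[0].series.stride
        assert (interior.min_waiting_ps >= stride).all()
        assert (interior.max_waiting_ps > interior.min_waiting_ps).all()
        # Markovianity: positional decorrelation faster than shortest waiting
        assert (interior.decorrelation_time_ps.median()
                < interior.max_waiting_ps.median())

    def test_convergence_trace_monotone_time(self, milestoning_samplings,
                                             milestoning_partition):
        tr = convergence_trace(milestoning_samplings[5], milestoning_partition,
                               n_points=5)
        assert tr.time_ps.is_monotonic_increasing
        assert {"n_lr_per_ps", "r_left", "r_right"} <= set(tr.columns)


class TestStrideSensitivity:
    def test_factor_one_is_identity(self, stride_samplings, milestoning_partition):
        tab = stride_sensitivity(stride_samplings, milestoning_partition, [1])
        model, _ = run_milestoning(stride_samplings, milestoning_partition)
        base = mfpt_profile(model, "outward").end_to_end
        assert tab.mfpt_ps.iloc[0] == pytest.approx(base, rel=1e-12)

    def test_coarse_stride_inflates_mfpt(self, stride_samplings,
                                         milestoning_partition):
        """0.2 and 0.5 ps recording agree within 5%; 5 ps inflates the MFPT
        by >20% and loses transitions (the recording-frequency bias)."""
        tab = stride_sensitivity(stride_samplings, milestoning_partition,
                                 [2, 5, 50]).set_index("factor")
        fine, mid, coarse = tab.loc[2], tab.loc[5], tab.loc[50]
        assert abs(fine.mfpt_ps - mid.mfpt_ps) / mid.mfpt_ps < 0.05
        assert coarse.mfpt_ps > 1.20 * mid.mfpt_ps
        assert coarse.total_transitions < mid.total_transitions


def test_merge_stats_pools_segments(milestoning_samplings, milestoning_partition):
    s = milestoning_samplings[3]
    from permeakit.trajectory import split_blocks
    halves = [detect_events(CellSampling(3, b), milestoning_partition)
              for b in split_blocks(s.series, 2)]
    merged = merge_stats(halves)
    assert merged.assigned_time == pytest.approx(sum(h.assigned_time for h in halves))
    assert sum(merged.counts.values()) == sum(sum(h.counts.values()) for h in halves)
    with pytest.raises(ValueError):
        merge_stats([halves[0], detect_events(CellSampling(2, s.series),
                                              milestoning_partition)])
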