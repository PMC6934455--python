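"""Analysis math: block traces, CSPs, shift statistics, superposition,
RMSF, hydrogen bonds and kinetics fits."""

import math

import numpy as np
import pandas as pd
import pytest

from morphmd.analysis import (
    AnalysisConfig,
    block_trace,
    combined_csp,
    compare_shifts,
    ensemble_average_shifts,
    fit_first_order,
    hbond_occupancy,
    mean_structure_displacement,
    rmsf,
    secondary_shifts,
    superpose,
    superpose_trajectory,
)


class TestBlockTrace:
    def test_constant_series(self):
        t = np.arange(10.0)
        rep = block_trace(np.full(10, 4.2), t, 5.0)
        assert np.allclose(rep.means, 4.2)
        assert np.allclose(rep.stds, 0.0)

    def test_two_point_blocks(self):
        rep = block_trace([1.0, 2.0, 3.0, 4.0], [0.0, 1.0, 2.0, 3.0], 2.0)
        assert np.allclose(rep.means, [1.5, 3.5])

    def test_partial_trailing_block_dropped(self):
        rep = block_trace(np.arange(5.0), np.arange(5.0), 2.0)
        assert rep.n_blocks == 2

    def test_block_longer_than_series(self):
        with pytest.raises(ValueError):
            block_trace([1.0, 2.0], [0.0, 1.0], 10.0)


class TestCombinedCSP:
    def test_identical_states_zero(self):
        assert combined_csp(8.1, 120.0, 8.1, 120.0) == 0.0

    def test_hand_value(self):
        # sqrt(0.5 * 0.1^2 + 0.07 * 1.0^2) = sqrt(0.075) = 0.27386...
        v = combined_csp(8.1, 121.0, 8.0, 120.0)
        assert v == pytest.approx(0.27386, abs=1e-5)

    def test_nitrogen_only(self):
        # sqrt(0.07) = 0.26458
        assert combined_csp(8.0, 121.0, 8.0, 120.0) == pytest.approx(0.26458, abs=1e-5)

    def test_symmetric_in_states(self):
        a = combined_csp(8.3, 118.0, 7.9, 121.5)
        b = combined_csp(7.9, 121.5, 8.3, 118.0)
        assert a == b

    def test_zero_iff_both_differences_zero(self):
        assert combined_csp(8.0, 120.0, 8.0, 120.1) > 0
        assert combined_csp(8.01, 120.0, 8.0, 120.0) > 0


def _table(rows):
    return pd.DataFrame(rows, columns=["resid", "resname", "atom", "nucleus", "shift_ppm"])


class TestEnsembleAverage:
    def test_identical_frames_identity(self):
        t = _table([(1, "ALA", "CA", "13Ca", 52.0)])
        avg, dropped = ensemble_average_shifts([t, t.copy()])
        assert avg["shift_ppm"].iloc[0] == 52.0
        assert dropped == []

    def test_two_frame_mean(self):
        t1 = _table([(1, "ALA", "CA", "13Ca", 1.0)])
        t2 = _table([(1, "ALA", "CA", "13Ca", 2.0)])
        avg, _ = ensemble_average_shifts([t1, t2])
        assert avg["shift_ppm"].iloc[0] == pytest.approx(1.5)

    def test_incomplete_key_dropped_and_reported(self):
        t1 = _table([(1, "ALA", "CA", "13Ca", 1.0), (2, "GLY", "CA", "13Ca", 3.0)])
        t2 = _table([(1, "ALA", "CA", "13Ca", 2.0)])
        avg, dropped = ensemble_average_shifts([t1, t2])
        assert len(avg) == 1
        assert dropped == [(2, "CA")]

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            ensemble_average_shifts([])


def _shift_frame(values, nucleus="13Ca", atom="CA"):
    return pd.DataFrame(
        {
            "resid": np.arange(1, len(values) + 1),
            "resname": ["ALA"] * len(values),
            "atom": [atom] * len(values),
            "nucleus": [nucleus] * len(values),
            "shift_ppm": values,
            "sec_ppm": values,
        }
    )


class TestCompareShifts:
    def test_perfect_agreement(self):
        t = _shift_frame([50.0, 52.0, 54.0, 56.0])
        comp = compare_shifts(t, t.copy())
        row = comp.row("13Ca")
        assert row["r"] == pytest.approx(1.0)
        assert row["rmsd"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset(self):
        a = _shift_frame([50.0, 52.0, 54.0, 56.0])
        b = a.copy()
        b["sec_ppm"] += 1.0
        comp = compare_shifts(a, b)
        row = comp.row("13Ca")
        assert row["r"] == pytest.approx(1.0)
        assert row["rmsd"] == pytest.approx(1.0)

    def test_anticorrelated(self):
        a = _shift_frame([1.0, 2.0, 3.0])
        b = _shift_frame([-1.0, -2.0, -3.0])
        comp = compare_shifts(a, b)
        assert comp.row("13Ca")["r"] == pytest.approx(-1.0)

    def test_small_class_skipped_with_warning(self):
        a = _shift_frame([1.0, 2.0])
        with pytest.warns(UserWarning, match="fewer than 3"):
            comp = compare_shifts(a, a.copy(), nucleus_classes=("13Ca",))
        assert "13Ca" in comp.skipped

    def test_pooled_carbon_row(self):
        frames = [
            _shift_frame([1.0, 2.0, 3.0], "13Ca", "CA"),
            _shift_frame([4.0, 5.0, 6.0], "13Cb", "CB"),
        ]
        a = pd.concat(frames, ignore_index=True)
        comp = compare_shifts(a, a.copy())
        pooled = comp.row("13C")
        assert pooled is not None and pooled["n"] == 6

    def test_invariant_under_shared_random_coil_catalogue(self):
        """Secondary-shift comparison is unchanged when the same rc table is
        subtracted from both sides (the definition of the secondary shift)."""
        raw = pd.DataFrame(
            {
                "resid": [1, 2, 3, 4],
                "resname": ["ALA", "GLY", "SER", "VAL"],
                "atom": ["CA"] * 4,
                "nucleus": ["13Ca"] * 4,
                "shift_ppm": [52.0, 45.1, 58.3, 62.0],
            }
        )
        other = raw.copy()
        other["shift_ppm"] += np.array([0.3, -0.2, 0.1, 0.4])
        rc = pd.DataFrame(
            {
                "resname": ["ALA", "GLY", "SER", "VAL"],
                "atom": ["CA"] * 4,
                "rc_ppm": [50.0, 44.0, 57.0, 61.0],
            }
        )
        direct = compare_shifts(raw.assign(sec_ppm=raw.shift_ppm),
                                other.assign(sec_ppm=other.shift_ppm))
        corrected = compare_shifts(secondary_shifts(raw, rc), secondary_shifts(other, rc))
        assert corrected.row("13Ca")["rmsd"] == pytest.approx(direct.row("13Ca")["rmsd"])


class TestSuperpose:
    def test_identity(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(6, 3))
        r, t, rmsd = superpose(x, x)
        assert np.allclose(r, np.eye(3), atol=1e-10)
        assert np.allclose(t, 0.0, atol=1e-10)
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_recovers_constructed_rotation(self):
        x = np.array([[1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0], [1.0, 1.0, 0]])
        rot90 = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        y = x @ rot90.T + np.array([2.0, -1.0, 0.5])
        r, t, rmsd = superpose(x, y)
        assert np.max(np.abs(r - rot90)) < 1e-8
        assert rmsd < 1e-8
        assert np.linalg.det(r) == pytest.approx(1.0)

    def test_collinear_selection_rejected(self):
        x = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]])
        with pytest.raises(ValueError, match="collinear|degenerate"):
            superpose(x, x + 1.0)

    def test_noise_rmsd_scaling(self):
        """With isotropic noise sigma the fitted rmsd approaches
        sigma*sqrt(3) from below (the rigid fit absorbs ~6 degrees of
        freedom), verified by Monte-Carlo simulation."""
        rng = np.random.default_rng(1)
        ref = rng.normal(scale=3.0, size=(100, 3))
        for sigma in (0.05, 0.1):
            vals = []
            for _ in range(40):
                noisy = ref + rng.normal(scale=sigma, size=ref.shape)
                vals.append(superpose(noisy, ref)[2])
            mean_rmsd = np.mean(vals)
            upper = sigma * math.sqrt(3.0)
            lower = sigma * math.sqrt(3.0) * math.sqrt(1.0 - 6.0 / (3 * len(ref)))
            assert 0.9 * lower <= mean_rmsd <= 1.02 * upper


class TestRmsf:
    def test_rigid_translations_give_zero(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(8, 3))
        frames = [base + shift for shift in ([0, 0, 0], [1, 2, 3], [-2, 0.5, 1])]
        assert np.max(rmsf(frames)) < 1e-10

    def test_two_point_alternation_half_distance(self):
        """An atom alternating between two points distance d apart has
        rmsf d/2 when frames are balanced."""
        base = np.array([[0.0, 0, 0], [3.0, 0, 0], [0, 3.0, 0], [0, 0, 3.0]])
        moved = base.copy()
        moved[0, 0] += 1.0  # d = 1 for atom 0
        frames = [base, moved, base, moved]
        vals = rmsf(frames, superposition_selection=[1, 2, 3], presuperposed=True)
        assert vals[0] == pytest.approx(0.5)

    def test_matches_bruteforce_loop(self):
        rng = np.random.default_rng(3)
        frames = [rng.normal(size=(5, 3)) for _ in range(10)]
        fitted = superpose_trajectory(frames, frames[0])
        expected = np.sqrt(
            np.mean(
                [np.sum((f - fitted.mean(axis=0)) ** 2, axis=1) for f in fitted],
                axis=0,
            )
        )
        assert np.allclose(rmsf(frames), expected, atol=1e-12)

    def test_single_frame_warns_and_zeroes(self):
        with pytest.warns(UserWarning):
            out = rmsf([np.zeros((4, 3))])
        assert np.all(out == 0)


class TestMeanStructureDisplacement:
    def test_same_trajectory_zero(self):
        rng = np.random.default_rng(4)
        frames = [rng.normal(size=(6, 3)) for _ in range(4)]
        d = mean_structure_displacement(frames, list(frames))
        assert np.max(d) < 1e-10

    def test_translation_removed_by_superposition(self):
        rng = np.random.default_rng(5)
        frames = [rng.normal(size=(6, 3)) for _ in range(4)]
        shifted = [f + np.array([5.0, -2.0, 1.0]) for f in frames]
        d = mean_structure_displacement(frames, shifted)
        assert np.max(d) < 1e-8

    def test_constructed_two_frame_means(self):
        base = np.array([[0.0, 0, 0], [4.0, 0, 0], [0, 4.0, 0], [0, 0, 4.0], [2.0, 2.0, 0]])
        a1 = base.copy()
        a2 = base.copy()
        b1 = base.copy()
        b2 = base.copy()
        b1[4] = [2.0, 2.0, 1.0]
        b2[4] = [2.0, 2.0, 3.0]
        d = mean_structure_displacement(
            [a1, a2], [b1, b2], superposition_selection=[0, 1, 2, 3]
        )
        # mean of b for atom 4 is (2,2,2); mean of a is (2,2,0) -> distance 2
        assert d[4] == pytest.approx(2.0, abs=1e-10)
        assert np.allclose(d[:4], 0.0, atol=1e-10)

    def test_mismatched_atom_sets_rejected(self):
        with pytest.raises(ValueError):
            mean_structure_displacement([np.zeros((4, 3))], [np.zeros((5, 3))])


class TestHbondOccupancy:
    def _frame(self, angle_deg, da=2.9):
        # donor at origin, hydrogen along x, acceptor at the given D-H-A angle
        h = np.array([1.0, 0.0, 0.0])
        ang = math.radians(angle_deg)
        acc = h + (da - 1.0) * np.array([math.cos(math.pi - ang), math.sin(math.pi - ang), 0.0]) * -1
        return np.vstack([[0.0, 0.0, 0.0], h, acc])

    def test_always_satisfied(self):
        frame = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.9, 0, 0]])
        assert hbond_occupancy([frame] * 5, 0, 1, 2) == 1.0

    def test_never_satisfied(self):
        frame = np.array([[0.0, 0, 0], [1.0, 0, 0], [9.0, 0, 0]])
        assert hbond_occupancy([frame] * 5, 0, 1, 2) == 0.0

    def test_counting(self):
        good = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.9, 0, 0]])
        bad = np.array([[0.0, 0, 0], [1.0, 0, 0], [9.0, 0, 0]])
        frames = [good] * 3 + [bad] * 7
        assert hbond_occupancy(frames, 0, 1, 2) == pytest.approx(0.3)

    def test_angle_criterion(self):
        # linear D-H...A passes; a 90-degree arrangement fails
        linear = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.9, 0, 0]])
        bent = np.array([[0.0, 0, 0], [1.0, 0, 0], [1.0, 1.5, 0]])
        cfg = AnalysisConfig()
        assert hbond_occupancy([linear], 0, 1, 2, cfg) == 1.0
        assert hbond_occupancy([bent], 0, 1, 2, cfg) == 0.0


class TestKinetics:
    def test_noiseless_decay_recovers_half_life(self):
        tau = 41.5
        t = np.linspace(0.0, 200.0, 12)
        y = 3.0 * np.exp(-t * math.log(2) / tau) + 0.4
        fit = fit_first_order(t, y, "decay")
        assert abs(fit.half_life - tau) / tau < 1e-3
        assert fit.identifiable

    def test_noiseless_buildup_recovers_half_life(self):
        tau = 41.5
        t = np.linspace(0.0, 200.0, 12)
        y = 2.0 * (1.0 - np.exp(-t * math.log(2) / tau)) + 0.1
        fit = fit_first_order(t, y, "buildup")
        assert abs(fit.half_life - tau) / tau < 1e-3

    def test_constant_series_flagged(self):
        fit = fit_first_order(np.arange(6.0), np.full(6, 2.0), "decay")
        assert not fit.identifiable
        assert abs(fit.amplitude) < 1e-6

    def test_noisy_monte_carlo_recovery(self):
        """5% Gaussian noise, 50 replicates: median half-life error < 5%."""
        tau = 41.5
        rng = np.random.default_rng(6)
        # a back-to-back series: 48 spectra over ~5 half-lives
        t = np.linspace(0.0, 200.0, 48)
        clean = 3.0 * np.exp(-t * math.log(2) / tau) + 0.4
        errs = []
        for _ in range(50):
            y = clean + rng.normal(scale=0.05 * 3.0, size=t.size)
            fit = fit_first_order(t, y, "decay")
            errs.append(abs(fit.half_life - tau) / tau)
        assert np.median(errs) < 0.05

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_first_order([0.0, 1.0, 2.0], [3.0, 2.0, 1.0], "decay")


class TestPredictorAdapter:
    def test_reads_predictor_style_columns(self, tmp_path):
        from morphmd.analysis import read_predictor_table

        path = tmp_path / "pred.tab"
        path.write_text(
            "RESID RESNAME ATOMNAME SHIFT RC_SHIFT\n"
            "1 ALA CA 52.2 50.0\n"
            "1 ALA N 121.3 123.0\n"
            "2 GLY HN 8.1 8.3\n"
        )
        df = read_predictor_table(path)
        assert list(df.columns) == [
            "resid", "resname", "atom", "nucleus", "shift_ppm", "rc_ppm", "sec_ppm"
        ]
        assert df["nucleus"].tolist() == ["13Ca", "15N", "1HN"]
        assert df["sec_ppm"].iloc[0] == pytest.approx(2.2)
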