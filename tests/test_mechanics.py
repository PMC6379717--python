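"""Step parameters, segment aggregates, stiffness and diagnostics."""

import numpy as np
import pandas as pd
import pytest

from methylflex.constants import kbt
from methylflex.geom3d import rotation_about_axis
from methylflex.mechanics import (compute_step_parameters,
                                  conditional_twist_stats, gaussianity_check,
                                  relative_change, segment_aggregate,
                                  step_parameters_from_frames, step_rotation,
                                  stiffness)
from methylflex.synth.backbone import (TwoStateBackboneModel,
                                       generate_backbone_series)
from methylflex.synth.duplex import DuplexBuildSpec, build_ideal_duplex
from methylflex.synth.helical import (HelicalMixtureModel,
                                      generate_helical_series,
                                      sample_from_stiffness)

KT300 = kbt(300.0)


class TestStepParameters:
    def test_roll_perturbation_recovered(self):
        """Rotating one base pair by 10 deg about the mid-frame y axis
        adds ~10 deg roll to the flanking step only."""
        arr = build_ideal_duplex(DuplexBuildSpec("GCGATCGC"))
        series0, (rot, orig) = compute_step_parameters(
            arr.coord, arr.atom_name, arr.res_id, arr.chain_id,
            arr.res_name, return_frames=True)
        # rotate bp 5 (chain A res 5 + chain B res 4) about its own y axis
        R5, o5 = rot[0, 4], orig[0, 4]
        Ry = R5 @ rotation_about_axis([0, 1, 0], 10.0) @ R5.T
        sel = (((arr.chain_id == "A") & (arr.res_id == 5))
               | ((arr.chain_id == "B") & (arr.res_id == 4)))
        coords = arr.coord.astype(float).copy()
        coords[sel] = (coords[sel] - o5) @ Ry.T + o5
        series1 = compute_step_parameters(coords, arr.atom_name, arr.res_id,
                                          arr.chain_id, arr.res_name)
        d_roll = (series1.set_index("step")["roll"]
                  - series0.set_index("step")["roll"])
        d_tilt = (series1.set_index("step")["tilt"]
                  - series0.set_index("step")["tilt"])
        # each flanking step gains a 10-deg hinge rotation whose roll
        # component is 10*cos(twist/2) in the mid-frame decomposition
        expected_roll = 10.0 * np.cos(np.radians(18.0))
        for s in (4, 5):
            assert abs(d_roll[s]) == pytest.approx(expected_roll, abs=0.1)
            assert np.hypot(d_roll[s], d_tilt[s]) == pytest.approx(10.0,
                                                                   abs=0.1)
        assert np.sign(d_roll[4]) == -np.sign(d_roll[5])
        far = d_roll.drop([4, 5]).abs().max()
        assert far < 1e-6

    def test_round_trip_of_random_steps(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            tilt, roll, twist = rng.uniform([-15, -15, 15], [15, 15, 45])
            R1 = rotation_about_axis(rng.normal(size=3),
                                     rng.uniform(0, 360))
            R2 = R1 @ step_rotation(tilt, roll, twist)
            df = step_parameters_from_frames(
                np.array([R1, R2]), np.array([[0, 0, 0], [0, 0, 3.38]]))
            got = df.iloc[0][["tilt", "roll", "twist"]].to_numpy()
            assert np.allclose(got, [tilt, roll, twist], atol=1e-8)


class TestSegmentAggregate:
    def test_straight_duplex_zero_bend(self):
        arr = build_ideal_duplex(DuplexBuildSpec("GCGATCGC"))
        series, frames = compute_step_parameters(
            arr.coord, arr.atom_name, arr.res_id, arr.chain_id,
            arr.res_name, return_frames=True)
        agg = segment_aggregate(series, [3, 4, 5, 6], frames=frames)
        assert agg["bend"].iloc[0] == pytest.approx(0.0, abs=1e-6)
        assert agg["twist"].iloc[0] == pytest.approx(36.0, abs=1e-6)
        assert agg["stretch"].iloc[0] == pytest.approx(3.38, abs=1e-6)

    def test_equal_twists_average_passthrough(self):
        rows = [(s, 0, 0, 0, 3.2, 0, 0, 34.0) for s in range(1, 5)]
        df = pd.DataFrame(rows, columns=["step", "frame", "shift", "slide",
                                         "rise", "tilt", "roll", "twist"])
        agg = segment_aggregate(df, [1, 2, 3, 4])
        assert agg["twist"].iloc[0] == 34.0
        assert agg["stretch"].iloc[0] == pytest.approx(3.2)

    def test_four_10deg_rolls_bend_40(self):
        """Four consecutive 10-deg rolls about parallel axes compose to
        a 40-deg bend (both the frame path and the composition path)."""
        rows = [(s, 0, 0, 0, 3.38, 0.0, 10.0, 0.0) for s in range(1, 5)]
        df = pd.DataFrame(rows, columns=["step", "frame", "shift", "slide",
                                         "rise", "tilt", "roll", "twist"])
        agg = segment_aggregate(df, [1, 2, 3, 4])
        assert agg["bend"].iloc[0] == pytest.approx(40.0, abs=1e-8)
        # frame path: synthesize pair frames by composing the same steps
        R = [np.eye(3)]
        for _ in range(4):
            R.append(R[-1] @ step_rotation(0.0, 10.0, 0.0))
        rot = np.array(R)[None]
        orig = np.zeros((1, 5, 3))
        series = step_parameters_from_frames(rot[0], orig[0])
        agg2 = segment_aggregate(series, [1, 2, 3, 4], frames=(rot, orig))
        assert agg2["bend"].iloc[0] == pytest.approx(40.0, abs=1e-8)

    def test_missing_step_rejected(self):
        df = pd.DataFrame([(1, 0, 0, 0, 3.4, 0, 0, 36.0)],
                          columns=["step", "frame", "shift", "slide",
                                   "rise", "tilt", "roll", "twist"])
        with pytest.raises(ValueError, match="missing"):
            segment_aggregate(df, [1, 2])


class TestStiffness:
    def test_1d_closed_form(self):
        """sigma = 7.2 deg at 300 K gives K = kT/sigma^2 = 0.0115
        kcal/(mol deg^2)."""
        rng = np.random.default_rng(3)
        x = rng.normal(36.0, 7.2, 2_000_00)
        df = pd.DataFrame({"frame": range(len(x)), "twist": x})
        res = stiffness(df, temperature=300.0)
        k = res.stiffness[0, 0]
        assert k == pytest.approx(KT300 / 7.2**2, rel=0.02)
        assert k == pytest.approx(0.0115, abs=0.0005)

    def test_3d_recovery_within_5_percent(self):
        sd = np.sqrt([0.0115, 0.45, 0.02])
        corr = 0.5 * np.ones((3, 3)) + 0.5 * np.eye(3)
        K0 = np.outer(sd, sd) * corr
        df = sample_from_stiffness(K0, 300.0, 100_000, seed=5)
        res = stiffness(df, temperature=300.0)
        assert np.all(np.abs(res.stiffness - K0) <= 0.05 * np.abs(K0))

    def test_kc_identity(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(5000, 3)) @ np.diag([1.0, 0.3, 5.0])
        res = stiffness(pd.DataFrame(X, columns=["a", "b", "c"]),
                        temperature=300.0)
        ident = res.stiffness @ res.covariance / KT300
        assert np.allclose(ident, np.eye(3), atol=1e-8)

    def test_singular_covariance_rejected(self):
        A = np.random.default_rng(0).normal(size=(100, 2))
        X = np.column_stack([A, A.sum(axis=1)])  # exactly collinear
        with pytest.raises(np.linalg.LinAlgError, match="condition"):
            stiffness(pd.DataFrame(X, columns=["a", "b", "c"]))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="samples"):
            stiffness(pd.DataFrame(np.zeros((3, 3)),
                                   columns=["a", "b", "c"]))


class TestRelativeChange:
    def test_identity_zero(self):
        df = sample_from_stiffness(np.diag([0.02, 0.3]), 300.0, 5000, seed=1,
                                   names=("twist", "bend"))
        res = stiffness(df)
        out = relative_change(res, res)
        assert np.allclose(out["stiffness_change_percent"], 0.0)
        assert np.allclose(out["mean_change_percent"].fillna(0.0), 0.0)

    def test_halved_diagonal_minus_50(self):
        rng = np.random.default_rng(2)
        a = stiffness(pd.DataFrame(rng.normal(0, 1, (20000, 2)),
                                   columns=["twist", "bend"]))
        b = stiffness(pd.DataFrame(
            rng.normal(0, np.sqrt(2), (20000, 2)),
            columns=["twist", "bend"]))
        out = relative_change(a, b)
        assert np.allclose(out["stiffness_change_percent"], -50.0, atol=5.0)

    def test_configured_40_percent_softening_recovered(self):
        """A condition generated with 40% lower bending stiffness is
        recovered as ~-40% within 5 points."""
        K_ref = np.diag([0.0115, 0.45, 0.02])
        K_mod = K_ref.copy()
        K_mod[2, 2] *= 0.6
        names = ("twist", "stretch", "bend")
        a = stiffness(sample_from_stiffness(K_ref, 300.0, 100_000, seed=11,
                                            names=names))
        b = stiffness(sample_from_stiffness(K_mod, 300.0, 100_000, seed=12,
                                            names=names))
        out = relative_change(a, b).set_index("variable")
        assert abs(out.loc["bend", "stiffness_change_percent"]
                   - (-40.0)) <= 5.0

    def test_unit_mismatch_rejected(self):
        rng = np.random.default_rng(3)
        a = stiffness(pd.DataFrame(rng.normal(size=(500, 1)),
                                   columns=["twist"]))
        b = stiffness(pd.DataFrame(rng.normal(size=(500, 1)),
                                   columns=["bend"]))
        with pytest.raises(ValueError, match="different variables"):
            relative_change(a, b)


class TestConditionalTwist:
    def _series(self, p_bii, n, seed):
        model = TwoStateBackboneModel(p_bii=p_bii, seed=seed)
        _, track = generate_backbone_series(model, 1, n)
        series = generate_helical_series(HelicalMixtureModel(seed=seed + 1),
                                         track)
        return series, track

    def test_sigmas_recovered(self):
        """Generator sigma(BI)=7.2, sigma(BII)=6.2 at P(BII)=0.1."""
        series, track = self._series(0.1, 100_000, seed=4)
        out = conditional_twist_stats(series, track)
        assert out["sigma_BI"] == pytest.approx(7.2, rel=0.02)
        assert out["sigma_BII"] == pytest.approx(6.2, rel=0.02)
        mix = np.sqrt(0.9 * 7.2**2 + 0.1 * 6.2**2)
        assert 6.2 < out["sigma_total"]
        assert out["sigma_total"] == pytest.approx(mix, rel=0.02)

    def test_law_of_total_variance_exact(self):
        series, track = self._series(0.35, 5000, seed=6)
        out = conditional_twist_stats(series, track)
        merged = series.merge(track[["step", "frame", "label"]],
                              on=["step", "frame"])
        tw = merged["twist"].to_numpy()
        assert out["sigma_total"] == pytest.approx(np.std(tw, ddof=1),
                                                   rel=1e-12)

    def test_all_bi_track(self):
        series, track = self._series(0.0, 20_000, seed=8)
        out = conditional_twist_stats(series, track)
        assert np.isnan(out["sigma_BII"])
        assert out["sigma_total"] == pytest.approx(out["sigma_BI"],
                                                   rel=1e-12)


class TestGaussianity:
    def test_gaussian_rarely_flagged(self):
        """Calibration: pure Gaussians are flagged in < 5% of seeded
        repetitions."""
        rng = np.random.default_rng(0)
        flags = 0
        reps = 100
        for _ in range(reps):
            df = pd.DataFrame({"frame": range(300),
                               "twist": rng.normal(36, 7, 300)})
            out = gaussianity_check(df)
            flags += int(out["flag_bimodal"].iloc[0])
        assert flags / reps < 0.05

    def test_separated_mixture_flagged(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(-4, 1, 400), rng.normal(4, 1, 400)])
        df = pd.DataFrame({"frame": range(800), "twist": x})
        assert gaussianity_check(df)["flag_bimodal"].iloc[0]

    def test_constant_series_degenerate_flag(self):
        df = pd.DataFrame({"frame": range(200), "twist": 36.0})
        out = gaussianity_check(df)
        assert out["flag_degenerate"].iloc[0]
        assert not out["flag_bimodal"].iloc[0]
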