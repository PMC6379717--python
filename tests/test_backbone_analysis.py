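"""Torsions, BI/BII classification, populations, Boltzmann inversion."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from conftest import independent_torsion
from methylflex.backbone import (FreeEnergyProfile,
                                 basin_free_energy_difference, block_error,
                                 classify_substates, compute_dihedral,
                                 delta_g_bii, extract_epsilon_zeta_stack,
                                 free_energy_profile, population_stats,
                                 transition_stats)
from methylflex.constants import kbt
from methylflex.synth.backbone import (TwoStateBackboneModel,
                                       generate_backbone_series)

KT300 = kbt(300.0)  # 0.59616123 kcal/mol


class TestTorsion:
    def test_cis_is_zero(self):
        p = [(1, 0, 0), (0, 0, 0), (0, 0, 1), (1, 0, 1)]
        assert compute_dihedral(*p) == pytest.approx(0.0, abs=1e-12)

    def test_trans_is_180(self):
        p = [(1, 0, 0), (0, 0, 0), (0, 0, 1), (-1, 0, 1)]
        assert compute_dihedral(*p) == pytest.approx(180.0, abs=1e-12)

    def test_matches_independent_formula_on_random_quadruples(self):
        rng = np.random.default_rng(0)
        for _ in range(2000):
            pts = rng.normal(size=(4, 3)) * 3
            try:
                t1 = compute_dihedral(*pts)
            except ValueError:
                continue
            t2 = independent_torsion(*pts)
            assert abs((t1 - t2 + 180) % 360 - 180) < 1e-9

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            compute_dihedral((0, 0, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0))
        with pytest.raises(ValueError, match="collinear"):
            compute_dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))


class TestClassification:
    def test_sign_rule_and_tie_break(self):
        series = pd.DataFrame({
            "step": [1, 1, 1], "strand": 1, "frame": [0, 1, 2],
            "eps_zeta": [-85.0, 70.0, 0.0]})
        track = classify_substates(series)
        assert track["label"].tolist() == ["BI", "BII", "BI"]

    def test_partition_is_exact(self):
        model = TwoStateBackboneModel(p_bii=0.4, seed=0)
        series, _ = generate_backbone_series(model, 2, 1000)
        track = classify_substates(series)
        stats = population_stats(track, n_blocks=2)
        assert stats["p_bi_percent"] + stats["p_bii_percent"] == 100.0


class TestPopulations:
    def test_all_bi_track(self):
        track = pd.DataFrame({"step": 1, "strand": 1,
                              "frame": range(100), "label": "BI"})
        stats = population_stats(track)
        assert stats["p_bi_percent"] == 100.0
        assert stats["error_percent"] == 0.0

    def test_alternating_track(self):
        track = pd.DataFrame({"step": 1, "strand": 1, "frame": range(1000),
                              "label": ["BI", "BII"] * 500})
        assert population_stats(track)["p_bi_percent"] == 50.0

    def test_empty_segment_rejected(self):
        track = pd.DataFrame({"step": [1], "strand": [1], "frame": [0],
                              "label": ["BI"]})
        with pytest.raises(ValueError, match="no records"):
            population_stats(track, segment=[99])


class TestTransitions:
    def test_constant_track(self):
        track = pd.DataFrame({"step": 1, "strand": 1, "frame": range(50),
                              "label": "BI"})
        out = transition_stats(track)
        assert out["n_transitions"].iloc[0] == 0
        assert out["mean_dwell_frames"].iloc[0] == 50

    def test_alternating_track(self):
        n = 40
        track = pd.DataFrame({"step": 1, "strand": 1, "frame": range(n),
                              "label": ["BI", "BII"] * (n // 2)})
        assert transition_stats(track)["n_transitions"].iloc[0] == n - 1

    def test_markov_dwell_matches_rate(self):
        """Two-state symmetric Markov chain with flip rate q: mean dwell
        approaches 1/q frames."""
        rng = np.random.default_rng(3)
        q, n = 0.05, 200_000
        flips = rng.random(n - 1) < q
        labels = np.empty(n, dtype=object)
        labels[0] = "BI"
        state = 0
        lab = ["BI", "BII"]
        for i, f in enumerate(flips, start=1):
            state ^= int(f)
            labels[i] = lab[state]
        track = pd.DataFrame({"step": 1, "strand": 1,
                              "frame": range(n), "label": labels})
        dwell = transition_stats(track)["mean_dwell_frames"].iloc[0]
        n_dwells = n * q
        se = (1 / q) / np.sqrt(n_dwells)
        assert abs(dwell - 1 / q) <= 3 * se

    def test_single_frame_rejected(self):
        track = pd.DataFrame({"step": [1], "strand": [1], "frame": [0],
                              "label": ["BI"]})
        with pytest.raises(ValueError, match=">= 2 frames"):
            transition_stats(track)


class TestFreeEnergyProfile:
    def test_two_bin_closed_form(self):
        """p = 0.9/0.1 at 300 K gives Delta F = kT ln 9 = 1.310 kcal/mol."""
        x = np.concatenate([np.full(9000, -90.0), np.full(1000, 90.0)])
        prof = free_energy_profile(x, bin_width=180.0, temperature=300.0)
        occ = prof.free_energy[prof.occupied()]
        assert occ.min() == 0.0
        assert occ.max() == pytest.approx(KT300 * np.log(9.0), abs=1e-9)
        assert occ.max() == pytest.approx(1.310, abs=0.001)

    def test_uniform_samples_flat_profile(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(-180, 180, 200_000)
        prof = free_energy_profile(x, bin_width=30.0)
        occ = prof.free_energy[prof.occupied()]
        assert np.nanmax(np.abs(occ)) < 0.02

    def test_empty_bins_marked_nan_not_zero(self):
        prof = free_energy_profile(np.full(100, -90.0), bin_width=5.0)
        assert np.isnan(prof.free_energy[~prof.occupied()]).all()

    def test_double_gaussian_matches_analytic_density(self):
        """Boltzmann inversion recovers -kT ln p of the generating
        two-basin density on well-populated bins."""
        rng = np.random.default_rng(7)
        n = 200_000
        w, mu1, mu2, sd = 0.85, -75.0, 70.0, 17.0
        comp = rng.random(n) < w
        x = np.where(comp, rng.normal(mu1, sd, n), rng.normal(mu2, sd, n))
        prof = free_energy_profile(x, bin_width=5.0, temperature=300.0)
        edges = prof.edges
        p_bin = (w * np.diff(norm.cdf(edges, mu1, sd))
                 + (1 - w) * np.diff(norm.cdf(edges, mu2, sd)))
        mask = prof.counts >= 500
        f_ana = -KT300 * np.log(p_bin[mask])
        f_est = prof.free_energy[mask]
        f_ana -= f_ana.min()
        f_est -= f_est.min()
        assert np.max(np.abs(f_est - f_ana)) <= 0.1

    def test_counting_and_inversion_agree(self):
        """Basin populations recomputed through exp(-F/kT) equal direct
        counting to 1e-12 relative."""
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(-75, 15, 5000),
                            rng.normal(70, 15, 2000)])
        prof = free_energy_profile(x, bin_width=5.0)
        p_bi, p_bii = prof.basin_populations()
        w = np.exp(-prof.free_energy[prof.occupied()] / KT300)
        centers = prof.centers[prof.occupied()]
        p_bii_from_f = w[centers > 0].sum() / w.sum()
        assert p_bii_from_f == pytest.approx(p_bii, rel=1e-12)

    def test_no_samples_rejected(self):
        with pytest.raises(ValueError, match="no samples"):
            free_energy_profile(np.array([]))


class TestBlockError:
    def test_identical_blocks_zero_error(self):
        assert block_error(np.tile([1.0, 2.0], 50), n_blocks=5) == 0.0

    def test_iid_gaussian_matches_sampling_theory(self):
        rng = np.random.default_rng(11)
        n_blocks, reps = 5, 100
        errs = [block_error(rng.normal(0, 1, 1000), n_blocks)
                for _ in range(reps)]
        expected = 1.0 / np.sqrt(1000 / n_blocks) / np.sqrt(n_blocks)
        assert np.mean(errs) == pytest.approx(expected, rel=0.3)

    def test_more_blocks_than_frames_rejected(self):
        with pytest.raises(ValueError, match="blocks"):
            block_error(np.arange(3), n_blocks=5)


class TestBasinFreeEnergy:
    def test_closed_form_at_case_population(self):
        """P(BI) = 83.6% gives dG(BI->BII) = +0.971 kcal/mol at 300 K."""
        n = 1_000_000
        n_bii = int(round(n * 0.164))
        x = np.concatenate([np.full(n - n_bii, -75.0), np.full(n_bii, 70.0)])
        prof = free_energy_profile(x, bin_width=5.0, temperature=300.0)
        assert delta_g_bii(prof) == pytest.approx(
            -KT300 * np.log(16.4 / 83.6), abs=1e-9)
        assert delta_g_bii(prof) == pytest.approx(0.971, abs=0.001)

    def test_identical_profiles_zero_ddg(self):
        x = np.concatenate([np.full(800, -75.0), np.full(200, 70.0)])
        prof = free_energy_profile(x)
        out = basin_free_energy_difference(prof, prof)
        assert out["delta_delta_g"] == 0.0

    def test_known_offset_recovered(self):
        """A configured BII-basin free-energy offset between two
        generated conditions is recovered from the profiles."""
        offset = 1.2  # kcal/mol
        p_a = 0.3
        ratio = (p_a / (1 - p_a)) * np.exp(-offset / KT300)
        p_b = ratio / (1 + ratio)
        rng = np.random.default_rng(13)
        n = 400_000

        def sample(p, seed):
            r = np.random.default_rng(seed)
            comp = r.random(n) < p
            return np.where(comp, r.normal(70, 15, n), r.normal(-75, 15, n))

        prof_a = free_energy_profile(sample(p_a, 1))
        prof_b = free_energy_profile(sample(p_b, 2))
        out = basin_free_energy_difference(prof_a, prof_b)
        assert out["delta_delta_g"] == pytest.approx(offset, abs=0.1)

    def test_empty_basin_rejected(self):
        prof = free_energy_profile(np.full(100, -75.0))
        with pytest.raises(ValueError, match="unoccupied|undefined"):
            delta_g_bii(prof)

    def test_temperature_mismatch_rejected(self):
        x = np.concatenate([np.full(80, -75.0), np.full(20, 70.0)])
        a = free_energy_profile(x, temperature=300.0)
        b = free_energy_profile(x, temperature=310.0)
        with pytest.raises(ValueError, match="temperature"):
            basin_free_energy_difference(a, b)


def test_extract_epsilon_zeta_errors_on_missing_atom(at_duplex):
    arr = at_duplex[~((at_duplex.chain_id == "A") & (at_duplex.res_id == 5)
                      & (at_duplex.atom_name == "O5'"))]
    with pytest.raises(ValueError, match=r"O5' of residue 5"):
        extract_epsilon_zeta_stack(arr)
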