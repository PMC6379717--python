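"""Pseudorotation, weak H-bonds, methyl distances, density maps."""

import numpy as np
import pandas as pd
import pytest

from methylflex.constants import MASS
from methylflex.geometry import (DensityMap2D, HBondCriteria, density_map_2d,
                                 global_res_ids, hbond_flags, hbond_series,
                                 methyl_sugar_distance, pucker_phase,
                                 pucker_series, ring_torsions,
                                 substate_coupling_stats)


def canonical_torsions(phase, tau_m=38.0):
    """Closed-form AS torsion set nu_j = tau_m cos(P + 144(j-2))."""
    return np.array([tau_m * np.cos(np.radians(phase + 144.0 * (j - 2)))
                     for j in range(5)])


class TestPucker:
    @pytest.mark.parametrize("phase,name", [(18.0, "C3'-endo"),
                                            (162.0, "C2'-endo")])
    def test_canonical_anchors(self, phase, name):
        p, amp = pucker_phase(canonical_torsions(phase))
        assert p == pytest.approx(phase, abs=2.0)
        assert amp == pytest.approx(38.0, abs=2.0)

    def test_planar_ring_undefined(self):
        p, amp = pucker_phase(np.zeros(5))
        assert np.isnan(p)
        assert amp == 0.0

    def test_exact_on_closed_form_inputs(self):
        for phase in np.arange(0, 360, 17.0):
            p, amp = pucker_phase(canonical_torsions(phase, 35.0))
            assert abs((p - phase + 180) % 360 - 180) < 1e-9
            assert amp == pytest.approx(35.0, abs=1e-9)

    def test_agrees_with_cremer_pople_construction(self):
        """Rings built with Cremer-Pople displacements measure an AS
        phase that tracks the CP phase up to a fixed convention offset,
        with dispersion < 3 deg over random puckered rings."""
        rng = np.random.default_rng(2)
        radius = 1.53 / (2 * np.sin(np.pi / 5))
        diffs = []
        for _ in range(1000):
            phi = rng.uniform(0, 2 * np.pi)
            q = rng.uniform(0.3, 0.45)
            ring = {}
            for j, name in enumerate(["O4'", "C1'", "C2'", "C3'", "C4'"]):
                th = 2 * np.pi * j / 5
                z = np.sqrt(0.4) * q * np.cos(phi + 4 * np.pi * j / 5)
                ring[name] = np.array([radius * np.cos(th),
                                       radius * np.sin(th), z])
            p_as, _ = pucker_phase(ring_torsions(lambda a: ring[a]))
            diffs.append((p_as - np.degrees(phi)) % 360.0)
        diffs = np.array(diffs)
        mean = np.degrees(np.angle(np.exp(1j * np.radians(diffs)).mean()))
        spread = np.abs((diffs - mean + 180) % 360 - 180)
        assert spread.max() < 3.0


class TestHBonds:
    def geometry(self, d_ho, angle_deg):
        """Donor C, H at origin->x, acceptor placed at given H distance
        and C-H...O angle."""
        c = np.array([[-1.09, 0.0, 0.0]])
        h = np.array([[0.0, 0.0, 0.0]])
        theta = np.radians(180.0 - angle_deg)
        o = np.array([[d_ho * np.cos(theta), d_ho * np.sin(theta), 0.0]])
        return c, h, o

    def test_good_geometry_flagged(self):
        c, h, o = self.geometry(2.2, 165.0)
        assert hbond_flags(c, h, o)["bonded"].iloc[0]

    def test_long_distance_not_flagged(self):
        c, h, o = self.geometry(4.0, 165.0)
        assert not hbond_flags(c, h, o)["bonded"].iloc[0]

    def test_bent_angle_not_flagged(self):
        c, h, o = self.geometry(2.2, 100.0)
        assert not hbond_flags(c, h, o)["bonded"].iloc[0]

    def test_occupancy_counts_planted_fraction(self):
        """35% of frames constructed inside criteria -> occupancy 0.35."""
        n, k = 200, 70
        cg, hg, og = self.geometry(2.2, 165.0)
        cb, hb, ob = self.geometry(4.0, 165.0)
        c = np.vstack([np.repeat(cg, k, 0), np.repeat(cb, n - k, 0)])
        h = np.vstack([np.repeat(hg, k, 0), np.repeat(hb, n - k, 0)])
        o = np.vstack([np.repeat(og, k, 0), np.repeat(ob, n - k, 0)])
        flags = hbond_flags(c, h, o)
        assert flags["bonded"].mean() == k / n

    def test_occupancy_monotone_under_tightening(self):
        rng = np.random.default_rng(4)
        n = 500
        c = rng.normal(0, 1, (n, 3))
        h = c + rng.normal(0, 0.3, (n, 3))
        o = h + rng.normal(1.2, 1.0, (n, 3))
        base = HBondCriteria()
        occ0 = hbond_flags(c, h, o, base)["bonded"].mean()
        for crit in (HBondCriteria(max_h_acceptor=2.0),
                     HBondCriteria(max_donor_acceptor=3.0),
                     HBondCriteria(min_angle=150.0)):
            assert hbond_flags(c, h, o, crit)["bonded"].mean() <= occ0

    def test_invalid_criteria_rejected(self):
        with pytest.raises(ValueError):
            HBondCriteria(max_h_acceptor=-1.0)
        with pytest.raises(ValueError):
            HBondCriteria(min_angle=0.0)

    def test_series_resolves_named_atoms(self, at_duplex):
        gids = global_res_ids(at_duplex.chain_id, at_duplex.res_id)
        occ, flags = hbond_series(at_duplex.coord, at_duplex.atom_name,
                                  gids, (7, "C6"), "H6", (6, "O3'"))
        assert 0.0 <= occ <= 1.0
        with pytest.raises(KeyError, match="resolves to 0"):
            hbond_series(at_duplex.coord, at_duplex.atom_name, gids,
                         (7, "C6"), "H99", (6, "O3'"))


class TestMethylSugarDistance:
    def test_constructed_distance_exact(self):
        """Methyl COM placed 4 A from C2' by construction."""
        names = np.array(["C7", "H71", "H72", "H73", "C2'"])
        res = np.array([2, 2, 2, 2, 1])
        m = np.array([MASS["C"], MASS["H"], MASS["H"], MASS["H"]])
        offsets = np.array([[0.5, 0, 0], [-0.3, 0.4, 0],
                            [-0.3, -0.2, 0.3], [0.1, -0.2, -0.3]])
        com_shift = (offsets * m[:, None]).sum(0) / m.sum()
        coords = np.vstack([offsets - com_shift + [4.0, 0, 0],
                            [[0.0, 0.0, 0.0]]])[None]
        d = methyl_sugar_distance(coords, names, res, 2, 1)
        assert d[0] == pytest.approx(4.0, abs=1e-6)

    def test_matches_independent_oracle_on_random_configs(self):
        rng = np.random.default_rng(8)
        names = np.array(["C7", "H71", "H72", "H73", "C2'"])
        res = np.array([2, 2, 2, 2, 1])
        coords = rng.normal(0, 3, (50, 5, 3))
        d = methyl_sugar_distance(coords, names, res, 2, 1)
        w = np.array([MASS["C"], MASS["H"], MASS["H"], MASS["H"]])
        for f in range(50):
            com = (coords[f, :4] * w[:, None]).sum(0) / w.sum()
            assert d[f] == pytest.approx(
                np.linalg.norm(com - coords[f, 4]), abs=1e-9)

    def test_uracil_marked_not_applicable(self):
        names = np.array(["H5", "C2'"])
        res = np.array([2, 1])
        coords = np.zeros((1, 2, 3))
        assert methyl_sugar_distance(coords, names, res, 2, 1) is None


class TestDensityMap:
    def test_single_point_single_cell(self):
        m = density_map_2d(np.zeros(10), np.zeros(10), bins=5,
                           ranges=[[-1, 1], [-1, 1]])
        assert m.density.sum() == pytest.approx(1.0, abs=1e-12)
        assert (m.density > 0).sum() == 1
        assert m.density.max() == 1.0

    def test_uniform_cells_near_multinomial_expectation(self):
        rng = np.random.default_rng(5)
        n, bins = 200_000, 10
        m = density_map_2d(rng.uniform(0, 1, n), rng.uniform(0, 1, n),
                           bins=bins, ranges=[[0, 1], [0, 1]])
        p = 1.0 / bins**2
        se = np.sqrt(p * (1 - p) / n)
        assert np.abs(m.density - p).max() <= 3.5 * se

    def test_marginals_equal_1d_histograms(self):
        rng = np.random.default_rng(6)
        x, y = rng.uniform(0, 1, 5000), rng.uniform(0, 1, 5000)
        m = density_map_2d(x, y, bins=20, ranges=[[0, 1], [0, 1]])
        hx, _ = np.histogram(x, bins=m.x_edges)
        hy, _ = np.histogram(y, bins=m.y_edges)
        assert np.allclose(m.marginal_x(), hx / len(x), atol=1e-12)
        assert np.allclose(m.marginal_y(), hy / len(y), atol=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length mismatch"):
            density_map_2d(np.zeros(3), np.zeros(4))

    def test_coupling_sign_follows_configuration(self):
        """A generator with BI <-> low-phase coupling yields the
        configured sign of the sample correlation."""
        rng = np.random.default_rng(9)
        n = 20_000
        labels = rng.random(n) < 0.3  # True = BII
        eps_zeta = np.where(labels, rng.normal(70, 15, n),
                            rng.normal(-75, 15, n))
        phase = np.where(labels, rng.normal(170, 10, n),
                         rng.normal(140, 10, n))
        assert np.corrcoef(eps_zeta, phase)[0, 1] > 0.5
        phase_anti = np.where(labels, rng.normal(140, 10, n),
                              rng.normal(170, 10, n))
        assert np.corrcoef(eps_zeta, phase_anti)[0, 1] < -0.5


class TestCouplingStats:
    def make(self, n, mean_bi, mean_bii, seed=0):
        rng = np.random.default_rng(seed)
        labels = np.where(rng.random(n) < 0.4, "BII", "BI")
        phase = np.where(labels == "BII",
                         rng.normal(mean_bii, 8, n),
                         rng.normal(mean_bi, 8, n)) % 360.0
        pucker = pd.DataFrame({"residue": 7, "frame": range(n),
                               "phase": phase, "amplitude": 38.0})
        track = pd.DataFrame({"step": 6, "strand": 1, "frame": range(n),
                              "label": labels})
        return pucker, track

    def test_configured_shift_recovered(self):
        """3'-ring phase 140 deg under BI and 170 deg under BII gives a
        recovered shift of -30 deg within 3 SE."""
        pucker, track = self.make(40_000, 140.0, 170.0, seed=1)
        out = substate_coupling_stats(pucker, track, residue=7, step=6)
        se = max(out["shift_block_error"], 0.2)
        assert abs(out["shift_BI_minus_BII"] - (-30.0)) <= 3 * se

    def test_identical_conditionals_zero_shift(self):
        pucker, track = self.make(40_000, 150.0, 150.0, seed=2)
        out = substate_coupling_stats(pucker, track, residue=7, step=6)
        assert abs(out["shift_BI_minus_BII"]) <= 3 * max(
            out["shift_block_error"], 0.2)

    def test_unpopulated_substate_undefined(self):
        n = 100
        pucker = pd.DataFrame({"residue": 7, "frame": range(n),
                               "phase": 150.0, "amplitude": 38.0})
        track = pd.DataFrame({"step": 6, "strand": 1, "frame": range(n),
                              "label": "BI"})
        out = substate_coupling_stats(pucker, track, residue=7, step=6)
        assert np.isnan(out["mean_phase_BII"])
        assert np.isnan(out["shift_BI_minus_BII"])
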