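"""Euclidean and solvent-accessible surface distances, satisfaction."""

import math

import numpy as np
import pytest

from xlstruct import DistanceConfig, ca_distance, measure_crosslinks, sasd
from xlstruct.distances import (UNREACHABLE, build_access_grid,
                                grid_shortest_path)
from xlstruct.xl_io import AtomRecord, MappedXL, StructureModel
from xlstruct.summarize import UniqueXL

from conftest import helix_chain_model


def point_model(points, model_id="pts", element="C"):
    atoms = [AtomRecord("A", i + 1, "LYS", "CA", tuple(map(float, p)), element)
             for i, p in enumerate(points)]
    return StructureModel(model_id, atoms)


FREE_CFG = DistanceConfig(atom_radii={"C": 0.0}, probe_radius=0.0)


class TestCaDistance:
    def test_identity_is_zero(self, trimer):
        assert ca_distance(trimer, ("A", 7), ("A", 7)) == 0.0

    def test_three_four_five_triangle(self):
        m = point_model([(0, 0, 0), (3, 4, 0)])
        assert ca_distance(m, ("A", 1), ("A", 2)) == pytest.approx(5.0)

    def test_consecutive_helix_residues(self):
        m = helix_chain_model(18)
        for i in range(1, 18):
            assert ca_distance(m, ("A", i), ("A", i + 1)) == pytest.approx(3.8, abs=1e-6)

    def test_symmetry(self, trimer):
        assert ca_distance(trimer, ("A", 7), ("B", 21)) == \
            ca_distance(trimer, ("B", 21), ("A", 7))

    def test_missing_alpha_carbon(self, trimer):
        with pytest.raises(KeyError):
            ca_distance(trimer, ("A", 7), ("Z", 1))


class TestSasd:
    def test_free_space_approaches_euclidean(self):
        m = point_model([(0, 0, 0), (10, 0, 0)])
        s = sasd(m, ("A", 1), ("A", 2), FREE_CFG)
        ed = 10.0
        # lower bound up to discretization; upper bound = 26-connectivity
        # overhead (<8%) plus two half-voxel snaps
        assert ed - 2 * FREE_CFG.grid_spacing <= s <= ed * 1.08 + 2 * FREE_CFG.grid_spacing

    def test_wall_forces_detour(self):
        endpoints = [(0, 0, 0), (10, 0, 0)]
        wall = [(5.0, y, z) for y in range(-9, 10, 2) for z in range(-9, 10, 2)]
        atoms = [AtomRecord("A", i + 1, "LYS", "CA", p, "C")
                 for i, p in enumerate(endpoints)]
        atoms += [AtomRecord("W", i + 1, "ALA", "CA", p, "C")
                  for i, p in enumerate(wall)]
        m = StructureModel("wall", atoms)
        cfg = DistanceConfig(grid_spacing=1.0)
        s = sasd(m, ("A", 1), ("A", 2), cfg)
        ed = ca_distance(m, ("A", 1), ("A", 2))
        assert math.isfinite(s) and s > ed + 5.0

    def test_endpoint_buried_beyond_rescue_radius(self):
        m = point_model([(0, 0, 0), (30, 0, 0)])
        cfg = DistanceConfig(max_search_radius=0.5)  # C vdW+probe = 3.1 A shell
        assert sasd(m, ("A", 1), ("A", 2), cfg) == UNREACHABLE

    def test_symmetry_within_one_grid_step(self, trimer):
        cfg = DistanceConfig(grid_spacing=2.0)
        grid = build_access_grid(trimer, cfg)
        a, b = ("A", 7), ("B", 14)
        s1 = sasd(trimer, a, b, cfg, grid=grid)
        s2 = sasd(trimer, b, a, cfg, grid=grid)
        assert abs(s1 - s2) <= cfg.grid_spacing

    def test_sasd_at_least_ed_minus_discretization(self, trimer):
        cfg = DistanceConfig(grid_spacing=2.0)
        grid = build_access_grid(trimer, cfg)
        for a, b in [(("A", 7), ("A", 21)), (("A", 7), ("B", 14)),
                     (("B", 7), ("C", 7))]:
            s = sasd(trimer, a, b, cfg, grid=grid)
            if math.isfinite(s):
                assert s >= ca_distance(trimer, *(a, b)) - 2 * cfg.grid_spacing

    def test_refining_grid_does_not_inflate_path(self):
        m = point_model([(0, 0, 0), (8, 3, 0)])
        coarse = sasd(m, ("A", 1), ("A", 2),
                      DistanceConfig(atom_radii={"C": 0.0}, probe_radius=0.0,
                                     grid_spacing=2.0))
        fine = sasd(m, ("A", 1), ("A", 2),
                    DistanceConfig(atom_radii={"C": 0.0}, probe_radius=0.0,
                                   grid_spacing=1.0))
        assert fine <= coarse + 2.0  # refinement never worsens beyond overhead


class TestGridShortestPath:
    def test_straight_line_free_grid(self):
        blocked = np.zeros((9, 5, 5), dtype=bool)
        d = grid_shortest_path(blocked, (0, 2, 2), (8, 2, 2), spacing=1.0)
        assert d == pytest.approx(8.0)

    def test_diagonal_costs(self):
        blocked = np.zeros((4, 4, 4), dtype=bool)
        d = grid_shortest_path(blocked, (0, 0, 0), (3, 3, 3), spacing=1.0)
        assert d == pytest.approx(3 * math.sqrt(3))

    def test_blocked_endpoint_unreachable(self):
        blocked = np.zeros((3, 3, 3), dtype=bool)
        blocked[0, 0, 0] = True
        assert grid_shortest_path(blocked, (0, 0, 0), (2, 2, 2)) == UNREACHABLE

    def test_budget_declares_unreachable(self):
        blocked = np.zeros((12, 3, 3), dtype=bool)
        assert grid_shortest_path(blocked, (0, 1, 1), (11, 1, 1),
                                  budget=5.0) == UNREACHABLE

    def test_wall_with_gap_matches_hand_path(self):
        blocked = np.zeros((7, 7, 1), dtype=bool)
        blocked[3, :, 0] = True
        blocked[3, 6, 0] = False  # single gap at the top
        d = grid_shortest_path(blocked, (0, 0, 0), (6, 0, 0), spacing=1.0)
        # around via the gap: diagonal climbs cost sqrt(2)
        assert math.isfinite(d) and d > 6.0


class TestMeasureCrosslinks:
    def _mapped(self, xl, *pairs):
        return MappedXL(xl=xl, candidates=tuple(pairs))

    def test_planted_satisfaction_labels(self, trimer, mapped, planted):
        _, truth = planted
        ms = measure_crosslinks(trimer, mapped, DistanceConfig())
        by_key = {(m.xl.endpoint_a, m.xl.endpoint_b): m for m in ms}
        for t in truth:
            m = by_key[((t["protein_a"], t["position_a"]),
                        (t["protein_b"], t["position_b"]))]
            assert m.satisfied == t["planted_satisfied"]
            assert m.ed == pytest.approx(t["true_ed"])

    def test_multi_candidate_takes_minimum_ed(self):
        m = point_model([(0, 0, 0), (50, 0, 0)])
        atoms = list(m.atoms) + [AtomRecord("B", 1, "LYS", "CA", (15.0, 0, 0), "C")]
        m2 = StructureModel("dimer", atoms)
        xl = UniqueXL(("P", 1), ("P", 99))
        mx = self._mapped(xl, (("A", 1), ("A", 2)), (("A", 1), ("B", 1)))
        out = measure_crosslinks(m2, [mx], DistanceConfig())
        assert out[0].chain_pair_used == ("A", "B")
        assert out[0].ed == pytest.approx(15.0) and out[0].satisfied

    def test_satisfied_count_monotone_in_cutoff(self, trimer, mapped):
        counts = []
        for cutoff in (60.0, 37.0, 25.0, 12.0, 5.0):
            ms = measure_crosslinks(trimer, mapped, DistanceConfig(cutoff=cutoff))
            counts.append(sum(m.satisfied for m in ms))
        assert counts == sorted(counts, reverse=True)

    def test_sasd_criterion_flag(self):
        m = point_model([(0, 0, 0), (10, 0, 0)])
        xl = UniqueXL(("P", 1), ("P", 2))
        cfg = DistanceConfig(atom_radii={"C": 0.0}, probe_radius=0.0,
                             criterion="sasd")
        out = measure_crosslinks(m, [self._mapped(xl, (("A", 1), ("A", 2)))], cfg)
        assert out[0].sasd is not None and out[0].satisfied
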