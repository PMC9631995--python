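import numpy as np
import pytest
from shapely import contains_xy
from shapely.geometry import MultiPoint

from oxoquartet import (
    assemble_core,
    build_quartet,
    cavity_diameter,
    hbond_geometry,
    o6_ring_distances,
    planarity_rmsd,
    stacking_overlap,
    step_parameters,
)
from oxoquartet.core import StructureModel
from oxoquartet.metrics import base_polygon_points

from conftest import random_rotation


def _transformed(struct, rng):
    R = random_rotation(rng)
    t = rng.normal(size=3) * 10
    return struct.transform(R, t)


class TestCavity:
    def test_oxog_cavity_from_printed_diagonal(self, oxog_template):
        q = build_quartet(
            oxog_template, mode="ring_size", value=5.72 / np.sqrt(2)
        )
        assert cavity_diameter(q) == pytest.approx(2.68, abs=0.01)

    def test_g_cavity_from_printed_diagonal(self, g_template):
        q = build_quartet(g_template, mode="ring_size", value=4.50 / np.sqrt(2))
        assert cavity_diameter(q) == pytest.approx(1.46, abs=0.01)

    def test_cavity_equals_diagonal_minus_two_oxygen_radii(self, oxog_quartet):
        _, diag = o6_ring_distances(oxog_quartet)
        assert cavity_diameter(oxog_quartet) == pytest.approx(
            diag - 2 * 1.52, abs=1e-9
        )

    def test_cavity_floors_at_zero(self, oxog_template):
        q = build_quartet(oxog_template, mode="ring_size", value=2.0)
        assert cavity_diameter(q) == 0.0

    def test_cavity_monotone_under_dilation(self, oxog_template):
        values = [
            cavity_diameter(
                build_quartet(oxog_template, mode="ring_size", value=v)
            )
            for v in (3.2, 3.6, 4.0, 4.4)
        ]
        assert values == sorted(values)

    def test_cavity_rigid_motion_invariant(self, oxog_quartet):
        from oxoquartet.metrics import _as_structure

        struct = _as_structure(oxog_quartet)
        base = cavity_diameter(struct)
        moved = _transformed(struct, np.random.default_rng(3))
        assert cavity_diameter(moved) == pytest.approx(base, abs=1e-9)


class TestO6Distances:
    def test_missing_o6_is_an_error(self):
        from oxoquartet import BaseId, get_template
        from oxoquartet.core import Residue

        t = get_template(BaseId.T)
        residues = [
            Residue(
                chain=c,
                number=1,
                resname="DT",
                atoms={a.name: a.position for a in t.atoms},
                elements={a.name: a.element for a in t.atoms},
                plane=0,
            )
            for c in "ABCD"
        ]
        with pytest.raises(KeyError, match="O6"):
            o6_ring_distances(StructureModel(residues=residues))


class TestHbondGeometry:
    def test_linear_bond_sums_distances(self):
        d = np.zeros(3)
        h = np.array([1.03, 0.0, 0.0])
        a = np.array([1.03 + 1.92, 0.0, 0.0])
        geom = hbond_geometry(d, h, a)
        assert geom.d_DA == pytest.approx(2.95, abs=1e-12)
        assert geom.theta_DHA == pytest.approx(180.0)

    def test_law_of_cosines_angle(self):
        """Independent law-of-cosines check: d_DH=1.03, d_HA=1.76,
        d_DA=2.78 implies theta ~ 170 deg."""
        cos_t = (1.03**2 + 1.76**2 - 2.78**2) / (2 * 1.03 * 1.76)
        expected = np.degrees(np.arccos(cos_t))
        d = np.zeros(3)
        h = np.array([1.03, 0.0, 0.0])
        theta = np.radians(180.0 - expected)
        a = h + 1.76 * np.array([np.cos(theta), np.sin(theta), 0.0])
        geom = hbond_geometry(d, h, a)
        assert geom.theta_DHA == pytest.approx(expected, abs=1e-9)
        assert geom.d_DA == pytest.approx(2.78, abs=1e-9)
        assert expected == pytest.approx(170.0, abs=0.5)

    def test_right_angle(self):
        geom = hbond_geometry(
            np.zeros(3), np.array([1.0, 0, 0]), np.array([1.0, 1.9, 0])
        )
        assert geom.theta_DHA == pytest.approx(90.0)

    def test_unbonded_donor_hydrogen_rejected(self):
        with pytest.raises(ValueError, match="covalent"):
            hbond_geometry(np.zeros(3), np.array([1.5, 0, 0]), np.array([3.0, 0, 0]))


class TestStacking:
    def test_eclipsed_planes_overlap_fully(self, g_quartet):
        core = assemble_core([g_quartet, g_quartet], [(3.3, 0.0)])
        struct = core.to_structure()
        res = struct.plane(0)[0]
        full_area = MultiPoint(
            [(p[0], p[1]) for p in base_polygon_points(res)]
        ).convex_hull.area
        assert stacking_overlap(core, 0) == pytest.approx(full_area, rel=1e-6)

    def test_disjoint_projection_gives_zero(self, g_quartet):
        struct = assemble_core([g_quartet, g_quartet], [(3.3, 0.0)]).to_structure()
        # push the upper plane 20 A sideways
        for r in struct.plane(1):
            for name in r.atoms:
                r.atoms[name] = r.atoms[name] + np.array([20.0, 0.0, 0.0])
        assert stacking_overlap(struct, 0) == 0.0

    def test_overlap_vs_monte_carlo_sampling(self, odn4_core):
        """Polygon-clipping area agrees with a seeded point-sampling
        estimate within 1%."""
        from oxoquartet.metrics import (
            _any_perpendicular,
            _heavy_coords,
            _plane_normal,
            _project_polygon,
            _ring_order,
        )

        struct = odn4_core.to_structure()
        k = 1
        lower = _ring_order(struct.plane(k))[0]
        upper = [r for r in struct.plane(k + 1) if r.chain == lower.chain][0]
        low_pts = _heavy_coords(struct.plane(k))
        up_pts = _heavy_coords(struct.plane(k + 1))
        normal = _plane_normal(low_pts) + _plane_normal(up_pts)
        normal /= np.linalg.norm(normal)
        origin = 0.5 * (low_pts.mean(axis=0) + up_pts.mean(axis=0))
        e1 = _any_perpendicular(normal)
        e2 = np.cross(normal, e1)
        p1 = _project_polygon(base_polygon_points(lower), origin, e1, e2)
        p2 = _project_polygon(base_polygon_points(upper), origin, e1, e2)
        exact = p1.intersection(p2).area

        rng = np.random.default_rng(1234)
        minx = min(p1.bounds[0], p2.bounds[0])
        miny = min(p1.bounds[1], p2.bounds[1])
        maxx = max(p1.bounds[2], p2.bounds[2])
        maxy = max(p1.bounds[3], p2.bounds[3])
        n = 1_000_000
        xs = rng.uniform(minx, maxx, n)
        ys = rng.uniform(miny, maxy, n)
        inside = contains_xy(p1, xs, ys) & contains_xy(p2, xs, ys)
        estimate = inside.mean() * (maxx - minx) * (maxy - miny)
        assert estimate == pytest.approx(exact, rel=0.01)

    def test_symmetric_and_bounded(self, odn4_core):
        """Overlap never exceeds the smaller of the two polygon areas."""
        from oxoquartet.metrics import _ring_order

        struct = odn4_core.to_structure()
        for k in range(struct.n_planes - 1):
            ordered = _ring_order(struct.plane(k))
            for s in range(4):
                area = stacking_overlap(struct, k, selector=s)
                res_low = ordered[s]
                res_up = [
                    r for r in struct.plane(k + 1) if r.chain == res_low.chain
                ][0]
                a1 = MultiPoint(
                    [(p[0], p[1]) for p in base_polygon_points(res_low)]
                ).convex_hull.area
                a2 = MultiPoint(
                    [(p[0], p[1]) for p in base_polygon_points(res_up)]
                ).convex_hull.area
                assert 0.0 <= area <= min(a1, a2) + 1e-6

    def test_built_analogue_shows_5prime_bias(self, odn4_core):
        """G->oxoG stacking beats oxoG->G already in the idealized core."""
        five = stacking_overlap(odn4_core, 1)
        three = stacking_overlap(odn4_core, 2)
        assert five > three

    def test_invalid_step_index(self, odn4_core):
        with pytest.raises(IndexError):
            stacking_overlap(odn4_core, 3)


class TestStepParameters:
    @pytest.mark.parametrize("rise,twist", [(2.94, 26.23), (3.21, 26.52), (3.13, 30.0)])
    def test_assembly_extraction_round_trip(self, g_quartet, rise, twist):
        core = assemble_core([g_quartet, g_quartet], [(rise, twist)])
        got = step_parameters(core, 0)
        assert got[0] == pytest.approx(rise, abs=1e-6)
        assert got[1] == pytest.approx(twist, abs=1e-6)

    def test_mixed_plane_round_trip(self, odn4_core):
        for k, (rise, twist) in enumerate(odn4_core.steps):
            got = step_parameters(odn4_core, k)
            assert got[0] == pytest.approx(rise, abs=1e-6)
            assert got[1] == pytest.approx(twist, abs=1e-6)

    def test_half_turn_twist(self, g_quartet):
        core = assemble_core([g_quartet, g_quartet], [(3.3, 180.0)])
        _, twist = step_parameters(core, 0)
        assert abs(twist) == pytest.approx(180.0, abs=1e-6)

    def test_rigid_motion_invariance(self, odn4_core):
        struct = odn4_core.to_structure()
        rng = np.random.default_rng(7)
        moved = _transformed(struct, rng)
        for k in range(struct.n_planes - 1):
            a = step_parameters(struct, k)
            b = step_parameters(moved, k)
            assert b[0] == pytest.approx(a[0], abs=1e-9)
            assert b[1] == pytest.approx(a[1], abs=1e-9)

    def test_index_out_of_range(self, odn4_core):
        with pytest.raises(IndexError):
            step_parameters(odn4_core, 5)


class TestPlanarity:
    def test_ideal_quartet_is_flat(self, oxog_quartet):
        assert planarity_rmsd(oxog_quartet) == pytest.approx(0.0, abs=1e-9)

    def test_matches_svd_plane_fit_oracle(self, oxog_quartet):
        """One base displaced 0.5 A along z; compare against a direct
        best-fit-plane RMSD computed independently."""
        from oxoquartet.metrics import _as_structure, _heavy_coords

        struct = _as_structure(oxog_quartet)
        for name in struct.plane(0)[2].atoms:
            struct.plane(0)[2].atoms[name] = struct.plane(0)[2].atoms[
                name
            ] + np.array([0.0, 0.0, 0.5])
        pts = _heavy_coords(struct.plane(0))
        centered = pts - pts.mean(axis=0)
        # oracle: smallest singular value of the centered cloud
        s = np.linalg.svd(centered, compute_uv=False)
        expected = s[-1] / np.sqrt(len(pts))
        assert planarity_rmsd(struct) == pytest.approx(expected, abs=1e-12)

    def test_rotation_invariant(self, oxog_quartet):
        from oxoquartet.metrics import _as_structure

        struct = _as_structure(oxog_quartet)
        for name in struct.plane(0)[1].atoms:
            struct.plane(0)[1].atoms[name] = struct.plane(0)[1].atoms[
                name
            ] + np.array([0.0, 0.0, 0.3])
        base = planarity_rmsd(struct)
        moved = _transformed(struct, np.random.default_rng(5))
        assert planarity_rmsd(moved) == pytest.approx(base, abs=1e-9)
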