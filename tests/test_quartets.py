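import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oxoquartet import (
    G_HOOGSTEEN_SCHEME,
    OXOG_QUARTET_SCHEME,
    HBondScheme,
    build_quartet,
    o6_ring_distances,
)
from oxoquartet.quartets import (
    InfeasibleGeometryError,
    SchemeMismatchError,
    default_scheme,
    solve_placement_residual,
)

from conftest import random_rotation


class TestSchemes:
    def test_target_count_validation(self):
        with pytest.raises(ValueError):
            HBondScheme(pairs=(("N1", "O8"),), target_HA=(1.9, 1.7))

    def test_scheme_template_mismatch(self, g_template):
        # O8 does not exist on unmodified guanine
        with pytest.raises(SchemeMismatchError):
            OXOG_QUARTET_SCHEME.validate(g_template)

    def test_default_scheme_reverses_for_mirrored_template(self, oxog_template):
        fwd = default_scheme(oxog_template)
        rev = default_scheme(oxog_template.flipped())
        assert rev.pairs == fwd.pairs
        assert rev.directions == tuple(-d for d in fwd.directions)


class TestHbondTargetMode:
    def test_fit_reaches_targets_with_near_linear_bonds(self, oxog_quartet):
        res = solve_placement_residual(oxog_quartet, OXOG_QUARTET_SCHEME)
        assert res < 0.01
        bases = oxog_quartet.residues()
        for k in range(4):
            d1 = np.linalg.norm(bases[k]["H1"] - bases[(k + 1) % 4]["O8"])
            d2 = np.linalg.norm(bases[(k + 1) % 4]["H7"] - bases[k]["O6"])
            assert d1 == pytest.approx(1.92, abs=0.05)
            assert d2 == pytest.approx(1.76, abs=0.05)

    def test_oxog_quartet_ring_size_matches_dft_range(self, oxog_quartet):
        neigh, diag = o6_ring_distances(oxog_quartet)
        # the free fit lands inside the cation-dependent range 3.72-4.04
        assert 3.7 < neigh < 4.1

    def test_inter_base_h1_h7_short_contact(self, oxog_quartet):
        """The quartet brings H1 of one base ~2.3 A from H7 of the next,
        explaining the strong imino-imino NOE."""
        bases = oxog_quartet.residues()
        dmin = min(
            np.linalg.norm(bases[i]["H1"] - bases[j]["H7"])
            for i in range(4)
            for j in range(4)
            if i != j
        )
        assert dmin == pytest.approx(2.3, abs=0.4)

    def test_amino_protons_not_hydrogen_bonded(self, oxog_quartet):
        """oxoG amino protons stay > 2.5 A from every acceptor, consistent
        with their exchange behaviour (not H-bond donors)."""
        bases = oxog_quartet.residues()
        dmin = min(
            np.linalg.norm(bases[i][h] - bases[j][a])
            for i in range(4)
            for j in range(4)
            if i != j
            for h in ("H21", "H22")
            for a in ("O6", "O8", "N3")
        )
        assert dmin > 2.5

    def test_explicit_targets_override_scheme(self, oxog_template):
        q = build_quartet(oxog_template, mode="hbond_target", value=(1.92, 1.76))
        assert solve_placement_residual(q, OXOG_QUARTET_SCHEME) < 0.01

    def test_wrong_target_count_errors(self, oxog_template):
        with pytest.raises(ValueError, match="targets"):
            build_quartet(oxog_template, mode="hbond_target", value=(1.92,))

    def test_infeasible_targets_raise_with_residual(self, oxog_template):
        with pytest.raises(InfeasibleGeometryError) as err:
            build_quartet(oxog_template, mode="hbond_target", value=(25.0, 0.4))
        assert err.value.residual > 0

    def test_mirrored_template_fit_is_mirror_image(self, oxog_template, oxog_quartet):
        flipped = oxog_template.flipped()
        q = build_quartet(flipped, default_scheme(flipped))
        neigh_f, diag_f = o6_ring_distances(q)
        neigh, diag = o6_ring_distances(oxog_quartet)
        assert neigh_f == pytest.approx(neigh, abs=1e-3)
        assert diag_f == pytest.approx(diag, abs=1e-3)


class TestRingSizeMode:
    @pytest.mark.parametrize(
        "ring,expected_diag,tol",
        [
            (3.87, 5.47, 0.02),  # in-plane K+ geometry
            (4.04, 5.72, 0.03),  # no-cation geometry
            (3.72, 5.27, 0.02),  # in-plane Na+ geometry
        ],
    )
    def test_tabulated_ring_sizes_give_printed_diagonals(
        self, oxog_template, ring, expected_diag, tol
    ):
        q = build_quartet(oxog_template, mode="ring_size", value=ring)
        neigh, diag = o6_ring_distances(q)
        assert neigh == pytest.approx(ring, abs=1e-9)
        assert diag == pytest.approx(expected_diag, abs=tol)

    def test_g_quartet_at_reference_ring_size(self, g_quartet):
        neigh, diag = o6_ring_distances(g_quartet)
        assert neigh == pytest.approx(3.15, abs=1e-9)
        # ideal C4 diagonal; the experimental average 4.50 A reflects
        # non-ideal real structures
        assert diag == pytest.approx(3.15 * np.sqrt(2), abs=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(ring=st.floats(min_value=0.5, max_value=8.0))
    def test_diagonal_is_sqrt2_times_neighboring(self, oxog_template, ring):
        q = build_quartet(oxog_template, mode="ring_size", value=ring)
        neigh, diag = o6_ring_distances(q)
        assert abs(diag - np.sqrt(2) * neigh) < 1e-9

    def test_ring_size_requires_o6(self):
        from oxoquartet import BaseId, get_template

        t = get_template(BaseId.T)
        scheme = HBondScheme(pairs=(("N3", "O2"),), target_HA=(1.9,))
        with pytest.raises(SchemeMismatchError, match="O6"):
            build_quartet(t, scheme, mode="ring_size", value=3.0)

    def test_degenerate_zero_ring(self, oxog_template):
        q = build_quartet(oxog_template, mode="ring_size", value=0.0)
        neigh, diag = o6_ring_distances(q)
        assert neigh == pytest.approx(0.0, abs=1e-9)
        assert diag == pytest.approx(0.0, abs=1e-9)


class TestPlacementResidual:
    def test_c4_symmetry_machine_precision(self, oxog_quartet):
        b0 = oxog_quartet.base_coordinates(0)
        from oxoquartet.quartets import _rotz

        for k in range(4):
            expected = b0 @ _rotz(k * np.pi / 2).T
            assert np.allclose(oxog_quartet.base_coordinates(k), expected, atol=1e-12)
            assert np.all(np.abs(oxog_quartet.base_coordinates(k)[:, 2]) < 1e-6)

    def test_off_symmetry_translation_increases_residual(self, oxog_quartet):
        base = solve_placement_residual(oxog_quartet, OXOG_QUARTET_SCHEME)
        bases = [oxog_quartet.base_coordinates(k) for k in range(4)]
        bases[2] = bases[2] + np.array([1.0, 0.0, 0.0])
        perturbed = solve_placement_residual(
            bases, OXOG_QUARTET_SCHEME, template=oxog_quartet.template
        )
        assert perturbed > base + 0.01

    def test_residual_invariant_under_rigid_motion(self, oxog_quartet):
        base = solve_placement_residual(oxog_quartet, OXOG_QUARTET_SCHEME)
        rng = np.random.default_rng(11)
        R = random_rotation(rng)
        t = rng.normal(size=3) * 5
        bases = [
            oxog_quartet.base_coordinates(k) @ R.T + t for k in range(4)
        ]
        moved = solve_placement_residual(
            bases, OXOG_QUARTET_SCHEME, template=oxog_quartet.template
        )
        assert moved == pytest.approx(base, abs=1e-9)

    def test_determinism(self, oxog_template):
        from oxoquartet.quartets import _fit_hbond_cached

        _fit_hbond_cached.cache_clear()
        q1 = build_quartet(oxog_template)
        _fit_hbond_cached.cache_clear()
        q2 = build_quartet(oxog_template)
        assert q1.transform0 == q2.transform0
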