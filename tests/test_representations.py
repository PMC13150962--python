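import numpy as np
import pytest

from conftest import random_rotation
from tmcbench.chem_core import AtomicStructure
from tmcbench.representations import (
    FeaturizerParams,
    LayoutError,
    UnsupportedVariantError,
    featurize_all,
    fit_featurizer,
    real_sph_harm,
)
from tmcbench.synthetic import vertical_charge_variant


def _moved(s, seed):
    R = random_rotation(seed)
    t = np.random.default_rng(seed).normal(size=3)
    return AtomicStructure(
        s.id + "_mv", s.atomic_numbers, s.coordinates @ R.T + t,
        s.total_charge, s.multiplicity, s.metal_index, dict(s.tags),
    )


def _permuted(s, seed):
    rng = np.random.default_rng(seed)
    p = rng.permutation(s.n_atoms)
    metal = None if s.metal_index is None else int(np.where(p == s.metal_index)[0][0])
    return AtomicStructure(
        s.id + "_pm", s.atomic_numbers[p], s.coordinates[p],
        s.total_charge, s.multiplicity, metal, dict(s.tags),
    )


class TestFitContract:
    def test_unseen_element_raises(self, water):
        f = fit_featurizer("slatm", [water])
        ch4 = AtomicStructure(
            "ch4", [6, 1, 1, 1, 1],
            [[0, 0, 0], [0.63, 0.63, 0.63], [-0.63, -0.63, 0.63],
             [-0.63, 0.63, -0.63], [0.63, -0.63, -0.63]],
            0, 1,
        )
        with pytest.raises(LayoutError, match="6"):
            f.transform(ch4)

    def test_fit_determinism(self, small_structures):
        h1 = fit_featurizer("slatm", small_structures).params_hash
        h2 = fit_featurizer("slatm", small_structures).params_hash
        assert h1 == h2

    def test_slatm_bag_enumeration_two_elements(self, water):
        f = fit_featurizer("slatm", [water])
        names = [n for n, _, _ in f.layout]
        assert sum(n.startswith("1b:") for n in names) == 2
        assert sum(n.startswith("2b:") for n in names) == 3
        assert sum(n.startswith("3b:") for n in names) == 4

    def test_layouts_identical_across_transforms(self, small_structures):
        f = fit_featurizer("soap", small_structures)
        v1 = f.transform(small_structures[0])
        v2 = f.transform(small_structures[1])
        assert v1.layout == v2.layout
        assert len(v1.values) == len(v2.values)

    def test_empty_fit_rejected(self):
        with pytest.raises(ValueError):
            fit_featurizer("slatm", [])


class TestSLATM:
    def test_isolated_atom_many_body_zero(self):
        atom = AtomicStructure("fe", [26], [[0, 0, 0]], 0, 5, metal_index=0)
        f = fit_featurizer("slatm", [atom])
        v = f.transform(atom)
        for name, off, length in f.layout:
            if name.startswith(("2b:", "3b:")):
                assert np.all(v.values[off : off + length] == 0.0)
            else:
                assert v.values[off] == 26.0

    def test_rigid_motion_and_permutation_invariance(self, hs_iron_hexaqua):
        f = fit_featurizer("slatm", [hs_iron_hexaqua])
        ref = f.transform(hs_iron_hexaqua).values
        moved = f.transform(_moved(hs_iron_hexaqua, 5)).values
        permuted = f.transform(_permuted(hs_iron_hexaqua, 6)).values
        assert np.abs(moved - ref).max() < 1e-10
        assert np.abs(permuted - ref).max() == 0.0

    def test_diatomic_two_body_quadrature(self):
        # the two-body bag integrates (trapezoid) to (Z^2/2) d^-6
        d = 2.0
        s = AtomicStructure("n2", [7, 7], [[0, 0, 0], [0, 0, d]], 0, 1)
        f = fit_featurizer("slatm", [s])
        v = f.transform(s)
        bag = v.bag("2b:N-N")
        integral = np.trapezoid(bag, f.r_grid)
        assert integral == pytest.approx(49.0 / 2.0 * d**-6, rel=0.02)

    def test_local_variant_requires_metal(self, water):
        f = fit_featurizer("slatm", [water])
        with pytest.raises(UnsupportedVariantError):
            f.transform(water, "local")

    def test_local_contains_metal_bags_only(self, hs_iron_hexaqua):
        f = fit_featurizer("slatm", [hs_iron_hexaqua])
        v = f.transform(hs_iron_hexaqua, "local")
        assert np.all(v.bag("2b:H-O") == 0.0)
        assert np.any(v.bag("2b:O-Fe") != 0.0)


class TestSOAP:
    def test_no_neighbors_zero_vector(self):
        lonely = AtomicStructure("fe", [26], [[0, 0, 0]], 0, 5, metal_index=0)
        f = fit_featurizer("soap", [lonely])
        assert np.all(f.transform(lonely, "local").values == 0.0)

    def test_rotation_invariance(self, hs_iron_hexaqua):
        f = fit_featurizer("soap", [hs_iron_hexaqua])
        ref = f.transform(hs_iron_hexaqua).values
        moved = f.transform(_moved(hs_iron_hexaqua, 8)).values
        denom = np.abs(ref).max()
        assert np.abs(moved - ref).max() / denom < 1e-8

    def test_real_harmonics_addition_theorem(self):
        rng = np.random.default_rng(0)
        u = rng.normal(size=3); u /= np.linalg.norm(u)
        v = rng.normal(size=3); v /= np.linalg.norm(v)
        Yu = real_sph_harm(3, u[None, :])
        Yv = real_sph_harm(3, v[None, :])
        from numpy.polynomial.legendre import legval

        for l in range(4):
            lhs = float((Yu[l] * Yv[l]).sum())
            coeffs = np.zeros(l + 1); coeffs[l] = 1.0
            rhs = (2 * l + 1) / (4 * np.pi) * legval(float(u @ v), coeffs)
            assert lhs == pytest.approx(rhs, abs=1e-12)

    def test_coefficients_match_spherical_quadrature(self):
        # single neighbor: compare c_nlm with direct 3D quadrature of the
        # smeared density against the orthonormal basis x real harmonics
        s = AtomicStructure("fecl", [26, 17], [[0, 0, 0], [0.8, 1.1, -0.6]], 2, 2, metal_index=0)
        params = FeaturizerParams(soap_n_max=3, soap_l_max=2)
        f = fit_featurizer("soap", [s], params)
        coeffs = f.expansion_coefficients(s, 0)[17]

        # quadrature: radial GL x Gauss-Legendre in cos(theta) x uniform phi
        nr, nt, nphi = 140, 60, 120
        xr, wr = np.polynomial.legendre.leggauss(nr)
        rmax = params.soap_r_cut + 5 * params.soap_sigma
        r = 0.5 * rmax * (xr + 1); wr = 0.5 * rmax * wr
        ct, wt = np.polynomial.legendre.leggauss(nt)
        phi = np.linspace(0, 2 * np.pi, nphi, endpoint=False)
        wphi = 2 * np.pi / nphi
        st = np.sqrt(1 - ct**2)
        # grid points
        R = r[:, None, None]
        X = R * st[None, :, None] * np.cos(phi[None, None, :])
        Y = R * st[None, :, None] * np.sin(phi[None, None, :])
        Z = np.broadcast_to(R * ct[None, :, None], X.shape)
        neighbor = s.coordinates[1]
        alpha = 1.0 / (2 * params.soap_sigma**2)
        rho = np.exp(-alpha * ((X - neighbor[0]) ** 2 + (Y - neighbor[1]) ** 2 + (Z - neighbor[2]) ** 2))
        unit = np.stack([X / R, Y / R, Z / R], axis=-1)
        harmonics = real_sph_harm(params.soap_l_max, unit)
        gbasis = np.exp(-f.b[None, :] * r[:, None] ** 2) @ f.W.T  # (nr, n_max)
        weight = (wr * r**2)[:, None, None] * wt[None, :, None] * wphi
        for l in range(params.soap_l_max + 1):
            for n in range(params.soap_n_max):
                integrand = rho * gbasis[:, n][:, None, None]
                for m in range(2 * l + 1):
                    val = float((integrand * harmonics[l][..., m] * weight).sum())
                    assert coeffs[l][n, m] == pytest.approx(val, abs=1e-5)


class TestEigenRep:
    def test_h_atom_vector(self):
        h = AtomicStructure("h", [1], [[0, 0, 0]], 0, 2)
        f = fit_featurizer("eigen", [h])
        v = f.transform(h)
        assert v.values[0] == pytest.approx(-13.6, abs=1e-10)
        assert np.all(v.values[1:] == 0.0)

    def test_charge_variants_differ(self, hs_iron_hexaqua):
        v = vertical_charge_variant(hs_iron_hexaqua)
        f = fit_featurizer("eigen", [hs_iron_hexaqua, v])
        a = f.transform(hs_iron_hexaqua).values
        b = f.transform(v).values
        assert np.linalg.norm(a - b) > 0.0

    def test_spin_states_differ_but_structure_reps_do_not(self, hs_iron_hexaqua):
        singlet = AtomicStructure(
            "ls_like", hs_iron_hexaqua.atomic_numbers, hs_iron_hexaqua.coordinates,
            hs_iron_hexaqua.total_charge, 1, 0,
        )
        both = [hs_iron_hexaqua, singlet]
        fe = fit_featurizer("eigen", both)
        fs = fit_featurizer("slatm", both)
        assert np.linalg.norm(fe.transform(both[0]).values - fe.transform(both[1]).values) > 0
        assert np.array_equal(fs.transform(both[0]).values, fs.transform(both[1]).values)

    def test_local_variant_unsupported(self, hs_iron_hexaqua):
        f = fit_featurizer("eigen", [hs_iron_hexaqua])
        with pytest.raises(UnsupportedVariantError):
            f.transform(hs_iron_hexaqua, "local")

    def test_padding_overflow_raises(self, water, hs_iron_hexaqua):
        f = fit_featurizer("eigen", [water])
        with pytest.raises(LayoutError):
            f.transform(
                AtomicStructure("w2", [8, 1, 1, 8, 1, 1],
                                np.vstack([water.coordinates, water.coordinates + 5.0]),
                                0, 1)
            )


class TestDensityRep:
    def test_closed_shell_halves_identical(self, water):
        f = fit_featurizer("density", [water])
        v = f.transform(water)
        for name, off, length in f.layout:
            half = length // 2
            a = v.values[off : off + half]
            b = v.values[off + half : off + length]
            assert np.abs(a - b).max() == 0.0

    def test_rotation_invariance(self, water):
        f = fit_featurizer("density", [water])
        ref = f.transform(water).values
        moved = f.transform(_moved(water, 13)).values
        assert np.abs(moved - ref).max() < 1e-8

    def test_vertical_pair_metal_blocks_differ(self, hs_iron_hexaqua):
        v = vertical_charge_variant(hs_iron_hexaqua)
        f = fit_featurizer("density", [hs_iron_hexaqua, v])
        a = f.transform(hs_iron_hexaqua, "local").values
        b = f.transform(v, "local").values
        assert np.linalg.norm(a - b) > 0.0


class TestInvariancePropertiesAllReps:
    @pytest.mark.parametrize("rep", ["slatm", "soap", "eigen", "density"])
    @pytest.mark.parametrize("seed", [21, 22])
    def test_rigid_motion(self, rep, seed, hs_iron_hexaqua):
        f = fit_featurizer(rep, [hs_iron_hexaqua])
        ref = f.transform(hs_iron_hexaqua).values
        moved = f.transform(_moved(hs_iron_hexaqua, seed)).values
        scale = max(np.abs(ref).max(), 1.0)
        assert np.abs(moved - ref).max() / scale < 1e-8

    @pytest.mark.parametrize("rep", ["slatm", "soap", "density"])
    def test_permutation_global(self, rep, hs_iron_hexaqua):
        f = fit_featurizer(rep, [hs_iron_hexaqua])
        ref = f.transform(hs_iron_hexaqua).values
        permuted = f.transform(_permuted(hs_iron_hexaqua, 23)).values
        scale = max(np.abs(ref).max(), 1.0)
        assert np.abs(permuted - ref).max() / scale < 1e-12

    def test_vector_length_constant(self, small_structures):
        f = fit_featurizer("eigen", small_structures)
        X = featurize_all(f, small_structures[:6])
        assert X.shape == (6, f.n_features)
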