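import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from corticalmask.normalization import (
    KernelOperator,
    KernelSpec,
    NormParams,
    build_kernel,
    energy,
    model_a_response,
    model_b_response,
    respond,
    stabilization_constant,
)

from conftest import make_toy_index, naive_normalized_response


class TestEnergy:
    def test_hand_example(self):
        assert np.allclose(energy(np.array([2.0, -3.0]), 2.0), [4.0, 9.0])

    def test_zero_and_gamma_one(self):
        y = np.array([0.0, -1.5, 2.0])
        assert np.allclose(energy(y, 1.0), np.abs(y))
        assert energy(np.zeros(3), 2.0).sum() == 0.0

    @given(
        arrays(np.float64, 8, elements=st.floats(-10, 10)),
        st.floats(0.5, 3.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_nonnegative(self, y, gamma):
        assert np.all(energy(y, gamma) >= 0)

    def test_invalid_gamma(self):
        with pytest.raises(ValueError):
            energy(np.ones(3), 0.0)


class TestBuildKernel:
    def test_matches_brute_force_double_loop(self, rng):
        idx = make_toy_index(n_bands=2, side=2)
        w = rng.uniform(0.5, 2.0, idx.n_coeffs)
        c = rng.uniform(0.5, 2.0, idx.n_coeffs)
        spec = KernelSpec(sigma_p=0.3, sigma_f=1.0, sigma_phi=30.0, w=w, c=c)
        H = build_kernel(idx, spec)
        W = idx.extent_deg
        for i in range(idx.n_coeffs):
            for j in range(idx.n_coeffs):
                d = np.abs(idx.positions[i] - idx.positions[j])
                d = np.minimum(d, W - d)
                gp = np.exp(-(d @ d) / (2 * spec.sigma_p**2))
                gf = np.exp(
                    -np.log2(idx.frequency_cpd[i] / idx.frequency_cpd[j]) ** 2
                    / (2 * spec.sigma_f**2)
                )
                dphi = abs(idx.orientation_deg[i] - idx.orientation_deg[j]) % 180
                dphi = min(dphi, 180 - dphi)
                gphi = np.exp(-(dphi**2) / (2 * spec.sigma_phi**2))
                assert H[i, j] == pytest.approx(c[i] * gp * gf * gphi * w[j])

    def test_intra_band_only_zeroes_cross_blocks(self, pyr16):
        idx = pyr16.index
        H = build_kernel(idx, KernelSpec(sigma_p=0.2, intra_band_only=True))
        for bi in idx.band_table:
            for bj in idx.band_table:
                block = H[idx.band_slice(bi.band_id), idx.band_slice(bj.band_id)]
                if bi.band_id != bj.band_id:
                    assert np.all(block == 0.0)
                else:
                    assert np.any(block > 0.0)

    def test_diagonal_entries(self, rng):
        idx = make_toy_index(n_bands=2, side=2)
        w = rng.uniform(0.5, 2.0, idx.n_coeffs)
        c = rng.uniform(0.5, 2.0, idx.n_coeffs)
        C = rng.uniform(0.5, 1.5, (2, 2))
        H = build_kernel(idx, KernelSpec(w=w, c=c, C_int=C))
        for i in range(idx.n_coeffs):
            b = idx.band_id[i]
            assert H[i, i] == pytest.approx(c[i] * C[b, b] * w[i])

    def test_inconsistent_weight_lengths_rejected(self):
        idx = make_toy_index()
        with pytest.raises(ValueError):
            build_kernel(idx, KernelSpec(w=np.ones(3)))

    def test_invalid_widths_rejected(self):
        with pytest.raises(ValueError):
            KernelSpec(sigma_p=-1.0)

    def test_operator_equals_dense_on_real_index(self, pyr16, rng):
        idx = pyr16.index
        w = rng.uniform(0.5, 2.0, idx.n_coeffs)
        c = rng.uniform(0.5, 2.0, idx.n_coeffs)
        for spec in (
            KernelSpec(sigma_p=0.15, sigma_f=1.0, sigma_phi=30.0, w=w, c=c),
            KernelSpec(sigma_p=0.1, intra_band_only=True, c=c),
        ):
            H = build_kernel(idx, spec)
            op = KernelOperator(idx, spec)
            v = rng.normal(size=idx.n_coeffs) ** 2
            assert np.allclose(H @ v, op.matvec(v), rtol=1e-12, atol=1e-14)
            assert np.allclose(H.sum(axis=1), op.row_sums(), rtol=1e-12)


class TestModelA:
    def test_hand_evaluated_example(self):
        idx = make_toy_index(n_bands=2, side=1)
        y = np.array([2.0, -1.0])
        H = np.array([[0.0, 0.5], [0.5, 0.0]])
        params = NormParams(gamma=1.0, b=np.array([1.0, 1.0]), variant="A")
        x = model_a_response(y, params, idx, H)
        assert np.allclose(x, [2.0 / 1.5, -1.0 / 2.0])

    def test_zero_input_zero_output(self):
        idx = make_toy_index()
        params = NormParams(gamma=2.0, b=1.0, variant="A")
        assert np.all(model_a_response(np.zeros(idx.n_coeffs), params, idx) == 0)

    def test_decoupled_limit_is_naka_rushton(self, rng):
        idx = make_toy_index()
        y = rng.normal(size=idx.n_coeffs)
        b = rng.uniform(0.5, 2.0, idx.n_coeffs)
        params = NormParams(gamma=2.0, b=b, variant="A")
        x = model_a_response(y, params, idx, H=np.zeros((idx.n_coeffs,) * 2))
        assert np.allclose(x, np.sign(y) * np.abs(y) ** 2 / b)

    def test_corrupted_denominator_rejected(self):
        idx = make_toy_index(n_bands=1, side=2)
        params = NormParams(gamma=1.0, b=1e-3, variant="A")
        H = np.full((4, 4), -10.0)
        with pytest.raises(ValueError, match="denominator"):
            model_a_response(np.ones(4), params, idx, H)


class TestStabilization:
    def test_trivial_case(self):
        idx = make_toy_index(n_bands=1, side=1)
        params = NormParams(
            gamma=1.0, b=1.0, kappa=1.0, e_star=np.ones(1), variant="B"
        )
        K = stabilization_constant(params, idx, H=np.zeros((1, 1)))
        assert np.allclose(K, 1.0)

    def test_hand_evaluated_three_coefficients(self):
        idx = make_toy_index(n_bands=3, side=1)
        e_star = np.array([1.0, 2.0, 4.0])
        b = np.array([0.5, 1.0, 2.0])
        kappa = np.array([1.0, 0.5, 2.0])
        H = np.array([[0.0, 0.1, 0.0], [0.1, 0.0, 0.1], [0.0, 0.1, 0.0]])
        params = NormParams(gamma=1.0, b=b, kappa=kappa, e_star=e_star, variant="B")
        K = stabilization_constant(params, idx, H)
        expect = kappa * (b + H @ e_star) / e_star
        assert np.allclose(K, expect)
        assert np.allclose(K, [0.7, 0.375, 1.1])

    def test_response_at_reference_energy_is_kappa(self, rng):
        # the invariant that defines the constant: x(e = e*) = sign(y) . kappa
        # for arbitrary valid parameters
        idx = make_toy_index(n_bands=3, side=2)
        n = idx.n_coeffs
        for _ in range(20):
            spec = KernelSpec(
                sigma_p=rng.uniform(0.05, 0.5),
                sigma_f=rng.uniform(0.5, 2.0),
                sigma_phi=rng.uniform(10, 60),
                w=rng.uniform(0.1, 3.0, n),
                c=rng.uniform(0.1, 3.0, n),
            )
            params = NormParams(
                gamma=rng.uniform(0.5, 2.5),
                b=rng.uniform(0.1, 5.0, n),
                kappa=rng.uniform(0.2, 3.0, n),
                e_star=rng.uniform(0.1, 4.0, n),
                kernel=spec,
                variant="B",
            )
            sgn = rng.choice([-1.0, 1.0], n)
            y = sgn * params.e_star ** (1.0 / params.gamma)
            x = model_b_response(y, params, idx)
            kappa = params.resolve_kappa(idx)
            assert np.max(np.abs(x - sgn * kappa) / np.abs(kappa)) < 1e-12

    def test_zero_e_star_rejected(self):
        idx = make_toy_index(n_bands=1, side=1)
        params = NormParams(
            gamma=1.0, b=1.0, e_star=np.zeros(1), variant="B"
        )
        with pytest.raises(ValueError, match="positive"):
            stabilization_constant(params, idx, H=np.zeros((1, 1)))


class TestModelB:
    def test_reduces_to_model_a_with_unit_K(self, rng):
        idx = make_toy_index(n_bands=2, side=2)
        n = idx.n_coeffs
        y = rng.normal(size=n)
        b = rng.uniform(0.5, 2.0, n)
        spec = KernelSpec(sigma_p=0.2, intra_band_only=True)
        pa = NormParams(gamma=2.0, b=b, kernel=spec, variant="A")
        pb = NormParams(
            gamma=2.0, b=b, e_star=np.ones(n), kernel=spec, variant="B"
        )
        H = build_kernel(idx, spec)
        xa = model_a_response(y, pa, idx, H)
        xb = model_b_response(y, pb, idx, H, K=np.ones(n))
        assert np.allclose(xa, xb)

    def test_monotone_in_input_scale(self, rng):
        idx = make_toy_index(n_bands=2, side=2)
        n = idx.n_coeffs
        y = rng.normal(size=n)
        params = NormParams(
            gamma=2.0, b=rng.uniform(0.5, 1.0, n),
            kappa=1.0, e_star=rng.uniform(0.5, 2.0, n),
            kernel=KernelSpec(sigma_p=0.3), variant="B",
        )
        prev = np.zeros(n)
        for t in np.linspace(0.05, 1.0, 12):
            x = np.abs(model_b_response(t * y, params, idx))
            assert np.all(x >= prev - 1e-12)
            prev = x

    def test_bounded_regardless_of_kernel_amplitude(self, rng):
        # the stabilization contract: responses stay bounded however the
        # kernel amplitudes grow
        idx = make_toy_index(n_bands=2, side=2)
        n = idx.n_coeffs
        y = rng.normal(size=n) * 3
        e_star = rng.uniform(0.5, 2.0, n)
        b = rng.uniform(0.5, 1.0, n)
        kappa = rng.uniform(0.5, 2.0, n)
        sup = []
        for amp in (1.0, 1e2, 1e4):
            params = NormParams(
                gamma=2.0, b=b, kappa=kappa, e_star=e_star,
                kernel=KernelSpec(sigma_p=0.3, c=amp), variant="B",
            )
            x = model_b_response(y, params, idx)
            K = stabilization_constant(params, idx)
            e = energy(y, 2.0)
            assert np.all(np.abs(x) <= np.abs(K) * e.max() / b + 1e-9)
            sup.append(np.max(np.abs(x)))
        assert sup[2] < 2.0 * sup[1]  # no divergence with amplitude

    def test_sign_preservation_both_variants(self, rng):
        idx = make_toy_index(n_bands=2, side=2)
        n = idx.n_coeffs
        y = rng.normal(size=n)
        pa = NormParams(gamma=1.5, b=0.5, variant="A")
        pb = NormParams(
            gamma=1.5, b=0.5, e_star=np.ones(n),
            kernel=KernelSpec(sigma_p=0.3), variant="B",
        )
        for params in (pa, pb):
            x = respond(y, params, idx)
            nz = y != 0
            assert np.all(np.sign(x[nz]) == np.sign(y[nz]))

    def test_masking_monotonicity(self, rng):
        # raising the energy of any other coefficient never raises x_i
        idx = make_toy_index(n_bands=2, side=2)
        n = idx.n_coeffs
        y = rng.uniform(0.5, 1.5, n)
        params = NormParams(
            gamma=2.0, b=0.5, kappa=1.0, e_star=np.ones(n),
            kernel=KernelSpec(sigma_p=0.3), variant="B",
        )
        x0 = model_b_response(y, params, idx)
        for j in range(n):
            y2 = y.copy()
            y2[j] *= 3.0
            x2 = model_b_response(y2, params, idx)
            others = np.arange(n) != j
            assert np.all(x2[others] <= x0[others] + 1e-12)


class TestOracleEquivalence:
    @pytest.mark.parametrize("variant", ["A", "B"])
    def test_vectorized_matches_naive_loop(self, rng, variant):
        idx = make_toy_index(n_bands=2, side=4)  # N = 32
        n = idx.n_coeffs
        y = rng.normal(size=n)
        b = rng.uniform(0.3, 2.0, n)
        spec = KernelSpec(
            sigma_p=0.25, w=rng.uniform(0.5, 2.0, n), c=rng.uniform(0.5, 2.0, n),
            intra_band_only=(variant == "A"),
        )
        H = build_kernel(idx, spec)
        if variant == "A":
            params = NormParams(gamma=2.0, b=b, kernel=spec, variant="A")
            x = model_a_response(y, params, idx, H)
            expect = naive_normalized_response(y, b, H, 2.0)
        else:
            e_star = rng.uniform(0.5, 2.0, n)
            params = NormParams(
                gamma=2.0, b=b, e_star=e_star, kernel=spec, variant="B"
            )
            K = stabilization_constant(params, idx, H)
            x = model_b_response(y, params, idx, H)
            expect = naive_normalized_response(y, b, H, 2.0, K)
        assert np.max(np.abs(x - expect)) < 1e-12
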