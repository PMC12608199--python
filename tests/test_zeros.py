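"""Partition-function zeros, heat capacity, decomposition, banding."""

import cmath
import math

import mpmath as mp
import numpy as np
import pytest

from hpfold.core import DEFAULT_PARAMS, HPSequence
from hpfold.enumeration import (
    DensityOfStates,
    PartitionPolynomial,
    build_polynomial,
    enumerate_dos,
)
from hpfold.zeros import (
    band_zeros,
    classify_foldability,
    component,
    decompose,
    find_zeros,
    heat_capacity_direct,
    transition_temperatures,
)


@pytest.fixture(scope="module")
def binomial():
    """4 x^10 + 21: the N=4 homopolymer partition function, with
    closed-form zeros of modulus (21/4)^(1/10) at angles pi(2k+1)/10."""
    dos = DensityOfStates({-10: 4, 0: 21}, HPSequence("HHHH"), DEFAULT_PARAMS)
    return build_polynomial(dos)


def cv_finite_difference(poly, t, h=1e-5):
    """Independent oracle: CV = dU/dT with U = -d ln Z / d beta = -x Z'/Z."""

    def horner(cs, x):
        acc = x * 0
        for c in cs:
            acc = acc * x + c
        return acc

    def u(temp):
        x = mp.e ** (1 / mp.mpf(temp))
        c = [mp.mpf(v) for v in reversed(poly.coefficients)]
        d1 = [v * (len(c) - 1 - i) for i, v in enumerate(c[:-1])]
        return float(-x * horner(d1, x) / horner(c, x))

    return (u(t + h) - u(t - h)) / (2 * h)


class TestFindZeros:
    def test_binomial_closed_form(self, binomial):
        zs = find_zeros(binomial, 60)
        assert len(zs) == 10
        r = (21 / 4) ** (1 / 10)
        expected = sorted(
            (
                complex(r * math.cos(a), r * math.sin(a))
                for a in (math.pi * (2 * k + 1) / 10 for k in range(10))
            ),
            key=lambda z: (round(z.real, 9), z.imag),
        )
        got = sorted(
            (complex(x) for x in zs.roots),
            key=lambda z: (round(z.real, 9), z.imag),
        )
        for a, b in zip(got, expected):
            assert abs(a - b) < 1e-12
        # polished well beyond double precision
        assert max(zs.residuals) < 1e-30

    def test_unit_conjugate_pair(self):
        poly = PartitionPolynomial((1, 0, 1))
        zs = find_zeros(poly, 60)
        got = sorted((complex(r) for r in zs.roots), key=lambda z: z.imag)
        assert abs(got[0] - (-1j)) < 1e-40 and abs(got[1] - 1j) < 1e-40

    def test_negative_real_roots(self):
        poly = PartitionPolynomial((2, 3, 1))  # (x+1)(x+2)
        zs = find_zeros(poly, 60)
        got = sorted(float(r.real) for r in zs.roots)
        assert got == pytest.approx([-2.0, -1.0], abs=1e-40)
        assert all(r.imag == 0 for r in zs.roots)

    def test_conjugate_closure_and_count(self, binomial):
        zs = find_zeros(binomial, 60)
        roots = [complex(r) for r in zs.roots]
        for r in roots:
            assert any(abs(r.conjugate() - s) < 1e-40 for s in roots)
        assert not any(r.imag == 0 and r.real > 1 for r in roots)

    def test_degree_zero_rejected(self):
        with pytest.raises(ValueError):
            find_zeros(PartitionPolynomial((5,)), 30)

    @pytest.mark.parametrize(
        "coeffs",
        [(3, 1, 4, 1, 5), (9, 2, 6, 5, 3, 5, 8), (1, 0, 0, 0, 2, 0, 7)],
    )
    def test_vieta_and_reconstruction(self, coeffs):
        poly = PartitionPolynomial(coeffs)
        zs = find_zeros(poly, 60)
        m = poly.degree
        with mp.workdps(70):
            s = sum(zs.roots)
            p = mp.mpf(1)
            for r in zs.roots:
                p *= r
            assert abs(s - (-mp.mpf(coeffs[-2]) / coeffs[-1])) < mp.mpf(10) ** -40
            assert abs(p - (-1) ** m * mp.mpf(coeffs[0]) / coeffs[-1]) < mp.mpf(10) ** -40
            # re-expand leading * prod (x - x_k) and compare all coefficients
            acc = [mp.mpc(poly.leading)]
            for r in zs.roots:
                nxt = [mp.mpc(0)] * (len(acc) + 1)
                for i, c in enumerate(acc):
                    nxt[i] += c * (-r)
                    nxt[i + 1] += c
                acc = nxt
            for c_exact, c_rec in zip(coeffs, acc):
                assert abs(c_rec - c_exact) < mp.mpf(10) ** -25


class TestHeatCapacity:
    def test_constant_polynomial_is_zero(self):
        poly = PartitionPolynomial((5,))
        assert heat_capacity_direct(poly, 2.5) == 0.0

    def test_vanishes_toward_x_one(self, binomial):
        assert heat_capacity_direct(binomial, 1 + 1e-9) < 1e-12

    def test_domain_error(self, binomial):
        for x in (1.0, 0.5, -2.0):
            with pytest.raises(ValueError):
                heat_capacity_direct(binomial, x)
        with pytest.raises(ValueError):
            component(1j, 1.0)

    def test_matches_finite_difference_oracle(self, binomial):
        for t in (1.2, 2.0, 6.0):  # away from peaks, CV appreciably nonzero
            x = math.exp(1 / t)
            direct = heat_capacity_direct(binomial, x)
            assert direct == pytest.approx(cv_finite_difference(binomial, t), rel=1e-5)

    def test_nonnegative_on_grid(self, binomial):
        for x in np.geomspace(1.001, math.e**2, 100):
            assert heat_capacity_direct(binomial, x) >= 0


class TestComponents:
    def test_vanishes_toward_x_one(self):
        assert abs(component(0.3 + 0.4j, 1 + 1e-12)) < 1e-20

    def test_pair_closed_form_equals_complex_sum(self, binomial):
        zs = find_zeros(binomial, 60)
        zk = complex(next(r for r in zs.roots if r.imag > 0))
        for x in np.geomspace(1.05, 7.0, 40):
            direct = -x * math.log(x) ** 2 * (
                zk / (x - zk) ** 2 + zk.conjugate() / (x - zk.conjugate()) ** 2
            )
            assert abs(direct.imag) < 1e-12
            assert component(zk, x, paired=True) == pytest.approx(
                direct.real, rel=1e-10, abs=1e-12
            )

    def test_some_component_goes_negative_yet_sum_does_not(self, binomial):
        zs = find_zeros(binomial, 60)
        grid = np.geomspace(1.01, math.e**2, 50)
        vals = np.array(
            [[component(complex(r), x, False) for x in grid] for r in zs.roots]
        )
        assert vals.min() < 0
        assert vals.sum(axis=0).min() > -1e-10

    def test_sum_identity_binomial(self, binomial):
        zs = find_zeros(binomial, 60)
        for x in np.geomspace(1.001, math.e**2, 200):
            cv = heat_capacity_direct(binomial, x)
            total = sum(component(complex(r), x, False) for r in zs.roots)
            assert abs(total - cv) / max(1.0, abs(cv)) < 1e-6

    def test_decompose_binomial_profiles(self, binomial):
        zs = band_zeros(find_zeros(binomial, 60))
        profiles = decompose(zs)
        assert len(profiles) == 5  # five conjugate pairs
        assert all(p.paired and not p.peakless for p in profiles)
        # the pair nearest the positive real axis dominates total CV at its peak
        nearest = min(profiles, key=lambda p: abs(cmath.phase(p.root)))
        x_peak = math.exp(1 / nearest.peak_t)
        cv_peak = heat_capacity_direct(binomial, x_peak)
        assert nearest.peak_height > 0.5 * cv_peak
        assert nearest.peak_t == pytest.approx(3.499, abs=0.01)

    def test_lone_real_roots_not_doubled(self):
        poly = PartitionPolynomial((2, 3, 1))
        zs = band_zeros(find_zeros(poly, 60))
        profiles = decompose(zs)
        assert len(profiles) == 2
        assert all(not p.paired for p in profiles)
        x = 1.7
        single = component(-1.0, x, paired=False)
        assert single == pytest.approx(
            -x * math.log(x) ** 2 * (-1.0 / (x + 1.0) ** 2), rel=1e-12
        )


class TestBandsAndTransitions:
    def test_binomial_single_band(self, binomial):
        zs = band_zeros(find_zeros(binomial, 60))
        assert zs.n_bands == 1
        report = transition_temperatures(zs, decompose(zs))
        assert report.t_f is None and report.t_theta is not None

    def test_single_pair_scores_zero(self):
        # two bands exist but there is no third component to cross over
        poly = PartitionPolynomial((6, 0, 5, 0, 1))  # (x^2+2)(x^2+3)
        zs = band_zeros(find_zeros(poly, 60))
        report = classify_foldability(transition_temperatures(zs, decompose(zs)))
        assert report.crossover_score == 0.0 and report.group == 1

    def test_small_chain_end_to_end_sum_identity(self):
        poly = build_polynomial(enumerate_dos("HHPPHH"))
        zs = band_zeros(find_zeros(poly, 60))
        for x in np.geomspace(1.01, math.e**2, 60):
            cv = heat_capacity_direct(poly, x)
            total = sum(component(complex(r), x, False) for r in zs.roots)
            assert abs(total - cv) / max(1.0, abs(cv)) < 1e-6
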