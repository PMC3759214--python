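"""Closed-form size densities: normalization, jump, limits, scale freedom,
and agreement with the first-principles numerical density."""

import math

import numpy as np
import pytest
from scipy import integrate

import metahist as mh
from metahist.density import theorem1_pdf_numeric, history_from_biological

from conftest import toy_history

C = 1e-9
VARIANTS = list(mh.Variant)


def _random_params(rng, variant):
    """A feasible parameter set in cell-count units with A > m."""
    m = 0.5 / C
    lnAm = rng.uniform(0.05, 3.0)
    lnMA = rng.uniform(0.1, 4.0)
    A = m * math.exp(lnAm)
    return mh.ModelParams(
        A=A,
        M=A * math.exp(lnMA),
        a0=0.0 if variant.homogeneous else math.exp(rng.uniform(-8, 1)),
        a1=(-math.exp(rng.uniform(-3, 2)) if variant is mh.Variant.FULL else None),
        b0=math.exp(rng.uniform(-2, 3)),
        b1=math.exp(rng.uniform(-2, 3)),
        variant=variant,
    )


def _quad_mass(d):
    p = d.params
    total = 0.0
    for lo, hi in ((d.m, min(p.A, p.M)), (min(p.A, p.M), p.M)):
        if hi <= lo:
            continue
        val, _ = integrate.quad(
            lambda u: d.pdf(math.exp(u)) * math.exp(u),
            math.log(lo), math.log(hi), limit=200,
        )
        total += val
    return total


class TestNormalization:
    @pytest.mark.parametrize("variant", VARIANTS, ids=lambda v: v.value)
    def test_integrates_to_one(self, variant):
        rng = np.random.default_rng(abs(hash(variant.value)) % 2**31)
        for _ in range(40):
            d = mh.size_density(_random_params(rng, variant))
            assert _quad_mass(d) == pytest.approx(1.0, abs=1e-6)

    def test_patient3_full_model(self, patient3_params):
        d = mh.size_density(patient3_params)
        assert _quad_mass(d) == pytest.approx(1.0, abs=1e-6)

    def test_breakpoint_below_threshold_branch(self):
        # A <= m: single-branch form
        p = mh.ModelParams(
            A=0.4 / C, M=30.0 / C, a0=0.2, b0=3.0, b1=1.0,
            variant=mh.Variant.SURGERY,
        )
        d = mh.size_density(p)
        assert d.jump_ratio() is None
        assert _quad_mass(d) == pytest.approx(1.0, abs=1e-6)


class TestJump:
    @pytest.mark.parametrize("variant", VARIANTS, ids=lambda v: v.value)
    def test_jump_equals_growth_acceleration(self, variant):
        """p(A+)/p(A-) = b0/b1 = gamma1/gamma0 for every variant with A > m."""
        rng = np.random.default_rng(7)
        for _ in range(10):
            p = _random_params(rng, variant)
            d = mh.size_density(p)
            ratio = d.pdf(p.A * (1 + 1e-10)) / d.pdf(p.A * (1 - 1e-10))
            assert ratio == pytest.approx(p.b0 / p.b1, rel=1e-6)

    def test_patient1_printed_value(self, patient1_params):
        d = mh.size_density(patient1_params)
        A = patient1_params.A
        ratio = d.pdf(A * (1 + 1e-9)) / d.pdf(A * (1 - 1e-9))
        assert ratio == pytest.approx(12.00 / 3.41, rel=1e-6)
        assert ratio == pytest.approx(3.5, rel=0.01)  # printed figure caption


class TestNestingLimits:
    def test_full_to_surgery(self, patient1_params):
        ps = patient1_params
        pl = mh.ModelParams(
            A=ps.A, M=ps.M, a0=ps.a0, a1=-1e6, b0=ps.b0, b1=ps.b1,
            variant=mh.Variant.FULL,
        )
        xs = np.geomspace(0.55 / C, 29.0 / C, 60)
        d_full, d_surg = mh.size_density(pl), mh.size_density(ps)
        # compare on the scale-free x*p(x) (order 1)
        assert np.max(np.abs(xs * (d_full.pdf(xs) - d_surg.pdf(xs)))) < 1e-6

    def test_surgery_to_homogeneous(self):
        kw = dict(A=1.85 / C, M=29.74 / C, b0=12.0, b1=3.41)
        p_eps = mh.ModelParams(a0=1e-10, variant=mh.Variant.SURGERY, **kw)
        p_hom = mh.ModelParams(a0=0.0, variant=mh.Variant.SURGERY_HOMOGENEOUS, **kw)
        xs = np.geomspace(0.55 / C, 29.0 / C, 60)
        assert np.max(np.abs(
            xs * (mh.size_density(p_eps).pdf(xs) - mh.size_density(p_hom).pdf(xs))
        )) < 1e-6

    def test_full_to_homogeneous(self):
        kw = dict(A=2.0 / C, M=20.0 / C, b0=5.0, b1=1.0)
        p_eps = mh.ModelParams(a0=1e-10, a1=-1e-10, variant=mh.Variant.FULL, **kw)
        p_hom = mh.ModelParams(a0=0.0, variant=mh.Variant.FULL_HOMOGENEOUS, **kw)
        xs = np.geomspace(0.55 / C, 19.9 / C, 60)
        assert np.max(np.abs(
            xs * (mh.size_density(p_eps).pdf(xs) - mh.size_density(p_hom).pdf(xs))
        )) < 1e-6

    def test_homogeneous_jump_survives_limit(self):
        kw = dict(A=1.85 / C, M=29.74 / C, b0=12.0, b1=3.41)
        d = mh.size_density(
            mh.ModelParams(a0=0.0, variant=mh.Variant.SURGERY_HOMOGENEOUS, **kw)
        )
        A = kw["A"]
        assert d.pdf(A * (1 + 1e-10)) / d.pdf(A * (1 - 1e-10)) == pytest.approx(
            12.0 / 3.41, rel=1e-6
        )


class TestScaleFreedom:
    def test_x_pdf_depends_only_on_ratios(self):
        """x*p(x) is invariant under joint rescaling of (x, m, A, M)."""
        base = dict(a0=0.05, b0=4.0, b1=1.2)
        xs = np.geomspace(0.6, 19.0, 25)
        p1 = mh.ModelParams(A=2.0, M=20.0, variant=mh.Variant.SURGERY, **base)
        ref = xs * mh.size_density(p1, m=0.5).pdf(xs)
        for k in (1e3, 1e9):
            pk = mh.ModelParams(A=2.0 * k, M=20.0 * k, variant=mh.Variant.SURGERY, **base)
            val = (xs * k) * mh.size_density(pk, m=0.5 * k).pdf(xs * k)
            np.testing.assert_allclose(val, ref, rtol=1e-12)


class TestCdf:
    def test_endpoints(self, patient1_params):
        d = mh.size_density(patient1_params)
        assert d.cdf(d.m) == pytest.approx(0.0, abs=1e-12)
        assert d.cdf(patient1_params.M) == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("variant", VARIANTS, ids=lambda v: v.value)
    def test_matches_quadrature(self, variant):
        rng = np.random.default_rng(11)
        p = _random_params(rng, variant)
        d = mh.size_density(p)
        for q in (0.7, 1.3, 2.5):
            x0 = d.m * q if d.m * q < p.M else p.M * 0.9
            expected = 0.0
            for lo, hi in ((d.m, min(p.A, x0)), (min(p.A, x0), x0)):
                if hi > lo:
                    expected += integrate.quad(
                        lambda u: d.pdf(math.exp(u)) * math.exp(u),
                        math.log(lo), math.log(hi), limit=200,
                    )[0]
            assert d.cdf(x0) == pytest.approx(expected, abs=1e-9)

    def test_median_by_bisection(self, patient1_params):
        d = mh.size_density(patient1_params)
        xm = d.median()
        assert d.cdf(xm) == pytest.approx(0.5, abs=1e-8)


class TestNumericOracle:
    """The closed forms against the first-principles quadrature density."""

    # five-point design per variant: (a0, b0, b1, a1, A, M)
    DESIGNS = {
        mh.Variant.SURGERY: [
            (0.1, 5.0, 1.0, None, 2.0, 20.0),
            (0.5, 2.0, 3.0, None, 1.2, 40.0),
            (1e-3, 12.0, 3.4, None, 1.85, 29.74),
            (2.0, 0.5, 0.2, None, 4.0, 15.0),
            (0.05, 1.0, 1.0, None, 1.1, 8.0),
        ],
        mh.Variant.SURGERY_HOMOGENEOUS: [
            (0.0, 5.0, 1.0, None, 2.0, 20.0),
            (0.0, 12.0, 3.41, None, 1.85, 29.74),
            (0.0, 0.3, 2.0, None, 3.0, 50.0),
            (0.0, 1.0, 0.2, None, 1.1, 10.0),
            (0.0, 2.0, 2.0, None, 1.15, 6.0),
        ],
        mh.Variant.FULL: [
            (0.1, 5.0, 1.0, -2.0, 2.0, 20.0),
            (0.4, 2.0, 2.0, -0.5, 1.5, 30.0),
            (0.02, 8.0, 0.7, -6.0, 2.5, 25.0),
            (1.0, 1.0, 1.0, -1.0, 3.0, 12.0),
            (0.2, 3.0, 0.5, -0.4, 1.1, 9.0),
        ],
        mh.Variant.FULL_HOMOGENEOUS: [
            (0.0, 5.0, 1.0, None, 2.0, 20.0),
            (0.0, 2.0, 2.0, None, 1.5, 30.0),
            (0.0, 8.0, 0.7, None, 2.5, 25.0),
            (0.0, 0.5, 1.5, None, 3.0, 12.0),
            (0.0, 3.0, 0.5, None, 1.1, 9.0),
        ],
    }

    @staticmethod
    def _setup(variant, a0, b0, b1, a1, A, M):
        resected = variant.resected
        if variant.homogeneous:
            # theta = 0 realized through an explicit zero-exponent history
            bio, rec = toy_history(a0=max(a0, 0.0), b0=b0, b1=b1, a1=a1, A=A, M=M,
                                   resected=resected)
            bio = mh.BiologicalParams(
                beta0=bio.beta0, beta1=bio.beta1, gamma0=bio.gamma0,
                gamma1=bio.gamma1, rho=bio.rho, theta=0.0, T=bio.T,
            )
        else:
            bio, rec = toy_history(a0=a0, b0=b0, b1=b1, a1=a1, A=A, M=M,
                                   resected=resected)
        params = mh.ModelParams(
            A=A, M=M, a0=a0, a1=(a1 if variant is mh.Variant.FULL else None),
            b0=b0, b1=b1, variant=variant,
        )
        return bio, rec, params

    @pytest.mark.parametrize("variant", VARIANTS, ids=lambda v: v.value)
    def test_closed_form_matches_first_principles(self, variant):
        m = 0.5
        for design in self.DESIGNS[variant]:
            bio, rec, params = self._setup(variant, *design)
            spec = history_from_biological(bio, rec)
            d = mh.size_density(params, m=m)
            A, M = params.A, params.M
            lo = max(m, A / 50)
            xs = np.r_[
                np.geomspace(max(m, lo) * 1.01, A * 0.995, 8) if A > m else [],
                np.geomspace(A * 1.005 if A > m else m * 1.01, M * 0.995, 9),
            ]
            num = theorem1_pdf_numeric(xs, spec, m)
            assert np.max(np.abs(num - d.pdf(xs))) < 1e-4

    def test_degenerate_latency_uniform_inceptions(self):
        """With zero latency and theta = 0, pre-treatment inceptions are
        uniform in time, so the size density is proportional to psi'(x) on
        (A, M]."""
        bio, rec = toy_history(a0=0.0, b0=5.0, b1=1.0, A=2.0, M=20.0, resected=True)
        bio = mh.BiologicalParams(
            beta0=bio.beta0, beta1=bio.beta1, gamma0=bio.gamma0, gamma1=bio.gamma1,
            rho=bio.rho, theta=0.0, T=bio.T,
        )
        spec = history_from_biological(bio, rec)
        spec.f_lat = None  # degenerate latency
        xs = np.geomspace(2.2, 19.0, 12)
        num = theorem1_pdf_numeric(xs, spec, m=0.5)
        # psi'(x) = 1/(gamma0 x) above A: num * x must be constant
        vals = num * xs
        assert np.max(np.abs(vals - vals.mean())) / vals.mean() < 1e-8

    def test_fd10_cap_differs_only_with_post_treatment_shedding(self):
        """For a resected primary the verbatim shedding cap is immaterial;
        for an intact primary it changes the post-treatment branch."""
        bio, rec = toy_history(a0=0.1, b0=5.0, b1=1.0, A=2.0, M=20.0, resected=True)
        spec = history_from_biological(bio, rec)
        xs = np.geomspace(0.55, 19.0, 10)
        np.testing.assert_allclose(
            theorem1_pdf_numeric(xs, spec, 0.5),
            theorem1_pdf_numeric(xs, spec, 0.5, shedding_cap="fd10"),
            rtol=1e-9,
        )
        bio_f, rec_f = toy_history(a0=0.1, b0=5.0, b1=1.0, a1=-0.3, A=2.0, M=20.0,
                                   resected=False)
        spec_f = history_from_biological(bio_f, rec_f)
        below_A = np.geomspace(0.55, 1.9, 6)
        a = theorem1_pdf_numeric(below_A, spec_f, 0.5)
        b = theorem1_pdf_numeric(below_A, spec_f, 0.5, shedding_cap="fd10")
        assert np.max(np.abs(a - b)) > 1e-4
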