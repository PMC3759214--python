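"""Unit and size conversions, growth laws, and the parameter conversions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import metahist as mh
from metahist.core import ConstraintError

C = 1e-9


class TestSizeVolume:
    @pytest.mark.parametrize(
        "volume, cells",
        [(1.85, 1.85e9), (C, 1.0), (0.5, 5e8)],
    )
    def test_conversion(self, volume, cells):
        assert mh.size_from_volume(volume) == pytest.approx(cells)
        assert mh.volume_from_size(cells) == pytest.approx(volume)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            mh.size_from_volume(0.0)


class TestGrowthLaws:
    def test_primary_initial_condition_and_observed_size(self, patient1_bio, patient1_record):
        bio, rec = patient1_bio, patient1_record
        tauV = rec.V - bio.T
        assert mh.primary_size(0.0, bio, tauV) == 1.0
        S = rec.S_v / C
        assert mh.primary_size(tauV, bio, tauV) == pytest.approx(S, rel=1e-9)

    def test_resected_primary_vanishes(self, patient1_bio, patient1_record):
        tauV = patient1_record.V - patient1_bio.T
        assert patient1_bio.beta1 == -math.inf
        assert mh.primary_size(tauV + 0.1, patient1_bio, tauV) == 0.0

    def test_metastasis_growth_piecewise_continuous(self, patient1_bio, patient1_record):
        bio = patient1_bio
        dt = patient1_record.W - patient1_record.V
        assert mh.metastasis_size(0.0, bio, dt) == 1.0
        left = mh.metastasis_size(dt * (1 - 1e-12), bio, dt)
        right = mh.metastasis_size(dt * (1 + 1e-12), bio, dt)
        at = mh.metastasis_size(dt, bio, dt)
        assert left == pytest.approx(at, rel=1e-9)
        assert right == pytest.approx(at, rel=1e-9)
        # size at the treatment switch is the breakpoint A
        assert at == pytest.approx(math.exp(bio.gamma1 * dt), rel=1e-12)

    def test_metastasis_growth_strictly_increasing(self, patient1_bio, patient1_record):
        dt = patient1_record.W - patient1_record.V
        ys = np.linspace(0.0, 3 * dt, 50)
        sizes = [mh.metastasis_size(y, patient1_bio, dt) for y in ys]
        assert np.all(np.diff(sizes) > 0)


class TestOnsetAge:
    def test_patient1_arithmetic(self):
        # V = 57.9, S = 2.7e10 cells, beta0 = 9.04 -> T about 55.2
        T = mh.onset_age(57.9, 2.7e10, 9.04)
        assert T == pytest.approx(57.9 - math.log(2.7e10) / 9.04, rel=1e-12)
        assert T == pytest.approx(55.24, abs=0.01)

    def test_onset_at_measurement_for_single_cell(self):
        assert mh.onset_age(50.0, 1.0, 2.0) == 50.0

    def test_growth_rate_bound_enforced(self):
        S, V = 1e10, 60.0
        with pytest.raises(ConstraintError):
            mh.onset_age(V, S, math.log(S) / V)


class TestConversions:
    def test_patient1_table_values(self, patient1_params, patient1_record):
        bio = mh.biological_from_model(patient1_params, patient1_record)
        assert bio.gamma0 == pytest.approx(1.047, rel=0.02)
        assert bio.gamma1 == pytest.approx(3.684, rel=0.02)
        assert bio.rho == pytest.approx(0.08, rel=0.02)
        assert bio.T == pytest.approx(55.3, abs=0.2)
        assert bio.beta0 == pytest.approx(9.1, rel=0.02)
        assert bio.theta == pytest.approx(4.2e-5, rel=0.02)
        assert bio.beta1 == -math.inf

    def test_patient11_acceleration_ratio(self):
        p = mh.ModelParams(
            A=2.73 / C, M=22.45 / C, a0=1.18e-3, a1=-11.52, b0=31.47, b1=6.25e-2,
            variant=mh.Variant.FULL,
        )
        rec = mh.PatientRecord("p11", V=71.8, W=72.7, S_v=47.0)
        bio = mh.biological_from_model(p, rec)
        assert bio.gamma1 / bio.gamma0 == pytest.approx(503.7, rel=0.005)
        # algebraic identity: the ratio is exactly b0/b1
        assert bio.gamma1 / bio.gamma0 == pytest.approx(31.47 / 6.25e-2, rel=1e-12)

    def test_equal_b_means_equal_growth_rates(self, patient1_record):
        p = mh.ModelParams(
            A=2.0 / C, M=20.0 / C, a0=1e-3, b0=4.0, b1=4.0,
            variant=mh.Variant.SURGERY,
        )
        bio = mh.biological_from_model(p, patient1_record)
        assert bio.gamma0 == pytest.approx(bio.gamma1, rel=1e-12)

    def test_unit_case(self):
        rec = mh.PatientRecord("u", V=50.0, W=51.0, S_v=20.0)
        bio = mh.BiologicalParams(
            beta0=1.0, beta1=-0.5, gamma0=2.0, gamma1=2.0, rho=0.5, theta=0.1, T=40.0,
        )
        p = mh.model_from_biological(bio, rec)
        assert p.b0 == pytest.approx(1.0)
        assert p.b1 == pytest.approx(1.0)

    def test_roundtrip_patient1(self, patient1_params, patient1_record):
        bio = mh.biological_from_model(patient1_params, patient1_record)
        back = mh.model_from_biological(
            bio, patient1_record, variant=mh.Variant.SURGERY
        )
        for attr in ("A", "M", "a0", "b0", "b1"):
            assert getattr(back, attr) == pytest.approx(
                getattr(patient1_params, attr), rel=1e-10
            )

    @settings(max_examples=200, deadline=None)
    @given(
        lnA=st.floats(0.5, 25.0),
        lnMA=st.floats(0.1, 5.0),
        a0=st.floats(1e-6, 3.0),
        a1=st.floats(-10.0, -1e-3),
        b0=st.floats(0.01, 50.0),
        b1=st.floats(0.01, 50.0),
    )
    def test_roundtrip_random_feasible(self, lnA, lnMA, a0, a1, b0, b1):
        """model -> biological -> model is the identity on feasible sets."""
        rec = mh.PatientRecord("r", V=60.0, W=65.0, S_v=20.0)
        p = mh.ModelParams(
            A=math.exp(lnA), M=math.exp(lnA + lnMA), a0=a0, a1=a1, b0=b0, b1=b1,
            variant=mh.Variant.FULL,
        )
        try:
            bio = mh.biological_from_model(p, rec)
        except ConstraintError:
            return  # onset before birth: infeasible draw
        back = mh.model_from_biological(bio, rec, variant=mh.Variant.FULL)
        for attr in ("A", "M", "a0", "a1", "b0", "b1"):
            assert getattr(back, attr) == pytest.approx(
                getattr(p, attr), rel=1e-10
            )

    def test_T_independent_of_primary_volume(self, patient1_params, patient1_record):
        bios = []
        for sv in (10.0, 20.0, 40.0):
            rec = mh.PatientRecord("p1", V=57.9, W=63.7, S_v=sv, surgery=True)
            bios.append(mh.biological_from_model(patient1_params, rec))
        assert bios[0].T == bios[1].T == bios[2].T
        # beta0 and theta depend on S only through its logarithm: a 4-fold
        # volume change moves them by ln(40/10)/ln(S) ~ 6%, and exactly
        # proportionally to ln(S)
        b0s = [b.beta0 for b in bios]
        ths = [b.theta for b in bios]
        assert (max(b0s) - min(b0s)) / b0s[1] < 0.06
        assert (max(ths) - min(ths)) / ths[1] < 0.06
        lnS = [math.log(sv / C) for sv in (10.0, 20.0, 40.0)]
        assert b0s[0] / b0s[2] == pytest.approx(lnS[0] / lnS[2], rel=1e-12)
        assert ths[2] / ths[0] == pytest.approx(lnS[0] / lnS[2], rel=1e-12)

    def test_negative_onset_rejected(self, patient1_record):
        p = mh.ModelParams(
            A=1.01, M=1e12, a0=0.0, b0=50.0, b1=1e-3,
            variant=mh.Variant.SURGERY_HOMOGENEOUS,
        )
        with pytest.raises(ConstraintError):
            mh.biological_from_model(p, patient1_record)


class TestConstraints:
    def test_patient1_published_fit_feasible(self, patient1_params, patient1_record):
        rep = mh.check_constraints(patient1_params, patient1_record)
        assert rep.passed

    def test_breakpoint_below_threshold_reported(self, patient1_record):
        p = mh.ModelParams(
            A=1e6, M=1e10, a0=0.0, b0=1.0, b1=1.0,
            variant=mh.Variant.SURGERY_HOMOGENEOUS,
        )
        rep = mh.check_constraints(p, patient1_record)
        assert not rep.above_threshold

    def test_onset_bound_is_strict(self, patient1_record):
        rec = patient1_record
        lnA, lnMA = math.log(2e9), math.log(10.0)
        bound = rec.V * lnA / ((rec.W - rec.V) * lnMA)
        p = mh.ModelParams(
            A=2e9, M=2e10, a0=0.0, b0=bound, b1=1.0,
            variant=mh.Variant.SURGERY_HOMOGENEOUS,
        )
        rep = mh.check_constraints(p, rec)
        assert not rep.onset_positive  # equality means onset at birth

    def test_invalid_ordering_rejected_by_type(self):
        with pytest.raises(ValueError):
            mh.ModelParams(A=10.0, M=5.0, a0=0.0, b0=1.0, b1=1.0,
                           variant=mh.Variant.SURGERY_HOMOGENEOUS)


class TestPatientRecord:
    def test_requires_V_before_W(self):
        with pytest.raises(ValueError):
            mh.PatientRecord("x", V=60.0, W=59.0)

    def test_met_sizes_sorted_cells(self):
        rec = mh.PatientRecord("x", V=50.0, W=55.0, met_volumes=(3.0, 1.0, 2.0))
        np.testing.assert_allclose(rec.met_sizes(), (1e9, 2e9, 3e9), rtol=1e-12)

    def test_volume_below_threshold_flagged(self):
        rec = mh.PatientRecord("x", V=50.0, W=55.0, met_volumes=(0.4,))
        with pytest.raises(ValueError):
            rec.validate_volumes()
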