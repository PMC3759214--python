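"""Domain types, unit conventions, growth laws and parameter conversions.

The natural history of a metastatic solid cancer is described on two scales:

* **biological parameters** — growth rates of the primary tumor before and
  after the start of treatment (``beta0``, ``beta1``, per year), growth rates
  of metastases before and after the start of treatment (``gamma0``,
  ``gamma1``), the mean metastasis latency ``rho`` (years), the shedding
  exponent ``theta`` (shedding intensity proportional to the primary size
  raised to ``theta``) and the unobserved age at disease onset ``T``;

* **model parameters** — the set ``{A, M, a0, a1, b0, b1}`` in which the
  size distribution of detectable metastases takes a closed form.  ``A`` is
  the size, at the survey age ``W``, of a metastasis whose inception
  coincided with the start of treatment (age ``V``); ``M`` is the maximal
  possible metastasis size (inception at onset); the dimensionless exponents
  are ``a0 = beta0*theta/gamma0``, ``a1 = beta1*theta/gamma1``,
  ``b0 = 1/(gamma0*rho)`` and ``b1 = 1/(gamma1*rho)``.

All density and likelihood arithmetic is carried out on *sizes* (cell
counts); volumes in cm^3 appear only at the I/O boundary, converted with the
cell volume ``c`` (1e-9 cm^3 by default).  The conversion between the two
parameter scales is exact and is exercised as an inverse pair in the tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Sequence

__all__ = [
    "Constants",
    "PatientRecord",
    "Variant",
    "ModelParams",
    "BiologicalParams",
    "SheddingParams",
    "ConstraintReport",
    "ConstraintError",
    "size_from_volume",
    "volume_from_size",
    "primary_size",
    "metastasis_size",
    "onset_age",
    "biological_from_model",
    "model_from_biological",
    "check_constraints",
]


class ConstraintError(ValueError):
    """A model-feasibility constraint is violated."""


@dataclass(frozen=True)
class Constants:
    """Physical conventions of the measurement process.

    c : volume of a single cancer cell, cm^3.
    m : detection threshold volume, cm^3 (PET/CT resolution limit).
    voxel : volume-measurement accuracy, cm^3 (informational only).
    """

    c: float = 1e-9
    m: float = 0.5
    voxel: float = 0.065

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("cell volume c must be positive")
        if self.m <= self.c:
            raise ValueError("detection threshold m must exceed cell volume c")

    @property
    def m_cells(self) -> float:
        """Detection threshold as a size (cell count)."""
        return self.m / self.c


DEFAULT_CONSTANTS = Constants()

#: Primary tumor volume (cm^3) imputed when the pathology estimate is missing.
DEFAULT_PRIMARY_VOLUME = 20.0


@dataclass(frozen=True)
class PatientRecord:
    """Clinical observables for a single patient.

    V, W are ages in years (start of treatment and metastasis survey);
    S_v is the primary tumor volume at V in cm^3 (imputed as 20 cm^3 when
    unavailable); ``met_volumes`` lists the detectable metastasis volumes in
    cm^3 (each at least the detection threshold).  The list may be empty only
    for records used as simulation frames.
    """

    patient_id: str
    V: float
    W: float
    S_v: float = DEFAULT_PRIMARY_VOLUME
    surgery: bool = False
    met_volumes: tuple = ()
    S_v_imputed: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.V < self.W):
            raise ValueError(
                f"patient {self.patient_id!r}: require 0 < V < W, got V={self.V}, W={self.W}"
            )
        if self.S_v <= 0:
            raise ValueError(f"patient {self.patient_id!r}: S_v must be positive")
        object.__setattr__(self, "met_volumes", tuple(float(v) for v in self.met_volumes))

    def validate_volumes(self, constants: Constants = DEFAULT_CONSTANTS) -> None:
        for v in self.met_volumes:
            if v < constants.m:
                raise ValueError(
                    f"patient {self.patient_id!r}: metastasis volume {v} cm^3 is below "
                    f"the detection threshold {constants.m} cm^3"
                )

    @property
    def n(self) -> int:
        return len(self.met_volumes)

    def met_sizes(self, constants: Constants = DEFAULT_CONSTANTS):
        """Observed metastasis sizes (cell counts), sorted ascending."""
        return tuple(sorted(v / constants.c for v in self.met_volumes))


class Variant(str, Enum):
    """Parametric model variants.

    surgery            : primary resected at V, non-recurrent (beta1 -> -inf);
    surgery_homogeneous: surgery variant with theta = 0 (a0 = 0);
    full               : primary in situ (or recurrent) with two growth rates;
    full_homogeneous   : full variant with theta = 0 (a0 = a1 = 0).
    """

    SURGERY = "surgery"
    SURGERY_HOMOGENEOUS = "surgery_homogeneous"
    FULL = "full"
    FULL_HOMOGENEOUS = "full_homogeneous"

    @property
    def homogeneous(self) -> bool:
        return self in (Variant.SURGERY_HOMOGENEOUS, Variant.FULL_HOMOGENEOUS)

    @property
    def resected(self) -> bool:
        return self in (Variant.SURGERY, Variant.SURGERY_HOMOGENEOUS)


@dataclass(frozen=True)
class ModelParams:
    """Model-scale parameter set {A, M, a0, a1, b0, b1}.

    A and M are sizes (cell counts), 1 < A < M.  a1 is None for the surgery
    variants (it corresponds to beta1 -> -inf); a0 is 0 for the homogeneous
    variants.
    """

    A: float
    M: float
    a0: float
    b0: float
    b1: float
    a1: Optional[float] = None
    variant: Variant = Variant.FULL

    def __post_init__(self) -> None:
        if not (1.0 < self.A < self.M):
            raise ValueError(f"require 1 < A < M, got A={self.A}, M={self.M}")
        if self.b0 <= 0 or self.b1 <= 0:
            raise ValueError("b0 and b1 must be positive")
        if self.a0 < 0:
            raise ValueError("a0 must be nonnegative")
        if self.variant.homogeneous and self.a0 != 0.0:
            raise ValueError("homogeneous variants require a0 = 0")
        if self.variant is Variant.FULL and self.a1 is None:
            raise ValueError("full variant requires a1")
        if self.variant.resected and self.a1 is not None:
            raise ValueError("surgery variants carry no a1 (beta1 -> -inf)")


@dataclass(frozen=True)
class BiologicalParams:
    """Biological-scale parameter set.

    Rates are per year.  beta1 may be negative (tumor shrinking under
    treatment); ``-inf`` encodes a non-recurrent resected primary; None marks
    beta1 as undefined (homogeneous variants, where a1/a0 is 0/0).
    """

    beta0: float
    gamma0: float
    gamma1: float
    rho: float
    theta: float
    T: float
    beta1: Optional[float] = None

    def __post_init__(self) -> None:
        if self.gamma0 <= 0 or self.gamma1 <= 0:
            raise ValueError("gamma0 and gamma1 must be positive")
        if self.rho <= 0:
            raise ValueError("rho must be positive")
        if self.theta < 0:
            raise ValueError("theta must be nonnegative")
        if self.T <= 0:
            raise ConstraintError(
                f"onset age T must be positive (constraint on b0/b1), got T={self.T}"
            )

    @property
    def acceleration_ratio(self) -> float:
        """gamma1/gamma0, the treatment-induced growth acceleration of metastases."""
        return self.gamma1 / self.gamma0


@dataclass(frozen=True)
class SheddingParams:
    """Shedding scale alpha (per year; the product alpha0*alpha1, not separately
    identifiable) and per-metastasis viability probability q.  Neither enters
    the size density of detectable metastases."""

    alpha: float = 1.0
    q: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not (0.0 <= self.q <= 1.0):
            raise ValueError("q must lie in [0, 1]")


# ---------------------------------------------------------------------------
# unit conversions and growth laws
# ---------------------------------------------------------------------------

def size_from_volume(v: float, constants: Constants = DEFAULT_CONSTANTS) -> float:
    """Convert a volume in cm^3 to a size (cell count)."""
    if v <= 0:
        raise ValueError(f"volume must be positive, got {v}")
    return v / constants.c


def volume_from_size(s: float, constants: Constants = DEFAULT_CONSTANTS) -> float:
    """Convert a size (cell count) to a volume in cm^3."""
    return s * constants.c


def primary_size(t: float, bio: BiologicalParams, V_minus_T: float) -> float:
    """Primary tumor size at time ``t`` since onset.

    exp(beta0*t) up to the start of treatment (t = V - T); thereafter the
    post-treatment law acts multiplicatively: exp(beta1*(t-(V-T))) * S.
    A non-recurrent resected primary (beta1 = -inf) has size 0 after V - T.
    """
    if t < 0:
        raise ValueError("t must be nonnegative")
    if t <= V_minus_T:
        return math.exp(bio.beta0 * t)
    S = math.exp(bio.beta0 * V_minus_T)
    if bio.beta1 is None:
        raise ValueError("beta1 undefined: post-treatment primary size unavailable")
    if bio.beta1 == -math.inf:
        return 0.0
    return S * math.exp(bio.beta1 * (t - V_minus_T))


def metastasis_size(y: float, bio: BiologicalParams, W_minus_V: float) -> float:
    """Size of a viable metastasis at time ``y`` since inception, surveyed at W.

    Counting backwards from the survey age, a metastasis younger than W - V
    grew entirely under treatment (rate gamma1); an older one grew at gamma0
    until V and at gamma1 for the final W - V years.
    """
    if y < 0:
        raise ValueError("y must be nonnegative")
    if y <= W_minus_V:
        return math.exp(bio.gamma1 * y)
    return math.exp(bio.gamma0 * (y - W_minus_V) + bio.gamma1 * W_minus_V)


def onset_age(V: float, S: float, beta0: float) -> float:
    """Age at disease onset, T = V - ln(S)/beta0.

    Requires beta0 > ln(S)/V so that T > 0 (the primary must have had time to
    grow from one cell to the observed size S within the patient's lifetime).
    """
    if S < 1:
        raise ValueError("primary size S must be at least one cell")
    lnS = math.log(S)
    if beta0 * V <= lnS:
        raise ConstraintError(
            f"growth-rate lower bound violated: beta0={beta0} must exceed ln(S)/V={lnS / V}"
        )
    return V - lnS / beta0


# ---------------------------------------------------------------------------
# model <-> biological conversions
# ---------------------------------------------------------------------------

def biological_from_model(
    p: ModelParams,
    rec: PatientRecord,
    constants: Constants = DEFAULT_CONSTANTS,
) -> BiologicalParams:
    """Convert model parameters {A, M, a0, a1, b0, b1} to biological parameters.

    With dt = W - V and A, M as cell counts:

        gamma1 = ln(A)/dt
        gamma0 = b1*ln(A)/(b0*dt)
        rho    = dt/(b1*ln(A))
        T      = V - (b0*dt/(b1*ln(A))) * ln(M/A)
        beta0  = b1*ln(A)*ln(S)/(b0*dt*ln(M/A))
        theta  = a0*ln(M/A)/ln(S)
        beta1  = (a1/a0)*ln(A)*ln(S)/(dt*ln(M/A))   (undefined when a0 = 0)

    where S = S_v/c is the primary size at the start of treatment.
    """
    dt = rec.W - rec.V
    lnA = math.log(p.A)
    lnMA = math.log(p.M / p.A)
    S = rec.S_v / constants.c
    lnS = math.log(S)

    gamma1 = lnA / dt
    gamma0 = p.b1 * lnA / (p.b0 * dt)
    rho = dt / (p.b1 * lnA)
    T = rec.V - (p.b0 * dt / (p.b1 * lnA)) * lnMA
    if T <= 0:
        raise ConstraintError(
            f"onset age T = {T:.3f} <= 0: b0/b1 exceeds V*ln(A)/((W-V)*ln(M/A))"
        )
    beta0 = p.b1 * lnA * lnS / (p.b0 * dt * lnMA)
    theta = p.a0 * lnMA / lnS

    beta1: Optional[float]
    if p.variant.resected:
        beta1 = -math.inf
    elif p.a0 == 0.0 or p.a1 is None:
        beta1 = None  # 0/0 in the homogeneous limit: not identifiable
    else:
        beta1 = (p.a1 / p.a0) * lnA * lnS / (dt * lnMA)

    return BiologicalParams(
        beta0=beta0, beta1=beta1, gamma0=gamma0, gamma1=gamma1,
        rho=rho, theta=theta, T=T,
    )


def model_from_biological(
    bio: BiologicalParams,
    rec: PatientRecord,
    constants: Constants = DEFAULT_CONSTANTS,
    variant: Optional[Variant] = None,
) -> ModelParams:
    """Convert biological parameters to the model scale (inverse of
    :func:`biological_from_model`; the pair round-trips to ~1e-15 relative)."""
    dt = rec.W - rec.V
    if bio.T >= rec.V:
        raise ConstraintError(f"onset age T={bio.T} must precede treatment age V={rec.V}")
    A = math.exp(bio.gamma1 * dt)
    M = math.exp(bio.gamma0 * (rec.V - bio.T) + bio.gamma1 * dt)
    a0 = bio.beta0 * bio.theta / bio.gamma0
    b0 = 1.0 / (bio.gamma0 * bio.rho)
    b1 = 1.0 / (bio.gamma1 * bio.rho)

    if variant is None:
        if bio.beta1 == -math.inf:
            variant = Variant.SURGERY_HOMOGENEOUS if bio.theta == 0 else Variant.SURGERY
        elif bio.theta == 0:
            variant = Variant.FULL_HOMOGENEOUS
        else:
            variant = Variant.FULL

    a1: Optional[float] = None
    if variant is Variant.FULL:
        if bio.beta1 is None:
            raise ValueError("full variant requires beta1")
        a1 = bio.beta1 * bio.theta / bio.gamma1
    if variant.homogeneous:
        a0 = 0.0

    return ModelParams(A=A, M=M, a0=a0, a1=a1, b0=b0, b1=b1, variant=variant)


# ---------------------------------------------------------------------------
# constraint report
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConstraintReport:
    """Pass/fail report of the model-feasibility constraints."""

    ordering: bool          # 1 < A < M
    above_threshold: bool   # A > m (in cells)
    onset_positive: bool    # b0/b1 < V*ln(A)/((W-V)*ln(M/A)), i.e. T > 0
    details: dict = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return self.ordering and self.above_threshold and self.onset_positive


def check_constraints(
    p: ModelParams,
    rec: PatientRecord,
    constants: Constants = DEFAULT_CONSTANTS,
) -> ConstraintReport:
    """Check 1 < A < M, A > m and the onset-positivity bound on b0/b1.

    The onset bound is strict: equality would put the disease onset at birth
    (T = 0), which is disallowed.
    """
    ordering = 1.0 < p.A < p.M
    above_threshold = p.A > constants.m_cells
    details: dict = {}
    onset_positive = False
    if ordering:
        dt = rec.W - rec.V
        lnA = math.log(p.A)
        lnMA = math.log(p.M / p.A)
        bound = rec.V * lnA / (dt * lnMA)
        ratio = p.b0 / p.b1
        onset_positive = ratio < bound
        details["b0_over_b1"] = ratio
        details["onset_bound"] = bound
        details["T"] = rec.V - (p.b0 * dt / (p.b1 * lnA)) * lnMA
    return ConstraintReport(
        ordering=ordering,
        above_threshold=above_threshold,
        onset_positive=onset_positive,
        details=details,
    )
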