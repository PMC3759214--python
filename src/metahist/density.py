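"""Size distributions of detectable metastases.

Conditional on their number, the sizes of metastases detectable in a given
secondary site at the survey age W are distributed as order statistics of an
i.i.d. sample from a density p(x) supported on [m, M], where m is the
detection threshold and M the maximal size (inception at disease onset).
The density is obtained by mapping the inception-time intensity of a
latency-convolved Poisson shedding process through the metastasis growth
law; it is free of the shedding scale alpha, the viability probability q and
the sample size n.

Under exponential growth laws and exponential latency the density has closed
forms for four variants (surgery / full, each with its homogeneous theta = 0
special case).  Each variant has two branches separated by a jump at
x = A, the size of a metastasis incepted at the start of treatment, with

    p(A+)/p(A-) = b0/b1 = gamma1/gamma0.

All closed forms are evaluated in log space (sizes are cell counts, ln M of
order 25) with guarded limits for exponents passing through zero, so that
global optimization can cross a0 = 0, a1 + b1 = 0 etc. without overflow.

:func:`theorem1_pdf_numeric` evaluates the same density from first
principles (adaptive quadrature of the shedding/latency convolution for
arbitrary growth laws and latency distributions) and serves as the
independent oracle for the closed forms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import integrate

from .core import (
    BiologicalParams,
    Constants,
    DEFAULT_CONSTANTS,
    ModelParams,
    PatientRecord,
    Variant,
)

__all__ = [
    "SizeDensity",
    "size_density",
    "pdf_surgery",
    "pdf_surgery_homogeneous",
    "pdf_full",
    "pdf_full_homogeneous",
    "cdf",
    "GeneralHistorySpec",
    "history_from_biological",
    "theorem1_pdf_numeric",
]


# ---------------------------------------------------------------------------
# guarded elementary integrals
#
#   g(z, L)  = (exp(z*L) - 1)/z        -> L        as z -> 0
#   G(a1,b1,L) = (g(a1,L) - g(-b1,L))/(a1+b1)     -> g'(-b1) as a1 -> -b1
#
# g is computed through expm1, which is accurate for any z != 0; only z == 0
# needs the explicit limit.  G needs a series guard because the numerator
# cancels as a1 + b1 -> 0.
# ---------------------------------------------------------------------------

def _g(z: float, L: float) -> float:
    """(exp(z*L) - 1)/z with the z -> 0 limit L."""
    if z == 0.0:
        return L
    return math.expm1(z * L) / z


def _ln_g(z: float, L: float) -> float:
    """ln of _g(z, L); valid for L >= 0 (returns -inf at L = 0)."""
    if L <= 0.0:
        return -math.inf
    if z == 0.0:
        return math.log(L)
    zL = z * L
    if zL > 350.0:  # expm1 would overflow; exp dominates
        return zL - math.log(z)
    return math.log(math.expm1(zL) / z)


def _g_prime(z: float, L: float) -> float:
    """d/dz of _g(z, L)."""
    zL = z * L
    if abs(zL) < 1e-4:
        return L * L / 2.0 + zL * L * L / 3.0 + zL * zL * L * L / 8.0
    return (L * z * math.exp(zL) - math.expm1(zL)) / (z * z)


def _G(a1: float, b1: float, L: float) -> float:
    """(g(a1, L) - g(-b1, L))/(a1 + b1), guarded as a1 + b1 -> 0.

    Nonnegative for L >= 0 because g(., L) is increasing in its first
    argument.
    """
    s = a1 + b1
    if abs(s) < 1e-6 * max(1.0, b1):
        return _g_prime(-b1, L) + 0.5 * s * _g_second(-b1, L)
    return (_g(a1, L) - _g(-b1, L)) / s


def _g_second(z: float, L: float) -> float:
    """d2/dz2 of _g(z, L)."""
    zL = z * L
    if abs(zL) < 1e-4:
        return L ** 3 / 3.0 + zL * L ** 3 / 4.0
    return (math.exp(zL) * (zL * zL - 2.0 * zL + 2.0) - 2.0) / (z ** 3)


def _ln_gvec(s: float, L: np.ndarray) -> np.ndarray:
    """Vectorized ln((exp(s*L)-1)/s) over an array L >= 0, scalar s."""
    L = np.asarray(L, dtype=float)
    if s == 0.0:
        with np.errstate(divide="ignore"):
            return np.log(L)
    z = s * L
    out = np.empty_like(L)
    big = z > 350.0
    if big.any():
        out[big] = z[big] - math.log(s)
    with np.errstate(divide="ignore"):
        out[~big] = np.log(np.expm1(z[~big]) / s)
    return out


def _logdiffexp(la, lb):
    """ln(exp(la) - exp(lb)) for la >= lb, elementwise."""
    la = np.asarray(la, dtype=float)
    lb = np.asarray(lb, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = la + np.log1p(-np.exp(np.minimum(lb - la, 0.0)))
    return np.where(np.isneginf(la), -np.inf, out)


# ---------------------------------------------------------------------------
# closed-form densities
# ---------------------------------------------------------------------------

class InfeasibleParams(ValueError):
    """Parameters do not define a proper density on [m, M]."""


@dataclass
class SizeDensity:
    """Closed-form density of detectable-metastasis sizes for one variant.

    Sizes are cell counts.  The support is [max(m, 1), M]; the density has a
    single jump at the breakpoint A when A > m, with p(A+)/p(A-) = b0/b1.
    Construction precomputes the log-normalizer, so repeated pdf/cdf calls
    (e.g. inside a likelihood loop) are cheap.
    """

    params: ModelParams
    m: float  # threshold size, cells

    def __post_init__(self) -> None:
        p = self.params
        if self.m <= 0:
            raise InfeasibleParams("threshold m must be positive")
        if p.M <= self.m:
            raise InfeasibleParams(
                f"empty support: M = {p.M:.4g} does not exceed threshold m = {self.m:.4g}"
            )
        self._lA = math.log(p.A)
        self._lM = math.log(p.M)
        self._lm = math.log(self.m)
        self._LMA = self._lM - self._lA
        self._above = p.A > self.m
        # when A <= m the breakpoint is invisible and the single-branch
        # (pre-treatment inception) form applies with lower limit m
        self._Llow = self._LMA if self._above else self._lM - self._lm
        self._LAm = self._lA - self._lm if self._above else 0.0
        self._ln_b10 = math.log(p.b1 / p.b0)
        a0 = p.a0
        self._lnK = a0 * self._LMA + math.log1p(-math.exp(-(a0 + p.b0) * self._LMA))
        self._s1 = (p.a1 + p.b1) if p.a1 is not None else None
        self._ln_left_total, self._lnC = self._log_normalizer()

    # -- normalization ------------------------------------------------------

    def _ln_right_cum(self, LMy) -> np.ndarray:
        """ln of the cumulative of the upper branch from its lower end down to
        ln(M/y) = LMy (LMy = 0 gives the full upper-branch integral)."""
        p = self.params
        LMy = np.asarray(LMy, dtype=float)
        Llow = self._Llow
        part1 = p.a0 * LMy + np.array(
            [_ln_g(p.a0, Llow - v) for v in np.atleast_1d(LMy)]
        ).reshape(LMy.shape)
        with np.errstate(invalid="ignore", divide="ignore"):
            part2 = (
                -p.b0 * LMy
                + np.log1p(-np.exp(-p.b0 * (Llow - LMy)))
                - math.log(p.b0)
            )
        return _logdiffexp(part1, part2)

    def _log_normalizer(self):
        p = self.params
        ln_right = float(self._ln_right_cum(0.0))
        if not self._above:
            return -math.inf, ln_right
        # lower-branch (post-treatment inception) total mass, by variant
        ln_t1 = self._lnK - math.log(p.b0) + math.log1p(-math.exp(-p.b1 * self._LAm))
        if p.variant in (Variant.SURGERY, Variant.SURGERY_HOMOGENEOUS):
            ln_left = ln_t1
        else:
            G = _G(p.a1 if p.a1 is not None else -math.inf, p.b1, self._LAm)
            if p.variant is Variant.FULL_HOMOGENEOUS:
                G = _G(0.0, p.b1, self._LAm)
            ln_t2 = (
                2.0 * self._ln_b10
                + math.log(p.a0 + p.b0)
                + p.a0 * self._LMA
                + (math.log(G) if G > 0 else -math.inf)
            )
            ln_left = np.logaddexp(ln_t1, ln_t2)
        return float(ln_left), float(np.logaddexp(ln_left, ln_right))

    # -- evaluation ---------------------------------------------------------

    @property
    def support(self):
        return (self.m, self.params.M)

    @property
    def breakpoint(self) -> float:
        return self.params.A

    @property
    def normalizer(self) -> float:
        """The normalization constant C (denominator of the printed forms)."""
        return math.exp(self._lnC)

    def jump_ratio(self) -> Optional[float]:
        """p(A+)/p(A-) = b0/b1, or None when the breakpoint is below m."""
        if not self._above:
            return None
        return self.params.b0 / self.params.b1

    def logpdf(self, x) -> np.ndarray:
        p = self.params
        x = np.asarray(x, dtype=float)
        scalar = x.ndim == 0
        x = np.atleast_1d(x)
        out = np.full(x.shape, -np.inf)
        inside = (x >= self.m) & (x <= p.M) & (x > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            lx = np.where(x > 0, np.log(x), -np.inf)
        left = inside & self._above & (x < p.A)
        right = inside & ~left
        if right.any():
            LMx = self._lM - lx[right]
            a0 = p.a0
            with np.errstate(divide="ignore", invalid="ignore"):
                val = a0 * LMx + np.log1p(-np.exp(-(a0 + p.b0) * LMx))
            out[right] = val - lx[right] - self._lnC
        if left.any():
            LAx = self._lA - lx[left]
            with np.errstate(divide="ignore", invalid="ignore"):
                if p.variant in (Variant.SURGERY, Variant.SURGERY_HOMOGENEOUS):
                    val = self._ln_b10 + self._lnK - p.b1 * LAx
                elif p.variant is Variant.FULL_HOMOGENEOUS:
                    val = self._ln_b10 + np.log1p(
                        -np.exp(-(p.b0 * self._LMA + p.b1 * LAx))
                    )
                else:  # FULL
                    t1 = self._lnK - p.b1 * LAx
                    t2 = (
                        self._ln_b10
                        + math.log(p.a0 + p.b0)
                        + p.a0 * self._LMA
                        - p.b1 * LAx
                        + _ln_gvec(self._s1, LAx)
                    )
                    val = self._ln_b10 + np.logaddexp(t1, t2)
            out[left] = val - lx[left] - self._lnC
        return out[0] if scalar else out

    def pdf(self, x) -> np.ndarray:
        return np.exp(self.logpdf(x))

    def _ln_left_cum(self, lx: np.ndarray) -> np.ndarray:
        """ln integral of the unnormalized density from m to y (y < A)."""
        p = self.params
        LAy = self._lA - lx
        base = (
            self._lnK
            - math.log(p.b0)
            - p.b1 * LAy
            + np.log1p(-np.exp(-p.b1 * (self._LAm - LAy)))
        )
        if p.variant in (Variant.SURGERY, Variant.SURGERY_HOMOGENEOUS):
            return base
        if p.variant is Variant.FULL_HOMOGENEOUS:
            a1 = 0.0
        else:
            a1 = p.a1
        Gm = _G(a1, p.b1, self._LAm)
        dG = np.array([max(Gm - _G(a1, p.b1, v), 0.0) for v in LAy])
        with np.errstate(divide="ignore"):
            extra = (
                2.0 * self._ln_b10
                + math.log(p.a0 + p.b0)
                + p.a0 * self._LMA
                + np.log(dG)
            )
        return np.logaddexp(base, extra)

    def cdf(self, x) -> np.ndarray:
        """P(X <= x); continuous, 0 at m and 1 at M."""
        p = self.params
        x = np.asarray(x, dtype=float)
        scalar = x.ndim == 0
        x = np.atleast_1d(x)
        out = np.zeros(x.shape)
        out[x >= p.M] = 1.0
        mid = (x > self.m) & (x < p.M)
        if mid.any():
            lx = np.log(x[mid])
            vals = np.empty(lx.shape)
            lower = self._above & (x[mid] < p.A)
            if lower.any():
                vals[lower] = self._ln_left_cum(lx[lower])
            if (~lower).any():
                ln_rc = self._ln_right_cum(self._lM - lx[~lower])
                vals[~lower] = np.logaddexp(self._ln_left_total, ln_rc)
            out[mid] = np.exp(vals - self._lnC)
        out = np.clip(out, 0.0, 1.0)
        return float(out[0]) if scalar else out

    def median(self, rtol: float = 1e-10) -> float:
        """Median size by bisection on the cdf."""
        from scipy.optimize import brentq

        return brentq(
            lambda y: self.cdf(y) - 0.5, self.m, self.params.M, rtol=rtol
        )


def size_density(
    params: ModelParams, m: Optional[float] = None,
    constants: Constants = DEFAULT_CONSTANTS,
) -> SizeDensity:
    """Build the closed-form size density for ``params``.

    ``m`` is the detection threshold as a *size* (cell count); by default it
    is taken from ``constants`` (0.5 cm^3 / 1e-9 cm^3).
    """
    return SizeDensity(params, m if m is not None else constants.m_cells)


def _variant_pdf(x, p: ModelParams, m: float, expect: tuple) -> np.ndarray:
    if p.variant not in expect:
        raise ValueError(f"params carry variant {p.variant}, expected one of {expect}")
    return SizeDensity(p, m).pdf(x)


def pdf_surgery(x, p: ModelParams, m: float) -> np.ndarray:
    """Surgery-model density (resected non-recurrent primary)."""
    return _variant_pdf(x, p, m, (Variant.SURGERY,))


def pdf_surgery_homogeneous(x, p: ModelParams, m: float) -> np.ndarray:
    """Homogeneous surgery model (theta = 0)."""
    return _variant_pdf(x, p, m, (Variant.SURGERY_HOMOGENEOUS,))


def pdf_full(x, p: ModelParams, m: float) -> np.ndarray:
    """Full model (primary in situ, two growth rates, post-treatment shedding)."""
    return _variant_pdf(x, p, m, (Variant.FULL,))


def pdf_full_homogeneous(x, p: ModelParams, m: float) -> np.ndarray:
    """Homogeneous full model (theta = 0)."""
    return _variant_pdf(x, p, m, (Variant.FULL_HOMOGENEOUS,))


def cdf(x, density: SizeDensity):
    """P(X <= x) under ``density``."""
    return density.cdf(x)


# ---------------------------------------------------------------------------
# first-principles numerical density (Theorem-1 oracle)
# ---------------------------------------------------------------------------

@dataclass
class GeneralHistorySpec:
    """A natural history specified by callables, for the numerical density.

    phi      : primary-tumor size at time s since onset (the full trajectory,
               0 after resection for a non-recurrent excised primary);
    Psi      : metastasis size at time y since inception (surveyed at W);
    psi      : inverse of Psi;
    psi_prime: derivative of psi;
    f_lat    : latency pdf, or None for degenerate (zero) latency;
    F_lat    : latency cdf (only used with f_lat);
    theta    : shedding exponent;
    T, V, W  : onset, treatment and survey ages (years).
    """

    phi: Callable[[float], float]
    Psi: Callable[[float], float]
    psi: Callable[[float], float]
    psi_prime: Callable[[float], float]
    f_lat: Optional[Callable[[float], float]]
    F_lat: Optional[Callable[[float], float]]
    theta: float
    T: float
    V: float
    W: float

    @property
    def max_size(self) -> float:
        return self.Psi(self.W - self.T)

    def shed_intensity(self, s: float) -> float:
        """Relative shedding intensity phi(s)^theta, 0 when the primary is gone."""
        ph = self.phi(s)
        if ph <= 0.0:
            return 0.0
        return ph ** self.theta


def history_from_biological(
    bio: BiologicalParams, rec: PatientRecord
) -> GeneralHistorySpec:
    """Exponential-law history for the given biological parameters."""
    tauV = rec.V - bio.T
    dt = rec.W - rec.V
    g0, g1 = bio.gamma0, bio.gamma1
    lnA = g1 * dt

    def phi(s: float) -> float:
        if s <= tauV:
            return math.exp(bio.beta0 * s)
        if bio.beta1 is None or bio.beta1 == -math.inf:
            return 0.0
        return math.exp(bio.beta0 * tauV + bio.beta1 * (s - tauV))

    def Psi(y: float) -> float:
        if y <= dt:
            return math.exp(g1 * y)
        return math.exp(g0 * (y - dt) + g1 * dt)

    def psi(x: float) -> float:
        lx = math.log(x)
        if lx <= lnA:
            return lx / g1
        return (lx - lnA) / g0 + dt

    def psi_prime(x: float) -> float:
        lx = math.log(x)
        if lx <= lnA:
            return 1.0 / (g1 * x)
        return 1.0 / (g0 * x)

    rho = bio.rho

    def f_lat(u: float) -> float:
        return math.exp(-u / rho) / rho if u >= 0 else 0.0

    def F_lat(u: float) -> float:
        return -math.expm1(-u / rho) if u > 0 else 0.0

    return GeneralHistorySpec(
        phi=phi, Psi=Psi, psi=psi, psi_prime=psi_prime,
        f_lat=f_lat, F_lat=F_lat, theta=bio.theta, T=bio.T, V=rec.V, W=rec.W,
    )


def theorem1_pdf_numeric(
    x,
    spec: GeneralHistorySpec,
    m: float,
    shedding_cap: str = "natural",
    epsabs: float = 1e-12,
    epsrel: float = 1e-10,
):
    """Density of detectable-metastasis sizes by adaptive quadrature.

    The inception intensity lambda(t) is built from first principles as the
    convolution of the shedding intensity (proportional to phi^theta over the
    full primary trajectory; a resected primary contributes nothing after V
    because phi = 0) with the latency density.  The size density is
    lambda(W - T - psi(x)) * psi'(x), normalized over [m, M].

    ``shedding_cap="fd10"`` truncates the shedding integral at V - T even for
    an intact primary, reproducing the printed single-treatment-mode
    convention for comparison; ``"natural"`` integrates the full trajectory.
    """
    if shedding_cap not in ("natural", "fd10"):
        raise ValueError("shedding_cap must be 'natural' or 'fd10'")
    tauV = spec.V - spec.T
    tauW = spec.W - spec.T
    M = spec.max_size
    if m >= M:
        raise ValueError("threshold at or above the maximal size: empty support")

    def lam(t: float) -> float:
        if t <= 0:
            return 0.0
        hi = min(t, tauV) if shedding_cap == "fd10" else t
        if spec.f_lat is None:
            return spec.shed_intensity(t)

        def integrand(s: float) -> float:
            return spec.shed_intensity(s) * spec.f_lat(t - s)

        pts = [p for p in (tauV,) if 0.0 < p < hi]
        val, _ = integrate.quad(
            integrand, 0.0, hi, points=pts or None,
            epsabs=epsabs, epsrel=epsrel, limit=200,
        )
        return val

    # normalizer: substitute t = W - T - psi(x); dt = -psi'(x) dx
    t_lo = tauW - spec.psi(M)  # = 0 up to rounding
    t_hi = tauW - spec.psi(m)
    pts = [p for p in (tauV,) if t_lo < p < t_hi]
    norm, _ = integrate.quad(
        lam, t_lo, t_hi, points=pts or None,
        epsabs=epsabs, epsrel=epsrel, limit=400,
    )
    if norm <= 0:
        raise ValueError("degenerate history: no inception mass on the support")

    xs = np.atleast_1d(np.asarray(x, dtype=float))
    out = np.zeros(xs.shape)
    for i, xi in enumerate(xs):
        if m <= xi <= M:
            out[i] = lam(tauW - spec.psi(xi)) * spec.psi_prime(xi) / norm
    return float(out[0]) if np.ndim(x) == 0 else out
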