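"""Forward stochastic simulator of the metastatic natural history.

Shedding events follow a Poisson process with intensity alpha*phi(t)^theta
over the primary trajectory (stopped by resection); each shed metastasis is
viable with probability q, waits an exponential latency (mean rho), then
proliferates exponentially (gamma0 before the start of treatment, gamma1
after).  Observation at the survey age W keeps metastases at or above the
detection threshold m.

The simulator and the closed-form size densities are independent
implementations of the same process: conditional on their number, simulated
detectable volumes must follow the closed-form density of the matching
variant (checked by KS tests), which is the module's central
cross-validation.  The generator stands in for the study's unpublished
per-patient metastasis volume lists and drives the parameter-recovery
experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import integrate

from .core import (
    BiologicalParams,
    Constants,
    DEFAULT_CONSTANTS,
    PatientRecord,
    SheddingParams,
    Variant,
    model_from_biological,
)

__all__ = [
    "SyntheticTruth",
    "SyntheticCohort",
    "simulate_inhomogeneous_poisson",
    "simulate_patient",
    "expected_detectable_count",
    "calibrate_alpha",
    "recovery_experiment",
]


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for a simulated patient: biological parameters, shedding
    scale/viability, the clinical frame (ages, primary volume, surgery flag)
    and the seed."""

    bio: BiologicalParams
    shed: SheddingParams
    rec: PatientRecord
    seed: int = 0

    @property
    def variant(self) -> Variant:
        resected = self.bio.beta1 == -math.inf
        if self.bio.theta == 0:
            return Variant.SURGERY_HOMOGENEOUS if resected else Variant.FULL_HOMOGENEOUS
        return Variant.SURGERY if resected else Variant.FULL

    def model_params(self, constants: Constants = DEFAULT_CONSTANTS):
        return model_from_biological(self.bio, self.rec, constants, variant=self.variant)


@dataclass(frozen=True)
class SyntheticCohort:
    """One simulated patient: event-level history plus the detectable volumes.

    Times are years since disease onset.  ``inception_times`` =
    ``shed_times`` + ``latencies`` for every shed metastasis; ``sizes_at_W``
    is 0 for non-viable metastases or inceptions after the survey.
    """

    shed_times: np.ndarray
    viable: np.ndarray
    latencies: np.ndarray
    inception_times: np.ndarray
    sizes_at_W: np.ndarray
    detectable_volumes: np.ndarray  # cm^3, ascending
    truth: SyntheticTruth

    @property
    def n_detectable(self) -> int:
        return len(self.detectable_volumes)

    def to_patient_record(self) -> PatientRecord:
        r = self.truth.rec
        return PatientRecord(
            patient_id=r.patient_id,
            V=r.V,
            W=r.W,
            S_v=r.S_v,
            surgery=r.surgery,
            met_volumes=tuple(self.detectable_volumes),
            S_v_imputed=r.S_v_imputed,
        )

    def to_dict(self) -> dict:
        return {
            "seed": self.truth.seed,
            "shed_times": self.shed_times.tolist(),
            "viable": self.viable.astype(int).tolist(),
            "latencies": self.latencies.tolist(),
            "inception_times": self.inception_times.tolist(),
            "sizes_at_W": self.sizes_at_W.tolist(),
            "detectable_volumes": self.detectable_volumes.tolist(),
        }


def simulate_inhomogeneous_poisson(
    intensity: Callable[[np.ndarray], np.ndarray],
    horizon: float,
    bound: float,
    rng,
    t0: float = 0.0,
) -> np.ndarray:
    """Exact thinning sampler on [t0, horizon] given a finite intensity bound.

    Candidate events are homogeneous at rate ``bound``; each is accepted with
    probability intensity(t)/bound.  Returns sorted accepted times.
    """
    if horizon < t0:
        raise ValueError("horizon must be >= t0")
    if bound < 0:
        raise ValueError("intensity bound must be nonnegative")
    rng = np.random.default_rng(rng)
    span = horizon - t0
    n_cand = rng.poisson(bound * span) if bound > 0 and span > 0 else 0
    if n_cand == 0:
        return np.empty(0)
    t = np.sort(rng.uniform(t0, horizon, size=n_cand))
    lam = np.asarray(intensity(t), dtype=float)
    if np.any(lam > bound * (1 + 1e-9)):
        raise ValueError("intensity exceeds the supplied bound on the horizon")
    keep = rng.uniform(0.0, bound, size=n_cand) < lam
    return t[keep]


def _shed_pieces(truth: SyntheticTruth):
    """(lo, hi, intensity callable, bound) per monotone segment."""
    bio, rec = truth.bio, truth.rec
    tauV, tauW = rec.V - bio.T, rec.W - bio.T
    a = truth.shed.alpha
    th = bio.theta
    pieces = []

    def pre(t):
        return a * np.exp(th * bio.beta0 * np.asarray(t))

    hi0 = min(tauV, tauW)
    pieces.append((0.0, hi0, pre, float(pre(hi0))))
    resected = bio.beta1 is None or bio.beta1 == -math.inf
    if tauW > tauV and not resected:
        lnS = bio.beta0 * tauV
        b1 = bio.beta1

        def post(t):
            return a * np.exp(th * (lnS + b1 * (np.asarray(t) - tauV)))

        end = tauV if b1 <= 0 else tauW
        pieces.append((tauV, tauW, post, float(post(end))))
    return pieces


def simulate_patient(
    truth: SyntheticTruth,
    constants: Constants = DEFAULT_CONSTANTS,
    voxel_round: bool = False,
) -> SyntheticCohort:
    """Simulate one patient's full metastatic history.

    Three independent random substreams (shedding, viability thinning,
    latency) are spawned from the seed, so changing q leaves the shedding
    times untouched.  Detectable volumes (>= m) are returned ascending.
    With ``voxel_round`` the volumes are additionally rounded to the imaging
    voxel size (off by default).
    """
    bio, rec = truth.bio, truth.rec
    tauV, tauW = rec.V - bio.T, rec.W - bio.T
    dt = rec.W - rec.V
    ss = np.random.SeedSequence(truth.seed)
    rng_shed, rng_thin, rng_lat = (np.random.default_rng(s) for s in ss.spawn(3))

    times = []
    for lo, hi, f, bound in _shed_pieces(truth):
        # sub-split so the per-segment bound stays tight for steep intensities
        edges = np.linspace(lo, hi, 17)
        for a_, b_ in zip(edges[:-1], edges[1:]):
            seg_bound = max(float(f(a_)), float(f(b_)))
            times.append(
                simulate_inhomogeneous_poisson(f, b_, seg_bound, rng_shed, t0=a_)
            )
    shed_times = np.sort(np.concatenate(times)) if times else np.empty(0)

    n = len(shed_times)
    viable = rng_thin.random(n) < truth.shed.q
    latencies = rng_lat.exponential(bio.rho, size=n)
    inception = shed_times + latencies

    sizes = np.zeros(n)
    live = viable & (inception < tauW)
    if live.any():
        y0 = inception[live]
        pre = np.maximum(tauV - y0, 0.0)
        post = np.minimum(dt, tauW - y0)
        sizes[live] = np.exp(bio.gamma0 * pre + bio.gamma1 * post)

    det = sizes >= constants.m_cells
    vols = np.sort(sizes[det]) * constants.c
    if voxel_round:
        vols = np.maximum(np.round(vols / constants.voxel) * constants.voxel, constants.m)
    return SyntheticCohort(
        shed_times=shed_times,
        viable=viable,
        latencies=latencies,
        inception_times=inception,
        sizes_at_W=sizes,
        detectable_volumes=vols,
        truth=truth,
    )


def expected_detectable_count(
    truth: SyntheticTruth, constants: Constants = DEFAULT_CONSTANTS
) -> float:
    """Expected number of detectable metastases at the survey age.

    q*alpha * int phi(s)^theta F(tauW - psi(m) - s) ds: a metastasis shed at
    s is detectable iff its inception happens early enough for the growth
    law to lift it to the threshold m by W.
    """
    bio, rec = truth.bio, truth.rec
    tauV, tauW = rec.V - bio.T, rec.W - bio.T
    dt = rec.W - rec.V
    m = constants.m_cells
    lnm = math.log(m)
    lnA = bio.gamma1 * dt
    psi_m = lnm / bio.gamma1 if lnm <= lnA else (lnm - lnA) / bio.gamma0 + dt
    t_max = tauW - psi_m
    if t_max <= 0:
        return 0.0
    resected = bio.beta1 is None or bio.beta1 == -math.inf
    hi = min(t_max, tauV) if resected else t_max
    th, rho = bio.theta, bio.rho
    lnS = bio.beta0 * tauV

    def integrand(s: float) -> float:
        if s <= tauV:
            lam = math.exp(th * bio.beta0 * s)
        else:
            lam = math.exp(th * (lnS + bio.beta1 * (s - tauV)))
        u = t_max - s
        return lam * (-math.expm1(-u / rho)) if u > 0 else 0.0

    pts = [p for p in (tauV,) if 0 < p < hi]
    val, _ = integrate.quad(integrand, 0.0, hi, points=pts or None, limit=200)
    return truth.shed.q * truth.shed.alpha * val


def calibrate_alpha(
    bio: BiologicalParams,
    rec: PatientRecord,
    n_target: float,
    q: float = 1.0,
    constants: Constants = DEFAULT_CONSTANTS,
) -> SheddingParams:
    """Shedding scale alpha such that the expected detectable count at the
    survey age equals ``n_target`` (the count is linear in alpha)."""
    base = SheddingParams(alpha=1.0, q=q)
    e1 = expected_detectable_count(
        SyntheticTruth(bio=bio, shed=base, rec=rec), constants
    )
    if e1 <= 0:
        raise ValueError("no detectable metastases are possible under this truth")
    return SheddingParams(alpha=n_target / e1, q=q)


def recovery_experiment(
    truth: SyntheticTruth,
    n_target: int,
    n_seeds: int,
    cfg,
    constants: Constants = DEFAULT_CONSTANTS,
) -> dict:
    """Simulate-and-refit experiment quantifying estimator accuracy.

    alpha is calibrated so the expected detectable count is ``n_target``
    (>= 10, the cohort inclusion criterion); for each seed a cohort is
    simulated and fitted with ``cfg``, and relative errors of gamma0,
    gamma1, rho, gamma1/gamma0 and the onset-to-treatment interval V - T
    are tabulated.  Fit failures are counted, not raised.
    """
    from .inference import fit_mle

    if n_target < 10:
        raise ValueError("n_target must be >= 10 (cohort inclusion criterion)")
    shed = calibrate_alpha(truth.bio, truth.rec, n_target, truth.shed.q, constants)
    base = SyntheticTruth(bio=truth.bio, shed=shed, rec=truth.rec, seed=truth.seed)
    bio = truth.bio
    true_vals = {
        "gamma0": bio.gamma0,
        "gamma1": bio.gamma1,
        "rho": bio.rho,
        "ratio": bio.gamma1 / bio.gamma0,
        "V_minus_T": truth.rec.V - bio.T,
    }
    ss = np.random.SeedSequence(truth.seed)
    rows = []
    failures = 0
    for i, child in enumerate(ss.spawn(n_seeds)):
        sim_seed = int(child.generate_state(1)[0] % (2**31))
        cohort = simulate_patient(
            SyntheticTruth(bio=bio, shed=shed, rec=truth.rec, seed=sim_seed),
            constants,
        )
        if cohort.n_detectable < 10:
            failures += 1
            continue
        rec = cohort.to_patient_record()
        try:
            fit = fit_mle(rec, _with_seed(cfg, sim_seed), constants)
        except Exception:
            failures += 1
            continue
        fb = fit.bio
        est = {
            "gamma0": fb.gamma0,
            "gamma1": fb.gamma1,
            "rho": fb.rho,
            "ratio": fit.params.b0 / fit.params.b1,
            "V_minus_T": truth.rec.V - fb.T,
        }
        row = {"seed": sim_seed, "n": cohort.n_detectable,
               "neg_loglik_per_n": fit.neg_loglik_per_n}
        for k, tv in true_vals.items():
            row[f"rel_err_{k}"] = abs(est[k] - tv) / abs(tv)
            row[f"est_{k}"] = est[k]
        rows.append(row)
    table = pd.DataFrame(rows)
    medians = {
        k: float(table[f"rel_err_{k}"].median()) if len(table) else math.nan
        for k in true_vals
    }
    return {
        "table": table,
        "median_rel_err": medians,
        "n_fits": len(rows),
        "n_failures": failures,
        "true_values": true_vals,
    }


def _with_seed(cfg, seed: int):
    from .inference import FitConfig

    return FitConfig(
        variant=cfg.variant,
        seed=seed,
        population_size=cfg.population_size,
        max_generations=cfg.max_generations,
        restarts=cfg.restarts,
        A_candidate_strategy=cfg.A_candidate_strategy,
        polish_candidates=cfg.polish_candidates,
        de_tol=cfg.de_tol,
        bounds=cfg.bounds,
    )
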