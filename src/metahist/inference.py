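"""Likelihood and constrained global maximum-likelihood fitting.

Given the observed metastasis volumes of one patient, the likelihood is
L = n! * prod p(X_i) with p the closed-form size density of the chosen
variant.  The likelihood is discontinuous in the breakpoint A at every
observed volume (the optimal A sits just above one of them), and has many
local maxima, so the fit combines three stages:

1. differential evolution over a log-parameterized box (positivity by
   construction, the onset-positivity constraint as a smooth penalty);
2. a "snap" pass that re-evaluates the best solution with A placed just
   above each observed volume in turn (right limit, delta = 1e-9);
3. a Nelder-Mead polish of the remaining free parameters at the best
   snapped breakpoints.

Results are reproducible from the seed; the reported per-observation
negative log-likelihood follows the convention -sum(ln p(X_i))/n (the n!
term does not affect the argmax and is reported separately).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize
from scipy.special import gammaln
from scipy.stats import qmc

from .core import (
    BiologicalParams,
    Constants,
    ConstraintError,
    ConstraintReport,
    DEFAULT_CONSTANTS,
    ModelParams,
    PatientRecord,
    Variant,
    biological_from_model,
    check_constraints,
)
from .density import InfeasibleParams, SizeDensity

__all__ = ["FitConfig", "FitResult", "log_likelihood", "fit_mle", "fit_all_variants"]

_PENALTY = 1e6
_SNAP_DELTA = 1e-9


@dataclass(frozen=True)
class FitConfig:
    """Optimizer configuration.

    ``A_candidate_strategy``: 'both' (default) runs the continuous search and
    the observed-volume snap; 'continuous' or 'snap_to_observed' select one.
    ``bounds`` optionally overrides the search box, keyed by free-parameter
    name ('lnA_m', 'lnM_A', 'ln_a0', 'a1', 'ln_b0', 'ln_b1').
    """

    variant: Variant = Variant.FULL
    seed: int = 0
    population_size: int = 15
    max_generations: int = 250
    restarts: int = 2
    A_candidate_strategy: str = "both"
    snap_candidates: int = 12
    snap_generations: int = 80
    polish_candidates: int = 3
    de_tol: float = 1e-6
    bounds: Optional[Dict[str, Tuple[float, float]]] = None

    def __post_init__(self) -> None:
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if self.A_candidate_strategy not in ("both", "continuous", "snap_to_observed"):
            raise ValueError("unknown A_candidate_strategy")


@dataclass(frozen=True)
class FitResult:
    """A fitted variant with diagnostics."""

    params: ModelParams
    bio: Optional[BiologicalParams]
    neg_loglik_per_n: float        # -sum(ln p(X_i))/n, the tabled convention
    loglik: float                  # ln n! + sum ln p(X_i)
    n: int
    seed: int
    constraint_report: Optional[ConstraintReport]
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        p = self.params
        out = {
            "variant": p.variant.value,
            "model_params": {
                "A_cells": p.A, "M_cells": p.M, "a0": p.a0,
                "a1": p.a1, "b0": p.b0, "b1": p.b1,
            },
            "neg_loglik_per_n": self.neg_loglik_per_n,
            "loglik": self.loglik,
            "n": self.n,
            "seed": self.seed,
            "diagnostics": self.diagnostics,
        }
        if self.bio is not None:
            b = self.bio
            out["biological_params"] = {
                "beta0": b.beta0,
                "beta1": None if b.beta1 is None else b.beta1,
                "gamma0": b.gamma0, "gamma1": b.gamma1,
                "rho": b.rho, "theta": b.theta, "T": b.T,
                "gamma1_over_gamma0": b.gamma1 / b.gamma0,
            }
        return out


def log_likelihood(
    volumes: Sequence[float],
    p: ModelParams,
    rec: PatientRecord,
    constants: Constants = DEFAULT_CONSTANTS,
) -> float:
    """ln n! + sum ln p(x_i), sizes x_i = volume/c.

    Returns -inf (infeasible, not an exception) when any observation falls
    outside the support [m, M].  The maximizing parameters are independent
    of the cell volume c: rescaling (volumes, m, c) jointly shifts the value
    by exactly -n*ln(k).
    """
    if len(volumes) == 0:
        raise ValueError("empty volume list")
    x = np.asarray(volumes, dtype=float) / constants.c
    try:
        dens = SizeDensity(p, constants.m_cells)
    except InfeasibleParams:
        return -math.inf
    lp = dens.logpdf(x)
    if not np.all(np.isfinite(lp)):
        return -math.inf
    return float(gammaln(len(x) + 1) + lp.sum())


# ---------------------------------------------------------------------------
# search-space encoding
# ---------------------------------------------------------------------------

_FREE = {
    Variant.FULL: ("lnA_m", "lnM_A", "ln_a0", "a1", "ln_b0", "ln_b1"),
    Variant.SURGERY: ("lnA_m", "lnM_A", "ln_a0", "ln_b0", "ln_b1"),
    Variant.FULL_HOMOGENEOUS: ("lnA_m", "lnM_A", "ln_b0", "ln_b1"),
    Variant.SURGERY_HOMOGENEOUS: ("lnA_m", "lnM_A", "ln_b0", "ln_b1"),
}


def _default_bounds(names, x_max: float, m: float) -> List[Tuple[float, float]]:
    span = math.log(x_max / m) + math.log(50.0)
    box = {
        "lnA_m": (1e-4, span),
        "lnM_A": (1e-4, span),
        "ln_a0": (-12.0, 6.0),
        "a1": (-30.0, 5.0),
        "ln_b0": (-12.0, 6.0),
        "ln_b1": (-12.0, 6.0),
    }
    return [box[n] for n in names]


def _decode(v: np.ndarray, names, variant: Variant, m: float) -> ModelParams:
    d = dict(zip(names, v))
    A = m * math.exp(d["lnA_m"])
    M = A * math.exp(d["lnM_A"])
    a0 = math.exp(d["ln_a0"]) if "ln_a0" in d else 0.0
    a1 = d.get("a1")
    if variant is not Variant.FULL:
        a1 = None
    return ModelParams(
        A=A, M=M, a0=a0, a1=a1,
        b0=math.exp(d["ln_b0"]), b1=math.exp(d["ln_b1"]), variant=variant,
    )


def _encode(p: ModelParams, names, m: float) -> np.ndarray:
    d = {
        "lnA_m": math.log(p.A / m),
        "lnM_A": math.log(p.M / p.A),
        "ln_a0": math.log(p.a0) if p.a0 > 0 else -12.0,
        "a1": p.a1 if p.a1 is not None else 0.0,
        "ln_b0": math.log(p.b0),
        "ln_b1": math.log(p.b1),
    }
    return np.array([d[n] for n in names])


class _Objective:
    """Penalized per-observation negative log-likelihood."""

    def __init__(self, rec, variant, constants):
        self.rec = rec
        self.variant = variant
        self.constants = constants
        self.x = np.asarray(rec.met_sizes(constants))
        self.n = len(self.x)
        self.m = constants.m_cells
        self.lnx = np.log(self.x)
        self.x_max = float(self.x.max())
        self.names = _FREE[variant]

    def params_or_none(self, v):
        try:
            return _decode(np.asarray(v, dtype=float), self.names, self.variant, self.m)
        except (ValueError, OverflowError):
            return None

    def __call__(self, v) -> float:
        p = self.params_or_none(v)
        if p is None:
            return _PENALTY * 10.0
        penalty = 0.0
        if p.M < self.x_max:
            penalty += _PENALTY + 1e3 * (math.log(self.x_max / p.M)) ** 2
        rep = check_constraints(p, self.rec, self.constants)
        if not rep.onset_positive:
            viol = rep.details.get("b0_over_b1", 1.0) - rep.details.get("onset_bound", 0.0)
            penalty += _PENALTY + 1e3 * max(viol, 0.0) ** 2
        if not rep.above_threshold:
            penalty += _PENALTY
        if penalty > 0:
            return penalty
        try:
            dens = SizeDensity(p, self.m)
        except InfeasibleParams:
            return _PENALTY * 10.0
        lp = dens.logpdf(self.x)
        if not np.all(np.isfinite(lp)):
            return _PENALTY
        return -float(lp.mean())


def _lhs_init(bounds, n_pop, rng, extra_rows=None):
    sampler = qmc.LatinHypercube(d=len(bounds), rng=rng)
    unit = sampler.random(n=n_pop)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    pop = lo + unit * (hi - lo)
    if extra_rows:
        for i, row in enumerate(extra_rows[: max(0, n_pop - 5)]):
            pop[i] = np.clip(row, lo, hi)
    return pop


def fit_mle(
    rec: PatientRecord,
    cfg: FitConfig,
    constants: Constants = DEFAULT_CONSTANTS,
    init_candidates: Optional[Sequence[np.ndarray]] = None,
) -> FitResult:
    """Constrained global MLE for one variant on one patient's volumes.

    Runs ``cfg.restarts`` differential-evolution searches (seed-derived
    substreams), then snaps the breakpoint A to the right limit of each
    observed volume and polishes the best snaps with Nelder-Mead.  The
    returned parameters always satisfy the feasibility constraints.
    """
    if rec.n == 0:
        raise ValueError("record has no observed metastasis volumes")
    if cfg.variant.resected and not rec.surgery:
        raise ValueError("surgery variants require a surgery patient record")
    obj = _Objective(rec, cfg.variant, constants)
    names = obj.names
    bounds = _default_bounds(names, obj.x_max, obj.m)
    if cfg.bounds:
        bounds = [cfg.bounds.get(n, b) for n, b in zip(names, bounds)]

    ss = np.random.SeedSequence(cfg.seed)
    streams = ss.spawn(cfg.restarts + 2)
    candidates: List[Tuple[float, np.ndarray]] = []
    n_pop = max(5, cfg.population_size)
    extra = [np.asarray(c, dtype=float) for c in (init_candidates or [])]

    if cfg.A_candidate_strategy in ("both", "continuous"):
        for r in range(cfg.restarts):
            rng = np.random.default_rng(streams[r])
            init = _lhs_init(bounds, n_pop * len(bounds), rng, extra_rows=extra)
            res = optimize.differential_evolution(
                obj,
                bounds,
                init=init,
                maxiter=cfg.max_generations,
                tol=cfg.de_tol,
                rng=rng,
                polish=False,
                updating="deferred",
            )
            candidates.append((float(res.fun), np.asarray(res.x)))
    for c in extra:
        candidates.append((obj(c), c))
    if not candidates:
        # snap-only strategy still needs a starting point for the free params
        rng = np.random.default_rng(streams[0])
        init = _lhs_init(bounds, 64, rng)
        vals = [obj(row) for row in init]
        best = init[int(np.argmin(vals))]
        candidates.append((float(min(vals)), best))

    candidates.sort(key=lambda t: t[0])
    best_fun, best_v = candidates[0]
    n_snap_fits = 0

    if cfg.A_candidate_strategy in ("both", "snap_to_observed"):
        i_A = names.index("lnA_m")
        free_idx = [i for i in range(len(names)) if i != i_A]
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])

        def profiled(A_snap, warm, rng, generations):
            """Optimize the remaining free parameters at a fixed breakpoint."""
            lnA = math.log(A_snap / obj.m)
            red_bounds = [bounds[i] for i in free_idx]
            # M must stay above the largest observation
            iM_red = free_idx.index(names.index("lnM_A"))
            lomin = max(red_bounds[iM_red][0], math.log(obj.x_max / A_snap) + 1e-12)
            if lomin >= red_bounds[iM_red][1]:
                return None
            red_bounds[iM_red] = (lomin, red_bounds[iM_red][1])

            def red_obj(u):
                v = np.empty(len(names))
                v[i_A] = lnA
                v[free_idx] = u
                return obj(v)

            rows = [np.clip(w[free_idx], [b[0] for b in red_bounds],
                            [b[1] for b in red_bounds]) for w in warm]
            init = _lhs_init(red_bounds, 8 * len(red_bounds), rng, extra_rows=rows)
            res = optimize.differential_evolution(
                red_obj, red_bounds, init=init, maxiter=generations,
                tol=1e-4, rng=rng, polish=False, updating="deferred",
            )
            v = np.empty(len(names))
            v[i_A] = lnA
            v[free_idx] = res.x
            return float(res.fun), v

        # breakpoint candidates: observed volumes at quantile positions, plus
        # the observation nearest the continuous optimum
        xs = obj.x
        k = min(len(xs), max(2, cfg.snap_candidates))
        idx = sorted(set(np.linspace(0, len(xs) - 1, k).astype(int)))
        A_cont = obj.m * math.exp(best_v[i_A])
        idx.append(int(np.argmin(np.abs(xs - A_cont))))
        warm = [best_v] + [c[1] for c in candidates[1:3]] + extra
        snap_rng = np.random.default_rng(streams[cfg.restarts])
        snap_best = None
        for j in sorted(set(idx)):
            A_snap = xs[j] * (1.0 + _SNAP_DELTA)
            w = warm if snap_best is None else warm + [snap_best[1]]
            out = profiled(A_snap, w, snap_rng, cfg.snap_generations)
            n_snap_fits += 1
            if out is None:
                continue
            candidates.append(out)
            if snap_best is None or out[0] < snap_best[0]:
                snap_best = out
        candidates.sort(key=lambda t: t[0])

        # Nelder-Mead polish of the leading candidates (breakpoint held at
        # its right limit; the likelihood is smooth in the other parameters)
        polished = []
        for fun0, v0 in candidates[: cfg.polish_candidates]:
            def reduced(u, v0=v0):
                v = v0.copy()
                v[free_idx] = u
                return obj(v)

            res = optimize.minimize(
                reduced, v0[free_idx], method="Nelder-Mead",
                options={"maxiter": 300 * len(free_idx),
                         "xatol": 1e-9, "fatol": 1e-11},
            )
            v = np.clip(v0.copy(), lo, hi)
            v[free_idx] = np.clip(res.x, lo[free_idx], hi[free_idx])
            polished.append((obj(v), v))
        candidates.extend(polished)
        candidates.sort(key=lambda t: t[0])
        best_fun, best_v = candidates[0]

        # iterative neighborhood refinement: with the winning nuisance
        # parameters, try every observed volume as the breakpoint (right
        # limit), polish, repeat until the sweep stops improving
        i_M = names.index("lnM_A")
        for _round in range(5):
            refine = []
            M_cur = obj.m * math.exp(best_v[i_A] + best_v[i_M])
            for xi in xs:
                A_snap = xi * (1.0 + _SNAP_DELTA)
                if A_snap >= M_cur:
                    continue
                v = best_v.copy()
                v[i_A] = math.log(A_snap / obj.m)
                v[i_M] = math.log(M_cur / A_snap)
                refine.append((obj(v), v))
            refine.sort(key=lambda t: t[0])
            if not refine or refine[0][0] >= best_fun - 1e-12:
                break
            fun0, v0 = refine[0]

            def reduced(u, v0=v0):
                v = v0.copy()
                v[free_idx] = u
                return obj(v)

            res = optimize.minimize(
                reduced, v0[free_idx], method="Nelder-Mead",
                options={"maxiter": 300 * len(free_idx),
                         "xatol": 1e-9, "fatol": 1e-11},
            )
            v = v0.copy()
            v[free_idx] = np.clip(res.x, lo[free_idx], hi[free_idx])
            fv = obj(v)
            candidates.extend([(fv, v), (fun0, v0)])
            candidates.sort(key=lambda t: t[0])
            if candidates[0][0] >= best_fun - 1e-12:
                best_fun, best_v = candidates[0]
                break
            best_fun, best_v = candidates[0]

    if best_fun >= _PENALTY:
        raise RuntimeError("no feasible parameter set found within the search bounds")

    params = obj.params_or_none(best_v)
    rep = check_constraints(params, rec, constants)
    bio: Optional[BiologicalParams] = None
    try:
        bio = biological_from_model(params, rec, constants)
    except ConstraintError:
        bio = None
    ll = log_likelihood(rec.met_volumes, params, rec, constants)
    return FitResult(
        params=params,
        bio=bio,
        neg_loglik_per_n=best_fun,
        loglik=ll,
        n=rec.n,
        seed=cfg.seed,
        constraint_report=rep,
        diagnostics={
            "variant": cfg.variant.value,
            "strategy": cfg.A_candidate_strategy,
            "restarts": cfg.restarts,
            "snap_profile_fits": n_snap_fits,
        },
    )


def fit_all_variants(
    rec: PatientRecord,
    cfg: FitConfig,
    constants: Constants = DEFAULT_CONSTANTS,
) -> List[FitResult]:
    """Fit every admissible variant and rank by per-observation deviance.

    Surgery patients get all four variants (the two-growth-rate full
    variants are kept as a diagnostic: their fitted beta1 should come out
    negative, mirroring a resected primary); systemic-treatment patients get
    the full pair only.  Homogeneous solutions are passed to the nested
    non-homogeneous fits as warm starts, so the richer model never ends up
    with a worse likelihood than its special case.
    """
    if rec.surgery:
        order = [
            Variant.SURGERY_HOMOGENEOUS,
            Variant.SURGERY,
            Variant.FULL_HOMOGENEOUS,
            Variant.FULL,
        ]
    else:
        order = [Variant.FULL_HOMOGENEOUS, Variant.FULL]

    m = constants.m_cells
    results: Dict[Variant, FitResult] = {}
    for variant in order:
        extra = []
        nested = {
            Variant.SURGERY: Variant.SURGERY_HOMOGENEOUS,
            Variant.FULL: Variant.FULL_HOMOGENEOUS,
        }.get(variant)
        if nested in results:
            pn = results[nested].params
            seedp = ModelParams(
                A=pn.A, M=pn.M, a0=math.exp(-12.0), b0=pn.b0, b1=pn.b1,
                a1=(-1e-6 if variant is Variant.FULL else None),
                variant=variant,
            )
            extra.append(_encode(seedp, _FREE[variant], m))
        sub_cfg = FitConfig(
            variant=variant,
            seed=cfg.seed,
            population_size=cfg.population_size,
            max_generations=cfg.max_generations,
            restarts=cfg.restarts,
            A_candidate_strategy=cfg.A_candidate_strategy,
            polish_candidates=cfg.polish_candidates,
            de_tol=cfg.de_tol,
            bounds=cfg.bounds,
        )
        res = fit_mle(rec, sub_cfg, constants, init_candidates=extra)
        if rec.surgery and not variant.resected:
            res.diagnostics["diagnostic_only"] = True
        results[variant] = res
    ranked = sorted(results.values(), key=lambda r: (r.neg_loglik_per_n, r.params.variant.value))
    return ranked
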