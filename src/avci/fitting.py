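"""Joint maximum-likelihood fitting of one model variant to all five tasks.

The joint objective sums the four task NLLs (the bimodal experiment
contributes the localization and report likelihood jointly).  Optimization
is bounded, derivative-free, multi-start: free parameters are mapped to the
unit cube by their bounds, starting points are Latin-hypercube draws from
the plausible sub-ranges, and each start is polished with Powell's method.
Warm starts from nested variants are supported so that richer variants never
fit worse than the models they nest.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import qmc

from .likelihoods import (
    QuadratureSpec,
    nll_bimodal,
    nll_discrimination,
    nll_toj,
    nll_unimodal_localization,
)
from .params import (
    DEFAULT_BOUNDS,
    ModelVariant,
    ObserverParams,
    ParamBounds,
    apply_variant,
    count_free_params,
    free_param_names,
    free_values,
)

__all__ = ["FitResult", "joint_nll", "fit_variant", "fit_all_variants"]

_TASKS = ("toj", "disc", "uniloc", "bimodal")
_BOUNDARY_FRAC = 0.01  # pin flag: within 1% of the bound range


def joint_nll(params: ObserverParams, dataset: dict[str, pd.DataFrame],
              spec: QuadratureSpec | None = None) -> float:
    """Sum of the four task NLLs for one full parameter set."""
    missing = [t for t in _TASKS if t not in dataset]
    if missing:
        raise ValueError(f"dataset is missing tables: {missing}")
    return (nll_toj(dataset["toj"], params)
            + nll_discrimination(dataset["disc"], params)
            + nll_unimodal_localization(dataset["uniloc"], params)
            + nll_bimodal(dataset["bimodal"], params, spec))


@dataclass
class FitResult:
    """Outcome of fitting one variant: best parameters and diagnostics."""

    variant: ModelVariant
    free_names: tuple[str, ...]
    best_values: np.ndarray
    nll: float
    aic: float
    start_nlls: list
    converged: bool
    boundary_pinned: dict

    @property
    def params(self) -> ObserverParams:
        return apply_variant(self.variant, self.best_values)

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["variant"] = {"mismatch_temporal": self.variant.mismatch_temporal,
                        "mismatch_spatial": self.variant.mismatch_spatial}
        d["best_values"] = [float(v) for v in self.best_values]
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        d = dict(d)
        d["variant"] = ModelVariant(**d["variant"])
        d["free_names"] = tuple(d["free_names"])
        d["best_values"] = np.asarray(d["best_values"], dtype=float)
        return cls(**d)

    @classmethod
    def from_json(cls, s: str) -> "FitResult":
        return cls.from_dict(json.loads(s))


def _unit_to_values(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    return lo + np.clip(x, 0.0, 1.0) * (hi - lo)


# parameters identified by the closed-form tasks (stage A) vs. those that
# only the bimodal task constrains (stage B)
_STAGE_A = {"aA", "bA", "sigmaA_act", "sigmaA_emp", "sigmaV", "sigmaDt_act",
            "bDt", "sigmaP", "lapse1", "lapse2", "lapse3", "sigmaMotor"}


def _powell_subset(names: tuple[str, ...], sub: list[str], values: np.ndarray,
                   objective_of_values, bounds: ParamBounds,
                   maxfev: int) -> np.ndarray:
    """Polish a subset of the free vector with Powell, others held fixed."""
    idx = [names.index(n) for n in sub]
    lo, hi = bounds.arrays(sub)

    def obj(xu: np.ndarray) -> float:
        v = values.copy()
        v[idx] = _unit_to_values(xu, lo, hi)
        return objective_of_values(v)

    x0 = np.clip((values[idx] - lo) / (hi - lo), 0.0, 1.0)
    res = minimize(obj, x0, method="Powell", bounds=[(0.0, 1.0)] * len(sub),
                   options={"xtol": 1e-4, "ftol": 1e-7, "maxfev": maxfev})
    out = values.copy()
    if res.fun <= obj(x0):
        out[idx] = _unit_to_values(res.x, lo, hi)
    return out


def staged_start(variant: ModelVariant, dataset: dict[str, pd.DataFrame],
                 bounds: ParamBounds = DEFAULT_BOUNDS, seed: int = 0,
                 spec: QuadratureSpec | None = None,
                 maxfev_cheap: int = 6000, maxfev_joint: int = 1500
                 ) -> ObserverParams:
    """Sequential initialization for the joint fit.

    Stage A fits the parameters the three closed-form tasks identify
    (remapping, unimodal noise and shrinkage, temporal-order noise, lapses,
    motor noise) against only those tasks' likelihoods; stage B then fits the
    bimodal-only parameters (bimodal auditory noise, causal prior and
    criterion, employed SOA uncertainty) against the bimodal likelihood with
    stage-A values held fixed.  The result is a starting point, not a joint
    optimum: the caller polishes it against the full joint NLL.
    """
    names = free_param_names(variant)
    plo, phi = bounds.plausible_arrays(names)
    values = 0.5 * (plo + phi)

    sub_a = [n for n in names if n in _STAGE_A]
    def cheap(v: np.ndarray) -> float:
        p = apply_variant(variant, v)
        return (nll_toj(dataset["toj"], p)
                + nll_discrimination(dataset["disc"], p)
                + nll_unimodal_localization(dataset["uniloc"], p))
    values = _powell_subset(names, sub_a, values, cheap, bounds, maxfev=maxfev_cheap)

    # the cheap tasks only constrain products such as w·aA, leaving a ridge
    # over (sigmaP, sigmaV, employed SDs); refit the bimodal-specific
    # parameters together with those shared ones against the joint NLL
    sub_b = [n for n in names
             if n not in _STAGE_A or n in ("sigmaP", "sigmaV", "sigmaMotor")]
    def jnt(v: np.ndarray) -> float:
        return joint_nll(apply_variant(variant, v), dataset, spec)
    values = _powell_subset(names, sub_b, values, jnt, bounds, maxfev=maxfev_joint)
    return apply_variant(variant, values)


def fit_variant(variant: ModelVariant, dataset: dict[str, pd.DataFrame],
                bounds: ParamBounds = DEFAULT_BOUNDS, n_starts: int = 20,
                seed: int = 0, spec: QuadratureSpec | None = None,
                extra_starts: list[ObserverParams] | None = None,
                maxfev: int | None = None, staged: bool = True) -> FitResult:
    """Best-of-starts bounded minimization of the joint NLL.

    With ``staged`` (the default) the first start is the sequential
    task-wise initialization from :func:`staged_start`; the remaining
    ``n_starts − 1`` starts are Latin-hypercube draws from the plausible
    ranges.  ``extra_starts`` adds full parameter sets (e.g. a nested
    variant's optimum) as additional starting points.  The reported optimum
    is never worse than any evaluated start, so warm-starting from a nested
    model guarantees the nested-NLL ordering up to optimizer tolerance.
    Deterministic under ``seed``.
    """
    if n_starts < 1 and not (staged or extra_starts):
        raise ValueError("need at least one start")
    names = free_param_names(variant)
    k = len(names)
    lo, hi = bounds.arrays(names)
    plo, phi = bounds.plausible_arrays(names)

    def objective(x: np.ndarray) -> float:
        return joint_nll(apply_variant(variant, _unit_to_values(x, lo, hi)), dataset, spec)

    n_lhs = max(n_starts - 1, 0) if staged else n_starts
    starts = []
    if staged:
        mc, mj = ((min(6000, 3 * maxfev), min(1500, maxfev))
                  if maxfev is not None else (6000, 1500))
        starts.append(free_values(
            staged_start(variant, dataset, bounds, seed=seed, spec=spec,
                         maxfev_cheap=mc, maxfev_joint=mj), variant))
    if n_lhs > 0:
        sampler = qmc.LatinHypercube(d=k, seed=seed)
        starts.extend(plo + sampler.random(n_lhs) * (phi - plo))
    for p0 in extra_starts or []:
        starts.append(free_values(p0, variant))
    unit_starts = [np.clip((s - lo) / (hi - lo), 0.0, 1.0) for s in starts]

    best_x, best_f = None, np.inf
    trace, any_success = [], False
    options = {"xtol": 1e-4, "ftol": 1e-7}
    if maxfev is not None:
        options["maxfev"] = maxfev
    for x0 in unit_starts:
        f0 = objective(x0)
        res = minimize(objective, x0, method="Powell",
                       bounds=[(0.0, 1.0)] * k, options=options)
        any_success = any_success or bool(res.success)
        x_star, f_star = (res.x, float(res.fun)) if res.fun <= f0 else (x0, f0)
        trace.append(f_star)
        if f_star < best_f:
            best_x, best_f = np.asarray(x_star, dtype=float), f_star
    if best_x is None or not np.isfinite(best_f):
        raise RuntimeError(
            f"optimization failed for variant {variant.name}: no finite NLL found "
            f"(start NLLs: {trace})")

    # polish the incumbent until it is a Powell fixed point (NLL change
    # below tolerance), so refitting from the optimum is a no-op; each
    # round gets one direction-set sweep's worth of evaluations
    polish_options = dict(options, maxfev=min(maxfev or 10**9, 30 * k))
    for _ in range(3):
        res = minimize(objective, best_x, method="Powell",
                       bounds=[(0.0, 1.0)] * k, options=polish_options)
        if res.fun < best_f:
            improved = best_f - res.fun
            best_x, best_f = np.asarray(res.x, dtype=float), float(res.fun)
            if improved < 5e-3:
                break
        else:
            break

    values = _unit_to_values(best_x, lo, hi)
    pinned = {n: bool(min(values[i] - lo[i], hi[i] - values[i])
                      < _BOUNDARY_FRAC * (hi[i] - lo[i]))
              for i, n in enumerate(names)}
    return FitResult(
        variant=variant,
        free_names=names,
        best_values=values,
        nll=best_f,
        aic=2.0 * count_free_params(variant) + 2.0 * best_f,
        start_nlls=trace,
        converged=any_success,
        boundary_pinned=pinned,
    )


def fit_all_variants(dataset: dict[str, pd.DataFrame],
                     bounds: ParamBounds = DEFAULT_BOUNDS, n_starts: int = 2,
                     seed: int = 0, spec: QuadratureSpec | None = None,
                     maxfev: int | None = None) -> dict[ModelVariant, FitResult]:
    """Fit all four variants, warm-starting richer variants from nested optima.

    The accurate (fully tied) variant is fitted first with the staged
    initialization plus ``n_starts − 1`` Latin-hypercube starts; each
    mismatch variant then starts from the best optimum among the variants
    it nests (employed fields initialized at their tied values).  Warm
    starts make the nested-NLL ordering hold by construction: a richer
    variant never reports a worse NLL than the best model it nests, and by
    transitivity never a worse NLL than any model it nests.
    """
    order = [ModelVariant(False, False), ModelVariant(True, False),
             ModelVariant(False, True), ModelVariant(True, True)]
    results: dict[ModelVariant, FitResult] = {}
    for i, variant in enumerate(order):
        nested = [r for v, r in results.items()
                  if (variant.mismatch_temporal or not v.mismatch_temporal)
                  and (variant.mismatch_spatial or not v.mismatch_spatial)]
        warm = [min(nested, key=lambda r: r.nll).params] if nested else []
        results[variant] = fit_variant(
            variant, dataset, bounds=bounds,
            n_starts=n_starts if not warm else 0,
            seed=seed + i, spec=spec, extra_starts=warm, maxfev=maxfev)
    return results
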