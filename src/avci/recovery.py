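"""Turnkey validation experiments: parameter recovery and model recovery.

Parameter recovery simulates full synthetic sessions from a known observer,
refits the generating variant, and summarizes how well the key uncertainty
parameters are recovered — in particular whether the qualitative headline
(employed uncertainty below actual uncertainty) is recoverable from data of
the designed size.  Model recovery generates data from each of the four
variants and tabulates which variant wins the AIC comparison.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .compare import compare_variants
from .fitting import fit_all_variants, fit_variant
from .likelihoods import QuadratureSpec
from .params import (
    ALL_VARIANTS,
    DEFAULT_BOUNDS,
    PAPER_REGIME,
    ModelVariant,
    ObserverParams,
    ParamBounds,
)
from .simulate import DEFAULT_DESIGN, ExperimentDesign, child_seeds, simulate_all

__all__ = ["RecoveryReport", "KEY_PARAMS", "run_parameter_recovery",
           "ModelRecoveryReport", "run_model_recovery", "variant_generating_params"]

KEY_PARAMS = ("sigmaDt_act", "sigmaDt_emp", "sigmaA_act", "sigmaA_emp")

# Validation runs use a coarser quadrature than the reference spec: accuracy
# checks (closed-form limits, Monte-Carlo equivalence) are run at the default
# resolution, while the many refits of a recovery experiment use this one.
FAST_SPEC = QuadratureSpec(nodes=21, halfwidth=4.0, grid_spacing=0.5, grid_half=60.0)


@dataclass
class RecoveryReport:
    """Parameter-recovery outcome across replicates."""

    generating: dict
    variant: dict
    n_reps: int
    seeds: list
    reduced: bool
    recovered: list            # per replicate: {param: value}
    rel_errors: dict           # per key param: list of (recovered/true − 1)
    frac_within_25pct: dict    # per key param
    bias: dict                 # per key param: mean relative error
    rel_rmse: dict             # per key param
    ratio_temporal: list       # recovered sigmaDt_emp / sigmaDt_act per replicate
    ratio_spatial: list        # recovered sigmaA_emp / sigmaA_act per replicate
    frac_ratio_lt1: dict       # {"temporal": ..., "spatial": ...}
    failures: list             # replicate indices whose fit errored
    threshold_rel_error: float = 0.25

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def variant_generating_params(variant: ModelVariant,
                              base: ObserverParams = PAPER_REGIME) -> ObserverParams:
    """Generating observer for a variant: tied fields collapse to actual values."""
    kw = {}
    if not variant.mismatch_temporal:
        kw["sigmaDt_emp"] = base.sigmaDt_act
    if not variant.mismatch_spatial:
        kw["sigmaA_emp"] = base.sigmaA_act
        kw["sigmaAVA_emp"] = base.sigmaAVA_act
    return base.replace(**kw) if kw else base


def run_parameter_recovery(generating: ObserverParams = PAPER_REGIME,
                           variant: ModelVariant = ModelVariant(True, True),
                           n_reps: int = 10, seed: int = 0,
                           spec: QuadratureSpec = FAST_SPEC,
                           reduced: bool = True,
                           design: ExperimentDesign | None = None,
                           bounds: ParamBounds = DEFAULT_BOUNDS,
                           n_starts: int = 2, maxfev: int | None = 3000,
                           fitter=fit_variant,
                           ) -> RecoveryReport:
    """Simulate → fit ``n_reps`` synthetic sessions and summarize recovery.

    With ``reduced`` the quarter-scale design is used.  Fit errors are
    recorded per replicate rather than raised.  ``fitter`` must have the
    signature of :func:`avci.fitting.fit_variant` (injectable for testing).
    """
    if n_reps < 3:
        raise ValueError("n_reps must be at least 3")
    design = design or (DEFAULT_DESIGN.reduced() if reduced else DEFAULT_DESIGN)
    seeds = child_seeds(seed, n_reps)
    recovered, failures = [], []
    ratio_t, ratio_s = [], []
    rel = {k: [] for k in KEY_PARAMS}
    for i, s in enumerate(seeds):
        data = simulate_all(design, generating, s)
        try:
            fit = fitter(variant, data, bounds=bounds, n_starts=n_starts,
                         seed=s, spec=spec, maxfev=maxfev)
        except Exception as exc:  # recorded, not fatal
            failures.append({"replicate": i, "error": str(exc)})
            continue
        p = fit.params
        recovered.append({n: float(getattr(p, n)) for n in fit.free_names})
        for k in KEY_PARAMS:
            rel[k].append(float(getattr(p, k) / getattr(generating, k) - 1.0))
        ratio_t.append(float(p.sigmaDt_emp / p.sigmaDt_act))
        ratio_s.append(float(p.sigmaA_emp / p.sigmaA_act))
    frac25 = {k: float(np.mean([abs(e) <= 0.25 for e in v])) if v else 0.0
              for k, v in rel.items()}
    bias = {k: float(np.mean(v)) if v else float("nan") for k, v in rel.items()}
    rmse = {k: float(np.sqrt(np.mean(np.square(v)))) if v else float("nan")
            for k, v in rel.items()}
    return RecoveryReport(
        generating=generating.to_dict(),
        variant={"mismatch_temporal": variant.mismatch_temporal,
                 "mismatch_spatial": variant.mismatch_spatial},
        n_reps=n_reps, seeds=seeds, reduced=reduced,
        recovered=recovered, rel_errors=rel,
        frac_within_25pct=frac25, bias=bias, rel_rmse=rmse,
        ratio_temporal=ratio_t, ratio_spatial=ratio_s,
        frac_ratio_lt1={
            "temporal": float(np.mean([r < 1.0 for r in ratio_t])) if ratio_t else 0.0,
            "spatial": float(np.mean([r < 1.0 for r in ratio_s])) if ratio_s else 0.0,
        },
        failures=failures,
    )


@dataclass
class ModelRecoveryReport:
    """Winner confusion matrix from fitting all variants to each variant's data."""

    n_participants: int
    seeds: list
    reduced: bool
    variant_names: list
    confusion: list            # rows: generating variant; cols: winning variant
    failures: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @property
    def matrix(self) -> np.ndarray:
        return np.asarray(self.confusion, dtype=int)


def run_model_recovery(n_participants: int = 3, seed: int = 0,
                       spec: QuadratureSpec = FAST_SPEC,
                       reduced: bool = True,
                       design: ExperimentDesign | None = None,
                       base: ObserverParams = PAPER_REGIME,
                       bounds: ParamBounds = DEFAULT_BOUNDS,
                       n_starts: int = 2, maxfev: int | None = 3000,
                       fitter=fit_all_variants,
                       ) -> ModelRecoveryReport:
    """Generate data from each variant, fit all four, tabulate AIC winners.

    ``fitter`` must have the signature of :func:`avci.fitting.fit_all_variants`.
    """
    design = design or (DEFAULT_DESIGN.reduced() if reduced else DEFAULT_DESIGN)
    seeds = child_seeds(seed, 4 * n_participants)
    confusion = np.zeros((4, 4), dtype=int)
    failures = []
    idx = {v: i for i, v in enumerate(ALL_VARIANTS)}
    si = 0
    for gv in ALL_VARIANTS:
        gen = variant_generating_params(gv, base)
        for _ in range(n_participants):
            s = seeds[si]
            si += 1
            data = simulate_all(design, gen, s)
            try:
                fits = fitter(data, bounds=bounds, n_starts=n_starts,
                              seed=s, spec=spec, maxfev=maxfev)
                winner = compare_variants(fits)["winner"]
            except Exception as exc:
                failures.append({"generating": gv.name, "seed": s, "error": str(exc)})
                continue
            confusion[idx[gv], idx[winner]] += 1
    return ModelRecoveryReport(
        n_participants=n_participants, seeds=seeds, reduced=reduced,
        variant_names=[v.name for v in ALL_VARIANTS],
        confusion=confusion.tolist(), failures=failures,
    )
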