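"""AIC-based model comparison and actual-vs-employed uncertainty contrasts.

Each participant's four variant fits are compared by AIC (2k + 2·NLL); the
winner is the variant with the lowest AIC, with exact ties broken toward
fewer free parameters.  Group-level contrasts test whether the employed
uncertainty differs from the actual uncertainty with a two-sided paired
t-test on the winning-model parameter values, excluding participants whose
relevant parameters were pinned at an optimization bound.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import FitResult
from .params import ALL_VARIANTS, ModelVariant, ObserverParams, count_free_params

__all__ = [
    "aic",
    "compare_variants",
    "comparison_table",
    "ContrastResult",
    "contrast_actual_vs_employed",
    "CONTRAST_FIELDS",
]

CONTRAST_FIELDS = {
    "temporal": ("sigmaDt_act", "sigmaDt_emp"),
    "spatial-unimodal": ("sigmaA_act", "sigmaA_emp"),
    "spatial-bimodal": ("sigmaAVA_act", "sigmaAVA_emp"),
}


def aic(nll: float, k: int) -> float:
    """Akaike information criterion, 2k + 2·NLL (lower is better)."""
    if k < 1:
        raise ValueError("k must be at least 1")
    return 2.0 * k + 2.0 * nll


def compare_variants(fits: dict[ModelVariant, FitResult] | list[FitResult]) -> dict:
    """One participant's comparison row: AIC per variant, ΔAIC, winner.

    Ties in AIC are broken toward the variant with fewer free parameters
    (and deterministically by variant order among equals).
    """
    if not isinstance(fits, dict):
        fits = {f.variant: f for f in fits}
    missing = [v for v in ALL_VARIANTS if v not in fits]
    if missing:
        raise ValueError(f"missing fits for variants: {[v.name for v in missing]}")
    aics = {v: aic(fits[v].nll, count_free_params(v)) for v in ALL_VARIANTS}
    winner = min(ALL_VARIANTS, key=lambda v: (aics[v], count_free_params(v)))
    best = aics[winner]
    return {
        "winner": winner,
        "aic": {v.name: aics[v] for v in ALL_VARIANTS},
        "delta_aic": {v.name: aics[v] - best for v in ALL_VARIANTS},
    }


def comparison_table(fits_per_participant: list[dict[ModelVariant, FitResult]]
                     ) -> pd.DataFrame:
    """Tidy per-participant table of AICs, ΔAICs and winner names."""
    rows = []
    for pid, fits in enumerate(fits_per_participant):
        row = compare_variants(fits)
        rec = {"participant": pid, "winner": row["winner"].name}
        for v in ALL_VARIANTS:
            rec[f"aic_{v.name}"] = row["aic"][v.name]
            rec[f"delta_aic_{v.name}"] = row["delta_aic"][v.name]
        rows.append(rec)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ContrastResult:
    """Paired comparison of actual vs. employed uncertainty across participants."""

    which: str
    median_actual: float
    median_employed: float
    sem_actual: float
    sem_employed: float
    t: float
    df: int
    p: float
    n_included: int
    excluded: tuple[int, ...]


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else float("nan")


def contrast_actual_vs_employed(
    winning: list[ObserverParams] | list[FitResult],
    which: str,
    pinned: list[dict] | None = None,
) -> ContrastResult:
    """Two-sided paired t-test of actual vs. employed uncertainty.

    ``winning`` holds each participant's winning-model parameters (or full
    FitResults, from which boundary-pin flags are taken automatically).
    Participants whose actual or employed parameter for this contrast is
    boundary-pinned are excluded from the test.  With zero variance of the
    paired differences the t statistic is reported as ±inf (or 0 for
    identical vectors) with a warning.
    """
    act_name, emp_name = CONTRAST_FIELDS[which]
    if winning and isinstance(winning[0], FitResult):
        pinned = [f.boundary_pinned for f in winning]
        winning = [f.params for f in winning]
    pinned = pinned or [{} for _ in winning]

    excluded = tuple(i for i, flags in enumerate(pinned)
                     if flags.get(act_name, False) or flags.get(emp_name, False))
    keep = [i for i in range(len(winning)) if i not in excluded]
    if len(keep) < 3:
        raise ValueError(f"contrast '{which}' needs at least 3 included "
                         f"participants, got {len(keep)}")
    actual = np.array([getattr(winning[i], act_name) for i in keep])
    employed = np.array([getattr(winning[i], emp_name) for i in keep])
    diff = actual - employed
    n = diff.size
    sd = float(np.std(diff, ddof=1))
    if sd == 0.0:
        if float(np.mean(diff)) == 0.0:
            t, p = 0.0, 1.0
        else:
            warnings.warn("zero variance of paired differences; t is infinite")
            t, p = float(np.sign(np.mean(diff))) * np.inf, 0.0
    else:
        t_res = stats.ttest_rel(actual, employed)
        t, p = float(t_res.statistic), float(t_res.pvalue)
    return ContrastResult(
        which=which,
        median_actual=float(np.median(actual)),
        median_employed=float(np.median(employed)),
        sem_actual=_sem(actual),
        sem_employed=_sem(employed),
        t=t, df=n - 1, p=p,
        n_included=n, excluded=excluded,
    )
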