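"""Per-trial inference machinery of the Bayesian observer.

All decision quantities are computed from internal measurements using the
observer's *employed* uncertainties; the *actual* uncertainties only govern
how measurements are distributed around the (remapped) stimuli and therefore
appear in the closed-form response probabilities, never inside the observer's
own inference.

Closed-form Gaussian identities used throughout:

    ∫ N(m; s, a²) N(s; μ, b²) ds             = N(m; μ, a² + b²)
    N(m1; s, a²) N(m2; s, b²)                = N(m1 − m2; 0, a² + b²) · N(s; c, v)
        with v = (1/a² + 1/b²)⁻¹, c = v (m1/a² + m2/b²)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy.special import expit, ndtr

from .params import ObserverParams

__all__ = [
    "MeasurementTriple",
    "remap_auditory",
    "shrink_estimate",
    "shrink_weight",
    "log_spatial_evidence_ratio",
    "log_temporal_evidence_ratio",
    "log_posterior_common_odds",
    "posterior_common",
    "conditional_estimates",
    "model_averaged_estimate",
    "p_report_afirst",
    "p_report_aright",
    "explicit_common_report",
]

ArrayLike = Union[float, np.ndarray]


@dataclass(frozen=True)
class MeasurementTriple:
    """Internal measurements on one bimodal trial.

    mA, mV: auditory and visual spatial measurements (deg);
    mDt: SOA measurement (ms, positive = auditory first).
    """

    mA: float
    mV: float
    mDt: float


def remap_auditory(sA: ArrayLike, params: ObserverParams) -> ArrayLike:
    """Remapped auditory location s′ = aA·sA + bA (mean internal measurement)."""
    return params.aA * np.asarray(sA, dtype=float) + params.bA


def shrink_weight(sigma_emp: ArrayLike, prior_sigma: ArrayLike) -> ArrayLike:
    """Shrinkage weight w = σP²/(σP² + σ̃²) on the measurement.

    The posterior mode is w·m + (1−w)·μP; w grows as the employed
    uncertainty shrinks, which is the behavioural lever that identifies
    employed separately from actual uncertainty.
    """
    sigma_emp = np.asarray(sigma_emp, dtype=float)
    prior_sigma = np.asarray(prior_sigma, dtype=float)
    if np.any(sigma_emp <= 0) or np.any(prior_sigma <= 0):
        raise ValueError("standard deviations must be strictly positive")
    return prior_sigma**2 / (prior_sigma**2 + sigma_emp**2)


def shrink_estimate(m: ArrayLike, sigma_emp: ArrayLike, prior_mu: ArrayLike,
                    prior_sigma: ArrayLike) -> ArrayLike:
    """Posterior-mode estimate for a single Gaussian measurement.

    Precision-weighted combination of the measurement (at employed precision)
    and the Gaussian prior: (m/σ̃² + μ/σP²)/(1/σ̃² + 1/σP²).
    """
    w = shrink_weight(sigma_emp, prior_sigma)
    return w * np.asarray(m, dtype=float) + (1.0 - w) * np.asarray(prior_mu, dtype=float)


def _log_norm_pdf(x: ArrayLike, mu: ArrayLike, var: ArrayLike) -> ArrayLike:
    x = np.asarray(x, dtype=float)
    return -0.5 * (np.log(2.0 * np.pi * var) + (x - mu) ** 2 / var)


def log_spatial_evidence_ratio(mA: ArrayLike, mV: ArrayLike,
                               params: ObserverParams) -> ArrayLike:
    """log L1,space − log L2,space for the causal posterior.

    Under C=1 one shared source location s is marginalized over the spatial
    prior: L1 = ∫ N(mA; s, σ̃AV,A²) N(mV; s, σV²) N(s; μP, σP²) ds.  Under
    C=2 the auditory and visual sources are independent draws from the
    prior, so L2 is the product of the two single-cue marginals.  Uses the
    bimodal-context employed auditory uncertainty.
    """
    p = params
    va = p.sigmaAVA_emp**2
    vv = p.sigmaV**2
    vp = p.sigmaP**2
    mA = np.asarray(mA, dtype=float)
    mV = np.asarray(mV, dtype=float)
    v_c = 1.0 / (1.0 / va + 1.0 / vv)
    c = v_c * (mA / va + mV / vv)
    logS1 = (_log_norm_pdf(mA - mV, 0.0, va + vv)
             + _log_norm_pdf(c, p.muP, v_c + vp))
    logS2 = _log_norm_pdf(mA, p.muP, va + vp) + _log_norm_pdf(mV, p.muP, vv + vp)
    return logS1 - logS2


def log_temporal_evidence_ratio(mDt: ArrayLike, params: ObserverParams) -> ArrayLike:
    """log L1,time − log L2,time for the causal posterior.

    Under C=1 the true SOA is marginalized over a zero-mean Gaussian prior
    (σPt1); under C=2 the SOA prior is uniform on ±rangeT (truncation of the
    measurement density is ignored), so L2 = 1/(2·rangeT).
    """
    p = params
    logT1 = _log_norm_pdf(np.asarray(mDt, dtype=float), 0.0,
                          p.sigmaDt_emp**2 + p.sigmaPt1**2)
    return logT1 + np.log(2.0 * p.rangeT)


def log_posterior_common_odds(mA: ArrayLike, mV: ArrayLike, mDt: ArrayLike,
                              params: ObserverParams) -> ArrayLike:
    """Log posterior odds of a common cause given one measurement triple.

    Combines the closed-form spatial and temporal evidence ratios with the
    prior odds of a common cause.  All marginals are exact Gaussians;
    bimodal-context employed uncertainties are used throughout.  Vectorized
    over broadcastable measurement arrays.
    """
    p = params
    if p.pCommon <= 0.0:
        return np.broadcast_to(-np.inf, np.broadcast_shapes(
            np.shape(mA), np.shape(mV), np.shape(mDt))).copy()
    if p.pCommon >= 1.0:
        return np.broadcast_to(np.inf, np.broadcast_shapes(
            np.shape(mA), np.shape(mV), np.shape(mDt))).copy()
    prior_odds = np.log(p.pCommon) - np.log1p(-p.pCommon)
    return (prior_odds
            + log_spatial_evidence_ratio(mA, mV, params)
            + log_temporal_evidence_ratio(mDt, params))


def posterior_common(meas: MeasurementTriple, params: ObserverParams) -> float:
    """Posterior probability of a common cause, p(C=1 | mA, mV, mDt).

    Physical stimulus locations never enter: the observer only sees its
    measurements.
    """
    log_odds = log_posterior_common_odds(meas.mA, meas.mV, meas.mDt, params)
    return float(expit(log_odds))


def conditional_estimates(meas: MeasurementTriple, params: ObserverParams
                          ) -> tuple[float, float]:
    """Auditory location estimates conditional on each causal scenario.

    Under C=1 the auditory and visual measurements and the spatial prior are
    fused by employed precision; under C=2 only the auditory measurement is
    shrunk toward the prior.
    """
    p = params
    pa = 1.0 / p.sigmaAVA_emp**2
    pv = 1.0 / p.sigmaV**2
    pp = 1.0 / p.sigmaP**2
    s1 = (meas.mA * pa + meas.mV * pv + p.muP * pp) / (pa + pv + pp)
    s2 = float(shrink_estimate(meas.mA, p.sigmaAVA_emp, p.muP, p.sigmaP))
    return float(s1), s2


def model_averaged_estimate(meas: MeasurementTriple, params: ObserverParams) -> float:
    """Final auditory location estimate: posterior-weighted model average.

    pC·ŝ(C=1) + (1−pC)·ŝ(C=2) — the causal posterior mixes the fused and
    segregated conditional estimates, producing ventriloquist shifts that
    fall off with spatial and temporal discrepancy.
    """
    pc = posterior_common(meas, params)
    s1, s2 = conditional_estimates(meas, params)
    return pc * s1 + (1.0 - pc) * s2


def p_report_afirst(soa: ArrayLike, params: ObserverParams) -> ArrayLike:
    """Probability of reporting "auditory first" at a given SOA (ms).

    lapse1/2 + (1−lapse1)·Φ((soa + bDt)/σΔt).  The 2AFC is symmetric with a
    flat decision prior, so the employed temporal uncertainty cancels and the
    task constrains only the actual SOA noise (and the temporal bias).
    """
    p = params
    z = (np.asarray(soa, dtype=float) + p.bDt) / p.sigmaDt_act
    return p.lapse1 / 2.0 + (1.0 - p.lapse1) * ndtr(z)


def p_report_aright(sA: ArrayLike, sV: ArrayLike, params: ObserverParams) -> ArrayLike:
    """Probability of reporting the auditory stimulus right of the visual one.

    The observer shrinks both measurements toward the spatial prior using
    employed uncertainties (wA uses σ̃A, the unimodal-context estimate) and
    compares the posterior modes; the measurement spread contributes with the
    *actual* auditory noise.  With μP = 0:

        p = lapse2/2 + (1−lapse2)·Φ((wA·(aA·sA+bA) − wV·sV) /
                                     sqrt(wA²σA² + wV²σV²))
    """
    p = params
    wA = shrink_weight(p.sigmaA_emp, p.sigmaP)
    wV = shrink_weight(p.sigmaV, p.sigmaP)
    num = (wA * (p.aA * np.asarray(sA, dtype=float) + p.bA)
           + (1.0 - wA) * p.muP
           - (wV * np.asarray(sV, dtype=float) + (1.0 - wV) * p.muP))
    den = np.sqrt(wA**2 * p.sigmaA_act**2 + wV**2 * p.sigmaV**2)
    return p.lapse2 / 2.0 + (1.0 - p.lapse2) * ndtr(num / den)


def explicit_common_report(pC: ArrayLike, params: ObserverParams) -> ArrayLike:
    """Probability of an explicit "common source" report given the posterior.

    Deterministic criterion rule with lapses:
    lapse4/2 + (1−lapse4)·[pC > critCommon].  Ties (pC == critCommon) count
    as "separate sources" (strict inequality).
    """
    p = params
    common = (np.asarray(pC, dtype=float) > p.critCommon).astype(float)
    return p.lapse4 / 2.0 + (1.0 - p.lapse4) * common
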