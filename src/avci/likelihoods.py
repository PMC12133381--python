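"""Per-task negative log-likelihoods of observed responses.

The binary tasks (temporal order, spatial discrimination) and the unimodal
localization task have closed-form trial likelihoods.  The bimodal task
requires marginalizing the latent measurement triple (mA, mV, mDt); this is
done by deterministic quadrature on Gaussian node grids centred on the
stimuli with the *actual* measurement SDs, while the observer's decisions at
each node use the *employed* uncertainties.  The localization response and
the explicit common-source report within a trial share one measurement
triple, so their joint likelihood is accumulated from the partitioned
measurement space rather than as independent margins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve
from scipy.special import expit
from scipy.stats import norm

from .observer import (
    log_spatial_evidence_ratio,
    log_temporal_evidence_ratio,
    p_report_afirst,
    p_report_aright,
    remap_auditory,
    shrink_weight,
)
from .params import ObserverParams
from .simulate import SCREEN_HALF_DEG

__all__ = [
    "QuadratureSpec",
    "BimodalPredictive",
    "nll_toj",
    "nll_discrimination",
    "nll_unimodal_localization",
    "bimodal_predictive",
    "bimodal_predictives",
    "nll_bimodal",
]

_P_CLAMP = 1e-9
_UNIFORM_DENS = 1.0 / (2.0 * SCREEN_HALF_DEG)  # lapse kernel over the screen


@dataclass(frozen=True)
class QuadratureSpec:
    """Deterministic integration settings for the bimodal response model.

    nodes: quadrature nodes per measurement dimension (odd, ≥ 21);
    halfwidth: extent of the node grid in measurement SDs (≥ 3);
    grid_spacing: localization response grid spacing in deg;
    grid_half: half-extent of the response grid in deg (must cover the
    screen plus the widest plausible estimates).
    """

    nodes: int = 61
    halfwidth: float = 4.0
    grid_spacing: float = 0.25
    grid_half: float = 60.0

    def __post_init__(self) -> None:
        if self.nodes < 21 or self.nodes % 2 == 0:
            raise ValueError("nodes must be odd and at least 21")
        if self.halfwidth < 3.0:
            raise ValueError("halfwidth must be at least 3 SDs")
        if self.grid_spacing <= 0 or self.grid_half <= SCREEN_HALF_DEG:
            raise ValueError("response grid must be positive and cover the screen")

    @property
    def response_grid(self) -> np.ndarray:
        n = int(round(2 * self.grid_half / self.grid_spacing)) + 1
        return -self.grid_half + self.grid_spacing * np.arange(n)


@dataclass(frozen=True)
class BimodalPredictive:
    """Model-predicted joint response distribution for one stimulus condition.

    ``grid`` is the localization response grid; ``dens_common`` and
    ``dens_separate`` are response densities conditional on each explicit
    report (each integrates to 1 on the grid, within tolerance);
    ``p_common`` is the probability of a "common source" report.  Lapses and
    motor noise are included.
    """

    grid: np.ndarray
    p_common: float
    dens_common: np.ndarray
    dens_separate: np.ndarray

    def joint_density(self, report_common: int) -> np.ndarray:
        """Joint density p(report)·f(r | report) on the grid."""
        if report_common:
            return self.p_common * self.dens_common
        return (1.0 - self.p_common) * self.dens_separate


def _clamp(p: np.ndarray) -> np.ndarray:
    return np.clip(p, _P_CLAMP, 1.0 - _P_CLAMP)


def _require_columns(table: pd.DataFrame, cols: tuple[str, ...], task: str) -> None:
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"{task} table is missing columns {missing}")


def nll_toj(table: pd.DataFrame, params: ObserverParams) -> float:
    """Bernoulli NLL of temporal-order reports (columns soa_ms, resp_afirst)."""
    _require_columns(table, ("soa_ms", "resp_afirst"), "toj")
    p = _clamp(np.asarray(p_report_afirst(table["soa_ms"].to_numpy(float), params)))
    r = table["resp_afirst"].to_numpy(int)
    return float(-np.sum(np.where(r == 1, np.log(p), np.log1p(-p))))


def nll_discrimination(table: pd.DataFrame, params: ObserverParams) -> float:
    """Bernoulli NLL of left/right discrimination reports.

    Staircase-placed auditory locations are fixed covariates: the adaptive
    placement rule depends only on past observed responses, so it is
    likelihood-ignorable given the recorded placements.
    """
    _require_columns(table, ("s_a_deg", "s_v_deg", "resp_aright"), "disc")
    p = _clamp(np.asarray(p_report_aright(
        table["s_a_deg"].to_numpy(float), table["s_v_deg"].to_numpy(float), params)))
    r = table["resp_aright"].to_numpy(int)
    return float(-np.sum(np.where(r == 1, np.log(p), np.log1p(-p))))


def nll_unimodal_localization(table: pd.DataFrame, params: ObserverParams) -> float:
    """Closed-form NLL of continuous unimodal localization responses.

    The response given the stimulus is Gaussian with mean w·s′ + (1−w)·μP
    and variance w²σ_act² + σ_motor² (shrinkage of a noisy measurement plus
    motor noise), mixed with a uniform lapse kernel over the screen.
    """
    _require_columns(table, ("modality", "s_deg", "resp_deg"), "uniloc")
    p = params
    mods = table["modality"].to_numpy(str)
    s = table["s_deg"].to_numpy(float)
    r = table["resp_deg"].to_numpy(float)
    is_a = mods == "A"
    mu_meas = np.where(is_a, remap_auditory(s, p), s)
    sig_act = np.where(is_a, p.sigmaA_act, p.sigmaV)
    w = np.where(is_a, shrink_weight(p.sigmaA_emp, p.sigmaP),
                 shrink_weight(p.sigmaV, p.sigmaP))
    mean = w * mu_meas + (1.0 - w) * p.muP
    sd = np.sqrt(w**2 * sig_act**2 + p.sigmaMotor**2)
    dens = ((1.0 - p.lapse3) * norm.pdf(r, mean, sd)
            + p.lapse3 * _UNIFORM_DENS * (np.abs(r) <= SCREEN_HALF_DEG))
    return float(-np.sum(np.log(np.clip(dens, _P_CLAMP, None))))


def _node_grid(spec: QuadratureSpec) -> tuple[np.ndarray, np.ndarray]:
    """Equally spaced standard-normal nodes and normalized weights."""
    z = np.linspace(-spec.halfwidth, spec.halfwidth, spec.nodes)
    w = np.exp(-0.5 * z**2)
    return z, w / w.sum()


def _sweep_numpy(lsr, s1, s2, ltr, si, ti, prior_odds, crit, wz, lo,
                 inv_spacing, n_grid):
    """Reference implementation of the 3-D node sweep (see _sweep below)."""
    nc = si.size
    n = wz.size
    log_odds = prior_odds + lsr[si][:, :, :, None] + ltr[ti][:, None, None, :]
    pc = expit(log_odds)
    est = s2[si][:, :, None, None] + pc * (s1[si][:, :, :, None]
                                           - s2[si][:, :, None, None])
    common = pc > crit
    w3 = (wz[:, None, None] * wz[None, :, None] * wz[None, None, :]).ravel()
    w3 = np.tile(w3, nc)
    pos = np.clip((est.reshape(nc, -1) - lo) * inv_spacing,
                  0.0, n_grid - 1.0 - 1e-9)
    i0 = pos.astype(np.int64)
    frac = (pos - i0).ravel()
    offs = (np.arange(nc)[:, None, None, None] * 2
            + common.reshape(nc, n, n, n)).reshape(nc, -1) * n_grid
    idx = (i0 + offs).ravel()
    size = 2 * nc * n_grid
    mass = (np.bincount(idx, weights=w3 * (1.0 - frac), minlength=size)
            + np.bincount(idx + 1, weights=w3 * frac, minlength=size + 1)[:size])
    return mass.reshape(nc, 2, n_grid)


try:  # fused jitted sweep; falls back to the vectorized reference
    from numba import njit

    @njit(cache=False)
    def _sweep_jit(lsr, s1, s2, ltr, si, ti, prior_odds, crit, wz, lo,
                   inv_spacing, n_grid):  # pragma: no cover - numerics checked via _sweep
        nc = si.size
        n = wz.size
        mass = np.zeros((nc, 2, n_grid))
        hi = n_grid - 1.0 - 1e-9
        for c in range(nc):
            a = si[c]
            t = ti[c]
            for i in range(n):
                s2i = s2[a, i]
                wi = wz[i]
                for j in range(n):
                    base = prior_odds + lsr[a, i, j]
                    d = s1[a, i, j] - s2i
                    wij = wi * wz[j]
                    for k in range(n):
                        x = base + ltr[t, k]
                        pc = 1.0 / (1.0 + np.exp(-x))
                        pos = (s2i + pc * d - lo) * inv_spacing
                        if pos < 0.0:
                            pos = 0.0
                        elif pos > hi:
                            pos = hi
                        i0 = int(pos)
                        frac = pos - i0
                        r = 1 if pc > crit else 0
                        w = wij * wz[k]
                        mass[c, r, i0] += w * (1.0 - frac)
                        mass[c, r, i0 + 1] += w * frac
        return mass

    _sweep = _sweep_jit
except ImportError:  # pragma: no cover
    _sweep = _sweep_numpy


def bimodal_predictives(conditions: np.ndarray, params: ObserverParams,
                        spec: QuadratureSpec | None = None
                        ) -> dict[tuple[float, float, float], BimodalPredictive]:
    """Predicted joint response distributions for a set of conditions.

    ``conditions`` is an (n, 3) array of (s_a_deg, s_v_deg, soa_ms) rows.
    The computation is batched: spatial evidence blocks are shared between
    conditions that differ only in SOA (a full 40-condition design costs
    eight spatial evaluations), the 3-D node sweep runs as one array
    operation over all conditions, and motor-noise convolution is applied to
    all per-condition mass vectors at once.
    """
    p = params
    spec = spec or QuadratureSpec()
    z, wz = _node_grid(spec)
    n = spec.nodes
    grid = spec.response_grid
    n_grid = grid.size
    lo = grid[0]

    conditions = np.atleast_2d(np.asarray(conditions, dtype=float))
    keys = [(float(a), float(v), float(t)) for a, v, t in conditions]
    keys = list(dict.fromkeys(keys))
    nc = len(keys)

    prior_odds = (np.inf if p.pCommon >= 1.0 else
                  -np.inf if p.pCommon <= 0.0 else
                  np.log(p.pCommon) - np.log1p(-p.pCommon))
    pa = 1.0 / p.sigmaAVA_emp**2
    pv = 1.0 / p.sigmaV**2
    pp = 1.0 / p.sigmaP**2

    # unique spatial (sA, sV) and temporal (soa) blocks, with condition maps
    skeys = list(dict.fromkeys(k[:2] for k in keys))
    tkeys = list(dict.fromkeys(k[2] for k in keys))
    si = np.array([skeys.index(k[:2]) for k in keys])
    ti = np.array([tkeys.index(k[2]) for k in keys])

    ns = len(skeys)
    lsr = np.empty((ns, n, n))
    s1 = np.empty((ns, n, n))
    s2 = np.empty((ns, n))
    for i, (sa, sv) in enumerate(skeys):
        mA = remap_auditory(sa, p) + z * p.sigmaAVA_act
        mV = sv + z * p.sigmaV
        lsr[i] = log_spatial_evidence_ratio(mA[:, None], mV[None, :], p)
        s1[i] = (mA[:, None] * pa + mV[None, :] * pv + p.muP * pp) / (pa + pv + pp)
        s2[i] = (mA * pa + p.muP * pp) / (pa + pp)
    ltr = np.empty((len(tkeys), n))
    for j, soa in enumerate(tkeys):
        mDt = soa + p.bDt + z * p.sigmaDt_act
        ltr[j] = log_temporal_evidence_ratio(mDt, p)

    # one (nc, n, n, n) node sweep over all conditions; at each node the
    # observer's estimate and report are computed with employed SDs and the
    # node's mass is scattered linearly onto the response grid
    mass = _sweep(lsr, s1, s2, ltr, si, ti, prior_odds, p.critCommon, wz,
                  lo, 1.0 / spec.grid_spacing, n_grid)

    if p.sigmaMotor > 0:
        k = int(np.ceil(4.0 * p.sigmaMotor / spec.grid_spacing))
        x = spec.grid_spacing * np.arange(-k, k + 1)
        kern = np.exp(-0.5 * (x / p.sigmaMotor) ** 2)
        kern /= kern.sum()
        flat = mass.reshape(-1, n_grid)
        pad = np.zeros((flat.shape[0], k))
        padded = np.concatenate([pad, flat, pad], axis=1)
        conv = fftconvolve(padded, kern[None, :], mode="same", axes=1)
        mass = conv[:, k:k + n_grid].reshape(nc, 2, n_grid)
        np.clip(mass, 0.0, None, out=mass)

    u = (np.abs(grid) <= SCREEN_HALF_DEG).astype(float)
    u /= u.sum()
    j_common = (1.0 - p.lapse4) * mass[:, 1] + p.lapse4 * 0.5 * u
    j_sep = (1.0 - p.lapse4) * mass[:, 0] + p.lapse4 * 0.5 * u
    p_common = j_common.sum(axis=1)

    out: dict[tuple[float, float, float], BimodalPredictive] = {}
    for i, key in enumerate(keys):
        pci = float(p_common[i])
        out[key] = BimodalPredictive(
            grid=grid,
            p_common=pci,
            dens_common=j_common[i] / max(pci, _P_CLAMP) / spec.grid_spacing,
            dens_separate=j_sep[i] / max(1.0 - pci, _P_CLAMP) / spec.grid_spacing,
        )
    return out


def bimodal_predictive(condition: tuple[float, float, float],
                       params: ObserverParams,
                       spec: QuadratureSpec | None = None) -> BimodalPredictive:
    """Predicted joint response distribution for one (sA, sV, SOA) condition."""
    return bimodal_predictives(np.array([condition]), params, spec)[
        (float(condition[0]), float(condition[1]), float(condition[2]))]


def nll_bimodal(table: pd.DataFrame, params: ObserverParams,
                spec: QuadratureSpec | None = None, cache: bool = True) -> float:
    """Joint NLL of (localization, common-source report) pairs.

    Each trial contributes −log[p(report)·f(response | report)] evaluated by
    linear interpolation of the cached predictive for its stimulus
    condition.  With ``cache=False`` every row recomputes its predictive
    (identical result; used to verify the cache).
    """
    _require_columns(table, ("s_a_deg", "s_v_deg", "soa_ms",
                             "resp_loc_deg", "resp_common"), "bimodal")
    spec = spec or QuadratureSpec()
    conds = table[["s_a_deg", "s_v_deg", "soa_ms"]].to_numpy(float)
    uniq, inv = np.unique(conds, axis=0, return_inverse=True)
    if cache:
        preds = bimodal_predictives(uniq, params, spec)
    resp = table["resp_loc_deg"].to_numpy(float)
    rep = table["resp_common"].to_numpy(int)
    total = 0.0
    for j, (sa, sv, soa) in enumerate(uniq):
        key = (float(sa), float(sv), float(soa))
        pred = preds[key] if cache else bimodal_predictive(key, params, spec)
        rows = inv == j
        for report in (0, 1):
            sel = rows & (rep == report)
            if not sel.any():
                continue
            joint = pred.joint_density(report)
            vals = np.interp(resp[sel], pred.grid, joint, left=0.0, right=0.0)
            total -= float(np.sum(np.log(np.clip(vals, _P_CLAMP, None))))
    return total
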