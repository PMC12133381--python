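"""Synthetic trial-table generation for the four audiovisual experiments.

Given a known generating observer, these simulators emulate the printed
study designs:

* Expt. 1 — audiovisual temporal-order judgments: 20 SOA levels spanning
  ±466.67 ms, 25 repetitions each (500 trials).
* Expt. 2 — audiovisual spatial discrimination: visual stimulus at ±12 deg,
  auditory location driven by four interleaved 1-up/1-down staircases of
  40 trials each (160 trials).
* Expt. 3 — unimodal localization: visual stimuli at ±4/±12 deg (20 reps
  each), auditory stimuli at the two locations perceptually aligned with
  ±12 deg (40 reps each; 160 trials).
* Expt. 4 — bimodal localization plus explicit common-source reports:
  4 visual × 2 auditory locations × 5 SOAs {0, ±250, ±400 ms} × 20 reps
  (800 trials).

All simulators are bit-for-bit reproducible given (design, params, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .observer import (
    log_posterior_common_odds,
    p_report_afirst,
    p_report_aright,
    remap_auditory,
    shrink_weight,
)
from .params import ObserverParams

__all__ = [
    "ExperimentDesign",
    "DEFAULT_DESIGN",
    "SCREEN_HALF_DEG",
    "aligned_auditory_location",
    "simulate_toj",
    "simulate_discrimination",
    "simulate_unimodal_localization",
    "simulate_bimodal",
    "simulate_all",
    "simulate_accuracy_precision",
    "child_seeds",
]

SCREEN_HALF_DEG = 34.0  # half of the 68-deg-wide screen; range of the lapse kernel


def child_seeds(seed: int, n: int) -> list[int]:
    """Derive n independent 31-bit child seeds from a master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


@dataclass(frozen=True)
class ExperimentDesign:
    """Stimulus levels and repetition counts for the four experiments."""

    toj_soas_ms: tuple = tuple(np.linspace(-466.67, 466.67, 20))
    toj_reps: int = 25
    disc_visual_deg: tuple = (-12.0, 12.0)
    disc_staircase_trials: int = 40
    disc_start_offset_deg: float = 16.0
    disc_steps_deg: tuple = (8.0, 4.0, 2.0, 1.0)
    uniloc_visual_deg: tuple = (-12.0, -4.0, 4.0, 12.0)
    uniloc_visual_reps: int = 20
    uniloc_auditory_targets_deg: tuple = (-12.0, 12.0)  # aligned-to targets
    uniloc_auditory_reps: int = 40
    bimodal_visual_deg: tuple = (-12.0, -4.0, 4.0, 12.0)
    bimodal_auditory_targets_deg: tuple = (-12.0, 12.0)
    bimodal_soas_ms: tuple = (-400.0, -250.0, 0.0, 250.0, 400.0)
    bimodal_reps: int = 20

    @property
    def n_trials(self) -> tuple[int, int, int, int]:
        """(Expt. 1, 2, 3, 4) trial counts implied by the design."""
        n1 = len(self.toj_soas_ms) * self.toj_reps
        n2 = 2 * len(self.disc_visual_deg) * self.disc_staircase_trials
        n3 = (len(self.uniloc_visual_deg) * self.uniloc_visual_reps
              + len(self.uniloc_auditory_targets_deg) * self.uniloc_auditory_reps)
        n4 = (len(self.bimodal_visual_deg) * len(self.bimodal_auditory_targets_deg)
              * len(self.bimodal_soas_ms) * self.bimodal_reps)
        return (n1, n2, n3, n4)

    def reduced(self) -> "ExperimentDesign":
        """Quarter-scale design for fast validation runs."""
        return replace(
            self,
            toj_reps=max(1, self.toj_reps // 4),
            disc_staircase_trials=max(4, self.disc_staircase_trials // 4),
            uniloc_visual_reps=max(1, self.uniloc_visual_reps // 4),
            uniloc_auditory_reps=max(2, self.uniloc_auditory_reps // 4),
            bimodal_reps=max(1, self.bimodal_reps // 4),
        )


DEFAULT_DESIGN = ExperimentDesign()


def aligned_auditory_location(target: float, params: ObserverParams) -> float:
    """Physical auditory location whose remapped value equals ``target``.

    Inverts the remapping: (target − bA)/aA.  This is the idealized outcome
    of the alignment staircases: an auditory stimulus placed here is
    perceived at the same location as a visual stimulus at ``target``.
    """
    if params.aA == 0:
        raise ValueError("degenerate remapping: aA = 0 has no aligned location")
    return (target - params.bA) / params.aA


def simulate_toj(design: ExperimentDesign, params: ObserverParams, seed: int
                 ) -> pd.DataFrame:
    """Simulate the temporal-order-judgment experiment.

    Returns a table with columns ``soa_ms`` and ``resp_afirst`` (1 = reported
    auditory first), rows in pseudorandom order.
    """
    rng = np.random.default_rng(seed)
    soas = np.repeat(np.asarray(design.toj_soas_ms, dtype=float), design.toj_reps)
    rng.shuffle(soas)
    pr = p_report_afirst(soas, params)
    resp = (rng.random(soas.size) < pr).astype(int)
    return pd.DataFrame({"soa_ms": soas, "resp_afirst": resp})


def _staircase(vloc: float, start: float, design: ExperimentDesign,
               params: ObserverParams, rng: np.random.Generator
               ) -> tuple[np.ndarray, np.ndarray]:
    """Run one 1-up/1-down staircase on the auditory location.

    A "right" report moves the auditory stimulus left and vice versa, so the
    placements converge on the location reported right 50% of the time.  The
    step starts at the largest configured size and halves at each response
    reversal until the smallest size is reached.
    """
    steps = list(design.disc_steps_deg)
    step_idx = 0
    s = start
    placements = np.empty(design.disc_staircase_trials)
    responses = np.empty(design.disc_staircase_trials, dtype=int)
    prev = None
    for t in range(design.disc_staircase_trials):
        placements[t] = s
        pr = float(p_report_aright(s, vloc, params))
        r = int(rng.random() < pr)
        responses[t] = r
        if prev is not None and r != prev and step_idx < len(steps) - 1:
            step_idx += 1
        prev = r
        s = s - steps[step_idx] if r == 1 else s + steps[step_idx]
    return placements, responses


def simulate_discrimination(design: ExperimentDesign, params: ObserverParams,
                            seed: int) -> pd.DataFrame:
    """Simulate the spatial-discrimination experiment (four staircases).

    Two staircases per visual location approach the alignment point from
    opposite sides.  Columns: ``staircase_id``, ``s_v_deg``, ``s_a_deg``,
    ``resp_aright``; rows in interleaved pseudorandom order.
    """
    rng = np.random.default_rng(seed)
    frames = []
    sc_id = 0
    for vloc in design.disc_visual_deg:
        for sign in (-1.0, 1.0):
            start = vloc + sign * design.disc_start_offset_deg
            placements, responses = _staircase(vloc, start, design, params, rng)
            frames.append(pd.DataFrame({
                "staircase_id": sc_id,
                "trial_in_staircase": np.arange(placements.size),
                "s_v_deg": vloc,
                "s_a_deg": placements,
                "resp_aright": responses,
            }))
            sc_id += 1
    table = pd.concat(frames, ignore_index=True)
    order = rng.permutation(len(table))
    return table.iloc[order].reset_index(drop=True)


def _auditory_locations(design_targets: tuple, params: ObserverParams) -> list[float]:
    return [aligned_auditory_location(t, params) for t in design_targets]


def simulate_unimodal_localization(design: ExperimentDesign,
                                   params: ObserverParams, seed: int
                                   ) -> pd.DataFrame:
    """Simulate the unimodal localization experiment.

    Auditory responses are the shrunken posterior mode of a noisy remapped
    measurement plus motor noise; visual responses are analogous with the
    (accurately employed) visual uncertainty.  Lapse trials are uniform on
    the screen.  Columns: ``modality`` ("A"/"V"), ``s_deg``, ``resp_deg``.
    """
    p = params
    rng = np.random.default_rng(seed)
    mods, stims = [], []
    for v in design.uniloc_visual_deg:
        mods += ["V"] * design.uniloc_visual_reps
        stims += [v] * design.uniloc_visual_reps
    for a in _auditory_locations(design.uniloc_auditory_targets_deg, p):
        mods += ["A"] * design.uniloc_auditory_reps
        stims += [a] * design.uniloc_auditory_reps
    mods = np.array(mods)
    stims = np.array(stims, dtype=float)
    order = rng.permutation(stims.size)
    mods, stims = mods[order], stims[order]

    is_a = mods == "A"
    mu = np.where(is_a, remap_auditory(stims, p), stims)
    sig_act = np.where(is_a, p.sigmaA_act, p.sigmaV)
    w = np.where(is_a, shrink_weight(p.sigmaA_emp, p.sigmaP),
                 shrink_weight(p.sigmaV, p.sigmaP))
    m = rng.normal(mu, sig_act)
    resp = w * m + (1.0 - w) * p.muP + rng.normal(0.0, p.sigmaMotor, stims.size)
    lapse = rng.random(stims.size) < p.lapse3
    resp[lapse] = rng.uniform(-SCREEN_HALF_DEG, SCREEN_HALF_DEG, int(lapse.sum()))
    return pd.DataFrame({"modality": mods, "s_deg": stims, "resp_deg": resp})


def simulate_bimodal(design: ExperimentDesign, params: ObserverParams, seed: int
                     ) -> pd.DataFrame:
    """Simulate the bimodal experiment: localization + common-source report.

    Each trial draws one measurement triple; the localization response is the
    model-averaged estimate plus motor noise and the explicit report applies
    the criterion rule to the *same* triple's causal posterior (the two
    responses share measurements within a trial).  Lapse trials (rate
    lapse4) produce a uniform localization response and a coin-flip report.
    Columns: ``s_a_deg``, ``s_v_deg``, ``soa_ms``, ``resp_loc_deg``,
    ``resp_common``.
    """
    p = params
    rng = np.random.default_rng(seed)
    a_locs = _auditory_locations(design.bimodal_auditory_targets_deg, p)
    rows = [(a, v, t)
            for v in design.bimodal_visual_deg
            for a in a_locs
            for t in design.bimodal_soas_ms
            for _ in range(design.bimodal_reps)]
    arr = np.array(rows, dtype=float)
    rng.shuffle(arr)
    sa, sv, soa = arr[:, 0], arr[:, 1], arr[:, 2]
    n = sa.size

    mA = rng.normal(remap_auditory(sa, p), p.sigmaAVA_act)
    mV = rng.normal(sv, p.sigmaV)
    mDt = rng.normal(soa + p.bDt, p.sigmaDt_act)

    pc = expit(log_posterior_common_odds(mA, mV, mDt, p))
    pa = 1.0 / p.sigmaAVA_emp**2
    pv = 1.0 / p.sigmaV**2
    pp = 1.0 / p.sigmaP**2
    s1 = (mA * pa + mV * pv + p.muP * pp) / (pa + pv + pp)
    s2 = (mA * pa + p.muP * pp) / (pa + pp)
    est = pc * s1 + (1.0 - pc) * s2

    resp_loc = est + rng.normal(0.0, p.sigmaMotor, n)
    resp_common = (pc > p.critCommon).astype(int)
    lapse = rng.random(n) < p.lapse4
    nl = int(lapse.sum())
    resp_loc[lapse] = rng.uniform(-SCREEN_HALF_DEG, SCREEN_HALF_DEG, nl)
    resp_common[lapse] = (rng.random(nl) < 0.5).astype(int)
    return pd.DataFrame({
        "s_a_deg": sa, "s_v_deg": sv, "soa_ms": soa,
        "resp_loc_deg": resp_loc, "resp_common": resp_common,
    })


def simulate_all(design: ExperimentDesign, params: ObserverParams, seed: int
                 ) -> dict[str, pd.DataFrame]:
    """Simulate a full synthetic session (all four experiments).

    Returns ``{"toj": ..., "disc": ..., "uniloc": ..., "bimodal": ...}``.
    """
    s1, s2, s3, s4 = child_seeds(seed, 4)
    return {
        "toj": simulate_toj(design, params, s1),
        "disc": simulate_discrimination(design, params, s2),
        "uniloc": simulate_unimodal_localization(design, params, s3),
        "bimodal": simulate_bimodal(design, params, s4),
    }


def simulate_accuracy_precision(params: ObserverParams, stimulus: float, n: int,
                                seed: int) -> tuple[float, float]:
    """Accuracy/precision of unimodal auditory localization at one stimulus.

    Simulates ``n`` localization responses and returns (signed mean error
    relative to the *physical* location, response SD).  Underestimating the
    employed uncertainty increases the shrinkage weight on the measurement,
    which pulls the mean response toward the remapped stimulus (smaller
    |error| when remapping is unbiased) at the cost of a larger spread.
    """
    if n < 1000:
        raise ValueError("n must be at least 1000 for stable moments")
    p = params
    rng = np.random.default_rng(seed)
    m = rng.normal(remap_auditory(stimulus, p), p.sigmaA_act, n)
    w = shrink_weight(p.sigmaA_emp, p.sigmaP)
    resp = w * m + (1.0 - w) * p.muP + rng.normal(0.0, p.sigmaMotor, n)
    return float(resp.mean() - stimulus), float(resp.std(ddof=1))
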