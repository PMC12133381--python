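"""Task likelihoods: closed forms vs. brute-force integration, quadrature
behaviour of the bimodal predictive, and identifiability smoke tests."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from avci.likelihoods import (
    QuadratureSpec,
    bimodal_predictive,
    nll_bimodal,
    nll_discrimination,
    nll_toj,
    nll_unimodal_localization,
)
from avci.likelihoods import _sweep_numpy, _sweep
from avci.observer import (
    p_report_afirst,
    p_report_aright,
    posterior_common,
    MeasurementTriple,
    remap_auditory,
    shrink_weight,
)
from avci.params import ObserverParams
from avci.simulate import (
    DEFAULT_DESIGN,
    simulate_bimodal,
    simulate_toj,
    simulate_unimodal_localization,
)


def _random_params(rng):
    return ObserverParams(
        aA=rng.uniform(0.7, 1.3), bA=rng.uniform(-5, 5),
        sigmaA_act=rng.uniform(2, 10), sigmaA_emp=rng.uniform(0.5, 8),
        sigmaAVA_act=rng.uniform(5, 20), sigmaAVA_emp=rng.uniform(2, 12),
        sigmaV=rng.uniform(0.5, 3), sigmaDt_act=rng.uniform(60, 250),
        sigmaDt_emp=rng.uniform(30, 200), bDt=rng.uniform(-60, 60),
        sigmaP=rng.uniform(5, 30), sigmaPt1=rng.uniform(60, 200),
        pCommon=rng.uniform(0.2, 0.8), critCommon=rng.uniform(0.3, 0.7),
        lapse1=rng.uniform(0, 0.1), lapse2=rng.uniform(0, 0.1),
        lapse3=rng.uniform(0, 0.1), lapse4=rng.uniform(0, 0.1),
        sigmaMotor=rng.uniform(0.5, 3),
    )


def test_gaussian_marginals_match_numeric_integration(rng):
    """The closed-form evidences inside the causal posterior, the binary-task
    psychometric functions, and the localization response density all agree
    with brute-force numeric integration to 1e-6 relative error on a
    randomized battery."""
    for _ in range(10):
        p = _random_params(rng)
        mA, mV = rng.normal(0, 10, 2)
        mDt = rng.normal(0, 250)

        # causal posterior via numeric marginalization of each evidence term
        # (finite ranges generously covering every factor's peak; tight
        # tolerances so the oracle is far more accurate than the 1e-6 bar)
        kw = dict(limit=500, epsabs=0.0, epsrel=1e-11)
        s_lim = (-300.0, 300.0)
        t_lim = (-5000.0, 5000.0)
        l1s = quad(lambda s: norm.pdf(mA, s, p.sigmaAVA_emp)
                   * norm.pdf(mV, s, p.sigmaV) * norm.pdf(s, p.muP, p.sigmaP),
                   *s_lim, points=[mA, mV, p.muP], **kw)[0]
        l2s = (quad(lambda s: norm.pdf(mA, s, p.sigmaAVA_emp)
                    * norm.pdf(s, p.muP, p.sigmaP),
                    *s_lim, points=[mA, p.muP], **kw)[0]
               * quad(lambda s: norm.pdf(mV, s, p.sigmaV)
                      * norm.pdf(s, p.muP, p.sigmaP),
                      *s_lim, points=[mV, p.muP], **kw)[0])
        l1t = quad(lambda dt: norm.pdf(mDt, dt, p.sigmaDt_emp)
                   * norm.pdf(dt, 0, p.sigmaPt1),
                   *t_lim, points=[mDt, 0.0], **kw)[0]
        l2t = 1.0 / (2 * p.rangeT)
        l1, l2 = l1s * l1t, l2s * l2t
        expected = p.pCommon * l1 / (p.pCommon * l1 + (1 - p.pCommon) * l2)
        got = posterior_common(MeasurementTriple(mA, mV, mDt), p)
        assert got == pytest.approx(expected, rel=1e-6)

        # temporal-order psychometric function via numeric integration of the
        # SOA measurement density over the decision region
        soa = rng.uniform(-450, 450)
        num = quad(lambda m: norm.pdf(m, soa + p.bDt, p.sigmaDt_act),
                   0, np.inf)[0]
        assert p_report_afirst(soa, p) == pytest.approx(
            p.lapse1 / 2 + (1 - p.lapse1) * num, rel=1e-6)

        # discrimination psychometric function via numeric integration over
        # the auditory measurement of the conditional visual decision rule
        sA, sV = rng.uniform(-15, 15, 2)
        wA = shrink_weight(p.sigmaA_emp, p.sigmaP)
        wV = shrink_weight(p.sigmaV, p.sigmaP)
        num = quad(lambda m: norm.pdf(m, p.aA * sA + p.bA, p.sigmaA_act)
                   * norm.cdf((wA * m / wV - sV) / p.sigmaV),
                   -np.inf, np.inf)[0]
        assert p_report_aright(sA, sV, p) == pytest.approx(
            p.lapse2 / 2 + (1 - p.lapse2) * num, rel=1e-6)

        # localization response density via numeric convolution of the
        # shrunken measurement with motor noise (response drawn within the
        # bulk of the predictive so the quadrature oracle is well-conditioned)
        s = rng.uniform(-15, 15)
        mu_resp = wA * (p.aA * s + p.bA)
        sd_resp = np.sqrt(wA**2 * p.sigmaA_act**2 + p.sigmaMotor**2)
        r = mu_resp + rng.uniform(-2, 2) * sd_resp
        table = pd.DataFrame({"modality": ["A"], "s_deg": [s], "resp_deg": [r]})
        pl = p.replace(lapse3=0.0)
        dens = quad(lambda m: norm.pdf(m, p.aA * s + p.bA, p.sigmaA_act)
                    * norm.pdf(r, wA * m, p.sigmaMotor),
                    -np.inf, np.inf, limit=200)[0]
        assert np.exp(-nll_unimodal_localization(table, pl)) == pytest.approx(
            dens, rel=1e-6)


def test_nll_toj_basics(regime):
    table = pd.DataFrame({"soa_ms": [-regime.bDt], "resp_afirst": [1]})
    p = regime.replace(lapse1=0.0)
    assert nll_toj(table, p) == pytest.approx(np.log(2))
    big = simulate_toj(DEFAULT_DESIGN, regime, seed=0)
    assert nll_toj(pd.concat([big, big]), regime) == pytest.approx(
        2 * nll_toj(big, regime))


def test_nll_discrimination_basics(regime):
    # a trial at the 50% point contributes log 2
    p = regime.replace(lapse2=0.0)
    wA = shrink_weight(p.sigmaA_emp, p.sigmaP)
    wV = shrink_weight(p.sigmaV, p.sigmaP)
    s50 = (wV * 12.0 / wA - p.bA) / p.aA
    t = pd.DataFrame({"staircase_id": [0], "s_v_deg": [12.0],
                      "s_a_deg": [s50], "resp_aright": [1]})
    assert nll_discrimination(t, p) == pytest.approx(np.log(2))
    t2 = pd.concat([t, t], ignore_index=True)
    assert nll_discrimination(t2, p) == pytest.approx(2 * np.log(2))


def test_nll_toj_truth_dominance(regime):
    """The generating parameters beat a 2x perturbation of the SOA noise in
    most replicates."""
    wins = 0
    for seed in range(10):
        t = simulate_toj(DEFAULT_DESIGN, regime, seed=seed)
        wins += nll_toj(t, regime) < nll_toj(
            t, regime.replace(sigmaDt_act=2 * regime.sigmaDt_act))
    assert wins >= 6


def test_nll_unimodal_gaussian_peak(regime):
    p = regime.replace(lapse3=0.0)
    w = shrink_weight(p.sigmaA_emp, p.sigmaP)
    mean = w * remap_auditory(5.0, p)
    var = w**2 * p.sigmaA_act**2 + p.sigmaMotor**2
    t = pd.DataFrame({"modality": ["A"], "s_deg": [5.0], "resp_deg": [mean]})
    assert np.exp(-nll_unimodal_localization(t, p)) == pytest.approx(
        1.0 / np.sqrt(2 * np.pi * var))


def test_unimodal_profile_dissociation(regime):
    """On synthetic unimodal data the profile-NLL minima over the actual and
    employed auditory SDs track their own generating values."""
    design = type(DEFAULT_DESIGN)(**{**DEFAULT_DESIGN.__dict__,
                                     "uniloc_auditory_reps": 2000,
                                     "uniloc_visual_reps": 1})
    for gen_emp, gen_act in [(1.46, 5.45), (4.0, 5.45)]:
        gen = regime.replace(sigmaA_emp=gen_emp, sigmaA_act=gen_act)
        t = simulate_unimodal_localization(design, gen, seed=8)
        emp_grid = np.linspace(0.5, 8.0, 40)
        prof = [nll_unimodal_localization(t, gen.replace(sigmaA_emp=e))
                for e in emp_grid]
        assert emp_grid[int(np.argmin(prof))] == pytest.approx(gen_emp, abs=1.0)
        act_grid = np.linspace(2.0, 10.0, 40)
        prof = [nll_unimodal_localization(t, gen.replace(sigmaA_act=a))
                for a in act_grid]
        assert act_grid[int(np.argmin(prof))] == pytest.approx(gen_act, abs=1.0)


def test_quadrature_spec_validation():
    with pytest.raises(ValueError):
        QuadratureSpec(nodes=20)
    with pytest.raises(ValueError):
        QuadratureSpec(nodes=19)
    with pytest.raises(ValueError):
        QuadratureSpec(halfwidth=2.0)
    with pytest.raises(ValueError):
        QuadratureSpec(grid_half=10.0)


def test_sweep_jit_matches_numpy_reference(rng):
    """The fused node-sweep kernel agrees with the vectorized reference."""
    n, ns, nt, nc, n_grid = 21, 3, 2, 5, 101
    lsr = rng.normal(size=(ns, n, n))
    s1 = rng.normal(size=(ns, n, n)) * 5
    s2 = rng.normal(size=(ns, n)) * 5
    ltr = rng.normal(size=(nt, n))
    si = rng.integers(0, ns, nc)
    ti = rng.integers(0, nt, nc)
    wz = np.exp(-0.5 * np.linspace(-4, 4, n) ** 2)
    wz /= wz.sum()
    args = (lsr, s1, s2, ltr, si, ti, 0.3, 0.5, wz, -20.0, 1.0 / 0.4, n_grid)
    np.testing.assert_allclose(_sweep(*args), _sweep_numpy(*args), atol=1e-12)


def test_bimodal_predictive_normalization(regime):
    pred = bimodal_predictive((11.8, -4.0, 250.0), regime)
    total = (pred.p_common * np.trapezoid(pred.dens_common, pred.grid)
             + (1 - pred.p_common) * np.trapezoid(pred.dens_separate, pred.grid))
    assert total == pytest.approx(1.0, abs=1e-6)
    assert 0.0 <= pred.p_common <= 1.0
    assert np.all(pred.dens_common >= 0) and np.all(pred.dens_separate >= 0)


def test_bimodal_predictive_segregated_limit(regime):
    """With the common-cause prior off and no lapses, the quadrature
    predictive reduces to the closed-form segregated response density: a
    Gaussian for the shrunken auditory measurement convolved with motor
    noise.  Max absolute density deviation below 1e-3 on the full grid."""
    p = regime.replace(pCommon=1e-12, lapse4=0.0)
    cond = (11.8, -12.0, 0.0)
    pred = bimodal_predictive(cond, p)
    w = shrink_weight(p.sigmaAVA_emp, p.sigmaP)
    mu = w * remap_auditory(cond[0], p)
    sd = np.sqrt(w**2 * p.sigmaAVA_act**2 + p.sigmaMotor**2)
    assert pred.p_common < 1e-9
    dens = (1 - pred.p_common) * pred.dens_separate
    assert np.max(np.abs(dens - norm.pdf(pred.grid, mu, sd))) < 1e-3


def test_bimodal_predictive_matches_monte_carlo(regime):
    """Quadrature predictive vs. a 10^6-draw Monte-Carlo simulation of the
    generative model: total variation below 0.02 on 0.5-deg bins."""
    rng = np.random.default_rng(7)
    p = _random_params(rng)
    cond = (11.0, -4.0, 250.0)
    tv = _tv_quad_vs_mc(cond, p, rng)
    assert tv < 0.02


def _tv_quad_vs_mc(cond, p, rng, n=1_000_000):
    from scipy.special import expit
    from avci.observer import log_posterior_common_odds

    pred = bimodal_predictive(cond, p)
    sa, sv, soa = cond
    mA = rng.normal(remap_auditory(sa, p), p.sigmaAVA_act, n)
    mV = rng.normal(sv, p.sigmaV, n)
    mDt = rng.normal(soa + p.bDt, p.sigmaDt_act, n)
    pc = expit(log_posterior_common_odds(mA, mV, mDt, p))
    pa, pv, pp = 1 / p.sigmaAVA_emp**2, 1 / p.sigmaV**2, 1 / p.sigmaP**2
    s1 = (mA * pa + mV * pv + p.muP * pp) / (pa + pv + pp)
    s2 = (mA * pa + p.muP * pp) / (pa + pp)
    est = pc * s1 + (1 - pc) * s2 + rng.normal(0, p.sigmaMotor, n)
    rep = (pc > p.critCommon).astype(int)
    lapse = rng.random(n) < p.lapse4
    est[lapse] = rng.uniform(-34, 34, int(lapse.sum()))
    rep[lapse] = (rng.random(int(lapse.sum())) < 0.5).astype(int)

    edges = np.arange(-60, 60.01, 0.5)
    tv = 0.0
    for r in (0, 1):
        mc_mass = np.histogram(est[rep == r], bins=edges)[0] / n
        joint = pred.joint_density(r) * 0.25
        q_mass = np.histogram(pred.grid, bins=edges, weights=joint)[0]
        tv += 0.5 * np.sum(np.abs(mc_mass - q_mass))
    return tv


def test_nll_bimodal_additivity_and_cache(regime, fast_spec):
    t = simulate_bimodal(DEFAULT_DESIGN.reduced(), regime, seed=4)
    nll = nll_bimodal(t, regime, fast_spec)
    assert np.isfinite(nll)
    assert nll_bimodal(pd.concat([t, t]), regime, fast_spec) == pytest.approx(2 * nll)
    assert nll_bimodal(t.head(40), regime, fast_spec, cache=False) == pytest.approx(
        nll_bimodal(t.head(40), regime, fast_spec, cache=True))


def test_nll_bimodal_truth_dominance(regime, fast_spec):
    """Generating parameters beat a 3x perturbation of the employed SOA
    uncertainty in most replicates."""
    wins = 0
    perturbed = regime.replace(sigmaDt_emp=3 * regime.sigmaDt_emp)
    for seed in range(10):
        t = simulate_bimodal(DEFAULT_DESIGN, regime, seed=seed)
        wins += nll_bimodal(t, regime, fast_spec) < nll_bimodal(
            t, perturbed, fast_spec)
    assert wins >= 6


def test_quadrature_refinement_converged(regime):
    """Refining the node grid 61 -> 121 changes the 800-trial bimodal NLL by
    less than 0.1 (discretization convergence)."""
    t = simulate_bimodal(DEFAULT_DESIGN, regime, seed=12)
    a = nll_bimodal(t, regime, QuadratureSpec(nodes=61))
    b = nll_bimodal(t, regime, QuadratureSpec(nodes=121))
    assert abs(a - b) < 0.1


def test_nll_finite_on_random_params(regime, reduced_session, rng):
    from avci.fitting import joint_nll
    for _ in range(20):
        p = _random_params(rng)
        assert np.isfinite(joint_nll(p, reduced_session))


def test_missing_columns_raise(regime):
    with pytest.raises(ValueError, match="missing columns"):
        nll_toj(pd.DataFrame({"soa_ms": [0.0]}), regime)
    with pytest.raises(ValueError, match="missing columns"):
        nll_bimodal(pd.DataFrame({"s_a_deg": [0.0]}), regime)
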