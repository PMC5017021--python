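"""Moderated differential statistics: fold-change conventions, BH step-up
against brute force, empirical-Bayes moment matching against independent
oracles (numerical solve and Bioconductor limma), and recovery properties
on simulated data."""

import json
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, special, stats

from metabotox import (
    CellCountModel,
    EffectSpec,
    ModeratedDifferential,
    StudyDesign,
    bh_adjust,
    fit_moderated,
    log2fc,
    run_qc,
    simulate_study,
)
from metabotox.diffstats import ModerationParams, estimate_prior, moderated_t


# ---------------------------------------------------------------------------
# log2 fold change


def test_log2fc_convention():
    assert log2fc(5.0, 5.0) == 0.0
    assert log2fc(14.0, 1.0) == pytest.approx(3.8073549, rel=1e-6)
    assert log2fc(1.0, 2.0) == -1.0
    with pytest.raises(ValueError):
        log2fc(0.0, 0.0)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


def bh_bruteforce(p):
    """Literal step-up: q_i = min over j with p_j-rank >= rank_i of m*p_j/j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for pos, idx in enumerate(order):
        candidates = [m * p[order[j]] / (j + 1) for j in range(pos, m)]
        q[idx] = min(1.0, min(candidates))
    return q


@pytest.mark.parametrize(
    "p,expected",
    [
        ([0.05], [0.05]),
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.001, 1.0], [0.002, 1.0]),
    ],
)
def test_bh_known_values(p, expected):
    np.testing.assert_allclose(bh_adjust(p), expected, rtol=1e-12)


def test_bh_matches_bruteforce_and_statsmodels():
    rng = np.random.default_rng(1)
    from statsmodels.stats.multitest import multipletests

    for _ in range(200):
        m = rng.integers(1, 40)
        p = np.round(rng.uniform(size=m), 3)  # rounding forces ties
        q = bh_adjust(p)
        np.testing.assert_allclose(q, bh_bruteforce(p), rtol=1e-12)
        np.testing.assert_allclose(q, multipletests(p, method="fdr_bh")[1], rtol=1e-10)


def test_bh_rejects_invalid():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])
    with pytest.raises(ValueError):
        bh_adjust([-0.1])


# ---------------------------------------------------------------------------
# moderated t


def test_d0_zero_equals_classical_pooled_t():
    rng = np.random.default_rng(2)
    x = rng.normal(0, 1, (100, 3))
    y = rng.normal(0.5, 1, (100, 3))
    delta = y.mean(1) - x.mean(1)
    s2 = (x.var(1, ddof=1) * 2 + y.var(1, ddof=1) * 2) / 4
    t_mod, p_mod, _, _ = moderated_t(delta, s2, 4, 3, 3, ModerationParams(0.0, 1.0))
    t_ref, p_ref = stats.ttest_ind(y, x, axis=1, equal_var=True)
    np.testing.assert_allclose(t_mod, t_ref, rtol=1e-12)
    np.testing.assert_allclose(p_mod, p_ref, rtol=1e-12)


def test_d0_infinite_shrinks_fully_to_prior():
    rng = np.random.default_rng(3)
    s2 = rng.chisquare(4, 50) / 4
    delta = rng.normal(size=50)
    t, p, s2_post, df = moderated_t(delta, s2, 4, 3, 3, ModerationParams(np.inf, 0.7))
    assert np.all(s2_post == 0.7)
    assert np.isinf(df)
    np.testing.assert_allclose(t, delta / np.sqrt(0.7 * (2 / 3)), rtol=1e-12)


def estimate_prior_bruteforce(s2, d):
    """Independent numerical solve of the log-variance moment equations."""
    e = np.log(s2) - special.digamma(d / 2) + np.log(d / 2)
    evar = e.var(ddof=1) - special.polygamma(1, d / 2)
    if evar <= 0:
        return np.inf, float(np.exp(e.mean()))
    f = lambda x: special.polygamma(1, x) - evar
    half_d0 = optimize.brentq(f, 1e-8, 1e8, xtol=1e-12, rtol=1e-14)
    d0 = 2 * half_d0
    s0 = np.exp(e.mean() + special.digamma(half_d0) - np.log(half_d0))
    return d0, float(s0)


def test_prior_moment_matching_agrees_with_bruteforce_solve():
    rng = np.random.default_rng(4)
    d = 4
    # variances from a genuine scaled-F hierarchy: s2 ~ s0^2 * F(d, d0)
    d0_true, s0_true = 6.0, 0.05
    s2 = s0_true * d0_true / rng.chisquare(d0_true, 2000) * rng.chisquare(d, 2000) / d
    params = estimate_prior(s2, d)
    d0_ref, s0_ref = estimate_prior_bruteforce(s2, d)
    assert params.d0 == pytest.approx(d0_ref, rel=1e-6)
    assert params.s0_sq == pytest.approx(s0_ref, rel=1e-6)
    # and the estimates recover the generating hyperparameters roughly
    assert params.d0 == pytest.approx(d0_true, rel=0.5)
    assert params.s0_sq == pytest.approx(s0_true, rel=0.2)


def test_prior_constant_variances_fall_back_to_infinite_d0():
    params = estimate_prior(np.full(100, 0.25), 4)
    assert np.isinf(params.d0)
    # under the chi-square sampling model E[log s2] is biased by
    # digamma(d/2) - log(d/2); the fallback inverts that on the log scale
    expected = 0.25 * np.exp(np.log(2.0) - special.digamma(2.0))
    assert params.s0_sq == pytest.approx(expected, rel=1e-9)
    d0_ref, s0_ref = estimate_prior_bruteforce(np.full(100, 0.25), 4)
    assert np.isinf(d0_ref) and params.s0_sq == pytest.approx(s0_ref, rel=1e-12)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
def test_moderated_t_agrees_with_limma():
    """Cross-check hyperparameters and moderated t against Bioconductor
    limma on a small two-group matrix."""
    rng = np.random.default_rng(5)
    mat = rng.normal(10, 1, (60, 6))
    mat[:10, 3:] += 1.5
    delta = mat[:, 3:].mean(1) - mat[:, :3].mean(1)
    s2 = (mat[:, :3].var(1, ddof=1) * 2 + mat[:, 3:].var(1, ddof=1) * 2) / 4
    params = estimate_prior(s2, 4)
    t_mod, p_mod, _, _ = moderated_t(delta, s2, 4, 3, 3, params)

    import tempfile
    from pathlib import Path

    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        pd.DataFrame(mat).to_csv(tmp / "mat.csv", index=False)
        script = tmp / "limma_check.R"
        script.write_text(
            """
            suppressMessages(library(limma))
            m <- as.matrix(read.csv(file.path(commandArgs(TRUE)[1], "mat.csv")))
            design <- cbind(Intercept = 1, Treated = c(0,0,0,1,1,1))
            fit <- eBayes(lmFit(m, design))
            out <- list(d0 = fit$df.prior, s0_sq = fit$s2.prior,
                        t = fit$t[, "Treated"], p = fit$p.value[, "Treated"])
            cat(jsonlite::toJSON(out, digits = 12))
            """
        )
        res = subprocess.run(
            ["Rscript", "--vanilla", str(script), str(tmp)],
            capture_output=True, text=True, timeout=120,
        )
        assert res.returncode == 0, res.stderr
        out = json.loads(res.stdout)
    assert params.d0 == pytest.approx(out["d0"][0], rel=1e-6)
    assert params.s0_sq == pytest.approx(out["s0_sq"][0], rel=1e-6)
    np.testing.assert_allclose(t_mod, np.asarray(out["t"]), rtol=1e-6)
    np.testing.assert_allclose(p_mod, np.asarray(out["p"]), rtol=1e-6)


# ---------------------------------------------------------------------------
# pipeline-level behaviour on simulated data


def _qc_normalized(noise_cv, seed, effects=EffectSpec(), n_features=300):
    tables, meta, counts, truth = simulate_study(
        StudyDesign(modes=("RP_pos",)), effects, CellCountModel(),
        noise_cv=noise_cv, seed=seed, n_features=n_features,
    )
    norm, _ = run_qc(tables["RP_pos"], meta, counts, truth.is_feature_ids["RP_pos"])
    return norm, meta, truth


def test_fit_moderated_requires_both_groups():
    norm, meta, _ = _qc_normalized(0.1, 0)
    model = ModeratedDifferential(norm, meta)
    with pytest.raises(ValueError):
        model.fit_timepoint(7.5)  # no samples at that time


def test_significant_counts_follow_effect_ramp():
    norm, meta, _ = _qc_normalized(0.2, 11)
    res = ModeratedDifferential(norm, meta).fit()
    counts = res.count_significant(0.05)
    # pre-onset time points essentially null, late ones non-decreasing
    assert counts.loc[0.0] <= 2 and counts.loc[3.0] <= 2
    assert counts.loc[6.0] <= counts.loc[12.0] <= counts.loc[24.0]
    assert res.count_significant(0.0).sum() == 0
    assert res.count_significant(0.05, on="p").sum() >= counts.sum()


def test_log2fc_recovery_improves_with_less_noise():
    maes = []
    for cv in (0.2, 0.05):
        norm, meta, truth = _qc_normalized(cv, 21)
        frame, _ = fit_moderated(norm, meta, 24.0)
        est = frame.set_index("feature_id")["log2fc"]
        true = truth.true_log2fc("RP_pos", 24.0)
        diff = true.index[true != 0].intersection(est.index)
        maes.append(float((est.loc[diff] - true.loc[diff]).abs().mean()))
    assert maes[1] < maes[0]
    assert maes[1] < 0.1


def test_power_monotone_in_effect_size():
    rates = []
    for fc in (0.5, 1.0, 2.0):
        hits = []
        for seed in range(3):
            norm, meta, truth = _qc_normalized(
                0.2, 100 + seed, EffectSpec(0.1, 6.0, fc), n_features=200
            )
            frame, _ = fit_moderated(norm, meta, 24.0)
            sig = set(frame.loc[frame["q"] < 0.05, "feature_id"])
            true = set(truth.differential_ids("RP_pos"))
            tested = set(frame["feature_id"]) & true
            hits.append(len(sig & true) / max(len(tested), 1))
        rates.append(np.mean(hits))
    assert rates[0] <= rates[1] <= rates[2]
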