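"""QC chain semantics: RSD arithmetic, boundary behaviour of each filter,
normalization arithmetic, and the chain's structural invariants."""

import numpy as np
import pandas as pd
import pytest

from metabotox import (
    CellCounts,
    FeatureTable,
    QCConfig,
    apply_noise_threshold,
    blank_filter,
    is_gate,
    normalize_alternative,
    normalize_cell_number,
    pool_rsd_filter,
    rsd,
    run_qc,
)
from metabotox.io import SampleMetadata
from metabotox.qc import ISGateError


def make_table(values: dict, sample_ids, blank_ids=(), pool_ids=(), mode="RP_pos"):
    """Tiny table + metadata from {feature_id: [intensities in col order]}."""
    cols = list(sample_ids) + list(blank_ids) + list(pool_ids)
    feats = pd.DataFrame(
        {"mz": 100.0, "rt": 60.0}, index=pd.Index(list(values), name="feature_id")
    )
    intens = pd.DataFrame.from_dict(values, orient="index", columns=cols).astype(float)
    intens.index.name = "feature_id"
    rows = []
    for i, s in enumerate(sample_ids):
        cond = "control" if i % 2 == 0 else "treated"
        rows.append((s, "sample", cond, 24.0, i))
    for b in blank_ids:
        rows.append((b, "blank", "none", np.nan, 0))
    for p in pool_ids:
        rows.append((p, "pool", "none", np.nan, 0))
    meta = SampleMetadata(
        pd.DataFrame(rows, columns=["injection_id", "role", "condition", "time_h", "replicate"])
    )
    return FeatureTable(feats, intens, mode), meta


@pytest.mark.parametrize(
    "values,expected",
    [([10, 10, 10], 0.0), ([1, 2, 3], 0.5), ([100, 120], 0.12856486930664),
     ([0.8, 1.0, 1.2], 0.2)],
)
def test_rsd_values(values, expected):
    assert rsd(values) == pytest.approx(expected, rel=1e-10)


def test_rsd_errors():
    with pytest.raises(ValueError):
        rsd([5.0])
    with pytest.raises(ValueError):
        rsd([0.0, 0.0])


def test_noise_threshold_boundary_strict_below():
    samples = [f"s{i}" for i in range(4)]
    table, meta = make_table(
        {"below": [99_999] * 4, "at": [100_000] * 4, "above": [150_000] * 4},
        samples,
    )
    out, report = apply_noise_threshold(table, meta, QCConfig())
    assert set(out.feature_ids) == {"at", "above"}
    assert report.removal_reasons == {"below": "noise_threshold"}
    # threshold 0 is the identity
    out0, _ = apply_noise_threshold(table, meta, QCConfig(noise_thresholds={"RP_pos": 0.0}))
    assert list(out0.feature_ids) == list(table.feature_ids)


def test_blank_filter_boundaries():
    samples = [f"s{i}" for i in range(36)]
    table, meta = make_table(
        {
            # sample intensities ........................ blank triplet
            "clean": [100.0] * 36 + [0.0] * 3,    # blank median 0 -> retained
            "dirty": [100.0] * 36 + [21.0] * 3,   # 21 > 20 everywhere -> removed
            "edge": [100.0] * 30 + [50.0] * 6 + [20.0] * 3,   # 20 <= 20 in exactly 30 -> retained
            "edge29": [100.0] * 29 + [50.0] * 7 + [20.0] * 3,  # holds in 29 only -> removed
        },
        samples,
        blank_ids=["b1", "b2", "b3"],
    )
    out, _ = blank_filter(table, meta, QCConfig())
    assert set(out.feature_ids) == {"clean", "edge"}


def test_blank_filter_matches_bruteforce_oracle():
    rng = np.random.default_rng(0)
    n_feat, n_samp, n_blank = 1000, 36, 6
    samples = [f"s{i}" for i in range(n_samp)]
    blanks = [f"b{i}" for i in range(n_blank)]
    vals = {}
    for i in range(n_feat):
        vals[f"F{i}"] = list(rng.lognormal(5, 1, n_samp)) + list(rng.lognormal(3.5, 1.5, n_blank))
    table, meta = make_table(vals, samples, blank_ids=blanks)
    cfg = QCConfig()
    out, _ = blank_filter(table, meta, cfg)
    kept = set(out.feature_ids)
    for fid in table.feature_ids:  # brute force, feature by feature
        b = float(np.median([table.intensities.at[fid, bb] for bb in blanks]))
        n_ok = sum(
            b <= cfg.blank_ratio * table.intensities.at[fid, s] for s in samples
        )
        assert (n_ok >= 30) == (fid in kept), fid


def test_blank_min_pass_scales_with_sample_count():
    cfg = QCConfig()
    assert cfg.blank_min_pass_for(36) == 30
    assert cfg.blank_min_pass_for(12) == 10  # ceil(5/6 * 12)
    assert cfg.blank_min_pass_for(13) == 11


def test_is_gate_strict_less_than():
    samples = ["s0", "s1", "s2"]
    table, meta = make_table(
        {
            "is_const": [5.0, 5.0, 5.0],
            "is_noisy": [1.0, 2.0, 3.0],       # RSD 0.5
            "is_edge": [4.0, 5.0, 6.0],        # sd 1, mean 5: RSD exactly 0.20
        },
        samples,
    )
    cfg = QCConfig()
    passed, values = is_gate(table, meta, ["is_const"], cfg)
    assert passed and values["is_const"] == 0.0
    passed, values = is_gate(table, meta, ["is_const", "is_noisy"], cfg)
    assert not passed and values["is_noisy"] == pytest.approx(0.5)
    passed, _ = is_gate(table, meta, ["is_edge"], cfg)
    assert not passed  # "less than 20 %" is strict
    with pytest.raises(KeyError, match="absent"):
        is_gate(table, meta, ["missing"], cfg)


def test_pool_rsd_filter_strict_less_than():
    samples = ["s0", "s1"]
    pools = ["p0", "p1", "p2"]
    table, meta = make_table(
        {
            "stable": [10, 10, 7, 7, 7],
            "unstable": [10, 10, 1, 2, 3],  # pool RSD 0.5
            "edge": [10, 10, 3, 4, 5],      # sd 1, mean 4: pool RSD exactly 0.25
        },
        samples,
        pool_ids=pools,
    )
    out, report = pool_rsd_filter(table, meta, QCConfig())
    assert set(out.feature_ids) == {"stable"}
    assert report.removal_reasons["edge"] == "pool_rsd_filter"
    with pytest.raises(ValueError):
        one_pool_table, one_pool_meta = make_table({"f": [1, 1, 1]}, samples, pool_ids=["p0"])
        pool_rsd_filter(one_pool_table, one_pool_meta, QCConfig())


def test_normalize_cell_number_arithmetic():
    samples = ["c1", "t1"]
    table, meta = make_table({"f": [1_000_000.0, 1_000_000.0]}, samples)
    counts = CellCounts(
        pd.DataFrame(
            {
                "condition": ["control", "treated"],
                "time_h": [24.0, 24.0],
                "mean_cells": [200_000.0, 100_000.0],
            }
        )
    )
    out = normalize_cell_number(table, meta, counts)
    assert out.intensities.at["f", "c1"] == pytest.approx(5.0)
    # treated count half of control, equal raw areas -> treated value 2x
    assert out.intensities.at["f", "t1"] == pytest.approx(10.0)
    with pytest.raises(KeyError):
        bad = CellCounts(counts.table[counts.table["condition"] == "control"])
        normalize_cell_number(table, meta, bad)


def test_normalize_cell_number_leaves_blanks_pools_untouched(rp_pos):
    table, meta, counts, _ = rp_pos
    out = normalize_cell_number(table, meta, counts)
    pd.testing.assert_frame_equal(
        out.intensities[meta.blank_ids + meta.pool_ids],
        table.intensities[meta.blank_ids + meta.pool_ids],
    )


def test_alternative_normalizations():
    samples = ["s0", "s1"]
    table, meta = make_table({"a": [3.0, 6.0], "b": [1.0, 2.0]}, samples)
    tic = normalize_alternative(table, meta, "TIC")
    assert tic.intensities["s0"].tolist() == [0.75, 0.25]
    # TIC output is invariant to a per-column rescaling
    scaled = table.copy()
    scaled.intensities["s0"] *= 7.0
    tic2 = normalize_alternative(scaled, meta, "TIC")
    pd.testing.assert_frame_equal(tic.intensities, tic2.intensities)
    hk = normalize_alternative(table, meta, "housekeeping", feature_id="b")
    assert hk.intensities.loc["b"].tolist() == [1.0, 1.0]
    assert hk.intensities.loc["a"].tolist() == [3.0, 3.0]
    with pytest.raises(ValueError):
        normalize_alternative(table, meta, "housekeeping", feature_id="zz")


def test_filter_monotonicity_and_idempotence(rp_pos):
    table, meta, counts, truth = rp_pos
    loose = QCConfig(blank_ratio=0.5, pool_rsd_max=0.8)
    strict = QCConfig()
    out_strict, _ = blank_filter(table, meta, strict)
    out_loose, _ = blank_filter(table, meta, loose)
    assert set(out_strict.feature_ids) <= set(out_loose.feature_ids)
    # raising the noise threshold never grows the retained set
    hi = QCConfig(noise_thresholds={"RP_pos": 500_000.0})
    out_hi, _ = apply_noise_threshold(table, meta, hi)
    out_lo, _ = apply_noise_threshold(table, meta, strict)
    assert set(out_hi.feature_ids) <= set(out_lo.feature_ids)
    # idempotence
    twice, _ = blank_filter(out_strict, meta, strict)
    assert list(twice.feature_ids) == list(out_strict.feature_ids)


def test_run_qc_report_reconciles_and_halts_on_is_failure(rp_pos):
    table, meta, counts, truth = rp_pos
    normalized, report = run_qc(table, meta, counts, truth.is_feature_ids["RP_pos"])
    for stage in report.stages:
        assert stage.n_input == stage.n_removed + stage.n_retained
    # stage chaining: each stage's input is the previous stage's output
    for prev, nxt in zip(report.stages, report.stages[1:]):
        assert prev.n_retained == nxt.n_input
    assert report.is_passed
    assert len(report.removal_reasons) == len(table.feature_ids) - len(normalized.feature_ids)
    # background features with a detectable blank signal never survive;
    # those whose blank level fell below the detection floor legitimately
    # pass (their blank median is zero)
    surviving_background = set(truth.background_ids("RP_pos")) & set(normalized.feature_ids)
    blank_medians = table.intensities[meta.blank_ids].median(axis=1)
    assert all(blank_medians[fid] == 0.0 for fid in surviving_background)

    # corrupt one IS -> dataset-level halt
    bad = table.copy()
    is_id = truth.is_feature_ids["RP_pos"][0]
    rng = np.random.default_rng(0)
    bad.intensities.loc[is_id, meta.sample_ids] = rng.lognormal(13, 0.5, 36)
    with pytest.raises(ISGateError, match="RSD gate failed"):
        run_qc(bad, meta, counts, truth.is_feature_ids["RP_pos"])
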