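"""Feature-level quality control and normalization for untargeted LC-MS
feature tables.

The filter chain runs in a fixed order — noise threshold, median-blank
ratio filter, internal-standard RSD gate, pooled-QC RSD filter — followed by
cell-number normalization of the analytical sample columns.  Boundary
semantics are deliberate and asymmetric: the blank comparison is inclusive
("the blank median was not allowed to exceed 20 % of the sample
intensity"), while both RSD gates are strict ("less than 20 %" / "less than
25 %").  Zero intensities take part in all comparisons as true zeros; no
imputation happens at this stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CellCounts, FeatureTable, SampleMetadata

#: Per-dataset noise thresholds (peak area) for the intracellular datasets.
DEFAULT_NOISE_THRESHOLDS = {
    "RP_pos": 100_000.0,
    "RP_neg": 20_000.0,
    "HILIC_pos": 150_000.0,
    "HILIC_neg": 50_000.0,
}


@dataclass
class QCConfig:
    """Thresholds of the QC chain.

    ``blank_min_pass``/``blank_n_samples`` encode the "30 out of 36
    samples" rule; for other sample counts the same 5/6 fraction is kept via
    ``ceil(blank_min_pass / blank_n_samples * n)``.
    """

    noise_thresholds: dict = field(default_factory=lambda: dict(DEFAULT_NOISE_THRESHOLDS))
    blank_ratio: float = 0.20
    blank_min_pass: int = 30
    blank_n_samples: int = 36
    is_rsd_max: float = 0.20
    pool_rsd_max: float = 0.25

    def __post_init__(self) -> None:
        for name in ("blank_ratio", "is_rsd_max", "pool_rsd_max"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.blank_min_pass > self.blank_n_samples:
            raise ValueError("blank_min_pass cannot exceed blank_n_samples")

    def noise_threshold_for(self, mode: str) -> float:
        return float(self.noise_thresholds.get(mode, 0.0))

    def blank_min_pass_for(self, n_samples: int) -> int:
        if n_samples == self.blank_n_samples:
            return self.blank_min_pass
        return math.ceil(self.blank_min_pass / self.blank_n_samples * n_samples)


@dataclass
class StageRecord:
    stage: str
    n_input: int
    n_removed: int
    n_retained: int


@dataclass
class FilterReport:
    """Per-stage feature accounting plus dataset-level IS gate results."""

    mode: str
    stages: list = field(default_factory=list)
    removal_reasons: dict = field(default_factory=dict)  # feature_id -> stage
    is_rsd: dict = field(default_factory=dict)  # IS feature id -> RSD
    is_passed: bool | None = None

    def record(self, stage: str, before: pd.Index, after: pd.Index) -> None:
        removed = before.difference(after)
        self.stages.append(StageRecord(stage, len(before), len(removed), len(after)))
        for fid in removed:
            self.removal_reasons[fid] = stage

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.stage, s.n_input, s.n_removed, s.n_retained) for s in self.stages],
            columns=["stage", "n_input", "n_removed", "n_retained"],
        )

    def reasons_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.removal_reasons.items()), columns=["feature_id", "stage"]
        )


class ISGateError(RuntimeError):
    """Internal-standard RSD gate failed: the dataset is not usable for
    differential analysis."""


def rsd(values) -> float:
    """Relative standard deviation: sample sd (n-1 denominator) over mean.

    Raises
    ------
    ValueError
        For fewer than two values or a non-positive mean.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("RSD requires at least 2 values")
    mean = arr.mean()
    if mean <= 0:
        raise ValueError("RSD undefined for non-positive mean")
    return float(arr.std(ddof=1) / mean)


def _rsd_rows(mat: np.ndarray) -> np.ndarray:
    """Row-wise RSD; rows with non-positive mean get +inf (treated as
    maximally unstable)."""
    mean = mat.mean(axis=1)
    sd = mat.std(axis=1, ddof=1)
    out = np.full(mat.shape[0], np.inf)
    ok = mean > 0
    out[ok] = sd[ok] / mean[ok]
    return out


def apply_noise_threshold(
    table: FeatureTable, meta: SampleMetadata, cfg: QCConfig, report: FilterReport | None = None
) -> tuple[FeatureTable, FilterReport]:
    """Remove features whose maximum intensity over analytical samples is
    strictly below the dataset's noise threshold."""
    report = report or FilterReport(table.mode)
    threshold = cfg.noise_threshold_for(table.mode)
    sample_max = table.intensities[meta.sample_ids].max(axis=1)
    keep = table.feature_ids[sample_max >= threshold]
    out = table.subset_features(keep)
    report.record("noise_threshold", table.feature_ids, out.feature_ids)
    return out, report


def blank_filter(
    table: FeatureTable, meta: SampleMetadata, cfg: QCConfig, report: FilterReport | None = None
) -> tuple[FeatureTable, FilterReport]:
    """Background removal by the median-blank rule.

    A feature is retained iff its median blank intensity B satisfies
    ``B <= blank_ratio * intensity`` in at least ``blank_min_pass`` of the
    analytical samples (inclusive comparison on both sides).
    """
    blanks = meta.blank_ids
    if not blanks:
        raise ValueError("blank filter enabled but no blank injections present")
    report = report or FilterReport(table.mode)
    samples = meta.sample_ids
    min_pass = cfg.blank_min_pass_for(len(samples))
    blank_median = table.intensities[blanks].median(axis=1).to_numpy()
    sample_mat = table.intensities[samples].to_numpy()
    n_pass = (blank_median[:, None] <= cfg.blank_ratio * sample_mat).sum(axis=1)
    keep = table.feature_ids[n_pass >= min_pass]
    out = table.subset_features(keep)
    report.record("blank_filter", table.feature_ids, out.feature_ids)
    return out, report


def is_gate(
    table: FeatureTable,
    meta: SampleMetadata,
    is_feature_ids,
    cfg: QCConfig,
    report: FilterReport | None = None,
) -> tuple[bool, dict]:
    """Dataset-level internal-standard gate.

    Each IS feature's RSD across all analytical samples must be strictly
    below ``is_rsd_max``; on failure the dataset is flagged unusable for
    differential analysis (no features are dropped).
    """
    for fid in is_feature_ids:
        if fid not in table.feature_ids:
            raise KeyError(f"internal-standard feature {fid!r} absent from table")
    values = {}
    for fid in is_feature_ids:
        values[fid] = rsd(table.intensities.loc[fid, meta.sample_ids].to_numpy())
    passed = all(v < cfg.is_rsd_max for v in values.values())
    if report is not None:
        report.is_rsd = values
        report.is_passed = passed
    return passed, values


def pool_rsd_filter(
    table: FeatureTable, meta: SampleMetadata, cfg: QCConfig, report: FilterReport | None = None
) -> tuple[FeatureTable, FilterReport]:
    """Retain features whose RSD across pooled-QC injections is strictly
    below ``pool_rsd_max`` (technical stability)."""
    pools = meta.pool_ids
    if len(pools) < 2:
        raise ValueError("pool RSD filter requires at least 2 pool injections")
    report = report or FilterReport(table.mode)
    pool_rsd = _rsd_rows(table.intensities[pools].to_numpy())
    keep = table.feature_ids[pool_rsd < cfg.pool_rsd_max]
    out = table.subset_features(keep)
    report.record("pool_rsd_filter", table.feature_ids, out.feature_ids)
    return out, report


def normalize_cell_number(
    table: FeatureTable, meta: SampleMetadata, counts: CellCounts
) -> FeatureTable:
    """Divide each analytical sample column by the mean viable cell number
    of its (condition, time) group; blanks and pools stay unscaled.

    Output units are peak area per cell.
    """
    out = table.copy()
    for inj in meta.sample_ids:
        cond, t = meta.condition_time_of(inj)
        n = counts.lookup(cond, t)
        if n <= 0:
            raise ValueError(f"non-positive cell count for {cond}/{t:g}")
        out.intensities[inj] = out.intensities[inj] / n
    return out


def normalize_alternative(
    table: FeatureTable, meta: SampleMetadata, method: str = "TIC", feature_id: str | None = None
) -> FeatureTable:
    """Alternative normalizations: total ion current or a housekeeping
    feature (both applied to analytical sample columns only)."""
    out = table.copy()
    if method == "TIC":
        for inj in meta.sample_ids:
            total = out.intensities[inj].sum()
            if total <= 0:
                raise ValueError(f"zero column sum for injection {inj!r}")
            out.intensities[inj] = out.intensities[inj] / total
    elif method == "housekeeping":
        if feature_id is None or feature_id not in table.feature_ids:
            raise ValueError(f"housekeeping feature {feature_id!r} absent from table")
        for inj in meta.sample_ids:
            ref = out.intensities.at[feature_id, inj]
            if ref <= 0:
                raise ValueError(f"zero housekeeping intensity in {inj!r}")
            out.intensities[inj] = out.intensities[inj] / ref
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return out


def run_qc(
    table: FeatureTable,
    meta: SampleMetadata,
    counts: CellCounts,
    is_feature_ids,
    cfg: QCConfig | None = None,
    normalize: bool = True,
) -> tuple[FeatureTable, FilterReport]:
    """Run the full QC chain in the fixed order noise -> blank -> IS gate ->
    pool RSD -> cell-number normalization.

    Raises
    ------
    ISGateError
        When an internal standard's RSD across samples is not strictly
        below the gate threshold.
    """
    cfg = cfg or QCConfig()
    report = FilterReport(table.mode)
    # IS features are spiked into every injection (blanks included), so the
    # blank rule removes them by construction; the dataset-level gate is
    # therefore evaluated on the unfiltered table.
    original = table
    table, _ = apply_noise_threshold(table, meta, cfg, report)
    table, _ = blank_filter(table, meta, cfg, report)
    passed, values = is_gate(original, meta, is_feature_ids, cfg, report)
    if not passed:
        failing = {k: v for k, v in values.items() if v >= cfg.is_rsd_max}
        raise ISGateError(
            f"{table.mode}: internal-standard RSD gate failed: "
            + ", ".join(f"{k}={v:.3f}" for k, v in failing.items())
        )
    table, _ = pool_rsd_filter(table, meta, cfg, report)
    if normalize:
        table = normalize_cell_number(table, meta, counts)
    return table, report


__all__ = [
    "DEFAULT_NOISE_THRESHOLDS",
    "QCConfig",
    "FilterReport",
    "StageRecord",
    "ISGateError",
    "rsd",
    "apply_noise_threshold",
    "blank_filter",
    "is_gate",
    "pool_rsd_filter",
    "normalize_cell_number",
    "normalize_alternative",
    "run_qc",
]
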