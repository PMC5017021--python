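"""Synthetic study generator emulating an in-vitro nanoparticle exposure
time course measured by untargeted LC-MS.

The generated design mirrors a 2-condition (control vs treated) x 6-time-point
(0, 1, 3, 6, 12, 24 h) x 3-replicate experiment — 36 analytical samples per
dataset — plus blank and pooled-QC injections and two internal-standard
features (ethylparaben, nitrotyrosine) spiked at a constant nominal level
into every injection.  Four datasets are produced by default, one per
separation/polarity combination (RP_pos, RP_neg, HILIC_pos, HILIC_neg).

Key modelling choices
---------------------
* Per-cell baseline abundances are log-normal (log10 mean 6, sd 0.8) so that
  the per-dataset noise thresholds bite on a realistic fraction of features.
* Measured peak areas scale with the viable cell number of the injection's
  (condition, time) group: treated cultures arrest and decline after an
  onset hour while controls keep doubling, which is exactly the distortion
  cell-number normalization exists to remove.
* Treatment effects act on the per-cell level as ``2**log2fc(t)`` with a
  log-linear ramp (or step) after an onset hour.
* Measurement noise is multiplicative log-normal.  Analytical samples carry
  the full per-feature coefficient of variation ``noise_cv`` (biological +
  technical); internal standards, blanks and pooled-QC injections carry only
  the injection-repeatability component ``technical_cv``, since the IS is
  spiked at extraction and pools are repeat injections of one mixture.
  Intensities below the detection floor are emitted as zero.
* Blanks carry ~0.2 % of the baseline signal except for a configurable
  fraction of "background" features whose blank level violates the
  median-blank rule on purpose; pools are the mean composition of all
  analytical samples plus technical noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CellCounts, CompoundTable, FeatureTable, SampleMetadata

PROTON_MASS = 1.00728
"""Mass of a proton in u, used for [M+H]+ / [M-H]- adduct arithmetic."""

#: Default per-dataset detection floors (peak area), matching the noise
#: thresholds the QC stage applies per separation/polarity dataset.
DEFAULT_DETECTION_FLOOR = {
    "RP_pos": 100_000.0,
    "RP_neg": 20_000.0,
    "HILIC_pos": 150_000.0,
    "HILIC_neg": 50_000.0,
}

#: Neutral monoisotopic masses (u) of the two internal standards.
IS_NEUTRAL_MASS = {
    "ethylparaben": 166.06299,
    "nitrotyrosine": 226.05897,
}


@dataclass
class StudyDesign:
    """Layout of the exposure time course and its QC injections."""

    time_points_h: tuple = (0.0, 1.0, 3.0, 6.0, 12.0, 24.0)
    n_replicates: int = 3
    n_blanks: int = 6
    n_pools: int = 8
    modes: tuple = ("RP_pos", "RP_neg", "HILIC_pos", "HILIC_neg")

    def __post_init__(self) -> None:
        tp = tuple(float(t) for t in self.time_points_h)
        if any(t < 0 for t in tp):
            raise ValueError("time points must be non-negative hours")
        if any(b >= a for a, b in zip(tp[1:], tp[:-1])):
            raise ValueError("time points must be strictly increasing")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates for any statistics")
        if not self.modes:
            raise ValueError("mode list must be non-empty")
        self.time_points_h = tp
        self.modes = tuple(self.modes)

    @property
    def n_samples(self) -> int:
        return 2 * len(self.time_points_h) * self.n_replicates


@dataclass
class EffectSpec:
    """Treatment effect trajectory applied to differential features."""

    fraction_differential: float = 0.10
    onset_h: float = 6.0
    max_log2fc: float = 2.0
    ramp_shape: str = "linear"  # or "step"

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_differential <= 1.0:
            raise ValueError("fraction_differential must be in [0, 1]")
        if not np.isfinite(self.max_log2fc):
            raise ValueError("max_log2fc must be finite")
        if self.ramp_shape not in ("linear", "step"):
            raise ValueError("ramp_shape must be 'linear' or 'step'")

    def log2fc_at(self, time_h: float, t_max: float) -> float:
        """True per-cell log2 fold change at ``time_h`` (0 before onset)."""
        if time_h <= self.onset_h:
            return 0.0
        if self.ramp_shape == "step":
            return self.max_log2fc
        return self.max_log2fc * (time_h - self.onset_h) / (t_max - self.onset_h)


@dataclass
class CellCountModel:
    """Viable cell numbers: exponential growth in controls; growth arrest
    followed by exponential decline in treated cultures."""

    seed_density: float = 1.0e6
    control_doubling_h: float = 24.0
    treated_arrest_h: float = 6.0
    treated_decline_rate: float = 0.03  # per hour

    def control(self, time_h: float) -> float:
        return self.seed_density * 2.0 ** (time_h / self.control_doubling_h)

    def treated(self, time_h: float) -> float:
        if time_h <= self.treated_arrest_h:
            return self.control(time_h)
        at_arrest = self.control(self.treated_arrest_h)
        return at_arrest * np.exp(-self.treated_decline_rate * (time_h - self.treated_arrest_h))

    def count(self, condition: str, time_h: float) -> float:
        if condition == "control":
            return self.control(time_h)
        if condition == "treated":
            return self.treated(time_h)
        raise ValueError(f"unknown condition {condition!r}")


@dataclass
class GroundTruth:
    """Per-feature generative truth for every simulated dataset.

    ``features`` columns: feature_id, mode, is_differential, is_background,
    is_internal_standard, compound (spiked identity or ''), baseline
    (per-cell area at seed density) and ``log2fc_<t>h`` per time point.
    """

    features: pd.DataFrame
    is_feature_ids: dict = field(default_factory=dict)  # mode -> [ids]

    def differential_ids(self, mode: str) -> list[str]:
        t = self.features
        sel = (t["mode"] == mode) & t["is_differential"]
        return t.loc[sel, "feature_id"].tolist()

    def background_ids(self, mode: str) -> list[str]:
        t = self.features
        sel = (t["mode"] == mode) & t["is_background"]
        return t.loc[sel, "feature_id"].tolist()

    def true_log2fc(self, mode: str, time_h: float) -> pd.Series:
        t = self.features[self.features["mode"] == mode]
        return t.set_index("feature_id")[f"log2fc_{time_h:g}h"]


def _noise_sigma(noise_cv: float) -> float:
    return float(np.sqrt(np.log1p(noise_cv**2)))


def _noise_factors(rng: np.random.Generator, shape, noise_cv: float) -> np.ndarray:
    """Multiplicative log-normal factors with mean 1 and CV ``noise_cv``."""
    if noise_cv == 0:
        return np.ones(shape)
    sigma = _noise_sigma(noise_cv)
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=shape)


def build_metadata(design: StudyDesign) -> SampleMetadata:
    rows = []
    for cond, tag in (("control", "C"), ("treated", "T")):
        for t in design.time_points_h:
            for rep in range(1, design.n_replicates + 1):
                rows.append((f"{tag}.{t:g}h.{rep}", "sample", cond, t, rep))
    for i in range(1, design.n_blanks + 1):
        rows.append((f"blank.{i}", "blank", "none", np.nan, i))
    for i in range(1, design.n_pools + 1):
        rows.append((f"pool.{i}", "pool", "none", np.nan, i))
    return SampleMetadata(pd.DataFrame(rows, columns=["injection_id", "role", "condition", "time_h", "replicate"]))


def build_cell_counts(design: StudyDesign, cells: CellCountModel) -> CellCounts:
    rows = [
        (cond, t, cells.count(cond, t))
        for cond in ("control", "treated")
        for t in design.time_points_h
    ]
    return CellCounts(pd.DataFrame(rows, columns=["condition", "time_h", "mean_cells"]))


def simulate_study(
    design: StudyDesign | None = None,
    effects: EffectSpec | None = None,
    cells: CellCountModel | None = None,
    noise_cv: float = 0.10,
    seed: int = 0,
    *,
    n_features: int = 800,
    background_fraction: float = 0.10,
    is_nominal: float = 5.0e6,
    technical_cv: float = 0.05,
    detection_floor: dict | float | None = None,
) -> tuple[dict, SampleMetadata, CellCounts, GroundTruth]:
    """Simulate feature tables, metadata, cell counts and ground truth.

    Parameters
    ----------
    design, effects, cells
        Study layout, treatment-effect trajectory and cell-growth model;
        defaults emulate the 10 ug/ml CuO-NP exposure design.
    noise_cv
        Coefficient of variation of the multiplicative noise on analytical
        sample intensities (biological + technical).
    seed
        Seed for the pseudo-random generator; identical seeds and parameters
        give bit-identical output.
    n_features
        Endogenous features per dataset (internal standards come extra).
    background_fraction
        Fraction of features constructed to violate the median-blank rule.
    is_nominal
        Constant nominal peak area of the two internal-standard features.
    technical_cv
        Injection-repeatability CV applied to internal standards, blanks
        and pooled-QC injections.
    detection_floor
        Peak areas below this are emitted as zero.  A mapping per mode, a
        scalar, or None for the per-mode defaults.

    Returns
    -------
    (tables, metadata, counts, truth)
        ``tables`` maps mode label to :class:`~metabotox.io.FeatureTable`.
    """
    design = design or StudyDesign()
    effects = effects or EffectSpec()
    cells = cells or CellCountModel()
    if noise_cv < 0 or technical_cv < 0:
        raise ValueError("noise CVs must be non-negative")
    tps = design.time_points_h
    t_max = tps[-1]
    if not (tps[0] <= effects.onset_h <= t_max):
        raise ValueError("effect onset must lie within the time range")

    meta = build_metadata(design)
    counts = build_cell_counts(design, cells)
    sample_rows = meta.table[meta.table["role"] == "sample"]

    tables: dict[str, FeatureTable] = {}
    truth_frames = []
    is_ids: dict[str, list[str]] = {}
    child_seeds = np.random.SeedSequence(seed).spawn(len(design.modes))

    for mode, ss in zip(design.modes, child_seeds):
        rng = np.random.default_rng(ss)
        floor = _floor_for(mode, detection_floor)
        polarity = mode.rsplit("_", 1)[-1]

        ids = [f"{mode}.F{i:04d}" for i in range(1, n_features + 1)]
        mz = rng.uniform(70.0, 950.0, n_features)
        rt = rng.uniform(30.0, 1200.0, n_features)
        baseline = 10.0 ** rng.normal(6.0, 0.8, n_features)

        n_diff = int(round(effects.fraction_differential * n_features))
        n_back = int(round(background_fraction * n_features))
        perm = rng.permutation(n_features)
        diff_idx = np.zeros(n_features, bool)
        diff_idx[perm[:n_diff]] = True
        back_idx = np.zeros(n_features, bool)
        back_idx[perm[n_diff : n_diff + n_back]] = True

        fc = {t: np.where(diff_idx, effects.log2fc_at(t, t_max), 0.0) for t in tps}

        # noiseless expected sample intensities: per-cell level x cell-number
        # scale x treatment effect
        expected = np.empty((n_features, len(sample_rows)))
        for j, row in enumerate(sample_rows.itertuples(index=False)):
            scale = cells.count(row.condition, row.time_h) / cells.seed_density
            eff = 2.0 ** fc[row.time_h] if row.condition == "treated" else 1.0
            expected[:, j] = baseline * scale * eff

        sample_mat = expected * _noise_factors(rng, expected.shape, noise_cv)

        blank_level = np.where(back_idx, 0.5 * baseline, 0.002 * baseline)
        blank_mat = blank_level[:, None] * _noise_factors(rng, (n_features, design.n_blanks), technical_cv)

        pool_base = expected.mean(axis=1)
        pool_mat = pool_base[:, None] * _noise_factors(rng, (n_features, design.n_pools), technical_cv)

        # internal standards: constant nominal level in every injection
        n_inj = len(sample_rows) + design.n_blanks + design.n_pools
        is_rows = []
        is_mz = []
        for name in ("ethylparaben", "nitrotyrosine"):
            level = is_nominal * _noise_factors(rng, n_inj, technical_cv)
            is_rows.append(level)
            offset = PROTON_MASS if polarity == "pos" else -PROTON_MASS
            is_mz.append(IS_NEUTRAL_MASS[name] + offset)
        mode_is_ids = [f"{mode}.IS.ethylparaben", f"{mode}.IS.nitrotyrosine"]
        is_ids[mode] = mode_is_ids

        full = np.vstack([np.hstack([sample_mat, blank_mat, pool_mat]), np.vstack(is_rows)])
        full[full < floor] = 0.0

        inj_ids = (
            sample_rows["injection_id"].tolist()
            + meta.blank_ids
            + meta.pool_ids
        )
        all_ids = ids + mode_is_ids
        features = pd.DataFrame(
            {
                "mz": np.concatenate([mz, is_mz]),
                "rt": np.concatenate([rt, [400.0, 500.0]]),
            },
            index=pd.Index(all_ids, name="feature_id"),
        )
        intensities = pd.DataFrame(full, index=features.index, columns=inj_ids)
        tables[mode] = FeatureTable(features, intensities, mode)

        tf = pd.DataFrame(
            {
                "feature_id": all_ids,
                "mode": mode,
                "is_differential": list(diff_idx) + [False, False],
                "is_background": list(back_idx) + [False, False],
                "is_internal_standard": [False] * n_features + [True, True],
                "compound": [""] * n_features + ["ethylparaben", "nitrotyrosine"],
                "baseline": list(baseline) + [is_nominal, is_nominal],
            }
        )
        for t in tps:
            tf[f"log2fc_{t:g}h"] = list(fc[t]) + [0.0, 0.0]
        truth_frames.append(tf)

    truth = GroundTruth(pd.concat(truth_frames, ignore_index=True), is_ids)
    return tables, meta, counts, truth


def _floor_for(mode: str, detection_floor) -> float:
    if detection_floor is None:
        return DEFAULT_DETECTION_FLOOR.get(mode, 0.0)
    if isinstance(detection_floor, dict):
        return float(detection_floor.get(mode, 0.0))
    return float(detection_floor)


ADDUCT_OFFSETS = {"[M+H]+": PROTON_MASS, "[M-H]-": -PROTON_MASS}


def spike_known_compounds(
    table: FeatureTable,
    compounds: CompoundTable,
    adduct: str = "[M+H]+",
    level: float = 1.0e6,
    truth: GroundTruth | None = None,
) -> tuple[FeatureTable, pd.DataFrame]:
    """Append features at the adduct m/z of each reference compound.

    The spiked features are injected at a constant ``level`` in every
    injection so they survive QC, and are returned in a record frame
    (and appended to ``truth`` when given) for recovery checks.
    """
    if adduct not in ADDUCT_OFFSETS:
        raise ValueError(f"unknown adduct {adduct!r}")
    if len(compounds) == 0:
        return table, pd.DataFrame(columns=["feature_id", "compound", "mz"])
    offset = ADDUCT_OFFSETS[adduct]
    rows = []
    feats = []
    for rec in compounds.table.itertuples(index=False):
        fid = f"{table.mode}.SPK.{rec.name}"
        mz = rec.neutral_mass + offset
        rt = rec.rt_s if np.isfinite(rec.rt_s) else 600.0
        feats.append((fid, mz, rt))
        rows.append({"feature_id": fid, "compound": rec.name, "mz": mz})
    add_features = pd.DataFrame(
        {"mz": [f[1] for f in feats], "rt": [f[2] for f in feats]},
        index=pd.Index([f[0] for f in feats], name="feature_id"),
    )
    add_intens = pd.DataFrame(
        level, index=add_features.index, columns=table.injections
    )
    out = FeatureTable(
        pd.concat([table.features, add_features]),
        pd.concat([table.intensities, add_intens]),
        table.mode,
    )
    record = pd.DataFrame(rows)
    if truth is not None and len(record):
        extra = pd.DataFrame(
            {
                "feature_id": record["feature_id"],
                "mode": table.mode,
                "is_differential": False,
                "is_background": False,
                "is_internal_standard": False,
                "compound": record["compound"],
                "baseline": level,
            }
        )
        for col in truth.features.columns:
            if col.startswith("log2fc_"):
                extra[col] = 0.0
        truth.features = pd.concat([truth.features, extra], ignore_index=True)
    return out, record
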