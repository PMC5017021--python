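"""End-to-end pipeline orchestration: validate -> QC -> normalize ->
differential statistics -> PCA -> cross-mode matching -> annotation ->
report bundle.

The pipeline is configured from a single YAML file (unknown keys rejected),
is deterministic given its seed, and writes every artefact together with a
manifest of versions, seeds and parameters.  A dataset whose
internal-standard gate fails is marked as failed and skipped; the remaining
datasets still run.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import annotate_features, annotations_frame, cross_mode_match
from .diffstats import ModeratedDifferential
from .io import (
    read_cell_counts,
    read_compound_table,
    read_feature_table,
    read_metadata,
    validate_design,
    write_feature_table,
)
from .multivariate import NipalsPCA, cluster_metabolites
from .qc import ISGateError, QCConfig, run_qc
from .simulate import CellCountModel, EffectSpec, StudyDesign, simulate_study


@dataclass
class PipelineConfig:
    """Schema-validated pipeline configuration."""

    seed: int = 0
    outdir: str = "metabotox_out"
    # inputs: either explicit paths per mode, or simulate=True
    simulate: bool = True
    feature_tables: dict = field(default_factory=dict)  # mode -> path
    metadata: str | None = None
    cell_counts: str | None = None
    compounds: str | None = None
    # QC
    noise_thresholds: dict | None = None
    blank_ratio: float = 0.20
    blank_min_pass: int = 30
    blank_n_samples: int = 36
    is_rsd_max: float = 0.20
    pool_rsd_max: float = 0.25
    # statistics
    alpha: float = 0.05
    sig_on: str = "q"
    # PCA
    pca_components: int = 2
    pca_scaling: str = "uv"
    pca_folds: int = 7
    pca_exclude: list = field(default_factory=list)  # manual outlier exclusion
    # annotation
    ppm_tolerance: float = 5.0
    rt_tol_s: float = 18.0
    ms2_threshold: float = 0.70
    # simulation knobs (used when simulate=True)
    noise_cv: float = 0.10
    n_features: int = 800
    fraction_differential: float = 0.10
    onset_h: float = 6.0
    max_log2fc: float = 2.0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def qc_config(self) -> QCConfig:
        kwargs = dict(
            blank_ratio=self.blank_ratio,
            blank_min_pass=self.blank_min_pass,
            blank_n_samples=self.blank_n_samples,
            is_rsd_max=self.is_rsd_max,
            pool_rsd_max=self.pool_rsd_max,
        )
        if self.noise_thresholds is not None:
            kwargs["noise_thresholds"] = dict(self.noise_thresholds)
        return QCConfig(**kwargs)


@dataclass
class ModeResult:
    mode: str
    failed: bool = False
    failure_reason: str = ""
    normalized: object = None
    filter_report: object = None
    differential: object = None
    pca: object = None


@dataclass
class PipelineResult:
    outdir: Path
    modes: dict
    manifest: dict
    venn: dict | None = None
    annotations: pd.DataFrame | None = None

    @property
    def completed_modes(self) -> list:
        return [m for m, r in self.modes.items() if not r.failed]


def _load_inputs(config: PipelineConfig):
    if config.simulate:
        design = StudyDesign()
        effects = EffectSpec(
            fraction_differential=config.fraction_differential,
            onset_h=config.onset_h,
            max_log2fc=config.max_log2fc,
        )
        tables, meta, counts, truth = simulate_study(
            design,
            effects,
            CellCountModel(),
            noise_cv=config.noise_cv,
            seed=config.seed,
            n_features=config.n_features,
        )
        is_ids = truth.is_feature_ids
        return tables, meta, counts, is_ids, truth
    tables = {mode: read_feature_table(p) for mode, p in config.feature_tables.items()}
    meta = read_metadata(config.metadata)
    counts = read_cell_counts(config.cell_counts)
    is_ids = {
        mode: [fid for fid in t.feature_ids if ".IS." in fid] for mode, t in tables.items()
    }
    return tables, meta, counts, is_ids, None


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline and write the report bundle."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables, meta, counts, is_ids, truth = _load_inputs(config)
    qc_cfg = config.qc_config()
    compounds = read_compound_table(config.compounds) if config.compounds else None

    modes: dict[str, ModeResult] = {}
    sig_tables = []
    normalized_tables = {}
    for mode, table in tables.items():
        res = ModeResult(mode)
        modes[mode] = res
        report = validate_design(table, meta, counts)
        if not report.ok:
            res.failed = True
            res.failure_reason = "validation: " + "; ".join(report.fatal)
            continue
        try:
            normalized, filt = run_qc(table, meta, counts, is_ids.get(mode, []), qc_cfg)
        except ISGateError as exc:
            res.failed = True
            res.failure_reason = str(exc)
            continue
        res.normalized = normalized
        res.filter_report = filt
        normalized_tables[mode] = normalized
        filt.to_frame().to_csv(outdir / f"{mode}.filter_report.tsv", sep="\t", index=False)
        filt.reasons_frame().to_csv(outdir / f"{mode}.removed_features.tsv", sep="\t", index=False)
        write_feature_table(normalized, outdir / f"{mode}.normalized.tsv")

        model = ModeratedDifferential(normalized, meta)
        results = model.fit(alpha=config.alpha)
        res.differential = results
        results.table.to_csv(outdir / f"{mode}.differential.tsv", sep="\t", index=False)
        counts_sig = results.count_significant(config.alpha, config.sig_on)
        counts_sig.rename(mode, inplace=True)
        sig_tables.append(counts_sig)

        # PCA on log2-normalized samples (rows = injections)
        sample_ids = [s for s in meta.sample_ids if s not in config.pca_exclude]
        mat = normalized.intensities[sample_ids].to_numpy(dtype=float)
        pseudo = model.pseudo
        logmat = np.log2(np.where(mat > 0, mat, pseudo)).T
        n_comp = min(config.pca_components, len(sample_ids) - 1, logmat.shape[1])
        pca = NipalsPCA(logmat, n_comp, scaling=config.pca_scaling)
        pca_res = pca.fit()
        pca_res.q2, pca_res.q2cum = pca.crossval_q2(config.pca_folds, seed=config.seed)
        res.pca = pca_res
        pca_res.scores_frame(sample_ids).to_csv(outdir / f"{mode}.pca_scores.tsv", sep="\t")
        pca_res.loadings_frame(normalized.feature_ids).to_csv(
            outdir / f"{mode}.pca_loadings.tsv", sep="\t"
        )
        pd.DataFrame(
            {"component": [f"PC{i+1}" for i in range(n_comp)], "r2": pca_res.r2,
             "r2cum": pca_res.r2cum, "q2": pca_res.q2, "q2cum": pca_res.q2cum}
        ).to_csv(outdir / f"{mode}.pca_metrics.tsv", sep="\t", index=False)
        try:
            from .plotting import score_plot

            score_plot(pca_res, meta, sample_ids, outdir / f"{mode}.score_plot.png", mode)
        except Exception:  # plotting is best-effort, never fatal
            pass

    # significant-count table across modes
    if sig_tables:
        sig = pd.concat(sig_tables, axis=1)
        sig.to_csv(outdir / "significant_counts.tsv", sep="\t")

    # cross-mode matching on QC-passing features
    venn = None
    if len(normalized_tables) >= 2:
        matches = cross_mode_match(normalized_tables.values(), config.ppm_tolerance)
        venn = {"+".join(sorted(k)): v for k, v in matches.venn.items()}
        pd.DataFrame(sorted(venn.items()), columns=["modes", "n_features"]).to_csv(
            outdir / "cross_mode_venn.tsv", sep="\t", index=False
        )

    # annotation of significant features against the compound table
    annotations = None
    if compounds is not None:
        records = []
        for mode, res in modes.items():
            if res.failed or res.differential is None:
                continue
            sig_ids = res.differential.table.loc[
                res.differential.table["q"] < config.alpha, "feature_id"
            ].unique()
            if len(sig_ids) == 0:
                continue
            sub = res.normalized.subset_features(
                [f for f in res.normalized.feature_ids if f in set(sig_ids)]
            )
            recs = annotate_features(
                sub, compounds, config.ppm_tolerance, config.rt_tol_s, config.ms2_threshold
            )
            frame = annotations_frame(recs)
            frame.insert(0, "mode", mode)
            records.append(frame)
        annotations = (
            pd.concat(records, ignore_index=True)
            if records
            else annotations_frame([]).assign(mode=pd.Series(dtype=str))
        )
        annotations.to_csv(outdir / "annotations.tsv", sep="\t", index=False)

    # fold-change heat map over significant features (24 h ranking)
    _write_heatmap(modes, outdir, config)

    manifest = {
        "package": "metabotox",
        "version": __version__,
        "seed": config.seed,
        "config": {k: _jsonable(v) for k, v in dataclasses.asdict(config).items()},
        "modes": {
            m: {"failed": r.failed, "reason": r.failure_reason} for m, r in modes.items()
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return PipelineResult(outdir, modes, manifest, venn, annotations)


def _write_heatmap(modes: dict, outdir: Path, config: PipelineConfig) -> None:
    for mode, res in modes.items():
        if res.failed or res.differential is None:
            continue
        tab = res.differential.table
        sig_ids = tab.loc[tab["q"] < config.alpha, "feature_id"].unique()
        if len(sig_ids) < 2:
            continue
        wide = (
            tab[tab["feature_id"].isin(sig_ids)]
            .pivot(index="feature_id", columns="time_h", values="log2fc")
            .dropna()
        )
        if len(wide) < 2:
            continue
        wide = wide.loc[wide.abs().max(axis=1).sort_values(ascending=False).index[:50]]
        tree = cluster_metabolites(wide)
        wide.iloc[tree.leaf_order].to_csv(outdir / f"{mode}.heatmap_log2fc.tsv", sep="\t")
        try:
            from .plotting import log2fc_heatmap

            log2fc_heatmap(wide, tree, outdir / f"{mode}.heatmap.png", mode)
        except Exception:
            pass


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, dict):
        return {k: _jsonable(x) for k, x in v.items()}
    if isinstance(v, (list, tuple)):
        return [_jsonable(x) for x in v]
    return v
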