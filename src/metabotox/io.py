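"""Readers/writers and in-memory containers for feature tables, sample
metadata, cell counts and compound reference tables.

All files are plain tab-separated text with an explicit header.  The contract
starts at the feature list: peak picking from raw mzML data is upstream of
this package.  Injection column order is metadata-driven, never positional.

Container conventions
---------------------
``FeatureTable``
    Per-feature ``m/z`` (u) and retention time (s) plus a dense, non-negative
    features x injections peak-area matrix.  The dataset label (``mode``)
    encodes separation ({RP, HILIC}) and ionization polarity ({pos, neg}),
    e.g. ``"RP_pos"``.
``SampleMetadata``
    One row per injection: role in {sample, blank, pool}, condition in
    {control, treated, none}, exposure time in hours, replicate index.
``CellCounts``
    Mean viable cell number per (condition, time) group, used for
    area-per-cell normalization.
``CompoundTable``
    Reference compounds: name, neutral monoisotopic mass (u), optional
    reference retention time, optional reference MS2 peak list, and a flag
    for the presence of a database MS2 spectrum.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ROLES = ("sample", "blank", "pool")
CONDITIONS = ("control", "treated", "none")

_META_COLUMNS = ["injection_id", "role", "condition", "time_h", "replicate"]


class FeatureTableError(ValueError):
    """Malformed feature table content."""


@dataclass
class FeatureTable:
    """A feature x injection peak-area matrix with feature annotations.

    Parameters
    ----------
    features : pandas.DataFrame
        Indexed by unique feature id; columns ``mz`` (u) and ``rt`` (s).
    intensities : pandas.DataFrame
        Indexed like ``features``; one column per injection; values are
        non-negative peak areas.
    mode : str
        Dataset label, ``<separation>_<polarity>`` (e.g. ``HILIC_neg``).
    """

    features: pd.DataFrame
    intensities: pd.DataFrame
    mode: str = "RP_pos"

    def __post_init__(self) -> None:
        if self.features.index.duplicated().any():
            dup = self.features.index[self.features.index.duplicated()][0]
            raise FeatureTableError(f"duplicate feature id {dup!r}")
        if not self.features.index.equals(self.intensities.index):
            raise FeatureTableError("features and intensities indices differ")
        for col in ("mz", "rt"):
            if col not in self.features.columns:
                raise FeatureTableError(f"missing feature column {col!r}")
        if (self.features["mz"] <= 0).any():
            raise FeatureTableError("m/z values must be positive")
        if (self.intensities.to_numpy() < 0).any():
            raise FeatureTableError("negative intensity encountered")

    @property
    def feature_ids(self) -> pd.Index:
        return self.features.index

    @property
    def injections(self) -> pd.Index:
        return self.intensities.columns

    @property
    def polarity(self) -> str:
        pol = self.mode.rsplit("_", 1)[-1]
        if pol not in ("pos", "neg"):
            raise ValueError(f"mode {self.mode!r} does not end in _pos/_neg")
        return pol

    def subset_features(self, ids) -> "FeatureTable":
        ids = pd.Index(ids)
        return FeatureTable(self.features.loc[ids], self.intensities.loc[ids], self.mode)

    def subset_injections(self, injections) -> "FeatureTable":
        return FeatureTable(self.features, self.intensities[list(injections)], self.mode)

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.features.copy(), self.intensities.copy(), self.mode)


@dataclass
class SampleMetadata:
    """Injection-level study metadata (roles, conditions, times, replicates)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in _META_COLUMNS if c not in t.columns]
        if missing:
            raise ValueError(f"metadata missing columns {missing}")
        if t["injection_id"].duplicated().any():
            raise ValueError("duplicate injection id in metadata")
        bad_role = set(t["role"]) - set(ROLES)
        if bad_role:
            raise ValueError(f"unknown roles {sorted(bad_role)}")
        bad_cond = set(t["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise ValueError(f"unknown conditions {sorted(bad_cond)}")
        samp = t[t["role"] == "sample"]
        if (samp["condition"] == "none").any():
            raise ValueError("analytical samples must have condition control/treated")
        if samp["time_h"].isna().any():
            raise ValueError("analytical samples must have a time point")
        qc = t[t["role"] != "sample"]
        if (qc["condition"] != "none").any():
            raise ValueError("blanks/pools must have condition 'none'")
        self.table = t.reset_index(drop=True)

    def _ids(self, role: str) -> list[str]:
        return self.table.loc[self.table["role"] == role, "injection_id"].tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self._ids("sample")

    @property
    def blank_ids(self) -> list[str]:
        return self._ids("blank")

    @property
    def pool_ids(self) -> list[str]:
        return self._ids("pool")

    def sample_ids_at(self, time_h: float, condition: str) -> list[str]:
        t = self.table
        sel = (t["role"] == "sample") & (t["condition"] == condition) & (t["time_h"] == time_h)
        return t.loc[sel, "injection_id"].tolist()

    @property
    def time_points(self) -> list[float]:
        t = self.table
        return sorted(t.loc[t["role"] == "sample", "time_h"].unique())

    def condition_time_of(self, injection_id: str) -> tuple[str, float]:
        row = self.table.set_index("injection_id").loc[injection_id]
        return row["condition"], row["time_h"]


@dataclass
class CellCounts:
    """Mean viable cell numbers per (condition, time_h) group."""

    table: pd.DataFrame  # columns: condition, time_h, mean_cells

    def __post_init__(self) -> None:
        for col in ("condition", "time_h", "mean_cells"):
            if col not in self.table.columns:
                raise ValueError(f"cell counts missing column {col!r}")
        if (self.table["mean_cells"] <= 0).any():
            raise ValueError("cell counts must be positive")
        if self.table.duplicated(["condition", "time_h"]).any():
            raise ValueError("duplicate (condition, time_h) in cell counts")

    def lookup(self, condition: str, time_h: float) -> float:
        t = self.table
        sel = (t["condition"] == condition) & (t["time_h"] == time_h)
        if not sel.any():
            raise KeyError(f"no cell count for {condition}/{time_h}")
        return float(t.loc[sel, "mean_cells"].iloc[0])

    def has(self, condition: str, time_h: float) -> bool:
        t = self.table
        return bool(((t["condition"] == condition) & (t["time_h"] == time_h)).any())


@dataclass
class CompoundTable:
    """Reference compounds for annotation.

    ``table`` columns: ``name``, ``neutral_mass`` (u, > 0), optional
    ``rt_s`` (reference retention time, NaN when absent), optional ``ms2``
    (reference peak list), optional ``ms2_db`` (bool: a database MS2
    spectrum exists).  MS2 peak lists are lists of ``(mz, relative
    intensity)`` with relative intensities in (0, 1].
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.copy()
        for col in ("name", "neutral_mass"):
            if col not in t.columns:
                raise ValueError(f"compound table missing column {col!r}")
        if len(t) and (t["neutral_mass"] <= 0).any():
            raise ValueError("neutral masses must be positive")
        if "rt_s" not in t.columns:
            t["rt_s"] = np.nan
        if "ms2" not in t.columns:
            t["ms2"] = None
        if "ms2_db" not in t.columns:
            t["ms2_db"] = False
        for peaks in t["ms2"]:
            if peaks:
                for _, rel in peaks:
                    if not (0.0 < rel <= 1.0):
                        raise ValueError("MS2 relative intensities must be in (0, 1]")
        self.table = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# feature table I/O


def write_feature_table(table: FeatureTable, path) -> None:
    """Write a feature table as TSV (full float precision, round-trip safe)."""
    df = table.features[["mz", "rt"]].copy()
    df = pd.concat([df, table.intensities], axis=1)
    df.index.name = "feature_id"
    with open(path, "w") as fh:
        fh.write(f"#mode={table.mode}\n")
        df.to_csv(fh, sep="\t", float_format="%.12g")


def read_feature_table(path) -> FeatureTable:
    """Read a feature table written by :func:`write_feature_table`.

    Raises
    ------
    FeatureTableError
        On duplicate ids, negative intensities or missing columns; malformed
        rows are reported with their (1-based) line number.
    """
    mode = "RP_pos"
    with open(path) as fh:
        first = fh.readline()
        header_offset = 1
        if first.startswith("#mode="):
            mode = first.strip().split("=", 1)[1]
            body = fh.read()
            header_offset = 2
        else:
            body = first + fh.read()
    df = pd.read_csv(_io.StringIO(body), sep="\t", dtype={"feature_id": str})
    for col in ("feature_id", "mz", "rt"):
        if col not in df.columns:
            raise FeatureTableError(f"{path}: missing column {col!r}")
    value_cols = [c for c in df.columns if c not in ("feature_id", "mz", "rt")]
    values = df[value_cols]
    bad = values.isna().any(axis=1) | df[["mz", "rt"]].isna().any(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + header_offset + 1
        raise FeatureTableError(f"{path}: malformed row at line {row}")
    if df["feature_id"].duplicated().any():
        dup = df.loc[df["feature_id"].duplicated(), "feature_id"].iloc[0]
        raise FeatureTableError(f"{path}: duplicate feature id {dup!r}")
    features = df.set_index("feature_id")[["mz", "rt"]]
    intensities = df.set_index("feature_id")[value_cols].astype(float)
    return FeatureTable(features, intensities, mode)


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.table.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype={"injection_id": str})
    return SampleMetadata(df)


def write_cell_counts(counts: CellCounts, path) -> None:
    counts.table.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_cell_counts(path) -> CellCounts:
    return CellCounts(pd.read_csv(path, sep="\t"))


def _format_ms2(peaks) -> str:
    if not peaks:
        return ""
    return ";".join(f"{mz:.6f}:{rel:.6g}" for mz, rel in peaks)


def _parse_ms2(text) -> list | None:
    if not isinstance(text, str) or not text.strip():
        return None
    out = []
    for part in text.strip().split(";"):
        mz, rel = part.split(":")
        out.append((float(mz), float(rel)))
    return out


def write_compound_table(compounds: CompoundTable, path) -> None:
    df = compounds.table.copy()
    df["ms2"] = [_format_ms2(p) for p in df["ms2"]]
    df["ms2_db"] = df["ms2_db"].astype(int)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_compound_table(path) -> CompoundTable:
    df = pd.read_csv(path, sep="\t")
    if "ms2" in df.columns:
        df["ms2"] = [_parse_ms2(v) for v in df["ms2"]]
    if "ms2_db" in df.columns:
        df["ms2_db"] = df["ms2_db"].fillna(0).astype(bool)
    return CompoundTable(df)


# ---------------------------------------------------------------------------
# minimal mzTab-M small-molecule summary reader


def read_mztab_sml(path, mode: str = "RP_pos") -> FeatureTable:
    """Read a minimal mzTab-M small-molecule (SML) summary into a FeatureTable.

    Only the ``SMH``/``SML`` lines are consulted; the required columns are
    ``SML_ID``, ``exp_mass_to_charge``, ``retention_time`` and any number of
    ``abundance_assay[...]`` columns.
    """
    header: list[str] | None = None
    rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "SMH":
                header = parts[1:]
            elif parts[0] == "SML":
                if header is None:
                    raise FeatureTableError(f"{path}: SML row before SMH header")
                rows.append(parts[1:])
    if header is None:
        raise FeatureTableError(f"{path}: no SMH header line found")
    df = pd.DataFrame(rows, columns=header)
    for col in ("SML_ID", "exp_mass_to_charge", "retention_time"):
        if col not in df.columns:
            raise FeatureTableError(f"{path}: missing SML column {col!r}")
    abundance = [c for c in df.columns if c.startswith("abundance_assay")]
    if not abundance:
        raise FeatureTableError(f"{path}: no abundance_assay columns")
    features = pd.DataFrame(
        {
            "mz": df["exp_mass_to_charge"].astype(float).to_numpy(),
            "rt": df["retention_time"].astype(float).to_numpy(),
        },
        index=pd.Index(df["SML_ID"].astype(str), name="feature_id"),
    )
    intensities = df[abundance].astype(float)
    intensities.index = features.index
    intensities.columns = [c[len("abundance_") :] for c in abundance]
    return FeatureTable(features, intensities, mode)


# ---------------------------------------------------------------------------
# design validation


@dataclass
class ValidationReport:
    """Findings from checking table/metadata/cell-count consistency."""

    fatal: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.fatal


def validate_design(table: FeatureTable, meta: SampleMetadata, counts: CellCounts | None = None) -> ValidationReport:
    """Cross-check a feature table against metadata and cell counts.

    Report-only: returns every finding rather than raising.  The pipeline
    refuses to run a dataset whose report has fatal findings.
    """
    report = ValidationReport()
    meta_ids = set(meta.table["injection_id"])
    table_ids = set(table.injections)
    for inj in sorted(table_ids - meta_ids):
        report.fatal.append(f"injection {inj!r} in table but missing from metadata")
    for inj in sorted(meta_ids - table_ids):
        report.fatal.append(f"injection {inj!r} in metadata but absent from table")
    for role, ids in (("sample", meta.sample_ids), ("blank", meta.blank_ids), ("pool", meta.pool_ids)):
        if not ids:
            level = report.fatal if role == "sample" else report.warnings
            level.append(f"no {role} injections in metadata")
    if counts is not None:
        samp = meta.table[meta.table["role"] == "sample"]
        for (cond, t), _ in samp.groupby(["condition", "time_h"]):
            if not counts.has(cond, t):
                report.fatal.append(f"no cell count for {cond}/{t:g}")
    return report
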