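"""Mass-based feature matching and identification-level annotation.

Features from different separation/polarity datasets are compared through
their inferred neutral mass (assuming protonation/deprotonation as the only
adducts) at a +/-5 ppm tolerance; the same tolerance drives compound
look-ups against a user-supplied reference table.  Identification
confidence follows the community reporting levels: level 1 (reference
substance confirms both retention time and MS2), level 1a (reference
retention time only), level 2 (MS2 match against a spectral database
without a reference substance), and "putative" (exact mass only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CompoundTable, FeatureTable
from .simulate import ADDUCT_OFFSETS


def ppm_error(observed_mass: float, reference_mass: float) -> float:
    """Relative mass deviation in parts per million."""
    if reference_mass <= 0:
        raise ValueError("reference mass must be positive")
    return 1e6 * (observed_mass - reference_mass) / reference_mass


def neutral_mass(mz: float, polarity: str | None = None, adduct: str | None = None) -> float:
    """Neutral monoisotopic mass from an observed m/z.

    Either an explicit adduct label or a polarity (mapped to [M+H]+ /
    [M-H]-) must be given.
    """
    if adduct is None:
        if polarity == "pos":
            adduct = "[M+H]+"
        elif polarity == "neg":
            adduct = "[M-H]-"
        else:
            raise ValueError(f"unknown polarity {polarity!r}")
    if adduct not in ADDUCT_OFFSETS:
        raise ValueError(f"unknown adduct {adduct!r}")
    offset = ADDUCT_OFFSETS[adduct]
    if mz <= offset:
        raise ValueError("m/z must exceed the adduct offset")
    return mz - offset


def mz_from_neutral(mass: float, polarity: str | None = None, adduct: str | None = None) -> float:
    """Inverse of :func:`neutral_mass`."""
    if adduct is None:
        adduct = "[M+H]+" if polarity == "pos" else "[M-H]-"
    if adduct not in ADDUCT_OFFSETS:
        raise ValueError(f"unknown adduct {adduct!r}")
    return mass + ADDUCT_OFFSETS[adduct]


@dataclass
class MassMatch:
    """A feature matched to another feature or to a compound by mass."""

    query: str
    target: str
    ppm: float
    adduct: str


@dataclass
class CrossModeMatches:
    """Cross-dataset mass matching: pairwise matches, mass clusters and
    Venn-region counts keyed by frozenset of dataset labels."""

    matches: list
    clusters: list  # list of dict mode -> [feature ids]
    venn: dict  # frozenset(modes) -> count

    def n_shared(self, *modes) -> int:
        want = set(modes)
        return sum(c for k, c in self.venn.items() if want <= set(k)) if modes else 0


def cross_mode_match(tables, tol_ppm: float = 5.0) -> CrossModeMatches:
    """Match features across datasets by inferred neutral mass.

    Features whose neutral masses agree within ``tol_ppm`` are linked;
    connected components form mass clusters, and each cluster contributes
    one count to the Venn region of the dataset set it spans.
    """
    tables = list(tables)
    if len(tables) < 2:
        raise ValueError("cross-mode matching needs at least 2 tables")
    entries = []  # (neutral mass, mode, feature id)
    for t in tables:
        pol = t.polarity
        for fid, mz in t.features["mz"].items():
            entries.append((neutral_mass(mz, pol), t.mode, fid))
    entries.sort()
    n = len(entries)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    matches = []
    for i in range(n):
        mi, modei, fidi = entries[i]
        for j in range(i + 1, n):
            mj, modej, fidj = entries[j]
            err = ppm_error(mj, mi)
            if err > tol_ppm:
                break
            if modei != modej:
                matches.append(MassMatch(fidi, fidj, err, "neutral-mass"))
            union(i, j)

    groups: dict[int, dict] = {}
    for i, (mass, mode, fid) in enumerate(entries):
        groups.setdefault(find(i), {}).setdefault(mode, []).append(fid)
    clusters = list(groups.values())
    venn: dict[frozenset, int] = {}
    for c in clusters:
        key = frozenset(c)
        venn[key] = venn.get(key, 0) + 1
    return CrossModeMatches(matches, clusters, venn)


def ms2_similarity(spec_a, spec_b, frag_tol_u: float = 0.01) -> float:
    """Normalized dot-product similarity of two MS2 peak lists.

    Peaks are paired greedily by smallest m/z difference within
    ``frag_tol_u``; intensities are square-root weighted; the score is the
    cosine of the aligned weight vectors, in [0, 1].
    """
    a = [(float(mz), float(i)) for mz, i in spec_a]
    b = [(float(mz), float(i)) for mz, i in spec_b]
    if not a or not b:
        raise ValueError("empty MS2 spectrum")
    candidates = []
    for i, (mza, _) in enumerate(a):
        for j, (mzb, _) in enumerate(b):
            d = abs(mza - mzb)
            if d <= frag_tol_u:
                candidates.append((d, i, j))
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for _, i, j in candidates:
        if i not in used_a and j not in used_b:
            pairs.append((i, j))
            used_a.add(i)
            used_b.add(j)
    wa = np.sqrt([i for _, i in a])
    wb = np.sqrt([i for _, i in b])
    num = sum(wa[i] * wb[j] for i, j in pairs)
    denom = np.linalg.norm(wa) * np.linalg.norm(wb)
    return float(num / denom) if denom > 0 else 0.0


LEVELS = ("1", "1a", "2", "putative")


def assign_level(
    mass_match: bool,
    ms2_db_match: bool = False,
    ref_rt_match: bool = False,
    ref_ms2_match: bool = False,
) -> str:
    """Identification confidence from the evidence flags.

    Reference substance confirming RT and MS2 -> level 1; RT only -> 1a;
    database MS2 match without a reference substance -> 2; exact mass
    only -> putative.  A mass match is prerequisite for any level.
    """
    if not mass_match:
        raise ValueError("a mass match is prerequisite for any identification level")
    if ref_rt_match and ref_ms2_match:
        return "1"
    if ref_rt_match:
        return "1a"
    if ms2_db_match:
        return "2"
    return "putative"


@dataclass
class AnnotationRecord:
    """A feature-to-compound assignment with its evidence trail."""

    feature_id: str
    compound: str
    ppm: float
    adduct: str
    mass_match: bool = True
    ms2_db_match: bool = False
    ref_rt_match: bool = False
    ref_ms2_match: bool = False
    level: str = "putative"
    ambiguous: bool = False


def annotate_features(
    table: FeatureTable,
    compounds: CompoundTable,
    tol_ppm: float = 5.0,
    rt_tol_s: float = 18.0,
    ms2_threshold: float = 0.70,
    feature_ms2: dict | None = None,
    frag_tol_u: float = 0.01,
) -> list:
    """Annotate features against a compound reference table.

    Every compound within ``tol_ppm`` of a feature's neutral mass yields a
    record; multiple hits on one feature are ranked by \\|ppm\\| and flagged
    ambiguous.  Retention-time evidence requires a reference RT within
    ``rt_tol_s`` (default 0.3 min); MS2 evidence requires a similarity of at
    least ``ms2_threshold`` against the reference (level 1) or database
    (level 2) spectrum, compared from ``feature_ms2`` (feature id -> peak
    list) when provided.
    """
    feature_ms2 = feature_ms2 or {}
    polarity = table.polarity
    records: list[AnnotationRecord] = []
    comp = compounds.table
    for fid, row in table.features.iterrows():
        nm = neutral_mass(row["mz"], polarity)
        hits = []
        for rec in comp.itertuples(index=False):
            err = ppm_error(nm, rec.neutral_mass)
            if abs(err) <= tol_ppm:
                hits.append((abs(err), err, rec))
        hits.sort(key=lambda h: h[0])
        for _, err, rec in hits:
            ref_rt = bool(np.isfinite(rec.rt_s) and abs(row["rt"] - rec.rt_s) <= rt_tol_s)
            spec = feature_ms2.get(fid)
            ref_ms2 = bool(
                rec.ms2 and spec and ms2_similarity(spec, rec.ms2, frag_tol_u) >= ms2_threshold
            )
            # database MS2 evidence counts only without a reference substance
            db_ms2 = bool(rec.ms2_db and spec and rec.ms2 and not (ref_rt or ref_ms2)
                          and ms2_similarity(spec, rec.ms2, frag_tol_u) >= ms2_threshold)
            level = assign_level(True, db_ms2, ref_rt, ref_ms2)
            records.append(
                AnnotationRecord(
                    feature_id=fid,
                    compound=rec.name,
                    ppm=err,
                    adduct="[M+H]+" if polarity == "pos" else "[M-H]-",
                    ms2_db_match=db_ms2,
                    ref_rt_match=ref_rt,
                    ref_ms2_match=ref_ms2,
                    level=level,
                    ambiguous=len(hits) > 1,
                )
            )
    return records


def annotations_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.feature_id, r.compound, r.ppm, r.adduct, r.mass_match, r.ms2_db_match,
             r.ref_rt_match, r.ref_ms2_match, r.level, r.ambiguous)
            for r in records
        ],
        columns=[
            "feature_id", "compound", "ppm", "adduct", "mass_match", "ms2_db_match",
            "ref_rt_match", "ref_ms2_match", "level", "ambiguous",
        ],
    )
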