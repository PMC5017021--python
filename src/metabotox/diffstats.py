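"""Per-timepoint moderated differential analysis of normalized feature
tables.

Each time point is analysed as an independent two-group (control vs
treated) contrast on log2-transformed intensities.  Per-feature residual
variances are shrunk toward a common prior by empirical Bayes: the observed
variances s^2 (d residual degrees of freedom each) are modelled as scaled-F
draws around a prior variance s0^2 with d0 prior degrees of freedom, the
hyperparameters are estimated by moment-matching on log s^2 (digamma /
trigamma method), and the moderated t statistic uses the posterior variance

    s^2_post = (d0 * s0^2 + d * s^2) / (d0 + d)

with d0 + d degrees of freedom.  Two-sided p-values are corrected across
features by Benjamini-Hochberg step-up within each time point.

Zero intensities are left-censored observations (below the detection
floor).  Before the log transform they are replaced by a pseudo-area of
half the smallest non-zero value of their injection column, and a feature
is only tested at a time point where it has at least two observed
(non-zero) values in each group: constant imputation of a fully censored
group would fabricate a near-zero variance and an artefactual fold change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .io import FeatureTable, SampleMetadata


@dataclass
class ModerationParams:
    """Empirical-Bayes hyperparameters: prior df ``d0`` (may be inf) and
    prior variance ``s0_sq``."""

    d0: float
    s0_sq: float


def log2fc(treated_mean: float, control_mean: float) -> float:
    """log2 of the treated/control mean ratio (the fold-change convention
    in which a 14-fold increase maps to log2fc ~ 3.807)."""
    if treated_mean <= 0 and control_mean <= 0:
        raise ValueError("log2 fold change undefined: both means non-positive")
    return float(np.log2(treated_mean / control_mean))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Sorted ascending, ``q_(i) = min_{j >= i} (m * p_(j) / j)`` capped at 1,
    returned in the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 60) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma inverse requires y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < tol * x:
            break
    return float(x)


def estimate_prior(s2, d: float) -> ModerationParams:
    """Moment-match the prior (d0, s0^2) from per-feature variances.

    Uses the log-variance moments: with e = log s^2 - digamma(d/2) +
    log(d/2), the excess variance of e over trigamma(d/2) identifies
    trigamma(d0/2) and hence d0; the mean of e then identifies s0^2.  When
    the excess variance is non-positive (variances essentially equal) the
    prior degrees of freedom are infinite and s0^2 is the harmonized mean
    level exp(mean(e)).
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 2:
        raise ValueError("prior estimation needs at least 2 positive variances")
    e = np.log(s2) - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, d / 2.0)
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0_sq = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0_sq = np.exp(emean)
    return ModerationParams(float(d0), float(s0_sq))


def moderated_t(delta, s2, d: float, n1: int, n2: int, params: ModerationParams):
    """Moderated t statistics and two-sided p-values for mean differences.

    ``params.d0`` may be 0 (classical pooled t), finite, or inf (all
    variances shrunk fully to the prior, normal reference distribution in
    the limit of infinite total df).
    """
    s2 = np.asarray(s2, dtype=float)
    delta = np.asarray(delta, dtype=float)
    d0 = params.d0
    if np.isinf(d0):
        s2_post = np.full_like(s2, params.s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * params.s0_sq + d * s2) / (d0 + d)
        df_total = d0 + d
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / se
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return t, p, s2_post, df_total


@dataclass
class DifferentialResults:
    """Results of per-timepoint moderated two-group contrasts.

    ``table`` columns: feature_id, time_h, mean_control, mean_treated,
    log2fc, s2, s2_post, t, p, q.  ``params`` maps time point to the
    estimated :class:`ModerationParams`.
    """

    table: pd.DataFrame
    params: dict
    alpha: float = 0.05

    def at_time(self, time_h: float) -> pd.DataFrame:
        return self.table[self.table["time_h"] == time_h].set_index("feature_id")

    def count_significant(self, alpha: float | None = None, on: str = "q") -> pd.Series:
        """Number of features with q (or raw p) strictly below alpha per
        time point."""
        alpha = self.alpha if alpha is None else alpha
        if on not in ("p", "q"):
            raise ValueError("on must be 'p' or 'q'")
        t = self.table
        counts = (
            t.assign(sig=t[on] < alpha)
            .groupby("time_h", sort=True)["sig"]
            .sum()
            .astype(int)
        )
        counts.name = f"n_significant_{on}<{alpha:g}"
        return counts

    def summary(self, top: int = 10) -> str:
        lines = ["Moderated differential analysis (control vs treated per time point)", ""]
        for t, pars in sorted(self.params.items()):
            d0 = "inf" if np.isinf(pars.d0) else f"{pars.d0:.2f}"
            n_sig = int((self.at_time(t)["q"] < self.alpha).sum())
            lines.append(
                f"  t={t:g} h: d0={d0}, s0^2={pars.s0_sq:.4g}, "
                f"q<{self.alpha:g}: {n_sig} features"
            )
        lines.append("")
        sub = self.table.nsmallest(top, "q")[
            ["feature_id", "time_h", "log2fc", "t", "p", "q"]
        ]
        lines.append(sub.to_string(index=False))
        return "\n".join(lines)


class ModeratedDifferential:
    """Model object for per-timepoint moderated differential analysis.

    Parameters
    ----------
    table : FeatureTable
        Normalized feature table (area per cell).
    meta : SampleMetadata
        Injection metadata; only analytical samples are used.
    transform : {"log2", "none"}
        Intensity transform before linear modelling.
    pseudo : float, optional
        Replacement for zero intensities before the log transform.  By
        default each injection column uses half its own smallest non-zero
        value: zeros are left-censored at the detection limit, and after
        per-column normalization that limit lives on a column-specific
        scale, which the column minimum tracks.
    """

    def __init__(
        self,
        table: FeatureTable,
        meta: SampleMetadata,
        transform: str = "log2",
        pseudo: float | None = None,
        min_observed_per_group: int = 2,
    ):
        if transform not in ("log2", "none"):
            raise ValueError("transform must be 'log2' or 'none'")
        self.table = table
        self.meta = meta
        self.transform = transform
        self.min_observed_per_group = min_observed_per_group
        sample_vals = table.intensities[meta.sample_ids].to_numpy(dtype=float)
        positive = sample_vals[sample_vals > 0]
        global_half_min = float(positive.min()) / 2.0 if positive.size else 1.0
        if pseudo is None:
            self.pseudo = global_half_min
            self._column_pseudo = {}
            for inj in meta.sample_ids:
                col = table.intensities[inj].to_numpy(dtype=float)
                pos = col[col > 0]
                self._column_pseudo[inj] = float(pos.min()) / 2.0 if pos.size else global_half_min
        else:
            self.pseudo = float(pseudo)
            self._column_pseudo = {inj: float(pseudo) for inj in meta.sample_ids}

    def _transformed(self, columns) -> np.ndarray:
        vals = self.table.intensities[list(columns)].to_numpy(dtype=float)
        if self.transform == "log2":
            fill = np.array([self._column_pseudo[c] for c in columns])
            vals = np.where(vals > 0, vals, fill[None, :])
            vals = np.log2(vals)
        return vals

    def fit_timepoint(self, time_h: float) -> tuple[pd.DataFrame, ModerationParams]:
        """Fit the two-group contrast at one time point."""
        ctrl = self.meta.sample_ids_at(time_h, "control")
        trt = self.meta.sample_ids_at(time_h, "treated")
        if len(ctrl) < 2 or len(trt) < 2:
            raise ValueError(f"need >= 2 replicates per group at t={time_h:g} h")
        # minimum-quantified-values rule: skip features a group of which is
        # (almost) entirely below the detection floor at this time point
        obs_c = (self.table.intensities[ctrl].to_numpy() > 0).sum(axis=1)
        obs_t = (self.table.intensities[trt].to_numpy() > 0).sum(axis=1)
        testable = (obs_c >= self.min_observed_per_group) & (obs_t >= self.min_observed_per_group)
        xc = self._transformed(ctrl)[testable]
        xt = self._transformed(trt)[testable]
        feature_ids = self.table.feature_ids[testable]
        n1, n2 = xt.shape[1], xc.shape[1]
        mean_c = xc.mean(axis=1)
        mean_t = xt.mean(axis=1)
        d = n1 + n2 - 2
        ss = xc.var(axis=1, ddof=1) * (n2 - 1) + xt.var(axis=1, ddof=1) * (n1 - 1)
        s2 = ss / d
        if np.all(s2 <= 0):
            raise ValueError("zero residual variance in every feature")
        params = estimate_prior(s2, d)
        delta = mean_t - mean_c
        if self.transform == "log2":
            lfc = delta
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                lfc = np.log2(mean_t / mean_c)
        t, p, s2_post, _ = moderated_t(delta, s2, d, n1, n2, params)
        q = bh_adjust(p)
        frame = pd.DataFrame(
            {
                "feature_id": feature_ids,
                "time_h": time_h,
                "mean_control": mean_c,
                "mean_treated": mean_t,
                "log2fc": lfc,
                "s2": s2,
                "s2_post": s2_post,
                "t": t,
                "p": p,
                "q": q,
            }
        )
        return frame, params

    def fit(self, time_points=None, alpha: float = 0.05) -> DifferentialResults:
        """Fit every requested time point (default: all with both groups)."""
        if time_points is None:
            time_points = [
                t
                for t in self.meta.time_points
                if self.meta.sample_ids_at(t, "control") and self.meta.sample_ids_at(t, "treated")
            ]
        frames = []
        params = {}
        for t in time_points:
            frame, pars = self.fit_timepoint(t)
            frames.append(frame)
            params[t] = pars
        return DifferentialResults(pd.concat(frames, ignore_index=True), params, alpha)


def fit_moderated(
    table: FeatureTable, meta: SampleMetadata, time_h: float, transform: str = "log2", pseudo: float | None = None
) -> tuple[pd.DataFrame, ModerationParams]:
    """Functional wrapper: one time point's moderated contrast."""
    return ModeratedDifferential(table, meta, transform, pseudo).fit_timepoint(time_h)


def count_significant(results: DifferentialResults, alpha: float = 0.05, on: str = "q") -> pd.Series:
    """Per-timepoint counts of significant features (q < alpha by default)."""
    return results.count_significant(alpha, on)
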