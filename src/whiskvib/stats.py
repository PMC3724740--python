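"""Group statistics for the species x angle study tables.

The core analysis is a mixed-design (split-plot) two-factor repeated-measures
ANOVA: species is a between-subject factor, angle of orientation a
within-subject factor, and every retained subject is measured at every angle.
The sums of squares decompose exactly:

    between-subject part:  species + subjects-within-species
    within-subject part:   angle + species x angle + residual

with species tested against the subjects-within-species mean square and the
within-subject terms tested against the residual (angle x subject within
species) mean square — the convention of standard commercial packages for
this design.  Unequal species sizes are handled by group-size-weighted
subject-mean decomposition, which keeps the sums of squares additive and
reproduces the (2, 2, 4, N-g, (N-g)(k-1)) degree-of-freedom layout.

Tukey HSD post-hoc comparisons are run within each species over angle pairs,
using the pooled within-subject residual mean square and the studentized
range distribution.  Simple OLS regressions of frequency/velocity on sample
length and per-cell summaries (mean, SE, range) round out the analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaTable",
    "TukeyResult",
    "RegressionResult",
    "InsufficientDataError",
    "UnbalancedDataError",
    "enforce_complete_cases",
    "mixed_anova",
    "tukey_within_species",
    "length_regression",
    "summarize_groups",
]

REQUIRED_COLUMNS = (
    "subject_id",
    "species",
    "angle_deg",
    "peak_freq_hz",
    "peak_vel_m_s",
    "length_cm",
)


class InsufficientDataError(ValueError):
    """Too few subjects (or lengths) remain for the requested analysis."""


class UnbalancedDataError(ValueError):
    """Subjects do not all share the same angle levels; run
    :func:`enforce_complete_cases` first."""


@dataclass
class AnovaTable:
    """Mixed-design ANOVA decomposition, one row per source of variation."""

    table: pd.DataFrame  # index: source; columns: SS, DF, MS, F, DFn, DFd, p
    dv: str

    def row(self, source: str) -> pd.Series:
        return self.table.loc[source]

    @property
    def ms_residual(self) -> float:
        return float(self.table.loc["residual", "MS"])

    @property
    def df_residual(self) -> int:
        return int(self.table.loc["residual", "DF"])


@dataclass
class TukeyResult:
    table: pd.DataFrame  # columns: species, angle_1, angle_2, mean_diff, p_adj
    dv: str


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int


def enforce_complete_cases(
    table: pd.DataFrame, angles: tuple = (0, 45, 90)
) -> tuple[pd.DataFrame, list[str]]:
    """Drop subjects missing any angle level (repeated-measures requirement).

    Returns the filtered table and the list of removed subject ids.  Raises
    :class:`InsufficientDataError` if any species retains fewer than 2
    subjects.
    """
    wanted = set(angles)
    keep, removed = [], []
    for sid, grp in table.groupby("subject_id", sort=False):
        (keep if set(grp["angle_deg"]) >= wanted else removed).append(sid)
    out = table[table["subject_id"].isin(keep)].reset_index(drop=True)
    counts = out.groupby("species")["subject_id"].nunique()
    low = counts[counts < 2]
    if len(out) == 0 or len(low):
        raise InsufficientDataError(
            f"fewer than 2 complete subjects remain for: {', '.join(low.index) or 'all species'}"
        )
    return out, removed


def _pivot(table: pd.DataFrame, dv: str):
    """Subjects x angles value matrix plus per-subject species labels."""
    angles = sorted(table["angle_deg"].unique())
    wide = table.pivot_table(
        index="subject_id", columns="angle_deg", values=dv, aggfunc="mean"
    )
    if wide.isna().any().any():
        raise UnbalancedDataError(
            "every subject must have a value at every angle; "
            "run enforce_complete_cases first"
        )
    species = table.drop_duplicates("subject_id").set_index("subject_id")["species"]
    species = species.loc[wide.index]
    return wide[angles].to_numpy(float), species.to_numpy(), angles


def mixed_anova(table: pd.DataFrame, dv: str = "peak_freq_hz") -> AnovaTable:
    """Mixed-design two-factor repeated-measures ANOVA.

    Species (between subjects) is tested against subjects-within-species;
    angle and the species x angle interaction (within subjects) against the
    angle x subject residual.  The subjects term itself is also reported with
    an F against the residual.
    """
    Y, species, angles = _pivot(table, dv)
    n_subj, k = Y.shape
    if k < 2:
        raise UnbalancedDataError("need at least 2 angle levels")
    groups = pd.unique(species)
    g = len(groups)
    gm = Y.mean()

    subj_means = Y.mean(axis=1)
    ss_between = k * float(((subj_means - gm) ** 2).sum())
    ss_species = 0.0
    for sp in groups:
        m = subj_means[species == sp]
        ss_species += k * m.size * (m.mean() - gm) ** 2
    ss_subjects = ss_between - ss_species

    D = Y - subj_means[:, None]  # within-subject deviations
    angle_dev = D.mean(axis=0)
    ss_angle = n_subj * float((angle_dev**2).sum())
    ss_inter = 0.0
    ss_resid = 0.0
    for sp in groups:
        Dg = D[species == sp]
        cell = Dg.mean(axis=0)
        ss_inter += Dg.shape[0] * float(((cell - angle_dev) ** 2).sum())
        ss_resid += float(((Dg - cell) ** 2).sum())

    df = {
        "angle": k - 1,
        "species": g - 1,
        "interaction": (g - 1) * (k - 1),
        "subjects": n_subj - g,
        "residual": (n_subj - g) * (k - 1),
    }
    ss = {
        "angle": ss_angle,
        "species": ss_species,
        "interaction": ss_inter,
        "subjects": ss_subjects,
        "residual": ss_resid,
    }
    if g == 1:  # one-way repeated-measures reduction
        terms = ("angle", "subjects", "residual")
        for t in ("species", "interaction"):
            del df[t], ss[t]
    else:
        terms = ("angle", "species", "interaction", "subjects", "residual")
    ms = {t: ss[t] / df[t] for t in ss}
    rows = []
    error_term = {
        "angle": "residual",
        "species": "subjects",
        "interaction": "residual",
        "subjects": "residual",
    }
    for term in terms:
        if term == "residual":
            rows.append(dict(source=term, SS=ss[term], DF=df[term], MS=ms[term],
                             F=np.nan, DFn=np.nan, DFd=np.nan, p=np.nan))
            continue
        err = error_term[term]
        if ms[err] == 0:  # degenerate (e.g. constant data): F undefined
            F, p = np.nan, np.nan
        else:
            F = ms[term] / ms[err]
            p = float(sps.f.sf(F, df[term], df[err]))
        rows.append(dict(source=term, SS=ss[term], DF=df[term], MS=ms[term],
                         F=F, DFn=df[term], DFd=df[err], p=p))
    out = pd.DataFrame(rows).set_index("source")
    return AnovaTable(table=out, dv=dv)


def tukey_within_species(
    table: pd.DataFrame, dv: str, anova: AnovaTable
) -> TukeyResult:
    """Tukey HSD over angle pairs within each species.

    Uses the pooled within-subject residual mean square from ``anova`` and
    the studentized range distribution with k = number of angles.  The mean
    difference is first angle minus second angle of each ordered pair.
    """
    Y, species, angles = _pivot(table, dv)
    k = len(angles)
    ms_err, df_err = anova.ms_residual, anova.df_residual
    rows = []
    for sp in pd.unique(species):
        Yg = Y[species == sp]
        n = Yg.shape[0]
        means = Yg.mean(axis=0)
        for i in range(k):
            for j in range(i + 1, k):
                diff = means[i] - means[j]
                se = math.sqrt(ms_err / n)
                q = abs(diff) / se
                p = float(sps.studentized_range.sf(q, k, df_err))
                rows.append(
                    dict(
                        species=sp,
                        angle_1=angles[i],
                        angle_2=angles[j],
                        mean_diff=diff,
                        p_adj=min(1.0, p),
                    )
                )
    return TukeyResult(table=pd.DataFrame(rows), dv=dv)


def length_regression(
    table: pd.DataFrame, dv: str = "peak_freq_hz", per_subject: bool = True
) -> RegressionResult:
    """OLS of the dependent variable on sample length (cm).

    With ``per_subject`` (default) the regression runs on one point per
    subject (the subject's mean across angles), so n equals the number of
    individuals sampled.
    """
    if per_subject:
        data = table.groupby("subject_id").agg({dv: "mean", "length_cm": "first"})
    else:
        data = table[[dv, "length_cm"]]
    x = data["length_cm"].to_numpy(float)
    y = data[dv].to_numpy(float)
    if np.unique(x).size < 3:
        raise InsufficientDataError("need >= 3 distinct length values")
    if np.ptp(x) == 0 or np.var(x) == 0:
        raise InsufficientDataError("length has zero variance")
    fit = sps.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n=x.size,
    )


def summarize_groups(table: pd.DataFrame, dv: str) -> pd.DataFrame:
    """Per species x angle cell: n, mean, SE (SD/sqrt(n)), min, max.

    Single-value cells report SE 0 with ``se_flagged`` set.
    """
    rows = []
    for (sp, ang), grp in table.groupby(["species", "angle_deg"]):
        vals = grp[dv].to_numpy(float)
        n = vals.size
        se = float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
        rows.append(
            dict(
                species=sp,
                angle_deg=ang,
                n=n,
                mean=float(vals.mean()),
                se=se,
                min=float(vals.min()),
                max=float(vals.max()),
                se_flagged=n <= 1,
            )
        )
    return pd.DataFrame(rows)
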