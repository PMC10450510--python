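"""Statistics over electron-microscopic synapse measurements.

One record is one measured active zone: a perforated synapse — a single
terminal whose active zone is split into two on the same postsynaptic
element — contributes two records sharing a synapse id.  Ratios of
perforated synapses are therefore computed over active zones, which is
the arithmetic that reproduces the printed group percentages, while
synapse-level counts remain derivable by de-duplicating the synapse id.

Covers length summaries (mean ± SEM, median [Q1-Q3]), categorical
contingencies (chi-square / Yates / Fisher), group comparisons with a
normality gate (ANOVA vs Kruskal-Wallis + Dunn's follow-up), and the
age-vs-epilepsy multiple regression on per-patient perforation fractions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

log = logging.getLogger("epicortex")

GROUPS = ("non-epileptic", "epileptic")
REGIONS = ("SPA", "NoSPA")
TARGETS = ("spine", "dendrite", "unidentified")

RECORD_COLUMNS = ["patient_id", "group", "region", "synapse_id",
                  "active_zone_length_um", "perforated", "target",
                  "multi_innervated", "age"]


def validate_records(df: pd.DataFrame) -> pd.DataFrame:
    """Check the active-zone record table's invariants."""
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if (df["active_zone_length_um"] <= 0).any():
        raise ValueError("active zone lengths must be positive")
    bad = ~df["group"].isin(GROUPS) | ~df["region"].isin(REGIONS) \
        | ~df["target"].isin(TARGETS)
    if bad.any():
        raise ValueError("unknown group/region/target label")
    multi = df.groupby(["group", "synapse_id"])["perforated"].agg(["size", "all"])
    if ((multi["size"] > 1) & ~multi["all"]).any():
        raise ValueError("a synapse with multiple active zones must be perforated")
    return df


def load_records(path: str | Path) -> pd.DataFrame:
    return validate_records(pd.read_csv(path, sep="\t"))


def write_records(df: pd.DataFrame, path: str | Path) -> None:
    df[RECORD_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.6f")


def length_summary(df: pd.DataFrame, by: list[str]) -> pd.DataFrame:
    """Per-group mean ± SEM and median [Q1-Q3] of active-zone lengths."""
    rows = []
    for keys, g in df.groupby(by, sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        x = g["active_zone_length_um"].to_numpy(dtype=float)
        if x.size < 2:
            log.warning("group %s: fewer than 2 records, omitted", keys)
            continue
        rows.append(dict(zip(by, keys)) | {
            "n": x.size,
            "mean": x.mean(),
            "sem": x.std(ddof=1) / np.sqrt(x.size),
            "median": float(np.median(x)),
            "q1": float(np.percentile(x, 25)),  # linear-interpolation quantiles
            "q3": float(np.percentile(x, 75)),
        })
    return pd.DataFrame(rows)


@dataclass
class Proportion:
    count: int
    total: int

    @property
    def fraction(self) -> float:
        return self.count / self.total

    @property
    def percent(self) -> float:
        """Percentage rounded to 1 decimal, the printed convention."""
        return round(100.0 * self.count / self.total, 1)


def proportion_counts(count: int, total: int) -> Proportion:
    if total <= 0:
        raise ValueError("zero denominator")
    return Proportion(int(count), int(total))


def proportion(df: pd.DataFrame, numerator, denominator=None) -> Proportion:
    """Fraction of records matching ``numerator`` among ``denominator``.

    Predicates are callables mapping the frame to a boolean Series (or
    boolean arrays); denominator defaults to all records.
    """
    den = np.asarray(denominator(df) if callable(denominator) else (
        denominator if denominator is not None else np.ones(len(df), bool)))
    num = np.asarray(numerator(df) if callable(numerator) else numerator)
    return proportion_counts(int((num & den).sum()), int(den.sum()))


def perforated_ratio(df: pd.DataFrame, by: str | None = None):
    """Perforated active zones over all active zones (per group if asked)."""
    if by is None:
        return proportion_counts(int(df["perforated"].sum()), len(df))
    return {k: proportion_counts(int(g["perforated"].sum()), len(g))
            for k, g in df.groupby(by)}


@dataclass
class ContingencyReport:
    table: np.ndarray
    test: str
    statistic: float
    p: float
    row_proportions: np.ndarray


def contingency_test(table, method: str = "chi-square") -> ContingencyReport:
    """Association test for an r x k count table.

    ``chi-square`` (Pearson, no correction), ``chi-square+yates`` (2x2),
    or ``fisher`` (2x2 exact); two-sided p throughout.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("need a 2-D table of non-negative integers")
    props = t / t.sum(axis=1, keepdims=True)
    if method == "fisher":
        if t.shape != (2, 2):
            raise ValueError("Fisher's exact test requires a 2x2 table")
        odds, p = stats.fisher_exact(t, alternative="two-sided")
        return ContingencyReport(t.astype(int), "fisher", float(odds), float(p), props)
    correction = method == "chi-square+yates"
    if not correction and method != "chi-square":
        raise ValueError(f"unknown method {method!r}")
    res = stats.chi2_contingency(t, correction=correction)
    if (res.expected_freq < 1).any():
        warnings.warn("expected cell count < 1; consider Fisher's exact test")
    name = "chi-square+Yates" if correction else "chi-square"
    return ContingencyReport(t.astype(int), name, float(res.statistic),
                             float(res.pvalue), props)


def _dunn_pairwise(groups: dict) -> list[dict]:
    """Dunn's rank-based multiple-comparison follow-up (no extra correction).

    Standard z statistic on mean pooled ranks with tie correction.
    """
    names = list(groups)
    pooled = np.concatenate([np.asarray(groups[k], float) for k in names])
    ranks = stats.rankdata(pooled)
    n_tot = pooled.size
    # tie correction
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts).sum())) / (12.0 * (n_tot - 1))
    base_var = n_tot * (n_tot + 1) / 12.0 - tie_term
    mean_ranks, sizes, start = {}, {}, 0
    for k in names:
        n = len(groups[k])
        mean_ranks[k] = ranks[start:start + n].mean()
        sizes[k] = n
        start += n
    out = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            se = np.sqrt(base_var * (1.0 / sizes[a] + 1.0 / sizes[b]))
            z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
            out.append({"pair": (a, b), "z": float(z),
                        "p": float(2 * stats.norm.sf(abs(z)))})
    return out


def group_compare(groups: dict, alpha: float = 0.05) -> dict:
    """Omnibus comparison of a metric across groups, with follow-up.

    Normality (D'Agostino-Pearson) gates parametric vs rank tests; groups
    with n < 3 are excluded with a warning, and groups too small for the
    normality test route to the rank branch.
    """
    groups = {k: np.asarray(v, float) for k, v in groups.items()}
    small = [k for k, v in groups.items() if v.size < 3]
    for k in small:
        log.warning("group %s: n < 3, excluded", k)
        del groups[k]
    if len(groups) < 2:
        return {"status": "insufficient"}

    def normal(v):
        if v.size < 8:
            return False  # cannot verify normality: use the rank branch
        if np.ptp(v) == 0:
            return False
        return stats.normaltest(v).pvalue >= alpha

    gaussian = all(normal(v) for v in groups.values())
    vals = list(groups.values())
    if len(groups) == 2:
        if np.ptp(np.concatenate(vals)) == 0:
            return {"status": "ok", "test": "degenerate", "statistic": float("nan"),
                    "p": 1.0, "pairwise": []}
        if gaussian:
            s, p = stats.ttest_ind(*vals)
            test = "t"
        else:
            s, p = stats.mannwhitneyu(*vals, alternative="two-sided")
            test = "mann-whitney"
        pairwise = []
    else:
        if gaussian:
            s, p = stats.f_oneway(*vals)
            test = "anova"
            pairwise = []
        else:
            s, p = stats.kruskal(*vals)
            test = "kruskal-wallis"
            pairwise = _dunn_pairwise(groups)
    return {"status": "ok", "test": test, "statistic": float(s), "p": float(p),
            "pairwise": pairwise}


def per_patient_perforation(df: pd.DataFrame) -> pd.DataFrame:
    """Per-patient perforated active-zone fraction with age and group."""
    rows = []
    for pid, g in df.groupby("patient_id"):
        rows.append({
            "patient_id": pid,
            "group": g["group"].iloc[0],
            "age": float(g["age"].iloc[0]),
            "perforated_fraction": float(g["perforated"].mean()),
            "n_active_zones": len(g),
        })
    return pd.DataFrame(rows)


def age_epilepsy_regression(patients: pd.DataFrame) -> dict:
    """OLS of perforated fraction on age and epilepsy status.

    Requires >= 4 patients and both groups present (otherwise the group
    indicator is constant and the design is collinear).
    """
    if len(patients) < 4:
        raise ValueError("need at least 4 patients")
    if patients["group"].nunique() < 2:
        raise ValueError("both patient groups must be present")
    X = sm.add_constant(pd.DataFrame({
        "age": patients["age"].astype(float),
        "epilepsy": (patients["group"] == "epileptic").astype(float),
    }))
    fit = sm.OLS(patients["perforated_fraction"].astype(float), X).fit()
    return {
        "coef": {k: float(v) for k, v in fit.params.items()},
        "p": {k: float(v) for k, v in fit.pvalues.items()},
        "r2": float(fit.rsquared),
        "n": int(fit.nobs),
    }
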