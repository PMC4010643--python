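"""Rank-based burden/clinicopathology association statistics.

Three nonparametric tests cover every comparison made on the cohort summary
table: Spearman rank correlation (midranks, t-approximation p-value) for two
continuous burden measures; the Wilcoxon rank-sum test for a burden measure
across two groups, using the normal approximation with tie-corrected
variance and *no* continuity correction; and Kruskal-Wallis for three or
more groups.  Invasive stages (pT1 and pT2+) are pooled against pTa for the
two-group stage tests, since burden measures do not separate pT1 from pT2.

The cohort summary fixture packaged with the library transcribes the
published per-tumour genome profiles (ESM/GSM mutation counts, percent of
genome copy-number altered, discrete CNV count, sub-clonal cluster count)
joined to patient demographics; the loader reproduces its summary columns
and the published rank statistics are recovered from it exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "spearman",
    "wilcoxon_ranksum",
    "kruskal_wallis",
    "association_screen",
    "load_cohort_summary",
    "stage_group",
]

STAGES = ("pTa", "pT1", "pT2")


def _clean_pairs(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    mask = ~(np.isnan(x) | np.isnan(y))
    return x[mask], y[mask]


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with midranks; p from the t approximation.

    Pairwise-complete cases only (NaNs dropped pairwise); requires >= 3
    complete pairs; raises on a constant vector, where the correlation is
    undefined.
    """
    x, y = _clean_pairs(x, y)
    if len(x) < 3:
        raise ValueError(f"need >= 3 complete pairs, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: Spearman correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def wilcoxon_ranksum(group_a, group_b, exact: bool = False) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns ``(z, p)``.

    Normal approximation with tie-corrected variance and no continuity
    correction (the variant under which the published burden-by-stage
    p-values are recovered).  ``exact=True`` switches to the exact
    Mann-Whitney null distribution (no ties allowed by scipy); z is then NaN.
    With all values identical across both groups, z = 0 and p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    if exact:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return float("nan"), float(res.pvalue)
    ranks = stats.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
    var = n1 * n2 / 12 * ((n + 1) - tie_term)
    z = (u1 - mu) / np.sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def kruskal_wallis(groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square p (k-1 df)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    groups = [g[~np.isnan(g)] for g in groups]
    groups = [g for g in groups if len(g) > 0]
    if len(groups) < 2:
        raise ValueError("need >= 2 non-empty groups")
    if np.ptp(np.concatenate(groups)) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


# ---------------------------------------------------------------------------
# Cohort summary
# ---------------------------------------------------------------------------

def stage_group(stage: str) -> str:
    """Collapse stage to the two-group coding: pTa vs invasive (pT1/pT2)."""
    if stage.startswith("pTa"):
        return "pTa"
    if stage.startswith(("pT1", "pT2", "pT3", "pT4")):
        return "pT1/pT2"
    raise ValueError(f"unknown stage {stage!r}")


def load_cohort_summary(
    profiles_path: str | None = None, demographics_path: str | None = None
) -> pd.DataFrame:
    """Load the per-tumour cohort summary (genome profiles + demographics).

    Columns: tumour, stage (pTa|pT1|pT2), stage_group, grade, age, sex,
    smoker (ever|never), tumour_pct, esm, gsm, cnv_pct, n_cnvs, clonality.
    Missing values (the exome-only tumour has no genome-wide measures) are
    NaN.  With no paths, the packaged published tables are used.
    """
    def _read(name, path):
        if path is not None:
            return pd.read_csv(path, sep="\t", dtype={"tumour": str})
        src = resources.files("somascape.data").joinpath(name)
        with resources.as_file(src) as p:
            return pd.read_csv(p, sep="\t", dtype={"tumour": str})

    prof = _read("genome_profiles.tsv", profiles_path)
    demo = _read("cohort_demographics.tsv", demographics_path)
    df = prof.merge(demo, on="tumour", how="left", validate="one_to_one")
    df["stage_group"] = df["stage"].map(stage_group)
    # ever-vs-never smoking: ex- and current smokers are "ever"; passive
    # exposure is not active smoking and codes as "never"
    df["smoker"] = df["smoking"].map(
        lambda s: "ever" if s in ("Ex-", "Current") else "never"
    )
    for col in ("esm", "gsm", "cnv_pct", "n_cnvs", "clonality", "age"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


BURDEN_VARIABLES = ("gsm", "cnv_pct", "clonality")


@dataclass
class AssociationResult:
    burden_variable: str
    factor: str
    test: str
    statistic: float
    p_value: float
    n: int
    note: str = ""


def association_screen(
    summary: pd.DataFrame,
    burden_vars=BURDEN_VARIABLES,
    factors=("stage_group", "grade_group", "sex", "smoker", "age"),
) -> pd.DataFrame:
    """Test every burden variable against every factor.

    Two-level factors get the Wilcoxon rank-sum test; continuous factors
    (age) get Spearman correlation; factors with one observed level, more
    than two levels, or fewer than 3 complete cases are reported as
    untestable rather than silently dropped.
    """
    df = summary.copy()
    if "grade_group" in factors and "grade_group" not in df.columns:
        df["grade_group"] = df["grade"].map(
            lambda g: "G3" if str(g) == "G3" else "G1,2"
        )
    rows = []
    for bv in burden_vars:
        for factor in factors:
            sub = df[[bv, factor]].dropna()
            if len(sub) < 3:
                rows.append(AssociationResult(bv, factor, "untestable",
                                              float("nan"), float("nan"),
                                              len(sub), "fewer than 3 complete cases"))
                continue
            if pd.api.types.is_numeric_dtype(sub[factor]):
                try:
                    rho, p = spearman(sub[bv], sub[factor])
                    rows.append(AssociationResult(bv, factor, "spearman",
                                                  rho, p, len(sub)))
                except ValueError as e:
                    rows.append(AssociationResult(bv, factor, "untestable",
                                                  float("nan"), float("nan"),
                                                  len(sub), str(e)))
                continue
            levels = sorted(sub[factor].unique())
            if len(levels) == 2:
                g1 = sub.loc[sub[factor] == levels[0], bv]
                g2 = sub.loc[sub[factor] == levels[1], bv]
                z, p = wilcoxon_ranksum(g1, g2)
                rows.append(AssociationResult(bv, factor, "wilcoxon", z, p, len(sub)))
            elif len(levels) > 2:
                h, p = kruskal_wallis(
                    [sub.loc[sub[factor] == lv, bv] for lv in levels]
                )
                rows.append(AssociationResult(bv, factor, "kruskal-wallis",
                                              h, p, len(sub)))
            else:
                rows.append(AssociationResult(bv, factor, "untestable",
                                              float("nan"), float("nan"),
                                              len(sub), "factor has one level"))
    return pd.DataFrame([r.__dict__ for r in rows])
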