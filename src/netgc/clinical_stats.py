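"""Clinical scoring, recovery classification and group/visit statistics.

The clinical side of the pipeline works on per-patient-per-visit score
tables: MoCA (0-30) plus five z-scored neuropsychological tests (HVLT,
verbal fluency, trail making, ipsilesional pegboard, SDMT), alongside
carried-but-unused severity/function scores (NIHSS, mRS, Barthel).

A patient's long-term recovery profile is *favourable* when strictly more
than half of the scored measures improve between visits 2 and 3; when the
visit-3 battery is missing entirely the classification falls back to the
MoCA change alone.  Connectivity summaries are compared across visits
(paired t-tests) and between groups (Welch two-sample t-tests), with
Bonferroni correction over the category family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SCORED_MEASURES",
    "Z_SCORE_TESTS",
    "RecoveryLabel",
    "ComparisonResult",
    "load_reference_cohort",
    "impairment_flags",
    "classify_recovery",
    "classify_all",
    "paired_t",
    "bonferroni",
    "stars",
    "compare_contrasts",
]

#: The five z-scored neuropsychological tests.
Z_SCORE_TESTS = ("hvlt", "verbal_fluency", "trail_making", "pegboard", "sdmt")

#: Measures entering the recovery classifier (MoCA plus the z-scored tests).
SCORED_MEASURES = ("moca",) + Z_SCORE_TESTS


def load_reference_cohort() -> pd.DataFrame:
    """The bundled six-patient longitudinal clinical score table.

    One row per patient-visit; empty cells mark a missing battery (patient
    4 returned for the scan but not full clinical testing at visit 3).
    """
    ref = resources.files("netgc").joinpath("data/cohort_clinical_scores.csv")
    with ref.open() as f:
        return pd.read_csv(f)


def impairment_flags(z_scores, threshold: float = 1.5) -> pd.Series:
    """Impairment flag per test: z strictly more than ``threshold`` SDs
    below the mean (z < -threshold).  Missing scores yield False."""
    z = pd.Series(z_scores, dtype=float)
    return (z < -threshold).fillna(False)


@dataclass(frozen=True)
class RecoveryLabel:
    """Visit-2 -> visit-3 recovery classification for one patient."""

    patient: object
    improved: dict            # measure -> bool, over measures scored at both visits
    n_improved: int
    n_scored: int
    label: str                # "favourable" | "unfavourable"
    fallback_used: bool = False

    @property
    def favourable(self) -> bool:
        return self.label == "favourable"


def classify_recovery(table: pd.DataFrame, patient) -> RecoveryLabel:
    """Label one patient's long-term recovery from visits 2 and 3.

    A measure counts as improved only when its visit-3 score is strictly
    greater than at visit 2 (ties are non-improvement).  The label is
    favourable iff improvements outnumber half of the measures scored at
    both visits.  If the entire visit-3 test battery is missing, the MoCA
    change alone decides (any decrease or tie -> unfavourable) and
    ``fallback_used`` is set.
    """
    rows = table[table["patient"] == patient]
    v2 = rows[rows["visit"] == 2]
    v3 = rows[rows["visit"] == 3]
    if len(v2) != 1 or len(v3) != 1:
        raise ValueError(f"patient {patient!r}: need exactly one visit-2 and "
                         "one visit-3 row")
    v2, v3 = v2.iloc[0], v3.iloc[0]

    battery_missing = all(pd.isna(v3[t]) for t in Z_SCORE_TESTS)
    if battery_missing:
        improved_moca = (pd.notna(v3["moca"]) and pd.notna(v2["moca"])
                         and float(v3["moca"]) > float(v2["moca"]))
        label = "favourable" if improved_moca else "unfavourable"
        return RecoveryLabel(patient=patient,
                             improved={"moca": improved_moca},
                             n_improved=int(improved_moca), n_scored=1,
                             label=label, fallback_used=True)

    improved = {}
    for measure in SCORED_MEASURES:
        a, b = v2.get(measure), v3.get(measure)
        if pd.isna(a) or pd.isna(b):
            continue  # scored at both visits only
        improved[measure] = float(b) > float(a)
    n_improved = sum(improved.values())
    n_scored = len(improved)
    label = "favourable" if n_improved > n_scored / 2 else "unfavourable"
    return RecoveryLabel(patient=patient, improved=improved,
                         n_improved=n_improved, n_scored=n_scored,
                         label=label, fallback_used=False)


def classify_all(table: pd.DataFrame) -> pd.DataFrame:
    """Recovery labels for every patient in a clinical table."""
    rows = []
    for patient in pd.unique(table["patient"]):
        lab = classify_recovery(table, patient)
        rows.append({"patient": patient, "label": lab.label,
                     "favourable": lab.favourable,
                     "n_improved": lab.n_improved, "n_scored": lab.n_scored,
                     "fallback_used": lab.fallback_used})
    return pd.DataFrame(rows)


def paired_t(a, b) -> tuple[float, float]:
    """Two-sided paired t-test; returns (t, raw p), df = n - 1.

    Raises on a degenerate contrast (all differences identical), where the
    t statistic is undefined, rather than returning a silent p-value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("paired_t needs two equal-length 1-D samples, n >= 2")
    d = a - b
    if np.std(d, ddof=1) == 0:
        raise ValueError("degenerate contrast: paired differences have zero "
                         "variance")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def bonferroni(raw_p: float, m: int) -> float:
    """Bonferroni-adjusted p-value: min(1, m * raw_p)."""
    if m < 1:
        raise ValueError("family size m must be >= 1")
    return min(1.0, m * raw_p)


def stars(p: float) -> str:
    """Significance stars at the 0.05 / 0.01 / 0.001 thresholds."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"


@dataclass(frozen=True)
class ComparisonResult:
    category: str
    contrast: str
    t: float
    p_raw: float
    p_adj: float
    m: int

    @property
    def stars(self) -> str:
        return stars(self.p_adj)


@dataclass(frozen=True)
class ContrastDesign:
    """What to compare on a summary table.

    ``visit_pairs`` yields within-group paired contrasts (one per group in
    ``groups``); ``group_pairs`` yields between-group contrasts at each
    visit (Welch two-sample, since the groups are independent and of
    unequal size).  ``categories`` is the summary category family; the
    Bonferroni family size equals its length (4 bilateral, 16
    lateralized).
    """

    categories: tuple
    groups: tuple = ("patient", "control")
    visit_pairs: tuple = ((1, 2), (2, 3))
    group_pairs: tuple = ()
    group_col: str = "group"


def compare_contrasts(summaries: pd.DataFrame,
                      design: ContrastDesign) -> pd.DataFrame:
    """All category x contrast tests with Bonferroni adjustment.

    ``summaries`` is a table with one row per subject-visit (columns
    ``subject``, ``visit``, the design's group column, and one column per
    category, as produced by
    :func:`netgc.network_summary.summary_table`).  Within-group visit
    contrasts are paired by subject id; between-group contrasts are
    Welch t-tests.  Degenerate (zero-link) rows are dropped first when the
    table carries a ``degenerate`` column.
    """
    df = summaries
    if "degenerate" in df.columns:
        df = df[~df["degenerate"].astype(bool)]
    m = len(design.categories)
    results = []

    def _add(category, contrast, t, p_raw):
        results.append(ComparisonResult(
            category=category, contrast=contrast, t=t, p_raw=p_raw,
            p_adj=bonferroni(p_raw, m), m=m))

    for group in design.groups:
        sub = df[df[design.group_col] == group]
        if sub.empty:
            continue
        for va, vb in design.visit_pairs:
            a = sub[sub["visit"] == va].set_index("subject")
            b = sub[sub["visit"] == vb].set_index("subject")
            common = a.index.intersection(b.index)  # pair by subject id
            if len(common) < 2:
                raise ValueError(
                    f"group {group!r}: fewer than 2 subjects with both "
                    f"visits {va} and {vb}")
            for cat in design.categories:
                try:
                    t, p = paired_t(a.loc[common, cat], b.loc[common, cat])
                except ValueError as exc:
                    # zero-variance differences: undecidable, not an abort
                    logger.warning("%s, %s visits %s-%s: %s",
                                   cat, group, va, vb, exc)
                    results.append(ComparisonResult(
                        category=cat, contrast=f"{group}: visit {va} vs {vb}",
                        t=float("nan"), p_raw=float("nan"),
                        p_adj=float("nan"), m=m))
                    continue
                _add(cat, f"{group}: visit {va} vs {vb}", t, p)

    for ga, gb in design.group_pairs:
        for visit in sorted(df["visit"].unique()):
            a = df[(df[design.group_col] == ga) & (df["visit"] == visit)]
            b = df[(df[design.group_col] == gb) & (df["visit"] == visit)]
            if len(a) < 2 or len(b) < 2:
                raise ValueError(f"contrast {ga} vs {gb} at visit {visit}: "
                                 "need n >= 2 per group")
            for cat in design.categories:
                res = stats.ttest_ind(a[cat], b[cat], equal_var=False)
                _add(cat, f"{ga} vs {gb}: visit {visit}",
                     float(res.statistic), float(res.pvalue))

    out = pd.DataFrame([{
        "category": r.category, "contrast": r.contrast, "t": r.t,
        "p_raw": r.p_raw, "p_adj": r.p_adj, "m": r.m, "stars": r.stars,
    } for r in results])
    return out
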