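"""Supporting-pathogenic yield: decision rules, score bins and per-gene summaries.

A filtered (rare, PTV/missense, panel-gene) variant counts as supporting
pathogenic if it is pathogenic/likely-pathogenic in ClinVar; an
uncertain-class protein-truncating variant; or an uncertain-class
missense variant at or above the tool's supporting-pathogenic threshold
(REVEL >= 0.644 or Phred-scaled CADD >= 20.000).  "Uncertain class"
covers both variants of uncertain significance and conflicting
interpretations, which the enrichment analyses treat together; variants
absent from the archive follow the same PTV/score rules through the
dedicated absent categories.  Benign-class and "other"-class variants
are never supporting.  Missense variants missing the tool's score are
tracked as a distinct unknown-score outcome so annotation gaps stay
visible rather than being silently counted as non-supporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Optional

import pandas as pd

from .calibration import DEFAULT_THRESHOLDS
from .errors import ValidationError
from .variants import ClinvarBin, CohortDataset, Consequence, VariantRecord

log = logging.getLogger(__name__)


class YieldCategory(str, Enum):
    """Mutually exclusive, exhaustive outcome of the supporting-pathogenic rules."""

    CLINVAR_PLP = "clinvar_plp"
    VUS_PTV = "vus_ptv"
    VUS_MISSENSE_ABOVE = "vus_missense_above"
    ABSENT_PTV = "absent_ptv"
    ABSENT_MISSENSE_ABOVE = "absent_missense_above"
    NOT_SUPPORTING = "not_supporting"
    UNKNOWN_SCORE = "unknown_score"


SUPPORTING_CATEGORIES = frozenset(
    {
        YieldCategory.CLINVAR_PLP,
        YieldCategory.VUS_PTV,
        YieldCategory.VUS_MISSENSE_ABOVE,
        YieldCategory.ABSENT_PTV,
        YieldCategory.ABSENT_MISSENSE_ABOVE,
    }
)

_REVEL_EDGES = (0.183, 0.644)
_CADD_EDGES = (10.0, 20.0)
_REVEL_LABELS = ("0.000-0.182", "0.183-0.643", ">=0.644")
_CADD_LABELS = ("0.000-9.999", "10.000-19.999", ">=20.000")


def bin_score(score: float, tool: str) -> str:
    """Three-way score bin with lower-inclusive internal boundaries.

    REVEL bins split at 0.183 and 0.644; Phred-scaled CADD bins split at
    10.0 and 20.0.  A negative score is invalid for either tool.
    """
    if tool == "revel":
        edges, labels = _REVEL_EDGES, _REVEL_LABELS
    elif tool == "cadd":
        edges, labels = _CADD_EDGES, _CADD_LABELS
    else:
        raise ValidationError(f"unknown tool {tool!r}")
    if score < 0:
        raise ValidationError(f"{tool} score must be >= 0, got {score}")
    if score >= edges[1]:
        return labels[2]
    if score >= edges[0]:
        return labels[1]
    return labels[0]


def classify_supporting(
    record: VariantRecord, tool: str, threshold: Optional[float] = None
) -> YieldCategory:
    """Apply the ordered supporting-pathogenic rules to one filtered record."""
    t = DEFAULT_THRESHOLDS[tool] if threshold is None else threshold
    b = record.clinvar_bin
    if b is ClinvarBin.P_LP:
        return YieldCategory.CLINVAR_PLP
    uncertain = b in (ClinvarBin.VUS, ClinvarBin.CONFLICTING)
    absent = b is ClinvarBin.ABSENT
    is_ptv = record.consequence_class is Consequence.PTV
    is_missense = record.consequence_class is Consequence.MISSENSE
    if uncertain and is_ptv:
        return YieldCategory.VUS_PTV
    if uncertain and is_missense:
        s = record.score(tool)
        if s is None:
            return YieldCategory.UNKNOWN_SCORE
        return YieldCategory.VUS_MISSENSE_ABOVE if s >= t else YieldCategory.NOT_SUPPORTING
    if absent and is_ptv:
        return YieldCategory.ABSENT_PTV
    if absent and is_missense:
        s = record.score(tool)
        if s is None:
            return YieldCategory.UNKNOWN_SCORE
        return YieldCategory.ABSENT_MISSENSE_ABOVE if s >= t else YieldCategory.NOT_SUPPORTING
    return YieldCategory.NOT_SUPPORTING


@dataclass
class YieldSummary:
    """Observed supporting-pathogenic counts for one dataset and one tool."""

    dataset: str
    tool: str
    threshold: float
    per_gene: pd.DataFrame  # gene, cohort, supporting, total, proportion
    by_category: pd.DataFrame  # gene, cohort, category, count
    totals: dict  # cohort -> {"supporting": int, "total": int, "proportion": float}


def yield_summary(
    dataset: CohortDataset, tool: str, threshold: Optional[float] = None
) -> YieldSummary:
    """Allele-weighted supporting-pathogenic counts per gene and cohort.

    ``dataset`` should already be filtered.  Counts weight each variant
    by its cohort allele count ("observed variants"); proportions are
    supporting counts over total observed counts per gene and cohort.
    Unknown-score observations are excluded from the supporting
    numerator but reported in the category breakdown.
    """
    t = DEFAULT_THRESHOLDS[tool] if threshold is None else threshold
    rows = []
    for r in dataset.records:
        cat = classify_supporting(r, tool, t)
        for cohort, weight in (("case", r.case_ac), ("control", r.control_ac)):
            if weight == 0:
                continue
            rows.append(
                {"gene": r.gene, "cohort": cohort, "category": cat.value, "count": weight}
            )
    if not rows:
        log.warning("yield_summary(%s, %s): no observed records", dataset.name, tool)
        empty = pd.DataFrame(columns=["gene", "cohort", "supporting", "total", "proportion"])
        by_cat = pd.DataFrame(columns=["gene", "cohort", "category", "count"])
        return YieldSummary(dataset.name, tool, t, empty, by_cat, {})
    frame = pd.DataFrame(rows)
    by_category = (
        frame.groupby(["gene", "cohort", "category"], sort=True)["count"].sum().reset_index()
    )
    supporting_set = {c.value for c in SUPPORTING_CATEGORIES}
    per_gene = (
        by_category.assign(
            supporting=lambda f: f["count"].where(f["category"].isin(supporting_set), 0)
        )
        .groupby(["gene", "cohort"], sort=True)
        .agg(supporting=("supporting", "sum"), total=("count", "sum"))
        .reset_index()
    )
    per_gene["proportion"] = per_gene["supporting"] / per_gene["total"]
    totals = {}
    for cohort, sub in per_gene.groupby("cohort"):
        supporting = int(sub["supporting"].sum())
        total = int(sub["total"].sum())
        totals[cohort] = {
            "supporting": supporting,
            "total": total,
            "proportion": supporting / total if total else None,
        }
    return YieldSummary(dataset.name, tool, t, per_gene, by_category, totals)


def per_gene_matrix(summaries: Iterable[YieldSummary]) -> pd.DataFrame:
    """Long-format gene x cohort x tool x category table of counts and proportions.

    Proportions are relative to the cohort's total observed count within
    each summary; merging summaries for the same tool from different
    datasets keeps them as separate rows (sum counts gene-wise first via
    ``merge_datasets`` if a pooled matrix is wanted).
    """
    summaries = list(summaries)
    if not summaries:
        raise ValidationError("at least one yield summary is required")
    frames = []
    for s in summaries:
        if s.by_category.empty:
            continue
        f = s.by_category.copy()
        f.insert(0, "dataset", s.dataset)
        f.insert(1, "tool", s.tool)
        totals = {c: v["total"] for c, v in s.totals.items()}
        f["proportion"] = [
            row.count_ / totals[row.cohort]
            for row in f.rename(columns={"count": "count_"}).itertuples()
        ]
        frames.append(f)
    if not frames:
        return pd.DataFrame(
            columns=["dataset", "tool", "gene", "cohort", "category", "count", "proportion"]
        )
    return pd.concat(frames, ignore_index=True)[
        ["dataset", "tool", "gene", "cohort", "category", "count", "proportion"]
    ]
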