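"""Variant data model: classification, rarity filtering and count aggregation.

The unit of analysis is an annotated variant observed in a case-control
sequencing cohort over a panel of disease genes.  Each variant carries a
coding consequence (protein-truncating, missense or synonymous), a ClinVar
classification binned into six categories, in-silico pathogenicity scores
(REVEL for missense variants only, on [0, 1]; Phred-scaled CADD, >= 0), a
reference-population allele frequency, and case/control allele counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional, Sequence

import pandas as pd

from .errors import ClassificationError, ValidationError

log = logging.getLogger(__name__)


class Consequence(str, Enum):
    """Coding consequence classes."""

    PTV = "PTV"
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"


class ClinvarBin(str, Enum):
    """Six-way binning of ClinVar classifications."""

    B_LB = "B_LB"
    CONFLICTING = "conflicting"
    VUS = "VUS"
    P_LP = "P_LP"
    ABSENT = "absent"
    OTHER = "other"


#: Annotation terms mapped to the protein-truncating class.  Both the
#: "start_loss"/"stop_loss" and the VEP "start_lost"/"stop_lost" spellings
#: are accepted.
PTV_TERMS = frozenset(
    {
        "splice_donor_variant",
        "splice_acceptor_variant",
        "frameshift_variant",
        "stop_gained",
        "start_loss",
        "stop_loss",
        "start_lost",
        "stop_lost",
    }
)

#: ClinVar labels that land in the "other" bin (normalised, substring match).
_OTHER_LABELS = ("protective", "drug response", "association", "risk factor", "risk allele")

#: Default rarity cutoff: reference-population allele frequency < 1%.
DEFAULT_AF_CUTOFF = 0.01


def reclassify_consequence(term: str) -> Consequence:
    """Map a raw annotation consequence term to a three-way coding class.

    Parameters
    ----------
    term
        Annotation-style consequence term, e.g. ``"stop_gained"``.
        Matching is case-insensitive.

    Returns
    -------
    Consequence
        ``PTV`` for splice donor/acceptor, frameshift, stop-gained,
        start-loss and stop-loss terms; ``MISSENSE`` for
        ``missense_variant``; ``SYNONYMOUS`` for ``synonymous_variant``.

    Raises
    ------
    ClassificationError
        If the term is empty or not one of the recognised coding terms.
        Unknown terms raise rather than coerce so upstream annotation
        problems stay visible.
    """
    if not isinstance(term, str) or not term.strip():
        raise ClassificationError("consequence term must be a non-empty string")
    t = term.strip().lower()
    if t in PTV_TERMS:
        return Consequence.PTV
    if t == "missense_variant":
        return Consequence.MISSENSE
    if t == "synonymous_variant":
        return Consequence.SYNONYMOUS
    raise ClassificationError(f"unclassifiable coding consequence term: {term!r}")


def bin_clinvar(raw: Optional[str]) -> ClinvarBin:
    """Bin a raw ClinVar classification string into six categories.

    ``None``/empty input means the variant is absent from the archive.
    Matching is by normalised lowercase substring: conflicting
    interpretations take precedence, then uncertain significance, then
    pathogenic/likely-pathogenic, then benign/likely-benign.  Protective,
    drug-response, association and risk-factor labels go to ``OTHER``; any
    unmapped non-missing label also goes to ``OTHER`` with a logged warning.
    """
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return ClinvarBin.ABSENT
    s = str(raw).strip().lower().replace("_", " ")
    if not s or s == "na":
        return ClinvarBin.ABSENT
    if "conflicting" in s:
        return ClinvarBin.CONFLICTING
    if "uncertain" in s or s == "vus":
        return ClinvarBin.VUS
    if "pathogenic" in s and "benign" not in s:
        return ClinvarBin.P_LP
    if "benign" in s and "pathogenic" not in s:
        return ClinvarBin.B_LB
    if any(lbl in s for lbl in _OTHER_LABELS):
        return ClinvarBin.OTHER
    log.warning("unmapped ClinVar label %r binned as 'other'", raw)
    return ClinvarBin.OTHER


def is_rare(pop_af: Optional[float], cutoff: float = DEFAULT_AF_CUTOFF) -> bool:
    """True iff the population allele frequency is strictly below ``cutoff``.

    A missing frequency counts as rare: absence from the reference
    population is the strongest evidence of rarity, and novel variants
    must survive the rarity filter.
    """
    if not 0.0 < cutoff <= 1.0:
        raise ValidationError(f"cutoff must be in (0, 1], got {cutoff}")
    if pop_af is None or pd.isna(pop_af):
        return True
    if not 0.0 <= pop_af <= 1.0:
        raise ValidationError(f"pop_af must be in [0, 1], got {pop_af}")
    return pop_af < cutoff


def is_vus_like(bin_: ClinvarBin) -> bool:
    """True for the uncertain-pathogenicity group: VUS, conflicting, or absent."""
    if not isinstance(bin_, ClinvarBin):
        raise ValidationError(f"not a ClinvarBin: {bin_!r}")
    return bin_ in (ClinvarBin.VUS, ClinvarBin.CONFLICTING, ClinvarBin.ABSENT)


@dataclass(frozen=True)
class VariantRecord:
    """One annotated variant (one alt allele at one site, 1-based position)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence_term: str
    consequence_class: Consequence
    clinvar_bin: ClinvarBin
    revel: Optional[float] = None
    cadd: Optional[float] = None
    pop_af: Optional[float] = None
    pop_ac: Optional[int] = None
    case_ac: int = 0
    control_ac: int = 0

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1 (1-based), got {self.pos}")
        if self.revel is not None:
            if not 0.0 <= self.revel <= 1.0:
                raise ValidationError(f"revel must be in [0, 1], got {self.revel}")
            if self.consequence_class is not Consequence.MISSENSE:
                raise ValidationError(
                    "revel scores apply to missense variants only; "
                    f"got a {self.consequence_class.value} record with revel={self.revel}"
                )
        if self.cadd is not None and self.cadd < 0:
            raise ValidationError(f"cadd must be >= 0, got {self.cadd}")
        if self.pop_af is not None and not 0.0 <= self.pop_af <= 1.0:
            raise ValidationError(f"pop_af must be in [0, 1], got {self.pop_af}")
        if self.pop_ac is not None and self.pop_ac < 0:
            raise ValidationError(f"pop_ac must be >= 0, got {self.pop_ac}")
        if self.case_ac < 0 or self.control_ac < 0:
            raise ValidationError("allele counts must be >= 0")

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def vus_like(self) -> bool:
        return is_vus_like(self.clinvar_bin)

    def score(self, tool: str) -> Optional[float]:
        """The record's score for ``tool`` ("revel" or "cadd")."""
        if tool == "revel":
            return self.revel
        if tool == "cadd":
            return self.cadd
        raise ValidationError(f"unknown tool {tool!r}; expected 'revel' or 'cadd'")

    def sort_key(self) -> tuple:
        try:
            ckey: tuple = (0, int(self.chrom))
        except ValueError:
            ckey = (1, self.chrom)
        return (*ckey, self.pos, self.ref, self.alt)


@dataclass
class CohortDataset:
    """A named collection of variant records with case/control sample sizes."""

    name: str
    n_cases: int
    n_controls: int
    records: list[VariantRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValidationError("n_cases and n_controls must be >= 1")
        for rec in self.records:
            self._check_record(rec)

    def _check_record(self, rec: VariantRecord) -> None:
        if rec.case_ac + rec.control_ac < 1:
            raise ValidationError(
                f"{rec.variant_id}: a cohort record must be observed at least once"
            )
        if rec.case_ac > 2 * self.n_cases or rec.control_ac > 2 * self.n_controls:
            raise ValidationError(
                f"{rec.variant_id}: allele count exceeds 2x the sample size"
            )

    def __len__(self) -> int:
        return len(self.records)


def filter_cohort(
    dataset: CohortDataset,
    genes: Sequence[str],
    cutoff: float = DEFAULT_AF_CUTOFF,
) -> CohortDataset:
    """Restrict a cohort to rare PTV/missense variants in the gene panel.

    Keeps records whose gene is in ``genes``, whose consequence class is
    PTV or missense, and which are rare (``is_rare``) at ``cutoff``.
    Synonymous records are removed.  The result is sorted by variant
    identity so filtering is deterministic and idempotent.
    """
    if not genes:
        raise ValidationError("gene panel must be non-empty")
    panel = set(genes)
    kept = [
        r
        for r in dataset.records
        if r.gene in panel
        and r.consequence_class in (Consequence.PTV, Consequence.MISSENSE)
        and is_rare(r.pop_af, cutoff)
    ]
    kept.sort(key=VariantRecord.sort_key)
    if not kept:
        log.warning("filter_cohort(%s): no records survived filtering", dataset.name)
    log.info(
        "filter_cohort(%s): %d records in, %d kept, %d removed",
        dataset.name,
        len(dataset.records),
        len(kept),
        len(dataset.records) - len(kept),
    )
    return CohortDataset(
        name=dataset.name,
        n_cases=dataset.n_cases,
        n_controls=dataset.n_controls,
        records=kept,
    )


def aggregate_counts(dataset: CohortDataset, mode: str) -> pd.DataFrame:
    """Cross-tabulate variant counts by ClinVar bin and consequence class.

    Two counting conventions are supported.  ``mode="unique"`` counts each
    distinct variant once per cohort in which it was observed (allele count
    > 0).  ``mode="observed"`` weights each variant by its cohort allele
    count, so one variant seen on three case alleles contributes 3 to the
    case column.  Observed counts are therefore >= unique counts in every
    category.

    Returns a DataFrame indexed by (clinvar_bin, consequence_class) with
    ``case`` and ``control`` columns.
    """
    if mode not in ("unique", "observed"):
        raise ValidationError(f"mode must be 'unique' or 'observed', got {mode!r}")
    rows = []
    for r in dataset.records:
        if mode == "observed":
            case_w, control_w = r.case_ac, r.control_ac
        else:
            case_w, control_w = int(r.case_ac > 0), int(r.control_ac > 0)
        rows.append(
            {
                "clinvar_bin": r.clinvar_bin.value,
                "consequence_class": r.consequence_class.value,
                "case": case_w,
                "control": control_w,
            }
        )
    if not rows:
        idx = pd.MultiIndex.from_arrays([[], []], names=["clinvar_bin", "consequence_class"])
        return pd.DataFrame({"case": [], "control": []}, index=idx, dtype=int)
    frame = pd.DataFrame(rows)
    out = frame.groupby(["clinvar_bin", "consequence_class"], sort=True)[
        ["case", "control"]
    ].sum()
    return out


def merge_datasets(datasets: Iterable[CohortDataset], name: str = "combined") -> CohortDataset:
    """Pool cohorts: sum sample sizes and, per variant identity, allele counts.

    Annotations (gene, scores, population frequency) are taken from the
    first dataset in which the variant appears; a missing population
    frequency/count is backfilled from a later occurrence when available.
    """
    datasets = list(datasets)
    if not datasets:
        raise ValidationError("merge_datasets needs at least one dataset")
    n_cases = sum(d.n_cases for d in datasets)
    n_controls = sum(d.n_controls for d in datasets)
    merged: dict[str, VariantRecord] = {}
    for d in datasets:
        for r in d.records:
            vid = r.variant_id
            if vid not in merged:
                merged[vid] = r
            else:
                prev = merged[vid]
                merged[vid] = replace(
                    prev,
                    case_ac=prev.case_ac + r.case_ac,
                    control_ac=prev.control_ac + r.control_ac,
                    pop_af=prev.pop_af if prev.pop_af is not None else r.pop_af,
                    pop_ac=prev.pop_ac if prev.pop_ac is not None else r.pop_ac,
                )
    records = sorted(merged.values(), key=VariantRecord.sort_key)
    return CohortDataset(name=name, n_cases=n_cases, n_controls=n_controls, records=records)
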