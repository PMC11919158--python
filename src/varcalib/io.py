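"""Tab-separated input/output for annotated variant tables.

The table dialect is one header row with columns::

    dataset chrom pos ref alt gene consequence_term clinvar_raw
    revel cadd pop_af pop_ac case_ac control_ac

one row per unique variant per dataset, with missing values encoded as
an empty string or ``NA``.  Written (filtered) tables append the
normalised columns ``consequence_class``, ``clinvar_bin`` and
``vus_like``.
"""

from __future__ import annotations

import math
from typing import Mapping, Optional, Sequence

import pandas as pd

from .errors import ValidationError
from .variants import (
    CohortDataset,
    VariantRecord,
    bin_clinvar,
    reclassify_consequence,
)

REQUIRED_COLUMNS = [
    "dataset",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "consequence_term",
    "clinvar_raw",
    "revel",
    "cadd",
    "pop_af",
    "pop_ac",
    "case_ac",
    "control_ac",
]

_NA = ("", "NA")

#: Canonical raw label written for each bin (records do not retain the
#: original archive string; these re-parse to the same bin).
_CANONICAL_CLINVAR = {
    "B_LB": "Benign/Likely benign",
    "conflicting": "Conflicting interpretations of pathogenicity",
    "VUS": "Uncertain significance",
    "P_LP": "Pathogenic/Likely pathogenic",
    "other": "risk factor",
    "absent": "",
}


def _opt_float(v) -> Optional[float]:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v in _NA:
        return None
    return float(v)


def _opt_int(v) -> Optional[int]:
    f = _opt_float(v)
    return None if f is None else int(round(f))


def read_variant_tables(
    path,
    cohort_sizes: Mapping[str, tuple[int, int]],
) -> dict[str, CohortDataset]:
    """Read an annotated variant table into one ``CohortDataset`` per dataset label.

    ``cohort_sizes`` maps each dataset label to ``(n_cases, n_controls)``;
    sample sizes are study metadata and are not carried in the per-variant
    table itself.
    """
    frame = pd.read_csv(
        path, sep="\t", dtype=str, na_values=list(_NA), keep_default_na=False
    )
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"input table is missing required column(s): {', '.join(missing)}")
    out: dict[str, CohortDataset] = {}
    for name, sub in frame.groupby("dataset", sort=True):
        if name not in cohort_sizes:
            raise ValidationError(f"no cohort sizes provided for dataset {name!r}")
        n_cases, n_controls = cohort_sizes[name]
        records = []
        for row in sub.itertuples(index=False):
            term = str(row.consequence_term)
            records.append(
                VariantRecord(
                    chrom=str(row.chrom),
                    pos=int(row.pos),
                    ref=str(row.ref),
                    alt=str(row.alt),
                    gene=str(row.gene),
                    consequence_term=term,
                    consequence_class=reclassify_consequence(term),
                    clinvar_bin=bin_clinvar(
                        None if pd.isna(row.clinvar_raw) else str(row.clinvar_raw)
                    ),
                    revel=_opt_float(row.revel),
                    cadd=_opt_float(row.cadd),
                    pop_af=_opt_float(row.pop_af),
                    pop_ac=_opt_int(row.pop_ac),
                    case_ac=int(row.case_ac),
                    control_ac=int(row.control_ac),
                )
            )
        out[str(name)] = CohortDataset(
            name=str(name), n_cases=n_cases, n_controls=n_controls, records=records
        )
    return out


def datasets_to_frame(
    datasets: Sequence[CohortDataset], normalized: bool = True
) -> pd.DataFrame:
    """Serialise cohorts back to the table dialect (optionally with normalised columns)."""
    rows = []
    for d in datasets:
        for r in d.records:
            row = {
                "dataset": d.name,
                "chrom": r.chrom,
                "pos": r.pos,
                "ref": r.ref,
                "alt": r.alt,
                "gene": r.gene,
                "consequence_term": r.consequence_term,
                "clinvar_raw": _CANONICAL_CLINVAR[r.clinvar_bin.value],
                "revel": r.revel,
                "cadd": r.cadd,
                "pop_af": r.pop_af,
                "pop_ac": r.pop_ac,
                "case_ac": r.case_ac,
                "control_ac": r.control_ac,
            }
            if normalized:
                row["consequence_class"] = r.consequence_class.value
                row["clinvar_bin"] = r.clinvar_bin.value
                row["vus_like"] = r.vus_like
            rows.append(row)
    return pd.DataFrame(rows)


def write_variant_table(datasets: Sequence[CohortDataset], path, normalized: bool = True) -> None:
    frame = datasets_to_frame(datasets, normalized=normalized)
    frame.to_csv(path, sep="\t", index=False, na_rep="NA")
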