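"""End-to-end evaluation pipeline: filter -> calibrate -> enrich -> associate -> yield.

``run_pipeline`` is a pure function of its inputs: given the same cohorts
and configuration it produces byte-identical reports.  Every stage logs
row counts in and out, and the stage log is returned (and serialised)
so conservation is machine-checkable.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import yaml

from . import calibration as cal
from . import association as assoc
from . import yields as yld
from .errors import PipelineError, ValidationError
from .io import read_variant_tables, write_variant_table
from .variants import (
    ClinvarBin,
    CohortDataset,
    filter_cohort,
    merge_datasets,
)

log = logging.getLogger(__name__)

RULE_VERSION = "supporting-pathogenic rules v1 (P/LP; uncertain PTV; uncertain missense >= threshold; absent PTV; absent missense >= threshold)"


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    genes: list[str]
    inputs: list[str] = field(default_factory=list)
    cohort_sizes: dict[str, tuple[int, int]] = field(default_factory=dict)
    af_cutoff: float = 0.01
    revel_threshold: float = 0.644
    cadd_threshold: float = 20.0
    counting: str = "observed"
    out_dir: Optional[str] = None
    seed: int = 0

    def validate(self) -> None:
        if not self.genes:
            raise ValidationError("gene panel must be non-empty")
        if not 0 < self.af_cutoff <= 1:
            raise ValidationError("af_cutoff must be in (0, 1]")
        if self.revel_threshold <= 0 or self.cadd_threshold <= 0:
            raise ValidationError("tool thresholds must be positive")
        if self.counting not in ("unique", "observed"):
            raise ValidationError("counting must be 'unique' or 'observed'")

    def threshold(self, tool: str) -> float:
        return self.revel_threshold if tool == "revel" else self.cadd_threshold

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        cfg = cls(
            genes=list(d["genes"]),
            inputs=list(d.get("inputs", [])),
            cohort_sizes={
                k: (int(v[0]), int(v[1])) for k, v in d.get("cohort_sizes", {}).items()
            },
            af_cutoff=float(d.get("af_cutoff", 0.01)),
            revel_threshold=float(d.get("revel_threshold", 0.644)),
            cadd_threshold=float(d.get("cadd_threshold", 20.0)),
            counting=str(d.get("counting", "observed")),
            out_dir=d.get("out_dir"),
            seed=int(d.get("seed", 0)),
        )
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _round6(x):
    """Round floats to 6 significant digits at serialisation time only."""
    if isinstance(x, float):
        if math.isnan(x):
            return None
        if math.isinf(x):
            return x
        return float(f"{x:.6g}")
    if isinstance(x, dict):
        return {k: _round6(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_round6(v) for v in x]
    return x


def _confusion_dict(c: cal.ConfusionSummary) -> dict:
    return {
        "tp": c.tp,
        "fp": c.fp,
        "tn": c.tn,
        "fn": c.fn,
        "accuracy": c.accuracy,
        "sensitivity": c.sensitivity,
        "specificity": c.specificity,
        "ppv": c.ppv,
        "npv": c.npv,
    }


def _corr_dict(r: assoc.CorrelationResult) -> dict:
    return {"r": r.r, "p": r.p, "n": r.n, "defined": r.defined}


@dataclass
class PipelineResult:
    """Everything a run produces: summary dict, stage log and per-stage tables."""

    summary: dict
    stage_log: list[dict]
    filtered: list[CohortDataset]
    tables: dict


def run_pipeline(
    datasets: Sequence[CohortDataset], config: RunConfig
) -> PipelineResult:
    """Execute the full evaluation on already-loaded cohorts.

    Stages: rarity/consequence/panel filtering; threshold calibration on
    the benign-vs-pathogenic missense truth set of the pooled unique
    variants; uncertain-variant enrichment per stratum (Fisher) and
    pooled (CMH, Bonferroni-adjusted); variant-level score/odds-ratio
    and score/carrier-ratio correlations; supporting-pathogenic yield.
    Any stage failure raises ``PipelineError`` naming the stage.
    """
    config.validate()
    if not datasets:
        raise PipelineError("filter: no input datasets")
    stage_log: list[dict] = []
    tables: dict = {}

    # --- Stage 1: filter ---------------------------------------------------
    filtered = []
    for d in datasets:
        f = filter_cohort(d, config.genes, config.af_cutoff)
        stage_log.append(
            {
                "stage": "filter",
                "dataset": d.name,
                "rows_in": len(d),
                "rows_out": len(f),
                "rows_dropped": len(d) - len(f),
            }
        )
        filtered.append(f)
    pooled = merge_datasets(filtered, name="combined")

    # --- Stage 2: calibration ---------------------------------------------
    calibration_summary = {}
    for tool in ("revel", "cadd"):
        try:
            data = cal.LabeledScores.from_records(pooled.records, tool)
            model = cal.fit_logistic(data)
            curve = cal.roc_curve(data)
            thr, tpr, fpr, j = cal.youden_optimal(curve)
            ks = cal.ks_two_sample(
                data.scores[~data.labels], data.scores[data.labels]
            )
            conf = cal.confusion_at(data, config.threshold(tool))
            metrics = cal.metric_curves(data)
        except Exception as exc:
            raise PipelineError(f"calibrate: {tool}: {exc}") from exc
        stage_log.append(
            {
                "stage": "calibrate",
                "dataset": "combined",
                "tool": tool,
                "rows_in": len(pooled),
                "rows_out": int(data.scores.size),
                "rows_dropped": len(pooled) - int(data.scores.size),
            }
        )
        calibration_summary[tool] = {
            "n_positive": data.n_pos,
            "n_negative": data.n_neg,
            "logistic": {
                "intercept": model.intercept,
                "slope": model.slope,
                "converged": model.converged,
                "separated": model.separated,
            },
            "auc": cal.auc(curve),
            "youden": {"threshold": thr, "tpr": tpr, "fpr": fpr, "j": j},
            "ks": {"d": ks.d_stat, "at_score": ks.at_score, "p": ks.p_value},
            "confusion_at_threshold": dict(
                threshold=config.threshold(tool), **_confusion_dict(conf)
            ),
        }
        tables[f"roc_{tool}"] = curve
        tables[f"metrics_{tool}"] = metrics

    # --- Stage 3: enrichment -----------------------------------------------
    enrichment_summary = {}
    enrichment_rows = []
    raw_results = []
    for tool in ("revel", "cadd"):
        per_tool = {}
        strata_by_bin: dict[str, list[assoc.ContingencyTable]] = {"below": [], "above": []}
        vus_counts_in = vus_counts_used = 0
        for f in filtered:
            vus = [r for r in f.records if r.vus_like]
            vus_counts_in += len(f.records)
            vus_counts_used += len(vus)
            bins = assoc.bin_by_threshold(
                vus, tool, config.threshold(tool), mode=config.counting
            )
            for label, table in bins.items():
                strata_by_bin[label].append(table)
                try:
                    or_, p = assoc.fisher_exact(table)
                except Exception as exc:
                    raise PipelineError(f"enrich: {tool}/{f.name}/{label}: {exc}") from exc
                res = {
                    "tool": tool,
                    "stratum": f.name,
                    "bin": label,
                    "a": table.a,
                    "b": table.b,
                    "c": table.c,
                    "d": table.d,
                    "odds_ratio": or_,
                    "p": p,
                }
                enrichment_rows.append(res)
                raw_results.append(res)
        for label, strata in strata_by_bin.items():
            try:
                cmh = assoc.cmh_test(strata, bin_label=f"{tool}:{label}")
            except Exception as exc:
                raise PipelineError(f"enrich: {tool}/combined/{label}: {exc}") from exc
            res = {
                "tool": tool,
                "stratum": "combined",
                "bin": label,
                "a": sum(t.a for t in strata),
                "b": sum(t.b for t in strata),
                "c": sum(t.c for t in strata),
                "d": sum(t.d for t in strata),
                "odds_ratio": cmh.odds_ratio,
                "ci_low": cmh.ci_low,
                "ci_high": cmh.ci_high,
                "p": cmh.p_value,
            }
            enrichment_rows.append(res)
            raw_results.append(res)
            per_tool[label] = res
        enrichment_summary[tool] = per_tool
        stage_log.append(
            {
                "stage": "enrich",
                "dataset": "all",
                "tool": tool,
                "rows_in": vus_counts_in,
                "rows_out": vus_counts_used,
                "rows_dropped": vus_counts_in - vus_counts_used,
            }
        )
    # Bonferroni across the whole enrichment family (every raw p computed).
    m = len(raw_results)
    adjusted = assoc.bonferroni([r["p"] for r in raw_results], m)
    for r, p_adj in zip(raw_results, adjusted):
        r["p_adjusted"] = p_adj
    tables["enrichment"] = enrichment_rows

    # --- Stage 4: variant-level association ---------------------------------
    vus_like_bins = (ClinvarBin.VUS, ClinvarBin.CONFLICTING)
    variant_summary = {}
    for tool in ("revel", "cadd"):
        variant_summary[tool] = {
            "odds_ratio_all": _corr_dict(
                assoc.score_vs_association(pooled, tool, "odds_ratio", None)
            ),
            "odds_ratio_vus": _corr_dict(
                assoc.score_vs_association(pooled, tool, "odds_ratio", vus_like_bins)
            ),
            "carrier_ratio_all": _corr_dict(
                assoc.score_vs_association(pooled, tool, "carrier_ratio", None)
            ),
            "carrier_ratio_vus": _corr_dict(
                assoc.score_vs_association(pooled, tool, "carrier_ratio", vus_like_bins)
            ),
        }
    stage_log.append(
        {
            "stage": "associate",
            "dataset": "combined",
            "rows_in": len(pooled),
            "rows_out": len(pooled),
            "rows_dropped": 0,
        }
    )

    # --- Stage 5: yield ------------------------------------------------------
    yield_summary_out = {}
    matrices = []
    for tool in ("revel", "cadd"):
        summaries = [
            yld.yield_summary(f, tool, config.threshold(tool)) for f in filtered
        ]
        pooled_summary = yld.yield_summary(pooled, tool, config.threshold(tool))
        yield_summary_out[tool] = {
            "combined": pooled_summary.totals,
            **{s.dataset: s.totals for s in summaries},
        }
        matrices.extend(summaries + [pooled_summary])
    tables["yield_matrix"] = yld.per_gene_matrix(matrices)
    stage_log.append(
        {
            "stage": "yield",
            "dataset": "all",
            "rows_in": sum(len(f) for f in filtered),
            "rows_out": sum(len(f) for f in filtered),
            "rows_dropped": 0,
        }
    )

    summary = {
        "config": {
            "genes": sorted(config.genes),
            "af_cutoff": config.af_cutoff,
            "revel_threshold": config.revel_threshold,
            "cadd_threshold": config.cadd_threshold,
            "counting": config.counting,
            "rule_version": RULE_VERSION,
        },
        "datasets": {
            d.name: {"n_cases": d.n_cases, "n_controls": d.n_controls, "n_records": len(d)}
            for d in datasets
        },
        "calibration": calibration_summary,
        "enrichment": enrichment_summary,
        "variant_level": variant_summary,
        "yield": yield_summary_out,
        "stages": stage_log,
    }
    return PipelineResult(
        summary=_round6(summary), stage_log=stage_log, filtered=filtered, tables=tables
    )


def summary_json(result: PipelineResult) -> str:
    """Deterministic serialisation of the run summary."""
    return json.dumps(result.summary, indent=2, sort_keys=True) + "\n"


def write_report(result: PipelineResult, out_dir) -> None:
    """Write the report bundle (summary JSON, stage TSVs, filtered table)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "summary.json").write_text(summary_json(result))
    write_variant_table(result.filtered, out / "filtered.tsv")
    import pandas as pd

    for tool in ("revel", "cadd"):
        curve = result.tables[f"roc_{tool}"]
        pd.DataFrame(
            {"threshold": curve.thresholds, "tpr": curve.tpr, "fpr": curve.fpr}
        ).to_csv(out / f"roc_{tool}.tsv", sep="\t", index=False)
        result.tables[f"metrics_{tool}"].to_csv(
            out / f"metrics_{tool}.tsv", sep="\t", index=False, na_rep="NA"
        )
    pd.DataFrame(result.tables["enrichment"]).to_csv(
        out / "enrichment.tsv", sep="\t", index=False, na_rep="NA"
    )
    result.tables["yield_matrix"].to_csv(
        out / "yield.tsv", sep="\t", index=False, na_rep="NA"
    )
    manifest = {
        "rule_version": RULE_VERSION,
        "stages": result.stage_log,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def run_from_files(config: RunConfig) -> PipelineResult:
    """Load input tables named in the config, run the pipeline, write reports."""
    if not config.inputs:
        raise PipelineError("filter: no input tables configured")
    datasets: list[CohortDataset] = []
    for path in config.inputs:
        try:
            loaded = read_variant_tables(path, config.cohort_sizes)
        except ValidationError as exc:
            raise PipelineError(f"load: {path}: {exc}") from exc
        datasets.extend(loaded[k] for k in sorted(loaded))
    result = run_pipeline(datasets, config)
    if config.out_dir:
        write_report(result, config.out_dir)
    return result
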