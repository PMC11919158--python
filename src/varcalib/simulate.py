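"""Synthetic case-control variant cohorts with designed statistical structure.

The generator emulates the shape of a two-consortium, gene-panel,
case-control rare-variant study: ~20 panel genes, six-way ClinVar class
labels with class-conditional score distributions (benign-like variants
scoring low, pathogenic-like variants scoring high), rare population
allele frequencies, allele-count-weighted observations, and a
configurable allele odds ratio with which high-scoring uncertain
variants are over-assigned to cases.  Every downstream stage of the
package is testable against the generator's recorded ground truth.

Enrichment is implemented by independent binomial assignment of each
allele to the case cohort with probability
``p = OR * p0 / (1 - p0 + OR * p0)``, where ``p0`` is the null
case-assignment probability ``n_cases / (n_cases + n_controls)``; this
keeps the designed odds ratio interpretable in the allele odds-ratio
sense used by the variant-level analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import GenerationError, ValidationError
from .variants import ClinvarBin, Consequence, CohortDataset, VariantRecord, is_vus_like

_BASES = np.array(["A", "C", "G", "T"])

_PTV_TERMS = np.array(
    ["stop_gained", "frameshift_variant", "splice_donor_variant", "splice_acceptor_variant"]
)


@dataclass(frozen=True)
class ScoreDist:
    """A parametric score distribution for one ClinVar class.

    Families: ``beta(a, b)`` on [0, 1] (bounded scores), ``gamma(shape,
    scale)`` on [0, inf) (Phred-like scores), and ``truncnorm(mu, sigma,
    low, high)`` — a normal truncated to the score support, useful when an
    analytic AUC for a pair of classes is wanted.
    """

    family: str
    params: tuple

    def validate(self) -> None:
        if self.family == "beta":
            a, b = self.params
            if a <= 0 or b <= 0:
                raise ValidationError(f"beta parameters must be positive, got {self.params}")
        elif self.family == "gamma":
            shape, scale = self.params
            if shape <= 0 or scale <= 0:
                raise ValidationError(f"gamma parameters must be positive, got {self.params}")
        elif self.family == "truncnorm":
            mu, sigma, low, high = self.params
            if sigma <= 0 or not low < high:
                raise ValidationError(f"invalid truncnorm parameters {self.params}")
        else:
            raise ValidationError(f"unknown score distribution family {self.family!r}")

    def mean(self) -> float:
        """Nominal mean (for truncnorm: the untruncated mu)."""
        if self.family == "beta":
            a, b = self.params
            return a / (a + b)
        if self.family == "gamma":
            shape, scale = self.params
            return shape * scale
        return self.params[0]

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "beta":
            a, b = self.params
            return rng.beta(a, b, size=n)
        if self.family == "gamma":
            shape, scale = self.params
            return rng.gamma(shape, scale, size=n)
        mu, sigma, low, high = self.params
        a, b = (low - mu) / sigma, (high - mu) / sigma
        return stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=n, random_state=rng)


def beta_for_mean(mean: float, concentration: float = 4.0) -> ScoreDist:
    """Beta distribution with the given mean and total concentration a+b."""
    return ScoreDist("beta", (mean * concentration, (1.0 - mean) * concentration))


def gamma_for_mean(mean: float, shape: float = 8.0) -> ScoreDist:
    """Gamma distribution with the given mean and shape (sd = mean/sqrt(shape))."""
    return ScoreDist("gamma", (shape, mean / shape))


@dataclass(frozen=True)
class AlleleFrequencyModel:
    """Rare-frequency model: AF = max_af * Beta(a, b), with a missing mass.

    ``max_af`` must sit below the rarity cutoff so every generated variant
    survives the rarity filter; ``missing_rate`` is the fraction of
    variants absent from the reference population (missing AF, treated as
    rare downstream); ``ref_n`` is the reference-population sample size
    used to convert frequencies to allele counts.
    """

    beta_a: float = 0.5
    beta_b: float = 4.0
    max_af: float = 0.0099
    missing_rate: float = 0.25
    ref_n: int = 51_592

    def validate(self) -> None:
        if self.beta_a <= 0 or self.beta_b <= 0:
            raise ValidationError("allele-frequency beta parameters must be positive")
        if not 0 < self.max_af < 1:
            raise ValidationError("max_af must be in (0, 1)")
        if not 0 <= self.missing_rate <= 1:
            raise ValidationError("missing_rate must be in [0, 1]")
        if self.ref_n < 1:
            raise ValidationError("ref_n must be >= 1")


@dataclass(frozen=True)
class CohortSpec:
    """Sizes for one synthetic dataset (one stratum of the study)."""

    name: str
    n_cases: int
    n_controls: int
    n_variants: int

    def validate(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValidationError("cohort sizes must be >= 1")
        if self.n_variants < 1:
            raise ValidationError("n_variants must be >= 1")


@dataclass
class SyntheticConfig:
    """Generative parameters for synthetic case-control cohorts."""

    genes: dict[str, float]
    cohorts: list[CohortSpec]
    class_mixture: dict[ClinvarBin, float]
    revel_model: dict[ClinvarBin, ScoreDist]
    cadd_model: dict[ClinvarBin, ScoreDist]
    af_model: AlleleFrequencyModel = field(default_factory=AlleleFrequencyModel)
    enrichment_or: float = 1.0
    enrichment_tool: str = "revel"
    enrichment_threshold: float = 0.644
    ptv_fraction: float = 0.10
    synonymous_fraction: float = 0.15
    allele_count_lambda: float = 2.9
    seed: int = 0

    def validate(self) -> None:
        if not self.genes or any(w <= 0 for w in self.genes.values()):
            raise ValidationError("genes must be non-empty with positive weights")
        if not self.cohorts:
            raise ValidationError("at least one cohort spec is required")
        for c in self.cohorts:
            c.validate()
        total = sum(self.class_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"class_mixture must sum to 1, got {total}")
        if any(p < 0 for p in self.class_mixture.values()):
            raise ValidationError("class_mixture probabilities must be >= 0")
        for b in ClinvarBin:
            if b not in self.revel_model or b not in self.cadd_model:
                raise ValidationError(f"score models must cover every ClinVar bin ({b})")
        for dist in (*self.revel_model.values(), *self.cadd_model.values()):
            dist.validate()
        self.af_model.validate()
        if self.enrichment_or <= 0:
            raise ValidationError("enrichment_or must be > 0")
        if self.enrichment_tool not in ("revel", "cadd"):
            raise ValidationError("enrichment_tool must be 'revel' or 'cadd'")
        if not 0 <= self.ptv_fraction <= 1 or not 0 <= self.synonymous_fraction <= 1:
            raise ValidationError("consequence fractions must be in [0, 1]")
        if self.ptv_fraction + self.synonymous_fraction > 1:
            raise ValidationError("ptv_fraction + synonymous_fraction must be <= 1")
        if self.allele_count_lambda < 0:
            raise ValidationError("allele_count_lambda must be >= 0")


#: Panel of 20 gene symbols emulating a definitive/moderate ALS gene panel,
#: weighted roughly by gene size (large multi-exon genes contribute more
#: variants).
_DEFAULT_GENES = {
    "ALS2": 2.5,
    "ANXA11": 1.0,
    "CHCHD10": 0.4,
    "FUS": 1.0,
    "GRN": 1.0,
    "KIF5A": 1.5,
    "MATR3": 0.8,
    "NEK1": 2.0,
    "OPTN": 1.0,
    "PFN1": 0.3,
    "SETX": 2.2,
    "SOD1": 0.4,
    "SPG11": 2.5,
    "SQSTM1": 0.9,
    "TARDBP": 0.6,
    "TBK1": 1.0,
    "TUBA4A": 0.6,
    "UBQLN2": 0.7,
    "VAPB": 0.4,
    "VCP": 1.0,
}

#: Class mixture over unique variants: roughly half the panel's variants
#: absent from the archive, benign classifications commoner than
#: pathogenic ones.
_DEFAULT_MIXTURE = {
    ClinvarBin.B_LB: 0.22,
    ClinvarBin.CONFLICTING: 0.05,
    ClinvarBin.VUS: 0.20,
    ClinvarBin.P_LP: 0.03,
    ClinvarBin.ABSENT: 0.48,
    ClinvarBin.OTHER: 0.02,
}

#: Class-conditional REVEL means (benign low, pathogenic high; uncertain
#: classes in between) and Phred-scaled CADD means.
_DEFAULT_REVEL_MEANS = {
    ClinvarBin.B_LB: 0.237,
    ClinvarBin.CONFLICTING: 0.304,
    ClinvarBin.VUS: 0.319,
    ClinvarBin.P_LP: 0.713,
    ClinvarBin.ABSENT: 0.319,
    ClinvarBin.OTHER: 0.26,
}
_DEFAULT_CADD_MEANS = {
    ClinvarBin.B_LB: 18.650,
    ClinvarBin.CONFLICTING: 19.032,
    ClinvarBin.VUS: 20.966,
    ClinvarBin.P_LP: 24.461,
    ClinvarBin.ABSENT: 20.966,
    ClinvarBin.OTHER: 19.0,
}


def default_config(seed: int = 0) -> SyntheticConfig:
    """Default study conditions: two consortium-sized strata over a 20-gene panel.

    Cohort sizes mirror a whole-exome stratum of 3,864 cases / 7,839
    controls with ~1,400 variants and a whole-genome stratum of 4,366
    cases / 1,832 controls with ~1,150 variants.  Class-conditional score
    means follow the observed per-class means of the emulated study
    (e.g. mean REVEL 0.237 for B/LB vs 0.713 for P/LP; mean CADD 18.650
    vs 24.461) and the designed case enrichment of high-scoring uncertain
    missense variants is an allele odds ratio of 1.378 above REVEL 0.644.
    """
    return SyntheticConfig(
        genes=dict(_DEFAULT_GENES),
        cohorts=[
            CohortSpec("exome_consortium", 3864, 7839, 1395),
            CohortSpec("genome_consortium", 4366, 1832, 1149),
        ],
        class_mixture=dict(_DEFAULT_MIXTURE),
        revel_model={b: beta_for_mean(m) for b, m in _DEFAULT_REVEL_MEANS.items()},
        cadd_model={b: gamma_for_mean(m) for b, m in _DEFAULT_CADD_MEANS.items()},
        af_model=AlleleFrequencyModel(),
        enrichment_or=1.378,
        enrichment_tool="revel",
        enrichment_threshold=0.644,
        ptv_fraction=0.10,
        synonymous_fraction=0.15,
        allele_count_lambda=2.9,
        seed=seed,
    )


def _draw_positions(rng: np.random.Generator, gene_idx: np.ndarray, n_genes: int) -> np.ndarray:
    """Unique 1-based positions, one block of coordinate space per gene."""
    block = 500_000
    pos = np.zeros(gene_idx.size, dtype=np.int64)
    for g in range(n_genes):
        mask = gene_idx == g
        k = int(mask.sum())
        if k == 0:
            continue
        lo = g * block + 1
        draws = rng.integers(lo, lo + block, size=k)
        while np.unique(draws).size < k:  # collisions are rare; redraw whole block
            draws = rng.integers(lo, lo + block, size=k)
        pos[mask] = draws
    return pos


def generate_cohort(
    config: SyntheticConfig, cohort_index: int = 0
) -> tuple[CohortDataset, pd.DataFrame]:
    """Generate one synthetic cohort dataset plus its ground-truth table.

    Deterministic given ``config.seed`` (and the cohort index).  Each
    variant draws a gene, ClinVar bin, consequence class, class-conditional
    scores, a rare population frequency, and case/control allele counts
    such that uncertain-class missense variants at or above the designed
    score threshold have expected allele odds ratio ``enrichment_or``
    while every other variant has expected odds ratio 1.
    """
    config.validate()
    spec = config.cohorts[cohort_index]
    rng = np.random.default_rng([config.seed, cohort_index])
    n = spec.n_variants

    gene_names = sorted(config.genes)
    weights = np.array([config.genes[g] for g in gene_names], dtype=float)
    weights /= weights.sum()
    gene_idx = rng.choice(len(gene_names), size=n, p=weights)
    pos = _draw_positions(rng, gene_idx, len(gene_names))
    chrom = np.array([str((g % 22) + 1) for g in gene_idx])
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4

    bins = list(config.class_mixture)
    bin_idx = rng.choice(len(bins), size=n, p=np.array(list(config.class_mixture.values())))
    clinvar = np.array([bins[i].value for i in bin_idx], dtype=object)

    p_syn, p_ptv = config.synonymous_fraction, config.ptv_fraction
    cons_draw = rng.choice(
        3, size=n, p=[p_syn, p_ptv, 1.0 - p_syn - p_ptv]
    )  # 0=synonymous, 1=PTV, 2=missense
    terms = np.empty(n, dtype=object)
    terms[cons_draw == 0] = "synonymous_variant"
    terms[cons_draw == 2] = "missense_variant"
    n_ptv = int((cons_draw == 1).sum())
    terms[cons_draw == 1] = _PTV_TERMS[rng.integers(0, len(_PTV_TERMS), size=n_ptv)]

    revel = np.full(n, np.nan)
    cadd = np.full(n, np.nan)
    for i, b in enumerate(bins):
        mask = bin_idx == i
        k = int(mask.sum())
        if k == 0:
            continue
        revel[mask] = config.revel_model[b].sample(rng, k)
        cadd[mask] = config.cadd_model[b].sample(rng, k)
    revel[cons_draw != 2] = np.nan  # REVEL applies to missense variants only
    np.clip(revel, 0.0, 1.0, out=revel)
    np.clip(cadd, 0.0, None, out=cadd)

    afm = config.af_model
    af = afm.max_af * rng.beta(afm.beta_a, afm.beta_b, size=n)
    af = np.minimum(af, afm.max_af * (1 - 1e-12))
    af_missing = rng.random(n) < afm.missing_rate
    pop_ac = np.floor(af * 2 * afm.ref_n).astype(np.int64)

    total_ac = 1 + rng.poisson(config.allele_count_lambda, size=n)
    score = revel if config.enrichment_tool == "revel" else cadd
    vus_like = np.array([is_vus_like(ClinvarBin(b)) for b in clinvar])
    enriched = (
        vus_like
        & (cons_draw == 2)
        & ~np.isnan(score)
        & (score >= config.enrichment_threshold)
    )
    p0 = spec.n_cases / (spec.n_cases + spec.n_controls)
    or_arr = np.where(enriched, config.enrichment_or, 1.0)
    p_case = or_arr * p0 / (1.0 - p0 + or_arr * p0)
    case_ac = rng.binomial(total_ac, p_case)
    control_ac = total_ac - case_ac
    if case_ac.max() > 2 * spec.n_cases or control_ac.max() > 2 * spec.n_controls:
        raise GenerationError(
            f"{spec.name}: generated allele counts exceed 2x a cohort size; "
            "the configuration is infeasible for these sample sizes"
        )

    records = []
    for i in range(n):
        b = ClinvarBin(clinvar[i])
        records.append(
            VariantRecord(
                chrom=chrom[i],
                pos=int(pos[i]),
                ref=_BASES[ref_idx[i]],
                alt=_BASES[alt_idx[i]],
                gene=gene_names[gene_idx[i]],
                consequence_term=str(terms[i]),
                consequence_class=(
                    Consequence.SYNONYMOUS,
                    Consequence.PTV,
                    Consequence.MISSENSE,
                )[cons_draw[i]],
                clinvar_bin=b,
                revel=None if math.isnan(revel[i]) else float(revel[i]),
                cadd=float(cadd[i]),
                pop_af=None if af_missing[i] else float(af[i]),
                pop_ac=None if af_missing[i] else int(pop_ac[i]),
                case_ac=int(case_ac[i]),
                control_ac=int(control_ac[i]),
            )
        )
    dataset = CohortDataset(
        name=spec.name, n_cases=spec.n_cases, n_controls=spec.n_controls, records=records
    )
    truth = pd.DataFrame(
        {
            "dataset": spec.name,
            "variant_id": [r.variant_id for r in records],
            "clinvar_bin": clinvar,
            "consequence_class": [r.consequence_class.value for r in records],
            "enriched": enriched,
            "designed_or": or_arr,
            "revel_class_mean": [config.revel_model[ClinvarBin(b)].mean() for b in clinvar],
            "cadd_class_mean": [config.cadd_model[ClinvarBin(b)].mean() for b in clinvar],
        }
    )
    return dataset, truth


def generate_study(config: SyntheticConfig) -> tuple[list[CohortDataset], pd.DataFrame]:
    """Generate every configured cohort (by default two strata) plus pooled truth."""
    datasets, truths = [], []
    for i in range(len(config.cohorts)):
        d, t = generate_cohort(config, i)
        datasets.append(d)
        truths.append(t)
    return datasets, pd.concat(truths, ignore_index=True)


# ---------------------------------------------------------------------------
# Config (de)serialisation for the CLI and for reproducible runs.

def config_to_dict(config: SyntheticConfig) -> dict:
    d = asdict(config)
    d["class_mixture"] = {b.value: p for b, p in config.class_mixture.items()}
    d["revel_model"] = {
        b.value: {"family": s.family, "params": list(s.params)}
        for b, s in config.revel_model.items()
    }
    d["cadd_model"] = {
        b.value: {"family": s.family, "params": list(s.params)}
        for b, s in config.cadd_model.items()
    }
    d["cohorts"] = [asdict(c) for c in config.cohorts]
    d["af_model"] = asdict(config.af_model)
    return d


def config_from_dict(d: dict) -> SyntheticConfig:
    cfg = SyntheticConfig(
        genes=dict(d["genes"]),
        cohorts=[CohortSpec(**c) for c in d["cohorts"]],
        class_mixture={ClinvarBin(k): float(v) for k, v in d["class_mixture"].items()},
        revel_model={
            ClinvarBin(k): ScoreDist(v["family"], tuple(v["params"]))
            for k, v in d["revel_model"].items()
        },
        cadd_model={
            ClinvarBin(k): ScoreDist(v["family"], tuple(v["params"]))
            for k, v in d["cadd_model"].items()
        },
        af_model=AlleleFrequencyModel(**d.get("af_model", {})),
        enrichment_or=float(d.get("enrichment_or", 1.0)),
        enrichment_tool=str(d.get("enrichment_tool", "revel")),
        enrichment_threshold=float(d.get("enrichment_threshold", 0.644)),
        ptv_fraction=float(d.get("ptv_fraction", 0.10)),
        synonymous_fraction=float(d.get("synonymous_fraction", 0.15)),
        allele_count_lambda=float(d.get("allele_count_lambda", 2.9)),
        seed=int(d.get("seed", 0)),
    )
    cfg.validate()
    return cfg
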