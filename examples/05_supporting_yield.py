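"""Supporting-pathogenic yield: how many observed variants pass the decision rules.

A filtered variant supports pathogenicity if it is P/LP in the archive,
an uncertain-class PTV, an uncertain-class missense variant at/above the
score threshold, or an archive-absent PTV or high-scoring missense
variant.  Counts are allele-weighted per cohort and gene.
"""

from varcalib import (
    default_config,
    filter_cohort,
    generate_study,
    merge_datasets,
    per_gene_matrix,
    yield_summary,
)

cfg = default_config(seed=1)
datasets, _ = generate_study(cfg)
pooled = merge_datasets(filter_cohort(d, list(cfg.genes)) for d in datasets)

for tool in ("revel", "cadd"):
    s = yield_summary(pooled, tool)
    case, control = s.totals["case"], s.totals["control"]
    print(
        f"{tool}: supporting-pathogenic {case['supporting']}/{case['total']} "
        f"({100 * case['proportion']:.2f}%) of case alleles vs "
        f"{control['supporting']}/{control['total']} "
        f"({100 * control['proportion']:.2f}%) of control alleles"
    )

matrix = per_gene_matrix([yield_summary(pooled, "revel")])
top = (
    matrix[matrix["category"] == "vus_missense_above"]
    .sort_values("count", ascending=False)
    .head(5)
)
print("\nTop genes contributing high-scoring uncertain missense alleles:")
print(top[["gene", "cohort", "count", "proportion"]].to_string(index=False))
print(
    "\nA case-minus-control gap in the supporting proportion reflects the"
    " designed enrichment of high-scoring uncertain variants in cases."
)
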