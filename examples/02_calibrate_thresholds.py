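"""Calibrate score thresholds against the benign/pathogenic truth set.

Pools the two synthetic strata, restricts to missense variants with a
benign/likely-benign (negative) or pathogenic/likely-pathogenic
(positive) archive classification, and computes the logistic model,
empirical ROC/AUC, Youden-optimal cut, KS distance, and confusion
metrics at the predetermined threshold.
"""

from varcalib import (
    LabeledScores,
    auc,
    confusion_at,
    default_config,
    filter_cohort,
    fit_logistic,
    generate_study,
    ks_two_sample,
    merge_datasets,
    roc_curve,
    youden_optimal,
)

cfg = default_config(seed=1)
datasets, _ = generate_study(cfg)
pooled = merge_datasets(filter_cohort(d, list(cfg.genes)) for d in datasets)

for tool, threshold in (("revel", 0.644), ("cadd", 20.0)):
    data = LabeledScores.from_records(pooled.records, tool)
    model = fit_logistic(data)
    curve = roc_curve(data)
    thr, tpr, fpr, j = youden_optimal(curve)
    ks = ks_two_sample(data.scores[~data.labels], data.scores[data.labels])
    conf = confusion_at(data, threshold)
    print(f"\n{tool}: {data.n_pos} pathogenic vs {data.n_neg} benign missense variants")
    print(f"  log-odds(P/LP) = {model.intercept:+.3f} {model.slope:+.3f} * score")
    print(f"  AUC = {auc(curve):.3f} (discrimination of pathogenic from benign)")
    print(f"  Youden J = {j:.3f} at threshold {thr:.3f} (TPR {tpr:.3f}, FPR {fpr:.3f})")
    print(f"  KS D = {ks.d_stat:.3f} at score {ks.at_score:.3f} -- equals J exactly")
    print(
        f"  at threshold {threshold}: sensitivity {conf.sensitivity:.3f}, "
        f"specificity {conf.specificity:.3f}, PPV {conf.ppv:.3f}, NPV {conf.npv:.3f}"
    )
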