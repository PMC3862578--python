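"""Run the three selectors (forward-backward wrapper, SVM-RFE, nearest
shrunken centroids) on the same planted dataset and compare what each
recovers."""

from wrapsel import (
    SyntheticSpec,
    cv_accuracy,
    forward_backward_select,
    generate_two_class_dataset,
    make_cv_plan,
    nsc_select,
    svm_rfe_rank,
)

spec = SyntheticSpec(
    n_pos=14, n_neg=18, n_genes=300,
    planted=((0, 2.5), (1, 2.5), (2, 2.5)), seed=7,
)
data = generate_two_class_dataset(spec)
planted = set(spec.planted_gene_ids())
plan = make_cv_plan(data.labels, k=5, r=5, seed=7)

fb = forward_backward_select(data, plan)
print(f"planted genes: {sorted(planted)}")
print(f"forward-backward: {fb.accepted}  (cv acc {fb.final_measure:.3f}, "
      f"{len(set(fb.accepted) & planted)}/3 planted)")

ranking = svm_rfe_rank(data, C=1.0, elimination_fraction=0.1)
top5 = ranking[:5]
print(f"SVM-RFE top 5:    {top5}  (cv acc "
      f"{cv_accuracy(data, top5, plan):.3f}, "
      f"{len(set(top5) & planted)}/3 planted)")

delta, active, acc = nsc_select(data, plan)
print(f"NSC at Delta*={delta:.2f}: {len(active)} active genes "
      f"(cv acc {acc:.3f}, {len(set(active) & planted)}/3 planted)")
print("The wrapper returns the smallest model; NSC keeps every gene whose")
print("shrunken score survives the threshold, so its list is usually larger.")
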