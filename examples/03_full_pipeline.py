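"""Full diagonal integration on a synthetic dataset with known pairing.

Generates the strong-linkage reference fixture, runs the complete
pipeline (akNN graphs -> hypergraph encoding -> p-best matching -> T
iterative CCA refinements -> final 1-to-N matching), and evaluates it
against the generator's ground truth.
"""

from hypermatch import (
    PipelineConfig,
    evaluate_integration,
    generate_multimodal,
    reference_fixtures,
    run_pipeline,
)

data = generate_multimodal(reference_fixtures()["easy_strong"])
print(f"linkage: p_link={data.linkage.p_link}, rho={data.linkage.rho:.2f} "
      f"({data.linkage.category})")

result = run_pipeline(data.x, data.y, data.linkage, PipelineConfig(seed=0))
print("mean matching degree per stage:",
      [round(d, 4) for d in result.diagnostics["mean_degree"]])

report = evaluate_integration(result.x_star, result.y_star, result.final_pairs,
                              data.x_labels, data.y_labels,
                              true_pairs=data.true_pairs, seed=0)
print(f"ACC       = {report.acc:.4f}   (label agreement of matched pairs)")
print(f"FOSCTTM   = {report.foscttm:.4f}   (0 = perfect cross-modal alignment)")
print(f"NMI/ARI   = {report.nmi:.4f}/{report.ari:.4f}")
print(f"S_bio     = {report.s_bio:.4f}")
print(f"S_batch   = {report.s_batch:.4f}")
print(f"S_overall = {report.s_overall:.4f}  (0.6*S_bio + 0.4*S_batch)")
# The matching degree should shrink across refinement iterations, and on
# this fixture the final matching recovers cell types almost perfectly.
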