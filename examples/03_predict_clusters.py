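"""Predict glycan clusters from glycogene expression (block-sPLS-DA).

Generates the three-cluster project preset (G0/G0F/G1F) with planted
day-0 markers, builds the block design matrix from cross-validated
pairwise sPLS correlations, runs 10-fold cross-validation of the
multiblock sparse discriminant model, and lists the genes selected in at
least 7 of 10 folds — the stable predictive genes.
"""

import warnings

warnings.filterwarnings("ignore")

from glygolgi.multiomic_predict import build_design, cross_validate, stability_select
from glygolgi.synthetic_data import make_dataset, project_b_spec

ds = make_dataset(project_b_spec(seed=7))
print("planted day-0 markers:", [(m.gene, m.cluster) for m in ds.true_markers])

design = build_design(ds.blocks)
print("\nblock design matrix (1 = strongly coupled, 0.1 = weakly):")
print(design)

report = cross_validate(ds.blocks, design, n_components=2, keep_x=6, seed=7)
print(f"\npooled CV AUC, day-0 block: {report.pooled_auc('day0'):.3f}")
print(f"pooled CV AUC, all blocks:  {report.pooled_auc():.3f}")

stable = stability_select(report, min_folds=7)
print("\nstable genes (selected in >= 7/10 folds):")
print(stable.to_string(index=False))
print(
    "\nThe day-0 stable list should recover the planted markers with the"
    "\nclass each is elevated in; day-6/day-10 blocks carry no signal."
)
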