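"""Lactation-phase discrimination with PCA and sparse PLS-DA.

Assembles the milk-scope feature matrix of a full default study (truth
level for speed), bins visits into six 50-DIM phases, and reports the
explained variances, the one-vs-rest AUROC per phase, and the features
the sparse model selects.
"""

import hrdcc

study = hrdcc.simulate_study(hrdcc.StudyConfig(), seed=1)
truth = study.truth_frame()
truth["denominator"] = "parent"
truth["mode"] = "reference"
truth = truth[["sample_id", "node", "percent", "denominator", "mode"]]

pm = hrdcc.assemble_matrix(truth, study.biomarkers, study.samples, scope="milk")
scores, loadings, evr = hrdcc.pca(pm, n_components=2)
print(f"PCA: PC1 {evr[0]:.1f} %, PC2 {evr[1]:.1f} % explained variance")

model = hrdcc.splsda_fit(pm, n_components=2, keep_x=5)
print(f"sPLS-DA: X-variate 1 {model.explained_x_variance[0]:.0f} %, "
      f"X-variate 2 {model.explained_x_variance[1]:.0f} %")
for phase in range(1, 7):
    auroc = hrdcc.auroc_one_vs_rest(model, pm, phase=phase)
    lo, hi = 50 * (phase - 1) + 1, min(50 * phase, 305)
    print(f"  phase {lo:03d}-{hi:03d} DIM vs others: AUROC {auroc:.3f}")
print("top features:", hrdcc.top_features(model, 5))
print("""
The first and last phases separate almost perfectly (early: low milk
viability and volatile counts plus metabolic markers; late: the opposed
gamma-delta / CD4+ T-cell trends), while mid-lactation phases blend into
their neighbours -- the U-shaped AUROC profile typical of a continuous
trajectory cut into bins.
""")
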