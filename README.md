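# hrdcc — high-resolution differential cell counts in bovine milk and blood

Dairy-cow immunomonitoring works today mostly through the somatic cell
count (SCC), a single concentration number that conflates very different
immune cell types. A *high-resolution differential cell count* (HRDCC)
instead quantifies, by flow cytometry, ten leukocyte subpopulations of
the three main immune populations — granulocytes (eosinophils, immature
CD11b-low granulocytes), monocytes/macrophages (blood: classical
CD14⁺CD16⁻, intermediate CD14⁺CD16⁺, nonclassical CD14⁻CD16⁺; milk:
classical and nonclassical macrophages), and lymphocytes (NK CD335⁺,
γδ-T, CD4⁺ T, CD8⁺ T, B CD21⁺) — plus cell viability and, in milk,
mammary epithelial cells (pan-cytokeratin⁺ CD45⁻), tracked in paired
milk and blood samples over an entire ~300-day lactation.

This package is a tested, reproducible implementation of that analysis
for researchers in veterinary immunology and milk diagnostics. Because
no event-level data from such studies is publicly deposited, it ships a
first-class synthetic study generator with complete ground truth, so
every stage of the pipeline can be validated quantitatively:

- **`hrdcc.simulate`** — an eight-cow longitudinal study: sampling
  schedules (twice weekly to 100 days in milk, weekly after), latent
  population trajectories with per-animal baselines, haptoglobin-defined
  inflammation episodes, serum biomarkers (haptoglobin, calcium, NEFA,
  β-HBA, bilirubin, GLDH), and 50,000-event FCS samples with hidden
  per-event truth labels (including debris, doublets, dead cells).
- **`hrdcc.gating`** — the hierarchical HRDCC gating tree in a
  fixed-threshold *reference* mode and a data-driven *auto* mode that
  places each gate at the kernel-density valley between the two highest
  modes, plus the two-mode concordance regression.
- **`hrdcc.longitudinal`** — robust outlier screening (IRLS cubic +
  FDR at rate Q), cubic polynomial and four-knot smoothing-spline
  trends, per-cow summaries.
- **`hrdcc.episodes`** — haptoglobin episode detection and in-episode
  cell-count contrasts (γδ-T down, CD4⁺ up, immature granulocytes null).
- **`hrdcc.multivariate`** — 50-DIM lactation-phase binning, PCA, a
  from-scratch sparse PLS-DA (NIPALS with soft-thresholded loadings,
  `keepX` active features per component) and one-vs-rest Mann–Whitney
  AUROCs.
- **`hrdcc.pipeline` / `hrdcc` CLI** — `simulate`, `gate`, `trend`,
  `episodes`, `cluster`, `run-all` over a directory of FCS files and
  CSV tables, with schema sidecars and a digest manifest.

## Worked example

```python
import numpy as np
import hrdcc

config = hrdcc.StudyConfig(n_animals=2, events_per_sample=20_000)
study = hrdcc.simulate_study(config, seed=1)

tree = hrdcc.build_tree("blood", config)
sample_id = study.samples.query("matrix == 'blood'").sample_id.iloc[10]
events = study.events_for(sample_id)
result = hrdcc.run_hrdcc(events, tree, mode="auto")
truth = study.states[sample_id].truth_percentages()
for node in ("granulocytes", "lymphocytes", "cd4_t_cells"):
    print(f"{node:14s} gated {result.percent_of_parent[node]:6.2f} %"
          f"  truth {truth[node]:6.2f} %")
```

prints

```
granulocytes   gated  49.45 %  truth  49.12 %
lymphocytes    gated  36.37 %  truth  36.20 %
cd4_t_cells    gated  33.66 %  truth  33.14 %
```

i.e. the automated gate placement recovers the latent composition of a
50%-granulocyte blood sample to within a few tenths of a percentage
point (main populations as % of CD45⁺ leukocytes, CD4⁺ T cells as % of
lymphocytes). The `examples/` directory holds one short script per
capability — simulation, gating concordance, longitudinal trends,
episode contrasts, and phase discrimination.

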