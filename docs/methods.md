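# Methods

## The measurement being modelled

Flow-cytometric differential cell counting of milk and blood from dairy
cows over one lactation. Each sample is a cloud of events (cells plus
debris, doublets and dead cells) in 15 channels: forward/side scatter,
a viability dye, an autofluorescence detector and 11 surface or
intracellular markers (CD45, CD14, CD16, CD11b, CD335, gdTCR, CD4, CD8,
CD21, pan-cytokeratin). The analysis reduces each sample to the HRDCC:
percentages of three main CD45⁺ populations (split by side scatter into
lymphocytes / monocytes-macrophages / granulocytes), ten subpopulations,
viability, and — in milk from 50 DIM onward — mammary epithelial cells
among CD45⁻ events.

Percentages are reported **percent-of-parent** by default (subsets
relative to their main population; main populations relative to CD45⁺,
where they sum to 100), with percent-of-CD45⁺ equivalents emitted
alongside. Percent-of-parent is the convention under which a blood CD4⁺
value of ~35 is interpretable (as a share of lymphocytes); switching
convention rescales values but never reorders siblings within a sample.

## Synthetic study generator

The generator is the package's ground-truth instrument, not a test
fixture. It emulates:

- **Design**: 8 animals, lactations drawn uniformly from 291–305 days;
  visits on day 1, twice weekly until 100 DIM, weekly thereafter; each
  visit independently missed with probability 0.035, which brings the
  ~57 scheduled visits to the observed ~55 per animal and matrix.
- **Latent composition** per visit, structured exactly like the gating
  hierarchy (main fractions of CD45⁺, subset fractions of each parent,
  viability, CD45⁻ classes). Milk granulocyte/lymphocyte fractions
  fluctuate with SD 0.10 before the level-out at ~150 DIM and 0.04
  after; milk γδ-T declines (≈42% → ≈6% of lymphocytes) and CD4⁺ rises
  (≈7% → ≈37%) through a linear component, a mid-lactation step and an
  end-of-lactation involution step (centre 260 DIM) that encodes the
  steeper T-cell change toward dry-off; milk viability recovers
  exponentially from ~50% at calving to ~93% (time constant 40 d).
  Blood is stationary around per-animal baselines. Two animals carry
  fixed blood CD4⁺ profiles — cow 1: mean 34.7% of lymphocytes, visit
  SD 2.9; cow 6: 19.7%, SD 2.6 — the remaining baselines draw from a
  between-animal spread (SD 0.05 on the fraction scale). Other
  populations get zero-mean per-animal offsets whose SDs shrink for
  small or strongly phase-trending populations; offset-shifted means are
  clamped to (0.005, 0.95), while structurally impossible *baseline*
  parameters raise an error.
- **Episodes**: a Poisson number (mean 1 per lactation) of inflammation
  windows of 10–22 days; overlapping windows merge. Within a window,
  haptoglobin rises by 0.40 g/L over its 0.08 g/L baseline (visit SD
  0.015), milk γδ-T shifts −8 points of lymphocytes and CD4⁺ +6, with
  the marker-negative lymphocyte remainder absorbing the imbalance.
  Immature granulocytes are deliberately untouched, so any detected
  association with inflammation downstream is a false positive. A small
  calving window (amplitude 0.04 g/L, time constant 5 d) occasionally
  produces a cow-5-style early elevation without systematically
  triggering the episode detector in healthy animals.
- **Biomarkers**: NEFA, β-HBA, bilirubin and GLDH start elevated and
  decay exponentially to baseline (negative-energy-balance phase);
  calcium dips briefly after calving; all values are positive, with
  multiplicative Gaussian noise (CV 10%, calcium 3%).
- **Events**: 50,000 per sample by default. Each population is a
  location-scale Gaussian cluster per channel *on the asinh scale*
  (negatives at 0.4 ± 0.3, positives at 3.0 ± 0.3, CD11b-low at 1.2,
  eosinophil autofluorescence at 2.6); instrument-scale values are
  `sinh(z) × cofactor` with cofactor 150, so the gating-side transform
  recovers Gaussians exactly. Scatter is linear (lymphocytes 18k ± 3.5k
  SSC, monocytes 50k ± 5k, granulocytes 95k ± 7k). Nuisance classes:
  6% debris (low scatter), 4% doublets (FSC-A ≈ 2 × FSC-H), and dead
  cells (high viability dye) at 1 − viability of the cell fraction.
  Nonclassical macrophages draw CD14 from an equal mixture of the
  positive and negative levels, matching their CD14⁺/⁻CD16⁺ definition.
  The milk pan-cytokeratin channel is *omitted* (not zeroed) before
  50 DIM, so consumers must handle a missing channel. A small CD45⁻
  pan-cytokeratin⁻ residual class (milk 2%, blood 1.5% of live cells)
  keeps the MEC gate's parent population bimodal, as in real washed
  samples.

Spillover/compensation, absolute concentrations (SCC-style counts),
antibody titration and instrument drift are not modelled; the simulator
emits compensated-scale data directly because the analysis consumes
compensated data. Consequently, passing tests demonstrate correctness of
the *analysis* under realistic composition, noise and nuisance
structure — not robustness to compensation artefacts or acquisition
drift.

### Calibration of the defaults

Sample sizes, schedules, the cow-1/cow-6 CD4⁺ profiles, and the
episode-null for immature granulocytes are fixed by the study design
being emulated. Trend shapes and effect sizes were calibrated once, as
shipped defaults, so that the generator encodes the study's reported
discriminability: in particular the milk T-cell trends carry a
continuing late-lactation component (the involution step above) large
enough that the last 50-DIM phase is nearly as separable as the first —
without it, a lactation that plateaus after mid-lactation cannot show
the reported first/last-phase symmetry. These are generator parameters,
not per-run tuning; every analysis and test runs against the same
shipped configuration.

## Gating

Both modes share the tree and differ only in threshold placement.

- **Reference mode** uses fixed cuts at the midpoints between the
  configured negative and positive signature locations — the stand-in
  for manually placed, FMO-informed gates, which are not tabulated
  anywhere for this assay.
- **Auto mode** re-derives each marker and scatter cut per sample from
  the parent population: a Gaussian-KDE (Silverman bandwidth, evaluated
  as a 512-bin smoothed histogram for speed) is scanned for modes;
  adjacent maxima are merged unless the valley between them drops below
  half the lower peak (suppressing jagged-top artefacts); the cut is the
  density minimum between the two highest modes, ties broken toward the
  channel median. Unimodal densities fall back to a per-node quantile;
  parents under 500 events fall back to the reference cut. The
  side-scatter split takes the two valleys between the three highest
  modes. Thresholding is fully deterministic.
- **Fixed rules in both modes**: debris = FSC-A and SSC-A jointly below
  the reference low-scatter gate; doublets = FSC-A/FSC-H > 1.5. These
  correspond to acquisition-wide scatter gates set once per experiment.
- Viability = live singlets / non-debris singlets × 100. Lymphocyte
  subsets are gated sequentially (NK → γδ-T → CD4⁺ → CD8⁺ → B) so no
  event lands in two sibling populations; nonclassical macrophages pool
  the two CD16⁺ quadrants.

Mode concordance is summarised by simple linear regression of pooled
(sample × node) percentages, automated on reference.

## Longitudinal statistics

Outlier screening precedes every trend fit: an IRLS cubic with Tukey
biweight resists the outliers, residuals are standardised by a
MAD-based scale, and two-sided t tail probabilities are screened with
Benjamini–Hochberg at rate Q (default 1%). This is an open equivalent
of robust-regression-and-outlier-removal procedures in commercial
software; numeric identity with any particular product is not claimed.
Trends are a least-squares cubic and a cubic regression spline with
four interior knots at the DIM quantiles {0.2, 0.4, 0.6, 0.8} of the
unflagged points (duplicate abscissae from pooled multi-animal series
are averaged first). Episode contrasts use a two-sided Mann–Whitney
test; for populations with strong lactation trends the package also
offers a detrended contrast against a spline fitted to out-of-episode
visits only, because a mid-lactation episode in a declining series is
otherwise compared against pooled early (high) and late (low) values
and loses power.

## Phase discrimination

Visits are binned into six 50-DIM phases (1–50 … 251–305; later DIMs
clamp to phase 6 with a warning). Feature matrices join milk and blood
HRDCCs of the same visit with the serum panel, drop incomplete visits
rather than impute, exclude MECs, and standardise columns. PCA is a
plain SVD of the standardised matrix. Sparse PLS-DA dummy-codes the
phase, centres both blocks, and per component iterates NIPALS updates
with soft-thresholding that keeps exactly `keepX` (default 5)
loading-weight entries, normalises, converges at 1e-6 or 500
iterations, then deflates both blocks by regression on the score. With
`keepX = p` it reduces to dense PLS-DA (verified against an independent
NIPALS implementation). The one-vs-rest AUROC uses the dummy-Y
regression prediction for the phase as the score, computed on the
fitted data — the single-fit convention matching how such AUROCs are
reported alongside score plots; cross-validation is intentionally out
of scope of the default read-out.

## Numerical and engineering choices

- All randomness flows from one integer seed through
  `numpy.random.SeedSequence` spawn keys fixed by (stage, animal,
  matrix, visit), so any single sample is reproducible in isolation and
  regeneration is bit-identical.
- FCS I/O is a minimal FCS 3.1 float list-mode implementation; truth
  labels travel in a `*_truth.csv` sidecar keyed by event index, never
  inside the FCS file.
- Soft-threshold ties at the `keepX` boundary (measure-zero in
  continuous data) fall back to hard top-`keepX` selection so sparsity
  is exact.
- Degenerate inputs raise: constant densities, zero-variance
  correlations, rank-deficient polynomial designs, empty samples, and
  samples whose events are entirely removed by nuisance gating.

## Known limitations

- Event clusters are Gaussian on the transformed scale; real cytometry
  shows heavier tails, spectral spillover residuals and acquisition
  drift, so real-data concordance between gating modes will be lower
  than the synthetic figure.
- The AUROCs are training-data values by convention; they quantify
  separation of the fitted scores, not out-of-sample classification.
- The episode detector is a threshold-run rule on haptoglobin; it makes
  no attempt to classify the underlying condition.
- Percentages, not absolute concentrations: without an SCC-style volume
  anchor the simulator and pipeline work entirely in fractions.
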