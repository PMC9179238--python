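"""Per-cow longitudinal description of a population percentage.

Fits the outlier-screened four-knot spline to one cow's milk gamma-delta
T-cell series (truth level, so the trend is exact) and summarises the
stationary blood CD4+ series of the two cows with fixed profiles.
"""

import numpy as np

import hrdcc

study = hrdcc.simulate_study(hrdcc.StudyConfig(), seed=1)

milk = sorted((s for s in study.states.values()
               if s.matrix == "milk" and s.animal_id == "cow1"),
              key=lambda s: s.dim)
dims = np.array([s.dim for s in milk], dtype=float)
gdt = np.array([100 * s.lymph_subsets["gd_t_cells"] for s in milk])
fit = hrdcc.fit_trend(dims, gdt, kind="spline4", q=0.01)
print(f"cow1 milk gd-T: {len(dims)} visits, {fit.flags.sum()} flagged as outliers")
print(f"  spline at DIM  25: {fit.predict(25.0):5.1f} %")
print(f"  spline at DIM 150: {fit.predict(150.0):5.1f} %")
print(f"  spline at DIM 290: {fit.predict(290.0):5.1f} %")

for cow in ("cow1", "cow6"):
    blood = [100 * s.lymph_subsets["cd4_t_cells"]
             for s in study.states.values()
             if s.matrix == "blood" and s.animal_id == cow]
    mean, sd, n = hrdcc.per_animal_summary(np.array(blood))
    print(f"{cow} blood CD4+: mean {mean:.1f} %, SD {sd:.1f}, n {n}")
print("""
Milk gamma-delta T cells decline several-fold over lactation, while each
cow's blood CD4+ level stays in a narrow band around its own baseline --
the two baselines differ by ~15 points between these cows.
""")
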