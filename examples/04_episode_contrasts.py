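"""Detect an inflammation episode and quantify its cell-count shifts.

Forces one haptoglobin episode (DIM 75-96, like a claw lesion detected
through the acute-phase response), recovers it from the serum series,
and contrasts milk gamma-delta T / CD4+ T / immature granulocytes inside
vs outside the episode.
"""

import numpy as np

import hrdcc

config = hrdcc.StudyConfig(n_animals=1)
config.episodes.rate_per_lactation = 0.0          # only the forced window
study = hrdcc.simulate_study(config, seed=3,
                             forced_episodes={"cow1": [(75, 96)]})

hp = study.biomarkers.query("analyte == 'haptoglobin'").sort_values("dim")
episodes = hrdcc.detect_episodes(hp.dim.to_numpy(), hp.value.to_numpy(),
                                 config.haptoglobin_threshold,
                                 animal_id="cow1")
for ep in episodes:
    print(f"episode: DIM {ep.start}-{ep.end}, {ep.n_visits} visits, "
          f"peak haptoglobin {ep.peak_haptoglobin:.2f} g/L")

milk = sorted((s for s in study.states.values() if s.matrix == "milk"),
              key=lambda s: s.dim)
dims = np.array([s.dim for s in milk], dtype=float)
for node, getter in (
        ("gd_t_cells", lambda s: s.lymph_subsets["gd_t_cells"]),
        ("cd4_t_cells", lambda s: s.lymph_subsets["cd4_t_cells"]),
        ("immature_granulocytes",
         lambda s: s.gran_subsets["immature_granulocytes"])):
    values = np.array([100 * getter(s) for s in milk])
    con = hrdcc.episode_contrast(dims, values, episodes, node, detrend=True)
    print(f"{node:22s} in-out difference {con.difference:+6.2f} points, "
          f"p = {con.p_value:.3g}")
print("""
Gamma-delta T cells drop and CD4+ T cells rise during the episode, while
immature granulocytes show no shift -- the generator encodes that null,
so a significant result there would indicate a pipeline artefact.
""")
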