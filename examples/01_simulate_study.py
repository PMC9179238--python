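"""Generate a small synthetic study and look at its anatomy.

Two cows, both matrices, a full lactation of visits; prints the visit
schedule density, the injected inflammation episodes, and one sample's
event-level composition (including the nuisance classes a cytometrist
would gate away).
"""

import collections

import hrdcc

config = hrdcc.StudyConfig(n_animals=2, events_per_sample=20_000)
study = hrdcc.simulate_study(config, seed=1)

for cow, grp in study.samples.groupby("animal_id"):
    milk = grp[grp.matrix == "milk"]
    print(f"{cow}: {len(milk)} milk visits, DIM {milk.dim.min()}-{milk.dim.max()}")

print("episodes:", [(e.animal_id, e.start, e.end) for e in study.episodes])

sample_id = study.samples.sample_id.iloc[0]
events = study.events_for(sample_id)
counts = collections.Counter(events.truth_labels)
print(f"\n{sample_id}: {events.n_events} events, channels: {events.channels}")
for label, n in counts.most_common(6):
    print(f"  {label:22s} {100 * n / events.n_events:5.1f} %")
print("""
The day-1 milk sample is dominated by dead cells (viability is lowest at
calving) and lacks the panCK channel, which is only recorded from 50 DIM.
""")
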