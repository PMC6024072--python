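"""Inter-rater agreement gating and photo -> minute -> 5-min aggregation.

Before annotating study data, an annotator must reach Cohen's kappa >= 0.85
against a reference in every category.  Here a candidate annotator is
simulated by flipping a few percent of a reference annotator's flags; the
gate reports kappa per concept and names any failure.  Aggregation then
collapses photo-level booleans to minute booleans (present at any point in
the minute) and 5-minute presence proportions.
"""

import numpy as np
import pandas as pd

from campm import gate_annotator, minutes_to_intervals, photos_to_minutes

rng = np.random.default_rng(0)
n = 600

# reference annotations for a training photo set, three concepts
reference = pd.DataFrame({
    "kitchen": rng.random(n) < 0.4,
    "smoking": rng.random(n) < 0.1,
    "road": rng.random(n) < 0.3,
})
# candidate: disagrees on 2% of kitchen/road photos, 12% of smoking photos
candidate = reference.copy()
for concept, flip_rate in [("kitchen", 0.02), ("smoking", 0.12), ("road", 0.02)]:
    flip = rng.random(n) < flip_rate
    candidate[concept] = np.where(flip, ~reference[concept], reference[concept])

result = gate_annotator(reference, candidate, threshold=0.85)
print("annotator gate:", "PASS" if result.passed else "FAIL")
for name, k in result.kappas.items():
    print(f"  {name:<10} kappa = {k.kappa:.3f}  (p_o={k.p_observed:.3f}, "
          f"p_e={k.p_expected:.3f})")
if result.failing:
    print("  failing categories:", ", ".join(result.failing))

# aggregation: 12 photos over 6 minutes, one participant-day
t0 = pd.Timestamp("2015-06-01 09:00:00")
photos = pd.DataFrame({
    "photo_id": [f"ph{i}" for i in range(12)],
    "participant_day": "P1_S1",
    "timestamp": [t0 + pd.Timedelta(seconds=35 * i) for i in range(12)],
    "codeable": True,
    "annotator_id": "A1",
    "kitchen": [True] * 8 + [False] * 4,
    "smoking": [False, True] * 6,
    "road": False,
})
minutes = photos_to_minutes(photos)
intervals = minutes_to_intervals(minutes)
print("\nminute flags (OR over codeable photos in the minute):")
print(minutes[["minute", "kitchen", "smoking", "n_photos"]].to_string(index=False))
print("\n5-min proportions (fraction of observed minutes carrying the concept):")
print(intervals.to_string(index=False))
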