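"""Segment one session into repetitions and extract its feature table.

Shows the three preprocessing stages on a single subject: band-splitting at
the 32 Hz working rate, repetition segmentation from the wrist angular-speed
envelope, and extraction of the 378-feature vector per repetition.
"""

import moveprof as mp
from moveprof import preprocess, segment

archetypes = mp.build_default_archetypes()
config = mp.CohortConfig(n_subjects=2, movements=("PUSH", "GST"), seed=7)
profiles = mp.default_profiles()
session = mp.generate_subject(archetypes, profiles["high"], config, seed=7)

filtered = preprocess.filter_session(session)
results = segment.segment_session(session, filtered)
for res in results:
    r0 = res.repetitions[0]
    durations = [f"{r.duration_s:.1f}" for r in res.repetitions]
    print(f"{r0.movement}/{r0.side}: {len(res.repetitions)} repetitions, "
          f"durations {durations} s, review={res.needs_review}")

table, _ = mp.session_features(session)
print(f"\nfeature table: {len(table)} repetitions x {len(table.feature_names)} features")
wrist = [c for c in table.feature_names if c.startswith("r_wrist_gyro_x_bandpass")]
print(table.data[["movement", "side"] + wrist].head(4).to_string(index=False))
# The band-pass dominant frequency of the driving wrist channel sits near each
# archetype's fundamental (PUSH 0.42 Hz, GST 0.33 Hz) for high-grade execution.
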