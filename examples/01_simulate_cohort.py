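"""Generate a small synthetic cohort and inspect its ground truth.

Builds a 3-subject cohort of the six default movement archetypes, writes the
sessions to disk in the per-sensor CSV + JSON manifest layout, and prints the
truth table. Each row of the truth table is one repetition with its
grade and its boundaries (pause-midpoint convention) in seconds.
"""

from pathlib import Path

import moveprof as mp

out = Path("scratch/example_cohort")
config = mp.CohortConfig(n_subjects=3, seed=42)
sessions, truth = mp.generate_cohort(config)

for session in sessions:
    mp.write_session(session, out / session.subject_id)

print(f"wrote {len(sessions)} sessions to {out}/")
print(f"{len(truth)} repetitions; grade counts per movement:")
print(truth.groupby(["movement", "grade"]).size().unstack(fill_value=0))
print("\nfirst repetitions of subject S00:")
print(truth.head(6).to_string(index=False))
# Expect 66 repetitions per subject: 5 bilateral movements x 2 sides x 6 reps
# plus 6 reps of the symmetric RTP movement, each with a low/medium/high grade.
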