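"""Evaluate movement identification and proficiency under repeated LOSO.

Runs the full study protocol at a reduced size (5 subjects, 2 repeats):
leave-one-subject-out cross-validation with nested per-fold feature selection,
reporting the repetition-level micro F1 for movement identification, and both
repetition-level and majority-vote (overall) micro F1 for each movement's
proficiency model and the unified model.
"""

import moveprof as mp

config = mp.CohortConfig(n_subjects=5, seed=17)
sessions, _ = mp.generate_cohort(config)
table, _ = mp.cohort_features(sessions)

ec = mp.EvalConfig(n_repeats=2, seed=4)
movement = mp.evaluate_movement_id(table, ec)
print(f"movement identification micro F1: "
      f"{100 * movement.f1_mean:.2f} +/- {100 * movement.f1_sd:.2f}%")
print("confusion matrix (rows = true):")
print(movement.confusion)

prof = mp.evaluate_proficiency(table, ec)
print("\nproficiency (micro F1 %):       repetitions    overall")
for name, rep in prof.items():
    print(f"  {name:8s} {100 * rep.f1_mean:21.2f} {100 * rep.overall_f1_mean:10.2f}")
# Majority-voting repetitions into one grade per (subject, movement, side)
# raises the score whenever more than half of a subject's repetitions are
# graded correctly — the same aggregation experts use when scoring a set.
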