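"""Simulate a small navigator cohort and compute integrated motion scores.

Generates 15 synthetic scans (32-channel navigator series with known
radiologist-style grades 1-5), runs preprocessing + the four coil-combination
metrics, and prints the integrated motion score of each subject.
"""

import tempfile
from pathlib import Path

from fidnav.pipeline import score_cohort
from fidnav.simulate import generate_cohort

with tempfile.TemporaryDirectory() as tmp:
    cohort_dir = Path(tmp) / "cohort"
    manifest = generate_cohort(cohort_dir, n_subjects=15, seed=7)
    scores = score_cohort(cohort_dir)

print(f"{'subject':>8} {'grade':>5} {'profile':>11} {'ccc x100':>9} {'delta':>7}")
merged = scores.merge(manifest[["subject_id", "profile"]], on="subject_id")
for row in merged.itertuples():
    print(f"{row.subject_id:>8} {row.grade:>5} {row.profile:>11} "
          f"{row.ccc * 100:>9.4f} {row.delta:>7.4f}")

print()
print("Scores are in 1/s (ccc shown x100). Low grades (heavy motion) should")
print("carry integrated scores orders of magnitude above the grade-5 noise floor.")
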