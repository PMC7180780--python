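"""Simulate a repeated-measurement cohort and show one subject's protocol.

Each subject is measured five times; for every sequence two trained observers
read the auscultatory pressure in whole mmHg and their average becomes the
reference SBP/DBP for that repeat.
"""

import pandas as pd

from ebrm import CohortConfig, simulate_cohort

cfg = CohortConfig(n_subjects=85, seed=0)
cohort = simulate_cohort(cfg)

subject = cohort[0]
print(f"cohort: {len(cohort)} subjects x 5 sequences = {5 * len(cohort)} rows")
print(f"subject {subject.subject_id}: true SBP/DBP = "
      f"{subject.true_sbp:.0f}/{subject.true_dbp:.0f} mmHg\n")

rows = [
    {
        "seq": s.seq_index,
        "nurse1_sbp": s.nurse1_sbp, "nurse2_sbp": s.nurse2_sbp, "ref_sbp": s.ref_sbp,
        "nurse1_dbp": s.nurse1_dbp, "nurse2_dbp": s.nurse2_dbp, "ref_dbp": s.ref_dbp,
    }
    for s in subject.sequences
]
print(pd.DataFrame(rows).to_string(index=False))
print("\nEach ref column is the mean of the two observer readings; the spread "
      "across sequences is within-subject physiological variation.")
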