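"""Run the full behavioural pipeline on a generated cohort.

Generates a synthetic three-group cohort (21 controls / 16 amputees /
17 congenital one-handers, 2 blocks x 48 images), maps stimulus sides to
intact/missing hands, filters invalid trials, assigns image difficulty
from the control group's per-image median RTs, trims log-RT outliers, and
prints group-level accuracy and signal-detection indices.
"""

import warnings

import numpy as np
import pandas as pd

from handrace import (
    apply_difficulty,
    assign_difficulty,
    filter_trials,
    generate_cohort,
    log_trim_rt,
    map_hands,
    sdt_indices,
    subject_summary,
)

trials, subjects, _ = generate_cohort(seed=42)
mapped = map_hands(trials, subjects)
valid, report = filter_trials(mapped)
print(f"{len(trials)} trials from {len(subjects)} subjects; "
      f"{len(trials) - len(valid)} dropped (noisy or no response); "
      f"{int(report['excluded'].sum())} subject(s) above the 27% no-response cutoff")

# difficulty split from the control group standing in as the reference
dmap = assign_difficulty(valid[valid["group"] == "controls"])
valid = apply_difficulty(valid, dmap)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    trimmed, counts = log_trim_rt(valid)
summary = subject_summary(valid, trimmed, counts)

print("\nper-group mean accuracy by hand:")
acc = summary.groupby(["group", "stimulus_hand"])["accuracy"].mean().unstack()
print(acc.round(3).to_string())

print("\nper-group mean RT (geometric, s) by difficulty:")
rt = np.exp(summary.groupby(["group", "difficulty"])["mean_log_rt"].mean()).unstack()
print(rt.round(3).to_string())

rows = []
for (sid, grp), sub in valid.groupby(["subject_id", "group"]):
    idx = sdt_indices(sub)
    rows.append({"group": grp, "d_prime": idx.d_prime, "criterion_c": idx.criterion_c})
sdt = pd.DataFrame(rows).groupby("group").mean()
print("\nmean signal-detection indices (intact hand = signal):")
print(sdt.round(3).to_string())
print(
    "\nA positive criterion c means over-reporting 'missing hand'; the"
    "\nsingle-simulator congenital group shows the largest c while d'"
    "\nstays comparable across groups."
)
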