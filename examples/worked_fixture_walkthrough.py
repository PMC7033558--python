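"""Walk the tiny worked fixture through the pipeline, by hand-checkable steps.

Three constructed subjects: S1 answers 10/12 correctly, S2 misses 4/12
responses (33%, above the 27% exclusion cutoff), and S3 is built with
5/6 hits and 2/6 false alarms under the intact-as-signal convention.
"""

from scipy import stats as sps

from handrace import filter_trials, map_hands, sdt_indices, worked_fixture

trials, handedness = worked_fixture()
mapped = map_hands(trials, handedness)
valid, report = filter_trials(mapped)

print("per-subject exclusion report:")
print(report.round(3).to_string(index=False))

s1 = valid[valid["subject_id"] == "S1"]
print(f"\nS1 accuracy: {int(s1['correct'].sum())}/{len(s1)} = {s1['correct'].mean():.4f}")

idx = sdt_indices(valid[valid["subject_id"] == "S3"])
zh, zf = sps.norm.ppf(5 / 6), sps.norm.ppf(2 / 6)
print(f"\nS3 signal detection: H = {idx.hit_rate:.3f}, F = {idx.false_alarm_rate:.3f}")
print(f"  d' = {idx.d_prime:.4f}  (hand arithmetic: z(5/6) - z(2/6) = {zh - zf:.4f})")
print(f"  c  = {idx.criterion_c:.4f}  (hand arithmetic: -(z(5/6)+z(2/6))/2 = {-(zh + zf) / 2:.4f})")
print("\nA negative c for S3 means a slight tendency to respond 'intact'.")
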