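"""Rebuild reading sessions from timestamps and plot recall-rate decline.

Sessions are cut wherever a reader's idle gap reaches the break threshold
(20 min here); position in session then proxies time on task.  With the
generator's drifting criterion, the recall rate falls from the start of a
session to position 200 while the cancer detection rate stays flat.
"""

from vigilread import BreakDefinition, SimConfig, rates_by_position, simulate_cohort
from vigilread.io import attach_women
from vigilread.sessions import apply_exclusions, included, position_bin_array, segment_sessions

women, events = simulate_cohort(SimConfig(n_women=100_000, seed=42))
first = events[events["reader_role"] == "first"]
merged = attach_women(first, women).sort_values(
    ["reader_id", "decision_timestamp"], kind="mergesort"
).reset_index(drop=True)

positioned = segment_sessions(merged, BreakDefinition(20.0))
records = included(apply_exclusions(positioned))
records = records[records["position"] <= 200]

print(f"analysis records: {len(records):,} "
      f"(dropped position 1, position > 200, moved and second-reader cases)")

bins = position_bin_array(records["position"].to_numpy())
recall = (records["decision"] == "recall").to_numpy()
tp = recall & (records["cancer_status"] != "none").to_numpy()
print("\nbin  positions  recall-rate  cancer-detection-rate      n")
for b, label in [(1, "2-30"), (2, "31-60"), (3, "61-90"), (4, "91-200")]:
    m = bins == b
    print(f"  {b}  {label:>8}  {100 * recall[m].mean():10.2f}%  "
          f"{100 * tp[m].mean():20.2f}%  {m.sum():7,}")
# Recall declines across bins (the reader grows more conservative with time
# on task) while detection is roughly constant: fewer false alarms at no
# cost in detected cancers.
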