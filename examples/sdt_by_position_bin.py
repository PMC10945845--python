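"""Signal-detection statistics by position bin: the constant-d' signature.

If declining recall reflected a vigilance decrement, discriminability d'
would fall with time on task.  Under the multiple-decision model it is the
criterion c that rises (readers become more conservative) while d' stays
flat — which is what the binned estimates on simulated data show.
"""

from vigilread import BreakDefinition, SimConfig, sdt_by_bin, simulate_cohort
from vigilread.io import attach_women
from vigilread.sessions import apply_exclusions, included, segment_sessions

women, events = simulate_cohort(SimConfig(n_women=200_000, seed=42))
first = events[events["reader_role"] == "first"]
merged = attach_women(first, women).sort_values(
    ["reader_id", "decision_timestamp"], kind="mergesort"
).reset_index(drop=True)
records = included(apply_exclusions(segment_sessions(merged, BreakDefinition(20.0))))
records = records[records["position"] <= 200]

table = sdt_by_bin(records)
wide = table.pivot(index="position_bin", columns="metric", values="value")
print("bin   d-prime   criterion")
for b, row in wide.iterrows():
    print(f"  {b}   {row['d_prime']:7.3f}   {row['criterion']:9.3f}")
# d' hovers around one level in every bin (pooling over readers attenuates
# it below the generating 2.79) while the criterion climbs from bin 1 to
# bin 4: a threshold shift, not a loss of discriminability.
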