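"""Programme-scale impact of the start-of-session recall excess.

The English programme screens about 2 million women a year.  If the recall
rate is 4.66% at the start of a session and 3.24% by the 200th case, the
start-of-session excess projects to tens of thousands of avoidable
false-positive recalls annually.
"""

from vigilread import projected_excess_recalls

absolute, relative = projected_excess_recalls(
    rate_start=0.0466, rate_end=0.0324, annual_volume=2_000_000
)
print(f"excess recalls per year : {absolute:,.0f}")
print(f"relative to the end rate: {relative:.0f}%")
# 28,400 excess recalls, a 44% relative increase over the end-of-session
# rate — the operational cost of the fresh-start criterion.
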