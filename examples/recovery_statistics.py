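"""Morphine-recovery table and pairwise Welch tests for protocols A-D.

Simulates replicate morphine measurements at the reported per-protocol
means/SDs (n=6 for A and C, n=3 for B and D), summarises them into the
recovery table (filtrate + cotton-wash means, totals, efficiency against
the 45 mg labelled content) and runs all pairwise Welch tests on the
totals.
"""

from partiquant import DEFAULT_RECOVERY_PARAMS, generate_measurements
from partiquant.recovery import build_report, pairwise_welch, summarize_method

measurements = generate_measurements(DEFAULT_RECOVERY_PARAMS, seed=42)
summaries = {
    m: summarize_method([x for x in measurements if x.method == m]) for m in "ABCD"
}
report = build_report(summaries, pairwise_welch(summaries, field="sum"))
print(report["markdown"])
print("\nefficiency_pct = 100 x (extracted + remaining) / 45 mg labelled content;")
print("stars mark Welch p-values below 0.05 / 0.01 / 0.001.")
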