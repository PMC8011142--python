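"""Generate a labelled synthetic ACC stream and segment it into bouts.

A back-mounted bird tracker records at 10.54 Hz; we cut the stream into
40-record (3.8 s) windows and keep only windows whose samples all carry
one behaviour label — windows straddling a behaviour switch are pruned.
"""

import ethoclass as ec

config, specs = ec.preset("stork")
series, intervals = ec.generate_series(specs, total_s=1800.0, fs=config.fs, seed=7)

bouts, pruned = ec.segment_series(series, intervals, config)
counts = {}
for b in bouts:
    counts[b.label] = counts.get(b.label, 0) + 1

print(f"stream: {len(series)} samples ({len(series) / config.fs:.0f} s), "
      f"{len(intervals)} behaviour episodes")
print(f"windows of {config.bout_len_records} records: "
      f"{len(bouts)} retained, {pruned} pruned (mixed behaviour)")
for label, n in sorted(counts.items()):
    print(f"  {label:>15}: {n} bouts")
# Retained + pruned equals the number of full windows; pruned windows are
# the price of guaranteeing that every training bout shows one behaviour.
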