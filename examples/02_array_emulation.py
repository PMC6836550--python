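"""Emulated array-CGH calling and the WGS-vs-array comparison.

A 628-kb heterozygous deletion is planted, probe log2 ratios are simulated
at 18-kb spacing, and CNVs are called with the three-consecutive-aberrant-
probe rule (cutoffs -0.65 / +0.35).  The WGS call set then confirms the
array call by direction-matched overlap.
"""

from cytowgs import (
    GenomicInterval, SvRecord, call_probes, compare_callsets, mlpa_call,
    synth,
)
from cytowgs.genome import GenomeModel

model = GenomeModel(contigs={"2": 243_199_373})
event = synth.SvEvent("2", 166_050_817, 166_679_227, "DEL", copy_number=1)
series = synth.simulate_probe_series(model, [event], spacing=18_000,
                                     noise_sd=0.15, seed=11)
calls = call_probes(series)
for c in calls:
    print(f"array call: {c.interval} {c.direction} "
          f"({c.n_probes} probes, mean log2 {c.mean_log2:.2f})")

wgs = [SvRecord("del", "DEL", GenomicInterval("2", 166_050_817, 166_679_227))]
report = compare_callsets(wgs, calls)
print(f"array calls confirmed by WGS: {report.n_found}/{report.n_cma} "
      f"({100 * report.found_fraction:.0f}%)")
# MLPA-style ratio interpretation of the same heterozygous deletion:
print(f"MLPA ratio 0.55 -> {mlpa_call(0.55)}")
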