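"""Detect a maternal segmental isodisomy on chromosome 15 from SNV zygosity.

SNV sites are simulated over a 102-Mb chromosome with an isodisomic segment
planted at 22.9-33.7 Mb; the windowed homozygosity track and RoH caller
recover the segment, and trio genotypes type it as maternal.
"""

from cytowgs import call_roh, classify_upd, synth, zygosity_track

CHR15 = 102_531_392
spec = synth.UpdSpec(22_900_000, 33_700_000, "isodisomy", "maternal")

sites, _ = synth.simulate_snp_sites(CHR15, het_rate=1 / 1500,
                                    upd=spec, error_rate=0.001, seed=1)
track = zygosity_track(sites, chrom="15", chrom_length=CHR15)
segments = call_roh(track)
for seg in segments:
    print(f"RoH segment: {seg.interval} "
          f"(mean hom fraction {seg.mean_hom_fraction:.3f})")

trio, _ = synth.simulate_trio_sites(CHR15, upd=spec, seed=1)
call = classify_upd(trio, segments, chrom="15", chrom_length=CHR15)
print(f"UPD call: {call.kind} ({call.parent}), region {call.region}")
# The recovered segment end (~33.7 Mb) matches the planted isodisomy;
# biparental incompatibilities in the trio confirm maternal origin.
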