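"""Quantify a mosaic trisomy 9 from whole-autosome read-depth bins.

Chromosome 9 carries an extra copy in 46% of cells; its median depth over
the autosomal baseline inverts to the cell fraction via f = 2(r - 1).
"""

from cytowgs import chrom_ratio, detect_aneuploidy, mosaic_fraction, synth
from cytowgs.genome import AUTOSOMES, GRCH37_LENGTHS

contigs = {c: GRCH37_LENGTHS[c] for c in AUTOSOMES}
bins, _ = synth.simulate_depth_bins(contigs, aneuploidy={"9": 0.46},
                                    depth=30, bin_bp=1000, seed=1)
cr = chrom_ratio(bins, "9")
f = mosaic_fraction(cr.ratio, "gain")
print(f"chr9 coverage ratio: {cr.ratio:.4f} (z = {cr.z:.0f})")
print(f"estimated mosaic fraction: {100 * f:.1f}% of cells")

calls = [c for c in detect_aneuploidy(bins) if c.call != "normal"]
print("genome-wide scan:",
      [(c.chrom, c.call, round(c.mosaic_fraction, 2)) for c in calls])
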