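"""Reconstruct derivative chromosomes and infer junction mechanisms.

Two geometries: a DEL-INV-DEL rearrangement (two deletions flanking an
inverted copy-neutral segment) and a ring chromosome 18 formed by fusing
both chromosome arms after terminal deletions.
"""

import numpy as np

from cytowgs import (
    Breakend, GenomicInterval, Junction, SvCluster, SvRecord,
    analyze_junction, classify_structure, infer_mechanism,
    reconstruct_derivative, synth,
)

# --- DEL-INV-DEL on chromosome 2 -------------------------------------------
s1, e1, e2, e3 = 166_050_817, 166_679_227, 166_818_452, 166_939_516
cluster = SvCluster(
    records=[SvRecord("del1", "DEL", GenomicInterval("2", s1, e1)),
             SvRecord("inv", "INV", GenomicInterval("2", e1, e2)),
             SvRecord("del2", "DEL", GenomicInterval("2", e2, e3))],
    junctions=[Junction(Breakend("2", s1, "L"), Breakend("2", e2, "L")),
               Junction(Breakend("2", e1, "R"), Breakend("2", e3, "R"))],
)
structures = reconstruct_derivative(cluster, {"2": 243_199_373})
for st in structures:
    print("derivative:", " ".join(f"{iv}{o}" for iv, o in st.segments))
print("topology:", classify_structure(structures, cluster))

# junction sequences with templated insertions -> replicative signature
rng = np.random.default_rng(0)
tpl = "".join(rng.choice(list("ACGT"), size=38))
fx = synth.synthesize_junction(mh=0, ins=tpl, seed=1)
context = [("junction2_flank",
            "".join(rng.choice(list("ACGT"), 40)) + tpl)]
analysis = analyze_junction(fx["ref_a"], fx["ref_b"], fx["junction_seq"],
                            cluster_context=context)
call = infer_mechanism([analysis])
print(f"junction: {len(analysis.inserted_seq)}-bp insertion, "
      f"{analysis.nontemplated_len} bp non-templated -> {call.label}")

# --- ring chromosome 18 -----------------------------------------------------
L18 = 78_077_248
ring = SvCluster(
    records=[SvRecord("dp", "DEL", GenomicInterval("18", 0, 1_652_788)),
             SvRecord("dq", "DEL", GenomicInterval("18", 62_984_563, L18))],
    junctions=[Junction(Breakend("18", 62_984_563, "L"),
                        Breakend("18", 1_652_788, "R"))],
)
structures = reconstruct_derivative(ring, {"18": L18})
print("topology:", classify_structure(structures, ring),
      "| retained:", str(structures[0].segments[0][0]))
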