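"""Clustering, derivative reconstruction, topology labels, junctions."""

from collections import Counter

import numpy as np
import pytest

from cytowgs import (
    Breakend,
    GenomicInterval,
    Junction,
    SvCluster,
    SvRecord,
    analyze_junction,
    classify_structure,
    cluster_rearrangements,
    duplication_topology,
    infer_mechanism,
    reconstruct_derivative,
    revcomp,
    synth,
)

GI = GenomicInterval


def _rec(rid, sv_type, chrom, s, e, **kw):
    return SvRecord(rid, sv_type, GI(chrom, s, e), **kw)


# RD_P393-style DEL-INV-DEL coordinates (chromosome 2)
S1, E1, E2, E3 = 166_050_817, 166_679_227, 166_818_452, 166_939_516
CHR2 = 243_199_373
CHR18 = 78_077_248


def del_inv_del_cluster():
    records = [
        _rec("del1", "DEL", "2", S1, E1),
        _rec("inv", "INV", "2", E1, E2),
        _rec("del2", "DEL", "2", E2, E3),
    ]
    junctions = [
        Junction(Breakend("2", S1, "L"), Breakend("2", E2, "L")),
        Junction(Breakend("2", E1, "R"), Breakend("2", E3, "R")),
    ]
    return SvCluster(records=records, junctions=junctions)


def ring18_cluster():
    records = [
        _rec("dp", "DEL", "18", 0, 1_652_788),
        _rec("dq", "DEL", "18", 62_984_563, CHR18),
    ]
    fusion = Junction(Breakend("18", 62_984_563, "L"),
                      Breakend("18", 1_652_788, "R"))
    return SvCluster(records=records, junctions=[fusion])


class TestClusterRearrangements:
    def test_contiguous_del_inv_del_is_one_cluster(self):
        records = [
            _rec("del1", "DEL", "2", S1, E1),
            _rec("inv", "INV", "2", E1, E2),
            _rec("del2", "DEL", "2", E2, E3),
        ]
        clusters = cluster_rearrangements(records)
        assert len(clusters) == 1 and len(clusters[0].records) == 3

    def test_isolated_del_is_singleton(self):
        records = [
            _rec("a", "DEL", "1", 1_000_000, 1_050_000),
            _rec("b", "DEL", "1", 50_000_000, 50_040_000),
        ]
        clusters = cluster_rearrangements(records)
        assert [len(c.records) for c in clusters] == [1, 1]

    def test_interchromosomal_breakends_union_clusters(self):
        """A duplication on chr3 joined to chr13 by mate breakends forms one
        cluster spanning both chromosomes."""
        records = [
            _rec("dup", "DUP", "3", 158_567_751, 160_802_139),
            SvRecord("bndA", "BND", GI("3", 160_802_139, 160_802_139),
                     partner=("13", 63_000_000, "L"), bnd_side="L"),
            SvRecord("bndB", "BND", GI("13", 63_000_000, 63_000_000),
                     partner=("3", 160_802_139, "L"), bnd_side="L"),
            _rec("far", "DEL", "5", 1_000_000, 1_050_000),
        ]
        clusters = cluster_rearrangements(records)
        sizes = sorted(len(c.records) for c in clusters)
        assert sizes == [1, 3]
        big = next(c for c in clusters if len(c.records) == 3)
        assert big.chromosomes() == ["13", "3"]
        assert len(big.junctions) == 1  # mate pair recognized


class TestReconstruct:
    def test_simple_del_two_segment_linear(self):
        cluster = SvCluster(records=[_rec("d", "DEL", "2", 100_000, 200_000)])
        (st,) = reconstruct_derivative(cluster, {"2": 500_000})
        assert not st.circular and not st.incomplete
        assert [(iv.start, iv.end, o) for iv, o in st.segments] == [
            (0, 100_000, "+"), (200_000, 500_000, "+"),
        ]

    def test_del_inv_del_keeps_inverted_middle(self):
        """The copy-neutral segment between the deletions appears once, in
        reverse orientation; the deleted segments are absent."""
        (st,) = reconstruct_derivative(del_inv_del_cluster(), {"2": CHR2})
        assert [(iv.start, iv.end, o) for iv, o in st.segments] == [
            (0, S1, "+"), (E1, E2, "-"), (E3, CHR2, "+"),
        ]

    def test_ring_chromosome_closed_walk(self):
        (st,) = reconstruct_derivative(ring18_cluster(), {"18": CHR18})
        assert st.circular
        assert [(iv.start, iv.end) for iv, _ in st.segments] == [
            (1_652_788, 62_984_563)
        ]

    def test_copy_number_conservation(self):
        """Every base of the cluster region appears with multiplicity equal
        to its copy number in the derivative haplotype."""
        cases = [
            (del_inv_del_cluster(), {"2": CHR2}),
            (SvCluster(records=[_rec("u", "DUP", "5", 100_000, 150_000)]),
             {"5": 400_000}),
            (ring18_cluster(), {"18": CHR18}),
        ]
        for cluster, contigs in cases:
            structures = reconstruct_derivative(cluster, contigs)
            seen = Counter()
            for st in structures:
                for iv, _ in st.segments:
                    seen[(iv.chrom, iv.start, iv.end)] += 1
            # expected multiplicity per elementary segment
            for (chrom, s, e), mult in seen.items():
                expected = 1
                for rec in cluster.records:
                    if rec.interval.chrom == chrom and \
                            rec.interval.start <= s and e <= rec.interval.end:
                        expected += {"DUP": 1, "DEL": -1}.get(rec.sv_type, 0)
                assert mult == max(expected, 0), (chrom, s, e)
            # deleted bases absent entirely
            for rec in cluster.records:
                if rec.sv_type == "DEL":
                    for iv_key in seen:
                        c, s, e = iv_key
                        if c == rec.interval.chrom:
                            assert not (rec.interval.start <= s
                                        and e <= rec.interval.end)

    def test_dangling_junction_flagged_incomplete(self):
        dangling = Junction(Breakend("2", 100_000, "L"),
                            Breakend("9", 5_000, "R"))
        cluster = SvCluster(records=[_rec("d", "DEL", "2", 100_000, 200_000)],
                            junctions=[dangling])
        structures = reconstruct_derivative(cluster, {"2": 500_000})
        assert any(st.incomplete for st in structures)


class TestClassifyStructure:
    def test_del_inv_del_label(self):
        cluster = del_inv_del_cluster()
        sts = reconstruct_derivative(cluster, {"2": CHR2})
        assert classify_structure(sts, cluster) == "DEL-INV-DEL"

    def test_ring_label(self):
        cluster = ring18_cluster()
        sts = reconstruct_derivative(cluster, {"18": CHR18})
        assert classify_structure(sts, cluster) == "ring"

    def test_tandem_dup_label(self):
        cluster = SvCluster(records=[_rec("u", "DUP", "5", 100_000, 150_000)])
        sts = reconstruct_derivative(cluster, {"5": 400_000})
        assert classify_structure(sts, cluster) == "tandem-DUP"

    def test_reciprocal_translocation_with_deletion(self):
        """9.3-Mb 4q deletion at one junction of a balanced 4;7 exchange."""
        bp4, bp7 = 181_000_000, 12_000_000
        cluster = SvCluster(
            records=[_rec("deln", "DEL", "4", bp4 - 9_300_000, bp4)],
            junctions=[
                Junction(Breakend("4", bp4 - 9_300_000, "L"),
                         Breakend("7", bp7, "R")),
                Junction(Breakend("7", bp7, "L"), Breakend("4", bp4, "R")),
            ],
        )
        sts = reconstruct_derivative(
            cluster, {"4": 191_154_276, "7": 159_138_663}
        )
        assert len(sts) == 2
        assert classify_structure(sts, cluster) == "reciprocal-translocation"

    def test_insertional_translocation(self):
        """2.23-Mb 3q segment inserted into chr13 with a 69.6-kb inverted
        acceptor segment."""
        a3, b3 = 158_567_751, 160_802_139
        p1, p2 = 63_000_000, 63_069_600
        cluster = SvCluster(
            records=[_rec("dup", "DUP", "3", a3, b3, copy_number=3)],
            junctions=[
                Junction(Breakend("13", p1, "L"), Breakend("3", a3, "R")),
                Junction(Breakend("3", b3, "L"), Breakend("13", p2, "L")),
                Junction(Breakend("13", p1, "R"), Breakend("13", p2, "R")),
            ],
        )
        sts = reconstruct_derivative(
            cluster, {"3": 198_022_430, "13": 115_169_878}
        )
        assert classify_structure(sts, cluster) == "insertional-translocation"
        (st,) = sts
        assert ("3", "-") not in [
            (iv.chrom, o) for iv, o in st.segments
        ]  # donor inserted in direct orientation here
        assert [(iv.start, iv.end, o) for iv, o in st.segments][2] == (
            p1, p2, "-"
        )

    def test_unbalanced_translocation(self):
        """Terminal 4q gain replacing a 27-kb terminal 2p loss."""
        L2, L4 = 243_199_373, 191_154_276
        a4 = 110_000_000
        cluster = SvCluster(
            records=[_rec("d2", "DEL", "2", 0, 27_000),
                     _rec("u4", "DUP", "4", a4, L4, copy_number=3)],
            junctions=[Junction(Breakend("4", a4, "R"),
                                Breakend("2", 27_000, "R"))],
        )
        sts = reconstruct_derivative(cluster, {"2": L2, "4": L4})
        assert classify_structure(sts, cluster) == "unbalanced-translocation"

    def test_del_nml_del_and_dup_nml_dup(self):
        c1 = SvCluster(records=[_rec("a", "DEL", "5", 100_000, 150_000),
                                _rec("b", "DEL", "5", 200_000, 260_000)])
        sts = reconstruct_derivative(c1, {"5": 500_000})
        assert classify_structure(sts, c1) == "DEL-NML-DEL"
        c2 = SvCluster(records=[_rec("a", "DUP", "7", 100_000, 150_000),
                                _rec("b", "DUP", "7", 200_000, 260_000)])
        sts = reconstruct_derivative(c2, {"7": 500_000})
        assert classify_structure(sts, c2) == "DUP-NML-DUP"

    def test_invariant_to_record_order_and_mirror(self):
        cluster = del_inv_del_cluster()
        sts = reconstruct_derivative(cluster, {"2": CHR2})
        label = classify_structure(sts, cluster)
        reordered = SvCluster(records=list(reversed(cluster.records)),
                              junctions=list(reversed(cluster.junctions)))
        sts2 = reconstruct_derivative(reordered, {"2": CHR2})
        assert classify_structure(sts2, reordered) == label
        mirrored = [st.mirrored() for st in sts]
        assert classify_structure(mirrored, cluster) == label


class TestDuplicationTopology:
    DUP = _rec("u", "DUP", "3", 158_567_751, 160_802_139)

    def test_head_to_tail_self_junction_is_tandem(self):
        j = Junction(Breakend("3", 160_802_139, "L"),
                     Breakend("3", 158_567_751, "R"))
        assert duplication_topology(self.DUP, [j]) == "tandem"

    def test_mates_on_other_chromosome_is_inserted(self):
        j = Junction(Breakend("3", 160_802_139, "L"),
                     Breakend("13", 63_000_000, "L"))
        assert duplication_topology(self.DUP, [j]) == "inserted"

    def test_no_junction_evidence_is_unknown(self):
        assert duplication_topology(self.DUP, []) == "unknown"

    def test_requires_dup_record(self):
        with pytest.raises(ValueError):
            duplication_topology(_rec("d", "DEL", "1", 0, 10), [])


class TestAnalyzeJunction:
    def test_blunt_concatenation(self):
        fx = synth.synthesize_junction(mh=0, ins="", seed=1)
        res = analyze_junction(fx["ref_a"], fx["ref_b"], fx["junction_seq"])
        assert res.microhomology_len == 0 and res.inserted_seq == ""

    def test_planted_5nt_insert(self):
        fx = synth.synthesize_junction(mh=0, ins="GTTAC", seed=2)
        res = analyze_junction(fx["ref_a"], fx["ref_b"], fx["junction_seq"])
        assert res.microhomology_len == 0
        assert res.inserted_seq == "GTTAC" and res.nontemplated_len == 5

    def test_planted_4bp_microhomology(self):
        fx = synth.synthesize_junction(mh=4, ins="", seed=3)
        res = analyze_junction(fx["ref_a"], fx["ref_b"], fx["junction_seq"])
        assert res.microhomology_len == 4 and res.inserted_seq == ""

    @pytest.mark.parametrize("mh", range(0, 11))
    @pytest.mark.parametrize("ins_len", [0, 1, 5, 13, 38, 60])
    def test_exact_recovery_grid(self, mh, ins_len):
        """(mh, ins) recovered exactly over the full grid with random
        flanks, several seeds each."""
        if mh and ins_len:
            return  # mutually exclusive by the junction model
        for seed in (10, 11, 12):
            rng = np.random.default_rng(seed * 1000 + mh * 64 + ins_len)
            ins = "".join(rng.choice(list("ACGT"), size=ins_len))
            fx = synth.synthesize_junction(mh=mh, ins=ins, seed=seed)
            res = analyze_junction(fx["ref_a"], fx["ref_b"],
                                   fx["junction_seq"])
            assert res.microhomology_len == mh
            assert res.inserted_seq == ins

    def test_retained_side_orientation(self):
        fx = synth.synthesize_junction(mh=0, ins="", seed=4)
        res = analyze_junction(revcomp(fx["ref_a"]), fx["ref_b"],
                               fx["junction_seq"], retained_a="R")
        assert res.microhomology_len == 0 and res.inserted_seq == ""

    def test_templated_fragments_found_on_both_strands(self):
        rng = np.random.default_rng(5)
        tpl = "".join(rng.choice(list("ACGT"), size=20))
        fx = synth.synthesize_junction(mh=0, ins=tpl, seed=5)
        ctx_fwd = "".join(rng.choice(list("ACGT"), size=50)) + tpl
        res = analyze_junction(fx["ref_a"], fx["ref_b"], fx["junction_seq"],
                               cluster_context=[("bp1", ctx_fwd)])
        assert [f.length for f in res.templated_fragments] == [20]
        assert res.nontemplated_len == 0
        ctx_rev = revcomp(ctx_fwd)
        res2 = analyze_junction(fx["ref_a"], fx["ref_b"], fx["junction_seq"],
                                cluster_context=[("bp1", ctx_rev)])
        assert [(f.length, f.strand) for f in res2.templated_fragments] == [
            (20, "-")
        ]

    def test_unalignable_junction_rejected(self):
        with pytest.raises(ValueError):
            analyze_junction("A" * 60, "A" * 60, "C" * 40)


class TestInferMechanism:
    def _junction(self, mh=0, ins="", ctx=None):
        fx = synth.synthesize_junction(mh=mh, ins=ins, seed=9)
        return analyze_junction(fx["ref_a"], fx["ref_b"], fx["junction_seq"],
                                cluster_context=ctx or [])

    def test_short_nontemplated_insertions_are_nhej(self):
        """8- and 5-nt random insertions, no microhomology, no templating."""
        j1 = self._junction(ins="GATCGATG")
        j2 = self._junction(ins="TTGCA")
        call = infer_mechanism([j1, j2])
        assert call.label == "NHEJ-like"

    def test_templated_insertions_are_replicative(self):
        rng = np.random.default_rng(6)
        t1 = "".join(rng.choice(list("ACGT"), size=38))
        ctx = [("junction2_flank", "".join(rng.choice(list("ACGT"), 30)) + t1)]
        j = self._junction(ins=t1, ctx=ctx)
        assert j.templated_fragments
        assert infer_mechanism([j]).label == "replicative-like"

    def test_recurrent_repeat_flanked_is_nahr(self):
        j = self._junction(mh=2)
        call = infer_mechanism([j], recurrent=True, repeat_flanked=True)
        assert call.label == "NAHR-like"

    def test_long_microhomology_unclassified(self):
        j = self._junction(mh=9)
        assert infer_mechanism([j]).label == "unclassified"

    def test_requires_junctions(self):
        with pytest.raises(ValueError):
            infer_mechanism([])
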