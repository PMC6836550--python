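"""Rearrangement clustering, derivative-chromosome reconstruction and
breakpoint-junction analysis.

A derivative chromosome is modelled as a walk over a breakend graph: nodes
are boundaries between reference segments, edges are either reference
adjacencies or novel junctions.  Each junction pairs two breakends; a
breakend ``(chrom, pos, side)`` retains the reference bases to its left
(``side='L'``) or right (``'R'``).  Walking from telomere to telomere while
consuming each junction once yields the ordered, signed segment list; a
closed walk is a ring chromosome.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .formats import GenomicInterval, SvRecord, normalize_chrom

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Breakend:
    """One side of a novel adjacency. side='L': bases ...→pos retained."""

    chrom: str
    pos: int
    side: str  # 'L' | 'R'

    def __post_init__(self) -> None:
        if self.side not in ("L", "R"):
            raise ValueError(f"breakend side must be 'L' or 'R', got {self.side!r}")


@dataclass(frozen=True)
class Junction:
    a: Breakend
    b: Breakend

    def ends(self) -> Tuple[Breakend, Breakend]:
        return (self.a, self.b)

    def other(self, end: Breakend) -> Breakend:
        if end == self.a:
            return self.b
        if end == self.b:
            return self.a
        raise ValueError("breakend not part of this junction")


@dataclass
class SvCluster:
    """SV records (plus junction evidence) forming one rearrangement."""

    records: List[SvRecord]
    junctions: List[Junction] = field(default_factory=list)

    def chromosomes(self) -> List[str]:
        chroms: Set[str] = set()
        for rec in self.records:
            chroms.add(normalize_chrom(rec.interval.chrom))
            if rec.partner is not None:
                chroms.add(normalize_chrom(rec.partner[0]))
        for j in self.junctions:
            chroms.add(normalize_chrom(j.a.chrom))
            chroms.add(normalize_chrom(j.b.chrom))
        return sorted(chroms)


def pair_breakend_records(records: Sequence[SvRecord]) -> List[Junction]:
    """Pair mate BND records into Junctions (mate symmetry required)."""
    bnds = [r for r in records if r.sv_type == "BND"]
    junctions: List[Junction] = []
    used: Set[int] = set()
    for i, a in enumerate(bnds):
        if i in used or a.partner is None:
            continue
        for j in range(i + 1, len(bnds)):
            if j in used:
                continue
            b = bnds[j]
            if b.partner is None:
                continue
            a_loc = (normalize_chrom(a.interval.chrom), a.interval.start)
            b_loc = (normalize_chrom(b.interval.chrom), b.interval.start)
            a_mate = (normalize_chrom(a.partner[0]), a.partner[1])
            b_mate = (normalize_chrom(b.partner[0]), b.partner[1])
            if a_mate == b_loc and b_mate == a_loc:
                junctions.append(
                    Junction(
                        Breakend(a_loc[0], a_loc[1], a.bnd_side or "L"),
                        Breakend(b_loc[0], b_loc[1], b.bnd_side or "L"),
                    )
                )
                used.update((i, j))
                break
    return junctions


# ---------------------------------------------------------------------------
# Clustering


def cluster_rearrangements(
    records: Sequence[SvRecord], max_gap: int = 1_000_000
) -> List[SvCluster]:
    """Cluster SVs lying within max_gap on a chromosome; interchromosomal
    breakend mates union their clusters.  Singletons are allowed."""
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    n = len(records)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    # loci: each record contributes its interval, BNDs also their mate locus
    loci: List[Tuple[str, int, int, int]] = []  # (chrom, start, end, rec idx)
    for i, rec in enumerate(records):
        iv = rec.interval
        loci.append((normalize_chrom(iv.chrom), iv.start, iv.end, i))
        if rec.partner is not None:
            c, p, _ = rec.partner
            loci.append((normalize_chrom(c), p, p, i))

    per_chrom: Dict[str, List[Tuple[int, int, int]]] = defaultdict(list)
    for chrom, s, e, i in loci:
        per_chrom[chrom].append((s, e, i))
    for entries in per_chrom.values():
        entries.sort()
        chain_end, chain_idx = None, None
        for s, e, i in entries:
            if chain_end is not None and s - chain_end <= max_gap:
                union(chain_idx, i)
                chain_end = max(chain_end, e)
            else:
                chain_end = e
            chain_idx = i
    clusters: Dict[int, List[SvRecord]] = defaultdict(list)
    order: Dict[int, int] = {}
    for i, rec in enumerate(records):
        root = find(i)
        clusters[root].append(rec)
        order.setdefault(root, i)
    out = []
    for root in sorted(clusters, key=lambda r: order[r]):
        recs = clusters[root]
        out.append(SvCluster(records=recs, junctions=pair_breakend_records(recs)))
    return out


# ---------------------------------------------------------------------------
# Derivative reconstruction


@dataclass
class DerivativeStructure:
    """Ordered, signed reference segments of a reconstructed derivative."""

    segments: List[Tuple[GenomicInterval, str]]  # (interval, '+'|'-')
    circular: bool = False
    incomplete: bool = False

    def mirrored(self) -> "DerivativeStructure":
        return DerivativeStructure(
            segments=[
                (iv, "+" if o == "-" else "-") for iv, o in reversed(self.segments)
            ],
            circular=self.circular,
            incomplete=self.incomplete,
        )


def _derived_junctions(
    cluster: SvCluster, contig_lengths: Dict[str, int]
) -> List[Junction]:
    """Explicit junctions plus naive CNV-implied ones.

    A DEL implies joining its left boundary to its right boundary; a DUP a
    head-to-tail self-junction; an INV two inverted junctions.  Naive
    junctions are suppressed when terminal (boundary at a contig end) or
    when a boundary coincides with an explicit breakend (the explicit
    evidence describes the true geometry, e.g. DEL-INV-DEL or an
    insertional duplication).
    """
    explicit = list(cluster.junctions)
    explicit_pos = {
        (normalize_chrom(be.chrom), be.pos) for j in explicit for be in j.ends()
    }
    out = list(explicit)
    for rec in cluster.records:
        if rec.sv_type not in ("DEL", "DUP", "INV"):
            continue
        chrom = normalize_chrom(rec.interval.chrom)
        s, e = rec.interval.start, rec.interval.end
        length = contig_lengths.get(chrom)
        terminal = s <= 0 or (length is not None and e >= length)
        touched = (chrom, s) in explicit_pos or (chrom, e) in explicit_pos
        if terminal or touched:
            continue
        if rec.sv_type == "DEL":
            out.append(Junction(Breakend(chrom, s, "L"), Breakend(chrom, e, "R")))
        elif rec.sv_type == "DUP":
            out.append(Junction(Breakend(chrom, e, "L"), Breakend(chrom, s, "R")))
        else:  # INV
            out.append(Junction(Breakend(chrom, s, "L"), Breakend(chrom, e, "L")))
            out.append(Junction(Breakend(chrom, s, "R"), Breakend(chrom, e, "R")))
    return out


@dataclass
class _Seg:
    chrom: str
    start: int
    end: int
    mult: int

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


def _build_segments(
    cluster: SvCluster,
    junctions: Sequence[Junction],
    contig_lengths: Dict[str, int],
) -> Dict[str, List[_Seg]]:
    cuts: Dict[str, Set[int]] = defaultdict(set)
    for j in junctions:
        for be in j.ends():
            cuts[normalize_chrom(be.chrom)].add(be.pos)
    for rec in cluster.records:
        if rec.sv_type in ("DEL", "DUP", "INV"):
            chrom = normalize_chrom(rec.interval.chrom)
            cuts[chrom].update((rec.interval.start, rec.interval.end))
    segs: Dict[str, List[_Seg]] = {}
    for chrom, positions in cuts.items():
        length = contig_lengths.get(chrom)
        if length is None:
            # junction into an unmodelled contig: leave it dangling so the
            # walk reports a partial structure instead of failing outright
            continue
        bounds = sorted({0, length} | {p for p in positions if 0 <= p <= length})
        chrom_segs = []
        for s, e in zip(bounds[:-1], bounds[1:]):
            mult = 1
            mid = (s + e) // 2
            for rec in cluster.records:
                if normalize_chrom(rec.interval.chrom) != chrom:
                    continue
                if rec.interval.start <= mid < rec.interval.end:
                    if rec.sv_type == "DEL":
                        mult -= 1
                    elif rec.sv_type == "DUP":
                        mult += 1
            chrom_segs.append(_Seg(chrom, s, e, max(mult, 0)))
        segs[chrom] = chrom_segs
    return segs


def reconstruct_derivative(
    cluster: SvCluster, contig_lengths: Dict[str, int]
) -> List[DerivativeStructure]:
    """Walk the breakend graph into derivative structures.

    Returns one structure per derivative chromosome; closed walks are
    flagged circular, walks hitting a dangling junction are flagged
    incomplete.
    """
    junctions = _derived_junctions(cluster, contig_lengths)
    segs = _build_segments(cluster, junctions, contig_lengths)

    end_map: Dict[Tuple[str, int, str], Junction] = {}
    for j in junctions:
        for be in j.ends():
            key = (normalize_chrom(be.chrom), be.pos, be.side)
            end_map[key] = j
    used: Set[int] = set()  # id() of consumed junctions

    by_start: Dict[Tuple[str, int], _Seg] = {}
    by_end: Dict[Tuple[str, int], _Seg] = {}
    for chrom, chrom_segs in segs.items():
        for sg in chrom_segs:
            by_start[(chrom, sg.start)] = sg
            by_end[(chrom, sg.end)] = sg

    def walk(start_seg: _Seg, direction: str) -> Optional[DerivativeStructure]:
        state = (start_seg, direction)
        start_state = state
        out: List[Tuple[GenomicInterval, str]] = []
        circular = False
        incomplete = False
        used_here: List[Junction] = []
        while True:
            sg, d = state
            if sg.mult <= 0:
                incomplete = True
                break
            sg.mult -= 1
            out.append((sg.interval, "+" if d == "+" else "-"))
            exit_be = (
                (sg.chrom, sg.end, "L") if d == "+" else (sg.chrom, sg.start, "R")
            )
            junction = end_map.get(exit_be)
            if junction is not None and id(junction) not in used:
                used.add(id(junction))
                used_here.append(junction)
                be = Breakend(*exit_be)
                partner = junction.other(be)
                pchrom = normalize_chrom(partner.chrom)
                if partner.side == "R":
                    nxt = by_start.get((pchrom, partner.pos))
                    nd = "+"
                else:
                    nxt = by_end.get((pchrom, partner.pos))
                    nd = "-"
                if nxt is None:
                    incomplete = True
                    break
                if (nxt, nd) == start_state:
                    circular = True
                    break
                state = (nxt, nd)
                continue
            # reference adjacency
            chrom_segs = segs[sg.chrom]
            idx = chrom_segs.index(sg)
            nxt_idx = idx + 1 if d == "+" else idx - 1
            if nxt_idx < 0 or nxt_idx >= len(chrom_segs):
                break  # telomere
            nxt = chrom_segs[nxt_idx]
            if nxt.mult <= 0:
                break  # terminal loss: derivative ends here
            state = (nxt, d)
        if not out:
            return None
        return DerivativeStructure(out, circular=circular, incomplete=incomplete)

    structures: List[DerivativeStructure] = []
    has_junctions = bool(junctions)

    def start_candidates():
        for chrom in sorted(segs):
            chrom_segs = segs[chrom]
            first = next((s for s in chrom_segs if s.mult > 0), None)
            if first is not None:
                yield (first, "+")
            last = next((s for s in reversed(chrom_segs) if s.mult > 0), None)
            if last is not None and last is not first:
                yield (last, "-")

    if not has_junctions:
        for chrom in sorted(segs):
            first = next((s for s in segs[chrom] if s.mult > 0), None)
            if first is not None:
                st = walk(first, "+")
                if st is not None:
                    structures.append(st)
        return structures

    progress = True
    while len(used) < len(junctions) and progress:
        progress = False
        for seg, d in start_candidates():
            before = len(used)
            st = walk(seg, d)
            if st is not None and len(used) > before:
                structures.append(st)
                progress = True
                break
            # roll back multiplicities consumed by a junction-free walk
            if st is not None and len(used) == before:
                for iv, _ in st.segments:
                    by_start[(normalize_chrom(iv.chrom), iv.start)].mult += 1
    if len(used) < len(junctions) and structures:
        structures[-1].incomplete = True
    return structures


# ---------------------------------------------------------------------------
# Topology classification


TOPOLOGY_LABELS = (
    "simple-DEL",
    "tandem-DUP",
    "DEL-INV-DEL",
    "DUP-NML-DUP",
    "DEL-NML-DEL",
    "insertional-translocation",
    "unbalanced-translocation",
    "reciprocal-translocation",
    "ring",
    "other-complex",
)


def _canonical(st: DerivativeStructure) -> DerivativeStructure:
    if st.segments and st.segments[0][1] == "-":
        return st.mirrored()
    return st


def _intrachromosomal_label(st: DerivativeStructure, cluster: SvCluster) -> str:
    st = _canonical(st)
    ivs = [iv for iv, _ in st.segments]
    span_lo = min(iv.start for iv in ivs)
    span_hi = max(iv.end for iv in ivs)
    # per-base multiplicity over the cluster span, from segment boundaries
    bounds = sorted({iv.start for iv in ivs} | {iv.end for iv in ivs})
    counts: List[Tuple[int, int, int]] = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        c = sum(1 for iv in ivs if iv.start <= s and e <= iv.end)
        counts.append((s, e, c))

    def runs(pred) -> int:
        n, inside = 0, False
        for s, e, c in counts:
            if pred(c) and not inside:
                n, inside = n + 1, True
            elif not pred(c):
                inside = False
        return n

    n_del = runs(lambda c: c == 0)
    n_dup = runs(lambda c: c >= 2)
    inverted = [i for i, (_, o) in enumerate(st.segments) if o == "-"]

    if n_dup == 0 and n_del == 1 and not inverted:
        return "simple-DEL"
    if n_dup == 0 and n_del == 2 and not inverted:
        return "DEL-NML-DEL"
    if n_dup == 0 and n_del == 2 and len(inverted) == 1:
        # inverted segment between the deleted regions
        return "DEL-INV-DEL"
    if n_dup == 1 and n_del == 0 and not inverted:
        # tandem iff the repeated segment appears in adjacent walk positions
        for i in range(len(st.segments) - 1):
            if st.segments[i][0] == st.segments[i + 1][0]:
                return "tandem-DUP"
        return "other-complex"
    if n_dup == 2 and n_del == 0:
        return "DUP-NML-DUP"
    return "other-complex"


def classify_structure(
    structures: Sequence[DerivativeStructure], cluster: SvCluster
) -> str:
    """Deterministic rule table over segment composition (see labels)."""
    if not structures:
        raise ValueError("classify_structure requires >=1 structure")
    if any(st.circular for st in structures):
        return "ring"

    multi = [
        st
        for st in structures
        if len({normalize_chrom(iv.chrom) for iv, _ in st.segments}) > 1
    ]
    if multi:
        if len(multi) == 2:
            chrom_ends = []
            for st in multi:
                c_first = normalize_chrom(st.segments[0][0].chrom)
                c_last = normalize_chrom(st.segments[-1][0].chrom)
                chrom_ends.append((c_first, c_last))
            (a1, b1), (a2, b2) = chrom_ends
            if a1 != b1 and a2 != b2 and {a1, b1} == {a2, b2}:
                return "reciprocal-translocation"
        st = _canonical(multi[0])
        backbone = normalize_chrom(st.segments[0][0].chrom)
        tail = normalize_chrom(st.segments[-1][0].chrom)
        interior = {
            normalize_chrom(iv.chrom) for iv, _ in st.segments[1:-1]
        } - {backbone}
        if backbone == tail and interior:
            return "insertional-translocation"
        if backbone != tail:
            return "unbalanced-translocation"
        return "other-complex"

    singles = [st for st in structures if st.segments]
    if len(singles) == 1:
        return _intrachromosomal_label(singles[0], cluster)
    return "other-complex"


def duplication_topology(
    dup: SvRecord,
    junctions: Sequence[Junction],
    bp_tol: int = 200,
) -> str:
    """'tandem' for a head-to-tail self-junction, 'inserted' when junction
    mates lie outside the duplicated interval, 'unknown' without evidence."""
    if dup.sv_type != "DUP":
        raise ValueError("duplication_topology expects a DUP record")
    chrom = normalize_chrom(dup.interval.chrom)
    s, e = dup.interval.start, dup.interval.end
    relevant = []
    for j in junctions:
        near = [
            be
            for be in j.ends()
            if normalize_chrom(be.chrom) == chrom
            and (abs(be.pos - s) <= bp_tol or abs(be.pos - e) <= bp_tol)
        ]
        if near:
            relevant.append(j)
    if not relevant:
        return "unknown"
    for j in relevant:
        a, b = j.ends()
        if normalize_chrom(a.chrom) == normalize_chrom(b.chrom) == chrom:
            ends = {(round(be.pos / 1), be.side) for be in j.ends()}
            head_to_tail = (
                abs(a.pos - e) <= bp_tol
                and a.side == "L"
                and abs(b.pos - s) <= bp_tol
                and b.side == "R"
            ) or (
                abs(b.pos - e) <= bp_tol
                and b.side == "L"
                and abs(a.pos - s) <= bp_tol
                and a.side == "R"
            )
            if head_to_tail:
                return "tandem"
    for j in relevant:
        a, b = j.ends()
        for be in (a, b):
            outside = normalize_chrom(be.chrom) != chrom or not (
                s - bp_tol <= be.pos <= e + bp_tol
            )
            if outside:
                return "inserted"
    return "unknown"


# ---------------------------------------------------------------------------
# Junction sequence analysis


@dataclass(frozen=True)
class TemplatedFragment:
    query_start: int  # offset within inserted_seq
    length: int
    source: str  # label of the contributing breakpoint flank
    source_offset: int
    strand: str  # '+' | '-'


@dataclass
class JunctionAnalysis:
    microhomology_len: int
    inserted_seq: str
    templated_fragments: List[TemplatedFragment]
    nontemplated_len: int

    def __post_init__(self) -> None:
        total = sum(f.length for f in self.templated_fragments)
        if total + self.nontemplated_len != len(self.inserted_seq):
            raise ValueError("templated + nontemplated must cover the insertion")
        if self.inserted_seq and self.microhomology_len:
            raise ValueError("microhomology and insertion are mutually exclusive")


def _common_prefix(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[i] == b[i]:
        i += 1
    return i


def analyze_junction(
    ref_a: str,
    ref_b: str,
    junction_seq: str,
    cluster_context: Optional[Sequence[Tuple[str, str]]] = None,
    retained_a: str = "L",
    retained_b: str = "R",
    min_templated: int = 10,
) -> JunctionAnalysis:
    """Decompose a junction sequence into microhomology / insertion.

    ``ref_a``/``ref_b`` are reference flank sequences around the two
    breakpoints, each at least as long as ``junction_seq``.  After
    orientation (a flank retained on its reference right side is
    reverse-complemented for A, and likewise for a left-retained B), the
    junction's first base aligns to the first base of the oriented A flank
    and its last base to the last base of the oriented B flank.  The
    maximal matching prefix/suffix then yields microhomology (overlap) or
    an inserted sequence (gap).  Maximal insertion substrings of length >=
    min_templated found exactly (either strand) in any cluster-context
    flank are reported as templated.
    """
    if not junction_seq:
        raise ValueError("junction_seq is empty")
    seq_a = ref_a if retained_a == "L" else revcomp(ref_a)
    seq_b = ref_b if retained_b == "R" else revcomp(ref_b)
    if len(seq_a) < len(junction_seq) or len(seq_b) < len(junction_seq):
        raise ValueError("flanks must be at least as long as the junction")
    p = _common_prefix(junction_seq, seq_a)
    s = _common_prefix(junction_seq[::-1], seq_b[::-1])
    if p == 0 and s == 0:
        raise ValueError("junction sequence aligns to neither flank")
    n = len(junction_seq)
    if p + s >= n:
        return JunctionAnalysis(
            microhomology_len=p + s - n,
            inserted_seq="",
            templated_fragments=[],
            nontemplated_len=0,
        )
    inserted = junction_seq[p : n - s]
    fragments = _templated_fragments(
        inserted, cluster_context or [], min_templated
    )
    covered = sum(f.length for f in fragments)
    return JunctionAnalysis(
        microhomology_len=0,
        inserted_seq=inserted,
        templated_fragments=fragments,
        nontemplated_len=len(inserted) - covered,
    )


def _templated_fragments(
    inserted: str,
    context: Sequence[Tuple[str, str]],
    min_templated: int,
) -> List[TemplatedFragment]:
    fragments: List[TemplatedFragment] = []
    i = 0
    n = len(inserted)
    while i <= n - min_templated:
        best: Optional[TemplatedFragment] = None
        hi = n
        lo = i + min_templated
        # longest match starting at i, over all contexts/strands
        for label, seq in context:
            for strand, s in (("+", seq), ("-", revcomp(seq))):
                length = lo - i
                # extend greedily while the substring still occurs
                L = None
                for cand in range(hi - i, min_templated - 1, -1):
                    off = s.find(inserted[i : i + cand])
                    if off != -1:
                        L = (cand, off)
                        break
                if L is not None and (best is None or L[0] > best.length):
                    best = TemplatedFragment(i, L[0], label, L[1], strand)
        if best is not None:
            fragments.append(best)
            i += best.length
        else:
            i += 1
    return fragments


# ---------------------------------------------------------------------------
# Mechanism inference


MECHANISM_LABELS = ("NHEJ-like", "replicative-like", "NAHR-like", "unclassified")


@dataclass
class MechanismCall:
    label: str
    evidence: List[str]


def infer_mechanism(
    junctions: Sequence[JunctionAnalysis],
    recurrent: bool = False,
    repeat_flanked: bool = False,
    min_templated: int = 10,
    max_mh_nhej: int = 4,
    max_ins_nhej: int = 20,
) -> MechanismCall:
    """Rules, in order: recurrent+repeat-flanked → NAHR-like; any templated
    fragment → replicative-like; short microhomology and short non-templated
    insertions everywhere → NHEJ-like; else unclassified."""
    if not junctions:
        raise ValueError("infer_mechanism requires >=1 junction")
    if recurrent and repeat_flanked:
        return MechanismCall(
            "NAHR-like", ["recurrent event with repeat-flanked breakpoints"]
        )
    templated = [
        f
        for j in junctions
        for f in j.templated_fragments
        if f.length >= min_templated
    ]
    if templated:
        ev = [
            f"templated insertion of {f.length} bp from {f.source} ({f.strand})"
            for f in templated
        ]
        return MechanismCall("replicative-like", ev)
    if all(
        j.microhomology_len <= max_mh_nhej and j.nontemplated_len <= max_ins_nhej
        for j in junctions
    ):
        ev = [
            f"junction {i + 1}: microhomology {j.microhomology_len} bp, "
            f"non-templated insertion {j.nontemplated_len} bp"
            for i, j in enumerate(junctions)
        ]
        return MechanismCall("NHEJ-like", ev)
    return MechanismCall("unclassified", ["no rule matched"])
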