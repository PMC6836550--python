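"""Multi-caller SV merging, frequency databases and the filtering cascade.

Two complementary pseudo-callers feed this module: a read-depth caller
("coverage", blind below ~5 kb) and a discordant-pair caller ("pairedread",
blind inside repeats).  Their call sets are merged by single-linkage
clustering, annotated with allele frequencies from population/internal
databases, and pushed through a size → quality → frequency → decoy cascade
with a gene-panel rescue lane that ignores the size cutoff.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from intervaltree import IntervalTree

from .formats import GenomicInterval, Panel, SvRecord, normalize_chrom
from .genome import DEFAULT_DECOY_CONTIGS, is_decoy


@dataclass
class CallerOutput:
    """One pseudo-caller's calls for one sample."""

    sample_id: str
    caller: str
    records: List[SvRecord]

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec.caller != self.caller:
                raise ValueError(
                    f"record {rec.id} carries caller {rec.caller!r}, "
                    f"expected {self.caller!r}"
                )


@dataclass
class MergedCall:
    representative: SvRecord
    members: List[Tuple[str, str, SvRecord]]  # (sample_id, caller, record)
    callers: Set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("MergedCall requires members")
        if not self.callers:
            self.callers = {c for _, c, _ in self.members}

    @property
    def interval(self) -> GenomicInterval:
        return self.representative.interval

    @property
    def sample_ids(self) -> Set[str]:
        return {s for s, _, _ in self.members}

    def length(self) -> int:
        return self.interval.length()


def records_match(
    a: SvRecord,
    b: SvRecord,
    bp_tol: int = 200,
    min_reciprocal_overlap: float = 0.7,
) -> bool:
    """SVDB-style pair criterion: same type on one contig, and either both
    breakpoints within bp_tol or reciprocal overlap above the cutoff."""
    if a.sv_type != b.sv_type:
        return False
    if normalize_chrom(a.interval.chrom) != normalize_chrom(b.interval.chrom):
        return False
    if (
        abs(a.interval.start - b.interval.start) <= bp_tol
        and abs(a.interval.end - b.interval.end) <= bp_tol
    ):
        return True
    return a.interval.reciprocal_overlap(b.interval) >= min_reciprocal_overlap


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _pick_representative(records: Sequence[SvRecord]) -> SvRecord:
    # highest pe_support, ties broken by smallest start then id for stability
    return min(
        records,
        key=lambda r: (-r.pe_support, r.interval.start, r.interval.end, r.id),
    )


def merge_callers(
    outputs: Sequence[CallerOutput],
    bp_tol: int = 200,
    min_reciprocal_overlap: float = 0.7,
) -> List[MergedCall]:
    """Single-linkage merge of caller outputs into MergedCalls.

    Output is independent of input order: clusters are sorted by
    (chrom, start, end, type) of their representative.
    """
    tagged: List[Tuple[str, str, SvRecord]] = [
        (out.sample_id, out.caller, rec)
        for out in outputs
        for rec in out.records
    ]
    if not tagged:
        return []

    # group by (contig, sv_type); sweep within group sorted by start
    groups: Dict[Tuple[str, str], List[int]] = defaultdict(list)
    for idx, (_, _, rec) in enumerate(tagged):
        groups[(normalize_chrom(rec.interval.chrom), rec.sv_type)].append(idx)

    uf = _UnionFind(len(tagged))
    for idxs in groups.values():
        idxs = sorted(idxs, key=lambda i: tagged[i][2].interval.start)
        for a_pos, i in enumerate(idxs):
            ri = tagged[i][2]
            for j in idxs[a_pos + 1:]:
                rj = tagged[j][2]
                # past any possible match: breakpoints too far AND no overlap
                if rj.interval.start - ri.interval.start > bp_tol and (
                    rj.interval.start >= ri.interval.end
                ):
                    break
                if records_match(ri, rj, bp_tol, min_reciprocal_overlap):
                    uf.union(i, j)

    clusters: Dict[int, List[int]] = defaultdict(list)
    for idx in range(len(tagged)):
        clusters[uf.find(idx)].append(idx)

    merged: List[MergedCall] = []
    for idxs in clusters.values():
        members = sorted(
            (tagged[i] for i in idxs),
            key=lambda m: (m[0], m[1], m[2].interval.start, m[2].id),
        )
        rep = _pick_representative([m[2] for m in members])
        rep = replace(rep, caller="merged", genes=set(rep.genes))
        merged.append(MergedCall(representative=rep, members=members))
    merged.sort(
        key=lambda mc: (
            normalize_chrom(mc.interval.chrom),
            mc.interval.start,
            mc.interval.end,
            mc.representative.sv_type,
        )
    )
    return merged


# ---------------------------------------------------------------------------
# Frequency databases


@dataclass
class FrequencyDb:
    """Clustered multi-sample SV observations with allele-frequency queries."""

    clusters: List[MergedCall]
    n_samples: int

    def __post_init__(self) -> None:
        for c in self.clusters:
            if not 0 <= len(c.sample_ids) <= self.n_samples:
                raise ValueError("cluster sample count exceeds n_samples")


def build_frequency_db(
    per_sample: Sequence[CallerOutput],
    bp_tol: int = 200,
    min_reciprocal_overlap: float = 0.7,
) -> FrequencyDb:
    """Cluster per-sample call sets into a frequency database.

    Each cluster's count is the number of distinct contributing samples.
    """
    ids = [out.sample_id for out in per_sample]
    dupes = [s for s, n in Counter(ids).items() if n > 1]
    if dupes:
        raise ValueError(f"duplicate sample_id(s): {sorted(dupes)}")
    clusters = merge_callers(per_sample, bp_tol, min_reciprocal_overlap)
    return FrequencyDb(clusters=clusters, n_samples=len(ids))


def query_af(
    record: SvRecord,
    db: FrequencyDb,
    bp_tol: int = 200,
    min_reciprocal_overlap: float = 0.7,
) -> float:
    """Allele frequency of the best-matching cluster (0 when unmatched)."""
    if db.n_samples == 0:
        raise ValueError("frequency database indexes zero samples")
    best = 0
    for cluster in db.clusters:
        if records_match(
            record, cluster.representative, bp_tol, min_reciprocal_overlap
        ):
            best = max(best, len(cluster.sample_ids))
    return best / db.n_samples


# ---------------------------------------------------------------------------
# Filtering cascade


@dataclass
class FilterConfig:
    """Thresholds of the SV filtering cascade.

    Defaults mirror routine clinical WGS-SV screening: intergenic calls kept
    above 10 kb, intragenic above 2 kb, paired-read-only calls need 6
    discordant pairs, coverage-only calls 5 kb, population AF <= 0.5% and
    internal AF < 1% retained, decoy-contig calls dropped, and panel SNVs
    kept below 1% MAF.
    """

    min_intergenic_bp: int = 10_000
    min_intragenic_bp: int = 2_000
    min_pe_support: int = 6
    min_coverage_call_bp: int = 5_000
    max_af_population: float = 0.005
    max_af_internal: float = 0.01
    decoy_contigs: frozenset = DEFAULT_DECOY_CONTIGS
    snv_max_maf: float = 0.01

    def __post_init__(self) -> None:
        for name in (
            "min_intergenic_bp",
            "min_intragenic_bp",
            "min_pe_support",
            "min_coverage_call_bp",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("max_af_population", "max_af_internal", "snv_max_maf"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")


def _panel_tree(panel: Panel) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = defaultdict(IntervalTree)
    for sym, iv in panel.intervals():
        if iv.length() > 0:
            trees[normalize_chrom(iv.chrom)].addi(iv.start, iv.end, sym)
    return trees


def classify_context(
    record: SvRecord, genes: Panel, trees: Optional[Dict[str, IntervalTree]] = None
) -> str:
    """'intragenic' iff the call overlaps any gene interval by >=1 bp.

    Side effect: populates the record's ``genes`` field with the overlapped
    symbols.
    """
    if trees is None:
        trees = _panel_tree(genes)
    iv = record.interval
    tree = trees.get(normalize_chrom(iv.chrom))
    hits = tree.overlap(iv.start, iv.end) if tree and iv.end > iv.start else set()
    if not hits and tree is not None and iv.end == iv.start:
        hits = tree.overlap(iv.start, iv.start + 1)
    record.genes = {h.data for h in hits}
    return "intragenic" if record.genes else "intergenic"


_STAGES = ("size", "quality", "frequency", "decoy")


def _passes_size(call: MergedCall, ctx: str, cfg: FilterConfig) -> bool:
    limit = cfg.min_intragenic_bp if ctx == "intragenic" else cfg.min_intergenic_bp
    return call.length() > limit


def _passes_quality(call: MergedCall, cfg: FilterConfig) -> bool:
    callers = call.callers
    if "coverage" in callers and "pairedread" in callers:
        return True
    if callers == {"pairedread"}:
        pe = max(r.pe_support for _, _, r in call.members)
        return pe >= cfg.min_pe_support
    if callers == {"coverage"}:
        return call.length() >= cfg.min_coverage_call_bp
    return True  # already-merged input: nothing further to check


def _passes_frequency(
    call: MergedCall,
    cfg: FilterConfig,
    pop_db: Optional[FrequencyDb],
    int_db: Optional[FrequencyDb],
) -> bool:
    rep = call.representative
    af_pop = rep.af_population
    if af_pop is None:
        af_pop = query_af(rep, pop_db) if pop_db is not None else 0.0
    af_int = rep.af_internal
    if af_int is None:
        af_int = query_af(rep, int_db) if int_db is not None else 0.0
    rep.af_population, rep.af_internal = af_pop, af_int
    return af_pop <= cfg.max_af_population and af_int < cfg.max_af_internal


def _on_decoy(call: MergedCall, cfg: FilterConfig) -> bool:
    rep = call.representative
    if is_decoy(rep.interval.chrom, cfg.decoy_contigs):
        return True
    if rep.partner is not None and is_decoy(rep.partner[0], cfg.decoy_contigs):
        return True
    return False


def filter_callset(
    calls: Sequence[MergedCall],
    cfg: FilterConfig,
    genes: Panel,
    pop_db: Optional[FrequencyDb] = None,
    int_db: Optional[FrequencyDb] = None,
) -> Tuple[List[MergedCall], Dict[str, int]]:
    """Apply the cascade in order size → quality → frequency → decoy.

    Returns (retained calls, per-stage rejection tally); each removed call is
    counted once, at its first failing stage.  Idempotent.
    """
    trees = _panel_tree(genes)
    tally = {stage: 0 for stage in _STAGES}
    retained: List[MergedCall] = []
    for call in calls:
        ctx = classify_context(call.representative, genes, trees)
        if not _passes_size(call, ctx, cfg):
            tally["size"] += 1
        elif not _passes_quality(call, cfg):
            tally["quality"] += 1
        elif not _passes_frequency(call, cfg, pop_db, int_db):
            tally["frequency"] += 1
        elif _on_decoy(call, cfg):
            tally["decoy"] += 1
        else:
            retained.append(call)
    return retained, tally


def panel_rescue(
    all_calls: Sequence[MergedCall],
    panel: Panel,
    cfg: Optional[FilterConfig] = None,
    pop_db: Optional[FrequencyDb] = None,
    int_db: Optional[FrequencyDb] = None,
) -> List[MergedCall]:
    """Calls with >=1 breakpoint junction inside a panel gene, kept without
    any size cutoff (quality/frequency/decoy stages still apply)."""
    cfg = cfg or FilterConfig()
    trees = _panel_tree(panel)
    rescued: List[MergedCall] = []
    for call in all_calls:
        rep = call.representative
        breakpoints = [
            (rep.interval.chrom, rep.interval.start),
            (rep.interval.chrom, rep.interval.end),
        ]
        if rep.partner is not None:
            breakpoints.append((rep.partner[0], rep.partner[1]))
        in_panel = False
        for chrom, pos in breakpoints:
            tree = trees.get(normalize_chrom(chrom))
            if tree and tree.overlap(pos, pos + 1):
                in_panel = True
                break
        if not in_panel:
            continue
        if not _passes_quality(call, cfg):
            continue
        if not _passes_frequency(call, cfg, pop_db, int_db):
            continue
        if _on_decoy(call, cfg):
            continue
        classify_context(rep, panel, trees)
        rescued.append(call)
    return rescued


def combine_retained(
    filtered: Sequence[MergedCall], rescued: Sequence[MergedCall]
) -> List[MergedCall]:
    """Duplicate-free union of the genome-wide and panel-rescue lanes."""
    seen = set()
    out: List[MergedCall] = []
    for call in list(filtered) + list(rescued):
        key = (
            normalize_chrom(call.interval.chrom),
            call.interval.start,
            call.interval.end,
            call.representative.sv_type,
            call.representative.id,
        )
        if key not in seen:
            seen.add(key)
            out.append(call)
    return out


def filter_snvs(
    records: Sequence[Tuple[str, Optional[float]]],
    panel: Panel,
    cfg: Optional[FilterConfig] = None,
) -> List[Tuple[str, float]]:
    """Keep (gene, MAF) pairs with MAF < snv_max_maf inside the panel.

    A missing MAF is treated as 0 (never observed in the population).
    """
    cfg = cfg or FilterConfig()
    out = []
    for gene, maf in records:
        maf = 0.0 if maf is None else maf
        if not 0.0 <= maf <= 1.0:
            raise ValueError(f"MAF out of [0,1]: {maf}")
        if maf < cfg.snv_max_maf and gene in panel:
            out.append((gene, maf))
    return out
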