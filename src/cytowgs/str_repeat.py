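"""Short-tandem-repeat genotyping from short reads.

Alleles shorter than the read length are sized exactly from reads that span
the whole repeat tract; expansions exceeding the read length are estimated
from the count of in-repeat reads (reads consisting almost entirely of
motif copies), inverting the read-sampling model:

    tract_bp  ≈  read_len + n_irr * read_len / allele_depth

where allele_depth is the per-base coverage of the expanded allele
(total depth / 2 for a heterozygote).  Only exact motif copies are counted;
interrupted or impure repeats are out of scope.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

#: genes whose repeat loci the default catalog must cover
CATALOG_GENES = (
    "AR", "ATN1", "ATXN1", "ATXN10", "ATXN2", "ATXN3", "ATXN7",
    "C9ORF72", "CACNA1A", "CBL", "CSTB", "DMPK", "FMR1", "FXN",
    "HTT", "JPH3", "PPP2R2B",
)


@dataclass(frozen=True)
class RepeatLocus:
    gene: str
    chrom: str
    start: int
    end: int
    motif: str
    pathogenic_min: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.motif) < 1:
            raise ValueError("motif must be >= 1 bp")

    @property
    def reference_units(self) -> int:
        return (self.end - self.start) // len(self.motif)


def load_catalog(path: Optional[str] = None) -> Dict[str, RepeatLocus]:
    """Load a repeat-locus catalog (default: the bundled 17-gene catalog
    with approximate GRCh37 coordinates; pathogenic thresholds are catalog
    configuration, not clinical assertions)."""
    if path is None:
        text = (
            resources.files("cytowgs").joinpath("data/str17_grch37.json").read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    catalog = {}
    for entry in json.loads(text):
        locus = RepeatLocus(
            gene=entry["gene"],
            chrom=str(entry["chrom"]),
            start=int(entry["start"]),
            end=int(entry["end"]),
            motif=entry["motif"],
            pathogenic_min=entry.get("pathogenic_min"),
        )
        catalog[locus.gene] = locus
    return catalog


@dataclass
class StrRead:
    seq: str
    origin_class: Optional[str] = None  # spanning | flanking | inrepeat

    @property
    def read_len(self) -> int:
        return len(self.seq)


def motif_fraction(seq: str, motif: str) -> float:
    """Largest fraction of the read covered by stride-aligned exact motif
    copies, over all phase offsets."""
    k = len(motif)
    n = len(seq)
    if n < k:
        return 0.0
    best = 0
    for p in range(k):
        covered = 0
        for j in range(p, n - k + 1, k):
            if seq[j : j + k] == motif:
                covered += k
        best = max(best, covered)
    return best / n


def classify_read(
    read: StrRead,
    locus: RepeatLocus,
    flank_a: str,
    flank_b: str,
    min_anchor: int = 15,
    min_inrepeat_fraction: float = 0.9,
) -> str:
    """spanning: both flank anchors present; flanking: exactly one;
    inrepeat: >=90% motif and no anchor."""
    if len(flank_a) < 20 or len(flank_b) < 20:
        raise ValueError("flanks must be >= 20 bp")
    anchor_a = flank_a[-min_anchor:]
    anchor_b = flank_b[:min_anchor]
    has_a = anchor_a in read.seq
    has_b = anchor_b in read.seq
    if has_a and has_b:
        cls = "spanning"
    elif has_a or has_b:
        cls = "flanking"
    elif motif_fraction(read.seq, locus.motif) >= min_inrepeat_fraction:
        cls = "inrepeat"
    else:
        cls = "flanking"
    read.origin_class = cls
    return cls


def _longest_motif_run(seq: str, motif: str) -> Tuple[int, int]:
    """(start, end) of the longest run of exact tandem motif copies."""
    k = len(motif)
    best = (0, 0)
    i = 0
    n = len(seq)
    while i <= n - k:
        if seq[i : i + k] == motif:
            j = i
            while j + k <= n and seq[j : j + k] == motif:
                j += k
            if j - i > best[1] - best[0]:
                best = (i, j)
            i = j
        else:
            i += 1
    return best


def count_spanning(
    read: StrRead,
    locus: RepeatLocus,
    flank_a: str,
    flank_b: str,
    min_anchor: int = 1,
) -> int:
    """Exact repeat-unit count from a read spanning the whole tract.

    The tract must be delimited inside the read by >= min_anchor flank
    bases on both sides that match the reference flanks exactly; otherwise
    a ValueError is raised (non-spanning read).
    """
    seq = read.seq
    k = len(locus.motif)
    i0, i1 = _longest_motif_run(seq, locus.motif)
    if i1 == i0:  # zero-copy tract: read must cross the flankA|flankB join
        for x in range(min_anchor, len(seq) - min_anchor + 1):
            if seq[:x] == flank_a[-x:] and seq[x:] == flank_b[: len(seq) - x]:
                return 0
        raise ValueError("read does not span the repeat tract")
    left, right = seq[:i0], seq[i1:]
    if (
        len(left) < min_anchor
        or len(right) < min_anchor
        or flank_a[-len(left):] != left
        or flank_b[: len(right)] != right
    ):
        raise ValueError("read does not span the repeat tract")
    return (i1 - i0) // k


def estimate_inrepeat(
    n_irr: int, read_len: int, depth: float, motif_len: int
) -> int:
    """Estimated repeat units of an expansion from in-repeat read counts.

    ``depth`` is the per-base coverage of the *expanded allele*.  Returns 0
    units when there are no in-repeat reads.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    if n_irr == 0:
        return 0
    tract_bp = read_len + n_irr * read_len / depth
    return round(tract_bp / motif_len)


@dataclass
class StrGenotypeResult:
    allele_short: int
    allele_long: int
    method_long: str  # 'spanning-exact' | 'inrepeat-estimated'
    pathogenic_flag: bool = False
    support: Dict[int, int] = field(default_factory=dict)
    n_inrepeat: int = 0

    def __post_init__(self) -> None:
        if self.allele_short > self.allele_long:
            raise ValueError("allele_short must be <= allele_long")


def genotype_str(
    locus: RepeatLocus,
    reads: Sequence[StrRead],
    depth: float,
    flank_a: str,
    flank_b: str,
    min_anchor_classify: int = 15,
    min_anchor_count: int = 1,
    irr_trigger: int = 1,
) -> StrGenotypeResult:
    """Genotype one locus from one sample's reads.

    The two most-supported exact spanning counts become the alleles; when
    in-repeat reads exceed the expected background (> irr_trigger) the long
    allele is replaced by the in-repeat estimate.
    """
    if not reads:
        raise ValueError("no reads supplied")
    support: Counter = Counter()
    n_irr = 0
    read_len = max(r.read_len for r in reads)
    for read in reads:
        # exact counting first: a read that delimits the full tract is
        # evidence of an exact allele even when its flanks are too short
        # for confident anchor classification
        try:
            n = count_spanning(read, locus, flank_a, flank_b, min_anchor_count)
        except ValueError:
            cls = classify_read(
                read, locus, flank_a, flank_b, min_anchor_classify
            )
            if cls == "inrepeat":
                n_irr += 1
            continue
        read.origin_class = "spanning"
        support[n] += 1

    if support:
        top = support.most_common()
        # order by support desc, then unit count for determinism
        top.sort(key=lambda kv: (-kv[1], kv[0]))
        a1 = top[0][0]
        a2 = top[1][0] if len(top) > 1 else a1
    else:
        a1 = a2 = locus.reference_units

    method_long = "spanning-exact"
    short, long_ = min(a1, a2), max(a1, a2)
    if n_irr > irr_trigger:
        long_ = estimate_inrepeat(n_irr, read_len, depth / 2.0, len(locus.motif))
        method_long = "inrepeat-estimated"
        short = min(short, long_)
    flag = (
        locus.pathogenic_min is not None and long_ >= locus.pathogenic_min
    )
    return StrGenotypeResult(
        allele_short=short,
        allele_long=long_,
        method_long=method_long,
        pathogenic_flag=flag,
        support=dict(support),
        n_inrepeat=n_irr,
    )
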