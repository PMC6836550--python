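"""Core genomic types and text formats.

The coordinate convention mirrors how clinical CNV tables print sizes: a
region written ``chrN:start-end`` has length ``end - start``.  All intervals
in the package are therefore treated as half-open-equivalent; no +1 anywhere.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple


class ParseError(ValueError):
    """Raised when a coordinate, ISCN or record string cannot be parsed."""


def normalize_chrom(chrom: str) -> str:
    """Strip a leading 'chr' prefix so 'chr2' and '2' compare equal."""
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"end < start in {self.chrom}:{self.start}-{self.end}"
            )

    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        if normalize_chrom(self.chrom) != normalize_chrom(other.chrom):
            return False
        return self.start < other.end and other.start < self.end

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if normalize_chrom(self.chrom) != normalize_chrom(other.chrom):
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def reciprocal_overlap(self, other: "GenomicInterval") -> float:
        """min(overlap/len_a, overlap/len_b); 0 for empty intervals."""
        ov = self.overlap_bp(other)
        if ov == 0 or self.length() == 0 or other.length() == 0:
            return 0.0
        return min(ov / self.length(), ov / other.length())

    def __str__(self) -> str:
        return f"chr{normalize_chrom(self.chrom)}:{self.start}-{self.end}"


_REGION_RE = re.compile(
    r"^(?:chr)?(?P<chrom>[A-Za-z0-9_.]+):(?P<start>[\d,]+)-(?P<end>[\d,]+)$"
)


def parse_region(text: str) -> GenomicInterval:
    """Parse ``chrN:start-end`` (thousands separators tolerated).

    >>> parse_region("chr2:166050817-166679227").length()
    628410
    """
    m = _REGION_RE.match(text.strip())
    if not m:
        raise ParseError(f"malformed region string: {text!r}")
    start = int(m.group("start").replace(",", ""))
    end = int(m.group("end").replace(",", ""))
    if end < start:
        raise ParseError(f"end < start in region string: {text!r}")
    return GenomicInterval(m.group("chrom"), start, end)


def format_region(iv: GenomicInterval) -> str:
    return str(iv)


# ---------------------------------------------------------------------------
# ISCN array strings


INHERITANCE_TOKENS = ("not maternal", "not paternal", "dn", "pat", "mat")
_INHERITANCE_MAP = {
    "not maternal": "not-maternal",
    "not paternal": "not-paternal",
}


@dataclass(frozen=True)
class IscnSegment:
    band: str
    interval: GenomicInterval
    copy_number: int


@dataclass(frozen=True)
class IscnRecord:
    """A parsed microarray ISCN string, e.g.

    ``arr[GRCh37] 2p21p22.1(39053852_42501893)x3 dn``
    """

    build: str
    segments: Tuple[IscnSegment, ...]
    inheritance: str = "unknown"

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("IscnRecord requires >=1 segment")
        for seg in self.segments:
            if seg.copy_number < 0:
                raise ValueError("copy number must be >= 0")


_ISCN_HEAD_RE = re.compile(r"^arr\[(?P<build>[^\]]+)\]\s*(?P<body>.*)$", re.S)
_ISCN_SEG_RE = re.compile(
    r"(?P<band>[0-9XY]+[pq][0-9a-zA-Z.]*(?:[pq]?(?:ter|[0-9a-zA-Z.]*))?)?"
    r"\((?P<start>[\d,]+)[_\-](?P<end>[\d,]+)\)x(?P<cn>\d+)"
)


def _chrom_from_band(band: str) -> str:
    m = re.match(r"^([0-9XY]+)[pq]", band)
    if not m:
        raise ParseError(f"cannot extract chromosome from band token {band!r}")
    return m.group(1)


def parse_iscn(text: str) -> IscnRecord:
    """Parse an ISCN microarray string into build, segments and inheritance.

    Both ``_`` and ``-`` are accepted as coordinate separators; band tokens
    are kept verbatim.  Comma-separated entries yield multiple segments.
    """
    text = text.strip()
    head = _ISCN_HEAD_RE.match(text)
    if not head:
        raise ParseError(f"ISCN string must start with 'arr[...]': {text!r}")
    body = head.group("body").strip()

    inheritance = "unknown"
    for tok in INHERITANCE_TOKENS:
        # inheritance tokens trail the whole string or individual segments
        pat = r"(?:^|[\s,()])" + tok.replace(" ", r"[\s-]") + r"(?:$|[\s,()])"
        if re.search(pat, body):
            inheritance = _INHERITANCE_MAP.get(tok, tok)
            break

    segments: List[IscnSegment] = []
    last_chrom: Optional[str] = None
    for m in _ISCN_SEG_RE.finditer(body):
        band = m.group("band") or ""
        start = int(m.group("start").replace(",", ""))
        end = int(m.group("end").replace(",", ""))
        if end < start:
            raise ParseError(f"end < start in ISCN segment {m.group(0)!r}")
        chrom = _chrom_from_band(band) if band else last_chrom
        if chrom is None:
            raise ParseError(f"segment without chromosome band: {m.group(0)!r}")
        last_chrom = chrom
        segments.append(
            IscnSegment(band, GenomicInterval(chrom, start, end), int(m.group("cn")))
        )
    if not segments:
        raise ParseError(f"no '(start_end)xN' segment found in {text!r}")
    return IscnRecord(head.group("build"), tuple(segments), inheritance)


# ---------------------------------------------------------------------------
# Size formatting


def format_size(length_bp: int, unit: str = "auto") -> str:
    """Render a size the way CNV tables print them ('3.45 Mb', '502 kb').

    kb/Mb values use 3 significant figures with trailing zeros dropped; bp
    uses thousands separators.  'auto' picks bp below 10 kb, kb below 1 Mb,
    Mb above.
    """
    if length_bp < 0:
        raise ValueError("negative length")
    if unit == "auto":
        if length_bp < 10_000:
            unit = "bp"
        elif length_bp < 1_000_000:
            unit = "kb"
        else:
            unit = "Mb"
    if unit == "bp":
        return f"{length_bp:,} bp"
    if unit == "kb":
        return f"{_sig3(length_bp / 1e3)} kb"
    if unit == "Mb":
        return f"{_sig3(length_bp / 1e6)} Mb"
    raise ValueError(f"unknown unit {unit!r}")


def _sig3(x: float) -> str:
    if x == 0:
        return "0"
    s = f"{x:.3g}"
    if "e" in s or "E" in s:  # very large values: fall back to plain int
        s = f"{x:.0f}"
    if "." in s:
        s = s.rstrip("0").rstrip(".")
    return s


# ---------------------------------------------------------------------------
# Structural-variant records


SV_TYPES = ("DEL", "DUP", "INV", "INS", "BND")
CALLERS = ("coverage", "pairedread", "merged")
CLASSIFICATION_TIERS = (
    "benign",
    "likely benign",
    "VUS",
    "likely pathogenic",
    "pathogenic",
)


@dataclass
class SvRecord:
    """One structural-variant call.

    ``partner`` carries (contig, position, orientation) for breakend records;
    orientation is 'L' when the partner retains its left side, 'R' for right.
    """

    id: str
    sv_type: str
    interval: GenomicInterval
    caller: str = "merged"
    partner: Optional[Tuple[str, int, str]] = None
    #: for BND records: which local reference side is retained ('L'/'R')
    bnd_side: Optional[str] = None
    pe_support: int = 0
    copy_number: Optional[int] = None
    af_population: Optional[float] = None
    af_internal: Optional[float] = None
    genes: Set[str] = field(default_factory=set)
    classification: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown sv_type {self.sv_type!r}")
        if self.caller not in CALLERS:
            raise ValueError(f"unknown caller {self.caller!r}")
        if self.pe_support < 0:
            raise ValueError("pe_support must be >= 0")
        for af in (self.af_population, self.af_internal):
            if af is not None and not (0.0 <= af <= 1.0):
                raise ValueError(f"allele frequency out of [0,1]: {af}")
        if self.classification is not None and self.classification not in CLASSIFICATION_TIERS:
            raise ValueError(f"unknown classification {self.classification!r}")

    def length(self) -> int:
        return self.interval.length()


# ---------------------------------------------------------------------------
# Gene panels


@dataclass
class Panel:
    """A named gene panel: symbol -> list of gene-body/exon intervals."""

    name: str
    genes: Dict[str, List[GenomicInterval]]

    def __post_init__(self) -> None:
        for sym, ivs in self.genes.items():
            if not ivs:
                raise ValueError(f"gene {sym} has no intervals")

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.genes

    def __len__(self) -> int:
        return len(self.genes)

    def intervals(self) -> List[Tuple[str, GenomicInterval]]:
        return [(sym, iv) for sym, ivs in self.genes.items() for iv in ivs]


def read_bed_panel(path: str, name: Optional[str] = None) -> Panel:
    """Read a BED file of gene intervals (4th column = gene symbol)."""
    genes: Dict[str, List[GenomicInterval]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}:{ln}: BED needs 4 columns (name)")
            iv = GenomicInterval(parts[0], int(parts[1]), int(parts[2]))
            genes.setdefault(parts[3], []).append(iv)
    return Panel(name or path, genes)


def write_bed_panel(panel: Panel, path: str) -> None:
    with open(path, "w") as fh:
        for sym in sorted(panel.genes):
            for iv in sorted(panel.genes[sym]):
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{sym}\n")
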