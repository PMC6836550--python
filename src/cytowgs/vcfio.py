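"""SV VCF 4.2 reading/writing (pysam-backed).

Custom INFO keys declared in the header carry what the toolchain needs
downstream: CALLER, PE (discordant-pair support), AF_POP / AF_INT (population
and internal-database allele frequencies), CN, GENES and CLASS.  Breakend
records use standard ALT breakend syntax; ``t[c:p[`` means the partner
retains its right side ('R'), ``t]c:p]`` its left side ('L').
"""

from __future__ import annotations

import re
from typing import Dict, List, Optional, Sequence, Tuple

import pysam

from .formats import GenomicInterval, ParseError, SvRecord
from .genome import GRCH37_LENGTHS

_INFO_LINES = [
    ('SVTYPE', '1', 'String', 'Type of structural variant'),
    ('SVLEN', '1', 'Integer', 'Length of the variant'),
    ('CALLER', '1', 'String', 'Originating caller (coverage/pairedread/merged)'),
    ('PE', '1', 'Integer', 'Discordant read-pair support'),
    ('AF_POP', '1', 'Float', 'Population SV database allele frequency'),
    ('AF_INT', '1', 'Float', 'Internal SV database allele frequency'),
    ('CN', '1', 'Integer', 'Copy number of the called segment'),
    ('GENES', '.', 'String', 'Overlapped gene symbols'),
    ('CLASS', '1', 'String', 'Five-tier clinical classification'),
]

_BND_ALT_RE = re.compile(
    r"^[ACGTN]*(?P<b1>[\[\]])(?P<chrom>[^:\[\]]+):(?P<pos>\d+)(?P<b2>[\[\]])[ACGTN]*$"
)


def _build_header(contigs: Dict[str, int]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    for key, number, vtype, desc in _INFO_LINES:
        header.info.add(key, number, vtype, desc)
    for alt in ("DEL", "DUP", "INV", "INS", "BND"):
        header.add_meta("ALT", items=[("ID", alt), ("Description", alt)])
    return header


def sv_vcf_write(
    records: Sequence[SvRecord],
    path: str,
    contigs: Optional[Dict[str, int]] = None,
) -> None:
    """Write SvRecords to an (uncompressed) VCF at *path*."""
    if contigs is None:
        contigs = dict(GRCH37_LENGTHS)
        for rec in records:  # make sure every contig is declared
            for c in {rec.interval.chrom} | (
                {rec.partner[0]} if rec.partner else set()
            ):
                contigs.setdefault(c, max(rec.interval.end, 1) + 1_000_000)
    header = _build_header(contigs)
    with pysam.VariantFile(path, "w", header=header) as vf:
        for rec in records:
            if rec.sv_type == "BND":
                if rec.partner is None:
                    raise ValueError(f"BND record {rec.id} lacks a partner")
                c, p, orient = rec.partner
                side = rec.bnd_side or "L"
                bracketed = f"[{c}:{p}[" if orient == "R" else f"]{c}:{p}]"
                alt = f"N{bracketed}" if side == "L" else f"{bracketed}N"
                out = vf.new_record(
                    contig=rec.interval.chrom,
                    start=rec.interval.start,
                    alleles=("N", alt),
                    id=rec.id,
                )
                out.info["SVTYPE"] = "BND"
            else:
                out = vf.new_record(
                    contig=rec.interval.chrom,
                    start=rec.interval.start,
                    stop=rec.interval.end,
                    alleles=("N", f"<{rec.sv_type}>"),
                    id=rec.id,
                )
                out.info["SVTYPE"] = rec.sv_type
            out.info["CALLER"] = rec.caller
            out.info["PE"] = rec.pe_support
            if rec.af_population is not None:
                out.info["AF_POP"] = rec.af_population
            if rec.af_internal is not None:
                out.info["AF_INT"] = rec.af_internal
            if rec.copy_number is not None:
                out.info["CN"] = rec.copy_number
            if rec.genes:
                out.info["GENES"] = tuple(sorted(rec.genes))
            if rec.classification is not None:
                out.info["CLASS"] = rec.classification.replace(" ", "_")
            vf.write(out)


def _prescan(path: str) -> List[Optional[int]]:
    """Validate SVTYPE/END/SVLEN consistency per record (with line numbers)
    and return each record's printed END (None when absent).

    The explicit scan is needed because htslib normalizes/clamps END and
    SVLEN while parsing, which would hide exactly the inconsistencies this
    reader is contracted to reject.
    """
    ends: List[Optional[int]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 8:
                raise ParseError(f"{path}:{ln}: truncated VCF line")
            pos = int(cols[1])
            info = {}
            for kv in cols[7].split(";"):
                if "=" in kv:
                    k, v = kv.split("=", 1)
                    info[k] = v
                else:
                    info[kv] = True
            svtype = info.get("SVTYPE")
            if svtype is None:
                raise ParseError(f"{path}:{ln}: missing SVTYPE")
            end = int(info["END"]) if "END" in info else None
            svlen = int(info["SVLEN"]) if "SVLEN" in info else None
            if svtype != "BND":
                if end is not None and end < pos:
                    raise ParseError(f"{path}:{ln}: END {end} < POS {pos}")
                if end is None and svlen is None:
                    raise ParseError(
                        f"{path}:{ln}: non-BND record without END or SVLEN"
                    )
                if end is not None and svlen is not None:
                    if abs(svlen) != end - (pos - 1):
                        raise ParseError(
                            f"{path}:{ln}: inconsistent END/SVLEN "
                            f"(END-start {end - pos + 1}, SVLEN {svlen})"
                        )
            ends.append(end)
    return ends


def sv_vcf_read(path: str) -> List[SvRecord]:
    """Read SvRecords back from a VCF; raises ParseError with the line
    number for malformed entries (missing SVTYPE, END before POS,
    END/SVLEN disagreement)."""
    ends = _prescan(path)
    out: List[SvRecord] = []
    with pysam.VariantFile(path) as vf:
        for n, rec in enumerate(vf):
            try:
                out.append(_from_pysam(rec, printed_end=ends[n]))
            except (KeyError, ValueError) as exc:
                raise ParseError(f"{path}: record {n + 1}: {exc}") from exc
    return out


def _from_pysam(
    rec: "pysam.VariantRecord", printed_end: Optional[int] = None
) -> SvRecord:
    info = rec.info
    if "SVTYPE" not in info:
        raise ParseError("missing SVTYPE")
    sv_type = info["SVTYPE"]
    start = rec.start  # 0-based
    partner = None
    bnd_side = None
    if sv_type == "BND":
        alt = rec.alts[0]
        m = _BND_ALT_RE.match(alt)
        if not m:
            raise ParseError(f"unparseable breakend ALT {alt!r}")
        orient = "R" if m.group("b1") == "[" else "L"
        bnd_side = "L" if alt[0] not in "[]" else "R"
        partner = (m.group("chrom"), int(m.group("pos")), orient)
        interval = GenomicInterval(rec.contig, start, start)
    else:
        svlen = info.get("SVLEN")
        if printed_end is not None:
            end = printed_end
        elif svlen is not None:
            end = start + abs(int(svlen))
        else:
            end = rec.stop
        if end < start:
            raise ParseError(f"END {end} < POS {start + 1}")
        interval = GenomicInterval(rec.contig, start, end)
    genes = set(info["GENES"]) if "GENES" in info else set()
    classification = (
        info["CLASS"].replace("_", " ") if "CLASS" in info else None
    )
    return SvRecord(
        id=rec.id or ".",
        sv_type=sv_type,
        interval=interval,
        caller=info.get("CALLER", "merged"),
        partner=partner,
        bnd_side=bnd_side,
        pe_support=int(info.get("PE", 0)),
        copy_number=int(info["CN"]) if "CN" in info else None,
        af_population=float(info["AF_POP"]) if "AF_POP" in info else None,
        af_internal=float(info["AF_INT"]) if "AF_INT" in info else None,
        genes=genes,
        classification=classification,
    )
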