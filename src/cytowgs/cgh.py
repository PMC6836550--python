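"""Array-emulation export: SV calls rendered as synthetic probe log2 ratios.

The output dialect is a self-describing UTF-8 XML document with one
``<probe chrom="" pos="" log2=""/>`` element per synthetic probe plus a
``<segments>`` block mirroring the calls.  It emulates how CNV calls look in
an array-CGH viewer and makes no claim of compatibility with any proprietary
array file format.
"""

from __future__ import annotations

import math
from typing import Dict, List, Sequence, Tuple
from xml.etree import ElementTree as ET

from .formats import GenomicInterval, SvRecord, normalize_chrom

#: finite plottable floor for log2(0/2)
LOG2_FLOOR = -3.0

#: default copy numbers assumed for calls that do not carry one
_DEFAULT_CN = {"DEL": 1, "DUP": 3}


def _call_log2(cn: int) -> float:
    if cn <= 0:
        return LOG2_FLOOR
    return math.log2(cn / 2.0)


def cgh_document(
    records: Sequence[SvRecord],
    contig_lengths: Dict[str, int],
    spacing: int = 18_000,
) -> Tuple[str, int]:
    """Build the XML document; returns (xml_text, n_skipped_records).

    Probes are placed every *spacing* bp (positions spacing, 2*spacing, ...;
    ``floor(contig_len/spacing)`` probes per contig).  log2 is 0 outside
    calls and log2(copy_number/2) inside, with copy 0 capped at −3.  Records
    without a copy number that are not DEL/DUP are skipped and counted.
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")

    usable: List[Tuple[SvRecord, int]] = []
    skipped = 0
    for rec in records:
        cn = rec.copy_number
        if cn is None:
            cn = _DEFAULT_CN.get(rec.sv_type)
        if cn is None:
            skipped += 1
            continue
        usable.append((rec, cn))

    root = ET.Element("cgh", attrib={"spacing": str(spacing), "build": "GRCh37"})
    probes_el = ET.SubElement(root, "probes")
    for chrom, length in contig_lengths.items():
        cnorm = normalize_chrom(chrom)
        calls = [
            (r.interval.start, r.interval.end, cn)
            for r, cn in usable
            if normalize_chrom(r.interval.chrom) == cnorm
        ]
        for k in range(1, length // spacing + 1):
            pos = k * spacing
            log2 = 0.0
            for s, e, cn in calls:
                if s <= pos < e:
                    log2 = _call_log2(cn)
                    break
            ET.SubElement(
                probes_el,
                "probe",
                attrib={"chrom": cnorm, "pos": str(pos), "log2": f"{log2:.4f}"},
            )
    seg_el = ET.SubElement(root, "segments")
    for rec, cn in usable:
        ET.SubElement(
            seg_el,
            "segment",
            attrib={
                "chrom": normalize_chrom(rec.interval.chrom),
                "start": str(rec.interval.start),
                "end": str(rec.interval.end),
                "cn": str(cn),
                "log2": f"{_call_log2(cn):.4f}",
                "type": rec.sv_type,
                "id": rec.id,
            },
        )
    ET.indent(root)
    text = ET.tostring(root, encoding="unicode", xml_declaration=True)
    return text + "\n", skipped


def write_cgh(
    records: Sequence[SvRecord],
    contig_lengths: Dict[str, int],
    spacing: int,
    path: str,
) -> int:
    """Write the emulation document to *path*; returns skipped-record count."""
    text, skipped = cgh_document(records, contig_lengths, spacing)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(text)
    return skipped


def read_cgh_probes(path: str) -> List[Tuple[str, int, float]]:
    """Read back the probe triples from an emulation document."""
    root = ET.parse(path).getroot()
    return [
        (p.attrib["chrom"], int(p.attrib["pos"]), float(p.attrib["log2"]))
        for p in root.iter("probe")
    ]
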