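"""Reference genome bookkeeping: contig lengths and simple genome models.

Coordinates throughout the package follow GRCh37/hg19 and are stored as
half-open-equivalent pairs (start, end) with length = end - start.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Tuple

from .formats import GenomicInterval, Panel, normalize_chrom

# GRCh37 primary-assembly chromosome lengths (bp).
GRCH37_LENGTHS: Dict[str, int] = {
    "1": 249250621,
    "2": 243199373,
    "3": 198022430,
    "4": 191154276,
    "5": 180915260,
    "6": 171115067,
    "7": 159138663,
    "8": 146364022,
    "9": 141213431,
    "10": 135534747,
    "11": 135006516,
    "12": 133851895,
    "13": 115169878,
    "14": 107349540,
    "15": 102531392,
    "16": 90354753,
    "17": 81195210,
    "18": 78077248,
    "19": 59128983,
    "20": 63025520,
    "21": 48129895,
    "22": 51304566,
    "X": 155270560,
    "Y": 59373566,
}

AUTOSOMES: Tuple[str, ...] = tuple(str(i) for i in range(1, 23))

#: Contigs treated as decoy/EBV by default when filtering call sets.
DEFAULT_DECOY_CONTIGS = frozenset({"hs37d5", "NC_007605"})


def is_decoy(chrom: str, decoys: frozenset = DEFAULT_DECOY_CONTIGS) -> bool:
    c = normalize_chrom(chrom)
    return c in decoys or "decoy" in c.lower()


@dataclass
class GenomeModel:
    """A toy genome for simulation: contig lengths plus annotation layers.

    repeat_regions marks NAHR-prone intervals (paired-read callers are blind
    to breakpoints inside them); gene_models is a Panel used for the
    intragenic/intergenic dichotomy.
    """

    contigs: Dict[str, int]
    repeat_regions: List["GenomicInterval"] = field(default_factory=list)
    gene_models: "Panel | None" = None

    def __post_init__(self) -> None:
        for iv in self.repeat_regions:
            L = self.contigs.get(normalize_chrom(iv.chrom))
            if L is None or iv.end > L:
                raise ValueError(f"repeat region {iv} outside contig bounds")

    @classmethod
    def grch37(cls, chroms: Mapping[str, int] | None = None) -> "GenomeModel":
        return cls(contigs=dict(chroms or GRCH37_LENGTHS))
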