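"""Coverage-based aneuploidy detection and mosaic-fraction estimation.

A chromosome present in three copies in a fraction f of cells shifts its
mean read depth by a factor 1 + f/2 relative to the disomic baseline, so
the coverage ratio r inverts to f = 2(r - 1) for gains (and f = 2(1 - r)
for losses).  Ratios use median/MAD statistics for robustness against
focal CNVs, and sex chromosomes are excluded from the baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .formats import normalize_chrom
from .genome import AUTOSOMES


@dataclass
class DepthBins:
    """Per-bin read counts: (chrom, start, depth)."""

    bins: List[Tuple[str, int, float]]
    bin_bp: int

    def __post_init__(self) -> None:
        if any(d < 0 for _, _, d in self.bins):
            raise ValueError("negative depth")

    def by_chrom(self) -> Dict[str, np.ndarray]:
        out: Dict[str, List[float]] = {}
        for chrom, _, depth in self.bins:
            out.setdefault(normalize_chrom(chrom), []).append(depth)
        return {c: np.asarray(v, dtype=float) for c, v in out.items()}

    @classmethod
    def from_tsv(cls, path: str, bin_bp: int) -> "DepthBins":
        bins = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                chrom, start, depth = line.split("\t")[:3]
                bins.append((chrom, int(start), float(depth)))
        return cls(bins, bin_bp)


@dataclass
class ChromosomeRatio:
    chrom: str
    ratio: float
    z: float
    n_bins: int
    n_baseline: int


_MAD_SCALE = 1.4826  # MAD -> sigma for a normal distribution


def chrom_ratio(
    bins: DepthBins,
    chrom: str,
    min_chrom_bins: int = 100,
    min_baseline_bins: int = 1000,
) -> ChromosomeRatio:
    """Median depth of *chrom* over the median autosomal baseline
    (excluding that chromosome and the sex chromosomes)."""
    chrom = normalize_chrom(chrom)
    per = bins.by_chrom()
    if chrom not in per or len(per[chrom]) < min_chrom_bins:
        raise ValueError(f"insufficient bins on chromosome {chrom}")
    baseline = [
        v for c, v in per.items() if c != chrom and c in AUTOSOMES
    ]
    if not baseline or sum(len(v) for v in baseline) < min_baseline_bins:
        raise ValueError("insufficient baseline bins")
    base = np.concatenate(baseline)
    base_med = float(np.median(base))
    if base_med <= 0:
        raise ValueError("baseline median depth is zero")
    target = per[chrom]
    ratio = float(np.median(target)) / base_med

    # z of the chromosome median under the baseline's median sampling noise
    mad = float(np.median(np.abs(base - base_med))) * _MAD_SCALE
    sigma_med = mad * 1.2533 / np.sqrt(len(target))  # se of a median
    z = (float(np.median(target)) - base_med) / sigma_med if sigma_med > 0 else 0.0
    return ChromosomeRatio(
        chrom=chrom,
        ratio=ratio,
        z=float(z),
        n_bins=len(target),
        n_baseline=len(base),
    )


def mosaic_fraction(ratio: float, direction: str) -> float:
    """Invert the single-extra/missing-copy mixture: gain f = 2(r-1),
    loss f = 2(1-r); clamped to [0, 1]."""
    if ratio <= 0:
        raise ValueError("ratio must be > 0")
    if direction == "gain":
        f = 2.0 * (ratio - 1.0)
    elif direction == "loss":
        f = 2.0 * (1.0 - ratio)
    else:
        raise ValueError(f"direction must be 'gain' or 'loss', got {direction!r}")
    return min(max(f, 0.0), 1.0)


@dataclass
class AneuploidyCall:
    chrom: str
    ratio: float
    z: float
    call: str  # trisomy | monosomy | mosaic-gain | mosaic-loss | normal
    mosaic_fraction: float = 0.0


def detect_aneuploidy(
    bins: DepthBins,
    z_min: float = 5.0,
    min_effect: float = 0.05,
    trisomy_ratio: float = 1.4,
    monosomy_ratio: float = 0.6,
) -> List[AneuploidyCall]:
    """Scan whole-genome bins for chromosome-scale dosage shifts.

    A chromosome is flagged when its shift is both statistically clear
    (|z| >= z_min) and of meaningful size (|ratio - 1| >= min_effect; the
    default corresponds to ~10% mosaicism, about the floor detectable at
    30x coverage).
    """
    calls: List[AneuploidyCall] = []
    present = [c for c in AUTOSOMES if c in bins.by_chrom()]
    for chrom in present:
        cr = chrom_ratio(bins, chrom)
        if abs(cr.z) < z_min or abs(cr.ratio - 1.0) < min_effect:
            calls.append(AneuploidyCall(chrom, cr.ratio, cr.z, "normal"))
            continue
        if cr.ratio >= trisomy_ratio:
            calls.append(AneuploidyCall(chrom, cr.ratio, cr.z, "trisomy", 1.0))
        elif cr.ratio <= monosomy_ratio:
            calls.append(AneuploidyCall(chrom, cr.ratio, cr.z, "monosomy", 1.0))
        elif cr.ratio > 1.0:
            calls.append(
                AneuploidyCall(
                    chrom, cr.ratio, cr.z, "mosaic-gain",
                    mosaic_fraction(cr.ratio, "gain"),
                )
            )
        else:
            calls.append(
                AneuploidyCall(
                    chrom, cr.ratio, cr.z, "mosaic-loss",
                    mosaic_fraction(cr.ratio, "loss"),
                )
            )
    return calls
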