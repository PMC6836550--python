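"""Emulated array-CGH / MLPA calling and the WGS-vs-array comparison.

Array calling follows the routine clinical rule: three consecutive aberrant
probes beyond a log2-ratio cutoff (−0.65 for losses, +0.35 for gains).  No
segmentation beyond the consecutive-probe rule is attempted.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from intervaltree import IntervalTree

from .formats import GenomicInterval, SvRecord, normalize_chrom

DEL_CUT = -0.65
DUP_CUT = 0.35
MIN_RUN = 3


@dataclass
class ProbeSeries:
    """Ordered (chrom, pos, log2_ratio) probe triples."""

    probes: List[Tuple[str, int, float]]

    def __post_init__(self) -> None:
        last: Dict[str, int] = {}
        for chrom, pos, _ in self.probes:
            c = normalize_chrom(chrom)
            if c in last and pos <= last[c]:
                raise ValueError(
                    f"probe positions not strictly increasing on {chrom}"
                )
            last[c] = pos

    @classmethod
    def from_tsv(cls, path: str) -> "ProbeSeries":
        probes = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                chrom, pos, log2 = line.split("\t")[:3]
                probes.append((chrom, int(pos), float(log2)))
        return cls(probes)

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            for chrom, pos, log2 in self.probes:
                fh.write(f"{chrom}\t{pos}\t{log2:.6f}\n")


@dataclass
class CmaCall:
    interval: GenomicInterval
    direction: str  # 'loss' | 'gain'
    n_probes: int
    mean_log2: float


def call_probes(
    series: ProbeSeries,
    del_cut: float = DEL_CUT,
    dup_cut: float = DUP_CUT,
    min_run: int = MIN_RUN,
) -> List[CmaCall]:
    """Maximal runs of >= min_run consecutive aberrant probes become calls.

    Runs never mix directions, and are broken by chromosome boundaries and
    by any probe inside the cutoffs (no gap tolerance).  The call interval
    spans the first to last aberrant probe position.
    """
    calls: List[CmaCall] = []
    run: List[Tuple[int, float]] = []
    run_chrom: Optional[str] = None
    run_dir: Optional[str] = None

    def flush() -> None:
        if run_dir is not None and len(run) >= min_run:
            positions = [p for p, _ in run]
            values = [v for _, v in run]
            calls.append(
                CmaCall(
                    interval=GenomicInterval(
                        run_chrom, positions[0], positions[-1]
                    ),
                    direction=run_dir,
                    n_probes=len(run),
                    mean_log2=float(np.mean(values)),
                )
            )

    for chrom, pos, log2 in series.probes:
        c = normalize_chrom(chrom)
        direction = (
            "loss" if log2 < del_cut else "gain" if log2 > dup_cut else None
        )
        if direction is None or c != run_chrom or direction != run_dir:
            flush()
            run, run_chrom, run_dir = [], c, direction
        if direction is not None:
            run.append((pos, log2))
    flush()
    return calls


def mlpa_call(ratio: float) -> str:
    """MLPA normalized-quotient call: <0.75 deletion, >1.3 duplication."""
    if ratio < 0:
        raise ValueError("MLPA ratio must be >= 0")
    if ratio < 0.75:
        return "deletion"
    if ratio > 1.3:
        return "duplication"
    return "normal"


_DIRECTION_OF_TYPE = {"DEL": "loss", "DUP": "gain"}


@dataclass
class ComparisonReport:
    n_cma: int
    n_found: int
    found_fraction: float
    median_size_found: Optional[float]
    median_size_not_found: Optional[float]
    quartiles_found: Tuple[Optional[float], Optional[float]]
    quartiles_not_found: Tuple[Optional[float], Optional[float]]
    gain_fraction_found: Optional[float]
    gain_fraction_not_found: Optional[float]

    def to_dict(self) -> dict:
        return {
            "n_cma": self.n_cma,
            "n_found": self.n_found,
            "found_fraction": self.found_fraction,
            "median_size_found": self.median_size_found,
            "median_size_not_found": self.median_size_not_found,
            "quartiles_found": list(self.quartiles_found),
            "quartiles_not_found": list(self.quartiles_not_found),
            "gain_fraction_found": self.gain_fraction_found,
            "gain_fraction_not_found": self.gain_fraction_not_found,
        }


def _size_stats(calls: Sequence[CmaCall]):
    if not calls:
        return None, (None, None), None
    sizes = np.array([c.interval.length() for c in calls], dtype=float)
    gains = np.mean([c.direction == "gain" for c in calls])
    q1, med, q3 = np.percentile(sizes, [25, 50, 75])
    return float(med), (float(q1), float(q3)), float(gains)


def compare_callsets(
    wgs: Sequence[SvRecord], cma: Sequence[CmaCall]
) -> ComparisonReport:
    """Fraction of array calls confirmed by a WGS call of matching direction.

    An array call counts as found iff it overlaps (>= 1 bp) a WGS DEL for a
    loss, or a WGS DUP for a gain.  Adding WGS records can only increase the
    found fraction.
    """
    trees: Dict[Tuple[str, str], IntervalTree] = defaultdict(IntervalTree)
    for rec in wgs:
        direction = _DIRECTION_OF_TYPE.get(rec.sv_type)
        if direction is None or rec.interval.length() == 0:
            continue
        trees[(normalize_chrom(rec.interval.chrom), direction)].addi(
            rec.interval.start, rec.interval.end
        )
    found: List[CmaCall] = []
    missed: List[CmaCall] = []
    for call in cma:
        tree = trees.get(
            (normalize_chrom(call.interval.chrom), call.direction)
        )
        hit = bool(
            tree
            and tree.overlap(
                call.interval.start, max(call.interval.end, call.interval.start + 1)
            )
        )
        (found if hit else missed).append(call)

    med_f, q_f, gain_f = _size_stats(found)
    med_m, q_m, gain_m = _size_stats(missed)
    n = len(cma)
    return ComparisonReport(
        n_cma=n,
        n_found=len(found),
        found_fraction=(len(found) / n) if n else 0.0,
        median_size_found=med_f,
        median_size_not_found=med_m,
        quartiles_found=q_f,
        quartiles_not_found=q_m,
        gain_fraction_found=gain_f,
        gain_fraction_not_found=gain_m,
    )
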