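"""Runs of homozygosity and uniparental-disomy classification.

The zygosity signal is the fraction of homozygous high-quality SNVs per
fixed genomic window (10 kb by default).  Its complement — the heterozygous
fraction — is exposed as well; an isodisomic (or autozygous) region shows a
homozygous fraction near 1 over megabases.  UPD typing uses trio genotypes
where available: sites where the child carries no allele transmissible from
one parent are evidence for uniparental inheritance from the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .formats import GenomicInterval

GENOTYPES = ("het", "hom_ref", "hom_alt")


@dataclass(frozen=True)
class SnpSite:
    pos: int
    genotype: str  # 'het' | 'hom_ref' | 'hom_alt'
    quality: float = 99.0

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.quality < 0:
            raise ValueError("quality must be >= 0")

    @property
    def is_hom(self) -> bool:
        return self.genotype != "het"


@dataclass
class ZygosityWindow:
    interval: GenomicInterval
    n_snps: int
    hom_fraction: Optional[float]  # None when n_snps < min_snps

    @property
    def het_fraction(self) -> Optional[float]:
        return None if self.hom_fraction is None else 1.0 - self.hom_fraction


@dataclass
class ZygosityTrack:
    chrom: str
    window_bp: int
    windows: List[ZygosityWindow]


def zygosity_track(
    sites: Sequence[SnpSite],
    chrom: str = "15",
    chrom_length: Optional[int] = None,
    window_bp: int = 10_000,
    min_quality: float = 20.0,
    min_snps: int = 5,
) -> ZygosityTrack:
    """Windowed homozygous-SNV fraction over a fixed tiling.

    Windows with fewer than min_snps qualifying sites are flagged missing
    (hom_fraction None).
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    qual = [s for s in sites if s.quality >= min_quality]
    if chrom_length is None:
        chrom_length = (max(s.pos for s in qual) + 1) if qual else window_bp
    n_windows = (chrom_length + window_bp - 1) // window_bp
    n_snps = np.zeros(n_windows, dtype=int)
    n_hom = np.zeros(n_windows, dtype=int)
    for s in qual:
        w = s.pos // window_bp
        if 0 <= w < n_windows:
            n_snps[w] += 1
            if s.is_hom:
                n_hom[w] += 1
    windows = []
    for w in range(n_windows):
        iv = GenomicInterval(
            chrom, w * window_bp, min((w + 1) * window_bp, chrom_length)
        )
        frac = (
            n_hom[w] / n_snps[w] if n_snps[w] >= min_snps else None
        )
        windows.append(ZygosityWindow(iv, int(n_snps[w]), frac))
    return ZygosityTrack(chrom=chrom, window_bp=window_bp, windows=windows)


@dataclass
class RohSegment:
    interval: GenomicInterval
    n_windows: int
    mean_hom_fraction: float


def call_roh(
    track: ZygosityTrack,
    min_hom_fraction: float = 0.95,
    min_len: int = 1_000_000,
    max_het_bridge: int = 1,
    merge_gap: int = 100_000,
) -> List[RohSegment]:
    """Maximal runs of windows with hom_fraction >= min_hom_fraction.

    Three tolerances mirror standard ROH-caller practice (a run of true
    autozygosity is interrupted by genotyping noise, not ended by it):
    missing windows (too few SNVs) bridge a run without contributing
    evidence; a below-threshold window with at most max_het_bridge
    heterozygous sites continues a run; and runs separated by a gap of at
    most merge_gap are merged before the length filter.  A merged run
    qualifies when its span is >= min_len.
    """
    runs: List[List[ZygosityWindow]] = []
    run: List[ZygosityWindow] = []
    for w in track.windows:
        if w.hom_fraction is None:
            continue  # bridge: neither breaks nor extends the evidence span
        n_het = round(w.n_snps * (1.0 - w.hom_fraction))
        if w.hom_fraction >= min_hom_fraction or (
            run and n_het <= max_het_bridge
        ):
            run.append(w)
        else:
            if run:
                runs.append(run)
            run = []
    if run:
        runs.append(run)

    merged: List[List[ZygosityWindow]] = []
    for r in runs:
        if merged and r[0].interval.start - merged[-1][-1].interval.end <= merge_gap:
            merged[-1] = merged[-1] + r
        else:
            merged.append(r)

    segments: List[RohSegment] = []
    for r in merged:
        start = r[0].interval.start
        end = r[-1].interval.end
        if end - start >= min_len:
            segments.append(
                RohSegment(
                    GenomicInterval(track.chrom, start, end),
                    n_windows=len(r),
                    mean_hom_fraction=float(
                        np.mean([w.hom_fraction for w in r])
                    ),
                )
            )
    return segments


# ---------------------------------------------------------------------------
# UPD classification


@dataclass(frozen=True)
class TrioSite:
    """Genotypes as allele multisets, e.g. ('A','A') or ('A','G')."""

    pos: int
    child: Tuple[str, str]
    mother: Optional[Tuple[str, str]] = None
    father: Optional[Tuple[str, str]] = None


@dataclass
class UpdCall:
    chrom: str
    kind: str  # isodisomy | heterodisomy | segmental-isodisomy | none
    parent: str  # maternal | paternal | undetermined
    evidence: Dict[str, int] = field(default_factory=dict)
    region: Optional[GenomicInterval] = None

    def __post_init__(self) -> None:
        if self.kind == "none" and self.parent != "undetermined":
            raise ValueError("kind=none implies parent=undetermined")


def _incompatible_with(parent: Tuple[str, str], child: Tuple[str, str]) -> bool:
    """True when no child allele could have been transmitted by the parent.

    (Conservative single-locus Mendelian check: the child must share at
    least one allele with each true biological parent.)
    """
    return not (set(child) & set(parent))


def classify_upd(
    sites: Sequence[TrioSite],
    roh: Sequence[RohSegment],
    chrom: str = "15",
    chrom_length: Optional[int] = None,
    min_informative: int = 20,
    segmental_margin: float = 0.10,
) -> UpdCall:
    """Classify uniparental disomy for one chromosome from trio genotypes.

    With both parents: sites incompatible with one parent are evidence for
    UPD of the other; isodisomy additionally requires overlap of the
    evidence with an RoH segment, heterodisomy is biparental-incompatibility
    without homozygosity.  With a single parent available, an RoH segment in
    which every homozygous child allele matches that parent is reported as
    consistent with that parent's isodisomy.  The call is 'segmental' when
    the evidence is confined to a subinterval of the chromosome.
    """
    none_call = UpdCall(chrom, "none", "undetermined")
    if not sites:
        return none_call
    have_mother = any(s.mother is not None for s in sites)
    have_father = any(s.father is not None for s in sites)
    if chrom_length is None:
        chrom_length = max(s.pos for s in sites) + 1

    if have_mother and have_father:
        maternal_ev: List[int] = []  # positions incompatible with father
        paternal_ev: List[int] = []  # positions incompatible with mother
        for s in sites:
            if s.mother is None or s.father is None:
                continue
            inc_f = _incompatible_with(s.father, s.child)
            inc_m = _incompatible_with(s.mother, s.child)
            if inc_f and not inc_m:
                maternal_ev.append(s.pos)
            elif inc_m and not inc_f:
                paternal_ev.append(s.pos)
        evidence = {
            "maternal_informative": len(maternal_ev),
            "paternal_informative": len(paternal_ev),
        }
        if (
            len(maternal_ev) >= min_informative
            and len(paternal_ev) >= min_informative
        ):
            call = UpdCall(chrom, "none", "undetermined", evidence)
            call.evidence["warning_contradictory"] = 1
            return call
        if len(maternal_ev) >= min_informative:
            parent, ev_pos = "maternal", maternal_ev
        elif len(paternal_ev) >= min_informative:
            parent, ev_pos = "paternal", paternal_ev
        else:
            return UpdCall(chrom, "none", "undetermined", evidence)
    elif have_mother or have_father:
        parent = "maternal" if have_mother else "paternal"
        avail = (lambda s: s.mother) if have_mother else (lambda s: s.father)
        ev_pos = []
        for seg in roh:
            lo, hi = seg.interval.start, seg.interval.end
            inside = [
                s
                for s in sites
                if lo <= s.pos < hi
                and avail(s) is not None
                and s.child[0] == s.child[1]
            ]
            matching = [s for s in inside if s.child[0] in avail(s)]
            if inside and len(matching) == len(inside):
                ev_pos.extend(s.pos for s in matching)
        evidence = {f"{parent}_informative": len(ev_pos)}
        if len(ev_pos) < min_informative:
            return UpdCall(chrom, "none", "undetermined", evidence)
    else:
        return none_call

    region = GenomicInterval(chrom, min(ev_pos), max(ev_pos) + 1)
    overlaps_roh = any(region.overlaps(seg.interval) for seg in roh)
    segmental = region.length() < (1.0 - segmental_margin) * chrom_length
    if overlaps_roh:
        kind = "segmental-isodisomy" if segmental else "isodisomy"
    else:
        kind = "heterodisomy"
    return UpdCall(chrom, kind, parent, evidence, region=region)
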