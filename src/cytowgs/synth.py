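"""Seeded synthetic-data generators for every input the toolkit consumes.

Each generator is a pure function of (specification, seed) and returns its
planted truth alongside the data, so recovery can be scored exactly.  The
two pseudo-callers emulate the complementary blind spots of read-depth and
discordant-pair SV calling: the depth caller reports CNVs >= 5 kb with
breakpoint jitter and sees repeat-flanked (recurrent) events, while the
pair caller reports exact breakpoints but misses events whose breakpoints
fall inside annotated repeats.  These are stylized emulations, not
calibrated models of any real caller.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .callset import CallerOutput
from .cma import ProbeSeries
from .formats import GenomicInterval, SvRecord, normalize_chrom
from .genome import GenomeModel
from .mosaic import DepthBins
from .roh_upd import SnpSite, TrioSite
from .str_repeat import RepeatLocus, StrRead

#: smallest CNV the depth pseudo-caller reports
COVERAGE_MIN_BP = 5_000
#: uniform breakpoint jitter of the depth pseudo-caller
COVERAGE_JITTER_BP = 500


@dataclass
class SvEvent:
    chrom: str
    start: int
    end: int
    sv_type: str  # DEL | DUP | INV
    copy_number: Optional[int] = None

    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


@dataclass
class TruthSet:
    """Planted events plus the seed that produced a dataset."""

    seed: int
    sv_events: List[dict] = field(default_factory=list)
    upd_segments: List[dict] = field(default_factory=list)
    str_alleles: List[dict] = field(default_factory=list)
    mosaic_fractions: List[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthSet":
        return cls(**json.loads(text))


def _in_repeat(model: GenomeModel, chrom: str, pos: int) -> bool:
    c = normalize_chrom(chrom)
    return any(
        normalize_chrom(iv.chrom) == c and iv.start <= pos < iv.end
        for iv in model.repeat_regions
    )


def simulate_sv_sample(
    model: GenomeModel,
    events: Sequence[SvEvent],
    seed: int,
    sample_id: str = "S1",
    depth: int = 30,
) -> Tuple[TruthSet, List[CallerOutput]]:
    """Run both pseudo-callers over planted events.

    Raises on overlapping planted events of the same type.  Deterministic
    for a fixed seed.
    """
    for i, a in enumerate(events):
        for b in events[i + 1:]:
            if a.sv_type == b.sv_type and a.interval().overlaps(b.interval()):
                raise ValueError(
                    f"overlapping planted events of the same type: {a} / {b}"
                )
        L = model.contigs.get(normalize_chrom(a.chrom))
        if L is None or a.end > L:
            raise ValueError(f"event outside contig bounds: {a}")

    rng = np.random.default_rng(seed)
    coverage: List[SvRecord] = []
    pairedread: List[SvRecord] = []
    for n, ev in enumerate(events):
        default_cn = {"DEL": 1, "DUP": 3}.get(ev.sv_type)
        cn = ev.copy_number if ev.copy_number is not None else default_cn
        # depth caller: dosage events >= 5 kb, jittered breakpoints
        if ev.sv_type in ("DEL", "DUP") and ev.end - ev.start >= COVERAGE_MIN_BP:
            js = int(rng.integers(-COVERAGE_JITTER_BP, COVERAGE_JITTER_BP + 1))
            je = int(rng.integers(-COVERAGE_JITTER_BP, COVERAGE_JITTER_BP + 1))
            start = max(0, ev.start + js)
            end = min(model.contigs[normalize_chrom(ev.chrom)], ev.end + je)
            if end > start:
                coverage.append(
                    SvRecord(
                        id=f"{sample_id}_cov_{n}",
                        sv_type=ev.sv_type,
                        interval=GenomicInterval(ev.chrom, start, end),
                        caller="coverage",
                        copy_number=cn,
                    )
                )
        # pair caller: exact breakpoints, blind inside repeats
        repeat_hit = _in_repeat(model, ev.chrom, ev.start) or _in_repeat(
            model, ev.chrom, ev.end
        )
        if not repeat_hit:
            pe = int(rng.binomial(depth, 0.5))
            pairedread.append(
                SvRecord(
                    id=f"{sample_id}_pe_{n}",
                    sv_type=ev.sv_type,
                    interval=ev.interval(),
                    caller="pairedread",
                    pe_support=pe,
                    copy_number=cn,
                )
            )
    truth = TruthSet(
        seed=seed,
        sv_events=[asdict(ev) for ev in events],
    )
    return truth, [
        CallerOutput(sample_id, "coverage", coverage),
        CallerOutput(sample_id, "pairedread", pairedread),
    ]


def simulate_probe_series(
    model: GenomeModel,
    events: Sequence[SvEvent],
    spacing: int = 18_000,
    noise_sd: float = 0.15,
    seed: int = 0,
) -> ProbeSeries:
    """Array-style probe log2 ratios: Gaussian noise around 0 outside the
    planted events and around log2(CN/2) inside (copy 0 floored at -3)."""
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    rng = np.random.default_rng(seed)
    probes: List[Tuple[str, int, float]] = []
    for chrom in sorted(model.contigs, key=str):
        length = model.contigs[chrom]
        c = normalize_chrom(chrom)
        for k in range(1, length // spacing + 1):
            pos = k * spacing
            level = 0.0
            for ev in events:
                if (
                    normalize_chrom(ev.chrom) == c
                    and ev.start <= pos < ev.end
                ):
                    cn = ev.copy_number
                    if cn is None:
                        cn = {"DEL": 1, "DUP": 3}.get(ev.sv_type, 2)
                    level = -3.0 if cn == 0 else float(np.log2(cn / 2.0))
                    break
            noise = float(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 0.0
            probes.append((c, pos, level + noise))
    return ProbeSeries(probes)


# ---------------------------------------------------------------------------
# SNP sites / trios


@dataclass
class UpdSpec:
    start: int
    end: int
    kind: str = "isodisomy"  # isodisomy | heterodisomy
    parent: str = "maternal"


def simulate_snp_sites(
    chrom_len: int,
    het_rate: float = 1.0 / 1500,
    hom_rate: float = 1.0 / 2000,
    upd: Optional[UpdSpec] = None,
    error_rate: float = 0.001,
    seed: int = 0,
) -> Tuple[List[SnpSite], TruthSet]:
    """Poisson-placed child SNV sites along one chromosome.

    Outside any planted isodisomy segment a site is heterozygous with
    probability het_rate/(het_rate+hom_rate); inside, the heterozygous
    probability drops to error_rate (genotyping noise).
    """
    rng = np.random.default_rng(seed)
    total = het_rate + hom_rate
    n = rng.poisson(total * chrom_len)
    positions = np.sort(rng.integers(0, chrom_len, size=n))
    p_het = het_rate / total
    sites: List[SnpSite] = []
    iso = upd is not None and upd.kind == "isodisomy"
    for pos in positions:
        inside = upd is not None and upd.start <= pos < upd.end
        if inside and iso:
            het = rng.random() < error_rate
        else:
            het = rng.random() < p_het
        geno = "het" if het else ("hom_alt" if rng.random() < 0.5 else "hom_ref")
        sites.append(SnpSite(int(pos), geno))
    truth = TruthSet(
        seed=seed,
        upd_segments=[asdict(upd)] if upd is not None else [],
    )
    return sites, truth


def simulate_trio_sites(
    chrom_len: int,
    site_rate: float = 1.0 / 1000,
    upd: Optional[UpdSpec] = None,
    seed: int = 0,
) -> Tuple[List[TrioSite], TruthSet]:
    """Trio genotypes at biallelic sites (alleles 'A'/'B', freq 0.5).

    Inside a planted segment the child's genotype follows the UPD kind:
    isodisomy duplicates one allele of the named parent, heterodisomy
    transmits both of that parent's alleles.
    """
    rng = np.random.default_rng(seed)
    n = rng.poisson(site_rate * chrom_len)
    positions = np.sort(rng.integers(0, chrom_len, size=n))
    alleles = np.array(["A", "B"])
    sites: List[TrioSite] = []
    for pos in positions:
        mother = tuple(alleles[rng.integers(0, 2, size=2)])
        father = tuple(alleles[rng.integers(0, 2, size=2)])
        inside = upd is not None and upd.start <= pos < upd.end
        if inside:
            src = mother if upd.parent == "maternal" else father
            if upd.kind == "isodisomy":
                a = src[rng.integers(0, 2)]
                child = (a, a)
            else:  # heterodisomy: both homologs of one parent
                child = (src[0], src[1])
        else:
            child = (
                mother[rng.integers(0, 2)],
                father[rng.integers(0, 2)],
            )
        sites.append(TrioSite(int(pos), child, mother, father))
    truth = TruthSet(seed=seed, upd_segments=[asdict(upd)] if upd else [])
    return sites, truth


# ---------------------------------------------------------------------------
# STR reads


_BASES = np.array(list("ACGT"))


def _random_flank(rng: np.random.Generator, length: int, avoid_end: str,
                  avoid_start: str) -> str:
    seq = "".join(rng.choice(_BASES, size=length))
    # guard bases so the flank never extends the repeat tract
    if avoid_end and seq[-1] == avoid_end:
        repl = next(b for b in "ACGT" if b != avoid_end)
        seq = seq[:-1] + repl
    if avoid_start and seq[0] == avoid_start:
        repl = next(b for b in "ACGT" if b != avoid_start)
        seq = repl + seq[1:]
    return seq


def simulate_str_reads(
    locus: RepeatLocus,
    alleles: Tuple[int, int],
    depth: float = 30.0,
    read_len: int = 151,
    flank_len: int = 1000,
    seed: int = 0,
) -> Tuple[List[StrRead], str, str, TruthSet]:
    """Error-free reads over a repeat locus for a diploid sample.

    Each allele is sequenced at depth/2; read starts are uniform over its
    haplotype (flank + motif*units + flank).  Returns (reads, flank_a,
    flank_b, truth); spanning/flanking/in-repeat classes arise naturally
    from the geometry.
    """
    if flank_len < read_len:
        raise ValueError("flank_len must be >= read_len")
    rng = np.random.default_rng(seed)
    motif = locus.motif
    flank_a = _random_flank(rng, flank_len, avoid_end=motif[-1], avoid_start="")
    flank_b = _random_flank(rng, flank_len, avoid_end="", avoid_start=motif[0])
    reads: List[StrRead] = []
    for units in alleles:
        hap = flank_a + motif * units + flank_b
        n_starts = len(hap) - read_len + 1
        n_reads = int(round((depth / 2.0) * n_starts / read_len))
        starts = rng.integers(0, n_starts, size=n_reads)
        for s in starts:
            reads.append(StrRead(hap[s : s + read_len]))
    truth = TruthSet(
        seed=seed,
        str_alleles=[
            {"gene": locus.gene, "allele_short": min(alleles),
             "allele_long": max(alleles)}
        ],
    )
    return reads, flank_a, flank_b, truth


# ---------------------------------------------------------------------------
# Junction fixtures


def synthesize_junction(
    mh: int = 0,
    ins: str = "",
    seed: int = 0,
    flank_len: int = 200,
    arm_len: int = 40,
) -> Dict[str, str]:
    """Build (ref_a, ref_b, junction_seq) with planted microhomology or
    insertion, guarded so the planted values are recovered exactly.

    The junction is P + M + S (microhomology M of length mh shared by both
    references) or P + ins + S; guard bases prevent accidental match
    extension past the planted breakpoints.  Microhomology and insertion
    are mutually exclusive.
    """
    if mh and ins:
        raise ValueError("microhomology and insertion are mutually exclusive")
    rng = np.random.default_rng(seed)

    def rand(n: int) -> str:
        return "".join(rng.choice(_BASES, size=n)) if n > 0 else ""

    def other(base: str) -> str:
        return next(b for b in "ACGT" if b != base)

    P, S = rand(arm_len), rand(arm_len)
    M = rand(mh)
    mid = M if mh else ins
    junction = P + mid + S
    # A continues past its breakpoint with X, B is preceded by Y
    first_after_a = mid[0] if ins else S[0]
    last_before_b = mid[-1] if ins else P[-1]
    X = rand(flank_len - arm_len - mh)
    X = other(first_after_a) + X[1:] if X else X
    Y = rand(flank_len - arm_len - mh)
    Y = Y[:-1] + other(last_before_b) if Y else Y
    ref_a = P + M + X
    ref_b = Y + M + S
    return {
        "ref_a": ref_a,
        "ref_b": ref_b,
        "junction_seq": junction,
        "inserted_seq": ins,
        "microhomology_len": mh,
    }


# ---------------------------------------------------------------------------
# Depth bins


def simulate_depth_bins(
    contig_lengths: Dict[str, int],
    aneuploidy: Optional[Dict[str, float]] = None,
    depth: float = 30.0,
    bin_bp: int = 1000,
    seed: int = 0,
) -> Tuple[DepthBins, TruthSet]:
    """Poisson per-bin read-base counts; an affected chromosome carries
    dosage 1 + f/2 for a planted mosaic gain fraction f."""
    aneuploidy = aneuploidy or {}
    rng = np.random.default_rng(seed)
    bins: List[Tuple[str, int, float]] = []
    lam0 = depth * bin_bp
    for chrom in contig_lengths:
        c = normalize_chrom(chrom)
        n = contig_lengths[chrom] // bin_bp
        dosage = 1.0 + aneuploidy.get(c, 0.0) / 2.0
        counts = rng.poisson(lam0 * dosage, size=n)
        starts = np.arange(n) * bin_bp
        bins.extend(zip([c] * n, starts.tolist(), counts.astype(float).tolist()))
    truth = TruthSet(
        seed=seed,
        mosaic_fractions=[
            {"chrom": c, "fraction": f} for c, f in aneuploidy.items()
        ],
    )
    return DepthBins(bins, bin_bp), truth


# ---------------------------------------------------------------------------
# Cohorts (frequency-database construction)


@dataclass
class CohortEvent:
    event: SvEvent
    carrier_fraction: float  # fraction of cohort samples carrying it
    label: str = ""


def simulate_sv_cohort(
    model: GenomeModel,
    cohort_events: Sequence[CohortEvent],
    n_samples: int,
    seed: int = 0,
    depth: int = 30,
) -> Tuple[List[CallerOutput], Dict[str, List[str]]]:
    """Per-sample paired-read call sets with planted common/private events.

    Returns one CallerOutput per sample plus {event label: carrier sample
    ids} as truth.  Carrier counts are exact: round(fraction * n_samples)
    samples drawn without replacement.
    """
    rng = np.random.default_rng(seed)
    sample_ids = [f"S{i:03d}" for i in range(n_samples)]
    carriers: Dict[str, List[str]] = {}
    per_sample: Dict[str, List[SvRecord]] = {s: [] for s in sample_ids}
    for k, ce in enumerate(cohort_events):
        label = ce.label or f"event{k}"
        n_carriers = int(round(ce.carrier_fraction * n_samples))
        chosen = sorted(
            rng.choice(n_samples, size=n_carriers, replace=False).tolist()
        )
        carriers[label] = [sample_ids[i] for i in chosen]
        for i in chosen:
            ev = ce.event
            per_sample[sample_ids[i]].append(
                SvRecord(
                    id=f"{sample_ids[i]}_{label}",
                    sv_type=ev.sv_type,
                    interval=ev.interval(),
                    caller="pairedread",
                    pe_support=int(rng.binomial(depth, 0.5)),
                )
            )
    outputs = [
        CallerOutput(s, "pairedread", per_sample[s]) for s in sample_ids
    ]
    return outputs, carriers
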