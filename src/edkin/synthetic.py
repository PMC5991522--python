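"""Synthetic fractionation RNA-seq with planted editing ground truth.

This module builds a toy reference (genome, gene models, repeats, SNPs),
plants A-to-I editing sites with known per-fraction editing ratios and a
known kinetic group, and simulates per-fraction read sets whose splicing
completeness increases along the maturation order of the four subcellular
fractions (ChA-, ChA+, NpA+, CpA+).  Every downstream stage of the package
can therefore be scored against exact ground truth.

Coordinates are 1-based inclusive throughout the package; BED output is
converted to 0-based half-open on write.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# constants & small utilities
# ---------------------------------------------------------------------------

#: Maturation-ordered fraction names: chromatin-associated poly(A)-,
#: chromatin-associated poly(A)+, nucleoplasmic poly(A)+, cytoplasmic poly(A)+.
CHA_MINUS = "ChA-"
CHA_PLUS = "ChA+"
NPA_PLUS = "NpA+"
CPA_PLUS = "CpA+"
FRACTION_ORDER = (CHA_MINUS, CHA_PLUS, NPA_PLUS, CPA_PLUS)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Transcript:
    """A gene model: ordered exons on one strand of one chromosome.

    ``exons`` are 1-based inclusive intervals in ascending genomic order
    (for minus-strand transcripts the transcript runs right to left).
    ``cds`` is the genomic span of the coding region, or ``None`` for a
    noncoding transcript.
    """

    id: str
    chromosome: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[int, int] | None = None

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if len(self.exons) < 1:
            raise ValueError("transcript needs >=1 exon")
        ex = list(self.exons)
        if ex != sorted(ex) or any(e < s for s, e in ex):
            raise ValueError("exons must be ascending, start<=end")
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            gap = s2 - e1 - 1
            if gap < 30:
                raise ValueError(
                    f"intron of {gap} nt in {self.id}: introns must be >=30 nt"
                )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Genomic intervals of the introns (ascending)."""
        return [
            (e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        ]

    @property
    def mature_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    def exon_rank(self, i: int) -> int:
        """Transcript-order index of genomic exon ``i`` (0-based)."""
        return i if self.strand == "+" else len(self.exons) - 1 - i


@dataclass(frozen=True)
class RepeatInterval:
    chromosome: str
    start: int
    end: int
    repeat_class: str  # e.g. "Alu", "L1"


@dataclass(frozen=True)
class InvertedRepeat:
    """A planted pair of reverse-complementary arms flanking an exon."""

    chromosome: str
    arm1: tuple[int, int]
    arm2: tuple[int, int]
    identity: float
    transcript_id: str
    exon: tuple[int, int]


@dataclass
class ReferenceBundle:
    """Toy reference: sequences, gene models and optional annotations."""

    chromosomes: dict[str, str]
    gene_models: list[Transcript]
    repeats: list[RepeatInterval] = field(default_factory=list)
    snps: list[tuple[str, int]] = field(default_factory=list)
    inverted_repeats: list[InvertedRepeat] = field(default_factory=list)
    exon_duplexes: list[InvertedRepeat] = field(default_factory=list)

    def validate(self) -> None:
        for seq in self.chromosomes.values():
            if set(seq) - set("ACGT"):
                raise ValueError("chromosome sequences must be A/C/G/T only")
        for t in self.gene_models:
            if t.chromosome not in self.chromosomes:
                raise ValueError(f"{t.id}: unknown chromosome {t.chromosome}")
            if t.end > len(self.chromosomes[t.chromosome]) or t.start < 1:
                raise ValueError(f"{t.id} exceeds chromosome bounds")

    def base(self, chromosome: str, pos: int) -> str:
        """Reference base (forward strand) at a 1-based position."""
        return self.chromosomes[chromosome][pos - 1]

    def transcripts_at(self, chromosome: str, pos: int) -> list[Transcript]:
        return [
            t
            for t in self.gene_models
            if t.chromosome == chromosome and t.start <= pos <= t.end
        ]


@dataclass(frozen=True)
class FractionProfile:
    """One subcellular fraction along the maturation order.

    ``splicing_completeness`` is the probability that a read over an
    intron-containing region derives from a fully spliced molecule; it is
    non-decreasing along ``order_index`` in the default configuration,
    mirroring the intronic-read gradient across ChA-, ChA+, NpA+, CpA+.
    """

    name: str
    order_index: int
    splicing_completeness: float
    depth: float = 50.0
    polya: bool = True

    def __post_init__(self):
        if not 0.0 <= self.splicing_completeness <= 1.0:
            raise ValueError("splicing_completeness must be in [0,1]")


def default_fractions(depth: float = 50.0) -> list[FractionProfile]:
    """The four study fractions with their default splicing completeness."""
    sc = {CHA_MINUS: 0.3, CHA_PLUS: 0.6, NPA_PLUS: 0.97, CPA_PLUS: 1.0}
    return [
        FractionProfile(
            name=n,
            order_index=i,
            splicing_completeness=sc[n],
            depth=depth,
            polya=(n != CHA_MINUS),
        )
        for i, n in enumerate(FRACTION_ORDER)
    ]


@dataclass(frozen=True)
class KineticTruth:
    """A planted editing site with its intended kinetic group.

    The editing ratio is zero in every fraction preceding the group's first
    edited fraction and strictly positive at and after it: group g sites are
    first edited in fraction g of the maturation order.
    """

    chromosome: str
    position: int
    strand: str
    intended_group: int
    er: tuple[float, ...]  # per fraction, maturation order

    def __post_init__(self):
        g = self.intended_group
        if not 1 <= g <= len(self.er):
            raise ValueError(f"group {g} outside fraction range")
        for i, er in enumerate(self.er):
            if not 0.0 <= er <= 1.0:
                raise ValueError("editing ratios must be in [0,1]")
            if i < g - 1 and er > 0:
                raise ValueError(
                    f"group {g} site has ER>0 in fraction index {i} "
                    "(before first edited fraction)"
                )
            if i >= g - 1 and er == 0:
                raise ValueError(
                    f"group {g} site has ER=0 in fraction index {i} "
                    "(at/after first edited fraction)"
                )


@dataclass(frozen=True)
class AlignedRead:
    """A SAM-style alignment record kept in memory.

    ``blocks`` are 1-based inclusive reference intervals (gaps between
    consecutive blocks are splice junctions); ``sequence`` is stored in
    reference-forward orientation, as in SAM.  Unaligned reads (the
    hyperediting pool) have empty ``blocks``.
    """

    id: str
    chromosome: str
    strand: str
    blocks: tuple[tuple[int, int], ...]
    sequence: str
    fraction: str
    mate_id: str | None = None

    def __post_init__(self):
        if self.blocks:
            if sum(e - s + 1 for s, e in self.blocks) != len(self.sequence):
                raise ValueError("block lengths must sum to sequence length")
            for (s1, e1), (s2, e2) in zip(self.blocks, self.blocks[1:]):
                if s2 <= e1:
                    raise ValueError("blocks must be non-overlapping, increasing")

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    def junction_gaps(self) -> list[tuple[int, int]]:
        """Intron intervals spliced out by this read."""
        return [
            (e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(self.blocks, self.blocks[1:])
        ]


@dataclass
class FractionReads:
    """Simulated reads for one fraction: aligned plus the unalignable
    hyperedited pool (which downstream rescue re-aligns)."""

    profile: FractionProfile
    mapped: list[AlignedRead]
    unmapped: list[AlignedRead]
    hyper_truth: list[AlignedRead] = field(default_factory=list)


# ---------------------------------------------------------------------------
# reference generation
# ---------------------------------------------------------------------------


@dataclass
class GenomeConfig:
    """Knobs for :func:`generate_reference`.

    The defaults give a compact genome that still exercises every feature
    the pipeline tests: multi-exon genes on both strands, a noncoding
    transcript, repeats, SNPs, a planted inverted repeat flanking a
    designated exon (dsRNA substrate) and a reverse-complement copy of an
    exon segment in its downstream intron (exon-intron duplex substrate).
    """

    seed: int = 0
    chrom_lengths: dict[str, int] = field(default_factory=lambda: {"chr1": 50_000})
    n_transcripts: int = 8
    exons_per_transcript: tuple[int, int] = (3, 5)
    exon_length: tuple[int, int] = (90, 180)
    intron_length: tuple[int, int] = (200, 700)
    intron_min: int = 30
    noncoding_fraction: float = 0.2
    minus_fraction: float = 0.3
    n_snps: int = 10
    n_random_repeats: int = 4
    plant_inverted_repeat: bool = True
    ir_arm_length: int = 60
    ir_identity: float = 0.85
    plant_exon_duplex: bool = True
    exon_duplex_length: int = 80
    exon_duplex_identity: float = 0.90


def _best_segment(length: int, mismatches: set[int],
                  match: int = 1, mismatch: int = -2) -> tuple[int, int]:
    """Length and identity-count of the maximal-scoring ungapped segment
    for a given mismatch-position set (Kadane over per-base scores)."""
    best = cur = 0
    best_span = (0, 0)
    start = 0
    for i in range(length):
        s = mismatch if i in mismatches else match
        if cur <= 0:
            cur, start = 0, i
        cur += s
        if cur > best:
            best = cur
            best_span = (start, i + 1)
    seg_len = best_span[1] - best_span[0]
    seg_matches = seg_len - sum(1 for i in mismatches
                                if best_span[0] <= i < best_span[1])
    return seg_len, seg_matches


def _mutate_fraction(seq: str, identity: float, rng: np.random.Generator,
                     protect_ends: int = 4, min_seed_run: int = 12) -> str:
    """Substitute bases so that ``seq`` keeps about ``identity`` identity.

    The mutation-position set is resampled until the planted homology is
    a well-formed single hit for a word-seeded +1/-2 local aligner: its
    maximal-scoring segment keeps >=80% of the arm length at >=80%
    identity and an exact run of at least ``min_seed_run`` bases remains
    for seeding.  This makes the planted identity claim hold under
    alignment, not just base-by-base.
    """
    n = len(seq)
    n_mut = int(round((1.0 - identity) * n))
    eligible = np.arange(protect_ends, n - protect_ends)
    for _ in range(500):
        chosen = set(int(p) for p in rng.choice(eligible, size=n_mut,
                                                replace=False))
        gaps = np.diff(sorted({-1, *chosen, n}))
        if (gaps.max() - 1) < min_seed_run:
            continue
        seg_len, seg_matches = _best_segment(n, chosen)
        if seg_len >= min(n, max(50, round(0.8 * n))) \
                and seg_matches >= 0.8 * seg_len:
            break
    else:
        raise ValueError("could not place mutations for the requested arm")
    out = list(seq)
    for p in chosen:
        out[p] = rng.choice([b for b in BASES if b != out[p]])
    return "".join(out)


def generate_reference(config: GenomeConfig) -> ReferenceBundle:
    """Build a deterministic toy reference from ``config``.

    Raises ``ValueError`` if the configuration asks for introns shorter
    than 30 nt (the 23-mer acceptor window plus donor window must fit).
    """
    if config.intron_min < 30 or config.intron_length[0] < 30:
        raise ValueError("introns must be >=30 nt so acceptor windows fit")
    rng = np.random.default_rng(config.seed)

    chromosomes: dict[str, list[str]] = {
        name: list(rng.choice(list(BASES), size=length))
        for name, length in config.chrom_lengths.items()
    }

    transcripts: list[Transcript] = []
    chrom_names = list(chromosomes)
    cursor = {name: 500 for name in chrom_names}
    tid = 0
    while tid < config.n_transcripts:
        chrom = chrom_names[tid % len(chrom_names)]
        seq = chromosomes[chrom]
        n_ex = int(rng.integers(*config.exons_per_transcript, endpoint=True))
        ex_lens = rng.integers(*config.exon_length, endpoint=True, size=n_ex)
        in_lens = rng.integers(*config.intron_length, endpoint=True, size=n_ex - 1)
        span = int(ex_lens.sum() + in_lens.sum())
        start = cursor[chrom] + int(rng.integers(100, 400))
        if start + span + 2500 > len(seq):
            tid += 1  # chromosome full; skip slot
            continue
        exons = []
        pos = start
        for i, el in enumerate(ex_lens):
            exons.append((pos, pos + int(el) - 1))
            if i < n_ex - 1:
                pos += int(el) + int(in_lens[i])
            else:
                pos += int(el)
        strand = "-" if rng.random() < config.minus_fraction else "+"
        coding = rng.random() >= config.noncoding_fraction
        cds = None
        if coding and n_ex >= 1:
            cds = (
                exons[0][0] + (exons[0][1] - exons[0][0]) // 2,
                exons[-1][0] + (exons[-1][1] - exons[-1][0]) // 2,
            )
        t = Transcript(
            id=f"t{tid:03d}", chromosome=chrom, strand=strand,
            exons=tuple(exons), cds=cds,
        )
        transcripts.append(t)
        cursor[chrom] = t.end + 200
        tid += 1
        # stamp canonical splice dinucleotides on the transcript strand
        for (istart, iend) in t.introns:
            if strand == "+":
                seq[istart - 1:istart + 1] = ["G", "T"]
                seq[iend - 2:iend] = ["A", "G"]
            else:
                seq[iend - 2:iend] = ["A", "C"]  # revcomp(GT)
                seq[istart - 1:istart + 1] = ["C", "T"]  # revcomp(AG)
    if not any(len(t.exons) > 1 for t in transcripts):
        raise ValueError("configuration produced no multi-exon transcript")

    # guarantee one acceptor whose -2 A sits in an ...AAG context: make the
    # last three intronic bases of one plus-strand intron read AAG
    for t in transcripts:
        if t.strand == "+" and t.introns:
            istart, iend = t.introns[0]
            chromosomes[t.chromosome][iend - 3] = "A"
            break

    repeats: list[RepeatInterval] = []
    inverted: list[InvertedRepeat] = []
    exon_dups: list[InvertedRepeat] = []

    def plant_pair(donor_seq: str, chrom: str, target_start: int, identity: float,
                   note: tuple) -> InvertedRepeat:
        arm = _mutate_fraction(revcomp(donor_seq), identity, rng)
        seq = chromosomes[chrom]
        seq[target_start - 1:target_start - 1 + len(arm)] = list(arm)
        t_id, exon, src = note
        return InvertedRepeat(
            chromosome=chrom, arm1=src,
            arm2=(target_start, target_start + len(arm) - 1),
            identity=identity, transcript_id=t_id, exon=exon,
        )

    multi = [t for t in transcripts if len(t.exons) >= 3]
    if config.plant_inverted_repeat and multi:
        t = multi[0]
        exon_i = 1  # internal exon, genomic order
        up_intron = t.introns[exon_i - 1]
        dn_intron = t.introns[exon_i]
        L = config.ir_arm_length
        # arm1 in the upstream intron, clear of splice windows
        a1s = up_intron[0] + 25
        if a1s + L - 1 > up_intron[1] - 25:
            raise ValueError("introns too short for the requested repeat arm")
        arm1 = (a1s, a1s + L - 1)
        a2s = dn_intron[0] + 25
        src_seq = "".join(chromosomes[t.chromosome][arm1[0] - 1:arm1[1]])
        ir = plant_pair(src_seq, t.chromosome, a2s, config.ir_identity,
                        (t.id, t.exons[exon_i], arm1))
        inverted.append(ir)
        repeats.append(RepeatInterval(t.chromosome, *ir.arm1, "Alu"))
        repeats.append(RepeatInterval(t.chromosome, *ir.arm2, "Alu"))
    if config.plant_exon_duplex and len(multi) >= 1:
        t = multi[-1]
        exon_i = 1
        es, ee = t.exons[exon_i]
        L = min(config.exon_duplex_length, ee - es + 1)
        dn_intron = t.introns[exon_i]
        tgt = dn_intron[0] + max(30, (dn_intron[1] - dn_intron[0]) // 3)
        if tgt + L - 1 > dn_intron[1] - 25:
            tgt = dn_intron[0] + 30
        src_seq = "".join(chromosomes[t.chromosome][es - 1:es + L - 1])
        dup = plant_pair(src_seq, t.chromosome, tgt, config.exon_duplex_identity,
                         (t.id, t.exons[exon_i], (es, es + L - 1)))
        exon_dups.append(dup)
        repeats.append(RepeatInterval(t.chromosome, *dup.arm2, "Alu"))

    for _ in range(config.n_random_repeats):
        chrom = chrom_names[int(rng.integers(len(chrom_names)))]
        s = int(rng.integers(1, len(chromosomes[chrom]) - 400))
        repeats.append(RepeatInterval(chrom, s, s + 300, "L1"))

    snps = []
    for _ in range(config.n_snps):
        chrom = chrom_names[int(rng.integers(len(chrom_names)))]
        snps.append((chrom, int(rng.integers(1, len(chromosomes[chrom])))))

    bundle = ReferenceBundle(
        chromosomes={k: "".join(v) for k, v in chromosomes.items()},
        gene_models=transcripts,
        repeats=repeats,
        snps=sorted(set(snps)),
        inverted_repeats=inverted,
        exon_duplexes=exon_dups,
    )
    bundle.validate()
    return bundle


# ---------------------------------------------------------------------------
# planting editing truth
# ---------------------------------------------------------------------------


@dataclass
class TruthSpec:
    """How many sites to plant per kinetic group, and the ER range used at
    and after each site's first edited fraction."""

    counts: dict[int, int] = field(
        default_factory=lambda: {1: 120, 2: 40, 3: 25, 4: 15}
    )
    er_range: tuple[float, float] = (0.2, 0.6)
    n_fractions: int = 4
    n_acceptor_edits: int = 0
    junction_margin: int = 6  # keep ordinary sites clear of splice junctions
    in_inverted_repeat: int = 0  # sites forced inside a planted repeat arm
    #: restrict ordinary sites to exons so that poly(A)+ fractions, whose
    #: reads are mostly spliced, still cover them (intronic sites vanish
    #: from mature RNA together with their introns)
    exonic_only: bool = True


def _is_homopolymer(seq: str, pos0: int, run: int = 5) -> bool:
    base = seq[pos0]
    left = pos0
    while left > 0 and seq[left - 1] == base:
        left -= 1
    right = pos0
    while right < len(seq) - 1 and seq[right + 1] == base:
        right += 1
    return right - left + 1 >= run


def _er_profile(group: int, n: int, er_range: tuple[float, float],
                rng: np.random.Generator) -> tuple[float, ...]:
    lo, hi = er_range
    # quantized to 1e-6 so the truth table round-trips exactly through TSV
    vals = np.sort(np.round(rng.uniform(lo, hi, size=n - group + 1), 6))
    vals = np.maximum(vals, 1e-6)
    return tuple([0.0] * (group - 1) + [float(v) for v in vals])


def plant_editing_truth(
    bundle: ReferenceBundle, spec: TruthSpec, seed: int
) -> list[KineticTruth]:
    """Choose editable A positions and assign each a kinetic group and a
    per-fraction editing-ratio profile.

    Sites are placed on transcript-strand adenosines (reference A on plus
    strand, reference T on minus strand), avoiding SNPs, homopolymer runs
    and splice-junction margins so that the caller's filters do not
    interfere with kinetic-group recovery.  Raises ``ValueError`` when more
    sites are requested than editable positions exist.
    """
    rng = np.random.default_rng(seed)
    taken: set[tuple[str, int]] = set(bundle.snps)
    snpset = set(bundle.snps)
    # keep ordinary sites out of planted-repeat neighbourhoods: simulated
    # hyperediting clusters there and would overwrite their ER profiles
    hyper_zone: set[tuple[str, int]] = set()
    for ir in bundle.inverted_repeats:
        for arm in (ir.arm1, ir.arm2):
            hyper_zone.update(
                (ir.chromosome, p)
                for p in range(arm[0] - 160, arm[1] + 161)
            )

    def eligible_positions(t: Transcript) -> list[int]:
        seq = bundle.chromosomes[t.chromosome]
        want = "A" if t.strand == "+" else "T"
        margins = set()
        for (istart, iend) in t.introns:
            for b in (istart, iend + 1):  # boundary between b-1 and b
                margins.update(range(b - spec.junction_margin, b + spec.junction_margin))
        if spec.exonic_only:
            # prefer internal exons: terminal exons sit in the coverage ramp
            # at transcript ends where depth is below its plateau value
            exons = t.exons[1:-1] if len(t.exons) >= 3 else t.exons
            ranges = [range(s, e + 1) for s, e in exons]
        else:
            ranges = [range(t.start, t.end + 1)]
        out = []
        for rg in ranges:
            for p in rg:
                if seq[p - 1] != want or p in margins:
                    continue
                if (t.chromosome, p) in snpset or _is_homopolymer(seq, p - 1):
                    continue
                if (t.chromosome, p) in hyper_zone:
                    continue
                out.append(p)
        return out

    pools: list[tuple[Transcript, list[int]]] = []
    for t in bundle.gene_models:
        pos = eligible_positions(t)
        if pos:
            pools.append((t, pos))
    if not pools:
        raise ValueError("no editable A positions in the bundle")

    flat = [(t, p) for t, ps in pools for p in ps]
    order = rng.permutation(len(flat))
    truths: list[KineticTruth] = []
    idx = 0

    def next_position() -> tuple[Transcript, int]:
        nonlocal idx
        while idx < len(order):
            t, p = flat[order[idx]]
            idx += 1
            if (t.chromosome, p) not in taken:
                taken.add((t.chromosome, p))
                return t, p
        raise ValueError("more sites requested than available A positions")

    # sites forced into a planted inverted-repeat arm (dsRNA-positive truth)
    if spec.in_inverted_repeat:
        if not bundle.inverted_repeats:
            raise ValueError("no inverted repeat planted in this bundle")
        ir = bundle.inverted_repeats[0]
        t = next(t for t in bundle.gene_models if t.id == ir.transcript_id)
        want = "A" if t.strand == "+" else "T"
        seq = bundle.chromosomes[ir.chromosome]
        arm_pos = [
            p for p in range(ir.arm1[0], ir.arm1[1] + 1)
            if seq[p - 1] == want and (ir.chromosome, p) not in taken
        ]
        if len(arm_pos) < spec.in_inverted_repeat:
            raise ValueError("repeat arm has too few A positions")
        for p in arm_pos[: spec.in_inverted_repeat]:
            taken.add((ir.chromosome, p))
            truths.append(
                KineticTruth(ir.chromosome, p, t.strand, 1,
                             _er_profile(1, spec.n_fractions, spec.er_range, rng))
            )

    for group, count in sorted(spec.counts.items()):
        if not 1 <= group <= spec.n_fractions:
            raise ValueError(f"group {group} outside 1..{spec.n_fractions}")
        for _ in range(count):
            t, p = next_position()
            truths.append(
                KineticTruth(
                    t.chromosome, p, t.strand, group,
                    _er_profile(group, spec.n_fractions, spec.er_range, rng),
                )
            )

    # acceptor -2 edits: the A of the intron-terminal AG, group 1
    planted_acc = 0
    for t in bundle.gene_models:
        if planted_acc >= spec.n_acceptor_edits:
            break
        for (istart, iend) in t.introns:
            if planted_acc >= spec.n_acceptor_edits:
                break
            pos = iend - 1 if t.strand == "+" else istart + 1
            if (t.chromosome, pos) in taken:
                continue
            taken.add((t.chromosome, pos))
            truths.append(
                KineticTruth(
                    t.chromosome, pos, t.strand, 1,
                    _er_profile(1, spec.n_fractions, spec.er_range, rng),
                )
            )
            planted_acc += 1
    if planted_acc < spec.n_acceptor_edits:
        raise ValueError("not enough acceptors for requested acceptor edits")
    return truths


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


def _mature_blocks(t: Transcript, m_start: int, length: int) -> tuple:
    """Genomic blocks of a read covering mature coordinates
    [m_start, m_start+length) of a spliced transcript (genomic order)."""
    blocks = []
    remaining = length
    offset = m_start
    for (s, e) in t.exons:
        el = e - s + 1
        if offset >= el:
            offset -= el
            continue
        take = min(el - offset, remaining)
        blocks.append((s + offset, s + offset + take - 1))
        remaining -= take
        offset = 0
        if remaining == 0:
            break
    return tuple(blocks)


def simulate_fraction_alignments(
    bundle: ReferenceBundle,
    truths: list[KineticTruth],
    profile: FractionProfile,
    read_len: int = 100,
    seed: int = 0,
    error_rate: float = 1e-3,
    hyper_fraction: float = 0.0,
    hyper_min_edits: int = 6,
    hyper_regions: list[tuple[str, int, int]] | None = None,
) -> FractionReads:
    """Simulate one fraction's read set.

    Each read derives from a fully spliced molecule with probability
    ``profile.splicing_completeness`` (mature-coordinate sampling, splice
    gaps in the alignment blocks) and otherwise from pre-mRNA (contiguous
    genomic sampling, so exon-intron boundary reads appear at rate
    1 - completeness).  At every planted site a covering read carries the
    edited G (transcript strand) with probability ER_f.

    A ``hyper_fraction`` of the read budget is emitted as hyperedited
    reads -- dense A-to-G conversion (at least ``hyper_min_edits``
    changes), unaligned, destined for the reduced-alphabet rescue.  Like
    real hyperediting, which clusters in dsRNA, these reads are confined
    to ``hyper_regions`` (default: the planted inverted-repeat arms, or
    the first transcript span when none exist) rather than scattered over
    every gene, so they do not perturb the editing ratios of ordinary
    planted sites elsewhere.
    """
    if profile.depth <= 0:
        raise ValueError("depth must be > 0")
    rng = np.random.default_rng(seed)
    er_index = profile.order_index
    truth_by_chrom: dict[str, dict[int, KineticTruth]] = {}
    for tr in truths:
        truth_by_chrom.setdefault(tr.chromosome, {})[tr.position] = tr

    mapped: list[AlignedRead] = []
    unmapped: list[AlignedRead] = []
    hyper_truth: list[AlignedRead] = []
    rid = 0

    sc = profile.splicing_completeness
    for t in bundle.gene_models:
        seq = bundle.chromosomes[t.chromosome]
        span_len = t.end - t.start + 1
        # per-base-balanced sampling: spliced molecules (abundance sc) are
        # read over mature coordinates, unspliced (1-sc) over the pre-mRNA
        # span, so exonic depth ~ depth and intronic depth ~ (1-sc)*depth,
        # and boundary-spanning reads appear at rate (1-sc) per junction
        n_spliced = int(np.ceil(profile.depth * sc * t.mature_length / read_len))
        n_unspliced = int(np.ceil(profile.depth * (1 - sc) * span_len / read_len))
        flags = [True] * n_spliced + [False] * n_unspliced
        truth_here = truth_by_chrom.get(t.chromosome, {})
        for spliced in flags:
            if spliced and t.mature_length > read_len:
                m_start = int(rng.integers(0, t.mature_length - read_len + 1))
                blocks = _mature_blocks(t, m_start, read_len)
            else:
                g_start = int(rng.integers(t.start, max(t.start, t.end - read_len + 1) + 1))
                blocks = ((g_start, min(g_start + read_len - 1, t.end)),)
            bases = []
            for (s, e) in blocks:
                bases.extend(seq[s - 1:e])
            # planted editing: flip transcript-strand A -> G
            offset = 0
            edited_g = "G" if t.strand == "+" else "C"
            for (s, e) in blocks:
                for p in range(s, e + 1):
                    tr = truth_here.get(p)
                    if tr is not None and tr.er[er_index] > 0:
                        if rng.random() < tr.er[er_index]:
                            bases[offset + p - s] = edited_g
                offset += e - s + 1
            if error_rate > 0:
                errs = np.flatnonzero(rng.random(len(bases)) < error_rate)
                for i in errs:
                    bases[i] = rng.choice([b for b in BASES if b != bases[i]])
            seq_out = "".join(bases)
            name = f"{profile.name}:{t.id}:{rid}"
            rid += 1
            mapped.append(
                AlignedRead(name, t.chromosome, t.strand, blocks, seq_out,
                            profile.name)
            )

    if hyper_fraction > 0:
        if hyper_regions is None:
            if bundle.inverted_repeats:
                hyper_regions = [
                    (ir.chromosome, max(1, arm[0] - 60), arm[1] + 60)
                    for ir in bundle.inverted_repeats
                    for arm in (ir.arm1, ir.arm2)
                ]
            else:
                t0 = bundle.gene_models[0]
                hyper_regions = [(t0.chromosome, t0.start, t0.end)]
        n_hyper = int(np.ceil(hyper_fraction * max(1, len(mapped))))
        for h in range(n_hyper):
            chrom, rs, re_ = hyper_regions[h % len(hyper_regions)]
            seq = bundle.chromosomes[chrom]
            hi = max(rs, min(re_, len(seq)) - read_len + 1)
            g_start = int(rng.integers(rs, hi + 1))
            g_end = min(g_start + read_len - 1, len(seq))
            host = bundle.transcripts_at(chrom, g_start)
            strand = host[0].strand if host else "+"
            a_base, g_base = ("A", "G") if strand == "+" else ("T", "C")
            bases = list(seq[g_start - 1:g_end])
            a_pos = [i for i, b in enumerate(bases) if b == a_base]
            if len(a_pos) < hyper_min_edits:
                continue  # A-poor stretch: no hyperedited read here
            n_edit = max(hyper_min_edits, int(round(0.8 * len(a_pos))))
            for i in rng.choice(a_pos, size=min(n_edit, len(a_pos)),
                                replace=False):
                bases[i] = g_base
            if error_rate > 0:
                errs = np.flatnonzero(rng.random(len(bases)) < error_rate)
                for i in errs:
                    bases[i] = rng.choice([b for b in BASES if b != bases[i]])
            seq_out = "".join(bases)
            name = f"{profile.name}:hyper:{rid}"
            rid += 1
            blocks = ((g_start, g_end),)
            hyper_truth.append(
                AlignedRead(name, chrom, strand, blocks, seq_out, profile.name)
            )
            unmapped.append(
                AlignedRead(name, chrom, strand, (), seq_out, profile.name)
            )
    return FractionReads(profile=profile, mapped=mapped, unmapped=unmapped,
                         hyper_truth=hyper_truth)


def simulate_bundle_reads(
    bundle: ReferenceBundle,
    truths: list[KineticTruth],
    profiles: list[FractionProfile] | None = None,
    read_len: int = 100,
    seed: int = 0,
    **kwargs,
) -> dict[str, FractionReads]:
    """Simulate every fraction, deriving one child seed per fraction."""
    profiles = profiles or default_fractions()
    out = {}
    for i, prof in enumerate(sorted(profiles, key=lambda p: p.order_index)):
        out[prof.name] = simulate_fraction_alignments(
            bundle, truths, prof, read_len=read_len,
            seed=(seed * 1009 + 17 * i) % (2**31 - 1), **kwargs,
        )
    return out


# ---------------------------------------------------------------------------
# concordance cohort (KD vs Ctrl splice events)
# ---------------------------------------------------------------------------


def simulate_concordance_cohort(
    n_events: int = 100,
    frac_positive: float = 0.9,
    effect: float = 0.15,
    base_psi: float = 0.6,
    depth: int = 200,
    seed: int = 0,
):
    """Simulate skipped-exon junction counts for a knockdown/control pair.

    A fraction ``frac_positive`` of events are built with PSI(KD) - PSI(Ctrl)
    = +``effect`` (the direction expected when an acceptor-disrupting edit is
    lost upon ADAR knockdown) and the rest with -``effect``.  Junction counts
    are binomial at the given read depth; PSI values are computed through the
    splicing module so the whole measurement path is exercised.

    Returns a list of :class:`edkin.splicing.SpliceEvent`.
    """
    from . import splicing  # deferred: splicing imports types from here

    rng = np.random.default_rng(seed)
    events = []
    for i in range(n_events):
        positive = rng.random() < frac_positive
        psi_ctrl = base_psi
        psi_kd = base_psi + (effect if positive else -effect)
        psi = {}
        for cond, p in (("Ctrl", psi_ctrl), ("KD", psi_kd)):
            incl = rng.binomial(depth, p)
            excl = depth - incl
            # inclusion events produce two junction reads (one per flank)
            psi[cond] = splicing.psi_se(2 * incl, excl)
        events.append(
            splicing.SpliceEvent(
                event_id=f"ev{i:04d}", transcript_id=f"t{i:04d}",
                exon=(1, 100), as_type="SE", psi=psi,
            )
        )
    return events


# ---------------------------------------------------------------------------
# on-disk round trip
# ---------------------------------------------------------------------------

GTF_SOURCE = "edkin"


def emit_bundle(
    bundle: ReferenceBundle,
    reads: dict[str, FractionReads],
    truths: list[KineticTruth],
    outdir: str,
) -> dict[str, str]:
    """Write the bundle as FASTA + GTF + BED + VCF + per-fraction SAM + TSV.

    Returns a map of artifact name -> path.  Raises ``FileNotFoundError``
    for a missing output directory.
    """
    import pysam

    if not os.path.isdir(outdir):
        raise FileNotFoundError(f"output directory does not exist: {outdir}")
    paths = {}

    fa = os.path.join(outdir, "genome.fa")
    with open(fa, "w") as fh:
        for name, seq in bundle.chromosomes.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
    paths["genome"] = fa

    gtf = os.path.join(outdir, "genes.gtf")
    with open(gtf, "w") as fh:
        for t in bundle.gene_models:
            attrs = f'gene_id "{t.id}"; transcript_id "{t.id}";'
            fh.write(
                f"{t.chromosome}\t{GTF_SOURCE}\ttranscript\t{t.start}\t{t.end}"
                f"\t.\t{t.strand}\t.\t{attrs}\n"
            )
            for (s, e) in t.exons:
                fh.write(
                    f"{t.chromosome}\t{GTF_SOURCE}\texon\t{s}\t{e}"
                    f"\t.\t{t.strand}\t.\t{attrs}\n"
                )
            if t.cds is not None:
                fh.write(
                    f"{t.chromosome}\t{GTF_SOURCE}\tCDS\t{t.cds[0]}\t{t.cds[1]}"
                    f"\t.\t{t.strand}\t.\t{attrs}\n"
                )
    paths["genes"] = gtf

    bed = os.path.join(outdir, "repeats.bed")
    with open(bed, "w") as fh:
        for r in bundle.repeats:
            fh.write(f"{r.chromosome}\t{r.start - 1}\t{r.end}\t{r.repeat_class}\t0\t+\n")
    paths["repeats"] = bed

    vcf = os.path.join(outdir, "snps.vcf")
    with open(vcf, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, seq in bundle.chromosomes.items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos in bundle.snps:
            ref = bundle.base(chrom, pos)
            alt = "G" if ref != "G" else "A"
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.\n")
    paths["snps"] = vcf

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [
            {"SN": name, "LN": len(seq)}
            for name, seq in bundle.chromosomes.items()
        ],
    }
    tids = {name: i for i, name in enumerate(bundle.chromosomes)}
    for frac, fr in reads.items():
        sam = os.path.join(outdir, f"{frac.replace('+', 'p').replace('-', 'm')}.sam")
        with pysam.AlignmentFile(sam, "w", header=header) as out:
            for r in fr.mapped + fr.unmapped:
                a = pysam.AlignedSegment(out.header)
                a.query_name = r.id
                a.query_sequence = r.sequence
                a.query_qualities = pysam.qualitystring_to_array("I" * len(r.sequence))
                if r.blocks:
                    a.reference_id = tids[r.chromosome]
                    a.reference_start = r.blocks[0][0] - 1
                    a.flag = 16 if r.strand == "-" else 0
                    cig = []
                    prev_end = None
                    for (s, e) in r.blocks:
                        if prev_end is not None:
                            cig.append((3, s - prev_end - 1))  # N
                        cig.append((0, e - s + 1))  # M
                        prev_end = e
                    a.cigartuples = cig
                else:
                    a.flag = 4
                    a.reference_id = -1
                    a.reference_start = -1
                a.set_tag("XF", r.fraction)
                out.write(a)
        paths[f"sam:{frac}"] = sam

    tsv = os.path.join(outdir, "truth.tsv")
    n_frac = len(truths[0].er) if truths else 4
    cols = [f"er_{i}" for i in range(n_frac)]
    rows = [
        dict(chromosome=tr.chromosome, position=tr.position, strand=tr.strand,
             group=tr.intended_group, **dict(zip(cols, tr.er)))
        for tr in truths
    ]
    pd.DataFrame(rows, columns=["chromosome", "position", "strand", "group"] + cols
                 ).to_csv(tsv, sep="\t", index=False, float_format="%.17g")
    paths["truth"] = tsv
    return paths


def read_genome(path: str) -> dict[str, str]:
    from pyfaidx import Fasta

    return {name: str(rec[:]).upper() for name, rec in Fasta(path).items()}


def read_gene_models(path: str) -> list[Transcript]:
    import pyranges as pr

    df = pr.read_gtf(path).df
    out = []
    for tid, grp in df.groupby("transcript_id", sort=True):
        ex = grp[grp.Feature == "exon"].sort_values("Start")
        cds = grp[grp.Feature == "CDS"]
        chrom = str(ex.Chromosome.iloc[0])
        strand = str(ex.Strand.iloc[0])
        exons = tuple((int(s) + 1, int(e)) for s, e in zip(ex.Start, ex.End))
        cds_iv = None
        if len(cds):
            cds_iv = (int(cds.Start.iloc[0]) + 1, int(cds.End.iloc[0]))
        out.append(Transcript(str(tid), chrom, strand, exons, cds_iv))
    return sorted(out, key=lambda t: t.id)


def read_repeats(path: str) -> list[RepeatInterval]:
    if os.path.getsize(path) == 0:
        return []
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name", "score", "strand"])
    return [
        RepeatInterval(str(r.chrom), int(r.start) + 1, int(r.end), str(r.name))
        for r in df.itertuples()
    ]


def read_snps(path: str) -> list[tuple[str, int]]:
    import pysam

    out = []
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            out.append((rec.chrom, rec.pos))
    return out


def read_alignments(path: str, fraction: str | None = None
                    ) -> tuple[list[AlignedRead], list[AlignedRead]]:
    """Read a SAM file back into (mapped, unmapped) AlignedRead lists."""
    import pysam

    mapped, unmapped = [], []
    with pysam.AlignmentFile(path, "r") as sam:
        for a in sam:
            frac = a.get_tag("XF") if a.has_tag("XF") else (fraction or "")
            if a.is_unmapped:
                unmapped.append(
                    AlignedRead(a.query_name, "", "+", (), a.query_sequence, frac)
                )
                continue
            blocks = []
            pos = a.reference_start + 1
            for op, ln in a.cigartuples:
                if op == 0:
                    blocks.append((pos, pos + ln - 1))
                    pos += ln
                elif op == 3:
                    pos += ln
                else:
                    raise ValueError(f"unsupported CIGAR op {op}")
            mapped.append(
                AlignedRead(
                    a.query_name, a.reference_name,
                    "-" if a.is_reverse else "+", tuple(blocks),
                    a.query_sequence, frac,
                )
            )
    return mapped, unmapped


def read_truth(path: str) -> list[KineticTruth]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    er_cols = [c for c in df.columns if c.startswith("er_")]
    return [
        KineticTruth(str(r.chromosome), int(r.position), str(r.strand),
                     int(r.group), tuple(float(getattr(r, c)) for c in er_cols))
        for r in df.itertuples()
    ]
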