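"""Per-fraction A-to-G editing-site calling from alignments.

The caller works from a strand-resolved pileup, applies the read-support
and coverage filters (>=2 edited-G reads, >=5 total reads), removes known
SNPs, homopolymer runs and splice-junction-proximal mismatches -- except
in the nascent chromatin fraction, where unspliced reads make
junction-proximal sites trustworthy -- and rescues hyperedited reads by
re-aligning them in a reduced A/G-collapsed alphabet.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synthetic import (
    AlignedRead,
    ReferenceBundle,
    Transcript,
    complement,
    revcomp,
)

_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


# ---------------------------------------------------------------------------
# pileup
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PileupEntry:
    """Base counts at one covered position, on the transcript strand."""

    chromosome: str
    position: int
    ref_base: str  # transcript-strand reference base
    strand: str
    counts: tuple[int, int, int, int]  # A, C, G, T on the transcript strand

    @property
    def coverage(self) -> int:
        return sum(self.counts)

    def count(self, base: str) -> int:
        return self.counts[_BASE_INDEX[base]]


@dataclass
class CallerParams:
    """Filter thresholds for editing-site detection.

    ``min_g``/``min_cov`` are the published support filters (two edited-G
    reads, five total).  ``junction_margin`` drops candidate sites within
    that many nt of an annotated splice junction except in the nascent
    fraction.  ``read_end_trim`` drops mismatching bases in the terminal
    nt of each read (a mapping-artifact guard); ``min_base_quality``
    applies only when quality strings are available (the simulator emits
    constant qualities, so it is a documented no-op on synthetic data).
    """

    min_g: int = 2
    min_cov: int = 5
    junction_margin: int = 4
    homopolymer_run: int = 5
    read_end_trim: int = 6
    min_base_quality: int = 25


def build_pileup(
    reads: list[AlignedRead],
    bundle: ReferenceBundle,
    read_end_trim: int = 6,
) -> dict[tuple[str, int], PileupEntry]:
    """Count bases per covered reference position.

    Splice gaps contribute no coverage.  Mismatching bases within
    ``read_end_trim`` nt of either read end are discarded (matches still
    count), suppressing alignment-edge artifacts.  Counts are reported on
    the strand of the annotated transcript overlapping the position
    (forward strand where no model overlaps).
    """
    counts: dict[str, np.ndarray] = {}
    for name, seq in bundle.chromosomes.items():
        counts[name] = np.zeros((len(seq) + 1, 4), dtype=np.int32)
    for r in reads:
        if r.chromosome not in counts:
            raise ValueError(f"read {r.id} maps to unknown chromosome {r.chromosome}")
        arr = counts[r.chromosome]
        ref = bundle.chromosomes[r.chromosome]
        rl = len(r.sequence)
        off = 0
        for (s, e) in r.blocks:
            for p in range(s, e + 1):
                qpos = off + p - s
                base = r.sequence[qpos]
                if base not in _BASE_INDEX:
                    continue
                if base != ref[p - 1] and (
                    qpos < read_end_trim or qpos >= rl - read_end_trim
                ):
                    continue
                arr[p, _BASE_INDEX[base]] += 1
            off += e - s + 1

    strand_of = _strand_map(bundle)
    pile: dict[tuple[str, int], PileupEntry] = {}
    for chrom, arr in counts.items():
        ref = bundle.chromosomes[chrom]
        covered = np.flatnonzero(arr.sum(axis=1))
        for p in covered:
            p = int(p)
            strand = strand_of(chrom, p)
            a, c, g, t = (int(x) for x in arr[p])
            if strand == "-":
                a, c, g, t = t, g, c, a
                refb = complement(ref[p - 1])
            else:
                refb = ref[p - 1]
            pile[(chrom, p)] = PileupEntry(chrom, p, refb, strand, (a, c, g, t))
    return pile


def _strand_map(bundle: ReferenceBundle):
    spans = {}
    for t in bundle.gene_models:
        spans.setdefault(t.chromosome, []).append((t.start, t.end, t.strand))
    for v in spans.values():
        v.sort()

    def strand_of(chrom: str, pos: int) -> str:
        for s, e, st in spans.get(chrom, ()):
            if s <= pos <= e:
                return st
            if s > pos:
                break
        return "+"

    return strand_of


# ---------------------------------------------------------------------------
# site calling
# ---------------------------------------------------------------------------


@dataclass
class SiteCall:
    """One candidate mismatch position in one fraction."""

    chromosome: str
    position: int
    strand: str
    g_count: int
    coverage: int
    mismatch_type: str  # e.g. "A-G"; only A-G propagates downstream

    @property
    def editing_ratio(self) -> float:
        return self.g_count / self.coverage


def _junction_margin_positions(bundle: ReferenceBundle, margin: int
                               ) -> set[tuple[str, int]]:
    out: set[tuple[str, int]] = set()
    for t in bundle.gene_models:
        for (istart, iend) in t.introns:
            for b in (istart, iend + 1):  # boundaries sit between b-1 and b
                out.update((t.chromosome, p)
                           for p in range(b - margin, b + margin))
    return out


def _in_homopolymer(seq: str, pos: int, run: int) -> bool:
    i = pos - 1
    base = seq[i]
    left = i
    while left > 0 and seq[left - 1] == base:
        left -= 1
    right = i
    while right < len(seq) - 1 and seq[right + 1] == base:
        right += 1
    return right - left + 1 >= run


def call_sites(
    pileup: dict[tuple[str, int], PileupEntry],
    bundle: ReferenceBundle,
    params: CallerParams | None = None,
    nascent: bool = False,
) -> list[SiteCall]:
    """Candidate A-to-G sites in one fraction's pileup.

    Keeps transcript-strand reference-A positions with at least ``min_g``
    G reads and ``min_cov`` coverage; drops known SNPs, homopolymer runs
    and (unless ``nascent``) junction-proximal positions.  Non-A-G
    mismatch positions passing the same support filters are returned with
    their mismatch type recorded, but only A-G calls feed the kinetic
    analysis downstream.
    """
    params = params or CallerParams()
    snps = set(bundle.snps)
    margins = (set() if nascent
               else _junction_margin_positions(bundle, params.junction_margin))
    out: list[SiteCall] = []
    for (chrom, pos), entry in sorted(pileup.items()):
        alts = [(b, entry.count(b)) for b in "ACGT"
                if b != entry.ref_base and entry.count(b) > 0]
        if not alts:
            continue
        alt, n_alt = max(alts, key=lambda x: x[1])
        if n_alt < params.min_g or entry.coverage < params.min_cov:
            continue
        if (chrom, pos) in snps:
            continue
        if _in_homopolymer(bundle.chromosomes[chrom], pos, params.homopolymer_run):
            continue
        if (chrom, pos) in margins:
            continue
        out.append(
            SiteCall(chrom, pos, entry.strand, n_alt, entry.coverage,
                     f"{entry.ref_base}-{alt}")
        )
    return out


# ---------------------------------------------------------------------------
# union across fractions
# ---------------------------------------------------------------------------


@dataclass
class EditingSite:
    """A candidate A-to-G position with per-fraction evidence.

    ``g_cov`` maps fraction name to (edited-G reads, total coverage) taken
    from that fraction's pileup, whether or not the site passed the calling
    filters there -- the union of per-fraction calls defines the site list,
    the pileups supply the counts for kinetic classification.
    """

    chromosome: str
    position: int
    strand: str
    g_cov: dict[str, tuple[int, int]]
    context: str = "unknown"
    repeat_class: str = "unknown"
    nearest_site_distance: int | None = None

    def er(self, fraction: str) -> float | None:
        g, cov = self.g_cov.get(fraction, (0, 0))
        return g / cov if cov else None


def collect_sites(
    calls_by_fraction: dict[str, list[SiteCall]],
    pileups_by_fraction: dict[str, dict[tuple[str, int], PileupEntry]],
) -> list[EditingSite]:
    """Pool A-G calls from all fractions and attach per-fraction counts."""
    union: dict[tuple[str, int], str] = {}
    for calls in calls_by_fraction.values():
        for c in calls:
            if c.mismatch_type == "A-G":
                union[(c.chromosome, c.position)] = c.strand
    sites = []
    for (chrom, pos), strand in sorted(union.items()):
        g_cov = {}
        for frac, pile in pileups_by_fraction.items():
            entry = pile.get((chrom, pos))
            if entry is None:
                g_cov[frac] = (0, 0)
            else:
                g_cov[frac] = (entry.count("G"), entry.coverage)
        sites.append(EditingSite(chrom, pos, strand, g_cov))
    return sites


# ---------------------------------------------------------------------------
# hyperediting rescue
# ---------------------------------------------------------------------------


@dataclass
class HyperParams:
    """Reduced-alphabet rescue parameters.

    Reads and genome are collapsed (A->G, and the complementary T->C
    collapse for antisense transcripts), re-aligned with exact-word seeding
    plus ungapped extension, and accepted only with a unique best placement.
    After reinstating the original bases a rescued read must show at least
    ``min_edits`` A-to-G (or T-to-C) mismatches, at most ``max_other``
    other mismatches, and its edited positions must span more than
    ``min_spread`` of the read length.
    """

    word_size: int = 20
    max_transformed_mismatch: int = 2
    min_edits: int = 5
    max_other: int = 1
    min_spread: float = 0.5


def _collapse(seq: str, frm: str, to: str) -> str:
    return seq.replace(frm, to)


class _CollapsedIndex:
    """Exact-word index of a collapsed genome."""

    def __init__(self, chromosomes: dict[str, str], frm: str, to: str, word: int):
        self.word = word
        self.seqs = {c: _collapse(s, frm, to) for c, s in chromosomes.items()}
        self.index: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in self.seqs.items():
            for i in range(len(seq) - word + 1):
                self.index.setdefault(seq[i:i + word], []).append((chrom, i))

    def candidates(self, read: str) -> set[tuple[str, int]]:
        w = self.word
        out: set[tuple[str, int]] = set()
        for off in (0, max(0, len(read) // 2 - w // 2), max(0, len(read) - w)):
            for chrom, i in self.index.get(read[off:off + w], ()):
                start = i - off
                if start >= 0 and start + len(read) <= len(self.seqs[chrom]):
                    out.add((chrom, start))
        return out


def hyperediting_rescue(
    unmapped_reads: list[AlignedRead],
    bundle: ReferenceBundle,
    params: HyperParams | None = None,
) -> list[AlignedRead]:
    """Re-align reads that failed normal alignment, in collapsed space.

    Both the A->G collapse (sense editing) and the T->C collapse (editing
    on the antisense-strand transcript, seen in reference orientation) are
    tried; the transform with the unique best placement wins.  Rescued
    reads come back as single-block alignments with original bases
    reinstated, ready to be pooled with the normally mapped reads.
    """
    params = params or HyperParams()
    idx = {
        "+": _CollapsedIndex(bundle.chromosomes, "A", "G", params.word_size),
        "-": _CollapsedIndex(bundle.chromosomes, "T", "C", params.word_size),
    }
    rescued: list[AlignedRead] = []
    for r in unmapped_reads:
        placements: list[tuple[int, str, str, int]] = []  # (mm, strand, chrom, start)
        for strand, ix in idx.items():
            frm, to = ("A", "G") if strand == "+" else ("T", "C")
            rc = _collapse(r.sequence, frm, to)
            for chrom, start in ix.candidates(rc):
                ref = ix.seqs[chrom][start:start + len(rc)]
                mm = sum(a != b for a, b in zip(rc, ref))
                if mm <= params.max_transformed_mismatch:
                    placements.append((mm, strand, chrom, start))
        if not placements:
            continue
        placements.sort()
        best = placements[0]
        if len(placements) > 1 and placements[1][0] == best[0]:
            continue  # ambiguous placement: discard
        mm, strand, chrom, start = best
        genome = bundle.chromosomes[chrom][start:start + len(r.sequence)]
        edit_from, edit_to = ("A", "G") if strand == "+" else ("T", "C")
        edits, other = [], 0
        for i, (g, b) in enumerate(zip(genome, r.sequence)):
            if g == b:
                continue
            if g == edit_from and b == edit_to:
                edits.append(i)
            else:
                other += 1
        if len(edits) < params.min_edits or other > params.max_other:
            continue
        if (edits[-1] - edits[0]) <= params.min_spread * len(r.sequence):
            continue
        rescued.append(
            AlignedRead(r.id, chrom, strand,
                        ((start + 1, start + len(r.sequence)),),
                        r.sequence, r.fraction, r.mate_id)
        )
    return rescued


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

_CONTEXT_PRECEDENCE = ("CDS", "UTR", "NC", "intron", "intergenic")


def _site_context(t_list: list[Transcript], pos: int) -> str:
    best = "intergenic"
    rank = {c: i for i, c in enumerate(_CONTEXT_PRECEDENCE)}
    for t in t_list:
        in_exon = any(s <= pos <= e for s, e in t.exons)
        if in_exon:
            if t.cds is None:
                ctx = "NC"
            elif t.cds[0] <= pos <= t.cds[1]:
                ctx = "CDS"
            else:
                ctx = "UTR"
        elif t.start <= pos <= t.end:
            ctx = "intron"
        else:
            continue
        if rank[ctx] < rank[best]:
            best = ctx
    return best


def annotate_sites(
    sites: list[EditingSite], bundle: ReferenceBundle
) -> list[EditingSite]:
    """Assign genomic context, repeat class and nearest-site distance.

    Context precedence is CDS > UTR > noncoding exon > intron > intergenic;
    repeat class is Alu / non-Alu repeat / nonrepeat from the bundle's
    repeat intervals; the nearest-neighbour distance is computed over the
    union of all sites, irrespective of kinetic group.
    """
    from intervaltree import IntervalTree

    rep_trees: dict[str, IntervalTree] = {}
    for r in bundle.repeats:
        rep_trees.setdefault(r.chromosome, IntervalTree()).addi(
            r.start, r.end + 1, r.repeat_class
        )
    by_chrom: dict[str, list[int]] = {}
    for s in sites:
        by_chrom.setdefault(s.chromosome, []).append(s.position)
    for v in by_chrom.values():
        v.sort()

    for s in sites:
        s.context = _site_context(
            bundle.transcripts_at(s.chromosome, s.position), s.position
        )
        classes = {
            iv.data for iv in rep_trees.get(s.chromosome, IntervalTree())
            [s.position]
        }
        if "Alu" in classes:
            s.repeat_class = "Alu"
        elif classes:
            s.repeat_class = "repeat"
        else:
            s.repeat_class = "nonrepeat"
        positions = by_chrom[s.chromosome]
        if len(positions) > 1:
            i = positions.index(s.position)
            dists = []
            if i > 0:
                dists.append(s.position - positions[i - 1])
            if i < len(positions) - 1:
                dists.append(positions[i + 1] - s.position)
            s.nearest_site_distance = min(dists)
        else:
            s.nearest_site_distance = None
    return sites
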