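"""Splicing completeness (coSI), splicing timing, novel exons and PSI.

coSI for an internal exon is S/(S+U): S counts reads spliced across either
of the exon's two flanking junctions, U counts reads running contiguously
across any of the four exon-intron boundaries of those introns.  Exons
complete early (coSI >= 0.95 already in chromatin-associated poly(A)- RNA)
are cotranscriptionally spliced (coTS); exons still incomplete in ChA+
(coSI <= 0.75) but finished by the nucleoplasm (>= 0.95) are
post-transcriptionally spliced (postTS).

PSI for a skipped exon uses junction counts only: inclusion reads I are
split across the two flanking junctions, so PSI = (I/2) / (I/2 + E) with E
the exon-skipping junction count.  ``delta_psi`` is PSI(KD) - PSI(Ctrl).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .synthetic import AlignedRead, ReferenceBundle, Transcript

COSI_MIN_READS = 10
COTS_THRESHOLD = 0.95
POSTTS_CHA_PLUS = 0.75
POSTTS_NPA_PLUS = 0.95

AS_TYPES = ("SE", "A3SS-short", "A3SS-long", "RI", "Complex")


@dataclass
class SpliceEvent:
    """An exon with its alternative-splicing type and PSI per condition."""

    event_id: str
    transcript_id: str
    exon: tuple[int, int]
    as_type: str
    psi: dict[str, float | None]
    cosi: dict[str, float | None] = field(default_factory=dict)
    timing: str = "other"
    chromosome: str = ""

    def delta_psi(self, kd: str = "KD", ctrl: str = "Ctrl") -> float | None:
        a, b = self.psi.get(kd), self.psi.get(ctrl)
        if a is None or b is None:
            return None
        return a - b


# ---------------------------------------------------------------------------
# junction bookkeeping
# ---------------------------------------------------------------------------


def junction_counts(reads: list[AlignedRead]) -> Counter:
    """Count reads supporting each splice junction (intron interval)."""
    c: Counter = Counter()
    for r in reads:
        for gap in r.junction_gaps():
            c[(r.chromosome, gap)] += 1
    return c


def _boundary_crossings(reads: list[AlignedRead], chrom: str,
                        boundaries: list[int]) -> int:
    """(read, boundary) crossing events: contiguous block across a
    boundary sitting between positions b-1 and b."""
    n = 0
    for r in reads:
        if r.chromosome != chrom:
            continue
        for b in boundaries:
            if any(s <= b - 1 and e >= b for s, e in r.blocks):
                n += 1
    return n


# ---------------------------------------------------------------------------
# coSI and timing
# ---------------------------------------------------------------------------


def compute_cosi(
    transcript: Transcript,
    exon_index: int,
    reads: list[AlignedRead],
    min_reads: int = COSI_MIN_READS,
) -> float | None:
    """Completed-splicing index of an internal exon in one read set.

    ``exon_index`` is genomic order (0-based).  Raises ``ValueError`` for a
    terminal exon; returns ``None`` when fewer than ``min_reads``
    splicing-informative reads are available.

    Each unspliced molecule exposes two boundaries per intron whereas a
    spliced molecule exposes one junction, so boundary crossings are
    weighted 1/2: coSI then estimates the spliced-molecule fraction
    without a systematic downward bias.
    """
    if exon_index <= 0 or exon_index >= len(transcript.exons) - 1:
        raise ValueError("coSI is defined for internal exons only")
    chrom = transcript.chromosome
    up_intron = transcript.introns[exon_index - 1]
    dn_intron = transcript.introns[exon_index]
    jc = junction_counts(reads)
    spliced = jc[(chrom, up_intron)] + jc[(chrom, dn_intron)]
    boundaries = [up_intron[0], up_intron[1] + 1, dn_intron[0], dn_intron[1] + 1]
    unspliced = 0.5 * _boundary_crossings(reads, chrom, boundaries)
    total = spliced + unspliced
    if total < min_reads:
        return None
    return spliced / total


def classify_timing(cosi: dict[str, float | None]) -> str:
    """coTS / postTS / other from per-fraction coSI values.

    coTS: coSI >= 0.95 already in ChA-.  postTS: coSI <= 0.75 in ChA+ and
    >= 0.95 in NpA+.  Missing or undefined required fractions yield
    "undefined".
    """
    cha_minus = cosi.get("ChA-")
    cha_plus = cosi.get("ChA+")
    npa_plus = cosi.get("NpA+")
    if cha_minus is not None and cha_minus >= COTS_THRESHOLD:
        return "coTS"
    if cha_plus is not None and npa_plus is not None:
        if cha_plus <= POSTTS_CHA_PLUS and npa_plus >= POSTTS_NPA_PLUS:
            return "postTS"
    if cha_minus is None and (cha_plus is None or npa_plus is None):
        return "undefined"
    return "other"


# ---------------------------------------------------------------------------
# novel exons
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExonCandidate:
    chromosome: str
    start: int
    end: int
    left_junction_reads: int
    right_junction_reads: int
    density: float
    novel: bool


def detect_novel_exons(
    reads: list[AlignedRead],
    bundle: ReferenceBundle,
    min_density: float = 10.0,
    min_junction_reads: int = 2,
    max_exon_length: int = 2000,
) -> list[ExonCandidate]:
    """Junction-bounded exon candidates from spliced reads.

    An interval between the end of one junction and the start of another
    is reported when each bounding junction has >= ``min_junction_reads``
    support and the interval's mean read coverage (total aligned bases /
    interval length) is >= ``min_density``.  Candidates matching an
    annotated exon exactly are flagged known, the rest novel.
    """
    jc = junction_counts(reads)
    by_chrom: dict[str, list[tuple[tuple[int, int], int]]] = {}
    for (chrom, gap), n in jc.items():
        if n >= min_junction_reads:
            by_chrom.setdefault(chrom, []).append((gap, n))
    annotated = {
        (t.chromosome, s, e) for t in bundle.gene_models for s, e in t.exons
    }
    out = []
    for chrom, gaps in by_chrom.items():
        gaps.sort()
        for (g1, n1) in gaps:
            for (g2, n2) in gaps:
                start, end = g1[1] + 1, g2[0] - 1
                if start > end or end - start + 1 > max_exon_length:
                    continue
                covered = 0
                for r in reads:
                    if r.chromosome != chrom:
                        continue
                    for (s, e) in r.blocks:
                        lo, hi = max(s, start), min(e, end)
                        if lo <= hi:
                            covered += hi - lo + 1
                density = covered / (end - start + 1)
                if density < min_density:
                    continue
                out.append(
                    ExonCandidate(chrom, start, end, n1, n2, density,
                                  novel=(chrom, start, end) not in annotated)
                )
    return sorted(out, key=lambda c: (c.chromosome, c.start, c.end))


# ---------------------------------------------------------------------------
# PSI
# ---------------------------------------------------------------------------


def psi_se(inclusion_reads: int, exclusion_reads: int,
           min_total: int = 10, min_exclusion: int = 2) -> float | None:
    """Skipped-exon PSI from junction counts.

    ``inclusion_reads`` pools both flanking junctions, hence the /2.
    Returns ``None`` unless inclusion+exclusion >= ``min_total`` or
    exclusion >= ``min_exclusion`` (the published coverage rule).
    """
    if inclusion_reads < 0 or exclusion_reads < 0:
        raise ValueError("negative junction counts")
    if (inclusion_reads + exclusion_reads) < min_total \
            and exclusion_reads < min_exclusion:
        return None
    half_i = inclusion_reads / 2
    if half_i + exclusion_reads == 0:
        return None
    return half_i / (half_i + exclusion_reads)


def psi_a3ss(primary_junction: int, alternative_junction: int,
             min_total: int = 10, min_exclusion: int = 2) -> float | None:
    """Usage of the primary acceptor among two competing acceptors."""
    if (primary_junction + alternative_junction) < min_total \
            and alternative_junction < min_exclusion:
        return None
    if primary_junction + alternative_junction == 0:
        return None
    return primary_junction / (primary_junction + alternative_junction)


def psi_ri(mean_intron_coverage: float, junction_reads: int,
           min_total: float = 10) -> float | None:
    """Retained-intron PSI: intronic density vs spliced junction support."""
    total = mean_intron_coverage + junction_reads
    if total < min_total:
        return None
    return mean_intron_coverage / total


def compute_psi_event(
    transcript: Transcript,
    exon_index: int,
    reads_by_condition: dict[str, list[AlignedRead]],
    event_id: str | None = None,
    min_total: int = 10,
    min_exclusion: int = 2,
    min_alt_evidence: int = 2,
    ri_min_density: float = 2.0,
) -> SpliceEvent:
    """Type one internal exon's alternative splicing and compute PSI per
    condition from junction evidence.

    Patterns considered: exon skipping (a junction bridging the two
    flanking introns), alternative acceptor (a junction sharing the donor
    but landing at a different acceptor; "short"/"long" refer to the exon
    produced relative to the annotated one), intron retention (contiguous
    coverage over a flanking intron).  More than one pattern with evidence
    makes the event Complex; with none, the exon is treated as a skipping
    event whose exclusion count is zero.
    """
    if exon_index <= 0 or exon_index >= len(transcript.exons) - 1:
        raise ValueError("internal exons only")
    chrom = transcript.chromosome
    es, ee = transcript.exons[exon_index]
    up_intron = transcript.introns[exon_index - 1]
    dn_intron = transcript.introns[exon_index]
    # acceptor side of the exon in transcript orientation
    acceptor_intron = up_intron if transcript.strand == "+" else dn_intron

    def analyse(reads):
        jc = junction_counts(reads)
        incl = jc[(chrom, up_intron)] + jc[(chrom, dn_intron)]
        skip = jc[(chrom, (up_intron[0], dn_intron[1]))]
        # competing acceptors: junctions sharing the donor end of the
        # acceptor-side intron but with a different acceptor end
        alt_acc = []
        skip_gap = (up_intron[0], dn_intron[1])
        for (c, gap), n in jc.items():
            if c != chrom or gap == acceptor_intron or gap == skip_gap:
                continue
            if transcript.strand == "+":
                if gap[0] == acceptor_intron[0] and n >= min_alt_evidence:
                    alt_acc.append((gap, n))
            else:
                if gap[1] == acceptor_intron[1] and n >= min_alt_evidence:
                    alt_acc.append((gap, n))
        intron_cov = 0.0
        ilen = up_intron[1] - up_intron[0] + 1
        for r in reads:
            if r.chromosome != chrom:
                continue
            for (s, e) in r.blocks:
                lo, hi = max(s, up_intron[0]), min(e, up_intron[1])
                if lo <= hi:
                    intron_cov += hi - lo + 1
        return jc, incl, skip, alt_acc, intron_cov / ilen

    per_cond = {c: analyse(rs) for c, rs in reads_by_condition.items()}
    evidence = set()
    for (_, incl, skip, alt_acc, ri_density) in per_cond.values():
        if skip >= min_exclusion:
            evidence.add("SE")
        for gap, _ in alt_acc:
            if transcript.strand == "+":
                longer = gap[1] < acceptor_intron[1]
            else:
                longer = gap[0] > acceptor_intron[0]
            evidence.add("A3SS-long" if longer else "A3SS-short")
        if ri_density >= ri_min_density:
            evidence.add("RI")
    if len(evidence) == 0:
        as_type = "SE"
    elif len(evidence) == 1:
        as_type = next(iter(evidence))
    else:
        as_type = "Complex"

    psi: dict[str, float | None] = {}
    for cond, (jc, incl, skip, alt_acc, ri_density) in per_cond.items():
        if as_type in ("SE", "Complex"):
            psi[cond] = psi_se(incl, skip, min_total, min_exclusion)
        elif as_type in ("A3SS-short", "A3SS-long"):
            primary = jc[(chrom, acceptor_intron)]
            alt = sum(n for _, n in alt_acc)
            psi[cond] = psi_a3ss(primary, alt, min_total, min_exclusion)
        else:  # RI
            junc = jc[(chrom, up_intron)]
            psi[cond] = psi_ri(ri_density, junc, min_total)
    return SpliceEvent(
        event_id=event_id or f"{transcript.id}:exon{exon_index}",
        transcript_id=transcript.id, exon=(es, ee), as_type=as_type,
        psi=psi, chromosome=chrom,
    )
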