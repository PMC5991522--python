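"""dsRNA duplex detection around editing sites and exons.

ADAR binds double-stranded RNA, typically the hairpin formed by a pair of
inverted repeats (in human, mostly inverted Alus).  This module detects
such structure by locally aligning sequence against the reverse
complement of its neighbourhood: a good local alignment between a window
and the reverse complement of nearby sequence is evidence of an
intramolecular duplex.

The aligner is an internal word-seeded, ungapped-extension local aligner
(match +1, mismatch -2, X-drop) with Karlin-Altschul E-values
E = K*m*n*exp(-lambda*S).  E-values are internally consistent but not
bit-compatible with NCBI BLASTN; ``local_align`` accepts any callable
with the same signature for users who want an external aligner.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

from .splicing import SpliceEvent
from .synthetic import ReferenceBundle, Transcript, revcomp

#: Karlin-Altschul parameters for the +1/-2 ungapped scoring system.
LAMBDA = 1.28
KA_K = 0.46


@dataclass
class AlignScoring:
    match: int = 1
    mismatch: int = -2
    word_size: int = 8
    xdrop: int = 10
    lam: float = LAMBDA
    k: float = KA_K

    def __post_init__(self):
        if self.match <= 0 or self.mismatch >= 0:
            raise ValueError("need match > 0 and mismatch < 0")


@dataclass(frozen=True)
class LocalHit:
    """One ungapped local alignment between query and subject."""

    q_start: int  # 0-based, half-open, in the query
    q_end: int
    s_start: int
    s_end: int
    score: int
    matches: int
    evalue: float

    @property
    def length(self) -> int:
        return self.q_end - self.q_start

    @property
    def identity(self) -> float:
        """Percent identity over the aligned length."""
        return 100.0 * self.matches / self.length if self.length else 0.0


def evalue(score: float, m: int, n: int,
           lam: float = LAMBDA, k: float = KA_K) -> float:
    """Karlin-Altschul expectation for a local score S in an m x n search."""
    return k * m * n * math.exp(-lam * score)


def local_align(
    query: str, subject: str, scoring: AlignScoring | None = None
) -> list[LocalHit]:
    """Ranked ungapped local alignments of ``query`` against ``subject``.

    Word-identical seeds are extended in both directions under an X-drop
    rule; overlapping hits on the same diagonal are collapsed to the best
    one.  Hits come back best score first.  Raises ``ValueError`` on empty
    sequences.
    """
    if not query or not subject:
        raise ValueError("empty sequence")
    sc = scoring or AlignScoring()
    w = sc.word_size
    m, n = len(query), len(subject)
    index: dict[str, list[int]] = {}
    for j in range(n - w + 1):
        index.setdefault(subject[j:j + w], []).append(j)

    best_on_diag: dict[int, LocalHit] = {}
    seen_span: dict[int, list[tuple[int, int]]] = {}
    for i in range(m - w + 1):
        word = query[i:i + w]
        for j in index.get(word, ()):
            diag = i - j
            spans = seen_span.setdefault(diag, [])
            if any(a <= i < b for a, b in spans):
                continue  # seed inside an already-extended hit
            qs, qe, score, matches = _extend(query, subject, i, j, w, sc)
            spans.append((qs, qe))
            hit = LocalHit(qs, qe, qs - diag, qe - diag, score, matches,
                           evalue(score, m, n, sc.lam, sc.k))
            prev = best_on_diag.get(diag)
            if prev is None or hit.score > prev.score:
                best_on_diag[diag] = hit
    return sorted(best_on_diag.values(), key=lambda h: (-h.score, h.q_start))


def _extend(query: str, subject: str, i: int, j: int, w: int,
            sc: AlignScoring) -> tuple[int, int, int, int]:
    """X-drop extension of an exact word seed; returns (q_start, q_end,
    score, matches) of the best-scoring segment found."""
    score = w * sc.match
    best = score
    qs, qe = i, i + w
    # right
    x, y = i + w, j + w
    cur = score
    bq = qe
    while x < len(query) and y < len(subject):
        cur += sc.match if query[x] == subject[y] else sc.mismatch
        x += 1
        y += 1
        if cur > best:
            best, bq = cur, x
        if best - cur > sc.xdrop:
            break
    qe = bq
    # left
    x, y = i - 1, j - 1
    cur = best
    bq = qs
    while x >= 0 and y >= 0:
        cur += sc.match if query[x] == subject[y] else sc.mismatch
        if cur > best:
            best, bq = cur, x
        if best - cur > sc.xdrop:
            break
        x -= 1
        y -= 1
    qs = bq
    matches = sum(
        1 for a, b in zip(query[qs:qe], subject[qs - (i - j):qe - (i - j)])
        if a == b
    )
    return qs, qe, best, matches


# ---------------------------------------------------------------------------
# duplex tests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DuplexHit:
    """A candidate intramolecular pairing between two genomic arms."""

    chromosome: str
    arm1: tuple[int, int]  # 1-based inclusive genomic interval
    arm2: tuple[int, int]
    length: int
    identity: float
    score: int
    evalue: float

    def __post_init__(self):
        if self.length < 1 or not 0 <= self.identity <= 100 or self.evalue < 0:
            raise ValueError("invalid duplex hit")


def _overlap_frac(a: tuple[int, int], b: tuple[int, int]) -> float:
    lo, hi = max(a[0], b[0]), min(a[1], b[1])
    if lo > hi:
        return 0.0
    shorter = min(a[1] - a[0], b[1] - b[0]) + 1
    return (hi - lo + 1) / shorter


def site_centered_duplex(
    genome: dict[str, str],
    chromosome: str,
    position: int,
    window: int = 4001,
    flank: int = 200,
    min_length: int = 50,
    min_identity: float = 80.0,
    scoring: AlignScoring | None = None,
) -> tuple[bool, DuplexHit | None]:
    """Does an editing site sit in a dsRNA-forming context?

    The reverse complement of the ``window``-nt sequence centred on the
    site is aligned against the site's immediate neighbourhood (site +/-
    ``flank``).  The neighbourhood trivially aligns to its own reverse
    complement inside the window, so hits whose two genomic arms
    substantially coincide are discarded as self-alignments; the best
    remaining ("second-best") alignment is tested against the length and
    identity thresholds.  Windows are truncated at chromosome ends.
    """
    seq = genome[chromosome]
    half = window // 2
    ws = max(1, position - half)
    we = min(len(seq), position + half)
    ns = max(1, position - flank)
    ne = min(len(seq), position + flank)
    win_seq = seq[ws - 1:we]
    neigh = seq[ns - 1:ne]
    query = revcomp(win_seq)
    hits = local_align(query, neigh, scoring)
    for h in hits:
        # genomic interval of the query arm: query index i <-> genomic we - i
        arm_q = (we - h.q_end + 1, we - h.q_start)
        arm_s = (ns + h.s_start, ns + h.s_end - 1)
        if _overlap_frac(arm_q, arm_s) > 0.5:
            continue  # self-alignment
        dup = DuplexHit(chromosome, arm_s, arm_q, h.length, h.identity,
                        h.score, h.evalue)
        passed = h.length >= min_length and h.identity >= min_identity
        return passed, dup
    return False, None


def exon_intron_duplex(
    genome: dict[str, str],
    transcript: Transcript,
    exon_index: int,
    min_identity: float = 70.0,
    max_evalue: float = 1e-3,
    intron_cap: int = 5000,
    scoring: AlignScoring | None = None,
) -> DuplexHit | None:
    """Best duplex between an exon and the reverse complement of its
    flanking introns, or ``None`` if no hit meets both thresholds.

    Introns are truncated to ``intron_cap`` nt adjacent to the exon.
    Raises ``ValueError`` when the exon has no flanking intron.
    """
    seq = genome[transcript.chromosome]
    es, ee = transcript.exons[exon_index]
    introns = []
    if exon_index > 0:
        s, e = transcript.introns[exon_index - 1]
        introns.append((max(s, e - intron_cap + 1), e))  # side adjacent to exon
    if exon_index < len(transcript.exons) - 1:
        s, e = transcript.introns[exon_index]
        introns.append((s, min(e, s + intron_cap - 1)))
    if not introns:
        raise ValueError("exon has no flanking intron")
    exon_seq = seq[es - 1:ee]
    best: DuplexHit | None = None
    for (s, e) in introns:
        subject = revcomp(seq[s - 1:e])
        for h in local_align(exon_seq, subject, scoring):
            if h.identity <= min_identity or h.evalue > max_evalue:
                continue
            # subject index j <-> genomic e - j
            arm2 = (e - h.s_end + 1, e - h.s_start)
            dup = DuplexHit(transcript.chromosome,
                            (es + h.q_start, es + h.q_end - 1), arm2,
                            h.length, h.identity, h.score, h.evalue)
            if best is None or dup.evalue < best.evalue:
                best = dup
            break  # hits are ranked; only the best per intron matters
    return best


# ---------------------------------------------------------------------------
# ADAR-direct-target funnel
# ---------------------------------------------------------------------------


@dataclass
class FunnelRecord:
    event: SpliceEvent
    delta_psi: float | None
    has_edit_within_flank: bool = False
    duplex: DuplexHit | None = None
    clip_overlap: bool = False
    passes: bool = False


@dataclass
class FunnelResult:
    records: list[FunnelRecord]
    stage_counts: dict[str, int]
    positive_fraction: float | None  # dPSI > 0 among passing exons


def adar_target_funnel(
    events: list[SpliceEvent],
    site_positions: list[tuple[str, int]],
    bundle: ReferenceBundle,
    clip_peaks: list[tuple[str, int, int]] | None = None,
    min_dpsi: float = 0.10,
    edit_flank: int = 500,
    min_identity: float = 70.0,
    max_evalue: float = 1e-3,
    kd: str = "KD",
    ctrl: str = "Ctrl",
) -> FunnelResult:
    """Monotone filter cascade selecting exons directly repressed by ADAR.

    Stages: |dPSI| >= ``min_dpsi`` (either direction) -> an editing site
    inside the exon or within ``edit_flank`` nt of an exon boundary -> an
    exon-intron duplex passing the identity and E-value thresholds.  CLIP
    peak overlap is recorded as supporting evidence, not as a filter.  The
    summary reports per-stage counts and the fraction of passing exons
    with a positive PSI change upon knockdown.
    """
    from intervaltree import IntervalTree

    t_by_id = {t.id: t for t in bundle.gene_models}
    clip_trees: dict[str, IntervalTree] = {}
    for chrom, s, e in clip_peaks or []:
        clip_trees.setdefault(chrom, IntervalTree()).addi(s, e + 1)
    sites_by_chrom: dict[str, list[int]] = {}
    for chrom, pos in site_positions:
        sites_by_chrom.setdefault(chrom, []).append(pos)

    records = []
    counts = {"events": len(events), "dpsi": 0, "edit_proximal": 0, "duplex": 0}
    for ev in events:
        dpsi = ev.delta_psi(kd, ctrl)
        rec = FunnelRecord(ev, dpsi)
        records.append(rec)
        if dpsi is None or abs(dpsi) < min_dpsi:
            continue
        counts["dpsi"] += 1
        es, ee = ev.exon
        lo, hi = es - edit_flank, ee + edit_flank
        rec.has_edit_within_flank = any(
            lo <= p <= hi for p in sites_by_chrom.get(ev.chromosome, ())
        )
        if not rec.has_edit_within_flank:
            continue
        counts["edit_proximal"] += 1
        t = t_by_id.get(ev.transcript_id)
        if t is None:
            continue
        exon_index = t.exons.index((es, ee))
        rec.duplex = exon_intron_duplex(
            bundle.chromosomes, t, exon_index,
            min_identity=min_identity, max_evalue=max_evalue,
        )
        if rec.duplex is None:
            continue
        counts["duplex"] += 1
        rec.passes = True
        tree = clip_trees.get(ev.chromosome)
        if tree is not None:
            span = (min(rec.duplex.arm1[0], rec.duplex.arm2[0]),
                    max(rec.duplex.arm1[1], rec.duplex.arm2[1]))
            rec.clip_overlap = bool(tree[span[0]:span[1] + 1])
    passing = [r for r in records if r.passes and r.delta_psi is not None]
    pos_frac = (
        sum(1 for r in passing if r.delta_psi > 0) / len(passing)
        if passing else None
    )
    return FunnelResult(records, counts, pos_frac)
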