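"""Splice-site windows, edit-induced strength changes, and concordance.

Donor (5'ss) windows are 9-mers: 3 exonic + 6 intronic nt; acceptor
(3'ss) windows are 23-mers: 20 intronic + 3 exonic nt.  Offsets are
labelled from the exon-intron boundary ("3e..1e|1i..6i" for donors,
"20i..1i|1e..3e" for acceptors); the A of the acceptor's invariant AG is
position 2i, and an A-to-G edit there (AG -> GG) destroys the canonical
acceptor.

Splice-site strength is scored with a first-order position-weight model
(log-odds against a uniform background) trained on the annotation-derived
windows of the supplied genome; any object with a ``score(sequence)``
method can be plugged in instead, e.g. a precomputed score table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .caller import EditingSite
from .splicing import SpliceEvent
from .synthetic import ReferenceBundle, complement

DONOR_EXONIC, DONOR_INTRONIC = 3, 6
ACCEPTOR_EXONIC, ACCEPTOR_INTRONIC = 3, 20


@dataclass(frozen=True)
class SpliceSiteWindow:
    """One donor or acceptor window in transcript orientation.

    ``positions`` lists the genomic coordinate of each window offset in
    transcript order, so ``sequence[i]`` is the (strand-corrected) base at
    ``positions[i]``; ``labels[i]`` is the field-standard offset label.
    """

    kind: str  # "donor" | "acceptor"
    transcript_id: str
    chromosome: str
    strand: str
    sequence: str
    positions: tuple[int, ...]
    labels: tuple[str, ...]

    def label_at(self, genomic_pos: int) -> str | None:
        try:
            return self.labels[self.positions.index(genomic_pos)]
        except ValueError:
            return None

    def position_of(self, label: str) -> int:
        return self.positions[self.labels.index(label)]


def _window_positions(kind: str, intron: tuple[int, int], strand: str
                      ) -> tuple[list[int], list[str]]:
    istart, iend = intron
    if kind == "donor":
        labels = [f"{i}e" for i in range(DONOR_EXONIC, 0, -1)] + \
                 [f"{i}i" for i in range(1, DONOR_INTRONIC + 1)]
        if strand == "+":
            pos = list(range(istart - DONOR_EXONIC, istart + DONOR_INTRONIC))
        else:
            pos = list(range(iend + DONOR_EXONIC, iend - DONOR_INTRONIC, -1))
    elif kind == "acceptor":
        labels = [f"{i}i" for i in range(ACCEPTOR_INTRONIC, 0, -1)] + \
                 [f"{i}e" for i in range(1, ACCEPTOR_EXONIC + 1)]
        if strand == "+":
            pos = list(range(iend - ACCEPTOR_INTRONIC + 1,
                             iend + ACCEPTOR_EXONIC + 1))
        else:
            pos = list(range(istart + ACCEPTOR_INTRONIC - 1,
                             istart - ACCEPTOR_EXONIC - 1, -1))
    else:
        raise ValueError(f"unknown window kind {kind!r}")
    return pos, labels


def make_window(kind: str, transcript_id: str, chromosome: str, strand: str,
                intron: tuple[int, int], seq: str) -> SpliceSiteWindow | None:
    """Build one window for an intron, or ``None`` when the intronic span
    does not fit (short introns) or the window leaves the chromosome."""
    ilen = intron[1] - intron[0] + 1
    need = DONOR_INTRONIC if kind == "donor" else ACCEPTOR_INTRONIC
    if ilen < need:
        return None
    pos, labels = _window_positions(kind, intron, strand)
    if min(pos) < 1 or max(pos) > len(seq):
        return None
    bases = [seq[p - 1] for p in pos]
    if strand == "-":
        bases = [complement(b) for b in bases]
    return SpliceSiteWindow(kind, transcript_id, chromosome, strand,
                            "".join(bases), tuple(pos), tuple(labels))


def extract_windows(
    bundle: ReferenceBundle,
    novel_exons=None,
) -> list[SpliceSiteWindow]:
    """Donor and acceptor windows for every annotated intron, strand-aware.

    Windows whose intronic span does not fit in the intron are skipped.
    ``novel_exons`` (optional ExonCandidate list) contribute windows for
    their flanking junction boundaries using the host transcript's strand.
    """
    out = []

    def add(kind, tid, chrom, strand, intron, seq):
        w = make_window(kind, tid, chrom, strand, intron, seq)
        if w is not None:
            out.append(w)

    for t in bundle.gene_models:
        seq = bundle.chromosomes[t.chromosome]
        for intron in t.introns:
            # donor sits at the transcript-strand start of the intron,
            # acceptor at its end; _window_positions handles orientation
            add("donor", t.id, t.chromosome, t.strand, intron, seq)
            add("acceptor", t.id, t.chromosome, t.strand, intron, seq)
    for cand in novel_exons or []:
        host = next(
            (t for t in bundle.gene_models
             if t.chromosome == cand.chromosome
             and t.start <= cand.start <= t.end), None
        )
        strand = host.strand if host else "+"
        tid = host.id if host else "novel"
        seq = bundle.chromosomes[cand.chromosome]
        # treat the candidate's bounding junction gaps as its introns
        up = (max(1, cand.start - 400), cand.start - 1)
        dn = (cand.end + 1, min(len(seq), cand.end + 400))
        if strand == "+":
            add("acceptor", tid, cand.chromosome, strand, up, seq)
            add("donor", tid, cand.chromosome, strand, dn, seq)
        else:
            add("acceptor", tid, cand.chromosome, strand, dn, seq)
            add("donor", tid, cand.chromosome, strand, up, seq)
    return out


def map_edit_positions(
    sites: list[EditingSite], windows: list[SpliceSiteWindow]
) -> list[tuple[EditingSite, SpliceSiteWindow, str]]:
    """Editing sites falling inside splice-site windows, with offset label.

    Labels are prefixed by the site kind: a site at the acceptor's -2
    intronic position becomes ``3'ss.2i``.
    """
    by_pos: dict[tuple[str, int], list[SpliceSiteWindow]] = {}
    for w in windows:
        for p in w.positions:
            by_pos.setdefault((w.chromosome, p), []).append(w)
    prefix = {"donor": "5'ss", "acceptor": "3'ss"}
    out = []
    for s in sites:
        for w in by_pos.get((s.chromosome, s.position), []):
            if w.strand != s.strand:
                continue
            label = f"{prefix[w.kind]}.{w.label_at(s.position)}"
            out.append((s, w, label))
            break  # one label per site
    return out


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


class PwmScorer:
    """Per-position log-odds splice-site model trained on observed windows.

    score(seq) = sum_i log2(p_i(base) / 0.25), with 0.5 pseudocounts.
    Train one scorer per window kind.
    """

    def __init__(self, sequences: list[str], pseudocount: float = 0.5):
        if not sequences:
            raise ValueError("no training windows")
        length = len(sequences[0])
        if any(len(s) != length for s in sequences):
            raise ValueError("training windows differ in length")
        self.length = length
        n = len(sequences)
        self.logp = []
        for i in range(length):
            col = {}
            for b in "ACGT":
                k = sum(1 for s in sequences if s[i] == b)
                col[b] = math.log2((k + pseudocount) / (n + 4 * pseudocount) / 0.25)
            self.logp.append(col)

    def score(self, seq: str) -> float:
        if len(seq) != self.length:
            raise ValueError("sequence length does not match the model")
        return sum(self.logp[i][b] for i, b in enumerate(seq))


def train_scorers(windows: list[SpliceSiteWindow]) -> dict[str, PwmScorer]:
    """One PWM scorer per window kind from annotation-derived windows."""
    return {
        kind: PwmScorer([w.sequence for w in windows if w.kind == kind])
        for kind in ("donor", "acceptor")
        if any(w.kind == kind for w in windows)
    }


@dataclass(frozen=True)
class SpliceEditImpact:
    """Score change caused by an A->G edit at one window offset."""

    chromosome: str
    position: int
    strand: str
    kind: str
    transcript_id: str
    offset_label: str
    score_ref: float
    score_edited: float

    @property
    def delta(self) -> float:
        return self.score_edited - self.score_ref


def score_delta(
    window: SpliceSiteWindow, offset_label: str, model,
    site: EditingSite | None = None,
) -> SpliceEditImpact:
    """Impact of editing the A at ``offset_label`` (e.g. "2i") to G.

    Raises ``ValueError`` when the window base at that offset is not an A
    on the window strand.
    """
    label = offset_label.split(".")[-1]
    i = window.labels.index(label)
    if window.sequence[i] != "A":
        raise ValueError(
            f"window base at {offset_label} is {window.sequence[i]}, not A"
        )
    edited = window.sequence[:i] + "G" + window.sequence[i + 1:]
    ref_score = model.score(window.sequence)
    ed_score = model.score(edited)
    return SpliceEditImpact(
        chromosome=window.chromosome,
        position=site.position if site else window.position_of(label),
        strand=window.strand, kind=window.kind,
        transcript_id=window.transcript_id,
        offset_label=offset_label if "." in offset_label
        else f"{'5' if window.kind == 'donor' else '3'}'ss.{label}",
        score_ref=ref_score, score_edited=ed_score,
    )


# ---------------------------------------------------------------------------
# direction concordance
# ---------------------------------------------------------------------------

#: Expected sign of PSI(KD) - PSI(Ctrl) when an acceptor-2i edit is lost
#: upon ADAR knockdown.  SE: the unedited AG is restored, inclusion rises.
#: A3SS (PSI = usage of the edited-form acceptor): usage shifts back to the
#: original acceptor, so the edited-form PSI falls.  RI: retention falls.
#: Complex events have no expected direction and are excluded.
EXPECTED_DPSI_SIGN = {
    "SE": +1,
    "A3SS-short": -1,
    "A3SS-long": -1,
    "RI": -1,
    "Complex": None,
}


def direction_concordance(
    events: list[SpliceEvent],
    kd: str = "KD",
    ctrl: str = "Ctrl",
) -> tuple[float | None, pd.DataFrame]:
    """Fraction of evaluable events whose PSI change matches expectation.

    Evaluable events have a single AS type with a defined expected sign
    and a defined, nonzero delta-PSI.  Returns (fraction, per-event table);
    the fraction is ``None`` when nothing is evaluable.
    """
    rows = []
    for ev in events:
        dpsi = ev.delta_psi(kd, ctrl)
        expected = EXPECTED_DPSI_SIGN.get(ev.as_type)
        evaluable = expected is not None and dpsi is not None and dpsi != 0
        concordant = None
        if evaluable:
            concordant = (dpsi > 0) == (expected > 0)
        rows.append(
            {"event_id": ev.event_id, "as_type": ev.as_type,
             "delta_psi": dpsi, "expected_sign": expected,
             "evaluable": evaluable, "concordant": concordant}
        )
    df = pd.DataFrame(rows)
    n_eval = int(df.evaluable.sum()) if len(df) else 0
    frac = float(df.loc[df.evaluable, "concordant"].mean()) if n_eval else None
    return frac, df
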