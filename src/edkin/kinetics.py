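"""Kinetic classification of editing sites across ordered fractions.

A site's per-fraction status is *edited* (>=1 edited-G read), *unedited*
(no G reads at coverage >= k) or *undetermined* (no G reads, coverage
< k).  Sites are assigned to kinetic group g when they are first edited in
fraction g, confidently unedited before it, and never confidently
unedited after it; otherwise they are excluded as coverage-ambiguous
(undetermined before the first edited fraction) or as reversals (unedited
after edited).  With four fractions a catalogued site -- one edited
somewhere -- can fall into 3^4 - 2^4 = 65 status categories.

Two coverage thresholds are used: k=20 when calling a fraction unedited in
general, and k=5 for the fractions after a group-1 site's first edited
fraction.  The lower k makes it *easier* to call those later fractions
unedited and hence to expel a site from group 1, so the group-1 count is a
conservative (under-)estimate; raising k toward 20 can only grow group 1.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .caller import EditingSite

EDITED = "edited"
UNEDITED = "unedited"
UNDETERMINED = "undetermined"

COVERAGE_AMBIGUOUS = "coverage_ambiguous"
REVERSAL = "reversal"

DEFAULT_K = 20
DEFAULT_K_GROUP1 = 5


def fraction_status(g_count: int, coverage: int, k: int) -> str:
    """Status of a site in one fraction at unedited-coverage threshold k."""
    if g_count < 0 or coverage < 0 or k < 1:
        raise ValueError("counts must be non-negative and k >= 1")
    if g_count > coverage:
        raise ValueError("g_count cannot exceed coverage")
    if g_count >= 1:
        return EDITED
    return UNEDITED if coverage >= k else UNDETERMINED


def enumerate_categories(n_fractions: int) -> set[tuple[str, ...]]:
    """All status tuples a catalogued site can occupy.

    A site enters the catalog only if it is edited in at least one
    fraction, so the count is 3**n - 2**n (tuples over three statuses
    minus the all-unedited/undetermined ones).
    """
    if n_fractions < 1:
        raise ValueError("need at least one fraction")
    return {
        t
        for t in itertools.product((EDITED, UNEDITED, UNDETERMINED),
                                   repeat=n_fractions)
        if EDITED in t
    }


@dataclass(frozen=True)
class KineticCall:
    """Group assignment (1-based fraction index of first editing) or an
    exclusion reason, with the per-fraction statuses used."""

    group: int | None
    exclusion_reason: str | None
    statuses: tuple[str, ...]
    er: tuple[float | None, ...]
    mz: float | None = None

    def __post_init__(self):
        if (self.group is None) == (self.exclusion_reason is None):
            raise ValueError("exactly one of group/exclusion must be set")


def assign_group(
    counts: list[tuple[int, int]],
    k_group1: int = DEFAULT_K_GROUP1,
    k_other: int = DEFAULT_K,
) -> KineticCall:
    """Classify one site from per-fraction (g_count, coverage), ordered by
    maturation.

    The first edited fraction proposes the group.  Earlier fractions must
    be confidently unedited at k_other; an undetermined earlier fraction
    makes the site coverage-ambiguous.  Later fractions must never be
    confidently unedited, judged at k_group1 for group-1 candidates and at
    k_other otherwise; a confident unedited after editing is a reversal.

    Returns ``None`` for a site never edited anywhere (such sites are not
    catalogued).
    """
    n = len(counts)
    if n < 1:
        raise ValueError("need at least one fraction")
    first_edited = next(
        (i for i, (g, _) in enumerate(counts) if g >= 1), None
    )
    if first_edited is None:
        return None
    k_later = k_group1 if first_edited == 0 else k_other
    statuses = []
    for i, (g, cov) in enumerate(counts):
        k = k_other if i <= first_edited else k_later
        statuses.append(fraction_status(g, cov, k))
    statuses = tuple(statuses)
    er = tuple(g / cov if cov else None for g, cov in counts)

    for i in range(first_edited):
        if statuses[i] == UNDETERMINED:
            return KineticCall(None, COVERAGE_AMBIGUOUS, statuses, er)
    for i in range(first_edited + 1, n):
        if statuses[i] == UNEDITED:
            return KineticCall(None, REVERSAL, statuses, er)
    ers = [e for e in er if e is not None]
    mz = mz_score(ers) if len(ers) == n and n >= 2 else None
    return KineticCall(first_edited + 1, None, statuses, er, mz)


def editing_ratio(g_count: int, coverage: int) -> float:
    """Fraction of reads carrying the edited G."""
    if coverage < 1:
        raise ValueError("editing ratio undefined at zero coverage")
    if not 0 <= g_count <= coverage:
        raise ValueError("need 0 <= g_count <= coverage")
    return g_count / coverage


def mz_score(er: list[float]) -> float | None:
    """Monotonicity z-score of an editing-ratio trajectory.

    Sum of the signs of consecutive differences divided by sqrt of the
    number of pairs: +sqrt(3) for a strictly increasing four-fraction
    trajectory, -sqrt(3) for strictly decreasing.  Undefined (``None``)
    when any two consecutive fractions are tied.
    """
    if len(er) < 2:
        raise ValueError("need at least two fractions")
    diffs = [b - a for a, b in zip(er, er[1:])]
    if any(d == 0 for d in diffs):
        return None
    return sum(1 if d > 0 else -1 for d in diffs) / math.sqrt(len(diffs))


def classify_sites(
    sites: list[EditingSite],
    fraction_order: list[str],
    k_group1: int = DEFAULT_K_GROUP1,
    k_other: int = DEFAULT_K,
) -> pd.DataFrame:
    """Kinetic calls for a site list; one row per site.

    Rows carry the group or exclusion reason, per-fraction status and ER,
    and the MZ score where defined.
    """
    rows = []
    for s in sites:
        counts = [s.g_cov.get(f, (0, 0)) for f in fraction_order]
        call = assign_group(counts, k_group1=k_group1, k_other=k_other)
        if call is None:
            continue
        row = {
            "chromosome": s.chromosome,
            "position": s.position,
            "strand": s.strand,
            "group": call.group,
            "exclusion_reason": call.exclusion_reason,
            "mz": call.mz,
            "context": s.context,
            "repeat_class": s.repeat_class,
            "nearest_site_distance": s.nearest_site_distance,
        }
        for f, st, e in zip(fraction_order, call.statuses, call.er):
            row[f"status_{f}"] = st
            row[f"er_{f}"] = e
        rows.append(row)
    return pd.DataFrame(rows)


def labelled_kinetics(
    counts_4su: tuple[int, int],
    counts_total: tuple[int, int],
    alpha: float = 0.05,
) -> str:
    """Kinetic class from metabolically labelled (4sU) vs total RNA counts.

    *early*: edited in both samples with no significant editing-ratio
    change (two-sided Fisher exact p > alpha); *intermediate*: edited in
    both with a significant increase in total RNA; *late*: unedited in the
    labelled sample but edited in total RNA; otherwise *unclassified*.
    """
    g1, c1 = counts_4su
    g2, c2 = counts_total
    if not (0 <= g1 <= c1 and 0 <= g2 <= c2):
        raise ValueError("invalid counts")
    er1 = g1 / c1 if c1 else 0.0
    er2 = g2 / c2 if c2 else 0.0
    if er1 == 0 and er2 > 0:
        return "late"
    if er1 > 0 and er2 > 0:
        _, p = stats.fisher_exact([[g1, c1 - g1], [g2, c2 - g2]])
        if p > alpha:
            return "early"
        if er2 > er1:
            return "intermediate"
    return "unclassified"


def context_enrichment(
    site_positions: list[tuple[str, int, str]],
    control_positions: list[tuple[str, int, str]],
    chromosomes: dict[str, str],
    half_window: int = 3,
) -> pd.DataFrame:
    """Per-offset base enrichment around editing sites vs control As.

    For each offset in [-half_window, +half_window] (transcript-strand
    orientation; the site itself is offset 0) and each base, reports the
    log2 ratio of base frequency in site neighbourhoods over control
    neighbourhoods (Haldane-corrected) and a two-proportion z statistic.
    Controls should be reference As drawn from the same genomic context
    class as the sites.
    """
    from .synthetic import revcomp

    if not control_positions:
        raise ValueError("empty control set")
    if half_window < 1:
        raise ValueError("half_window must be >= 1")

    def neighbourhoods(positions):
        seqs = []
        for chrom, pos, strand in positions:
            seq = chromosomes[chrom]
            lo, hi = pos - half_window, pos + half_window
            if lo < 1 or hi > len(seq):
                continue
            window = seq[lo - 1:hi]
            seqs.append(window if strand == "+" else revcomp(window))
        return seqs

    site_seqs = neighbourhoods(site_positions)
    ctrl_seqs = neighbourhoods(control_positions)
    w = 2 * half_window + 1
    rows = []
    for off in range(-half_window, half_window + 1):
        i = off + half_window
        for base in "ACGT":
            ks = sum(1 for s in site_seqs if s[i] == base)
            kc = sum(1 for s in ctrl_seqs if s[i] == base)
            ns, nc = len(site_seqs), len(ctrl_seqs)
            # common frequency floor so that zero counts on both sides give
            # zero enrichment regardless of the two sample sizes
            eps = 0.5 / (max(ns, nc) + 1)
            fs = max(ks / ns, eps)
            fc = max(kc / nc, eps)
            log2_ratio = math.log2(fs / fc)
            pooled = (ks + kc) / (ns + nc)
            se = math.sqrt(pooled * (1 - pooled) * (1 / ns + 1 / nc))
            z = ((ks / ns) - (kc / nc)) / se if se > 0 else 0.0
            rows.append(
                {"offset": off, "base": base, "site_freq": ks / ns,
                 "control_freq": kc / nc, "log2_enrichment": log2_ratio,
                 "z": z}
            )
    return pd.DataFrame(rows)
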