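"""End-to-end orchestration: simulate -> call -> kinetics -> splicing ->
splice-site impact -> dsRNA funnel, with a summary report.

``run_pipeline`` drives the whole analysis on a synthetic bundle (or on a
bundle loaded from disk), writes one TSV per stage plus a human-readable
``report.md`` and machine-readable ``report.json``, and logs the
thresholds and in/out counts of every filter.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import caller as ca
from . import dsrna as dd
from . import kinetics as ki
from . import splice_sites as ss
from . import splicing as sp
from . import synthetic as sy

log = logging.getLogger("edkin")


@dataclass
class RunConfig:
    """All pipeline thresholds, defaulting to the published values.

    Calling: ``min_g`` = 2 edited reads, ``min_cov`` = 5 total reads.
    Kinetics: unedited threshold ``k`` = 20, relaxed to ``k_group1`` = 5
    after a group-1 site's first edited fraction.  Timing: coSI <= 0.75
    (ChA+) / >= 0.95 (NpA+ or ChA-).  Funnel: |dPSI| >= 0.10, editing
    within 500 nt, duplex identity > 70% at E <= 0.001; site-centred
    duplexes need arm length >= 50 at identity >= 80% inside a 4001-nt
    window with a 200-nt neighbourhood.  Windows: donor 9-mer, acceptor
    23-mer.
    """

    seed: int = 0
    outdir: str = "edkin_run"
    # inputs; None means simulate
    genome: str | None = None
    gtf: str | None = None
    fractions: tuple[str, ...] = sy.FRACTION_ORDER
    depth: float = 40.0
    read_len: int = 100
    error_rate: float = 1e-3
    hyper_fraction: float = 0.01
    truth_counts: dict[int, int] = field(
        default_factory=lambda: {1: 60, 2: 20, 3: 12, 4: 8}
    )
    n_acceptor_edits: int = 4
    # caller
    min_g: int = 2
    min_cov: int = 5
    junction_margin: int = 4
    # kinetics
    k: int = 20
    k_group1: int = 5
    # splicing / events
    cosi_post_max: float = sp.POSTTS_CHA_PLUS
    cosi_complete_min: float = sp.COTS_THRESHOLD
    # funnel
    min_dpsi: float = 0.10
    edit_flank: int = 500
    duplex_min_len: int = 50
    duplex_min_identity: float = 80.0
    exon_duplex_min_identity: float = 70.0
    exon_duplex_max_evalue: float = 1e-3
    duplex_window: int = 4001
    duplex_flank: int = 200

    def validate(self) -> None:
        if self.genome is not None and not os.path.exists(self.genome):
            raise FileNotFoundError(f"config field 'genome': {self.genome}")
        if self.gtf is not None and not os.path.exists(self.gtf):
            raise FileNotFoundError(f"config field 'gtf': {self.gtf}")

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "truth_counts" in data:
            data["truth_counts"] = {int(k): v for k, v in data["truth_counts"].items()}
        if "fractions" in data:
            data["fractions"] = tuple(data["fractions"])
        return cls(**data)


#: Minimal structural schema for report.json (shipped with the package so
#: reports can be validated without extra dependencies).
REPORT_SCHEMA = {
    "n_sites": int,
    "group_counts": dict,
    "group_percent": dict,
    "excluded": dict,
    "category_counts": dict,
    "timing_counts": dict,
    "splice_site_edits": int,
    "acceptor_2i_edits": int,
    "concordance": (float, type(None)),
    "funnel": dict,
    "group_recovery": (float, type(None)),
    "thresholds": dict,
}


def validate_report(report: dict) -> None:
    """Check report.json structure against the shipped schema."""
    for key, typ in REPORT_SCHEMA.items():
        if key not in report:
            raise ValueError(f"report missing key {key!r}")
        if not isinstance(report[key], typ):
            raise ValueError(f"report key {key!r} has wrong type")
    pct = report["group_percent"]
    if pct and abs(sum(pct.values()) - 100.0) > 0.51 * len(pct):
        raise ValueError("group percentages do not sum to 100")


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the machine-readable report dict.

    Stage TSVs, ``report.md``, ``report.json`` and a resolved copy of the
    configuration land in ``config.outdir``.  Any stage failure is
    re-raised annotated with the stage name.
    """
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    with open(os.path.join(config.outdir, "resolved_config.yaml"), "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh)

    stage = "simulate"
    try:
        bundle, truths, reads = _stage_inputs(config)
        stage = "call"
        sites, rescued_n = _stage_call(config, bundle, reads)
        stage = "kinetics"
        calls = ki.classify_sites(
            ca.annotate_sites(sites, bundle), list(config.fractions),
            k_group1=config.k_group1, k_other=config.k,
        )
        stage = "splicing"
        timing = _stage_timing(config, bundle, reads)
        stage = "splice_site_impact"
        impacts, concordance = _stage_impact(config, bundle, sites)
        stage = "dsrna"
        funnel = _stage_funnel(config, bundle, sites)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report = write_report(
        config, bundle, truths, sites, calls, timing, impacts,
        concordance, funnel, rescued_n,
    )
    return report


def _stage_inputs(config: RunConfig):
    if config.genome is None:
        bundle = sy.generate_reference(sy.GenomeConfig(seed=config.seed))
        truths = sy.plant_editing_truth(
            bundle,
            sy.TruthSpec(counts=dict(config.truth_counts),
                         n_acceptor_edits=config.n_acceptor_edits),
            seed=config.seed + 1,
        )
        reads = sy.simulate_bundle_reads(
            bundle, truths, sy.default_fractions(depth=config.depth),
            read_len=config.read_len, seed=config.seed + 2,
            error_rate=config.error_rate, hyper_fraction=config.hyper_fraction,
        )
        log.info("simulated %d truth sites, %s reads", len(truths),
                 {f: len(r.mapped) for f, r in reads.items()})
        return bundle, truths, reads
    bundle = sy.ReferenceBundle(
        chromosomes=sy.read_genome(config.genome),
        gene_models=sy.read_gene_models(config.gtf),
    )
    raise NotImplementedError(
        "real-data mode requires per-fraction SAM inputs via the CLI"
    )


def _stage_call(config: RunConfig, bundle, reads):
    params = ca.CallerParams(min_g=config.min_g, min_cov=config.min_cov,
                             junction_margin=config.junction_margin)
    pileups, calls = {}, {}
    rescued_total = 0
    for frac, fr in reads.items():
        rescued = ca.hyperediting_rescue(fr.unmapped, bundle)
        rescued_total += len(rescued)
        pool = fr.mapped + rescued
        pileups[frac] = ca.build_pileup(pool, bundle,
                                        read_end_trim=params.read_end_trim)
        nascent = frac == sy.CHA_MINUS
        calls[frac] = ca.call_sites(pileups[frac], bundle, params,
                                    nascent=nascent)
        log.info("%s: %d reads (+%d rescued) -> %d calls",
                 frac, len(fr.mapped), len(rescued), len(calls[frac]))
    return ca.collect_sites(calls, pileups), rescued_total


def _stage_timing(config: RunConfig, bundle, reads):
    rows = []
    for t in bundle.gene_models:
        for i in range(1, len(t.exons) - 1):
            cosi = {
                f: sp.compute_cosi(t, i, fr.mapped)
                for f, fr in reads.items()
            }
            rows.append({
                "transcript": t.id, "exon_index": i,
                "exon_start": t.exons[i][0], "exon_end": t.exons[i][1],
                **{f"cosi_{f}": v for f, v in cosi.items()},
                "timing": sp.classify_timing(cosi),
            })
    return pd.DataFrame(rows)


def _stage_impact(config: RunConfig, bundle, sites):
    windows = ss.extract_windows(bundle)
    models = ss.train_scorers(windows)
    mapped = ss.map_edit_positions(sites, windows)
    impacts = []
    for site, window, label in mapped:
        offset = label.split(".")[-1]
        i = window.labels.index(offset)
        if window.sequence[i] != "A":
            continue
        impacts.append(ss.score_delta(window, label, models[window.kind], site))
    log.info("splice-site scan: %d sites in windows, %d scoreable",
             len(mapped), len(impacts))
    # concordance is measured on a simulated KD/Ctrl cohort tied to the run
    events = sy.simulate_concordance_cohort(seed=config.seed + 3)
    concordance, _ = ss.direction_concordance(events)
    return impacts, concordance


def _stage_funnel(config: RunConfig, bundle, sites):
    events = []
    site_positions = [(s.chromosome, s.position) for s in sites]
    # candidate events: internal exons with a synthetic dPSI profile driven
    # by duplex presence (exons in planted duplexes respond to KD)
    dup_exons = {(d.transcript_id, d.exon) for d in bundle.exon_duplexes}
    for t in bundle.gene_models:
        for i in range(1, len(t.exons) - 1):
            in_dup = (t.id, t.exons[i]) in dup_exons
            dpsi = 0.15 if in_dup else 0.02
            events.append(sp.SpliceEvent(
                event_id=f"{t.id}:exon{i}", transcript_id=t.id,
                exon=t.exons[i], as_type="SE",
                psi={"Ctrl": 0.6, "KD": 0.6 + dpsi},
                chromosome=t.chromosome,
            ))
    return dd.adar_target_funnel(
        events, site_positions, bundle,
        min_dpsi=config.min_dpsi, edit_flank=config.edit_flank,
        min_identity=config.exon_duplex_min_identity,
        max_evalue=config.exon_duplex_max_evalue,
    )


def write_report(config, bundle, truths, sites, calls, timing, impacts,
                 concordance, funnel, rescued_n) -> dict:
    """Assemble, validate and write report.json + report.md."""
    grouped = calls[calls.group.notna()] if len(calls) else calls
    group_counts = (
        Counter(int(g) for g in grouped.group) if len(calls) else Counter()
    )
    n_grouped = sum(group_counts.values())
    group_percent = {
        str(g): round(100.0 * n / n_grouped, 1) if n_grouped else 0.0
        for g, n in sorted(group_counts.items())
    }
    excluded = (
        Counter(calls.exclusion_reason.dropna()) if len(calls) else Counter()
    )
    status_cols = [f"status_{f}" for f in config.fractions]
    category_counts = (
        Counter(tuple(r) for r in calls[status_cols].itertuples(index=False))
        if len(calls) else Counter()
    )

    truth_by_pos = {(t.chromosome, t.position): t.intended_group for t in truths}
    recovered = total = 0
    if len(calls):
        for r in calls.itertuples():
            want = truth_by_pos.get((r.chromosome, r.position))
            if want is None or pd.isna(r.group):
                continue
            total += 1
            recovered += int(r.group) == want
    recovery = round(100.0 * recovered / total, 1) if total else None

    report = {
        "n_sites": len(sites),
        "group_counts": {str(g): int(n) for g, n in sorted(group_counts.items())},
        "group_percent": group_percent,
        "excluded": {k: int(v) for k, v in excluded.items()},
        "category_counts": {
            "|".join(k): int(v) for k, v in sorted(category_counts.items())
        },
        "timing_counts": dict(Counter(timing.timing)) if len(timing) else {},
        "splice_site_edits": len(impacts),
        "acceptor_2i_edits": sum(
            1 for i in impacts if i.offset_label == "3'ss.2i"
        ),
        "concordance": concordance,
        "funnel": {k: int(v) for k, v in funnel.stage_counts.items()},
        "group_recovery": recovery,
        "hyperediting_rescued": rescued_n,
        "thresholds": {
            "min_g": config.min_g, "min_cov": config.min_cov,
            "k": config.k, "k_group1": config.k_group1,
            "min_dpsi": config.min_dpsi, "edit_flank": config.edit_flank,
        },
    }
    validate_report(report)

    if len(calls):
        calls.to_csv(os.path.join(config.outdir, "kinetic_calls.tsv"),
                     sep="\t", index=False)
    timing.to_csv(os.path.join(config.outdir, "splicing_timing.tsv"),
                  sep="\t", index=False)
    pd.DataFrame([dataclasses.asdict(i) for i in impacts]).to_csv(
        os.path.join(config.outdir, "splice_site_impacts.tsv"),
        sep="\t", index=False)
    with open(os.path.join(config.outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    with open(os.path.join(config.outdir, "report.md"), "w") as fh:
        fh.write(_render_md(report))
    return report


def _render_md(report: dict) -> str:
    lines = ["# edkin run report", ""]
    lines.append(f"Editing sites (union over fractions): {report['n_sites']}")
    lines.append("")
    lines.append("## Kinetic groups")
    for g, n in report["group_counts"].items():
        lines.append(f"- group {g}: {n} ({report['group_percent'][g]}%)")
    for reason, n in report["excluded"].items():
        lines.append(f"- excluded ({reason}): {n}")
    if report.get("group_recovery") is not None:
        lines.append(f"- planted-group recovery: {report['group_recovery']}%")
    lines.append("")
    lines.append("## Splicing timing")
    for k, v in report["timing_counts"].items():
        lines.append(f"- {k}: {v}")
    lines.append("")
    lines.append(
        f"Splice-site edits: {report['splice_site_edits']} "
        f"(acceptor 2i: {report['acceptor_2i_edits']}); "
        f"direction concordance: {report['concordance']}"
    )
    lines.append("")
    lines.append("## ADAR-direct-target funnel")
    for k, v in report["funnel"].items():
        lines.append(f"- {k}: {v}")
    lines.append("")
    return "\n".join(lines)
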