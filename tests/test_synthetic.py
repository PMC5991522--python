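"""Generator contracts: determinism, planted structure, sampling rates,
and lossless round trips through the on-disk formats."""

import math

import numpy as np
import pytest

from edkin import synthetic as sy


def _hamming_identity(a: str, b: str) -> float:
    assert len(a) == len(b)
    return sum(x == y for x, y in zip(a, b)) / len(a)


class TestGenerateReference:
    def test_deterministic_for_fixed_seed(self):
        cfg = sy.GenomeConfig(seed=1)
        b1, b2 = sy.generate_reference(cfg), sy.generate_reference(cfg)
        assert b1.chromosomes == b2.chromosomes
        assert b1.gene_models == b2.gene_models
        assert b1.repeats == b2.repeats and b1.snps == b2.snps

    def test_planted_inverted_repeat_identity(self, bundle):
        # direct string-comparison oracle on the two arms
        ir = bundle.inverted_repeats[0]
        seq = bundle.chromosomes[ir.chromosome]
        a1 = seq[ir.arm1[0] - 1:ir.arm1[1]]
        a2 = seq[ir.arm2[0] - 1:ir.arm2[1]]
        assert ir.arm1[1] - ir.arm1[0] + 1 >= 50
        assert _hamming_identity(sy.revcomp(a1), a2) >= 0.80

    def test_acceptor_editable_A_context_exists(self, bundle):
        # at least one plus-strand acceptor reads ...AAG at the 3'ss
        found = False
        for t in bundle.gene_models:
            if t.strand != "+":
                continue
            for (_, iend) in t.introns:
                if bundle.chromosomes[t.chromosome][iend - 3:iend] == "AAG":
                    found = True
        assert found

    def test_transcript_invariants(self, bundle):
        for t in bundle.gene_models:
            assert len(t.exons) >= 1
            for (s1, e1), (s2, _) in zip(t.exons, t.exons[1:]):
                assert s2 - e1 - 1 >= 30
            assert t.end <= len(bundle.chromosomes[t.chromosome])

    def test_short_intron_config_rejected(self):
        with pytest.raises(ValueError, match="30"):
            sy.generate_reference(sy.GenomeConfig(seed=1, intron_min=10,
                                                  intron_length=(10, 20)))


class TestPlantEditingTruth:
    def test_group_profiles_respect_invariant(self, truths):
        for t in truths:
            g = t.intended_group
            assert all(e == 0 for e in t.er[:g - 1])
            assert all(e > 0 for e in t.er[g - 1:])

    def test_group4_only_edited_in_last_fraction(self, truths):
        for t in truths:
            if t.intended_group == 4:
                assert t.er[:3] == (0.0, 0.0, 0.0) and t.er[3] > 0

    def test_invalid_profile_rejected(self):
        with pytest.raises(ValueError):
            sy.KineticTruth("chr1", 100, "+", 2, (0.1, 0.2, 0.3, 0.4))
        with pytest.raises(ValueError):
            sy.KineticTruth("chr1", 100, "+", 3, (0.0, 0.0, 0.0, 0.3))

    def test_sites_land_on_transcript_strand_A(self, bundle, truths):
        for t in truths:
            base = bundle.base(t.chromosome, t.position)
            assert base == ("A" if t.strand == "+" else "T")

    def test_too_many_sites_rejected(self, bundle):
        with pytest.raises(ValueError, match="available A positions"):
            sy.plant_editing_truth(
                bundle, sy.TruthSpec(counts={1: 10 ** 6}), seed=0
            )


class TestSimulateFractionAlignments:
    def test_zero_er_zero_errors_gives_no_G(self, bundle):
        truth = sy.KineticTruth(
            bundle.gene_models[0].chromosome,
            _an_exonic_A(bundle, bundle.gene_models[0]),
            bundle.gene_models[0].strand, 2, (0.0, 0.5, 0.5, 0.5),
        )
        fr = sy.simulate_fraction_alignments(
            bundle, [truth], sy.default_fractions(depth=30)[0],
            seed=5, error_rate=0.0,
        )
        g, cov = _site_counts(fr.mapped, truth)
        assert cov > 0 and g == 0

    def test_er_converges_binomially(self, bundle):
        """Observed G fraction is within 3 binomial sigma of the truth ER."""
        t0 = bundle.gene_models[0]
        truth = sy.KineticTruth(t0.chromosome, _an_exonic_A(bundle, t0),
                                t0.strand, 1, (0.5, 0.5, 0.5, 0.5))
        fr = sy.simulate_fraction_alignments(
            bundle, [truth], sy.default_fractions(depth=200)[0],
            seed=6, error_rate=0.0,
        )
        g, cov = _site_counts(fr.mapped, truth)
        assert cov >= 100
        assert abs(g / cov - 0.5) < 3 * math.sqrt(0.25 / cov)

    def test_complete_splicing_means_no_boundary_reads(self, bundle):
        fr = sy.simulate_fraction_alignments(
            bundle, [], sy.FractionProfile("x", 0, 1.0, depth=30),
            seed=7, error_rate=0.0,
        )
        for t in bundle.gene_models:
            for (istart, iend) in t.introns:
                for b in (istart, iend + 1):
                    assert not any(
                        s <= b - 1 and e >= b
                        for r in fr.mapped if r.chromosome == t.chromosome
                        for s, e in r.blocks
                    )

    def test_boundary_read_rate_tracks_incompleteness(self, bundle):
        sc = 0.7
        fr = sy.simulate_fraction_alignments(
            bundle, [], sy.FractionProfile("x", 0, sc, depth=80),
            seed=8, error_rate=0.0,
        )
        t = bundle.gene_models[0]
        istart, iend = t.introns[0]
        spliced = sum(1 for r in fr.mapped
                      if (istart, iend) in r.junction_gaps())
        unspliced = sum(
            1 for r in fr.mapped if r.chromosome == t.chromosome
            and any(s <= istart - 1 and e >= istart for s, e in r.blocks)
        )
        frac = unspliced / (unspliced + spliced)
        sigma = math.sqrt(sc * (1 - sc) / (unspliced + spliced))
        assert abs(frac - (1 - sc)) < 4 * sigma

    def test_hyperedited_reads_in_separate_pool(self, bundle, fraction_reads):
        fr = fraction_reads[sy.CHA_MINUS]
        assert fr.unmapped, "expected hyperedited reads"
        for r in fr.unmapped:
            assert r.blocks == ()
        for r in fr.hyper_truth:  # each carries >=5 dense edits vs reference
            (s, e), = r.blocks
            ref = bundle.chromosomes[r.chromosome][s - 1:e]
            frm, to = ("A", "G") if r.strand == "+" else ("T", "C")
            edits = sum(1 for a, b in zip(ref, r.sequence)
                        if a == frm and b == to)
            assert edits >= 5
        assert {r.id for r in fr.unmapped} == {r.id for r in fr.hyper_truth}

    def test_depth_precondition(self, bundle):
        with pytest.raises(ValueError, match="depth"):
            sy.simulate_fraction_alignments(
                bundle, [], sy.FractionProfile("x", 0, 0.5, depth=0), seed=1
            )


class TestRoundTrip:
    def test_bundle_round_trips_losslessly(self, bundle, truths,
                                           fraction_reads, tmp_path):
        paths = sy.emit_bundle(bundle, fraction_reads, truths, str(tmp_path))
        assert sy.read_genome(paths["genome"]) == bundle.chromosomes
        assert sy.read_gene_models(paths["genes"]) == sorted(
            bundle.gene_models, key=lambda t: t.id
        )
        assert sy.read_repeats(paths["repeats"]) == bundle.repeats
        assert sy.read_snps(paths["snps"]) == bundle.snps
        assert sy.read_truth(paths["truth"]) == truths
        frac = sy.CHA_MINUS
        mapped, unmapped = sy.read_alignments(paths[f"sam:{frac}"])
        orig = fraction_reads[frac]
        assert mapped == orig.mapped
        assert [r.sequence for r in unmapped] == [
            r.sequence for r in orig.unmapped
        ]

    def test_missing_outdir_errors(self, bundle, truths):
        with pytest.raises(FileNotFoundError):
            sy.emit_bundle(bundle, {}, truths, "/nonexistent/dir/xyz")


def test_fraction_profile_defaults_are_maturation_ordered():
    profs = sy.default_fractions()
    idx = [p.order_index for p in profs]
    assert idx == sorted(idx) and len(set(idx)) == len(idx)
    scs = [p.splicing_completeness for p in profs]
    assert scs == sorted(scs)


# helpers ------------------------------------------------------------------


def _an_exonic_A(bundle, t):
    want = "A" if t.strand == "+" else "T"
    s, e = t.exons[1] if len(t.exons) >= 3 else t.exons[0]
    for p in range(s, e + 1):
        if bundle.base(t.chromosome, p) == want:
            return p
    raise AssertionError("no A in exon")


def _site_counts(reads, truth):
    g = cov = 0
    want_g = "G" if truth.strand == "+" else "C"
    for r in reads:
        if r.chromosome != truth.chromosome:
            continue
        off = 0
        for (s, e) in r.blocks:
            if s <= truth.position <= e:
                cov += 1
                g += r.sequence[off + truth.position - s] == want_g
            off += e - s + 1
    return g, cov
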