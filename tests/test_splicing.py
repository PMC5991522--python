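"""coSI and timing classes, novel-exon detection, PSI closed forms and
the knockdown/control delta-PSI convention."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edkin import splicing as sp
from edkin import synthetic as sy


class TestCosi:
    def test_closed_forms(self, bundle, fraction_reads):
        # synthetic junction/boundary counts via hand-built reads
        t = next(t for t in bundle.gene_models if len(t.exons) >= 3)
        up, dn = t.introns[0], t.introns[1]
        chrom = t.chromosome
        ref = bundle.chromosomes[chrom]

        def junc_read(intron, rid):
            s, e = intron
            blocks = ((s - 10, s - 1), (e + 1, e + 10))
            seq = ref[s - 11:s - 1] + ref[e:e + 10]
            return sy.AlignedRead(rid, chrom, t.strand, blocks, seq, "f")

        def boundary_read(b, rid):  # contiguous across boundary (b-1, b)
            blocks = ((b - 10, b + 9),)
            return sy.AlignedRead(rid, chrom, t.strand, blocks,
                                  ref[b - 11:b + 9], "f")

        spliced = [junc_read(up, f"s{i}") for i in range(6)]
        # 4 crossings at weight 1/2 each -> U = 2; coSI = 6/8
        unspliced = [boundary_read(up[0], "u0"), boundary_read(up[1] + 1, "u1"),
                     boundary_read(dn[0], "u2"), boundary_read(dn[1] + 1, "u3")]
        assert sp.compute_cosi(t, 1, spliced + unspliced, min_reads=2) == 0.75
        assert sp.compute_cosi(t, 1, spliced, min_reads=2) == 1.0
        assert sp.compute_cosi(t, 1, unspliced * 3, min_reads=2) == 0.0

    def test_min_evidence_returns_none(self, bundle):
        t = next(t for t in bundle.gene_models if len(t.exons) >= 3)
        assert sp.compute_cosi(t, 1, []) is None

    def test_terminal_exon_rejected(self, bundle):
        t = bundle.gene_models[0]
        with pytest.raises(ValueError, match="internal"):
            sp.compute_cosi(t, 0, [])

    @given(s=st.integers(0, 50), u=st.integers(0, 50), extra=st.integers(1, 10))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_monotone_in_spliced_reads(self, s, u, extra):
        def cosi(S, U):
            total = S + U
            return S / total if total >= 1 else None
        a, b = cosi(s, u), cosi(s + extra, u)
        if a is not None and b is not None:
            assert b >= a


class TestClassifyTiming:
    @pytest.mark.parametrize(
        "cosi,expected",
        [
            ({"ChA-": 0.97, "ChA+": 0.99, "NpA+": 1.0}, "coTS"),
            ({"ChA-": 0.3, "ChA+": 0.70, "NpA+": 0.96}, "postTS"),
            ({"ChA-": 0.3, "ChA+": 0.80, "NpA+": 0.96}, "other"),
            ({"ChA-": 0.3, "ChA+": 0.70, "NpA+": 0.90}, "other"),
            ({"ChA-": None, "ChA+": None, "NpA+": None}, "undefined"),
        ],
    )
    def test_threshold_rules(self, cosi, expected):
        assert sp.classify_timing(cosi) == expected

    def test_default_fractions_give_postts(self, bundle, fraction_reads):
        """With completeness (0.3, 0.6, 0.97, 1.0) internal exons are
        post-transcriptionally spliced in >=90% of cases."""
        results = []
        for t in bundle.gene_models:
            for i in range(1, len(t.exons) - 1):
                cosi = {f: sp.compute_cosi(t, i, fr.mapped)
                        for f, fr in fraction_reads.items()}
                results.append(sp.classify_timing(cosi))
        assert results
        assert results.count("postTS") / len(results) >= 0.9

    def test_high_nascent_completeness_gives_cots(self, bundle):
        profs = [sy.FractionProfile(n, i, s, depth=50, polya=(n != "ChA-"))
                 for i, (n, s) in enumerate(zip(sy.FRACTION_ORDER,
                                                (0.97, 0.99, 1.0, 1.0)))]
        reads = sy.simulate_bundle_reads(bundle, [], profs, seed=21,
                                         error_rate=0.0)
        results = []
        for t in bundle.gene_models:
            for i in range(1, len(t.exons) - 1):
                cosi = {f: sp.compute_cosi(t, i, fr.mapped)
                        for f, fr in reads.items()}
                results.append(sp.classify_timing(cosi))
        assert results.count("coTS") / len(results) >= 0.9


class TestNovelExons:
    def _exon_with_reads(self, bundle, n_left, n_right, n_cover):
        """Hand-build junction + coverage reads around an unannotated exon."""
        chrom = next(iter(bundle.chromosomes))
        ref = bundle.chromosomes[chrom]
        start, end = 30001, 30080  # intergenic in the fixture genome
        reads = []
        for i in range(n_left):
            blocks = ((start - 110, start - 101), (start, start + 9))
            seq = ref[start - 111:start - 101] + ref[start - 1:start + 9]
            reads.append(sy.AlignedRead(f"l{i}", chrom, "+", blocks, seq, "f"))
        for i in range(n_right):
            blocks = ((end - 9, end), (end + 101, end + 110))
            seq = ref[end - 10:end] + ref[end + 100:end + 110]
            reads.append(sy.AlignedRead(f"r{i}", chrom, "+", blocks, seq, "f"))
        for i in range(n_cover):
            blocks = ((start, end),)
            reads.append(sy.AlignedRead(f"c{i}", chrom, "+", blocks,
                                        ref[start - 1:end], "f"))
        return (chrom, start, end), reads

    def test_planted_novel_exon_reported(self, bundle):
        (chrom, start, end), reads = self._exon_with_reads(bundle, 3, 3, 12)
        cands = sp.detect_novel_exons(reads, bundle)
        match = [c for c in cands if (c.start, c.end) == (start, end)]
        assert len(match) == 1 and match[0].novel
        assert match[0].density >= 10

    def test_single_junction_read_insufficient(self, bundle):
        _, reads = self._exon_with_reads(bundle, 3, 1, 12)
        cands = sp.detect_novel_exons(reads, bundle)
        assert not [c for c in cands if c.end == 30080]

    def test_annotated_exon_flagged_known(self, bundle):
        t = next(t for t in bundle.gene_models if len(t.exons) >= 3)
        s, e = t.exons[1]
        chrom = t.chromosome
        ref = bundle.chromosomes[chrom]
        up, dn = t.introns[0], t.introns[1]
        reads = []
        for i in range(3):
            blocks = ((up[0] - 10, up[0] - 1), (s, s + 9))
            seq = ref[up[0] - 11:up[0] - 1] + ref[s - 1:s + 9]
            reads.append(sy.AlignedRead(f"l{i}", chrom, t.strand, blocks, seq, "f"))
            blocks = ((e - 9, e), (dn[1] + 1, dn[1] + 10))
            seq = ref[e - 10:e] + ref[dn[1]:dn[1] + 10]
            reads.append(sy.AlignedRead(f"r{i}", chrom, t.strand, blocks, seq, "f"))
        for i in range(15):
            reads.append(sy.AlignedRead(f"c{i}", chrom, t.strand,
                                        ((s, e),), ref[s - 1:e], "f"))
        cands = sp.detect_novel_exons(reads, bundle)
        match = [c for c in cands if (c.start, c.end) == (s, e)]
        assert match and not match[0].novel


class TestPsi:
    @pytest.mark.parametrize("i,e,psi", [(8, 4, 0.5), (10, 0, 1.0),
                                         (16, 4, 2 / 3)])
    def test_se_closed_forms(self, i, e, psi):
        assert sp.psi_se(i, e) == pytest.approx(psi)

    def test_coverage_rule(self):
        # total < 10 and exclusion < 2 -> undefined
        assert sp.psi_se(4, 1) is None
        assert sp.psi_se(0, 2) == 0.0   # rescued by the exclusion clause
        assert sp.psi_se(9, 1) == pytest.approx((4.5) / 5.5)

    @given(i=st.integers(0, 100), e=st.integers(0, 100),
           extra=st.integers(1, 20))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_monotone_in_inclusion(self, i, e, extra):
        a, b = sp.psi_se(i, e), sp.psi_se(i + extra, e)
        if a is not None and b is not None:
            assert b >= a

    def test_delta_psi_antisymmetric(self):
        ev = sp.SpliceEvent("e", "t", (1, 10), "SE",
                            {"Ctrl": 0.4, "KD": 0.55})
        assert ev.delta_psi("KD", "Ctrl") == pytest.approx(
            -ev.delta_psi("Ctrl", "KD"))

    def test_event_typing_se_and_skip_junction(self, bundle):
        t = next(x for x in bundle.gene_models if len(x.exons) >= 3
                 and x.strand == "+")
        chrom, ref = t.chromosome, bundle.chromosomes[t.chromosome]
        up, dn = t.introns[0], t.introns[1]
        s, e = t.exons[1]

        def jread(gap, rid):
            blocks = ((gap[0] - 10, gap[0] - 1), (gap[1] + 1, gap[1] + 10))
            seq = ref[gap[0] - 11:gap[0] - 1] + ref[gap[1]:gap[1] + 10]
            return sy.AlignedRead(rid, chrom, t.strand, blocks, seq, "f")

        incl = [jread(up, f"i{k}") for k in range(5)] + \
               [jread(dn, f"j{k}") for k in range(5)]
        skip = [jread((up[0], dn[1]), f"s{k}") for k in range(5)]
        ev = sp.compute_psi_event(t, 1, {"Ctrl": incl + skip, "KD": incl})
        assert ev.as_type == "SE"
        assert ev.psi["Ctrl"] == pytest.approx(5 / (5 + 5))
        assert ev.psi["KD"] == pytest.approx(1.0)
        assert ev.delta_psi() == pytest.approx(0.5)
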