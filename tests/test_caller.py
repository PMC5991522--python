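"""Editing-site caller: pileup counting, support filters, the nascent
junction exception, hyperediting rescue, and site annotation."""

import pytest

from edkin import caller as ca
from edkin import synthetic as sy


def _read(chrom, blocks, seq, strand="+", frac="ChA-", rid="r"):
    return sy.AlignedRead(rid, chrom, strand, tuple(blocks), seq, frac)


@pytest.fixture(scope="module")
def tiny_bundle():
    # 60 nt, one plus-strand transcript with a 30 nt intron
    seq = "ACGTACGTAC" "GTACGTACGT" "GTAAGTACGT" "ACGTACGTAG" "ACGTACGTAC" "GTACGTACGT"
    t = sy.Transcript("t0", "c", "+", ((1, 20), (51, 60)))
    return sy.ReferenceBundle(chromosomes={"c": seq}, gene_models=[t])


class TestBuildPileup:
    def test_matching_bases_counted(self, tiny_bundle):
        ref = tiny_bundle.chromosomes["c"]
        reads = [_read("c", [(8, 17)], ref[7:17], rid=f"r{i}") for i in range(3)]
        pile = ca.build_pileup(reads, tiny_bundle)
        entry = pile[("c", 10)]
        assert entry.coverage == 3
        assert entry.count(ref[9]) == 3

    def test_splice_gap_contributes_nothing(self, tiny_bundle):
        ref = tiny_bundle.chromosomes["c"]
        reads = [_read("c", [(11, 20), (51, 60)], ref[10:20] + ref[50:60])]
        pile = ca.build_pileup(reads, tiny_bundle)
        assert ("c", 30) not in pile
        assert pile[("c", 15)].coverage == 1

    def test_mixed_bases_sum_to_coverage(self, tiny_bundle):
        ref = tiny_bundle.chromosomes["c"]
        pos = 10  # interior, clear of the 6-nt end trim for these reads
        reads = []
        for i in range(10):
            s = list(ref[1:19])
            if i < 3:
                s[pos - 2] = "G"
            reads.append(_read("c", [(2, 19)], "".join(s), rid=f"r{i}"))
        pile = ca.build_pileup(reads, tiny_bundle)
        entry = pile[("c", pos)]
        assert entry.coverage == 10
        assert entry.count("G") == 3

    def test_unknown_chromosome_rejected(self, tiny_bundle):
        with pytest.raises(ValueError, match="unknown chromosome"):
            ca.build_pileup([_read("x", [(1, 4)], "ACGT")], tiny_bundle)

    def test_minus_strand_counts_are_complemented(self):
        seq = "A" * 0 + "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT"
        t = sy.Transcript("t0", "c", "-", ((1, 40),))
        b = sy.ReferenceBundle(chromosomes={"c": seq}, gene_models=[t])
        # reference T at pos 16 (0-based 15); read carries C = edited G on '-'
        s = list(seq[7:27])
        assert s[8] == "T"
        s[8] = "C"
        pile = ca.build_pileup([_read("c", [(8, 27)], "".join(s), strand="-")], b)
        entry = pile[("c", 16)]
        assert entry.strand == "-" and entry.ref_base == "A"
        assert entry.count("G") == 1


class TestCallSites:
    def _pileup_single(self, bundle, pos, g, cov):
        ref = bundle.chromosomes["c"]
        reads = []
        for i in range(cov):
            s = list(ref[pos - 11:pos + 8])
            if i < g:
                s[10] = "G"
            reads.append(_read("c", [(pos - 10, pos + 8)], "".join(s),
                               rid=f"r{i}"))
        return ca.build_pileup(reads, bundle)

    def test_one_supporting_read_rejected_two_accepted(self, tiny_bundle):
        ref = tiny_bundle.chromosomes["c"]
        pos = next(p for p in range(12, 19) if ref[p - 1] == "A")
        pile = self._pileup_single(tiny_bundle, pos, g=1, cov=10)
        assert not ca.call_sites(pile, tiny_bundle)
        pile = self._pileup_single(tiny_bundle, pos, g=2, cov=5)
        calls = ca.call_sites(pile, tiny_bundle)
        assert [(c.position, c.mismatch_type) for c in calls] == [(pos, "A-G")]

    def test_junction_margin_respected_except_nascent(self, tiny_bundle):
        # acceptor -2 position: intron (21,50) ends at 50; site at 49 ('A')
        assert tiny_bundle.chromosomes["c"][48] == "A"
        pile = self._pileup_single(tiny_bundle, 49, g=3, cov=10)
        assert not ca.call_sites(pile, tiny_bundle, nascent=False)
        nascent = ca.call_sites(pile, tiny_bundle, nascent=True)
        assert [c.position for c in nascent] == [49]

    def test_nascent_calls_are_superset(self, bundle, pileups):
        pile = pileups[sy.CHA_MINUS]
        with_exc = {c.position for c in
                    ca.call_sites(pile, bundle, nascent=True)}
        without = {c.position for c in
                   ca.call_sites(pile, bundle, nascent=False)}
        assert without <= with_exc

    def test_snp_positions_excluded(self, tiny_bundle):
        ref = tiny_bundle.chromosomes["c"]
        pos = next(p for p in range(12, 19) if ref[p - 1] == "A")
        b = sy.ReferenceBundle(chromosomes=tiny_bundle.chromosomes,
                               gene_models=tiny_bundle.gene_models,
                               snps=[("c", pos)])
        pile = self._pileup_single(b, pos, g=3, cov=10)
        assert not ca.call_sites(pile, b)

    def test_homopolymer_positions_excluded(self):
        seq = "ACGTACGTGC" + "AAAAA" + "CGTACGTACG" * 3
        t = sy.Transcript("t0", "c", "+", ((1, len(seq)),))
        b = sy.ReferenceBundle(chromosomes={"c": seq}, gene_models=[t])
        reads = []
        for i in range(10):
            s = list(seq[1:31])
            if i < 4:
                s[11] = "G"  # inside the AAAAA run
            reads.append(_read("c", [(2, 31)], "".join(s), rid=f"r{i}"))
        pile = ca.build_pileup(reads, b)
        assert not ca.call_sites(pile, b)

    def test_planted_sites_called_no_false_positives(
            self, bundle, truths, site_calls):
        """Error-free simulation: every sufficiently edited planted site is
        called in each fraction, and nothing else is."""
        truth_pos = {(t.chromosome, t.position): t for t in truths}
        order = list(sy.FRACTION_ORDER)
        for frac, calls in site_calls.items():
            fi = order.index(frac)
            for c in calls:
                assert (c.chromosome, c.position) in truth_pos
            called = {(c.chromosome, c.position) for c in calls}
            for t in truths:
                if t.er[fi] >= 0.2 and _exonic(bundle, t):
                    assert (t.chromosome, t.position) in called


def _exonic(bundle, truth):
    return any(
        s <= truth.position <= e
        for t in bundle.gene_models if t.chromosome == truth.chromosome
        for s, e in t.exons
    )


class TestHyperediting:
    def test_constructed_read_rescued_with_edits(self, bundle):
        t = next(t for t in bundle.gene_models if t.strand == "+")
        start = t.exons[0][0]
        seg = bundle.chromosomes[t.chromosome][start - 1:start + 99]
        all_a = [i for i, b in enumerate(seg) if b == "A"]
        # spread the edits across the read so the clustering filter passes
        a_pos = sorted({all_a[round(j * (len(all_a) - 1) / 5)] for j in range(6)})
        assert len(a_pos) == 6
        s = list(seg)
        for i in a_pos:
            s[i] = "G"
        read = sy.AlignedRead("h", "", "+", (), "".join(s), "ChA-")
        out = ca.hyperediting_rescue([read], bundle)
        assert len(out) == 1
        r = out[0]
        assert r.chromosome == t.chromosome
        assert r.blocks == ((start, start + 99),)
        # reinstated read shows exactly the 6 planted A-G mismatches
        ref = bundle.chromosomes[r.chromosome][start - 1:start + 99]
        mism = [(a, b) for a, b in zip(ref, r.sequence) if a != b]
        assert mism == [("A", "G")] * 6

    def test_ambiguous_placement_discarded(self):
        # two identical genome copies -> two equally good placements
        unit = "ACGTTCAGGTCCATGACTGA" * 5
        genome = {"c": unit + "TTTTCCCC" + unit}
        t = sy.Transcript("t0", "c", "+", ((1, len(genome["c"])),))
        b = sy.ReferenceBundle(chromosomes=genome, gene_models=[t])
        s = list(unit[:60])
        for i in [j for j, x in enumerate(s) if x == "A"][:6]:
            s[i] = "G"
        read = sy.AlignedRead("h", "", "+", (), "".join(s), "f")
        assert ca.hyperediting_rescue([read], b) == []

    def test_unedited_read_not_rescued(self, bundle):
        t = bundle.gene_models[0]
        seg = bundle.chromosomes[t.chromosome][t.start - 1:t.start + 99]
        read = sy.AlignedRead("h", "", "+", (), seg, "f")
        assert ca.hyperediting_rescue([read], bundle) == []

    def test_simulated_hyper_reads_recovered(self, bundle, fraction_reads):
        """>=90% of simulated hyperedited reads come back, on the right
        chromosome at the right coordinates."""
        total = rescued = correct = 0
        for fr in fraction_reads.values():
            truth = {r.id: r for r in fr.hyper_truth}
            out = ca.hyperediting_rescue(fr.unmapped, bundle)
            total += len(fr.unmapped)
            rescued += len(out)
            for r in out:
                want = truth[r.id]
                assert r.chromosome == want.chromosome
                correct += r.blocks == want.blocks
        assert total > 20
        assert rescued / total >= 0.9
        assert correct == rescued


class TestAnnotateSites:
    def test_context_precedence_and_classes(self, bundle):
        t = next(t for t in bundle.gene_models if t.cds and len(t.exons) >= 3)
        intron_pos = (t.introns[0][0] + t.introns[0][1]) // 2
        cds_pos = (t.cds[0] + t.cds[1]) // 2
        # ensure the CDS midpoint is exonic; otherwise pick an exon in CDS
        if not any(s <= cds_pos <= e for s, e in t.exons):
            cds_pos = next(s for s, e in t.exons if t.cds[0] <= s <= t.cds[1])
        sites = [
            ca.EditingSite(t.chromosome, intron_pos, t.strand, {}),
            ca.EditingSite(t.chromosome, cds_pos, t.strand, {}),
            ca.EditingSite(t.chromosome, 5, "+", {}),  # upstream intergenic
        ]
        out = ca.annotate_sites(sites, bundle)
        assert out[0].context == "intron"
        assert out[1].context == "CDS"
        assert out[2].context == "intergenic"

    def test_repeat_class_assignment(self, bundle):
        ir = bundle.inverted_repeats[0]
        rep = next(r for r in bundle.repeats if r.repeat_class == "L1")
        sites = [
            ca.EditingSite(ir.chromosome, ir.arm1[0] + 5, "+", {}),
            ca.EditingSite(rep.chromosome, rep.start + 5, "+", {}),
            ca.EditingSite(ir.chromosome, 3, "+", {}),
        ]
        out = ca.annotate_sites(sites, bundle)
        assert out[0].repeat_class == "Alu"
        assert out[1].repeat_class in ("repeat", "Alu")  # L1 may overlap Alu
        assert out[2].repeat_class == "nonrepeat"

    def test_nearest_distance_symmetric_pair(self):
        b = sy.ReferenceBundle(chromosomes={"c": "ACGT" * 100},
                               gene_models=[sy.Transcript("t", "c", "+",
                                                          ((1, 400),))])
        sites = [ca.EditingSite("c", 100, "+", {}),
                 ca.EditingSite("c", 130, "+", {})]
        out = ca.annotate_sites(sites, b)
        assert [s.nearest_site_distance for s in out] == [30, 30]
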