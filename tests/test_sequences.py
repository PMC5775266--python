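import numpy as np
import pytest

from asrna_screen.exceptions import InsufficientFlankError, InvalidSequenceError
from asrna_screen.orientation import ClassifierParams
from asrna_screen.records import Strand
from asrna_screen.sequences import (
    OligoConstraints,
    design_race_oligo,
    find_trans_targets,
    oligo_metrics,
    predict_amplicon,
    reverse_complement,
)

from conftest import make_gene, random_dna
from oracles import oracle_best_oligo, oracle_trans_scan, revcomp


class TestOligoMetrics:
    @pytest.mark.parametrize(
        "seq, tm, gc, rc",
        [
            ("ATGC", 12.0, 0.5, "GCAT"),
            ("GGCC", 16.0, 1.0, "GGCC"),
            ("ATAT", 8.0, 0.0, "ATAT"),
        ],
    )
    def test_wallace_rule_values(self, seq, tm, gc, rc):
        assert oligo_metrics(seq) == (tm, gc, rc)

    def test_invalid_character_raises(self):
        with pytest.raises(InvalidSequenceError):
            oligo_metrics("ATXG")


class TestDesignRaceOligo:
    def _locus(self, rng, gc=0.6, length=200, gene_start=101):
        contig = random_dna(rng, length, gc=gc)
        gene = make_gene(gene_start, gene_start + 60, Strand.PLUS, chrom="c")
        return contig, gene

    def test_footprint_contains_full_window_and_matches_exhaustive_oracle(self, rng):
        params = ClassifierParams()
        constraints = OligoConstraints()
        found = 0
        for _ in range(30):
            contig, gene = self._locus(rng)
            oligo = design_race_oligo(gene, {"c": contig}, constraints, params)
            expected = oracle_best_oligo(
                contig, 86, 104, Strand.PLUS,
                constraints.min_len, constraints.max_len,
                constraints.tm_min, constraints.tm_max,
                constraints.gc_min, constraints.gc_max,
            )
            if oligo is None:
                assert expected is None
                continue
            found += 1
            assert (oligo.sequence, oligo.genome_interval.start, oligo.genome_interval.end) == expected
            assert oligo.genome_interval.start <= 86 and oligo.genome_interval.end >= 104
        assert found > 0  # GC-balanced loci must yield designs at least sometimes

    def test_minus_strand_oligo_is_mrna_sense(self, rng):
        contig = random_dna(rng, 200, gc=0.6)
        gene = make_gene(40, 100, Strand.MINUS, chrom="c")
        oligo = design_race_oligo(gene, {"c": contig})
        if oligo is not None:
            iv = oligo.genome_interval
            assert iv.start <= 100 - 3 and iv.end >= 100 + 15
            assert oligo.sequence == revcomp(contig[iv.start - 1 : iv.end])

    def test_insufficient_flank_raises(self, rng):
        contig = random_dna(rng, 200)
        gene = make_gene(5, 60, Strand.PLUS, chrom="c")
        with pytest.raises(InsufficientFlankError):
            design_race_oligo(gene, {"c": contig})

    def test_homopolymer_has_no_solution(self):
        contig = "A" * 200
        gene = make_gene(101, 160, Strand.PLUS, chrom="c")
        assert design_race_oligo(gene, {"c": contig}) is None

    def test_result_passes_its_own_constraints(self, rng):
        constraints = OligoConstraints()
        for _ in range(10):
            contig = random_dna(rng, 200, gc=0.72)
            gene = make_gene(101, 160, Strand.PLUS, chrom="c")
            oligo = design_race_oligo(gene, {"c": contig}, constraints)
            if oligo is not None:
                assert constraints.admits(oligo.sequence)


class TestPredictAmplicon:
    def test_end_to_end_product(self, rng):
        template = random_dna(rng, 50)
        pred = predict_amplicon(template[:20], revcomp(template[-18:]), template)
        assert pred.found and pred.product_length_nt == 50

    def test_no_opposing_site_not_found(self, rng):
        # both primers match the template in the same orientation: no convergent pair
        for _ in range(10):
            template = random_dna(rng, 80)
            fwd, rev = template[:15], template[40:55]
            if revcomp(rev) in template or revcomp(fwd) in template:
                continue  # chance opposing site; try another template
            assert not predict_amplicon(fwd, rev, template).found

    def test_absent_primer_not_found(self, rng):
        template = random_dna(rng, 60)
        foreign = "ACGT" * 5
        if foreign not in template:
            assert not predict_amplicon(foreign, revcomp(template[-15:]), template).found

    def test_strand_symmetry(self, rng):
        """Same product from the reverse-complement template with swapped primers."""
        for _ in range(20):
            template = random_dna(rng, 120)
            fwd, rev = template[10:25], revcomp(template[80:100])
            direct = predict_amplicon(fwd, rev, template)
            flipped = predict_amplicon(rev, fwd, revcomp(template))
            assert direct.found == flipped.found
            if direct.found:
                assert direct.product_length_nt == flipped.product_length_nt

    def test_shortest_product_reported(self):
        spacer = "CCCCCCCCCCCC"
        fwd = "ACCTGACCTGACCT"
        rev_site = "GGGGTTTTAAAACC"  # rev primer binds here (two possible sites)
        template = fwd + spacer + rev_site + spacer * 4 + rev_site
        pred = predict_amplicon(fwd, revcomp(rev_site), template)
        assert pred.found
        assert pred.product_length_nt == len(fwd) + len(spacer) + len(rev_site)

    def test_short_primer_rejected(self):
        with pytest.raises(InvalidSequenceError):
            predict_amplicon("ACGT", "ACGTACGTACGTACGT", "ACGT" * 30)


class TestFindTransTargets:
    def test_verbatim_implant_found_once(self, rng):
        genome = random_dna(rng, 5000)
        query = genome[1000:1040]
        hits = find_trans_targets(query, {"c": genome}, min_identity=0.9, min_len=20)
        plus_hits = [h for h in hits if h.strand_of_match is Strand.PLUS]
        assert any(h.interval.start == 1001 and h.identity_fraction == 1.0 for h in plus_hits)

    def test_two_mismatches_found_at_090_absent_at_098(self, rng):
        genome = random_dna(rng, 3000)
        window = list(genome[500:540])
        window[5] = {"A": "C", "C": "A", "G": "T", "T": "G"}[window[5]]
        window[25] = {"A": "C", "C": "A", "G": "T", "T": "G"}[window[25]]
        query = "".join(window)  # identity 38/40 = 0.95
        found_90 = find_trans_targets(query, {"c": genome}, 0.9, 20)
        found_98 = find_trans_targets(query, {"c": genome}, 0.98, 20)
        assert any(h.interval.start == 501 for h in found_90)
        assert not any(h.interval.start == 501 for h in found_98)

    def test_absent_query_empty(self, rng):
        genome = random_dna(rng, 1000)
        query = "AT" * 15  # low-complexity probe unlikely at 0.97 in GC-balanced noise
        hits = find_trans_targets(query, {"c": genome}, min_identity=0.97, min_len=20)
        assert hits == [] or all(h.identity_fraction >= 0.97 for h in hits)

    def test_matches_sliding_window_oracle(self, rng):
        genome = random_dna(rng, 400)
        query = genome[100:130]
        hits = find_trans_targets(query, {"c": genome}, 0.85, 20)
        oracle_hits = oracle_trans_scan(query, {"c": genome}, 0.85)
        oracle_starts = {(c, s, st) for c, s, st, _ in oracle_hits}
        # every reported hit is a true oracle window
        for h in hits:
            assert (h.interval.chrom, h.interval.start, h.strand_of_match.value) in oracle_starts
        # and every oracle window is covered by a reported (possibly merged) hit
        for chrom, start, strand, _ in oracle_hits:
            assert any(
                h.interval.chrom == chrom
                and h.strand_of_match.value == strand
                and abs(h.interval.start - start) < len(query)
                for h in hits
            )

    def test_identity_one_equals_exact_search(self, rng):
        genome = random_dna(rng, 2000)
        query = genome[700:740]
        hits = find_trans_targets(query, {"c": genome}, 1.0, 20)
        exact_plus = {i + 1 for i in range(len(genome)) if genome[i : i + 40] == query}
        rc = revcomp(genome)
        exact_minus = {len(genome) - (i + 40) + 1 for i in range(len(genome)) if rc[i : i + 40] == query}
        got = {(h.interval.start, h.strand_of_match.value) for h in hits}
        expected = {(s, "+") for s in exact_plus} | {(s, "-") for s in exact_minus}
        assert got == expected

    def test_bad_identity_raises(self):
        with pytest.raises(ValueError):
            find_trans_targets("ACGT" * 10, {"c": "ACGT" * 100}, min_identity=1.5)
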