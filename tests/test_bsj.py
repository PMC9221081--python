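"""Back-splice detection: IDs, geometry, scoring, refinement, quantification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circena.bsj import (
    CircCandidate,
    KmerIndex,
    SegmentAlignment,
    SpliceScorer,
    build_pseudo_circular_reference,
    contiguous_align,
    detect_circrnas,
    filter_candidates,
    find_head_to_tail,
    make_circ_id,
    parse_circ_id,
    quantify_junction_reads,
    refine_junction,
    score_splice_sites,
    split_align,
)
from circena.config import PipelineConfig
from circena.io import ExonAnnotation, GenomeSequence, ReadRecord, revcomp
from circena.synthetic import simulate_dataset


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestCircId:
    @pytest.mark.parametrize(
        "chrom, a, b, expected",
        [
            (4, 44595116, 44595667, "chr4_44595667_44595116_-551"),
            (1, 838250, 848114, "chr1_848114_838250_-9864"),
            (2, 48775963, 48776160, "chr2_48776160_48775963_-197"),
            (8, 44002030, 44017157, "chr8_44017157_44002030_-15127"),
        ],
    )
    def test_published_identifiers(self, chrom, a, b, expected):
        assert make_circ_id(chrom, a, b) == expected
        assert make_circ_id(chrom, b, a) == expected  # order-insensitive

    def test_zero_span_rejected(self):
        with pytest.raises(ValueError, match="span"):
            make_circ_id(1, 100, 100)

    @given(
        chrom=st.integers(1, 22),
        lo=st.integers(1, 10**8),
        span=st.integers(1, 10**6),
    )
    @settings(max_examples=200, deadline=None)
    def test_parse_inverts_make(self, chrom, lo, span):
        hi = lo + span
        parsed = parse_circ_id(make_circ_id(chrom, lo, hi))
        assert parsed == (f"chr{chrom}", hi, lo, -span)

    def test_inconsistent_span_suffix_rejected(self):
        with pytest.raises(ValueError, match="span"):
            parse_circ_id("chr1_200_100_-50")


@pytest.fixture(scope="module")
def uniform_scorer():
    return SpliceScorer(np.full((9, 4), 0.25), np.full((23, 4), 0.25))


class TestSpliceScorer:
    def test_background_pwm_scores_zero_everywhere(self, uniform_scorer):
        assert uniform_scorer.score_donor_window("ACGTACGTA") == pytest.approx(0.0)
        assert uniform_scorer.score_acceptor_window("A" * 23) == pytest.approx(0.0)

    def test_consensus_window_attains_column_max_sum(self):
        rng = np.random.default_rng(0)
        donor = rng.dirichlet(np.ones(4), size=9)
        acceptor = rng.dirichlet(np.ones(4), size=23)
        scorer = SpliceScorer(donor, acceptor)
        consensus = "".join("ACGT"[j] for j in donor.argmax(axis=1))
        assert scorer.score_donor_window(consensus) == pytest.approx(
            scorer.max_donor_score()
        )

    def test_non_gt_donor_scores_below_consensus(self, dataset):
        genome_map = {g.chrom_name: g for g in dataset.genome}
        scorer = SpliceScorer.from_annotation(genome_map, dataset.annotations)
        gt_window = "CAG" + "GTAAGT"
        non_gt = "CAG" + "CCAAGT"
        assert scorer.score_donor_window(non_gt) < scorer.score_donor_window(gt_window)

    def test_annotated_junctions_score_high_both_strands(self, dataset, default_config):
        genome_map = {g.chrom_name: g for g in dataset.genome}
        scorer = SpliceScorer.from_annotation(genome_map, dataset.annotations)
        for j in dataset.truth.planted_junctions:
            d, a = score_splice_sites(
                scorer, genome_map, j.chrom, j.strand, j.donor_pos, j.acceptor_pos
            )
            assert d + a >= default_config.min_splice_score

    def test_out_of_bounds_window_errors(self, dataset):
        genome_map = {g.chrom_name: g for g in dataset.genome}
        scorer = SpliceScorer.from_annotation(genome_map, dataset.annotations)
        with pytest.raises(ValueError, match="bounds"):
            score_splice_sites(scorer, genome_map, "chr1", "+", 10**7, 5)


@pytest.fixture(scope="module")
def genome():
    rng = np.random.default_rng(7)
    return [GenomeSequence("chr1", random_dna(rng, 3000))]


@pytest.fixture(scope="module")
def index(genome, default_config):
    return KmerIndex.from_genome(genome, default_config.seed_kmer)


class TestAlignment:
    def test_exact_substring_aligns_contiguously(self, genome, index, default_config):
        read = ReadRecord("r", genome[0].slice1(501, 600))
        hit = contiguous_align(read, index, None, default_config)
        assert hit is not None and (hit.ref_start, hit.ref_end) == (501, 600)

    def test_reverse_complement_also_aligns(self, genome, index, default_config):
        read = ReadRecord("r", revcomp(genome[0].slice1(501, 600)))
        hit = contiguous_align(read, index, None, default_config)
        assert hit is not None and hit.strand == "-"

    def test_all_n_read_aligns_nowhere(self, genome, index, default_config):
        read = ReadRecord("r", "N" * 100)
        assert contiguous_align(read, index, None, default_config) is None
        assert split_align(read, index, default_config) == []

    def test_chimeric_read_splits_into_two_segments(self, genome, index, default_config):
        chrom = genome[0]
        read = ReadRecord("r", chrom.slice1(1000, 1049) + chrom.slice1(500, 549))
        segments = split_align(read, index, default_config)
        intervals = {(s.read_start, s.read_end): (s.ref_start, s.ref_end)
                     for s in segments}
        assert any(rs <= 1000 and re >= 1049 for rs, re in intervals.values())
        assert any(rs <= 500 and re >= 549 for rs, re in intervals.values())

    def test_read_shorter_than_seed_yields_nothing(self, index, default_config):
        assert split_align(ReadRecord("r", "ACGTACGT"), index, default_config) == []

    def test_repetitive_read_drops_ambiguous_seeds(self, default_config):
        poly = [GenomeSequence("chr1", "A" * 2000)]
        idx = KmerIndex.from_genome(poly, default_config.seed_kmer,
                                    default_config.max_seed_hits)
        assert split_align(ReadRecord("r", "A" * 80), idx, default_config) == []


class TestHeadToTail:
    def seg(self, read_start, read_end, ref_start, ref_end, strand="+", chrom="chr1"):
        return SegmentAlignment("r", read_start, read_end, chrom, strand,
                                ref_start, ref_end, read_end - read_start)

    def test_reverse_order_pair_yields_candidate(self, default_config):
        cand = find_head_to_tail(
            [self.seg(0, 50, 1000, 1049), self.seg(50, 100, 500, 549)],
            default_config,
        )
        assert cand is not None
        assert (cand.donor_pos, cand.acceptor_pos) == (1049, 500)

    def test_pair_beyond_one_megabase_rejected(self, default_config):
        cand = find_head_to_tail(
            [self.seg(0, 50, 2_500_000, 2_500_049), self.seg(50, 100, 500, 549)],
            default_config,
        )
        assert cand is None

    def test_collinear_pair_is_linear_splice_not_candidate(self, default_config):
        cand = find_head_to_tail(
            [self.seg(0, 50, 500, 549), self.seg(50, 100, 1000, 1049)],
            default_config,
        )
        assert cand is None

    def test_different_strand_pair_rejected(self, default_config):
        cand = find_head_to_tail(
            [self.seg(0, 50, 1000, 1049, "+"), self.seg(50, 100, 500, 549, "-")],
            default_config,
        )
        assert cand is None

    def test_large_read_gap_rejected(self, default_config):
        cand = find_head_to_tail(
            [self.seg(0, 40, 1000, 1039), self.seg(50, 100, 500, 549)],
            default_config,
        )
        assert cand is None


class TestRefineJunction:
    def test_radius_zero_keeps_candidate(self, dataset, default_config):
        genome_map = {g.chrom_name: g for g in dataset.genome}
        scorer = SpliceScorer.from_annotation(genome_map, dataset.annotations)
        j = dataset.truth.planted_junctions[0]
        raw = CircCandidate(j.chrom, j.strand, j.acceptor_pos, j.donor_pos, {"r"})
        out = refine_junction(raw, scorer, genome_map, window_radius=0)
        assert (out.donor_pos, out.acceptor_pos) == (j.donor_pos, j.acceptor_pos)

    def test_microhomology_shift_recovers_planted_junction(self):
        """A back-splice candidate misplaced by a 2-nt homology tract is
        pulled back to the canonical boundaries by splice-score refinement."""
        rng = np.random.default_rng(3)
        # exon1 [1..200] | intron [201..300] | exon2 [301..500] | intron ...
        # back-splice circle = exon2: acceptor 301, donor 500.
        exon1 = random_dna(rng, 197) + "CAG"
        intron = "GTAAGT" + random_dna(rng, 74) + "".join(
            rng.choice(["C", "T"], 17)
        ) + "CAG"
        # 2-nt homology: the bases after the donor (the downstream intron's
        # "GT") equal the first two bases of exon2
        exon2 = "GT" + random_dna(rng, 195) + "CAG"
        tail = "GTAAGT" + random_dna(rng, 100)
        chrom = GenomeSequence("chr1", exon1 + intron + exon2 + tail)
        genome = {"chr1": chrom}
        ann = ExonAnnotation("g", "t", "chr1", "+", ((1, 200), (301, 500)))
        scorer = SpliceScorer.from_annotation(genome, [ann] * 5)
        # alignment overran the homology: raw boundaries both +2 off truth
        raw = CircCandidate("chr1", "+", 301 + 2, 500 + 2, {"r"})
        out = refine_junction(raw, scorer, genome, window_radius=5)
        assert (out.acceptor_pos, out.donor_pos) == (301, 500)

    def test_exact_tie_prefers_smallest_shift(self):
        # uniform scorer: every shift scores 0; homology everywhere (poly-A)
        chrom = GenomeSequence("chr1", "A" * 1000)
        scorer = SpliceScorer(np.full((9, 4), 0.25), np.full((23, 4), 0.25))
        raw = CircCandidate("chr1", "+", 400, 600, {"r"})
        out = refine_junction(raw, scorer, {"chr1": chrom}, window_radius=5)
        assert (out.acceptor_pos, out.donor_pos) == (400, 600)


class TestFilterCandidates:
    def cand(self, support, donor_score, acceptor_score):
        return CircCandidate(
            "chr1", "+", 100, 600,
            {f"r{i}" for i in range(support)}, donor_score, acceptor_score,
        )

    def test_boundary_support_and_score_kept(self, default_config):
        kept = filter_candidates([self.cand(2, 5.0, 5.0)], default_config)
        assert len(kept) == 1

    def test_single_read_support_dropped(self, default_config):
        assert filter_candidates([self.cand(1, 10.0, 5.0)], default_config) == []

    def test_score_just_below_threshold_dropped(self, default_config):
        assert filter_candidates([self.cand(5, 5.0, 4.9)], default_config) == []

    def test_support_merges_across_duplicate_candidates(self, default_config):
        a = CircCandidate("chr1", "+", 100, 600, {"r1"}, 6.0, 6.0)
        b = CircCandidate("chr1", "+", 100, 600, {"r2"}, 6.0, 6.0)
        kept = filter_candidates([a, b], default_config)
        assert len(kept) == 1 and kept[0].support == 2


@pytest.fixture(scope="module")
def single_exon():
    rng = np.random.default_rng(5)
    seq = random_dna(rng, 700)
    genome = {"chr1": GenomeSequence("chr1", seq)}
    ann = ExonAnnotation("g", "t", "chr1", "+", ((101, 200),))
    return genome, ann


class TestPseudoCircularReference:
    def test_single_exon_circle_is_tail_plus_head(self, single_exon):
        genome, ann = single_exon
        cand = CircCandidate("chr1", "+", 101, 200, {"r"})
        ref = build_pseudo_circular_reference(cand, [ann], genome, flank_len=50)
        circle = genome["chr1"].slice1(101, 200)
        assert ref.sequence == circle[50:] + circle[:50]
        assert ref.junction_offset == 50

    def test_two_exon_circle_excludes_intron(self, dataset):
        genome_map = {g.chrom_name: g for g in dataset.genome}
        ann = next(a for a in dataset.annotations if a.strand == "+")
        (e1, e2) = ann.exons[0], ann.exons[1]
        cand = CircCandidate(ann.chrom, "+", e1[0], e2[1], {"r"})
        ref = build_pseudo_circular_reference(cand, [ann], genome_map, 60)
        intron = genome_map[ann.chrom].slice1(e1[1] + 1, e2[0] - 1)
        assert intron[:20] not in ref.sequence

    def test_circle_shorter_than_flank_rotates_without_duplication(self, single_exon):
        genome, ann = single_exon
        cand = CircCandidate("chr1", "+", 101, 200, {"r"})
        ref = build_pseudo_circular_reference(cand, [ann], genome, flank_len=150)
        circle = genome["chr1"].slice1(101, 200)
        assert len(ref.sequence) == len(circle)
        assert ref.sequence == circle[50:] + circle[:50]


@pytest.fixture(scope="module")
def pseudo():
    rng = np.random.default_rng(9)
    return random_dna(rng, 94) + random_dna(rng, 94)


class TestQuantifyJunctionReads:
    def test_exact_six_nt_overhang_counted(self, pseudo, default_config):
        read = ReadRecord("r", pseudo[88 : 88 + 100])  # 6 nt left of junction 94
        assert quantify_junction_reads([read], pseudo, 94, default_config) == 1

    def test_five_nt_overhang_not_counted(self, pseudo, default_config):
        read = ReadRecord("r", pseudo[89 : 89 + 99])  # 5 nt left of junction
        assert quantify_junction_reads([read], pseudo, 94, default_config) == 0

    def test_count_matches_kmer_oracle_on_planted_fixture(
        self, dataset, default_config
    ):
        """Junction-read counts equal the brute-force count of reads containing
        the junction-spanning 12-mer (or its reverse complement)."""
        from circena.synthetic import _circle_sequence_for

        genome_map = {g.chrom_name: g for g in dataset.genome}
        read_len = len(dataset.reads[0].sequence)
        flank = read_len - default_config.min_overhang_nt
        for junction in dataset.truth.planted_junctions[:4]:
            circle = _circle_sequence_for(junction, dataset.annotations, genome_map)
            pseudo = circle[-flank:] + circle[:flank]
            k = 2 * default_config.min_overhang_nt
            kmer = circle[-k // 2 :] + circle[: k // 2]
            oracle = sum(
                kmer in r.sequence or kmer in revcomp(r.sequence)
                for r in dataset.reads
            )
            got = quantify_junction_reads(dataset.reads, pseudo, flank,
                                          default_config)
            assert got == oracle == junction.n_supporting_reads


class TestPlantedRecovery:
    def test_error_free_recall_is_one_with_no_false_junctions(
        self, dataset, detected_circrnas
    ):
        truth = {
            (j.chrom, j.strand, j.acceptor_pos, j.donor_pos)
            for j in dataset.truth.planted_junctions
        }
        found = {
            (c.candidate.chrom, c.candidate.strand,
             c.candidate.acceptor_pos, c.candidate.donor_pos)
            for c in detected_circrnas
        }
        assert found == truth

    def test_candidates_satisfy_invariants(self, detected_circrnas, default_config):
        for c in detected_circrnas:
            cand = c.candidate
            assert cand.donor_pos > cand.acceptor_pos
            assert cand.span <= default_config.max_junction_span_bp
            assert cand.support >= default_config.min_support_reads
            assert cand.splice_score >= default_config.min_splice_score
            parsed = parse_circ_id(c.id)
            assert parsed[1] == cand.donor_pos and parsed[2] == cand.acceptor_pos

    def test_noisy_reads_recall_at_least_ninety_percent(self, default_config):
        ds = simulate_dataset(rng_seed=1, error_rate=0.005)
        circ = detect_circrnas(ds.reads, ds.genome, ds.annotations, default_config)
        truth = {
            (j.chrom, j.strand, j.acceptor_pos, j.donor_pos)
            for j in ds.truth.planted_junctions
        }
        found = {
            (c.candidate.chrom, c.candidate.strand,
             c.candidate.acceptor_pos, c.candidate.donor_pos)
            for c in circ
        }
        assert len(truth & found) / len(truth) >= 0.9
        assert not found - truth
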