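"""Sequence-based origin prediction: intergenic extraction, repeat search
(checked against a brute-force all-substring-pairs oracle), G-string and
inverted-pair rules."""

import numpy as np
import pytest
from numpy.lib.stride_tricks import sliding_window_view

from orimfa import (
    Chromosome,
    Feature,
    extract_upstream_intergenic,
    find_repeated_motifs,
    generate_genome,
    has_g_string,
    predict_origins,
    reverse_complement,
)
from orimfa.orb import encode, maximal_repeat_pairs

from conftest import ORB_CONSENSUS, random_dna


# --------------------------------------------------------------- oracle

def brute_force_seed_pairs(seq: str, m: int, max_mismatch: int) -> set:
    """All substring pairs of length exactly ``m`` (either orientation)
    within the mismatch budget, by direct pairwise Hamming comparison.

    A repeat of any length >= m within budget exists iff one exists at
    exactly m (every length-m window of a longer match is itself a match),
    so this is a complete existence oracle for the repeat search.
    """
    enc, n = encode(seq), len(seq)
    rc = encode(reverse_complement(seq))
    W = sliding_window_view(enc, m)
    Wr = sliding_window_view(rc, m)
    seeds = set()
    mism = (W[:, None, :] != W[None, :, :]).sum(axis=2)
    for i, j in np.argwhere(mism <= max_mismatch):
        if i < j:
            seeds.add((int(i), int(j), "+"))
    mism_rc = (W[:, None, :] != Wr[None, :, :]).sum(axis=2)
    for i, k in np.argwhere(mism_rc <= max_mismatch):
        j = n - int(k) - m
        if int(i) != j:
            seeds.add((min(int(i), j), max(int(i), j), "-"))
    return seeds


def pair_covers_seed(pair, seed, m):
    i, j, strand = seed
    if pair.strand != strand:
        return False
    within_a = pair.pos_a <= i and i + m <= pair.pos_a + pair.length
    within_b = pair.pos_b <= j and j + m <= pair.pos_b + pair.length
    if strand == "+":
        return within_a and within_b and pair.pos_b - pair.pos_a == j - i
    return (within_a and within_b
            and pair.pos_a + pair.pos_b + pair.length == i + j + m)


def assert_agrees_with_oracle(seq, min_len, max_mismatch):
    seeds = brute_force_seed_pairs(seq, min_len, max_mismatch)
    pairs = maximal_repeat_pairs(seq, min_len, 35, max_mismatch)
    # completeness: every oracle pair is inside some reported maximal pair
    for seed in seeds:
        assert any(pair_covers_seed(p, seed, min_len) for p in pairs), seed
    # soundness: every reported pair really matches within budget
    for p in pairs:
        a = seq[p.pos_a : p.pos_a + p.length]
        b = seq[p.pos_b : p.pos_b + p.length]
        if p.strand == "-":
            b = reverse_complement(b)
        d = sum(x != y for x, y in zip(a, b))
        assert d == p.mismatches <= max_mismatch
        assert min_len <= p.length <= 35
    return seeds, pairs


# --------------------------------------------------------------- fixtures

def genes():
    return [
        Feature("up", "gene", 3_000, 4_200, "+"),
        Feature("target_plus", "gene", 5_000, 6_000, "+"),
        Feature("target_minus", "gene", 5_000, 6_000, "-"),
        Feature("down", "gene", 6_800, 7_900, "+"),
    ]


class TestExtractUpstreamIntergenic:
    def test_plus_strand_gap_to_previous_gene(self):
        ann = [g for g in genes() if g.id != "target_minus"]
        region = extract_upstream_intergenic(ann, "target_plus",
                                             Chromosome("chr", 10_000))
        assert (region.start, region.end) == (4_200, 5_000)

    def test_minus_strand_gap_to_next_gene(self):
        ann = [g for g in genes() if g.id != "target_plus"]
        region = extract_upstream_intergenic(ann, "target_minus",
                                             Chromosome("chr", 10_000))
        assert (region.start, region.end) == (6_000, 6_800)

    def test_truncated_to_max_span(self):
        ann = [Feature("g", "gene", 9_000, 9_500, "+")]
        region = extract_upstream_intergenic(ann, "g", Chromosome("chr", 10_000),
                                             max_span=2_000)
        assert (region.start, region.end) == (7_000, 9_000)

    def test_absent_gene_rejected(self):
        with pytest.raises(ValueError, match="not found"):
            extract_upstream_intergenic(genes(), "nope", Chromosome("chr", 10_000))

    def test_zero_gap_rejected(self):
        ann = [Feature("a", "gene", 0, 5_000, "+"),
               Feature("b", "gene", 5_000, 6_000, "+")]
        with pytest.raises(ValueError, match="no intergenic region"):
            extract_upstream_intergenic(ann, "b", Chromosome("chr", 10_000))

    def test_planted_genome_region_contains_both_orbs(self, planted_genome):
        chrom, features = planted_genome
        for gid in ("cdc6_1", "cdc6_2"):
            region = extract_upstream_intergenic(features, gid, chrom)
            orbs = [f for f in features
                    if f.type == "ORB" and f.attributes["parent_gene"] == gid]
            assert len(orbs) == 2
            for orb in orbs:
                assert region.start <= orb.start and orb.end <= region.end


class TestFindRepeatedMotifs:
    def test_planted_exact_inverted_pair(self):
        rng = np.random.default_rng(3)
        core = ORB_CONSENSUS + "AATTCCAT"  # 30-mer
        seq = (random_dna(rng, 60) + core + random_dna(rng, 50)
               + reverse_complement(core) + random_dna(rng, 60))
        motifs = find_repeated_motifs(seq, max_mismatch=0)
        assert len(motifs) == 1
        (motif,) = motifs
        assert motif.strands() == {"+", "-"}
        # planted footprints are contained in the recovered instances
        starts = sorted(i.position for i in motif.instances)
        assert starts[0] <= 60 and 60 + 30 <= starts[0] + motif.length
        assert starts[1] <= 140 and 140 + 30 <= starts[1] + motif.length

    def test_random_sequences_agree_with_brute_force(self):
        rng = np.random.default_rng(17)
        for _ in range(8):
            seq = random_dna(rng, int(rng.integers(100, 400)), gc=0.6)
            for mm in (0, 1):
                assert_agrees_with_oracle(seq, 18, mm)

    def test_random_500bp_exact_search_is_empty(self):
        seq = random_dna(np.random.default_rng(29), 500)
        seeds = brute_force_seed_pairs(seq, 18, 0)
        assert seeds == set()
        assert find_repeated_motifs(seq, max_mismatch=0) == []

    def test_mismatch_budget_controls_recovery(self):
        # 30-mer pair with mismatches at core positions 14 and 16: every
        # length-18 window of the pair contains both, so the repeat is
        # recoverable at budget 2 but not at budget 1
        rng = np.random.default_rng(41)
        core = ORB_CONSENSUS + "AATTCCAT"
        mutated = list(core)
        mutated[14] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[14]]
        mutated[16] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[16]]
        mutated = "".join(mutated)
        seq = (random_dna(rng, 60) + core + random_dna(rng, 50)
               + mutated + random_dna(rng, 60))
        assert find_repeated_motifs(seq, max_mismatch=2)
        assert find_repeated_motifs(seq, max_mismatch=1) == []

    def test_strand_symmetry_of_pair_set(self):
        rng = np.random.default_rng(53)
        core = ORB_CONSENSUS + "AATTCCAT"
        seq = (random_dna(rng, 40) + core + random_dna(rng, 30)
               + reverse_complement(core) + random_dna(rng, 40))
        fwd = maximal_repeat_pairs(seq, 18, 35, 0)
        rev = maximal_repeat_pairs(reverse_complement(seq), 18, 35, 0)
        n = len(seq)
        remapped = sorted(
            (n - p.pos_b - p.length, n - p.pos_a - p.length, p.length, p.strand)
            for p in rev
        )
        assert remapped == sorted((p.pos_a, p.pos_b, p.length, p.strand) for p in fwd)

    def test_degenerate_characters_rejected(self):
        with pytest.raises(ValueError, match="non-ACGT"):
            find_repeated_motifs("ACGTN" * 20)

    def test_too_short_region_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            find_repeated_motifs("ACGT" * 5)


class TestGString:
    @pytest.mark.parametrize(
        "consensus,expected",
        [
            ("ACGGGGTATATATATATATA", True),   # 4-G run
            ("A" * 20, False),
            ("ATATATCCCCATATATATAT", True),   # C run = G run on the other strand
            ("ACGGGTATATATATATATAT", False),  # only 3 G
        ],
    )
    def test_g_run_rule(self, consensus, expected):
        assert has_g_string(consensus) is expected

    def test_empty_consensus_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            has_g_string("")


class TestPredictOrigins:
    def test_planted_loci_all_predicted(self):
        chrom, features = generate_genome(
            length=120_000,
            cdc6_loci=[(10_000, "+"), (40_000, "-"), (70_000, "+"), (100_000, "+")],
            orb_consensus=ORB_CONSENSUS,
            orb_spacing=30,
            seed=19,
        )
        ids = [f.id for f in features if f.type == "gene"]
        preds, failures = predict_origins(chrom, features, ids, max_mismatch=1)
        assert failures == []
        assert sorted(p.gene_id for p in preds) == sorted(ids)
        for p in preds:
            assert {"+", "-"} <= p.orb.strands()
            assert p.orb.g_string

    def test_same_strand_pair_excluded(self):
        # plant the motif twice on the same strand upstream of the gene
        rng = np.random.default_rng(7)
        upstream = (random_dna(rng, 40) + ORB_CONSENSUS + random_dna(rng, 40)
                    + ORB_CONSENSUS + random_dna(rng, 40))
        seq = random_dna(rng, 2_000) + upstream + "ATG" + random_dna(rng, 1_197)
        gene_start = 2_000 + len(upstream)
        chrom = Chromosome("chr", len(seq), sequence=seq)
        ann = [Feature("cdc6_x", "gene", gene_start, gene_start + 1_200, "+")]
        preds, failures = predict_origins(chrom, ann, ["cdc6_x"], max_mismatch=0)
        assert preds == []
        assert [f.step for f in failures] == ["no inverted pair"]

    def test_motif_without_g_run_excluded(self):
        rng = np.random.default_rng(13)
        core = "ATCATCATACTATCAATCGATA"  # 22-mer, no G/C run of 4
        assert not has_g_string(core)
        upstream = (random_dna(rng, 40) + core + random_dna(rng, 40)
                    + reverse_complement(core) + random_dna(rng, 40))
        seq = random_dna(rng, 1_500) + upstream + random_dna(rng, 1_200)
        gene_start = 1_500 + len(upstream)
        chrom = Chromosome("chr", len(seq), sequence=seq)
        ann = [Feature("cdc6_y", "gene", gene_start, gene_start + 1_100, "+")]
        preds, failures = predict_origins(chrom, ann, ["cdc6_y"], max_mismatch=0)
        assert preds == []
        assert [f.step for f in failures] == ["no G-string"]

    def test_no_repeat_reported_when_upstream_is_random(self):
        rng = np.random.default_rng(23)
        seq = random_dna(rng, 4_000)
        chrom = Chromosome("chr", 4_000, sequence=seq)
        ann = [Feature("cdc6_z", "gene", 2_500, 3_700, "+")]
        preds, failures = predict_origins(chrom, ann, ["cdc6_z"], max_mismatch=0)
        assert preds == []
        assert [f.step for f in failures] == ["no repeated motif"]
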