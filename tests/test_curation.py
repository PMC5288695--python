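"""Redundancy clustering, isoform curation and refinement detectors."""

import pytest
from Bio.Seq import reverse_complement

from decurate.curation import (
    curate_isoforms,
    detect_frameshift,
    detect_intron_retention,
    greedy_cluster,
    merge_fragments,
    pairwise_identity,
)
from decurate.synth import reverse_translate, simulate_proteome
from oracles import greedy_cluster_reference


def _random_nt(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


def _mutate(seq, k, rng):
    """k substitutions at distinct positions."""
    chars = list(seq)
    for i in rng.choice(len(chars), size=k, replace=False):
        chars[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[chars[i]]
    return "".join(chars)


class TestPairwiseIdentity:
    def test_identical(self, rng):
        s = _random_nt(rng, 200)
        assert pairwise_identity(s, s) == 1.0

    def test_single_terminal_mismatch(self):
        assert pairwise_identity("ACGTACGT", "ACGTACGA") == pytest.approx(7 / 8)

    def test_reverse_complement_orientation(self, rng):
        s = _random_nt(rng, 300)
        assert pairwise_identity(s, reverse_complement(s)) == 1.0

    def test_contained_fragment_full_identity(self, rng):
        s = _random_nt(rng, 500)
        assert pairwise_identity(s[100:300], s) == 1.0

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACGT")


class TestGreedyCluster:
    def test_identical_pair_one_cluster(self, rng):
        s = _random_nt(rng, 400)
        cs = greedy_cluster({"a": s, "b": s})
        assert len(cs.clusters) == 1
        assert cs.representatives == ["a"]  # tie broken lexicographically

    def test_threshold_boundary_96_vs_90(self, rng):
        s = _random_nt(rng, 500)
        near = _mutate(s, 20, rng)  # 96% identity
        far = _mutate(s, 50, rng)  # 90% identity
        assert len(greedy_cluster({"a": s, "b": near}).clusters) == 1
        assert len(greedy_cluster({"a": s, "b": far}).clusters) == 2

    def test_planted_duplicates_collapse_to_one_representative(self, rng):
        parent = _random_nt(rng, 600)
        contigs = {"parent": parent}
        for i in range(5):
            contigs[f"dup{i}"] = _mutate(parent, 12, rng)  # 98% identity
        cs = greedy_cluster(contigs)
        # equal lengths: ties break lexicographically, so dup0 represents
        assert cs.representatives == ["dup0"]
        assert sorted(cs.clusters["dup0"]) == sorted(contigs)

    def test_matches_reference_on_random_sets(self, rng):
        """Greedy clustering agrees with an all-pairs brute-force rerun."""
        parents = [_random_nt(rng, int(rng.integers(200, 800))) for _ in range(8)]
        contigs = {}
        for i, p in enumerate(parents):
            contigs[f"p{i}"] = p
            for j in range(int(rng.integers(0, 4))):
                k = max(1, int(0.02 * len(p)))
                contigs[f"p{i}d{j}"] = _mutate(p, k, rng)
        got = greedy_cluster(contigs, 0.95).clusters
        want = greedy_cluster_reference(contigs, pairwise_identity, 0.95)
        assert got == want

    def test_fixpoint_on_representatives(self, rng):
        contigs = {f"c{i}": _random_nt(rng, int(rng.integers(200, 600))) for i in range(12)}
        cs = greedy_cluster(contigs)
        reps = {r: contigs[r] for r in cs.representatives}
        cs2 = greedy_cluster(reps)
        assert sorted(cs2.representatives) == sorted(cs.representatives)

    def test_representative_is_longest_member(self, rng):
        parent = _random_nt(rng, 500)
        contigs = {"zshort": parent[:400], "afull": parent}
        cs = greedy_cluster(contigs)
        assert cs.representatives == ["afull"]


class TestCurateIsoforms:
    def test_exact_substring_redundant(self, rng):
        s = _random_nt(rng, 800)
        verdicts = curate_isoforms({"long": s, "sub": s[100:500]})
        assert verdicts == {"long": "retained", "sub": "redundant"}

    def test_unique_internal_segment_retained(self, rng):
        s = _random_nt(rng, 800)
        variant = s[:300] + _random_nt(rng, 100) + s[300:600]
        verdicts = curate_isoforms({"full": s, "variant": variant})
        assert verdicts["variant"] == "retained"

    def test_single_member_retained(self, rng):
        assert curate_isoforms({"only": _random_nt(rng, 300)}) == {"only": "retained"}


class TestMergeFragments:
    def test_exact_overlap_arithmetic(self, rng):
        parent = _random_nt(rng, 870)
        a, b = parent[:530], parent[500:]  # 500+overlap30 / 370
        merged = merge_fragments(a, b)
        assert merged == parent
        assert len(merged) == 870

    def test_no_overlap_returns_none(self, rng):
        assert merge_fragments(_random_nt(rng, 300), _random_nt(rng, 300)) is None

    def test_argument_order_irrelevant(self, rng):
        parent = _random_nt(rng, 600)
        a, b = parent[:350], parent[320:]
        assert merge_fragments(b, a) == parent


def _coding_contig(rng, n_aa=120):
    """Contig with UTRs and a planted ORF encoding a random protein."""
    prot = list(simulate_proteome(1, (n_aa, n_aa), rng).values())[0]
    orf = reverse_translate(prot, rng)
    utr5, utr3 = _random_nt(rng, 60), _random_nt(rng, 60)
    return utr5 + orf + utr3, prot, len(utr5)


class TestIntronRetention:
    def test_planted_insert_flagged_and_excised(self, rng):
        contig, prot, s = _coding_contig(rng)
        point = s + 3 * 60
        insert = "GT" + _random_nt(rng, 56) + "AG"
        broken = contig[:point] + insert + contig[point:]
        flag = detect_intron_retention("c", broken, prot)
        assert flag is not None and flag.kind == "intron_retention"
        assert flag.corrected == contig  # excision restores the planted parent

    def test_contiguous_alignment_unflagged(self, rng):
        contig, prot, _ = _coding_contig(rng)
        assert detect_intron_retention("c", contig, prot) is None

    def test_non_gt_ag_insert_unflagged(self, rng):
        contig, prot, s = _coding_contig(rng)
        point = s + 3 * 60
        insert = "CC" + _random_nt(rng, 56) + "TT"
        broken = contig[:point] + insert + contig[point:]
        assert detect_intron_retention("c", broken, prot) is None


class TestFrameshift:
    def test_planted_deletion_flagged_at_junction(self, rng):
        contig, prot, s = _coding_contig(rng)
        at = s + 3 * 60 + 1
        broken = contig[:at] + contig[at + 1 :]
        flag = detect_frameshift("c", broken, prot)
        assert flag is not None and flag.kind == "frameshift"
        lo = int(flag.evidence.split(":")[1].split("-")[0])
        assert abs(lo - at) <= 15  # junction localised near the deletion

    def test_clean_orf_unflagged(self, rng):
        contig, prot, _ = _coding_contig(rng)
        assert detect_frameshift("c", contig, prot) is None

    def test_long_junction_unflagged(self, rng):
        """Frame change across a 200-nt junction is not a single-base indel."""
        contig, prot, s = _coding_contig(rng)
        point = s + 3 * 60
        # 200-nt junk insert whose length is not a codon multiple
        broken = contig[:point] + "CC" + _random_nt(rng, 196) + "TT" + contig[point:]
        assert detect_frameshift("c", broken, prot) is None
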