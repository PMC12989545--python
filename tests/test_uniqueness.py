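"""Singleton screen: alignment engine, clustering, refinement, filtering."""

import math
import random

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from strainmark.seqio import ProteinRecord
from strainmark.uniqueness import (
    KA_K,
    KA_LAMBDA,
    MarkerCandidate,
    ScreenConfig,
    align_pair,
    cluster_proteins,
    evalue,
    filter_candidates,
    find_singletons,
    refine_by_background,
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"

_B62 = substitution_matrices.load("BLOSUM62")


def _score(a: str, b: str) -> float:
    if a == "X" or b == "X":
        return 0.0
    return float(_B62[a, b])


def sw_affine_oracle(a: str, b: str, gap_open: float = 12.0, gap_extend: float = 1.0):
    """Independent Smith-Waterman/Gotoh: returns the optimal local score.

    First gapped residue costs gap_open, each further one gap_extend —
    the same affine convention as the production aligner.
    """
    n, m = len(a), len(b)
    NEG = -1e9
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_extend)
            H[i][j] = max(
                0.0,
                H[i - 1][j - 1] + _score(a[i - 1], b[j - 1]),
                E[i][j],
                F[i][j],
            )
            best = max(best, H[i][j])
    return best


class TestAlignPair:
    def test_identical_sequences(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        res = align_pair(seq, seq)
        assert res.identity == 1.0
        assert res.coverage_a == res.coverage_b == 1.0

    def test_containment_coverage(self):
        rng = random.Random(3)
        b = "".join(rng.choice(AA20) for _ in range(100))
        a = b[:50]
        res = align_pair(a, b)
        assert res.coverage_a == 1.0
        assert res.coverage_b == pytest.approx(0.5, abs=0.02)
        assert res.identity == 1.0

    def test_score_matches_dp_oracle_on_random_pairs(self):
        rng = random.Random(42)
        for _ in range(30):
            a = "".join(rng.choice(AA20) for _ in range(rng.randint(30, 60)))
            b = "".join(rng.choice(AA20) for _ in range(rng.randint(30, 60)))
            assert align_pair(a, b).score == sw_affine_oracle(a, b)

    def test_identity_on_mutated_pair_is_exact(self):
        # substitutions only, interior positions: the optimal local
        # alignment is the full-length ungapped one, so identity is the
        # Hamming fraction
        rng = random.Random(7)
        base = "".join(rng.choice(AA20) for _ in range(120))
        seq = list(base)
        pos = rng.sample(range(2, 118), 12)
        for p in pos:
            seq[p] = rng.choice([c for c in AA20 if c != seq[p]])
        res = align_pair(base, "".join(seq))
        assert res.identity == pytest.approx((120 - 12) / 120)

    def test_x_is_neutral(self):
        res = align_pair("MKTAYIAKQR", "MKTAXIAKQR")
        assert res.score == align_pair("MKTAYIAKQR", "MKTAYIAKQR").score - _score("Y", "Y")

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            align_pair("", "MKT")


def _prot(i, seq, strain="s"):
    return ProteinRecord(id=f"p{i:03d}", sequence=seq, strain=strain, product="protein")


class TestClustering:
    def test_identical_pair_one_cluster(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQ"
        clusters = cluster_proteins([_prot(1, seq), _prot(2, seq)])
        assert len(clusters) == 1 and len(clusters[0].members) == 2

    def test_half_identity_pair_two_singletons(self):
        rng = random.Random(5)
        a = "".join(rng.choice(AA20) for _ in range(80))
        b = list(a)
        for p in rng.sample(range(2, 78), 40):  # mutate half the positions
            b[p] = rng.choice([c for c in AA20 if c != b[p]])
        b = "".join(b)
        assert align_pair(a, b).identity < 0.8  # oracle confirms below threshold
        clusters = cluster_proteins([_prot(1, a), _prot(2, b)])
        assert len(clusters) == 2

    def test_partition_property(self, pangenome42):
        proteomes, _ = pangenome42
        prots = [p for plist in proteomes.values() for p in plist]
        clusters = cluster_proteins(prots)
        all_members = [m for c in clusters for m in c.members]
        assert sorted(all_members) == sorted(p.id for p in prots)

    def test_prefilter_equivalence(self, pangenome42):
        proteomes, _ = pangenome42
        prots = [p for plist in proteomes.values() for p in plist]
        with_f = cluster_proteins(prots, use_prefilter=True)
        without_f = cluster_proteins(prots, use_prefilter=False)
        assert [sorted(c.members) for c in with_f] == [sorted(c.members) for c in without_f]

    def test_permutation_invariance(self, pangenome42):
        proteomes, _ = pangenome42
        prots = [p for plist in proteomes.values() for p in plist]
        shuffled = list(prots)
        random.Random(99).shuffle(shuffled)
        c1 = cluster_proteins(prots)
        c2 = cluster_proteins(shuffled)
        assert [sorted(c.members) for c in c1] == [sorted(c.members) for c in c2]

    def test_pangenome_truth(self, pangenome42):
        proteomes, truth = pangenome42
        prots = [p for plist in proteomes.values() for p in plist]
        clusters = cluster_proteins(prots)
        multi = [c for c in clusters if len(c.strains_present) > 1]
        assert len(multi) == 50  # every core family is one multi-strain cluster
        assert all(len(c.members) == 5 for c in multi)
        singles = find_singletons(clusters, "focal")
        assert singles == sorted(truth.truth["singleton_ids"])

    def test_empty_input_error(self):
        with pytest.raises(ValueError):
            cluster_proteins([])


class TestFindSingletons:
    def test_focal_copy_of_background_not_returned(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        prots = [_prot(1, seq, "focal"), _prot(2, seq, "bg1")]
        clusters = cluster_proteins(prots)
        assert find_singletons(clusters, "focal") == []

    def test_missing_focal_strain_error(self):
        clusters = cluster_proteins([_prot(1, "MKTAYIAKQRQISFVK", "bg1")])
        with pytest.raises(ValueError, match="absent"):
            find_singletons(clusters, "focal")


class TestRefineAndFilter:
    def test_empty_panel_all_zero_lexicographic(self):
        rng = random.Random(1)
        prots = [_prot(i, "".join(rng.choice(AA20) for _ in range(60))) for i in (3, 1, 2)]
        cands = refine_by_background([p.id for p in prots], prots, [])
        assert [c.homolog_count for c in cands] == [0, 0, 0]
        assert [c.protein.id for c in cands] == sorted(p.id for p in prots)

    def test_exact_copy_in_panel_ranks_last(self):
        rng = random.Random(2)
        seqs = ["".join(rng.choice(AA20) for _ in range(80)) for _ in range(3)]
        prots = [_prot(i, s) for i, s in enumerate(seqs)]
        panel = [ProteinRecord(id="bgcopy", sequence=seqs[0], strain="bg")]
        cands = refine_by_background([p.id for p in prots], prots, panel)
        assert cands[-1].protein.id == "p000"
        assert cands[-1].homolog_count == 1
        assert cands[-1].best_identity == 1.0
        # the e-value of a self-match is astronomically significant
        s = align_pair(seqs[0], seqs[0]).score
        assert evalue(s, 80, 80) == KA_K * 80 * 80 * math.exp(-KA_LAMBDA * s) < 1e-50

    def test_unrelated_panel_no_homologs(self):
        rng = random.Random(6)
        cand = _prot(0, "".join(rng.choice(AA20) for _ in range(100)))
        panel = [
            ProteinRecord(id=f"bg{i}", sequence="".join(rng.choice(AA20) for _ in range(100)),
                          strain="bg")
            for i in range(10)
        ]
        (c,) = refine_by_background([cand.id], [cand], panel)
        assert c.homolog_count == 0 and c.best_identity == 0.0

    def test_funnel_16_of_23_short(self):
        # 23 candidates, 16 shorter than 300 bp -> 7 survive the length filter
        cands = []
        for i in range(23):
            bp = 150 if i < 16 else 600
            cands.append(
                MarkerCandidate(
                    protein=ProteinRecord(
                        id=f"c{i:02d}", sequence="A" * (bp // 3 - 1),
                        coding_length_bp=bp, product="predicted enzyme"),
                    homolog_count=0, best_identity=0.0,
                )
            )
        retained, dropped = filter_candidates(cands)
        assert len(retained) == 7 and len(dropped) == 16
        assert all(d.reasons == ("too_short",) for d in dropped)

    def test_boundary_length_exactly_300_retained(self):
        c = MarkerCandidate(
            protein=ProteinRecord(id="c", sequence="A" * 99, coding_length_bp=300,
                                  product="enzyme"),
            homolog_count=0, best_identity=0.0)
        retained, dropped = filter_candidates([c])
        assert retained and not dropped

    def test_hypothetical_dropped_with_reason(self):
        c = MarkerCandidate(
            protein=ProteinRecord(id="c", sequence="A" * 200, coding_length_bp=603,
                                  product="hypothetical protein"),
            homolog_count=0, best_identity=0.0)
        retained, dropped = filter_candidates([c])
        assert not retained and dropped[0].reasons == ("hypothetical",)


class TestScreenConfig:
    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            ScreenConfig(cluster_identity=1.5)
        with pytest.raises(ValueError):
            ScreenConfig(min_gene_length_bp=0)
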