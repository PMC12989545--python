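"""Binding-site search vs exhaustive oracle, amplicon prediction,
specificity flags against generator truth."""

import random

import pytest

from strainmark.insilico import find_binding_sites, predict_amplicons, specificity_check
from strainmark.seqio import GenomeRecord, revcomp
from strainmark.synth import generate_offtarget_panel, random_genome

from conftest import PLANT_PRIMER

COMP = {"A": "T", "T": "A", "G": "C", "C": "G", "N": "N"}


def binding_oracle(primer, genome_seq, max_mismatch=2, anchor3_len=3):
    """Position-by-position scan of both strands, written independently
    of the production (vectorised) implementation."""
    m = len(primer)
    hits = []
    for start in range(len(genome_seq) - m + 1):
        win = genome_seq[start : start + m]
        # + strand: primer left-to-right, 3' end at the right
        mm = sum(1 for p, g in zip(primer, win) if g == "N" or p != g)
        anchor_mm = sum(
            1 for p, g in zip(primer[-anchor3_len:], win[-anchor3_len:]) if g == "N" or p != g
        )
        if mm <= max_mismatch and anchor_mm == 0:
            hits.append((start, start + m, "+", mm))
        # - strand: primer complements the window read right-to-left,
        # 3' end at the window's left edge
        mm = sum(1 for p, g in zip(primer, reversed(win)) if g == "N" or p != COMP[g])
        anchor_mm = sum(
            1
            for p, g in zip(primer[-anchor3_len:], reversed(win[: anchor3_len]))
            if g == "N" or p != COMP[g]
        )
        if mm <= max_mismatch and anchor_mm == 0:
            hits.append((start, start + m, "-", mm))
    return sorted(hits)


class TestFindBindingSites:
    def test_planted_verbatim_site(self):
        g = random_genome(1000, seed=21)
        seq = list(g.sequence)
        seq[100:120] = list(PLANT_PRIMER)
        g = GenomeRecord(id="g", sequence="".join(seq))
        plus = [s for s in find_binding_sites(PLANT_PRIMER, g) if s.strand == "+"]
        assert any(s.start == 100 and s.mismatches == 0 for s in plus)

    def test_planted_revcomp_site_minus_strand(self):
        g = random_genome(1000, seed=22)
        seq = list(g.sequence)
        seq[700:720] = list(revcomp(PLANT_PRIMER))
        g = GenomeRecord(id="g", sequence="".join(seq))
        minus = [s for s in find_binding_sites(PLANT_PRIMER, g) if s.strand == "-"]
        assert any(s.start == 700 and s.mismatches == 0 for s in minus)

    def test_3prime_anchor_mismatch_rejected(self):
        g = random_genome(1000, seed=23)
        seq = list(g.sequence)
        internal = list(PLANT_PRIMER)
        internal[5] = {"A": "C", "C": "A", "G": "T", "T": "G"}[internal[5]]
        seq[100:120] = internal
        terminal = list(PLANT_PRIMER)
        terminal[-1] = {"A": "C", "C": "A", "G": "T", "T": "G"}[terminal[-1]]
        seq[500:520] = terminal
        g = GenomeRecord(id="g", sequence="".join(seq))
        starts = {s.start for s in find_binding_sites(PLANT_PRIMER, g, max_mismatch=2)}
        assert 100 in starts and 500 not in starts

    def test_n_never_matches(self):
        g = GenomeRecord(id="g", sequence="A" * 40 + PLANT_PRIMER.replace("C", "N") + "A" * 40)
        assert find_binding_sites(PLANT_PRIMER, g, max_mismatch=2) == []

    def test_primer_longer_than_genome(self):
        g = GenomeRecord(id="g", sequence="ACGTACGTAC")
        assert find_binding_sites(PLANT_PRIMER, g) == []

    def test_matches_exhaustive_oracle_on_random_genomes(self):
        rng = random.Random(31)
        for trial in range(8):
            g = random_genome(3000, seed=100 + trial)
            primer = "".join(rng.choice("ACGT") for _ in range(rng.randint(12, 16)))
            got = sorted(
                (s.start, s.end, s.strand, s.mismatches)
                for s in find_binding_sites(primer, g, max_mismatch=3)
            )
            assert got == binding_oracle(primer, g.sequence, max_mismatch=3)


class TestPredictAmplicons:
    def _genome_with_product(self, product_bp, seed=41, genome_len=3000, at=500):
        g = random_genome(genome_len, seed=seed)
        seq = list(g.sequence)
        seq[at : at + 20] = list(PLANT_PRIMER)
        rev_site = revcomp(PLANT_PRIMER)
        seq[at + product_bp - 20 : at + product_bp] = list(rev_site)
        return GenomeRecord(id="g", sequence="".join(seq))

    def test_planted_400bp_product(self):
        g = self._genome_with_product(400)
        hits = predict_amplicons((PLANT_PRIMER, PLANT_PRIMER), g)
        assert len(hits) >= 1
        h = hits[0]
        assert h.length_bp == 400
        assert h.sequence == g.sequence[h.start : h.end]

    def test_product_beyond_cap_not_reported(self):
        g = self._genome_with_product(2500, genome_len=4000)
        assert predict_amplicons((PLANT_PRIMER, PLANT_PRIMER), g, max_product_bp=2000) == []

    def test_two_forward_sites_two_amplicons(self):
        g = random_genome(3000, seed=43)
        seq = list(g.sequence)
        seq[200:220] = list(PLANT_PRIMER)
        seq[400:420] = list(PLANT_PRIMER)
        seq[780:800] = list(revcomp(PLANT_PRIMER))
        g = GenomeRecord(id="g", sequence="".join(seq))
        hits = predict_amplicons((PLANT_PRIMER, PLANT_PRIMER), g)
        lengths = sorted(h.length_bp for h in hits)
        # the planted primer equals the planted reverse primer here, so
        # both orientations report each pairing; dedupe by coordinates
        coords = sorted({(h.start, h.end) for h in hits})
        assert coords == [(200, 800), (400, 800)]
        assert 600 in lengths and 400 in lengths

    def test_strand_symmetry(self):
        g = self._genome_with_product(400, seed=44)
        g_rc = GenomeRecord(id="g_rc", sequence=revcomp(g.sequence))
        fwd_hits = predict_amplicons((PLANT_PRIMER, PLANT_PRIMER), g)
        rc_hits = predict_amplicons((PLANT_PRIMER, PLANT_PRIMER), g_rc)
        assert sorted(h.length_bp for h in fwd_hits) == sorted(h.length_bp for h in rc_hits)
        assert len(fwd_hits) == len(rc_hits)


class TestSpecificity:
    PAIR = (PLANT_PRIMER, "CACCTTCGAGTGGACCTTGT")

    def _target(self):
        g = random_genome(3000, seed=51)
        seq = list(g.sequence)
        seq[500:520] = list(self.PAIR[0])
        seq[880:900] = list(revcomp(self.PAIR[1]))
        return GenomeRecord(id="target", sequence="".join(seq))

    def test_clean_panel_specific(self):
        genomes, _ = generate_offtarget_panel(self.PAIR, decoy_spec="none",
                                              target_product_bp=400, seed=61)
        report = specificity_check(self.PAIR, self._target(), genomes)
        assert report.specific
        assert all(not v for v in report.mispriming.values())

    def test_comparable_decoy_flagged(self):
        genomes, truth = generate_offtarget_panel(self.PAIR, decoy_spec="comparable_product",
                                                  target_product_bp=400, seed=62)
        report = specificity_check(self.PAIR, self._target(), genomes)
        assert not report.specific
        assert all(report.mispriming[g] for g in truth.truth["planted"])

    def test_long_product_not_flagged_at_default_fraction(self):
        genomes, _ = generate_offtarget_panel(self.PAIR, decoy_spec="long_product",
                                              target_product_bp=400, genome_len_bp=6000,
                                              seed=63)
        report = specificity_check(self.PAIR, self._target(), genomes, max_product_bp=5000)
        assert report.specific
        # the 5x-length products exist, they are just not comparable
        assert any(len(h) for h in report.offtarget_amplicons.values())

    def test_single_site_binds_but_no_amplicon(self):
        genomes, truth = generate_offtarget_panel(self.PAIR, decoy_spec="single_site",
                                                  target_product_bp=400, seed=64)
        report = specificity_check(self.PAIR, self._target(), genomes)
        assert report.specific
        for g in genomes:
            sites = find_binding_sites(self.PAIR[0], g)
            assert any(s.start == truth.truth["planted"][g.id]["forward_site"] for s in sites)
            assert report.offtarget_amplicons[g.id] == []

    def test_no_target_product_hard_error(self):
        clean = random_genome(2000, seed=65)
        with pytest.raises(ValueError, match="no target product"):
            specificity_check(self.PAIR, clean, [])
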