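"""In-silico PCR: primer binding-site search, amplicon prediction and
off-target (mispriming) specificity checks.

Binding is an ungapped mismatch-count model: a primer binds a genomic
window when the total number of mismatches is within a budget and the
3'-terminal anchor bases match exactly (polymerase extension is most
sensitive to 3' mismatches). N in the genome never matches any primer
base. No thermodynamic duplex model is applied — the mismatch rule keeps
the predictions exactly reproducible and easy to audit.

A primer pair amplifies wherever a forward-strand site and a downstream
reverse-strand site converge within a product-size cap; the product
length is measured 5'-end to 5'-end, inclusive of both primers. The
specificity verdict flags an off-target genome when it yields a product
of length comparable to the intended one (within a configurable
fraction, default +/-25%) — such products are the ones that would
confound a melt-curve assay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .primers import PrimerPair
from .seqio import GenomeRecord, revcomp


@dataclass(frozen=True)
class BindingSite:
    genome_id: str
    start: int
    end: int
    strand: str  # '+': primer as given matches the forward strand
    mismatches: int
    role: str = ""  # forward / reverse


@dataclass
class AmpliconHit:
    genome_id: str
    start: int
    end: int
    forward_site: BindingSite
    reverse_site: BindingSite
    sequence: str

    @property
    def length_bp(self) -> int:
        return self.end - self.start


@dataclass
class SpecificityReport:
    target_amplicons: list[AmpliconHit]
    offtarget_amplicons: dict[str, list[AmpliconHit]]
    mispriming: dict[str, bool]
    comparable_fraction: float = 0.25

    @property
    def specific(self) -> bool:
        return not any(self.mispriming.values())


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _scan_strand(
    primer: str, genome_seq: str, max_mismatch: int, anchor3_len: int
) -> list[tuple[int, int]]:
    """(start, mismatches) of windows where the primer (5'->3', left to
    right along genome_seq) binds with its 3' end rightmost."""
    m, n = len(primer), len(genome_seq)
    if m > n:
        return []
    g = _encode(genome_seq)
    p = _encode(primer)
    win = np.lib.stride_tricks.sliding_window_view(g, m)
    # N (0x4E) in the genome never matches a primer base
    mism = ((win != p) | (win == ord("N"))).astype(np.int32)
    total = mism.sum(axis=1)
    anchor = mism[:, m - anchor3_len :].sum(axis=1)
    hits = np.nonzero((total <= max_mismatch) & (anchor == 0))[0]
    return [(int(i), int(total[i])) for i in hits]


def find_binding_sites(
    primer: str,
    genome: GenomeRecord,
    max_mismatch: int = 2,
    anchor3_len: int = 3,
    role: str = "",
) -> list[BindingSite]:
    """All ungapped binding sites of a primer on both strands of a genome.

    A '+' site means the primer sequence itself matches the forward
    strand (3' end at the site's right edge); a '-' site means the primer
    binds the reverse strand (its reverse complement appears on the
    forward strand, primer 3' end at the site's left edge).
    """
    bad = set(primer) - set("ACGT")
    if bad:
        raise ValueError(f"primer contains non-ACGT residues {sorted(bad)}")
    m = len(primer)
    sites = [
        BindingSite(genome.id, start, start + m, "+", mm, role)
        for start, mm in _scan_strand(primer, genome.sequence, max_mismatch, anchor3_len)
    ]
    # reverse strand: primer binds where revcomp(primer) appears forward;
    # the primer's 3' anchor maps to the window's LEFT end, so scan the
    # reverse-complemented genome and map coordinates back
    n = len(genome.sequence)
    for start_rc, mm in _scan_strand(primer, revcomp(genome.sequence), max_mismatch, anchor3_len):
        end = n - start_rc
        sites.append(BindingSite(genome.id, end - m, end, "-", mm, role))
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def predict_amplicons(
    pair: PrimerPair | tuple[str, str],
    genome: GenomeRecord,
    max_product_bp: int = 2000,
    max_mismatch: int = 2,
    anchor3_len: int = 3,
) -> list[AmpliconHit]:
    """Predicted PCR products of a primer pair on one genome.

    Both orientations are enumerated: forward primer on '+' with reverse
    primer on '-', and the swap (reverse on '+', forward on '-'). Product
    length runs 5'-end to 5'-end inclusive of both primers and is capped
    at max_product_bp.
    """
    if isinstance(pair, tuple):
        fwd_seq, rev_seq = pair
    else:
        fwd_seq, rev_seq = pair.forward.sequence, pair.reverse.sequence
    hits: list[AmpliconHit] = []
    for left_seq, right_seq, left_role, right_role in (
        (fwd_seq, rev_seq, "forward", "reverse"),
        (rev_seq, fwd_seq, "reverse", "forward"),
    ):
        left_sites = [
            s
            for s in find_binding_sites(left_seq, genome, max_mismatch, anchor3_len, left_role)
            if s.strand == "+"
        ]
        right_sites = [
            s
            for s in find_binding_sites(right_seq, genome, max_mismatch, anchor3_len, right_role)
            if s.strand == "-"
        ]
        for ls in left_sites:
            for rs in right_sites:
                if ls.start >= rs.end:  # must converge, left 5' upstream
                    continue
                length = rs.end - ls.start
                if length > max_product_bp:
                    continue
                hits.append(
                    AmpliconHit(
                        genome_id=genome.id,
                        start=ls.start,
                        end=rs.end,
                        forward_site=ls,
                        reverse_site=rs,
                        sequence=genome.sequence[ls.start : rs.end],
                    )
                )
    hits.sort(key=lambda h: (h.start, h.end))
    return hits


def specificity_check(
    pair: PrimerPair | tuple[str, str],
    target_genome: GenomeRecord,
    offtarget_genomes: list[GenomeRecord],
    comparable_fraction: float = 0.25,
    max_product_bp: int = 2000,
    max_mismatch: int = 2,
    anchor3_len: int = 3,
) -> SpecificityReport:
    """Flag off-target genomes producing comparably long products.

    An off-target genome mis-primes when any of its predicted amplicons
    has length within [(1-f)L, (1+f)L] of a target product length L. The
    pair is "specific" when no off-target genome is flagged.
    """
    target_hits = predict_amplicons(pair, target_genome, max_product_bp, max_mismatch, anchor3_len)
    if not target_hits:
        raise ValueError("no target product: primer pair yields no amplicon on the target genome")
    target_lengths = [h.length_bp for h in target_hits]
    off_hits: dict[str, list[AmpliconHit]] = {}
    flags: dict[str, bool] = {}
    for g in offtarget_genomes:
        hits = predict_amplicons(pair, g, max_product_bp, max_mismatch, anchor3_len)
        off_hits[g.id] = hits
        flags[g.id] = any(
            (1 - comparable_fraction) * L <= h.length_bp <= (1 + comparable_fraction) * L
            for h in hits
            for L in target_lengths
        )
    return SpecificityReport(
        target_amplicons=target_hits,
        offtarget_amplicons=off_hits,
        mispriming=flags,
        comparable_fraction=comparable_fraction,
    )
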