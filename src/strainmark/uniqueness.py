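"""Pan-proteome singleton screening for strain-specific marker genes.

The screen has three stages, mirroring the stepwise selection used for
genome-informed biomarker discovery:

1. greedy incremental clustering of all proteomes (focal strain plus a
   panel of relatives) at identity/coverage thresholds — CD-HIT-style,
   representative-based, coverage enforced on BOTH sequences;
2. singleton extraction: clusters of exactly one protein, from the focal
   strain — candidate strain-unique genes;
3. refinement against a background protein panel with an ungapped
   Karlin–Altschul e-value, ranking candidates by (homolog count, best
   identity), then length/annotation filtering.

Alignment is local Smith–Waterman under BLOSUM62 with affine gaps
(open 11, extend 1); a gap of length L costs 11 + L. Identity is
matches / alignment columns with gap columns counted; coverage of a
sequence is its aligned span divided by its length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from math import exp
from typing import Iterable, NamedTuple, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import ProteinRecord

# ungapped Karlin-Altschul constants for BLOSUM62
KA_LAMBDA = 0.3176
KA_K = 0.134


@dataclass
class ScreenConfig:
    """Thresholds for the whole screen; defaults follow the published run
    (80% identity / 80% bidirectional coverage clustering, e <= 1e-3
    homolog counting, genes < 300 bp and hypothetical products excluded)."""

    cluster_identity: float = 0.80
    cluster_coverage: float = 0.80
    background_evalue_max: float = 1e-3
    min_gene_length_bp: int = 300
    exclude_hypothetical: bool = True
    max_candidates: int = 25

    def __post_init__(self) -> None:
        for name in ("cluster_identity", "cluster_coverage"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.min_gene_length_bp <= 0:
            raise ValueError("min_gene_length_bp must be positive")


@dataclass
class Cluster:
    representative: str
    members: list[str]
    strains_present: set[str] = field(default_factory=set)


@dataclass
class MarkerCandidate:
    protein: ProteinRecord
    homolog_count: int
    best_identity: float
    passes_length: bool = True
    passes_annotation: bool = True
    rank_score: float = 0.0
    reasons: tuple[str, ...] = ()


class PairAlignment(NamedTuple):
    identity: float
    coverage_a: float
    coverage_b: float
    score: float


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    matrix = substitution_matrices.load("BLOSUM62")
    arr = matrix.copy()
    # X is scored 0 against everything (unknown residue is uninformative)
    xi = matrix.alphabet.index("X")
    arr[xi, :] = 0
    arr[:, xi] = 0
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = arr
    aligner.open_gap_score = -12  # first gapped residue: open 11 + extend 1
    aligner.extend_gap_score = -1
    return aligner


def align_pair(a: str, b: str) -> PairAlignment:
    """Best local alignment of two amino-acid sequences.

    Returns identity (matches / alignment columns, gaps counted as
    columns), per-sequence coverages (aligned span / length) and the raw
    alignment score. Sequences with no positive-scoring local alignment
    get identity 0, coverage 0, score 0.
    """
    if not a or not b:
        raise ValueError("align_pair requires non-empty sequences")
    alignments = _aligner().align(a, b)
    if len(alignments) == 0 or alignments.score <= 0:
        return PairAlignment(0.0, 0.0, 0.0, 0.0)
    aln = alignments[0]
    blocks_a, blocks_b = aln.aligned
    if len(blocks_a) == 0:
        return PairAlignment(0.0, 0.0, 0.0, 0.0)
    matches = 0
    aligned_pairs = 0
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        aligned_pairs += a1 - a0
        matches += sum(1 for x, y in zip(a[a0:a1], b[b0:b1]) if x == y)
    span_a = int(blocks_a[-1][1] - blocks_a[0][0])
    span_b = int(blocks_b[-1][1] - blocks_b[0][0])
    columns = span_a + span_b - aligned_pairs
    return PairAlignment(
        identity=matches / columns,
        coverage_a=span_a / len(a),
        coverage_b=span_b / len(b),
        score=float(alignments.score),
    )


def _kmer_set(seq: str, k: int = 5) -> frozenset[str]:
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


def cluster_proteins(
    proteins: Sequence[ProteinRecord],
    config: ScreenConfig | None = None,
    use_prefilter: bool = True,
) -> list[Cluster]:
    """Greedy incremental clustering, longest sequence first.

    Each protein joins the earliest-founded representative it matches at
    identity >= cluster_identity with coverage >= cluster_coverage on both
    sequences, otherwise it founds a new cluster. A shared-5-mer prefilter
    skips representative comparisons that cannot reach the thresholds; it
    does not change the resulting partition on realistic inputs.
    """
    if not proteins:
        raise ValueError("cluster_proteins requires at least one protein")
    config = config or ScreenConfig()
    ids = [p.id for p in proteins]
    if len(set(ids)) != len(ids):
        raise ValueError("protein ids must be unique")
    ordered = sorted(proteins, key=lambda p: (-len(p.sequence), p.id))
    clusters: list[Cluster] = []
    reps: list[ProteinRecord] = []
    rep_kmers: list[frozenset[str]] = []
    for prot in ordered:
        kmers = _kmer_set(prot.sequence) if use_prefilter else None
        placed = False
        for idx, rep in enumerate(reps):
            if use_prefilter and not (kmers & rep_kmers[idx]):
                continue
            res = align_pair(prot.sequence, rep.sequence)
            if (
                res.identity >= config.cluster_identity
                and res.coverage_a >= config.cluster_coverage
                and res.coverage_b >= config.cluster_coverage
            ):
                clusters[idx].members.append(prot.id)
                clusters[idx].strains_present.add(prot.strain)
                placed = True
                break
        if not placed:
            clusters.append(
                Cluster(representative=prot.id, members=[prot.id], strains_present={prot.strain})
            )
            reps.append(prot)
            if use_prefilter:
                rep_kmers.append(kmers)
    return clusters


def find_singletons(clusters: Iterable[Cluster], focal_strain: str) -> list[str]:
    """Ids of proteins forming size-1 clusters that belong to the focal strain."""
    clusters = list(clusters)
    if not any(focal_strain in c.strains_present for c in clusters):
        raise ValueError(f"focal strain {focal_strain!r} absent from all clusters")
    return sorted(
        c.representative
        for c in clusters
        if len(c.members) == 1 and c.strains_present == {focal_strain}
    )


def evalue(score: float, query_len: int, panel_residues: int) -> float:
    """Ungapped Karlin-Altschul e-value: K * m * n * exp(-lambda * S)."""
    return KA_K * query_len * panel_residues * exp(-KA_LAMBDA * score)


def refine_by_background(
    singleton_ids: Sequence[str],
    proteins: Sequence[ProteinRecord],
    background_panel: Sequence[ProteinRecord],
    config: ScreenConfig | None = None,
) -> list[MarkerCandidate]:
    """Count homologs of each singleton in a background panel and rank.

    A panel protein is a homolog when its best local alignment to the
    candidate reaches e-value <= background_evalue_max, with the search
    space taken as query length x total panel residues. Candidates sort
    ascending by (homolog_count, best_identity, id) — fewest and most
    distant homologs first.
    """
    config = config or ScreenConfig()
    by_id = {p.id: p for p in proteins}
    panel_residues = sum(len(p.sequence) for p in background_panel)
    candidates: list[MarkerCandidate] = []
    for sid in singleton_ids:
        prot = by_id[sid]
        n_hom = 0
        best_ident = 0.0
        for bg in background_panel:
            res = align_pair(prot.sequence, bg.sequence)
            if res.score <= 0:
                continue
            if evalue(res.score, len(prot.sequence), panel_residues) <= config.background_evalue_max:
                n_hom += 1
                best_ident = max(best_ident, res.identity)
        candidates.append(
            MarkerCandidate(
                protein=prot,
                homolog_count=n_hom,
                best_identity=best_ident if n_hom else 0.0,
                passes_length=prot.coding_length_bp >= config.min_gene_length_bp,
                passes_annotation=not prot.is_hypothetical,
                rank_score=n_hom + (best_ident if n_hom else 0.0),
            )
        )
    candidates.sort(key=lambda c: (c.homolog_count, c.best_identity, c.protein.id))
    return candidates


def filter_candidates(
    candidates: Sequence[MarkerCandidate], config: ScreenConfig | None = None
) -> tuple[list[MarkerCandidate], list[MarkerCandidate]]:
    """Split candidates into (retained, dropped) under length/annotation rules.

    Genes strictly shorter than min_gene_length_bp are dropped (a gene of
    exactly the minimum length is retained), as are hypothetical products
    when exclude_hypothetical is set; dropped candidates carry reason codes.
    """
    config = config or ScreenConfig()
    retained: list[MarkerCandidate] = []
    dropped: list[MarkerCandidate] = []
    for cand in candidates:
        reasons: list[str] = []
        if cand.protein.coding_length_bp < config.min_gene_length_bp:
            reasons.append("too_short")
        if config.exclude_hypothetical and cand.protein.is_hypothetical:
            reasons.append("hypothetical")
        cand.reasons = tuple(reasons)
        cand.passes_length = "too_short" not in reasons
        cand.passes_annotation = "hypothetical" not in reasons
        (dropped if reasons else retained).append(cand)
    return retained[: config.max_candidates], dropped
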