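"""Two-assembly novel-region scan.

Finds intervals of a query assembly with no significant nucleotide
similarity to a reference assembly — the regions a resequencing effort
adds relative to a prior deposit. The engine is classic seed-and-extend:
shared k-mers (both strands) are extended ungapped with an X-drop under
match +1 / mismatch -2 scoring; extensions whose ungapped
Karlin-Altschul e-value (lambda = 1.28, K = 0.46 for +1/-2) is at or
below the threshold mark their query interval as covered. Maximal
uncovered intervals of at least min_region_bp are reported, annotated
with any overlapping features.

Coordinates are linear: circular replicons should be rotated to a
common start before comparison, otherwise the rotation breakpoint
shows up as (at most one) spurious region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import exp, log

from .seqio import FeatureRecord, GenomeRecord, revcomp


@dataclass
class NoveltyConfig:
    seed_k: int = 15
    evalue_max: float = 1e-10
    min_region_bp: int = 10
    xdrop: int = 20

    def __post_init__(self) -> None:
        if self.seed_k < 11:
            raise ValueError("seed_k must be >= 11")
        if self.min_region_bp < 1:
            raise ValueError("min_region_bp must be >= 1")


# ungapped Karlin-Altschul constants for match +1 / mismatch -2
KA_LAMBDA_NT = 1.28
KA_K_NT = 0.46

MATCH = 1
MISMATCH = -2


@dataclass
class NovelRegion:
    query_id: str
    start: int
    end: int
    feature_ids: list[str] = field(default_factory=list)

    @property
    def length_bp(self) -> int:
        return self.end - self.start


def _min_significant_score(m: int, n: int, evalue_max: float) -> float:
    # smallest S with K*m*n*exp(-lambda*S) <= evalue_max
    return (log(KA_K_NT * m * n) - log(evalue_max)) / KA_LAMBDA_NT


def _extend_xdrop(q: str, s: str, qi: int, si: int, k: int, xdrop: int) -> tuple[int, int, int]:
    """Extend a k-mer seed ungapped in both directions with X-drop.

    Returns (query_start, query_end, score) of the best-scoring ungapped
    segment through the seed.
    """
    score = k * MATCH
    # right extension
    best = score
    best_right = qi + k
    i, j = qi + k, si + k
    cur = score
    while i < len(q) and j < len(s):
        cur += MATCH if q[i] == s[j] and q[i] != "N" else MISMATCH
        i += 1
        j += 1
        if cur > best:
            best, best_right = cur, i
        elif best - cur > xdrop:
            break
    # left extension from the best right-extended state
    score = best
    best_left = qi
    i, j = qi - 1, si - 1
    cur = score
    while i >= 0 and j >= 0:
        cur += MATCH if q[i] == s[j] and q[i] != "N" else MISMATCH
        if cur > score:
            score, best_left = cur, i
        elif score - cur > xdrop:
            break
        i -= 1
        j -= 1
    return best_left, best_right, score


def _covered_intervals(query: str, reference: str, config: NoveltyConfig) -> list[tuple[int, int]]:
    k = config.seed_k
    min_score = _min_significant_score(len(query), len(reference), config.evalue_max)
    # index reference k-mers (both strands folded into one index)
    ref_index: dict[str, list[int]] = {}
    for strand_seq in (reference, revcomp(reference)):
        for i in range(len(strand_seq) - k + 1):
            kmer = strand_seq[i : i + k]
            if "N" in kmer:
                continue
            ref_index.setdefault(kmer, []).append(i if strand_seq is reference else -(i + 1))
    covered: list[tuple[int, int]] = []
    # per (strand, diagonal) high-water mark to avoid re-extending seeds
    # inside an already-processed alignment
    diag_seen: dict[tuple[int, int], int] = {}
    rc_ref = revcomp(reference)
    for qi in range(len(query) - k + 1):
        kmer = query[qi : qi + k]
        hits = ref_index.get(kmer)
        if not hits:
            continue
        for h in hits:
            if h >= 0:
                strand, si, subject = 0, h, reference
            else:
                strand, si, subject = 1, -h - 1, rc_ref
            key = (strand, qi - si)
            if diag_seen.get(key, -1) >= qi:
                continue
            qs, qe, score = _extend_xdrop(query, subject, qi, si, k, config.xdrop)
            diag_seen[key] = qe
            if score >= min_score:
                covered.append((qs, qe))
    return _merge(covered)


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [intervals[0]]
    for s, e in intervals[1:]:
        ls, le = merged[-1]
        if s <= le:
            merged[-1] = (ls, max(le, e))
        else:
            merged.append((s, e))
    return merged


def find_novel_regions(
    query: GenomeRecord, reference: GenomeRecord, config: NoveltyConfig | None = None
) -> list[NovelRegion]:
    """Maximal query intervals not covered by any significant alignment.

    Regions are disjoint, sorted, each at least min_region_bp long, and
    annotated with the ids of features overlapping them by >= 1 bp.
    """
    config = config or NoveltyConfig()
    if len(query) < config.seed_k or len(reference) < config.seed_k:
        raise ValueError("both genomes must be at least seed_k long")
    covered = _covered_intervals(query.sequence, reference.sequence, config)
    regions: list[NovelRegion] = []
    pos = 0
    for s, e in covered + [(len(query), len(query))]:
        if s - pos >= config.min_region_bp:
            regions.append(NovelRegion(query_id=query.id, start=pos, end=s))
        pos = max(pos, e)
    for r in regions:
        r.feature_ids = [
            f.id for f in query.features if f.start < r.end and f.end > r.start
        ]
    return regions


@dataclass
class NoveltySummary:
    region_count: int
    total_bp: int
    gene_count: int
    trna_count: int


def summarize_novelty(
    regions: list[NovelRegion], features: list[FeatureRecord] | None = None
) -> NoveltySummary:
    """Aggregate counts: regions, total novel bp, overlapped genes/tRNAs.

    A feature counts once however many regions it straddles; tRNAs are
    recognised by a product description starting with "tRNA".
    """
    if features is None:
        features = []
    overlapped: dict[str, FeatureRecord] = {}
    for f in features:
        for r in regions:
            if f.start < r.end and f.end > r.start:
                overlapped[f.id] = f
                break
    trna = sum(1 for f in overlapped.values() if f.product.lower().startswith("trna"))
    return NoveltySummary(
        region_count=len(regions),
        total_bp=sum(r.length_bp for r in regions),
        gene_count=len(overlapped) - trna,
        trna_count=trna,
    )
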