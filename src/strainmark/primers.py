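"""Primer enumeration and scoring under explicit quality criteria.

Criteria (all configurable): amplicon length > 300 bp (suitable for
real-time PCR with melt analysis), primer self-complementarity score
between 0 and 4, GC content between 40% and 60%, plus standard primer
length / melting-temperature windows used for ranking.

Self-complementarity is scored over all ungapped antiparallel alignments
of a primer against itself: every offset of the sequence against its
reverse complement, best contiguous window, +1 per Watson-Crick pair and
-1 per non-pair. The "end3" mode restricts windows to those covering the
primer's 3'-terminal base, a proxy for extensible primer dimers.

Melting temperatures are nearest-neighbor (SantaLucia 1998 unified
parameters), Tm = dH / (dS + R ln(Ct/4)) - 273.15 + 16.6 log10[Na+].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .seqio import GenomeRecord, revcomp

R_GAS = 1.987  # cal / (mol K)

# SantaLucia (1998) unified nearest-neighbor parameters,
# dH in kcal/mol, dS in cal/(mol K), 5'->3' dinucleotides
NN_PARAMS: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2), "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "GT": (-8.4, -22.4), "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}
# complementary-strand equivalents
for _d, _v in list(NN_PARAMS.items()):
    NN_PARAMS.setdefault(revcomp(_d), _v)

NN_INIT_GC = (0.1, -2.8)   # initiation with terminal G·C
NN_INIT_AT = (2.3, 4.1)    # initiation with terminal A·T


@dataclass
class PrimerCriteria:
    """Pass/fail thresholds for a primer pair.

    min_amplicon_bp encodes the strict "amplicon length > 300 bp" rule as
    >= 301 on integer lengths.
    """

    min_amplicon_bp: int = 301
    gc_min_pct: float = 40.0
    gc_max_pct: float = 60.0
    selfcomp_max: int = 4
    primer_len_min: int = 18
    primer_len_max: int = 24
    tm_min_c: float = 57.0
    tm_max_c: float = 63.0
    max_pair_tm_diff_c: float = 2.0

    def __post_init__(self) -> None:
        if self.gc_min_pct >= self.gc_max_pct:
            raise ValueError("gc_min_pct must be < gc_max_pct")
        if self.primer_len_min > self.primer_len_max:
            raise ValueError("primer_len_min must be <= primer_len_max")
        if self.min_amplicon_bp <= 0:
            raise ValueError("min_amplicon_bp must be positive")


@dataclass
class Primer:
    sequence: str  # 5' -> 3'
    gc_pct: float = field(init=False)
    tm_c: float = field(init=False)
    selfcomp_any: int = field(init=False)
    selfcomp_3p: int = field(init=False)

    def __post_init__(self) -> None:
        self.gc_pct = round(gc_content(self.sequence), 1)
        self.tm_c = primer_tm(self.sequence)
        self.selfcomp_any = self_complementarity(self.sequence, "any")
        self.selfcomp_3p = self_complementarity(self.sequence, "end3")


@dataclass
class PrimerPair:
    forward: Primer
    reverse: Primer
    amplicon_start: int
    amplicon_end: int
    passes: dict[str, bool] = field(default_factory=dict)

    @property
    def amplicon_len(self) -> int:
        return self.amplicon_end - self.amplicon_start


def _check_acgt(seq: str, op: str) -> None:
    if not seq:
        raise ValueError(f"{op}: empty sequence")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"{op}: non-ACGT residues {sorted(bad)}")


def gc_content(seq: str) -> float:
    """GC percentage: 100 * (#G + #C) / length, exact rational."""
    _check_acgt(seq, "gc_content")
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


def self_complementarity(seq: str, mode: str = "any") -> int:
    """Self-dimer score of a primer (see module docstring).

    mode "any": best window anywhere; mode "end3": best window covering
    the 3'-terminal base. Scores are clamped at 0.
    """
    _check_acgt(seq, "self_complementarity")
    if len(seq) < 4:
        raise ValueError("self_complementarity requires length >= 4")
    if mode not in ("any", "end3"):
        raise ValueError(f"unknown mode {mode!r}")
    n = len(seq)
    rc = revcomp(seq)
    best = 0
    for shift in range(-(n - 1), n):
        if mode == "any":
            # Kadane over the overlap of seq and shifted revcomp
            cur = 0
            for i in range(max(0, -shift), min(n, n - shift)):
                cur = max(0, cur + (1 if seq[i] == rc[i + shift] else -1))
                best = max(best, cur)
        else:
            # windows must cover seq's 3'-terminal base (i = n-1)
            if not (0 <= n - 1 + shift < n):
                continue
            # best suffix sum ending at i = n-1
            cur = 0
            best_suffix = -n
            for i in range(n - 1, max(0, -shift) - 1, -1):
                cur += 1 if seq[i] == rc[i + shift] else -1
                best_suffix = max(best_suffix, cur)
            best = max(best, best_suffix)
    return max(best, 0)


def primer_tm(seq: str, na_mM: float = 50.0, oligo_nM: float = 500.0) -> float:
    """Nearest-neighbor melting temperature of a primer in degrees C."""
    _check_acgt(seq, "primer_tm")
    if not (10 <= len(seq) <= 40):
        raise ValueError(f"primer_tm: length {len(seq)} outside [10, 40]")
    dh, ds = 0.0, 0.0
    for i in range(len(seq) - 1):
        h, s = NN_PARAMS[seq[i : i + 2]]
        dh += h
        ds += s
    for terminal in (seq[0], seq[-1]):
        h, s = NN_INIT_GC if terminal in "GC" else NN_INIT_AT
        dh += h
        ds += s
    ct = oligo_nM * 1e-9
    tm_k = (dh * 1000.0) / (ds + R_GAS * math.log(ct / 4.0))
    return tm_k - 273.15 + 16.6 * math.log10(na_mM / 1000.0)


def design_primer_pairs(
    target: GenomeRecord | str,
    criteria: PrimerCriteria | None = None,
    max_pairs: int = 20,
) -> tuple[list[PrimerPair], str | None]:
    """Enumerate and rank primer pairs on a target gene.

    Every (forward window, reverse window) combination within the primer
    length range is considered; a pair is kept when both primers satisfy
    GC, self-complementarity and Tm criteria, the pair Tm difference is
    within bounds, and the amplicon (5'-end to 5'-end, both primers
    included) reaches the minimum length. Ranking: smallest |dTm|, then
    smallest combined self-complementarity, then mean GC closest to 50%,
    ties broken by coordinates. Returns (ranked pairs, reason) where
    reason is set when the result is empty.
    """
    criteria = criteria or PrimerCriteria()
    seq = target.sequence if isinstance(target, GenomeRecord) else target
    n = len(seq)
    if n < criteria.min_amplicon_bp:
        return [], "target_too_short"

    def windows() -> list[tuple[int, int]]:
        out = []
        for length in range(criteria.primer_len_min, criteria.primer_len_max + 1):
            for start in range(0, n - length + 1):
                out.append((start, start + length))
        return out

    def primer_ok(p: Primer) -> bool:
        return (
            criteria.gc_min_pct <= p.gc_pct <= criteria.gc_max_pct
            and p.selfcomp_any <= criteria.selfcomp_max
            and criteria.tm_min_c <= p.tm_c <= criteria.tm_max_c
        )

    # score forward candidates once; reverse primers read the - strand
    fwd: list[tuple[int, int, Primer]] = []
    rev: list[tuple[int, int, Primer]] = []
    for s, e in windows():
        window = seq[s:e]
        if set(window) - set("ACGT"):
            continue
        pf = Primer(window)
        if primer_ok(pf):
            fwd.append((s, e, pf))
        pr = Primer(revcomp(window))
        if primer_ok(pr):
            rev.append((s, e, pr))

    pairs: list[PrimerPair] = []
    for fs, fe, pf in fwd:
        for rs, re_, pr in rev:
            if rs < fe:  # primers must not overlap; forward 5' of reverse
                continue
            amplicon_len = re_ - fs  # 5'-end to 5'-end, inclusive of both
            if amplicon_len < criteria.min_amplicon_bp:
                continue
            if abs(pf.tm_c - pr.tm_c) > criteria.max_pair_tm_diff_c:
                continue
            pairs.append(
                PrimerPair(
                    forward=pf,
                    reverse=pr,
                    amplicon_start=fs,
                    amplicon_end=re_,
                    passes={
                        "amplicon_length": True,
                        "gc": True,
                        "selfcomp": True,
                        "tm_range": True,
                        "pair_tm_diff": True,
                    },
                )
            )
    if not pairs:
        return [], "no_pair_satisfies_criteria"
    pairs.sort(
        key=lambda p: (
            abs(p.forward.tm_c - p.reverse.tm_c),
            p.forward.selfcomp_any + p.reverse.selfcomp_any,
            abs((p.forward.gc_pct + p.reverse.gc_pct) / 2.0 - 50.0),
            p.amplicon_start,
            p.amplicon_end,
        )
    )
    return pairs[:max_pairs], None
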