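"""Deterministic synthetic-data generators with planted ground truth.

Each generator is a pure function of its parameters and a seed, and
returns both the generated artifact(s) and a TruthTable recording what
was planted — the answer key the screening, PCR-prediction, melt
classification and novelty-scan stages are judged against.

What the generators emulate, and what they do not:

* ``generate_pangenome`` — a focal proteome carrying strain-unique genes
  among background proteomes that share core gene families at a
  controlled identity. Core families diverge by substitutions only (no
  indels), placed at the SAME positions in every non-focal strain so
  that all cross-strain pairs sit at ~the requested identity; real
  pan-genomes have indels, paralogy and phylogenetic structure that this
  deliberately lacks.
* ``generate_offtarget_panel`` — random genomes with primer-binding
  decoys planted per scenario (none / comparable product / overly long
  product / one orphan site), standing in for near-relative genomes in
  a specificity screen.
* ``generate_qpcr_dataset`` — per-group Bernoulli colonization with
  Gaussian Ct and Tm around assay-specific values; negatives either
  stay flat, amplify late, or melt off-peak. Control groups never
  contain the organism.
* ``plant_insertions`` — a query genome made from a reference by
  inserting random sequence at non-overlapping positions, the ground
  truth for the novel-region scanner.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .melt import QpcrObservation
from .primers import PrimerPair
from .seqio import GenomeRecord, ProteinRecord, revcomp
from .uniqueness import align_pair

AA20 = "ACDEFGHIKLMNPQRSTVWY"
NT4 = "ACGT"


@dataclass
class TruthTable:
    """The planted answer set plus the parameters that produced it."""

    kind: str
    params: dict
    truth: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"kind": self.kind, "params": self.params, "truth": self.truth},
                      fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthTable":
        with open(path) as fh:
            d = json.load(fh)
        return cls(kind=d["kind"], params=d["params"], truth=d["truth"])


def _random_seq(rng: np.random.Generator, length: int, alphabet: str = NT4) -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def _mutate_at(rng: np.random.Generator, seq: str, positions: Sequence[int], alphabet: str) -> str:
    out = list(seq)
    for p in positions:
        choices = [c for c in alphabet if c != out[p]]
        out[p] = choices[rng.integers(len(choices))]
    return "".join(out)


# ---------------------------------------------------------------------------
# Pangenome


def generate_pangenome(
    n_background: int = 4,
    n_core: int = 50,
    core_identity: float = 0.95,
    n_planted_singletons: int = 5,
    gene_len_range_bp: tuple[int, int] = (150, 900),
    gc_range: tuple[float, float] = (0.4, 0.7),
    seed: int = 42,
    focal_strain: str = "focal",
    validate: bool = True,
) -> tuple[dict[str, list[ProteinRecord]], TruthTable]:
    """Proteomes for one focal and n_background strains with planted truth.

    Core families are generated once and point-mutated (substitutions
    only, at family-wide fixed positions) so every cross-strain pair of a
    family sits at ~core_identity. Planted singletons are random genes
    present only in the focal strain. Gene lengths are drawn from
    gene_len_range_bp, with at least one planted singleton forced below
    300 bp when the range permits, so downstream length filtering is
    exercised.
    """
    if n_background < 1:
        raise ValueError("n_background must be >= 1")
    if not (0.5 < core_identity <= 1.0):
        raise ValueError("core_identity must be in (0.5, 1]")
    lo, hi = gene_len_range_bp
    if lo < 60 or hi < lo:
        raise ValueError("gene_len_range_bp must be sane (>= 60 bp, lo <= hi)")
    rng = np.random.default_rng(seed)
    strains = [focal_strain] + [f"bg{i+1}" for i in range(n_background)]
    proteomes: dict[str, list[ProteinRecord]] = {s: [] for s in strains}

    for fam in range(n_core):
        aa_len = int(rng.integers(lo, hi + 1)) // 3
        ancestor = _random_seq(rng, aa_len, AA20)
        n_mut = int(round((1.0 - core_identity) * aa_len))
        # interior positions only: terminal mismatches would be clipped by
        # local alignment and bias the identity audit
        positions = (2 + rng.choice(aa_len - 4, size=n_mut, replace=False)) if n_mut else []
        # each non-focal strain gets a DISTINCT substitute residue at every
        # mutated position, so every cross-strain pair differs at exactly
        # the mutated positions and all pairwise identities coincide
        subs: dict[int, list[str]] = {}
        for p in positions:
            alts = [c for c in AA20 if c != ancestor[p]]
            subs[int(p)] = list(rng.permutation(alts))
        for si, s in enumerate(strains):
            if s == focal_strain:
                seq = ancestor
            else:
                chars = list(ancestor)
                for p in positions:
                    chars[int(p)] = subs[int(p)][si - 1]
                seq = "".join(chars)
            proteomes[s].append(
                ProteinRecord(
                    id=f"{s}_core{fam:03d}",
                    sequence=seq,
                    strain=s,
                    coding_length_bp=3 * aa_len + 3,
                    product=f"core family {fam} protein",
                )
            )

    planted_ids: list[str] = []
    lengths = [int(rng.integers(lo, hi + 1)) for _ in range(n_planted_singletons)]
    if lo < 300 and n_planted_singletons > 0 and all(l >= 300 for l in lengths):
        lengths[0] = int(rng.integers(lo, 300))
    for i, bp in enumerate(lengths):
        pid = f"{focal_strain}_planted{i:02d}"
        prot = ProteinRecord(
            id=pid,
            sequence=_random_seq(rng, bp // 3, AA20),
            strain=focal_strain,
            coding_length_bp=bp,
            product=f"planted marker {i}",
        )
        proteomes[focal_strain].append(prot)
        planted_ids.append(pid)

    if validate:
        _validate_pangenome(proteomes, strains, focal_strain, planted_ids, core_identity)

    truth = TruthTable(
        kind="pangenome",
        params={
            "n_background": n_background, "n_core": n_core,
            "core_identity": core_identity,
            "n_planted_singletons": n_planted_singletons,
            "gene_len_range_bp": list(gene_len_range_bp), "seed": seed,
            "focal_strain": focal_strain,
        },
        truth={"singleton_ids": planted_ids,
               "planted_lengths_bp": lengths},
    )
    return proteomes, truth


def _validate_pangenome(proteomes, strains, focal_strain, planted_ids, core_identity) -> None:
    # audit one core family: all cross-strain pairs near the target identity
    fam0 = {s: proteomes[s][0] for s in strains}
    for i, s1 in enumerate(strains):
        for s2 in strains[i + 1 :]:
            res = align_pair(fam0[s1].sequence, fam0[s2].sequence)
            if abs(res.identity - core_identity) > 0.02:
                raise ValueError(
                    f"core identity audit failed: {s1} vs {s2} at {res.identity:.3f}, "
                    f"target {core_identity}"
                )
    # planted singletons must not be clusterable with any background protein
    for pid in planted_ids:
        prot = next(p for p in proteomes[focal_strain] if p.id == pid)
        for s in strains:
            if s == focal_strain:
                continue
            for bg in proteomes[s]:
                res = align_pair(prot.sequence, bg.sequence)
                if (
                    res.identity >= core_identity - 0.1
                    and min(res.coverage_a, res.coverage_b) >= 0.8
                ):
                    raise ValueError(
                        f"planted gene {pid} resembles background {bg.id} "
                        f"(identity {res.identity:.2f})"
                    )


# ---------------------------------------------------------------------------
# Off-target panel


def generate_offtarget_panel(
    pair: PrimerPair | tuple[str, str],
    n_genomes: int = 3,
    decoy_spec: str = "none",
    genome_len_bp: int = 5000,
    seed: int = 42,
    target_product_bp: int | None = None,
) -> tuple[list[GenomeRecord], TruthTable]:
    """Random off-target genomes with planted primer-binding decoys.

    decoy_spec: "none" (clean genomes), "comparable_product" (convergent
    sites giving a product within +/-10% of the target's),
    "long_product" (a product 5x the target length), "single_site"
    (forward site only — binds but cannot amplify).
    """
    if isinstance(pair, tuple):
        fwd, rev = pair
        target_len = target_product_bp or 400
    else:
        fwd, rev = pair.forward.sequence, pair.reverse.sequence
        target_len = target_product_bp or pair.amplicon_len
    if genome_len_bp <= 2 * target_len:
        raise ValueError("genome_len_bp must exceed twice the amplicon length")
    rng = np.random.default_rng(seed)
    genomes: list[GenomeRecord] = []
    planted: dict[str, dict] = {}
    for g in range(n_genomes):
        seq = list(_random_seq(rng, genome_len_bp))
        info: dict = {"decoy": decoy_spec}
        if decoy_spec != "none":
            if decoy_spec == "comparable_product":
                product = int(target_len * float(rng.uniform(0.9, 1.1)))
            elif decoy_spec == "long_product":
                product = 5 * target_len
            else:  # single_site
                product = None
            start = int(rng.integers(0, genome_len_bp - (product or len(fwd)) - 1))
            seq[start : start + len(fwd)] = list(fwd)
            info["forward_site"] = start
            if product is not None:
                rc = revcomp(rev)
                seq[start + product - len(rev) : start + product] = list(rc)
                info["reverse_site"] = start + product - len(rev)
                info["product_bp"] = product
        gid = f"offtarget_{g+1}"
        genomes.append(GenomeRecord(id=gid, sequence="".join(seq), role="offtarget"))
        planted[gid] = info
    truth = TruthTable(
        kind="offtarget_panel",
        params={"decoy_spec": decoy_spec, "n_genomes": n_genomes,
                "genome_len_bp": genome_len_bp, "seed": seed,
                "target_product_bp": target_len},
        truth={"planted": planted},
    )
    return genomes, truth


# ---------------------------------------------------------------------------
# qPCR dataset


def generate_qpcr_dataset(
    crops: Sequence[str] = ("wheat", "corn", "oilseed_rape", "pea", "tomato"),
    timepoints: Sequence[int] = (14, 28),
    n_per_group: int = 6,
    true_positive_rate: float = 0.8,
    control_tm_c: float = 84.6,
    assay_id: str = "copG",
    ct_mu: float = 22.0,
    ct_sd: float = 3.0,
    tm_sd: float = 0.15,
    negative_model: str = "absent",
    seed: int = 42,
) -> tuple[list[QpcrObservation], TruthTable]:
    """Per-group Bernoulli colonization with noisy Ct/Tm readouts.

    Positives draw Ct ~ Normal(22, 3) truncated to (0, 40] and
    Tm ~ Normal(control_tm, 0.15). Negatives follow negative_model:
    "absent" (no amplification), "late_ct" (Ct ~ Normal(35, 2), on-peak
    Tm), or "offpeak_tm" (normal Ct, Tm shifted >= 1.5 degC). An
    untreated control group is generated alongside and never colonized.
    """
    if not (0.0 <= true_positive_rate <= 1.0):
        raise ValueError("true_positive_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    obs: list[QpcrObservation] = []
    truth_status: dict[str, bool] = {}

    def draw_ct_pos() -> float:
        while True:
            v = float(rng.normal(ct_mu, ct_sd))
            if 0.0 < v <= 40.0:
                return v

    def make_negative(sid, crop, tp, group) -> QpcrObservation:
        if negative_model == "late_ct":
            ct = float(np.clip(rng.normal(35.0, 2.0), 0.01, 40.0))
            tm = float(rng.normal(control_tm_c, tm_sd))
        elif negative_model == "offpeak_tm":
            ct = draw_ct_pos()
            shift = 1.5 + abs(float(rng.normal(0.0, 1.0)))
            tm = control_tm_c + shift * (1 if rng.random() < 0.5 else -1)
        else:
            ct = tm = None
        return QpcrObservation(sample_id=sid, assay_id=assay_id, ct=ct, tm_c=tm,
                               crop=crop, timepoint_days=tp, group=group)

    for crop in crops:
        for tp in timepoints:
            for i in range(n_per_group):
                sid = f"{crop}_d{tp}_t{i:02d}"
                colonized = bool(rng.random() < true_positive_rate)
                truth_status[sid] = colonized
                if colonized:
                    obs.append(QpcrObservation(
                        sample_id=sid, assay_id=assay_id,
                        ct=draw_ct_pos(),
                        tm_c=float(rng.normal(control_tm_c, tm_sd)),
                        crop=crop, timepoint_days=tp, group="treated"))
                else:
                    obs.append(make_negative(sid, crop, tp, "treated"))
            for i in range(n_per_group):
                sid = f"{crop}_d{tp}_c{i:02d}"
                truth_status[sid] = False
                obs.append(make_negative(sid, crop, tp, "control"))
    truth = TruthTable(
        kind="qpcr_dataset",
        params={"crops": list(crops), "timepoints": list(timepoints),
                "n_per_group": n_per_group,
                "true_positive_rate": true_positive_rate,
                "control_tm_c": control_tm_c, "assay_id": assay_id,
                "negative_model": negative_model, "seed": seed},
        truth={"colonized": truth_status},
    )
    return obs, truth


def write_qpcr_csv(observations: Sequence[QpcrObservation], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample,assay,crop,timepoint_days,group,ct,tm_c\n")
        for o in observations:
            ct = "" if o.ct is None else f"{o.ct:.4f}"
            tm = "" if o.tm_c is None else f"{o.tm_c:.4f}"
            fh.write(f"{o.sample_id},{o.assay_id},{o.crop},{o.timepoint_days},{o.group},{ct},{tm}\n")


# ---------------------------------------------------------------------------
# Planted insertions


def plant_insertions(
    reference: GenomeRecord,
    n_insertions: int = 4,
    len_range_bp: tuple[int, int] = (200, 800),
    seed: int = 42,
) -> tuple[GenomeRecord, TruthTable]:
    """Query genome = reference + random-sequence insertions.

    Insertion points are uniform and non-overlapping; truth records the
    exact inserted intervals in QUERY coordinates.
    """
    rng = np.random.default_rng(seed)
    lo, hi = len_range_bp
    n = len(reference.sequence)
    # keep insertion points well separated and away from the ends so each
    # planted interval maps to exactly one novel region with seedable flanks
    margin, min_sep = 200, 200
    if n_insertions > 0 and n < 2 * margin + n_insertions * min_sep:
        raise ValueError("reference too short for requested insertions")
    points: list[int] = []
    if n_insertions:
        for _ in range(1000):
            cand = sorted(int(p) for p in rng.integers(margin, n - margin, size=n_insertions))
            if all(b - a >= min_sep for a, b in zip(cand, cand[1:])):
                points = cand
                break
        else:
            raise ValueError("could not place non-overlapping insertions")
    pieces: list[str] = []
    intervals: list[tuple[int, int]] = []
    prev = 0
    offset = 0
    for p in points:
        ins_len = int(rng.integers(lo, hi + 1))
        pieces.append(reference.sequence[prev:p])
        start_q = p + offset
        pieces.append(_random_seq(rng, ins_len))
        intervals.append((start_q, start_q + ins_len))
        offset += ins_len
        prev = p
    pieces.append(reference.sequence[prev:])
    query = GenomeRecord(id=f"{reference.id}_resequenced", sequence="".join(pieces))
    truth = TruthTable(
        kind="planted_insertions",
        params={"n_insertions": n_insertions, "len_range_bp": list(len_range_bp),
                "seed": seed, "reference_id": reference.id},
        truth={"insertions": [list(t) for t in intervals]},
    )
    return query, truth


def random_genome(length: int, seed: int, gid: str = "genome", gc: float = 0.5) -> GenomeRecord:
    """A uniform-random genome (optionally GC-biased) for fixtures."""
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    seq = "".join(rng.choice(list("ACGT"), size=length, p=p))
    return GenomeRecord(id=gid, sequence=seq)
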