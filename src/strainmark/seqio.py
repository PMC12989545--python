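"""Sequence and annotation I/O plus the shared domain records.

All coordinates inside the package are 0-based half-open; conversion to the
1-based inclusive conventions of GFF3 happens only at the file boundary.
Nucleotide sequences are normalised on load: uppercased, with every IUPAC
ambiguity code other than N collapsed to N (a conservative choice — an N
never matches a primer base, so specificity claims cannot hinge on an
ambiguous reference base).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

NT_ALPHABET = set("ACGTN")
# IUPAC one-letter ambiguity codes that collapse to N on load
IUPAC_AMBIGUOUS = set("RYSWKMBDHVU")
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

#: product descriptions treated as uninformative annotation (case-insensitive
#: substring match); configurable wherever it is consumed
HYPOTHETICAL_TERMS = (
    "hypothetical protein",
    "uncharacterized protein",
    "domain of unknown function",
    "duf",
)

GenomeRole = Literal["focal", "background", "offtarget"]


@dataclass(frozen=True)
class FeatureRecord:
    """An annotated gene interval on a genome (0-based, half-open)."""

    id: str
    start: int
    end: int
    strand: str
    product: str = "hypothetical protein"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"feature {self.id!r}: require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.id!r}: strand must be '+' or '-', got {self.strand!r}")

    @property
    def length_bp(self) -> int:
        return self.end - self.start


@dataclass
class GenomeRecord:
    """A named nucleotide sequence with optional feature annotations."""

    id: str
    sequence: str
    features: list[FeatureRecord] = field(default_factory=list)
    source_strain: str = ""
    role: GenomeRole = "focal"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"genome {self.id!r}: empty sequence")
        bad = set(self.sequence) - NT_ALPHABET
        if bad:
            raise ValueError(f"genome {self.id!r}: non-normalised residues {sorted(bad)}")
        for f in self.features:
            if f.end > len(self.sequence):
                raise ValueError(
                    f"genome {self.id!r}: feature {f.id!r} end {f.end} beyond sequence "
                    f"length {len(self.sequence)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


def is_hypothetical(product: str, terms: Sequence[str] = HYPOTHETICAL_TERMS) -> bool:
    """Whether a product description denotes an uninformative annotation."""
    p = product.strip().lower()
    return any(t.lower() in p for t in terms)


@dataclass
class ProteinRecord:
    """A protein with its source strain, coding length and annotation."""

    id: str
    sequence: str
    strain: str = ""
    coding_length_bp: int = 0
    product: str = "hypothetical protein"
    hypothetical_terms: Sequence[str] = HYPOTHETICAL_TERMS

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - AA_ALPHABET
        if bad:
            raise ValueError(f"protein {self.id!r}: illegal residues {sorted(bad)}")
        if self.coding_length_bp == 0:
            # default: CDS length incl. stop codon
            self.coding_length_bp = 3 * len(self.sequence) + 3

    @property
    def is_hypothetical(self) -> bool:
        return is_hypothetical(self.product, self.hypothetical_terms)


# ---------------------------------------------------------------------------
# FASTA


def _normalise_nt(seq: str, record_id: str) -> str:
    seq = seq.upper()
    out = []
    warned = False
    for pos, c in enumerate(seq):
        if c in NT_ALPHABET:
            out.append(c)
        elif c in IUPAC_AMBIGUOUS:
            if not warned:
                logger.warning(
                    "record %s: IUPAC ambiguity code %r at position %d mapped to N",
                    record_id, c, pos,
                )
                warned = True
            out.append("N")
        else:
            raise ValueError(
                f"record {record_id!r}: illegal nucleotide {c!r} at position {pos}"
            )
    return "".join(out)


def _validate_aa(seq: str, record_id: str) -> str:
    seq = seq.upper()
    for pos, c in enumerate(seq):
        if c not in AA_ALPHABET:
            raise ValueError(
                f"record {record_id!r}: illegal amino-acid residue {c!r} at position {pos}"
            )
    return seq


def read_fasta(path: str | Path, alphabet: Literal["nt", "aa"]) -> list:
    """Read a FASTA file into GenomeRecords (nt) or ProteinRecords (aa).

    Headers are truncated at the first whitespace; duplicate ids and empty
    files are hard errors; sequences are uppercased and alphabet-validated.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: empty FASTA file")
    seen: set[str] = set()
    out = []
    for rec in records:
        rid = rec.id  # Biopython already truncates at whitespace
        if rid in seen:
            raise ValueError(f"{path}: duplicate record id {rid!r}")
        seen.add(rid)
        raw = str(rec.seq)
        if alphabet == "nt":
            out.append(GenomeRecord(id=rid, sequence=_normalise_nt(raw, rid)))
        else:
            out.append(ProteinRecord(id=rid, sequence=_validate_aa(raw, rid)))
    return out


def write_fasta(records: Iterable, path: str | Path, width: int = 60) -> None:
    """Write records (anything with .id and .sequence) as wrapped FASTA."""
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecords)


# ---------------------------------------------------------------------------
# Annotations (GFF3 / TSV)

_TSV_COLS = ["seqid", "feature_id", "start", "end", "strand", "product"]


def read_annotations(
    path: str | Path, dialect: Literal["gff3", "tsv"]
) -> dict[str, list[FeatureRecord]]:
    """Read gene annotations into per-genome FeatureRecord lists.

    Both dialects use 1-based inclusive coordinates on disk; features are
    converted to the internal 0-based half-open convention here. A missing
    product defaults to "hypothetical protein".
    """
    path = Path(path)
    result: dict[str, list[FeatureRecord]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if dialect == "gff3":
                if len(fields) != 9:
                    raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(fields)}")
                seqid, _src, _ftype, start_s, end_s, _score, strand, _phase, attrs = fields
                attr_map = _parse_gff_attributes(attrs)
                fid = attr_map.get("ID") or attr_map.get("locus_tag") or f"feature_{lineno}"
                product = attr_map.get("product", "hypothetical protein")
            else:
                if fields == _TSV_COLS:  # header row
                    continue
                if len(fields) < 5:
                    raise ValueError(f"{path}:{lineno}: expected >=5 TSV columns, got {len(fields)}")
                seqid, fid, start_s, end_s, strand = fields[:5]
                product = fields[5] if len(fields) > 5 and fields[5] else "hypothetical protein"
            start1, end1 = int(start_s), int(end_s)
            if start1 > end1:
                raise ValueError(f"{path}:{lineno}: start {start1} > end {end1}")
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: unsupported strand {strand!r}")
            feat = FeatureRecord(
                id=fid, start=start1 - 1, end=end1, strand=strand, product=product
            )
            result.setdefault(seqid, []).append(feat)
    return result


def _parse_gff_attributes(attrs: str) -> dict[str, str]:
    out = {}
    for item in attrs.split(";"):
        item = item.strip()
        if item and "=" in item:
            k, v = item.split("=", 1)
            out[k] = v
    return out


def write_annotations_gff3(
    features_by_genome: dict[str, list[FeatureRecord]],
    path: str | Path,
    source: str = "strainmark",
) -> None:
    """Write features back out as GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for seqid in features_by_genome:
            for f in features_by_genome[seqid]:
                attrs = f"ID={f.id};product={f.product}"
                fh.write(
                    f"{seqid}\t{source}\tgene\t{f.start + 1}\t{f.end}\t.\t{f.strand}\t.\t{attrs}\n"
                )


def apply_protein_annotations(
    proteins: Iterable[ProteinRecord],
    features_by_seqid: dict[str, list[FeatureRecord]],
) -> list[ProteinRecord]:
    """Join product descriptions and coding lengths onto proteins.

    Features are matched to proteins by feature id regardless of the
    seqid they were grouped under; unmatched proteins keep their
    defaults (and hence count as hypothetical downstream).
    """
    by_id = {
        f.id: f for feats in features_by_seqid.values() for f in feats
    }
    out = []
    for p in proteins:
        f = by_id.get(p.id)
        if f is not None:
            p.product = f.product
            p.coding_length_bp = f.length_bp
        out.append(p)
    return out


def attach_features(
    genomes: Iterable[GenomeRecord], features_by_genome: dict[str, list[FeatureRecord]]
) -> list[GenomeRecord]:
    """Join annotations onto genomes by id; unknown seqids warn and are skipped."""
    genome_ids = {g.id for g in genomes}
    for seqid in features_by_genome:
        if seqid not in genome_ids:
            warnings.warn(f"annotation seqid {seqid!r} matches no genome; skipped")
    return [
        replace(g, features=list(features_by_genome.get(g.id, [])))
        for g in genomes
    ]


# ---------------------------------------------------------------------------
# Tabular writers

def write_tsv_report(rows: Sequence[dict], path: str | Path, columns: Sequence[str] | None = None) -> None:
    """Write a list of uniform dict rows as a deterministic TSV.

    Column order follows `columns` or the first row's key order; floats are
    serialised with 4 decimals. Mixed types within a column are a hard error.
    """
    path = Path(path)
    if columns is None:
        columns = list(rows[0].keys()) if rows else []
    col_types: dict[str, type] = {}
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            cells = []
            for col in columns:
                v = row[col]
                t = bool if isinstance(v, bool) else (float if isinstance(v, float) else type(v))
                prev = col_types.setdefault(col, t)
                if t is not prev and not (
                    {t, prev} <= {int, float}
                ):
                    raise ValueError(f"column {col!r}: mixed types {prev.__name__}/{t.__name__}")
                if isinstance(v, bool):
                    cells.append("true" if v else "false")
                elif isinstance(v, float):
                    cells.append(f"{v:.4f}")
                else:
                    cells.append(str(v))
            fh.write("\t".join(cells) + "\n")


def write_bed(regions: Sequence, path: str | Path, name_attr: str = "id") -> None:
    """Write intervals (0-based half-open .start/.end on .query_id or genome id) as BED."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\n")
        for r in regions:
            chrom = getattr(r, "query_id", None) or getattr(r, "genome_id", None) or getattr(r, name_attr, "region")
            fh.write(f"{chrom}\t{r.start}\t{r.end}\n")


REVCOMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the normalised {A,C,G,T,N} alphabet."""
    return seq.translate(REVCOMP)[::-1]
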