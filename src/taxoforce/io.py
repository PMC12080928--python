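"""Readers, writers and basic summary statistics for the pipeline's file formats.

Supported formats: FASTA (nucleotide and protein), BLAST tabular (outfmt 6),
Roary-style ``gene_presence_absence.csv``, plain binary TSV matrices, symmetric
similarity matrices in TSV, and two-column habitat tables.  Plain-text and
gzip-compressed files are both accepted.
"""

from __future__ import annotations

import csv
import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "GenomeRecord",
    "ProteomeRecord",
    "HitRecord",
    "PresenceAbsenceMatrix",
    "HabitatDesign",
    "parse_fasta",
    "genome_stats",
    "parse_hits_table",
    "write_hits_table",
    "parse_presence_absence",
    "write_presence_absence",
    "read_habitat_table",
    "write_habitat_table",
    "read_similarity_tsv",
    "write_similarity_tsv",
    "write_fasta",
]

# IUPAC alphabets; '*' (stop) and '-' (gap) tolerated in proteins, '-' in DNA.
_NT_ALPHABET = frozenset("ACGTURYSWKMBDHVN-")
_AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYBJOUXZ*-")
_UNAMBIG_NT = frozenset("ACGT")

# Fixed metadata columns of Roary's gene_presence_absence.csv; everything to
# their right is a genome column.
_ROARY_META_COLUMNS = (
    "Gene",
    "Non-unique Gene name",
    "Annotation",
    "No. isolates",
    "No. sequences",
    "Avg sequences per isolate",
    "Genome Fragment",
    "Order within Fragment",
    "Accessory Fragment",
    "Accessory Order with Fragment",
    "QC",
    "Min group size nuc",
    "Max group size nuc",
    "Avg group size nuc",
)


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


@dataclass
class GenomeRecord:
    """A nucleotide assembly: one or more contig sequences under one label."""

    genome_id: str
    sequences: list[str]

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences)

    @property
    def gc_percent(self) -> float:
        return genome_stats(self)[1]


@dataclass
class ProteomeRecord:
    """The predicted proteome of one genome; ``protein_count`` is the POCP T_i."""

    genome_id: str
    proteins: dict[str, str] = field(default_factory=dict)

    @property
    def protein_count(self) -> int:
        return len(self.proteins)


class HitRecord(NamedTuple):
    """One row of a BLAST tabular (outfmt 6) search result.

    Coordinates are 1-based inclusive, as in the source dialect.
    """

    query_id: str
    subject_id: str
    pident: float
    aln_length: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float


def parse_fasta(path: str | Path, alphabet: str = "nucleotide"):
    """Parse a FASTA file into a :class:`GenomeRecord` or :class:`ProteomeRecord`.

    Parameters
    ----------
    path
        FASTA file (optionally gzipped).  The record id is the first
        whitespace-delimited token of each header; sequences are uppercased.
    alphabet
        ``"nucleotide"`` returns a :class:`GenomeRecord` whose sequences are
        the contigs; ``"protein"`` returns a :class:`ProteomeRecord` keyed by
        protein id.  The genome id defaults to the file stem.

    Raises
    ------
    ValueError
        On an empty file, a duplicate record id, or a character outside the
        IUPAC alphabet (reported with its record and position).
    """
    if alphabet not in ("nucleotide", "protein"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    allowed = _NT_ALPHABET if alphabet == "nucleotide" else _AA_ALPHABET
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    ids: list[str] = []
    seqs: dict[str, str] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            rid = rec.id
            if rid in seqs:
                raise ValueError(f"duplicate record id {rid!r} in {path}")
            seq = str(rec.seq).upper()
            bad = set(seq) - allowed
            if bad:
                pos = next(i for i, ch in enumerate(seq, start=1) if ch in bad)
                raise ValueError(
                    f"illegal character {sorted(bad)[0]!r} at position {pos} "
                    f"of record {rid!r} in {path}"
                )
            ids.append(rid)
            seqs[rid] = seq
    if not ids:
        raise ValueError(f"no records in {path}")

    genome_id = path.name.removesuffix(".gz")
    genome_id = Path(genome_id).stem
    if alphabet == "nucleotide":
        return GenomeRecord(genome_id=genome_id, sequences=[seqs[i] for i in ids])
    return ProteomeRecord(genome_id=genome_id, proteins=seqs)


def write_fasta(record: GenomeRecord | ProteomeRecord, path: str | Path, width: int = 80) -> None:
    """Write a record back to FASTA (contigs named ``<genome_id>_<k>``)."""
    with _open_text(path, "wt") as fh:
        if isinstance(record, ProteomeRecord):
            items = record.proteins.items()
        else:
            items = (
                (f"{record.genome_id}_{k + 1}", s) for k, s in enumerate(record.sequences)
            )
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def genome_stats(genome: GenomeRecord) -> tuple[int, float]:
    """Total assembly length (bases) and G+C content (percent).

    GC is computed as 100·(G+C)/(A+C+G+T): IUPAC ambiguity codes and gaps are
    excluded from both numerator and denominator, so the value is invariant
    under N-runs, contig order and reverse-complementation.
    """
    if not genome.sequences:
        raise ValueError(f"genome {genome.genome_id!r} has no sequences")
    counts = {b: 0 for b in "ACGT"}
    total_len = 0
    for seq in genome.sequences:
        total_len += len(seq)
        for b in "ACGT":
            counts[b] += seq.count(b)
    unambig = sum(counts.values())
    if unambig == 0:
        raise ValueError(
            f"genome {genome.genome_id!r} has no unambiguous bases; GC undefined"
        )
    gc = 100.0 * (counts["G"] + counts["C"]) / unambig
    return total_len, gc


def parse_hits_table(path: str | Path) -> list[HitRecord]:
    """Parse a 12-column BLAST outfmt-6 file; '#' comment lines are skipped."""
    hits: list[HitRecord] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}: line {lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                hits.append(
                    HitRecord(
                        query_id=fields[0],
                        subject_id=fields[1],
                        pident=float(fields[2]),
                        aln_length=int(fields[3]),
                        mismatch=int(fields[4]),
                        gapopen=int(fields[5]),
                        qstart=int(fields[6]),
                        qend=int(fields[7]),
                        sstart=int(fields[8]),
                        send=int(fields[9]),
                        evalue=float(fields[10]),
                        bitscore=float(fields[11]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
    return hits


def write_hits_table(hits: Sequence[HitRecord], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.pident:g}\t{h.aln_length}\t"
                f"{h.mismatch}\t{h.gapopen}\t{h.qstart}\t{h.qend}\t{h.sstart}\t"
                f"{h.send}\t{h.evalue:g}\t{h.bitscore:g}\n"
            )


class PresenceAbsenceMatrix:
    """Binary genome × CDS-cluster matrix (the pangenome).

    Rows are genomes, columns are CDS clusters; values are 0/1.  All-zero rows
    are rejected (a genome with no gene is a parsing artefact, not data).
    """

    def __init__(self, df: pd.DataFrame):
        values = df.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise ValueError("presence/absence matrix must be binary (0/1)")
        if df.columns.duplicated().any():
            raise ValueError("duplicate CDS cluster labels")
        zero_rows = df.index[values.sum(axis=1) == 0].tolist()
        if zero_rows:
            raise ValueError(f"all-zero rows for genomes: {zero_rows}")
        self.df = df.astype(np.int8)

    @property
    def genomes(self) -> list[str]:
        return list(self.df.index)

    @property
    def cds_clusters(self) -> list[str]:
        return list(self.df.columns)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.df.shape

    def __eq__(self, other) -> bool:
        return isinstance(other, PresenceAbsenceMatrix) and self.df.equals(other.df)


@dataclass
class HabitatDesign:
    """Genome → habitat category assignment (the CCA constraint)."""

    assignment: dict[str, str]

    def __post_init__(self):
        if not self.assignment:
            raise ValueError("empty habitat design")

    @property
    def habitats(self) -> list[str]:
        # insertion-ordered distinct habitats
        return list(dict.fromkeys(self.assignment.values()))

    @property
    def genomes(self) -> list[str]:
        return list(self.assignment)

    def members(self, habitat: str) -> list[str]:
        return [g for g, h in self.assignment.items() if h == habitat]

    def require_covering(self, genomes: Sequence[str]) -> None:
        missing = [g for g in genomes if g not in self.assignment]
        if missing:
            raise ValueError(f"genomes without a habitat assignment: {missing}")


def parse_presence_absence(path: str | Path, dialect: str = "roary_csv") -> PresenceAbsenceMatrix:
    """Read a gene presence/absence matrix.

    ``roary_csv`` expects Roary's ``gene_presence_absence.csv`` layout: gene
    rows, the fixed metadata columns, then one column per genome where any
    non-empty cell (including multi-locus paralog cells) counts as presence.
    ``tsv_binary`` expects a plain TSV with genomes as rows, clusters as
    columns and 0/1 values.
    """
    if dialect == "tsv_binary":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return PresenceAbsenceMatrix(df)
    if dialect != "roary_csv":
        raise ValueError(f"unknown dialect {dialect!r}")

    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "Gene" not in raw.columns:
        raise ValueError(f"{path}: no 'Gene' column; not a Roary-style CSV")
    meta = [c for c in _ROARY_META_COLUMNS if c in raw.columns]
    genome_cols = [c for c in raw.columns if c not in meta]
    if not genome_cols:
        raise ValueError(f"{path}: no genome columns found")

    genes = raw["Gene"].tolist()
    seen: dict[str, int] = {}
    labels = []
    for g in genes:
        if g in seen:
            seen[g] += 1
            labels.append(f"{g}_{seen[g]}")
        else:
            seen[g] = 0
            labels.append(g)
    if any(seen.values()):
        dups = [g for g, k in seen.items() if k]
        warnings.warn(f"duplicate gene labels disambiguated: {dups}")

    binary = (raw[genome_cols].to_numpy() != "").astype(np.int8)
    df = pd.DataFrame(binary.T, index=genome_cols, columns=labels)
    return PresenceAbsenceMatrix(df)


def write_presence_absence(
    pa: PresenceAbsenceMatrix, path: str | Path, dialect: str = "tsv_binary"
) -> None:
    if dialect == "tsv_binary":
        pa.df.to_csv(path, sep="\t")
        return
    if dialect != "roary_csv":
        raise ValueError(f"unknown dialect {dialect!r}")
    # minimal Roary-compatible CSV: metadata columns present but sparse
    with _open_text(path, "wt", ) as fh:
        writer = csv.writer(fh, quoting=csv.QUOTE_ALL)
        writer.writerow(list(_ROARY_META_COLUMNS) + pa.genomes)
        arr = pa.values
        for j, gene in enumerate(pa.cds_clusters):
            n_iso = int(arr[:, j].sum())
            meta = [gene, "", "", str(n_iso), str(n_iso), "1.0"] + [""] * 8
            cells = [f"{g}_{gene}" if arr[i, j] else "" for i, g in enumerate(pa.genomes)]
            writer.writerow(meta + cells)


def read_habitat_table(path: str | Path) -> HabitatDesign:
    """Read a two-column ``genome_id<TAB>habitat`` table (header optional)."""
    assignment: dict[str, str] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            if lineno == 1 and fields[0].lower() in ("genome", "genome_id"):
                continue
            g, h = fields
            if g in assignment:
                raise ValueError(f"{path}: duplicate genome {g!r}")
            assignment[g] = h
    if not assignment:
        raise ValueError(f"{path}: no habitat assignments")
    return HabitatDesign(assignment)


def write_habitat_table(design: HabitatDesign, path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("genome_id\thabitat\n")
        for g, h in design.assignment.items():
            fh.write(f"{g}\t{h}\n")


def read_similarity_tsv(path: str | Path, index_kind: str = "AAI"):
    """Read a symmetric similarity matrix TSV (genome ids as header row+column)."""
    from .delineation import SimilarityMatrix

    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column genome ids differ")
    return SimilarityMatrix(
        genomes=list(df.index), values=df.to_numpy(dtype=float), index_kind=index_kind
    )


def write_similarity_tsv(matrix, path: str | Path) -> None:
    pd.DataFrame(matrix.values, index=matrix.genomes, columns=matrix.genomes).to_csv(
        path, sep="\t", float_format="%.2f"
    )
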