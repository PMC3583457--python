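"""Annotated-protein records, proteomes, and flat-file I/O.

A proteome is a set of proteins with genomic positions.  The authoritative
neighbor metric throughout the package is the ordinal gene ``index`` (rank of
the gene on its replicon, 0-based); nucleotide coordinates are carried for
GFF3 round-tripping but never used to define neighborhoods.

On-disk layout (one pair of files per taxon):

* protein FASTA, header ``taxon|replicon|protein_id|index``
* GFF3 v3, 1-based inclusive coordinates, one CDS row per protein with
  ``ID``, ``index`` and ``plasmid`` attributes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 standard amino acids, alphabetical one-letter order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Residues accepted in input sequences (X = unknown).
ALPHABET = frozenset(AMINO_ACIDS + "X")

GFF_COLUMNS = [
    "seqid", "source", "type", "start", "end",
    "score", "strand", "phase", "attributes",
]


class SequenceAlphabetError(ValueError):
    """A sequence contains a residue outside the 20-letter alphabet + X."""


def validate_sequence(sequence: str, label: str = "sequence") -> None:
    """Raise :class:`SequenceAlphabetError` naming the first bad residue."""
    if not sequence:
        raise ValueError(f"{label}: empty sequence")
    for pos, aa in enumerate(sequence):
        if aa not in ALPHABET:
            raise SequenceAlphabetError(
                f"{label}: residue {aa!r} at position {pos} is outside the "
                f"amino-acid alphabet (20 standard residues + X)"
            )


@dataclass(frozen=True)
class ProteinRecord:
    """One annotated protein with its sequence and genomic position."""

    protein_id: str
    taxon_id: str
    replicon_id: str
    index: int              # ordinal gene rank on replicon, 0-based
    start: int              # 1-based inclusive nt coordinate
    end: int
    strand: str             # '+' or '-'
    is_plasmid: bool
    sequence: str

    def __post_init__(self) -> None:
        validate_sequence(self.sequence, self.protein_id)
        if self.start > self.end:
            raise ValueError(f"{self.protein_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.protein_id}: strand must be '+' or '-'")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Proteome:
    """All annotated proteins of one taxon, indexed by id and by replicon."""

    taxon_id: str
    records: List[ProteinRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.records = sorted(self.records, key=lambda r: (r.replicon_id, r.index))
        self._by_id: Dict[str, ProteinRecord] = {}
        self._by_replicon: Dict[str, List[ProteinRecord]] = {}
        for rec in self.records:
            if rec.protein_id in self._by_id:
                raise ValueError(f"duplicate protein id {rec.protein_id!r}")
            self._by_id[rec.protein_id] = rec
            self._by_replicon.setdefault(rec.replicon_id, []).append(rec)
        for replicon, recs in self._by_replicon.items():
            indices = [r.index for r in recs]
            if len(set(indices)) != len(indices):
                raise ValueError(
                    f"{self.taxon_id}/{replicon}: duplicate ordinal gene indices"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._by_id

    def get(self, protein_id: str) -> ProteinRecord:
        return self._by_id[protein_id]

    @property
    def replicons(self) -> List[str]:
        return sorted(self._by_replicon)

    def replicon_records(self, replicon_id: str) -> List[ProteinRecord]:
        """Records of one replicon, ascending ordinal index."""
        return list(self._by_replicon.get(replicon_id, []))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(proteome: Proteome, path: Path) -> None:
    records = [
        SeqRecord(
            Seq(rec.sequence),
            id=f"{rec.taxon_id}|{rec.replicon_id}|{rec.protein_id}|{rec.index}",
            description="",
        )
        for rec in proteome
    ]
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta")


def _parse_fasta_header(header: str) -> Dict[str, str]:
    parts = header.split("|")
    if len(parts) != 4:
        raise ValueError(
            f"FASTA header {header!r} is not 'taxon|replicon|protein_id|index'"
        )
    return {
        "taxon_id": parts[0],
        "replicon_id": parts[1],
        "protein_id": parts[2],
        "index": parts[3],
    }


def read_fasta_sequences(path: Path) -> Dict[str, str]:
    """Map protein_id -> sequence from a per-taxon FASTA."""
    out: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        meta = _parse_fasta_header(rec.id)
        out[meta["protein_id"]] = str(rec.seq)
    return out


# ---------------------------------------------------------------------------
# GFF3 (package dialect: CDS rows only)
# ---------------------------------------------------------------------------

def write_gff3(proteome: Proteome, path: Path) -> None:
    lines = ["##gff-version 3"]
    for rec in proteome:
        attrs = f"ID={rec.protein_id};index={rec.index};plasmid={str(rec.is_plasmid).lower()}"
        lines.append(
            "\t".join(
                [
                    rec.replicon_id, "rebscan", "CDS",
                    str(rec.start), str(rec.end), ".",
                    rec.strand, "0", attrs,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_attributes(raw: str) -> Dict[str, str]:
    out: Dict[str, str] = {}
    for chunk in raw.strip().split(";"):
        if chunk and "=" in chunk:
            key, value = chunk.split("=", 1)
            out[key.strip()] = value.strip()
    return out


def read_gff3_table(path: Path) -> pd.DataFrame:
    """Read CDS rows of a GFF3 file into a flat table.

    Columns: protein_id, replicon_id, index, start, end, strand, is_plasmid.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", names=GFF_COLUMNS, header=None, dtype=str
    )
    df = df[df["type"] == "CDS"].copy()
    rows = []
    for _, row in df.iterrows():
        attrs = _parse_attributes(row["attributes"])
        if "ID" not in attrs:
            raise ValueError(f"GFF3 CDS row without ID attribute in {path}")
        rows.append(
            {
                "protein_id": attrs["ID"],
                "replicon_id": row["seqid"],
                "index": int(attrs.get("index", -1)),
                "start": int(row["start"]),
                "end": int(row["end"]),
                "strand": row["strand"],
                "is_plasmid": attrs.get("plasmid", "false") == "true",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id", "replicon_id", "index",
            "start", "end", "strand", "is_plasmid",
        ],
    )


def read_proteome(taxon_id: str, fasta_path: Path, gff_path: Path) -> Proteome:
    """Assemble a Proteome from its FASTA + GFF3 pair.

    Every CDS must have a sequence and vice versa; mismatches raise with the
    offending ids named.
    """
    seqs = read_fasta_sequences(fasta_path)
    table = read_gff3_table(gff_path)
    gff_ids = set(table["protein_id"])
    missing_seq = sorted(gff_ids - set(seqs))
    missing_cds = sorted(set(seqs) - gff_ids)
    if missing_seq:
        raise ValueError(f"{taxon_id}: CDS without FASTA sequence: {missing_seq}")
    if missing_cds:
        raise ValueError(f"{taxon_id}: FASTA record without CDS: {missing_cds}")
    records = [
        ProteinRecord(
            protein_id=row.protein_id,
            taxon_id=taxon_id,
            replicon_id=row.replicon_id,
            index=int(row.index),
            start=int(row.start),
            end=int(row.end),
            strand=row.strand,
            is_plasmid=bool(row.is_plasmid),
            sequence=seqs[row.protein_id],
        )
        for row in table.itertuples()
    ]
    return Proteome(taxon_id=taxon_id, records=records)


def pool_records(proteomes: Iterable[Proteome]) -> List[ProteinRecord]:
    """All records of several proteomes, deterministic order (taxon, id)."""
    out: List[ProteinRecord] = []
    for proteome in sorted(proteomes, key=lambda p: p.taxon_id):
        out.extend(proteome.records)
    return out


def taxon_of_map(proteomes: Iterable[Proteome]) -> Dict[str, str]:
    """protein_id -> taxon_id over a collection of proteomes."""
    return {rec.protein_id: rec.taxon_id for p in proteomes for rec in p}
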