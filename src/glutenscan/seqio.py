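"""Sequence I/O: protein records and FASTA round-tripping.

FASTA parsing/writing is delegated to :mod:`Bio.SeqIO`; this module adds
the domain record type (accession, class and species annotation), UniProt
header normalisation and the peptide-export header convention
``parent|start-end|enzyme|mcN``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from glutenscan.errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: The 20 standard residues plus X for ambiguity.
ALLOWED_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: Protein classes used for class-level aggregation. B/C/D/gamma are the
#: hordein subfamilies; ALP (avenin-like protein) is prolamin-family but
#: not strictly a hordein and is excluded from net-hordein totals.
PROTEIN_CLASSES = (
    "B-hordein",
    "C-hordein",
    "D-hordein",
    "gamma-hordein",
    "ALP",
    "wheat-HMW-glutenin",
    "other",
)

HORDEIN_CLASSES = frozenset({"B-hordein", "C-hordein", "D-hordein", "gamma-hordein"})

SPECIES_TAGS = ("barley", "wheat", "shared-Poaceae", "other")

_UNIPROT_HEADER = re.compile(r"^(?:sp|tr)\|([^|]+)\|")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein (or peptide) sequence with identity and class annotation."""

    accession: str
    sequence: str
    description: str = ""
    protein_class: str | None = None
    species_tag: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"empty sequence for accession {self.accession!r}")
        bad = set(self.sequence) - ALLOWED_RESIDUES
        if bad:
            raise ValidationError(
                f"sequence of {self.accession!r} contains invalid letters: "
                f"{''.join(sorted(bad))}"
            )
        if self.protein_class is not None and self.protein_class not in PROTEIN_CLASSES:
            raise ValidationError(
                f"unknown protein_class {self.protein_class!r} for {self.accession!r}"
            )
        if self.species_tag is not None and self.species_tag not in SPECIES_TAGS:
            raise ValidationError(
                f"unknown species_tag {self.species_tag!r} for {self.accession!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def _parse_header(header: str) -> tuple[str, str]:
    """Split a FASTA description line into (accession, free-text description).

    UniProt-style ``db|ACC|name`` tokens are reduced to the bare accession.
    """
    token, _, rest = header.partition(" ")
    m = _UNIPROT_HEADER.match(token)
    accession = m.group(1) if m else token
    return accession, rest.strip()


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA file into :class:`ProteinRecord` objects.

    Sequences are uppercased and trailing ``*`` stop markers stripped.
    Raises :class:`FormatError` if the first non-blank line is not a FASTA
    header, and :class:`ValidationError` for records with empty sequences
    or duplicate accessions.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FormatError(
                        f"{path}: line {lineno} is not a FASTA header "
                        f"(expected '>'): {line.strip()[:40]!r}"
                    )
                break
        else:
            logger.warning("%s: empty FASTA file, no records read", path)
            return []

    records: list[ProteinRecord] = []
    seen: set[str] = set()
    empties: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        accession, description = _parse_header(rec.description)
        seq = str(rec.seq).upper().replace("*", "")
        if not seq:
            empties.append(accession)
            continue
        if accession in seen:
            raise ValidationError(f"{path}: duplicate accession {accession!r}")
        seen.add(accession)
        records.append(ProteinRecord(accession=accession, sequence=seq, description=description))
    if empties:
        raise ValidationError(
            f"{path}: records with empty sequences: {', '.join(empties)}"
        )
    return records


def read_peptide_list(path: str | Path) -> list[str]:
    """Read detected peptides from FASTA or a one-sequence-per-line list.

    Any plain-text peptide list a search engine exports can be consumed;
    blank lines are skipped and sequences are uppercased.
    """
    path = Path(path)
    with open(path) as fh:
        first = ""
        for line in fh:
            if line.strip():
                first = line
                break
    if first.startswith(">"):
        return [r.sequence for r in read_fasta(path)]
    peptides: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            seq = line.strip().upper()
            if not seq:
                continue
            bad = set(seq) - ALLOWED_RESIDUES
            if bad:
                raise ValidationError(
                    f"{path}: line {lineno}: invalid residue(s) {''.join(sorted(bad))}"
                )
            peptides.append(seq)
    return peptides


def write_peptides_fasta(peptides: Sequence, path: str | Path) -> Path:
    """Write digestion products as FASTA with self-describing headers.

    Header convention: ``parent_accession|start-end|enzyme|mcN`` — enough
    to recover coordinates and provenance by parsing the accession token
    after a round-trip through :func:`read_fasta`.
    """
    if not peptides:
        raise ValidationError("refusing to write an empty peptide FASTA")
    path = Path(path)
    records = [
        SeqRecord(
            Seq(p.sequence),
            id=f"{p.parent_accession}|{p.start}-{p.end}|{p.enzyme}|mc{p.missed_cleavages}",
            description="",
        )
        for p in peptides
    ]
    SeqIO.write(records, str(path), "fasta")
    return path
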