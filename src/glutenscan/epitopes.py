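"""Epitope motif lists, scanning, intact-core matching and censuses.

Three motif classes are handled:

``R5``
    Short motifs (QQPFP and variants) recognised by the R5 monoclonal
    antibody used in regulatory gluten ELISAs. A hit means the sample
    would be expected to elicit an ELISA signal.
``DQ_core``
    9-residue cores presented by HLA-DQ2/DQ8 that drive T-cell responses
    in coeliac disease. A peptide-level hit requires the full 9-mer.
``immunogenic_Tcell``
    Longer confirmed T-cell epitope regions; a peptide-level hit requires
    at least 9 contiguous residues of the region to survive digestion
    intact (the intact-core criterion).

Protein-level scanning reports every full-motif occurrence, including
overlapping ones — prolamin repeat regions make overlaps the norm, and
undercounting them would bias the census. Peptide-level scanning uses the
longest contiguous stretch of the motif present in the peptide, because a
proteolytic fragment can retain a clinically relevant core without
containing the whole annotated region.
"""

from __future__ import annotations

import csv
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from glutenscan.errors import ConfigurationError, ValidationError
from glutenscan.seqio import ProteinRecord

logger = logging.getLogger(__name__)

EPITOPE_CLASSES = ("R5", "DQ_core", "immunogenic_Tcell")

#: Motif sequences use the standard 20 letters only (no X: ambiguity
#: never matches inside motifs).
_MOTIF_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class EpitopeMotif:
    """A named antibody-recognition or T-cell epitope sequence."""

    motif_id: str
    sequence: str
    epitope_class: str
    source: str = ""
    min_core_match: int | None = None

    def __post_init__(self) -> None:
        if self.epitope_class not in EPITOPE_CLASSES:
            raise ValidationError(
                f"motif {self.motif_id!r}: unknown class {self.epitope_class!r}"
            )
        bad = set(self.sequence) - _MOTIF_RESIDUES
        if bad:
            raise ValidationError(
                f"motif {self.motif_id!r}: invalid residue(s) {''.join(sorted(bad))}"
            )
        if len(self.sequence) < 5:
            raise ValidationError(f"motif {self.motif_id!r}: length must be >= 5")
        if self.min_core_match is None:
            default = len(self.sequence) if self.epitope_class == "R5" else 9
            object.__setattr__(self, "min_core_match", default)
        if self.epitope_class == "DQ_core" and (
            len(self.sequence) != 9 or self.min_core_match != 9
        ):
            raise ValidationError(
                f"motif {self.motif_id!r}: DQ_core motifs are 9-mers with "
                "min_core_match 9"
            )
        if self.epitope_class == "immunogenic_Tcell" and self.min_core_match != 9:
            raise ValidationError(
                f"motif {self.motif_id!r}: immunogenic_Tcell motifs use the "
                "9-residue intact-core criterion"
            )
        if self.min_core_match > len(self.sequence):
            raise ValidationError(
                f"motif {self.motif_id!r}: min_core_match exceeds motif length"
            )


@dataclass(frozen=True)
class EpitopeHit:
    """One occurrence of (part of) a motif in a protein or peptide."""

    motif_id: str
    epitope_class: str
    target_id: str
    target_kind: str  # "protein" | "peptide"
    position: int  # 1-based start of matched_span in the target
    matched_span: str
    intact: bool


def load_motif_list(path: str | Path) -> list[EpitopeMotif]:
    """Load a motif list from a tab-separated config file.

    Expected columns: motif_id, sequence, epitope_class, source, and
    optionally min_core_match (blank = class default). Duplicate
    (sequence, epitope_class) pairs are rejected.
    """
    path = Path(path)
    motifs: list[EpitopeMotif] = []
    seen: set[tuple[str, str]] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"motif_id", "sequence", "epitope_class"}
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise ConfigurationError(
                f"{path}: motif list missing column(s): {', '.join(sorted(missing))}"
            )
        for row in reader:
            mcm = (row.get("min_core_match") or "").strip()
            motif = EpitopeMotif(
                motif_id=row["motif_id"].strip(),
                sequence=row["sequence"].strip().upper(),
                epitope_class=row["epitope_class"].strip(),
                source=(row.get("source") or "").strip(),
                min_core_match=int(mcm) if mcm else None,
            )
            key = (motif.sequence, motif.epitope_class)
            if key in seen:
                raise ValidationError(
                    f"{path}: duplicate (sequence, class) pair for motif "
                    f"{motif.motif_id!r}"
                )
            seen.add(key)
            motifs.append(motif)
    return motifs


def default_motif_list() -> list[EpitopeMotif]:
    """The curated starter motif list shipped with the package.

    Contains the four R5 antibody motifs, canonical HLA-DQ2.5/DQ8 9-mer
    cores in Sollid nomenclature, and curated confirmed T-cell epitope
    regions (including the one recorded against IEDB epitope 226653).
    See the data file header for provenance; users screening a specific
    matrix should extend or replace it.
    """
    with resources.as_file(
        resources.files("glutenscan.data").joinpath("motifs.tsv")
    ) as p:
        return load_motif_list(p)


def scan_sequence(
    sequence: str,
    motifs: Sequence[EpitopeMotif],
    target_id: str = "",
    target_kind: str = "protein",
) -> list[EpitopeHit]:
    """Report every full-motif occurrence in ``sequence``.

    Overlapping occurrences are all reported; order is deterministic by
    (position, motif_id).
    """
    if not motifs:
        raise ConfigurationError("empty motif list")
    hits: list[EpitopeHit] = []
    for motif in motifs:
        m = motif.sequence
        w = len(m)
        for i in range(len(sequence) - w + 1):
            if sequence[i : i + w] == m:
                hits.append(
                    EpitopeHit(
                        motif_id=motif.motif_id,
                        epitope_class=motif.epitope_class,
                        target_id=target_id,
                        target_kind=target_kind,
                        position=i + 1,
                        matched_span=m,
                        intact=True,
                    )
                )
    hits.sort(key=lambda h: (h.position, h.motif_id))
    return hits


def _longest_shared_span(peptide: str, motif: str) -> tuple[int, str]:
    """Longest contiguous substring of ``motif`` present in ``peptide``.

    Returns (1-based position in peptide, span); span is "" when nothing
    is shared. Ties resolve to the earliest motif substring and earliest
    peptide position, which keeps output deterministic.
    """
    for w in range(min(len(motif), len(peptide)), 0, -1):
        for j in range(len(motif) - w + 1):
            sub = motif[j : j + w]
            pos = peptide.find(sub)
            if pos != -1:
                return pos + 1, sub
    return 0, ""


def intact_core_hits(
    peptide_sequence: str,
    motifs: Sequence[EpitopeMotif],
    target_id: str = "",
) -> list[EpitopeHit]:
    """Peptide-level hits under the intact-core criterion.

    For each motif the longest contiguous motif substring present in the
    peptide is found; a hit is emitted only when its length reaches the
    motif's min_core_match (full motif for R5, >= 9 residues for DQ_core
    and T-cell regions).
    """
    if not motifs:
        raise ConfigurationError("empty motif list")
    hits: list[EpitopeHit] = []
    for motif in motifs:
        pos, span = _longest_shared_span(peptide_sequence, motif.sequence)
        if span and len(span) >= motif.min_core_match:
            hits.append(
                EpitopeHit(
                    motif_id=motif.motif_id,
                    epitope_class=motif.epitope_class,
                    target_id=target_id,
                    target_kind="peptide",
                    position=pos,
                    matched_span=span,
                    intact=True,
                )
            )
    hits.sort(key=lambda h: (h.position, h.motif_id))
    return hits


@dataclass
class CensusReport:
    """Epitope census over a collection of proteins or peptides.

    instance_counts
        total hit occurrences per epitope class.
    carrier_counts
        distinct carriers (grouped targets / distinct peptide sequences)
        with at least one hit, per class.
    overlap_counts
        carriers split into {"R5_only", "DQ_only", "both"}, where "DQ"
        pools DQ_core with immunogenic_Tcell (the T-cell classes describe
        the same clinical risk; the full lattice below keeps them apart).
    subset_counts
        carriers keyed by the exact frozenset of classes hitting them.
    hits
        per-carrier hit lists.
    """

    instance_counts: dict[str, int]
    carrier_counts: dict[str, int]
    overlap_counts: dict[str, int]
    subset_counts: dict[frozenset, int]
    hits: dict[str, list[EpitopeHit]]

    @property
    def total_carriers(self) -> int:
        return sum(self.subset_counts.values())


def _build_report(hits_by_carrier: Mapping[str, list[EpitopeHit]]) -> CensusReport:
    instance_counts = {c: 0 for c in EPITOPE_CLASSES}
    carriers_by_class: dict[str, set[str]] = {c: set() for c in EPITOPE_CLASSES}
    for carrier, hits in hits_by_carrier.items():
        for h in hits:
            instance_counts[h.epitope_class] += 1
            carriers_by_class[h.epitope_class].add(carrier)
    carrier_counts = {c: len(s) for c, s in carriers_by_class.items()}

    subset_counts: dict[frozenset, int] = defaultdict(int)
    overlap = {"R5_only": 0, "DQ_only": 0, "both": 0}
    for carrier, hits in hits_by_carrier.items():
        classes = frozenset(h.epitope_class for h in hits)
        if not classes:
            continue
        subset_counts[classes] += 1
        has_r5 = "R5" in classes
        has_dq = bool(classes & {"DQ_core", "immunogenic_Tcell"})
        if has_r5 and has_dq:
            overlap["both"] += 1
        elif has_r5:
            overlap["R5_only"] += 1
        else:
            overlap["DQ_only"] += 1
    return CensusReport(
        instance_counts=instance_counts,
        carrier_counts=carrier_counts,
        overlap_counts=overlap,
        subset_counts=dict(subset_counts),
        hits={k: v for k, v in hits_by_carrier.items() if v},
    )


def census_proteins(
    proteins: Sequence[ProteinRecord],
    motifs: Sequence[EpitopeMotif],
    group_map: Mapping[str, str] | None = None,
) -> CensusReport:
    """Full-motif census over proteins.

    ``group_map`` (accession -> group id) collapses homologous accessions
    so each protein group is counted once — the conservative convention
    when peptides map to many Poaceae isoforms. Default: one group per
    accession. Instance counts are summed over all member proteins.
    """
    if not proteins:
        raise ValidationError("protein collection is empty")
    accessions = {p.accession for p in proteins}
    if group_map is not None:
        unknown = set(group_map) - accessions
        if unknown:
            raise ValidationError(
                f"group_map references unknown accession(s): {', '.join(sorted(unknown))}"
            )
    hits_by_carrier: dict[str, list[EpitopeHit]] = defaultdict(list)
    for protein in proteins:
        carrier = (group_map or {}).get(protein.accession, protein.accession)
        hits_by_carrier.setdefault(carrier, [])
        hits_by_carrier[carrier].extend(
            scan_sequence(protein.sequence, motifs, target_id=protein.accession)
        )
    return _build_report(hits_by_carrier)


def census_peptides(
    peptides: Iterable[str],
    motifs: Sequence[EpitopeMotif],
) -> CensusReport:
    """Intact-core census over detected peptides.

    Peptides are deduplicated by sequence first — the same immunogenic
    peptide occurs on many homologous proteins but is counted once.
    """
    unique = sorted(set(p.upper() for p in peptides))
    hits_by_carrier = {
        pep: intact_core_hits(pep, motifs, target_id=pep) for pep in unique
    }
    return _build_report(hits_by_carrier)


def annotate_peptides(
    peptides: Iterable[str],
    motifs: Sequence[EpitopeMotif],
) -> dict[str, dict[str, bool]]:
    """Per-peptide epitope status flags used for heatmap annotation.

    ``r5`` = carries a full R5 motif; ``immunogenic`` = carries an intact
    (>= 9 contiguous residues) DQ core or confirmed T-cell epitope region.
    """
    out: dict[str, dict[str, bool]] = {}
    for pep in peptides:
        seq = pep.upper()
        if seq in out:
            continue
        hits = intact_core_hits(seq, motifs, target_id=seq)
        classes = {h.epitope_class for h in hits}
        out[seq] = {
            "r5": "R5" in classes,
            "immunogenic": bool(classes & {"DQ_core", "immunogenic_Tcell"}),
        }
    return out
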