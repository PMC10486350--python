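"""In silico enzymatic digestion with trypsin and chymotrypsin rules.

Cleavage is C-terminal to the enzyme's specificity residues — K/R for
trypsin, F/W/Y/L/M for chymotrypsin (broad specificity) — optionally
suppressed when the next residue is proline. The proline rule matters
for prolamins: repeat regions are proline-rich, so K/R-P and F/L-P
junctions survive digestion and long epitope-bearing peptides persist.
A suppressed site is not a site at all: it does not count toward missed
cleavages.
"""

from __future__ import annotations

from dataclasses import dataclass

from glutenscan.errors import ConfigurationError, ValidationError
from glutenscan.seqio import ProteinRecord

#: C-terminal cleavage residues per supported enzyme. X never cleaves.
ENZYME_RULES: dict[str, frozenset[str]] = {
    "trypsin": frozenset("KR"),
    "chymotrypsin": frozenset("FWYLM"),
}


@dataclass(frozen=True)
class DigestSpec:
    """Parameters of one in silico digest.

    max_missed_cleavages and min_length default to the community-standard
    2 and 5; proline suppression is on by default (see module docstring).
    """

    enzyme: str = "trypsin"
    max_missed_cleavages: int = 2
    min_length: int = 5
    proline_rule: bool = True
    #: Overridable specificity set; None = ENZYME_RULES[enzyme].
    cleavage_residues: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.enzyme not in ENZYME_RULES:
            raise ConfigurationError(
                f"unknown enzyme {self.enzyme!r}; supported: {sorted(ENZYME_RULES)}"
            )
        if self.min_length < 1:
            raise ValidationError("min_length must be >= 1")
        if not 0 <= self.max_missed_cleavages <= 5:
            raise ValidationError("max_missed_cleavages must be in [0, 5]")

    @property
    def residues(self) -> frozenset[str]:
        return self.cleavage_residues or ENZYME_RULES[self.enzyme]


@dataclass(frozen=True)
class DigestPeptide:
    """One proteolytic peptide with 1-based inclusive parent coordinates."""

    sequence: str
    parent_accession: str
    start: int
    end: int
    missed_cleavages: int
    enzyme: str

    def __len__(self) -> int:
        return len(self.sequence)


def cleavage_sites(sequence: str, spec: DigestSpec) -> list[int]:
    """0-based indices i such that the bond after sequence[i] is cleaved.

    Only positions with a following residue qualify (the C-terminus is a
    boundary, not a site). With the proline rule on, a specificity residue
    followed by P is skipped entirely.
    """
    residues = spec.residues
    sites = []
    for i in range(len(sequence) - 1):
        if sequence[i] not in residues:
            continue
        if spec.proline_rule and sequence[i + 1] == "P":
            continue
        sites.append(i)
    return sites


def digest(protein: ProteinRecord, spec: DigestSpec) -> list[DigestPeptide]:
    """Digest a protein, returning peptides with up to
    ``spec.max_missed_cleavages`` internal sites and length >=
    ``spec.min_length``, ordered by (start, end).
    """
    seq = protein.sequence
    # Fragment boundaries: 0, each site+1, and the C-terminus.
    bounds = [0] + [i + 1 for i in cleavage_sites(seq, spec)] + [len(seq)]
    peptides: list[DigestPeptide] = []
    n_frag = len(bounds) - 1
    for i in range(n_frag):
        for mc in range(spec.max_missed_cleavages + 1):
            j = i + mc + 1
            if j > n_frag:
                break
            start, end = bounds[i], bounds[j]
            if end - start < spec.min_length:
                continue
            peptides.append(
                DigestPeptide(
                    sequence=seq[start:end],
                    parent_accession=protein.accession,
                    start=start + 1,
                    end=end,
                    missed_cleavages=mc,
                    enzyme=spec.enzyme,
                )
            )
    peptides.sort(key=lambda p: (p.start, p.end))
    return peptides


def digest_all(
    proteins: list[ProteinRecord], spec: DigestSpec
) -> list[DigestPeptide]:
    """Digest a protein collection, preserving input protein order."""
    out: list[DigestPeptide] = []
    for prot in proteins:
        out.extend(digest(prot, spec))
    return out
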