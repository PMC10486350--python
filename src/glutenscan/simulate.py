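"""Synthetic inputs with exact ground truth for every pipeline stage.

Two generators mirror the statistical structure the analysis assumes:

* prolamin-like sequences — repetitive, Q/P-rich, poor in trypsin
  cleavage sites — with epitope motifs planted at exactly known counts
  (verified post hoc by an independent naive scanner and redrawn on
  collision);
* MRM transition tables with known per-peptide true abundances, three
  transitions per peptide, oxidised/reduced Met precursor pairs, four
  technical replicates and multiplicative lognormal noise (the standard
  noise model for MS peak intensities).

``simulate_study`` chains them into a full input bundle, including an
ELISA-like readout generated as a monotone function of each sample's
true net hordein abundance, with optional per-sample suppression to
emulate ELISA signal loss on hydrolysed samples.

Everything is reproducible from the spec seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from glutenscan.digest import DigestSpec, digest
from glutenscan.errors import GenerationError, ValidationError
from glutenscan.seqio import ProteinRecord

#: Default Q/P-rich repeat units emulating prolamin repeat regions.
DEFAULT_REPEAT_POOL = ("PQQP", "QQPFP", "QPQQ", "PFPQ")

#: Background residue weights: glutamine/proline dominated with the rest
#: of the prolamin-typical alphabet at low weight.
DEFAULT_BACKGROUND_WEIGHTS = {
    "Q": 6.0, "P": 4.0, "F": 1.0, "L": 1.5, "S": 1.0, "G": 1.0, "A": 1.0,
    "V": 1.0, "I": 0.8, "Y": 0.6, "T": 0.6, "E": 0.6, "H": 0.5, "N": 0.5,
    "R": 0.5, "K": 0.5, "C": 0.3, "M": 0.3, "W": 0.1, "D": 0.3,
}

_SIM_CLASSES = ("B-hordein", "C-hordein", "D-hordein", "gamma-hordein", "ALP")


@dataclass(frozen=True)
class SequenceSimSpec:
    """Parameters for prolamin-like sequence generation."""

    n_proteins: int = 20
    length_range: tuple[int, int] = (150, 300)
    repeat_unit_pool: tuple[str, ...] = DEFAULT_REPEAT_POOL
    #: motif sequence -> occurrences planted per protein
    plant_plan: Mapping[str, int] = field(default_factory=dict)
    background_alphabet_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BACKGROUND_WEIGHTS)
    )
    seed: int = 0
    retry_limit: int = 50

    def __post_init__(self) -> None:
        if self.n_proteins < 0:
            raise ValidationError("n_proteins must be non-negative")
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ValidationError("invalid length_range")
        if any(w <= 0 for w in self.background_alphabet_weights.values()):
            raise ValidationError("background weights must be positive")
        for motif in self.plant_plan:
            if len(motif) > lo:
                raise ValidationError(
                    f"planted motif {motif!r} longer than the minimum protein length"
                )
        # Nested motifs make exact per-motif counts unsatisfiable: planting
        # the longer one necessarily adds occurrences of the shorter.
        for a in self.plant_plan:
            for b in self.plant_plan:
                if a != b and a in b:
                    raise ValidationError(
                        f"planted motif {a!r} is a substring of {b!r}; exact "
                        "planted counts would be unsatisfiable"
                    )


def count_occurrences(sequence: str, motif: str) -> int:
    """Naive overlapping-occurrence count, used as the planting oracle.

    Deliberately independent of the production scanner so that
    planted-count verification cannot be circular.
    """
    n = 0
    for i in range(len(sequence) - len(motif) + 1):
        if sequence[i : i + len(motif)] == motif:
            n += 1
    return n


def _background(rng: np.random.Generator, spec: SequenceSimSpec, length: int) -> str:
    letters = list(spec.background_alphabet_weights)
    weights = np.array([spec.background_alphabet_weights[l] for l in letters])
    weights = weights / weights.sum()
    parts: list[str] = []
    size = 0
    while size < length:
        if spec.repeat_unit_pool and rng.random() < 0.5:
            unit = spec.repeat_unit_pool[rng.integers(len(spec.repeat_unit_pool))]
        else:
            unit = str(rng.choice(letters, p=weights))
        parts.append(unit)
        size += len(unit)
    return "".join(parts)[:length]


def _scrub(sequence: str, motifs: Sequence[str]) -> str:
    """Destroy accidental motif occurrences by point substitution.

    The replacement residue is chosen to be absent from every planted
    motif, so scrubbing one occurrence cannot create another.
    """
    used = set("".join(motifs))
    replacement = next(
        (r for r in "HDNWTGAVKRE" if r not in used), None
    )
    if replacement is None:
        raise GenerationError("no residue available to scrub accidental occurrences")
    seq = list(sequence)
    for motif in motifs:
        while True:
            s = "".join(seq)
            i = s.find(motif)
            if i == -1:
                break
            seq[i + len(motif) // 2] = replacement
    return "".join(seq)


def simulate_proteins(
    spec: SequenceSimSpec,
) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Generate prolamin-like proteins with exactly known planted motifs.

    Returns (proteins, truth) where truth has one row per (accession,
    motif) with the exact planted occurrence count, verified by the
    independent naive scanner. Raises :class:`GenerationError` when the
    plant density makes collision-free placement impossible within the
    retry limit.
    """
    rng = np.random.default_rng(spec.seed)
    motifs = sorted(spec.plant_plan)
    proteins: list[ProteinRecord] = []
    truth_rows: list[dict] = []
    for k in range(spec.n_proteins):
        accession = f"SYN{k + 1:04d}"
        length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        for attempt in range(spec.retry_limit):
            backbone = _scrub(_background(rng, spec, length), motifs)
            # Insert planted copies at random non-adjacent anchor points.
            inserts: list[str] = []
            for motif in motifs:
                inserts.extend([motif] * spec.plant_plan[motif])
            rng.shuffle(inserts)
            if inserts:
                anchors = sorted(
                    rng.choice(len(backbone) + 1, size=len(inserts), replace=False)
                )
                pieces = []
                prev = 0
                for anchor, ins in zip(anchors, inserts):
                    pieces.append(backbone[prev:anchor])
                    pieces.append(ins)
                    prev = anchor
                pieces.append(backbone[prev:])
                candidate = "".join(pieces)
            else:
                candidate = backbone
            if all(
                count_occurrences(candidate, m) == spec.plant_plan[m] for m in motifs
            ):
                break
        else:
            raise GenerationError(
                f"could not place planted motifs in {accession} within "
                f"{spec.retry_limit} attempts; lower the plant density"
            )
        proteins.append(
            ProteinRecord(
                accession=accession,
                sequence=candidate,
                description="synthetic prolamin-like protein",
                protein_class=_SIM_CLASSES[k % len(_SIM_CLASSES)],
                species_tag="barley",
            )
        )
        for motif in motifs:
            truth_rows.append(
                {
                    "accession": accession,
                    "motif": motif,
                    "planted_count": spec.plant_plan[motif],
                }
            )
    truth = pd.DataFrame(truth_rows, columns=["accession", "motif", "planted_count"])
    return proteins, truth


@dataclass(frozen=True)
class QuantSimSpec:
    """Parameters for MRM transition-table generation."""

    n_samples: int = 2
    n_replicates: int = 4
    #: peptide sequence -> true abundance (same across samples unless
    #: per-sample truths are supplied to the internal generator).
    peptides: Mapping[str, float] = field(default_factory=dict)
    n_transitions: int = 3
    transition_fractions: tuple[float, ...] = (0.5, 0.3, 0.2)
    met_ox_fraction: float = 0.1
    noise_sigma: float = 0.1
    dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.transition_fractions) - 1.0) > 1e-9:
            raise ValidationError("transition_fractions must sum to 1")
        if len(self.transition_fractions) != self.n_transitions:
            raise ValidationError("need one fraction per transition")
        if not 0 <= self.met_ox_fraction < 1:
            raise ValidationError("met_ox_fraction must be in [0, 1)")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        if not 0 <= self.dropout_rate < 1:
            raise ValidationError("dropout_rate must be in [0, 1)")
        if any(a < 0 for a in self.peptides.values()):
            raise ValidationError("true abundances must be non-negative")


def _transition_rows(
    truth: pd.DataFrame, spec: QuantSimSpec, rng: np.random.Generator
) -> pd.DataFrame:
    """Expand a (sample_id, peptide_sequence, true_abundance) truth table
    into noisy transition-level rows."""
    rows: list[dict] = []
    for rec in truth.itertuples(index=False):
        mod_split = (
            [("reduced", 1.0 - spec.met_ox_fraction), ("met_oxidised", spec.met_ox_fraction)]
            if "M" in rec.peptide_sequence and spec.met_ox_fraction > 0
            else [("none", 1.0)]
        )
        for replicate in range(1, spec.n_replicates + 1):
            noise = np.exp(rng.normal(0.0, spec.noise_sigma)) if spec.noise_sigma else 1.0
            for mod_state, share in mod_split:
                for t, fraction in enumerate(spec.transition_fractions):
                    if spec.dropout_rate and rng.random() < spec.dropout_rate:
                        continue
                    rows.append(
                        {
                            "sample_id": rec.sample_id,
                            "replicate": replicate,
                            "peptide_sequence": rec.peptide_sequence,
                            "mod_state": mod_state,
                            "transition_id": f"t{t + 1}",
                            "peak_area": rec.true_abundance * fraction * share * noise,
                        }
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id", "replicate", "peptide_sequence", "mod_state",
            "transition_id", "peak_area",
        ],
    )


def simulate_transitions(
    spec: QuantSimSpec,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a transition table with known true abundances.

    Noise is a single multiplicative lognormal factor per
    (peptide, replicate) — transitions of one replicate co-vary, as they
    do on an instrument — so with sigma 0 and no dropout a replicate's
    transition sum equals the true abundance exactly (fractions and the
    oxidised/reduced Met split conserve the total).
    Returns (transition table, truth table).
    """
    rng = np.random.default_rng(spec.seed)
    samples = [f"S{i + 1}" for i in range(spec.n_samples)]
    truth = pd.DataFrame(
        [
            {"sample_id": s, "peptide_sequence": p, "true_abundance": a}
            for s in samples
            for p, a in spec.peptides.items()
        ]
    )
    return _transition_rows(truth, spec, rng), truth


@dataclass
class StudyBundle:
    """End-to-end synthetic study: every input the pipeline consumes plus
    the ground truth for each of them."""

    proteins: list[ProteinRecord]
    protein_truth: pd.DataFrame
    peptides: list[str]
    class_map: dict[str, str]
    transitions: pd.DataFrame
    quant_truth: pd.DataFrame
    elisa: pd.DataFrame
    suppressed_samples: tuple[str, ...]


def simulate_study(
    seq_spec: SequenceSimSpec,
    quant_spec: QuantSimSpec,
    digest_spec: DigestSpec | None = None,
    peptides_per_protein: int = 3,
    suppression_factor: float = 1.0,
    suppressed_samples: Sequence[str] = (),
) -> StudyBundle:
    """Simulate a full screening study.

    Proteins are generated, digested, and the first
    ``peptides_per_protein`` unique fully-specific peptides of each
    protein become the monitored panel, inheriting the parent's protein
    class. Per-sample hordein levels are log-spaced over two orders of
    magnitude; ELISA-like mg/kg values are a monotone (linear) transform
    of each sample's true net hordein abundance, multiplied by
    ``suppression_factor`` for ``suppressed_samples`` to emulate
    ELISA-signal suppression on hydrolysed matrices.
    """
    if not 0 < suppression_factor <= 1.0:
        raise ValidationError("suppression_factor must be in (0, 1]")
    digest_spec = digest_spec or DigestSpec(enzyme="chymotrypsin")
    rng = np.random.default_rng(quant_spec.seed + 1)

    proteins, protein_truth = simulate_proteins(seq_spec)
    class_map: dict[str, str] = {}
    panel: list[str] = []
    for protein in proteins:
        count = 0
        for pep in digest(protein, digest_spec):
            if pep.missed_cleavages > 0 or pep.sequence in class_map:
                continue
            class_map[pep.sequence] = protein.protein_class or "other"
            panel.append(pep.sequence)
            count += 1
            if count >= peptides_per_protein:
                break

    samples = [f"S{i + 1}" for i in range(quant_spec.n_samples)]
    # Per-sample hordein level: two orders of magnitude, shuffled so the
    # sample index carries no information.
    levels = np.geomspace(1.0, 100.0, num=len(samples))
    rng.shuffle(levels)
    base = 10 ** rng.uniform(4.0, 6.0, size=len(panel))
    truth_rows = [
        {
            "sample_id": s,
            "peptide_sequence": p,
            "true_abundance": float(base[j] * levels[i]),
        }
        for i, s in enumerate(samples)
        for j, p in enumerate(panel)
    ]
    quant_truth = pd.DataFrame(truth_rows)
    transitions = _transition_rows(quant_truth, spec=quant_spec, rng=rng)

    hordein_classes = {"B-hordein", "C-hordein", "D-hordein", "gamma-hordein"}
    truth_with_class = quant_truth.assign(
        protein_class=quant_truth["peptide_sequence"].map(class_map)
    )
    net_true = (
        truth_with_class[truth_with_class["protein_class"].isin(hordein_classes)]
        .groupby("sample_id")["true_abundance"]
        .sum()
        .reindex(samples, fill_value=0.0)
    )
    # Monotone ELISA emulation: scale so the highest-gluten sample reads
    # ~150 mg/kg, then apply suppression.
    scale = 150.0 / net_true.max() if net_true.max() > 0 else 0.0
    elisa_values = net_true * scale
    for s in suppressed_samples:
        if s not in elisa_values.index:
            raise ValidationError(f"suppressed sample {s!r} not in study")
        elisa_values.loc[s] *= suppression_factor
    elisa = pd.DataFrame(
        {
            "sample_id": samples,
            "gluten_mg_per_kg": [float(elisa_values[s]) for s in samples],
            "label_group": [
                "low_gluten" if elisa_values[s] < 20.0 else "control" for s in samples
            ],
        }
    )
    return StudyBundle(
        proteins=proteins,
        protein_truth=protein_truth,
        peptides=panel,
        class_map=class_map,
        transitions=transitions,
        quant_truth=quant_truth,
        elisa=elisa,
        suppressed_samples=tuple(suppressed_samples),
    )
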