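"""Pipeline orchestration: config, manifest, and the census/quant stages.

One configuration mapping drives all stages; the CLI is a thin wrapper.
Reports are plain tab-separated files plus a structured JSON summary, so
they diff cleanly and open in a spreadsheet. A run manifest (config
snapshot, input checksums, package version, per-stage record counts) is
written before any report and finalised with counts on success.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

import glutenscan
from glutenscan.digest import DigestSpec
from glutenscan.epitopes import (
    annotate_peptides,
    census_peptides,
    census_proteins,
    default_motif_list,
    load_motif_list,
)
from glutenscan.errors import ConfigurationError, ValidationError
from glutenscan.mrm import (
    default_wheat_markers,
    elisa_concordance,
    heatmap_matrix,
    net_hordein,
    quantify_peptides,
    read_elisa_table,
    read_transition_report,
    summarise_classes,
    wheat_panel,
)
from glutenscan.seqio import read_fasta, read_peptide_list

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and settings for one pipeline run. All paths are optional;
    each stage checks for what it needs and fails with a named path."""

    proteome_fasta: str | None = None
    peptide_list: str | None = None
    motif_list: str | None = None
    transition_report: str | None = None
    column_map: dict[str, str] = field(default_factory=dict)
    elisa_table: str | None = None
    class_map: str | None = None
    group_map: str | None = None
    wheat_markers: str | None = None
    detection_threshold: float = 0.0
    rank_margin: int = 3
    digest: dict[str, Any] = field(default_factory=dict)
    report_dir: str = "reports"
    seed: int = 0
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(
                f"{path}: unknown config key(s): {', '.join(sorted(unknown))}"
            )
        return cls(**data)

    def digest_spec(self) -> DigestSpec:
        return DigestSpec(**self.digest) if self.digest else DigestSpec()

    def require(self, *names: str) -> None:
        for name in names:
            value = getattr(self, name)
            if value is None:
                raise ConfigurationError(f"config key {name!r} is required for this stage")
            if not Path(value).exists():
                raise ConfigurationError(f"{name}: no such file: {value}")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_two_column_map(path: str | Path, key: str, value: str) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in (key, value):
        if col not in df.columns:
            raise ConfigurationError(f"{path}: missing column {col!r}")
    return dict(zip(df[key], df[value]))


class Manifest:
    """Run manifest: written before any report, finalised with counts."""

    def __init__(self, config: PipelineConfig, report_dir: Path):
        self.path = report_dir / "manifest.json"
        self.data: dict[str, Any] = {
            "software": {"name": "glutenscan", "version": glutenscan.__version__},
            "timestamp_utc": datetime.now(timezone.utc).isoformat(timespec="seconds"),
            "config": {k: getattr(config, k) for k in config.__dataclass_fields__},
            "input_checksums": {},
            "stage_counts": {},
        }
        for key in (
            "proteome_fasta", "peptide_list", "motif_list", "transition_report",
            "elisa_table", "class_map", "group_map", "wheat_markers",
        ):
            value = getattr(config, key)
            if value and Path(value).exists():
                self.data["input_checksums"][key] = _sha256(value)
        self.write()

    def count(self, stage: str, n: int) -> None:
        self.data["stage_counts"][stage] = int(n)
        logger.info("stage %s: %d records", stage, n)

    def write(self) -> None:
        self.path.parent.mkdir(parents=True, exist_ok=True)
        with open(self.path, "w") as fh:
            json.dump(self.data, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _census_frames(report) -> dict[str, pd.DataFrame]:
    per_class = pd.DataFrame(
        {
            "epitope_class": list(report.instance_counts),
            "instance_count": list(report.instance_counts.values()),
            "carrier_count": [report.carrier_counts[c] for c in report.instance_counts],
        }
    )
    overlap = pd.DataFrame(
        {
            "subset": list(report.overlap_counts),
            "carrier_count": list(report.overlap_counts.values()),
        }
    )
    lattice = pd.DataFrame(
        {
            "classes": ["+".join(sorted(k)) for k in report.subset_counts],
            "carrier_count": list(report.subset_counts.values()),
        }
    ).sort_values("classes", ignore_index=True)
    hit_rows = [
        {
            "carrier": carrier,
            "motif_id": h.motif_id,
            "epitope_class": h.epitope_class,
            "target_id": h.target_id,
            "position": h.position,
            "matched_span": h.matched_span,
            "intact": h.intact,
        }
        for carrier in sorted(report.hits)
        for h in report.hits[carrier]
    ]
    hits = pd.DataFrame(
        hit_rows,
        columns=["carrier", "motif_id", "epitope_class", "target_id",
                 "position", "matched_span", "intact"],
    )
    return {"per_class": per_class, "overlap": overlap, "lattice": lattice, "hits": hits}


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, na_rep="NA")


def _load_motifs(config: PipelineConfig):
    if config.motif_list:
        config.require("motif_list")
        return load_motif_list(config.motif_list)
    logger.info("no motif_list configured; using the shipped curated starter list")
    return default_motif_list()


def run_census(config: PipelineConfig) -> dict[str, Any]:
    """Protein- and peptide-level epitope censuses with overlap tables."""
    report_dir = Path(config.report_dir)
    report_dir.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(config, report_dir)
    motifs = _load_motifs(config)
    manifest.count("motifs", len(motifs))

    summary: dict[str, Any] = {}
    if config.proteome_fasta:
        config.require("proteome_fasta")
        proteins = read_fasta(config.proteome_fasta)
        manifest.count("proteins", len(proteins))
        group_map = (
            _load_two_column_map(config.group_map, "accession", "group_id")
            if config.group_map
            else None
        )
        census = census_proteins(proteins, motifs, group_map=group_map)
        frames = _census_frames(census)
        for name, df in frames.items():
            _write_tsv(df, report_dir / f"protein_census_{name}.tsv")
        summary["protein_census"] = {
            "instance_counts": census.instance_counts,
            "carrier_counts": census.carrier_counts,
            "overlap_counts": census.overlap_counts,
        }
    if config.peptide_list:
        config.require("peptide_list")
        peptides = read_peptide_list(config.peptide_list)
        manifest.count("peptides", len(peptides))
        if not peptides:
            logger.warning("peptide list %s is empty; zero-count census", config.peptide_list)
        census = census_peptides(peptides, motifs)
        frames = _census_frames(census)
        for name, df in frames.items():
            _write_tsv(df, report_dir / f"peptide_census_{name}.tsv")
        summary["peptide_census"] = {
            "instance_counts": census.instance_counts,
            "carrier_counts": census.carrier_counts,
            "overlap_counts": census.overlap_counts,
        }
    if not summary:
        raise ConfigurationError(
            "census stage needs proteome_fasta and/or peptide_list"
        )
    with open(report_dir / "census_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest.write()
    return summary


def run_quant(config: PipelineConfig) -> dict[str, Any]:
    """MRM quantitation: peptide/class tables, net hordein ranking,
    heatmap matrix, wheat panel and ELISA concordance."""
    config.require("transition_report")
    report_dir = Path(config.report_dir)
    report_dir.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(config, report_dir)
    motifs = _load_motifs(config)

    measurements = read_transition_report(config.transition_report, config.column_map)
    manifest.count("transition_measurements", len(measurements))
    quants = quantify_peptides(measurements, config.detection_threshold)
    manifest.count("peptide_quants", len(quants))
    _write_tsv(quants, report_dir / "peptide_quant.tsv")

    summary: dict[str, Any] = {}
    net = None
    if config.class_map:
        config.require("class_map")
        class_map = _load_two_column_map(
            config.class_map, "peptide_sequence", "protein_class"
        )
        classes = summarise_classes(quants, class_map)
        _write_tsv(classes, report_dir / "class_summary.tsv")
        if classes.attrs["unmapped_peptides"]:
            _write_tsv(
                pd.DataFrame({"peptide_sequence": classes.attrs["unmapped_peptides"]}),
                report_dir / "unmapped_peptides.tsv",
            )
        net = net_hordein(classes)
        ranking = net.sort_values(ascending=False).to_frame().reset_index()
        _write_tsv(ranking, report_dir / "net_hordein_ranking.tsv")
        manifest.count("class_summaries", len(classes))
        summary["net_hordein"] = {k: float(v) for k, v in net.items()}

    annotations = annotate_peptides(quants["peptide_sequence"].unique(), motifs)
    matrix, ann = heatmap_matrix(quants, annotations)
    _write_tsv(matrix, report_dir / "heatmap_matrix.tsv", index=True)
    _write_tsv(ann.reset_index(), report_dir / "heatmap_annotations.tsv")

    markers = (
        read_peptide_list(config.wheat_markers)
        if config.wheat_markers
        else default_wheat_markers()
    )
    panel = wheat_panel(quants, markers)
    _write_tsv(panel, report_dir / "wheat_panel.tsv")
    summary["wheat_contaminated_samples"] = sorted(
        panel.loc[panel["contaminated"], "sample_id"]
    )

    if config.elisa_table:
        config.require("elisa_table")
        elisa = read_elisa_table(config.elisa_table)
        if net is not None:
            unmatched = sorted(
                set(elisa["sample_id"]) ^ set(net.index)
            )
            if unmatched:
                raise ValidationError(
                    "sample ids do not match between ELISA and quant tables: "
                    + ", ".join(unmatched)
                )
        concordance = elisa_concordance(elisa, net, rank_margin=config.rank_margin)
        _write_tsv(concordance["mismatch_table"], report_dir / "elisa_mismatch.tsv")
        summary["elisa_concordance"] = {
            k: v for k, v in concordance.items() if k != "mismatch_table"
        }
        summary["elisa_concordance"]["mismatch_samples"] = list(
            concordance["mismatch_table"]["sample_id"]
        )
    with open(report_dir / "quant_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest.write()
    return summary


def run_all(config: PipelineConfig) -> dict[str, Any]:
    """Census + quantitation + a joined peptide annotation table
    (epitope status columns merged into quant rows)."""
    summary: dict[str, Any] = {}
    if config.proteome_fasta or config.peptide_list:
        summary["census"] = run_census(config)
    summary["quant"] = run_quant(config)

    report_dir = Path(config.report_dir)
    quants = pd.read_csv(report_dir / "peptide_quant.tsv", sep="\t")
    motifs = _load_motifs(config)
    flags = annotate_peptides(quants["peptide_sequence"].unique(), motifs)
    quants["r5_positive"] = quants["peptide_sequence"].map(lambda p: flags[p]["r5"])
    quants["immunogenic_positive"] = quants["peptide_sequence"].map(
        lambda p: flags[p]["immunogenic"]
    )
    _write_tsv(quants, report_dir / "peptide_quant_annotated.tsv")
    return summary
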