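"""MRM peak-area aggregation, class summaries and ELISA concordance.

Transition-level peak areas (as exported by targeted-proteomics software
such as Skyline) are aggregated bottom-up:

transition -> replicate-level peptide sum (over the three transitions and
over oxidised/reduced Met precursor forms) -> per-sample peptide abundance
(mean over technical replicates, with a replicate CV) -> protein-class
summaries -> per-sample net hordein signal (B-, C-, D-, gamma-hordein
only; avenin-like proteins are prolamin-family but not hordeins and are
excluded from the net total).

The net hordein signal is a *relative* gluten measure; the concordance
report compares its per-sample ranking against R5 competitive ELISA
mg/kg values to surface samples where the two techniques disagree.

Tables are plain :class:`pandas.DataFrame` objects throughout; one row of
the transition table is one TransitionMeasurement (sample, replicate,
peptide, mod state, transition, area).
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from glutenscan.errors import FormatError, ValidationError
from glutenscan.seqio import HORDEIN_CLASSES, PROTEIN_CLASSES

logger = logging.getLogger(__name__)

#: Canonical transition-table columns. retention_time is optional.
TRANSITION_COLUMNS = (
    "sample_id",
    "replicate",
    "peptide_sequence",
    "mod_state",
    "transition_id",
    "peak_area",
)

MOD_STATES = ("reduced", "met_oxidised", "none")

#: Strings treated as missing peak areas in exports.
_MISSING_AREA = {"", "#N/A", "#N/A!", "NA", "NAN"}


def read_transition_report(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a comma-separated transition-results export.

    ``column_map`` maps canonical names (see TRANSITION_COLUMNS) to the
    header names actually present, e.g. ``{"peak_area": "Area"}``.
    Blank or ``#N/A`` areas are treated as missing (not zero), logged and
    dropped; negative areas raise :class:`ValidationError` with the row
    number; a missing mandatory column raises :class:`FormatError`.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    rename = {v: k for k, v in (column_map or {}).items()}
    raw = raw.rename(columns=rename)

    mandatory = ["sample_id", "replicate", "peptide_sequence", "transition_id", "peak_area"]
    for col in mandatory:
        if col not in raw.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    if "mod_state" not in raw.columns:
        raw["mod_state"] = "none"

    df = raw.copy()
    df["mod_state"] = df["mod_state"].replace("", "none")
    bad_mod = set(df["mod_state"]) - set(MOD_STATES)
    if bad_mod:
        raise ValidationError(f"{path}: unknown mod_state value(s): {sorted(bad_mod)}")

    area_str = df["peak_area"].str.strip().str.upper()
    missing = area_str.isin(_MISSING_AREA)
    if missing.any():
        logger.warning(
            "%s: %d transition row(s) with missing peak area dropped", path, missing.sum()
        )
        df = df[~missing]
    df["peak_area"] = df["peak_area"].astype(float)
    negative = df.index[df["peak_area"] < 0]
    if len(negative):
        # +2: header line plus 1-based numbering of the CSV file.
        raise ValidationError(
            f"{path}: negative peak area at row {negative[0] + 2}"
        )
    df["replicate"] = df["replicate"].astype(int)
    if (df["replicate"] < 1).any():
        raise ValidationError(f"{path}: replicate numbers must be positive")
    df["peptide_sequence"] = df["peptide_sequence"].str.upper()

    key = ["sample_id", "replicate", "peptide_sequence", "mod_state", "transition_id"]
    dup = df.duplicated(subset=key)
    if dup.any():
        first = df[dup].iloc[0]
        raise ValidationError(
            f"{path}: duplicate transition measurement for "
            f"{tuple(first[k] for k in key)}"
        )
    keep = [c for c in df.columns if c in TRANSITION_COLUMNS + ("retention_time",)]
    return df[keep].reset_index(drop=True)


def quantify_peptides(
    measurements: pd.DataFrame,
    detection_threshold: float = 0.0,
) -> pd.DataFrame:
    """Aggregate transitions into per-sample peptide abundances.

    Per (sample, peptide): each replicate's areas are summed over all
    transitions and over reduced/oxidised Met forms; ``summed_area`` is
    the mean of the replicate-level sums and ``cv`` their sample
    (n-1 denominator) SD divided by the mean. A peptide absent from some
    of a sample's replicates has the missing replicate sums treated as 0
    and is flagged in the log. ``detected`` is summed_area > threshold.
    """
    if measurements.empty:
        return pd.DataFrame(
            columns=["sample_id", "peptide_sequence", "summed_area", "cv",
                     "n_replicates", "detected"]
        )
    rep_sums = (
        measurements.groupby(["sample_id", "peptide_sequence", "replicate"], sort=True)[
            "peak_area"
        ]
        .sum()
        .rename("rep_sum")
        .reset_index()
    )
    # The replicate set of a sample = all replicates seen for any peptide.
    reps_per_sample = {
        s: sorted(g["replicate"].unique())
        for s, g in measurements.groupby("sample_id")
    }
    rows = []
    n_padded = 0
    for (sample, peptide), grp in rep_sums.groupby(
        ["sample_id", "peptide_sequence"], sort=True
    ):
        expected = reps_per_sample[sample]
        sums = grp.set_index("replicate")["rep_sum"].reindex(expected)
        if sums.isna().any():
            n_padded += 1
            sums = sums.fillna(0.0)
        mean = float(sums.mean())
        cv = float(sums.std(ddof=1) / mean) if len(sums) > 1 and mean > 0 else np.nan
        rows.append(
            {
                "sample_id": sample,
                "peptide_sequence": peptide,
                "summed_area": mean,
                "cv": cv,
                "n_replicates": len(expected),
                "detected": mean > detection_threshold,
            }
        )
    if n_padded:
        logger.warning(
            "%d (sample, peptide) pair(s) missing from some replicates; "
            "missing replicate sums treated as 0",
            n_padded,
        )
    return pd.DataFrame(rows)


def summarise_classes(
    peptide_quants: pd.DataFrame,
    class_map: Mapping[str, str],
) -> pd.DataFrame:
    """Per-sample, per-protein-class abundance summaries.

    ``class_map`` assigns each peptide sequence a protein class. Output
    columns: mean_area and sd_area over member peptide abundances,
    net_area (their sum) and n_peptides. Unmapped peptides are excluded
    with a warning and listed in ``result.attrs["unmapped_peptides"]``.
    """
    unknown_classes = set(class_map.values()) - set(PROTEIN_CLASSES)
    if unknown_classes:
        raise ValidationError(f"unknown protein class(es): {sorted(unknown_classes)}")
    q = peptide_quants.copy()
    q["protein_class"] = q["peptide_sequence"].map(class_map)
    unmapped = sorted(q.loc[q["protein_class"].isna(), "peptide_sequence"].unique())
    if unmapped:
        logger.warning(
            "%d peptide(s) without a class assignment excluded from class "
            "summaries: %s",
            len(unmapped),
            ", ".join(unmapped),
        )
        q = q.dropna(subset=["protein_class"])
    summary = (
        q.groupby(["sample_id", "protein_class"], sort=True)["summed_area"]
        .agg(mean_area="mean", sd_area=lambda s: s.std(ddof=1), net_area="sum",
             n_peptides="size")
        .reset_index()
    )
    summary.attrs["unmapped_peptides"] = unmapped
    return summary


def net_hordein(class_summaries: pd.DataFrame) -> pd.Series:
    """Per-sample net hordein peak area (sum over B/C/D/gamma classes).

    ALP and any non-hordein class never contribute. Samples present in
    the summary but with no hordein signal report 0.
    """
    hordein = class_summaries[class_summaries["protein_class"].isin(HORDEIN_CLASSES)]
    totals = hordein.groupby("sample_id")["net_area"].sum()
    all_samples = class_summaries["sample_id"].unique()
    return totals.reindex(sorted(all_samples), fill_value=0.0).rename("net_hordein_area")


def heatmap_matrix(
    peptide_quants: pd.DataFrame,
    annotations: Mapping[str, Mapping] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Samples x peptides abundance matrix plus an annotation sidecar.

    Undetected (sample, peptide) cells are NaN — the distinguished
    missing marker (rendered grey in heatmap software, "NA" on disk).
    ``annotations`` maps peptide sequence to fields such as r5,
    immunogenic, protein_class and enzyme; they are carried alongside as
    one row per peptide. Row and column order is sorted, hence stable
    across runs.
    """
    detected = peptide_quants[peptide_quants["detected"]]
    matrix = detected.pivot_table(
        index="sample_id",
        columns="peptide_sequence",
        values="summed_area",
        aggfunc="first",
    )
    matrix = matrix.reindex(
        index=sorted(peptide_quants["sample_id"].unique()),
        columns=sorted(peptide_quants["peptide_sequence"].unique()),
    )
    ann_rows = []
    for pep in matrix.columns:
        row = {"peptide_sequence": pep}
        row.update((annotations or {}).get(pep, {}))
        ann_rows.append(row)
    ann = pd.DataFrame(ann_rows).set_index("peptide_sequence")
    return matrix, ann


def default_wheat_markers() -> list[str]:
    """Curated wheat-specific marker peptides shipped with the package."""
    text = (
        resources.files("glutenscan.data").joinpath("wheat_markers.txt").read_text()
    )
    return [
        line.strip().upper()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]


def wheat_panel(
    peptide_quants: pd.DataFrame,
    wheat_marker_list: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-sample wheat-contamination panel.

    For every sample: the number of wheat marker peptides detected, their
    combined abundance, and a contamination flag raised when at least one
    marker is seen.
    """
    markers = [m.upper() for m in (wheat_marker_list or default_wheat_markers())]
    q = peptide_quants[peptide_quants["peptide_sequence"].isin(markers)]
    rows = []
    for sample in sorted(peptide_quants["sample_id"].unique()):
        sub = q[(q["sample_id"] == sample) & q["detected"]]
        rows.append(
            {
                "sample_id": sample,
                "markers_detected": int(sub["peptide_sequence"].nunique()),
                "marker_area": float(sub["summed_area"].sum()),
                "contaminated": bool(len(sub)),
            }
        )
    return pd.DataFrame(rows)


def read_elisa_table(path: str | Path) -> pd.DataFrame:
    """Read a two-or-three-column ELISA results table.

    Columns: sample_id, gluten_mg_per_kg, optional label_group
    (control / low_gluten).
    """
    df = pd.read_csv(path)
    for col in ("sample_id", "gluten_mg_per_kg"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    df["gluten_mg_per_kg"] = df["gluten_mg_per_kg"].astype(float)
    if not np.isfinite(df["gluten_mg_per_kg"]).all():
        raise ValidationError(f"{path}: non-finite ELISA value")
    if (df["gluten_mg_per_kg"] < 0).any():
        raise ValidationError(f"{path}: negative ELISA value")
    if "label_group" in df.columns:
        bad = set(df["label_group"]) - {"control", "low_gluten"}
        if bad:
            raise ValidationError(f"{path}: unknown label_group value(s): {sorted(bad)}")
    return df


def default_elisa_table() -> pd.DataFrame:
    """The 14-beer R5 competitive ELISA survey shipped with the package.

    Five control beers (C1-C5) and nine beers marketed as low-gluten or
    gluten-free (LG1-LG9), gluten in mg/kg.
    """
    with resources.as_file(
        resources.files("glutenscan.data").joinpath("beer_elisa.csv")
    ) as p:
        return read_elisa_table(p)


def elisa_concordance(
    elisa_records: pd.DataFrame,
    net_hordein_area: pd.Series | None = None,
    rank_margin: int = 3,
) -> dict:
    """ELISA-vs-LC-MS concordance report.

    Returns a dict with

    * ``group_means`` — mean mg/kg per label group, rounded to 1 decimal,
      and ``group_means_raw`` unrounded;
    * ``low_gluten_vs_max_control_percent`` — the low-gluten group mean
      as a percentage of the highest control ELISA value (nearest
      integer), plus the raw ratio;
    * ``spearman_rho`` — rank correlation between ELISA mg/kg and net
      hordein MS signal over paired samples (None with a warning when
      fewer than 3 pairs);
    * ``mismatch_table`` — samples whose ELISA rank and LC-MS rank differ
      by more than ``rank_margin`` (ranked ascending in both).
    """
    report: dict = {}
    if "label_group" in elisa_records.columns:
        raw = elisa_records.groupby("label_group")["gluten_mg_per_kg"].mean()
        report["group_means_raw"] = raw.to_dict()
        report["group_means"] = {k: round(v, 1) for k, v in raw.items()}
        if "low_gluten" in raw.index:
            controls = elisa_records.loc[
                elisa_records["label_group"] == "control", "gluten_mg_per_kg"
            ]
            if len(controls):
                ratio = 100.0 * raw["low_gluten"] / controls.max()
                report["low_gluten_vs_max_control_percent_raw"] = float(ratio)
                report["low_gluten_vs_max_control_percent"] = int(round(ratio))

    report["spearman_rho"] = None
    report["mismatch_table"] = pd.DataFrame(
        columns=["sample_id", "elisa_rank", "ms_rank", "rank_difference"]
    )
    if net_hordein_area is None:
        return report

    paired = elisa_records.set_index("sample_id")["gluten_mg_per_kg"].to_frame()
    paired["net_hordein_area"] = net_hordein_area
    paired = paired.dropna()
    if len(paired) < 3:
        logger.warning(
            "only %d paired sample(s); rank correlation omitted", len(paired)
        )
        return report

    rho, _ = stats.spearmanr(paired["gluten_mg_per_kg"], paired["net_hordein_area"])
    report["spearman_rho"] = float(rho)
    elisa_rank = paired["gluten_mg_per_kg"].rank(method="average")
    ms_rank = paired["net_hordein_area"].rank(method="average")
    diff = (elisa_rank - ms_rank).abs()
    mismatch = pd.DataFrame(
        {
            "sample_id": paired.index,
            "elisa_rank": elisa_rank.values,
            "ms_rank": ms_rank.values,
            "rank_difference": diff.values,
        }
    )
    report["mismatch_table"] = (
        mismatch[mismatch["rank_difference"] > rank_margin]
        .sort_values("rank_difference", ascending=False)
        .reset_index(drop=True)
    )
    return report
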