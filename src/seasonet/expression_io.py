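"""Reading, validation and normalisation of the tabular inputs.

Canonical expression input is a long (tidy) TSV with columns
``gene_id, tissue, season, timepoint_index, value`` and an optional
``date`` column; one row per measured band intensity.  Wide matrices are an
export convenience only — the six conditions share a gene list but not
necessarily a sampling calendar, so rows are keyed by condition.

Missing timepoints are a hard error rather than imputed: the downstream
screen and correlation statistics run on short series (around eight
timepoints) where silent imputation would dominate the result.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .model import (
    AnnotationSet,
    ConditionKey,
    ExpressionMatrix,
    GeneAnnotation,
    PrecipitationSeries,
)

logger = logging.getLogger(__name__)

EXPRESSION_COLUMNS = ["gene_id", "tissue", "season", "timepoint_index", "value"]


def normalize_intensity(raw, background, reference) -> np.ndarray:
    """Reference-normalise band intensities.

    Each lane's background is subtracted from the raw band intensity
    (clamped at zero: a band fainter than its lane background means no
    detectable expression), then divided by the background-subtracted
    reference-gene intensity of the same lane.

    Raises ``ValueError`` naming the lane if the reference does not exceed
    the background anywhere.
    """
    raw = np.asarray(raw, dtype=float)
    background = np.asarray(background, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if not (raw.shape == background.shape == reference.shape):
        raise ValueError("raw, background and reference series must have equal length")
    denom = reference - background
    bad = np.flatnonzero(denom <= 0)
    if bad.size:
        raise ValueError(
            f"reference intensity not above background in lane(s) {bad.tolist()}"
        )
    return np.maximum(raw - background, 0.0) / denom


def load_expression(path) -> dict[ConditionKey, ExpressionMatrix]:
    """Load a long-format expression TSV into one matrix per condition.

    Validates that every (gene, condition) series is complete over that
    condition's timepoints, that no (gene, condition, timepoint) is
    duplicated, and that all values are nonnegative.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "tissue": str, "season": str})
    missing = [c for c in EXPRESSION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"expression TSV missing columns {missing}")
    if df["value"].isna().any() or (df["value"] < 0).any():
        bad = df.loc[df["value"].isna() | (df["value"] < 0), "gene_id"].unique().tolist()
        raise ValueError(f"negative or missing expression values for genes {bad}")

    dup = df.duplicated(subset=["gene_id", "tissue", "season", "timepoint_index"])
    if dup.any():
        rows = df.loc[dup, ["gene_id", "tissue", "season", "timepoint_index"]]
        raise ValueError(f"duplicate (gene, condition, timepoint) rows:\n{rows.to_string(index=False)}")

    matrices: dict[ConditionKey, ExpressionMatrix] = {}
    for (tissue, season), sub in df.groupby(["tissue", "season"], sort=True):
        cond = ConditionKey(tissue, season)
        wide = sub.pivot(index="gene_id", columns="timepoint_index", values="value")
        wide = wide.sort_index(axis=0).sort_index(axis=1)
        wide.columns.name = None
        wide.index.name = "gene_id"
        if wide.isna().any().any():
            ragged = wide.index[wide.isna().any(axis=1)].tolist()
            raise ValueError(
                f"{cond.label}: gene(s) {ragged} missing one or more timepoints"
            )
        dates = None
        if "date" in sub.columns and sub["date"].notna().any():
            by_tp = sub.drop_duplicates("timepoint_index").sort_values("timepoint_index")
            dates = by_tp["date"].astype(str).tolist()
        matrices[cond] = ExpressionMatrix(condition=cond, values=wide, dates=dates)
    logger.info("loaded %d condition matrices from %s", len(matrices), path)
    return matrices


def write_expression(matrices: dict[ConditionKey, ExpressionMatrix], path) -> None:
    """Write matrices back to the canonical long TSV (round-trips with load)."""
    rows = []
    for cond in sorted(matrices):
        m = matrices[cond]
        for gene in m.genes:
            for j, tp in enumerate(m.timepoints):
                row = {
                    "gene_id": gene,
                    "tissue": cond.tissue,
                    "season": cond.season,
                    "timepoint_index": tp,
                    "value": m.values.at[gene, tp],
                }
                if m.dates is not None:
                    row["date"] = m.dates[j]
                rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_annotations(path) -> AnnotationSet:
    """Load the annotation TSV (id, description, is_tf, tf_family)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("id", "description", "is_tf", "tf_family"):
        if col not in df.columns:
            raise ValueError(f"annotation TSV missing column {col!r}")
    annotations = []
    for _, row in df.iterrows():
        is_tf = str(row["is_tf"]).strip().lower() in ("true", "1", "yes")
        family = row["tf_family"].strip() or None
        annotations.append(
            GeneAnnotation(
                id=row["id"].strip(),
                description=row["description"],
                is_tf=is_tf,
                tf_family=family,
            )
        )
    out = AnnotationSet(annotations)
    if not out.annotations:
        logger.warning("annotation file %s is empty; all genes treated as non-TF", path)
    return out


def reconcile_annotations(
    annset: AnnotationSet, matrices: dict[ConditionKey, ExpressionMatrix]
) -> AnnotationSet:
    """Tolerate genes present in expression but absent from the annotation.

    Unannotated genes are appended with ``is_tf=False`` and a logged warning,
    so downstream TF extraction never fails on an incomplete table.
    """
    known = {a.id for a in annset.annotations}
    observed: set[str] = set()
    for m in matrices.values():
        observed.update(m.genes)
    extra = sorted(observed - known)
    if extra:
        logger.warning("genes missing from annotation, assumed non-TF: %s", extra)
    return AnnotationSet(annset.annotations + [GeneAnnotation(id=g) for g in extra])


def load_precipitation(path) -> PrecipitationSeries:
    """Load a precipitation TSV (timepoint_index, [date], precipitation_mm)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("timepoint_index", "precipitation_mm"):
        if col not in df.columns:
            raise ValueError(f"precipitation TSV missing column {col!r}")
    df = df.sort_values("timepoint_index")
    dates = df["date"].astype(str).tolist() if "date" in df.columns else None
    return PrecipitationSeries(
        timepoints=df["timepoint_index"].astype(int).tolist(),
        values=df["precipitation_mm"].to_numpy(dtype=float),
        dates=dates,
    )


def write_precipitation(series: PrecipitationSeries, path) -> None:
    df = pd.DataFrame({"timepoint_index": series.timepoints, "precipitation_mm": series.values})
    if series.dates is not None:
        df.insert(1, "date", series.dates)
    df.to_csv(path, sep="\t", index=False)


def align_precipitation(
    series: PrecipitationSeries, matrix: ExpressionMatrix
) -> PrecipitationSeries:
    """Reorder/subset precipitation to exactly the matrix's timepoints."""
    index = {tp: i for i, tp in enumerate(series.timepoints)}
    missing = [tp for tp in matrix.timepoints if tp not in index]
    if missing:
        raise ValueError(
            f"{matrix.condition.label}: timepoints {missing} absent from precipitation series"
        )
    order = [index[tp] for tp in matrix.timepoints]
    return PrecipitationSeries(
        timepoints=list(matrix.timepoints),
        values=series.values[order],
        season=series.season,
        dates=[series.dates[i] for i in order] if series.dates else None,
    )
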