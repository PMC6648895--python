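"""Bait-prey co-enrichment screen over a panel of TAP purifications.

The screen asks, for each bait purification, which proteins are
over-represented relative to the whole panel. The processing chain follows
the label-free quantification convention used for such panels:

1. each purification column is normalized to percent of its total
   intensity (:func:`normalize_relative`);
2. undetected proteins (exact zeros) are replaced by 0.0001 percent so
   logarithms are defined (:func:`replace_zeros`); the matrix is not
   renormalized afterwards;
3. relative intensities are log10-transformed for display
   (:func:`log10_matrix`) and rows ordered by functional group and mean
   signal for a heat map (:func:`heatmap_order`);
4. for a focal purification, each protein's relative intensity is compared
   with its mean over the panel, excluding designated outlier
   purifications (:func:`reference_mean`, :func:`enrichment_table`).
   Proteins present at panel-typical levels fall on the identity diagonal
   (log10 ratio 0); dedicated chaperone candidates sit far above it.
5. :func:`rank_candidates` formalizes the visual call with explicit
   thresholds on the log10 enrichment ratio and on the focal relative
   intensity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import (
    GROUP_ORDER,
    RPROTEIN_GROUPS,
    ZERO_REPLACEMENT,
    AnnotationMap,
    IntensityTable,
    RelativeIntensityTable,
    ScreenDesign,
    ValidationError,
)

#: Default candidate thresholds: >= 10-fold enrichment, >= 0.01 percent focal signal.
DEFAULT_MIN_LOG10_RATIO: float = 1.0
DEFAULT_MIN_RELINT: float = 0.01


def normalize_relative(table: IntensityTable) -> RelativeIntensityTable:
    """Scale every purification column to percent of its total intensity."""
    sums = table.data.sum(axis=0)
    zero_cols = sums.index[sums <= 0]
    if len(zero_cols):
        raise ValidationError(
            f"purification {zero_cols[0]!r} has zero total intensity"
        )
    rel = table.data.div(sums, axis=1) * 100.0
    return RelativeIntensityTable(rel, zero_replaced=False)


def replace_zeros(table: RelativeIntensityTable) -> RelativeIntensityTable:
    """Substitute exact zeros with 0.0001 percent; no renormalization."""
    if table.zero_replaced:
        raise ValidationError("zeros have already been replaced in this table")
    rel = table.data.where(table.data != 0.0, ZERO_REPLACEMENT)
    return RelativeIntensityTable(rel, zero_replaced=True)


def log10_matrix(table: RelativeIntensityTable) -> pd.DataFrame:
    """Elementwise base-10 logarithm; requires zero replacement first.

    The minimum attainable value is log10(0.0001) = -4 (undetected).
    """
    if not table.zero_replaced:
        raise ValidationError("replace zeros before taking logarithms")
    if (table.data.to_numpy() <= 0).any():
        raise ValidationError("log10_matrix requires strictly positive values")
    return np.log10(table.data)


@dataclass
class HeatmapMatrix:
    """Row-ordered log10 relative intensities with group labels and boundaries."""

    data: pd.DataFrame
    groups: pd.Series
    boundaries: list[int]


def heatmap_order(log_matrix: pd.DataFrame, annotation: AnnotationMap) -> HeatmapMatrix:
    """Order rows by functional group, then by descending mean log10 signal.

    Ties in the mean are broken lexicographically by protein identifier, so
    the order is a deterministic total order, independent of input row order.
    """
    groups = pd.Series(
        {p: annotation.group(p) for p in log_matrix.index}, name="group"
    )
    order_idx = {g: i for i, g in enumerate(GROUP_ORDER)}
    mean_signal = log_matrix.mean(axis=1)
    key = pd.DataFrame(
        {
            "g": groups.map(order_idx),
            "neg_mean": -mean_signal,
            "pid": log_matrix.index.astype(str),
        },
        index=log_matrix.index,
    )
    ordered = key.sort_values(["g", "neg_mean", "pid"], kind="mergesort").index
    data = log_matrix.loc[ordered]
    g_sorted = groups.loc[ordered]
    boundaries = [
        i for i in range(1, len(g_sorted)) if g_sorted.iloc[i] != g_sorted.iloc[i - 1]
    ]
    return HeatmapMatrix(data=data, groups=g_sorted, boundaries=boundaries)


def _reference_columns(
    table: RelativeIntensityTable, design: ScreenDesign, focal: str
) -> list[str]:
    if focal not in table.purifications:
        raise ValidationError(f"unknown focal purification {focal!r}")
    # Outliers are excluded from every reference mean except their own:
    # when the focal purification is itself an outlier it is re-included so
    # that its representation can still be drawn against a defined mean.
    excluded = design.outliers - {focal}
    cols = [c for c in table.purifications if c not in excluded]
    if len(cols) < 2:
        raise ValidationError(
            f"reference mean for {focal!r} would use fewer than 2 purifications"
        )
    return cols


def reference_mean(
    table: RelativeIntensityTable,
    design: ScreenDesign,
    focal: str,
    leave_one_out: bool = False,
) -> pd.Series:
    """Per-protein mean relative intensity over the outlier-excluded panel.

    The focal purification is included in its own reference (the mean is
    taken over *all* non-outlier purifications); ``leave_one_out=True``
    switches to a mean that excludes the focal column as well.
    """
    if not table.zero_replaced:
        raise ValidationError("reference_mean expects a zero-replaced table")
    cols = _reference_columns(table, design, focal)
    if leave_one_out:
        cols = [c for c in cols if c != focal]
        if len(cols) < 2:
            raise ValidationError(
                f"leave-one-out reference for {focal!r} would use fewer than 2 "
                "purifications"
            )
    return table.data[cols].mean(axis=1)


@dataclass
class EnrichmentTable:
    """Per-protein enrichment of one focal purification versus the panel mean.

    ``data`` columns: relint_focal, reference_mean, log10_ratio, rank
    (1 = most enriched; ties broken lexicographically by protein id),
    is_bait, group, contaminant.
    """

    focal: str
    bait: str
    data: pd.DataFrame


def enrichment_table(
    table: RelativeIntensityTable,
    design: ScreenDesign,
    focal: str,
    annotation: AnnotationMap | None = None,
    leave_one_out: bool = False,
) -> EnrichmentTable:
    """log10(focal / panel-mean) per protein, with dense descending ranks."""
    design.validate_against(table)
    ref = reference_mean(table, design, focal, leave_one_out=leave_one_out)
    if (ref <= 0).any():
        raise ValidationError("reference mean contains non-positive values")
    focal_col = table.data[focal]
    ratio = np.log10(focal_col / ref)
    order = (
        pd.DataFrame({"r": -ratio, "pid": ratio.index.astype(str)})
        .sort_values(["r", "pid"], kind="mergesort")
        .index
    )
    rank = pd.Series(np.arange(1, len(order) + 1), index=order).reindex(ratio.index)
    bait = design.baits[focal]
    ann = annotation or AnnotationMap({})
    df = pd.DataFrame(
        {
            "relint_focal": focal_col,
            "reference_mean": ref,
            "log10_ratio": ratio,
            "rank": rank,
            "is_bait": ratio.index == bait,
            "group": [ann.group(p) for p in ratio.index],
            "contaminant": [ann.is_contaminant(p) for p in ratio.index],
        }
    )
    return EnrichmentTable(focal=focal, bait=bait, data=df)


def rank_candidates(
    etable: EnrichmentTable,
    min_log10_ratio: float = DEFAULT_MIN_LOG10_RATIO,
    min_relint: float = DEFAULT_MIN_RELINT,
) -> pd.DataFrame:
    """Non-bait proteins passing both thresholds, most enriched first.

    Contaminant-flagged proteins are kept in the list but labeled, so a
    carbohydrate-metabolism enzyme riding high in one purification is
    visible rather than silently called a chaperone candidate.
    """
    if min_log10_ratio < 0 or min_relint < 0:
        raise ValidationError("candidate thresholds must be non-negative")
    df = etable.data
    sel = (
        ~df["is_bait"]
        & (df["log10_ratio"] >= min_log10_ratio)
        & (df["relint_focal"] >= min_relint)
    )
    out = df.loc[sel].copy()
    out = out.loc[
        pd.DataFrame({"r": -out["log10_ratio"], "pid": out.index.astype(str)})
        .sort_values(["r", "pid"], kind="mergesort")
        .index
    ]
    return out


def top_nonbait(etable: EnrichmentTable) -> str:
    """Identifier of the most enriched non-bait protein in a focal purification."""
    df = etable.data.loc[~etable.data["is_bait"]]
    order = (
        pd.DataFrame({"r": -df["log10_ratio"], "pid": df.index.astype(str)})
        .sort_values(["r", "pid"], kind="mergesort")
        .index
    )
    return str(order[0])


def rprotein_fraction(
    table: RelativeIntensityTable, annotation: AnnotationMap, purification: str
) -> float:
    """Percent of a purification's signal contributed by 40S + 60S r-proteins.

    Computed on true (not zero-replaced) relative intensities.
    """
    if table.zero_replaced:
        raise ValidationError("rprotein_fraction expects unreplaced relative intensities")
    if purification not in table.purifications:
        raise ValidationError(f"unknown purification {purification!r}")
    mask = [annotation.group(p) in RPROTEIN_GROUPS for p in table.proteins]
    return float(table.data.loc[mask, purification].sum())
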