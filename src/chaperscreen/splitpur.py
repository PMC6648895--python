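"""Split-tag purification comparison (partner-enriched vs partner-depleted).

In a split purification, one bait's complexes are partitioned by a second
affinity tag on a partner protein into a partner-containing (enriched) and
a partner-free (depleted) pool. Because the bait dominates the eluates in
such designs, normalization here excludes the bait from the per-column
total: non-bait proteins sum to 100 percent, and the bait's own share is
expressed on the same bait-excluded scale (it may exceed 100 percent when
the bait carries more than half of the raw signal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import (
    GROUP_ORDER,
    AnnotationMap,
    IntensityTable,
    RelativeIntensityTable,
    ValidationError,
)


def normalize_excluding_bait(table: IntensityTable, bait: str) -> RelativeIntensityTable:
    """Percent of the bait-excluded total, per purification column.

    Every protein including the bait is divided by (column total - bait
    intensity). With bait intensity 0 this reduces to the ordinary
    percent-of-total normalization.
    """
    if bait not in table.proteins:
        raise ValidationError(f"bait {bait!r} absent from intensity table")
    denom = table.data.sum(axis=0) - table.data.loc[bait]
    bad = denom.index[denom <= 0]
    if len(bad):
        raise ValidationError(
            f"bait-excluded total of purification {bad[0]!r} is non-positive"
        )
    rel = table.data.div(denom, axis=1) * 100.0
    return RelativeIntensityTable(rel, zero_replaced=False, bait_excluded=bait)


def _replace_zeros_raw(df: pd.DataFrame) -> pd.DataFrame:
    from .io import ZERO_REPLACEMENT

    return df.where(df != 0.0, ZERO_REPLACEMENT)


@dataclass
class SplitComparison:
    """Per-protein comparison of the enriched against the depleted pool.

    ``data`` columns: relint_enriched, relint_depleted (bait-excluded
    percent), log10_enriched, log10_depleted (after zero replacement),
    log10_difference, is_bait, group.
    ``group_summary``: share of the bait-excluded total per functional
    group in each pool (percent, bait row excluded).
    """

    bait: str
    data: pd.DataFrame
    group_summary: pd.DataFrame


def split_compare(
    enriched: IntensityTable,
    depleted: IntensityTable,
    bait: str,
    annotation: AnnotationMap | None = None,
    enriched_column: str | None = None,
    depleted_column: str | None = None,
) -> SplitComparison:
    """Compare one enriched against one depleted purification column.

    The two tables are outer-aligned on the union of proteins (missing
    proteins count as undetected, intensity 0), normalized with the bait
    excluded from the denominator, zero-replaced and log10-transformed.
    """
    e_col = enriched_column or enriched.purifications[0]
    d_col = depleted_column or depleted.purifications[0]
    if e_col not in enriched.purifications:
        raise ValidationError(f"unknown enriched column {e_col!r}")
    if d_col not in depleted.purifications:
        raise ValidationError(f"unknown depleted column {d_col!r}")

    universe = sorted(set(enriched.proteins) | set(depleted.proteins))
    e_raw = enriched.data[e_col].reindex(universe).fillna(0.0)
    d_raw = depleted.data[d_col].reindex(universe).fillna(0.0)
    merged = IntensityTable(
        pd.DataFrame({"enriched": e_raw, "depleted": d_raw}, index=universe)
    )
    rel = normalize_excluding_bait(merged, bait)
    logged = np.log10(_replace_zeros_raw(rel.data))

    ann = annotation or AnnotationMap({})
    groups = pd.Series([ann.group(p) for p in universe], index=universe, name="group")
    df = pd.DataFrame(
        {
            "relint_enriched": rel.data["enriched"],
            "relint_depleted": rel.data["depleted"],
            "log10_enriched": logged["enriched"],
            "log10_depleted": logged["depleted"],
            "log10_difference": logged["enriched"] - logged["depleted"],
            "is_bait": pd.Index(universe) == bait,
            "group": groups,
        }
    )

    nonbait = rel.data.drop(index=bait)
    summary = (
        nonbait.groupby(groups.drop(index=bait))
        .sum()
        .reindex(list(GROUP_ORDER))
        .dropna(how="all")
    )
    summary.index.name = "group"
    summary.columns = ["share_enriched", "share_depleted"]
    return SplitComparison(bait=bait, data=df, group_summary=summary)
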