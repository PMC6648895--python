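"""Shared fixtures and independent brute-force oracles.

The oracles recompute every pipeline quantity from the definitions using
plain Python loops and ``math`` only, so they share no code path with the
vectorized implementation they check.
"""

from __future__ import annotations

import math

import pandas as pd
import pytest

from chaperscreen import AnnotationMap, IntensityTable, ScreenDesign

ZERO_SUB = 0.0001


# ---------------------------------------------------------------------------
# Brute-force oracles (pure-Python, from definitions)
# ---------------------------------------------------------------------------

def brute_relative(columns: dict[str, list[float]]) -> dict[str, list[float]]:
    """Percent-of-total per column, plain loops."""
    out = {}
    for name, col in columns.items():
        total = sum(col)
        out[name] = [100.0 * v / total for v in col]
    return out


def brute_enrichment(
    columns: dict[str, list[float]],
    focal: str,
    outliers: set[str] = frozenset(),
) -> list[float]:
    """log10(relint_focal / reference_mean) per protein, from definitions.

    Normalization to percent, zero substitution, outlier-excluded mean
    (re-including the focal purification when it is itself an outlier) and
    the log ratio are all recomputed with scalar arithmetic.
    """
    rel = brute_relative(columns)
    repl = {k: [v if v != 0 else ZERO_SUB for v in col] for k, col in rel.items()}
    excluded = set(outliers) - {focal}
    ref_cols = [k for k in columns if k not in excluded]
    n = len(repl[focal])
    ratios = []
    for i in range(n):
        mean = sum(repl[k][i] for k in ref_cols) / len(ref_cols)
        ratios.append(math.log10(repl[focal][i] / mean))
    return ratios


def brute_cotrans(matrix: list[list[float]], partners: list[int]) -> dict:
    """Two-way background correction and unit-mean scaling, from definitions.

    ``partners[i]`` is the cognate column index of row i.
    """
    n_rows, n_cols = len(matrix), len(matrix[0])
    purif_bg = []
    for i in range(n_rows):
        vals = [matrix[i][j] for j in range(n_cols) if j != partners[i]]
        purif_bg.append(sum(vals) / len(vals))
    amp_bg = []
    for j in range(n_cols):
        vals = [matrix[i][j] for i in range(n_rows) if partners[i] != j]
        amp_bg.append(sum(vals) / len(vals))
    corrected = [
        [matrix[i][j] / (purif_bg[i] * amp_bg[j]) for j in range(n_cols)]
        for i in range(n_rows)
    ]
    bg_cells = [
        corrected[i][j]
        for i in range(n_rows)
        for j in range(n_cols)
        if j != partners[i]
    ]
    bg_mean = sum(bg_cells) / len(bg_cells)
    normalized = [[v / bg_mean for v in row] for row in corrected]
    scores = [normalized[i][partners[i]] for i in range(n_rows)]
    return {
        "purification_background": purif_bg,
        "amplicon_background": amp_bg,
        "corrected": corrected,
        "normalized": normalized,
        "cognate_scores": scores,
    }


# ---------------------------------------------------------------------------
# Small shared fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def toy_table() -> IntensityTable:
    """3 proteins x 4 purifications; CHAP detected only in the last column."""
    return IntensityTable(
        pd.DataFrame(
            {
                "S1": [90.0, 10.0, 0.0],
                "S2": [85.0, 15.0, 0.0],
                "S3": [88.0, 12.0, 0.0],
                "S4": [80.0, 15.0, 5.0],
            },
            index=["RPS2", "RPS3", "CHAP"],
        )
    )


@pytest.fixture
def toy_design() -> ScreenDesign:
    return ScreenDesign(
        {"S1": "RPS2", "S2": "RPS3", "S3": "RPS2", "S4": "RPS2"}
    )


@pytest.fixture
def toy_annotation() -> AnnotationMap:
    return AnnotationMap(
        {"RPS2": "40S r-protein", "RPS3": "40S r-protein", "CHAP": "other"}
    )
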