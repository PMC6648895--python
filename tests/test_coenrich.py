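"""Relative-intensity normalization, heat-map ordering and enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from chaperscreen import (
    AnnotationMap,
    IntensityTable,
    ScreenDesign,
    ValidationError,
    enrichment_table,
    heatmap_order,
    log10_matrix,
    normalize_relative,
    rank_candidates,
    reference_mean,
    replace_zeros,
    rprotein_fraction,
    top_nonbait,
)
from conftest import brute_enrichment


def _table(cols: dict, index: list[str]) -> IntensityTable:
    return IntensityTable(pd.DataFrame(cols, index=index))


# ---------------------------------------------------------------------------
# normalize_relative / replace_zeros / log10
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "col,expected",
    [
        ([1.0, 1.0, 2.0], [25.0, 25.0, 50.0]),
        ([3.0, 0.0, 1.0], [75.0, 0.0, 25.0]),
    ],
)
def test_normalize_relative_examples(col, expected):
    t = _table({"S1": col}, [f"P{i}" for i in range(len(col))])
    rel = normalize_relative(t)
    assert np.allclose(rel.data["S1"].to_numpy(), expected, rtol=1e-12)
    assert not rel.zero_replaced


def test_normalize_single_protein_is_identity_case():
    rel = normalize_relative(_table({"S1": [7.3]}, ["P0"]))
    assert rel.data.loc["P0", "S1"] == pytest.approx(100.0, rel=1e-12)


def test_normalize_rejects_all_zero_column():
    with pytest.raises(ValidationError, match="S1"):
        normalize_relative(_table({"S1": [0.0, 0.0]}, ["A", "B"]))


def test_replace_zeros_substitutes_exact_zeros_only():
    rel = normalize_relative(_table({"S1": [3.0, 0.0, 1.0]}, ["A", "B", "C"]))
    repl = replace_zeros(rel)
    assert repl.data["S1"].tolist() == [75.0, 0.0001, 25.0]
    assert repl.zero_replaced
    # a column with k zeros sums to 100 + 0.0001 k; no renormalization
    assert repl.data["S1"].sum() == pytest.approx(100.0001, abs=1e-12)


def test_replace_zeros_no_op_without_zeros_and_rejects_double_application():
    rel = normalize_relative(_table({"S1": [1.0, 3.0]}, ["A", "B"]))
    repl = replace_zeros(rel)
    assert (repl.data.to_numpy() == rel.data.to_numpy()).all()
    with pytest.raises(ValidationError, match="already"):
        replace_zeros(repl)


def test_log10_matrix_closed_forms():
    rel = normalize_relative(_table({"S1": [0.0, 100.0 / 2.5 * 2.5]}, ["A", "B"]))
    # force a column containing an exact 0 and a 100
    repl = replace_zeros(rel)
    lm = log10_matrix(repl)
    assert lm.loc["A", "S1"] == pytest.approx(-4.0, abs=1e-12)
    assert lm.loc["B", "S1"] == pytest.approx(2.0, abs=1e-12)


def test_log10_of_2_5_percent():
    df = pd.DataFrame({"S1": [2.5, 97.5]}, index=["A", "B"])
    from chaperscreen import RelativeIntensityTable

    repl = replace_zeros(RelativeIntensityTable(df))
    assert log10_matrix(repl).loc["A", "S1"] == pytest.approx(0.39794, abs=1e-5)


def test_log10_requires_zero_replacement():
    rel = normalize_relative(_table({"S1": [1.0, 1.0]}, ["A", "B"]))
    with pytest.raises(ValidationError):
        log10_matrix(rel)


# ---------------------------------------------------------------------------
# heatmap ordering
# ---------------------------------------------------------------------------

def test_heatmap_order_groups_before_mean():
    lm = pd.DataFrame(
        {"S1": [1.2, 0.3, 2.0], "S2": [1.2, 0.3, 2.0]},
        index=["R_hi", "R_lo", "AF1"],
    )
    ann = AnnotationMap(
        {"R_hi": "40S r-protein", "R_lo": "40S r-protein", "AF1": "ribosome AF"}
    )
    heat = heatmap_order(lm, ann)
    assert list(heat.data.index) == ["R_hi", "R_lo", "AF1"]
    assert heat.boundaries == [2]


def test_heatmap_order_single_group_descending_and_ties_lexicographic():
    lm = pd.DataFrame({"S1": [0.5, 1.5, 0.5]}, index=["B", "A", "Aa"])
    ann = AnnotationMap({})
    heat = heatmap_order(lm, ann)
    assert list(heat.data.index) == ["A", "Aa", "B"]


def test_heatmap_order_input_order_independent_and_idempotent():
    rng = np.random.default_rng(42)
    lm = pd.DataFrame(
        rng.normal(size=(8, 3)),
        index=[f"P{i}" for i in range(8)],
        columns=["S1", "S2", "S3"],
    )
    ann = AnnotationMap({"P0": "histone", "P3": "40S r-protein"})
    ref = heatmap_order(lm, ann)
    shuffled = lm.sample(frac=1.0, random_state=7)
    again = heatmap_order(shuffled, ann)
    assert list(again.data.index) == list(ref.data.index)
    twice = heatmap_order(ref.data, ann)
    assert list(twice.data.index) == list(ref.data.index)


# ---------------------------------------------------------------------------
# reference mean and enrichment
# ---------------------------------------------------------------------------

def _relint_fixture(values: list[float]):
    """Four purifications where one protein has the given relints."""
    from chaperscreen import RelativeIntensityTable

    other = [100.0 - v for v in values]
    df = pd.DataFrame(
        {f"S{i + 1}": [values[i], other[i]] for i in range(4)}, index=["X", "Y"]
    )
    return replace_zeros(RelativeIntensityTable(df))


def test_reference_mean_includes_focal():
    repl = _relint_fixture([0.1, 0.1, 0.1, 10.0])
    design = ScreenDesign({f"S{i}": "X" for i in range(1, 5)})
    ref = reference_mean(repl, design, "S4")
    assert ref["X"] == pytest.approx(2.575, rel=1e-12)


def test_reference_mean_excludes_outliers():
    repl = _relint_fixture([0.1, 0.1, 0.1, 10.0])
    design = ScreenDesign({f"S{i}": "X" for i in range(1, 5)}, outliers={"S1"})
    ref = reference_mean(repl, design, "S4")
    assert ref["X"] == pytest.approx((0.1 + 0.1 + 10.0) / 3, rel=1e-12)


def test_outlier_focal_included_in_its_own_reference():
    repl = _relint_fixture([0.1, 0.1, 0.1, 10.0])
    design = ScreenDesign({f"S{i}": "X" for i in range(1, 5)}, outliers={"S4"})
    # S4 is an outlier but is re-included when it is itself the focal sample
    ref_for_s4 = reference_mean(repl, design, "S4")
    assert ref_for_s4["X"] == pytest.approx(2.575, rel=1e-12)
    # ... and excluded from everyone else's reference
    ref_for_s1 = reference_mean(repl, design, "S1")
    assert ref_for_s1["X"] == pytest.approx(0.1, rel=1e-12)


def test_reference_mean_leave_one_out_flag():
    repl = _relint_fixture([0.1, 0.1, 0.1, 10.0])
    design = ScreenDesign({f"S{i}": "X" for i in range(1, 5)})
    ref = reference_mean(repl, design, "S4", leave_one_out=True)
    assert ref["X"] == pytest.approx(0.1, rel=1e-12)


def test_enrichment_log_ratio_value():
    repl = _relint_fixture([0.1, 0.1, 0.1, 10.0])
    design = ScreenDesign({f"S{i}": "Y" for i in range(1, 5)})
    et = enrichment_table(repl, design, "S4")
    assert et.data.loc["X", "log10_ratio"] == pytest.approx(
        math.log10(10.0 / 2.575), rel=1e-12
    )


def test_uniform_protein_lies_on_diagonal(toy_design):
    t = _table(
        {"S1": [2.0, 6.0], "S2": [1.0, 3.0], "S3": [4.0, 12.0], "S4": [10.0, 30.0]},
        ["RPS2", "RPS3"],
    )
    repl = replace_zeros(normalize_relative(t))
    for focal in ["S1", "S2", "S3", "S4"]:
        et = enrichment_table(repl, toy_design, focal)
        assert np.allclose(et.data["log10_ratio"].to_numpy(), 0.0, atol=1e-12)


def test_focal_only_protein_ranks_first(toy_table, toy_design, toy_annotation):
    repl = replace_zeros(normalize_relative(toy_table))
    et = enrichment_table(repl, toy_design, "S4", toy_annotation)
    assert et.data.loc["CHAP", "rank"] == 1
    assert top_nonbait(et) == "CHAP"
    assert sorted(et.data["rank"]) == [1, 2, 3]


def test_rank_candidates_thresholds(toy_table, toy_design, toy_annotation):
    # In a 4-sample panel the focal-inclusive mean caps the ratio at 4x
    # (log10 0.6), so the toy is screened with a matching threshold.
    repl = replace_zeros(normalize_relative(toy_table))
    et = enrichment_table(repl, toy_design, "S4", toy_annotation)
    cands = rank_candidates(et, min_log10_ratio=0.5)
    assert list(cands.index) == ["CHAP"]
    assert rank_candidates(et, min_log10_ratio=float("inf")).empty
    with pytest.raises(ValidationError):
        rank_candidates(et, min_log10_ratio=-1.0)


def test_rank_candidates_default_thresholds_on_wide_panel():
    """A focal-specific protein at 5% clears the 10-fold default cut once
    the panel is wide enough for the focal-inclusive mean to dilute."""
    n = 11
    cols = {f"S{j}": [95.0, 5.0 if j == n - 1 else 0.0] for j in range(n)}
    cols = {k: [v[0], v[1]] for k, v in cols.items()}
    t = IntensityTable(pd.DataFrame(cols, index=["RPS2", "CHAP"]))
    repl = replace_zeros(normalize_relative(t))
    design = ScreenDesign({f"S{j}": "RPS2" for j in range(n)})
    et = enrichment_table(repl, design, f"S{n - 1}")
    cands = rank_candidates(et)
    assert list(cands.index) == ["CHAP"]
    assert cands.loc["CHAP", "log10_ratio"] > 1.0


def test_bait_excluded_from_candidates(toy_table, toy_annotation):
    design = ScreenDesign({"S1": "RPS2", "S2": "RPS3", "S3": "RPS2", "S4": "CHAP"})
    repl = replace_zeros(normalize_relative(toy_table))
    et = enrichment_table(repl, design, "S4", toy_annotation)
    assert et.data.loc["CHAP", "is_bait"]
    assert "CHAP" not in rank_candidates(et, 0.0, 0.0).index


# ---------------------------------------------------------------------------
# r-protein fraction
# ---------------------------------------------------------------------------

def test_rprotein_fraction_examples(toy_annotation):
    t = _table({"S1": [60.0, 12.0, 28.0]}, ["RPS2", "RPS3", "CHAP"])
    rel = normalize_relative(t)
    assert rprotein_fraction(rel, toy_annotation, "S1") == pytest.approx(72.0)
    t_all = _table({"S1": [60.0, 40.0]}, ["RPS2", "RPS3"])
    assert rprotein_fraction(
        normalize_relative(t_all), toy_annotation, "S1"
    ) == pytest.approx(100.0)


def test_rprotein_fraction_requires_unreplaced_table(toy_annotation):
    rel = normalize_relative(_table({"S1": [1.0, 0.0]}, ["RPS2", "CHAP"]))
    with pytest.raises(ValidationError):
        rprotein_fraction(replace_zeros(rel), toy_annotation, "S1")
    with pytest.raises(ValidationError):
        rprotein_fraction(rel, toy_annotation, "NOPE")


# ---------------------------------------------------------------------------
# properties
# ---------------------------------------------------------------------------

@settings(derandomize=True, max_examples=40, deadline=None)
@given(
    scales=st.lists(
        st.floats(min_value=0.01, max_value=1e4), min_size=3, max_size=3
    ),
    seed=st.integers(0, 10_000),
)
def test_scale_invariance_of_relative_and_enrichment(scales, seed):
    """Multiplying raw columns by positive constants changes nothing downstream."""
    rng = np.random.default_rng(seed)
    raw = rng.exponential(100.0, (5, 3)) + 0.01
    idx = [f"P{i}" for i in range(5)]
    cols = ["S1", "S2", "S3"]
    t1 = IntensityTable(pd.DataFrame(raw, index=idx, columns=cols))
    t2 = IntensityTable(
        pd.DataFrame(raw * np.asarray(scales), index=idx, columns=cols)
    )
    r1 = replace_zeros(normalize_relative(t1))
    r2 = replace_zeros(normalize_relative(t2))
    assert np.allclose(r1.data.to_numpy(), r2.data.to_numpy(), rtol=1e-9)
    design = ScreenDesign({c: "P0" for c in cols})
    e1 = enrichment_table(r1, design, "S2")
    e2 = enrichment_table(r2, design, "S2")
    assert np.allclose(
        e1.data["log10_ratio"].to_numpy(), e2.data["log10_ratio"].to_numpy(),
        atol=1e-9,
    )


@settings(derandomize=True, max_examples=30, deadline=None)
@given(seed=st.integers(0, 100_000), outlier=st.booleans())
def test_enrichment_matches_brute_force(seed, outlier):
    """Vectorized enrichment equals the scalar from-definitions oracle."""
    rng = np.random.default_rng(seed)
    n_prot = int(rng.integers(2, 6))
    n_samp = int(rng.integers(3, 6))
    grid = np.array([0.0, 1.0, 2.0, 5.0, 10.0])
    mat = rng.choice(grid, size=(n_prot, n_samp))
    mat[0, :] = np.maximum(mat[0, :], 1.0)  # keep columns non-degenerate
    cols = {f"S{j}": mat[:, j].tolist() for j in range(n_samp)}
    outliers = {"S0"} if outlier and n_samp > 3 else set()
    focal = f"S{n_samp - 1}"

    expected = brute_enrichment(cols, focal, outliers)

    idx = [f"P{i}" for i in range(n_prot)]
    t = IntensityTable(pd.DataFrame(mat, index=idx, columns=list(cols)))
    repl = replace_zeros(normalize_relative(t))
    design = ScreenDesign({c: "P0" for c in cols}, outliers=outliers)
    et = enrichment_table(repl, design, focal)
    got = et.data["log10_ratio"].to_numpy()
    assert np.allclose(got, expected, rtol=1e-12, atol=1e-12)
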