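"""Co-translational chaperone-mRNA association from qRT-PCR N0 values.

A chaperone that binds its client r-protein while the client is still on
the ribosome co-purifies the client's mRNA. The assay quantifies, for each
chaperone purification p and mRNA amplicon m, the starting concentration
N0 in the TEV eluate and in the total extract. The analysis is:

1. ratio[p, m] = mean(N0 TEV replicates) / mean(N0 total replicates)
   (:func:`replicate_ratios`) — ratio of replicate means, not mean of
   replicate ratios;
2. two-way background correction (:func:`background_means`,
   :func:`normalize_cotrans`): per-purification and per-amplicon
   background means are computed over the non-cognate cells only (the
   cell pairing a purification with its own client mRNA is excluded), and
   each ratio is divided by both its row and its column background;
3. the corrected matrix is rescaled so the mean over all non-cognate
   (background) cells is exactly 1. The cognate cell of each purification
   then reads directly as a fold enrichment over background; values near 1
   mean no co-translational association.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import N0Table, ValidationError

logger = logging.getLogger("chaperscreen")


@dataclass
class RatioMatrix:
    """TEV/total mRNA abundance ratios, purifications x amplicons.

    ``partners`` maps each purification (row) to its single cognate
    amplicon (column).
    """

    ratios: pd.DataFrame
    partners: dict[str, str]

    def __post_init__(self) -> None:
        if (self.ratios.to_numpy() <= 0).any():
            raise ValidationError("mRNA abundance ratios must be positive")
        for p in self.ratios.index:
            if p not in self.partners:
                raise ValidationError(f"purification {p!r} has no cognate amplicon")
            if self.partners[p] not in self.ratios.columns:
                raise ValidationError(
                    f"cognate amplicon {self.partners[p]!r} of {p!r} not in matrix"
                )

    def cognate_mask(self) -> pd.DataFrame:
        """Boolean matrix marking each purification's cognate cell."""
        mask = pd.DataFrame(
            False, index=self.ratios.index, columns=self.ratios.columns
        )
        for p, m in self.partners.items():
            if p in mask.index:
                mask.loc[p, m] = True
        return mask


def replicate_ratios(n0: N0Table, expected_replicates: int = 3) -> RatioMatrix:
    """Collapse technical replicates into one TEV/total ratio per (p, m).

    The arithmetic mean of the available replicates is taken per fraction;
    plates with fewer than ``expected_replicates`` wells log a warning but
    are not rejected. A (purification, amplicon) pair missing either
    fraction entirely is an error.
    """
    df = n0.records
    means = (
        df.groupby(["purification", "amplicon", "fraction"])["n0"]
        .agg(["mean", "size"])
        .reset_index()
    )
    short = means.loc[means["size"] < expected_replicates]
    for _, row in short.iterrows():
        logger.warning(
            "(%s, %s, %s) has %d replicate(s), expected %d",
            row["purification"], row["amplicon"], row["fraction"],
            row["size"], expected_replicates,
        )
    wide = means.pivot_table(
        index=["purification", "amplicon"], columns="fraction", values="mean"
    )
    for frac in ("TEV", "total"):
        if frac not in wide.columns:
            wide[frac] = np.nan
    missing = wide.index[wide[["TEV", "total"]].isna().any(axis=1)]
    if len(missing):
        p, m = missing[0]
        raise ValidationError(f"missing TEV or total fraction for ({p}, {m})")
    if (wide["total"] <= 0).any() or (wide["TEV"] <= 0).any():
        raise ValidationError("non-positive replicate mean")
    ratio = (wide["TEV"] / wide["total"]).unstack("amplicon")
    if ratio.isna().any().any():
        p = ratio.index[ratio.isna().any(axis=1)][0]
        raise ValidationError(f"incomplete amplicon panel for purification {p!r}")
    ratio.index.name = "purification"
    partners = {p: n0.partners[p] for p in ratio.index}
    return RatioMatrix(ratios=ratio, partners=partners)


def background_means(rm: RatioMatrix) -> tuple[pd.Series, pd.Series]:
    """Row (purification) and column (amplicon) means over non-cognate cells."""
    mask = rm.cognate_mask()
    bg = rm.ratios.where(~mask)
    if bg.count(axis=1).min() < 1:
        raise ValidationError("a purification has no background cells left")
    if bg.count(axis=0).min() < 1:
        raise ValidationError("an amplicon has no background cells left")
    purification_bg = bg.mean(axis=1)
    amplicon_bg = bg.mean(axis=0)
    purification_bg.name = "purification_background"
    amplicon_bg.name = "amplicon_background"
    return purification_bg, amplicon_bg


@dataclass
class CotransResult:
    """Two-way background-corrected, unit-mean normalized mRNA ratios.

    ``normalized`` has mean exactly 1 over the non-cognate cells;
    ``cognate_scores`` gives each purification's normalized cognate value
    and its rank within that purification's row (1 = highest).
    """

    ratios: pd.DataFrame
    purification_background: pd.Series
    amplicon_background: pd.Series
    corrected: pd.DataFrame
    normalized: pd.DataFrame
    cognate_scores: pd.DataFrame
    partners: dict[str, str]


def normalize_cotrans(rm: RatioMatrix) -> CotransResult:
    """Divide by row and column backgrounds, then set the background mean to 1."""
    p_bg, m_bg = background_means(rm)
    corrected = rm.ratios.div(p_bg, axis=0).div(m_bg, axis=1)
    mask = rm.cognate_mask()
    bg_mean = corrected.where(~mask).stack().mean()
    if not np.isfinite(bg_mean) or bg_mean <= 0:
        raise ValidationError("corrected background mean is not positive")
    normalized = corrected / bg_mean

    rows = []
    for p in normalized.index:
        m = rm.partners[p]
        row = normalized.loc[p]
        score = row[m]
        rank = int((row > score).sum()) + 1
        rows.append(
            {"purification": p, "amplicon": m, "cognate_score": score,
             "rank_in_row": rank}
        )
    scores = pd.DataFrame(rows).set_index("purification")
    return CotransResult(
        ratios=rm.ratios,
        purification_background=p_bg,
        amplicon_background=m_bg,
        corrected=corrected,
        normalized=normalized,
        cognate_scores=scores,
        partners=dict(rm.partners),
    )


def permutation_pvalues(
    rm: RatioMatrix, n_permutations: int = 1000, seed: int = 0
) -> pd.DataFrame:
    """Optional permutation null for cognate scores.

    The partner map is shuffled (amplicon labels permuted across
    purifications) ``n_permutations`` times; the p-value of each
    purification is the fraction of permutations in which its shuffled
    cognate score is at least its observed score. Off the default path;
    the screening analysis itself attaches no significance model.
    """
    rng = np.random.default_rng(seed)
    observed = normalize_cotrans(rm).cognate_scores["cognate_score"]
    purifs = list(rm.ratios.index)
    amplicons = [rm.partners[p] for p in purifs]
    hits = pd.Series(0, index=observed.index, dtype=int)
    for _ in range(n_permutations):
        perm = rng.permutation(amplicons)
        shuffled = RatioMatrix(rm.ratios, dict(zip(purifs, perm)))
        sc = normalize_cotrans(shuffled).cognate_scores["cognate_score"]
        hits += (sc >= observed).astype(int)
    out = pd.DataFrame(
        {
            "cognate_score": observed,
            "p_value": (hits + 1) / (n_permutations + 1),
        }
    )
    return out
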