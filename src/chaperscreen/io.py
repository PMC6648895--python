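"""Data model, readers/writers and validation for screen inputs.

The pipeline's unit of analysis is a protein x purification intensity
matrix from label-free quantification (e.g. a MaxQuant proteinGroups
export), together with three side tables: a protein -> functional-group
annotation, a screen design mapping each purification to its bait protein
(and flagging outlier purifications), and a qRT-PCR table of N0 starting
concentrations for the co-translational binding assay.

All tabular containers wrap a :class:`pandas.DataFrame`; missing cells are
materialized as explicit zeros (protein not detected), never NaN, because
the downstream zero-replacement step presupposes explicit zeros.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("chaperscreen")

#: Closed vocabulary of protein functional groups, in fixed display order.
GROUP_ORDER: tuple[str, ...] = (
    "40S r-protein",
    "60S r-protein",
    "ribosome AF",
    "translation factor",
    "cell division",
    "histone",
    "transcription",
    "other",
)

#: Groups counted as ribosomal proteins by :func:`~chaperscreen.coenrich.rprotein_fraction`.
RPROTEIN_GROUPS: frozenset[str] = frozenset({"40S r-protein", "60S r-protein"})

#: Replacement value (percent scale) for undetected proteins before log transform.
ZERO_REPLACEMENT: float = 0.0001


class ValidationError(ValueError):
    """An input violates a data-model invariant."""


class ParseError(ValueError):
    """A file could not be parsed into the expected layout."""


def _check_axis_unique(values, what: str) -> None:
    s = pd.Index(values)
    if s.has_duplicates:
        dups = sorted(s[s.duplicated()].unique().tolist())
        raise ValidationError(f"duplicate {what}: {', '.join(map(str, dups))}")


@dataclass
class IntensityTable:
    """Raw label-free intensities, proteins as rows, purifications as columns.

    Parameters
    ----------
    data:
        Non-negative intensity matrix with unique protein identifiers as the
        index and unique purification identifiers as columns. NaN cells are
        filled with 0 on construction.
    dropped_rows:
        Number of decoy/contaminant rows removed by the reader (informational).
    """

    data: pd.DataFrame
    dropped_rows: int = 0

    def __post_init__(self) -> None:
        df = self.data
        _check_axis_unique(df.index, "protein identifier")
        _check_axis_unique(df.columns, "purification identifier")
        df = df.astype(float).fillna(0.0)
        if (df.to_numpy() < 0).any():
            bad = df.index[(df < 0).any(axis=1)][0]
            raise ValidationError(f"negative intensity for protein {bad!r}")
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        df.index.name = "protein"
        self.data = df

    @property
    def proteins(self) -> list[str]:
        return list(self.data.index)

    @property
    def purifications(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class RelativeIntensityTable:
    """Per-purification intensities on the percent-of-total scale.

    ``zero_replaced`` records whether undetected cells (exact zeros) have
    been substituted with :data:`ZERO_REPLACEMENT`; the matrix is *not*
    renormalized after replacement, so a column with k zeros sums to
    ``100 + k * ZERO_REPLACEMENT``.

    ``bait_excluded`` names a bait protein that was excluded from the
    normalization denominator (split-purification convention): the
    column-sum invariant then applies to the non-bait rows only, and the
    bait's own value may exceed 100 percent.
    """

    data: pd.DataFrame
    zero_replaced: bool = False
    bait_excluded: str | None = None

    def __post_init__(self) -> None:
        _check_axis_unique(self.data.index, "protein identifier")
        _check_axis_unique(self.data.columns, "purification identifier")
        vals = self.data.to_numpy()
        if (vals < 0).any():
            raise ValidationError("relative intensities must be non-negative")
        if self.zero_replaced and (vals <= 0).any():
            # Replacement substitutes exact zeros with ZERO_REPLACEMENT; a
            # genuinely detected intensity may still fall below that floor.
            raise ValidationError("zero_replaced table contains non-positive values")
        if not self.zero_replaced:
            summed = self.data
            if self.bait_excluded is not None:
                if self.bait_excluded not in self.data.index:
                    raise ValidationError(
                        f"bait {self.bait_excluded!r} absent from table"
                    )
                summed = self.data.drop(index=self.bait_excluded)
            sums = summed.to_numpy().sum(axis=0)
            ok = np.isclose(sums, 100.0, rtol=1e-9) | (sums == 0.0)
            if not ok.all():
                bad = self.data.columns[~ok][0]
                raise ValidationError(
                    f"column {bad!r} does not sum to 100 (got {sums[~ok][0]!r})"
                )

    @property
    def proteins(self) -> list[str]:
        return list(self.data.index)

    @property
    def purifications(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class AnnotationMap:
    """Protein -> functional group assignment with optional contaminant flags.

    Proteins absent from the map default to ``"other"`` (a warning is
    logged once per unknown protein on lookup).
    """

    groups: dict[str, str]
    contaminants: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        bad = {g for g in self.groups.values() if g not in GROUP_ORDER}
        if bad:
            raise ValidationError(
                f"unknown group label(s) {sorted(bad)}; allowed: {list(GROUP_ORDER)}"
            )
        self._warned: set[str] = set()

    def group(self, protein: str) -> str:
        try:
            return self.groups[protein]
        except KeyError:
            if protein not in self._warned:
                logger.warning("protein %r not annotated; defaulting to 'other'", protein)
                self._warned.add(protein)
            return "other"

    def is_contaminant(self, protein: str) -> bool:
        return protein in self.contaminants


@dataclass
class ScreenDesign:
    """Purification -> bait mapping plus the outlier purification set.

    Outlier purifications are excluded from the panel reference mean except
    when they are themselves the focal purification under analysis.
    """

    baits: dict[str, str]
    outliers: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        extra = self.outliers - set(self.baits)
        if extra:
            raise ValidationError(
                f"outlier purification(s) not in design: {sorted(extra)}"
            )

    def validate_against(self, table: IntensityTable | RelativeIntensityTable) -> None:
        """Check bait/outlier identifiers against a concrete intensity table."""
        missing_purifs = set(self.baits) - set(table.purifications)
        if missing_purifs:
            raise ValidationError(
                f"design purification(s) absent from table: {sorted(missing_purifs)}"
            )
        missing_baits = set(self.baits.values()) - set(table.proteins)
        if missing_baits:
            raise ValidationError(
                f"bait protein(s) absent from table: {sorted(missing_baits)}"
            )


@dataclass
class N0Table:
    """qRT-PCR starting concentrations (N0, arbitrary fluorescence units).

    ``records`` has columns purification, amplicon, fraction
    ("TEV" or "total"), replicate, n0. ``partners`` maps each purification
    to its single cognate amplicon (the mRNA of the bait's client).
    """

    records: pd.DataFrame
    partners: dict[str, str]

    REQUIRED = ("purification", "amplicon", "fraction", "replicate", "n0")

    def __post_init__(self) -> None:
        df = self.records
        missing = set(self.REQUIRED) - set(df.columns)
        if missing:
            raise ParseError(f"N0 table missing column(s): {sorted(missing)}")
        df = df.copy()
        df["n0"] = df["n0"].astype(float)
        if (df["n0"] <= 0).any():
            bad = df.loc[df["n0"] <= 0].iloc[0]
            raise ValidationError(
                f"non-positive N0 for ({bad['purification']}, {bad['amplicon']}, "
                f"{bad['fraction']})"
            )
        bad_frac = set(df["fraction"].unique()) - {"TEV", "total"}
        if bad_frac:
            raise ValidationError(f"unknown fraction label(s): {sorted(bad_frac)}")
        purifs = set(df["purification"].unique())
        amplicons = set(df["amplicon"].unique())
        for p in purifs:
            if p not in self.partners:
                raise ValidationError(f"purification {p!r} has no cognate amplicon")
        for p, m in self.partners.items():
            if m not in amplicons:
                raise ValidationError(
                    f"cognate amplicon {m!r} of purification {p!r} absent from table"
                )
        self.records = df

    @property
    def purifications(self) -> list[str]:
        return sorted(self.records["purification"].unique())

    @property
    def amplicons(self) -> list[str]:
        return sorted(self.records["amplicon"].unique())


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_intensity_table(path: str | Path, dialect: str = "wide-tsv") -> IntensityTable:
    """Read an intensity matrix from ``path``.

    Dialects
    --------
    ``"wide-tsv"``
        First column ``protein``, one further column per purification.
    ``"maxquant-proteinGroups"``
        MaxQuant proteinGroups.txt layout: protein identifiers from the
        ``Protein IDs`` column (or the first column), sample intensities
        from every ``Intensity <sample>`` column. Decoy (``REV__``) and
        contaminant (``CON__``) rows, and rows marked '+' in ``Reverse`` /
        ``Potential contaminant``, are dropped and counted in the log.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "wide-tsv":
        df = pd.read_csv(path, sep="\t", dtype={0: str}, float_precision="round_trip")
        if df.shape[1] < 2 or df.columns[0] != "protein":
            raise ParseError(
                f"wide-tsv requires a leading 'protein' column; got {df.columns[0]!r}"
            )
        df = df.set_index("protein")
        try:
            df = df.astype(float)
        except ValueError as exc:
            raise ParseError(f"non-numeric intensity in {path.name}: {exc}") from exc
        return IntensityTable(df)
    if dialect == "maxquant-proteinGroups":
        df = pd.read_csv(path, sep="\t", dtype=str)
        id_col = "Protein IDs" if "Protein IDs" in df.columns else df.columns[0]
        int_cols = [c for c in df.columns if c.startswith("Intensity ")]
        if not int_cols:
            raise ParseError(
                "maxquant-proteinGroups dialect requires 'Intensity <sample>' columns"
            )
        ids = df[id_col].astype(str)
        drop = ids.str.startswith("REV__") | ids.str.startswith("CON__")
        for flag_col in ("Reverse", "Potential contaminant"):
            if flag_col in df.columns:
                drop |= df[flag_col].fillna("") == "+"
        n_dropped = int(drop.sum())
        if n_dropped:
            logger.info(
                "dropped %d decoy/contaminant row(s) from %s", n_dropped, path.name
            )
        kept = df.loc[~drop]
        mat = kept[int_cols].apply(pd.to_numeric, errors="raise").fillna(0.0)
        mat.index = kept[id_col].astype(str)
        mat.index.name = "protein"
        mat.columns = [c[len("Intensity "):] for c in int_cols]
        return IntensityTable(mat, dropped_rows=n_dropped)
    raise ParseError(f"unknown dialect {dialect!r}")


def read_annotation(path: str | Path) -> AnnotationMap:
    """Read a protein annotation TSV with columns protein, group[, contaminant]."""
    df = pd.read_csv(Path(path), sep="\t", dtype=str)
    for col in ("protein", "group"):
        if col not in df.columns:
            raise ParseError(f"annotation file missing column {col!r}")
    _check_axis_unique(df["protein"], "protein identifier in annotation")
    groups = dict(zip(df["protein"], df["group"]))
    contaminants: set[str] = set()
    if "contaminant" in df.columns:
        flags = df["contaminant"].fillna("0").astype(int)
        contaminants = set(df.loc[flags == 1, "protein"])
    return AnnotationMap(groups, contaminants)


def read_design(path: str | Path) -> ScreenDesign:
    """Read a screen design YAML: ``baits: {purification: bait}`` + ``outliers: [...]``."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping) or "baits" not in doc:
        raise ParseError("design YAML must contain a 'baits' mapping")
    baits = {str(k): str(v) for k, v in doc["baits"].items()}
    outliers = {str(x) for x in doc.get("outliers") or []}
    return ScreenDesign(baits, outliers)


def read_n0(path: str | Path, partners: Mapping[str, str] | str | Path) -> N0Table:
    """Read an N0 CSV (purification,amplicon,fraction,replicate,n0).

    ``partners`` is either a mapping or the path of a YAML file with a
    ``partners: {purification: amplicon}`` mapping.
    """
    df = pd.read_csv(Path(path), dtype={"purification": str, "amplicon": str,
                                        "fraction": str},
                     float_precision="round_trip")
    if isinstance(partners, (str, Path)):
        with open(partners) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, Mapping) or "partners" not in doc:
            raise ParseError("partner YAML must contain a 'partners' mapping")
        partners = {str(k): str(v) for k, v in doc["partners"].items()}
    return N0Table(df, dict(partners))


# ---------------------------------------------------------------------------
# Writers (round-trip safe: full float repr, tab/comma separated text)
# ---------------------------------------------------------------------------

def write_intensity_table(
    table: IntensityTable | RelativeIntensityTable, path: str | Path
) -> None:
    """Write a wide TSV that :func:`read_intensity_table` reads back bit-identically."""
    df = table.data.copy()
    df.index.name = "protein"
    df.to_csv(Path(path), sep="\t", float_format=None)


def write_annotation(annotation: AnnotationMap, path: str | Path) -> None:
    proteins = sorted(annotation.groups)
    df = pd.DataFrame(
        {
            "protein": proteins,
            "group": [annotation.groups[p] for p in proteins],
            "contaminant": [int(p in annotation.contaminants) for p in proteins],
        }
    )
    df.to_csv(Path(path), sep="\t", index=False)


def write_design(design: ScreenDesign, path: str | Path) -> None:
    doc = {"baits": dict(design.baits), "outliers": sorted(design.outliers)}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def write_n0(n0: N0Table, path: str | Path, partner_path: str | Path | None = None) -> None:
    n0.records.to_csv(Path(path), index=False)
    if partner_path is not None:
        with open(partner_path, "w") as fh:
            yaml.safe_dump({"partners": dict(n0.partners)}, fh, sort_keys=True)
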