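"""Seeded generators for TAP-MS screens, split purifications and qPCR plates.

Every pipeline stage can be exercised against ground truth: the generators
return both the input tables and a truth record listing every planted
(bait, partner) pair with its fold enrichment.

The screen generator emulates the structure such panels show in practice:

* a dominant, shared ribosome-like proteome present in every purification
  (core r-proteins carry the bulk of the signal);
* each purification's bait over-represented in its own sample;
* dedicated-chaperone partners present at trace levels panel-wide and
  boosted k-fold only in their bait's purification — combined with
  abundance-dependent dropout this reproduces the hallmark of a dedicated
  chaperone, which is detected robustly in its cognate purification and
  only sporadically elsewhere;
* sporadic contaminants present in a random subset of purifications;
* multiplicative log-normal noise on every cell;
* dropout to zero with probability decreasing in abundance, calibrated so
  the overall zero rate matches the requested ``dropout_rate``.

Generators are pure functions of (config, seed): identical configuration
gives identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import (
    AnnotationMap,
    IntensityTable,
    N0Table,
    ScreenDesign,
    ValidationError,
)


# ---------------------------------------------------------------------------
# TAP-MS screen
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenSimConfig:
    """Configuration of a simulated bait-purification panel.

    Abundances are in arbitrary intensity units on a log10 scale. The
    default panel mirrors a small-subunit r-protein screen: 25
    purifications over 200 proteins, a core ribosomal proteome around
    1e3 units per protein, chaperone partners three orders of magnitude
    below the core, and a 20 percent global zero rate.
    """

    n_purifications: int = 25
    n_core_proteins: int = 60
    n_background_proteins: int = 95
    n_trace_proteins: int = 34
    n_contaminants: int = 10
    n_specific_partners: int = 1
    fold_enrichment: float = 10.0
    bait_boost: float = 2.0
    contaminant_presence: float = 0.7
    noise_sigma_log10: float = 0.3
    dropout_rate: float = 0.2
    core_log10_mean: float = 3.0
    core_log10_sd: float = 0.35
    background_log10_mean: float = 1.2
    background_log10_sd: float = 0.2
    trace_log10_mean: float = -0.35
    trace_log10_sd: float = 0.25
    partner_log10_base: float = 0.5
    contaminant_log10_mean: float = 1.3
    contaminant_log10_sd: float = 0.2
    dropout_steepness: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_purifications, self.n_core_proteins, self.n_background_proteins,
            self.n_trace_proteins, self.n_contaminants, self.n_specific_partners,
        )
        if any(c < 0 for c in counts):
            raise ValidationError("all counts must be non-negative")
        if self.n_core_proteins < self.n_purifications:
            raise ValidationError("need at least one core protein per bait")
        if self.n_specific_partners > self.n_purifications:
            raise ValidationError("at most one planted partner per purification")
        if self.fold_enrichment <= 0 or self.bait_boost <= 0:
            raise ValidationError("fold factors must be positive")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValidationError("dropout_rate must lie in [0, 1]")
        if not 0.0 <= self.contaminant_presence <= 1.0:
            raise ValidationError("contaminant_presence must lie in [0, 1]")
        if self.noise_sigma_log10 < 0:
            raise ValidationError("noise sigma must be non-negative")


@dataclass
class ScreenTruth:
    """Ground truth of a simulated screen."""

    planted: list[dict] = field(default_factory=list)  # purification/bait/partner/fold
    contaminants: list[str] = field(default_factory=list)
    dropout_location_log10: float = float("nan")
    zero_fraction: float = float("nan")

    def to_dict(self) -> dict:
        return asdict(self)


def _dropout_probabilities(
    values: np.ndarray, rate: float, steepness: float
) -> tuple[np.ndarray, float]:
    """Logistic dropout probability in log10 abundance.

    The location parameter is solved by bisection so the mean dropout
    probability over the positive cells equals ``rate``.
    """
    pos = values > 0
    logv = np.log10(values[pos])
    if rate <= 0:
        return np.zeros_like(values), -np.inf
    if rate >= 1:
        return np.where(pos, 1.0, 0.0), np.inf

    def mean_p(loc: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp((logv - loc) / steepness))))

    lo, hi = logv.min() - 10.0, logv.max() + 10.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mean_p(mid) < rate:
            lo = mid
        else:
            hi = mid
    loc = 0.5 * (lo + hi)
    p = np.zeros_like(values)
    p[pos] = 1.0 / (1.0 + np.exp((np.log10(values[pos]) - loc) / steepness))
    return p, loc


def simulate_screen(
    cfg: ScreenSimConfig,
) -> tuple[IntensityTable, AnnotationMap, ScreenDesign, ScreenTruth]:
    """Generate one seeded screen panel with planted chaperone partners."""
    rng = np.random.default_rng(cfg.seed)
    P = cfg.n_purifications

    baits = [f"RPS{i + 1:02d}" for i in range(P)]
    purifs = [f"{b}-TAP" for b in baits]
    n_extra_core = cfg.n_core_proteins - P
    # Split the non-bait core between the remaining functional groups.
    n40 = min(n_extra_core, max(0, n_extra_core // 6))
    n60 = min(n_extra_core - n40, n_extra_core // 2)
    naf = min(n_extra_core - n40 - n60, n_extra_core // 3)
    ntf = n_extra_core - n40 - n60 - naf
    core = (
        baits
        + [f"RPS{P + i + 1:02d}" for i in range(n40)]
        + [f"RPL{i + 1:02d}" for i in range(n60)]
        + [f"AF{i + 1:02d}" for i in range(naf)]
        + [f"TF{i + 1:02d}" for i in range(ntf)]
    )
    background = [f"BG{i + 1:03d}" for i in range(cfg.n_background_proteins)]
    trace = [f"TRC{i + 1:02d}" for i in range(cfg.n_trace_proteins)]
    contam = [f"CONT{i + 1:02d}" for i in range(cfg.n_contaminants)]
    partners = [f"CHAP{i + 1:02d}" for i in range(cfg.n_specific_partners)]
    proteins = core + background + trace + contam + partners

    base = np.concatenate(
        [
            10 ** rng.normal(cfg.core_log10_mean, cfg.core_log10_sd, len(core)),
            10 ** rng.normal(
                cfg.background_log10_mean, cfg.background_log10_sd, len(background)
            ),
            10 ** rng.normal(cfg.trace_log10_mean, cfg.trace_log10_sd, len(trace)),
            10 ** rng.normal(
                cfg.contaminant_log10_mean, cfg.contaminant_log10_sd, len(contam)
            ),
            10 ** np.full(len(partners), cfg.partner_log10_base),
        ]
    )
    mean = np.tile(base[:, None], (1, P))

    # Sporadic contaminant presence per purification.
    c0 = len(core) + len(background) + len(trace)
    present = rng.random((len(contam), P)) < cfg.contaminant_presence
    mean[c0 : c0 + len(contam)] *= present

    # Bait over-representation.
    for j, b in enumerate(baits):
        mean[proteins.index(b), j] *= cfg.bait_boost

    # Planted partners: one dedicated bait purification each.
    truth = ScreenTruth()
    host = rng.choice(P, size=cfg.n_specific_partners, replace=False)
    for k, partner in enumerate(partners):
        j = int(host[k])
        mean[proteins.index(partner), j] *= cfg.fold_enrichment
        truth.planted.append(
            {
                "purification": purifs[j],
                "bait": baits[j],
                "partner": partner,
                "fold_enrichment": cfg.fold_enrichment,
            }
        )
    truth.contaminants = list(contam)

    noisy = mean * 10 ** rng.normal(0.0, cfg.noise_sigma_log10, mean.shape)
    # Detectability follows the underlying abundance, not the measurement
    # noise: dropout probabilities are computed on the pre-noise means.
    p_drop, loc = _dropout_probabilities(
        mean, cfg.dropout_rate, cfg.dropout_steepness
    )
    keep = rng.random(noisy.shape) >= p_drop
    values = np.where(keep, noisy, 0.0)
    truth.dropout_location_log10 = float(loc)
    truth.zero_fraction = float((values == 0).mean())

    table = IntensityTable(pd.DataFrame(values, index=proteins, columns=purifs))

    groups: dict[str, str] = {}
    for p in baits + [f"RPS{P + i + 1:02d}" for i in range(n40)]:
        groups[p] = "40S r-protein"
    for p in [f"RPL{i + 1:02d}" for i in range(n60)]:
        groups[p] = "60S r-protein"
    for p in [f"AF{i + 1:02d}" for i in range(naf)]:
        groups[p] = "ribosome AF"
    for p in [f"TF{i + 1:02d}" for i in range(ntf)]:
        groups[p] = "translation factor"
    # Background proteins cycle through the non-ribosomal groups.
    bg_groups = ("other", "cell division", "histone", "transcription")
    for i, p in enumerate(background):
        groups[p] = bg_groups[i % len(bg_groups)]
    for p in trace + partners:
        groups[p] = "other"
    for p in contam:
        groups[p] = "other"
    annotation = AnnotationMap(groups, contaminants=set(contam))

    design = ScreenDesign(dict(zip(purifs, baits)))
    return table, annotation, design, truth


def simulate_split(
    cfg: ScreenSimConfig,
    bait: str = "NAP1",
    partner_fold: float = 5.0,
) -> tuple[IntensityTable, AnnotationMap, ScreenTruth]:
    """Generate an enriched/depleted split-purification pair.

    Emulates a bait with a dual life (histone/cell-division partners plus a
    ribosomal client): the shared co-purifying pool holds both ribosomal
    proteins and chromatin/cell-division partners at comparable levels, the
    client-containing (enriched) pool over-represents r-proteins and
    assembly factors ``partner_fold``-fold, and the client-free (depleted)
    pool over-represents histones and cell-division partners by the same
    factor. The bait carries more signal than the whole co-purifying pool,
    as for an over-stoichiometric bait band.
    """
    rng = np.random.default_rng(cfg.seed)
    counts = {
        "40S r-protein": ("RPS", 12),
        "60S r-protein": ("RPL", 12),
        "ribosome AF": ("AF", 8),
        "translation factor": ("TF", 4),
        "histone": ("HIS", 5),
        "cell division": ("CDV", 5),
        "transcription": ("TRX", 4),
        "other": ("OTH", 10),
    }
    groups: dict[str, str] = {}
    names: list[str] = []
    for g, (prefix, n) in counts.items():
        for i in range(n):
            name = f"{prefix}{i + 1:02d}"
            names.append(name)
            groups[name] = g
    base = 10 ** rng.normal(2.0, 0.4, len(names))
    enriched = base * 10 ** rng.normal(0.0, cfg.noise_sigma_log10, len(names))
    depleted = base * 10 ** rng.normal(0.0, cfg.noise_sigma_log10, len(names))
    up_enriched = {"40S r-protein", "60S r-protein", "ribosome AF"}
    up_depleted = {"histone", "cell division"}
    for i, name in enumerate(names):
        g = groups[name]
        if g in up_enriched:
            enriched[i] *= partner_fold
        elif g in up_depleted:
            depleted[i] *= partner_fold
    df = pd.DataFrame({"enriched": enriched, "depleted": depleted}, index=names)
    bait_row = pd.DataFrame(
        [[df["enriched"].sum() * 1.2, df["depleted"].sum() * 1.2]],
        index=[bait],
        columns=df.columns,
    )
    df = pd.concat([bait_row, df])
    groups[bait] = "other"
    truth = ScreenTruth(
        planted=[{"purification": "enriched", "bait": bait,
                  "partner": "r-protein pool", "fold_enrichment": partner_fold}]
    )
    return IntensityTable(df), AnnotationMap(groups), truth


# ---------------------------------------------------------------------------
# qRT-PCR co-translational assay
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CotransSimConfig:
    """Configuration of a simulated qPCR plate for the co-translational assay.

    ``enrichment`` is either a scalar applied to every cognate
    (purification, amplicon) cell, or a mapping purification -> fold.
    Row/column nuisance factors model purification efficiency and amplicon
    amplification differences; ``noise_sigma_log10`` is per-cell
    multiplicative noise on the TEV eluate, ``replicate_cv`` the
    coefficient of variation of technical replicate wells.
    """

    n_purifications: int = 5
    n_amplicons: int = 5
    enrichment: float | tuple[float, ...] = 8.0
    row_sigma_log10: float = 0.2
    col_sigma_log10: float = 0.2
    noise_sigma_log10: float = 0.0
    replicate_cv: float = 0.0
    n_replicates: int = 3
    capture_efficiency: float = 0.05
    total_log10_mean: float = 3.0
    total_log10_sd: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_purifications < 2 or self.n_amplicons < 2:
            raise ValidationError("need at least a 2 x 2 design")
        if self.n_purifications > self.n_amplicons:
            raise ValidationError(
                "partner map must be injective: more amplicons than purifications "
                "required"
            )
        if self.n_replicates < 1:
            raise ValidationError("need at least one technical replicate")
        folds = (
            (self.enrichment,)
            if isinstance(self.enrichment, (int, float))
            else tuple(self.enrichment)
        )
        if any(f <= 0 for f in folds):
            raise ValidationError("enrichment folds must be positive")
        if not isinstance(self.enrichment, (int, float)) and len(
            tuple(self.enrichment)
        ) != self.n_purifications:
            raise ValidationError("need one enrichment fold per purification")


@dataclass
class CotransTruth:
    """Ground truth of a simulated co-translational assay."""

    partners: dict[str, str]
    enrichments: dict[str, float]

    def to_dict(self) -> dict:
        return asdict(self)


def simulate_cotrans(cfg: CotransSimConfig) -> tuple[N0Table, CotransTruth]:
    """Generate a seeded N0 plate with planted cognate-cell enrichment."""
    rng = np.random.default_rng(cfg.seed)
    purifs = [f"CHAP{i + 1:02d}-TAP" for i in range(cfg.n_purifications)]
    amplicons = [f"MRNA{i + 1:02d}" for i in range(cfg.n_amplicons)]
    partners = dict(zip(purifs, amplicons))
    folds = (
        {p: float(cfg.enrichment) for p in purifs}
        if isinstance(cfg.enrichment, (int, float))
        else dict(zip(purifs, map(float, cfg.enrichment)))
    )

    row = 10 ** rng.normal(0.0, cfg.row_sigma_log10, cfg.n_purifications)
    col = 10 ** rng.normal(0.0, cfg.col_sigma_log10, cfg.n_amplicons)
    sigma_rep = np.sqrt(np.log(1.0 + cfg.replicate_cv**2)) if cfg.replicate_cv else 0.0

    records = []
    for i, p in enumerate(purifs):
        for j, m in enumerate(amplicons):
            total_mean = 10 ** rng.normal(cfg.total_log10_mean, cfg.total_log10_sd)
            ratio_true = cfg.capture_efficiency * row[i] * col[j]
            if partners[p] == m:
                ratio_true *= folds[p]
            cell_noise = 10 ** rng.normal(0.0, cfg.noise_sigma_log10)
            tev_mean = total_mean * ratio_true * cell_noise
            for r in range(cfg.n_replicates):
                wob_t = np.exp(rng.normal(0.0, sigma_rep)) if sigma_rep else 1.0
                wob_e = np.exp(rng.normal(0.0, sigma_rep)) if sigma_rep else 1.0
                records.append((p, m, "total", r + 1, total_mean * wob_t))
                records.append((p, m, "TEV", r + 1, tev_mean * wob_e))
    df = pd.DataFrame(
        records, columns=["purification", "amplicon", "fraction", "replicate", "n0"]
    )
    return N0Table(df, partners), CotransTruth(partners=partners, enrichments=folds)
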