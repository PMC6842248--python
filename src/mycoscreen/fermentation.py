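"""Fermentation titre normalisation, control comparisons, and trend fits.

Shake-flask measurements are normalised before any comparison: secreted
protein per gram fungal dry weight (mg/g biomass), and each organic acid per
gram of depleted glucose (g/g). Mutant-versus-progenitor comparisons use
two-sided pooled-variance Student's t-tests at matching doxycycline doses,
without multiple-testing correction (each strain x dose x variable cell is a
single planned contrast; the report states how many tests were run).
Protein-versus-acid relationships across strain x dose means are fitted with
least-squares polynomials (degree 1 or 2) and summarised by R².
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FermentationRecord",
    "NormalizedTitres",
    "ComparisonResult",
    "TrendFit",
    "normalize",
    "normalize_table",
    "pairwise_t_test",
    "compare_to_control",
    "fit_trend",
    "correlation_table",
    "records_from_frame",
    "FERMENTATION_COLUMNS",
]

logger = logging.getLogger(__name__)

FERMENTATION_COLUMNS = [
    "strain",
    "dox_ug_ml",
    "replicate",
    "protein_mg",
    "dry_weight_g",
    "citric_g_l",
    "oxaloacetate_g_l",
    "glucose_depleted_g_l",
]


@dataclass(frozen=True)
class FermentationRecord:
    """One shake-flask measurement row."""

    strain: str
    dox_ug_ml: float
    replicate: int
    protein_mg: float
    dry_weight_g: float
    citric_g: float
    oxaloacetate_g: float
    glucose_depleted_g: float

    def __post_init__(self) -> None:
        for name in (
            "protein_mg",
            "dry_weight_g",
            "citric_g",
            "oxaloacetate_g",
            "glucose_depleted_g",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass(frozen=True)
class NormalizedTitres:
    """Per-biomass and per-glucose specific titres; NaN where undefined."""

    protein_mg_per_g_biomass: float
    citric_g_per_g_glucose: float
    oxaloacetate_g_per_g_glucose: float


@dataclass(frozen=True)
class ComparisonResult:
    """Pooled-variance t-test of a mutant group against the control group."""

    t_statistic: float
    p_value: float
    significant: bool
    strain: str | None = None
    dox_ug_ml: float | None = None
    variable: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")


@dataclass(frozen=True)
class TrendFit:
    """Least-squares polynomial fit with coefficient-of-determination."""

    degree: int
    coefficients: tuple[float, ...]  # highest degree first
    r_squared: float

    def __post_init__(self) -> None:
        if len(self.coefficients) != self.degree + 1:
            raise ValueError("coefficient count must equal degree + 1")
        if self.r_squared > 1 + 1e-12:
            raise ValueError("R² cannot exceed 1")

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.polyval(self.coefficients, np.asarray(x, dtype=float))


def normalize(record: FermentationRecord) -> NormalizedTitres:
    """Specific titres: protein / dry weight, acids / depleted glucose.

    A zero denominator yields NaN (undefined) rather than 0, with a logged
    warning, so downstream means never mistake a missing ratio for absence.
    """
    if record.dry_weight_g > 0:
        protein = record.protein_mg / record.dry_weight_g
    else:
        logger.warning(
            "zero dry weight for %s (dox %s, rep %d): protein titre undefined",
            record.strain,
            record.dox_ug_ml,
            record.replicate,
        )
        protein = float("nan")
    if record.glucose_depleted_g > 0:
        citric = record.citric_g / record.glucose_depleted_g
        oxalo = record.oxaloacetate_g / record.glucose_depleted_g
    else:
        logger.warning(
            "zero depleted glucose for %s (dox %s, rep %d): acid titres undefined",
            record.strain,
            record.dox_ug_ml,
            record.replicate,
        )
        citric = oxalo = float("nan")
    return NormalizedTitres(
        protein_mg_per_g_biomass=protein,
        citric_g_per_g_glucose=citric,
        oxaloacetate_g_per_g_glucose=oxalo,
    )


def records_from_frame(frame: pd.DataFrame) -> list[FermentationRecord]:
    """Parse the standard fermentation CSV columns into records."""
    missing = [c for c in FERMENTATION_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"fermentation table missing columns: {missing}")
    return [
        FermentationRecord(
            strain=str(r.strain),
            dox_ug_ml=float(r.dox_ug_ml),
            replicate=int(r.replicate),
            protein_mg=float(r.protein_mg),
            dry_weight_g=float(r.dry_weight_g),
            citric_g=float(r.citric_g_l),
            oxaloacetate_g=float(r.oxaloacetate_g_l),
            glucose_depleted_g=float(r.glucose_depleted_g_l),
        )
        for r in frame.itertuples(index=False)
    ]


def normalize_table(frame: pd.DataFrame) -> pd.DataFrame:
    """Append normalised titre columns to a fermentation table."""
    out = frame.copy()
    titres = [normalize(rec) for rec in records_from_frame(frame)]
    out["protein_mg_per_g_biomass"] = [t.protein_mg_per_g_biomass for t in titres]
    out["citric_g_per_g_glucose"] = [t.citric_g_per_g_glucose for t in titres]
    out["oxaloacetate_g_per_g_glucose"] = [
        t.oxaloacetate_g_per_g_glucose for t in titres
    ]
    return out


def pairwise_t_test(
    mutant_values: Sequence[float],
    control_values: Sequence[float],
    alpha: float = 0.05,
) -> ComparisonResult:
    """Two-sided two-sample Student's t-test with pooled variance.

    With zero pooled variance the statistic is degenerate: equal means give
    t = 0, p = 1 by convention; unequal means give an infinite statistic and
    p = 0.
    """
    a = np.asarray(mutant_values, dtype=float)
    b = np.asarray(control_values, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a.mean() == b.mean():
            return ComparisonResult(t_statistic=0.0, p_value=1.0, significant=False)
        t = math.inf if a.mean() > b.mean() else -math.inf
        return ComparisonResult(t_statistic=t, p_value=0.0, significant=0.0 < alpha)
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return ComparisonResult(
        t_statistic=float(t), p_value=float(p), significant=bool(p < alpha)
    )


def compare_to_control(
    frame: pd.DataFrame,
    control_strain: str,
    alpha: float = 0.05,
    variables: Sequence[str] = (
        "protein_mg_per_g_biomass",
        "citric_g_per_g_glucose",
        "oxaloacetate_g_per_g_glucose",
    ),
) -> pd.DataFrame:
    """t-test every mutant strain against the control at matching doses.

    Operates on normalised titres (columns added if absent). Returns one row
    per strain x dose x variable with t, p and the significance call.
    """
    if control_strain not in set(frame["strain"]):
        raise ValueError(f"control strain {control_strain!r} absent from table")
    table = (
        frame
        if "protein_mg_per_g_biomass" in frame.columns
        else normalize_table(frame)
    )
    rows = []
    for (strain, dose), group in table.groupby(["strain", "dox_ug_ml"], sort=True):
        if strain == control_strain:
            continue
        control = table[
            (table["strain"] == control_strain) & (table["dox_ug_ml"] == dose)
        ]
        if len(control) < 2 or len(group) < 2:
            logger.warning(
                "skipping %s at dox %s: fewer than two replicates in a group",
                strain,
                dose,
            )
            continue
        for var in variables:
            res = pairwise_t_test(
                group[var].to_numpy(), control[var].to_numpy(), alpha=alpha
            )
            rows.append(
                {
                    "strain": strain,
                    "dox_ug_ml": dose,
                    "variable": var,
                    "t_statistic": res.t_statistic,
                    "p_value": res.p_value,
                    "significant": res.significant,
                }
            )
    report = pd.DataFrame(
        rows,
        columns=["strain", "dox_ug_ml", "variable", "t_statistic", "p_value", "significant"],
    )
    logger.info("ran %d pairwise t-tests (no multiplicity correction)", len(report))
    return report


def fit_trend(x: Sequence[float], y: Sequence[float], degree: int) -> TrendFit:
    """Least-squares polynomial of degree 1 or 2 with R² = 1 - SS_res/SS_tot.

    For constant y (SS_tot = 0) R² is defined as 0.
    """
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be matching one-dimensional vectors")
    if xa.size < degree + 2:
        raise ValueError(f"need at least {degree + 2} points for degree {degree}")
    if np.ptp(xa) == 0:
        raise ValueError("x values are all equal; trend undefined")
    coeffs = np.polyfit(xa, ya, degree)
    residuals = ya - np.polyval(coeffs, xa)
    ss_res = float(residuals @ residuals)
    ss_tot = float(((ya - ya.mean()) ** 2).sum())
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return TrendFit(
        degree=degree,
        coefficients=tuple(float(c) for c in coeffs),
        r_squared=min(r2, 1.0),
    )


def correlation_table(records: Sequence[FermentationRecord]) -> pd.DataFrame:
    """Strain x dose means of normalised protein and acid titres.

    One row per strain x dose with the replicate count; this is the table the
    protein-versus-acid trend fits consume.
    """
    rows = []
    for rec in records:
        titres = normalize(rec)
        rows.append(
            {
                "strain": rec.strain,
                "dox_ug_ml": rec.dox_ug_ml,
                "protein_mg_per_g_biomass": titres.protein_mg_per_g_biomass,
                "citric_g_per_g_glucose": titres.citric_g_per_g_glucose,
                "oxaloacetate_g_per_g_glucose": titres.oxaloacetate_g_per_g_glucose,
            }
        )
    table = pd.DataFrame(rows)
    grouped = (
        table.groupby(["strain", "dox_ug_ml"], sort=True)
        .agg(
            protein_mg_per_g_biomass=("protein_mg_per_g_biomass", "mean"),
            citric_g_per_g_glucose=("citric_g_per_g_glucose", "mean"),
            oxaloacetate_g_per_g_glucose=("oxaloacetate_g_per_g_glucose", "mean"),
            n_replicates=("protein_mg_per_g_biomass", "size"),
        )
        .reset_index()
    )
    return grouped
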