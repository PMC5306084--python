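"""Viability-curve processing and BMC10 (EC10) determination.

Resazurin fluorescence readouts are blank-subtracted and normalized to
vehicle controls (100 %).  Each biological replicate's concentration-
response is fitted with a four-parameter logistic on log10 concentration
(top initialized at 100 and bounded to [80, 120], bottom bounded to
[0, 50]); technical replicates are averaged before fitting.  The fitted
curves are averaged pointwise on a shared log10 grid and BMC10 is the
concentration where the averaged curve crosses 90 % viability, snapped to
the last measured concentration at or below the crossing; if the curve
never drops below 90 % within the tested range the result is "above tested
range".
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, curve_fit

from .io_model import ValidationError

log = logging.getLogger(__name__)


@dataclass
class ViabilityCurve:
    """Per-replicate viability (%) over an ascending concentration series."""

    concentrations: np.ndarray  # strictly increasing, positive, one unit
    viability: np.ndarray  # (n_replicates, n_concentrations), vehicle = 100
    conc_unit: str = ""
    compound: str = ""

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.viability = np.atleast_2d(np.asarray(self.viability, dtype=float))
        if np.any(self.concentrations <= 0):
            raise ValidationError("concentrations must be positive")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValidationError("concentrations must be strictly increasing")
        if self.viability.shape[1] != self.concentrations.size:
            raise ValidationError("viability shape does not match concentrations")
        if not np.isfinite(self.viability).all():
            raise ValidationError("non-finite viability values")


def normalize_viability(
    raw: pd.DataFrame,
    compound: str | None = None,
) -> ViabilityCurve:
    """Blank-subtract and vehicle-normalize a fluorescence plate table.

    ``raw`` columns: well, concentration, conc_unit, role
    (blank | vehicle_control | treated), fluorescence, and optionally
    bio_replicate.  viability = 100 * (signal - mean blank) /
    (mean vehicle - mean blank), computed within each biological replicate.
    """
    required = {"concentration", "role", "fluorescence"}
    missing = required - set(raw.columns)
    if missing:
        raise ValidationError(f"plate table missing columns: {sorted(missing)}")
    tab = raw.copy()
    if compound is not None and "compound" in tab.columns:
        tab = tab[(tab["compound"] == compound) | (tab["role"].isin(["blank", "vehicle_control"]))]
    if "bio_replicate" not in tab.columns:
        tab["bio_replicate"] = 1
    unit = ""
    if "conc_unit" in tab.columns:
        units = set(tab.loc[tab["role"] == "treated", "conc_unit"].dropna())
        if len(units) > 1:
            raise ValidationError(f"mixed concentration units: {sorted(units)}")
        unit = units.pop() if units else ""
    concs = np.sort(
        tab.loc[tab["role"] == "treated", "concentration"].astype(float).unique()
    )
    if concs.size == 0:
        raise ValidationError("no treated wells in plate table")
    reps = sorted(tab["bio_replicate"].unique())
    viability = np.empty((len(reps), concs.size))
    for r, rep in enumerate(reps):
        sub = tab[tab["bio_replicate"] == rep]
        blanks = sub.loc[sub["role"] == "blank", "fluorescence"].astype(float)
        vehicles = sub.loc[sub["role"] == "vehicle_control", "fluorescence"].astype(float)
        if blanks.empty or vehicles.empty:
            raise ValidationError(
                f"replicate {rep}: need >= 1 blank and >= 1 vehicle well"
            )
        blank = blanks.mean()
        vehicle = vehicles.mean()
        if vehicle <= blank:
            raise ValidationError(
                f"replicate {rep}: vehicle signal <= blank (assay failure)"
            )
        span = vehicle - blank
        for c, conc in enumerate(concs):
            sel = (sub["role"] == "treated") & (
                sub["concentration"].astype(float) == conc
            )
            signals = sub.loc[sel, "fluorescence"].astype(float)
            if signals.empty:
                raise ValidationError(
                    f"replicate {rep}: no wells at concentration {conc}"
                )
            # technical replicates averaged within the experiment
            viability[r, c] = 100.0 * (signals.mean() - blank) / span
    return ViabilityCurve(
        concentrations=concs,
        viability=viability,
        conc_unit=unit,
        compound=compound or "",
    )


# ---------------------------------------------------------------------------
# Four-parameter logistic
# ---------------------------------------------------------------------------


def four_pl(logc: np.ndarray, top: float, bottom: float, log_ec50: float, hill: float):
    """Decreasing 4PL on log10 concentration (hill > 0 means decline)."""
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logc - log_ec50)))


@dataclass
class DoseResponseFit:
    top: float
    bottom: float
    log_ec50: float
    hill: float
    converged: bool
    degenerate: bool = False

    def predict(self, logc: np.ndarray) -> np.ndarray:
        return four_pl(logc, self.top, self.bottom, self.log_ec50, self.hill)


def fit_dose_response(curve: ViabilityCurve) -> list[DoseResponseFit]:
    """Least-squares 4PL per biological replicate on log10 concentration.

    Bounds: top [80, 120] (initialized at 100), bottom [0, 50], hill
    (0.1, 10], EC50 within three decades of the tested range.  Replicates
    with an essentially flat response are flagged degenerate (no EC50) and
    non-convergent fits are flagged for exclusion from averaging.
    """
    if curve.concentrations.size < 4:
        raise ValidationError("dose-response fit needs >= 4 concentrations")
    logc = np.log10(curve.concentrations)
    fits: list[DoseResponseFit] = []
    for r in range(curve.viability.shape[0]):
        y = curve.viability[r]
        if y.max() - y.min() < 5.0:
            log.info("replicate %d: flat response, degenerate fit flagged", r)
            fits.append(
                DoseResponseFit(
                    top=float(y.mean()),
                    bottom=float(y.mean()),
                    log_ec50=float("nan"),
                    hill=float("nan"),
                    converged=False,
                    degenerate=True,
                )
            )
            continue
        p0 = [100.0, max(min(y.min(), 50.0), 0.0), float(np.median(logc)), 1.0]
        bounds = (
            [80.0, 0.0, logc.min() - 3.0, 0.1],
            [120.0, 50.0, logc.max() + 3.0, 10.0],
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    four_pl, logc, y, p0=p0, bounds=bounds, maxfev=20000
                )
            fits.append(DoseResponseFit(*popt, converged=True))
        except RuntimeError:
            warnings.warn(f"replicate {r}: 4PL fit did not converge; excluded")
            fits.append(
                DoseResponseFit(100.0, 0.0, float("nan"), float("nan"), converged=False)
            )
    return fits


@dataclass
class BMCResult:
    """BMC10 read-off from the averaged fitted curve."""

    bmc10: float | None  # None when above tested range
    above_range: bool
    method: str  # interpolated | last_data_point | above_range
    interpolated: float | None
    grid_logc: np.ndarray
    averaged_curve: np.ndarray
    conc_unit: str = ""


def bmc10(
    fits: list[DoseResponseFit],
    curve: ViabilityCurve,
    threshold: float = 90.0,
    grid_points: int = 200,
) -> BMCResult:
    """Average the converged fitted curves and read off the 90 % crossing.

    The averaged curve is evaluated on a shared log10 grid over the tested
    range.  BMC10 is the last measured concentration at or below the first
    crossing of the threshold; the interpolated crossing itself is also
    reported.  If the averaged curve stays above the threshold the result
    is "above tested range".
    """
    usable = [f for f in fits if f.converged]
    if not usable:
        raise ValidationError("no converged dose-response fits")
    logc = np.log10(curve.concentrations)
    grid = np.linspace(logc.min(), logc.max(), grid_points)
    avg = np.mean([f.predict(grid) for f in usable], axis=0)
    below = avg < threshold
    if not below.any():
        return BMCResult(
            bmc10=None,
            above_range=True,
            method="above_range",
            interpolated=None,
            grid_logc=grid,
            averaged_curve=avg,
            conc_unit=curve.conc_unit,
        )
    first = int(np.argmax(below))
    if first == 0:
        # already below threshold at the lowest tested concentration
        warnings.warn(
            "averaged curve below threshold at the lowest tested concentration"
        )
        crossing = grid[0]
    else:
        # exact root of the averaged curve between the bracketing grid points
        def avg_minus_threshold(x):
            return np.mean([f.predict(np.asarray(x)) for f in usable]) - threshold

        crossing = float(
            brentq(avg_minus_threshold, grid[first - 1], grid[first], xtol=1e-12)
        )
    interpolated = float(10.0**crossing)
    at_or_below = curve.concentrations[
        np.log10(curve.concentrations) <= crossing + 1e-6
    ]
    if at_or_below.size:
        value = float(at_or_below.max())
        method = "last_data_point"
    else:
        value = float(curve.concentrations.min())
        method = "lowest_tested"
    return BMCResult(
        bmc10=value,
        above_range=False,
        method=method,
        interpolated=interpolated,
        grid_logc=grid,
        averaged_curve=avg,
        conc_unit=curve.conc_unit,
    )
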