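"""Mg dose-response curves: bell fits, magnesium optima, normalization.

Maximal synthesis rates plotted against added Mg²⁺ form a bell-shaped
profile; the added-Mg concentration giving the highest rate is the
*magnesium optimum* of a construct.  The bell is realised as a Gaussian
``A·exp(-(Mg - c)² / (2 w²))`` fitted by least squares with a fixed,
documented initialisation (center at the argmax point, width a quarter
of the grid span, amplitude the maximum rate), so fits are
deterministic.  The Gaussian family is isolated behind
:func:`fit_bell` so an alternative bell (e.g. log-normal) can be
substituted in one place.

Because absolute free Mg²⁺ differs between lysate preparations, each
extract is calibrated with a reference construct: its fitted optimum and
peak rate anchor the added-Mg scale and the rate unit, and all curves
from that lysate are normalized to the reference peak.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import FitError, InputError, StateError

#: minimum distinct Mg levels required for a bell fit / calibration
MIN_GRID_POINTS = 4
#: margin (mM) beyond the measured grid before an optimum is flagged
#: as extrapolated
EXTRAPOLATION_MARGIN = 0.2


@dataclass(frozen=True)
class BellFit:
    amplitude: float   # ALU/min
    optimum: float     # mM added Mg
    width: float       # mM


@dataclass(frozen=True)
class MgResponseCurve:
    """Per-construct rate-vs-Mg profile with its fitted bell."""

    construct: str
    k_mM: float
    points: pd.DataFrame          # columns mg_mM, mean_rate, sd_rate, n_reps
    bell: Optional[BellFit] = None
    normalized: bool = False
    reference: Optional[str] = None
    lysate: str = "L1"

    @property
    def extrapolated(self) -> bool:
        if self.bell is None:
            return False
        mg = self.points["mg_mM"]
        return not (
            mg.min() - EXTRAPOLATION_MARGIN
            <= self.bell.optimum
            <= mg.max() + EXTRAPOLATION_MARGIN
        )


@dataclass(frozen=True)
class CalibrationRecord:
    """Reference-construct anchor for one lysate preparation."""

    lysate: str
    reference_construct: str
    reference_optimum: float   # mM added Mg
    reference_peak: float      # ALU/min

    def __post_init__(self):
        if self.reference_peak <= 0:
            raise InputError("reference peak rate must be positive")


def _gaussian(x, amp, center, width):
    return amp * np.exp(-((x - center) ** 2) / (2.0 * width**2))


def fit_bell(
    mg: Sequence[float], rates: Sequence[float]
) -> BellFit:
    """Least-squares Gaussian fit of rate vs added Mg.

    Requires >= 4 distinct Mg levels and non-constant rates; raises
    :class:`FitError` on degenerate data rather than silently falling
    back.
    """
    x = np.asarray(mg, dtype=float)
    y = np.asarray(rates, dtype=float)
    if len(np.unique(x)) < MIN_GRID_POINTS:
        raise FitError(
            f"bell fit needs >= {MIN_GRID_POINTS} distinct Mg values "
            f"(got {len(np.unique(x))})"
        )
    if np.allclose(y, y[0]):
        raise FitError("bell fit is degenerate: all rates equal")
    span = float(x.max() - x.min())
    p0 = (float(y.max()), float(x[int(np.argmax(y))]), span / 4.0)
    try:
        popt, _ = curve_fit(
            _gaussian,
            x,
            y,
            p0=p0,
            bounds=([0.0, x.min() - 5 * span, 1e-4], [np.inf, x.max() + 5 * span, 10 * span]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitError(f"bell fit did not converge: {exc}") from exc
    amp, center, width = (float(v) for v in popt)
    return BellFit(amplitude=amp, optimum=center, width=abs(width))


def build_curves(rates: pd.DataFrame, fit: bool = True) -> list[MgResponseCurve]:
    """Average replicates per (lysate, construct, K, Mg) and fit bells.

    ``rates`` is the per-well rate table (columns construct, mg_mM,
    k_mM, replicate, lysate, max_rate).  Constructs with fewer than 4
    Mg levels are returned unfitted.
    """
    curves = []
    for (lysate, construct, k), grp in rates.groupby(
        ["lysate", "construct", "k_mM"], sort=True
    ):
        pts = (
            grp.groupby("mg_mM")["max_rate"]
            .agg(mean_rate="mean", sd_rate="std", n_reps="count")
            .reset_index()
            .sort_values("mg_mM", ignore_index=True)
        )
        pts["sd_rate"] = pts["sd_rate"].fillna(0.0)
        bell = None
        if fit and len(pts) >= MIN_GRID_POINTS and not np.allclose(
            pts["mean_rate"], pts["mean_rate"].iloc[0]
        ):
            bell = fit_bell(pts["mg_mM"], pts["mean_rate"])
        curves.append(
            MgResponseCurve(
                construct=str(construct),
                k_mM=float(k),
                points=pts,
                bell=bell,
                lysate=str(lysate),
            )
        )
    return curves


def mg_optimum(curve: MgResponseCurve) -> float:
    """The fitted bell center, in mM added Mg."""
    if curve.bell is None:
        raise StateError(
            f"{curve.construct}: curve has no fitted bell; fit it first"
        )
    return curve.bell.optimum


def calibrate_extract(
    rates: pd.DataFrame,
    lysate: str,
    reference_construct: str = "M7-Luc-M7",
    k_mM: Optional[float] = None,
) -> CalibrationRecord:
    """Fit the reference construct for one lysate and record its anchor.

    The reference must cover at least ``MIN_GRID_POINTS`` Mg levels.
    The recorded peak rate is the fitted bell amplitude.
    """
    sel = rates[(rates["lysate"] == lysate) & (rates["construct"] == reference_construct)]
    if k_mM is not None:
        sel = sel[sel["k_mM"] == k_mM]
    n_levels = sel["mg_mM"].nunique()
    if n_levels < MIN_GRID_POINTS:
        raise InputError(
            f"lysate {lysate!r}: reference construct covers only "
            f"{n_levels} Mg levels (need >= {MIN_GRID_POINTS})"
        )
    mean = sel.groupby("mg_mM")["max_rate"].mean()
    bell = fit_bell(mean.index.to_numpy(), mean.to_numpy())
    return CalibrationRecord(
        lysate=lysate,
        reference_construct=reference_construct,
        reference_optimum=bell.optimum,
        reference_peak=bell.amplitude,
    )


def normalize_to_reference(
    curves: Sequence[MgResponseCurve], calibration: CalibrationRecord
) -> list[MgResponseCurve]:
    """Divide every rate by the reference peak rate of the same lysate.

    The reference construct's value at its optimum becomes 1.0.
    Normalizing an already-normalized curve against the same reference
    is a no-op (idempotent).
    """
    out = []
    for c in curves:
        if c.lysate != calibration.lysate:
            raise InputError(
                f"curve lysate {c.lysate!r} does not match calibration "
                f"lysate {calibration.lysate!r}"
            )
        if c.normalized:
            if c.reference != calibration.reference_construct:
                raise InputError(
                    f"curve already normalized to {c.reference!r}"
                )
            out.append(c)
            continue
        peak = calibration.reference_peak
        pts = c.points.copy()
        pts["mean_rate"] = pts["mean_rate"] / peak
        pts["sd_rate"] = pts["sd_rate"] / peak
        bell = (
            replace(c.bell, amplitude=c.bell.amplitude / peak)
            if c.bell is not None
            else None
        )
        out.append(
            replace(
                c,
                points=pts,
                bell=bell,
                normalized=True,
                reference=calibration.reference_construct,
            )
        )
    return out


def compare_optima(curve_a: MgResponseCurve, curve_b: MgResponseCurve) -> float:
    """Signed difference of fitted magnesium optima, a - b (mM).

    Defined only within one K level; comparing across K levels is
    refused because monovalent salt shifts the loading optimum.
    """
    if curve_a.k_mM != curve_b.k_mM:
        raise InputError(
            f"cannot compare optima across K levels "
            f"({curve_a.k_mM} vs {curve_b.k_mM} mM)"
        )
    return mg_optimum(curve_a) - mg_optimum(curve_b)


def normalize_dual_reporter(firefly: float, renilla: float) -> float:
    """Firefly/Renilla ratio for transfection-efficiency normalization."""
    if renilla <= 0:
        raise InputError(f"Renilla signal must be positive (got {renilla})")
    return firefly / renilla


def curve_table(curves: Sequence[MgResponseCurve]) -> pd.DataFrame:
    rows = []
    for c in curves:
        rows.append(
            {
                "construct": c.construct,
                "k_mM": c.k_mM,
                "lysate": c.lysate,
                "amplitude": c.bell.amplitude if c.bell else np.nan,
                "optimum_mM": c.bell.optimum if c.bell else np.nan,
                "width_mM": c.bell.width if c.bell else np.nan,
                "normalized": c.normalized,
                "extrapolated": c.extrapolated,
            }
        )
    cols = [
        "construct", "k_mM", "lysate", "amplitude", "optimum_mM",
        "width_mM", "normalized", "extrapolated",
    ]
    return pd.DataFrame(rows, columns=cols)
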