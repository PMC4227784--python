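"""Fit scanning-model parameters to printed experimental observations.

The observations that constrain the model are fold changes of reporter
flux between constructs or Mg levels, and magnesium optima of
flux-vs-Mg profiles.  An *optimum* here is defined exactly as the
analysis pipeline defines it: a Gaussian bell fitted to the closed-form
flux evaluated on the experimental Mg grid (0.2–1.4 mM, step 0.2), so a
fitted parameter set and the end-to-end pipeline agree on what they
measure.

Fitting minimises weighted squared residuals — log-scale for fold
changes, linear (mM) for optima, one-sided hinge for bound-type
observations — by a coarse grid over the stiffest parameters followed
by trust-region least squares over all of them.  The optimisation is
deterministic; ``seed`` only feeds optional multi-start jitter.

The shipped ``paper2014`` preset is the output of :func:`fit_params`
with the default constraint set.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import InputError
from .model import ConstructSpec, ContextResponse, ScanningParams, closed_form_flux
from .response import fit_bell

MG_GRID = (0.2, 0.4, 0.6, 0.8, 1.0, 1.2, 1.4)
K_LEVELS = (60.0, 90.0, 120.0, 150.0)

WT = "M7-Luc-M7"


class ModelEnv:
    """Cached flux / grid-optimum evaluations for one parameter set."""

    def __init__(self, params: ScanningParams, constructs: dict[str, ConstructSpec]):
        self.params = params
        self.constructs = constructs
        self._flux: dict[tuple[str, float, float], float] = {}
        self._opt: dict[tuple[str, float], float] = {}

    def flux(self, name: str, mg: float, k: float) -> float:
        key = (name, mg, k)
        if key not in self._flux:
            self._flux[key] = closed_form_flux(
                self.constructs[name], self.params, mg, k
            ).reporter_flux
        return self._flux[key]

    def grid_optimum(self, name: str, k: float) -> float:
        """Bell-fit center of the flux profile on the experimental grid."""
        key = (name, k)
        if key not in self._opt:
            values = [self.flux(name, mg, k) for mg in MG_GRID]
            self._opt[key] = fit_bell(MG_GRID, values).optimum
        return self._opt[key]


@dataclass(frozen=True)
class Constraint:
    """One printed observation: (observable, target, comparison, weight).

    ``observe`` maps a :class:`ModelEnv` to the observable's value.
    ``cmp`` is ``eq`` (two-sided), ``ge`` or ``le`` (one-sided hinge);
    ``scale`` is ``log`` for fold changes or ``linear`` for mM
    quantities; ``tol`` sets the residual unit (residual 1 at the
    tolerance edge).
    """

    name: str
    observe: Callable[[ModelEnv], float]
    target: float
    cmp: str = "eq"
    scale: str = "log"
    tol: float = 0.1
    weight: float = 1.0

    def residual(self, env: ModelEnv) -> tuple[float, float, float]:
        """Return (observed value, misfit in tolerance units, weighted
        residual).  |misfit| <= 1 means the observation is met within
        its documented tolerance."""
        v = self.observe(env)
        if self.scale == "log":
            d = np.log(max(v, 1e-12) / self.target) / self.tol
        else:
            d = (v - self.target) / self.tol
        if self.cmp == "ge":
            d = min(d, 0.0)
        elif self.cmp == "le":
            d = max(d, 0.0)
        return v, d, self.weight * d


def default_constraints() -> list[Constraint]:
    """The printed observation set constraining the TRPM7 leader model.

    Folds carry a 10% relative tolerance (log scale), optimum positions
    and deltas ±0.05 mM, and the K-invariance of the wild-type optimum
    a ±0.1 mM band.  Weights reflect the package's fitting priorities:
    the reference-construct anchor (wild-type optimum at 60 mM K) is
    weighted hardest because every normalized quantity is expressed
    relative to it; the stop-knockout fold is down-weighted because it
    is structurally unreachable in this model family (see the methods
    note) and would otherwise distort the feasible observations.
    """
    cs = [
        Constraint(
            "uAUG1 knockout alleviates inhibition >= 2-fold (at WT optimum, 60 mM K)",
            lambda e: (
                e.flux("1AUC-Luc-M7", e.grid_optimum(WT, 60.0), 60.0)
                / e.flux(WT, e.grid_optimum(WT, 60.0), 60.0)
            ),
            target=2.2,
            cmp="ge",
            scale="log",
            tol=0.1,
        ),
        Constraint(
            "no-uORF leader: flux(0.6)/flux(1.4) = 2 (60 mM K)",
            lambda e: (
                e.flux("1AUC2AUC-Luc-M7", 0.6, 60.0)
                / e.flux("1AUC2AUC-Luc-M7", 1.4, 60.0)
            ),
            target=2.0,
            tol=0.1,
            weight=2.0,
        ),
        Constraint(
            "WT leader: flux(0.6)/flux(1.4) = 10 (60 mM K)",
            lambda e: e.flux(WT, 0.6, 60.0) / e.flux(WT, 1.4, 60.0),
            target=10.0,
            tol=0.1,
            weight=2.0,
        ),
        Constraint(
            "uORF2 stop knockout halves flux (at WT optimum, 60 mM K)",
            lambda e: (
                e.flux(WT, e.grid_optimum(WT, 60.0), 60.0)
                / e.flux("2stopCGA-Luc-M7", e.grid_optimum(WT, 60.0), 60.0)
            ),
            target=2.0,
            tol=0.1,
            weight=0.1,
        ),
        Constraint(
            "uORF2 stop knockout does not shift the optimum (60 mM K)",
            lambda e: abs(
                e.grid_optimum(WT, 60.0)
                - e.grid_optimum("2stopCGA-Luc-M7", 60.0)
            ),
            target=0.0,
            cmp="le",
            scale="linear",
            tol=0.05,
        ),
        Constraint(
            "beta-globin minus WT optimum = +0.4 mM at 120 mM K",
            lambda e: (
                e.grid_optimum("beta-Luc-M7", 120.0)
                - e.grid_optimum(WT, 120.0)
            ),
            target=0.4,
            scale="linear",
            tol=0.05,
        ),
        Constraint(
            "beta-globin minus WT optimum = +0.2 mM at 60 mM K",
            lambda e: (
                e.grid_optimum("beta-Luc-M7", 60.0) - e.grid_optimum(WT, 60.0)
            ),
            target=0.2,
            scale="linear",
            tol=0.05,
            weight=2.0,
        ),
        Constraint(
            "WT optimum = 0.8 mM added Mg at 60 mM K",
            lambda e: e.grid_optimum(WT, 60.0),
            target=0.8,
            scale="linear",
            tol=0.05,
            weight=60.0,
        ),
        Constraint(
            "WT optimum invariant across K (spread over 60-150 mM K)",
            lambda e: (
                max(e.grid_optimum(WT, k) for k in K_LEVELS)
                - min(e.grid_optimum(WT, k) for k in K_LEVELS)
            ),
            target=0.0,
            cmp="le",
            scale="linear",
            tol=0.1,
        ),
    ]
    return cs


# ---------------------------------------------------------------------------
# Parameter vector <-> ScanningParams

_PARAM_NAMES = (
    "center_intercept",
    "center_slope",
    "loading_width",
    "p_strong",
    "reinit_prob",
    "adequate_floor",
    "adequate_ceil",
    "adequate_midpoint",
    "adequate_steepness",
)
_LOWER = np.array([0.4, 0.0005, 0.10, 0.30, 0.02, 0.0, 0.70, 0.30, 0.008])
_UPPER = np.array([1.2, 0.0100, 0.50, 0.90, 0.50, 0.30, 1.00, 1.20, 0.300])

WEAK_DEFAULT = ContextResponse(floor=0.02, ceil=0.5, midpoint=1.0, steepness=0.15)


def params_from_vector(x: Sequence[float], loading_amp: float = 100.0) -> ScanningParams:
    c0, c1, w, ps, q, f2, c2, m2, s2 = (float(v) for v in x)
    f2 = min(f2, c2)  # keep floor <= ceil even at bound corners
    return ScanningParams(
        loading_amp=loading_amp,
        loading_center=(c0, c1),
        loading_width=w,
        contexts={
            "strong": ContextResponse(ps, ps, 0.8, 1.0),
            "adequate": ContextResponse(f2, c2, m2, s2),
            "weak": WEAK_DEFAULT,
        },
        reinit_prob=q,
    )


@dataclass
class FitResult:
    params: ScanningParams
    report: pd.DataFrame = field(repr=False)
    cost: float = np.nan

    @property
    def max_abs_misfit(self) -> float:
        """Worst constraint misfit, in tolerance units (<=1 means met)."""
        return float(self.report["misfit"].abs().max())

    @property
    def max_abs_residual(self) -> float:
        return float(self.report["residual"].abs().max())


def evaluate_constraints(
    params: ScanningParams,
    constructs: dict[str, ConstructSpec],
    constraints: Sequence[Constraint],
) -> pd.DataFrame:
    """Per-constraint observed values and scaled residuals."""
    env = ModelEnv(params, constructs)
    rows = []
    for c in constraints:
        try:
            value, misfit, resid = c.residual(env)
            err = ""
        except Exception as exc:  # degenerate point: report, don't raise
            value, misfit, resid, err = np.nan, 50.0, 50.0, str(exc)
        rows.append(
            {"constraint": c.name, "observed": value, "target": c.target,
             "cmp": c.cmp, "misfit": misfit, "residual": resid, "error": err}
        )
    return pd.DataFrame(rows)


def fit_params(
    constructs: dict[str, ConstructSpec],
    constraints: Optional[Sequence[Constraint]] = None,
    seed: int = 0,
    n_starts: int = 3,
    coarse: bool = True,
) -> FitResult:
    """Fit ScanningParams to a constraint set.

    A coarse grid over the stiff parameters (loading width, reinitiation
    probability, adequate-class midpoint/steepness) seeds trust-region
    least squares over all nine parameters.  An infeasible constraint
    set does not raise: the report carries the worst residuals.
    """
    if constraints is None:
        constraints = default_constraints()
    if not constraints:
        raise InputError("constraint set must be nonempty")
    constraints = list(constraints)

    def residual_vec(x: np.ndarray) -> np.ndarray:
        params = params_from_vector(x)
        env = ModelEnv(params, constructs)
        out = np.empty(len(constraints))
        for i, c in enumerate(constraints):
            try:
                out[i] = c.residual(env)[2]
            except Exception:
                out[i] = 50.0
        return out

    def warm_start(w: float, q: float, s2: float, m2: float) -> np.ndarray:
        # Analytic seed.  The no-uORF 0.6/1.4 fold fixes the loading
        # asymmetry at 60 mM K, giving the 60 mM K bell center; the
        # beta-WT optimum deltas set the K-slope of the center; the
        # adequate-class cliff sits just above the wild-type optimum so
        # that the loading/transmission balance pins that optimum near
        # 0.8 mM while the 2-vs-10-fold pair is carried by the cliff.
        c60 = 1.0 - w**2 * np.log(2.0) / 0.8
        c1 = 0.003
        c0 = c60 - 60.0 * c1
        x = np.array([c0, c1, w, 0.60, q, 0.0, 0.99, m2, s2])
        return np.clip(x, _LOWER, _UPPER)

    candidates = []
    if coarse:
        grid = itertools.product(
            (0.18, 0.21, 0.24, 0.28),
            (0.14, 0.18, 0.22),
            (0.012, 0.02, 0.032),
            (0.82, 0.85, 0.88, 0.91),
        )
        for w, q, s2, m2 in grid:
            x0 = warm_start(w, q, s2, m2)
            candidates.append((float(np.sum(residual_vec(x0) ** 2)), x0))
        candidates.sort(key=lambda t: t[0])
        starts = [x for _, x in candidates[: max(1, n_starts)]]
    else:
        starts = [warm_start(0.21, 0.18, 0.02, 0.85)]

    rng = np.random.default_rng(seed)
    best = None
    for j, x0 in enumerate(starts):
        if j > 0:
            x0 = np.clip(
                x0 * (1 + 0.02 * rng.standard_normal(x0.size)), _LOWER, _UPPER
            )
        sol = least_squares(
            residual_vec,
            np.clip(x0, _LOWER, _UPPER),
            bounds=(_LOWER, _UPPER),
            method="trf",
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
            max_nfev=4000,
            diff_step=1e-4,
        )
        if best is None or sol.cost < best.cost:
            best = sol

    params = params_from_vector(best.x)
    report = evaluate_constraints(params, constructs, constraints)
    return FitResult(params=params, report=report, cost=float(best.cost))
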