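"""Leaky-scanning / reinitiation model of Mg²⁺-dependent translation initiation.

The model is a multiplicative branching process over the AUG codons of a
reporter mRNA, scanned 5'→3' by 43S preinitiation complexes:

* **Loading.**  The rate at which complexes are loaded at the cap is a
  Gaussian bell in added Mg²⁺ whose center shifts with added K⁺
  (``amp · exp(-(Mg - center(K))² / (2 width²))``, ``center(K)`` affine
  in K).  Monovalent and divalent cations compete for ribosomal binding
  sites, so more K⁺ requires more Mg²⁺ for an initiation-competent 43S —
  hence the positive center slope.  Uncapped mRNA loads at a small
  residual fraction ``uncapped_scale``.
* **Start-site selection.**  At each AUG the probability of initiation
  depends on the Kozak context class and on Mg²⁺ through a logistic
  ``p(Mg) = floor + (ceil - floor)·σ((Mg - midpoint)/steepness)``:
  suboptimal contexts are recognised more efficiently at high Mg²⁺
  (stiffer, less leaky scanning), while strong contexts are effectively
  Mg-independent (modelled with floor == ceil).
* **uORF fate.**  A ribosome initiating at a uORF that overlaps the
  reporter ORF is sequestered (it elongates past the reporter start and
  is lost to reporter synthesis).  After translating a uORF that
  terminates upstream of the reporter, the 40S resumes scanning with
  reinitiation probability ``reinit_prob`` and is otherwise released.
* **Reporter flux** = loading rate × probability that a scanning
  complex reaches the reporter AUG and initiates there.

Both an exact closed form (mass propagation over the branch tree) and a
per-ribosome Monte-Carlo twin are provided; they agree to binomial
sampling error by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Optional, Union

import numpy as np
import yaml

from .errors import InputError, ParameterError
from .leader import UORF, LeaderAnnotation

CONTEXT_CLASSES = ("strong", "adequate", "weak")


@dataclass(frozen=True)
class ContextResponse:
    """Logistic Mg-response of one Kozak context class.

    floor/ceil are the low-/high-Mg initiation probabilities; midpoint
    (mM) and steepness (mM) place the logistic transition.  A flat
    (Mg-independent) class is expressed as floor == ceil.
    """

    floor: float
    ceil: float
    midpoint: float
    steepness: float

    def __post_init__(self):
        if not (0.0 <= self.floor <= self.ceil <= 1.0):
            raise ParameterError(
                f"context probabilities must satisfy 0 <= floor <= ceil <= 1 "
                f"(got floor={self.floor}, ceil={self.ceil})"
            )
        if self.steepness <= 0:
            raise ParameterError("logistic steepness must be positive")

    def prob(self, mg: float) -> float:
        z = (mg - self.midpoint) / self.steepness
        sigma = 0.5 * (1.0 + math.tanh(0.5 * z))  # numerically safe logistic
        return self.floor + (self.ceil - self.floor) * sigma


@dataclass(frozen=True)
class ScanningParams:
    """All parameters of the loading + leaky-scanning + reinitiation model.

    ``loading_center`` is (intercept mM, slope mM per mM K) of the
    affine map from added K to the loading-bell center in added Mg.
    """

    loading_amp: float
    loading_center: tuple[float, float]
    loading_width: float
    contexts: dict[str, ContextResponse]
    reinit_prob: float
    uncapped_scale: float = 0.05

    def __post_init__(self):
        if self.loading_width <= 0:
            raise ParameterError("loading_width must be positive")
        if self.loading_amp <= 0:
            raise ParameterError("loading_amp must be positive")
        if not 0.0 <= self.reinit_prob <= 1.0:
            raise ParameterError("reinit_prob must be in [0, 1]")
        if not 0.0 <= self.uncapped_scale <= 1.0:
            raise ParameterError("uncapped_scale must be in [0, 1]")
        missing = set(CONTEXT_CLASSES) - set(self.contexts)
        if missing:
            raise ParameterError(
                f"missing context classes: {sorted(missing)}"
            )

    def center(self, k: float) -> float:
        c0, c1 = self.loading_center
        return c0 + c1 * k

    def context(self, cls: str) -> ContextResponse:
        try:
            return self.contexts[cls]
        except KeyError:
            raise ParameterError(f"unknown context class {cls!r}") from None

    # -- (de)serialisation ---------------------------------------------
    def to_dict(self) -> dict:
        return {
            "loading_amp": float(self.loading_amp),
            "loading_center": [float(x) for x in self.loading_center],
            "loading_width": float(self.loading_width),
            "reinit_prob": float(self.reinit_prob),
            "uncapped_scale": float(self.uncapped_scale),
            "contexts": {
                cls: {
                    "floor": float(c.floor),
                    "ceil": float(c.ceil),
                    "midpoint": float(c.midpoint),
                    "steepness": float(c.steepness),
                }
                for cls, c in self.contexts.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScanningParams":
        return cls(
            loading_amp=d["loading_amp"],
            loading_center=tuple(d["loading_center"]),
            loading_width=d["loading_width"],
            contexts={
                name: ContextResponse(**cd)
                for name, cd in d["contexts"].items()
            },
            reinit_prob=d["reinit_prob"],
            uncapped_scale=d.get("uncapped_scale", 0.05),
        )


def load_params_preset(name: str = "paper2014") -> ScanningParams:
    """Load a packaged ScanningParams preset (YAML under magscan/data)."""
    ref = resources.files("magscan").joinpath(f"data/{name}.yaml")
    try:
        text = ref.read_text()
    except FileNotFoundError:
        raise ParameterError(f"no packaged parameter preset {name!r}") from None
    return ScanningParams.from_dict(yaml.safe_load(text))


def loading_rate(
    params: ScanningParams, mg: float, k: float, capped: bool = True
) -> float:
    """Cap-dependent 43S loading rate at (added Mg, added K)."""
    if mg <= 0:
        raise ParameterError(f"added Mg must be positive (got {mg})")
    if k < 0:
        raise ParameterError(f"added K must be nonnegative (got {k})")
    c = params.center(k)
    rate = params.loading_amp * math.exp(
        -((mg - c) ** 2) / (2.0 * params.loading_width**2)
    )
    return rate if capped else rate * params.uncapped_scale


def site_init_prob(params: ScanningParams, context_cls: str, mg: float) -> float:
    """Initiation probability of a scanning complex at an AUG of the
    given context class, at the given added Mg (mM)."""
    if mg <= 0:
        raise ParameterError(f"added Mg must be positive (got {mg})")
    return params.context(context_cls).prob(mg)


# ---------------------------------------------------------------------------
# Constructs


@dataclass(frozen=True)
class ConstructSpec:
    """A reporter construct: an annotated leader plus point mutations.

    ``knocked_out_augs`` are uAUG positions mutated AUG→AUC (the site is
    skipped by scanning); ``knocked_out_stops`` are uORF stop positions
    mutated UGA→CGA, which extends the uORF past the reporter start and
    makes it sequestering; ``reporter_at`` is the AUG whose downstream
    ORF is the measured reporter (the main AUG by default; a uAUG for
    fusion constructs).
    """

    name: str
    annotation: LeaderAnnotation
    knocked_out_augs: frozenset[int] = frozenset()
    knocked_out_stops: frozenset[int] = frozenset()
    reporter_at: Optional[int] = None
    capped: bool = True

    def __post_init__(self):
        ann = self.annotation
        uaug_positions = {u.start for u in ann.uorfs}
        stop_positions = {
            u.stop_start for u in ann.uorfs if u.stop_start is not None
        }
        if self.reporter_at is None:
            object.__setattr__(self, "reporter_at", ann.leader.main_start)
        bad = self.knocked_out_augs - uaug_positions
        if bad:
            raise InputError(
                f"{self.name}: no uAUG at position(s) {sorted(bad)}"
            )
        bad = self.knocked_out_stops - stop_positions
        if bad:
            raise InputError(
                f"{self.name}: no uORF stop codon at position(s) {sorted(bad)}"
            )
        if (
            self.reporter_at != ann.leader.main_start
            and self.reporter_at not in uaug_positions
        ):
            raise InputError(
                f"{self.name}: reporter position {self.reporter_at} is not "
                "an AUG of this leader"
            )


@dataclass(frozen=True)
class AugKnockout:
    pos: int


@dataclass(frozen=True)
class StopKnockout:
    pos: int


@dataclass(frozen=True)
class FuseReporter:
    pos: int


Mutation = Union[AugKnockout, StopKnockout, FuseReporter]


def apply_mutation(construct: ConstructSpec, mutation: Mutation) -> ConstructSpec:
    """Return a new construct with one mutation applied."""
    if isinstance(mutation, AugKnockout):
        return replace(
            construct,
            knocked_out_augs=construct.knocked_out_augs | {mutation.pos},
        )
    if isinstance(mutation, StopKnockout):
        return replace(
            construct,
            knocked_out_stops=construct.knocked_out_stops | {mutation.pos},
        )
    if isinstance(mutation, FuseReporter):
        return replace(construct, reporter_at=mutation.pos)
    raise InputError(f"unknown mutation {mutation!r}")


# ---------------------------------------------------------------------------
# Scanning path


@dataclass(frozen=True)
class _Site:
    pos: int
    cls: str
    knocked_out: bool
    is_reporter: bool
    sequesters: bool      # initiation removes the ribosome from reporter path
    resume_pos: int       # scanning resumes here after reinitiation


def _uorf_sequesters(u: UORF, construct: ConstructSpec) -> bool:
    if u.stop_start is None or u.stop_start in construct.knocked_out_stops:
        return True
    return u.stop_start + 2 >= construct.reporter_at


def _scan_path(construct: ConstructSpec) -> list[_Site]:
    ann = construct.annotation
    main = ann.leader.main_start
    sites: list[_Site] = []
    for u in ann.uorfs:
        if u.start == construct.reporter_at:
            sites.append(_Site(u.start, u.context.cls, False, True, True, 0))
            continue
        sites.append(
            _Site(
                pos=u.start,
                cls=u.context.cls,
                knocked_out=u.start in construct.knocked_out_augs,
                is_reporter=False,
                sequesters=_uorf_sequesters(u, construct),
                resume_pos=(u.stop_start + 3) if u.stop_start is not None else 0,
            )
        )
    if construct.reporter_at == main:
        sites.append(_Site(main, ann.main_context.cls, False, True, True, 0))
    return sorted(sites, key=lambda s: s.pos)


@dataclass(frozen=True)
class FluxResult:
    """Reporter flux and the full branching-outcome distribution."""

    construct: str
    mg: float
    k: float
    reporter_flux: float
    branch_probabilities: dict[str, float] = field(repr=False)


def closed_form_flux(
    construct: ConstructSpec,
    params: ScanningParams,
    mg: float,
    k: float,
) -> FluxResult:
    """Exact reporter flux by mass propagation over the scanning tree.

    Probability mass is injected at the 5' end and pushed through the
    AUG sites in order; reinitiating mass re-enters downstream of the
    terminating uORF's stop codon.  Branch probabilities sum to 1
    exactly (up to float rounding).
    """
    sites = _scan_path(construct)
    load = loading_rate(params, mg, k, construct.capped)
    outcomes: dict[str, float] = {}

    def add(key: str, mass: float) -> None:
        outcomes[key] = outcomes.get(key, 0.0) + mass

    # (next position to scan from, mass); processed in position order
    work: list[tuple[int, float]] = [(1, 1.0)]
    while work:
        from_pos, mass = work.pop()
        if mass == 0.0:
            continue
        site = next((s for s in sites if s.pos >= from_pos), None)
        if site is None:
            add("scanned_through", mass)
            continue
        if site.is_reporter:
            p = site_init_prob(params, site.cls, mg)
            add("initiated_reporter", mass * p)
            add("scanned_through", mass * (1.0 - p))
            continue
        p = 0.0 if site.knocked_out else site_init_prob(params, site.cls, mg)
        initiated = mass * p
        work.append((site.pos + 1, mass * (1.0 - p)))
        if initiated == 0.0:
            continue
        if site.sequesters:
            add(f"sequestered_at_{site.pos}", initiated)
        else:
            q = params.reinit_prob
            add(f"released_after_{site.pos}", initiated * (1.0 - q))
            work.append((site.resume_pos, initiated * q))

    return FluxResult(
        construct=construct.name,
        mg=mg,
        k=k,
        reporter_flux=load * outcomes.get("initiated_reporter", 0.0),
        branch_probabilities=outcomes,
    )


def simulate_scanning(
    construct: ConstructSpec,
    params: ScanningParams,
    mg: float,
    k: float,
    n_ribosomes: int,
    seed: int,
) -> FluxResult:
    """Monte-Carlo twin of :func:`closed_form_flux`.

    Each of ``n_ribosomes`` scanning complexes makes independent
    Bernoulli decisions along the same site path; the returned flux uses
    the empirical reporter-initiation frequency.
    """
    if n_ribosomes < 1:
        raise ParameterError("n_ribosomes must be >= 1")
    rng = np.random.default_rng(seed)
    sites = _scan_path(construct)
    load = loading_rate(params, mg, k, construct.capped)
    site_p = [
        0.0
        if (not s.is_reporter and s.knocked_out)
        else site_init_prob(params, s.cls, mg)
        for s in sites
    ]
    q = params.reinit_prob

    counts: dict[str, int] = {}
    pos = np.ones(n_ribosomes, dtype=np.int64)  # next scan position
    fate = np.full(n_ribosomes, "", dtype=object)
    active = np.ones(n_ribosomes, dtype=bool)
    for s, p in zip(sites, site_p):
        enc = active & (pos <= s.pos)
        n_enc = int(enc.sum())
        if n_enc == 0:
            continue
        init = np.zeros(n_ribosomes, dtype=bool)
        init[enc] = rng.random(n_enc) < p
        if s.is_reporter:
            fate[enc & init] = "initiated_reporter"
            fate[enc & ~init] = "scanned_through"
            active[enc] = False
        elif s.sequesters:
            fate[enc & init] = f"sequestered_at_{s.pos}"
            active[enc & init] = False
            pos[enc & ~init] = s.pos + 1
        else:
            n_init = int(init.sum())
            reinit = np.zeros(n_ribosomes, dtype=bool)
            reinit[init] = rng.random(n_init) < q
            fate[init & ~reinit] = f"released_after_{s.pos}"
            active[init & ~reinit] = False
            pos[init & reinit] = s.resume_pos
            pos[enc & ~init] = s.pos + 1
    fate[active] = "scanned_through"
    labels, ns = np.unique(fate, return_counts=True)
    counts = dict(zip(labels.tolist(), ns.tolist()))
    frac = {key: n / n_ribosomes for key, n in counts.items()}
    return FluxResult(
        construct=construct.name,
        mg=mg,
        k=k,
        reporter_flux=load * frac.get("initiated_reporter", 0.0),
        branch_probabilities=frac,
    )
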