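"""Synthetic data: leader fixtures and in vitro translation datasets.

Two generators live here.

**Leader fixtures.**  :func:`make_leader_fixture` builds an RNA sequence
realising a prescribed uORF geometry (uAUG positions, uORF lengths,
main-start position, Kozak context bases, GC target for filler).  Fixed
motif bases (AUGs, stop codons, context positions) are placed first;
filler is drawn GC-biased and then repaired so that no unintended
upstream AUG and no premature in-frame stop inside a declared uORF
survives.  The result is verified by re-annotation: generation fails
loudly if the annotated geometry does not match the spec.

The shipped TRPM7-like geometry places uAUG1 at nt 101 (strong context,
A-3/A+4) starting a 390-nt uORF1 that overlaps the main CDS by 206 nt,
and uAUG2 at nt 217 (adequate context, U-3/G+4) starting a 63-nt uORF2
that ends 5 nt upstream of the main AUG at nt 285.  The two uAUGs are
out of frame with each other and with the main CDS.  (A uAUG1→uAUG2
spacing divisible by 3 would put uORF2's stop codon in uORF1's reading
frame and truncate uORF1, so the spacing here is 116 nt — the unique
choice under which all four printed geometry figures hold at once.)

**Translation experiments.**  :func:`simulate_experiment` emulates a
plate-reader run: for every well (construct × Mg × K × replicate ×
lysate) the true synthesis rate R is the closed-form model flux at the
lysate's effective Mg, and the cumulative signal follows an onset-lag ×
late-slowdown envelope ``R·[t - τ_on(1 - e^{-t/τ_on})]·e^{-t/τ_off}``
with per-read multiplicative Gaussian noise.  A ground-truth table
(true rates and true per-construct optima) is emitted alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, ParameterError
from .leader import (
    STOP_CODONS,
    LeaderAnnotation,
    LeaderSequence,
    annotate,
)
from .model import (
    AugKnockout,
    ConstructSpec,
    FuseReporter,
    ScanningParams,
    StopKnockout,
    apply_mutation,
    closed_form_flux,
)
from .response import fit_bell

# ---------------------------------------------------------------------------
# Geometry fixtures


@dataclass(frozen=True)
class GeometrySpec:
    """Prescribed uORF architecture for a generated leader."""

    name: str
    length: int
    main_start: int
    uaug_positions: tuple[int, ...] = ()
    uorf_lengths: tuple[Optional[int], ...] = ()  # incl. start+stop codons
    gc_target: float = 0.5
    #: (minus3, plus4) bases per uAUG, aligned with uaug_positions
    contexts: tuple[tuple[str, str], ...] = ()
    main_context: tuple[str, str] = ("A", "G")

    def __post_init__(self):
        if len(self.uorf_lengths) != len(self.uaug_positions):
            raise InputError("one uORF length per uAUG position required")
        if self.contexts and len(self.contexts) != len(self.uaug_positions):
            raise InputError("one context pair per uAUG position required")
        if not (1 <= self.main_start <= self.length - 2):
            raise InputError("main_start outside sequence")
        for pos, ln in zip(self.uaug_positions, self.uorf_lengths):
            if not 1 <= pos < self.main_start:
                raise InputError(f"uAUG position {pos} not upstream of main")
            if ln is not None:
                if ln % 3 != 0 or ln < 6:
                    raise InputError(
                        f"uORF length {ln} must be a positive multiple of 3"
                    )
                if pos + ln - 1 > self.length:
                    raise InputError(
                        f"uORF at {pos} (length {ln}) exceeds the sequence"
                    )
        if not 0.0 <= self.gc_target <= 1.0:
            raise InputError("gc_target must be in [0, 1]")


_TRPM7_LIKE = GeometrySpec(
    name="trpm7-mouse-like",
    length=540,
    main_start=285,
    uaug_positions=(101, 217),
    uorf_lengths=(390, 63),
    gc_target=0.675,
    contexts=(("A", "A"), ("U", "G")),
    main_context=("A", "G"),
)

_BETA_LIKE = GeometrySpec(
    name="beta-globin-like",
    length=140,
    main_start=51,
    uaug_positions=(),
    uorf_lengths=(),
    gc_target=0.50,
    main_context=("A", "G"),
)

#: the TRPM7-like geometry satisfies the uORF1 figures (390 nt / 206 nt
#: overlap) and the uORF2 figures (63 nt / 5 nt gap) simultaneously, so
#: both named presets resolve to it
GEOMETRY_PRESETS: dict[str, GeometrySpec] = {
    "trpm7-mouse-like": _TRPM7_LIKE,
    "uorf1-paper": replace(_TRPM7_LIKE, name="uorf1-paper"),
    "uorf2-paper": replace(_TRPM7_LIKE, name="uorf2-paper"),
    "beta-globin-like": _BETA_LIKE,
}

_BASES = np.array(list("ACGU"))


def _draw_base(rng: np.random.Generator, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return str(rng.choice(_BASES, p=p))


def make_leader_fixture(spec: GeometrySpec, seed: int = 0) -> LeaderSequence:
    """Generate a leader sequence realising ``spec`` exactly.

    Deterministic under ``seed``.  Tightly packed geometries can make a
    particular stop-codon choice collide with a neighbouring fixed
    motif, so each stop codon is tried in all three variants
    (UGA/UAA/UAG) before the spec is declared unsatisfiable.  Raises
    :class:`InputError` if no assignment works (conflicting fixed
    bases, or a repaired sequence that still fails re-annotation).
    """
    import itertools

    n_stops = sum(1 for ln in spec.uorf_lengths if ln is not None)
    last_err: Optional[InputError] = None
    for combo in itertools.product(("UGA", "UAA", "UAG"), repeat=n_stops):
        try:
            return _build_fixture(spec, seed, combo)
        except InputError as err:
            last_err = err
    raise last_err if last_err is not None else InputError(
        f"{spec.name}: unsatisfiable geometry"
    )


def _build_fixture(
    spec: GeometrySpec, seed: int, stop_codons: tuple[str, ...]
) -> LeaderSequence:
    rng = np.random.default_rng(seed)
    seq: list[Optional[str]] = [None] * spec.length
    fixed = [False] * spec.length

    def place(pos1: int, motif: str) -> None:
        for off, b in enumerate(motif):
            i = pos1 - 1 + off
            if fixed[i] and seq[i] != b:
                raise InputError(
                    f"{spec.name}: conflicting fixed base at position "
                    f"{i + 1} ({seq[i]} vs {b})"
                )
            seq[i], fixed[i] = b, True

    place(spec.main_start, "AUG")
    m3, p4 = spec.main_context
    if spec.main_start >= 4:
        place(spec.main_start - 3, m3)
    if spec.main_start + 3 <= spec.length:
        place(spec.main_start + 3, p4)
    contexts = spec.contexts or tuple(
        ("A", "G") for _ in spec.uaug_positions
    )
    stop_starts: list[Optional[int]] = []
    stop_iter = iter(stop_codons)
    for pos, ln, (m3, p4) in zip(
        spec.uaug_positions, spec.uorf_lengths, contexts
    ):
        place(pos, "AUG")
        if pos >= 4:
            place(pos - 3, m3)
        if pos + 3 <= spec.length:
            place(pos + 3, p4)
        if ln is None:
            stop_starts.append(None)
        else:
            stop_starts.append(pos + ln - 3)
            place(pos + ln - 3, next(stop_iter))

    for i in range(spec.length):
        if seq[i] is None:
            seq[i] = _draw_base(rng, spec.gc_target)

    declared = set(spec.uaug_positions)

    def violations() -> list[tuple[int, int]]:
        """(start_index0, kind) of codons that must be broken."""
        bad = []
        s = "".join(seq)
        # unintended upstream AUGs
        for p in range(spec.main_start - 1):
            if s[p : p + 3] == "AUG" and (p + 1) not in declared:
                bad.append((p, 0))
        # premature in-frame stops inside declared uORFs
        for pos, stop in zip(spec.uaug_positions, stop_starts):
            limit = stop - 1 if stop is not None else spec.length - 2
            for p in range(pos + 2, limit, 3):
                if s[p : p + 3] in STOP_CODONS:
                    bad.append((p, 1))
        return bad

    for _ in range(500):
        bad = violations()
        if not bad:
            break
        for p, _kind in bad:
            free = [i for i in range(p, p + 3) if i < spec.length and not fixed[i]]
            if not free:
                raise InputError(
                    f"{spec.name}: fixed bases force a forbidden codon at "
                    f"position {p + 1}"
                )
            i = free[int(rng.integers(len(free)))]
            old = seq[i]
            while seq[i] == old:
                seq[i] = _draw_base(rng, spec.gc_target)
    else:
        raise InputError(f"{spec.name}: could not repair filler sequence")

    leader = LeaderSequence(spec.name, "".join(seq), spec.main_start)
    _verify_geometry(leader, spec, stop_starts)
    return leader


def _verify_geometry(
    leader: LeaderSequence,
    spec: GeometrySpec,
    stop_starts: Sequence[Optional[int]],
) -> None:
    ann = annotate(leader)
    got = tuple(u.start for u in ann.uorfs)
    if got != tuple(spec.uaug_positions):
        raise InputError(
            f"{spec.name}: generated uAUGs {got} != declared "
            f"{tuple(spec.uaug_positions)}"
        )
    for u, ln, stop in zip(ann.uorfs, spec.uorf_lengths, stop_starts):
        if u.length_nt != ln or u.stop_start != stop:
            raise InputError(
                f"{spec.name}: uORF at {u.start} annotated as length "
                f"{u.length_nt} (stop {u.stop_start}), declared {ln} ({stop})"
            )


# ---------------------------------------------------------------------------
# Construct registry

#: seed fixing the canonical fixture sequences behind named constructs
_FIXTURE_SEED = 20141017


def _trpm7_annotation() -> LeaderAnnotation:
    return annotate(make_leader_fixture(_TRPM7_LIKE, _FIXTURE_SEED))


def _beta_annotation() -> LeaderAnnotation:
    return annotate(make_leader_fixture(_BETA_LIKE, _FIXTURE_SEED))


def build_construct(name: str) -> ConstructSpec:
    """Resolve a named reporter construct.

    Knockout/fusion names follow the reporter-mRNA naming of the assay:
    ``1AUC``/``2AUC`` knock out uAUG1/uAUG2 (AUG→AUC), ``2stopCGA``
    knocks out the uORF2 stop (UGA→CGA, making uORF2 overlap the main
    ORF), ``2ndLuc`` fuses the reporter to the uAUG2.
    """
    if name not in CONSTRUCT_PRESETS:
        raise InputError(
            f"unknown construct {name!r}; available: "
            + ", ".join(sorted(CONSTRUCT_PRESETS))
        )
    return CONSTRUCT_PRESETS[name]()


def _m7() -> ConstructSpec:
    return ConstructSpec(name="M7-Luc-M7", annotation=_trpm7_annotation())


def _beta() -> ConstructSpec:
    return ConstructSpec(name="beta-Luc-M7", annotation=_beta_annotation())


def _1auc() -> ConstructSpec:
    c = apply_mutation(_m7(), AugKnockout(101))
    return replace(c, name="1AUC-Luc-M7")


def _2auc() -> ConstructSpec:
    c = apply_mutation(_m7(), AugKnockout(217))
    return replace(c, name="2AUC-Luc-M7")


def _1auc2auc() -> ConstructSpec:
    c = apply_mutation(apply_mutation(_m7(), AugKnockout(101)), AugKnockout(217))
    return replace(c, name="1AUC2AUC-Luc-M7")


def _2stop() -> ConstructSpec:
    ann = _trpm7_annotation()
    stop = ann.uorf_at(217).stop_start
    c = apply_mutation(_m7(), StopKnockout(stop))
    return replace(c, name="2stopCGA-Luc-M7")


def _2ndluc() -> ConstructSpec:
    c = apply_mutation(_m7(), FuseReporter(217))
    return replace(c, name="2ndLuc-M7")


CONSTRUCT_PRESETS = {
    "M7-Luc-M7": _m7,
    "beta-Luc-M7": _beta,
    "1AUC-Luc-M7": _1auc,
    "2AUC-Luc-M7": _2auc,
    "1AUC2AUC-Luc-M7": _1auc2auc,
    "2stopCGA-Luc-M7": _2stop,
    "2ndLuc-M7": _2ndluc,
}


# ---------------------------------------------------------------------------
# Experiment simulation


@dataclass(frozen=True)
class ExperimentDesign:
    """Layout and noise model of a simulated in vitro translation run."""

    constructs: tuple[str, ...] = ("M7-Luc-M7", "beta-Luc-M7")
    mg_grid: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8, 1.0, 1.2, 1.4)
    k_levels: tuple[float, ...] = (60.0,)
    replicates: int = 3
    #: lysate id -> basal added-Mg offset (mM); effective Mg = added + offset
    lysates: dict[str, float] = field(default_factory=lambda: {"L1": 0.0})
    interval_min: float = 1.0
    duration_min: float = 60.0
    noise_sd: float = 0.03
    tau_on_min: float = 3.0
    tau_off_min: float = 120.0
    seed: int = 0

    def __post_init__(self):
        if not self.mg_grid or not self.k_levels or not self.constructs:
            raise InputError("constructs, mg_grid and k_levels must be nonempty")
        if self.replicates < 1:
            raise InputError("replicates must be >= 1")
        if self.noise_sd < 0:
            raise InputError("noise_sd must be >= 0")


def random_lysates(
    n: int, seed: int, offset_range: float = 0.1
) -> dict[str, float]:
    """Lysates with basal-Mg offsets drawn uniformly in ±offset_range mM."""
    rng = np.random.default_rng(seed)
    return {
        f"L{i + 1}": float(rng.uniform(-offset_range, offset_range))
        for i in range(n)
    }


def _envelope(t: np.ndarray, tau_on: float, tau_off: float) -> np.ndarray:
    """Cumulative-signal shape: onset lag then late-phase slowdown."""
    ramp = t - tau_on * (1.0 - np.exp(-t / tau_on)) if tau_on > 0 else t
    return ramp * np.exp(-t / tau_off)


def simulate_experiment(
    design: ExperimentDesign, params: ScanningParams
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate every well of a design; return (traces, ground_truth).

    ``traces`` is long-format (time_min, signal_alu, construct, mg_mM,
    k_mM, replicate, lysate).  ``ground_truth`` carries one row per
    (construct, K, lysate, Mg) with the true model flux, plus the true
    bell-fit optimum over the nominal added-Mg grid.  Identical seeds
    give byte-identical outputs; the noise stream is independent of the
    ground truth.
    """
    rng = np.random.default_rng(design.seed)
    t = np.arange(
        design.interval_min,
        design.duration_min + design.interval_min / 2,
        design.interval_min,
    )
    shape = _envelope(t, design.tau_on_min, design.tau_off_min)

    constructs = {name: build_construct(name) for name in design.constructs}
    trace_blocks, truth_rows = [], []
    for lysate, offset in design.lysates.items():
        for name, construct in constructs.items():
            for k in design.k_levels:
                fluxes = [
                    closed_form_flux(
                        construct, params, mg + offset, k
                    ).reporter_flux
                    for mg in design.mg_grid
                ]
                try:
                    true_opt = fit_bell(design.mg_grid, fluxes).optimum
                except Exception:
                    true_opt = float("nan")
                for mg, r_true in zip(design.mg_grid, fluxes):
                    truth_rows.append(
                        {
                            "construct": name,
                            "k_mM": k,
                            "lysate": lysate,
                            "mg_mM": mg,
                            "true_rate": r_true,
                            "true_optimum_mM": true_opt,
                        }
                    )
                    for rep in range(1, design.replicates + 1):
                        clean = r_true * shape
                        if design.noise_sd > 0:
                            noise = rng.normal(
                                1.0, design.noise_sd, size=clean.shape
                            )
                            signal = np.clip(clean * noise, 0.0, None)
                        else:
                            signal = clean
                        trace_blocks.append(
                            pd.DataFrame(
                                {
                                    "time_min": t,
                                    "signal_alu": signal,
                                    "construct": name,
                                    "mg_mM": mg,
                                    "k_mM": k,
                                    "replicate": f"r{rep}",
                                    "lysate": lysate,
                                }
                            )
                        )
    traces = pd.concat(trace_blocks, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return traces, truth
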