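"""Adaptive reference-frame selection for drift-free DIC of moving tissue.

Spontaneously contracting tissue has no stationary reference frame: minor
frame shifts left after each contraction cycle accumulate into measurement
error when every frame is correlated against one static reference.  The
adaptive scheme scores each analysed frame by the Frobenius norm of its
displacement matrix and, whenever that score drops below a threshold
``t_adapt`` (the noise floor / latent displacement of candidate reference
frames), adopts the frame as the new reference for subsequent frames.
Each new reference is a rest state near zero absolute displacement, so
displacements reported against it remain absolute measurements.

``t_adapt`` is estimated from two quiescent frames and finalised by
iterative refinement: the threshold is raised in fixed increments until
the per-cycle baseline of the norm series stops drifting.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import signal as sp_signal

from .io import ImageStack
from .piv import DisplacementField, multipass_piv

__all__ = [
    "ARConfig",
    "FrameRecord",
    "ReferenceTrace",
    "RefinementError",
    "frobenius_norm",
    "round_up_to_step",
    "estimate_tadapt",
    "run_ardic",
    "baseline_drift",
    "cycle_minima",
    "refine_tadapt",
]

log = logging.getLogger(__name__)


@dataclass
class ARConfig:
    """Adaptive-reference parameters.

    ``t_adapt`` is in px units of the displacement matrix (the norm of the
    raw PIV output); conversion to um is presentation only.
    ``drift_tolerance`` bounds the acceptable slope of per-cycle baseline
    minima, in norm units per cycle.
    """

    t_adapt: float
    initial_reference_index: int = 0
    refine: bool = True
    refine_step: float = 0.1
    refine_max_iters: int = 20
    drift_tolerance: float = 0.1
    accumulate: bool = False

    def __post_init__(self) -> None:
        if not self.t_adapt > 0:
            raise ValueError("t_adapt must be > 0")
        if not self.refine_step > 0:
            raise ValueError("refine_step must be > 0")


@dataclass
class FrameRecord:
    frame_index: int
    reference_index: int
    frobenius_norm: float
    switched: bool


@dataclass
class ReferenceTrace:
    """Per-frame reference bookkeeping plus the threshold history."""

    records: list[FrameRecord] = dc_field(default_factory=list)
    t_adapt: float = float("nan")
    t_adapt_history: list[dict] = dc_field(default_factory=list)

    @property
    def norms(self) -> np.ndarray:
        return np.array([r.frobenius_norm for r in self.records])

    @property
    def frames(self) -> np.ndarray:
        return np.array([r.frame_index for r in self.records])

    @property
    def references(self) -> np.ndarray:
        return np.array([r.reference_index for r in self.records])

    @property
    def switches(self) -> np.ndarray:
        return np.array([r.switched for r in self.records], dtype=bool)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "frame": self.frames,
                "reference": self.references,
                "frobenius_norm": self.norms,
                "switched": self.switches.astype(int),
            }
        )


class RefinementError(RuntimeError):
    """Raised when threshold refinement exhausts its iteration budget."""

    def __init__(self, history: list[dict]):
        self.history = history
        super().__init__(
            "t_adapt refinement did not converge; history: "
            + ", ".join(f"{h['t_adapt']:.3g}->drift {h['baseline_drift']:.3g}"
                        for h in history)
        )


def frobenius_norm(field: DisplacementField) -> float:
    """sqrt(sum over valid vectors of u^2 + v^2), in px.

    Invalid vectors are excluded; an all-invalid field is an error since
    no norm is measurable.
    """
    ok = field.valid
    if not ok.any():
        raise ValueError("displacement field has no valid vectors")
    return float(np.sqrt(np.sum(field.u[ok] ** 2 + field.v[ok] ** 2)))


def round_up_to_step(x: float, step: float) -> float:
    """Ceiling of ``x`` to the next multiple of ``step`` (floor one step).

    1.25 with step 0.1 rounds to 1.3; an exact multiple stays put; zero
    never rounds below one step.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    k = math.ceil(x / step - 1e-9)
    return max(1, k) * step


def estimate_tadapt(
    stack: ImageStack,
    rest_frame_a: int,
    rest_frame_b: int,
    schedule=None,
    refine_step: float = 0.1,
) -> float:
    """Initial threshold: norm between two caller-designated rest frames."""
    fld = multipass_piv(stack.frames[rest_frame_a], stack.frames[rest_frame_b],
                        schedule)
    norm = frobenius_norm(fld)
    return round(round_up_to_step(norm, refine_step), 10)


def run_ardic(
    stack: ImageStack,
    config: ARConfig,
    schedule=None,
    adaptive: bool = True,
) -> tuple[list[DisplacementField], ReferenceTrace]:
    """Run DIC over the stack with (or without) adaptive re-referencing.

    For each frame past the initial reference, the displacement field is
    measured against the active reference and its Frobenius norm recorded.
    When the norm falls below ``t_adapt`` the frame becomes the reference
    for *subsequent* frames — its own field is still reported against the
    previous reference, so every measurement stays well defined.

    With ``config.accumulate`` the fields are additionally chained through
    the reference offsets so they express displacement versus the initial
    reference (useful for genuinely drifting tissue).
    """
    ref = config.initial_reference_index
    if not 0 <= ref < stack.n_frames - 1:
        raise ValueError("initial_reference_index out of range")
    fields: list[DisplacementField] = []
    trace = ReferenceTrace(t_adapt=config.t_adapt)
    offset_u = offset_v = None  # chained offset of the active reference

    for t in range(ref + 1, stack.n_frames):
        fld = multipass_piv(stack.frames[ref], stack.frames[t], schedule)
        fld.frame_index = t
        fld.reference_index = ref
        norm = frobenius_norm(fld)
        switched = adaptive and norm < config.t_adapt
        trace.records.append(FrameRecord(t, ref, norm, switched))

        if config.accumulate:
            if offset_u is None:
                offset_u = np.zeros(fld.shape)
                offset_v = np.zeros(fld.shape)
            fld = fld.copy()
            fld.u = fld.u + offset_u
            fld.v = fld.v + offset_v
        fields.append(fld)

        if switched:
            log.info("frame %d adopted as reference (norm %.3f < %.3f)",
                     t, norm, config.t_adapt)
            if config.accumulate:
                offset_u = fields[-1].u.copy()
                offset_v = fields[-1].v.copy()
            ref = t

    norms = trace.norms
    if adaptive and not trace.switches.any() and len(norms) > 3:
        if np.all(np.diff(norms) > 0):
            log.warning(
                "no reference switch occurred and norms grow monotonically; "
                "t_adapt=%.3g is likely too small", config.t_adapt
            )
    return fields, trace


# ---------------------------------------------------------------------------
# baseline drift of the norm series


def _dominant_period(series: np.ndarray) -> int:
    """Dominant period in samples from the FFT of the detrended series."""
    x = series - series.mean()
    if len(x) < 4 or np.allclose(x, 0):
        return max(2, len(series) // 4)
    spec = np.abs(np.fft.rfft(x * np.hanning(len(x)))) ** 2
    spec[0] = 0.0
    k = int(np.argmax(spec))
    if k == 0:
        return max(2, len(series) // 4)
    return max(2, int(round(len(x) / k)))


def cycle_minima(norms: np.ndarray) -> np.ndarray:
    """Indices of per-cycle minima of the norm series.

    Minima are local minima separated by at least half the dominant period
    of the series (period found by FFT).
    """
    norms = np.asarray(norms, dtype=float)
    if len(norms) < 3:
        return np.arange(len(norms))
    period = _dominant_period(norms)
    dist = max(1, period // 2)
    idx, _ = sp_signal.find_peaks(-norms, distance=dist)
    if len(idx) == 0:
        idx = np.array([int(np.argmin(norms))])
    return idx


def baseline_drift(norms: np.ndarray) -> float:
    """Least-squares slope of per-cycle minimum norms, per cycle."""
    idx = cycle_minima(np.asarray(norms, dtype=float))
    if len(idx) < 2:
        return 0.0
    y = np.asarray(norms, dtype=float)[idx]
    x = np.arange(len(idx), dtype=float)
    return float(np.polyfit(x, y, 1)[0])


def refine_tadapt(
    stack: ImageStack,
    config: ARConfig,
    schedule=None,
) -> tuple[float, ReferenceTrace, list[dict]]:
    """Iteratively raise ``t_adapt`` until the norm baseline stops drifting.

    Returns the first threshold whose per-cycle baseline slope is within
    ``config.drift_tolerance``, the trace of that final run, and the full
    refinement history.
    """
    t = config.t_adapt
    history: list[dict] = []
    for iteration in range(config.refine_max_iters):
        cfg = ARConfig(
            t_adapt=t,
            initial_reference_index=config.initial_reference_index,
            refine=False,
            refine_step=config.refine_step,
            drift_tolerance=config.drift_tolerance,
            accumulate=config.accumulate,
        )
        _, trace = run_ardic(stack, cfg, schedule)
        drift = baseline_drift(trace.norms)
        entry = {"iteration": iteration, "t_adapt": round(t, 10),
                 "baseline_drift": drift}
        history.append(entry)
        log.info("refinement iter %d: t_adapt=%.3g baseline drift %.4g/cycle",
                 iteration, t, drift)
        if abs(drift) <= config.drift_tolerance:
            trace.t_adapt_history = history
            return round(t, 10), trace, history
        t = round(t + config.refine_step, 10)
    raise RefinementError(history)
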