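"""Synthetic speckle videos with analytically known displacement fields.

Every downstream stage of the pipeline is testable against exact ground
truth by warping a speckle texture with closed-form displacement fields:
uniform shifts, sinusoidal deformation ramps (the classic planar DIC
benchmark geometry), and trains of spatially localised contraction pulses
emulating spontaneously beating cardiomyocyte monolayers, optionally with
slow inter-cycle drift of the whole field of view.

The beating pulse superposes two Gaussian-localised components per
origin, modulated in time by a raised-cosine envelope clipped at zero
(``env(t) = max(0, cos(2 pi f t + phase))^2``) so genuine rest frames
exist between beats:

* a translation bump ``A_t * exp(-r^2 / (2 sigma^2))`` along a per-origin
  direction — the bulk tug of the contracting patch on its surroundings,
  which makes the displacement maximum blob-like as in real tissue
  recordings;
* a radial inward pull ``-A_r * (r/sigma) * exp(1/2 - r^2/(2 sigma^2))
  * r_hat`` (zero at the centre, peak ``A_r`` on the ring ``r = sigma``)
  whose negative divergence produces compressive strain at the centre
  with tensile lobes outside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .io import DEFAULT_PIXEL_SIZE_UM, ImageStack
from . import piv as _piv

__all__ = [
    "SpeckleSpec",
    "PulseOrigin",
    "MotionSpec",
    "GroundTruth",
    "make_speckle",
    "warp_frame",
    "beating_sequence",
    "dic_challenge_pair",
    "preset_beating",
    "preset_refinement",
    "preset_dic_challenge",
]

REST_ENVELOPE_TOL = 0.01  # envelope fraction below which a frame counts as rest


@dataclass(frozen=True)
class SpeckleSpec:
    """Random speckle texture: Gaussian blobs on a dark background."""

    shape_px: tuple[int, int] = (256, 256)
    speckle_density: float = 12.0  # particles per 100 px^2
    speckle_radius_px: float = 1.0  # Gaussian blob sigma
    intensity_noise_sd: float = 0.0  # additive noise, fraction of dynamic range
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.shape_px) <= 0:
            raise ValueError("shape_px must be strictly positive")
        if self.speckle_density < 0:
            raise ValueError("speckle_density must be >= 0")


@dataclass(frozen=True)
class PulseOrigin:
    """One contraction origin of a pulse train."""

    x_px: float
    y_px: float
    amplitude_px: float  # peak of the translation bump, px
    sigma_px: float
    frequency_hz: float
    phase_rad: float = math.pi  # default: frame 0 is a rest frame
    onset_s: float = 0.0  # envelope gated to zero before this time
    contraction_px: float | None = None  # radial peak; default amplitude/2
    direction_rad: float = 0.0  # translation direction

    @property
    def radial_px(self) -> float:
        return (self.amplitude_px / 2.0 if self.contraction_px is None
                else self.contraction_px)


@dataclass(frozen=True)
class MotionSpec:
    """Analytic motion model for a synthetic sequence."""

    kind: str  # uniform_shift | sinusoidal | pulse_train
    n_frames: int = 2
    fps: float = 5.0
    origins: tuple[PulseOrigin, ...] = ()
    shift_px: tuple[float, float] = (0.0, 0.0)
    amplitude_px: float = 0.0  # sinusoidal amplitude
    wavelength_px: float = 256.0
    drift_px_per_frame: tuple[float, float] = (0.0, 0.0)
    drift_mode: str = "per_frame"  # per_frame | per_cycle
    drift_profile: str = "uniform"  # uniform | linear_x
    drift_scale_px: float = 0.0  # length scale of the linear_x profile
    drift_offset_cycles: float = 0.0  # baseline offset applied to every frame

    def __post_init__(self) -> None:
        if self.kind not in ("uniform_shift", "sinusoidal", "pulse_train"):
            raise ValueError(f"unknown motion kind {self.kind!r}")
        if self.drift_mode not in ("per_frame", "per_cycle"):
            raise ValueError("drift_mode must be per_frame or per_cycle")
        if self.drift_profile not in ("uniform", "linear_x"):
            raise ValueError("drift_profile must be uniform or linear_x")
        for o in self.origins:
            if not np.isfinite(o.amplitude_px):
                raise ValueError("amplitude must be finite")
            if o.frequency_hz >= self.fps / 2:
                raise ValueError(
                    f"origin frequency {o.frequency_hz} Hz violates Nyquist "
                    f"at {self.fps} FPS"
                )

    # -- temporal envelopes -------------------------------------------------

    def envelope(self, origin: PulseOrigin, t_s) -> np.ndarray:
        """Raised-cosine beat envelope in [0, 1], clipped at zero."""
        t = np.asarray(t_s, dtype=float)
        c = np.cos(2 * np.pi * origin.frequency_hz * t + origin.phase_rad)
        return np.where(t >= origin.onset_s, np.clip(c, 0.0, None) ** 2, 0.0)

    def _drift_at(self, frame_index: int) -> tuple[float, float]:
        dx, dy = self.drift_px_per_frame
        if self.drift_mode == "per_frame":
            k = float(frame_index)
        else:
            if not self.origins:
                k = 0.0
            else:
                f0 = self.origins[0].frequency_hz
                k = float(np.floor(frame_index * f0 / self.fps))
        k += self.drift_offset_cycles
        return dx * k, dy * k

    def displacement(self, frame_index: int, x: np.ndarray, y: np.ndarray):
        """Exact displacement (u, v) in px of ``frame_index`` vs frame 0."""
        x = np.asarray(x, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        t = frame_index / self.fps
        u = np.zeros_like(x)
        v = np.zeros_like(y)
        if self.kind == "uniform_shift":
            u += self.shift_px[0] * (frame_index > 0)
            v += self.shift_px[1] * (frame_index > 0)
        elif self.kind == "sinusoidal":
            u += self.amplitude_px * np.sin(2 * np.pi * x / self.wavelength_px)
        elif self.kind == "pulse_train":
            for o in self.origins:
                env = float(self.envelope(o, t))
                if env < 1e-12:
                    continue
                dx = x - o.x_px
                dy = y - o.y_px
                g = np.exp(-(dx**2 + dy**2) / (2 * o.sigma_px**2))
                u += env * o.amplitude_px * math.cos(o.direction_rad) * g
                v += env * o.amplitude_px * math.sin(o.direction_rad) * g
                scale = -o.radial_px * env * math.exp(0.5) / o.sigma_px
                u += scale * dx * g
                v += scale * dy * g
        ddx, ddy = self._drift_at(frame_index)
        if self.drift_profile == "linear_x" and self.drift_scale_px > 0:
            g = 0.5 + x / self.drift_scale_px
            return u + ddx * g, v + ddy * g
        return u + ddx, v + ddy


@dataclass
class GroundTruth:
    """Exact displacement truth for a synthetic sequence.

    ``u_grid``/``v_grid`` hold the analytic field sampled on the PIV grid
    for every frame; dense full-resolution fields are available through
    :meth:`displacement`.
    """

    motion: MotionSpec
    grid_x: np.ndarray
    grid_y: np.ndarray
    u_grid: np.ndarray  # (n_frames, ny, nx)
    v_grid: np.ndarray
    origin_envelopes: np.ndarray  # (n_origins, n_frames), fraction of amplitude
    rest_frames: np.ndarray  # bool, pulse envelopes all below REST_ENVELOPE_TOL
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    @property
    def magnitude_grid(self) -> np.ndarray:
        return np.hypot(self.u_grid, self.v_grid)

    def displacement(self, frame_index: int, x, y):
        return self.motion.displacement(frame_index, x, y)

    def contraction_mask(self, frame_index: int, threshold_um: float) -> np.ndarray:
        """Thresholding the truth field — exact by construction."""
        mag_um = self.magnitude_grid[frame_index] * self.pixel_size_um
        return mag_um > threshold_um

    def to_frame(self):
        """Long-format table (frame, grid_x, grid_y, u_px, v_px)."""
        import pandas as pd

        n = self.u_grid.shape[0]
        gx, gy = np.meshgrid(self.grid_x, self.grid_y)
        rows = [
            pd.DataFrame(
                {
                    "frame": k,
                    "grid_x": gx.ravel(),
                    "grid_y": gy.ravel(),
                    "u_px": self.u_grid[k].ravel(),
                    "v_px": self.v_grid[k].ravel(),
                }
            )
            for k in range(n)
        ]
        return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# image synthesis


def make_speckle(spec: SpeckleSpec) -> np.ndarray:
    """Render the speckle texture; deterministic for a given seed."""
    rows, cols = spec.shape_px
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.speckle_density * rows * cols / 100.0))
    img = np.zeros((rows, cols), dtype=np.float64)
    if n > 0:
        ys = rng.uniform(0, rows - 1, n)
        xs = rng.uniform(0, cols - 1, n)
        amps = rng.uniform(0.5, 1.0, n)
        # bilinear scatter of sub-pixel impulses, then Gaussian blur
        y0 = np.floor(ys).astype(int)
        x0 = np.floor(xs).astype(int)
        fy = ys - y0
        fx = xs - x0
        for dy, dx, wgt in (
            (0, 0, (1 - fy) * (1 - fx)),
            (0, 1, (1 - fy) * fx),
            (1, 0, fy * (1 - fx)),
            (1, 1, fy * fx),
        ):
            np.add.at(
                img,
                (np.clip(y0 + dy, 0, rows - 1), np.clip(x0 + dx, 0, cols - 1)),
                amps * wgt,
            )
        img = gaussian_filter(img, spec.speckle_radius_px, mode="constant")
        peak = img.max()
        if peak > 0:
            img = img / peak
    if spec.intensity_noise_sd > 0:
        img = img + rng.normal(0.0, spec.intensity_noise_sd, img.shape)
    return np.clip(img, 0.0, 1.0)


def warp_frame(image: np.ndarray, displacement_fn, method: str = "bicubic"):
    """Warp ``image`` by a displacement field: out(x) = in(x - d(x)).

    ``displacement_fn(x, y) -> (u, v)`` must return finite values at every
    pixel.  ``method`` is ``"bicubic"`` (spline interpolation) or
    ``"spectral"`` (Fourier 4x upsampling followed by linear sampling),
    the latter mirroring how the classic sinusoidal DIC benchmark images
    were produced.
    """
    image = np.asarray(image, dtype=np.float64)
    rows, cols = image.shape
    yy, xx = np.mgrid[0:rows, 0:cols].astype(np.float64)
    u, v = displacement_fn(xx, yy)
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if not (np.isfinite(u).all() and np.isfinite(v).all()):
        raise ValueError("displacement field contains non-finite values")
    if method == "bicubic":
        return map_coordinates(image, [yy - v, xx - u], order=3, mode="mirror")
    if method == "spectral":
        up = 4
        fine = _fourier_upsample(image, up)
        coords = [(yy - v) * up, (xx - u) * up]
        return map_coordinates(fine, coords, order=1, mode="mirror")
    raise ValueError(f"unknown warp method {method!r}")


def _fourier_upsample(image: np.ndarray, factor: int) -> np.ndarray:
    rows, cols = image.shape
    f = np.fft.fftshift(np.fft.fft2(image))
    big = np.zeros((rows * factor, cols * factor), dtype=complex)
    r0 = (rows * factor - rows) // 2
    c0 = (cols * factor - cols) // 2
    big[r0 : r0 + rows, c0 : c0 + cols] = f
    out = np.fft.ifft2(np.fft.ifftshift(big)) * factor**2
    return out.real


def beating_sequence(
    speckle: SpeckleSpec,
    motion: MotionSpec,
    schedule=None,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> tuple[ImageStack, GroundTruth]:
    """Synthesize a beating-tissue video plus exact ground truth.

    Every frame is warped directly from the (noise-free) base speckle by
    the total analytic displacement, so no interpolation error accumulates
    over time; per-frame sensor noise is added afterwards.
    """
    if motion.kind != "pulse_train":
        raise ValueError("beating_sequence requires a pulse_train motion")
    base = make_speckle(replace(speckle, intensity_noise_sd=0.0))
    rng = np.random.default_rng(np.random.SeedSequence([speckle.seed, 0xBEA7]))
    gx, gy = _piv.final_grid(speckle.shape_px, schedule)
    gxx, gyy = np.meshgrid(gx.astype(float), gy.astype(float))

    frames = np.empty((motion.n_frames,) + tuple(speckle.shape_px))
    u_grid = np.empty((motion.n_frames, len(gy), len(gx)))
    v_grid = np.empty_like(u_grid)
    u0, v0 = motion.displacement(0, gxx, gyy)
    frame0_moves = bool(np.abs(u0).max() > 0 or np.abs(v0).max() > 0)
    for k in range(motion.n_frames):
        if k == 0 and not frame0_moves:
            frames[0] = base
        else:
            frames[k] = warp_frame(base, lambda x, y: motion.displacement(k, x, y))
        if speckle.intensity_noise_sd > 0:
            frames[k] = np.clip(
                frames[k] + rng.normal(0, speckle.intensity_noise_sd, base.shape),
                0.0,
                1.0,
            )
        # ground truth is displacement relative to frame 0
        uk, vk = motion.displacement(k, gxx, gyy)
        u_grid[k] = uk - u0
        v_grid[k] = vk - v0
    u_grid[0] = 0.0
    v_grid[0] = 0.0

    t = np.arange(motion.n_frames) / motion.fps
    if motion.origins:
        envs = np.stack([motion.envelope(o, t) for o in motion.origins])
    else:
        envs = np.zeros((0, motion.n_frames))
    rest = (
        np.all(envs < REST_ENVELOPE_TOL, axis=0)
        if envs.size
        else np.ones(motion.n_frames, dtype=bool)
    )
    stack = ImageStack(frames, fps=motion.fps, pixel_size_um=pixel_size_um,
                       source="synthetic:pulse_train")
    truth = GroundTruth(motion, gx, gy, u_grid, v_grid, envs, rest,
                        pixel_size_um=pixel_size_um)
    return stack, truth


def dic_challenge_pair(
    amplitude_px: float = 2.0,
    wavelength_schedule=((256, 256),),
    shape_px: tuple[int, int] = (256, 768),
    noise_sd: float = 0.0,
    resolvable_min_wavelength_px: float = 128.0,
    speckle: SpeckleSpec | None = None,
    seed: int = 0,
):
    """Reference/deformed pair with a known sinusoidal deformation.

    ``wavelength_schedule`` is a sequence of ``(band_width_px, wavelength_px)``
    strips along x; the phase accumulates continuously across strips so the
    displacement stays smooth while the strain gradient increases.  Bands
    with wavelength below ``resolvable_min_wavelength_px`` are deliberately
    allowed — they mark the unresolvable region of the benchmark.

    Returns ``(ref_image, def_image, truth)`` where ``truth`` carries the
    dense displacement evaluator and the resolvable-region mask.
    """
    if speckle is None:
        speckle = SpeckleSpec(shape_px=shape_px, intensity_noise_sd=0.0, seed=seed)
    rows, cols = speckle.shape_px
    xs = np.arange(cols, dtype=np.float64)
    lam = np.empty(cols)
    pos = 0
    for width, wl in wavelength_schedule:
        lam[pos : pos + int(width)] = float(wl)
        pos += int(width)
    if pos < cols:
        lam[pos:] = wavelength_schedule[-1][1]
    phase = np.concatenate([[0.0], np.cumsum(2 * np.pi / lam)])[:cols]
    u_profile = amplitude_px * np.sin(phase)
    resolvable = lam >= resolvable_min_wavelength_px

    def disp(x, y):
        xi = np.clip(np.rint(x).astype(int), 0, cols - 1)
        return u_profile[xi], np.zeros_like(np.asarray(y, float))

    ref = make_speckle(replace(speckle, intensity_noise_sd=0.0))
    deformed = warp_frame(ref, disp)
    if noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD1C]))
        ref = np.clip(ref + rng.normal(0, noise_sd, ref.shape), 0, 1)
        deformed = np.clip(deformed + rng.normal(0, noise_sd, ref.shape), 0, 1)

    motion = MotionSpec(kind="sinusoidal", n_frames=2, amplitude_px=amplitude_px)
    gx, gy = _piv.final_grid(speckle.shape_px)
    gxx, gyy = np.meshgrid(gx.astype(float), gy.astype(float))
    u1, v1 = disp(gxx, gyy)
    u_grid = np.stack([np.zeros_like(u1), u1])
    v_grid = np.stack([np.zeros_like(v1), v1])
    truth = GroundTruth(
        motion,
        gx,
        gy,
        u_grid,
        v_grid,
        origin_envelopes=np.zeros((0, 2)),
        rest_frames=np.array([True, False]),
    )
    truth.resolvable_profile = resolvable  # type: ignore[attr-defined]
    truth.resolvable_grid = resolvable[gx]  # type: ignore[attr-defined]
    truth.displacement_fn = disp  # type: ignore[attr-defined]
    return ref, deformed, truth


# ---------------------------------------------------------------------------
# bundled presets (the study conditions of the synthetic experiments)


def _origin_layout(n_origins: int, shape_px) -> list[tuple[float, float]]:
    rows, cols = shape_px
    # fractions chosen so centres fall between vector-grid points: a pulse
    # centre exactly on a grid point would leave a one-cell hole in the
    # supra-threshold annulus (the radial field vanishes at its centre)
    layouts = {
        1: [(0.547, 0.5)],
        2: [(0.266, 0.5), (0.734, 0.5)],
        3: [(0.266, 0.266), (0.734, 0.266), (0.5, 0.766)],
    }
    if n_origins not in layouts:
        raise ValueError("presets support 1-3 origins")
    return [(fx * cols, fy * rows) for fx, fy in layouts[n_origins]]


def preset_beating(
    n_origins: int = 1,
    shape_px: tuple[int, int] = (256, 256),
    duration_s: float = 8.0,
    fps: float = 5.0,
    frequency_hz: float = 1.25,
    amplitude_px: float = 3.0,
    sigma_px: float = 64.0,
    noise_sd: float = 0.01,
    drift_px_per_cycle: float = 0.0,
    onset_stagger_frames: float = 0.0,
    seed: int = 0,
    schedule=None,
):
    """Beating-monolayer fixture: localized pulses, optional slow drift.

    Defaults follow the reference acquisition: 5 FPS, 1.25 Hz beating
    (75 BPM), peak displacement of a few px (~3 um).  ``drift_px_per_cycle``
    adds a continuous horizontal translation emulating the minor frame
    shifts left after each contraction cycle.  ``onset_stagger_frames``
    delays successive origins' beats by that many frames each.
    """
    centres = _origin_layout(n_origins, shape_px)
    origins = []
    for i, (cx, cy) in enumerate(centres):
        delay_s = i * onset_stagger_frames / fps
        origins.append(
            PulseOrigin(
                x_px=cx,
                y_px=cy,
                amplitude_px=amplitude_px,
                sigma_px=sigma_px,
                frequency_hz=frequency_hz,
                phase_rad=math.pi - 2 * math.pi * frequency_hz * delay_s,
                onset_s=delay_s,
                direction_rad=2 * math.pi * i / max(len(centres), 1),
            )
        )
    frames_per_cycle = fps / frequency_hz
    motion = MotionSpec(
        kind="pulse_train",
        n_frames=int(round(duration_s * fps)) + 1,
        fps=fps,
        origins=tuple(origins),
        drift_px_per_frame=(drift_px_per_cycle / frames_per_cycle, 0.0),
        drift_mode="per_frame",
    )
    speckle = SpeckleSpec(shape_px=shape_px, intensity_noise_sd=noise_sd, seed=seed)
    return beating_sequence(speckle, motion, schedule=schedule)


#: PIV response of a uniform sub-pixel shift, measured once on the default
#: speckle/schedule during development; converts a requested rest-to-rest
#: Frobenius norm into the per-vector shift that produces it.
UNIFORM_SHIFT_RESPONSE = 1.0105


def preset_refinement(
    target_rest_norm: float = 1.45,
    shape_px: tuple[int, int] = (256, 256),
    n_cycles: int = 8,
    fps: float = 5.0,
    frequency_hz: float = 1.25,
    amplitude_px: float = 3.0,
    sigma_px: float = 64.0,
    noise_sd: float = 0.003,
    seed: int = 0,
    schedule=None,
):
    """Fixture for adaptive-threshold refinement.

    Inter-cycle frame shifts are modelled as a per-cycle step translation
    sized so the Frobenius norm between rest frames of consecutive cycles
    is ``target_rest_norm`` (the latent displacement the adaptive threshold
    must clear), while rest frames within one cycle differ only by sensor
    noise.
    """
    gx, gy = _piv.final_grid(shape_px, schedule)
    # the inter-cycle shift is graded linearly across x so per-vector
    # sub-pixel phases span a full cycle and estimator biases average out
    cols = shape_px[1]
    g = 0.5 + gx.astype(float) / cols
    sum_g2 = len(gy) * float((g**2).sum())
    step = target_rest_norm / (math.sqrt(sum_g2) * UNIFORM_SHIFT_RESPONSE)
    frames_per_cycle = fps / frequency_hz
    (cx, cy), = _origin_layout(1, shape_px)
    motion = MotionSpec(
        kind="pulse_train",
        n_frames=int(round(n_cycles * frames_per_cycle)) + 1,
        fps=fps,
        origins=(
            PulseOrigin(cx, cy, amplitude_px, sigma_px, frequency_hz),
        ),
        drift_px_per_frame=(step, 0.0),
        drift_mode="per_cycle",
        drift_profile="linear_x",
        drift_scale_px=float(cols),
        drift_offset_cycles=3.0,
    )
    speckle = SpeckleSpec(shape_px=shape_px, intensity_noise_sd=noise_sd, seed=seed)
    return beating_sequence(speckle, motion, schedule=schedule)


def preset_dic_challenge(seed: int = 0, noise_sd: float = 0.0):
    """Sinusoidal-deformation pair: A = 2 px, wavelength 256 px."""
    return dic_challenge_pair(
        amplitude_px=2.0,
        wavelength_schedule=((768, 256),),
        shape_px=(256, 768),
        noise_sd=noise_sd,
        seed=seed,
    )
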