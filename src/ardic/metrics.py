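"""Physiology-based contraction metrics.

A grid point is "contracting" when its displacement magnitude exceeds the
average in vivo sarcomere shortening of one sarcomere, 0.14 um (stricter
multiples, e.g. four sarcomeres = 0.56 um, are supported as alternate
thresholds).  From the per-frame masks follow beating area and coverage,
the beating rate (FFT of the displacement signal, verified by a peak
counter), the contraction volume (area x magnitude, normalised by the
vector block size), frequency/magnitude heat maps, and the high/low
contraction-volume group comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy import stats

from .piv import DisplacementField

__all__ = [
    "SARCOMERE_UM",
    "NORM_BLOCK_AREA_UM2",
    "ContractionCriteria",
    "BpmEstimate",
    "contraction_mask",
    "beating_area",
    "displacement_signal",
    "bpm_fft",
    "bpm_peaks",
    "contraction_volume",
    "cv_series",
    "cv_split",
    "heatmaps",
    "compare_cv_groups",
]

#: Average in vivo shortening of a single sarcomere, um.
SARCOMERE_UM = 0.14
#: Area of one 24 px DIC vector block, um^2, used to normalise CV.
NORM_BLOCK_AREA_UM2 = 532.6
#: Minimum spectral peak prominence (peak power / median band power) below
#: which an FFT beating-rate estimate is flagged unreliable.  Set from
#: simulated white-noise signals, which stay well under this value, while
#: clean pulse trains exceed it by orders of magnitude.
MIN_SPECTRAL_PROMINENCE = 50.0


@dataclass(frozen=True)
class ContractionCriteria:
    """Thresholds defining spontaneous beating."""

    threshold_um: float = SARCOMERE_UM
    alt_thresholds_um: tuple[float, ...] = (4 * SARCOMERE_UM,)
    min_region_area_um2: float = 4840.0  # "10 DIC vector units"

    def __post_init__(self) -> None:
        if self.threshold_um <= 0 or any(t <= 0 for t in self.alt_thresholds_um):
            raise ValueError("thresholds must be positive")


@dataclass
class BpmEstimate:
    """Beating rate estimate; ``bpm`` is None when no beat is detectable."""

    bpm: float | None
    method: str
    prominence: float = float("nan")
    reliable: bool = True


def contraction_mask(
    field: DisplacementField,
    pixel_size_um: float,
    threshold_um: float = SARCOMERE_UM,
) -> np.ndarray:
    """Boolean grid mask of supra-threshold displacement (invalid excluded)."""
    return field.valid & (field.magnitude * pixel_size_um > threshold_um)


def beating_area(
    mask: np.ndarray,
    block_area_um2: float,
    n_valid: int | None = None,
) -> tuple[float, float]:
    """(area_um2, coverage_pct) of a contraction mask.

    Coverage is relative to the number of valid grid points (border
    windows carry no measurement), or to the full grid when ``n_valid``
    is omitted.
    """
    count = int(np.count_nonzero(mask))
    total = int(n_valid) if n_valid is not None else int(mask.size)
    coverage = 100.0 * count / total if total else 0.0
    return count * block_area_um2, coverage


def displacement_signal(
    fields,
    pixel_size_um: float,
    threshold_um: float = SARCOMERE_UM,
) -> np.ndarray:
    """Per-frame displacement signal driving the BPM estimate.

    Mean |d| (um) over the grid points that exceed the contraction
    threshold at least once in the video; an empty active set yields an
    all-NaN signal (no beating area).
    """
    mags = np.stack([f.magnitude_um(pixel_size_um) for f in fields])
    valid = np.stack([f.valid for f in fields])
    mags = np.where(valid, mags, 0.0)
    ever = (mags > threshold_um).any(axis=0)
    if not ever.any():
        return np.full(len(fields), np.nan)
    return mags[:, ever].mean(axis=1)


def bpm_fft(sig: np.ndarray, fps: float, f_min_hz: float = 0.2,
            nyquist_guard: float = 0.95) -> BpmEstimate:
    """Beating rate from the FFT of the displacement signal.

    Mean-detrended, Hann-windowed, zero-padded >= 8x; the rate is the
    frequency of maximum power in (f_min_hz, guard * fps/2) times 60.
    The guard band below Nyquist keeps aliased harmonics that fold onto
    exactly fps/2 from tying with the fundamental.  A flat or spectrally
    flat signal is reported as absent/unreliable, never as 0.
    """
    sig = np.asarray(sig, dtype=float)
    sig = sig[np.isfinite(sig)]
    if len(sig) < 8 or np.ptp(sig) == 0:
        return BpmEstimate(None, "fft", reliable=False)
    x = (sig - sig.mean()) * np.hanning(len(sig))
    nfft = 1 << int(np.ceil(np.log2(8 * len(x))))
    spec = np.abs(np.fft.rfft(x, nfft)) ** 2
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fps)
    band = (freqs > f_min_hz) & (freqs < nyquist_guard * fps / 2)
    if not band.any():
        return BpmEstimate(None, "fft", reliable=False)
    power = spec[band]
    k = int(np.argmax(power))
    prominence = float(power[k] / max(np.median(power), 1e-30))
    bpm = 60.0 * float(freqs[band][k])
    return BpmEstimate(bpm, "fft", prominence=prominence,
                       reliable=prominence >= MIN_SPECTRAL_PROMINENCE)


def bpm_peaks(sig: np.ndarray, fps: float, refractory_s: float = 0.33) -> float:
    """Beating rate from an automated peak counter.

    Counts local maxima above mean + 0.5 std separated by at least the
    refractory period (0.33 s ~ 180 BPM, below the Nyquist ceiling of a
    5 FPS acquisition).
    """
    sig = np.asarray(sig, dtype=float)
    sig = np.where(np.isfinite(sig), sig, np.nanmin(sig) if np.isfinite(sig).any() else 0.0)
    if len(sig) < 3 or np.ptp(sig) == 0:
        return 0.0
    height = sig.mean() + 0.5 * sig.std()
    distance = max(1, int(round(refractory_s * fps)))
    peaks, _ = sp_signal.find_peaks(sig, height=height, distance=distance)
    duration_s = len(sig) / fps
    return 60.0 * len(peaks) / duration_s


def contraction_volume(
    field: DisplacementField,
    mask: np.ndarray,
    pixel_size_um: float,
    block_area_um2: float = NORM_BLOCK_AREA_UM2,
    norm_area_um2: float = NORM_BLOCK_AREA_UM2,
) -> float:
    """Sum of masked displacement magnitudes weighted by block area.

    cv = sum over masked vectors of |d|_um * block_area / norm_area; with
    block area equal to the normalisation area this reduces to the plain
    sum of supra-threshold magnitudes in um.
    """
    mag_um = field.magnitude_um(pixel_size_um)
    return float(np.sum(mag_um[mask & field.valid]) * block_area_um2 / norm_area_um2)


def cv_series(
    fields,
    pixel_size_um: float,
    threshold_um: float = SARCOMERE_UM,
    block_area_um2: float = NORM_BLOCK_AREA_UM2,
    norm_area_um2: float = NORM_BLOCK_AREA_UM2,
) -> np.ndarray:
    """Contraction volume for every field in a sequence."""
    return np.array(
        [
            contraction_volume(
                f,
                contraction_mask(f, pixel_size_um, threshold_um),
                pixel_size_um,
                block_area_um2,
                norm_area_um2,
            )
            for f in fields
        ]
    )


def cv_split(cv: np.ndarray) -> tuple[np.ndarray, float]:
    """High/low CV labels: high iff cv >= max(cv) - std(cv).

    Returns (high_labels, cutoff).  Labels are invariant to uniform
    scaling of the series; a constant series is all high.
    """
    cv = np.asarray(cv, dtype=float)
    cutoff = float(cv.max() - cv.std())
    return cv >= cutoff, cutoff


def heatmaps(
    fields,
    pixel_size_um: float,
    threshold_um: float = SARCOMERE_UM,
) -> tuple[np.ndarray, np.ndarray]:
    """(frequency_map, magnitude_map) accumulated over the whole video.

    The frequency map is the mean of the per-frame binary contraction
    masks (fraction of frames each point contracts, in [0, 1]); the
    magnitude map is the mean displacement magnitude in um.  Both are pure
    accumulations, invariant to frame order.
    """
    masks = np.stack(
        [contraction_mask(f, pixel_size_um, threshold_um) for f in fields]
    )
    mags = np.stack(
        [np.where(f.valid, f.magnitude_um(pixel_size_um), 0.0) for f in fields]
    )
    return masks.mean(axis=0), mags.mean(axis=0)


def compare_cv_groups(
    max_speed: np.ndarray,
    max_tensile: np.ndarray,
    max_compressive: np.ndarray,
    high: np.ndarray,
) -> pd.DataFrame:
    """Welch comparison of per-frame maxima between high- and low-CV frames.

    ``max_compressive`` holds the (negative) extreme principal strain per
    frame.  Returns mean, SEM, n per group and the Welch two-sample
    p-value per quantity.
    """
    high = np.asarray(high, dtype=bool)
    rows = []
    for name, series in (
        ("max_speed_um_s", np.asarray(max_speed, float)),
        ("max_tensile_strain", np.asarray(max_tensile, float)),
        ("max_compressive_strain", np.asarray(max_compressive, float)),
    ):
        a = series[high]
        b = series[~high]
        if len(a) > 1 and len(b) > 1 and (np.ptp(a) > 0 or np.ptp(b) > 0):
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        else:
            p = float("nan")
        for label, grp in (("high", a), ("low", b)):
            rows.append(
                {
                    "quantity": name,
                    "group": label,
                    "n": len(grp),
                    "mean": float(grp.mean()) if len(grp) else float("nan"),
                    "sem": float(grp.std(ddof=1) / np.sqrt(len(grp)))
                    if len(grp) > 1
                    else float("nan"),
                    "welch_p": p,
                }
            )
    return pd.DataFrame(rows)
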