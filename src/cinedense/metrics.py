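"""Image-quality metrics for DENSE series.

Covers the four quantities used to compare encoding frequencies:

* **Rician-corrected SNR** — MR magnitude noise in a signal-free background is
  Rayleigh distributed, so the underlying complex-noise SD is
  ``sigma = sqrt(2 / (4 - pi)) * sigma_M ~= 1.526 * sigma_M`` and the true
  signal is ``S = sqrt(M^2 - sigma^2)``; SNR = S / sigma.
* **Wrap fraction** — per axis, the maximum over frames of the percentage of
  wrapped pixels inside the myocardial segmentation; reported as the mean of
  the x and y maxima (which may occur at different frames).
* **Blood-pool dephasing curve** — mean blood magnitude per frame as a
  percentage of the first cardiac phase, with the fifth-frame value as the
  early-systole summary.
* **Stationary phase-noise RMSE** — root-mean-square phase (radians) of a
  stationary series per axis; converted to a 2D displacement RMSE (mm) by
  dividing by ``2 pi k_e`` per axis and adding the axes by vector addition.
  In the small-noise regime the radian RMSE is ~ 1/SNR, independent of k_e.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .encode import DenseSeries
from .unwrap import Segmentation

__all__ = [
    "RICIAN_FACTOR",
    "NoiseCharacterization",
    "rician_correct",
    "snr_series",
    "wrap_fraction",
    "blood_curve",
    "phase_rmse",
    "corner_background_roi",
]

#: sigma = RICIAN_FACTOR * sigma_M for Rayleigh-distributed background magnitude
RICIAN_FACTOR = float(np.sqrt(2.0 / (4.0 - np.pi)))


@dataclass
class NoiseCharacterization:
    """Noise summary of a stationary series.

    ``rmse_x_rad`` / ``rmse_y_rad`` are per-axis phase RMSEs about zero truth;
    ``rmse_2d_mm = sqrt((rmse_x/(2 pi ke))^2 + (rmse_y/(2 pi ke))^2)``.
    """

    snr_per_frame: np.ndarray
    sigma_measured: float
    sigma_true: float
    signal_measured: float
    signal_true: float
    rmse_x_rad: float
    rmse_y_rad: float
    rmse_2d_mm: float
    ke_cycles_per_mm: float

    @property
    def snr(self) -> float:
        return float(np.mean(self.snr_per_frame))


def rician_correct(m: float, sigma_m: float) -> tuple[float, float, float]:
    """Correct measured signal and noise for Rician magnitude statistics.

    Parameters are the mean measured magnitude ``m`` in a tissue ROI and the
    magnitude SD ``sigma_m`` in a signal-free background ROI.  Returns
    ``(S, sigma, SNR)``.  If ``m`` falls below the corrected noise level the
    signal is clamped to zero with a warning (noise-only region).
    """
    if m < 0:
        raise ValueError("m must be >= 0")
    if sigma_m <= 0:
        raise ValueError("sigma_m must be > 0")
    sigma = RICIAN_FACTOR * sigma_m
    if m**2 < sigma**2:
        warnings.warn("measured signal below noise floor; clamping S to 0", stacklevel=2)
        s = 0.0
    else:
        s = float(np.sqrt(m**2 - sigma**2))
    return s, sigma, s / sigma


def corner_background_roi(shape: tuple[int, int], size: int = 16) -> np.ndarray:
    """Signal-free ROI: four ``size`` x ``size`` corner squares of the image."""
    roi = np.zeros(shape, dtype=bool)
    roi[:size, :size] = roi[:size, -size:] = True
    roi[-size:, :size] = roi[-size:, -size:] = True
    return roi


def snr_series(
    series: DenseSeries, myo_masks: np.ndarray, background_roi: np.ndarray
) -> np.ndarray:
    """Per-frame Rician-corrected myocardial SNR.

    Per frame: ``M`` = mean magnitude in the myocardial mask, ``sigma_M`` =
    SD of magnitude in the (tissue-free) background ROI.
    """
    if not background_roi.any():
        raise ValueError("empty background ROI")
    if (background_roi[None] & myo_masks).any():
        raise ValueError("background ROI overlaps the myocardium")
    out = np.full(series.n_frames, np.nan)
    for t in range(series.n_frames):
        mask = myo_masks[t]
        if not mask.any():
            continue
        m = float(series.magnitude[t][mask].mean())
        sigma_m = float(series.magnitude[t][background_roi].std(ddof=1))
        if sigma_m == 0.0:
            raise ZeroDivisionError("noise-free series: background SD is zero")
        out[t] = rician_correct(m, sigma_m)[2]
    return out


def wrap_fraction(wrapped_maps: np.ndarray, seg: Segmentation) -> float:
    """Wrap-fraction summary (%) from per-frame per-axis wrapped-pixel maps.

    For x and y independently, take the maximum over frames of the percentage
    of wrapped pixels within the segmentation, then average the two maxima.
    """
    n_frames = wrapped_maps.shape[0]
    counts = seg.myo_masks.reshape(n_frames, -1).sum(axis=1)
    if not counts.any():
        raise ValueError("empty segmentation")
    maxima = []
    for ax in range(2):
        pct = np.zeros(n_frames)
        nz = counts > 0
        wrapped_in_mask = (wrapped_maps[:, ax] & seg.myo_masks).reshape(n_frames, -1)
        pct[nz] = 100.0 * wrapped_in_mask.sum(axis=1)[nz] / counts[nz]
        maxima.append(pct.max())
    return float(np.mean(maxima))


def blood_curve(
    series: DenseSeries, blood_masks: np.ndarray, report_frame: int = 5
) -> tuple[np.ndarray, float]:
    """Blood-pool signal per frame as % of the first cardiac phase.

    Returns the full curve and the value at ``report_frame`` (1-based; the
    default fifth frame corresponds to ~85 ms into the cycle at 17 ms/frame).
    """
    means = np.array(
        [
            series.magnitude[t][blood_masks[t]].mean() if blood_masks[t].any() else np.nan
            for t in range(series.n_frames)
        ]
    )
    if not np.isfinite(means[0]) or means[0] == 0:
        raise ValueError("no blood signal at the first cardiac phase")
    curve = 100.0 * means / means[0]
    return curve, float(curve[report_frame - 1])


def phase_rmse(stationary_series: DenseSeries, mask: np.ndarray | None = None) -> NoiseCharacterization:
    """Phase-noise characterization of a stationary (zero-truth) series.

    RMSE per axis is the root-mean-square of the phase over the phantom mask
    and all frames (truth is identically zero for a stationary phantom, so no
    reference subtraction is needed).  The caller is responsible for passing
    a genuinely stationary series.
    """
    n_frames = stationary_series.n_frames
    if mask is None:
        mask = stationary_series.magnitude[0] > 0.5 * stationary_series.magnitude[0].max()
    masks = np.repeat(mask[None], n_frames, axis=0)

    ke = stationary_series.encoding.ke_cycles_per_mm
    rmse = []
    for ph in (stationary_series.phase_x, stationary_series.phase_y):
        vals = ph[masks]
        rmse.append(float(np.sqrt(np.mean(vals**2))))
    rmse_x, rmse_y = rmse
    rmse_2d = float(np.hypot(rmse_x / (2 * np.pi * ke), rmse_y / (2 * np.pi * ke)))

    roi = corner_background_roi(stationary_series.shape)
    m = float(np.mean([stationary_series.magnitude[t][mask].mean() for t in range(n_frames)]))
    sigma_m = float(
        np.mean([stationary_series.magnitude[t][roi].std(ddof=1) for t in range(n_frames)])
    )
    if sigma_m > 0:
        snr_pf = snr_series(stationary_series, masks, roi)
        s, sigma, _ = rician_correct(m, sigma_m)
    else:
        snr_pf = np.full(n_frames, np.inf)
        s, sigma = m, 0.0
    return NoiseCharacterization(
        snr_per_frame=snr_pf,
        sigma_measured=sigma_m,
        sigma_true=sigma,
        signal_measured=m,
        signal_true=s,
        rmse_x_rad=rmse_x,
        rmse_y_rad=rmse_y,
        rmse_2d_mm=rmse_2d,
        ke_cycles_per_mm=ke,
    )
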