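"""Analytic deforming left-ventricle phantom with closed-form ground truth.

The phantom is a short-axis annulus (endocardium to epicardium) that contracts,
thickens and twists through a simulated cardiac cycle.  The deformation is an
incompressible (area-preserving) mapping in polar coordinates about the grid
centre,

    (R, Theta)  ->  ( r(R, t), Theta + alpha(R, t) ),
    r(R, t)^2 = R^2 + c(t),

so every kinematic quantity -- trajectories, Eulerian displacement maps, the
Lagrangian finite strain tensor, and rotation about the centroid -- has a
closed form.  This makes the phantom a ground-truth oracle for the whole
encode / unwrap / mechanics pipeline.

``c(t)`` is chosen so that the area-averaged circumferential Lagrangian strain
over the wall equals ``activation(t) * peak_ecc``: with the effective mid-wall
radius ``R_eff^2 = (R_epi^2 - R_endo^2) / (2 ln(R_epi/R_endo))`` (the inverse
of the area mean of 1/R^2),

    c(t) = (lambda^2 - 1) * R_eff^2,   lambda = sqrt(2 * a(t) * peak_ecc + 1),

which is the circumferential stretch prescribed at the effective mid-wall.
The rotation is ``alpha(R, t) = a(t) * (peak_twist + grad * (R - R_mid))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import io

import numpy as np
import pandas as pd

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "build_phantom",
    "stationary_phantom",
    "activation_curve",
]

N_SEGMENTS = 6


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, deformation targets and timing of the synthetic ventricle.

    Parameters mirror a typical mid-ventricular short-axis cine acquisition:
    a 128 x 128 matrix at 2.8 x 2.8 mm^2 with ~17 ms between frames, and an
    average end-systolic frame of 20.
    """

    grid_size: int = 128
    pixel_mm: float = 2.8
    n_frames: int = 30
    frame_ms: float = 17.0
    endo_radius_mm: float = 25.0
    epi_radius_mm: float = 35.0
    peak_ecc: float = -0.20
    peak_twist_deg: float = 8.0
    twist_transmural_grad_deg_per_mm: float = 0.0
    es_frame: int = 20
    diastolic_residual: float = 0.3
    blood_decay_base: float = 0.25
    blood_decay_per_ke: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.endo_radius_mm < self.epi_radius_mm:
            raise ValueError("endo_radius_mm must be < epi_radius_mm")
        if not (-0.5 < self.peak_ecc <= 0.0):
            raise ValueError("peak_ecc must lie in (-0.5, 0]")
        if not (2 <= self.es_frame <= self.n_frames):
            raise ValueError("need n_frames >= es_frame >= 2")
        half_fov = self.grid_size * self.pixel_mm / 2.0
        if self.epi_radius_mm >= half_fov:
            raise ValueError("grid does not cover the epicardium")
        if not (0.0 <= self.diastolic_residual <= 1.0):
            raise ValueError("diastolic_residual must lie in [0, 1]")

    @property
    def effective_midwall_radius_mm(self) -> float:
        """Radius at which the prescribed circumferential stretch acts.

        Inverse of the area-averaged 1/R^2 across the wall, so the prescribed
        strain equals the area-mean circumferential strain.
        """
        ri2, ro2 = self.endo_radius_mm**2, self.epi_radius_mm**2
        return float(
            np.sqrt((ro2 - ri2) / (2.0 * np.log(self.epi_radius_mm / self.endo_radius_mm)))
        )

    @property
    def frame_times_ms(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_ms


def activation_curve(config: PhantomConfig) -> np.ndarray:
    """Smooth activation ramp a(t): 0 at frame 1, 1 at end-systole.

    Raised-cosine rise to end-systole followed by a raised-cosine partial
    relaxation toward ``diastolic_residual`` at the last frame (the acquired
    window rarely covers complete relaxation).  C1-continuous, so a 10th-order
    polynomial fit over ~30 frames represents it well.
    """
    n = config.n_frames
    es = config.es_frame - 1  # 0-based index of end-systole
    a = np.zeros(n)
    i = np.arange(n)
    rise = i <= es
    a[rise] = 0.5 * (1.0 - np.cos(np.pi * i[rise] / es))
    if es < n - 1:
        u = (i[~rise] - es) / (n - 1 - es)
        a[~rise] = 1.0 - (1.0 - config.diastolic_residual) * 0.5 * (1.0 - np.cos(np.pi * u))
    return a


@dataclass
class PhantomTruth:
    """Ground truth for one synthetic subject.

    Frames are 0-indexed in arrays; frame 0 is end-diastole (reported tables
    use 1-based frame numbers, so it is "frame 1" there).  All coordinates
    are in mm about the grid centre.

    Attributes
    ----------
    material_coords : (N, 2) end-diastolic positions of tracked tissue points.
    trajectories : (n_frames, N, 2) analytic positions of those points.
    eulerian_disp : (n_frames, 2, H, W) per-axis displacement (mm) from
        end-diastole to the current frame, evaluated at the current pixel
        position; zero outside the myocardium.
    myo_masks, blood_masks : (n_frames, H, W) boolean tissue masks.
    truth_curves : tidy table of closed-form Ecc/Err (%) and twist (deg),
        per segment and global, per frame.
    """

    config: PhantomConfig
    activation: np.ndarray
    material_coords: np.ndarray
    material_segments: np.ndarray
    trajectories: np.ndarray
    eulerian_disp: np.ndarray
    myo_masks: np.ndarray
    blood_masks: np.ndarray
    truth_curves: pd.DataFrame
    stationary: bool = False
    _peaks: dict = field(default_factory=dict, repr=False)

    @property
    def n_frames(self) -> int:
        return self.config.n_frames

    @property
    def grid_mm(self) -> tuple[np.ndarray, np.ndarray]:
        return pixel_grid_mm(self.config)

    def global_curve(self, measure: str) -> np.ndarray:
        g = self.truth_curves[self.truth_curves.segment == "global"]
        return g.sort_values("frame")[measure].to_numpy()

    def peak(self, measure: str) -> float:
        """Signed extremum of the global truth curve."""
        curve = self.global_curve(measure)
        return float(curve[np.argmax(np.abs(curve))])

    @property
    def max_displacement_mm(self) -> float:
        d = self.trajectories - self.material_coords[None, :, :]
        return float(np.max(np.hypot(d[..., 0], d[..., 1])))

    def to_truth_table(self) -> str:
        """Truth curves as delimited text (round-trips with ``pd.read_csv``)."""
        buf = io.StringIO()
        self.truth_curves.to_csv(buf, index=False)
        return buf.getvalue()


def pixel_grid_mm(config: PhantomConfig) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-centre coordinates (x, y) in mm, origin at the grid centre."""
    n = config.grid_size
    coords = (np.arange(n) - (n - 1) / 2.0) * config.pixel_mm
    x, y = np.meshgrid(coords, coords, indexing="xy")
    return x, y


def _area_coefficient(config: PhantomConfig, a: np.ndarray) -> np.ndarray:
    lam2 = 2.0 * a * config.peak_ecc + 1.0
    return (lam2 - 1.0) * config.effective_midwall_radius_mm**2


def _twist_rad(config: PhantomConfig, a: np.ndarray, radius: np.ndarray) -> np.ndarray:
    """alpha(R, t) in radians; a broadcast against radius."""
    r_mid = 0.5 * (config.endo_radius_mm + config.epi_radius_mm)
    per_point = config.peak_twist_deg + config.twist_transmural_grad_deg_per_mm * (
        radius - r_mid
    )
    return np.deg2rad(a * per_point)


def _segment_labels(angles: np.ndarray) -> np.ndarray:
    """Six 60-degree sectors, segment 1 starting at the +x axis, CCW."""
    return (np.mod(angles, 2.0 * np.pi) // (np.pi / 3.0)).astype(int) + 1


def build_phantom(config: PhantomConfig) -> PhantomTruth:
    """Build the deforming annulus and its closed-form ground truth.

    Raises
    ------
    ValueError
        If the requested shortening would evert the annulus, i.e. the
        endocardial radius would become imaginary (``R_endo^2 + c(t) <= 0``).
    """
    a = activation_curve(config)
    c = _area_coefficient(config, a)
    if np.any(config.endo_radius_mm**2 + c <= 0.0):
        raise ValueError(
            "deformation everts the annulus: peak_ecc too negative for "
            f"endo_radius_mm={config.endo_radius_mm} "
            f"(need R_endo^2 > {-c.min():.1f} mm^2)"
        )

    x, y = pixel_grid_mm(config)
    r_pix = np.hypot(x, y)
    phi_pix = np.arctan2(y, x)

    # material points: pixel centres inside the end-diastolic annulus
    ed_mask = (r_pix >= config.endo_radius_mm) & (r_pix <= config.epi_radius_mm)
    mat_x, mat_y = x[ed_mask], y[ed_mask]
    big_r = np.hypot(mat_x, mat_y)
    big_theta = np.arctan2(mat_y, mat_x)
    material_coords = np.column_stack([mat_x, mat_y])
    material_segments = _segment_labels(big_theta)

    n_frames = config.n_frames
    # analytic trajectories
    r_t = np.sqrt(big_r[None, :] ** 2 + c[:, None])  # (T, N)
    alpha_t = _twist_rad(config, a[:, None], big_r[None, :])
    theta_t = big_theta[None, :] + alpha_t
    trajectories = np.stack([r_t * np.cos(theta_t), r_t * np.sin(theta_t)], axis=-1)
    trajectories[0] = material_coords  # exact at end-diastole (a(0) = 0)

    # closed-form strain at each material point:
    #   Ecc = (r^2/R^2 - 1)/2,  Err = ((R/r)^2 + r^2 alpha'^2 - 1)/2
    alpha_prime = np.deg2rad(a[:, None] * config.twist_transmural_grad_deg_per_mm)
    ecc_pt = 0.5 * (r_t**2 / big_r[None, :] ** 2 - 1.0)
    err_pt = 0.5 * ((big_r[None, :] / r_t) ** 2 + (r_t * alpha_prime) ** 2 - 1.0)
    twist_pt = np.rad2deg(alpha_t)

    truth_curves = _aggregate_curves(ecc_pt, err_pt, twist_pt, material_segments)

    # per-frame masks and Eulerian displacement on the pixel grid
    r_endo_t = np.sqrt(config.endo_radius_mm**2 + c)
    r_epi_t = np.sqrt(config.epi_radius_mm**2 + c)
    myo_masks = (r_pix[None] >= r_endo_t[:, None, None]) & (
        r_pix[None] <= r_epi_t[:, None, None]
    )
    blood_masks = r_pix[None] < r_endo_t[:, None, None]

    eulerian = np.zeros((n_frames, 2, *r_pix.shape))
    for t in range(n_frames):
        m = myo_masks[t]
        big_r_inv = np.sqrt(r_pix[m] ** 2 - c[t])  # invert r(R)
        theta_inv = phi_pix[m] - _twist_rad(config, a[t], big_r_inv)
        eulerian[t, 0][m] = x[m] - big_r_inv * np.cos(theta_inv)
        eulerian[t, 1][m] = y[m] - big_r_inv * np.sin(theta_inv)

    return PhantomTruth(
        config=config,
        activation=a,
        material_coords=material_coords,
        material_segments=material_segments,
        trajectories=trajectories,
        eulerian_disp=eulerian,
        myo_masks=myo_masks,
        blood_masks=blood_masks,
        truth_curves=truth_curves,
    )


def _aggregate_curves(
    ecc_pt: np.ndarray,
    err_pt: np.ndarray,
    twist_pt: np.ndarray,
    segments: np.ndarray,
) -> pd.DataFrame:
    """Segment means, then the global curve as the mean of the six segments."""
    rows = []
    n_frames = ecc_pt.shape[0]
    seg_means = {}
    for meas, pt in (("ecc_pct", 100.0 * ecc_pt), ("err_pct", 100.0 * err_pt), ("twist_deg", twist_pt)):
        seg_means[meas] = np.stack(
            [pt[:, segments == s].mean(axis=1) for s in range(1, N_SEGMENTS + 1)]
        )  # (6, T)
    for t in range(n_frames):
        for s in range(1, N_SEGMENTS + 1):
            rows.append(
                {
                    "frame": t + 1,
                    "segment": str(s),
                    "ecc_pct": seg_means["ecc_pct"][s - 1, t],
                    "err_pct": seg_means["err_pct"][s - 1, t],
                    "twist_deg": seg_means["twist_deg"][s - 1, t],
                }
            )
        rows.append(
            {
                "frame": t + 1,
                "segment": "global",
                "ecc_pct": seg_means["ecc_pct"][:, t].mean(),
                "err_pct": seg_means["err_pct"][:, t].mean(),
                "twist_deg": seg_means["twist_deg"][:, t].mean(),
            }
        )
    return pd.DataFrame(rows)


def stationary_phantom(config: PhantomConfig) -> PhantomTruth:
    """Uniform-signal stationary disc for noise-floor studies.

    The disc (radius = ``epi_radius_mm``) is treated as "myocardium" for
    SNR/phase-noise measurement; there is no blood pool and no motion.
    """
    x, y = pixel_grid_mm(config)
    r_pix = np.hypot(x, y)
    disc = r_pix <= config.epi_radius_mm
    n_frames = config.n_frames

    mat_x, mat_y = x[disc], y[disc]
    material_coords = np.column_stack([mat_x, mat_y])
    material_segments = _segment_labels(np.arctan2(mat_y, mat_x))
    trajectories = np.repeat(material_coords[None, :, :], n_frames, axis=0)

    zeros_pt = np.zeros((n_frames, material_coords.shape[0]))
    truth_curves = _aggregate_curves(zeros_pt, zeros_pt, zeros_pt, material_segments)

    return PhantomTruth(
        config=config,
        activation=np.zeros(n_frames),
        material_coords=material_coords,
        material_segments=material_segments,
        trajectories=trajectories,
        eulerian_disp=np.zeros((n_frames, 2, *r_pix.shape)),
        myo_masks=np.repeat(disc[None], n_frames, axis=0),
        blood_masks=np.zeros((n_frames, *r_pix.shape), dtype=bool),
        truth_curves=truth_curves,
        stationary=True,
    )
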