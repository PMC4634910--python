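"""Cardiac mechanics from Eulerian displacement fields.

The pipeline mirrors standard DENSE post-processing: spatially smoothed
Eulerian displacement maps are converted into Lagrangian trajectories of
material points seeded at end-diastole (fixed-point solution of
``x(t) = X + u(x(t), t)``), the trajectories are temporally fitted with a
10th-order polynomial, and the 2D Lagrangian finite strain tensor

    E = (F^T F - I) / 2

is evaluated per material point from a local least-squares estimate of the
deformation gradient ``F``.  Circumferential strain (Ecc, negative for
shortening), radial strain (Err, positive for thickening) and twist (rotation
about the end-diastolic endocardial centroid, counterclockwise positive
viewed from apex toward base) are aggregated in six 60-degree segments; the
global curve is the mean of the six segmental curves and peaks are the signed
extrema of the global curves.

The module-level functions are the pipeline stages; :class:`DenseMechanicsModel`
/ :class:`DenseMechanicsResults` wrap them in a fit/results interface.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial import legendre
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator
from scipy.spatial import cKDTree

from .encode import DenseSeries
from .phantom import N_SEGMENTS, pixel_grid_mm
from .unwrap import EulerianField, Segmentation, unwrap_series

__all__ = [
    "TrajectorySet",
    "MechanicsResult",
    "build_trajectories",
    "fit_temporal",
    "strain_curves",
    "twist_curve",
    "compute_mechanics",
    "DenseMechanicsModel",
    "DenseMechanicsResults",
]


@dataclass
class TrajectorySet:
    """Material points and their per-frame positions (mm).

    For raw (unfitted) trajectories, positions at the first frame equal the
    material points exactly; after temporal fitting they may differ by the
    fit residual, and downstream strain/twist use the first-frame positions
    as the material reference so that all curves are exactly zero at frame 1.
    """

    material_points: np.ndarray  # (N, 2)
    positions: np.ndarray  # (T, N, 2)
    valid: np.ndarray  # (N,) bool
    poly_order: int | None = None

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def displacements(self) -> np.ndarray:
        return self.positions - self.material_points[None]


@dataclass
class MechanicsResult:
    """Segmental and global strain/twist curves and their peaks.

    ``curves`` is tidy: frame (1-based), segment ("1".."6" or "global") and
    whichever of ecc_pct / err_pct / twist_deg were computed.
    """

    curves: pd.DataFrame
    peaks: dict[str, float] = field(default_factory=dict)
    n_points: int = 0

    def global_curve(self, measure: str) -> np.ndarray:
        g = self.curves[self.curves.segment == "global"].sort_values("frame")
        return g[measure].to_numpy()

    @staticmethod
    def merge(*parts: "MechanicsResult") -> "MechanicsResult":
        curves = parts[0].curves
        for p in parts[1:]:
            extra = [c for c in p.curves.columns if c not in curves.columns]
            curves = curves.merge(
                p.curves[["frame", "segment"] + extra], on=["frame", "segment"]
            )
        peaks: dict[str, float] = {}
        for p in parts:
            peaks.update(p.peaks)
        return MechanicsResult(
            curves=curves, peaks=peaks, n_points=max(p.n_points for p in parts)
        )

    def to_table(self) -> str:
        buf = _io.StringIO()
        self.curves.to_csv(buf, index=False)
        return buf.getvalue()


def _masked_gradient(u: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel (du/dcol, du/drow) using only valid neighbours.

    Central differences where both neighbours are valid, one-sided at mask
    edges, zero where no valid neighbour exists.
    """
    grads = []
    for axis in (1, 0):  # column (x) then row (y)
        fwd = np.zeros_like(u)
        bwd = np.zeros_like(u)
        ok_f = np.zeros_like(mask)
        ok_b = np.zeros_like(mask)
        sl_c = [slice(None)] * 2
        sl_n = [slice(None)] * 2
        sl_c[axis], sl_n[axis] = slice(0, -1), slice(1, None)
        fwd[tuple(sl_c)] = u[tuple(sl_n)] - u[tuple(sl_c)]
        ok_f[tuple(sl_c)] = mask[tuple(sl_n)]
        bwd[tuple(sl_n)] = u[tuple(sl_n)] - u[tuple(sl_c)]
        ok_b[tuple(sl_n)] = mask[tuple(sl_c)]
        n_ok = ok_f.astype(int) + ok_b.astype(int)
        g = np.where(
            n_ok > 0,
            (np.where(ok_f, fwd, 0.0) + np.where(ok_b, bwd, 0.0)) / np.maximum(n_ok, 1),
            0.0,
        )
        g[~mask] = 0.0
        grads.append(g)
    return grads[0], grads[1]


def _smooth_and_fill(field: EulerianField, seg: Segmentation, sd_px: float) -> np.ndarray:
    """Mask-normalized Gaussian smoothing of u, then first-order fill.

    Smoothing is confined to the mask (normalized convolution, so edge pixels
    are not dragged toward zero).  Outside the mask, values are linearly
    extrapolated from the nearest valid pixel using masked finite-difference
    gradients, so bilinear interpolation near the wall boundary stays
    first-order accurate instead of flattening to the edge value.
    """
    out = np.zeros_like(field.disp_mm)
    n_frames = field.n_frames
    for t in range(n_frames):
        mask = field.valid[t]
        if not mask.any():
            continue
        _, (iy, ix) = ndimage.distance_transform_edt(~mask, return_indices=True)
        rows, cols = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]]
        d_col = (cols - ix).astype(float)
        d_row = (rows - iy).astype(float)
        for ax in range(2):
            u = np.nan_to_num(field.disp_mm[t, ax], nan=0.0)
            if sd_px > 0:
                num = ndimage.gaussian_filter(u * mask, sd_px)
                den = ndimage.gaussian_filter(mask.astype(float), sd_px)
                sm = np.where(den > 1e-12, num / np.maximum(den, 1e-12), 0.0)
                sm[~mask] = 0.0
            else:
                sm = np.where(mask, u, 0.0)
            gx, gy = _masked_gradient(sm, mask)
            nearest = sm[iy, ix]
            out[t, ax] = np.where(
                mask, sm, nearest + gx[iy, ix] * d_col + gy[iy, ix] * d_row
            )
    return out


def build_trajectories(
    field: EulerianField,
    seg: Segmentation,
    smooth_sd_px: float = 1.0,
    max_iter: int = 50,
    tol_mm: float = 1e-9,
) -> TrajectorySet:
    """Lagrangian trajectories from per-frame Eulerian displacement maps.

    Material points are the pixel centres inside the end-diastolic mask.  For
    each later frame the current position solves ``x = X + u(x, t)`` by
    fixed-point iteration with bilinear interpolation of the (smoothed)
    Eulerian field; points that fail to converge within ``max_iter`` steps
    are flagged invalid.
    """
    n = seg.myo_masks.shape[1]
    coords = (np.arange(n) - (n - 1) / 2.0) * seg.pixel_mm
    ed_mask = seg.myo_masks[0]
    gx, gy = np.meshgrid(coords, coords, indexing="xy")
    material = np.column_stack([gx[ed_mask], gy[ed_mask]])

    u_filled = _smooth_and_fill(field, seg, smooth_sd_px)
    n_frames = field.n_frames
    n_pts = material.shape[0]
    positions = np.empty((n_frames, n_pts, 2))
    positions[0] = material
    valid = np.ones(n_pts, dtype=bool)

    for t in range(1, n_frames):
        interp = [
            RegularGridInterpolator(
                (coords, coords), u_filled[t, ax].T, bounds_error=False, fill_value=0.0
            )
            for ax in range(2)
        ]
        x = positions[t - 1].copy()
        converged = np.zeros(n_pts, dtype=bool)
        for _ in range(max_iter):
            u_here = np.column_stack([interp[0](x), interp[1](x)])
            x_new = material + u_here
            converged = np.hypot(*(x_new - x).T) < tol_mm
            x = x_new
            if converged.all():
                break
        valid &= converged
        positions[t] = x
    if not valid.all():
        warnings.warn(
            f"{(~valid).sum()} of {n_pts} trajectories did not converge", stacklevel=2
        )
    return TrajectorySet(material_points=material, positions=positions, valid=valid)


def fit_temporal(traj: TrajectorySet, order: int = 10) -> TrajectorySet:
    """Least-squares polynomial fit of each displacement component over time.

    Uses a Legendre basis on time scaled to [-1, 1] (numerically equivalent
    to a raw degree-``order`` polynomial fit, far better conditioned).  If
    fewer than ``order + 1`` frames are available the order is reduced with a
    warning.  Fitted first-frame positions can differ from the material
    points by the fit residual; see :class:`TrajectorySet`.
    """
    n_frames = traj.n_frames
    if n_frames <= order:
        warnings.warn(
            f"only {n_frames} frames: reducing polynomial order to {n_frames - 1}",
            stacklevel=2,
        )
        order = n_frames - 1
    tau = np.linspace(-1.0, 1.0, n_frames)
    basis = legendre.legvander(tau, order)  # (T, order+1)
    d = traj.displacements.reshape(n_frames, -1)  # (T, N*2)
    coeffs, *_ = np.linalg.lstsq(basis, d, rcond=None)
    fitted = (basis @ coeffs).reshape(traj.positions.shape)
    return TrajectorySet(
        material_points=traj.material_points,
        positions=traj.material_points[None] + fitted,
        valid=traj.valid.copy(),
        poly_order=order,
    )


def _neighbor_pairs(ref: np.ndarray, valid: np.ndarray, radius_mm: float):
    tree = cKDTree(ref[valid])
    idx_map = np.nonzero(valid)[0]
    pairs = tree.query_pairs(radius_mm, output_type="ndarray")
    if pairs.size == 0:
        return np.empty(0, int), np.empty(0, int)
    i = np.concatenate([pairs[:, 0], pairs[:, 1]])
    j = np.concatenate([pairs[:, 1], pairs[:, 0]])
    return idx_map[i], idx_map[j]


def _deformation_gradients(
    traj: TrajectorySet, radius_mm: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-point, per-frame F by least squares over material neighbourhoods.

    Minimizes ``sum_j |dx_j - F dX_j|^2`` over neighbours within
    ``radius_mm`` of each point at the (fitted) reference frame.  Returns
    (F of shape (T, N, 2, 2), usable mask of shape (N,)); points with a
    degenerate (rank < 2) neighbourhood are excluded.
    """
    ref = traj.positions[0]
    n_frames, n_pts = traj.n_frames, ref.shape[0]
    ii, jj = _neighbor_pairs(ref, traj.valid, radius_mm)

    d_ref = ref[jj] - ref[ii]  # (P, 2)
    a_mat = np.zeros((n_pts, 2, 2))
    np.add.at(a_mat, ii, np.einsum("pi,pj->pij", d_ref, d_ref))
    det = a_mat[:, 0, 0] * a_mat[:, 1, 1] - a_mat[:, 0, 1] * a_mat[:, 1, 0]
    scale = np.maximum(np.einsum("nii->n", a_mat), 1e-30)
    usable = traj.valid & (det > 1e-9 * scale**2)

    a_inv = np.zeros_like(a_mat)
    d_ok = det[usable]
    a_inv[usable, 0, 0] = a_mat[usable, 1, 1] / d_ok
    a_inv[usable, 1, 1] = a_mat[usable, 0, 0] / d_ok
    a_inv[usable, 0, 1] = -a_mat[usable, 0, 1] / d_ok
    a_inv[usable, 1, 0] = -a_mat[usable, 1, 0] / d_ok

    f_all = np.zeros((n_frames, n_pts, 2, 2))
    for t in range(n_frames):
        d_cur = traj.positions[t][jj] - traj.positions[t][ii]
        b_mat = np.zeros((n_pts, 2, 2))
        np.add.at(b_mat, ii, np.einsum("pi,pj->pij", d_cur, d_ref))
        f_all[t] = np.einsum("nij,njk->nik", b_mat, a_inv)
    return f_all, usable


def _aggregate(
    values_pt: np.ndarray,  # (T, N)
    segments: np.ndarray,
    usable: np.ndarray,
    name: str,
) -> pd.DataFrame:
    n_frames = values_pt.shape[0]
    seg_curves = np.full((N_SEGMENTS, n_frames), np.nan)
    for s in range(1, N_SEGMENTS + 1):
        sel = usable & (segments == s)
        if sel.any():
            seg_curves[s - 1] = values_pt[:, sel].mean(axis=1)
    rows = []
    for t in range(n_frames):
        for s in range(1, N_SEGMENTS + 1):
            rows.append({"frame": t + 1, "segment": str(s), name: seg_curves[s - 1, t]})
        rows.append(
            {"frame": t + 1, "segment": "global", name: np.nanmean(seg_curves[:, t])}
        )
    return pd.DataFrame(rows)


def _peak(curve: np.ndarray) -> float:
    return float(curve[np.argmax(np.abs(np.nan_to_num(curve)))])


def strain_curves(
    traj: TrajectorySet, seg: Segmentation, neighborhood_mm: float | None = None
) -> MechanicsResult:
    """Segmental/global Ecc and Err (%) from the Lagrangian strain tensor.

    Radial/circumferential directions are end-diastolic: ``e_r`` points from
    the end-diastolic endocardial centroid to the material point, ``e_c`` is
    its 90-degree counterclockwise rotation.
    """
    if neighborhood_mm is None:
        neighborhood_mm = 1.5 * seg.pixel_mm
    f_all, usable = _deformation_gradients(traj, neighborhood_mm)
    ref = traj.positions[0]
    rel = ref - seg.ed_centroid
    rr = np.hypot(rel[:, 0], rel[:, 1])
    usable = usable & (rr > 1e-9)
    e_r = np.zeros_like(rel)
    e_r[usable] = rel[usable] / rr[usable, None]
    e_c = np.column_stack([-e_r[:, 1], e_r[:, 0]])

    c_tensor = np.einsum("tnji,tnjk->tnik", f_all, f_all)  # F^T F
    e_tensor = 0.5 * (c_tensor - np.eye(2)[None, None])
    ecc = 100.0 * np.einsum("ni,tnij,nj->tn", e_c, e_tensor, e_c)
    err = 100.0 * np.einsum("ni,tnij,nj->tn", e_r, e_tensor, e_r)

    segments = seg.segment_of(traj.material_points)
    df = _aggregate(ecc, segments, usable, "ecc_pct").merge(
        _aggregate(err, segments, usable, "err_pct"), on=["frame", "segment"]
    )
    result = MechanicsResult(curves=df, n_points=int(usable.sum()))
    result.peaks["ecc_pct"] = _peak(result.global_curve("ecc_pct"))
    result.peaks["err_pct"] = _peak(result.global_curve("err_pct"))
    return result


def twist_curve(traj: TrajectorySet, seg: Segmentation) -> MechanicsResult:
    """Segmental/global twist (degrees) about the end-diastolic centroid."""
    ref = traj.positions[0] - seg.ed_centroid
    cur = traj.positions - seg.ed_centroid  # (T, N, 2)
    rr = np.hypot(ref[:, 0], ref[:, 1])
    usable = traj.valid & (rr > 1e-9)
    cross = ref[None, :, 0] * cur[:, :, 1] - ref[None, :, 1] * cur[:, :, 0]
    dot = ref[None, :, 0] * cur[:, :, 0] + ref[None, :, 1] * cur[:, :, 1]
    angle = np.rad2deg(np.arctan2(cross, dot))

    segments = seg.segment_of(traj.material_points)
    df = _aggregate(angle, segments, usable, "twist_deg")
    result = MechanicsResult(curves=df, n_points=int(usable.sum()))
    result.peaks["twist_deg"] = _peak(result.global_curve("twist_deg"))
    return result


def compute_mechanics(
    traj: TrajectorySet, seg: Segmentation, neighborhood_mm: float | None = None
) -> MechanicsResult:
    """Strain and twist curves/peaks in one result."""
    return MechanicsResult.merge(
        strain_curves(traj, seg, neighborhood_mm), twist_curve(traj, seg)
    )


# ---------------------------------------------------------------------------
# model/results interface


class DenseMechanicsModel:
    """Cardiac-mechanics analysis of one encoded DENSE series.

    Parameters
    ----------
    series : DenseSeries
        Magnitude + wrapped-phase image series.
    seg : Segmentation
        Myocardial segmentation (manual contours or phantom-derived).
    smooth_sd_px : float
        Gaussian spatial-smoothing SD applied to the Eulerian displacement
        maps, in pixels.
    poly_order : int
        Temporal polynomial order for trajectory fitting.
    neighborhood_mm : float, optional
        Material neighbourhood radius for the deformation-gradient fit
        (default 1.5 pixels).

    Examples
    --------
    >>> model = DenseMechanicsModel(series, seg)
    >>> res = model.fit()
    >>> res.peaks["ecc_pct"]
    """

    def __init__(
        self,
        series: DenseSeries,
        seg: Segmentation,
        smooth_sd_px: float = 1.0,
        poly_order: int = 10,
        neighborhood_mm: float | None = None,
    ) -> None:
        self.series = series
        self.seg = seg
        self.smooth_sd_px = smooth_sd_px
        self.poly_order = poly_order
        self.neighborhood_mm = neighborhood_mm

    def fit(self) -> "DenseMechanicsResults":
        field = unwrap_series(self.series, self.seg)
        raw = build_trajectories(field, self.seg, smooth_sd_px=self.smooth_sd_px)
        fitted = fit_temporal(raw, order=self.poly_order)
        mech = compute_mechanics(fitted, self.seg, self.neighborhood_mm)
        return DenseMechanicsResults(self, field, fitted, mech)


class DenseMechanicsResults:
    """Results of :meth:`DenseMechanicsModel.fit`.

    Carries the recovered Eulerian field, fitted trajectories, the segmental
    and global strain/twist curves, and peak values; ``summary()`` prints a
    compact report with between-segment dispersion as a heterogeneity
    indicator.
    """

    def __init__(
        self,
        model: DenseMechanicsModel,
        field: EulerianField,
        trajectories: TrajectorySet,
        mechanics: MechanicsResult,
    ) -> None:
        self.model = model
        self.field = field
        self.trajectories = trajectories
        self.mechanics = mechanics

    @property
    def curves(self) -> pd.DataFrame:
        return self.mechanics.curves

    @property
    def peaks(self) -> dict[str, float]:
        return self.mechanics.peaks

    def peak_frame(self, measure: str) -> int:
        curve = self.mechanics.global_curve(measure)
        return int(np.argmax(np.abs(np.nan_to_num(curve)))) + 1

    def segment_peak_sd(self, measure: str) -> float:
        t = self.peak_frame(measure)
        seg_vals = self.curves[
            (self.curves.frame == t) & (self.curves.segment != "global")
        ][measure]
        return float(seg_vals.std(ddof=1))

    def summary(self) -> str:
        enc = self.model.series.encoding
        lines = [
            "DENSE cardiac mechanics",
            "=" * 55,
            f"encoding frequency : {enc.ke_cycles_per_mm:.3f} cycles/mm",
            f"frames             : {self.model.series.n_frames}",
            f"material points    : {self.mechanics.n_points}",
            f"polynomial order   : {self.trajectories.poly_order}",
            "-" * 55,
            f"{'measure':<22}{'peak':>10}{'frame':>8}{'seg SD':>12}",
        ]
        labels = {
            "ecc_pct": "peak Ecc (%)",
            "err_pct": "peak Err (%)",
            "twist_deg": "peak twist (deg)",
        }
        for key, label in labels.items():
            if key in self.peaks:
                lines.append(
                    f"{label:<22}{self.peaks[key]:>10.2f}"
                    f"{self.peak_frame(key):>8d}{self.segment_peak_sd(key):>12.2f}"
                )
        lines.append("=" * 55)
        return "\n".join(lines)
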