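"""Phase unwrapping and Eulerian displacement recovery inside the myocardium.

Encoded phase is only known modulo 2*pi; whenever tissue moves farther than
``1/(2 k_e)`` the phase wraps and the displacement map is ambiguous.  This
module resolves the ambiguity with quality-guided region growing within the
myocardial segmentation (quality = inverse local wrapped-phase-gradient
magnitude), frame-to-frame: each frame's solution is referenced to the
previous frame's, and the first frame assumes near-zero early-systolic motion
(``|u| < 1/(2 k_e)``).  The output per axis satisfies, at every masked pixel,

    phi_unwrapped == phi_wrapped  (mod 2*pi)        exactly,

and displacement follows as ``phi_unwrapped / (2 pi k_e)``.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .encode import DenseSeries
from .phantom import PhantomTruth, pixel_grid_mm

__all__ = [
    "Segmentation",
    "EulerianField",
    "unwrap_series",
    "wrapped_pixel_map",
    "segmentation_from_truth",
    "segmentation_from_contours",
    "read_contours",
    "write_contours",
]

TWO_PI = 2.0 * np.pi


@dataclass
class Segmentation:
    """Myocardial segmentation: contours, masks and segment geometry.

    ``endo_contours`` / ``epi_contours`` are per-frame (K, 2) polygons in mm
    (image coordinates, origin at the grid centre).  ``myo_masks`` is the
    per-frame boolean region between the contours.  ``ed_centroid`` is the
    centroid of the end-diastolic (first-frame) endocardial contour; segments
    are six 60-degree sectors about it, segment 1 starting at the +x axis.
    """

    endo_contours: list[np.ndarray]
    epi_contours: list[np.ndarray]
    myo_masks: np.ndarray
    ed_centroid: np.ndarray
    pixel_mm: float

    @property
    def n_frames(self) -> int:
        return self.myo_masks.shape[0]

    def segment_of(self, points_mm: np.ndarray) -> np.ndarray:
        """Segment label (1..6) of end-diastolic positions about the centroid."""
        rel = np.asarray(points_mm) - self.ed_centroid
        ang = np.mod(np.arctan2(rel[..., 1], rel[..., 0]), TWO_PI)
        return (ang // (np.pi / 3.0)).astype(int) + 1


@dataclass
class EulerianField:
    """Recovered per-frame displacement maps (mm) inside the mask.

    ``disp_mm`` is (n_frames, 2, H, W), NaN outside the valid region;
    ``unwrapped_phase`` the matching unwrapped phase in radians.
    """

    disp_mm: np.ndarray
    unwrapped_phase: np.ndarray
    valid: np.ndarray
    ke_cycles_per_mm: float
    skipped_frames: list[int] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return self.disp_mm.shape[0]


def segmentation_from_truth(truth: PhantomTruth, n_vertices: int = 120) -> Segmentation:
    """Exact segmentation from the known phantom geometry (no manual step)."""
    cfg = truth.config
    ang = np.linspace(0.0, TWO_PI, n_vertices, endpoint=False)
    circle = np.column_stack([np.cos(ang), np.sin(ang)])
    endo, epi = [], []
    for t in range(cfg.n_frames):
        m = truth.myo_masks[t]
        x, y = pixel_grid_mm(cfg)
        r = np.hypot(x, y)[m]
        endo.append(circle * r.min())
        epi.append(circle * r.max())
    return Segmentation(
        endo_contours=endo,
        epi_contours=epi,
        myo_masks=truth.myo_masks.copy(),
        ed_centroid=np.zeros(2),
        pixel_mm=cfg.pixel_mm,
    )


def _neighbors(y: int, x: int, h: int, w: int):
    if y > 0:
        yield y - 1, x
    if y < h - 1:
        yield y + 1, x
    if x > 0:
        yield y, x - 1
    if x < w - 1:
        yield y, x + 1


def _quality(phase: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Negative mean wrapped phase-gradient magnitude to masked 4-neighbours."""
    from .encode import wrap_phase

    h, w = phase.shape
    grad_sum = np.zeros((h, w))
    grad_n = np.zeros((h, w))
    for shift in ((1, 0), (0, 1)):
        sl_a = (slice(0, h - shift[0]), slice(0, w - shift[1]))
        sl_b = (slice(shift[0], h), slice(shift[1], w))
        both = mask[sl_a] & mask[sl_b]
        dd = np.abs(wrap_phase(phase[sl_b] - phase[sl_a]))
        grad_sum[sl_a][both] += dd[both]
        grad_n[sl_a][both] += 1
        grad_sum[sl_b][both] += dd[both]
        grad_n[sl_b][both] += 1
    q = -grad_sum / np.maximum(grad_n, 1)
    q[~mask] = -np.inf
    return q


def _unwrap_component(
    phase: np.ndarray, comp: np.ndarray, quality: np.ndarray
) -> np.ndarray:
    """Quality-guided region growing over one connected component.

    Returns the unwrapped phase on ``comp`` (exactly ``phase + 2*pi*k`` with
    integer ``k`` per pixel).  The growth queue is ordered by descending
    quality with lexicographic (y, x) tie-breaking for determinism.
    """
    h, w = phase.shape
    out = np.full((h, w), np.nan)
    ys, xs = np.nonzero(comp)
    seed_idx = np.lexsort((xs, ys, -quality[ys, xs]))[0]
    sy, sx = int(ys[seed_idx]), int(xs[seed_idx])
    out[sy, sx] = phase[sy, sx]
    done = np.zeros((h, w), dtype=bool)
    done[sy, sx] = True
    heap: list[tuple[float, int, int, int, int]] = []
    for ny, nx in _neighbors(sy, sx, h, w):
        if comp[ny, nx]:
            heapq.heappush(heap, (-quality[ny, nx], ny, nx, sy, sx))
    while heap:
        _, y, x, ry, rx = heapq.heappop(heap)
        if done[y, x]:
            continue
        k = np.round((out[ry, rx] - phase[y, x]) / TWO_PI)
        out[y, x] = phase[y, x] + TWO_PI * k
        done[y, x] = True
        for ny, nx in _neighbors(y, x, h, w):
            if comp[ny, nx] and not done[ny, nx]:
                heapq.heappush(heap, (-quality[ny, nx], ny, nx, y, x))
    return out


def _rereference(
    unwrapped: np.ndarray, comp: np.ndarray, prev: np.ndarray | None
) -> np.ndarray:
    """Shift a component by an integer multiple of 2*pi to its temporal seed.

    With a previous-frame solution, matches the component's median phase to it
    over the overlap; otherwise assumes near-zero motion (median phase in
    (-pi, pi]).
    """
    vals = unwrapped[comp]
    offset_ref = None
    if prev is not None:
        overlap = comp & np.isfinite(prev)
        if overlap.sum() >= 5:
            offset_ref = np.median(unwrapped[overlap] - prev[overlap])
    if offset_ref is None:
        offset_ref = np.median(vals)
    k = np.round(offset_ref / TWO_PI)
    unwrapped[comp] = vals - TWO_PI * k
    return unwrapped


def unwrap_series(series: DenseSeries, seg: Segmentation) -> EulerianField:
    """Unwrap both phase axes over all frames and convert to displacement.

    Empty-mask frames are flagged and skipped; disconnected mask components
    are unwrapped independently (with a warning), each referenced to the
    previous frame's solution where they overlap.
    """
    if series.magnitude.shape[1:] != seg.myo_masks.shape[1:]:
        raise ValueError("series and segmentation grids differ")
    if series.n_frames != seg.n_frames:
        raise ValueError("series and segmentation frame counts differ")
    ke = series.encoding.ke_cycles_per_mm
    n_frames, (h, w) = series.n_frames, series.shape
    phase_unw = np.full((n_frames, 2, h, w), np.nan)
    valid = np.zeros((n_frames, h, w), dtype=bool)
    skipped: list[int] = []

    for ax in range(2):
        prev: np.ndarray | None = None
        for t in range(n_frames):
            mask = seg.myo_masks[t]
            if not mask.any():
                if ax == 0:
                    skipped.append(t)
                prev = None
                continue
            phase = series.phase(ax)[t]
            labels, n_comp = ndimage.label(mask)
            if n_comp > 1:
                warnings.warn(
                    f"frame {t + 1}: {n_comp} disconnected mask components "
                    "unwrapped independently",
                    stacklevel=2,
                )
            q = _quality(phase, mask)
            frame_out = np.full((h, w), np.nan)
            for c in range(1, n_comp + 1):
                comp = labels == c
                comp_unw = _unwrap_component(phase, comp, q)
                comp_unw = _rereference(comp_unw, comp, prev)
                frame_out[comp] = comp_unw[comp]
            phase_unw[t, ax] = frame_out
            prev = frame_out
            if ax == 0:
                valid[t] = mask

    disp = phase_unw / (TWO_PI * ke)
    return EulerianField(
        disp_mm=disp,
        unwrapped_phase=phase_unw,
        valid=valid,
        ke_cycles_per_mm=ke,
        skipped_frames=skipped,
    )


def wrapped_pixel_map(
    source: PhantomTruth | EulerianField,
    seg: Segmentation,
    ke: float | None = None,
) -> np.ndarray:
    """Boolean (n_frames, 2, H, W) map of pixels whose true phase wrapped.

    A pixel is wrapped iff its unwrapped phase ``2 pi ke u`` falls outside
    (-pi, pi].  Ground truth (simulation) or a recovered unwrapped solution
    (measured data) can serve as the source.
    """
    if isinstance(source, PhantomTruth):
        if ke is None:
            raise ValueError("ke required when using ground truth")
        phase = TWO_PI * ke * source.eulerian_disp  # (T, 2, H, W)
    elif isinstance(source, EulerianField):
        phase = np.nan_to_num(source.unwrapped_phase, nan=0.0)
    else:
        raise TypeError("source must be PhantomTruth or EulerianField")
    wrapped = (phase > np.pi) | (phase <= -np.pi)
    wrapped &= seg.myo_masks[:, None, :, :]
    return wrapped


# ---------------------------------------------------------------------------
# contour file plumbing (for externally supplied manual segmentations)

CONTOUR_COLUMNS = ["frame", "contour", "x_mm", "y_mm"]


def write_contours(seg: Segmentation, path) -> None:
    """Write contours as a delimited table: frame, contour, x_mm, y_mm."""
    rows = []
    for t in range(seg.n_frames):
        for name, contour in (("endo", seg.endo_contours[t]), ("epi", seg.epi_contours[t])):
            for x, y in contour:
                rows.append({"frame": t + 1, "contour": name, "x_mm": x, "y_mm": y})
    pd.DataFrame(rows, columns=CONTOUR_COLUMNS).to_csv(path, index=False)


def read_contours(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(CONTOUR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"contour table missing columns: {sorted(missing)}")
    return df


def segmentation_from_contours(
    contours: pd.DataFrame, grid_size: int, pixel_mm: float
) -> Segmentation:
    """Rasterize endo/epi contour polygons into per-frame myocardial masks."""
    from matplotlib.path import Path as MplPath

    frames = sorted(contours["frame"].unique())
    n = grid_size
    coords = (np.arange(n) - (n - 1) / 2.0) * pixel_mm
    gx, gy = np.meshgrid(coords, coords, indexing="xy")
    pts = np.column_stack([gx.ravel(), gy.ravel()])

    endo_list, epi_list, masks = [], [], []
    for f in frames:
        sub = contours[contours["frame"] == f]
        endo = sub[sub["contour"] == "endo"][["x_mm", "y_mm"]].to_numpy()
        epi = sub[sub["contour"] == "epi"][["x_mm", "y_mm"]].to_numpy()
        if len(endo) < 3 or len(epi) < 3:
            raise ValueError(f"frame {f}: need >= 3 vertices per contour")
        inside_epi = MplPath(epi).contains_points(pts).reshape(n, n)
        inside_endo = MplPath(endo).contains_points(pts).reshape(n, n)
        masks.append(inside_epi & ~inside_endo)
        endo_list.append(endo)
        epi_list.append(epi)

    ed_endo = endo_list[0]
    return Segmentation(
        endo_contours=endo_list,
        epi_contours=epi_list,
        myo_masks=np.array(masks),
        ed_centroid=ed_endo.mean(axis=0),
        pixel_mm=pixel_mm,
    )
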