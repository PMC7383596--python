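"""Rate maps, grid-field detection, spatial autocorrelation and gridness.

Rate maps use 2-cm bins smoothed with a five-bin boxcar applied to spike
counts and occupancy before division; unvisited bins are masked rather
than zero-filled.  The spatial autocorrelogram is the Pearson correlation
of the rate map with itself at every spatial lag, computed over the
overlapping valid bins only.  Gridness is the classic six-fold rotational
symmetry score on an annulus around the central peak, with significance
from a spike-versus-tracking circular time-shift shuffle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .signals import MOVEMENT_SPEED_CM_S, Trajectory

__all__ = [
    "RateMap",
    "FieldSet",
    "GridnessResult",
    "rate_map",
    "detect_fields",
    "spatial_autocorrelation",
    "gridness",
    "gridness_shuffle_test",
]

MIN_OVERLAP_BINS = 20


@dataclass
class RateMap:
    """Smoothed firing-rate map with occupancy and an unvisited-bin mask."""

    rate: np.ndarray  # Hz; NaN where unvisited
    occupancy: np.ndarray  # s per bin (raw, unsmoothed)
    counts: np.ndarray  # raw spike counts per bin
    bin_cm: float
    extent: float

    @property
    def ndim(self) -> int:
        return self.rate.ndim

    @property
    def visited(self) -> np.ndarray:
        return self.occupancy > 0

    def bin_centers(self) -> np.ndarray:
        n = self.rate.shape[0]
        return (np.arange(n) + 0.5) * self.bin_cm


@dataclass
class FieldSet:
    """Detected firing fields of one rate map."""

    labels: np.ndarray  # 0 = background, 1..n_fields
    peak_rates: np.ndarray  # Hz, per field
    centers: np.ndarray  # cm; (n,) in 1D or (n, 2) in 2D (peak-bin centers)
    bin_cm: float

    @property
    def n_fields(self) -> int:
        return len(self.peak_rates)

    @property
    def cv(self) -> float:
        """Coefficient of variation of per-field peak rates."""
        if self.n_fields < 2:
            return np.nan
        return float(np.std(self.peak_rates) / np.mean(self.peak_rates))


@dataclass
class GridnessResult:
    score: float
    scale_cm: float
    low_confidence: bool = False
    threshold: float | None = None
    significant: bool | None = None


def _spike_sample_idx(spike_times, trajectory: Trajectory):
    return np.clip(
        np.round(np.asarray(spike_times) / trajectory.dt).astype(int), 0, trajectory.n - 1
    )


def rate_map(
    spike_times: np.ndarray,
    trajectory: Trajectory,
    bin_cm: float = 2.0,
    smooth_bins: int = 5,
    speed_threshold: float = MOVEMENT_SPEED_CM_S,
) -> RateMap:
    """Movement-filtered firing-rate map in ``bin_cm``-sided bins.

    Spike counts and occupancy are both smoothed with a ``smooth_bins``
    boxcar before division, restricting to samples (and spikes) with
    running speed at or above the movement threshold.
    """
    n_bins = int(np.ceil(trajectory.extent / bin_cm))
    move = trajectory.movement_mask(speed_threshold)
    if not move.any():
        raise ValueError("no movement samples above the speed threshold")
    pos = trajectory.positions[move]
    idx = _spike_sample_idx(spike_times, trajectory)
    spk_keep = trajectory.movement_mask(speed_threshold)[idx]
    spos = trajectory.positions[idx[spk_keep]]
    if trajectory.ndim == 1:
        occ = np.bincount(
            np.clip((pos / bin_cm).astype(int), 0, n_bins - 1), minlength=n_bins
        ).astype(float) * trajectory.dt
        cnt = np.bincount(
            np.clip((spos / bin_cm).astype(int), 0, n_bins - 1), minlength=n_bins
        ).astype(float)
    else:
        bx = np.clip((pos[:, 0] / bin_cm).astype(int), 0, n_bins - 1)
        by = np.clip((pos[:, 1] / bin_cm).astype(int), 0, n_bins - 1)
        occ = np.bincount(bx * n_bins + by, minlength=n_bins * n_bins).astype(float)
        occ = occ.reshape(n_bins, n_bins) * trajectory.dt
        sx = np.clip((spos[:, 0] / bin_cm).astype(int), 0, n_bins - 1)
        sy = np.clip((spos[:, 1] / bin_cm).astype(int), 0, n_bins - 1)
        cnt = np.bincount(sx * n_bins + sy, minlength=n_bins * n_bins).astype(float)
        cnt = cnt.reshape(n_bins, n_bins)
    sm_occ = ndimage.uniform_filter(occ, smooth_bins, mode="constant")
    sm_cnt = ndimage.uniform_filter(cnt, smooth_bins, mode="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(sm_occ > 0, sm_cnt / np.maximum(sm_occ, 1e-300), np.nan)
    rate[occ == 0] = np.nan  # unvisited bins stay masked
    return RateMap(rate=rate, occupancy=occ, counts=cnt, bin_cm=bin_cm, extent=trajectory.extent)


def detect_fields(rmap: RateMap, threshold_frac: float = 0.1, min_bins: int | None = None) -> FieldSet:
    """Detect firing fields as contiguous super-threshold bin sets.

    A field is a connected component (8-connectivity in 2D) of bins whose
    rate exceeds ``threshold_frac`` of the map peak, containing at least 5
    bins in 1D or 10 bins in 2D.
    """
    rate = rmap.rate
    if min_bins is None:
        min_bins = 5 if rate.ndim == 1 else 10
    finite = np.isfinite(rate)
    if not finite.any():
        return FieldSet(np.zeros_like(rate, dtype=int), np.array([]), np.array([]), rmap.bin_cm)
    peak = np.nanmax(rate)
    above = finite & (rate > threshold_frac * peak)
    structure = np.ones((3,) * rate.ndim)
    labels, n = ndimage.label(above, structure=structure)
    peaks, centers = [], []
    out = np.zeros_like(labels)
    k = 0
    for lab in range(1, n + 1):
        mask = labels == lab
        if mask.sum() < min_bins:
            continue
        k += 1
        out[mask] = k
        vals = np.where(mask, rate, -np.inf)
        arg = np.unravel_index(np.nanargmax(vals), rate.shape)
        peaks.append(rate[arg])
        centers.append((np.asarray(arg) + 0.5) * rmap.bin_cm)
    centers = np.array(centers) if centers else np.empty((0, rate.ndim))
    if rate.ndim == 1 and len(centers):
        centers = centers.ravel()
    return FieldSet(labels=out, peak_rates=np.asarray(peaks, float), centers=centers, bin_cm=rmap.bin_cm)


def _fft_xcorr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Full 2D cross-correlation sum_i a[i] * b[i + lag] via FFT."""
    from scipy.fft import irfft2, rfft2

    h, w = a.shape[-2:]
    sh = (2 * h, 2 * w)
    fa = rfft2(a, s=sh)
    fb = rfft2(b, s=sh)
    out = irfft2(np.conj(fa) * fb, s=sh)
    return np.roll(out, (h - 1, w - 1), axis=(-2, -1))[..., : 2 * h - 1, : 2 * w - 1]


def _masked_autocorr_batch(maps: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Pearson autocorrelation surfaces for a batch of masked rate maps.

    ``maps`` is (B, H, W) with NaN at invalid bins; ``mask`` (H, W) is the
    shared validity mask.  Returns (B, 2H-1, 2W-1) with NaN where the
    overlap has fewer than MIN_OVERLAP_BINS bins.  At lag l the sums over
    the overlap satisfy sum_y(l) = sum_x(-l), so only one of each pair is
    transformed and the mirror is obtained by flipping.
    """
    from scipy.fft import irfft2, rfft2

    m = mask.astype(np.float32)
    h, w = m.shape
    sh = (2 * h, 2 * w)
    x = np.where(mask[None], np.nan_to_num(maps), 0.0).astype(np.float32)
    fm = rfft2(m, s=sh)
    fx = rfft2(x, s=sh)
    fx2 = rfft2(x * x, s=sh)

    def corr(fa, fb):
        out = irfft2(np.conj(fa) * fb, s=sh)
        return np.roll(out, (h - 1, w - 1), axis=(-2, -1))[..., : 2 * h - 1, : 2 * w - 1]

    def mirror(a):
        return a[..., ::-1, ::-1]

    n = corr(fm, fm)
    sxy = corr(fx, fx)
    sx = corr(fx, fm)  # sum of x over overlap, indexed by "left" factor
    sxx = corr(fx2, fm)
    sy = mirror(sx)
    syy = mirror(sxx)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = n * sxy - sx * sy
        den = np.sqrt((n * sxx - sx**2) * (n * syy - sy**2))
        ac = (num / den).astype(np.float64)
    ac[..., n < MIN_OVERLAP_BINS - 0.5] = np.nan
    ac = np.clip(ac, -1.0, 1.0)
    ac[..., h - 1, w - 1] = 1.0
    return ac


def spatial_autocorrelation(rmap: RateMap) -> np.ndarray:
    """Spatial autocorrelogram of a 2D rate map (Pearson at each lag)."""
    if rmap.ndim != 2:
        raise ValueError("spatial autocorrelation requires a 2D rate map")
    mask = np.isfinite(rmap.rate)
    return _masked_autocorr_batch(rmap.rate[None], mask)[0]


_ROT_CACHE: dict = {}


def _rotation_weights(shape: tuple, angle_deg: float):
    """Cached bilinear gather indices and weights for a centre rotation."""
    key = (shape, angle_deg)
    cached = _ROT_CACHE.get(key)
    if cached is not None:
        return cached
    h, w = shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    a = np.deg2rad(angle_deg)
    ys = cy + np.cos(a) * (yy - cy) - np.sin(a) * (xx - cx)
    xs = cx + np.sin(a) * (yy - cy) + np.cos(a) * (xx - cx)
    inside = (ys >= 0) & (ys <= h - 1) & (xs >= 0) & (xs <= w - 1)
    y0 = np.clip(np.floor(ys).astype(int), 0, h - 2)
    x0 = np.clip(np.floor(xs).astype(int), 0, w - 2)
    fy = np.clip(ys - y0, 0.0, 1.0)
    fx = np.clip(xs - x0, 0.0, 1.0)
    flat00 = (y0 * w + x0).ravel()
    weights = (
        ((1 - fy) * (1 - fx)).ravel(),
        ((1 - fy) * fx).ravel(),
        (fy * (1 - fx)).ravel(),
        (fy * fx).ravel(),
    )
    cached = (flat00, weights, inside.ravel(), w)
    _ROT_CACHE[key] = cached
    return cached


def _rotate_batch(stack: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate a (B, H, W) stack about the centre (bilinear; NaN outside)."""
    squeeze = stack.ndim == 2
    if squeeze:
        stack = stack[None]
    b, h, w = stack.shape
    flat00, (w00, w01, w10, w11), inside, _ = _rotation_weights((h, w), angle_deg)
    flat = stack.reshape(b, h * w)
    out = (
        flat[:, flat00] * w00
        + flat[:, flat00 + 1] * w01
        + flat[:, flat00 + w] * w10
        + flat[:, flat00 + w + 1] * w11
    )
    out[:, ~inside] = np.nan
    out = out.reshape(b, h, w)
    return out[0] if squeeze else out


def _rotated(surface: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate a surface about its centre (bilinear, NaN outside)."""
    return _rotate_batch(surface, angle_deg)


_RADIUS_CACHE: dict = {}


def _radius_grid(shape: tuple) -> np.ndarray:
    r = _RADIUS_CACHE.get(shape)
    if r is None:
        h, w = shape
        cy, cx = (h - 1) // 2, (w - 1) // 2
        yy, xx = np.mgrid[0:h, 0:w]
        r = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
        _RADIUS_CACHE[shape] = r
    return r


def _central_peak_radius(ac: np.ndarray, threshold: float = 0.3) -> float:
    h, w = ac.shape
    cy, cx = (h - 1) // 2, (w - 1) // 2
    above = np.isfinite(ac) & (ac > threshold)
    labels, _ = ndimage.label(above)
    centre_lab = labels[cy, cx]
    if centre_lab == 0:
        return 2.0
    yy, xx = np.nonzero(labels == centre_lab)
    r = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    return float(r.max()) + 1.0


def _autocorr_peaks(ac: np.ndarray, inner: float) -> np.ndarray:
    """Radii and positions of local maxima outside the central peak."""
    h, w = ac.shape
    cy, cx = (h - 1) // 2, (w - 1) // 2
    filled = np.where(np.isfinite(ac), ac, -np.inf)
    local_max = ndimage.maximum_filter(filled, size=3) == filled
    yy, xx = np.nonzero(local_max & np.isfinite(ac) & (ac > 0))
    r = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    keep = r > inner
    order = np.argsort(r[keep])
    return np.stack([r[keep][order], yy[keep][order], xx[keep][order]], axis=1)


def gridness(
    ac: np.ndarray,
    bin_cm: float = 2.0,
    outer_factor: float = 1.25,
    central_threshold: float = 0.3,
    _rots: dict | None = None,
) -> GridnessResult:
    """Six-fold rotational-symmetry score of an autocorrelation surface.

    The score is min(correlation at 60 and 120 degree rotations) minus
    max(correlation at 30, 90 and 150 degrees), evaluated on an annulus
    from the edge of the central peak out to ``outer_factor`` times the
    median radius of the six peaks closest to the centre.  The grid scale
    estimate is the median distance of those six peaks.  With fewer than
    six detectable peaks the best-available annulus is used and the result
    flagged low-confidence.
    """
    h, w = ac.shape
    cy, cx = (h - 1) // 2, (w - 1) // 2
    max_r = min(cy, cx)
    inner = min(_central_peak_radius(ac, central_threshold), 0.5 * max_r)
    peaks = _autocorr_peaks(ac, inner)
    low_conf = len(peaks) < 6
    if len(peaks) >= 3:
        six = peaks[:6]
        med_r = float(np.median(six[:, 0]))
        scale = med_r * bin_cm
        outer = min(outer_factor * med_r, max_r)
    else:
        scale = np.nan
        outer = 0.8 * max_r
        low_conf = True
    outer = max(outer, inner + 3.0)
    r = _radius_grid((h, w))
    annulus = (r > inner) & (r <= outer)
    cors = {}
    for ang in (30, 60, 90, 120, 150):
        rot = _rots[ang] if _rots is not None else _rotated(ac, ang)
        both = annulus & np.isfinite(ac) & np.isfinite(rot)
        if both.sum() < MIN_OVERLAP_BINS:
            cors[ang] = np.nan
            continue
        a = ac[both]
        b = rot[both]
        a = a - a.mean()
        b = b - b.mean()
        denom = np.sqrt((a**2).sum() * (b**2).sum())
        cors[ang] = float((a * b).sum() / denom) if denom > 0 else np.nan
    score = min(cors[60], cors[120]) - max(cors[30], cors[90], cors[150])
    return GridnessResult(score=float(score), scale_cm=scale, low_confidence=low_conf)


def _shifted_rate_maps(
    spike_times: np.ndarray,
    trajectory: Trajectory,
    shifts: np.ndarray,
    bin_cm: float,
    smooth_bins: int,
    speed_threshold: float,
):
    """Smoothed rate maps for circularly time-shifted copies of a spike train.

    Occupancy is shared (the trajectory does not move); only spike
    positions change.  Returns (maps (B, H, W) with NaN at unvisited bins,
    visited mask (H, W)).
    """
    n_bins = int(np.ceil(trajectory.extent / bin_cm))
    move = trajectory.movement_mask(speed_threshold)
    pos = trajectory.positions[move]
    bx = np.clip((pos[:, 0] / bin_cm).astype(int), 0, n_bins - 1)
    by = np.clip((pos[:, 1] / bin_cm).astype(int), 0, n_bins - 1)
    occ = np.bincount(bx * n_bins + by, minlength=n_bins * n_bins).astype(float)
    occ = occ.reshape(n_bins, n_bins) * trajectory.dt
    sm_occ = ndimage.uniform_filter(occ, smooth_bins, mode="constant")
    duration = trajectory.duration
    times = np.mod(np.asarray(spike_times)[None, :] + shifts[:, None], duration)
    idx = np.clip(np.round(times / trajectory.dt).astype(int), 0, trajectory.n - 1)
    keep = move[idx]
    b = len(shifts)
    sx = np.clip((trajectory.positions[idx.ravel(), 0] / bin_cm).astype(int), 0, n_bins - 1)
    sy = np.clip((trajectory.positions[idx.ravel(), 1] / bin_cm).astype(int), 0, n_bins - 1)
    shuf_i = np.repeat(np.arange(b), idx.shape[1])
    flat = (shuf_i * n_bins * n_bins + sx * n_bins + sy)[keep.ravel()]
    cnt = np.bincount(flat, minlength=b * n_bins * n_bins).astype(float)
    cnt = cnt.reshape(b, n_bins, n_bins)
    sm_cnt = ndimage.uniform_filter(cnt, (1, smooth_bins, smooth_bins), mode="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        maps = np.where(sm_occ[None] > 0, sm_cnt / np.maximum(sm_occ, 1e-300)[None], np.nan)
    maps[:, occ == 0] = np.nan
    return maps, occ > 0


def gridness_shuffle_test(
    spike_times: np.ndarray,
    trajectory: Trajectory,
    n_shuffles: int = 100,
    percentile: float = 99.0,
    seed: int | None = None,
    bin_cm: float = 2.0,
    smooth_bins: int = 5,
    speed_threshold: float = MOVEMENT_SPEED_CM_S,
) -> GridnessResult:
    """Gridness with significance from a spike-vs-tracking time shift shuffle.

    Each surrogate rotates the spike train relative to the tracking data by
    a shift drawn uniformly from [1, T-1] s; the true gridness is
    significant iff it exceeds the stated percentile of the surrogate
    gridness distribution.
    """
    rng = np.random.default_rng(seed)
    duration = trajectory.duration
    shifts = np.concatenate([[0.0], rng.uniform(1.0, duration - 1.0, size=n_shuffles)])
    maps, visited = _shifted_rate_maps(
        spike_times, trajectory, shifts, bin_cm, smooth_bins, speed_threshold
    )
    acs = _masked_autocorr_batch(maps, visited)
    rots = {ang: _rotate_batch(acs, ang) for ang in (30, 60, 90, 120, 150)}
    true_res = gridness(acs[0], bin_cm=bin_cm, _rots={a: rots[a][0] for a in rots})
    shuf_scores = np.array(
        [
            gridness(acs[i], bin_cm=bin_cm, _rots={a: rots[a][i] for a in rots}).score
            for i in range(1, len(acs))
        ]
    )
    threshold = float(np.percentile(shuf_scores, percentile))
    true_res.threshold = threshold
    true_res.significant = bool(true_res.score > threshold)
    return true_res
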