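"""Centre-axis tracing and sliding-window PCA supercoil quantification.

A filament's centre axis is traced from subunit positions by the two-strand
midpoint construction: for subunit ``i`` the anchor is the midpoint of its
strand-opposite neighbours ``i-1`` and ``i+1``, and the axis point ``c_i``
is the midpoint of subunit ``i`` and that anchor.  The resulting ordered
3D trace is analysed with a 300 nm sliding window stepped every 25 nm:
within each window a principal-component decomposition gives the local axis
(PC1) and transverse deviations (PC2, PC3); peaks and troughs of PC2 along
PC1 yield the window's peak-to-peak amplitude, and twice the PC1 distance
between the amplitude-defining peak/trough pair gives the supercoil pitch.
A frame is called a supercoil when its maximal window amplitude reaches
16 nm (about twice the filament diameter) and, when pitch bounds are
enabled, the pitch lies within 75-350 nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import interpolate, signal

__all__ = [
    "Trace", "WindowMetrics", "SupercoilCall",
    "centre_axis", "window_pca", "classify_supercoil", "eccentricity",
    "phase_offset", "align_traces", "resample_trace", "frame_supercoil_calls",
    "AMPLITUDE_CUTOFF_NM", "PITCH_BOUNDS_NM", "WINDOW_NM", "STEP_NM",
]

WINDOW_NM = 300.0
STEP_NM = 25.0
AMPLITUDE_CUTOFF_NM = 16.0
PITCH_BOUNDS_NM = (75.0, 350.0)
#: minimum peak/trough prominence (nm) used to suppress noise
PEAK_PROMINENCE_NM = 1.0


@dataclass
class Trace:
    """Ordered centre-axis points (nm)."""

    points: np.ndarray
    source: str = "simulation"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[0] < 3:
            raise ValueError("a trace needs at least 3 ordered points")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("non-finite trace coordinates")

    @property
    def n_points(self) -> int:
        return len(self.points)

    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.points, axis=0), axis=1)

    def arc_length(self) -> np.ndarray:
        """Cumulative arc length, starting at 0."""
        return np.concatenate([[0.0], np.cumsum(self.segment_lengths())])

    @property
    def contour_length(self) -> float:
        return float(self.segment_lengths().sum())


@dataclass
class WindowMetrics:
    """Shape descriptors of one sliding window."""

    start_nm: float
    axes: np.ndarray               # (3, ndim) principal axes, rows
    coords: np.ndarray             # (k, ndim) projections onto the axes
    amplitude_nm: float            # peak-to-peak along PC2
    pitch_nm: Optional[float]      # 2 x PC1 peak-trough distance
    eccentricity: Optional[float] = None


@dataclass
class SupercoilCall:
    amplitude_nm: float
    pitch_nm: Optional[float]
    is_supercoil: bool
    window: Optional[WindowMetrics] = None
    amplitude_cutoff_nm: float = AMPLITUDE_CUTOFF_NM
    pitch_bounds_nm: Optional[tuple[float, float]] = PITCH_BOUNDS_NM


def centre_axis(positions: np.ndarray, source: str = "simulation") -> Trace:
    """Centre-axis trace of a two-strand filament frame.

    c_i = midpoint(subunit i, midpoint(subunit i-1, subunit i+1)); the two
    terminal subunits are dropped.
    """
    p = np.asarray(positions, dtype=float)
    if len(p) < 3:
        raise ValueError("need at least 3 subunits")
    anchors = 0.5 * (p[:-2] + p[2:])
    c = 0.5 * (p[1:-1] + anchors)
    return Trace(points=c, source=source)


def _pca(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal axes (rows, descending variance) and projected coords."""
    centred = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    # sign convention: PC1 points along increasing trace order
    if centred[-1] @ vt[0] < centred[0] @ vt[0]:
        vt[0] = -vt[0]
    if vt.shape[0] == 3 and np.linalg.det(vt) < 0:
        vt[2] = -vt[2]
    return vt, centred @ vt.T


def _extrema(u: np.ndarray, prominence: float) -> tuple[np.ndarray, np.ndarray]:
    peaks, _ = signal.find_peaks(u, prominence=prominence)
    troughs, _ = signal.find_peaks(-u, prominence=prominence)
    return peaks, troughs


def _amplitude_and_pitch(t: np.ndarray, u: np.ndarray,
                         prominence: float) -> tuple[float, Optional[float]]:
    """Max |PC2 difference| between *neighbouring* peak/trough, and the
    pitch (2 x PC1 separation) of the pair realizing it."""
    peaks, troughs = _extrema(u, prominence)
    if len(peaks) == 0 or len(troughs) == 0:
        return 0.0, None
    kinds = np.concatenate([np.ones(len(peaks), dtype=int),
                            -np.ones(len(troughs), dtype=int)])
    idx = np.concatenate([peaks, troughs])
    order = np.argsort(idx)
    idx, kinds = idx[order], kinds[order]
    best_amp, best_pitch = 0.0, None
    for a, b in zip(range(len(idx) - 1), range(1, len(idx))):
        if kinds[a] == kinds[b]:
            continue
        amp = abs(u[idx[a]] - u[idx[b]])
        if amp > best_amp:
            best_amp = amp
            best_pitch = 2.0 * abs(t[idx[a]] - t[idx[b]])
    return best_amp, best_pitch


def window_pca(trace: Trace, window_nm: float = WINDOW_NM,
               step_nm: float = STEP_NM,
               prominence_nm: float = PEAK_PROMINENCE_NM) -> list[WindowMetrics]:
    """Sliding-window PCA along the trace contour.

    The last partial window is dropped.  Returns an empty list (with a
    warning) if the contour is shorter than one window.
    """
    s = trace.arc_length()
    total = s[-1]
    out: list[WindowMetrics] = []
    if total < window_nm:
        import warnings
        warnings.warn("trace contour shorter than the analysis window",
                      stacklevel=2)
        return out
    start = 0.0
    while start + window_nm <= total + 1e-9:
        mask = (s >= start - 1e-9) & (s <= start + window_nm + 1e-9)
        pts = trace.points[mask]
        if len(pts) >= 4:
            axes, coords = _pca(pts)
            amp, pitch = _amplitude_and_pitch(coords[:, 0], coords[:, 1],
                                              prominence_nm)
            out.append(WindowMetrics(start_nm=start, axes=axes, coords=coords,
                                     amplitude_nm=amp, pitch_nm=pitch))
        start += step_nm
    return out


def classify_supercoil(windows: Sequence[WindowMetrics],
                       amplitude_cutoff_nm: float = AMPLITUDE_CUTOFF_NM,
                       pitch_bounds_nm: Optional[tuple[float, float]] = PITCH_BOUNDS_NM,
                       ) -> SupercoilCall:
    """Frame-level supercoil call from the maximal-amplitude window."""
    if not windows:
        raise ValueError("no windows to classify")
    best = max(windows, key=lambda w: w.amplitude_nm)
    amp, pitch = best.amplitude_nm, best.pitch_nm
    ok = amp >= amplitude_cutoff_nm
    if ok and pitch_bounds_nm is not None:
        ok = pitch is not None and pitch_bounds_nm[0] <= pitch <= pitch_bounds_nm[1]
    return SupercoilCall(amplitude_nm=amp, pitch_nm=pitch, is_supercoil=bool(ok),
                         window=best, amplitude_cutoff_nm=amplitude_cutoff_nm,
                         pitch_bounds_nm=pitch_bounds_nm)


def eccentricity(window: WindowMetrics) -> float:
    """Eccentricity of the supercoil cross-section.

    An ellipse is fitted to the PC2-PC3 projection of the window (direct
    least-squares conic fit via skimage); if the fit is degenerate the
    PCA axis-ratio sqrt(1 - lambda3/lambda2) is used instead.
    """
    if window.coords.shape[1] < 3 or window.coords.shape[0] < 5:
        raise ValueError("eccentricity needs >= 5 points of a 3D window")
    xy = window.coords[:, 1:3]
    try:
        from skimage.measure import EllipseModel
        model = EllipseModel()
        if model.estimate(xy):
            a, b = model.params[2], model.params[3]
            a, b = max(a, b), min(a, b)
            if np.isfinite(a) and a > 0 and b >= 0:
                return float(np.sqrt(max(0.0, 1.0 - (b / a) ** 2)))
    except Exception:
        pass
    centred = xy - xy.mean(axis=0)
    lam = np.linalg.svd(centred, compute_uv=False) ** 2
    if lam[0] <= 0:
        return 0.0
    return float(np.sqrt(max(0.0, 1.0 - lam[1] / lam[0])))


def phase_offset(window: WindowMetrics,
                 prominence_nm: float = PEAK_PROMINENCE_NM) -> Optional[float]:
    """Fractional wavelength offset between the PC1-PC2 and PC1-PC3
    oscillations, in [0, 0.5].

    An ideal circular helix gives 0.25 (sine vs cosine).  Returns None when
    either projection shows no detectable oscillation (e.g. a planar sine,
    whose PC3 component is flat).
    """
    if window.coords.shape[1] < 3:
        return None
    t = window.coords[:, 0]
    wavelength = window.pitch_nm
    if wavelength is None or wavelength <= 0:
        return None
    offsets = []
    ex2 = np.sort(np.concatenate(_extrema(window.coords[:, 1], prominence_nm)))
    ex3 = np.sort(np.concatenate(_extrema(window.coords[:, 2], prominence_nm)))
    if len(ex2) == 0 or len(ex3) == 0:
        return None
    for i in ex2:
        d = np.min(np.abs(t[ex3] - t[i]))
        offsets.append(d / wavelength)
    off = float(np.median(offsets))
    # fold into [0, 0.5]
    off = off % 1.0
    return min(off, 1.0 - off) if off > 0.5 else off


def frame_supercoil_calls(frames, window_nm: float = WINDOW_NM,
                          step_nm: float = STEP_NM,
                          amplitude_cutoff_nm: float = AMPLITUDE_CUTOFF_NM,
                          pitch_bounds_nm: Optional[tuple[float, float]] = PITCH_BOUNDS_NM,
                          burn_in_frac: float = 0.0) -> list[SupercoilCall]:
    """Centre-axis trace + window PCA + supercoil call for every frame."""
    frames = frames[int(len(frames) * burn_in_frac):]
    calls = []
    for fr in frames:
        windows = window_pca(centre_axis(fr), window_nm, step_nm)
        if windows:
            calls.append(classify_supercoil(windows, amplitude_cutoff_nm,
                                            pitch_bounds_nm))
    return calls


def resample_trace(trace: Trace, spacing_nm: float = 0.96,
                   smoothing: float = 0.0) -> Trace:
    """Smoothing-spline fit resampled at even arc length.

    Default spacing is 9.6 A (the tomogram-trace convention); ``smoothing``
    is the scipy splprep ``s`` factor (150 was used for manually picked
    tomogram traces; 0 interpolates).
    """
    if trace.n_points < 4:
        raise ValueError("need at least 4 points to fit a spline")
    if spacing_nm >= trace.contour_length:
        raise ValueError("spacing exceeds the trace contour length")
    u = trace.arc_length()
    u = u / u[-1]
    tck, _ = interpolate.splprep(trace.points.T, u=u, s=smoothing, k=3)
    # even arc-length resampling via a dense intermediate evaluation
    dense = np.linspace(0, 1, max(20 * trace.n_points, 1000))
    pts = np.array(interpolate.splev(dense, tck)).T
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.arange(0.0, s[-1] + 1e-9, spacing_nm)
    u_of_s = np.interp(targets, s, dense)
    out = np.array(interpolate.splev(u_of_s, tck)).T
    return Trace(points=out, source=trace.source)


def align_traces(traces: Sequence[Trace], window_nm: float = 350.0,
                 n_samples: int = 141) -> dict:
    """Align supercoil traces on their maximal-amplitude extremum.

    Each trace is PCA-decomposed globally; the PC2 extremum of largest
    magnitude is moved to the centre, the PC2 sign is normalized so the
    second derivative at the centre is positive (the centre is a trough),
    and traces whose decomposition runs backwards are end-flipped.  Traces
    are then sampled on a common PC1 grid spanning ``window_nm`` and
    averaged.
    """
    if len(traces) < 2:
        raise ValueError("need at least two traces to align")
    grid = np.linspace(-window_nm / 2, window_nm / 2, n_samples)
    aligned_pc2, aligned_pc3 = [], []
    for tr in traces:
        axes, coords = _pca(tr.points)
        t, u2 = coords[:, 0], coords[:, 1]
        u3 = coords[:, 2] if coords.shape[1] == 3 else np.zeros_like(u2)
        if t[-1] < t[0]:  # inverted decomposition: flip the starting end
            t, u2, u3 = t[::-1], u2[::-1], u3[::-1]
        i0 = int(np.argmax(np.abs(u2)))
        if u2[i0] > 0:  # sign-normalize: centre extremum must be a trough
            u2 = -u2
        tc = t - t[i0]
        aligned_pc2.append(np.interp(grid, tc, u2, left=np.nan, right=np.nan))
        aligned_pc3.append(np.interp(grid, tc, u3, left=np.nan, right=np.nan))
    pc2 = np.array(aligned_pc2)
    pc3 = np.array(aligned_pc3)
    return {
        "grid_nm": grid,
        "pc2": pc2,
        "pc3": pc3,
        "mean_pc2": np.nanmean(pc2, axis=0),
        "mean_pc3": np.nanmean(pc3, axis=0),
    }
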