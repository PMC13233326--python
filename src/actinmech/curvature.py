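"""Boltzmann curvature statistics and 2D filament-trace quantification.

A free, unloaded semiflexible filament samples curvatures according to the
Boltzmann weight of its bending energy

    E(kappa) = 1/2 k_B T L_p L kappa^2,

so the curvature distribution over a discrete grid is

    P(kappa) = exp(-alpha L_p L kappa^2 / 2) / Z,

with L_p the persistence length (um), L the segment length (um), kappa the
curvature (1/um), and alpha a dimensionless multiplicative adjustment that
serves as a proxy for a different effective persistence length (alpha = 1
is the bare wormlike-chain prediction).  Only the product alpha*L_p*L is
identifiable.

The module also implements the 2D trace rules used on projection images:
sliding-window (300 nm / 25 nm) PC decomposition with peak-to-peak
amplitude, the 325 nm minimum-contour retention rule, and the
oscillating-curvature supercoil segment selection (a >= 200 A run of
instantaneous curvature >= +1.5/um *and* one of <= -1.5/um on the same
filament, terminal regions excluded).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import interpolate, optimize

from .traces import Trace, WindowMetrics, _amplitude_and_pitch, _pca
from .units import KB

__all__ = [
    "Spline2D", "bend_energy", "curvature_pmf", "fit_alpha",
    "select_oscillating_segments", "quantify_trace_2d",
]

#: default curvature sampling interval: three pixels at 4.32 A/px, in nm
CURVATURE_SAMPLE_NM = 1.296
#: default terminal exclusion: 50 pixels at 4.32 A/px, in nm
TERMINAL_TRIM_NM = 21.6
#: minimum oscillating-run length: 200 A
MIN_RUN_NM = 20.0
CURVATURE_THRESHOLD_PER_UM = 1.5
MIN_TRACE_LENGTH_NM = 325.0


@dataclass
class Spline2D:
    """A planar filament trace with analytic signed curvature.

    Curvature sign convention: positive = left turn along the
    parameterization (only sign changes matter for segment selection).
    """

    points: np.ndarray          # (n, 2) nm
    smoothing: float = 0.0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("expected (n, 2) planar coordinates")
        if len(self.points) < 4:
            raise ValueError("need at least 4 points")
        u = np.concatenate([[0.0], np.cumsum(
            np.linalg.norm(np.diff(self.points, axis=0), axis=1))])
        self._length = float(u[-1])
        self._tck, _ = interpolate.splprep(self.points.T, u=u / u[-1],
                                           s=self.smoothing, k=3)

    @property
    def contour_length(self) -> float:
        return self._length

    def sample_curvature(self, ds_nm: float = CURVATURE_SAMPLE_NM
                         ) -> tuple[np.ndarray, np.ndarray]:
        """(arc positions nm, signed curvature 1/um) at fixed arc intervals."""
        if ds_nm <= 0:
            raise ValueError("sampling interval must be positive")
        u = np.linspace(0, 1, max(int(4 * self._length / ds_nm), 200))
        xy = np.array(interpolate.splev(u, self._tck)).T
        seg = np.linalg.norm(np.diff(xy, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        targets = np.arange(0.0, s[-1] + 1e-9, ds_nm)
        ut = np.interp(targets, s, u)
        dx, dy = interpolate.splev(ut, self._tck, der=1)
        ddx, ddy = interpolate.splev(ut, self._tck, der=2)
        kappa_nm = (dx * ddy - dy * ddx) / np.power(dx * dx + dy * dy, 1.5)
        return targets, kappa_nm * 1000.0  # 1/nm -> 1/um


def bend_energy(kappa_per_um, L_p_um: float, L_um: float,
                temperature_K: float = 298.0):
    """Bending energy E = 1/2 k_B T L_p L kappa^2, in joules."""
    if L_p_um <= 0 or L_um <= 0:
        raise ValueError("persistence and segment lengths must be positive")
    kappa = np.asarray(kappa_per_um, dtype=float)
    return 0.5 * KB * temperature_K * L_p_um * L_um * kappa**2


def curvature_pmf(grid_per_um: np.ndarray, L_p_um: float, L_um: float,
                  alpha: float = 1.0) -> np.ndarray:
    """Normalized Boltzmann curvature probabilities over a finite grid."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    grid = np.asarray(grid_per_um, dtype=float)
    if grid.size == 0 or not np.all(np.isfinite(grid)):
        raise ValueError("grid must be finite and non-empty")
    logw = -0.5 * alpha * L_p_um * L_um * grid**2
    logw -= logw.max()
    w = np.exp(logw)
    return w / w.sum()


def fit_alpha(observed_per_um: np.ndarray, L_p_um: float, L_um: float,
              grid: Optional[np.ndarray] = None) -> float:
    """Maximum-likelihood adjustment factor under the discretized model.

    Observations are assigned to the nearest grid point; with no grid
    supplied a symmetric grid spanning the data is built.  Returns
    ``numpy.inf`` (with a warning) for degenerate all-zero data.
    """
    obs = np.asarray(observed_per_um, dtype=float)
    if obs.size < 2:
        raise ValueError("need at least 2 observations")
    m2 = float(np.mean(obs**2))
    if m2 == 0.0:
        warnings.warn("all observed curvatures are zero; alpha is unbounded",
                      stacklevel=2)
        return float(np.inf)
    if grid is None:
        span = max(np.abs(obs).max() * 1.5, 1e-6)
        grid = np.linspace(-span, span, 401)
    grid = np.sort(np.asarray(grid, dtype=float))
    idx = np.clip(np.searchsorted(grid, obs), 1, len(grid) - 1)
    idx -= (obs - grid[idx - 1]) < (grid[idx] - obs)
    counts = np.bincount(idx, minlength=len(grid))

    def nll(log_alpha: float) -> float:
        p = curvature_pmf(grid, L_p_um, L_um, np.exp(log_alpha))
        with np.errstate(divide="ignore"):
            lp = np.log(p)
        return -float(np.sum(counts * np.where(counts > 0, lp, 0.0)))

    # continuous-Gaussian moment estimate seeds the search
    a0 = 1.0 / (L_p_um * L_um * m2)
    res = optimize.minimize_scalar(nll, bracket=(np.log(a0) - 1, np.log(a0) + 1))
    return float(np.exp(res.x))


def _runs(mask: np.ndarray, s: np.ndarray, min_len_nm: float) -> list[tuple[float, float]]:
    """Contiguous True runs of arc-length >= min_len_nm, as (start, end) nm."""
    runs = []
    start = None
    for i, flag in enumerate(mask):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if s[i - 1] - s[start] >= min_len_nm:
                runs.append((float(s[start]), float(s[i - 1])))
            start = None
    if start is not None and s[len(mask) - 1] - s[start] >= min_len_nm:
        runs.append((float(s[start]), float(s[-1])))
    return runs


def select_oscillating_segments(spline: Spline2D,
                                kappa_thresh_per_um: float = CURVATURE_THRESHOLD_PER_UM,
                                min_run_nm: float = MIN_RUN_NM,
                                trim_nm: float = TERMINAL_TRIM_NM,
                                ds_nm: float = CURVATURE_SAMPLE_NM,
                                ) -> tuple[bool, dict]:
    """Supercoil segment selection on a 2D trace.

    True iff, after trimming the terminal regions, the trace contains a run
    of at least ``min_run_nm`` where curvature stays >= +threshold *and*
    another where it stays <= -threshold — excluding straight filaments and
    filaments curving uniformly in one direction.
    """
    s, kappa = spline.sample_curvature(ds_nm)
    keep = (s >= trim_nm) & (s <= s[-1] - trim_nm)
    s, kappa = s[keep], kappa[keep]
    if len(s) < 2:
        return False, {"positive_runs": [], "negative_runs": []}
    pos = _runs(kappa >= kappa_thresh_per_um, s, min_run_nm)
    neg = _runs(kappa <= -kappa_thresh_per_um, s, min_run_nm)
    return bool(pos and neg), {"positive_runs": pos, "negative_runs": neg}


def quantify_trace_2d(points_nm: np.ndarray, window_nm: float = 300.0,
                      step_nm: float = 25.0,
                      min_length_nm: float = MIN_TRACE_LENGTH_NM,
                      prominence_nm: float = 1.0) -> dict:
    """Sliding-window amplitude quantification of a 2D filament trace.

    Traces shorter than ``min_length_nm`` are rejected.  Returns the best
    window's peak-to-peak amplitude, its pitch (wavelength) and the mean
    absolute curvature within that window.
    """
    pts = np.asarray(points_nm, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("expected (n, 2) planar coordinates")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] < min_length_nm:
        raise ValueError(
            f"trace contour {s[-1]:.0f} nm below the {min_length_nm:.0f} nm "
            "retention threshold")

    spline = Spline2D(pts)
    s_k, kappa = spline.sample_curvature()

    best = {"amplitude_nm": 0.0, "pitch_nm": None, "window_start_nm": None,
            "mean_abs_curvature_per_um": None}
    start = 0.0
    while start + window_nm <= s[-1] + 1e-9:
        mask = (s >= start - 1e-9) & (s <= start + window_nm + 1e-9)
        wpts = pts[mask]
        if len(wpts) >= 4:
            _, coords = _pca(wpts)
            amp, pitch = _amplitude_and_pitch(coords[:, 0], coords[:, 1],
                                              prominence_nm)
            if amp > best["amplitude_nm"]:
                kmask = (s_k >= start) & (s_k <= start + window_nm)
                best = {"amplitude_nm": float(amp), "pitch_nm": pitch,
                        "window_start_nm": float(start),
                        "mean_abs_curvature_per_um":
                            float(np.mean(np.abs(kappa[kmask]))) if kmask.any() else None}
        start += step_nm
    return best
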