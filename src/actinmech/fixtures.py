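"""Synthetic inputs with machine-readable ground truth.

Every generator returns both the data object the pipeline consumes and a
dict of the parameters that generated it, so estimator tests always compare
against the construction rather than hard-coded numbers.  Noise is isotropic
Gaussian displacement per point; seeded generation is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .geometry import HelicalGeometry, PotentialParams, build_filament
from .traces import Trace

__all__ = [
    "FixtureSpec", "make_supercoil_trace", "make_planar_sine",
    "make_straight_trace", "make_wlc_traces", "make_modulated_lattice",
    "make_trace2d",
]

#: default sampling step: 9.6 A, the tomogram-trace resampling convention
DEFAULT_STEP_NM = 0.96


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative description of one synthetic input."""

    kind: str                       # straight | planar_sine | circular_supercoil |
                                    # elliptical_supercoil | wlc_thermal |
                                    # modulated_lattice | trace2d
    params: dict = field(default_factory=dict)
    noise_sd_nm: float = 0.0
    seed: int = 0

    def make(self):
        makers = {
            "straight": make_straight_trace,
            "planar_sine": make_planar_sine,
            "circular_supercoil": make_supercoil_trace,
            "elliptical_supercoil": make_supercoil_trace,
            "wlc_thermal": make_wlc_traces,
            "trace2d": make_trace2d,
        }
        if self.kind not in makers and self.kind != "modulated_lattice":
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if self.kind == "modulated_lattice":
            return make_modulated_lattice(**self.params)
        return makers[self.kind](**self.params, noise_sd_nm=self.noise_sd_nm,
                                 seed=self.seed)


def _noise(rng: np.random.Generator, shape, sd: float) -> np.ndarray:
    return rng.normal(0.0, sd, shape) if sd > 0 else np.zeros(shape)


def make_supercoil_trace(radius_nm: float = 10.0, pitch_nm: float = 200.0,
                         length_nm: float = 1000.0, axis_ratio: float = 1.0,
                         phase_rad: float = 0.0, step_nm: float = 2.5,
                         noise_sd_nm: float = 0.0, seed: int = 0,
                         ) -> tuple[Trace, dict]:
    """Helical trace about a straight axis: ground-truth amplitude 2R,
    pitch p; an ``axis_ratio`` > 1 squeezes the cross-section into an
    ellipse (major axis R), giving eccentricity sqrt(1 - 1/axis_ratio^2)."""
    if pitch_nm <= 0 or length_nm <= 0:
        raise ValueError("pitch and length must be positive")
    if radius_nm < 0 or axis_ratio < 1.0:
        raise ValueError("radius >= 0 and axis_ratio >= 1 required")
    rng = np.random.default_rng(seed)
    z = np.arange(0.0, length_nm + 1e-9, step_nm)
    theta = 2.0 * np.pi * z / pitch_nm + phase_rad
    pts = np.column_stack([
        radius_nm * np.cos(theta),
        (radius_nm / axis_ratio) * np.sin(theta),
        z,
    ])
    pts += _noise(rng, pts.shape, noise_sd_nm)
    truth = {
        "amplitude_nm": 2.0 * radius_nm,
        "pitch_nm": pitch_nm,
        "eccentricity": float(np.sqrt(1.0 - 1.0 / axis_ratio**2)),
        "phase_offset": 0.25,
        "noise_sd_nm": noise_sd_nm,
    }
    return Trace(points=pts, source="synthetic"), truth


def make_planar_sine(amplitude_nm: float = 10.0, wavelength_nm: float = 200.0,
                     length_nm: float = 1000.0, step_nm: float = 2.5,
                     noise_sd_nm: float = 0.0, seed: int = 0,
                     ) -> tuple[Trace, dict]:
    """Planar sinusoid: peak-to-peak amplitude 2A, flat cross-section."""
    rng = np.random.default_rng(seed)
    x = np.arange(0.0, length_nm + 1e-9, step_nm)
    pts = np.column_stack([
        x, amplitude_nm * np.sin(2.0 * np.pi * x / wavelength_nm),
        np.zeros_like(x)])
    pts += _noise(rng, pts.shape, noise_sd_nm)
    truth = {"amplitude_nm": 2.0 * amplitude_nm, "pitch_nm": wavelength_nm,
             "eccentricity": 1.0}
    return Trace(points=pts, source="synthetic"), truth


def make_straight_trace(length_nm: float = 1000.0, step_nm: float = 2.5,
                        noise_sd_nm: float = 0.0, seed: int = 0,
                        ) -> tuple[Trace, dict]:
    rng = np.random.default_rng(seed)
    z = np.arange(0.0, length_nm + 1e-9, step_nm)
    pts = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
    pts += _noise(rng, pts.shape, noise_sd_nm)
    return Trace(points=pts, source="synthetic"), {"amplitude_nm": 0.0}


def make_wlc_traces(persistence_um: float = 9.0, length_nm: float = 270.0,
                    n_traces: int = 500, step_nm: float = DEFAULT_STEP_NM,
                    noise_sd_nm: float = 0.0, seed: int = 0,
                    ) -> tuple[list[Trace], dict]:
    """Discrete wormlike chains with tangent correlations exp(-s/P).

    Each bond bends by Gaussian transverse angles of variance step/P per
    component (two components), the standard discretization whose tangent
    autocorrelation decays as exp(-s/P) in 3D.
    """
    if persistence_um <= 0 or length_nm <= 0:
        raise ValueError("P and L must be positive")
    rng = np.random.default_rng(seed)
    p_nm = persistence_um * 1000.0
    n_steps = int(round(length_nm / step_nm))
    traces = []
    for _ in range(n_traces):
        t = np.array([0.0, 0.0, 1.0])
        pts = np.zeros((n_steps + 1, 3))
        for i in range(n_steps):
            # transverse kick in the frame of the current tangent
            e1 = np.cross(t, [1.0, 0.0, 0.0])
            if np.linalg.norm(e1) < 1e-6:
                e1 = np.cross(t, [0.0, 1.0, 0.0])
            e1 /= np.linalg.norm(e1)
            e2 = np.cross(t, e1)
            a1, a2 = rng.normal(0.0, np.sqrt(step_nm / p_nm), 2)
            t = t + a1 * e1 + a2 * e2
            t /= np.linalg.norm(t)
            pts[i + 1] = pts[i] + step_nm * t
        pts += _noise(rng, pts.shape, noise_sd_nm)
        traces.append(Trace(points=pts, source="synthetic"))
    truth = {"persistence_um": persistence_um, "length_nm": length_nm,
             "step_nm": step_nm}
    return traces, truth


def make_modulated_lattice(rise_profile_nm: np.ndarray,
                           twist_profile_deg: np.ndarray,
                           radius_nm: float = 1.6) -> tuple[np.ndarray, dict]:
    """Protomer chain built by sequential per-interface rise/twist.

    Constant canonical profiles reproduce the canonical lattice exactly.
    Returns (positions (n, 3) nm, ground truth).
    """
    h = np.asarray(rise_profile_nm, dtype=float)
    b = np.deg2rad(np.asarray(twist_profile_deg, dtype=float))
    if h.shape != b.shape:
        raise ValueError("profiles must have equal length")
    n = len(h) + 1
    z = np.concatenate([[0.0], np.cumsum(h)])
    phi = np.concatenate([[0.0], np.cumsum(b)])
    pts = np.column_stack([radius_nm * np.cos(phi), radius_nm * np.sin(phi), z])
    truth = {"rise_nm": h, "twist_deg": np.rad2deg(b), "radius_nm": radius_nm}
    return pts, truth


def make_trace2d(kind: str = "sine", peak_kappa_per_um: float = 3.0,
                 wavelength_nm: Optional[float] = None,
                 length_nm: float = 600.0, step_nm: float = 1.0,
                 noise_sd_nm: float = 0.0, seed: int = 0) -> tuple[np.ndarray, dict]:
    """2D curves with analytically known signed curvature.

    kinds: "sine" (y = A sin(2 pi x / lambda), peak curvature ~ A (2pi/l)^2),
    "arc" (constant curvature +peak_kappa), "straight".
    For the sine, the requested peak curvature sets the amplitude given the
    wavelength (default 400 nm).
    """
    rng = np.random.default_rng(seed)
    if kind == "straight":
        x = np.arange(0.0, length_nm + 1e-9, step_nm)
        pts = np.column_stack([x, np.zeros_like(x)])
        truth = {"kappa_per_um": 0.0}
    elif kind == "arc":
        r_nm = 1000.0 / peak_kappa_per_um
        smax = min(length_nm, 2 * np.pi * r_nm * 0.9)
        s = np.arange(0.0, smax, step_nm)
        ang = s / r_nm
        pts = np.column_stack([r_nm * np.sin(ang), r_nm * (1 - np.cos(ang))])
        truth = {"kappa_per_um": peak_kappa_per_um}
    elif kind == "sine":
        lam = wavelength_nm or 400.0
        k = 2.0 * np.pi / lam                     # 1/nm
        amp = (peak_kappa_per_um / 1000.0) / k**2  # kappa_max = A k^2
        x = np.arange(0.0, length_nm + 1e-9, step_nm)
        pts = np.column_stack([x, amp * np.sin(k * x)])
        truth = {"kappa_per_um": peak_kappa_per_um, "wavelength_nm": lam,
                 "amplitude_nm": amp}
    else:
        raise ValueError(f"unknown 2D trace kind {kind!r}")
    pts = pts + _noise(rng, pts.shape, noise_sd_nm)
    return pts, truth
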