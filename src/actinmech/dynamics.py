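"""Langevin dynamics of the filament spring network.

The integrator is a BAOAB splitting of the Langevin equation (velocity
Verlet interleaved with an exact Ornstein-Uhlenbeck friction/noise step),
which samples configurational averages accurately even at fairly large time
steps.  Constraints: permanently fixed subunits never move; a rigid end
group translates without rotating (its forces, velocities and thermal kicks
are averaged over the group).  Bond rupture is irreversible: once a diagonal
or longitudinal bond exceeds its critical length it is removed, together
with every angle/dihedral whose bonded path runs through it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernels
from .geometry import (DIAGONAL, FilamentLattice, critical_bond_lengths)
from .protocols import ForceProtocol, compile_protocol, tether_ends
from .units import UnitSystem, make_units, stokes_friction

__all__ = ["SimConfig", "SimState", "Trajectory", "run",
           "potential_energy", "forces", "check_ruptures"]


@dataclass(frozen=True)
class SimConfig:
    """Integration settings (reduced units unless noted).

    gamma: friction in reduced mass/time; None -> Stokes drag of water at
    room temperature for a subunit-sized sphere (~61.5 reduced).
    """

    n_steps: int
    dt: float = 0.005
    gamma: Optional[float] = None
    temperature_K: float = 298.0
    frame_interval: int = 100
    seed: int = 0
    rupture_enabled: bool = False
    rupture_thresholds: Optional[tuple[float, float]] = None  # (diag, long) nm
    #: a bond severs after staying beyond threshold for this long (reduced
    #: time); thermal excursions above threshold last ~0.05 reduced time, so
    #: the default only passes sustained, mechanically driven overextension
    rupture_dwell_time: float = 0.25
    max_disp: float = 2.78  # abort threshold, nm per step

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.n_steps < 1 or self.frame_interval < 1:
            raise ValueError("invalid integration settings")
        if self.gamma is not None and self.gamma < 0:
            raise ValueError("friction must be non-negative")

    def resolved_gamma(self, units: UnitSystem) -> float:
        if self.gamma is not None:
            return self.gamma
        return units.friction_to_reduced(stokes_friction())


@dataclass
class SimState:
    """Instantaneous mechanical state."""

    positions: np.ndarray
    velocities: np.ndarray
    bond_intact: np.ndarray
    step: int = 0
    fixed: tuple[int, ...] = ()


@dataclass
class Trajectory:
    """Time-ordered frames with bond-intactness flags and run metadata."""

    frames: np.ndarray          # (F, n, 3) nm
    times: np.ndarray           # (F,) reduced time
    bond_intact: np.ndarray     # (F, m) bool
    rupture_events: list[tuple[int, int]]  # (step, bond id)
    final_velocities: np.ndarray
    lattice: FilamentLattice
    config: SimConfig
    protocol: ForceProtocol
    metadata: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def first_rupture_step(self) -> Optional[int]:
        return self.rupture_events[0][0] if self.rupture_events else None


class IntegrationError(RuntimeError):
    pass


def _topology_arrays(lattice: FilamentLattice):
    p = lattice.params
    return dict(
        bonds=lattice.bonds, bond_l0=lattice.bond_l0,
        bond_class=lattice.bond_class, k_l=p.k_l,
        angles=lattice.angles, angle_theta0=lattice.angle_theta0,
        k_theta=p.k_theta,
        dihedrals=lattice.dihedrals, dihedral_phi0=lattice.dihedral_phi0,
        k_phi=p.k_phi, n_mult=p.n_mult,
    )


def potential_energy(positions: np.ndarray, lattice: FilamentLattice,
                     bond_intact: Optional[np.ndarray] = None) -> dict[str, float]:
    """Per-term potential energy (reduced units): bond, angle, dihedral."""
    if not np.all(np.isfinite(positions)):
        raise ValueError("non-finite coordinates")
    t = _topology_arrays(lattice)
    intact = (np.ones(len(lattice.bonds), dtype=np.bool_)
              if bond_intact is None else np.asarray(bond_intact, dtype=np.bool_))
    ang_act, dih_act = _active_terms(lattice, intact)
    f = np.zeros_like(positions)
    vb, va, vd = _kernels.bonded_forces(
        np.ascontiguousarray(positions, dtype=np.float64), f,
        t["bonds"], t["bond_l0"], intact, t["k_l"],
        t["angles"], t["angle_theta0"], ang_act, t["k_theta"],
        t["dihedrals"], t["dihedral_phi0"], dih_act, t["k_phi"], t["n_mult"])
    return {"bond": vb, "angle": va, "dihedral": vd, "total": vb + va + vd}


def forces(positions: np.ndarray, lattice: FilamentLattice,
           bond_intact: Optional[np.ndarray] = None) -> np.ndarray:
    """Per-subunit internal forces, -grad V (reduced energy / nm)."""
    if not np.all(np.isfinite(positions)):
        raise ValueError("non-finite coordinates")
    t = _topology_arrays(lattice)
    intact = (np.ones(len(lattice.bonds), dtype=np.bool_)
              if bond_intact is None else np.asarray(bond_intact, dtype=np.bool_))
    ang_act, dih_act = _active_terms(lattice, intact)
    f = np.zeros_like(positions, dtype=np.float64)
    _kernels.bonded_forces(
        np.ascontiguousarray(positions, dtype=np.float64), f,
        t["bonds"], t["bond_l0"], intact, t["k_l"],
        t["angles"], t["angle_theta0"], ang_act, t["k_theta"],
        t["dihedrals"], t["dihedral_phi0"], dih_act, t["k_phi"], t["n_mult"])
    return f


def _active_terms(lattice: FilamentLattice, bond_intact: np.ndarray):
    """Angle/dihedral activity masks: a term dies with any constituent bond."""
    ab = lattice.angle_bonds
    db = lattice.dihedral_bonds
    ext = np.append(bond_intact, True)  # padding index -1 -> always intact
    ang_act = ext[ab].all(axis=1)
    dih_act = ext[db].all(axis=1)
    return np.ascontiguousarray(ang_act), np.ascontiguousarray(dih_act)


def check_ruptures(state: SimState, lattice: FilamentLattice,
                   thresholds: tuple[float, float]) -> list[int]:
    """Bond ids whose instantaneous length exceeds the class threshold.

    Marks them broken in ``state.bond_intact`` (irreversibly: already-broken
    bonds are never re-flagged or restored).
    """
    l_diag, l_long = thresholds
    d = np.linalg.norm(state.positions[lattice.bonds[:, 0]]
                       - state.positions[lattice.bonds[:, 1]], axis=1)
    thr = np.where(lattice.bond_class == DIAGONAL, l_diag, l_long)
    newly = np.flatnonzero(state.bond_intact & (d > thr))
    state.bond_intact[newly] = False
    return list(newly)


def run(lattice: FilamentLattice, config: SimConfig,
        protocol: Optional[ForceProtocol] = None,
        units: Optional[UnitSystem] = None,
        initial_state: Optional[SimState] = None) -> Trajectory:
    """Integrate the Langevin dynamics and return the trajectory.

    Deterministic for a given (seed, config, protocol).  Raises
    :class:`IntegrationError` if any subunit moves more than
    ``config.max_disp`` nm in one step.
    """
    units = units or make_units()
    n = lattice.n_subunits
    protocol = protocol or tether_ends(0, 0, n)
    arrs = compile_protocol(protocol, n, config.n_steps, units)
    t = _topology_arrays(lattice)

    if initial_state is not None:
        pos = np.array(initial_state.positions, dtype=np.float64)
        vel = np.array(initial_state.velocities, dtype=np.float64)
        intact = np.array(initial_state.bond_intact, dtype=np.bool_)
    else:
        pos = np.array(lattice.positions, dtype=np.float64)
        vel = np.zeros_like(pos)
        intact = np.ones(len(lattice.bonds), dtype=np.bool_)
    ang_act, dih_act = _active_terms(lattice, intact)

    thresholds = config.rupture_thresholds or critical_bond_lengths(
        radius_nm=lattice.geometry.radius_nm)

    n_frames = config.n_steps // config.frame_interval + 1
    frames = np.zeros((n_frames, n, 3))
    frame_intact = np.zeros((n_frames, len(lattice.bonds)), dtype=np.bool_)
    times = np.zeros(n_frames)
    rupture_steps = np.zeros(len(lattice.bonds), dtype=np.int64)
    rupture_bonds = np.zeros(len(lattice.bonds), dtype=np.int64)

    gamma = config.resolved_gamma(units)
    kT = units.kT(config.temperature_K)

    status, fcount, n_rupt = _kernels.run_langevin(
        pos, vel, config.dt, gamma, kT, config.n_steps, config.frame_interval,
        config.seed,
        t["bonds"], t["bond_l0"], t["bond_class"], intact, t["k_l"],
        t["angles"], t["angle_theta0"], ang_act, t["k_theta"],
        t["dihedrals"], t["dihedral_phi0"], dih_act, t["k_phi"], t["n_mult"],
        lattice.angle_bonds, lattice.dihedral_bonds,
        arrs["fixed_mask"], arrs["rigid"],
        arrs["ev_sub"], arrs["ev_start"], arrs["ev_end"], arrs["ev_mode"],
        arrs["ev_sign"], arrs["ev_mag"], arrs["ev_vec"],
        arrs["axis_from"], arrs["axis_to"],
        config.rupture_enabled, thresholds[0], thresholds[1],
        max(1, round(config.rupture_dwell_time / config.dt)),
        config.max_disp,
        frames, frame_intact, times,
        rupture_steps, rupture_bonds)

    if status == _kernels.STATUS_UNSTABLE:
        raise IntegrationError(
            f"integration unstable after {fcount} recorded frames: per-step "
            f"displacement exceeded {config.max_disp} nm; reduce dt "
            f"(dt={config.dt}) or stiffnesses")

    events = [(int(rupture_steps[i]), int(rupture_bonds[i])) for i in range(n_rupt)]
    return Trajectory(
        frames=frames[:fcount], times=times[:fcount],
        bond_intact=frame_intact[:fcount], rupture_events=events,
        final_velocities=vel, lattice=lattice, config=config, protocol=protocol,
        metadata={"seed": config.seed, "gamma": gamma, "kT": kT,
                  "thresholds_nm": tuple(thresholds)},
    )
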