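"""Helical filament lattice: canonical geometry, spring-network topology,
equilibrium values and structure-derived rupture thresholds.

F-actin is modelled as two right-handed strands intertwining into a
left-handed one-start (genetic) helix: subunit ``i`` sits at cylindrical
coordinates (r, i*beta, i*h) with canonical rise h = 2.78 nm, twist
beta = -166.67 deg and radius r = 1.6 nm.  Each subunit is bonded to its
four nearest neighbours: "diagonal" bonds i<->i+1 (cross-strand, along the
genetic helix) and "longitudinal" bonds i<->i+2 (same strand).  Bending is
resisted by six harmonic angles per interior subunit (all pairs of its four
bonded neighbours with the subunit at the vertex) and twisting by two
dihedrals originated per subunit: one along the long-pitch strand
(i, i+2, i+4, i+6) and one along the short-pitch genetic helix
(i, i+1, i+2, i+3).

All equilibrium bond lengths, angles and dihedrals are *measured* from the
generated canonical coordinates so geometry and topology cannot drift apart.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "CANONICAL_RISE_NM",
    "CANONICAL_TWIST_DEG",
    "CANONICAL_RADIUS_NM",
    "HelicalGeometry",
    "PotentialParams",
    "FilamentLattice",
    "build_filament",
    "equilibrium_bond_lengths",
    "critical_bond_lengths",
    "bond_angle",
    "dihedral_angle",
]

CANONICAL_RISE_NM = 2.78
CANONICAL_TWIST_DEG = -166.67
CANONICAL_RADIUS_NM = 1.6

#: rise/twist intervals measured off the supercoil reconstruction, used to
#: derive the mechanical-severing bond-length thresholds
SUPERCOIL_RISE_RANGE_NM = (2.5, 3.2)
SUPERCOIL_TWIST_RANGE_DEG = (-177.0, -154.0)

DIAGONAL = 0
LONGITUDINAL = 1


class TopologyError(ValueError):
    """Raised when a filament is too short to carry the full topology."""


@dataclass(frozen=True)
class HelicalGeometry:
    """Helical lattice parameters.

    rise_nm: axial translation per subunit (h, nm), > 0.
    twist_deg: rotation per subunit (beta, degrees); negative = left-handed.
    radius_nm: subunit centroid distance from the filament axis (r, nm).
    n_subunits: number of subunits.
    """

    rise_nm: float = CANONICAL_RISE_NM
    twist_deg: float = CANONICAL_TWIST_DEG
    radius_nm: float = CANONICAL_RADIUS_NM
    n_subunits: int = 400

    def __post_init__(self) -> None:
        if self.rise_nm <= 0:
            raise ValueError("rise must be positive")
        if self.radius_nm < 0:
            raise ValueError("radius must be non-negative")
        if not (-180.0 <= self.twist_deg < 180.0):
            raise ValueError("twist must lie in [-180, 180) degrees")
        if self.n_subunits < 4:
            raise TopologyError("need at least 4 subunits for the spring network")

    @property
    def twist_rad(self) -> float:
        return np.deg2rad(self.twist_deg)


@dataclass(frozen=True)
class PotentialParams:
    """Stiffness constants of the spring network, in reduced units.

    k_l: harmonic bond stiffness (energy / nm^2).
    k_theta: harmonic angle bending constant (energy / rad^2).
    k_phi: dihedral bending constant (energy); multiplicity n_mult = 1.
    """

    k_l: float
    k_theta: float
    k_phi: float
    n_mult: int = 1

    def __post_init__(self) -> None:
        if min(self.k_l, self.k_theta, self.k_phi) < 0:
            raise ValueError("stiffnesses must be non-negative")
        if self.n_mult < 1:
            raise ValueError("dihedral multiplicity must be >= 1")


@dataclass
class FilamentLattice:
    """Subunit positions plus bonded topology with equilibrium values.

    bonds: (m, 2) int array of subunit indices.
    bond_class: (m,) int array, DIAGONAL (i<->i+1) or LONGITUDINAL (i<->i+2).
    bond_l0: equilibrium lengths measured from ``positions`` (nm).
    angles: (a, 3) int array (j, i, k) with vertex i in the middle.
    dihedrals: (d, 4) int array.
    """

    geometry: HelicalGeometry
    params: PotentialParams
    positions: np.ndarray
    bonds: np.ndarray
    bond_class: np.ndarray
    bond_l0: np.ndarray
    angles: np.ndarray
    angle_theta0: np.ndarray
    dihedrals: np.ndarray
    dihedral_phi0: np.ndarray
    # per-angle / per-dihedral constituent bond ids (for rupture bookkeeping)
    angle_bonds: np.ndarray = field(default=None, repr=False)
    dihedral_bonds: np.ndarray = field(default=None, repr=False)

    @property
    def n_subunits(self) -> int:
        return len(self.positions)

    def with_params(self, params: PotentialParams) -> "FilamentLattice":
        """Same lattice with different stiffnesses."""
        out = FilamentLattice(**{**self.__dict__, "params": params})
        return out

    # -- serialization ----------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write geometry + stiffnesses as JSON and coordinates as CSV."""
        path = Path(path)
        meta = {
            "geometry": asdict(self.geometry),
            "params": asdict(self.params),
            "units": {"length": "nm", "angle": "rad"},
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
        header = "index,x_nm,y_nm,z_nm"
        rows = np.column_stack([np.arange(self.n_subunits), self.positions])
        np.savetxt(path.with_suffix(".csv"), rows, delimiter=",",
                   header=header, comments="", fmt=["%d", "%.9f", "%.9f", "%.9f"])

    @classmethod
    def load(cls, path: str | Path) -> "FilamentLattice":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        lattice = build_filament(HelicalGeometry(**meta["geometry"]),
                                 PotentialParams(**meta["params"]))
        coords = np.loadtxt(path.with_suffix(".csv"), delimiter=",", skiprows=1)
        lattice.positions = coords[:, 1:4].copy()
        return lattice

    def to_pdb(self, path: str | Path) -> None:
        """One pseudo-atom per subunit centroid, for visualization."""
        lines = []
        for i, (x, y, z) in enumerate(self.positions * 10.0):  # nm -> A
            lines.append(
                f"ATOM  {i + 1:5d}  CA  ACT A{(i % 9999) + 1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
            )
        lines.append("END")
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# geometric primitives

def helical_positions(geometry: HelicalGeometry) -> np.ndarray:
    """Subunit centroids of the ideal helix, (n, 3) in nm."""
    i = np.arange(geometry.n_subunits)
    ang = i * geometry.twist_rad
    r = geometry.radius_nm
    return np.column_stack([r * np.cos(ang), r * np.sin(ang), i * geometry.rise_nm])


def bond_angle(p_j: np.ndarray, p_i: np.ndarray, p_k: np.ndarray) -> float:
    """Angle at vertex ``p_i`` between arms to ``p_j`` and ``p_k`` (rad)."""
    u = p_j - p_i
    v = p_k - p_i
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral angle of four points, in (-pi, pi]."""
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(np.arctan2(np.dot(m, n2), np.dot(n1, n2)))


# ---------------------------------------------------------------------------
# lattice construction

def _angle_triplets(n: int) -> list[tuple[int, int, int]]:
    """Six angles per interior vertex: all pairs of {i-2, i-1, i+1, i+2}."""
    triplets = []
    for i in range(n):
        nbrs = [j for j in (i - 2, i - 1, i + 1, i + 2) if 0 <= j < n]
        for j, k in itertools.combinations(nbrs, 2):
            triplets.append((j, i, k))
    return triplets


def _dihedral_quadruplets(n: int) -> list[tuple[int, int, int, int]]:
    """Two dihedrals originated per subunit.

    Short-pitch: (i, i+1, i+2, i+3) along the genetic helix.  Long-pitch
    span: (i, i+1, i+3, i+4), crossing strands around one long-pitch step.
    A pure same-strand quadruplet (i, i+2, i+4, i+6) is avoided because its
    three bond vectors are nearly collinear (~3 deg apart), which makes the
    torsion angle ill-conditioned and its force singular under thermal
    bending; the strand-crossing span resists rotation of the long-pitch
    path with well-separated bond directions.
    """
    quads = []
    for i in range(n):
        if i + 4 < n:
            quads.append((i, i + 1, i + 3, i + 4))
        if i + 3 < n:
            quads.append((i, i + 1, i + 2, i + 3))
    return quads


def _bond_id_map(bonds: np.ndarray) -> dict[tuple[int, int], int]:
    return {tuple(sorted(b)): idx for idx, b in enumerate(map(tuple, bonds))}


def build_filament(geometry: HelicalGeometry,
                   params: PotentialParams) -> FilamentLattice:
    """Generate the canonical lattice and measure its equilibrium values.

    Subunit ``i`` sits at cylindrical coordinates (r, i*beta, i*h).  All
    equilibrium bond lengths / angles / dihedrals are realized distances and
    angles of the generated coordinates.
    """
    n = geometry.n_subunits
    if n < 4:
        raise TopologyError("need at least 4 subunits for the spring network")
    pos = helical_positions(geometry)

    diag = [(i, i + 1) for i in range(n - 1)]
    longi = [(i, i + 2) for i in range(n - 2)]
    bonds = np.array(diag + longi, dtype=np.int64)
    bond_class = np.array([DIAGONAL] * len(diag) + [LONGITUDINAL] * len(longi),
                          dtype=np.int64)
    bond_l0 = np.linalg.norm(pos[bonds[:, 0]] - pos[bonds[:, 1]], axis=1)

    triplets = _angle_triplets(n)
    angles = np.array(triplets, dtype=np.int64)
    theta0 = np.array([bond_angle(pos[j], pos[i], pos[k]) for j, i, k in triplets])

    quads = _dihedral_quadruplets(n)
    dihedrals = np.array(quads, dtype=np.int64)
    phi0 = np.array([dihedral_angle(pos[a], pos[b], pos[c], pos[d])
                     for a, b, c, d in quads])

    # constituent-bond bookkeeping for rupture-driven deactivation
    bid = _bond_id_map(bonds)

    def path_bonds(indices: tuple[int, ...]) -> list[int]:
        out = []
        seq = sorted(indices)
        for a, b in zip(seq[:-1], seq[1:]):
            key = (a, b)
            if key in bid:
                out.append(bid[key])
            else:  # span 2 handled, anything else decomposes into steps of 1
                for c in range(a, b):
                    out.append(bid[(c, c + 1)])
        return out

    angle_bonds = np.full((len(triplets), 4), -1, dtype=np.int64)
    for idx, (j, i, k) in enumerate(triplets):
        bl = sorted(set(path_bonds((j, i)) + path_bonds((i, k))))
        angle_bonds[idx, : len(bl)] = bl[:4]

    dihedral_bonds = np.full((len(quads), 3), -1, dtype=np.int64)
    for idx, (a, b, c, d) in enumerate(quads):
        bl = [bid[tuple(sorted((a, b)))], bid[tuple(sorted((b, c)))],
              bid[tuple(sorted((c, d)))]]
        dihedral_bonds[idx] = bl

    return FilamentLattice(
        geometry=geometry, params=params, positions=pos,
        bonds=bonds, bond_class=bond_class, bond_l0=bond_l0,
        angles=angles, angle_theta0=theta0,
        dihedrals=dihedrals, dihedral_phi0=phi0,
        angle_bonds=angle_bonds, dihedral_bonds=dihedral_bonds,
    )


# ---------------------------------------------------------------------------
# closed-form bond lengths and rupture thresholds

def equilibrium_bond_lengths(geometry: HelicalGeometry) -> tuple[float, float]:
    """Closed-form diagonal and longitudinal bond lengths (nm).

    l_diag = sqrt(2 r^2 (1 - cos|beta|) + h^2)
    l_long = 2 sqrt((r sin|beta|)^2 + h^2)
    """
    h = geometry.rise_nm
    r = geometry.radius_nm
    b = abs(geometry.twist_rad)
    l_diag = np.sqrt(2.0 * r**2 * (1.0 - np.cos(b)) + h**2)
    l_long = 2.0 * np.sqrt((r * np.sin(b)) ** 2 + h**2)
    return float(l_diag), float(l_long)


def critical_bond_lengths(h_range_nm: tuple[float, float] = SUPERCOIL_RISE_RANGE_NM,
                          twist_range_deg: tuple[float, float] = SUPERCOIL_TWIST_RANGE_DEG,
                          radius_nm: float = CANONICAL_RADIUS_NM,
                          n_grid: int = 201) -> tuple[float, float]:
    """Maximum diagonal/longitudinal bond lengths over a rise x twist box.

    These maxima define the irreversible bond-rupture thresholds.  The
    expressions are monotone in h, so maxima lie on the boundary; a fine grid
    over the box (corners included) is evaluated for safety.
    """
    h_lo, h_hi = h_range_nm
    b_lo, b_hi = twist_range_deg
    if h_lo > h_hi or b_lo > b_hi:
        raise ValueError("empty parameter range")
    hs = np.linspace(h_lo, h_hi, n_grid)
    bs = np.deg2rad(np.abs(np.linspace(b_lo, b_hi, n_grid)))
    H, B = np.meshgrid(hs, bs, indexing="ij")
    r = radius_nm
    l_diag = np.sqrt(2.0 * r**2 * (1.0 - np.cos(B)) + H**2)
    l_long = 2.0 * np.sqrt((r * np.sin(B)) ** 2 + H**2)
    return float(l_diag.max()), float(l_long.max())
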