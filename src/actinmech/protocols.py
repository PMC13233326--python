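"""Declarative force protocols: tethering, constant end forces, release,
stochastic motor firing and end torque.

A :class:`ForceProtocol` is a plain data object: a set of permanently fixed
subunits, optional rigid (translating, non-rotating) groups, and a schedule
of force events.  Magnitudes are stated in piconewtons per subunit and
converted to reduced units only when the protocol is compiled for the
integrator.  Axial events are *follower* forces by default: their direction
is recomputed every step as the unit vector from the anchor-group centroid
to the forced-group centroid, so compression keeps pushing the free end
toward the anchor after buckling (a fixed-direction variant can be expressed
with explicit-vector events).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np

from ._kernels import MODE_AXIAL, MODE_EXPLICIT, MODE_TORQUE
from .units import UnitSystem

__all__ = [
    "ForceEvent",
    "ForceProtocol",
    "tether_ends",
    "constant_end_force",
    "force_then_release",
    "stochastic_motors",
    "end_torque",
    "compile_protocol",
]


@dataclass(frozen=True)
class ForceEvent:
    """One scheduled per-subunit force.

    mode: "vector" (explicit direction), "axial" (follower along the
    anchor->end axis; ``sign`` +1 pulls away from the anchor, -1 pushes
    toward it) or "torque" (lever x axis construction at the filament end).
    magnitude_pn is per subunit.
    """

    subunit: int
    mode: str
    magnitude_pn: float
    sign: int = 1
    start_step: int = 0
    end_step: int | None = None  # None -> end of run
    vector: tuple[float, float, float] | None = None


@dataclass(frozen=True)
class ForceProtocol:
    fixed: tuple[int, ...] = ()
    rigid_group: tuple[int, ...] = ()
    events: tuple[ForceEvent, ...] = ()
    axis_from: tuple[int, ...] = ()
    axis_to: tuple[int, ...] = ()
    release_step: int | None = None
    description: str = ""

    def validate(self, n_subunits: int, n_steps: int) -> None:
        idx = set(self.fixed) | set(self.rigid_group) | {e.subunit for e in self.events}
        if idx and (min(idx) < 0 or max(idx) >= n_subunits):
            raise ValueError("protocol references nonexistent subunits")
        if set(self.fixed) & {e.subunit for e in self.events}:
            raise ValueError("forced subunits must not be fixed")
        for e in self.events:
            if e.magnitude_pn < 0:
                raise ValueError("force magnitudes must be non-negative")
            end = n_steps if e.end_step is None else e.end_step
            if e.start_step < 0 or end > n_steps:
                raise ValueError("event window outside run length")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ForceProtocol":
        events = tuple(
            ForceEvent(**{**e, "vector": tuple(e["vector"]) if e["vector"] else None})
            for e in d["events"]
        )
        return cls(
            fixed=tuple(d["fixed"]), rigid_group=tuple(d["rigid_group"]),
            events=events, axis_from=tuple(d["axis_from"]),
            axis_to=tuple(d["axis_to"]), release_step=d["release_step"],
            description=d.get("description", ""),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ForceProtocol":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# builders mirroring the study's perturbation conditions

def tether_ends(n_fixed_start: int, n_fixed_end: int, n_subunits: int = 400) -> ForceProtocol:
    """Thermal-control protocol with zero, one or two ends tethered."""
    if n_fixed_start < 0 or n_fixed_end < 0:
        raise ValueError("counts must be non-negative")
    fixed = tuple(range(n_fixed_start)) + tuple(
        range(n_subunits - n_fixed_end, n_subunits))
    return ForceProtocol(fixed=fixed,
                         description=f"thermal, {n_fixed_start}+{n_fixed_end} fixed")


def constant_end_force(total_force_pn: float, mode: str,
                       n_subunits: int = 400, n_end: int = 5,
                       per_subunit: bool = False) -> ForceProtocol:
    """Fix the first ``n_end`` subunits and load the last ``n_end``.

    The terminal group is rigid (translates without rotating) and carries
    ``total_force_pn`` split equally over its members (or
    ``total_force_pn`` *each* if ``per_subunit``) along the instantaneous
    end-to-end axis; ``mode`` is "tension" (away from the anchor) or
    "compression" (toward it).
    """
    if total_force_pn < 0:
        raise ValueError("force must be non-negative")
    if mode not in ("tension", "compression"):
        raise ValueError("mode must be 'tension' or 'compression'")
    if total_force_pn == 0:
        # no load: both terminal groups are simply tethered
        return tether_ends(n_end, n_end, n_subunits)
    fixed = tuple(range(n_end))
    forced = tuple(range(n_subunits - n_end, n_subunits))
    per = total_force_pn if per_subunit else total_force_pn / n_end
    sign = 1 if mode == "tension" else -1
    events = tuple(ForceEvent(subunit=i, mode="axial", magnitude_pn=per, sign=sign)
                   for i in forced) if total_force_pn > 0 else ()
    return ForceProtocol(
        fixed=fixed, rigid_group=forced if total_force_pn > 0 else (),
        events=events, axis_from=fixed, axis_to=forced,
        description=f"{mode} {total_force_pn} pN total",
    )


def force_then_release(base: ForceProtocol, release_step: int) -> ForceProtocol:
    """Truncate all force events at ``release_step``; tethers are retained."""
    if release_step < 0:
        raise ValueError("release step must be non-negative")
    events = tuple(
        replace(e, end_step=release_step if e.end_step is None
                else min(e.end_step, release_step))
        for e in base.events
    )
    return replace(base, events=events, release_step=release_step,
                   description=base.description + f", release at {release_step}")


def stochastic_motors(n_steps: int, n_subunits: int = 400, n_motors: int = 5,
                      per_motor_force_pn: float = 6.0, mode: str = "compression",
                      seed: int = 0,
                      duration_frac_range: tuple[float, float] = (0.05, 0.25),
                      refire: bool = True,
                      n_fixed: int = 5) -> ForceProtocol:
    """Asynchronous motor-firing schedule.

    ``n_motors`` subunits are drawn from the lower half of the filament,
    each pushed ("compression") or pulled ("tension") axially with
    ``per_motor_force_pn`` for a random duration (uniform fraction of the
    run).  When an event ends a new subunit/duration is drawn (``refire``)
    so roughly ``n_motors`` stay active; concurrent events never share a
    subunit.  Deterministic for a given seed.
    """
    if mode not in ("tension", "compression"):
        raise ValueError("mode must be 'tension' or 'compression'")
    rng = np.random.default_rng(seed)
    lo, hi = n_subunits // 2, n_subunits
    sign = 1 if mode == "tension" else -1
    fixed = tuple(range(n_fixed))
    events: list[ForceEvent] = []
    active: list[tuple[int, int]] = []  # (subunit, end_step)

    def draw(start: int) -> None:
        busy = {s for s, end in active if end > start}
        choices = [i for i in range(lo, hi) if i not in busy]
        sub = int(rng.choice(choices))
        dur = int(rng.uniform(*duration_frac_range) * n_steps)
        end = min(start + max(dur, 1), n_steps)
        events.append(ForceEvent(subunit=sub, mode="axial",
                                 magnitude_pn=per_motor_force_pn, sign=sign,
                                 start_step=start, end_step=end))
        active.append((sub, end))

    for _ in range(n_motors):
        draw(0)
    if refire:
        # replace each finished motor until the run ends
        while True:
            active.sort(key=lambda se: se[1])
            sub, end = active.pop(0)
            if end >= n_steps:
                break
            draw(end)

    return ForceProtocol(
        fixed=fixed, events=tuple(events),
        axis_from=fixed if n_fixed else (0,),
        axis_to=tuple(range(n_subunits - 5, n_subunits)),
        description=f"motors {mode} x{n_motors}, {per_motor_force_pn} pN each",
    )


def end_torque(per_subunit_force_pn: float, sense: str,
               n_subunits: int = 400) -> ForceProtocol:
    """Twisting protocol: first two subunits fixed, the last two loaded.

    The rotation axis is defined by the midpoints of the last three
    subunits; levers are the projections of the terminal subunits off that
    axis and the force direction is lever x axis, recomputed every step.
    ``sense`` is "over_twist" or "under_twist" (mirror images).
    """
    if n_subunits < 4:
        raise ValueError("filament too short for a torque protocol")
    if sense not in ("over_twist", "under_twist"):
        raise ValueError("sense must be 'over_twist' or 'under_twist'")
    sign = 1 if sense == "over_twist" else -1
    events = tuple(ForceEvent(subunit=i, mode="torque",
                              magnitude_pn=per_subunit_force_pn, sign=sign)
                   for i in (n_subunits - 2, n_subunits - 1))
    return ForceProtocol(fixed=(0, 1), events=events,
                         description=f"torque {sense}, {per_subunit_force_pn} pN/subunit")


# ---------------------------------------------------------------------------

_MODES = {"vector": MODE_EXPLICIT, "axial": MODE_AXIAL, "torque": MODE_TORQUE}


def compile_protocol(protocol: ForceProtocol, n_subunits: int, n_steps: int,
                     units: UnitSystem) -> dict[str, np.ndarray]:
    """Flatten a protocol into the integer/float arrays the kernel consumes."""
    protocol.validate(n_subunits, n_steps)
    fixed_mask = np.zeros(n_subunits, dtype=np.bool_)
    fixed_mask[list(protocol.fixed)] = True
    rigid = np.asarray(protocol.rigid_group, dtype=np.int64)

    ev = protocol.events
    m = len(ev)
    ev_sub = np.array([e.subunit for e in ev], dtype=np.int64)
    ev_start = np.array([e.start_step for e in ev], dtype=np.int64)
    ev_end = np.array([n_steps if e.end_step is None else e.end_step for e in ev],
                      dtype=np.int64)
    ev_mode = np.array([_MODES[e.mode] for e in ev], dtype=np.int64)
    ev_sign = np.array([e.sign for e in ev], dtype=np.float64)
    ev_mag = units.force_pn_to_reduced(
        np.array([e.magnitude_pn for e in ev], dtype=np.float64))
    ev_vec = np.zeros((m, 3))
    for t, e in enumerate(ev):
        if e.vector is not None:
            ev_vec[t] = units.force_pn_to_reduced(np.asarray(e.vector, dtype=float))
    if m == 0:
        ev_sub = np.zeros(0, dtype=np.int64)
        ev_mag = np.zeros(0)
    return {
        "fixed_mask": fixed_mask, "rigid": rigid,
        "ev_sub": ev_sub, "ev_start": ev_start, "ev_end": ev_end,
        "ev_mode": ev_mode, "ev_sign": ev_sign,
        "ev_mag": np.asarray(ev_mag, dtype=np.float64), "ev_vec": ev_vec,
        "axis_from": np.asarray(protocol.axis_from, dtype=np.int64),
        "axis_to": np.asarray(protocol.axis_to, dtype=np.int64),
    }
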