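"""Calibrated default parameters and named protocol presets.

``DEFAULT_POTENTIALS`` is the stiffness set recovered by
:func:`actinmech.calibration.calibrate` against the standard targets
(stretch stiffness 31 pN/nm, persistence length 9 um, cumulative
twist-variance slope 0.6 deg^2 per subunit) for the canonical geometry,
using the Langevin (dynamic) estimator.  Regenerate with::

    from actinmech.calibration import calibrate
    print(calibrate(estimator="dynamic").params)   # ~30 min

The fast harmonic estimator converges to a different k_theta/k_phi split
because the fluctuating ensemble is anharmonically stiffer in bending than
the Hessian expansion (see docs/methods.md).
"""

from __future__ import annotations

from .geometry import PotentialParams
from .protocols import (ForceProtocol, constant_end_force, end_torque,
                        force_then_release, stochastic_motors, tether_ends)

# reduced units: energy k_B*298K, length nm (see actinmech.units).
# Recovered with calibrate(estimator="dynamic"): Langevin-measured stretch
# stiffness 30.5 pN/nm (39 subunits, 0.298 K), persistence length 9.06 um
# (100-subunit thermal runs), cumulative twist-variance slope 0.60 deg^2
# per subunit.
DEFAULT_POTENTIALS = PotentialParams(k_l=34.99707553481969,
                                     k_theta=1332.7238144004605,
                                     k_phi=310.91679942557687)


def protocol_preset(name: str, n_subunits: int, n_steps: int = 0,
                    **kwargs) -> ForceProtocol:
    """Named presets mirroring the study's conditions."""
    if name == "thermal":
        return tether_ends(kwargs.get("n_fixed_start", 0),
                           kwargs.get("n_fixed_end", 0), n_subunits)
    if name in ("tension", "compression"):
        return constant_end_force(kwargs.get("force_pn", 10.0), name,
                                  n_subunits,
                                  per_subunit=kwargs.get("per_subunit", False))
    if name == "release":
        base = constant_end_force(kwargs.get("force_pn", 10.0),
                                  kwargs.get("mode", "compression"), n_subunits)
        return force_then_release(base, kwargs["release_step"])
    if name == "motors":
        return stochastic_motors(n_steps, n_subunits,
                                 mode=kwargs.get("mode", "compression"),
                                 seed=kwargs.get("seed", 0))
    if name == "torque":
        return end_torque(kwargs.get("force_pn", 80.0),
                          kwargs.get("sense", "over_twist"), n_subunits)
    raise ValueError(f"unknown protocol preset {name!r}")
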