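"""Elementary flow physics: Poiseuille's law and pulsatile velocity.

These closed forms motivate the experimental design (the R^4 sensitivity of
flow to vessel radius is why small occlusions matter for stroke) and drive
the 1 Hz pulsatile modulation applied by the simulator's pulse emulator.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["bulk_flow", "poiseuille_flow", "pulsation_velocity"]


def bulk_flow(pressure_drop: float, resistance: float) -> float:
    """Bulk flow BF = dP / R for a lumped vascular resistance.

    Parameters are in consistent units (e.g. Pa and Pa.s/m^3).
    """
    if pressure_drop <= 0 or resistance <= 0:
        raise ValueError("pressure_drop and resistance must be positive")
    return pressure_drop / resistance


def poiseuille_flow(
    pressure_drop: float, radius: float, viscosity: float, length: float
) -> float:
    """Laminar volumetric flow rate Q = dP * pi * R^4 / (8 * eta * L).

    Parameters
    ----------
    pressure_drop : Pa
    radius : m
    viscosity : Pa.s
    length : m

    Returns
    -------
    float
        Flow rate in m^3/s.
    """
    for name, v in (
        ("pressure_drop", pressure_drop),
        ("radius", radius),
        ("viscosity", viscosity),
        ("length", length),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    return pressure_drop * math.pi * radius**4 / (8.0 * viscosity * length)


def pulsation_velocity(t, mean_velocity: float, modulation: float, freq: float):
    """Instantaneous velocity of a pulsatile flow, v(t) = v0*(1 + m*sin(2*pi*f*t)).

    The raised sine emulates a 1 Hz heartbeat driven by a reciprocating piston
    contracting the supply pipe.  ``modulation`` must lie in [0, 1) so the
    instantaneous velocity never becomes negative; the average over an integer
    number of periods equals ``mean_velocity``.

    ``t`` may be a scalar or array of times in seconds.
    """
    if not 0.0 <= modulation < 1.0:
        raise ValueError(f"modulation must be in [0, 1), got {modulation}")
    if mean_velocity < 0:
        raise ValueError("mean_velocity must be non-negative")
    t = np.asarray(t, dtype=float)
    v = mean_velocity * (1.0 + modulation * np.sin(2.0 * np.pi * freq * t))
    return v if v.ndim else float(v)
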