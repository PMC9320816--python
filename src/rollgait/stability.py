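"""Mediolateral stability outcomes: peak COM excursion and MOS variability.

The extrapolated center of mass (XCOM) augments the mediolateral COM
position with its velocity scaled by the inverted-pendulum eigenfrequency
``omega0 = sqrt(g / l)`` (Hof's construction):

    XCOM(t) = com_ml(t) + v_ml(t) / omega0

The margin of stability (MOS) at a right heel strike is the signed distance
from the XCOM to the lateral base-of-support boundary of the landing foot,
positive when the XCOM lies inside the base.  The two trial-level outcomes
are

* ``peak_com_excursion`` — maximum absolute deviation of the mediolateral
  COM from its trial mean, and
* ``mos_variability`` — the sample SD of the right-limb MOS series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import MissingKinematicsError
from .events import StepSegmentation

__all__ = [
    "GRAVITY",
    "StabilityOutcomes",
    "extrapolated_com",
    "mos_series",
    "peak_com_excursion",
    "outcomes",
]

GRAVITY = 9.81  # m/s^2


@dataclass(frozen=True)
class StabilityOutcomes:
    """Trial-level stability summary."""

    peak_com_excursion: float  # m
    mos_values: np.ndarray  # m, one per right heel strike
    mos_variability: float  # m, sample SD of mos_values
    omega0: float  # 1/s, pendulum eigenfrequency sqrt(g/l)


def extrapolated_com(
    com_ml, com_ml_velocity, leg_length: float, g: float = GRAVITY
) -> np.ndarray:
    """Hof's extrapolated center of mass, ``com + v / sqrt(g/l)``.

    Accepts scalars or arrays; the pendulum length is the subject's leg
    length.
    """
    if leg_length <= 0:
        raise ValueError(f"leg_length must be positive, got {leg_length}")
    if g <= 0:
        raise ValueError(f"g must be positive, got {g}")
    omega0 = np.sqrt(g / leg_length)
    return np.asarray(com_ml, dtype=float) + np.asarray(com_ml_velocity, dtype=float) / omega0


def mos_series(signal, segmentation: StepSegmentation, g: float = GRAVITY) -> np.ndarray:
    """Right-limb margins of stability, one per right heel strike.

    ``signal.right_bos_boundary`` holds the lateral BOS boundary position of
    each successive right foot placement; MOS is ``boundary - XCOM`` evaluated
    at the heel-strike sample, with the lateral axis oriented so that a
    positive margin means the XCOM lies medial to (inside) the boundary.
    """
    for attr in ("com_ml", "com_ml_velocity", "right_bos_boundary"):
        if getattr(signal, attr, None) is None:
            raise MissingKinematicsError(
                f"trial {signal.subject_id}: missing gold-standard field '{attr}'"
            )
    rhs = segmentation.right_heel_strikes()
    if rhs.size < 2:
        raise MissingKinematicsError(
            f"trial {signal.subject_id}: need >= 2 right heel strikes, got {rhs.size}"
        )
    boundary = np.asarray(signal.right_bos_boundary, dtype=float)
    if boundary.size != rhs.size:
        raise MissingKinematicsError(
            f"trial {signal.subject_id}: {boundary.size} BOS boundary values for "
            f"{rhs.size} detected right heel strikes"
        )
    xcom = extrapolated_com(
        np.asarray(signal.com_ml, dtype=float)[rhs],
        np.asarray(signal.com_ml_velocity, dtype=float)[rhs],
        signal.leg_length,
        g=g,
    )
    return boundary - xcom


def peak_com_excursion(com_ml) -> float:
    """Maximum absolute mediolateral COM deviation from the trial mean, m."""
    com_ml = np.asarray(com_ml, dtype=float)
    return float(np.max(np.abs(com_ml - np.mean(com_ml))))


def outcomes(signal, segmentation: StepSegmentation, g: float = GRAVITY) -> StabilityOutcomes:
    """Both stability outcomes for one trial from gold-standard kinematics."""
    if getattr(signal, "com_ml", None) is None:
        raise MissingKinematicsError(
            f"trial {signal.subject_id}: missing gold-standard field 'com_ml'"
        )
    mos = mos_series(signal, segmentation, g=g)
    return StabilityOutcomes(
        peak_com_excursion=peak_com_excursion(signal.com_ml),
        mos_values=mos,
        mos_variability=float(np.std(mos, ddof=1)),
        omega0=float(np.sqrt(g / signal.leg_length)),
    )
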