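"""Forward models of the spoiled gradient-echo (FLASH) steady state.

Three algebraically related forms of the steady-state signal are provided:

* :func:`ernst_signal` — the exact Ernst equation
  ``S = A sin(a) (1 - E) / (1 - cos(a) E)`` with ``E = exp(-R1 TR)``;
* :func:`ernst_signal_tau` — the same signal after the half-angle tangent
  substitution ``tau = 2 tan(a/2)``, which makes the expression rational
  in ``tau``;
* :func:`pade_signal` — the [1/1] Pade approximant of the tau form around
  ``R1 TR = 0``, ``S ≈ A tau R1 TR / (tau^2/2 + R1 TR)``, whose rational
  structure admits closed-form inversion for R1 and A from two (or more)
  volumes even when the flip angles are large and the TRs differ.

Units are seconds and radians throughout the library; degrees and
milliseconds are accepted only at CLI/config boundaries.  The transmit
field ``ft`` is a dimensionless fraction (1.0 = nominal flip angle
achieved).  All forward models broadcast elementwise over array inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

ArrayLike = Union[float, np.ndarray]

__all__ = [
    "AcquisitionProtocol",
    "TissueParams",
    "TransmitField",
    "PreparedAngles",
    "half_angle_tau",
    "ernst_signal",
    "ernst_signal_tau",
    "pade_signal",
    "ernst_angle_rad",
]


def _check_finite(name: str, x: ArrayLike) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite, got non-finite values")
    return arr


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Nominal flip angles and repetition times of a multi-volume FLASH protocol.

    Parameters
    ----------
    flip_nominal_deg:
        Nominal excitation flip angles in degrees, one per volume
        (conventionally PD-weighted first, T1-weighted second).
    tr_s:
        Repetition times in seconds, one per volume.
    """

    flip_nominal_deg: tuple
    tr_s: tuple

    def __init__(self, flip_nominal_deg: Sequence[float], tr_s: Sequence[float]):
        flips = tuple(float(f) for f in flip_nominal_deg)
        trs = tuple(float(t) for t in tr_s)
        if len(flips) != len(trs):
            raise ValueError(
                f"flip_nominal_deg and tr_s must have equal length, "
                f"got {len(flips)} and {len(trs)}"
            )
        if len(flips) < 2:
            raise ValueError("a protocol needs at least two volumes")
        if not all(0.0 < f < 180.0 for f in flips):
            raise ValueError(f"flip angles must be in (0, 180) degrees, got {flips}")
        if not all(t > 0.0 for t in trs):
            raise ValueError(f"repetition times must be positive, got {trs}")
        object.__setattr__(self, "flip_nominal_deg", flips)
        object.__setattr__(self, "tr_s", trs)

    @property
    def n_volumes(self) -> int:
        return len(self.flip_nominal_deg)

    @property
    def flip_nominal_rad(self) -> np.ndarray:
        return np.deg2rad(self.flip_nominal_deg)

    @property
    def tr_s_array(self) -> np.ndarray:
        return np.asarray(self.tr_s, dtype=float)

    @property
    def equal_tr(self) -> bool:
        return len(set(self.tr_s)) == 1

    @classmethod
    def in_vivo_7t(cls) -> "AcquisitionProtocol":
        """7T in vivo MPM dual flip angle protocol (5/27 deg, TR 31.6 ms)."""
        return cls(flip_nominal_deg=(5.0, 27.0), tr_s=(0.0316, 0.0316))

    @classmethod
    def postmortem_7t(cls) -> "AcquisitionProtocol":
        """7T postmortem dual flip angle protocol (18/84 deg, TR 70 ms)."""
        return cls(flip_nominal_deg=(18.0, 84.0), tr_s=(0.070, 0.070))


@dataclass(frozen=True)
class TissueParams:
    """Longitudinal relaxation rate R1 (s^-1) and signal amplitude A (a.u.).

    ``A`` is proportional to proton density modulated by receive
    sensitivity; its absolute scale is arbitrary.  Fields may be scalars
    or arrays (e.g. voxel maps).
    """

    r1_per_s: ArrayLike
    a_au: ArrayLike = 1.0

    def __post_init__(self):
        r1 = _check_finite("r1_per_s", self.r1_per_s)
        a = _check_finite("a_au", self.a_au)
        if np.any(r1 <= 0):
            raise ValueError("r1_per_s must be > 0")
        if np.any(a <= 0):
            raise ValueError("a_au must be > 0")


@dataclass(frozen=True)
class TransmitField:
    """Dimensionless ratio of actual to nominal flip angle (B1+ scale).

    1.0 means the nominal angle is achieved; values can be a scalar or a
    voxel field.  Percent values belong at interface boundaries only.
    """

    ft: ArrayLike

    def __post_init__(self):
        ft = _check_finite("ft", self.ft)
        if np.any(ft <= 0):
            raise ValueError("ft must be > 0")


def half_angle_tau(alpha_rad: ArrayLike) -> np.ndarray:
    """Half-angle tangent transform ``tau = 2 tan(alpha/2)``.

    Strictly increasing on ``[0, pi)``; ``tau >= alpha`` with equality
    only at 0, and ``tau -> alpha`` as ``alpha -> 0``.
    """
    alpha = _check_finite("alpha_rad", alpha_rad)
    if np.any(alpha < 0) or np.any(alpha >= np.pi):
        raise ValueError("alpha_rad must be in [0, pi); tan has a pole at pi")
    return 2.0 * np.tan(alpha / 2.0)


@dataclass(frozen=True)
class PreparedAngles:
    """Actual flip angles (radians) and their half-angle tangents.

    ``alpha_rad`` and ``tau`` have shape ``(n_volumes,) + ft.shape`` so a
    scalar transmit field yields one angle per volume and a voxel field
    yields one angle map per volume.
    """

    alpha_rad: np.ndarray
    tau: np.ndarray

    @classmethod
    def from_protocol(
        cls, protocol: AcquisitionProtocol, ft: ArrayLike = 1.0
    ) -> "PreparedAngles":
        """Scale nominal angles by the transmit field and transform to tau."""
        ft_arr = _check_finite("ft", ft)
        if np.any(ft_arr <= 0):
            raise ValueError("ft must be > 0")
        nominal = protocol.flip_nominal_rad
        alpha = np.stack([f * ft_arr for f in nominal])
        if np.any(alpha >= np.pi):
            raise ValueError(
                "ft scales an actual flip angle to >= 180 degrees; "
                "the Ernst model is not defined there"
            )
        return cls(alpha_rad=alpha, tau=2.0 * np.tan(alpha / 2.0))

    @property
    def n_volumes(self) -> int:
        return self.alpha_rad.shape[0]


def _one_minus_e(r1tr: np.ndarray) -> np.ndarray:
    # -expm1(-x) is accurate for all x >= 0, including x << 1 where the
    # naive 1 - exp(-x) cancels catastrophically (the short-TR regime).
    return -np.expm1(-r1tr)


def ernst_signal(
    tissue: TissueParams, alpha_rad: ArrayLike, tr_s: ArrayLike
) -> np.ndarray:
    """Exact Ernst equation for the perfectly spoiled FLASH steady state.

    ``S = A sin(a) (1 - E) / (1 - cos(a) E)`` with ``E = exp(-R1 TR)``.
    Broadcasts elementwise over arrays of angle and/or TR.
    """
    alpha = _check_finite("alpha_rad", alpha_rad)
    tr = _check_finite("tr_s", tr_s)
    if np.any(alpha < 0) or np.any(alpha >= np.pi):
        raise ValueError("alpha_rad must be in [0, pi)")
    if np.any(tr <= 0):
        raise ValueError("tr_s must be > 0")
    r1 = np.asarray(tissue.r1_per_s, dtype=float)
    a = np.asarray(tissue.a_au, dtype=float)
    r1tr = r1 * tr
    e = np.exp(-r1tr)
    return a * np.sin(alpha) * _one_minus_e(r1tr) / (1.0 - np.cos(alpha) * e)


def ernst_signal_tau(
    tissue: TissueParams, tau: ArrayLike, tr_s: ArrayLike
) -> np.ndarray:
    """Ernst equation in half-angle tangent form.

    ``S = A tau (1 - E) / ((1 - E) + (tau/2)^2 (1 + E))`` — algebraically
    identical to :func:`ernst_signal` at ``alpha = 2 arctan(tau/2)``.
    """
    tau_arr = _check_finite("tau", tau)
    tr = _check_finite("tr_s", tr_s)
    if np.any(tau_arr < 0):
        raise ValueError("tau must be >= 0")
    if np.any(tr <= 0):
        raise ValueError("tr_s must be > 0")
    r1 = np.asarray(tissue.r1_per_s, dtype=float)
    a = np.asarray(tissue.a_au, dtype=float)
    r1tr = r1 * tr
    e = np.exp(-r1tr)
    one_minus = _one_minus_e(r1tr)
    return a * tau_arr * one_minus / (one_minus + (tau_arr / 2.0) ** 2 * (1.0 + e))


def pade_signal(tissue: TissueParams, tau: ArrayLike, tr_s: ArrayLike) -> np.ndarray:
    """[1/1] Pade approximant of the tau-form Ernst signal around R1 TR = 0.

    ``S ≈ A tau R1 TR / (tau^2/2 + R1 TR)``.  Exact to first order in
    ``R1 TR`` at any fixed tau; the residual grows with ``R1 TR`` but not
    with the flip angle, which is what makes the derived estimators
    accurate at large angles.  Returns 0 at the continuous limit
    ``tau = R1 TR = 0``.
    """
    tau_arr = _check_finite("tau", tau)
    tr = _check_finite("tr_s", tr_s)
    if np.any(tau_arr < 0):
        raise ValueError("tau must be >= 0")
    if np.any(tr <= 0):
        raise ValueError("tr_s must be > 0")
    r1 = np.asarray(tissue.r1_per_s, dtype=float)
    a = np.asarray(tissue.a_au, dtype=float)
    r1tr = r1 * tr
    num = a * tau_arr * r1tr
    den = tau_arr**2 / 2.0 + r1tr
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return out


def ernst_angle_rad(r1_per_s: ArrayLike, tr_s: ArrayLike) -> np.ndarray:
    """Flip angle maximizing the Ernst signal: ``cos(a_E) = exp(-R1 TR)``."""
    r1 = _check_finite("r1_per_s", r1_per_s)
    tr = _check_finite("tr_s", tr_s)
    return np.arccos(np.exp(-r1 * tr))
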