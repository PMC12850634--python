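"""Closed-form and fitted inversions of the FLASH steady-state models.

Five estimators of (R1, A) from multi flip angle data:

* :func:`estimate_pade` — closed-form inversion of the [1/1] Pade signal
  model; accurate at large flip angles and valid for unequal TRs.
* :func:`estimate_small_angle` — the conventional small-angle closed form
  (identical algebra with the flip angle ``alpha`` in place of ``tau``),
  which acquires a transmit-field-dependent bias at large angles.
* :func:`estimate_exact_equal_tr` — exact two-point Ernst inversion,
  available only when the two TRs are equal; serves as the reference.
* :func:`despot1_fit` — DESPOT1-like linearization of the Pade model for
  N >= 2 volumes with possibly differing TRs.
* :func:`nonlinear_fit` — direct least-squares fit of the tau-form Ernst
  equation; the slow but assumption-free oracle.

All closed forms are vectorized: signals and prepared angles may carry
trailing voxel dimensions.  Per-voxel failures (zero denominators,
non-physical intermediates, non-positive parameters) yield
``valid=False`` with NaN outputs and a cause code — never exceptions —
while protocol-level degeneracies (equal flip angles, rank-deficient
designs) raise, since they indicate misconfiguration rather than noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import scipy.optimize

from .signal_model import PreparedAngles, TissueParams, ernst_signal_tau

ArrayLike = Union[float, np.ndarray]

METHODS = ("pade", "small_angle", "exact_equal_tr", "despot1", "nonlinear")

#: Cause codes attached to per-voxel estimates (0 = valid).
CAUSE_LABELS = {
    0: "valid",
    1: "zero_denominator",
    2: "nonphysical_e1",
    3: "nonpositive_parameter",
    4: "nonfinite_input",
}


class DegenerateProtocolError(ValueError):
    """Raised when the acquisition protocol cannot separate R1 from A
    (e.g. both volumes share the same flip angle)."""


class UnsupportedProtocolError(ValueError):
    """Raised when an estimator's protocol assumptions are violated
    (e.g. the exact equal-TR solution with unequal TRs)."""


@dataclass
class ParameterEstimate:
    """Paired (R1, A) estimate with validity flags.

    Fields are scalars or arrays of matching shape.  Where ``valid`` is
    False both numeric fields are NaN.  ``cause`` holds the per-element
    failure code from :data:`CAUSE_LABELS` (0 where valid).
    """

    r1_per_s: np.ndarray
    a_au: np.ndarray
    valid: np.ndarray
    method: str
    cause: Optional[np.ndarray] = None

    def item(self) -> tuple:
        """Scalar (r1, a, valid) view for 0-d estimates."""
        return (
            float(np.asarray(self.r1_per_s)),
            float(np.asarray(self.a_au)),
            bool(np.asarray(self.valid)),
        )


def _as_signal_pair(signals) -> tuple:
    s = np.asarray(signals, dtype=float)
    if s.shape[0] != 2:
        raise ValueError(f"expected exactly 2 volumes, got {s.shape[0]}")
    return s[0], s[1]


def _finalize(r1, a, cause, method) -> ParameterEstimate:
    r1 = np.asarray(r1, dtype=float)
    a = np.asarray(a, dtype=float)
    bad_param = (cause == 0) & ~(
        np.isfinite(r1) & np.isfinite(a) & (r1 > 0) & (a > 0)
    )
    cause = np.where(bad_param, 3, cause)
    valid = cause == 0
    r1 = np.where(valid, r1, np.nan)
    a = np.where(valid, a, np.nan)
    return ParameterEstimate(r1_per_s=r1, a_au=a, valid=valid, method=method, cause=cause)


def _two_point_closed_form(s1, s2, g1, g2, tr1, tr2, method) -> ParameterEstimate:
    """Shared algebra of the Pade and small-angle estimators.

    ``g`` is tau (Pade) or alpha (small angle):
    ``R1 = 0.5 [(S1 g1/TR1) - (S2 g2/TR2)] / [(S2/g2) - (S1/g1)]``,
    ``A  = S1 S2 [(TR1 g2/g1) - (TR2 g1/g2)] / [S2 TR1 g2 - S1 TR2 g1]``.
    """
    cause = np.zeros(np.broadcast(s1, s2, g1, g2).shape, dtype=np.int8)
    cause = np.where(np.isfinite(s1) & np.isfinite(s2), cause, 4)
    with np.errstate(invalid="ignore", divide="ignore"):
        den_r1 = s2 / g2 - s1 / g1
        r1 = 0.5 * (s1 * g1 / tr1 - s2 * g2 / tr2) / den_r1
        den_a = s2 * tr1 * g2 - s1 * tr2 * g1
        a = s1 * s2 * (tr1 * g2 / g1 - tr2 * g1 / g2) / den_a
    cause = np.where((cause == 0) & ((den_r1 == 0) | (den_a == 0)), 1, cause)
    return _finalize(r1, a, cause, method)


def _check_two_trs(tr_s) -> tuple:
    tr = np.atleast_1d(np.asarray(tr_s, dtype=float))
    if tr.size == 1:
        tr = np.repeat(tr, 2)
    if tr.size != 2:
        raise ValueError("expected two repetition times")
    if np.any(tr <= 0):
        raise ValueError("tr_s must be > 0")
    return tr[0], tr[1]


def estimate_pade(
    signals, prepared: PreparedAngles, tr_s
) -> ParameterEstimate:
    """Closed-form (R1, A) from two volumes via the Pade signal model.

    Accurate whenever ``R1 TR`` is small, regardless of flip angle size,
    and does not require the two TRs to be equal.
    """
    s1, s2 = _as_signal_pair(signals)
    tr1, tr2 = _check_two_trs(tr_s)
    tau1, tau2 = prepared.tau[0], prepared.tau[1]
    if np.all(tau1 == tau2):
        raise DegenerateProtocolError(
            "tau1 == tau2 everywhere: equal effective flip angles cannot "
            "separate R1 from A"
        )
    return _two_point_closed_form(s1, s2, tau1, tau2, tr1, tr2, "pade")


def estimate_small_angle(
    signals, prepared: PreparedAngles, tr_s
) -> ParameterEstimate:
    """Conventional small-angle closed form (alpha in place of tau).

    Identical formulas to :func:`estimate_pade` with the flip angle in
    radians substituted for its half-angle tangent; biased when the
    actual flip angles are not small.
    """
    s1, s2 = _as_signal_pair(signals)
    tr1, tr2 = _check_two_trs(tr_s)
    a1, a2 = prepared.alpha_rad[0], prepared.alpha_rad[1]
    if np.all(a1 == a2):
        raise DegenerateProtocolError("alpha1 == alpha2 everywhere")
    return _two_point_closed_form(s1, s2, a1, a2, tr1, tr2, "small_angle")


def estimate_exact_equal_tr(
    signals, prepared: PreparedAngles, tr_s
) -> ParameterEstimate:
    """Exact two-point inversion of the Ernst equation for equal TRs.

    Solves for ``E1 = exp(-R1 TR)`` as
    ``E1 = [S1/sin(a1) - S2/sin(a2)] / [S1/tan(a1) - S2/tan(a2)]``,
    then ``R1 = -ln(E1)/TR`` and
    ``A = (S1/sin(a1)) (1 - E1 cos(a1)) / (1 - E1)``.
    Voxels with ``E1`` outside (0, 1) are flagged invalid.
    """
    s1, s2 = _as_signal_pair(signals)
    tr = np.atleast_1d(np.asarray(tr_s, dtype=float))
    if tr.size > 1 and not np.all(tr == tr[0]):
        raise UnsupportedProtocolError(
            "exact analytical solution requires TR1 == TR2; use "
            "estimate_pade or despot1_fit for unequal TRs"
        )
    tr = float(tr[0])
    if tr <= 0:
        raise ValueError("tr_s must be > 0")
    a1, a2 = prepared.alpha_rad[0], prepared.alpha_rad[1]
    if np.all(a1 == a2):
        raise DegenerateProtocolError("alpha1 == alpha2 everywhere")
    cause = np.zeros(np.broadcast(s1, s2, a1, a2).shape, dtype=np.int8)
    cause = np.where(np.isfinite(s1) & np.isfinite(s2), cause, 4)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = s1 / np.sin(a1) - s2 / np.sin(a2)
        den = s1 / np.tan(a1) - s2 / np.tan(a2)
        e1 = num / den
        cause = np.where((cause == 0) & (den == 0), 1, cause)
        cause = np.where((cause == 0) & ~((e1 > 0) & (e1 < 1)), 2, cause)
        r1 = -np.log(np.where((e1 > 0) & (e1 < 1), e1, 0.5)) / tr
        a = (s1 / np.sin(a1)) * (1.0 - e1 * np.cos(a1)) / (1.0 - e1)
    r1 = np.where(cause == 0, r1, np.nan)
    return _finalize(r1, a, cause, "exact_equal_tr")


def despot1_fit(signals, prepared: PreparedAngles, tr_s) -> ParameterEstimate:
    """DESPOT1-like linear fit of the Pade model over N >= 2 volumes.

    The Pade model rearranges to the line ``y = A - x / (2 R1)`` with
    ``x = S tau / TR`` and ``y = S / tau``; ordinary least squares over
    the volumes gives ``R1 = -1/(2 slope)`` and ``A = intercept``.
    Unlike classical DESPOT1 the TRs may differ between volumes.
    Unweighted least squares, the canonical DESPOT1 choice.
    """
    s = np.asarray(signals, dtype=float)
    n = s.shape[0]
    if n < 2:
        raise ValueError("need at least two volumes")
    tau = prepared.tau
    if np.all(tau == tau[0]):
        raise DegenerateProtocolError("all tau equal: design is rank deficient")
    tr = np.atleast_1d(np.asarray(tr_s, dtype=float))
    if tr.size == 1:
        tr = np.repeat(tr, n)
    if tr.size != n:
        raise ValueError("tr_s length must match number of volumes")
    tr = tr.reshape((n,) + (1,) * (s.ndim - 1))
    cause = np.zeros(s.shape[1:] if s.ndim > 1 else (), dtype=np.int8)
    cause = np.where(np.all(np.isfinite(s), axis=0), cause, 4)
    with np.errstate(invalid="ignore", divide="ignore"):
        x = s * tau / tr
        y = s / tau
        xm = x.mean(axis=0)
        ym = y.mean(axis=0)
        sxx = ((x - xm) ** 2).sum(axis=0)
        sxy = ((x - xm) * (y - ym)).sum(axis=0)
        if np.all(sxx == 0):
            raise DegenerateProtocolError(
                "all linearized abscissae identical: rank-deficient fit"
            )
        slope = sxy / sxx
        intercept = ym - slope * xm
        r1 = -1.0 / (2.0 * slope)
        a = intercept
    cause = np.where((cause == 0) & (sxx == 0), 1, cause)
    cause = np.where((cause == 0) & ~(slope < 0), 3, cause)
    return _finalize(r1, a, cause, "despot1")


def nonlinear_fit(
    signals,
    prepared: PreparedAngles,
    tr_s,
    x0: Optional[tuple] = None,
) -> ParameterEstimate:
    """Direct least-squares fit of the tau-form Ernst equation (one voxel).

    Minimizes squared signal residuals over ``(log R1, log A)`` — the log
    parameterization enforces positivity without constrained-optimization
    machinery.  Initialized from :func:`estimate_pade` (two volumes) or
    :func:`despot1_fit` (more), unless ``x0 = (r1_init, a_init)`` is given.
    Serves as the accuracy oracle for the closed forms.
    """
    s = np.asarray(signals, dtype=float).reshape(-1)
    n = s.size
    tau = np.asarray(prepared.tau, dtype=float).reshape(-1)
    if tau.size != n:
        raise ValueError("signals and prepared angles must have one entry per volume")
    tr = np.atleast_1d(np.asarray(tr_s, dtype=float))
    if tr.size == 1:
        tr = np.repeat(tr, n)
    nan_est = ParameterEstimate(
        r1_per_s=np.float64(np.nan),
        a_au=np.float64(np.nan),
        valid=np.False_,
        method="nonlinear",
    )
    if not np.all(np.isfinite(s)):
        return nan_est

    if x0 is None:
        init = (
            estimate_pade(s, prepared, tr)
            if n == 2
            else despot1_fit(s, prepared, tr)
        )
        if bool(np.asarray(init.valid)):
            x0 = (float(init.r1_per_s), float(init.a_au))
        else:
            # crude fallback: mid-scale R1, amplitude from the largest signal
            x0 = (1.0, max(float(np.max(np.abs(s))), 1e-6))
    if not (x0[0] > 0 and x0[1] > 0):
        return nan_est

    def residuals(p):
        tissue = TissueParams(r1_per_s=np.exp(p[0]), a_au=np.exp(p[1]))
        return ernst_signal_tau(tissue, tau, tr) - s

    try:
        sol = scipy.optimize.least_squares(
            residuals,
            x0=np.log(np.asarray(x0, dtype=float)),
            method="lm",
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
    except Exception:
        return nan_est
    if not sol.success:
        return nan_est
    r1, a = np.exp(sol.x)
    return ParameterEstimate(
        r1_per_s=np.float64(r1),
        a_au=np.float64(a),
        valid=np.True_,
        method="nonlinear",
        cause=np.int8(0),
    )


def get_estimator(method: str):
    """Look up an estimator callable by its label."""
    table = {
        "pade": estimate_pade,
        "small_angle": estimate_small_angle,
        "exact_equal_tr": estimate_exact_equal_tr,
        "exact": estimate_exact_equal_tr,
        "despot1": despot1_fit,
        "nonlinear": nonlinear_fit,
    }
    try:
        return table[method]
    except KeyError:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}") from None
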