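"""Estimator correctness: exact inversions, known biases, oracle agreement,
and invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vfamap.estimators import (
    DegenerateProtocolError,
    UnsupportedProtocolError,
    despot1_fit,
    estimate_exact_equal_tr,
    estimate_pade,
    estimate_small_angle,
    nonlinear_fit,
)
from vfamap.signal_model import (
    AcquisitionProtocol,
    PreparedAngles,
    TissueParams,
    ernst_signal,
    pade_signal,
)


def ernst_pair(protocol, tissue, ft=1.0):
    """Noiseless Ernst signals + prepared angles for a two-volume protocol."""
    prep = PreparedAngles.from_protocol(protocol, ft)
    tr = protocol.tr_s_array.reshape((-1,) + (1,) * (prep.alpha_rad.ndim - 1))
    sig = ernst_signal(tissue, prep.alpha_rad, tr)
    return sig, prep, protocol.tr_s_array


# randomized but bounded protocol/tissue draws for round-trip properties
valid_draws = st.tuples(
    st.floats(0.1, 5.0),      # r1
    st.floats(0.1, 10.0),     # a
    st.floats(2.0, 30.0),     # alpha1 deg
    st.floats(35.0, 120.0),   # alpha2 deg
    st.floats(5.0, 100.0),    # tr1 ms
    st.floats(5.0, 100.0),    # tr2 ms
    st.floats(0.5, 1.3),      # ft
)


class TestPadeInversion:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(valid_draws)
    def test_round_trip_on_pade_signals(self, draw):
        """estimate_pade is the exact algebraic inverse of pade_signal."""
        r1, a, a1, a2, tr1, tr2, ft = draw
        protocol = AcquisitionProtocol([a1, a2], [tr1 * 1e-3, tr2 * 1e-3])
        prep = PreparedAngles.from_protocol(protocol, ft)
        tissue = TissueParams(r1, a)
        sig = pade_signal(tissue, prep.tau, protocol.tr_s_array)
        est = estimate_pade(sig, prep, protocol.tr_s_array)
        assert bool(est.valid)
        assert float(est.r1_per_s) == pytest.approx(r1, rel=1e-10)
        assert float(est.a_au) == pytest.approx(a, rel=1e-10)

    def test_postmortem_round_trip(self, postmortem_protocol):
        prep = PreparedAngles.from_protocol(postmortem_protocol)
        tissue = TissueParams(2.0, 1.0)
        sig = pade_signal(tissue, prep.tau, postmortem_protocol.tr_s_array)
        est = estimate_pade(sig, prep, postmortem_protocol.tr_s_array)
        assert float(est.r1_per_s) == pytest.approx(2.0, rel=1e-10)
        assert float(est.a_au) == pytest.approx(1.0, rel=1e-10)

    def test_accurate_on_ernst_signals_across_ft(self, in_vivo_protocol):
        """On exact Ernst data the Pade closed form stays accurate over the
        whole in vivo transmit-field range."""
        ft = np.arange(0.45, 1.3501, 0.05)
        sig, prep, tr = ernst_pair(in_vivo_protocol, TissueParams(0.82, 1.0), ft)
        est = estimate_pade(sig, prep, tr)
        rel = np.abs(est.r1_per_s / 0.82 - 1.0)
        assert np.all(est.valid)
        assert np.max(rel) < 1e-3  # < 0.1% everywhere

    def test_zero_signals_flagged_invalid(self, in_vivo_protocol):
        prep = PreparedAngles.from_protocol(in_vivo_protocol)
        est = estimate_pade([0.0, 0.0], prep, in_vivo_protocol.tr_s_array)
        assert not bool(est.valid)
        assert np.isnan(float(est.r1_per_s)) and np.isnan(float(est.a_au))

    def test_equal_tau_is_configuration_fault(self):
        protocol = AcquisitionProtocol([20.0, 27.0], [0.03, 0.03])
        prep = PreparedAngles.from_protocol(protocol)
        prep_bad = PreparedAngles(
            alpha_rad=np.stack([prep.alpha_rad[0]] * 2),
            tau=np.stack([prep.tau[0]] * 2),
        )
        with pytest.raises(DegenerateProtocolError):
            estimate_pade([0.1, 0.1], prep_bad, protocol.tr_s_array)


class TestSmallAngleEstimator:
    def test_in_vivo_bias_at_high_ft(self, in_vivo_protocol):
        """At ft = 1.35 (actual angles 6.75/36.45 deg) the small-angle
        closed form underestimates R1 by about 4%."""
        sig, prep, tr = ernst_pair(in_vivo_protocol, TissueParams(0.82, 1.0), 1.35)
        est = estimate_small_angle(sig, prep, tr)
        rel_pct = 100.0 * (float(est.r1_per_s) - 0.82) / 0.82
        assert rel_pct == pytest.approx(-4.0, abs=0.25)

    def test_postmortem_bias_is_much_larger(self, postmortem_protocol):
        sig, prep, tr = ernst_pair(postmortem_protocol, TissueParams(2.0, 1.0), 1.1)
        est = estimate_small_angle(sig, prep, tr)
        rel_r1 = abs(float(est.r1_per_s) / 2.0 - 1.0)
        rel_a = abs(float(est.a_au) - 1.0)
        assert rel_r1 > 0.15  # tens of percent, far beyond the in vivo 4%
        assert rel_a > 0.05

    def test_converges_to_pade_at_small_angles(self):
        """tau -> alpha as angles -> 0, so the two closed forms agree in the
        joint small-angle, short-TR limit.

        At fixed R1*TR the relative difference plateaus at a small constant
        set by the shared R1*TR truncation rather than vanishing; scaling
        TR together with the angles removes that floor.
        """
        tissue = TissueParams(0.82, 1.0)

        def rel_diff(scale, tr_scale):
            protocol = AcquisitionProtocol(
                [5.0 * scale, 27.0 * scale],
                [0.0316 * tr_scale, 0.0316 * tr_scale],
            )
            sig, prep, tr = ernst_pair(protocol, tissue)
            r1_sa = float(estimate_small_angle(sig, prep, tr).r1_per_s)
            r1_pd = float(estimate_pade(sig, prep, tr).r1_per_s)
            return abs(r1_sa / r1_pd - 1.0)

        # joint scaling: > 10x shrinkage over a factor-4 angle reduction
        joint = [rel_diff(s, s) for s in (1.0, 0.5, 0.25)]
        assert joint[1] < joint[0]
        assert joint[2] < 0.1 * joint[0]
        # fixed R1*TR: difference stays small (bounded plateau), never grows
        fixed = [rel_diff(s, 1.0) for s in (1.0, 0.5, 0.25, 0.125)]
        assert all(d < 0.005 for d in fixed[1:])
        assert max(fixed) == fixed[0]

    def test_equal_angles_rejected(self):
        protocol = AcquisitionProtocol([10.0, 27.0], [0.03, 0.03])
        prep = PreparedAngles.from_protocol(protocol)
        prep_bad = PreparedAngles(
            alpha_rad=np.stack([prep.alpha_rad[1]] * 2),
            tau=np.stack([prep.tau[1]] * 2),
        )
        with pytest.raises(DegenerateProtocolError):
            estimate_small_angle([0.1, 0.1], prep_bad, protocol.tr_s_array)


class TestExactEqualTr:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(valid_draws)
    def test_round_trip_on_ernst_signals(self, draw):
        """The two-point Ernst inversion recovers the generating model."""
        r1, a, a1, a2, tr1, _tr2, ft = draw
        protocol = AcquisitionProtocol([a1, a2], [tr1 * 1e-3, tr1 * 1e-3])
        tissue = TissueParams(r1, a)
        sig, prep, tr = ernst_pair(protocol, tissue, ft)
        est = estimate_exact_equal_tr(sig, prep, tr)
        assert bool(est.valid)
        assert float(est.r1_per_s) == pytest.approx(r1, rel=1e-10)
        assert float(est.a_au) == pytest.approx(a, rel=1e-10)

    def test_unequal_tr_rejected(self):
        protocol = AcquisitionProtocol([5.0, 27.0], [0.02, 0.0316])
        prep = PreparedAngles.from_protocol(protocol)
        with pytest.raises(UnsupportedProtocolError):
            estimate_exact_equal_tr([0.05, 0.09], prep, protocol.tr_s_array)

    def test_nonphysical_e1_flagged_invalid(self, in_vivo_protocol):
        """A noisy pair driving E1 = exp(-R1 TR) outside (0, 1) yields an
        invalid voxel, not an exception."""
        prep = PreparedAngles.from_protocol(in_vivo_protocol)
        sig, _, tr = ernst_pair(in_vivo_protocol, TissueParams(0.82, 1.0))
        # inflate the T1-weighted signal until no physical E1 can explain it
        est = estimate_exact_equal_tr([sig[0], sig[1] * 5.0], prep, tr)
        assert not bool(est.valid)
        assert np.isnan(float(est.r1_per_s))


class TestDespot1:
    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(valid_draws)
    def test_two_volumes_reduce_to_pade(self, draw):
        """Two-point least squares collapses algebraically to the Pade
        closed form."""
        r1, a, a1, a2, tr1, tr2, ft = draw
        protocol = AcquisitionProtocol([a1, a2], [tr1 * 1e-3, tr2 * 1e-3])
        tissue = TissueParams(r1, a)
        sig, prep, tr = ernst_pair(protocol, tissue, ft)
        e_pade = estimate_pade(sig, prep, tr)
        e_lin = despot1_fit(sig, prep, tr)
        assert float(e_lin.r1_per_s) == pytest.approx(float(e_pade.r1_per_s), rel=1e-10)
        assert float(e_lin.a_au) == pytest.approx(float(e_pade.a_au), rel=1e-10)

    def test_exact_on_collinear_pade_signals(self):
        """Pade-generated signals put every volume exactly on the
        linearized line, for unequal TRs and N = 3."""
        protocol = AcquisitionProtocol([5.0, 15.0, 40.0], [0.020, 0.0316, 0.070])
        prep = PreparedAngles.from_protocol(protocol)
        tissue = TissueParams(1.5, 1.0)
        sig = pade_signal(tissue, prep.tau, protocol.tr_s_array)
        est = despot1_fit(sig, prep, protocol.tr_s_array)
        assert float(est.r1_per_s) == pytest.approx(1.5, rel=1e-10)
        assert float(est.a_au) == pytest.approx(1.0, rel=1e-10)

    def test_noisy_monte_carlo_self_consistency(self, rng):
        """Mean recovered R1 over replicates stays within 3 standard errors
        of the (Pade-model) truth at SNR 100."""
        protocol = AcquisitionProtocol(
            [4.0, 10.0, 17.0, 25.0, 35.0], [0.0316] * 5
        )
        prep = PreparedAngles.from_protocol(protocol)
        tissue = TissueParams(0.82, 1.0)
        sig = pade_signal(tissue, prep.tau, protocol.tr_s_array)
        n_reps = 200
        noisy = sig[:, None] + rng.normal(0, sig[0] / 100.0, size=(5, n_reps))
        prep_rep = PreparedAngles(
            alpha_rad=prep.alpha_rad[:, None], tau=prep.tau[:, None]
        )
        est = despot1_fit(noisy, prep_rep, protocol.tr_s_array)
        r1 = est.r1_per_s[est.valid]
        se = r1.std(ddof=1) / np.sqrt(r1.size)
        assert abs(r1.mean() - 0.82) < 3 * se

    def test_rank_deficient_design_rejected(self):
        protocol = AcquisitionProtocol([10.0, 27.0], [0.03, 0.03])
        prep = PreparedAngles.from_protocol(protocol)
        prep_bad = PreparedAngles(
            alpha_rad=np.stack([prep.alpha_rad[0]] * 2),
            tau=np.stack([prep.tau[0]] * 2),
        )
        with pytest.raises(DegenerateProtocolError):
            despot1_fit([0.1, 0.1], prep_bad, protocol.tr_s_array)


class TestNonlinearFit:
    @pytest.mark.parametrize("ft", [0.6, 1.0, 1.35])
    def test_noiseless_recovery(self, in_vivo_protocol, ft):
        sig, prep, tr = ernst_pair(in_vivo_protocol, TissueParams(0.82, 1.0), ft)
        est = nonlinear_fit(sig, prep, tr)
        assert bool(est.valid)
        assert float(est.r1_per_s) == pytest.approx(0.82, rel=1e-8)
        assert float(est.a_au) == pytest.approx(1.0, rel=1e-8)

    def test_initialization_independence(self, postmortem_protocol):
        sig, prep, tr = ernst_pair(postmortem_protocol, TissueParams(2.0, 1.0), 0.9)
        base = nonlinear_fit(sig, prep, tr)
        for fac_r1, fac_a in [(0.5, 1.5), (1.5, 0.5), (1.5, 1.5)]:
            alt = nonlinear_fit(
                sig, prep, tr,
                x0=(2.0 * fac_r1, 1.0 * fac_a),
            )
            assert float(alt.r1_per_s) == pytest.approx(
                float(base.r1_per_s), rel=1e-6
            )

    def test_agrees_with_exact_solution(self, in_vivo_protocol):
        for ft in (0.5, 0.9, 1.3):
            sig, prep, tr = ernst_pair(in_vivo_protocol, TissueParams(0.82, 1.0), ft)
            e_ex = estimate_exact_equal_tr(sig, prep, tr)
            e_nl = nonlinear_fit(sig, prep, tr)
            assert float(e_nl.r1_per_s) == pytest.approx(
                float(e_ex.r1_per_s), rel=1e-8
            )
            assert float(e_nl.a_au) == pytest.approx(float(e_ex.a_au), rel=1e-8)

    def test_pade_closer_to_oracle_than_small_angle(self, in_vivo_protocol):
        """At the top of the in vivo transmit range the Pade estimate sits
        far closer to the nonlinear-fit oracle than the small-angle one."""
        sig, prep, tr = ernst_pair(in_vivo_protocol, TissueParams(0.82, 1.0), 1.35)
        r1_nl = float(nonlinear_fit(sig, prep, tr).r1_per_s)
        d_pade = abs(float(estimate_pade(sig, prep, tr).r1_per_s) - r1_nl)
        d_sa = abs(float(estimate_small_angle(sig, prep, tr).r1_per_s) - r1_nl)
        assert d_pade < d_sa


class TestSharedInvariances:
    @pytest.mark.parametrize(
        "estimator",
        [estimate_pade, estimate_small_angle, estimate_exact_equal_tr, despot1_fit,
         nonlinear_fit],
    )
    def test_scale_equivariance(self, in_vivo_protocol, estimator):
        """Scaling both signals by c leaves R1 unchanged and scales A by c."""
        sig, prep, tr = ernst_pair(in_vivo_protocol, TissueParams(0.82, 1.0), 0.9)
        base = estimator(sig, prep, tr)
        scaled = estimator(7.5 * sig, prep, tr)
        assert float(scaled.r1_per_s) == pytest.approx(
            float(base.r1_per_s), rel=1e-8
        )
        assert float(scaled.a_au) == pytest.approx(
            7.5 * float(base.a_au), rel=1e-8
        )

    def test_accuracy_ordering_on_both_protocols(
        self, in_vivo_protocol, postmortem_protocol
    ):
        """|Pade error| < |small-angle error| in R1 at every point of a
        5%-step ft grid for both protocols."""
        for protocol, r1, lo, hi in [
            (in_vivo_protocol, 0.82, 0.45, 1.35),
            (postmortem_protocol, 2.0, 0.60, 1.10),
        ]:
            ft = np.arange(lo, hi + 1e-9, 0.05)
            sig, prep, tr = ernst_pair(protocol, TissueParams(r1, 1.0), ft)
            err_p = np.abs(estimate_pade(sig, prep, tr).r1_per_s - r1)
            err_s = np.abs(estimate_small_angle(sig, prep, tr).r1_per_s - r1)
            assert np.all(err_p < err_s)
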