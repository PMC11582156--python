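"""Independent brute-force oracles used by the test suite.

The forward-model oracle integrates the piecewise-constant two-pool
longitudinal ODE with explicit fixed-step RK4 (dt <= 10 us) instead of the
closed-form matrix-exponential flows used by the package, and reads out the
periodic steady state the same way (free-pool Mz just before each readout
excitation, averaged over the spoke train).
"""

from __future__ import annotations

import numpy as np

from uteqmt.core_model import (
    LineshapeKind,
    MTProtocol,
    SaturationPulse,
    TissueParams,
    derive_kba,
    derive_r1a,
    saturation_rates,
)


def _rk4_segment(A: np.ndarray, b: np.ndarray, X: np.ndarray, duration: float, dt: float):
    """RK4-integrate dX/dt = A X + B through one constant-coefficient segment.

    X stacks the homogeneous propagator columns and the affine part as a
    (..., 2, 3) array; B couples b into the affine column only.
    """
    n = max(1, int(np.ceil(duration / dt)))
    h = duration / n
    B = np.zeros(X.shape)
    B[..., :, 2] = b
    for _ in range(n):
        k1 = A @ X + B
        k2 = A @ (X + 0.5 * h * k1) + B
        k3 = A @ (X + 0.5 * h * k2) + B
        k4 = A @ (X + h * k3) + B
        X = X + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    return X


def oracle_spectrum(
    p: TissueParams,
    protocol: MTProtocol,
    dt: float = 5e-6,
) -> np.ndarray:
    """Steady-state signal matrix (n_powers, n_offsets) by brute force."""
    r1a = derive_r1a(p)
    k_ba = derive_kba(p)
    A0 = np.array([[-(r1a + p.k_ab), k_ba], [p.k_ab, -(p.r1b + k_ba)]])
    b0 = np.array([r1a * p.m0a, p.r1b * p.m0b])
    timing = protocol.timing
    tau = protocol.pulse_duration_s
    t_rec = timing.recovery_s(tau)
    n = timing.n_spokes
    cos_fa = np.cos(np.deg2rad(timing.excitation_fa_deg))
    sin_fa = np.sin(np.deg2rad(timing.excitation_fa_deg))
    C = np.array([[cos_fa, 0.0], [0.0, 1.0]])

    # batched over all (power, offset) conditions
    conds = [
        (pw, off) for pw in protocol.powers_deg for off in protocol.offsets_hz
    ]
    A_sat = np.empty((len(conds), 2, 2))
    for i, (pw, off) in enumerate(conds):
        pulse = SaturationPulse(
            flip_angle_deg=pw, offset_hz=off,
            duration_s=tau, shape=protocol.pulse_shape,
        )
        w_b, w_a = saturation_rates(pulse, p, protocol.lineshape)
        A_sat[i] = A0 - np.diag([w_a, w_b])

    # propagate [I | 0] through one full cycle to obtain the affine cycle map
    X = np.zeros((len(conds), 2, 3))
    X[:, 0, 0] = X[:, 1, 1] = 1.0
    X = _rk4_segment(A_sat, b0, X, tau, dt)
    readout_maps = []  # affine maps from cycle start to each before-spoke state
    for j in range(n):
        readout_maps.append(X.copy())
        X = C @ X
        if j < n - 1:
            X = _rk4_segment(np.broadcast_to(A0, A_sat.shape), b0, X, timing.inter_spoke_tr_s, dt)
    X = _rk4_segment(np.broadcast_to(A0, A_sat.shape), b0, X, t_rec, dt)

    P_cycle = X[:, :, :2]
    c_cycle = X[:, :, 2]
    M0 = np.linalg.solve(np.eye(2) - P_cycle, c_cycle[..., None])[..., 0]
    reads = []
    for Xj in readout_maps:
        Mj = np.einsum("kij,kj->ki", Xj[:, :, :2], M0) + Xj[:, :, 2]
        reads.append(Mj[:, 0])
    if protocol.spoke_average:
        mz = np.mean(reads, axis=0)
    else:
        mz = reads[0]
    sig = sin_fa * mz
    return sig.reshape(protocol.n_powers, protocol.n_offsets)


def mmf_kab_single_pool_limit(p: TissueParams, protocol: MTProtocol) -> np.ndarray:
    """Closed-form single-pool steady state (no exchange, no bound pool):
    the decoupled limit of the full model, for the k_ab -> 0, mmf -> 0 check."""
    r1a = 1.0 / p.t1_obs  # derive_r1a collapses to R1obs at k_ab = 0
    timing = protocol.timing
    tau = protocol.pulse_duration_s
    t_rec = timing.recovery_s(tau)
    n = timing.n_spokes
    cos_fa = np.cos(np.deg2rad(timing.excitation_fa_deg))
    sin_fa = np.sin(np.deg2rad(timing.excitation_fa_deg))
    out = np.empty((protocol.n_powers, protocol.n_offsets))
    for i, pw in enumerate(protocol.powers_deg):
        for j, off in enumerate(protocol.offsets_hz):
            pulse = SaturationPulse(pw, off, tau, protocol.pulse_shape)
            _, w_a = saturation_rates(pulse, p, protocol.lineshape)
            # scalar affine flows: m(t) = e^{-at} m0 + (b/a)(1 - e^{-at})
            def flow(a, t, m):
                e = np.exp(-a * t)
                return e * m + (r1a * p.m0a / a) * (1.0 - e)

            # fixed point of the scalar cycle map
            # m -> recovery(C * spoke-train(sat(m)))
            # iterate to convergence (contraction)
            m = p.m0a
            for _ in range(10000):
                m_prev = m
                m = flow(r1a + w_a, tau, m)
                reads = []
                for s in range(n):
                    reads.append(m)
                    m = cos_fa * m
                    if s < n - 1:
                        m = flow(r1a, timing.inter_spoke_tr_s, m)
                m = flow(r1a, t_rec, m)
                if abs(m - m_prev) < 1e-13 * p.m0a:
                    break
            out[i, j] = sin_fa * np.mean(reads)
    return out
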