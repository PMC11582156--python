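"""Two-pool pulsed-saturation qMT forward model.

The binary spin bath (BSB) model describes a tissue as a free-water pool
(``a``) and a macromolecular pool (``b``) coupled by magnetization exchange.
Pulsed off-resonance saturation is handled with the rectangular-pulse (RP)
approximation: the shaped MT pulse is replaced by a rectangular pulse of the
same duration whose amplitude carries the same average power, so that each
segment of the MT cycle is a constant-coefficient affine ODE for the two
longitudinal magnetizations.  The model is extended for a multi-spoke
(center-out radial) readout train after each MT preparation pulse: each
excitation instantaneously scales the free-pool longitudinal magnetization by
``cos(FA)`` and the periodic steady state over one full TR cycle is obtained
from the composed affine cycle map.

All internal units are SI (s, s^-1, Hz, rad/s); flip angles are accepted in
degrees at the interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "TissueParams",
    "SaturationPulse",
    "SequenceTiming",
    "LineshapeKind",
    "DerivedRates",
    "MTProtocol",
    "derive_r1a",
    "derive_kba",
    "absorption_lineshape",
    "pulse_omega1_rms",
    "saturation_rates",
    "simulate_signal",
    "simulate_spectrum",
    "SpectrumModel",
]


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

class LineshapeKind(str, Enum):
    """Absorption lineshape of a pool.

    The macromolecular pool of collagen-dominated tissue is modelled with a
    Gaussian lineshape by default; the free pool is always Lorentzian.
    """

    GAUSSIAN = "gaussian"
    LORENTZIAN = "lorentzian"
    SUPER_LORENTZIAN = "super_lorentzian"


@dataclass(frozen=True)
class TissueParams:
    """Ground-truth or fitted two-pool parameters of one voxel.

    Parameters
    ----------
    mmf:
        Macromolecular fraction M0b/(M0a+M0b), dimensionless in (0, 1).
    k_ab:
        Exchange rate free -> macromolecular pool, s^-1.
    t1_obs:
        Observed (apparent mono-exponential) longitudinal relaxation time, s.
    t2a, t2b:
        Transverse relaxation times of the free and macromolecular pools, s.
    r1b:
        Macromolecular-pool longitudinal rate, s^-1 (conventionally fixed
        to 1 s^-1).
    m0a:
        Free-pool equilibrium magnetization, arbitrary units.

    Note that the free-pool longitudinal rate R1a is *derived* from
    ``t1_obs`` (see :func:`derive_r1a`), and the bound-pool size is
    ``m0b = m0a * mmf / (1 - mmf)``.
    """

    mmf: float
    k_ab: float
    t1_obs: float
    t2a: float
    t2b: float = 15e-6
    r1b: float = 1.0
    m0a: float = 100.0

    def __post_init__(self) -> None:
        if not (0.0 < self.mmf < 1.0):
            raise ValueError(f"mmf must lie in (0, 1), got {self.mmf}")
        if self.k_ab < 0:
            raise ValueError(f"k_ab must be >= 0, got {self.k_ab}")
        for name in ("t1_obs", "t2a", "t2b", "r1b", "m0a"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")

    @property
    def m0b(self) -> float:
        return self.m0a * self.mmf / (1.0 - self.mmf)

    def with_(self, **kwargs) -> "TissueParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class SaturationPulse:
    """Off-resonance MT preparation pulse.

    ``flip_angle_deg`` is the total equivalent on-resonance rotation of the
    pulse; ``shape`` selects the omega1(t) envelope used to compute the
    average saturation power of the equivalent rectangular pulse.
    """

    flip_angle_deg: float
    offset_hz: float
    duration_s: float = 8e-3
    shape: str = "fermi"

    def __post_init__(self) -> None:
        if self.flip_angle_deg < 0:
            raise ValueError("flip_angle_deg must be >= 0")
        if self.offset_hz <= 0:
            raise ValueError("offset_hz must be > 0")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        if self.shape not in _PULSE_SHAPES:
            raise ValueError(
                f"unknown pulse shape {self.shape!r}; choose from {sorted(_PULSE_SHAPES)}"
            )


@dataclass(frozen=True)
class SequenceTiming:
    """Timing of one MT cycle: preparation pulse plus readout spoke train."""

    tr_s: float = 86e-3
    n_spokes: int = 13
    inter_spoke_tr_s: float = 5e-3
    excitation_fa_deg: float = 10.0

    def __post_init__(self) -> None:
        if self.n_spokes < 1:
            raise ValueError("n_spokes must be >= 1")

    def recovery_s(self, sat_duration_s: float) -> float:
        """Free-recovery time after the last spoke, filling the TR."""
        t = self.tr_s - sat_duration_s - (self.n_spokes - 1) * self.inter_spoke_tr_s
        if t <= 0:
            raise ValueError(
                "tr_s must exceed saturation duration plus the spoke train "
                f"({self.tr_s} s given, {self.tr_s - t} s needed)"
            )
        return t


@dataclass(frozen=True)
class DerivedRates:
    """Rates derived from :class:`TissueParams` (never stored on it)."""

    r1a: float
    k_ba: float
    m0b: float


@dataclass(frozen=True)
class MTProtocol:
    """Measurement grid: saturation powers x offsets plus sequence timing."""

    powers_deg: tuple = (400.0, 800.0, 1200.0)
    offsets_hz: tuple = (2000.0, 5000.0, 10000.0, 20000.0, 50000.0)
    timing: SequenceTiming = field(default_factory=SequenceTiming)
    pulse_duration_s: float = 8e-3
    pulse_shape: str = "fermi"
    lineshape: LineshapeKind = LineshapeKind.GAUSSIAN
    spoke_average: bool = True

    def __post_init__(self) -> None:
        if len(self.powers_deg) == 0 or len(self.offsets_hz) == 0:
            raise ValueError("powers_deg and offsets_hz must be nonempty")
        object.__setattr__(self, "powers_deg", tuple(float(p) for p in self.powers_deg))
        object.__setattr__(self, "offsets_hz", tuple(float(o) for o in self.offsets_hz))
        object.__setattr__(self, "lineshape", LineshapeKind(self.lineshape))

    @property
    def n_powers(self) -> int:
        return len(self.powers_deg)

    @property
    def n_offsets(self) -> int:
        return len(self.offsets_hz)

    @property
    def reference_index(self) -> tuple:
        """(power index, offset index) of the SNR reference condition:
        lowest saturation power, largest offset frequency."""
        return (int(np.argmin(self.powers_deg)), int(np.argmax(self.offsets_hz)))

    def subset_powers(self, keep: Sequence[float]) -> "MTProtocol":
        """Protocol restricted to the given power levels (degrees)."""
        keep = [float(k) for k in keep]
        missing = [k for k in keep if k not in self.powers_deg]
        if missing:
            raise ValueError(f"powers {missing} not in protocol {self.powers_deg}")
        return replace(self, powers_deg=tuple(keep))

    def power_indices(self, keep: Sequence[float]) -> list:
        return [self.powers_deg.index(float(k)) for k in keep]


# --------------------------------------------------------------------------
# Derived rates
# --------------------------------------------------------------------------

def derive_r1a(p: TissueParams) -> float:
    """Free-pool longitudinal rate from the observed T1.

    R1a = R1obs - k_ab (R1b - R1obs) / (R1b - R1obs + k_ba) with
    k_ba = k_ab (1 - MMF) / MMF.  The observed rate R1obs is the slow
    eigenvalue of the two-pool longitudinal relaxation-exchange matrix, which
    this relation inverts.  With ``k_ab = 0`` it collapses to R1obs.
    """
    r1obs = 1.0 / p.t1_obs
    if p.k_ab == 0.0:
        return r1obs
    k_ba = derive_kba(p)
    denom = p.r1b - r1obs + k_ba
    if abs(denom) < 1e-12 * max(1.0, abs(p.r1b), abs(r1obs), k_ba):
        raise ZeroDivisionError(
            "degenerate R1a denominator: R1b - R1obs + k_ba is zero "
            f"(R1b={p.r1b}, R1obs={r1obs}, k_ba={k_ba})"
        )
    r1a = r1obs - p.k_ab * (p.r1b - r1obs) / denom
    if not np.isfinite(r1a) or r1a <= 0:
        raise ValueError(f"derived R1a is not a finite positive rate: {r1a}")
    return float(r1a)


def derive_kba(p: TissueParams) -> float:
    """Reverse exchange rate k_ba = k_ab (1 - MMF) / MMF (detailed balance)."""
    return float(p.k_ab * (1.0 - p.mmf) / p.mmf)


def derived_rates(p: TissueParams) -> DerivedRates:
    return DerivedRates(r1a=derive_r1a(p), k_ba=derive_kba(p), m0b=p.m0b)


# --------------------------------------------------------------------------
# Lineshapes
# --------------------------------------------------------------------------

_SL_CUTOFF_HZ = 1e3  # divergence guard for the super-Lorentzian on-resonance


def absorption_lineshape(
    offset_hz,
    t2: float,
    kind: LineshapeKind = LineshapeKind.GAUSSIAN,
    *,
    sl_cutoff_hz: float = _SL_CUTOFF_HZ,
    sl_extrapolate: bool = False,
):
    """Absorption lineshape g(offset) in seconds.

    gaussian:   g = (t2 / sqrt(2 pi)) exp(-(2 pi f t2)^2 / 2)
    lorentzian: g = (t2 / pi) / (1 + (2 pi f t2)^2)
    super_lorentzian: orientation average of Gaussians with effective
        T2 / |3 cos^2(theta) - 1|; diverges on resonance, so offsets below
        ``sl_cutoff_hz`` raise unless ``sl_extrapolate`` is set, in which case
        the value at the cutoff is used.
    """
    if t2 <= 0:
        raise ValueError("t2 must be > 0")
    kind = LineshapeKind(kind)
    f = np.asarray(offset_hz, dtype=float)
    w = 2.0 * np.pi * f * t2
    if kind is LineshapeKind.GAUSSIAN:
        out = (t2 / np.sqrt(2.0 * np.pi)) * np.exp(-0.5 * w**2)
    elif kind is LineshapeKind.LORENTZIAN:
        out = (t2 / np.pi) / (1.0 + w**2)
    else:
        out = _super_lorentzian(f, t2, sl_cutoff_hz, sl_extrapolate)
    return out if out.ndim else float(out)


def _super_lorentzian(f: np.ndarray, t2: float, cutoff_hz: float, extrapolate: bool):
    below = np.abs(f) < cutoff_hz
    if np.any(below) and not extrapolate:
        raise ValueError(
            f"super-Lorentzian lineshape requested at |offset| < {cutoff_hz} Hz "
            "where it diverges; raise the offset or enable extrapolation"
        )
    f_eval = np.where(below, cutoff_hz, np.abs(f))
    # Orientation average over theta with Gauss-Legendre quadrature on cos(theta)
    u, wts = np.polynomial.legendre.leggauss(64)
    u = 0.5 * (u + 1.0)  # cos(theta) in (0, 1)
    wts = 0.5 * wts
    denom = np.abs(3.0 * u**2 - 1.0)
    denom = np.maximum(denom, 1e-9)
    t2_eff = t2 / denom  # effective per-orientation T2
    arg = 2.0 * np.pi * f_eval[..., None] * t2_eff
    vals = np.sqrt(2.0 / np.pi) * t2_eff * np.exp(-2.0 * arg**2)
    return np.sum(wts * vals, axis=-1)


# --------------------------------------------------------------------------
# Pulse envelopes and saturation rates
# --------------------------------------------------------------------------

def _fermi_envelope(x: np.ndarray) -> np.ndarray:
    # flat-top Fermi window on [0, 1]: transition width 2% of the duration
    return 1.0 / (1.0 + np.exp((np.abs(x - 0.5) - 0.35) / 0.02))


def _gaussian_envelope(x: np.ndarray) -> np.ndarray:
    # Gaussian truncated at +-3 sigma
    return np.exp(-0.5 * ((x - 0.5) / (1.0 / 6.0)) ** 2)


_PULSE_SHAPES = {
    "rect": lambda x: np.ones_like(x),
    "fermi": _fermi_envelope,
    "gaussian": _gaussian_envelope,
}


def _shape_moments(shape: str) -> tuple:
    """(mean, mean-square) of the unit-amplitude envelope over its duration."""
    x = np.linspace(0.0, 1.0, 4001)
    fx = _PULSE_SHAPES[shape](x)
    i1 = np.trapezoid(fx, x)
    i2 = np.trapezoid(fx**2, x)
    return float(i1), float(i2)


_SHAPE_MOMENTS = {s: _shape_moments(s) for s in _PULSE_SHAPES}


def pulse_omega1_rms(flip_angle_deg: float, duration_s: float, shape: str = "fermi") -> float:
    """Root-mean-square Rabi frequency (rad/s) of the equivalent rectangular
    pulse: omega1_rms^2 = (1/tau) integral omega1(t)^2 dt, with the peak
    amplitude set so the envelope integrates to the requested flip angle."""
    if shape not in _SHAPE_MOMENTS:
        raise ValueError(f"unknown pulse shape {shape!r}")
    theta = np.deg2rad(flip_angle_deg)
    i1, i2 = _SHAPE_MOMENTS[shape]
    omega1_max = theta / (duration_s * i1)
    return float(omega1_max * np.sqrt(i2))


def saturation_rates(
    pulse: SaturationPulse,
    p: TissueParams,
    kind: LineshapeKind = LineshapeKind.GAUSSIAN,
) -> tuple:
    """(W_b, W_a): saturation rates of the bound and free pools, s^-1.

    W = pi * omega1_rms^2 * g(offset), with the bound-pool lineshape at t2b
    for W_b and the free-pool Lorentzian at t2a for W_a (direct saturation).
    """
    w1rms = pulse_omega1_rms(pulse.flip_angle_deg, pulse.duration_s, pulse.shape)
    g_b = absorption_lineshape(pulse.offset_hz, p.t2b, kind)
    g_a = absorption_lineshape(pulse.offset_hz, p.t2a, LineshapeKind.LORENTZIAN)
    w_b = np.pi * w1rms**2 * g_b
    w_a = np.pi * w1rms**2 * g_a
    return float(w_b), float(w_a)


# --------------------------------------------------------------------------
# Affine piecewise-constant ODE machinery (batched closed-form 2x2 flows)
# --------------------------------------------------------------------------

def _affine_flow(A: np.ndarray, b: np.ndarray, t: float) -> tuple:
    """Flow map of dM/dt = A M + b over time t for batched 2x2 systems.

    Returns (E, f) with M(t) = E @ M(0) + f, using the closed-form (Putzer)
    expression for the 2x2 matrix exponential; A must be invertible (always
    true for relaxation-exchange matrices with positive rates).
    """
    a11 = A[..., 0, 0]
    a12 = A[..., 0, 1]
    a21 = A[..., 1, 0]
    a22 = A[..., 1, 1]
    tr = a11 + a22
    det = a11 * a22 - a12 * a21
    disc = np.sqrt(np.maximum(tr * tr - 4.0 * det, 0.0))
    lam1 = 0.5 * (tr + disc)
    lam2 = 0.5 * (tr - disc)
    e1 = np.exp(lam1 * t)
    e2 = np.exp(lam2 * t)
    # r = (e1 - e2) / (lam1 - lam2), with the confluent limit t*e1
    dl = lam1 - lam2
    small = np.abs(dl) < 1e-12 * np.maximum(1.0, np.abs(lam1))
    r = np.where(small, t * e1, (e1 - e2) / np.where(small, 1.0, dl))
    E = np.empty(np.broadcast(a11, a11).shape + (2, 2))
    E[..., 0, 0] = e1 + r * (a11 - lam1)
    E[..., 0, 1] = r * a12
    E[..., 1, 0] = r * a21
    E[..., 1, 1] = e1 + r * (a22 - lam1)
    # f = A^-1 (E - I) b
    EmI_b0 = (E[..., 0, 0] - 1.0) * b[..., 0] + E[..., 0, 1] * b[..., 1]
    EmI_b1 = E[..., 1, 0] * b[..., 0] + (E[..., 1, 1] - 1.0) * b[..., 1]
    f = np.empty(E.shape[:-1])
    f[..., 0] = (a22 * EmI_b0 - a12 * EmI_b1) / det
    f[..., 1] = (-a21 * EmI_b0 + a11 * EmI_b1) / det
    return E, f


try:  # compiled kernel for the voxel-fitting hot path
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def deco(f):
            return f

        return deco


@_njit(cache=True)
def _flow2_scalar(a11, a12, a21, a22, b1, b2, t):
    """Closed-form affine flow of one 2x2 system over time t (scalar form)."""
    tr = a11 + a22
    det = a11 * a22 - a12 * a21
    disc2 = tr * tr - 4.0 * det
    disc = np.sqrt(disc2) if disc2 > 0.0 else 0.0
    lam1 = 0.5 * (tr + disc)
    lam2 = 0.5 * (tr - disc)
    e1 = np.exp(lam1 * t)
    e2 = np.exp(lam2 * t)
    dl = lam1 - lam2
    if abs(dl) < 1e-12 * max(1.0, abs(lam1)):
        r = t * e1
    else:
        r = (e1 - e2) / dl
    E11 = e1 + r * (a11 - lam1)
    E12 = r * a12
    E21 = r * a21
    E22 = e1 + r * (a22 - lam1)
    g1 = (E11 - 1.0) * b1 + E12 * b2
    g2 = E21 * b1 + (E22 - 1.0) * b2
    f1 = (a22 * g1 - a12 * g2) / det
    f2 = (-a21 * g1 + a11 * g2) / det
    return E11, E12, E21, E22, f1, f2


@_njit(cache=True)
def _ss_signal_kernel(
    wa, wb, r1a, kab, kba, r1b, m0a, m0b,
    tau, dt_spoke, t_rec, n_spokes, cos_fa, sin_fa, spoke_avg,
):
    """Periodic steady-state readout for a flat list of (W_a, W_b) pairs."""
    K = wa.shape[0]
    out = np.empty(K)
    a11_0 = -(r1a + kab)
    a12 = kba
    a21 = kab
    a22_0 = -(r1b + kba)
    b1 = r1a * m0a
    b2 = r1b * m0b
    Ei11, Ei12, Ei21, Ei22, fi1, fi2 = _flow2_scalar(
        a11_0, a12, a21, a22_0, b1, b2, dt_spoke
    )
    Er11, Er12, Er21, Er22, fr1, fr2 = _flow2_scalar(
        a11_0, a12, a21, a22_0, b1, b2, t_rec
    )
    # one spoke step on the before-spoke state: D = E_i C, C = diag(cos_fa, 1)
    D11 = Ei11 * cos_fa
    D12 = Ei12
    D21 = Ei21 * cos_fa
    D22 = Ei22
    # power sums over the spoke train (all plain 2x2 scalars)
    Dj11, Dj12, Dj21, Dj22 = 1.0, 0.0, 0.0, 1.0
    Ss11, Ss12, Ss21, Ss22 = 1.0, 0.0, 0.0, 1.0  # sum_{j<n} D^j
    Sj11, Sj12, Sj21, Sj22 = 1.0, 0.0, 0.0, 1.0
    Sw11, Sw12, Sw21, Sw22 = 0.0, 0.0, 0.0, 0.0
    for _ in range(n_spokes - 1):
        Sw11 += Sj11
        Sw12 += Sj12
        Sw21 += Sj21
        Sw22 += Sj22
        n11 = D11 * Dj11 + D12 * Dj21
        n12 = D11 * Dj12 + D12 * Dj22
        n21 = D21 * Dj11 + D22 * Dj21
        n22 = D21 * Dj12 + D22 * Dj22
        Dj11, Dj12, Dj21, Dj22 = n11, n12, n21, n22
        Ss11 += Dj11
        Ss12 += Dj12
        Ss21 += Dj21
        Ss22 += Dj22
        Sj11 += Dj11
        Sj12 += Dj12
        Sj21 += Dj21
        Sj22 += Dj22
    S111 = Sj11 - Dj11
    S112 = Sj12 - Dj12
    S121 = Sj21 - Dj21
    S122 = Sj22 - Dj22
    # T = E_r C D^(n-1);  t = E_r C S1 f_i + f_r
    CD11 = cos_fa * Dj11
    CD12 = cos_fa * Dj12
    CD21 = Dj21
    CD22 = Dj22
    T11 = Er11 * CD11 + Er12 * CD21
    T12 = Er11 * CD12 + Er12 * CD22
    T21 = Er21 * CD11 + Er22 * CD21
    T22 = Er21 * CD12 + Er22 * CD22
    u1 = S111 * fi1 + S112 * fi2
    u2 = S121 * fi1 + S122 * fi2
    v1 = cos_fa * u1
    v2 = u2
    t1 = Er11 * v1 + Er12 * v2 + fr1
    t2 = Er21 * v1 + Er22 * v2 + fr2
    w1 = Sw11 * fi1 + Sw12 * fi2
    w2 = Sw21 * fi1 + Sw22 * fi2
    inv_n = 1.0 / n_spokes
    for k in range(K):
        Es11, Es12, Es21, Es22, fs1, fs2 = _flow2_scalar(
            a11_0 - wa[k], a12, a21, a22_0 - wb[k], b1, b2, tau
        )
        P11 = T11 * Es11 + T12 * Es21
        P12 = T11 * Es12 + T12 * Es22
        P21 = T21 * Es11 + T22 * Es21
        P22 = T21 * Es12 + T22 * Es22
        c1 = T11 * fs1 + T12 * fs2 + t1
        c2 = T21 * fs1 + T22 * fs2 + t2
        M11 = 1.0 - P11
        M12 = -P12
        M21 = -P21
        M22 = 1.0 - P22
        detM = M11 * M22 - M12 * M21
        if detM == 0.0 or not np.isfinite(detM):
            out[k] = np.nan
            continue
        M01 = (M22 * c1 - M12 * c2) / detM
        M02 = (-M21 * c1 + M11 * c2) / detM
        x1 = Es11 * M01 + Es12 * M02 + fs1
        x2 = Es21 * M01 + Es22 * M02 + fs2
        if spoke_avg:
            out[k] = sin_fa * (Ss11 * x1 + Ss12 * x2 + w1) * inv_n
        else:
            out[k] = sin_fa * x1
    return out


class SpectrumModel:
    """Vectorized steady-state signal over a full (power x offset) grid.

    Precomputes everything that does not depend on the tissue parameters
    (pulse powers, bound-pool lineshape values, timing) so that repeated
    evaluation during nonlinear fitting is cheap.  The bound-pool T2 is part
    of the precomputation and therefore fixed per instance.
    """

    def __init__(self, protocol: MTProtocol, t2b: float = 15e-6):
        self.protocol = protocol
        self.t2b = float(t2b)
        self.timing = protocol.timing
        P = np.asarray(protocol.powers_deg, dtype=float)
        O = np.asarray(protocol.offsets_hz, dtype=float)
        w1rms = np.array(
            [pulse_omega1_rms(pw, protocol.pulse_duration_s, protocol.pulse_shape) for pw in P]
        )
        g_b = absorption_lineshape(O, self.t2b, protocol.lineshape)
        self.w1rms_sq = w1rms**2  # (P,)
        self.offsets = O
        self.w_b = np.pi * self.w1rms_sq[:, None] * np.asarray(g_b)[None, :]  # (P, O)
        self.tau = protocol.pulse_duration_s
        self.dt_spoke = self.timing.inter_spoke_tr_s
        self.t_rec = self.timing.recovery_s(self.tau)
        self.n_spokes = self.timing.n_spokes
        fa = np.deg2rad(self.timing.excitation_fa_deg)
        self.cos_fa = np.cos(fa)
        self.sin_fa = np.sin(fa)
        self.spoke_average = protocol.spoke_average

    def w_a(self, t2a: float) -> np.ndarray:
        g_a = absorption_lineshape(self.offsets, t2a, LineshapeKind.LORENTZIAN)
        return np.pi * self.w1rms_sq[:, None] * np.asarray(g_a)[None, :]

    def spectrum(self, m0a, mmf, k_ab, r1obs, t2a, *, r1b=1.0, clamp_r1a=False):
        """Signal matrix (n_powers, n_offsets) in arbitrary units."""
        k_ba = k_ab * (1.0 - mmf) / mmf
        denom = r1b - r1obs + k_ba
        if clamp_r1a:
            # keep the optimizer's objective finite in the unphysical corner
            # where the R1a relation degenerates (denominator through zero)
            sign = np.sign(denom) if denom != 0 else 1.0
            denom = sign * max(abs(denom), 1e-8)
            r1a = r1obs - k_ab * (r1b - r1obs) / denom
            r1a = float(np.clip(r1a, 1e-6, 1e6))
        else:
            if abs(denom) < 1e-12 * max(1.0, abs(r1b), abs(r1obs), abs(k_ba)):
                raise ZeroDivisionError(
                    "degenerate R1a denominator for "
                    f"mmf={mmf}, k_ab={k_ab}, r1obs={r1obs}, r1b={r1b}"
                )
            r1a = r1obs - k_ab * (r1b - r1obs) / denom
        m0b = m0a * mmf / (1.0 - mmf)
        w_a = self.w_a(t2a)  # (P, O)
        if _HAVE_NUMBA:
            out = _ss_signal_kernel(
                np.ascontiguousarray(w_a.ravel()),
                np.ascontiguousarray(self.w_b.ravel()),
                float(r1a), float(k_ab), float(k_ba), float(r1b),
                float(m0a), float(m0b),
                self.tau, self.dt_spoke, self.t_rec, self.n_spokes,
                self.cos_fa, self.sin_fa, self.spoke_average,
            ).reshape(w_a.shape)
            if not np.all(np.isfinite(out)):
                raise FloatingPointError(
                    "singular steady-state system for parameters "
                    f"mmf={mmf}, k_ab={k_ab}, r1obs={r1obs}, t2a={t2a}"
                )
            return out
        A0 = np.array(
            [[-(r1a + k_ab), k_ba], [k_ab, -(r1b + k_ba)]]
        )
        b0 = np.array([r1a * m0a, r1b * m0b])
        A_sat = np.broadcast_to(A0, w_a.shape + (2, 2)).copy()
        A_sat[..., 0, 0] -= w_a
        A_sat[..., 1, 1] -= self.w_b
        E_s, f_s = _affine_flow(A_sat, b0, self.tau)
        E_i, f_i = _affine_flow(A0, b0, self.dt_spoke)
        E_r, f_r = _affine_flow(A0, b0, self.t_rec)
        C = np.array([[self.cos_fa, 0.0], [0.0, 1.0]])
        n = self.n_spokes
        # The spoke train is condition-independent (no saturation between
        # spokes), so its affine pieces are plain 2x2 and can be composed
        # once per parameter set.  With the before-spoke recurrence
        # M(j+1) = D M(j) + f_i, D = E_i C:
        #   M(n)      = D^(n-1) M(1) + S1 f_i,       S1 = sum_{i<n-1} D^i
        #   sum_j M(j)= Ssum M(1) + Sw f_i
        D = E_i @ C
        I2 = np.eye(2)
        Dj = I2.copy()   # D^j
        Ssum = I2.copy()  # sum_{j=0}^{n-1} D^j
        Sj = I2.copy()   # sum_{i=0}^{j-1} D^i at current j
        Sw = np.zeros((2, 2))
        for _ in range(n - 1):
            Sw = Sw + Sj
            Dj = D @ Dj
            Ssum = Ssum + Dj
            Sj = Sj + Dj
        S1 = Sj - Dj  # sum_{i=0}^{n-2} D^i
        # full-cycle affine map from start-of-saturation state:
        #   end = E_r C M(n) + f_r = T (E_s M0 + f_s) + t
        T = E_r @ C @ Dj
        t = E_r @ (C @ (S1 @ f_i)) + f_r
        Pm = np.einsum("ij,...jk->...ik", T, E_s)
        c = f_s @ T.T + t
        # periodic steady state: M0 = Pm M0 + c  (batched 2x2 solve)
        M = I2 - Pm
        detM = M[..., 0, 0] * M[..., 1, 1] - M[..., 0, 1] * M[..., 1, 0]
        if np.any(np.abs(detM) < 1e-300) or not np.all(np.isfinite(detM)):
            raise FloatingPointError(
                "singular steady-state system for parameters "
                f"mmf={mmf}, k_ab={k_ab}, r1obs={r1obs}, t2a={t2a}"
            )
        M0 = np.empty(c.shape)
        M0[..., 0] = (M[..., 1, 1] * c[..., 0] - M[..., 0, 1] * c[..., 1]) / detM
        M0[..., 1] = (-M[..., 1, 0] * c[..., 0] + M[..., 0, 0] * c[..., 1]) / detM
        # free-pool longitudinal magnetization just before each excitation
        M1 = np.einsum("...ij,...j->...i", E_s, M0) + f_s
        if self.spoke_average:
            acc = M1 @ Ssum.T + Sw @ f_i
            return self.sin_fa * acc[..., 0] / n
        return self.sin_fa * M1[..., 0]


def simulate_signal(
    p: TissueParams,
    pulse: SaturationPulse,
    timing: SequenceTiming | None = None,
    kind: LineshapeKind = LineshapeKind.GAUSSIAN,
    *,
    spoke_average: bool = True,
) -> float:
    """Steady-state MT-weighted signal (a.u.) for one measurement condition."""
    timing = timing or SequenceTiming()
    protocol = MTProtocol(
        powers_deg=(pulse.flip_angle_deg,) if pulse.flip_angle_deg > 0 else (0.0,),
        offsets_hz=(pulse.offset_hz,),
        timing=timing,
        pulse_duration_s=pulse.duration_s,
        pulse_shape=pulse.shape,
        lineshape=kind,
        spoke_average=spoke_average,
    )
    return float(simulate_spectrum(p, protocol)[0, 0])


def simulate_spectrum(p: TissueParams, protocol: MTProtocol) -> np.ndarray:
    """Signal matrix (n_powers, n_offsets) for a full measurement grid."""
    model = SpectrumModel(protocol, t2b=p.t2b)
    r1obs = 1.0 / p.t1_obs
    out = model.spectrum(p.m0a, p.mmf, p.k_ab, r1obs, p.t2a, r1b=p.r1b)
    if np.any(out <= 0) or not np.all(np.isfinite(out)):
        raise FloatingPointError(f"non-positive steady-state signal for {p}")
    return out
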