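"""Forward models for single-quantum CPMG relaxation dispersion under two-site exchange.

The observable is the effective transverse relaxation rate

    R2,eff(nu_CPMG) = -(1/T_relax) * ln(|M_A(T_relax)| / |M_A(0)|)

of the ground-state (A) methyl resonance after a constant-time CPMG pulse
train, for a spin exchanging between a ground state A and a sparsely
populated excited state B:

    A  <--k_AB-->  B,    k_ex = k_AB + k_BA,  p_B = k_AB / k_ex.

Transverse magnetization in the two states evolves under the Bloch-McConnell
matrix (ground-state rotating frame; Delta-omega in rad/s, same exchange-free
rate R2,0 in both states):

    L = [[-R2,0 - k_AB,            k_BA        ],
         [       k_AB,  -R2,0 - k_BA - i*Dw ]]

Each 180-degree refocusing pulse complex-conjugates the transverse
magnetization; the train is the echo unit (t/2 - 180 - t/2) repeated n times
with nu_CPMG = 1/(2 t) and n = T_relax * 2 * nu rounded to an even integer.

Because R2,0 enters as a multiple of the identity it separates additively
from the exchange contribution; all propagation here is done on the
exchange-only matrix and R2,0 is added at the end.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ExchangeParams",
    "FieldContext",
    "CpmgSchedule",
    "InvalidInputError",
    "NumericalFailureError",
    "bm_r2eff",
    "carver_richards_r2eff",
    "rex_fast_limit",
    "dispersion_curve",
    "GAMMA_RATIO_13C_1H",
]

#: gyromagnetic ratio of 13C relative to 1H (used to derive 13C Larmor
#: frequencies from spectrometer 1H frequencies)
GAMMA_RATIO_13C_1H = 0.25145


class InvalidInputError(ValueError):
    """Raised for parameter or schedule values outside the model's domain."""


class NumericalFailureError(ArithmeticError):
    """Raised when magnetization propagation overflows or loses all signal."""


@dataclass(frozen=True)
class ExchangeParams:
    """Two-site exchange parameter set for one methyl group.

    Parameters
    ----------
    k_ex : float
        Exchange rate constant k_AB + k_BA, s^-1. Must be > 0.
    p_B : float
        Excited-state population, dimensionless, in [0, 0.5).
    dw_ppm : float
        Absolute 13C chemical-shift difference |Delta-omega| between the
        states, in ppm (field independent; the sign is not identifiable
        from single-quantum CPMG data).
    r20_by_field : mapping
        Exchange-free transverse relaxation rate R2,0 (s^-1) per field
        label, shared by both exchanging states.
    """

    k_ex: float
    p_B: float
    dw_ppm: float
    r20_by_field: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.k_ex > 0):
            raise InvalidInputError(f"k_ex must be > 0, got {self.k_ex}")
        if not (0.0 <= self.p_B < 0.5):
            raise InvalidInputError(f"p_B must be in [0, 0.5), got {self.p_B}")
        if self.dw_ppm < 0:
            raise InvalidInputError(f"dw_ppm must be >= 0, got {self.dw_ppm}")
        for label, r20 in self.r20_by_field.items():
            if r20 < 0:
                raise InvalidInputError(f"R2,0 for field {label!r} must be >= 0, got {r20}")

    @property
    def k_AB(self) -> float:
        """Forward rate A->B, s^-1 (= p_B * k_ex)."""
        return self.p_B * self.k_ex

    @property
    def k_BA(self) -> float:
        """Reverse rate B->A, s^-1 (= (1 - p_B) * k_ex)."""
        return (1.0 - self.p_B) * self.k_ex

    def r20(self, field_label: str) -> float:
        try:
            return float(self.r20_by_field[field_label])
        except KeyError:
            raise InvalidInputError(
                f"no R2,0 defined for field {field_label!r}; "
                f"known fields: {sorted(self.r20_by_field)}"
            ) from None


@dataclass(frozen=True)
class FieldContext:
    """Static-field context: B0 in tesla and the 13C Larmor frequency in MHz."""

    label: str
    b0_tesla: float
    larmor_13c_mhz: float

    def __post_init__(self) -> None:
        if not (self.larmor_13c_mhz > 0):
            raise InvalidInputError("larmor_13c_mhz must be > 0")

    def dw_rad_s(self, dw_ppm: float) -> float:
        """Convert a shift difference in ppm to rad/s at this field."""
        return dw_ppm * 2.0 * math.pi * self.larmor_13c_mhz

    @classmethod
    def from_proton_mhz(cls, label: str, b0_tesla: float, proton_mhz: float) -> "FieldContext":
        return cls(label, b0_tesla, proton_mhz * GAMMA_RATIO_13C_1H)


def _n_pulses(t_relax: float, nu: float) -> int:
    """Number of refocusing pulses implied by nu = 1/(2t): nearest even integer."""
    raw = t_relax * 2.0 * nu
    n = 2 * round(raw / 2.0)
    if n < 2:
        raise InvalidInputError(
            f"nu = {nu} s^-1 implies {raw:.3g} pulses in t_relax = {t_relax} s; "
            "at least 2 refocusing pulses are required"
        )
    return int(n)


@dataclass(frozen=True)
class CpmgSchedule:
    """Constant-time CPMG schedule: relaxation period and refocusing frequencies.

    nu_CPMG = 1/(2 t) with t the delay between consecutive 180-degree pulses;
    each frequency must fit an even number (>= 2) of pulses into t_relax.
    """

    t_relax: float
    nu_cpmg: tuple[float, ...]

    def __init__(self, t_relax: float, nu_cpmg: Sequence[float]):
        if not (t_relax > 0):
            raise InvalidInputError(f"t_relax must be > 0, got {t_relax}")
        nu = tuple(float(v) for v in nu_cpmg)
        for v in nu:
            if not (v > 0):
                raise InvalidInputError(f"nu_cpmg values must be > 0, got {v}")
            _n_pulses(t_relax, v)  # validates n >= 2
        object.__setattr__(self, "t_relax", float(t_relax))
        object.__setattr__(self, "nu_cpmg", nu)

    def n_pulses(self, nu: float) -> int:
        return _n_pulses(self.t_relax, nu)


# ---------------------------------------------------------------------------
# numerical Bloch-McConnell propagation (production path)
# ---------------------------------------------------------------------------

def _exchange_matrix(k_AB: float, k_BA: float, dw: float) -> np.ndarray:
    """Exchange-only evolution matrix (R2,0 removed; it is purely additive)."""
    return np.array(
        [[-k_AB, k_BA], [k_AB, -k_BA - 1j * dw]], dtype=complex
    )


def _half_delay_propagators(K: np.ndarray, tau: np.ndarray) -> np.ndarray:
    """exp(K * tau) for a batch of half-delays tau, via 2x2 eigendecomposition."""
    mu, W = np.linalg.eig(K)
    Winv = np.linalg.inv(W)
    e = np.exp(np.multiply.outer(tau, mu))  # (m, 2)
    # P = W @ diag(e) @ Winv, batched over tau
    return np.einsum("ij,mj,jk->mik", W, e, Winv)


def _r2eff_exchange_only(
    k_ex: float, p_B: float, dw: float, t_relax: float, nus: np.ndarray
) -> np.ndarray:
    """Exchange contribution to R2,eff (i.e. R2,eff with R2,0 = 0) per nu.

    Propagates M = (p_A, p_B) through the echo train. Two consecutive echo
    units (t/2 - 180 - t/2), with the 180 pulse acting as complex
    conjugation, compose to the *linear* map U = P conj(P) conj(P) P, so the
    even-pulse train is U^(n/2); the matrix power is taken in closed form
    from the eigenvalues of U.
    """
    nus = np.asarray(nus, dtype=float)
    if p_B == 0.0 or dw == 0.0:
        return np.zeros_like(nus)
    p_A = 1.0 - p_B
    k_AB = p_B * k_ex
    k_BA = p_A * k_ex
    K = _exchange_matrix(k_AB, k_BA, dw)

    n = np.array([_n_pulses(t_relax, v) for v in nus])
    tau = t_relax / (2.0 * n)  # half the inter-pulse delay
    P = _half_delay_propagators(K, tau)
    Pc = np.conj(P)
    U = P @ Pc @ Pc @ P  # linear propagator over one echo pair (4 tau)

    trU = U[:, 0, 0] + U[:, 1, 1]
    detU = U[:, 0, 0] * U[:, 1, 1] - U[:, 0, 1] * U[:, 1, 0]
    disc = np.sqrt(trU * trU / 4.0 - detU)
    l1 = trU / 2.0 + disc
    l2 = trU / 2.0 - disc

    m = n // 2
    M0 = np.array([p_A, p_B], dtype=complex)
    w = U[:, 0, 0] * p_A + U[:, 0, 1] * p_B  # (U @ M0)[0]

    scale = np.maximum(np.abs(l1), np.abs(l2))
    degenerate = np.abs(l1 - l2) <= 1e-12 * np.maximum(scale, 1e-300)
    with np.errstate(invalid="ignore", divide="ignore"):
        MA = (l1**m * (w - l2 * p_A) - l2**m * (w - l1 * p_A)) / (l1 - l2)
    if np.any(degenerate):
        lam = trU / 2.0
        MA_deg = lam ** (m - 1) * (m * w - (m - 1) * lam * p_A)
        MA = np.where(degenerate, MA_deg, MA)

    amp = np.abs(MA) / p_A
    if not np.all(np.isfinite(amp)) or np.any(amp <= 0.0):
        raise NumericalFailureError(
            "magnetization propagation failed (overflow/underflow) for "
            f"k_ex={k_ex}, p_B={p_B}, dw={dw} rad/s, t_relax={t_relax}"
        )
    return -np.log(amp) / t_relax


def bm_r2eff(
    params: ExchangeParams,
    field: FieldContext,
    schedule: CpmgSchedule,
    nu: float,
) -> float:
    """R2,eff from numerical Bloch-McConnell propagation at one nu_CPMG.

    Magnetization starts at exchange equilibrium, (p_A, p_B); the reported
    rate follows the ground-state component: R2,eff = -(1/T) ln|M_A(T)|/p_A.
    """
    if not (nu > 0):
        raise InvalidInputError(f"nu must be > 0, got {nu}")
    dw = field.dw_rad_s(params.dw_ppm)
    rex = _r2eff_exchange_only(
        params.k_ex, params.p_B, dw, schedule.t_relax, np.array([float(nu)])
    )[0]
    return params.r20(field.label) + rex


def dispersion_curve(
    params: ExchangeParams,
    field: FieldContext,
    schedule: CpmgSchedule,
) -> np.ndarray:
    """Noiseless R2,eff over every nu in the schedule (same order), s^-1."""
    if not schedule.nu_cpmg:
        raise InvalidInputError("schedule has no nu_CPMG values")
    dw = field.dw_rad_s(params.dw_ppm)
    rex = _r2eff_exchange_only(
        params.k_ex, params.p_B, dw, schedule.t_relax, np.asarray(schedule.nu_cpmg)
    )
    return params.r20(field.label) + rex


# ---------------------------------------------------------------------------
# closed-form solutions (cross-check oracles)
# ---------------------------------------------------------------------------

def _cr72(k_ex: float, p_B: float, dw: float, nu: float) -> float:
    """Classic Carver-Richards (CR72) expression, dominant eigenvalue only.

    Accurate in fast/intermediate exchange with modest p_B; known to deviate
    when the minor eigenmode contributes (slow exchange with large dw, or
    large p_B).
    """
    p_A = 1.0 - p_B
    psi = k_ex**2 - dw**2
    zeta = -2.0 * dw * k_ex * (p_A - p_B)
    s = math.hypot(psi, zeta)
    d_pos = 0.5 * (1.0 + (psi + 2.0 * dw**2) / s)
    d_neg = 0.5 * (-1.0 + (psi + 2.0 * dw**2) / s)
    eta_pos = math.sqrt(max(psi + s, 0.0)) / (2.0**1.5 * nu)
    eta_neg = math.sqrt(max(-psi + s, 0.0)) / (2.0**1.5 * nu)
    arg = d_pos * math.cosh(eta_pos) - d_neg * math.cos(eta_neg)
    return k_ex / 2.0 - nu * math.acosh(max(arg, 1.0))


def _exact_closed_form(
    k_ex: float, p_B: float, dw: float, t_relax: float, nu: float
) -> float:
    """Exact closed-form R2,eff for the even-pulse two-site CPMG train.

    Scalar evaluation of the echo-pair propagator built from the analytic
    2x2 matrix exponential, keeping *both* eigenmodes and the equilibrium
    initial condition (Baldwin-type exact solution). Agrees with numerical
    propagation to machine precision; written independently of the batched
    matrix algebra used by :func:`bm_r2eff`.
    """
    p_A = 1.0 - p_B
    k_AB = p_B * k_ex
    k_BA = p_A * k_ex
    n = _n_pulses(t_relax, nu)
    tau = t_relax / (2.0 * n)

    t0 = -(k_ex + 1j * dw)              # trace of the exchange-only matrix
    f = (-k_AB + k_BA + 1j * dw) / 2.0  # half the diagonal difference
    g = cmath.sqrt(f * f + k_AB * k_BA)
    E = cmath.exp(t0 * tau / 2.0)
    ch = cmath.cosh(g * tau)
    shg = cmath.sinh(g * tau) / g if abs(g) > 1e-14 else tau
    P00 = E * (ch + f * shg)
    P11 = E * (ch - f * shg)
    P01 = E * k_BA * shg
    P10 = E * k_AB * shg

    # A = P conj(P); U = A conj(A) spans one echo pair
    A00 = P00 * P00.conjugate() + P01 * P10.conjugate()
    A01 = P00 * P01.conjugate() + P01 * P11.conjugate()
    A10 = P10 * P00.conjugate() + P11 * P10.conjugate()
    A11 = P10 * P01.conjugate() + P11 * P11.conjugate()
    U00 = A00 * A00.conjugate() + A01 * A10.conjugate()
    U01 = A00 * A01.conjugate() + A01 * A11.conjugate()
    trU = abs(A00) ** 2 + abs(A11) ** 2 + 2.0 * (A01 * A10.conjugate()).real
    detU = abs(A00 * A11 - A01 * A10) ** 2

    disc = cmath.sqrt(trU * trU / 4.0 - detU)
    l1 = trU / 2.0 + disc
    l2 = trU / 2.0 - disc
    m = n // 2
    w = U00 * p_A + U01 * p_B
    if abs(l1 - l2) > 1e-13 * max(abs(l1), 1e-300):
        MA = (l1**m * (w - l2 * p_A) - l2**m * (w - l1 * p_A)) / (l1 - l2)
    else:
        lam = trU / 2.0
        MA = lam ** (m - 1) * (m * w - (m - 1) * lam * p_A)
    amp = abs(MA) / p_A
    if not math.isfinite(amp) or amp <= 0.0:
        raise NumericalFailureError(
            f"closed-form evaluation failed for k_ex={k_ex}, p_B={p_B}, dw={dw}"
        )
    return -math.log(amp) / t_relax


def carver_richards_r2eff(
    params: ExchangeParams,
    field: FieldContext,
    schedule: CpmgSchedule,
    nu: float,
    approx: bool = False,
) -> float:
    """Closed-form R2,eff for the two-site Carver-Richards CPMG problem.

    By default evaluates the exact closed-form solution of the even-pulse
    train (both eigenmodes of the echo-pair propagator retained), which
    matches Bloch-McConnell propagation at all exchange timescales. With
    ``approx=True`` it returns the classic CR72 dominant-eigenvalue
    expression instead, which is approximate where its derivation
    assumptions break (slow exchange with large Delta-omega, large p_B).
    """
    if not (nu > 0):
        raise InvalidInputError(f"nu must be > 0, got {nu}")
    r20 = params.r20(field.label)
    if params.dw_ppm == 0.0 or params.p_B == 0.0:
        return r20
    dw = field.dw_rad_s(params.dw_ppm)
    if approx:
        return r20 + _cr72(params.k_ex, params.p_B, dw, float(nu))
    return r20 + _exact_closed_form(
        params.k_ex, params.p_B, dw, schedule.t_relax, float(nu)
    )


def rex_fast_limit(params: ExchangeParams, field: FieldContext) -> float:
    """Fast-exchange limit of the exchange contribution: p_A p_B Dw^2 / k_ex.

    Valid for k_ex >> Delta-omega (rad/s); used as an analytic anchor for
    property tests and quick magnitude estimates.
    """
    if params.k_ex <= 0:
        raise InvalidInputError("k_ex must be > 0")
    dw = field.dw_rad_s(params.dw_ppm)
    return (1.0 - params.p_B) * params.p_B * dw * dw / params.k_ex
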