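"""Two-site Bloch-McConnell simulation of CEST profiles.

The magnetization of a spin exchanging between a ground state G (major) and
an excited state E (minor) is propagated under a weak saturation field that
is stepped across offsets.  Dips in the normalized intensity I/I0 appear at
the resonance positions of both states; the dip at the minor-state shift is
what makes CEST sensitive to sparsely populated conformers.

Model choices
-------------
* State vector ``(Mx_G, My_G, Mz_G, Mx_E, My_E, Mz_E)``; relaxation decays
  toward zero because profiles are normalized (the far-off-resonance plateau
  is therefore ``exp(-R1 * t_sat)``).
* The one-bond 13C-13C coupling of the detected (terminal) carbon splits its
  resonance into a doublet.  It is modelled as the equal-weight average of
  two independent two-site systems offset by +-J_CC/2 in both states, which
  reproduces the line broadening of the profile without a four-state
  Liouvillian.
* Saturation-field (B1) inhomogeneity is handled by Gauss-Hermite quadrature
  over a normal distribution of B1 values (default sd = 5% of nominal).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.linalg import expm

from .errors import InvalidParameterError, PropagationError

__all__ = [
    "SpinExchangeParams",
    "GlobalExchangeParams",
    "CestSchedule",
    "CestProfile",
    "build_liouvillian",
    "propagate",
    "b1_quadrature",
    "simulate_intensities",
    "simulate_cest_profile",
]

TWO_PI = 2.0 * np.pi

# index of Mz of the ground state in the 6-component magnetization vector
_IZ_G = 2


def _require_finite(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not np.isfinite(value):
            raise InvalidParameterError(f"{name} must be finite, got {value!r}")


@dataclass
class SpinExchangeParams:
    """Per-spin two-state parameters.

    Chemical shifts are in ppm relative to the carrier; rates in s^-1;
    ``j_cc`` is the one-bond 13C-13C scalar coupling in Hz.  The
    longitudinal rate R1 is shared by both states.
    """

    label: str
    shift_ground: float
    shift_excited: float
    r1: float
    r2_ground: float
    r2_excited: float
    j_cc: float = 0.0

    def __post_init__(self) -> None:
        _require_finite(
            shift_ground=self.shift_ground,
            shift_excited=self.shift_excited,
            r1=self.r1,
            r2_ground=self.r2_ground,
            r2_excited=self.r2_excited,
            j_cc=self.j_cc,
        )
        if self.r1 <= 0:
            raise InvalidParameterError(f"R1 must be > 0, got {self.r1}")
        if self.r2_ground < 0 or self.r2_excited < 0:
            raise InvalidParameterError("transverse rates must be >= 0")
        if self.j_cc < 0:
            raise InvalidParameterError("J_CC must be >= 0")


@dataclass
class GlobalExchangeParams:
    """Global two-site exchange parameters shared across spins.

    ``k_ex`` is the sum of forward and backward rates; ``p_e`` the
    fractional population of the minor (excited) state, < 0.5 by definition.
    """

    k_ex: float
    p_e: float

    def __post_init__(self) -> None:
        _require_finite(k_ex=self.k_ex, p_e=self.p_e)
        if self.k_ex < 0:
            raise InvalidParameterError(f"k_ex must be >= 0, got {self.k_ex}")
        if not (0.0 <= self.p_e < 0.5):
            raise InvalidParameterError(
                f"p_e must lie in [0, 0.5), got {self.p_e}"
            )

    @property
    def k_ge(self) -> float:
        """Forward (ground -> excited) rate, k_ex * p_E."""
        return self.k_ex * self.p_e

    @property
    def k_eg(self) -> float:
        """Backward (excited -> ground) rate, k_ex * (1 - p_E)."""
        return self.k_ex * (1.0 - self.p_e)


@dataclass
class CestSchedule:
    """Saturation schedule: offsets stepped at one field strength.

    ``offsets`` are in Hz relative to the carrier, ``b1_field`` is the
    nominal saturation field in Hz, ``t_sat`` the saturation duration in s,
    and ``spectrometer_freq`` (MHz) converts ppm <-> Hz at the I/O boundary.
    """

    offsets: np.ndarray
    b1_field: float
    t_sat: float
    spectrometer_freq: float
    b1_inhomogeneity: float = 0.05
    n_b1_quadrature: int = 5

    def __post_init__(self) -> None:
        self.offsets = np.atleast_1d(np.asarray(self.offsets, dtype=float))
        if self.offsets.size == 0:
            raise InvalidParameterError("offsets must be non-empty")
        if self.t_sat < 0:
            raise InvalidParameterError("t_sat must be >= 0")
        if self.b1_field <= 0:
            raise InvalidParameterError("b1_field must be > 0")
        if self.b1_inhomogeneity < 0:
            raise InvalidParameterError("b1_inhomogeneity must be >= 0")
        if self.spectrometer_freq <= 0:
            raise InvalidParameterError("spectrometer_freq must be > 0")

    def ppm_to_hz(self, ppm: float | np.ndarray) -> float | np.ndarray:
        return np.asarray(ppm) * self.spectrometer_freq

    def hz_to_ppm(self, hz: float | np.ndarray) -> float | np.ndarray:
        return np.asarray(hz) / self.spectrometer_freq


@dataclass
class CestProfile:
    """Observed or simulated normalized intensities, one per offset."""

    label: str
    schedule: CestSchedule
    intensities: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != self.schedule.offsets.shape:
            raise InvalidParameterError(
                "one intensity per offset required: "
                f"{self.intensities.shape} vs {self.schedule.offsets.shape}"
            )
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.intensities.shape:
                raise InvalidParameterError("sigma shape must match intensities")


def _liouvillian_batch(
    delta_g_hz: np.ndarray,
    delta_e_hz: np.ndarray,
    b1_hz: float,
    k_ge: float,
    k_eg: float,
    r1: float,
    r2g: float,
    r2e: float,
) -> np.ndarray:
    """Stack of 6x6 Bloch-McConnell generators, one per offset.

    ``delta_*_hz`` are the state resonance positions minus the saturation
    offset (plus the doublet term), in Hz.
    """
    delta_g_hz = np.atleast_1d(delta_g_hz)
    n = delta_g_hz.shape[0]
    og = TWO_PI * delta_g_hz
    oe = TWO_PI * np.atleast_1d(delta_e_hz)
    w1 = TWO_PI * b1_hz

    L = np.zeros((n, 6, 6))
    # ground-state Bloch block
    L[:, 0, 0] = -r2g - k_ge
    L[:, 0, 1] = -og
    L[:, 1, 0] = og
    L[:, 1, 1] = -r2g - k_ge
    L[:, 1, 2] = w1
    L[:, 2, 1] = -w1
    L[:, 2, 2] = -r1 - k_ge
    # excited-state Bloch block
    L[:, 3, 3] = -r2e - k_eg
    L[:, 3, 4] = -oe
    L[:, 4, 3] = oe
    L[:, 4, 4] = -r2e - k_eg
    L[:, 4, 5] = w1
    L[:, 5, 4] = -w1
    L[:, 5, 5] = -r1 - k_eg
    # exchange coupling between like components
    for i in range(3):
        L[:, i, i + 3] = k_eg
        L[:, i + 3, i] = k_ge
    return L


def build_liouvillian(
    spin: SpinExchangeParams,
    globals_: GlobalExchangeParams,
    offset_hz: float,
    b1_hz: float,
    doublet_sign: int,
    spectrometer_freq: float,
) -> np.ndarray:
    """Bloch-McConnell generator for one offset and one doublet component.

    Parameters
    ----------
    offset_hz, b1_hz
        Saturation offset and field strength in Hz.
    doublet_sign
        +1 or -1, selecting the one-bond doublet component at
        shift +- J_CC/2 (applied identically in both states).
    spectrometer_freq
        MHz, used to convert the ppm chemical shifts to Hz.
    """
    if doublet_sign not in (-1, 1):
        raise InvalidParameterError("doublet_sign must be +1 or -1")
    _require_finite(offset_hz=offset_hz, b1_hz=b1_hz)
    dg = spin.shift_ground * spectrometer_freq
    de = spin.shift_excited * spectrometer_freq
    half_j = doublet_sign * spin.j_cc / 2.0
    return _liouvillian_batch(
        np.array([dg - offset_hz + half_j]),
        np.array([de - offset_hz + half_j]),
        b1_hz,
        globals_.k_ge,
        globals_.k_eg,
        spin.r1,
        spin.r2_ground,
        spin.r2_excited,
    )[0]


def propagate(L: np.ndarray, m0: np.ndarray, t: float) -> np.ndarray:
    """Evolve a magnetization vector: ``expm(L t) @ m0``."""
    if not np.all(np.isfinite(L)):
        raise PropagationError("non-finite entries in the generator")
    return expm(L * t) @ np.asarray(m0, dtype=float)


def _propagate_mz_ground(L: np.ndarray, m0: np.ndarray, t: float) -> np.ndarray:
    """Ground-state Mz after time t for a stack of generators.

    Uses a batched eigendecomposition (the generators are generically
    diagonalizable); falls back to per-matrix matrix exponentials if the
    eigenvector matrix is ill-conditioned.
    """
    try:
        w, V = np.linalg.eig(L)
        y = np.linalg.solve(V, np.broadcast_to(m0, L.shape[:-1])[..., None])
        out = (V @ (np.exp(w * t)[..., None] * y))[..., _IZ_G, 0]
        out = np.real(out)
        if not np.all(np.isfinite(out)):
            raise np.linalg.LinAlgError("non-finite eigen-propagation")
        return out
    except np.linalg.LinAlgError:
        res = np.empty(L.shape[0])
        for i in range(L.shape[0]):
            res[i] = (expm(L[i] * t) @ m0)[_IZ_G]
        return res


def b1_quadrature(
    b1: float, inhomogeneity: float, n_points: int = 5
) -> list[tuple[float, float]]:
    """Quadrature nodes and weights for the B1 inhomogeneity average.

    Gauss-Hermite nodes mapped onto a normal distribution centred at ``b1``
    with sd ``inhomogeneity * b1``; the weights sum to 1 and the first two
    moments of the distribution are reproduced exactly.
    """
    if inhomogeneity < 0:
        raise InvalidParameterError("inhomogeneity must be >= 0")
    if n_points < 1 or n_points % 2 == 0:
        raise InvalidParameterError("n_points must be odd and >= 1")
    if inhomogeneity == 0 or n_points == 1:
        return [(float(b1), 1.0)]
    nodes, weights = hermgauss(n_points)
    sd = inhomogeneity * b1
    values = b1 + np.sqrt(2.0) * sd * nodes
    weights = weights / np.sqrt(np.pi)
    return [(float(v), float(w)) for v, w in zip(values, weights)]


def simulate_intensities(
    spin: SpinExchangeParams,
    globals_: GlobalExchangeParams,
    schedule: CestSchedule,
) -> np.ndarray:
    """Normalized CEST intensities I/I0 for every offset of the schedule.

    For each offset the ground-state Mz after saturation is averaged over
    the two doublet components and the B1 quadrature, starting from the
    equilibrium populations (1 - p_E, p_E) on the longitudinal components.
    I0 is the t_sat = 0 signal, so the result equals Mz_G(t_sat) / (1 - p_E).
    """
    p_g = 1.0 - globals_.p_e
    m0 = np.array([0.0, 0.0, p_g, 0.0, 0.0, globals_.p_e])
    quad = b1_quadrature(
        schedule.b1_field, schedule.b1_inhomogeneity, schedule.n_b1_quadrature
    )
    dg = spin.shift_ground * schedule.spectrometer_freq - schedule.offsets
    de = spin.shift_excited * schedule.spectrometer_freq - schedule.offsets

    acc = np.zeros_like(schedule.offsets)
    for sign in (1.0, -1.0):
        half_j = sign * spin.j_cc / 2.0
        for b1_val, weight in quad:
            L = _liouvillian_batch(
                dg + half_j,
                de + half_j,
                b1_val,
                globals_.k_ge,
                globals_.k_eg,
                spin.r1,
                spin.r2_ground,
                spin.r2_excited,
            )
            mz = _propagate_mz_ground(L, m0, schedule.t_sat)
            acc += 0.5 * weight * mz
    if not np.all(np.isfinite(acc)):
        bad = schedule.offsets[~np.isfinite(acc)]
        raise PropagationError(f"propagation failed at offsets {bad} Hz")
    return acc / p_g


def simulate_cest_profile(
    spin: SpinExchangeParams,
    globals_: GlobalExchangeParams,
    schedule: CestSchedule,
) -> CestProfile:
    """Forward-simulate a noiseless CEST profile for one spin."""
    return CestProfile(
        label=spin.label,
        schedule=schedule,
        intensities=simulate_intensities(spin, globals_, schedule),
    )
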