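"""Long-range 13C-13C scalar couplings and the Karplus map to rotamers.

A three-bond coupling 3J(Ca-Cd) is measured from the ratio of a cross peak
(magnetization that evolved under the long-range coupling) to the diagonal
peak:

    I_c / I_d = tan^2(2 pi J T_J)

where T_J is the coupling evolution delay.  Passive couplings cancel in the
ratio.  The coupling reports on the chi2 side-chain dihedral through a
Karplus relation J(theta) = A cos^2(theta) + B cos(theta) + C: large J for
trans, small J for gauche, intermediate J for a rotamer-averaging side
chain.  Uncertainties are propagated by a Monte-Carlo resampling of the two
peak heights with the spectral noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, InvalidParameterError, UnmeasurableError

__all__ = [
    "CouplingMeasurement",
    "CouplingEstimate",
    "KarplusCoefficients",
    "PLACEHOLDER_KARPLUS",
    "ROTAMER_ANGLES_DEG",
    "inept_delays",
    "ratio_from_j",
    "jcc_from_ratio",
    "karplus_j",
    "rotamer_averaged_j",
]

TWO_PI = 2.0 * np.pi

# chi2 rotamer dihedral angles (IUPAC), degrees
ROTAMER_ANGLES_DEG = {"trans": 180.0, "gauche_plus": 60.0, "gauche_minus": -60.0}


@dataclass
class CouplingMeasurement:
    """Diagonal/cross peak heights with spectral noise and evolution delay."""

    i_d: float
    i_c: float
    noise_rmsd: float
    t_j: float

    def __post_init__(self) -> None:
        if self.i_d <= 0:
            raise InvalidParameterError(f"I_d must be > 0, got {self.i_d}")
        if self.t_j <= 0:
            raise InvalidParameterError(f"T_J must be > 0, got {self.t_j}")
        if self.noise_rmsd < 0:
            raise InvalidParameterError("noise_rmsd must be >= 0")


@dataclass
class CouplingEstimate:
    """Extracted coupling with Monte-Carlo standard deviation."""

    j_hz: float
    j_sd_hz: float
    consistent_with_zero: bool = False

    def __iter__(self):
        return iter((self.j_hz, self.j_sd_hz))


@dataclass
class KarplusCoefficients:
    """Coefficients of J(theta) = A cos^2(theta) + B cos(theta) + C, in Hz.

    Literature coefficients for the relevant 13C-13C coupling must be
    supplied by the user; :data:`PLACEHOLDER_KARPLUS` is a documented
    stand-in with the right order of magnitude, not a calibrated set.
    """

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            if not np.isfinite(getattr(self, name)):
                raise InvalidParameterError(f"coefficient {name} must be finite")


# Synthetic placeholder with a realistic magnitude for aliphatic 3J(CC):
# max ~ 4 Hz at trans, ~ 1 Hz at gauche.  For quantitative work supply
# calibrated literature coefficients instead.
PLACEHOLDER_KARPLUS = KarplusCoefficients(a=3.4, b=-0.8, c=1.0)


def inept_delays(j_cc: float) -> tuple[float, float]:
    """INEPT transfer delays (Delta, T) in seconds for a one-bond coupling.

    Delta = 1/(4 J) refocuses/defocuses the doublet over half a transfer;
    T = 1/(2 J) = 2 Delta is the full antiphase evolution period.
    """
    if j_cc <= 0:
        raise InvalidParameterError(f"J_CC must be > 0, got {j_cc}")
    delta = 1.0 / (4.0 * j_cc)
    return delta, 2.0 * delta


def ratio_from_j(j_hz: float, t_j: float) -> float:
    """Cross/diagonal intensity ratio tan^2(2 pi J T_J).

    Valid for 0 <= 2 pi J T_J < pi/2 (before the tangent diverges).
    """
    if t_j <= 0:
        raise InvalidParameterError(f"T_J must be > 0, got {t_j}")
    if j_hz < 0:
        raise DomainError(f"J must be >= 0, got {j_hz}")
    arg = TWO_PI * j_hz * t_j
    if arg >= np.pi / 2.0:
        raise DomainError(
            f"2 pi J T_J = {arg:.4f} >= pi/2: outside the invertible branch"
        )
    return float(np.tan(arg) ** 2)


def jcc_from_ratio(
    m: CouplingMeasurement, n_mc: int = 1000, seed: int = 0
) -> CouplingEstimate:
    """Invert the intensity ratio to a coupling, with Monte-Carlo errors.

    J = arctan(sqrt(I_c/I_d)) / (2 pi T_J).  ``n_mc`` Gaussian draws
    perturb both peak heights by the spectral noise; perturbed negative
    ratios are truncated at zero.  A cross peak that is negative beyond the
    noise is reported as J consistent with zero and flagged.
    """
    if m.i_d <= m.noise_rmsd:
        raise UnmeasurableError(
            "diagonal peak does not rise above the spectral noise"
        )
    flagged = False
    i_c = m.i_c
    if i_c < 0:
        if -i_c > m.noise_rmsd:
            flagged = True
        i_c = 0.0
    j = float(np.arctan(np.sqrt(i_c / m.i_d)) / (TWO_PI * m.t_j))

    if n_mc < 2 or m.noise_rmsd == 0:
        return CouplingEstimate(j, 0.0, flagged)
    rng = np.random.default_rng(seed)
    i_d_draws = m.i_d + rng.normal(0.0, m.noise_rmsd, n_mc)
    i_c_draws = m.i_c + rng.normal(0.0, m.noise_rmsd, n_mc)
    # guard against sign flips of the reference peak in the noise draws
    i_d_draws = np.maximum(i_d_draws, 1e-12 * m.i_d)
    ratios = np.maximum(i_c_draws / i_d_draws, 0.0)
    j_draws = np.arctan(np.sqrt(ratios)) / (TWO_PI * m.t_j)
    return CouplingEstimate(j, float(np.std(j_draws, ddof=1)), flagged)


def karplus_j(chi2_deg: float, coeffs: KarplusCoefficients) -> float:
    """Karplus coupling (Hz) at a chi2 dihedral angle in degrees."""
    if not np.isfinite(chi2_deg):
        raise InvalidParameterError("chi2_deg must be finite")
    c = np.cos(np.deg2rad(chi2_deg))
    return float(coeffs.a * c * c + coeffs.b * c + coeffs.c)


def rotamer_averaged_j(pops, coeffs: KarplusCoefficients) -> float:
    """Population-weighted Karplus coupling over the three chi2 rotamers.

    ``pops`` provides (p_trans, p_gauche_plus, p_gauche_minus) summing to 1
    (a :class:`~sidechain_nmr.rotamers.RotamerPopulations` or any
    3-sequence).  Fast rotamer exchange averages J linearly in the
    populations, so the result always lies between the smallest and largest
    single-rotamer coupling.
    """
    p = np.asarray(
        getattr(pops, "as_array", lambda: pops)(), dtype=float
    )
    if p.shape != (3,):
        raise InvalidParameterError("populations must have three components")
    if np.any(p < -1e-9) or abs(p.sum() - 1.0) > 1e-6:
        raise InvalidParameterError(
            f"populations must be a simplex point, got {p} (sum {p.sum()})"
        )
    angles = [
        ROTAMER_ANGLES_DEG["trans"],
        ROTAMER_ANGLES_DEG["gauche_plus"],
        ROTAMER_ANGLES_DEG["gauche_minus"],
    ]
    return float(sum(pi * karplus_j(a, coeffs) for pi, a in zip(p, angles)))
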