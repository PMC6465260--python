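"""Rotamer populations from aliphatic 13C chemical shifts.

Aliphatic 13C shifts of side-chain carbons report on the rotameric sampling
of the adjacent dihedral: the observed shift is the population-weighted
average of three pure-rotamer reference shifts,

    delta_obs(atom) = sum_r p_r * delta_ref(atom, r),   r in {t, g+, g-}.

Given reference shifts for one or more atoms of a residue, the populations
are recovered by constrained least squares on the probability simplex.  The
reference basis is configuration data (literature-calibrated values differ
by residue type and must be supplied by the user).

The module also provides screening utilities over assigned-shift tables:
per-atom robust distribution statistics and detection of "isolated"
terminal/penultimate carbon pairs whose shift distributions are separated
well enough for frequency-selective excitation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, MappingError

__all__ = [
    "RotamerPopulations",
    "RotamerShiftBasis",
    "ShiftRecord",
    "Chi2Thresholds",
    "TERMINAL_PENULTIMATE_PAIRS",
    "populations_from_shifts",
    "classify_chi2_state",
    "shift_distribution_stats",
    "find_isolated_terminal_pairs",
]

ROTAMER_ORDER = ("trans", "gauche_plus", "gauche_minus")

# Residue-type specific terminal (13C_t) / penultimate (13C_p) bonded pairs
# whose shift distributions are candidates for selective excitation.
TERMINAL_PENULTIMATE_PAIRS = (
    ("ARG", "CD", "CG"),
    ("ILE", "CD1", "CG1"),
    ("ILE", "CG2", "CB"),
    ("LYS", "CE", "CD"),
    ("PRO", "CD", "CG"),
    ("THR", "CG2", "CB"),
    ("VAL", "CG1", "CB"),
    ("VAL", "CG2", "CB"),
)


@dataclass
class RotamerPopulations:
    """Fractional populations of the three staggered rotamers."""

    p_trans: float
    p_gauche_plus: float
    p_gauche_minus: float
    underdetermined: bool = False

    def __post_init__(self) -> None:
        p = self.as_array()
        if np.any(p < -1e-9) or np.any(p > 1.0 + 1e-9):
            raise InvalidParameterError(f"populations outside [0, 1]: {p}")
        if abs(p.sum() - 1.0) > 1e-6:
            raise InvalidParameterError(
                f"populations must sum to 1 within 1e-6, got {p.sum()}"
            )

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.p_trans, self.p_gauche_plus, self.p_gauche_minus]
        )


@dataclass
class RotamerShiftBasis:
    """Pure-rotamer reference shifts (ppm) per atom of one residue type.

    ``references`` maps an atom name to its (trans, gauche+, gauche-)
    reference shifts.
    """

    references: Mapping[str, Sequence[float]]

    def __post_init__(self) -> None:
        for atom, refs in self.references.items():
            refs = np.asarray(refs, dtype=float)
            if refs.shape != (3,) or not np.all(np.isfinite(refs)):
                raise InvalidParameterError(
                    f"basis for atom {atom!r} needs three finite shifts"
                )

    def matrix(self, atoms: Sequence[str]) -> np.ndarray:
        rows = []
        for atom in atoms:
            if atom not in self.references:
                raise MappingError(f"no reference shifts for atom {atom!r}")
            rows.append(np.asarray(self.references[atom], dtype=float))
        return np.vstack(rows)


@dataclass
class ShiftRecord:
    """One assigned chemical shift: residue type, atom name, shift in ppm."""

    res_type: str
    atom: str
    shift_ppm: float

    def __post_init__(self) -> None:
        if not (-10.0 <= self.shift_ppm <= 90.0):
            raise InvalidParameterError(
                f"{self.shift_ppm} ppm outside the aliphatic 13C window"
            )


@dataclass
class Chi2Thresholds:
    """Cutoffs for the rule-based chi2 state classification.

    ``j_large``/``j_small`` split the coupling axis (Hz): above j_large the
    dihedral is trans, below j_small it is gauche, in between the side
    chain is called dynamic.  ``shift_large`` (ppm) separates gauche-plus
    (large terminal shift) from gauche-minus within the small-J branch.
    """

    j_large: float
    j_small: float
    shift_large: float

    def __post_init__(self) -> None:
        if self.j_small > self.j_large:
            raise InvalidParameterError("j_small must be <= j_large")


def _solve_simplex_lsq(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimize ||A p - b||^2 (+ tiny ridge) over the probability simplex.

    Exact active-set enumeration over the 7 facets of the 3-simplex; the
    ridge (1e-10 relative) selects the minimum-norm solution when the
    system is under-determined without visibly perturbing determined
    solutions.
    """
    n = A.shape[1]
    ridge = 1e-10 * max(1.0, float(np.trace(A.T @ A)))
    best = None
    best_obj = np.inf
    for r in range(1, n + 1):
        for free in itertools.combinations(range(n), r):
            free = list(free)
            Af = A[:, free]
            H = 2.0 * (Af.T @ Af + ridge * np.eye(r))
            K = np.zeros((r + 1, r + 1))
            K[:r, :r] = H
            K[:r, r] = 1.0
            K[r, :r] = 1.0
            rhs = np.concatenate([2.0 * Af.T @ b, [1.0]])
            try:
                sol = np.linalg.solve(K, rhs)
            except np.linalg.LinAlgError:
                continue
            pf = sol[:r]
            if np.any(pf < -1e-10):
                continue
            p = np.zeros(n)
            p[free] = np.clip(pf, 0.0, None)
            p /= p.sum()
            resid = A @ p - b
            obj = float(resid @ resid + ridge * (p @ p))
            if obj < best_obj - 1e-15:
                best_obj = obj
                best = p
    assert best is not None
    return best


def populations_from_shifts(
    observed: Sequence[tuple[str, float]],
    basis: RotamerShiftBasis,
) -> RotamerPopulations:
    """Invert observed shifts to rotamer populations on the simplex.

    With fewer than two informative shifts the three populations are not
    uniquely determined; the minimum-norm simplex solution is returned and
    the ``underdetermined`` flag set.
    """
    if len(observed) == 0:
        raise InvalidParameterError("at least one observed shift is required")
    atoms = [a for a, _ in observed]
    b = np.array([s for _, s in observed], dtype=float)
    A = basis.matrix(atoms)

    stacked = np.vstack([A, np.ones((1, 3))])
    underdetermined = np.linalg.matrix_rank(stacked, tol=1e-8) < 3

    p = _solve_simplex_lsq(A, b)
    return RotamerPopulations(
        p_trans=float(p[0]),
        p_gauche_plus=float(p[1]),
        p_gauche_minus=float(p[2]),
        underdetermined=bool(underdetermined),
    )


def classify_chi2_state(
    shift_ppm: float, j_hz: float, thresholds: Chi2Thresholds
) -> str:
    """Rule-based chi2 rotamer label from a terminal shift and a 3J value.

    Large J -> 'trans'; small J with a large terminal shift -> 'gauche_plus';
    small J with a small shift -> 'gauche_minus'; intermediate J ->
    'dynamic' (rotamer averaging).
    """
    if j_hz >= thresholds.j_large:
        return "trans"
    if j_hz <= thresholds.j_small:
        if shift_ppm >= thresholds.shift_large:
            return "gauche_plus"
        return "gauche_minus"
    return "dynamic"


def shift_distribution_stats(
    records: Iterable[ShiftRecord],
    n_bins: int = 50,
    outlier_sd: float = 5.0,
) -> pd.DataFrame:
    """Robust per-(residue, atom) statistics of a chemical-shift table.

    Outliers beyond ``outlier_sd`` standard deviations are removed once
    before the final mean/sd; a fixed-bin histogram is attached per group.
    Groups with fewer than two records are dropped.
    """
    records = list(records)
    if not records:
        return pd.DataFrame(
            columns=["res_type", "atom", "n", "mean", "sd", "hist", "bin_edges"]
        )
    df = pd.DataFrame(
        {
            "res_type": [r.res_type for r in records],
            "atom": [r.atom for r in records],
            "shift_ppm": [r.shift_ppm for r in records],
        }
    )
    rows = []
    for (res, atom), grp in df.groupby(["res_type", "atom"], sort=True):
        x = grp["shift_ppm"].to_numpy()
        if x.size < 2:
            continue
        mu, sd = float(np.mean(x)), float(np.std(x, ddof=1))
        if sd > 0:
            keep = np.abs(x - mu) <= outlier_sd * sd
            x = x[keep]
        mu, sd = float(np.mean(x)), float(np.std(x, ddof=1)) if x.size > 1 else 0.0
        hist, edges = np.histogram(x, bins=n_bins)
        rows.append(
            {
                "res_type": res,
                "atom": atom,
                "n": int(x.size),
                "mean": mu,
                "sd": sd,
                "hist": hist,
                "bin_edges": edges,
            }
        )
    return pd.DataFrame(rows)


def find_isolated_terminal_pairs(
    stats: pd.DataFrame,
    min_separation_sd: float,
    pairs: Sequence[tuple[str, str, str]] = TERMINAL_PENULTIMATE_PAIRS,
) -> list[tuple[str, str, str, float]]:
    """Terminal/penultimate pairs with well-separated shift distributions.

    For each bonded pair the separation score is
    |mu_t - mu_p| / sqrt(sd_t^2 + sd_p^2); pairs scoring at or above
    ``min_separation_sd`` are returned as
    (res_type, terminal_atom, penultimate_atom, score).  Pairs with missing
    statistics are skipped with a warning.
    """
    indexed = stats.set_index(["res_type", "atom"]) if len(stats) else stats
    out = []
    for res, term, penu in pairs:
        try:
            row_t = indexed.loc[(res, term)]
            row_p = indexed.loc[(res, penu)]
        except (KeyError, AttributeError):
            warnings.warn(
                f"missing shift statistics for {res} {term}-{penu}; skipped",
                stacklevel=2,
            )
            continue
        denom = float(np.sqrt(row_t["sd"] ** 2 + row_p["sd"] ** 2))
        if denom == 0:
            score = np.inf if row_t["mean"] != row_p["mean"] else 0.0
        else:
            score = float(abs(row_t["mean"] - row_p["mean"]) / denom)
        if score >= min_separation_sd:
            out.append((res, term, penu, score))
    return out
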