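"""Global least-squares fitting of CEST profiles.

The target function is the chi-square

    chi2(p) = sum_i (I_obs,i - I_calc,i(p))^2 / sigma_i^2

summed over all saturation offsets and field strengths of all profiles.
The exchange rate ``k_ex`` and the excited-state population ``p_E`` are
global (shared by every spin); each spin contributes its own ground- and
excited-state shifts, R1 and transverse rates.  CEST chi-square surfaces
are multimodal in the excited-state shift, so the fit is multi-started over
a grid of initial excited-state positions and the lowest-chi2 solution is
kept (ties broken by the smaller p_E).

Per-parameter uncertainties come from the covariance matrix at the optimum;
the joint uncertainty of (k_ex, p_E) can additionally be mapped by a grid
search in which the pair is fixed at each node and all other parameters are
re-optimized.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import lmfit
import numpy as np

from .errors import ConfigurationError, InvalidParameterError, MappingError
from .spin_models import (
    CestProfile,
    GlobalExchangeParams,
    SpinExchangeParams,
    simulate_intensities,
)

__all__ = [
    "FitConfig",
    "FitResult",
    "GridSearchResult",
    "chi_square",
    "fit_cest",
    "grid_search_uncertainty",
]

# two-parameter joint 1-sigma contour of a chi-square surface
DELTA_CHI2_JOINT_1SIGMA = 2.30

_P_E_CEILING = 0.4999


@dataclass
class FitConfig:
    """Settings of the global CEST fit.

    ``share_r2`` constrains R2_ground = R2_excited per spin (used when the
    data cannot determine the excited-state linewidth independently).
    ``init_grid_omega_e`` holds ppm starting values for the excited-state
    shift; None means an 11-point grid spanning the offset window.
    """

    share_r2: bool = False
    init_grid_omega_e: Sequence[float] | None = None
    init_k_ex: float = 100.0
    init_p_e: float = 0.02
    init_grid_k_ex: Sequence[float] = (30.0, 100.0, 300.0)
    init_grid_p_e: Sequence[float] = (0.005, 0.02, 0.05)
    max_iterations: int = 2000
    tolerance: float = 1e-10
    n_refine_starts: int = 3
    refine_max_nfev: int = 80
    restart_max_nfev: int = 120
    n_polish: int = 2
    shift_scan_hz: float = 8.0
    shift_scan_points: int = 17
    shift_scan_rounds: int = 3
    shift_scan_nfev: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ConfigurationError("tolerance must be > 0")
        if self.init_grid_omega_e is not None and len(self.init_grid_omega_e) == 0:
            raise ConfigurationError("init_grid_omega_e must be non-empty")


@dataclass
class FitResult:
    """Outcome of a global CEST fit."""

    global_params: GlobalExchangeParams
    spin_params: dict[str, SpinExchangeParams]
    chi2: float
    dof: int
    uncertainties: dict[str, float]
    success: bool
    message: str = ""
    flags: list[str] = field(default_factory=list)
    seed: int = 0

    @property
    def reduced_chi2(self) -> float:
        return self.chi2 / self.dof


@dataclass
class GridSearchResult:
    """chi2 surface over a (k_ex, p_E) grid with other parameters re-fit."""

    k_ex_values: np.ndarray
    p_e_values: np.ndarray
    chi2_surface: np.ndarray
    delta_chi2_threshold: float
    region_mask: np.ndarray
    truncated: bool

    def confidence_interval(self, axis: str) -> tuple[float, float]:
        """1-D extent of the joint confidence region along 'k_ex' or 'p_e'."""
        values = self.k_ex_values if axis == "k_ex" else self.p_e_values
        which = np.any(self.region_mask, axis=1 if axis == "k_ex" else 0)
        if not which.any():
            i = np.unravel_index(np.argmin(self.chi2_surface), self.chi2_surface.shape)
            v = values[i[0] if axis == "k_ex" else i[1]]
            return (v, v)
        return (float(values[which].min()), float(values[which].max()))

    def profile_interval(
        self, axis: str, delta_chi2: float = 1.0
    ) -> tuple[float, float]:
        """1-D profile-chi2 interval (other global parameter minimized out)."""
        if axis == "k_ex":
            values, prof = self.k_ex_values, self.chi2_surface.min(axis=1)
        else:
            values, prof = self.p_e_values, self.chi2_surface.min(axis=0)
        which = prof - prof.min() <= delta_chi2
        return (float(values[which].min()), float(values[which].max()))


def _slug(label: str) -> str:
    s = re.sub(r"\W", "_", label)
    return s if not s[:1].isdigit() else "s" + s


def _group_profiles(
    profiles: Sequence[CestProfile],
) -> dict[str, list[CestProfile]]:
    groups: dict[str, list[CestProfile]] = {}
    for p in profiles:
        groups.setdefault(p.label, []).append(p)
    return groups


def chi_square(
    profiles: Sequence[CestProfile],
    global_params: GlobalExchangeParams,
    spin_params: Mapping[str, SpinExchangeParams],
) -> float:
    """Weighted sum of squared residuals over all profiles and offsets."""
    total = 0.0
    for prof in profiles:
        if prof.label not in spin_params:
            raise MappingError(
                f"no model spin for profile label {prof.label!r}"
            )
        if prof.sigma is None or np.any(prof.sigma <= 0):
            raise InvalidParameterError(
                f"profile {prof.label!r} needs strictly positive sigma"
            )
        calc = simulate_intensities(
            spin_params[prof.label], global_params, prof.schedule
        )
        total += float(np.sum(((prof.intensities - calc) / prof.sigma) ** 2))
    return total


def _params_to_models(
    params: lmfit.Parameters,
    groups: Mapping[str, list[CestProfile]],
    j_cc: Mapping[str, float],
) -> tuple[GlobalExchangeParams, dict[str, SpinExchangeParams]]:
    glob = GlobalExchangeParams(
        k_ex=float(params["k_ex"].value),
        p_e=min(float(params["p_e"].value), _P_E_CEILING),
    )
    spins = {}
    for label in groups:
        key = _slug(label)
        spins[label] = SpinExchangeParams(
            label=label,
            shift_ground=float(params[f"{key}_w_g"].value),
            shift_excited=float(params[f"{key}_w_e"].value),
            r1=max(float(params[f"{key}_r1"].value), 1e-9),
            r2_ground=float(params[f"{key}_r2g"].value),
            r2_excited=float(params[f"{key}_r2e"].value),
            j_cc=j_cc[label],
        )
    return glob, spins


def _residuals(
    params: lmfit.Parameters,
    groups: Mapping[str, list[CestProfile]],
    j_cc: Mapping[str, float],
) -> np.ndarray:
    glob, spins = _params_to_models(params, groups, j_cc)
    chunks = []
    for label, profs in groups.items():
        for prof in profs:
            calc = simulate_intensities(spins[label], glob, prof.schedule)
            chunks.append((prof.intensities - calc) / prof.sigma)
    return np.concatenate(chunks)


def _initial_spin_guesses(profs: list[CestProfile]) -> dict[str, float]:
    """Data-driven starting values for one spin from its deepest profile."""
    prof = profs[0]
    sched = prof.schedule
    i_min = int(np.argmin(prof.intensities))
    w_g = float(sched.hz_to_ppm(sched.offsets[i_min]))
    plateau = float(np.median(np.sort(prof.intensities)[-5:]))
    plateau = min(max(plateau, 1e-3), 1.0 - 1e-9)
    r1 = -np.log(plateau) / sched.t_sat if sched.t_sat > 0 else 0.2
    r1 = float(np.clip(r1, 0.01, 50.0))
    return {"w_g": w_g, "r1": r1, "r2": 5.0}


def _build_parameters(
    groups: Mapping[str, list[CestProfile]],
    config: FitConfig,
    omega_e_init: Mapping[str, float],
) -> lmfit.Parameters:
    params = lmfit.Parameters()
    params.add("k_ex", value=config.init_k_ex, min=0.0, max=1e5)
    params.add("p_e", value=config.init_p_e, min=0.0, max=_P_E_CEILING)
    for label, profs in groups.items():
        key = _slug(label)
        guess = _initial_spin_guesses(profs)
        half_window = max(
            float(np.max(np.abs(p.schedule.hz_to_ppm(p.schedule.offsets))))
            for p in profs
        )
        params.add(
            f"{key}_w_g", value=guess["w_g"],
            min=guess["w_g"] - half_window, max=guess["w_g"] + half_window,
        )
        params.add(
            f"{key}_w_e", value=omega_e_init[label],
            min=-2.0 * half_window, max=2.0 * half_window,
        )
        params.add(f"{key}_r1", value=guess["r1"], min=1e-4, max=100.0)
        params.add(f"{key}_r2g", value=guess["r2"], min=0.0, max=1e4)
        if config.share_r2:
            params.add(f"{key}_r2e", expr=f"{key}_r2g")
        else:
            params.add(f"{key}_r2e", value=guess["r2"], min=0.0, max=1e4)
    return params


def _minimize(
    params: lmfit.Parameters,
    groups: Mapping[str, list[CestProfile]],
    j_cc: Mapping[str, float],
    max_nfev: int | None,
    ftol: float,
) -> lmfit.minimizer.MinimizerResult:
    return lmfit.minimize(
        _residuals,
        params,
        args=(groups, j_cc),
        method="least_squares",
        max_nfev=max_nfev,
        ftol=ftol,
        xtol=ftol,
        gtol=ftol,
        x_scale="jac",
    )


def fit_cest(
    profiles: Sequence[CestProfile],
    config: FitConfig | None = None,
    j_cc: Mapping[str, float] | float = 0.0,
    warm_start: FitResult | None = None,
) -> FitResult:
    """Fit the two-site exchange model globally to a set of CEST profiles.

    Parameters
    ----------
    profiles
        One or more profiles; profiles sharing a label share spin
        parameters (e.g. the same spin at two saturation fields).
    j_cc
        One-bond coupling (Hz) of each detected spin, held fixed during the
        fit: either a mapping label -> Hz or a single value for all spins.
    warm_start
        Start from a previous solution instead of the multi-start grid
        (used by the grid search and by nested-model comparisons).
    """
    config = config or FitConfig()
    if len(profiles) == 0:
        raise ConfigurationError("at least one profile is required")
    for p in profiles:
        if p.intensities.size < 10:
            raise ConfigurationError(
                f"profile {p.label!r} has fewer than 10 points"
            )
        if p.sigma is None or np.any(p.sigma <= 0):
            raise InvalidParameterError(
                f"profile {p.label!r} needs strictly positive sigma"
            )
    groups = _group_profiles(profiles)
    if not isinstance(j_cc, Mapping):
        j_cc = {label: float(j_cc) for label in groups}
    for label in groups:
        if label not in j_cc:
            raise MappingError(f"no J_CC supplied for spin {label!r}")

    n_points = sum(p.intensities.size for p in profiles)

    if warm_start is not None:
        params = _parameters_from_result(warm_start, groups, config)
        final = _minimize(
            params, groups, j_cc, config.max_iterations, config.tolerance
        )
    else:
        final = _staged_fit(groups, j_cc, config)

    dof = n_points - final.nvarys
    if dof <= 0:
        raise ConfigurationError(
            f"dof = {dof} <= 0: {n_points} points, {final.nvarys} parameters"
        )
    chi2 = float(np.sum(final.residual**2))
    glob, spins = _params_to_models(final.params, groups, j_cc)

    uncertainties = {}
    for name, par in final.params.items():
        if par.vary and par.stderr is not None:
            uncertainties[name] = float(par.stderr)

    flags = []
    p_e_err = uncertainties.get("p_e", np.inf)
    if glob.p_e < max(1e-4, 2.0 * p_e_err) or glob.p_e < 1e-4:
        flags.append("omega_e_unidentifiable")
    if not final.success:
        flags.append("not_converged")

    return FitResult(
        global_params=glob,
        spin_params=spins,
        chi2=chi2,
        dof=dof,
        uncertainties=uncertainties,
        success=bool(final.success),
        message=str(final.message),
        flags=flags,
        seed=config.seed,
    )


def _staged_fit(
    groups: Mapping[str, list[CestProfile]],
    j_cc: Mapping[str, float],
    config: FitConfig,
) -> lmfit.minimizer.MinimizerResult:
    """Three-stage minimization of the multimodal CEST chi-square.

    1. Multi-start over excited-state shift positions, screened by their
       initial chi2; the best few starts are refined briefly and only the
       refined excited-state shifts are kept.
    2. Restarts over a coarse (k_ex, p_E) grid, each from *fresh*
       data-driven per-spin parameters plus the learned shifts: the
       surface has distinct basins along the exchange parameters
       (inflated-R2E solutions compensating a wrong k_ex), and per-spin
       parameters adapted to a wrong (k_ex, p_E) trap the refit there.
    3. The lowest-chi2 restarts are polished to full tolerance; the best
       polished solution wins, ties broken by the smaller p_E.
    4. Fine fixed-shift scans: chi2 is rugged on a 1-3 Hz scale in the
       state shifts (points on the steep dip edges are exquisitely
       sensitive to the dip position), so each shift is stepped over a
       +-shift_scan_hz window with everything else re-optimized, and any
       improvement is re-polished.  Repeats until no shift moves.
    """
    starts = _multi_starts(groups, config)
    scored = []
    for params in starts:
        chi0 = float(np.sum(_residuals(params, groups, j_cc) ** 2))
        scored.append((chi0, params))
    scored.sort(key=lambda t: t[0])
    n_refine = max(1, min(config.n_refine_starts, len(scored)))

    stage1 = []
    for _, params in scored[:n_refine]:
        res = _minimize(params, groups, j_cc, config.refine_max_nfev, 1e-8)
        stage1.append((float(np.sum(res.residual**2)), res))
    stage1.sort(key=lambda t: t[0])
    seed_params = stage1[0][1].params
    omega_e = {
        label: float(seed_params[f"{_slug(label)}_w_e"].value)
        for label in groups
    }

    stage2 = []
    for k0 in config.init_grid_k_ex:
        for p0 in config.init_grid_p_e:
            p = _build_parameters(groups, config, omega_e)
            p["k_ex"].value = float(k0)
            p["p_e"].value = float(p0)
            res = _minimize(p, groups, j_cc, config.restart_max_nfev, 1e-8)
            stage2.append((float(np.sum(res.residual**2)), res))
    # the briefly-refined stage-1 winner also competes
    stage2.append(stage1[0])
    stage2.sort(key=lambda t: t[0])

    polished = []
    for _, res in stage2[: max(1, config.n_polish)]:
        fin = _minimize(
            res.params, groups, j_cc, config.max_iterations, config.tolerance
        )
        polished.append(fin)
    polished.sort(
        key=lambda r: (
            float(np.sum(r.residual**2)),
            float(r.params["p_e"].value),
        )
    )
    return _shift_ripple_scan(polished[0], groups, j_cc, config)


def _shift_ripple_scan(
    best: lmfit.minimizer.MinimizerResult,
    groups: Mapping[str, list[CestProfile]],
    j_cc: Mapping[str, float],
    config: FitConfig,
) -> lmfit.minimizer.MinimizerResult:
    """Escape the fine-scale ripples of chi2 in the state chemical shifts."""
    if config.shift_scan_rounds < 1 or config.shift_scan_points < 1:
        return best
    sfrq = next(iter(groups.values()))[0].schedule.spectrometer_freq
    best_chi = float(np.sum(best.residual**2))
    shift_names = [
        name
        for label in groups
        for name in (f"{_slug(label)}_w_g", f"{_slug(label)}_w_e")
    ]
    for _ in range(config.shift_scan_rounds):
        improved = False
        for name in shift_names:
            centre = float(best.params[name].value)
            offsets_ppm = (
                np.linspace(-config.shift_scan_hz, config.shift_scan_hz,
                            config.shift_scan_points)
                / sfrq
            )
            found = None
            for cand in centre + offsets_ppm:
                p = best.params.copy()
                p[name].set(value=cand, vary=False)
                res = _minimize(p, groups, j_cc, config.shift_scan_nfev, 1e-8)
                chi = float(np.sum(res.residual**2))
                if chi < best_chi - 0.5 and (found is None or chi < found[0]):
                    found = (chi, res)
            if found is not None:
                q = found[1].params.copy()
                q[name].set(
                    vary=True,
                    min=best.params[name].min,
                    max=best.params[name].max,
                )
                res = _minimize(
                    q, groups, j_cc, config.max_iterations, config.tolerance
                )
                chi = float(np.sum(res.residual**2))
                if chi < best_chi - 1e-9:
                    best, best_chi = res, chi
                    improved = True
        if not improved:
            break
    return best


def _multi_starts(
    groups: Mapping[str, list[CestProfile]], config: FitConfig
) -> list[lmfit.Parameters]:
    """Starting parameter sets for the excited-state shift multi-start."""
    any_prof = next(iter(groups.values()))[0]
    sched = any_prof.schedule
    window = sched.hz_to_ppm(np.array([sched.offsets.min(), sched.offsets.max()]))
    if config.init_grid_omega_e is None:
        grid = list(np.linspace(window[0], window[1], 11))
    else:
        grid = list(config.init_grid_omega_e)

    starts = []
    # one start per grid value, all spins initialized at the same position
    for g in grid:
        starts.append(
            _build_parameters(groups, config, {label: g for label in groups})
        )
    # one data-driven start: per spin, the grid value nearest the second
    # deepest feature of its own profile (cheap 1-spin screen)
    per_spin = {}
    for label, profs in groups.items():
        prof = profs[0]
        ints = prof.intensities.copy()
        sched = prof.schedule
        i_main = int(np.argmin(ints))
        # mask the main dip before searching for a secondary one
        width_hz = 5.0 * sched.b1_field
        mask = np.abs(sched.offsets - sched.offsets[i_main]) < width_hz
        ints[mask] = np.inf
        i_second = int(np.argmin(ints))
        per_spin[label] = float(sched.hz_to_ppm(sched.offsets[i_second]))
    starts.append(_build_parameters(groups, config, per_spin))
    return starts


def _parameters_from_result(
    result: FitResult,
    groups: Mapping[str, list[CestProfile]],
    config: FitConfig,
) -> lmfit.Parameters:
    params = _build_parameters(
        groups,
        config,
        {label: result.spin_params[label].shift_excited for label in groups},
    )
    params["k_ex"].value = result.global_params.k_ex
    params["p_e"].value = result.global_params.p_e
    for label in groups:
        key = _slug(label)
        sp = result.spin_params[label]
        params[f"{key}_w_g"].value = sp.shift_ground
        params[f"{key}_r1"].value = sp.r1
        params[f"{key}_r2g"].value = sp.r2_ground
        if not config.share_r2:
            params[f"{key}_r2e"].value = sp.r2_excited
    return params


def grid_search_uncertainty(
    profiles: Sequence[CestProfile],
    fit: FitResult,
    k_grid: Sequence[float],
    p_grid: Sequence[float],
    config: FitConfig | None = None,
    j_cc: Mapping[str, float] | float = 0.0,
    max_nfev: int = 60,
    delta_chi2: float = DELTA_CHI2_JOINT_1SIGMA,
) -> GridSearchResult:
    """Map the chi2 surface over a (k_ex, p_E) grid.

    At each node the global pair is fixed and all per-spin parameters are
    re-optimized starting from the fitted optimum.  The joint 1-sigma
    confidence region is the set of nodes with chi2 - chi2_min <= 2.30.
    """
    config = config or FitConfig()
    groups = _group_profiles(profiles)
    if not isinstance(j_cc, Mapping):
        j_cc = {label: float(j_cc) for label in groups}
    k_grid = np.asarray(k_grid, dtype=float)
    p_grid = np.asarray(p_grid, dtype=float)

    truncated = not (
        k_grid.min() <= fit.global_params.k_ex <= k_grid.max()
        and p_grid.min() <= fit.global_params.p_e <= p_grid.max()
    )
    if truncated:
        import warnings

        warnings.warn(
            "fitted optimum lies outside the grid; region will be truncated",
            stacklevel=2,
        )

    surface = np.empty((k_grid.size, p_grid.size))
    for i, k in enumerate(k_grid):
        for j, p in enumerate(p_grid):
            params = _parameters_from_result(fit, groups, config)
            params["k_ex"].set(value=float(k), vary=False)
            params["p_e"].set(value=float(p), vary=False)
            res = _minimize(params, groups, j_cc, max_nfev, 1e-8)
            surface[i, j] = float(np.sum(res.residual**2))

    mask = surface - surface.min() <= delta_chi2
    return GridSearchResult(
        k_ex_values=k_grid,
        p_e_values=p_grid,
        chi2_surface=surface,
        delta_chi2_threshold=delta_chi2,
        region_mask=mask,
        truncated=truncated,
    )
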