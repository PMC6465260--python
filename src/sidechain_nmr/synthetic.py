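"""Ground-truth generators for synthetic datasets.

Every generator takes an explicit seed, draws all randomness from a single
``numpy.random.default_rng(seed)``, and returns a :class:`TruthRecord`
alongside the data so that any dataset can be regenerated bit-identically
and compared against its known ground truth.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import yaml

from .couplings import CouplingMeasurement, ratio_from_j
from .errors import InvalidParameterError
from .rotamers import ShiftRecord
from .spin_models import (
    CestProfile,
    CestSchedule,
    GlobalExchangeParams,
    SpinExchangeParams,
    simulate_intensities,
)

__all__ = [
    "TruthRecord",
    "valine_schedule",
    "arg_thr_schedule",
    "exchange_study_conditions",
    "generate_cest_dataset",
    "generate_coupling_peaks",
    "generate_shift_table",
]


@dataclass
class TruthRecord:
    """Serializable record of a generator call: parameters, seed, noise."""

    generator: str
    parameters: dict[str, Any]
    seed: int
    noise: dict[str, float] = field(default_factory=dict)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "TruthRecord":
        return cls(**yaml.safe_load(text))


def valine_schedule(
    b1_field: float = 25.0,
    t_sat: float = 0.5,
    spectrometer_freq: float = 150.9,
    b1_inhomogeneity: float = 0.05,
) -> CestSchedule:
    """Saturation grid used for valine spins: 50 offsets over +-600 Hz."""
    return CestSchedule(
        offsets=np.linspace(-600.0, 600.0, 50),
        b1_field=b1_field,
        t_sat=t_sat,
        spectrometer_freq=spectrometer_freq,
        b1_inhomogeneity=b1_inhomogeneity,
    )


def arg_thr_schedule(
    b1_field: float = 25.0,
    t_sat: float = 0.5,
    spectrometer_freq: float = 150.9,
    b1_inhomogeneity: float = 0.05,
) -> CestSchedule:
    """Saturation grid used for arginine/threonine: 42 offsets, +-300 Hz."""
    return CestSchedule(
        offsets=np.linspace(-300.0, 300.0, 42),
        b1_field=b1_field,
        t_sat=t_sat,
        spectrometer_freq=spectrometer_freq,
        b1_inhomogeneity=b1_inhomogeneity,
    )


def exchange_study_conditions() -> tuple[
    list[SpinExchangeParams], GlobalExchangeParams, CestSchedule
]:
    """Reference millisecond-exchange study: three valine-like spins.

    Ground truth mirrors the conformational exchange of T4 lysozyme L99A at
    278 K as seen by 13C side-chain CEST: global k_ex = 128 s^-1 and
    p_E = 1.15%, spins with R1 in the 0.12-0.24 s^-1 range, ground-state R2
    of a few s^-1, a 35 Hz one-bond coupling, and state shifts inside the
    50-point +-600 Hz valine saturation grid.
    """
    spins = [
        SpinExchangeParams("V103CG2", 1.0, -1.2, 0.20, 4.0, 6.0, 35.0),
        SpinExchangeParams("V111CG1", -0.7, 1.5, 0.15, 6.0, 8.0, 35.0),
        SpinExchangeParams("V87CG2", 0.35, 2.3, 0.24, 8.0, 10.0, 35.0),
    ]
    globals_ = GlobalExchangeParams(k_ex=128.0, p_e=0.0115)
    return spins, globals_, valine_schedule()


def generate_cest_dataset(
    spins: Sequence[SpinExchangeParams],
    globals_: GlobalExchangeParams,
    schedule: CestSchedule,
    noise_sd: float,
    seed: int,
) -> tuple[list[CestProfile], TruthRecord]:
    """Forward-simulate CEST profiles and add i.i.d. Gaussian noise.

    The sigma column of each profile is set to ``noise_sd`` (the generating
    value), matching the convention of fitting correctly weighted data.
    """
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    profiles = []
    for spin in spins:
        clean = simulate_intensities(spin, globals_, schedule)
        noisy = clean + rng.normal(0.0, noise_sd, size=clean.shape) if noise_sd > 0 else clean
        profiles.append(
            CestProfile(
                label=spin.label,
                schedule=schedule,
                intensities=noisy,
                sigma=np.full_like(clean, noise_sd),
            )
        )
    truth = TruthRecord(
        generator="generate_cest_dataset",
        parameters={
            "spins": [asdict(s) for s in spins],
            "globals": asdict(globals_),
            "schedule": {
                "offsets": schedule.offsets.tolist(),
                "b1_field": schedule.b1_field,
                "t_sat": schedule.t_sat,
                "spectrometer_freq": schedule.spectrometer_freq,
                "b1_inhomogeneity": schedule.b1_inhomogeneity,
                "n_b1_quadrature": schedule.n_b1_quadrature,
            },
        },
        seed=seed,
        noise={"noise_sd": noise_sd},
    )
    return profiles, truth


def generate_coupling_peaks(
    j_true: float,
    t_j: float,
    i_d_amp: float,
    noise_rmsd: float,
    seed: int,
    n_replicates: int = 1,
) -> tuple[list[CouplingMeasurement], TruthRecord]:
    """Diagonal/cross peak-height pairs with I_c/I_d = tan^2(2 pi J T_J).

    Gaussian noise of sd ``noise_rmsd`` is added independently to both
    heights of every replicate.
    """
    ratio = ratio_from_j(j_true, t_j)
    rng = np.random.default_rng(seed)
    measurements = []
    for _ in range(n_replicates):
        i_d = i_d_amp + (rng.normal(0.0, noise_rmsd) if noise_rmsd > 0 else 0.0)
        i_c = i_d_amp * ratio + (
            rng.normal(0.0, noise_rmsd) if noise_rmsd > 0 else 0.0
        )
        measurements.append(
            CouplingMeasurement(
                i_d=i_d, i_c=i_c, noise_rmsd=noise_rmsd, t_j=t_j
            )
        )
    truth = TruthRecord(
        generator="generate_coupling_peaks",
        parameters={
            "j_true": j_true,
            "t_j": t_j,
            "i_d_amp": i_d_amp,
            "n_replicates": n_replicates,
        },
        seed=seed,
        noise={"noise_rmsd": noise_rmsd},
    )
    return measurements, truth


def generate_shift_table(
    spec: Mapping[tuple[str, str], tuple[float, float]],
    n: int,
    seed: int,
) -> tuple[list[ShiftRecord], TruthRecord]:
    """Gaussian chemical-shift records per (residue type, atom).

    ``spec`` maps (res_type, atom) -> (mean ppm, sd ppm); ``n`` records are
    drawn for each entry.
    """
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    rng = np.random.default_rng(seed)
    records = []
    for (res_type, atom), (mean, sd) in spec.items():
        draws = rng.normal(mean, sd, size=n)
        records.extend(
            ShiftRecord(res_type=res_type, atom=atom, shift_ppm=float(x))
            for x in draws
        )
    truth = TruthRecord(
        generator="generate_shift_table",
        parameters={
            "spec": {f"{r}/{a}": [m, s] for (r, a), (m, s) in spec.items()},
            "n": n,
        },
        seed=seed,
    )
    return records, truth
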