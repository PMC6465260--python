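"""Plain-text readers and writers.

All on-disk formats are tab-separated tables with ``#``-prefixed metadata
headers, plus a YAML configuration format describing spins, global exchange
parameters and a saturation schedule.  ppm <-> Hz conversions happen only
here and in the schedule helpers, never inside the numerics.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .couplings import CouplingMeasurement
from .errors import InvalidParameterError
from .rotamers import RotamerShiftBasis, ShiftRecord
from .spectra import Spectrum1D
from .spin_models import (
    CestProfile,
    CestSchedule,
    GlobalExchangeParams,
    SpinExchangeParams,
)

__all__ = [
    "write_cest_profiles",
    "read_cest_profiles",
    "save_config",
    "load_config",
    "read_peak_table",
    "write_coupling_table",
    "read_shift_table",
    "write_shift_table",
    "read_spectrum",
    "write_spectrum",
    "load_shift_basis",
]


def _meta_line(**kv: float) -> str:
    return "# " + " ".join(f"{k}={v!r}" for k, v in kv.items())


def _parse_meta(lines: list[str]) -> dict[str, float]:
    meta: dict[str, float] = {}
    for line in lines:
        for token in line.lstrip("#").split():
            if "=" in token:
                k, v = token.split("=", 1)
                meta[k] = float(v)
    return meta


def write_cest_profiles(path: str | Path, profiles: Sequence[CestProfile]) -> None:
    """Write profiles sharing one schedule to a TSV with a ``#`` header."""
    if not profiles:
        raise InvalidParameterError("no profiles to write")
    sched = profiles[0].schedule
    rows = []
    for prof in profiles:
        if prof.schedule is not profiles[0].schedule and not (
            np.array_equal(prof.schedule.offsets, sched.offsets)
            and prof.schedule.b1_field == sched.b1_field
        ):
            raise InvalidParameterError(
                "all profiles in one file must share a schedule"
            )
        sigma = (
            prof.sigma
            if prof.sigma is not None
            else np.full_like(prof.intensities, np.nan)
        )
        for off, inten, sig in zip(sched.offsets, prof.intensities, sigma):
            rows.append((prof.label, off, inten, sig))
    df = pd.DataFrame(
        rows, columns=["label", "offset_hz", "intensity_norm", "sigma"]
    )
    header = _meta_line(
        b1_hz=sched.b1_field,
        t_sat_s=sched.t_sat,
        sfrq_mhz=sched.spectrometer_freq,
        b1_inhom=sched.b1_inhomogeneity,
    )
    with open(path, "w") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_cest_profiles(path: str | Path) -> list[CestProfile]:
    """Read a CEST profile TSV back into per-label profiles."""
    path = Path(path)
    meta_lines = [
        line for line in path.read_text().splitlines() if line.startswith("#")
    ]
    meta = _parse_meta(meta_lines)
    df = pd.read_csv(path, sep="\t", comment="#")
    profiles = []
    for label, grp in df.groupby("label", sort=False):
        schedule = CestSchedule(
            offsets=grp["offset_hz"].to_numpy(),
            b1_field=meta["b1_hz"],
            t_sat=meta["t_sat_s"],
            spectrometer_freq=meta["sfrq_mhz"],
            b1_inhomogeneity=meta.get("b1_inhom", 0.05),
        )
        sigma = grp["sigma"].to_numpy()
        profiles.append(
            CestProfile(
                label=str(label),
                schedule=schedule,
                intensities=grp["intensity_norm"].to_numpy(),
                sigma=None if np.all(np.isnan(sigma)) else sigma,
            )
        )
    return profiles


def save_config(
    path: str | Path,
    spins: Sequence[SpinExchangeParams],
    globals_: GlobalExchangeParams,
    schedule: CestSchedule,
) -> None:
    """Round-trippable YAML description of a simulation/fit setup."""
    doc = {
        "spins": [asdict(s) for s in spins],
        "globals": asdict(globals_),
        "schedule": {
            "offsets": [float(x) for x in schedule.offsets],
            "b1_field": schedule.b1_field,
            "t_sat": schedule.t_sat,
            "spectrometer_freq": schedule.spectrometer_freq,
            "b1_inhomogeneity": schedule.b1_inhomogeneity,
            "n_b1_quadrature": schedule.n_b1_quadrature,
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def load_config(
    path: str | Path,
) -> tuple[list[SpinExchangeParams], GlobalExchangeParams, CestSchedule]:
    doc = yaml.safe_load(Path(path).read_text())
    spins = [SpinExchangeParams(**s) for s in doc["spins"]]
    globals_ = GlobalExchangeParams(**doc["globals"])
    schedule = CestSchedule(
        offsets=np.asarray(doc["schedule"]["offsets"], dtype=float),
        b1_field=doc["schedule"]["b1_field"],
        t_sat=doc["schedule"]["t_sat"],
        spectrometer_freq=doc["schedule"]["spectrometer_freq"],
        b1_inhomogeneity=doc["schedule"].get("b1_inhomogeneity", 0.05),
        n_b1_quadrature=doc["schedule"].get("n_b1_quadrature", 5),
    )
    return spins, globals_, schedule


def read_peak_table(
    path: str | Path, t_j: float
) -> list[tuple[str, CouplingMeasurement]]:
    """Read ``label I_d I_c noise_rmsd`` rows for coupling extraction."""
    df = pd.read_csv(path, sep=r"\s+", comment="#")
    out = []
    for _, row in df.iterrows():
        out.append(
            (
                str(row["label"]),
                CouplingMeasurement(
                    i_d=float(row["I_d"]),
                    i_c=float(row["I_c"]),
                    noise_rmsd=float(row["noise_rmsd"]),
                    t_j=t_j,
                ),
            )
        )
    return out


def write_coupling_table(
    path: str | Path, rows: Sequence[tuple[str, float, float]]
) -> None:
    """Write ``label J_hz J_sd_hz`` rows."""
    df = pd.DataFrame(rows, columns=["label", "J_hz", "J_sd_hz"])
    df.to_csv(path, sep="\t", index=False)


def read_shift_table(path: str | Path) -> list[ShiftRecord]:
    """Read ``res_type atom shift_ppm`` rows."""
    df = pd.read_csv(path, sep=r"\s+", comment="#")
    return [
        ShiftRecord(
            res_type=str(r["res_type"]),
            atom=str(r["atom"]),
            shift_ppm=float(r["shift_ppm"]),
        )
        for _, r in df.iterrows()
    ]


def write_shift_table(path: str | Path, records: Sequence[ShiftRecord]) -> None:
    df = pd.DataFrame(
        {
            "res_type": [r.res_type for r in records],
            "atom": [r.atom for r in records],
            "shift_ppm": [r.shift_ppm for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_spectrum(path: str | Path) -> Spectrum1D:
    """Read a ``freq_hz amplitude`` TSV."""
    df = pd.read_csv(path, sep=r"\s+", comment="#")
    return Spectrum1D(
        axis=df["freq_hz"].to_numpy(), amplitude=df["amplitude"].to_numpy()
    )


def write_spectrum(path: str | Path, spectrum: Spectrum1D) -> None:
    df = pd.DataFrame(
        {"freq_hz": spectrum.axis, "amplitude": spectrum.amplitude}
    )
    df.to_csv(path, sep="\t", index=False)


def load_shift_basis(path: str | Path) -> dict[str, RotamerShiftBasis]:
    """Load per-residue rotamer reference shifts from YAML.

    Expected layout::

        VAL:
          CG1: {trans: 21.5, gauche_plus: 20.1, gauche_minus: 19.0}
    """
    doc = yaml.safe_load(Path(path).read_text())
    out = {}
    for res, atoms in doc.items():
        refs = {
            atom: (v["trans"], v["gauche_plus"], v["gauche_minus"])
            for atom, v in atoms.items()
        }
        out[str(res)] = RotamerShiftBasis(references=refs)
    return out
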