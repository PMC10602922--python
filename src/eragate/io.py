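"""File formats: long-format time-series CSV, titration CSV, FASTA, JSON
reports and flat-TOML run configuration.

Time-series CSV columns: ``time_s, sample_id, condition, replicate,
fluorescence_au`` (``replicate`` optional on read, defaulting to 1).
Titration CSV columns: ``concentration_nM, fluorescence_au, replicate``.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .calibration import CalibrationModel, FluorescenceSeries
from .energetics import EnergyModel
from .kinetics import MMFit
from .sequences import Alphabet, DuplexLayout, NucleicSequence
from .simulate import RateParams, ReactionSystem, Trajectory

__all__ = [
    "TIMESERIES_COLUMNS",
    "read_timeseries_csv",
    "write_timeseries_csv",
    "trajectory_to_frame",
    "read_titration_csv",
    "write_titration_csv",
    "read_fasta",
    "write_fasta",
    "write_layout_json",
    "read_layout_json",
    "write_calibration_json",
    "read_calibration_json",
    "write_mmfit_json",
    "RunConfig",
    "load_config",
]

TIMESERIES_COLUMNS = ("time_s", "sample_id", "condition", "fluorescence_au")
FLOAT_FORMAT = "%.10g"


class FormatError(ValueError):
    """A file does not conform to its declared format."""


# ---------------------------------------------------------------- time series

def read_timeseries_csv(path) -> list[FluorescenceSeries]:
    """Read a long-format fluorescence CSV into one series per
    (sample_id, condition, replicate) group, times sorted ascending."""
    df = pd.read_csv(path)
    missing = [c for c in TIMESERIES_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if "replicate" not in df.columns:
        df = df.assign(replicate=1)
    series = []
    for (sample, condition, replicate), grp in df.groupby(
            ["sample_id", "condition", "replicate"], sort=True):
        grp = grp.sort_values("time_s")
        times = grp["time_s"].to_numpy(dtype=float)
        if np.unique(times).size != times.size:
            raise FormatError(
                f"{path}: duplicated time point for sample {sample!r} "
                f"replicate {replicate}"
            )
        series.append(FluorescenceSeries(
            times, grp["fluorescence_au"].to_numpy(dtype=float),
            metadata={"sample_id": sample, "condition": condition,
                      "replicate": int(replicate)},
        ))
    return series


def write_timeseries_csv(path, series_list) -> None:
    rows = []
    for s in series_list:
        meta = s.metadata
        for t, v in zip(s.times, s.values):
            rows.append({
                "time_s": t,
                "sample_id": meta.get("sample_id", ""),
                "condition": meta.get("condition", ""),
                "replicate": meta.get("replicate", 1),
                "fluorescence_au": v,
            })
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def trajectory_to_frame(traj: Trajectory) -> pd.DataFrame:
    """Wide table of species concentrations versus time."""
    data = {"time_s": traj.times}
    data.update(traj.species)
    return pd.DataFrame(data)


# ----------------------------------------------------------------- titrations

def read_titration_csv(path) -> list[tuple[float, float]]:
    df = pd.read_csv(path)
    for col in ("concentration_nM", "fluorescence_au"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return list(zip(df["concentration_nM"].astype(float),
                    df["fluorescence_au"].astype(float)))


def write_titration_csv(path, points, replicate: int = 1) -> None:
    pd.DataFrame(
        [{"concentration_nM": c, "fluorescence_au": f, "replicate": replicate}
         for c, f in points]
    ).to_csv(path, index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------- FASTA

def read_fasta(path, alphabet: Alphabet) -> list[NucleicSequence]:
    """Read FASTA records, normalizing U/T to the declared alphabet."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper()
        residues = (residues.replace("T", "U") if alphabet is Alphabet.RNA
                    else residues.replace("U", "T"))
        out.append(NucleicSequence(residues, alphabet, name=rec.id))
    return out


def write_fasta(path, sequences) -> None:
    records = [SeqRecord(Seq(s.residues), id=s.name or f"seq{i}", description="")
               for i, s in enumerate(sequences, 1)]
    SeqIO.write(records, str(path), "fasta")


# ----------------------------------------------------------------------- JSON

def write_layout_json(path, layout: DuplexLayout, extra: dict | None = None) -> None:
    payload = dataclasses.asdict(layout)
    payload["toehold_direction"] = layout.toehold_direction.value
    payload.update(extra or {})
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_layout_json(path) -> dict:
    return json.loads(Path(path).read_text())


def write_calibration_json(path, calib: CalibrationModel) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(calib), indent=2,
                                     sort_keys=True) + "\n")


def read_calibration_json(path) -> CalibrationModel:
    return CalibrationModel(**json.loads(Path(path).read_text()))


def write_mmfit_json(path, fit: MMFit) -> None:
    payload = dataclasses.asdict(fit)
    payload["kcat_over_KM_per_M_s"] = fit.kcat_over_KM
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


# -------------------------------------------------------------- configuration

@dataclasses.dataclass
class RunConfig:
    """All tunable simulator/fit parameters plus the run seed.

    Parsed from a flat TOML file with optional ``[energy]``, ``[rates]``,
    ``[system]``, ``[onepot]`` and ``[noise]`` tables; unknown keys are
    rejected by name, and absent keys take the module defaults.
    """

    energy: EnergyModel = dataclasses.field(default_factory=EnergyModel)
    rates: RateParams = dataclasses.field(default_factory=RateParams)
    system: ReactionSystem = dataclasses.field(default_factory=ReactionSystem)
    sigma_au: float = 0.05
    seed: int = 0
    output_dir: Path = Path(".")


_SECTION_TYPES = {"energy": EnergyModel, "rates": RateParams,
                  "system": ReactionSystem}
_TOP_KEYS = {"seed", "output_dir", "sigma_au"}


def load_config(path) -> RunConfig:
    """Load a RunConfig from a flat TOML file, rejecting unknown keys."""
    try:
        raw = tomllib.loads(Path(path).read_text())
    except tomllib.TOMLDecodeError as exc:
        raise FormatError(f"{path}: malformed config: {exc}") from exc
    kwargs: dict = {}
    for key, value in raw.items():
        if key in _SECTION_TYPES:
            cls = _SECTION_TYPES[key]
            valid = {f.name for f in dataclasses.fields(cls)}
            unknown = set(value) - valid
            if unknown:
                raise FormatError(
                    f"{path}: unknown key(s) {sorted(unknown)} in [{key}]")
            kwargs[key] = cls(**value)
        elif key in _TOP_KEYS:
            kwargs[key if key != "output_dir" else "output_dir"] = (
                Path(value) if key == "output_dir" else value)
        else:
            raise FormatError(f"{path}: unknown config key {key!r}")
    return RunConfig(**kwargs)
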