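"""Readers and writers for the package's file formats.

All formats are plain text: YAML for parameters and schedules, CSV for
observations, trajectories and incidence data, JSON for fit reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .calibration import FitResult, ObservedSeries
from .dynamics import ModelParams, SimOutput
from .metastasis import IncidenceData
from .pk import ANTIANGIOGENIC, CYTOTOXIC, DoseEvent, PKParams

__all__ = [
    "load_model_params",
    "load_pk_params",
    "load_schedule",
    "read_observed_csv",
    "write_observed_csv",
    "write_trajectories_csv",
    "write_concentrations_csv",
    "read_incidence_csv",
    "write_incidence_csv",
    "write_fit_report",
]

logger = logging.getLogger(__name__)

_MODEL_FIELDS = {f.name for f in dataclasses.fields(ModelParams)}


def _load_structured(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def load_model_params(path: str | Path) -> ModelParams:
    """Read a ModelParams mapping from YAML or JSON.

    A missing ``tau`` defaults to 0 (its calibrated value in this system);
    unknown keys raise with the offending names.
    """
    raw = _load_structured(path)
    unknown = set(raw) - _MODEL_FIELDS
    if unknown:
        raise ValueError(f"{path}: unknown parameter field(s): {sorted(unknown)}")
    if "tau" not in raw:
        logger.info(
            "%s: tau not given; defaulting the stable-vessel loss rate to 0 "
            "(its consistently calibrated value in this system)", path
        )
        raw["tau"] = 0.0
    missing = {"a", "b", "d", "e_txl", "e_beva"} - set(raw)
    if missing:
        raise ValueError(f"{path}: missing required field(s): {sorted(missing)}")
    return ModelParams(**{k: float(v) for k, v in raw.items()})


def load_pk_params(path: str | Path) -> dict[str, PKParams]:
    """Read per-drug PK constants: {drug: {ka_per_day, ke_per_day, scale}}."""
    raw = _load_structured(path)
    out = {}
    for drug in (CYTOTOXIC, ANTIANGIOGENIC):
        if drug not in raw:
            raise ValueError(f"{path}: missing PK section for {drug!r}")
        entry = raw[drug]
        out[drug] = PKParams(
            ka=float(entry["ka_per_day"]),
            ke=float(entry["ke_per_day"]),
            scale=float(entry.get("scale", entry["ke_per_day"])),
        )
    return out


def load_schedule(path: str | Path) -> tuple[DoseEvent, ...]:
    """Read a dose list: [{drug, day, dose_mg_per_kg}, ...]."""
    raw = _load_structured(path)
    if not isinstance(raw, list):
        raise ValueError(f"{path}: schedule file must contain a list of doses")
    doses = []
    for i, entry in enumerate(raw):
        try:
            doses.append(
                DoseEvent(
                    drug=entry["drug"],
                    time=float(entry["day"]),
                    dose=float(entry["dose_mg_per_kg"]),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"{path}: invalid dose entry #{i + 1}: {exc}") from exc
    return tuple(sorted(doses, key=lambda d: d.time))


def read_observed_csv(path: str | Path) -> list[ObservedSeries]:
    """Read grouped kinetics: columns group,time_days,mean_fold[,sem,n]."""
    df = pd.read_csv(path)
    required = {"group", "time_days", "mean_fold"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s): {sorted(missing)}")
    series = []
    for group, sub in df.groupby("group", sort=False):
        sub = sub.sort_values("time_days")
        series.append(
            ObservedSeries(
                group=str(group),
                times=sub["time_days"].to_numpy(float),
                y=sub["mean_fold"].to_numpy(float),
                sem=sub["sem"].to_numpy(float) if "sem" in sub else None,
                n=int(sub["n"].iloc[0]) if "n" in sub else None,
            )
        )
    return series


def write_observed_csv(series: Sequence[ObservedSeries], path: str | Path) -> None:
    frames = []
    for s in series:
        frames.append(
            pd.DataFrame(
                {
                    "group": s.group,
                    "time_days": s.times,
                    "mean_fold": s.y,
                    "sem": s.sem if s.sem is not None else np.nan,
                    "n": s.n if s.n is not None else pd.NA,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_trajectories_csv(sims: Iterable[SimOutput], path: str | Path) -> None:
    pd.concat([s.to_frame() for s in sims], ignore_index=True).to_csv(
        path, index=False
    )


def write_concentrations_csv(
    times: np.ndarray,
    conc_cyto: np.ndarray,
    conc_anti: np.ndarray,
    path: str | Path,
) -> None:
    pd.DataFrame(
        {
            "time_days": times,
            "conc_cytotoxic": conc_cyto,
            "conc_antiangiogenic": conc_anti,
        }
    ).to_csv(path, index=False)


def read_incidence_csv(path: str | Path) -> list[IncidenceData]:
    """Read per-animal onsets: group,site,animal_id,onset_day,study_end_day.

    An empty ``onset_day`` marks a censored animal.
    """
    df = pd.read_csv(path)
    required = {"group", "site", "animal_id", "onset_day", "study_end_day"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s): {sorted(missing)}")
    out = []
    for (group, site), sub in df.groupby(["group", "site"], sort=False):
        durations = sub["study_end_day"].unique()
        if len(durations) != 1:
            raise ValueError(
                f"{path}: group {group!r} site {site!r} mixes study_end_day values"
            )
        out.append(
            IncidenceData(
                group=str(group),
                site=str(site),
                onset_times=sub["onset_day"].to_numpy(float),
                duration=float(durations[0]),
            )
        )
    return out


def write_incidence_csv(datasets: Sequence[IncidenceData], path: str | Path) -> None:
    frames = []
    for data in datasets:
        frames.append(
            pd.DataFrame(
                {
                    "group": data.group,
                    "site": data.site,
                    "animal_id": np.arange(1, data.n_animals + 1),
                    "onset_day": data.onset_times,
                    "study_end_day": data.duration,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_fit_report(result: FitResult, path: str | Path) -> None:
    """Machine-readable fit summary (JSON)."""
    payload = {
        "theta_hat": result.theta_hat,
        "standard_errors": result.se,
        "J_min": result.J_min,
        "converged": result.converged,
        "n_obs": result.n_obs,
        "n_params": result.n_params,
        "n_fev": result.n_fev,
        "message": result.message,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
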