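"""CSV and config-file dialects.

Time courses: columns ``time_s, fraction_extended[, sigma]``.
Titrations: columns ``enzyme_nM, anisotropy, rel_intensity``.
Gel lanes: long format with columns ``time_s, length_nt, intensity`` (or one
file per time point with ``length_nt, intensity``).
Configs are YAML key-value files with nested sections.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .binding import TitrationCurve
from .burst_fit import BurstFitResult, TimeCourse
from .mechanism import ParameterError, SpeciesState, SPECIES
from .product_distribution import LaneProfile

__all__ = [
    "read_timecourse", "write_timecourse",
    "read_titration", "write_titration",
    "read_lanes", "write_lanes",
    "write_trajectory", "fit_report_frame",
    "load_config", "dump_config",
]


def read_timecourse(path: str | Path, condition: str = "") -> TimeCourse:
    df = pd.read_csv(path)
    for col in ("time_s", "fraction_extended"):
        if col not in df.columns:
            raise ParameterError(f"{path}: missing column {col!r}")
    sigma = df["sigma"].to_numpy() if "sigma" in df.columns else None
    return TimeCourse(df["time_s"].to_numpy(), df["fraction_extended"].to_numpy(),
                      condition=condition, sigma=sigma)


def write_timecourse(tc: TimeCourse, path: str | Path) -> None:
    cols = {"time_s": tc.times, "fraction_extended": tc.extension_fraction}
    if tc.sigma is not None:
        cols["sigma"] = tc.sigma
    pd.DataFrame(cols).to_csv(path, index=False)


def read_titration(path: str | Path, dna_total: float) -> TitrationCurve:
    df = pd.read_csv(path)
    for col in ("enzyme_nM", "anisotropy", "rel_intensity"):
        if col not in df.columns:
            raise ParameterError(f"{path}: missing column {col!r}")
    return TitrationCurve(df["enzyme_nM"].to_numpy(), dna_total,
                          df["anisotropy"].to_numpy(), df["rel_intensity"].to_numpy())


def write_titration(curve: TitrationCurve, path: str | Path) -> None:
    pd.DataFrame({
        "enzyme_nM": curve.enzyme_total,
        "anisotropy": curve.anisotropy,
        "rel_intensity": curve.relative_intensity,
    }).to_csv(path, index=False)


def read_lanes(path: str | Path) -> list[LaneProfile]:
    """Read a long-format lane table (time_s, length_nt, intensity)."""
    df = pd.read_csv(path)
    for col in ("time_s", "length_nt", "intensity"):
        if col not in df.columns:
            raise ParameterError(f"{path}: missing column {col!r}")
    lanes = []
    for t, grp in df.groupby("time_s", sort=True):
        grp = grp.sort_values("length_nt")
        if not np.array_equal(grp["length_nt"].to_numpy(),
                              np.arange(len(grp))):
            raise ParameterError(f"{path}: lane at t={t} not contiguous from length 0")
        lanes.append(LaneProfile(grp["intensity"].to_numpy(), time=float(t)))
    return lanes


def write_lanes(lanes: list[LaneProfile], path: str | Path) -> None:
    rows = [
        {"time_s": ln.time, "length_nt": int(l), "intensity": v}
        for ln in lanes
        for l, v in zip(ln.lengths, ln.band_intensity)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_trajectory(states: list[SpeciesState], path: str | Path) -> None:
    """Scheme trajectory as CSV: time_s then one column per species."""
    df = pd.DataFrame([{ "time_s": s.time, **{sp: getattr(s, sp) for sp in SPECIES}}
                       for s in states])
    df.to_csv(path, index=False)


def fit_report_frame(result: BurstFitResult) -> pd.DataFrame:
    """Machine-readable one-row fit report."""
    row = {
        "A": result.A, "k_fast": result.k_fast, "k_slow": result.k_slow,
        "n_phases": result.n_phases, "k_fast_fixed": result.k_fast_fixed,
        "rss": result.rss, "k_slow_at_bound": result.k_slow_at_bound,
        "multiphase_unresolved": result.multiphase_unresolved,
    }
    for name, se in result.stderr.items():
        row[f"se_{name}"] = se
    return pd.DataFrame([row])


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ParameterError(f"{path}: config must be a mapping")
    return cfg


def dump_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
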