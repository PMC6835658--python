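"""CSV/YAML interchange for formulations, profiles and tablet properties.

All files are UTF-8 CSV with a header row and '.' as the decimal mark.
Missing numeric values (e.g. hardness of a tablet too elastic to break) are
empty cells on disk and ``None`` in memory — never zero.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from .data import (
    DesignBounds,
    DissolutionProfile,
    Formulation,
    PrintParameters,
    TabletProperties,
)

__all__ = [
    "SchemaError",
    "load_formulation_table",
    "write_formulation_table",
    "load_profiles",
    "write_profiles",
    "load_properties",
    "write_properties",
    "write_print_parameters",
    "load_design_config",
    "write_design_config",
]

FORMULATION_COLUMNS = ("id", "pegda", "peg400", "water", "riboflavin", "ibuprofen")
PROFILE_COLUMNS = ("id", "time_h", "released_pct", "sd_pct")
PROPERTY_COLUMNS = (
    "id", "weight_mg", "diameter_mm", "thickness_mm", "hardness_n", "drug_load_mg"
)


class SchemaError(ValueError):
    """A required column is missing or unresolvable."""


def _read_csv(path: str | Path, required: Sequence[str],
              dialect: Optional[Mapping[str, str]] = None) -> pd.DataFrame:
    frame = pd.read_csv(path)
    if dialect:
        frame = frame.rename(columns={v: k for k, v in dialect.items()})
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {missing}; found {list(frame.columns)}"
        )
    return frame


def load_formulation_table(
    path: str | Path, dialect: Optional[Mapping[str, str]] = None
) -> list[Formulation]:
    """Read formulations.csv, optionally mapping canonical names to file columns.

    ``dialect`` maps canonical column names (``pegda`` ...) to the names used
    in the file.  Row order is preserved; every row is validated on load.
    """
    frame = _read_csv(path, FORMULATION_COLUMNS, dialect)
    return [
        Formulation(
            id=str(row["id"]),
            pegda=float(row["pegda"]),
            peg400=float(row["peg400"]),
            water=float(row["water"]),
            riboflavin=float(row["riboflavin"]),
            ibuprofen=float(row["ibuprofen"]),
        )
        for _, row in frame.iterrows()
    ]


def write_formulation_table(path: str | Path, formulations: Sequence[Formulation]) -> None:
    frame = pd.DataFrame(
        [
            {
                "id": f.id,
                "pegda": round(f.pegda, 2),
                "peg400": round(f.peg400, 2),
                "water": round(f.water, 2),
                "riboflavin": round(f.riboflavin, 2),
                "ibuprofen": round(f.ibuprofen, 2),
            }
            for f in formulations
        ],
        columns=list(FORMULATION_COLUMNS),
    )
    frame.to_csv(path, index=False, float_format="%.2f")


def load_profiles(path: str | Path) -> dict[str, DissolutionProfile]:
    """Read profiles.csv (long format: one row per formulation x time point)."""
    frame = _read_csv(path, PROFILE_COLUMNS[:3])
    profiles: dict[str, DissolutionProfile] = {}
    for fid, group in frame.groupby("id", sort=False):
        group = group.sort_values("time_h")
        sd = None
        if "sd_pct" in group.columns and group["sd_pct"].notna().all():
            sd = tuple(group["sd_pct"].astype(float))
        profiles[str(fid)] = DissolutionProfile(
            times=tuple(group["time_h"].astype(float)),
            released=tuple(group["released_pct"].astype(float)),
            sd=sd,
        )
    return profiles


def write_profiles(path: str | Path, profiles: Mapping[str, DissolutionProfile]) -> None:
    rows = []
    for fid, profile in profiles.items():
        for k, (t, q) in enumerate(zip(profile.times, profile.released)):
            rows.append(
                {
                    "id": fid,
                    "time_h": t,
                    "released_pct": q,
                    "sd_pct": profile.sd[k] if profile.sd is not None else None,
                }
            )
    pd.DataFrame(rows, columns=list(PROFILE_COLUMNS)).to_csv(path, index=False)


def _none_if_nan(value: float) -> Optional[float]:
    return None if (value is None or (isinstance(value, float) and math.isnan(value))) else float(value)


def load_properties(path: str | Path) -> dict[str, TabletProperties]:
    frame = _read_csv(path, PROPERTY_COLUMNS[:1])
    out: dict[str, TabletProperties] = {}
    for _, row in frame.iterrows():
        out[str(row["id"])] = TabletProperties(
            weight=float(row["weight_mg"]),
            diameter=float(row["diameter_mm"]),
            thickness=float(row["thickness_mm"]),
            hardness=_none_if_nan(row.get("hardness_n")),
            drug_load=float(row["drug_load_mg"]),
        )
    return out


def write_properties(path: str | Path, props: Mapping[str, TabletProperties]) -> None:
    frame = pd.DataFrame(
        [
            {
                "id": fid,
                "weight_mg": p.weight,
                "diameter_mm": p.diameter,
                "thickness_mm": p.thickness,
                "hardness_n": p.hardness,
                "drug_load_mg": p.drug_load,
            }
            for fid, p in props.items()
        ],
        columns=list(PROPERTY_COLUMNS),
    )
    frame.to_csv(path, index=False)


def write_print_parameters(path: str | Path, params: Mapping[str, PrintParameters]) -> None:
    frame = pd.DataFrame(
        [
            {
                "id": fid,
                "exposure_time_s": p.exposure_time,
                "bottom_exposure_s": p.bottom_exposure,
                "layer_thickness_mm": p.layer_thickness,
                "bottom_layers": p.bottom_layers,
            }
            for fid, p in params.items()
        ]
    )
    frame.to_csv(path, index=False)


def load_design_config(path: str | Path) -> dict:
    """Read a YAML design config: component bounds and fixed-component levels."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    bounds = raw.get("bounds", {})
    config = dict(raw)
    config["bounds"] = DesignBounds(
        pegda=tuple(bounds.get("pegda", DesignBounds.pegda)),
        peg400=tuple(bounds.get("peg400", DesignBounds.peg400)),
        water=tuple(bounds.get("water", DesignBounds.water)),
        mixture_total=float(bounds.get("mixture_total", DesignBounds.mixture_total)),
    )
    return config


def write_design_config(path: str | Path, bounds: DesignBounds,
                        fixed: Optional[Mapping[str, float]] = None) -> None:
    payload = {
        "bounds": {
            "pegda": list(bounds.pegda),
            "peg400": list(bounds.peg400),
            "water": list(bounds.water),
            "mixture_total": bounds.mixture_total,
        },
        "fixed": dict(fixed or {"riboflavin": 0.10, "ibuprofen": 5.00}),
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
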