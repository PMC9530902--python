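"""CSV and YAML interfaces for the tidy rate table, raw assay records,
plate-reader exports, and run configuration."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .types import (
    ConfigurationError,
    FluctuationAssay,
    GrowthCurve,
    PlateCounts,
    RATE_TABLE_COLUMNS,
    validate_rate_table,
)


def write_rate_table(table: pd.DataFrame, path: str | Path) -> None:
    validate_rate_table(table)
    table[RATE_TABLE_COLUMNS].to_csv(path, index=False)


def read_rate_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    validate_rate_table(table)
    return table


def write_assays(assays: Sequence[FluctuationAssay], path: str | Path) -> None:
    """Raw fluctuation records: assay_id, culture_index, mutant_count."""
    rows = [
        {"assay_id": a.assay_id, "culture_index": i, "mutant_count": int(c)}
        for a in assays
        for i, c in enumerate(a.mutant_counts)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_assays(
    path: str | Path,
    target_size_bp: int,
    plates: Mapping[str, PlateCounts] | None = None,
) -> list[FluctuationAssay]:
    df = pd.read_csv(path)
    assays = []
    for assay_id, group in df.groupby("assay_id", sort=False):
        counts = group.sort_values("culture_index")["mutant_count"].to_numpy()
        assays.append(
            FluctuationAssay(
                assay_id=str(assay_id),
                mutant_counts=counts,
                target_size_bp=target_size_bp,
                plate_counts=plates.get(str(assay_id)) if plates else None,
            )
        )
    return assays


def write_plates(plates: Mapping[str, PlateCounts], path: str | Path) -> None:
    """CFU plate records: assay_id, plate_index, dilution, colony_count."""
    rows = [
        {
            "assay_id": assay_id,
            "plate_index": i,
            "dilution": d,
            "colony_count": int(c),
        }
        for assay_id, p in plates.items()
        for i, (d, c) in enumerate(zip(p.dilutions, p.colony_counts))
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_plates(path: str | Path) -> dict[str, PlateCounts]:
    df = pd.read_csv(path)
    out = {}
    for assay_id, group in df.groupby("assay_id", sort=False):
        group = group.sort_values("plate_index")
        out[str(assay_id)] = PlateCounts(
            tuple(group["dilution"].astype(float)),
            tuple(group["colony_count"].astype(int)),
        )
    return out


def write_plate_reader(curves: Sequence[GrowthCurve], path: str | Path) -> None:
    """Plate-reader layout: column 1 = time in hours, one column per well."""
    from .synthetic import curves_to_frame

    curves_to_frame(curves).to_csv(path, index=False)


def read_plate_reader(path: str | Path) -> list[GrowthCurve]:
    df = pd.read_csv(path)
    time_col = df.columns[0]
    times = df[time_col].to_numpy(dtype=float)
    return [
        GrowthCurve(str(col), times, df[col].to_numpy(dtype=float))
        for col in df.columns[1:]
    ]


def read_well_map(path: str | Path) -> pd.DataFrame:
    """Sidecar map assigning wells to strain/medium (role 'blank' allowed):
    columns well, strain, medium (strain='blank' marks blank wells)."""
    df = pd.read_csv(path)
    required = {"well", "strain", "medium"}
    if not required.issubset(df.columns):
        raise ConfigurationError(f"well map needs columns {sorted(required)}")
    return df


def save_config(config: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(config), fh, sort_keys=True)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigurationError("config file must be a mapping")
    return data
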