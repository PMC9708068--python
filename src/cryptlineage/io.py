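"""Readers and writers for the package's plain-text table dialects.

Track table (CSV): one row per cell per frame with columns
``cell_id,parent_id,frame,t_hr,x_um,y_um,z_um,is_paneth,died``.
``parent_id`` is empty for root cells.  Identifiers are treated as opaque
strings and round-trip bit-exactly.

Axis annotation (CSV): ``frame,point_index,x_um,y_um,z_um`` — manually
placed crypt-axis control points, 3-6 per annotated frame.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

TRACK_COLUMNS = ["cell_id", "parent_id", "frame", "t_hr", "x_um", "y_um", "z_um", "is_paneth", "died"]
AXIS_COLUMNS = ["frame", "point_index", "x_um", "y_um", "z_um"]


def read_track_table(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={"cell_id": str, "parent_id": str, "frame": int, "is_paneth": int, "died": int},
        keep_default_na=False,
    )
    missing = set(TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"track table missing columns: {sorted(missing)}")
    return df[TRACK_COLUMNS]


def write_track_table(df: pd.DataFrame, path) -> None:
    out = df[TRACK_COLUMNS].copy()
    out["parent_id"] = out["parent_id"].fillna("")
    out.to_csv(path, index=False)


def read_axis_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"frame": int, "point_index": int})
    missing = set(AXIS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"axis annotation missing columns: {sorted(missing)}")
    return df[AXIS_COLUMNS]


def write_axis_annotation(df: pd.DataFrame, path) -> None:
    df[AXIS_COLUMNS].to_csv(path, index=False)


def write_pair_stats(counts, path, include_death: bool = False) -> None:
    """Division-pattern counts as TSV: one row per category with count and
    fraction under the chosen normalization (with or without death pairs)."""
    rows = counts.as_rows(include_death=include_death)
    pd.DataFrame(rows, columns=["category", "count", "fraction"]).to_csv(path, sep="\t", index=False)


def write_clone_distribution(dist, path) -> None:
    df = pd.DataFrame(
        {
            "size": dist.sizes,
            "fraction": dist.fractions,
            "bootstrap_sd": dist.bootstrap_sd,
            "n_clones": dist.n_clones,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_summary_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def write_event_series(series, path) -> None:
    """Simulation event series as TSV: t_hr, N_niche, N_diff, N_total."""
    df = pd.DataFrame(series, columns=["t_hr", "N_niche", "N_diff"])
    df["N_total"] = df["N_niche"] + df["N_diff"]
    df.to_csv(path, sep="\t", index=False)
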