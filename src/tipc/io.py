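"""Cell-table reading, output writing and run configuration."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__

REQUIRED_COLUMNS = ("sample_id", "x", "y", "cell_type")

#: identity mapping used when the input already carries compartment labels
DEFAULT_MAPPING = {"tumor": "tumor", "stroma": "stroma", "immune": "immune"}


def read_cells(path, mapping: dict | None = None, units: str = "um",
               px_per_um: float = 2.0) -> pd.DataFrame:
    """Read a per-cell CSV into a validated cell table.

    The CSV must have columns ``sample_id, x, y, cell_type`` (plus an
    optional ``roi_id``); ``mapping`` translates arbitrary ``cell_type``
    strings onto the three compartments {tumor, stroma, immune}. In
    replacement mode the caller simply maps a second immune phenotype to
    the "stroma" slot — the algorithm is agnostic to what that slot
    means. Coordinates declared in pixels are converted to µm with
    ``px_per_um`` (default 2 px = 1 µm).
    """
    mapping = dict(DEFAULT_MAPPING if mapping is None else mapping)
    if units not in ("um", "px"):
        raise ValueError(f"units must be 'um' or 'px', got {units!r}")
    df = pd.read_csv(path, comment="#")
    if df.empty:
        raise ValueError(f"{path}: empty cell table")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for col in ("x", "y"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(~np.isfinite(vals.to_numpy()))
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric or missing {col} at data rows "
                f"{[int(i) + 1 for i in bad[:10]]}"
            )
        df[col] = vals.astype(float)
    if units == "px":
        if px_per_um <= 0:
            raise ValueError("px_per_um must be positive")
        df["x"] = df["x"] / px_per_um
        df["y"] = df["y"] / px_per_um
    unmapped = sorted(set(df["cell_type"].astype(str)) - set(mapping))
    if unmapped:
        raise ValueError(
            f"{path}: cell_type values {unmapped} missing from the phenotype mapping; "
            f"add them to the 'phenotypes' section of the config"
        )
    df["compartment"] = df["cell_type"].astype(str).map(mapping)
    bad_targets = sorted(set(df["compartment"]) - {"tumor", "stroma", "immune"})
    if bad_targets:
        raise ValueError(
            f"{path}: phenotype mapping targets {bad_targets} are not in "
            "{'tumor', 'stroma', 'immune'}"
        )
    keep = ["sample_id"] + (["roi_id"] if "roi_id" in df.columns else []) + \
        ["x", "y", "compartment"]
    out = df[keep].copy()
    out["sample_id"] = out["sample_id"].astype(str)
    return out


def write_cells(cells: pd.DataFrame, path) -> None:
    """Write a cell table back to CSV (µm coordinates, compartment as cell_type)."""
    df = cells.rename(columns={"compartment": "cell_type"})
    df.to_csv(path, index=False, float_format="%.10g")


@dataclass
class RunConfig:
    """Resolved configuration of a full pipeline run."""

    cells: str | None = None                 # input CSV; None -> synthetic cohort
    out_dir: str = "tipc_out"
    phenotypes: dict = field(default_factory=lambda: dict(DEFAULT_MAPPING))
    replacement_mode: bool = False           # documentation flag: "stroma" slot holds a
                                             # second immune phenotype
    units: str = "um"
    px_per_um: float = 2.0
    sizes: tuple = (30.0, 35.0, 40.0, 45.0)
    side_len: float | None = None            # fixed subregion size; None -> optimal_hex_len
    use_shifts: bool = True
    tie: str = "low"
    mixed: str = "dual"
    immune_only: str = "both_high"
    k_range: tuple = (2, 3, 4, 5, 6)
    k: int | None = None                     # fixed cluster number; None -> optimal_k
    reps: int = 50
    frac: float = 0.8
    seed: int = 0
    tau: float = 0.025
    eta: float = 0.9
    min_abs: int = 30
    min_frac: float = 0.03
    mh_grid_size: float = 5.0
    r_max: float = 20.0
    n_synthetic_samples: int = 20            # used only when cells is None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("sizes", "k_range"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        if not self.sizes:
            raise ValueError("config: empty size sweep")
        if any(s <= 0 for s in self.sizes):
            raise ValueError("config: subregion sizes must be positive")
        if not 0 < self.frac <= 1:
            raise ValueError("config: frac must be in (0, 1]")
        if min(self.k_range) < 2:
            raise ValueError("config: k_range must start at 2 or above")
        if self.units not in ("um", "px"):
            raise ValueError("config: units must be 'um' or 'px'")

    def to_canonical_json(self) -> str:
        d = asdict(self)
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
        return json.dumps(d, sort_keys=True)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_canonical_json().encode()).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, config: RunConfig | None = None,
                index: bool = False) -> None:
    """Write a CSV with a provenance header comment (tool version + config hash)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tag = f"# tipc {__version__}"
    if config is not None:
        tag += f" config={config.config_hash}"
    with open(path, "w") as fh:
        fh.write(tag + "\n")
        df.to_csv(fh, index=index, float_format="%.10g")


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kwargs)
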