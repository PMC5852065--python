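"""Readers, writers, and run configuration.

Sample data travels as plain TSV with a fixed six-column header
(``time  replica  lambda  temperature_K  U0_kcal_mol  u_kcal_mol``) plus a
JSON metadata sidecar (``<name>.meta.json``) carrying the state grid, the
seed, and the model description -- enough to reproduce the file bit-for-bit
from the same code version.  Results and reports are JSON.  Run
configuration is TOML, echoed back as resolved JSON for provenance.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .alchemical import (
    DEFAULT_UMAX,
    DEFAULT_LAMBDAS,
    BindingSite,
    InvalidInputError,
    StateGrid,
    default_temperature_ladder,
)
from .sampler import SAMPLE_COLUMNS, SampleSet
from . import toys

__all__ = [
    "SampleSetFormatError",
    "read_sampleset",
    "write_sampleset",
    "RunConfig",
]


class SampleSetFormatError(InvalidInputError):
    """Malformed sample table (message names the defect and the line)."""


def write_sampleset(samples: SampleSet, path) -> Path:
    """Write the sample TSV and its metadata sidecar; returns the TSV path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    samples.data.to_csv(path, sep="\t", index=False, float_format="%.10g")
    meta = dict(samples.meta)
    meta["grid"] = samples.grid.to_dict()
    with open(path.with_suffix(path.suffix + ".meta.json"), "w") as fh:
        json.dump(meta, fh, indent=1)
    return path


def read_sampleset(path, grid: Optional[StateGrid] = None) -> SampleSet:
    """Read and validate a sample TSV.

    The grid comes from (in order) the ``grid`` argument, the metadata
    sidecar, or the distinct (lambda, T) values in the file itself.  Rows
    with states outside the declared grid, non-numeric fields, or
    non-monotone per-replica times are rejected with the offending line
    numbers (1-based, header = line 1).
    """
    path = Path(path)
    if not path.exists():
        raise SampleSetFormatError(f"no such file: {path}")
    if path.stat().st_size == 0:
        raise SampleSetFormatError(f"empty input file: {path}")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise SampleSetFormatError(f"empty input file: {path}") from None
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise SampleSetFormatError(
            f"{path}: missing required columns {missing}; header must be "
            f"{list(SAMPLE_COLUMNS)}"
        )
    num = df[list(SAMPLE_COLUMNS)].apply(pd.to_numeric, errors="coerce")
    bad = num.isna().any(axis=1)
    if bad.any():
        lines = (np.nonzero(bad.to_numpy())[0] + 2)[:5]
        raise SampleSetFormatError(
            f"{path}: malformed (non-numeric) rows at lines {lines.tolist()}"
        )
    if len(num) == 0:
        raise SampleSetFormatError(f"{path}: no data rows")
    num["replica"] = num["replica"].astype(int)

    meta: dict = {}
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if grid is None and sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
        if "grid" in meta:
            grid = StateGrid.from_dict(meta["grid"])
    if grid is None:
        lams = sorted(num["lambda"].unique())
        temps = sorted(num["temperature_K"].unique())
        grid = StateGrid(lams, temps)

    ss = SampleSet(num, grid, meta)
    # grid membership with line numbers
    lams = np.asarray(grid.lambdas)
    temps = np.asarray(grid.temperatures)
    in_lam = np.min(
        np.abs(num["lambda"].to_numpy()[:, None] - lams[None, :]), axis=1
    ) <= 1e-9
    in_temp = np.min(
        np.abs(num["temperature_K"].to_numpy()[:, None] - temps[None, :]), axis=1
    ) <= 1e-9
    bad = ~(in_lam & in_temp)
    if bad.any():
        lines = (np.nonzero(bad)[0] + 2)[:5]
        raise SampleSetFormatError(
            f"{path}: rows with (lambda, T) not in the declared grid at "
            f"lines {lines.tolist()}"
        )
    for rep, sub in num.groupby("replica"):
        t = sub["time"].to_numpy()
        if np.any(np.diff(t) <= 0):
            first = int(sub.index[np.argmax(np.diff(t) <= 0) + 1]) + 2
            raise SampleSetFormatError(
                f"{path}: time not strictly increasing for replica {rep} "
                f"(line {first})"
            )
    return ss


# ---------------------------------------------------------------------------
# Run configuration


_MODEL_BUILDERS = {
    "harmonic_well": toys.harmonic_well,
    "gaussian_well": toys.gaussian_well,
    "square_well": toys.square_well,
    "bimodal_well": toys.bimodal_well,
}


@dataclass
class RunConfig:
    """Resolved run configuration.

    TOML layout (all sections optional, shown with defaults)::

        [grid]
        lambdas = [0.0, ..., 1.0]        # default: the 26-step schedule
        temperatures = [300.0, ...]      # default: 8 geometric, 300-379 K

        [model]
        kind = "harmonic_well"           # harmonic/gaussian/square/bimodal
        depth = -60.0
        spring = 2.0                     # kind-specific parameters

        [site]
        radius = 6.0
        force_constant = 3.0

        [sampler]
        n_sweeps = 20000
        swap_period = 2
        sample_period = 10
        step_size = 1.0
        moves_per_sweep = 1
        seed = 1

        [estimate]
        u_max = 1000.0
        tol = 1e-10

        [diagnostics]
        n_candidates = 50
        overlap_threshold = 0.03
    """

    lambdas: list = field(default_factory=lambda: list(DEFAULT_LAMBDAS))
    temperatures: list = field(
        default_factory=lambda: list(default_temperature_ladder())
    )
    model: dict = field(
        default_factory=lambda: {"kind": "harmonic_well", "depth": -60.0,
                                 "spring": 2.0}
    )
    site: dict = field(
        default_factory=lambda: {"radius": 6.0, "force_constant": 3.0}
    )
    sampler: dict = field(
        default_factory=lambda: {
            "n_sweeps": 20000, "swap_period": 2, "sample_period": 10,
            "step_size": 1.0, "moves_per_sweep": 1, "seed": 1,
        }
    )
    estimate: dict = field(
        default_factory=lambda: {"u_max": DEFAULT_UMAX, "tol": 1e-10}
    )
    diagnostics: dict = field(
        default_factory=lambda: {"n_candidates": 50, "overlap_threshold": 0.03}
    )

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        cfg = cls()
        grid = raw.get("grid", {})
        if "lambdas" in grid:
            cfg.lambdas = [float(x) for x in grid["lambdas"]]
        if "temperatures" in grid:
            cfg.temperatures = [float(x) for x in grid["temperatures"]]
        for sec in ("model", "site", "sampler", "estimate", "diagnostics"):
            getattr(cfg, sec).update(raw.get(sec, {}))
        cfg.build_grid()  # validate eagerly
        cfg.build_model()
        return cfg

    def build_grid(self) -> StateGrid:
        return StateGrid(self.lambdas, self.temperatures)

    def build_site(self) -> BindingSite:
        return BindingSite(
            radius=float(self.site.get("radius", 6.0)),
            force_constant=float(self.site.get("force_constant", 3.0)),
        )

    def build_model(self) -> toys.ToyComplexModel:
        spec = dict(self.model)
        kind = spec.pop("kind", "harmonic_well")
        if kind not in _MODEL_BUILDERS:
            raise InvalidInputError(f"unknown model kind {kind!r}")
        return _MODEL_BUILDERS[kind](site=self.build_site(), **spec)

    def to_dict(self) -> dict:
        return {
            "grid": {"lambdas": self.lambdas, "temperatures": self.temperatures},
            "model": self.model,
            "site": self.site,
            "sampler": self.sampler,
            "estimate": self.estimate,
            "diagnostics": self.diagnostics,
        }

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    def echo_json(self, path) -> None:
        """Write the resolved configuration (with its hash) for provenance."""
        d = self.to_dict()
        d["config_hash"] = self.config_hash()
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)
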