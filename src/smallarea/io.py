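"""Reading and writing the artifacts of a small-area analysis.

The canonical input is a per-area CSV (one row per census block group:
observed event count, women at risk, covariates) plus a GAL neighbor file;
the canonical outputs are a risk-surface CSV (and optional GeoJSON) and a
posterior-draw CSV.  All CSVs are comma-separated UTF-8 with '.' decimals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AreaTable",
    "RunConfig",
    "read_area_table",
    "write_area_table",
    "write_risk_surface",
    "read_run_config",
]

#: columns every area table must carry, in canonical order
REQUIRED_COLUMNS = ("area_id", "observed", "population")

#: fixed risk-surface column order (stable across runs)
SURFACE_COLUMNS = ("area_id", "risk_mean", "risk_lo", "risk_hi",
                   "exceedance", "spatial_mean")


@dataclass
class AreaTable:
    """Per-area data: counts O_i, population at risk, covariates X_i, E_i.

    ``area_id`` values are opaque strings (census codes survive untouched);
    all internal indexing is 0-based file order.  ``expected`` is optional
    on input and is filled by internal standardization in the pipeline.
    """

    area_id: list[str]
    observed: np.ndarray
    population: np.ndarray
    covariates: pd.DataFrame
    expected: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.area_id = [str(a) for a in self.area_id]
        self.observed = np.asarray(self.observed)
        self.population = np.asarray(self.population)
        n = len(self.area_id)
        if len(set(self.area_id)) != n:
            dup = sorted({a for a in self.area_id if self.area_id.count(a) > 1})
            raise ValueError(f"duplicate area_id values: {dup}")
        if self.observed.shape != (n,) or self.population.shape != (n,):
            raise ValueError("observed/population length does not match area_id")
        if np.any(self.observed != np.floor(self.observed)) or np.any(self.observed < 0):
            bad = int(np.flatnonzero((self.observed < 0) |
                                     (self.observed != np.floor(self.observed)))[0])
            raise ValueError(f"observed must be a nonnegative integer count (row {bad})")
        self.observed = self.observed.astype(np.int64)
        if np.any(self.population <= 0):
            bad = int(np.flatnonzero(self.population <= 0)[0])
            raise ValueError(f"population must be positive (row {bad})")
        self.covariates = pd.DataFrame(self.covariates).reset_index(drop=True)
        if len(self.covariates) != n:
            raise ValueError("covariate rows do not match area count")
        if self.covariates.isna().any().any():
            col = self.covariates.columns[self.covariates.isna().any()][0]
            raise ValueError(f"covariate column {col!r} has missing cells")
        if self.expected is not None:
            self.expected = np.asarray(self.expected, dtype=float)
            if self.expected.shape != (n,) or np.any(self.expected <= 0):
                raise ValueError("expected counts must be positive, one per area")
            tot_o, tot_e = self.observed.sum(), self.expected.sum()
            if tot_o > 0 and abs(tot_e - tot_o) > 1e-9 * tot_o:
                raise ValueError("expected counts must sum to the observed total "
                                 "(internal standardization)")

    @property
    def n_areas(self) -> int:
        return len(self.area_id)

    @property
    def covariate_names(self) -> list[str]:
        return list(self.covariates.columns)

    def covariate_matrix(self, names: list[str] | None = None,
                         scaling: dict[str, float] | None = None) -> np.ndarray:
        """Design matrix for the requested covariates, optionally rescaled.

        ``scaling`` maps a covariate name to a multiplicative factor applied
        before fitting (e.g. cadastral value in thousands).
        """
        names = self.covariate_names if names is None else list(names)
        missing = [c for c in names if c not in self.covariates.columns]
        if missing:
            raise KeyError(f"unknown covariates: {missing}")
        X = self.covariates[names].to_numpy(dtype=float).copy()
        if scaling:
            for k, f in scaling.items():
                if k in names:
                    X[:, names.index(k)] *= f
        return X

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"area_id": self.area_id,
                           "observed": self.observed,
                           "population": self.population})
        df = pd.concat([df, self.covariates.reset_index(drop=True)], axis=1)
        if self.expected is not None:
            df["expected"] = self.expected
        return df


def read_area_table(path) -> AreaTable:
    """Read and validate a per-area CSV; row order is preserved."""
    df = pd.read_csv(path, dtype={"area_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    cov_cols = [c for c in df.columns if c not in REQUIRED_COLUMNS + ("expected",)]
    return AreaTable(
        area_id=df["area_id"].tolist(),
        observed=df["observed"].to_numpy(),
        population=df["population"].to_numpy(),
        covariates=df[cov_cols],
        expected=df["expected"].to_numpy() if "expected" in df.columns else None,
    )


def write_area_table(table: AreaTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


def write_risk_surface(surface, path, geometry: list | None = None) -> None:
    """Write a risk surface as CSV, and as GeoJSON when polygons are given.

    The CSV columns are fixed: area_id, posterior mean relative risk, 2.5%
    and 97.5% quantiles, exceedance probability P(lambda_i > 1), posterior
    mean of the spatial component.  ``geometry`` is an optional list of
    GeoJSON-style geometry dicts (or objects with ``__geo_interface__``),
    one per area, in area order.
    """
    df = pd.DataFrame({
        "area_id": surface.area_id,
        "risk_mean": surface.risk_mean,
        "risk_lo": surface.risk_lo,
        "risk_hi": surface.risk_hi,
        "exceedance": surface.exceedance,
        "spatial_mean": surface.spatial_mean,
    }, columns=list(SURFACE_COLUMNS))
    df.to_csv(path, index=False)
    if geometry is not None:
        if len(geometry) != len(surface.area_id):
            raise ValueError(f"geometry count {len(geometry)} does not match "
                             f"{len(surface.area_id)} areas")
        feats = []
        for rec, geom in zip(df.to_dict("records"), geometry):
            geom = getattr(geom, "__geo_interface__", geom)
            feats.append({"type": "Feature", "geometry": geom, "properties": rec})
        gj = {"type": "FeatureCollection", "features": feats}
        with open(str(path) + ".geojson", "wt", encoding="utf-8") as fh:
            json.dump(gj, fh)


@dataclass
class RunConfig:
    """Run-level configuration mirroring the YAML consumed by the CLI."""

    seed: int
    covariates: list[str] = field(default_factory=list)
    model: str = "m3"
    prior_beta_variance: float = 1e5
    sigma_upper: float = 1.0
    n_iter: int = 100_000
    burn_in: int = 10_000
    n_chains: int = 2
    thin: int = 10
    relevance_threshold: float = 0.90
    covariate_scaling: dict[str, float] = field(default_factory=dict)
    extras: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed must be set explicitly as an integer")


def read_run_config(path) -> RunConfig:
    with open(path, "rt", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__ if f != "extras"}
    kwargs = {k: v for k, v in raw.items() if k in known}
    extras = {k: v for k, v in raw.items() if k not in known}
    if "seed" not in kwargs:
        raise ValueError(f"{path}: config must set an explicit seed")
    return RunConfig(extras=extras, **kwargs)
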