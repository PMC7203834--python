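"""Readers, writers, date imputation, GeoJSON map export and run manifests.

File dialects
-------------
* cases CSV: one row per case; see :data:`CASE_COLUMNS` for the column
  dictionary.  Readers validate category vocabularies and collect malformed
  rows into a rejects report instead of silently dropping or coercing them;
  the one sanctioned coercion is PSA top/bottom-coding to [0.1, 98.0]
  (registry documentation convention), which warns.
* adjacency: two-column tab/space-separated edge list of county ids
  (``#`` comments allowed).
* county attributes CSV: fips, appalachia (0/1), rucc (1-9), catchment (0/1).
* standard population CSV: band_start, band_end, weight.
* county covariates CSV: wide, fips-keyed; metadata CSV: factor,
  log_transform, domain.
* maps: GeoJSON FeatureCollection with per-county value + quantile class.
"""

from __future__ import annotations

import datetime as _dt
import json
import warnings
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .graphs import CountyGraph

__all__ = [
    "CASE_COLUMNS",
    "read_cases",
    "write_cases",
    "read_graph",
    "write_graph",
    "read_standard_population",
    "read_county_covariates",
    "read_covariate_metadata",
    "impute_partial_date",
    "synthetic_geometry",
    "export_county_geojson",
    "write_manifest",
    "load_config",
]

_VOCAB = {
    "race": {"white", "black", "asian", "other_unknown"},
    "ethnicity": {"hispanic", "non_hispanic", "unknown"},
    "insurance": {"insured", "uninsured", "unknown"},
    "stage_path": {"T1", "T2", "T3", "T4", "unknown"},
    "stage_clin": {"T1", "T2", "T3", "T4", "unknown"},
    "metastasis": {"yes", "no", "unknown"},
    "ln_positive": {"yes", "no", "unknown"},
    "treatment": {"radiation_only", "surgery_only", "both", "neither", "unknown"},
    "event": {"pc_death", "other_death", "censored"},
}

CASE_COLUMNS: dict[str, str] = {
    "case_id": "unique case identifier",
    "age_at_dx": "age at diagnosis, years (integer)",
    "race": "white | black | asian | other_unknown",
    "ethnicity": "hispanic | non_hispanic | unknown",
    "insurance": "insured | uninsured | unknown",
    "psa": "serum PSA ng/mL, top-coded 98.0 / bottom-coded 0.1; may be empty",
    "gleason_path_primary": "pathology Gleason primary pattern (2-5) or empty",
    "gleason_path_secondary": "pathology Gleason secondary pattern (2-5) or empty",
    "gleason_clin_primary": "clinical Gleason primary pattern (2-5) or empty",
    "gleason_clin_secondary": "clinical Gleason secondary pattern (2-5) or empty",
    "stage_path": "pathology tumor stage T1-T4 | unknown",
    "stage_clin": "clinical tumor stage T1-T4 | unknown",
    "metastasis": "distant metastasis yes | no | unknown",
    "ln_positive": "positive lymph nodes yes | no | unknown",
    "treatment": "radiation_only | surgery_only | both | neither | unknown",
    "county_fips": "county id (zero-padded FIPS-style string)",
    "followup_months": "follow-up from diagnosis, months (>= 0)",
    "event": "pc_death | other_death | censored",
}

_MANDATORY = [c for c in CASE_COLUMNS if c != "psa"]


class SchemaError(ValueError):
    """Input file does not match the documented schema."""


def read_cases(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a registry cases CSV.

    Returns ``(cases, rejects)``; rejects carries the offending row index,
    column and value for every malformed entry.  Missing mandatory columns
    raise :class:`SchemaError` listing them.
    """
    df = pd.read_csv(path, dtype={"county_fips": str, "case_id": str})
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {missing}")
    bad_rows: list[dict] = []

    def flag(mask, col):
        for i in df.index[mask]:
            bad_rows.append({"row": int(i), "column": col, "value": df.loc[i, col]})

    for col, vocab in _VOCAB.items():
        mask = ~df[col].isin(vocab)
        flag(mask, col)
    age = pd.to_numeric(df["age_at_dx"], errors="coerce")
    flag(age.isna(), "age_at_dx")
    fu = pd.to_numeric(df["followup_months"], errors="coerce")
    flag(fu.isna() | (fu < 0), "followup_months")
    for col in ("gleason_path_primary", "gleason_path_secondary",
                "gleason_clin_primary", "gleason_clin_secondary"):
        v = pd.to_numeric(df[col], errors="coerce")
        flag(v.notna() & ~v.isin([2, 3, 4, 5]), col)

    if "psa" in df.columns:
        psa = pd.to_numeric(df["psa"], errors="coerce")
        out_of_range = psa.notna() & ((psa < 0.1) | (psa > 98.0))
        if out_of_range.any():
            warnings.warn(
                f"{int(out_of_range.sum())} PSA values outside [0.1, 98.0] "
                "were top/bottom-coded", stacklevel=2)
        df["psa"] = psa.clip(0.1, 98.0)

    rejects = pd.DataFrame(bad_rows, columns=["row", "column", "value"])
    good = df.drop(index=sorted({r["row"] for r in bad_rows}))
    return good.reset_index(drop=True), rejects


def write_cases(df: pd.DataFrame, path) -> None:
    cols = [c for c in CASE_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in cols]
    df[cols + extra].to_csv(path, index=False)


def read_graph(adjacency_path, attrs_path) -> CountyGraph:
    """Build a CountyGraph from an edge-list file and an attributes CSV."""
    attrs = pd.read_csv(attrs_path, comment="#", dtype={"fips": str})
    need = {"fips", "appalachia", "rucc", "catchment"}
    if not need <= set(attrs.columns):
        raise SchemaError(f"attributes CSV needs columns {sorted(need)}")
    g = nx.Graph()
    for row in attrs.itertuples(index=False):
        g.add_node(row.fips, appalachia=bool(row.appalachia),
                   rucc=int(row.rucc), catchment=bool(row.catchment))
    with open(adjacency_path) as f:
        for ln, line in enumerate(f, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise SchemaError(f"adjacency line {ln}: expected two ids")
            a, b = parts
            for c in (a, b):
                if c not in g:
                    raise SchemaError(f"adjacency references unknown county {c!r}")
            g.add_edge(a, b)
    return CountyGraph(g)


def write_graph(graph: CountyGraph, adjacency_path, attrs_path) -> None:
    attrs = graph.attrs().reset_index(names="fips")
    attrs[["appalachia", "catchment"]] = attrs[["appalachia", "catchment"]].astype(int)
    attrs.to_csv(attrs_path, index=False)
    with open(adjacency_path, "w") as f:
        for a, b in sorted(tuple(sorted(e)) for e in graph.graph.edges()):
            f.write(f"{a}\t{b}\n")


def read_standard_population(path):
    from .incidence import StandardPopulation

    df = pd.read_csv(path, comment="#")
    need = {"band_start", "band_end", "weight"}
    if not need <= set(df.columns):
        raise SchemaError(f"standard population CSV needs columns {sorted(need)}")
    return StandardPopulation(df["band_start"], df["band_end"], df["weight"])


def read_county_covariates(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"fips": str})
    if "fips" not in df.columns:
        raise SchemaError("county covariates CSV needs a 'fips' column")
    return df.set_index("fips")


def read_covariate_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"factor", "log_transform", "domain"}
    if not need <= set(df.columns):
        raise SchemaError(f"metadata CSV needs columns {sorted(need)}")
    df["log_transform"] = df["log_transform"].astype(bool)
    return df.set_index("factor")


def impute_partial_date(year, month=None, day=None) -> tuple[_dt.date, bool]:
    """Complete a partial diagnosis date with mid-period conventions.

    Missing month -> July; missing day -> 15th.  Returns (date, imputed
    flag).  A missing year is a hard rejection.
    """
    if year is None or (isinstance(year, float) and np.isnan(year)):
        raise ValueError("year is mandatory; record rejected")
    imputed = False
    if month is None or (isinstance(month, float) and np.isnan(month)):
        month, imputed = 7, True
    if day is None or (isinstance(day, float) and np.isnan(day)):
        day, imputed = 15, True
    return _dt.date(int(year), int(month), int(day)), imputed


def synthetic_geometry(county_ids) -> dict[str, list]:
    """Synthetic unit-square polygons, one per county, laid out row-major on
    a near-square lattice in sorted-id order.

    A deterministic stand-in for real county boundaries so choropleth
    export is testable without shipping geographic data.
    """
    ids = sorted(county_ids)
    ncol = int(np.ceil(np.sqrt(len(ids))))
    geoms = {}
    for k, cid in enumerate(ids):
        r, c = divmod(k, ncol)
        geoms[cid] = [[
            [float(c), float(-r)], [float(c + 1), float(-r)],
            [float(c + 1), float(-r - 1)], [float(c), float(-r - 1)],
            [float(c), float(-r)],
        ]]
    return geoms


def export_county_geojson(
    values, geometry: dict[str, list], n_classes: int = 5
) -> tuple[dict, dict]:
    """Build a GeoJSON FeatureCollection for a county -> value map.

    Each feature carries the value and its quantile class (1..n_classes);
    counties present in the geometry but absent from the value map carry
    null values and a ``missing_value`` flag.  Returns ``(geojson,
    report)`` where the report lists id mismatches in both directions.
    """
    vals = pd.Series(values, dtype=float)
    common = [c for c in geometry if c in vals.index]
    report = {
        "no_geometry": sorted(set(vals.index) - set(geometry)),
        "no_value": sorted(set(geometry) - set(vals.index)),
    }
    if common:
        v = vals.loc[common].to_numpy()
        if np.ptp(v) == 0:
            cls = {c: (n_classes + 1) // 2 for c in common}
        else:
            qs = np.quantile(v, np.linspace(0, 1, n_classes + 1)[1:-1])
            cls = {c: int(np.searchsorted(qs, vals[c], side="left")) + 1 for c in common}
    else:
        cls = {}
    features = []
    for cid in sorted(geometry):
        has = cid in vals.index
        features.append({
            "type": "Feature",
            "geometry": {"type": "Polygon", "coordinates": geometry[cid]},
            "properties": {
                "fips": cid,
                "value": float(vals[cid]) if has else None,
                "quantile_class": cls.get(cid),
                "missing_value": not has,
            },
        })
    return {"type": "FeatureCollection", "features": features}, report


def write_manifest(outdir, step: str, inputs: dict, seed, timings: dict | None = None) -> Path:
    """Write a manifest JSON recording everything needed to re-run a step."""
    import geoaft

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "step": step,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "seed": None if seed is None else int(seed),
        "versions": {
            "geoaft": geoaft.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "timings_s": timings or {},
        "written_utc": _dt.datetime.now(_dt.timezone.utc).isoformat(),
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def load_config(path) -> dict:
    """Load a YAML or JSON run configuration; referenced paths must exist."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise SchemaError("config must be a mapping")
    for key, val in cfg.items():
        if key.endswith(("_path", "_file")) and not Path(val).exists():
            raise SchemaError(f"config path {key} = {val!r} does not exist")
    return cfg
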