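"""Tab-separated table schemas shared across the pipeline.

All tables are UTF-8 TSV with ``NA`` for missing values and full-precision
floats, so a write/read round trip is lossless.  Every file starts with
comment lines recording the seed and a config hash for provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd

SCREEN_COLUMNS = [
    "oligomycin_ug_per_ml", "orf", "gene", "auc", "K", "r", "L", "r_squared",
    "K_ci_lo", "K_ci_hi", "r_ci_lo", "r_ci_hi", "L_ci_lo", "L_ci_hi",
]
INTERACTION_COLUMNS = ["orf", "gene", "orf_effect_K0", "interaction_INT", "n_no_growth"]
TIMESERIES_COLUMNS = ["culture_id", "time_h", "intensity"]


class SchemaError(ValueError):
    """Raised when a table does not match its declared schema."""


def config_hash(config: Any) -> str:
    """Stable short hash of a configuration object."""
    if is_dataclass(config) and not isinstance(config, type):
        payload = asdict(config)
    elif isinstance(config, Mapping):
        payload = dict(config)
    else:
        payload = {"repr": repr(config)}
    text = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def write_table(
    df: pd.DataFrame, path: str | Path, seed: int | None = None, config: Any = None
) -> None:
    """Write a TSV with provenance header comments and NA for missing."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        if config is not None:
            fh.write(f"# config_hash={config_hash(config)}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA", float_format="%.17g")


def read_table(path: str | Path, required_columns: Iterable[str] | None = None) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table`, validating the schema."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        lines = fh.readlines()
    body_start = 0
    while body_start < len(lines) and lines[body_start].startswith("#"):
        body_start += 1
    if body_start == len(lines):
        raise SchemaError(f"{path}: no header row")
    header = lines[body_start].rstrip("\n").split("\t")
    for i, line in enumerate(lines[body_start + 1:], start=body_start + 2):
        if line.strip() and len(line.rstrip("\n").split("\t")) != len(header):
            raise SchemaError(f"{path}: ragged row at line {i}")
    if required_columns is not None:
        missing = [c for c in required_columns if c not in header]
        if missing:
            raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    return pd.read_csv(
        path, sep="\t", comment="#", na_values="NA", keep_default_na=False,
        float_precision="round_trip",
    )


def fits_to_screen_table(fit_records: Iterable[Mapping[str, Any]]) -> pd.DataFrame:
    """Assemble fit results (dicts with dose/orf/gene plus a
    GrowthCurveFit under 'fit') into the screen-sheet layout."""
    rows = []
    for rec in fit_records:
        fit = rec["fit"]
        rows.append(
            {
                "oligomycin_ug_per_ml": rec["dose"],
                "orf": rec["orf"],
                "gene": rec.get("gene", rec["orf"]),
                "auc": fit.auc,
                "K": fit.K,
                "r": fit.r,
                "L": fit.L,
                "r_squared": fit.r_squared,
                "K_ci_lo": fit.ci_lower.get("K", np.nan),
                "K_ci_hi": fit.ci_upper.get("K", np.nan),
                "r_ci_lo": fit.ci_lower.get("r", np.nan),
                "r_ci_hi": fit.ci_upper.get("r", np.nan),
                "L_ci_lo": fit.ci_lower.get("L", np.nan),
                "L_ci_hi": fit.ci_upper.get("L", np.nan),
            }
        )
    return pd.DataFrame(rows, columns=SCREEN_COLUMNS)


def results_to_interaction_table(results: Iterable[Any]) -> pd.DataFrame:
    """Interaction-sheet layout: ORF, gene, ORF effect (K0), interaction
    value (INT), and the number of high doses with no growth."""
    rows = [
        {
            "orf": r.strain_id,
            "gene": r.strain_id,
            "orf_effect_K0": r.K0,
            "interaction_INT": r.INT,
            "n_no_growth": r.tier,
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=INTERACTION_COLUMNS)


def series_to_table(series: Iterable[Any]) -> pd.DataFrame:
    """Long-format time-series table (culture_id, time_h, intensity)."""
    rows = []
    for ts in series:
        for t, y in zip(ts.times, ts.intensities):
            rows.append({"culture_id": ts.culture_id, "time_h": t, "intensity": y})
    return pd.DataFrame(rows, columns=TIMESERIES_COLUMNS)


def table_to_series(df: pd.DataFrame) -> list:
    """Inverse of :func:`series_to_table`."""
    from .growth import TimeSeries

    missing = [c for c in TIMESERIES_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s) {', '.join(missing)}")
    out = []
    for cid, grp in df.groupby("culture_id", sort=False):
        grp = grp.sort_values("time_h")
        out.append(
            TimeSeries(str(cid), grp["time_h"].to_numpy(), grp["intensity"].to_numpy())
        )
    return out


def profiles_to_table(profiles: Iterable[Any], columns: Iterable[str]) -> pd.DataFrame:
    cols = list(columns)
    rows = []
    for p in profiles:
        row: dict[str, Any] = {"gene": p.gene_id}
        for c, v, m in zip(cols, p.values, p.mask):
            row[c] = np.nan if m else v
        rows.append(row)
    return pd.DataFrame(rows, columns=["gene"] + cols)


def table_to_profiles(df: pd.DataFrame, columns: Iterable[str]) -> list:
    from .clustering import make_profile

    cols = list(columns)
    missing = [c for c in ["gene"] + cols if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s) {', '.join(missing)}")
    return [
        make_profile(str(row["gene"]), [row[c] for c in cols], cols)
        for _, row in df.iterrows()
    ]


def read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV (term_id, gene_id) -> term -> gene set."""
    df = read_table(path, required_columns=["term_id", "gene_id"])
    return {
        str(term): set(map(str, grp["gene_id"]))
        for term, grp in df.groupby("term_id", sort=True)
    }
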