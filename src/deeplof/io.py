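"""Readers and writers: gene tables (TSV), BED intervals, feature configs,
checkpoints and run configs.

Native table dialect is TSV with a header row; missing values are encoded as
empty strings or ``NA``.  Genomic intervals follow the BED convention
(0-based, half-open, strand ignored).  Checkpoints are flat JSON mappings of
parameter names to (nested) lists, which keeps every artifact human-readable
and diffable.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .features import FeatureSpec
from .network import PriorNetworkParams, params_from_arrays, params_to_arrays

logger = logging.getLogger("deeplof")

__all__ = [
    "read_gene_table",
    "write_score_table",
    "read_score_table",
    "read_bed",
    "read_feature_config",
    "write_feature_config",
    "save_checkpoint",
    "load_checkpoint",
    "write_run_config",
]

REQUIRED_COLUMNS = ("gene_id", "obs_lof", "exp_lof")
_NA_VALUES = ["", "NA"]


def read_gene_table(path, sep: str = "\t") -> pd.DataFrame:
    """Read a gene-level TSV with columns gene_id, obs_lof, exp_lof, features.

    Observed counts must be nonnegative integers, expected counts positive
    reals, and gene identifiers unique; violations raise with row context.
    """
    df = pd.read_csv(path, sep=sep, na_values=_NA_VALUES, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate gene_id values, e.g. {dup.iloc[0]!r}")
    obs = pd.to_numeric(df["obs_lof"], errors="coerce")
    bad = df.index[obs.isna() | (obs < 0) | (obs != obs.round())]
    if len(bad):
        raise ValueError(
            f"{path}: obs_lof must be a nonnegative integer (row {bad[0] + 2}, "
            f"value {df.loc[bad[0], 'obs_lof']!r})"
        )
    df["obs_lof"] = obs.astype(int)
    exp = pd.to_numeric(df["exp_lof"], errors="coerce")
    bad = df.index[exp.isna() | (exp <= 0)]
    if len(bad):
        raise ValueError(
            f"{path}: exp_lof must be a positive number (row {bad[0] + 2}, "
            f"value {df.loc[bad[0], 'exp_lof']!r})"
        )
    df["exp_lof"] = exp.astype(float)
    feature_cols = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    n_missing = int(df[feature_cols].isna().sum().sum()) if feature_cols else 0
    logger.info(
        "read %d genes (%d feature columns, %d missing feature values) from %s",
        len(df), len(feature_cols), n_missing, path,
    )
    return df


def write_score_table(path, table: pd.DataFrame) -> None:
    """Write gene_id / posterior_mean_eta / deeplof_score, 6 decimals, sorted
    by gene_id for diff stability."""
    cols = ["gene_id", "posterior_mean_eta", "deeplof_score"]
    out = table[cols].sort_values("gene_id")
    if not np.isfinite(out[cols[1:]].to_numpy(dtype=float)).all():
        raise ValueError("refusing to write non-finite scores")
    out.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_score_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"gene_id": str})


def read_bed(path) -> pd.DataFrame:
    """Read BED3+ intervals; extra columns are preserved as annotation.

    Validates 0 <= start < end per line and reports the 1-based line number
    on failure.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected at least 3 BED columns")
            chrom, start_s, end_s = parts[:3]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from err
            if start < 0:
                raise ValueError(f"{path}:{lineno}: negative start coordinate")
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start must be < end ({start} >= {end})")
            row = {"chrom": chrom, "start": start, "end": end}
            if len(parts) > 3:
                row["name"] = parts[3]
            for i, extra in enumerate(parts[4:]):
                row[f"col{i + 5}"] = extra
            rows.append(row)
    return pd.DataFrame(rows)


def read_feature_config(path) -> list[FeatureSpec]:
    """Load feature specs from a YAML/JSON mapping.

    Layout: ``features: [{name, kind, log_transform}, ...]`` or a bare list.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    items = data["features"] if isinstance(data, dict) else data
    return [
        FeatureSpec(
            name=item["name"],
            kind=item["kind"],
            log_transform=bool(item.get("log_transform", False)),
        )
        for item in items
    ]


def write_feature_config(path, specs: list[FeatureSpec]) -> None:
    payload = {
        "features": [
            {"name": s.name, "kind": s.kind, "log_transform": s.log_transform}
            for s in specs
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def save_checkpoint(path, params: PriorNetworkParams, meta: dict | None = None) -> None:
    """Serialize network parameters (plus metadata) to a flat JSON archive."""
    arrays = params_to_arrays(params)
    payload = {
        k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in arrays.items()
    }
    if meta:
        payload["meta"] = meta
    Path(path).write_text(json.dumps(payload, indent=1))


def load_checkpoint(path) -> tuple[PriorNetworkParams, dict]:
    payload = json.loads(Path(path).read_text())
    meta = payload.pop("meta", {})
    return params_from_arrays(payload), meta


def write_run_config(path, config: dict) -> None:
    """Record the exact configuration (and seed) alongside every output."""
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
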