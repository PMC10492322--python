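"""File formats, configuration and provenance headers.

Formats handled: GMT gene-set files, TSV expression matrices (gene ids in
the first column, one header row of sample ids), two-column sample-label
CSVs, the MRM batch CSV schema, and the pipeline's own CSV outputs.  Every
file this package writes starts with a single comment line carrying the tool
version, a hash of the run configuration, and the seed, so outputs are
self-describing and reruns are byte-comparable.  Dialect: UTF-8, "."
decimal, no thousands separators.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .modscore import ExpressionDataset

__all__ = [
    "TOOL_VERSION",
    "read_gmt",
    "write_gmt",
    "read_expression",
    "write_expression",
    "read_labels",
    "write_labels",
    "read_batch",
    "read_table",
    "write_table",
    "config_hash",
    "load_config",
    "write_manifest",
]

TOOL_VERSION = "0.1.0"

log = logging.getLogger("modmet")


# ---------------------------------------------------------------------------
# Provenance header
# ---------------------------------------------------------------------------

def _header_line(seed: int | None, cfg_hash: str) -> str:
    return f"# modmet {TOOL_VERSION} config={cfg_hash} seed={seed}\n"


def config_hash(config: dict) -> str:
    """Short deterministic hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    cfg_hash: str = "none",
    index: bool = True,
) -> Path:
    """Write a CSV with the provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_header_line(seed, cfg_hash))
        df.to_csv(fh, index=index)
    return path


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kwargs)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT file: per line module-id, description, >= 1 gene id.

    Duplicate gene ids within a module are deduplicated with a warning;
    duplicate module ids are an error, as is any line with < 3 fields.
    """
    modules: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: malformed GMT line "
                    f"({len(fields)} field(s), need module-id, description, "
                    "and at least one gene)"
                )
            mod_id, _desc, *genes = fields
            genes = [g for g in genes if g]
            if mod_id in modules:
                raise ValueError(f"{path}:{lineno}: duplicate module id {mod_id!r}")
            unique = list(dict.fromkeys(genes))
            if len(unique) < len(genes):
                warnings.warn(
                    f"{path}:{lineno}: module {mod_id!r} has duplicate gene "
                    "ids; deduplicated",
                    stacklevel=2,
                )
            modules[mod_id] = unique
    return modules


def write_gmt(
    modules: dict[str, list[str]], path: str | Path, description: str = "na"
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for mod_id, genes in modules.items():
            fh.write("\t".join([mod_id, description, *genes]) + "\n")
    return path


# ---------------------------------------------------------------------------
# Expression matrix and labels
# ---------------------------------------------------------------------------

def read_labels(path: str | Path) -> dict[str, str]:
    """Two-column CSV (sample_id, group) -> mapping."""
    df = read_table(path, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: label file needs sample_id and group columns")
    sample_col, group_col = df.columns[:2]
    return dict(zip(df[sample_col], df[group_col]))


def write_labels(labels: dict[str, str], path: str | Path, **hdr) -> Path:
    df = pd.DataFrame(
        {"sample_id": list(labels), "group": list(labels.values())}
    )
    return write_table(df, path, index=False, **hdr)


def read_expression(
    path: str | Path, labels_path: str | Path, log2: bool = True
) -> ExpressionDataset:
    """TSV expression matrix joined with its sample labels.

    First column holds gene ids, the header row the sample ids.  Samples
    without a label are dropped with a warning; duplicate gene ids and
    non-numeric cells are rejected.
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if df.index.duplicated().any():
        dup = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"{path}: duplicate gene id(s): {dup[:5]}")
    for j, col in enumerate(df.columns):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric value at gene {bad[0]!r}, sample {col!r}"
            )
        df[col] = numeric
    labels = read_labels(labels_path)
    unlabeled = [s for s in df.columns if s not in labels]
    if unlabeled:
        warnings.warn(
            f"{len(unlabeled)} sample(s) without labels dropped: "
            f"{unlabeled[:5]}",
            stacklevel=2,
        )
        log.info("dropped %d unlabeled sample column(s)", len(unlabeled))
        df = df.drop(columns=unlabeled)
    return ExpressionDataset(
        gene_ids=list(df.index.astype(str)),
        sample_ids=list(df.columns.astype(str)),
        values=df.to_numpy(dtype=float),
        labels={s: labels[s] for s in df.columns},
        log2=log2,
    )


def write_expression(
    dataset: ExpressionDataset, path: str | Path,
    seed: int | None = None, cfg_hash: str = "none",
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_header_line(seed, cfg_hash))
        dataset.to_frame().rename_axis("gene_id").to_csv(fh, sep="\t")
    return path


# ---------------------------------------------------------------------------
# MRM batch table
# ---------------------------------------------------------------------------

BATCH_COLUMNS = [
    "sample_id", "role", "analyte", "quantifier_area",
    "qualifier_area", "is_area", "nominal_conc",
]

ROLES = {"calibrator", "qc", "pooled", "unknown"}


def read_batch(path: str | Path) -> pd.DataFrame:
    df = read_table(path)
    missing = [c for c in BATCH_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: batch table missing column(s) {missing}")
    bad = set(df["role"]) - ROLES
    if bad:
        raise ValueError(f"{path}: unknown sample role(s) {sorted(bad)}")
    return df[BATCH_COLUMNS]


# ---------------------------------------------------------------------------
# Run configuration and manifest
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return cfg


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    outdir: str | Path,
    seed: int,
    cfg_hash: str,
    stages: list[str],
    outputs: list[Path],
    inputs: list[Path] = (),
) -> Path:
    """JSON manifest of a run: seed, config hash, checksums of every artifact."""
    manifest = {
        "tool": "modmet",
        "version": TOOL_VERSION,
        "seed": seed,
        "config_hash": cfg_hash,
        "stages": stages,
        "inputs": {Path(p).name: file_sha256(p) for p in inputs},
        "outputs": {Path(p).name: file_sha256(p) for p in outputs},
    }
    path = Path(outdir) / "manifest.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
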