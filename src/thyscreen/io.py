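"""Readers, writers and model bundles.

Input tables are delimited text (CSV/TSV) or SDF; outputs are CSV, JSON and
Markdown.  A trained endpoint is persisted as a *bundle* directory:

    bundle/
      metadata.json   endpoint name, group, descriptor manifest tag, seeds,
                      member count, curated-dataset hash, retained feature
                      columns, known experimental labels
      model.joblib    the fitted conformal aggregate + descriptorizer

The loader refuses bundles written under a different format version or an
unknown descriptor manifest, so a model can never silently score a matrix
it was not trained for.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import joblib
import pandas as pd
from rdkit import Chem

from ._manifest import DESCRIPTOR_SETS
from .curation import CurationLog
from .screening import EndpointModel

__all__ = [
    "read_activity_table",
    "read_inventory",
    "write_curated",
    "save_bundle",
    "load_bundle",
    "dataset_hash",
    "BUNDLE_FORMAT_VERSION",
]

BUNDLE_FORMAT_VERSION = 1


def _read_delimited(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep, dtype=str)


def _read_sdf(path: str | Path, activity_field: str = "activity"
              ) -> pd.DataFrame:
    rows = []
    supplier = Chem.SDMolSupplier(str(path))
    for i, mol in enumerate(supplier):
        if mol is None:
            rows.append((f"SDF{i:05d}", "", ""))
            continue
        cid = mol.GetProp("_Name") if mol.HasProp("_Name") and \
            mol.GetProp("_Name") else f"SDF{i:05d}"
        act = mol.GetProp(activity_field) if mol.HasProp(activity_field) else ""
        rows.append((cid, Chem.MolToSmiles(mol), act))
    return pd.DataFrame(rows, columns=["id", "smiles", "activity"])


def read_activity_table(path: str | Path, activity_field: str = "activity"
                        ) -> pd.DataFrame:
    """Read a structure-activity table (CSV/TSV or SDF) into columns
    ``id``, ``smiles``, ``activity``."""
    path = Path(path)
    if path.suffix.lower() == ".sdf":
        return _read_sdf(path, activity_field)
    df = _read_delimited(path)
    missing = {"id", "smiles", "activity"} - set(df.columns)
    if missing:
        raise ValueError(
            f"{path.name}: missing required column(s) {sorted(missing)}")
    return df[["id", "smiles", "activity"]]


def read_inventory(path: str | Path) -> pd.DataFrame:
    """Read a screening inventory (CSV/TSV or SDF) with ``id``, ``smiles``."""
    path = Path(path)
    if path.suffix.lower() == ".sdf":
        return _read_sdf(path)[["id", "smiles"]]
    df = _read_delimited(path)
    missing = {"id", "smiles"} - set(df.columns)
    if missing:
        raise ValueError(
            f"{path.name}: missing required column(s) {sorted(missing)}")
    return df[["id", "smiles"]]


def write_curated(df: pd.DataFrame, log: CurationLog, out_csv: str | Path,
                  out_log: str | Path | None = None):
    """Write a curated dataset CSV and its curation log JSON."""
    df.to_csv(out_csv, index=False)
    if out_log is not None:
        Path(out_log).write_text(json.dumps(asdict(log), indent=2) + "\n")


def dataset_hash(df: pd.DataFrame) -> str:
    """Order-independent SHA-256 of a curated dataset's rows."""
    rows = sorted(",".join(map(str, r)) for r in df.itertuples(index=False))
    return hashlib.sha256("\n".join(rows).encode()).hexdigest()


def save_bundle(endpoint: EndpointModel, path: str | Path,
                extra_metadata: dict | None = None):
    """Persist an endpoint model as a bundle directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    model = endpoint.model
    desc = endpoint.descriptorizer
    meta = {
        "format_version": BUNDLE_FORMAT_VERSION,
        "endpoint": endpoint.name,
        "group": endpoint.group,
        "descriptor_set": desc.descriptor_set,
        "feature_names": list(desc.feature_names_),
        "dropped_columns": list(desc.dropped_columns_),
        "n_models": int(model.n_models),
        "n_estimators": int(model.n_estimators),
        "calibration_fraction": model.calibration_fraction,
        "base_seed": int(model.random_state),
        "classes": [str(c) for c in model.classes_],
        "pos_label": str(model.pos_label_),
        "n_invalid_members": int(model.n_invalid_members_),
        "known_labels": {k: list(v) for k, v in
                         sorted(endpoint.known_labels.items())},
    }
    meta.update(extra_metadata or {})
    (path / "metadata.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True) + "\n")
    joblib.dump({"model": model, "descriptorizer": desc},
                path / "model.joblib")


def load_bundle(path: str | Path) -> EndpointModel:
    """Load a bundle directory back into an :class:`EndpointModel`."""
    path = Path(path)
    meta = json.loads((path / "metadata.json").read_text())
    if meta.get("format_version") != BUNDLE_FORMAT_VERSION:
        raise ValueError(
            f"bundle format {meta.get('format_version')} not supported "
            f"(expected {BUNDLE_FORMAT_VERSION})")
    if meta["descriptor_set"] not in DESCRIPTOR_SETS:
        raise ValueError(
            f"bundle uses unknown descriptor manifest "
            f"{meta['descriptor_set']!r}")
    payload = joblib.load(path / "model.joblib")
    return EndpointModel(
        name=meta["endpoint"],
        group=meta["group"],
        model=payload["model"],
        descriptorizer=payload["descriptorizer"],
        known_labels={k: tuple(v) for k, v in meta["known_labels"].items()},
    )
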