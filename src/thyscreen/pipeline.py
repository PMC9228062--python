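"""End-to-end endpoint training: curated table in, endpoint model out.

Glue between curation, featurization and the conformal core.  The sequence
for one endpoint is: stratified 20% validation split on the curated
compounds, descriptorizer fit on the working training partition (so
validation compounds are featurized exactly like future screening
compounds), aggregated conformal fit on the working partition, and a record
of every training/validation structure key with its experimental label so
screening can report known compounds as known rather than predicted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .conformal import AggregatedConformalClassifier, SplitPlan
from .descriptors import RDKitDescriptorizer
from ._manifest import DEFAULT_DESCRIPTOR_SET
from .screening import EndpointModel, THYROID_GROUP

__all__ = ["TrainedEndpoint", "train_endpoint"]


@dataclass
class TrainedEndpoint:
    """An endpoint model plus its held-out validation partition."""

    endpoint: EndpointModel
    X_val: np.ndarray
    y_val: np.ndarray
    smiles_val: list[str]


def train_endpoint(
    curated: pd.DataFrame,
    name: str,
    group: str = THYROID_GROUP,
    plan: SplitPlan = SplitPlan(),
    n_models: int = 50,
    n_estimators: int = 300,
    descriptor_set: str = DEFAULT_DESCRIPTOR_SET,
) -> TrainedEndpoint:
    """Train one endpoint from a curated dataset.

    Parameters
    ----------
    curated : DataFrame
        Columns ``structure_key``, ``canonical_smiles``, ``activity``
        (binary, "active"/"inactive"), e.g. from
        :func:`thyscreen.curation.curate_dataframe`.
    name, group : str
        Endpoint identity and battery group tag.
    plan : SplitPlan
        Validation fraction, member split fractions and base seed.

    Returns
    -------
    TrainedEndpoint
        The fitted endpoint (model + descriptorizer + known labels) and the
        validation partition, already featurized, for performance sweeps.
    """
    required = {"structure_key", "canonical_smiles", "activity"}
    missing = required - set(curated.columns)
    if missing:
        raise ValueError(f"curated table missing columns: {sorted(missing)}")
    y = curated["activity"].to_numpy(dtype=object)
    if set(np.unique(y)) - {"active", "inactive"}:
        raise ValueError("activity labels must be 'active'/'inactive'")

    idx_work, idx_val = train_test_split(
        np.arange(len(curated)), test_size=plan.validation_fraction,
        stratify=y if plan.stratified else None,
        random_state=plan.base_seed)
    work = curated.iloc[idx_work]
    val = curated.iloc[idx_val]

    desc = RDKitDescriptorizer(descriptor_set=descriptor_set)
    desc.fit(work["canonical_smiles"].tolist())
    X_work = desc.transform(work["canonical_smiles"].tolist())
    X_val = desc.transform(val["canonical_smiles"].tolist())

    model = AggregatedConformalClassifier(
        n_models=n_models, n_estimators=n_estimators,
        calibration_fraction=plan.calibration_fraction,
        pos_label="active", random_state=plan.base_seed)
    model.fit(X_work, work["activity"].to_numpy(dtype=object))

    known = {
        row.structure_key: (row.activity, origin)
        for part, origin in ((work, "training"), (val, "validation"))
        for row in part.itertuples(index=False)
    }
    endpoint = EndpointModel(name=name, group=group, model=model,
                             descriptorizer=desc, known_labels=known)
    return TrainedEndpoint(
        endpoint=endpoint, X_val=X_val,
        y_val=val["activity"].to_numpy(dtype=object),
        smiles_val=val["canonical_smiles"].tolist())
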