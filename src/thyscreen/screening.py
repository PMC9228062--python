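"""Inventory screening against a battery of per-endpoint conformal models.

A battery groups endpoint models into *thyroid-specific* targets (receptor
and transport proteins, iodide uptake, deiodinases, peroxidase) and
*general* xenobiotic-metabolism targets (nuclear receptors regulating
phase I/II enzymes).  Screening a chemical inventory assigns every compound
one status per endpoint:

* ``known_active`` / ``known_inactive`` — the standardized structure occurs
  in that endpoint's training or validation data, so the experimental label
  overrides the model;
* ``predicted_active`` / ``predicted_inactive`` — single-label conformal
  prediction at the chosen significance level (default 0.1, favoring a high
  active-region hit rate and low false-positive rate over raw efficiency);
* ``uncertain_both`` / ``empty`` — the uncertain and outside-domain
  regions;
* ``not_covered`` — the compound could not be standardized or featurized.

Compounds are then ranked by how many models in a group call them active
(known or predicted); compounds flagged by many independent thyroid-related
endpoints are the strongest candidates for follow-up testing (default
threshold: at least nine thyroid-specific active calls).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .conformal import AggregatedConformalClassifier, REGION_BOTH, REGION_EMPTY
from .curation import standardize_structure
from .descriptors import RDKitDescriptorizer

__all__ = [
    "EndpointModel",
    "EndpointBattery",
    "screen",
    "summarize",
    "prioritize",
    "THYROID_GROUP",
    "GENERAL_GROUP",
]

THYROID_GROUP = "thyroid_specific"
GENERAL_GROUP = "general"

KNOWN_STATUSES = {"known_active", "known_inactive"}
ACTIVE_STATUSES = {"known_active", "predicted_active"}


@dataclass
class EndpointModel:
    """One endpoint's fitted model plus what it already knows.

    ``known_labels`` maps structure keys of training/validation compounds
    to ``(label, origin)`` with label in {"active", "inactive"} and origin
    in {"training", "validation"}.
    """

    name: str
    group: str  # THYROID_GROUP | GENERAL_GROUP
    model: AggregatedConformalClassifier
    descriptorizer: RDKitDescriptorizer
    known_labels: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self):
        if self.group not in (THYROID_GROUP, GENERAL_GROUP):
            raise ValueError(f"unknown group {self.group!r}")


class EndpointBattery:
    """A named, grouped collection of endpoint models."""

    def __init__(self, endpoints: list[EndpointModel] | None = None):
        self._endpoints: dict[str, EndpointModel] = {}
        for e in endpoints or []:
            self.add(e)

    def add(self, endpoint: EndpointModel):
        if endpoint.name in self._endpoints:
            raise ValueError(f"duplicate endpoint name {endpoint.name!r}")
        self._endpoints[endpoint.name] = endpoint

    def __iter__(self):
        return iter(self._endpoints.values())

    def __len__(self):
        return len(self._endpoints)

    def names(self, group: str | None = None) -> list[str]:
        return [e.name for e in self
                if group is None or e.group == group]

    def __getitem__(self, name: str) -> EndpointModel:
        return self._endpoints[name]


def _status_from_region(region: str, active_label, inactive_label) -> str:
    if region == REGION_BOTH:
        return "uncertain_both"
    if region == REGION_EMPTY:
        return "empty"
    return "predicted_active" if region == str(active_label) \
        else "predicted_inactive"


def screen(
    battery: EndpointBattery,
    inventory: pd.DataFrame,
    significance_level: float = 0.1,
) -> pd.DataFrame:
    """Screen an inventory (columns ``id``, ``smiles``) against a battery.

    Returns a wide DataFrame with one status column per endpoint, a
    decidability column per endpoint, and per-group active-call counts.
    Known experimental labels (structure-key match against an endpoint's
    training or validation data) override model predictions.  Compounds
    failing standardization get ``not_covered`` everywhere.
    """
    missing = {"id", "smiles"} - set(inventory.columns)
    if missing:
        raise ValueError(f"inventory missing columns: {sorted(missing)}")
    ids = inventory["id"].astype(str).tolist()
    std = [standardize_structure(s) for s in inventory["smiles"]]
    covered = [i for i, s in enumerate(std) if s.ok]
    out = pd.DataFrame({"id": ids})
    out["structure_key"] = [s.structure_key if s.ok else None for s in std]

    smiles_cov = [std[i].canonical_smiles for i in covered]
    for endpoint in battery:
        col = np.full(len(ids), "not_covered", dtype=object)
        dec = np.full(len(ids), np.nan)
        if covered:
            X = endpoint.descriptorizer.transform(smiles_cov)
            regions = endpoint.model.predict_region(X, significance_level)
            decs = endpoint.model.decidability(X)
            active_label = endpoint.model.pos_label_
            inactive_label = next(c for c in endpoint.model.classes_
                                  if c != active_label)
            for j, i in enumerate(covered):
                key = std[i].structure_key
                known = endpoint.known_labels.get(key)
                if known is not None:
                    col[i] = f"known_{known[0]}"
                else:
                    col[i] = _status_from_region(
                        str(regions[j]), active_label, inactive_label)
                dec[i] = decs[j]
        out[f"status_{endpoint.name}"] = col
        out[f"decidability_{endpoint.name}"] = dec

    for group in (THYROID_GROUP, GENERAL_GROUP):
        names = battery.names(group)
        if names:
            status = out[[f"status_{n}" for n in names]]
            out[f"active_count_{group}"] = status.isin(ACTIVE_STATUSES) \
                .sum(axis=1).astype(int)
            out[f"decidability_sum_{group}"] = \
                out[[f"decidability_{n}" for n in names]].sum(axis=1)
        else:
            out[f"active_count_{group}"] = 0
            out[f"decidability_sum_{group}"] = 0.0
    return out


def summarize(records: pd.DataFrame, battery: EndpointBattery,
              group: str = THYROID_GROUP) -> pd.DataFrame:
    """Histogram of compounds per number of active models in a group.

    Bins run from 0 to the number of models in the group and partition the
    inventory exactly.  Within each bin compounds are split by provenance
    of their active calls: ``known`` (at least one experimentally known
    active), ``predicted`` (model calls only), and for the zero bin
    ``uncertain`` (no single-label call anywhere in the group) vs
    ``inactive``.
    """
    names = battery.names(group)
    n_bins = len(names) + 1
    status = records[[f"status_{n}" for n in names]]
    counts = records[f"active_count_{group}"]
    known_any = status.isin({"known_active"}).any(axis=1)
    uncertain_all = status.isin({"uncertain_both", "empty", "not_covered"}) \
        .all(axis=1)
    rows = []
    for b in range(n_bins):
        in_bin = counts == b
        known = int((in_bin & known_any).sum())
        if b == 0:
            uncertain = int((in_bin & uncertain_all).sum())
            predicted = 0
            inactive = int(in_bin.sum()) - known - uncertain
        else:
            predicted = int((in_bin & ~known_any).sum())
            uncertain = 0
            inactive = 0
        rows.append({"active_models": b, "n_compounds": int(in_bin.sum()),
                     "known": known, "predicted": predicted,
                     "uncertain": uncertain, "inactive": inactive})
    return pd.DataFrame(rows)


def prioritize(records: pd.DataFrame, min_active_models: int = 9,
               group: str = THYROID_GROUP) -> pd.DataFrame:
    """Rank compounds of concern: active in at least ``min_active_models``
    models of the group, ordered by active count (desc), then summed
    decidability (desc), then compound id (asc) for stable ties."""
    count_col = f"active_count_{group}"
    dec_col = f"decidability_sum_{group}"
    hits = records[records[count_col] >= min_active_models].copy()
    hits = hits.sort_values(
        by=[count_col, dec_col, "id"],
        ascending=[False, False, True],
        kind="mergesort").reset_index(drop=True)
    return hits
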