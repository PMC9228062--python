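"""Molecular descriptor featurization.

Turns standardized structures into a fixed-width numeric matrix of 2-D
physicochemical descriptors.  The descriptor list is pinned in a versioned
manifest (:mod:`thyscreen._manifest`) so matrices remain comparable across
library upgrades; a model refuses to score a matrix computed under a
different manifest.

Sanitization policy (tree ensembles need finite inputs): descriptor columns
that are non-finite for more than ``max_nonfinite_fraction`` of the training
compounds are dropped at fit time; remaining non-finite entries are imputed
with the training-set column median, which is stored and re-applied at
prediction time.  No scaling is applied — random forests are scale-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from ._manifest import DESCRIPTOR_SETS, DEFAULT_DESCRIPTOR_SET

__all__ = [
    "DescriptorMatrix",
    "RDKitDescriptorizer",
    "compute_descriptors",
    "descriptor_names",
]


def descriptor_names(descriptor_set: str = DEFAULT_DESCRIPTOR_SET) -> list[str]:
    """Return the pinned descriptor name list for a manifest tag."""
    try:
        return list(DESCRIPTOR_SETS[descriptor_set])
    except KeyError:
        raise KeyError(
            f"unknown descriptor_set {descriptor_set!r}; "
            f"known: {sorted(DESCRIPTOR_SETS)}"
        ) from None


@dataclass
class DescriptorMatrix:
    """A dense descriptor matrix aligned to an ordered compound list."""

    compound_ids: list[str]
    descriptor_names: list[str]
    values: np.ndarray  # (n_compounds, n_descriptors)
    descriptor_set: str = DEFAULT_DESCRIPTOR_SET
    #: compounds excluded because descriptor computation failed, with reason
    failed: dict[str, str] = field(default_factory=dict)
    #: (row, column) positions that were non-finite before sanitization
    nonfinite_report: list[tuple[str, str]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.compound_ids,
                            columns=self.descriptor_names)


def _raw_descriptor_rows(
    smiles_list: Sequence[str], names: list[str]
) -> tuple[list[int], np.ndarray, dict[int, str]]:
    """Compute raw descriptor values; NaN for individual descriptor failures,
    whole-row failure for unparsable structures."""
    funcs = dict(Descriptors._descList)
    fns = [funcs[n] for n in names]
    ok_rows: list[int] = []
    failed: dict[int, str] = {}
    values = []
    for i, smi in enumerate(smiles_list):
        mol = Chem.MolFromSmiles(smi) if isinstance(smi, str) else None
        if mol is None:
            failed[i] = "unparsable"
            continue
        row = np.empty(len(fns))
        for j, fn in enumerate(fns):
            try:
                row[j] = fn(mol)
            except Exception:
                row[j] = np.nan
        ok_rows.append(i)
        values.append(row)
    mat = np.vstack(values) if values else np.empty((0, len(fns)))
    return ok_rows, mat, failed


class RDKitDescriptorizer(BaseEstimator, TransformerMixin):
    """Transformer mapping SMILES strings to a sanitized descriptor matrix.

    Parameters
    ----------
    descriptor_set : str
        Tag of the pinned descriptor manifest.
    max_nonfinite_fraction : float
        Columns non-finite in more than this fraction of the fit data are
        dropped; survivors are median-imputed.

    Attributes
    ----------
    feature_names_ : list of str
        Descriptor columns retained after fitting.
    dropped_columns_ : list of str
        Columns removed for excessive non-finite values.
    medians_ : ndarray
        Training medians used to impute non-finite entries at transform time.

    Notes
    -----
    ``transform`` raises on unparsable SMILES; use
    :func:`compute_descriptors` for batch runs that must account for
    failures row by row.
    """

    def __init__(self, descriptor_set: str = DEFAULT_DESCRIPTOR_SET,
                 max_nonfinite_fraction: float = 0.05):
        self.descriptor_set = descriptor_set
        self.max_nonfinite_fraction = max_nonfinite_fraction

    def fit(self, X: Sequence[str], y=None):
        names = descriptor_names(self.descriptor_set)
        ok, mat, failed = _raw_descriptor_rows(list(X), names)
        if failed:
            bad = [list(X)[i] for i in sorted(failed)][:5]
            raise ValueError(f"unparsable SMILES during fit, e.g. {bad}")
        mat = np.asarray(mat, dtype=float)
        with np.errstate(invalid="ignore"):
            bad_frac = (~np.isfinite(mat)).mean(axis=0) if len(mat) else \
                np.zeros(len(names))
        keep = bad_frac <= self.max_nonfinite_fraction
        self.feature_names_ = [n for n, k in zip(names, keep) if k]
        self.dropped_columns_ = [n for n, k in zip(names, keep) if not k]
        sub = mat[:, keep]
        sub_masked = np.where(np.isfinite(sub), sub, np.nan)
        self.medians_ = np.nanmedian(sub_masked, axis=0) if len(sub) else \
            np.zeros(keep.sum())
        self.medians_ = np.where(np.isfinite(self.medians_), self.medians_, 0.0)
        self.n_features_in_ = 1
        return self

    def transform(self, X: Sequence[str]) -> np.ndarray:
        check_is_fitted(self, "feature_names_")
        names = descriptor_names(self.descriptor_set)
        ok, mat, failed = _raw_descriptor_rows(list(X), names)
        if failed:
            bad = [list(X)[i] for i in sorted(failed)][:5]
            raise ValueError(f"unparsable SMILES during transform, e.g. {bad}")
        keep = [i for i, n in enumerate(names) if n in set(self.feature_names_)]
        sub = np.asarray(mat, dtype=float)[:, keep]
        nonfinite = ~np.isfinite(sub)
        if nonfinite.any():
            sub = np.where(nonfinite, np.broadcast_to(self.medians_, sub.shape),
                           sub)
        return sub

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "feature_names_")
        return np.asarray(self.feature_names_, dtype=object)


def compute_descriptors(
    structures: Sequence[str],
    compound_ids: Sequence[str] | None = None,
    descriptor_set: str = DEFAULT_DESCRIPTOR_SET,
    sanitize: bool = True,
) -> DescriptorMatrix:
    """Compute the descriptor matrix for a batch of structures.

    Rows that fail completely (unparsable structure) are excluded from the
    matrix and recorded in ``failed`` with a reason.  Individual non-finite
    descriptor values are listed in ``nonfinite_report``; with
    ``sanitize=True`` they are imputed with the batch column median (0 where
    a column has no finite value), otherwise left as NaN for downstream
    handling.  Deterministic for a fixed manifest tag.
    """
    names = descriptor_names(descriptor_set)
    structures = list(structures)
    if compound_ids is None:
        compound_ids = [str(i) for i in range(len(structures))]
    compound_ids = [str(c) for c in compound_ids]
    if len(compound_ids) != len(structures):
        raise ValueError("compound_ids and structures length mismatch")
    ok, mat, failed = _raw_descriptor_rows(structures, names)
    kept_ids = [compound_ids[i] for i in ok]
    report = [
        (kept_ids[r], names[c])
        for r, c in zip(*np.where(~np.isfinite(mat)))
    ]
    if sanitize and mat.size:
        masked = np.where(np.isfinite(mat), mat, np.nan)
        with np.errstate(all="ignore"):
            med = np.nanmedian(masked, axis=0)
        med = np.where(np.isfinite(med), med, 0.0)
        mat = np.where(np.isfinite(mat), mat, np.broadcast_to(med, mat.shape))
    return DescriptorMatrix(
        compound_ids=kept_ids,
        descriptor_names=names,
        values=mat,
        descriptor_set=descriptor_set,
        failed={compound_ids[i]: reason for i, reason in failed.items()},
        nonfinite_report=report,
    )
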