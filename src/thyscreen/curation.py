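"""Chemical structure standardization and structure-activity dataset curation.

Raw bioactivity tables are noisy: salts and solvates, mixtures, inorganic
species, "inconclusive" assay calls and duplicate structures with possibly
conflicting labels.  This module normalizes each structure to a canonical
single-component organic form and collapses the table to one binary-labeled
record per unique structure.

The standardization pipeline applied to every SMILES is:

1. parse and sanitize (includes aromatization);
2. remove explicit hydrogens;
3. strip salt/solvent fragments from a fixed, versioned fragment list
   (if stripping would remove everything, the largest stripped *organic*
   fragment is restored — e.g. sodium acetate yields acetic acid);
4. reject anything left with no organic fragment (``inorganic``) or more
   than one organic fragment (``mixture``);
5. neutralize charges where chemically valid;
6. canonicalize the tautomer;
7. emit canonical SMILES plus an InChIKey used as the structure key for
   order-independent duplicate detection.

Duplicates with concordant labels collapse to a single record; duplicates
with conflicting labels are omitted entirely, and "inconclusive" records are
dropped before de-duplication.
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "RawRecord",
    "CuratedRecord",
    "CurationLog",
    "StandardizationResult",
    "FRAGMENT_STRIP_LIST_VERSION",
    "standardize_structure",
    "curate_dataset",
    "curate_dataframe",
]

#: Version tag of the salt/solvent fragment list below; recorded in logs.
FRAGMENT_STRIP_LIST_VERSION = "strip-v1"

# Counterions and solvents removed during salt stripping, as canonical
# SMILES of the isolated fragment.  Inorganic ions need not be listed: any
# carbon-free fragment is dropped by the organic/inorganic rule anyway.
_STRIP_FRAGMENTS_RAW = [
    # halides / simple inorganic ions (listed for completeness of intent)
    "[Cl-]", "[Br-]", "[I-]", "[F-]",
    "[Na+]", "[K+]", "[Li+]", "[Ca+2]", "[Mg+2]", "[Zn+2]", "[Al+3]",
    "[NH4+]", "O=S(=O)([O-])[O-]", "O=S(=O)([O-])O", "O=[N+]([O-])[O-]",
    "O=P([O-])([O-])[O-]", "O=P(O)(O)O", "Cl", "Br", "I", "O=S(=O)(O)O",
    # small organic counterions
    "CC(=O)[O-]", "CC(=O)O",                      # acetate / acetic acid
    "C(=O)[O-]", "OC=O",                          # formate / formic acid
    "OC(=O)C(=O)O", "[O-]C(=O)C(=O)[O-]",         # oxalic acid / oxalate
    "OC(=O)/C=C/C(=O)O",                          # fumaric acid
    "CS(=O)(=O)O", "CS(=O)(=O)[O-]",              # mesylate
    "Cc1ccc(S(=O)(=O)O)cc1", "Cc1ccc(S(=O)(=O)[O-])cc1",  # tosylate
    "OC(=O)CC(O)(CC(=O)O)C(=O)O",                 # citric acid
    "OC(=O)C(O)C(O)C(=O)O",                       # tartaric acid
    "C(CC(=O)O)C(=O)O",                           # succinic acid
    "OC(=O)C=CC(=O)O",                            # maleic acid
    "CCN(CC)CC",                                  # triethylamine
    # common solvents
    "O", "CO", "CCO", "CC(C)O", "CC(=O)C", "CS(C)=O", "CC#N",
    "ClCCl", "ClC(Cl)Cl", "C1CCOC1", "CCOCC", "CCOC(C)=O",
]

# Carbon-containing species conventionally treated as inorganic.
_INORGANIC_CARBON = {
    "O=C=O", "[C-]#[O+]", "C#N", "[C-]#N", "N#C[S-]", "S=C=[N-]",
    "O=C([O-])[O-]", "O=C(O)O", "O=C([O-])O",
}


def _canon(smiles: str) -> str | None:
    mol = Chem.MolFromSmiles(smiles)
    return Chem.MolToSmiles(mol) if mol is not None else None


_STRIP_FRAGMENTS = frozenset(
    c for c in (_canon(s) for s in _STRIP_FRAGMENTS_RAW) if c is not None
)

_UNCHARGER = rdMolStandardize.Uncharger()
_TAUTOMERIZER = rdMolStandardize.TautomerEnumerator()


@dataclass(frozen=True)
class RawRecord:
    """One row of an uncurated structure-activity table."""

    source_id: str
    smiles: str
    activity: str


@dataclass(frozen=True)
class CuratedRecord:
    """A standardized unique structure with a binary activity label."""

    structure_key: str
    canonical_smiles: str
    activity: str  # "active" | "inactive"


@dataclass
class CurationLog:
    """Counts of records removed per reason during curation."""

    input_count: int = 0
    retained: int = 0
    unparsable: int = 0
    inorganic: int = 0
    mixture: int = 0
    inconclusive: int = 0
    unknown_label: int = 0
    duplicate_concordant_merged: int = 0
    duplicate_conflict_omitted: int = 0
    warnings: list = field(default_factory=list)

    @property
    def removed(self) -> int:
        return self.input_count - self.retained

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass(frozen=True)
class StandardizationResult:
    """Outcome of standardizing one SMILES string.

    Either ``ok`` with canonical SMILES + structure key, or a typed
    rejection (``unparsable`` | ``inorganic`` | ``mixture``).
    """

    ok: bool
    canonical_smiles: str | None = None
    structure_key: str | None = None
    reason: str | None = None

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.ok


def _is_organic(frag: Chem.Mol) -> bool:
    """Organic = contains carbon and is not a conventional inorganic carbon
    species (carbonate, cyanide, carbon oxides...)."""
    if not any(a.GetAtomicNum() == 6 for a in frag.GetAtoms()):
        return False
    return Chem.MolToSmiles(frag) not in _INORGANIC_CARBON


def standardize_structure(smiles: str) -> StandardizationResult:
    """Standardize one SMILES to a canonical single-component organic form.

    Never raises on bad input; failures come back as typed rejections so a
    batch run can account for every record.

    Parameters
    ----------
    smiles : str
        Input structure, possibly multi-component ("." separated).

    Returns
    -------
    StandardizationResult
        ``ok=True`` with `canonical_smiles` and `structure_key` (InChIKey),
        or ``ok=False`` with `reason` in {"unparsable", "inorganic",
        "mixture"}.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        return StandardizationResult(ok=False, reason="unparsable")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return StandardizationResult(ok=False, reason="unparsable")
    mol = Chem.RemoveHs(mol)

    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    kept = [f for f in frags if Chem.MolToSmiles(f) not in _STRIP_FRAGMENTS]
    if not kept:
        # Everything matched the strip list; restore the largest stripped
        # organic fragment so plain salts of small acids survive.
        organics = [f for f in frags if _is_organic(f)]
        if organics:
            kept = [max(organics, key=lambda f: f.GetNumHeavyAtoms())]
    organic = [f for f in kept if _is_organic(f)]
    if len(organic) == 0:
        return StandardizationResult(ok=False, reason="inorganic")
    if len(organic) > 1:
        # Two organic components = a mixture; the larger one is NOT kept.
        return StandardizationResult(ok=False, reason="mixture")

    parent = organic[0]
    try:
        parent = _UNCHARGER.uncharge(parent)
        parent = _TAUTOMERIZER.Canonicalize(parent)
        canonical = Chem.MolToSmiles(parent)
        key = Chem.MolToInchiKey(parent)
    except Exception:
        return StandardizationResult(ok=False, reason="unparsable")
    if not key:
        return StandardizationResult(ok=False, reason="unparsable")
    return StandardizationResult(ok=True, canonical_smiles=canonical,
                                 structure_key=key)


_ACTIVE_ALIASES = {"active", "1", "1.0", "true", "pos", "positive", "a"}
_INACTIVE_ALIASES = {"inactive", "0", "0.0", "false", "neg", "negative", "ia"}
_INCONCLUSIVE_ALIASES = {"inconclusive", "ambiguous", "equivocal"}


def _normalize_label(activity) -> str | None:
    """Map a raw activity label to 'active'/'inactive'/'inconclusive'."""
    label = str(activity).strip().lower()
    if label in _ACTIVE_ALIASES:
        return "active"
    if label in _INACTIVE_ALIASES:
        return "inactive"
    if label in _INCONCLUSIVE_ALIASES:
        return "inconclusive"
    return None


def curate_dataset(
    records: Iterable[RawRecord | tuple | dict],
) -> tuple[list[CuratedRecord], CurationLog]:
    """Curate raw structure-activity records into a modeling-ready dataset.

    Records whose activity is inconclusive (or unrecognized) are dropped,
    structures are standardized, and duplicates are resolved by label
    concordance: concordant duplicates merge into one record, conflicting
    duplicates are omitted entirely.  Output order follows first appearance
    of each retained structure, which together with key-based de-duplication
    makes the retained set independent of input order.

    Returns
    -------
    (records, log) : (list of CuratedRecord, CurationLog)
        ``log`` accounts for every input record: removed + retained equals
        the input count.
    """
    log = CurationLog()
    by_key: dict[str, dict] = {}
    order: list[str] = []

    for rec in records:
        if isinstance(rec, dict):
            rec = RawRecord(str(rec["source_id"]), rec["smiles"], rec["activity"])
        elif isinstance(rec, tuple):
            rec = RawRecord(str(rec[0]), rec[1], rec[2])
        log.input_count += 1

        label = _normalize_label(rec.activity)
        if label == "inconclusive":
            log.inconclusive += 1
            continue
        if label is None:
            log.unknown_label += 1
            continue
        std = standardize_structure(rec.smiles)
        if not std.ok:
            setattr(log, std.reason, getattr(log, std.reason) + 1)
            continue
        entry = by_key.get(std.structure_key)
        if entry is None:
            by_key[std.structure_key] = {
                "smiles": std.canonical_smiles,
                "labels": [label],
            }
            order.append(std.structure_key)
        else:
            entry["labels"].append(label)

    curated: list[CuratedRecord] = []
    for key in order:
        entry = by_key[key]
        labels = set(entry["labels"])
        extra = len(entry["labels"]) - 1
        if len(labels) == 1:
            curated.append(CuratedRecord(key, entry["smiles"], entry["labels"][0]))
            log.duplicate_concordant_merged += extra
        else:
            log.duplicate_conflict_omitted += len(entry["labels"])
    log.retained = len(curated)
    if log.input_count and not curated:
        log.warnings.append("all input records were removed during curation")
    return curated, log


def curate_dataframe(df: pd.DataFrame) -> tuple[pd.DataFrame, CurationLog]:
    """Curate a DataFrame with columns ``id``, ``smiles``, ``activity``.

    Thin wrapper over :func:`curate_dataset` returning a DataFrame with
    columns ``structure_key``, ``canonical_smiles``, ``activity``.
    """
    missing = {"id", "smiles", "activity"} - set(df.columns)
    if missing:
        raise ValueError(f"input table missing columns: {sorted(missing)}")
    records = [
        RawRecord(str(r.id), r.smiles, r.activity)
        for r in df.itertuples(index=False)
    ]
    curated, log = curate_dataset(records)
    out = pd.DataFrame(
        [(c.structure_key, c.canonical_smiles, c.activity) for c in curated],
        columns=["structure_key", "canonical_smiles", "activity"],
    )
    return out, log
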