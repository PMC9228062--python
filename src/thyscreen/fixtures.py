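"""Synthetic datasets with known structure for every pipeline stage.

Two generators, deliberately separate:

* :func:`gen_gaussian` draws a labeled feature-space dataset from two
  multivariate normals a known distance apart.  It is exchangeable by
  construction, which isolates the conformal machinery (validity,
  nestedness, p-value distributions) from any chemistry.
* :func:`gen_molecules` enumerates substituted single-ring aromatics and
  labels them with a deterministic structural rule — by default *active iff
  the molecule carries both a halogen and a hydroxyl group*, echoing the
  halogenated/hydroxylated chemotypes typical of thyroid-axis binders —
  plus an optional label-noise flip.  It exercises the full
  curate → featurize → train → screen pipeline without any external data.

Class-imbalance presets mirror the regimes seen in public thyroid
bioactivity panels: from well-balanced literature sets (~30-40% actives)
down to high-throughput screens with under 1% actives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem

__all__ = [
    "GaussianSpec",
    "MoleculeRuleSpec",
    "IMBALANCE_PRESETS",
    "gen_gaussian",
    "gen_molecules",
    "halogen_and_hydroxyl",
]

#: active fractions spanning the imbalance regimes of typical endpoints
IMBALANCE_PRESETS = {
    "extreme": 0.007,   # receptor antagonists with a handful of actives
    "hts": 0.03,        # typical high-throughput screen
    "balanced": 0.30,   # curated literature enzyme-inhibition sets
    "rich": 0.40,       # small binding panels
}


@dataclass(frozen=True)
class GaussianSpec:
    """Two-Gaussian feature-space dataset specification.

    ``class_separation`` is the Euclidean distance between the class means
    in units of the (identity) within-class standard deviation.
    """

    n: int
    active_fraction: float
    dimension: int = 10
    class_separation: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.active_fraction < 1.0:
            raise ValueError("active_fraction must be in (0, 1)")
        if round(self.n * self.active_fraction) < 2:
            raise ValueError(
                "spec implies fewer than 2 active compounds; increase n or "
                "active_fraction")
        if self.class_separation < 0:
            raise ValueError("class_separation must be >= 0")


def gen_gaussian(spec: GaussianSpec) -> tuple[np.ndarray, np.ndarray]:
    """Draw an exactly stratified two-class Gaussian dataset.

    Returns ``(X, y)`` where ``X`` is ``(n, dimension)`` and ``y`` holds
    string labels ``"active"``/``"inactive"`` with exactly
    ``round(n * active_fraction)`` actives.  The active mean sits at
    distance ``class_separation`` from the inactive mean (at the origin)
    along the diagonal; covariance is the identity for both classes, so at
    separation 0 the labels are independent of the features.  Reproducible
    from ``seed``; rows are shuffled so label order carries no information.
    """
    rng = np.random.default_rng(spec.seed)
    n_act = int(round(spec.n * spec.active_fraction))
    n_ina = spec.n - n_act
    d = spec.dimension
    shift = spec.class_separation / np.sqrt(d)
    X = np.vstack([
        rng.standard_normal((n_act, d)) + shift,
        rng.standard_normal((n_ina, d)),
    ])
    y = np.array(["active"] * n_act + ["inactive"] * n_ina, dtype=object)
    perm = rng.permutation(spec.n)
    return X[perm], y[perm]


# ---------------------------------------------------------------- molecules

#: substituents attachable to the aromatic ring, as SMILES branches
_SUBSTITUENTS = [
    "F", "Cl", "Br", "I",                      # halogens
    "O",                                       # hydroxyl
    "C", "CC", "OC", "N", "C#N",               # alkyl / methoxy / amino / nitrile
    "[N+](=O)[O-]", "C(F)(F)F", "C(=O)O", "C=O",
]
_HALOGENS = {"F", "Cl", "Br", "I"}

_HALOGEN_Q = Chem.MolFromSmarts("[F,Cl,Br,I]")
_HYDROXYL_Q = Chem.MolFromSmarts("[OX2H]")


def halogen_and_hydroxyl(smiles: str) -> bool:
    """The default activity rule: halogen AND hydroxyl both present."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    return bool(mol.HasSubstructMatch(_HALOGEN_Q)
                and mol.HasSubstructMatch(_HYDROXYL_Q))


@dataclass(frozen=True)
class MoleculeRuleSpec:
    """Rule-labeled substituted-benzene dataset specification.

    Molecules are benzenes carrying 1-3 substituents from a fixed menu.
    The activity rule is deterministic on the structure (default: halogen
    AND hydroxyl); ``label_noise`` then flips each label independently.
    ``active_fraction`` steers generation toward the requested prevalence
    of rule-actives.
    """

    n: int
    active_fraction: float = 0.30
    label_noise: float = 0.0
    max_substituents: int = 3
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must be in [0, 0.5)")
        if not 0.0 < self.active_fraction < 1.0:
            raise ValueError("active_fraction must be in (0, 1)")


def _make_smiles(subs: list[str], rng: np.random.Generator) -> str | None:
    """Place substituents on distinct ring positions of benzene."""
    if len(subs) > 5:
        return None
    positions = rng.choice(5, size=len(subs), replace=False)
    branch = [""] * 5
    for s, p in zip(subs, positions):
        branch[p] = f"({s})"
    smi = "c1" + "".join(f"c{b}" for b in branch) + "1"
    mol = Chem.MolFromSmiles(smi)
    return Chem.MolToSmiles(mol) if mol is not None else None


def gen_molecules(spec: MoleculeRuleSpec) -> pd.DataFrame:
    """Generate a unique-structure SMILES dataset with rule-based labels.

    Returns a DataFrame with columns ``id``, ``smiles``, ``activity``
    (post-noise label) and ``rule_active`` (the deterministic pre-noise
    truth) — the extra column lets tests count exactly how many labels the
    noise flipped.  All structures are canonical, unique, and pass
    standardization unchanged, so a clean generation round-trips the
    curation stage with zero removals.
    """
    rng = np.random.default_rng(spec.seed)
    seen: set[str] = set()
    rows = []
    non_halogen = [s for s in _SUBSTITUENTS if s not in _HALOGENS]
    attempts = 0
    while len(rows) < spec.n:
        attempts += 1
        if attempts > 200 * spec.n:
            raise RuntimeError(
                "substituent space exhausted before reaching n unique "
                "molecules; lower n or raise max_substituents")
        want_active = rng.random() < spec.active_fraction
        k = int(rng.integers(1, spec.max_substituents + 1))
        if want_active:
            k = max(k, 2)
            subs = [str(rng.choice(sorted(_HALOGENS))), "O"]
            subs += [str(rng.choice(_SUBSTITUENTS))
                     for _ in range(k - 2)]
        else:
            # avoid the halogen+hydroxyl conjunction
            if rng.random() < 0.5:
                pool = non_halogen
            else:
                pool = [s for s in _SUBSTITUENTS if s not in ("O", "C(=O)O")]
            subs = [str(rng.choice(pool)) for _ in range(k)]
        smi = _make_smiles(subs, rng)
        if smi is None or smi in seen:
            continue
        rule = halogen_and_hydroxyl(smi)
        if rule != want_active:
            continue
        seen.add(smi)
        rows.append((f"MOL{len(rows):05d}", smi, rule))
    df = pd.DataFrame(rows, columns=["id", "smiles", "rule_active"])
    flip = rng.random(spec.n) < spec.label_noise
    label = df["rule_active"].to_numpy() ^ flip
    df["activity"] = np.where(label, "active", "inactive")
    return df[["id", "smiles", "activity", "rule_active"]]
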