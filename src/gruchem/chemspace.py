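"""Chemical-space analysis on a 7-property profile.

Each molecule is reduced to seven interpretable properties — H-bond
acceptors, H-bond donors, rotatable bonds, aromatic rings, aliphatic
rings, heteroatoms and molecular weight — then embedded in 2-D with t-SNE
to compare the space covered by a generated library with that of known
actives.  Overlap is additionally quantified (the embedding is only a
picture): for each generated molecule we ask whether any of its k nearest
neighbours *in standardized property space* is a known active.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PropertyVector",
    "PROPERTY_NAMES",
    "property_vector",
    "property_table",
    "embed",
    "overlap_report",
]

PROPERTY_NAMES = ("hba", "hbd", "rotatable_bonds", "aromatic_rings",
                  "aliphatic_rings", "heteroatoms", "mol_weight")


@dataclass(frozen=True)
class PropertyVector:
    """Seven topology-only properties of one molecule."""

    hba: int
    hbd: int
    rotatable_bonds: int
    aromatic_rings: int
    aliphatic_rings: int
    heteroatoms: int
    mol_weight: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PROPERTY_NAMES], dtype=float)


def property_vector(smiles: str, heteroatoms_in_rings: bool = False) -> PropertyVector:
    """Compute the 7-property vector for one molecule.

    ``heteroatoms`` counts all non-carbon heavy atoms by default; with
    ``heteroatoms_in_rings=True`` it counts only heteroatoms that are ring
    members (the narrower reading of "heterocycle atoms").
    """
    from rdkit import Chem
    from rdkit.Chem import Descriptors, Lipinski

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles!r}")
    if heteroatoms_in_rings:
        het = sum(1 for a in mol.GetAtoms()
                  if a.GetAtomicNum() not in (1, 6) and a.IsInRing())
    else:
        het = Lipinski.NumHeteroatoms(mol)
    return PropertyVector(
        hba=int(Lipinski.NumHAcceptors(mol)),
        hbd=int(Lipinski.NumHDonors(mol)),
        rotatable_bonds=int(Lipinski.NumRotatableBonds(mol)),
        aromatic_rings=int(Lipinski.NumAromaticRings(mol)),
        aliphatic_rings=int(Lipinski.NumAliphaticRings(mol)),
        heteroatoms=int(het),
        mol_weight=float(Descriptors.MolWt(mol)),
    )


def property_table(smiles: Sequence[str], set_tag: str | None = None,
                   **kwargs) -> pd.DataFrame:
    """Property vectors for a list of molecules, optionally tagged by set."""
    rows = [property_vector(s, **kwargs).as_array() for s in smiles]
    df = pd.DataFrame(rows, columns=list(PROPERTY_NAMES))
    df.insert(0, "smiles", list(smiles))
    if set_tag is not None:
        df.insert(1, "set", set_tag)
    return df


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def embed(table: pd.DataFrame, seed: int, perplexity: float = 30.0,
          n_iter: int = 1000) -> pd.DataFrame:
    """t-SNE the standardized 7-property table into 2-D.

    Returns the table plus ``x``/``y`` columns; deterministic for a fixed
    seed.  Raises when perplexity >= number of rows (t-SNE requirement).
    """
    from sklearn.manifold import TSNE

    X = table[list(PROPERTY_NAMES)].to_numpy(dtype=float)
    if len(X) < 3:
        raise ValueError("need at least 3 rows to embed")
    if perplexity >= len(X):
        raise ValueError(f"perplexity {perplexity} must be < n rows {len(X)}")
    Z = _standardize(X)
    ts = TSNE(n_components=2, perplexity=perplexity, max_iter=n_iter,
              random_state=seed, init="pca")
    xy = ts.fit_transform(Z)
    out = table.copy()
    out["x"] = xy[:, 0]
    out["y"] = xy[:, 1]
    return out


def overlap_report(table: pd.DataFrame, generated_tag: str = "generated",
                   known_tags: Sequence[str] = ("known_train", "known_test"),
                   k: int = 5) -> dict:
    """How much of the generated set lives among the known actives.

    For each generated molecule, find its ``k`` nearest neighbours among
    *all* molecules in standardized property space (not in the embedded
    plane, which distorts distances) and record whether at least one is a
    known active.  Also reports per-property mean/sd per set.
    """
    from scipy.spatial import cKDTree

    if "set" not in table.columns:
        raise ValueError("table needs a 'set' column")
    tags = set(table["set"])
    if generated_tag not in tags:
        raise ValueError(f"no rows tagged {generated_tag!r}")
    known_present = [t for t in known_tags if t in tags]
    if not known_present:
        raise ValueError(f"no rows tagged any of {known_tags}")
    X = _standardize(table[list(PROPERTY_NAMES)].to_numpy(dtype=float))
    is_gen = (table["set"] == generated_tag).to_numpy()
    is_known = table["set"].isin(known_present).to_numpy()
    tree = cKDTree(X)
    # k+1 because the query point is its own nearest neighbour
    _, nn = tree.query(X[is_gen], k=k + 1)
    nn = np.atleast_2d(nn)[:, 1:]
    near_known = is_known[nn].any(axis=1)
    per_set = (table.groupby("set")[list(PROPERTY_NAMES)]
               .agg(["mean", "std"]))
    return {
        "overlap_fraction": float(near_known.mean()),
        "k": k,
        "n_generated": int(is_gen.sum()),
        "n_known": int(is_known.sum()),
        "per_property": per_set,
    }
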