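"""Per-residue contact frequencies of docked ligand poses.

Given a protein structure and a set of ligand poses (from any docking
tool), a residue is *in contact* with a ligand when at least one of its
heavy atoms lies within a distance cutoff (default 5.0 Å, inclusive) of any
ligand heavy atom.  The contact frequency of a residue is the fraction of
ligands in the set that contact it; residues above a frequency threshold
are binding hotspots.

Hydrogens are ignored by default because docked poses rarely carry a
consistent protonation state; pass ``include_hydrogens=True`` to the
loaders to keep them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "Protein",
    "PoseSet",
    "ContactProfile",
    "load_protein",
    "load_ligand_poses",
    "contact_residues",
    "contact_frequencies",
    "hotspot_filter",
    "profile_similarity",
]

DEFAULT_CUTOFF = 5.0


@dataclass
class Protein:
    """Flat atomic arrays with residue identifiers."""

    coords: np.ndarray   # (N, 3) float
    chain: np.ndarray    # (N,) str
    resnum: np.ndarray   # (N,) int
    resname: np.ndarray  # (N,) str
    element: np.ndarray  # (N,) str

    def __post_init__(self):
        if not np.isfinite(self.coords).all():
            raise ValueError("protein coordinates contain non-finite values")

    @property
    def residue_keys(self) -> list[tuple[str, int, str]]:
        """Unique (chain, resnum, resname) triples in file order."""
        seen, out = set(), []
        for c, n, r in zip(self.chain, self.resnum, self.resname):
            key = (str(c), int(n), str(r))
            if key not in seen:
                seen.add(key)
                out.append(key)
        return out


@dataclass
class PoseSet:
    """A protein plus one pose per ligand."""

    protein: Protein
    ligand_coords: list[np.ndarray]  # each (M_i, 3)
    ligand_ids: list[str]

    def __post_init__(self):
        for c in self.ligand_coords:
            if not np.isfinite(c).all():
                raise ValueError("ligand coordinates contain non-finite values")


@dataclass
class ContactProfile:
    """Per-residue occurrence frequency across a ligand set."""

    frequencies: pd.Series  # index: (chain, resnum, resname), values in [0, 1]
    n_ligands: int
    cutoff: float

    def to_frame(self) -> pd.DataFrame:
        df = self.frequencies.rename("frequency").reset_index()
        df.columns = ["chain", "resnum", "resname", "frequency"]
        return df


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def load_protein(path: str | Path, include_hydrogens: bool = False) -> Protein:
    """Read a PDB file into flat atom arrays (heavy atoms by default)."""
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("protein", str(path))
    coords, chains, resnums, resnames, elements = [], [], [], [], []
    model = next(structure.get_models())
    for chain in model:
        for residue in chain:
            if residue.id[0] != " ":  # skip waters / heteroatoms
                continue
            for atom in residue:
                el = (atom.element or "").strip().upper()
                if not include_hydrogens and el == "H":
                    continue
                coords.append(atom.coord)
                chains.append(chain.id)
                resnums.append(residue.id[1])
                resnames.append(residue.get_resname())
                elements.append(el)
    if not coords:
        raise ValueError(f"no atoms read from {path}")
    return Protein(coords=np.asarray(coords, dtype=float),
                   chain=np.asarray(chains), resnum=np.asarray(resnums),
                   resname=np.asarray(resnames), element=np.asarray(elements))


def load_ligand_poses(path: str | Path,
                      include_hydrogens: bool = False) -> tuple[list[np.ndarray], list[str]]:
    """Read ligand poses from SDF, MOL2 or PDB into coordinate arrays."""
    from rdkit import Chem

    path = Path(path)
    suffix = path.suffix.lower()
    mols = []
    if suffix == ".sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=not include_hydrogens,
                                      sanitize=False)
        mols = [m for m in supplier if m is not None]
    elif suffix == ".mol2":
        mol = Chem.MolFromMol2File(str(path), removeHs=not include_hydrogens,
                                   sanitize=False)
        mols = [mol] if mol is not None else []
    elif suffix == ".pdb":
        mol = Chem.MolFromPDBFile(str(path), removeHs=not include_hydrogens,
                                  sanitize=False)
        mols = [mol] if mol is not None else []
    else:
        raise ValueError(f"unsupported pose format: {suffix}")
    if not mols:
        raise ValueError(f"no ligand poses read from {path}")
    coords, ids = [], []
    for i, mol in enumerate(mols):
        conf = mol.GetConformer()
        keep = [a.GetIdx() for a in mol.GetAtoms()
                if include_hydrogens or a.GetAtomicNum() > 1]
        xyz = np.array([list(conf.GetAtomPosition(j)) for j in keep])
        coords.append(xyz)
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        ids.append(name or f"pose-{i}")
    return coords, ids


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------

def contact_residues(protein: Protein, ligand_coords: np.ndarray,
                     cutoff: float = DEFAULT_CUTOFF,
                     method: str = "kdtree") -> set[tuple[str, int, str]]:
    """Residues with any atom within ``cutoff`` (inclusive) of the ligand.

    ``method='kdtree'`` uses a spatial index; ``method='brute'`` computes
    all pairwise distances.  Both give identical results — the brute-force
    path exists as an independent cross-check.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    lig = np.asarray(ligand_coords, dtype=float)
    if lig.size == 0:
        raise ValueError("empty ligand pose")
    if method == "brute":
        d2 = ((protein.coords[:, None, :] - lig[None, :, :]) ** 2).sum(axis=2)
        hit = (d2 <= cutoff * cutoff).any(axis=1)
    elif method == "kdtree":
        tree = cKDTree(lig)
        dist, _ = tree.query(protein.coords, k=1,
                             distance_upper_bound=cutoff * (1 + 1e-12))
        hit = dist <= cutoff
    else:
        raise ValueError(f"unknown method {method!r}")
    return {(str(c), int(n), str(r))
            for c, n, r in zip(protein.chain[hit], protein.resnum[hit],
                               protein.resname[hit])}


def contact_frequencies(ps: PoseSet, cutoff: float = DEFAULT_CUTOFF,
                        method: str = "kdtree") -> ContactProfile:
    """Fraction of ligands contacting each residue.

    Every residue of the protein appears in the profile; residues no ligand
    touches get frequency 0.
    """
    if len(ps.ligand_coords) == 0:
        raise ValueError("pose set contains no ligands")
    keys = ps.protein.residue_keys
    counts = {k: 0 for k in keys}
    for lig in ps.ligand_coords:
        for k in contact_residues(ps.protein, lig, cutoff, method):
            counts[k] += 1
    n = len(ps.ligand_coords)
    idx = pd.MultiIndex.from_tuples(keys, names=["chain", "resnum", "resname"])
    freq = pd.Series([counts[k] / n for k in keys], index=idx)
    return ContactProfile(frequencies=freq, n_ligands=n, cutoff=cutoff)


def hotspot_filter(profile: ContactProfile,
                   threshold: float = 0.5) -> list[tuple[str, int, str]]:
    """Residues with frequency strictly above the threshold, sorted
    descending by frequency (ties keep protein order)."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must be in [0, 1]")
    hits = profile.frequencies[profile.frequencies > threshold]
    hits = hits.sort_values(ascending=False, kind="stable")
    return [tuple(k) for k in hits.index]


def profile_similarity(a: ContactProfile, b: ContactProfile) -> float:
    """Pearson correlation of two profiles over the union of residues
    (missing residues count as frequency 0)."""
    union = a.frequencies.index.union(b.frequencies.index)
    va = a.frequencies.reindex(union, fill_value=0.0).to_numpy()
    vb = b.frequencies.reindex(union, fill_value=0.0).to_numpy()
    if va.std() == 0 or vb.std() == 0:
        raise ValueError("constant profile: correlation undefined")
    return float(np.corrcoef(va, vb)[0, 1])


def write_pdb(protein: Protein, path: str | Path) -> None:
    """Write the atom arrays as a minimal (but column-correct) PDB file.

    Atom names are synthesized per residue as element + counter (C1, C2, ...)
    since the flat representation does not keep original names.
    """
    lines = []
    counter: dict[tuple, int] = {}
    for i in range(len(protein.coords)):
        ch = str(protein.chain[i])[:1]
        rn = int(protein.resnum[i])
        rname = str(protein.resname[i])[:3]
        el = str(protein.element[i])[:2].upper()
        key = (ch, rn, el)
        counter[key] = counter.get(key, 0) + 1
        name = f"{el}{counter[key]}"[:4]
        x, y, z = protein.coords[i]
        lines.append(
            f"ATOM  {i + 1:5d} {name:<4s} {rname:<3s} {ch}{rn:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {el:>2s}")
    Path(path).write_text("\n".join(lines) + "\nEND\n")


def write_profile(profile: ContactProfile, csv_path: str | Path,
                  json_path: str | Path | None = None) -> None:
    df = profile.to_frame()
    df.to_csv(csv_path, index=False)
    if json_path is not None:
        import json

        payload = {
            "cutoff": profile.cutoff,
            "n_ligands": profile.n_ligands,
            "frequencies": {f"{c}:{n}:{r}": f for (c, n, r), f
                            in profile.frequencies.items()},
        }
        Path(json_path).write_text(json.dumps(payload, indent=2))
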