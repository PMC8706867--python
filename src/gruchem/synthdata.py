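"""Synthetic fixtures: toy SMILES corpora, labeled descriptor data, and
miniature protein--ligand complexes.

The corpus generator assembles molecules as graphs (RDKit ``RWMol``) —
growing acyclic skeletons from C/N/O/S, attaching pre-built five- and
six-membered rings, halogen leaves, formal charges and tetrahedral stereo
centres — then emits canonical SMILES.  Because every emitted string comes
from a sanitized molecular graph, the corpus is valid by construction; no
string mutation is ever involved.

These generators stand in for the large public corpora and the curated
inhibitor tables a real campaign would use: they reproduce the *grammar*
(token inventory, ring/branch/charge/stereo syntax) and controllable class
structure, not real chemistry or bioactivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import RWMol

from gruchem.corpus import SmilesRecord, canonicalize
from gruchem.contacts import Protein, PoseSet

__all__ = [
    "CorpusSpec",
    "LabeledSpec",
    "gen_corpus",
    "gen_focused",
    "gen_labeled",
    "gen_complex",
]

_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2, "F": 1, "Cl": 1, "Br": 1, "I": 1}
_CHAIN_ATOMS = ["C", "C", "C", "C", "C", "C", "N", "O", "S"]  # C-rich mix
_HALOGENS = ["F", "Cl", "Br", "I"]

# Kekulé ring templates: (atom symbols, bond orders around the cycle)
_AROMATIC_RINGS = [
    (["C"] * 6, [2, 1, 2, 1, 2, 1]),            # benzene
    (["N", "C", "C", "C", "C", "C"], [2, 1, 2, 1, 2, 1]),  # pyridine
    (["N", "C", "C", "C", "C"], [1, 2, 1, 2, 1]),          # pyrrole -> [nH]
    (["O", "C", "C", "C", "C"], [1, 2, 1, 2, 1]),          # furan
    (["S", "C", "C", "C", "C"], [1, 2, 1, 2, 1]),          # thiophene
]
_ALIPHATIC_RINGS = [
    (["C"] * 6, [1] * 6),                        # cyclohexane
    (["C"] * 5, [1] * 5),                        # cyclopentane
    (["C", "C", "C", "C", "C", "O"], [1] * 6),   # tetrahydropyran
    (["C", "C", "C", "C", "N"], [1] * 5),        # pyrrolidine
]


@dataclass(frozen=True)
class CorpusSpec:
    """What the toy corpus should contain.

    ``length_range`` bounds the heavy-atom count; feature flags switch whole
    grammar families (rings, branches, halogens, charges, stereo) on or off.
    """

    n: int
    seed: int = 0
    rings: bool = True
    branches: bool = True
    halogens: bool = True
    charges: bool = True
    stereo: bool = True
    length_range: tuple[int, int] = (10, 16)

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid length_range")


@dataclass(frozen=True)
class LabeledSpec:
    """Two-class descriptor dataset with controllable separability.

    ``effect_size`` is the class-mean separation on each informative column
    in units of the within-class standard deviation; 0 means the classes are
    statistically identical.
    """

    n_pos: int
    n_neg: int
    effect_size: float = 2.0
    n_informative: int = 10
    n_features: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("both classes must be nonempty")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.n_informative > self.n_features:
            raise ValueError("n_informative exceeds n_features")


# ---------------------------------------------------------------------------
# molecular graph assembly
# ---------------------------------------------------------------------------

def _free_valence(mol: RWMol, idx: int) -> int:
    atom = mol.GetAtomWithIdx(idx)
    used = int(sum(b.GetBondTypeAsDouble() for b in atom.GetBonds()))
    return _VALENCE[atom.GetSymbol()] - used


def _attach_ring(mol: RWMol, at: int, template, rng) -> None:
    symbols, orders = template
    start = mol.GetNumAtoms()
    for sym in symbols:
        mol.AddAtom(Chem.Atom(sym))
    k = len(symbols)
    for i in range(k):
        bt = Chem.BondType.DOUBLE if orders[i] == 2 else Chem.BondType.SINGLE
        mol.AddBond(start + i, start + (i + 1) % k, bt)
    # bond the growth point to a ring carbon with free valence
    carbons = [start + i for i, s in enumerate(symbols)
               if s == "C" and _free_valence(mol, start + i) >= 1]
    mol.AddBond(at, int(rng.choice(carbons)), Chem.BondType.SINGLE)


def _grow_molecule(rng: np.random.Generator, spec: CorpusSpec) -> str | None:
    """One attempt at a random molecule; returns canonical SMILES or None."""
    lo, hi = spec.length_range
    target = int(rng.integers(lo, hi + 1))
    if not spec.branches:
        # an unbranched skeleton rules out rings and side groups too:
        # grow a simple heteroatom-mixed chain instead
        m = _linear_chain(rng, target, spec)
        if m is None:
            return None
        rec = canonicalize(Chem.MolToSmiles(m))
        return rec.canonical if rec.is_valid else None
    mol = RWMol()
    mol.AddAtom(Chem.Atom("C"))
    while mol.GetNumAtoms() < target:
        open_sites = [i for i in range(mol.GetNumAtoms())
                      if _free_valence(mol, i) >= 1]
        if not open_sites:
            break
        at = int(rng.choice(open_sites))
        room = target - mol.GetNumAtoms()
        r = rng.random()
        if spec.rings and room >= 5 and r < 0.18:
            pool = _AROMATIC_RINGS + (_ALIPHATIC_RINGS if room >= 5 else [])
            tpl = pool[int(rng.integers(len(pool)))]
            if len(tpl[0]) <= room:
                _attach_ring(mol, at, tpl, rng)
                continue
        if spec.halogens and r > 0.92:
            new = mol.AddAtom(Chem.Atom(_HALOGENS[int(rng.integers(4))]))
            mol.AddBond(at, new, Chem.BondType.SINGLE)
        elif r > 0.84 and _free_valence(mol, at) >= 2:
            new = mol.AddAtom(Chem.Atom("O"))  # carbonyl
            mol.AddBond(at, new, Chem.BondType.DOUBLE)
        else:
            sym = _CHAIN_ATOMS[int(rng.integers(len(_CHAIN_ATOMS)))]
            new = mol.AddAtom(Chem.Atom(sym))
            mol.AddBond(at, new, Chem.BondType.SINGLE)
    if spec.charges and rng.random() < 0.25:
        # protonate a random amine N or deprotonate a terminal O
        ns = [a.GetIdx() for a in mol.GetAtoms()
              if a.GetSymbol() == "N" and not a.IsInRing()
              and _free_valence(mol, a.GetIdx()) >= 1]
        os_ = [a.GetIdx() for a in mol.GetAtoms()
               if a.GetSymbol() == "O" and a.GetDegree() == 1]
        if ns and rng.random() < 0.5:
            mol.GetAtomWithIdx(int(rng.choice(ns))).SetFormalCharge(1)
        elif os_:
            mol.GetAtomWithIdx(int(rng.choice(os_))).SetFormalCharge(-1)
    try:
        m = mol.GetMol()
        Chem.SanitizeMol(m)
    except (Chem.AtomValenceException, Chem.KekulizeException, ValueError):
        return None
    if spec.stereo and rng.random() < 0.35:
        centers = Chem.FindMolChiralCenters(m, includeUnassigned=True,
                                            useLegacyImplementation=False)
        unassigned = [idx for idx, tag in centers if tag == "?"]
        if unassigned:
            idx = int(rng.choice(unassigned))
            tag = (Chem.ChiralType.CHI_TETRAHEDRAL_CW if rng.random() < 0.5
                   else Chem.ChiralType.CHI_TETRAHEDRAL_CCW)
            m.GetAtomWithIdx(idx).SetChiralTag(tag)
    smiles = Chem.MolToSmiles(m, isomericSmiles=True)
    rec = canonicalize(smiles)
    if not rec.is_valid or not (lo <= rec.heavy_atoms <= hi):
        return None
    return rec.canonical


def _linear_chain(rng: np.random.Generator, target: int, spec: CorpusSpec):
    mol = RWMol()
    prev = mol.AddAtom(Chem.Atom("C"))
    for _ in range(target - 1):
        sym = _CHAIN_ATOMS[int(rng.integers(len(_CHAIN_ATOMS)))]
        new = mol.AddAtom(Chem.Atom(sym))
        mol.AddBond(prev, new, Chem.BondType.SINGLE)
        prev = new
    try:
        m = mol.GetMol()
        Chem.SanitizeMol(m)
        return m
    except (Chem.AtomValenceException, ValueError):
        return None


def gen_corpus(spec: CorpusSpec) -> list[SmilesRecord]:
    """Generate ``spec.n`` unique, valid, canonical SMILES records.

    Raises if the spec is infeasible (range too narrow for the requested
    count) after a bounded number of attempts.
    """
    rng = np.random.default_rng(spec.seed)
    seen: set[str] = set()
    out: list[SmilesRecord] = []
    max_attempts = 80 * spec.n + 1000
    attempts = 0
    while len(out) < spec.n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not generate {spec.n} unique molecules in "
                f"{max_attempts} attempts; spec too narrow")
        smi = _grow_molecule(rng, spec)
        if smi is None or smi in seen:
            continue
        seen.add(smi)
        out.append(canonicalize(smi, source_id=f"synth-{len(out)}"))
    return out


def gen_focused(spec: CorpusSpec, bias: str = "aromatic_rings",
                target: float = 2.0) -> tuple[list[SmilesRecord], dict]:
    """A property-biased focused set for transfer-learning experiments.

    Generates molecules whose mean of ``bias`` (a
    :mod:`gruchem.chemspace` property name) is pushed toward ``target`` by
    rejection sampling over the corpus generator.  Returns the records plus
    a report with the achieved mean, its standard error and the unbiased
    baseline mean, so the bias margin is explicit.
    """
    from gruchem.chemspace import property_vector

    valid_names = {"hba", "hbd", "rotatable_bonds", "aromatic_rings",
                   "aliphatic_rings", "heteroatoms", "mol_weight"}
    if bias not in valid_names:
        raise ValueError(f"bias must be one of {sorted(valid_names)}")
    rng = np.random.default_rng(spec.seed)
    baseline = gen_corpus(CorpusSpec(n=min(200, 4 * spec.n), seed=spec.seed + 1,
                                     rings=spec.rings, branches=spec.branches,
                                     halogens=spec.halogens, charges=spec.charges,
                                     stereo=spec.stereo,
                                     length_range=spec.length_range))
    base_vals = [getattr(property_vector(r.canonical), bias) for r in baseline]
    base_mean = float(np.mean(base_vals))

    seen: set[str] = set()
    out: list[SmilesRecord] = []
    vals: list[float] = []
    attempts, max_attempts = 0, 300 * spec.n + 2000
    while len(out) < spec.n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(f"bias toward {bias}={target} unachievable "
                               f"with this corpus spec")
        smi = _grow_molecule(rng, spec)
        if smi is None or smi in seen:
            continue
        val = getattr(property_vector(smi), bias)
        # accept if it moves the running mean toward the target
        if abs(val - target) <= abs(base_mean - target) * 0.6 + 0.5:
            seen.add(smi)
            out.append(canonicalize(smi, source_id=f"focus-{len(out)}"))
            vals.append(val)
    arr = np.asarray(vals, dtype=float)
    report = {
        "bias": bias,
        "target": target,
        "focused_mean": float(arr.mean()),
        "focused_sem": float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else 0.0,
        "baseline_mean": base_mean,
        "margin": float(arr.mean() - base_mean),
    }
    return out, report


# ---------------------------------------------------------------------------
# labeled descriptor data
# ---------------------------------------------------------------------------

def gen_labeled(spec: LabeledSpec) -> tuple[pd.DataFrame, np.ndarray]:
    """Two Gaussian clusters on a 200-column descriptor layout.

    Informative columns get class means separated by ``effect_size`` (in sd
    units, sd = 1); all other columns are pure noise.  Returns the feature
    table (columns named like the descriptor registry) and a 0/1 label array
    (1 = positive class), positives first.
    """
    from gruchem.screen import descriptor_names

    rng = np.random.default_rng(spec.seed)
    names = descriptor_names()[: spec.n_features]
    if len(names) < spec.n_features:
        names = names + [f"synth_{i}" for i in range(len(names), spec.n_features)]
    n = spec.n_pos + spec.n_neg
    X = rng.standard_normal((n, spec.n_features))
    informative = rng.choice(spec.n_features, size=spec.n_informative,
                             replace=False)
    X[: spec.n_pos, informative] += spec.effect_size / 2.0
    X[spec.n_pos:, informative] -= spec.effect_size / 2.0
    y = np.concatenate([np.ones(spec.n_pos, dtype=int),
                        np.zeros(spec.n_neg, dtype=int)])
    df = pd.DataFrame(X, columns=names)
    df.attrs["informative_columns"] = [names[i] for i in sorted(informative)]
    return df, y


# ---------------------------------------------------------------------------
# miniature protein--ligand complexes
# ---------------------------------------------------------------------------

# N, CA, C, O relative to the residue origin (Å).  All atoms sit in the
# y = 0 plane so a ligand anchored at (CA_x, d, CA_z) is exactly d Å from
# the CA and strictly farther from every other atom of the residue.
_BACKBONE_OFFSETS = np.array([
    [0.0, 0.0, 0.0],
    [1.46, 0.0, 0.0],
    [2.9, 0.0, 0.5],
    [3.5, 0.0, -0.5],
])
_BACKBONE_NAMES = ["N", "CA", "C", "O"]
_RES_NAMES = ["ALA", "GLY", "SER", "VAL", "LEU", "THR", "ASP", "LYS"]


def gen_complex(n_residues: int, placements: Sequence[tuple[int, int, float]],
                seed: int = 0, ligand_atoms: int = 3,
                residue_spacing: float = 8.0) -> tuple[PoseSet, dict]:
    """Synthetic pose set with known ground-truth contacts.

    ``placements`` is a list of ``(ligand_index, residue_index, distance)``
    triples: ligand *i* is centred so its nearest atom sits exactly
    ``distance`` Å from the CA of residue *j* (and far from all other
    residues, which sit ``residue_spacing`` Å apart on a line).  Returns the
    PoseSet and a ground-truth map ``{ligand_id: {residue_index: distance}}``.
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    rng = np.random.default_rng(seed)
    coords, chains, resnums, resnames, elements = [], [], [], [], []
    for i in range(n_residues):
        origin = np.array([i * residue_spacing, 0.0, 0.0])
        name = _RES_NAMES[i % len(_RES_NAMES)]
        for off, aname in zip(_BACKBONE_OFFSETS, _BACKBONE_NAMES):
            coords.append(origin + off)
            chains.append("A")
            resnums.append(i + 1)
            resnames.append(name)
            elements.append(aname[0])
    protein = Protein(coords=np.asarray(coords, dtype=float),
                      chain=np.asarray(chains), resnum=np.asarray(resnums),
                      resname=np.asarray(resnames),
                      element=np.asarray(elements))

    n_ligands = 1 + max(p[0] for p in placements) if placements else 0
    ligands: list[np.ndarray] = []
    truth: dict[str, dict[int, float]] = {}
    for li in range(n_ligands):
        mine = [(res, d) for (l, res, d) in placements if l == li]
        # default: park far away on -y
        parts = []
        lig_truth: dict[int, float] = {}
        if not mine:
            parts.append(np.array([[0.0, -500.0, 0.0]]))
        for res, d in mine:
            ca = protein.coords[4 * res + 1]  # CA of residue index `res`
            anchor = ca + np.array([0.0, d, 0.0])
            cluster = [anchor]
            for _ in range(ligand_atoms - 1):
                # extra atoms strictly farther from the protein line (y grows)
                cluster.append(anchor + np.array([rng.uniform(-0.3, 0.3),
                                                  rng.uniform(0.5, 1.0),
                                                  rng.uniform(-0.3, 0.3)]))
            parts.append(np.asarray(cluster))
            lig_truth[res] = d
        ligands.append(np.vstack(parts))
        truth[f"lig-{li}"] = lig_truth
    ps = PoseSet(protein=protein, ligand_coords=ligands,
                 ligand_ids=[f"lig-{i}" for i in range(n_ligands)])
    return ps, truth
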