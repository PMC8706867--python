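"""SMILES corpus curation, tokenization and vocabulary handling.

Curation mirrors the common preprocessing of large generative-model corpora:
canonicalize every string with RDKit, keep molecules with 10--100 heavy atoms
and a canonical SMILES shorter than 140 characters, drop duplicates and any
molecule on a blocklist (e.g. known actives that must be held out of
pretraining).

Tokenization is regex based: bracket atoms ``[...]``, the two-letter organic
subset elements ``Cl``/``Br`` and ``%nn`` ring closures are single tokens;
everything else is one character.  This guarantees an exact round trip
``detokenize(tokenize(s)) == s`` for any RDKit-canonical SMILES.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger

# RDKit is chatty about unparseable strings; invalid input is an expected
# outcome of curation, not an error condition worth a console line each.
RDLogger.DisableLog("rdApp.error")

__all__ = [
    "SmilesRecord",
    "Vocabulary",
    "TokenSequence",
    "CurationReport",
    "canonicalize",
    "filter_corpus",
    "tokenize",
    "build_vocabulary",
    "read_smiles",
    "write_smiles",
    "curate_file",
]

BOS = "<bos>"
EOS = "<eos>"
PAD = "<pad>"

# Bracket atoms, two-letter halogens, %nn ring closures, then any single char.
_TOKEN_RE = re.compile(r"\[[^\]]+\]|Br|Cl|%\d{2}|.")

DEFAULT_MIN_HEAVY = 10
DEFAULT_MAX_HEAVY = 100
DEFAULT_MAX_LEN = 140


@dataclass(frozen=True)
class SmilesRecord:
    """One molecule: the raw string plus its canonical form and validity."""

    raw: str
    canonical: str | None
    heavy_atoms: int
    is_valid: bool
    source_id: str | None = None


@dataclass(frozen=True)
class TokenSequence:
    """An encoded SMILES: BOS + chemical-token indices + EOS."""

    indices: tuple[int, ...]

    @property
    def length(self) -> int:
        return len(self.indices)


@dataclass
class CurationReport:
    """Counts of records removed per curation rule."""

    n_input: int = 0
    n_invalid: int = 0
    n_heavy_out_of_range: int = 0
    n_too_long: int = 0
    n_blocklisted: int = 0
    n_duplicate: int = 0
    n_kept: int = 0

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


def canonicalize(raw: str, source_id: str | None = None) -> SmilesRecord:
    """Parse ``raw`` and return its canonical (isomeric) SMILES record.

    Never raises on unparseable input: the record comes back with
    ``is_valid=False`` and no canonical string.  Charges and stereo markers
    are preserved (ionic and isomeric molecules stay ionic and isomeric).
    """
    if not raw or not raw.strip():
        raise ValueError("empty SMILES input")
    mol = Chem.MolFromSmiles(raw)
    if mol is None:
        return SmilesRecord(raw=raw, canonical=None, heavy_atoms=0,
                            is_valid=False, source_id=source_id)
    canonical = Chem.MolToSmiles(mol, isomericSmiles=True)
    return SmilesRecord(raw=raw, canonical=canonical,
                        heavy_atoms=mol.GetNumHeavyAtoms(),
                        is_valid=True, source_id=source_id)


def filter_corpus(
    records: Iterable[SmilesRecord],
    blocklist: Iterable[str] = (),
    min_heavy: int = DEFAULT_MIN_HEAVY,
    max_heavy: int = DEFAULT_MAX_HEAVY,
    max_len: int = DEFAULT_MAX_LEN,
    report: CurationReport | None = None,
) -> list[SmilesRecord]:
    """Apply the corpus curation rules and deduplicate on canonical SMILES.

    Keeps valid records with ``min_heavy <= heavy_atoms <= max_heavy`` whose
    canonical string is shorter than ``max_len`` characters and not on the
    blocklist.  The blocklist is compared in canonical form, so callers may
    pass raw SMILES.  Pass a :class:`CurationReport` to collect per-rule
    removal counts.
    """
    block: set[str] = set()
    for s in blocklist:
        rec = s if isinstance(s, SmilesRecord) else canonicalize(s)
        if rec.is_valid:
            block.add(rec.canonical)
    if report is None:
        report = CurationReport()
    seen: set[str] = set()
    kept: list[SmilesRecord] = []
    for rec in records:
        report.n_input += 1
        if not rec.is_valid or rec.canonical is None:
            report.n_invalid += 1
            continue
        if not (min_heavy <= rec.heavy_atoms <= max_heavy):
            report.n_heavy_out_of_range += 1
            continue
        if len(rec.canonical) >= max_len:
            report.n_too_long += 1
            continue
        if rec.canonical in block:
            report.n_blocklisted += 1
            continue
        if rec.canonical in seen:
            report.n_duplicate += 1
            continue
        seen.add(rec.canonical)
        kept.append(rec)
    report.n_kept = len(kept)
    return kept


def tokenize(s: str) -> list[str]:
    """Split a SMILES string into chemical tokens (no specials)."""
    tokens = _TOKEN_RE.findall(s)
    if "".join(tokens) != s:  # pragma: no cover - regex covers all chars
        raise ValueError(f"tokenization failed to cover {s!r}")
    return tokens


class Vocabulary:
    """Bijective token <-> index mapping with PAD/BOS/EOS specials.

    Index 0 is PAD so padded batches are zero-filled; chemical tokens are
    stored sorted, which makes the vocabulary a deterministic function of the
    corpus token set.
    """

    def __init__(self, chemical_tokens: Sequence[str]):
        uniq = sorted(set(chemical_tokens))
        for sp in (PAD, BOS, EOS):
            if sp in uniq:
                raise ValueError(f"special token {sp!r} found in corpus tokens")
        self.tokens: list[str] = [PAD, BOS, EOS] + uniq
        self._index = {t: i for i, t in enumerate(self.tokens)}

    # -- specials ---------------------------------------------------------
    @property
    def pad(self) -> int:
        return self._index[PAD]

    @property
    def bos(self) -> int:
        return self._index[BOS]

    @property
    def eos(self) -> int:
        return self._index[EOS]

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self._index

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Vocabulary) and self.tokens == other.tokens

    def index_of(self, token: str) -> int:
        return self._index[token]

    # -- encode / decode --------------------------------------------------
    def encode(self, s: str) -> TokenSequence:
        """BOS + token indices + EOS.  Raises KeyError naming any OOV token."""
        idx = [self.bos]
        for tok in tokenize(s):
            if tok not in self._index:
                raise KeyError(f"token {tok!r} not in vocabulary")
            idx.append(self._index[tok])
        idx.append(self.eos)
        return TokenSequence(indices=tuple(idx))

    def decode(self, t: TokenSequence | Sequence[int]) -> str:
        """Inverse of :meth:`encode`; strips specials."""
        indices = t.indices if isinstance(t, TokenSequence) else t
        out = []
        for i in indices:
            tok = self.tokens[i]
            if tok == EOS:
                break
            if tok in (BOS, PAD):
                continue
            out.append(tok)
        return "".join(out)

    # -- persistence ------------------------------------------------------
    def to_dict(self) -> dict:
        return {"tokens": self.tokens}

    @classmethod
    def from_dict(cls, d: dict) -> "Vocabulary":
        v = cls.__new__(cls)
        v.tokens = list(d["tokens"])
        v._index = {t: i for i, t in enumerate(v.tokens)}
        return v


def build_vocabulary(records: Iterable[SmilesRecord | str]) -> Vocabulary:
    """Collect every chemical token occurring in the corpus."""
    tokens: set[str] = set()
    n = 0
    for rec in records:
        s = rec if isinstance(rec, str) else rec.canonical
        if s is None:
            continue
        tokens.update(tokenize(s))
        n += 1
    if n == 0:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    return Vocabulary(sorted(tokens))


# ---------------------------------------------------------------------------
# File I/O: line-delimited .smi (optional second column = id) and CSV.
# ---------------------------------------------------------------------------

def read_smiles(path: str | Path, smiles_column: str = "smiles") -> list[SmilesRecord]:
    """Read SMILES from ``.smi`` (whitespace-separated, optional id column)
    or ``.csv`` (named SMILES column, optional ``id`` column)."""
    path = Path(path)
    records: list[SmilesRecord] = []
    if path.suffix.lower() == ".csv":
        import pandas as pd

        df = pd.read_csv(path)
        if smiles_column not in df.columns:
            raise ValueError(f"column {smiles_column!r} not in {path}")
        ids = df["id"].astype(str) if "id" in df.columns else [None] * len(df)
        for s, i in zip(df[smiles_column], ids):
            records.append(canonicalize(str(s), source_id=i))
    else:
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                sid = parts[1] if len(parts) > 1 else None
                records.append(canonicalize(parts[0], source_id=sid))
    return records


def write_smiles(records: Iterable[SmilesRecord], path: str | Path) -> None:
    """Write canonical SMILES, one per line, with ids where present."""
    with open(path, "w") as fh:
        for rec in records:
            s = rec.canonical if rec.is_valid else rec.raw
            if rec.source_id:
                fh.write(f"{s}\t{rec.source_id}\n")
            else:
                fh.write(f"{s}\n")


def curate_file(
    in_path: str | Path,
    out_path: str | Path,
    blocklist_path: str | Path | None = None,
    min_heavy: int = DEFAULT_MIN_HEAVY,
    max_heavy: int = DEFAULT_MAX_HEAVY,
    max_len: int = DEFAULT_MAX_LEN,
    report_path: str | Path | None = None,
) -> CurationReport:
    """End-to-end curation of one file; returns (and optionally writes) the
    per-rule removal report."""
    records = read_smiles(in_path)
    blocklist = []
    if blocklist_path is not None:
        blocklist = [r.canonical for r in read_smiles(blocklist_path) if r.is_valid]
    report = CurationReport()
    kept = filter_corpus(records, blocklist, min_heavy, max_heavy, max_len, report)
    write_smiles(kept, out_path)
    if report_path is not None:
        Path(report_path).write_text(report.to_json())
    return report
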