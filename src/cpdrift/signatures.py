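"""Signature molecular descriptor: canonical atom-rooted fragment counts.

For every heavy atom and every height h in {1, 2, 3}, the induced subgraph
of atoms within h bonds of that atom is encoded as a canonical rooted
string and counted.  A molecule with N heavy atoms therefore contributes
exactly N rooted fragments per height.  Test/score molecules are encoded
against the fragment vocabulary of the *training* set: novel fragments are
silently dropped.

Canonical encoding
------------------
The canonical form of a rooted fragment is the lexicographically minimal
depth-first traversal string over all possible DFS orders, found by exact
branch-and-bound search.  Atom token = element symbol plus formal-charge
signs ("N+", "O-"); bond tokens are "-", "=", "#", ":" (aromatic).  Each
branch is parenthesised; a ring-closure bond is emitted at the later-visited
endpoint as ``<bond>@<visit index>``.  The string is decodable back to the
rooted graph, so two fragments share a canonical string iff they are
isomorphic as rooted labelled graphs, and the encoding is invariant under
any relabelling of the molecule's atom indices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from rdkit import Chem
from scipy import sparse
from scipy.io import mmread, mmwrite

logger = logging.getLogger(__name__)

__all__ = [
    "SignatureKey",
    "SignatureMatrix",
    "enumerate_signatures",
    "build_vocabulary",
    "featurise",
    "write_signature_matrix",
    "read_signature_matrix",
    "DEFAULT_HEIGHTS",
]

DEFAULT_HEIGHTS: tuple[int, ...] = (1, 2, 3)

_BOND_TOKENS = {
    Chem.BondType.SINGLE: "-",
    Chem.BondType.DOUBLE: "=",
    Chem.BondType.TRIPLE: "#",
    Chem.BondType.AROMATIC: ":",
}


@dataclass(frozen=True, order=True)
class SignatureKey:
    height: int
    canon: str


@dataclass
class SignatureMatrix:
    """Sparse count matrix over a fixed fragment vocabulary."""

    vocabulary: list[SignatureKey]
    counts: sparse.csr_matrix
    row_ids: list[str]

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.row_ids), len(self.vocabulary)):
            raise ValueError("counts shape does not match row_ids x vocabulary")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("signature counts must be nonnegative")


def _atom_token(atom: Chem.Atom) -> str:
    tok = atom.GetSymbol()
    c = atom.GetFormalCharge()
    if c > 0:
        tok += "+" * c
    elif c < 0:
        tok += "-" * (-c)
    return tok


def _bond_token(bond: Chem.Bond) -> str:
    return _BOND_TOKENS.get(bond.GetBondType(), "~")


def _rooted_canon(
    adj: Mapping[int, list[tuple[int, str]]],
    atom_tok: Mapping[int, str],
    root: int,
) -> str:
    """Lexicographically minimal DFS string of a connected rooted graph.

    Exact search over DFS orders: at every node the unvisited neighbours are
    tried in every order, pruned against the best complete string found so
    far.  Ring closures are emitted on arrival at the later endpoint, sorted
    by (visit index, bond token), so they involve no search choice.
    """
    best: str | None = None

    def closures(v: int, parent: int, vindex: dict[int, int]) -> list[str]:
        back = [
            (vindex[w], bt)
            for (w, bt) in adj[v]
            if w in vindex and w != parent
        ]
        back.sort()
        return [f"{bt}@{i}" for i, bt in back]

    def rec(agenda: list[tuple[int, int]], vindex: dict[int, int], cur: str) -> None:
        # agenda entries: (node, its tree parent); root's parent is -1
        nonlocal best
        while True:
            if best is not None and cur > best[: len(cur)]:
                return
            if not agenda:
                if best is None or cur < best:
                    best = cur
                return
            u, _ = agenda[-1]
            cands = [(bt, v) for (v, bt) in adj[u] if v not in vindex]
            if not cands:
                agenda = agenda[:-1]
                if agenda:
                    cur += ")"
                continue
            cands.sort(key=lambda c: c[0] + atom_tok[c[1]])
            if len(cands) == 1:
                bt, v = cands[0]
                vindex = dict(vindex)
                vindex[v] = len(vindex)
                cur += "(" + bt + atom_tok[v] + "".join(closures(v, u, vindex))
                agenda = agenda + [(v, u)]
                continue
            for bt, v in cands:
                vi = dict(vindex)
                vi[v] = len(vi)
                rec(
                    agenda + [(v, u)],
                    vi,
                    cur + "(" + bt + atom_tok[v] + "".join(closures(v, u, vi)),
                )
            return

    rec([(root, -1)], {root: 0}, atom_tok[root])
    assert best is not None
    return best


def enumerate_signatures(
    mol: Chem.Mol, heights: Iterable[int] = DEFAULT_HEIGHTS
) -> dict[SignatureKey, int]:
    """Count canonical rooted fragments of ``mol`` at the given heights.

    For each height h the number of fragments (with multiplicity) equals
    the number of heavy atoms.  An empty or None molecule yields {}.
    """
    if mol is None or mol.GetNumAtoms() == 0:
        return {}
    n = mol.GetNumAtoms()
    atom_tok = {a.GetIdx(): _atom_token(a) for a in mol.GetAtoms()}
    adj_full: dict[int, list[tuple[int, str]]] = {i: [] for i in range(n)}
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        bt = _bond_token(bond)
        adj_full[i].append((j, bt))
        adj_full[j].append((i, bt))
    dist = Chem.GetDistanceMatrix(mol)

    counts: dict[SignatureKey, int] = {}
    for h in sorted(set(heights)):
        if h < 1:
            raise ValueError("signature heights must be >= 1")
        for root in range(n):
            nodes = {i for i in range(n) if dist[root][i] <= h}
            adj = {
                u: [(v, bt) for (v, bt) in adj_full[u] if v in nodes]
                for u in nodes
            }
            key = SignatureKey(h, _rooted_canon(adj, atom_tok, root))
            counts[key] = counts.get(key, 0) + 1
    return counts


def build_vocabulary(
    molecules: Iterable[Chem.Mol], heights: Iterable[int] = DEFAULT_HEIGHTS
) -> list[SignatureKey]:
    """Union of all signature keys over the training molecules.

    Deterministically ordered lexicographically by (height, canon); the
    vocabulary fixes the descriptor space for any later featurisation.
    """
    keys: set[SignatureKey] = set()
    for mol in molecules:
        keys.update(enumerate_signatures(mol, heights))
    return sorted(keys)


def featurise(
    molecules: Sequence[Chem.Mol],
    vocabulary: Sequence[SignatureKey],
    heights: Iterable[int] = DEFAULT_HEIGHTS,
    row_ids: Sequence[str] | None = None,
    binary: bool = False,
) -> SignatureMatrix:
    """Encode molecules against a fixed vocabulary as a sparse count matrix.

    Fragments absent from the vocabulary are dropped; a molecule sharing no
    fragment with the vocabulary yields an all-zero row (kept, logged).
    With ``binary=True`` counts are clipped to presence/absence.
    """
    index = {key: j for j, key in enumerate(vocabulary)}
    rows, cols, data = [], [], []
    for i, mol in enumerate(molecules):
        sig = enumerate_signatures(mol, heights)
        hit = False
        for key, count in sig.items():
            j = index.get(key)
            if j is not None:
                rows.append(i)
                cols.append(j)
                data.append(1 if binary else count)
                hit = True
        if not hit:
            logger.info("molecule %d shares no fragment with the vocabulary", i)
    counts = sparse.csr_matrix(
        (data, (rows, cols)),
        shape=(len(molecules), len(vocabulary)),
        dtype=np.int64,
    )
    ids = list(row_ids) if row_ids is not None else [str(i) for i in range(len(molecules))]
    return SignatureMatrix(vocabulary=list(vocabulary), counts=counts, row_ids=ids)


def write_signature_matrix(sm: SignatureMatrix, mtx_path, vocab_path, ids_path) -> None:
    """Write MTX matrix plus sidecar vocabulary and row-id text files."""
    mmwrite(str(mtx_path), sm.counts)
    with open(vocab_path, "w") as fh:
        for key in sm.vocabulary:
            fh.write(f"{key.height}\t{key.canon}\n")
    with open(ids_path, "w") as fh:
        for rid in sm.row_ids:
            fh.write(f"{rid}\n")


def read_signature_matrix(mtx_path, vocab_path, ids_path=None) -> SignatureMatrix:
    """Read a (possibly pre-computed) fingerprint matrix with sidecars.

    Vocabulary lines are either ``height<TAB>canon`` or a bare fragment
    string per line (pre-computed matrices from other tools); bare lines
    get height 0 recorded as "unknown".
    """
    counts = sparse.csr_matrix(mmread(str(mtx_path)))
    vocabulary = []
    with open(vocab_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if "\t" in line:
                h, canon = line.split("\t", 1)
                vocabulary.append(SignatureKey(int(h), canon))
            else:
                vocabulary.append(SignatureKey(0, line))
    if ids_path is not None:
        with open(ids_path) as fh:
            row_ids = [line.rstrip("\n") for line in fh if line.strip()]
    else:
        row_ids = [str(i) for i in range(counts.shape[0])]
    return SignatureMatrix(vocabulary=vocabulary, counts=counts, row_ids=row_ids)
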