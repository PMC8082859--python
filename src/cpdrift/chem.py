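"""Molecule standardisation and per-endpoint dataset cleaning.

Raw screening records (SDF or SMILES + label columns, "X" = missing) are
turned into clean, deduplicated per-endpoint datasets:

1. drop records whose label for the endpoint is missing;
2. discard InChI duplicates with disagreeing labels (pre-standardisation);
3. standardise each structure — keep the largest covalently connected
   organic fragment (salt strip), neutralise common charged groups, reject
   structures with no carbon or fewer than four heavy atoms;
4. repeat the conflicting-duplicate check on the standardised InChIs, since
   distinct parents can collapse to one structure after salt stripping.

"Organic" is operationalised as "contains at least one carbon atom after
salt stripping".  Neutralisation follows a fixed SMARTS rule (protonate
anions / deprotonate cations whose valence allows it); charges that cannot
be neutralised that way, e.g. quaternary ammoniums or nitro groups, are
kept as-is rather than rejected.  Identity is the standard InChI string of
the standardised structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Mol

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

MISSING = None  # sentinel for a missing label

__all__ = [
    "RawRecord",
    "MoleculeRecord",
    "Rejection",
    "PreprocessReport",
    "standardise",
    "deduplicate",
    "preprocess_dataset",
    "read_sdf",
    "read_smiles_csv",
    "write_records_csv",
    "write_report_csv",
]


@dataclass
class RawRecord:
    structure: Mol | None
    labels: dict[str, int | None]
    source_id: str = ""


@dataclass
class MoleculeRecord:
    structure: Mol
    inchi: str
    labels: dict[str, int | None]
    source_id: str = ""
    provenance: str = ""


@dataclass(frozen=True)
class Rejection:
    source_id: str
    reason: str  # non_organic | too_small | unparseable


@dataclass
class PreprocessReport:
    """Counts of removals per reason; |input| = |output| + sum of counts."""

    missing_label: int = 0
    unparseable: int = 0
    non_organic: int = 0
    too_small: int = 0
    conflict_pre: int = 0
    duplicate_pre: int = 0
    conflict_post: int = 0
    duplicate_post: int = 0

    def total(self) -> int:
        return sum(vars(self).values())


# protonate anions / deprotonate cations where valence allows; the pattern
# excludes zwitterionic partners so internal salts stay untouched
_NEUTRALISE = Chem.MolFromSmarts(
    "[+1!h0!$([*]~[-1,-2,-3,-4]),-1!$([*]~[+1,+2,+3,+4])]"
)


def _neutralise(mol: Mol) -> Mol:
    matches = [i for (i,) in mol.GetSubstructMatches(_NEUTRALISE)]
    if not matches:
        return mol
    mol = Chem.RWMol(mol)
    for idx in matches:
        atom = mol.GetAtomWithIdx(idx)
        charge = atom.GetFormalCharge()
        h = atom.GetTotalNumHs()
        atom.SetFormalCharge(0)
        atom.SetNumExplicitHs(max(0, h - charge))
        atom.UpdatePropertyCache()
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    return out


def standardise(record: RawRecord) -> MoleculeRecord | Rejection:
    """Standardise one raw record or return a reasoned rejection.

    Keeps the largest organic (carbon-containing) fragment, neutralises
    common charged groups, requires at least four heavy atoms, and attaches
    the standard InChI of the result.  Never raises for a bad structure.
    """
    mol = record.structure
    if mol is None:
        return Rejection(record.source_id, "unparseable")
    try:
        frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
        organic = []
        for f in frags:
            if any(a.GetAtomicNum() == 6 for a in f.GetAtoms()):
                organic.append(f)
        if not organic:
            return Rejection(record.source_id, "non_organic")
        organic.sort(
            key=lambda f: (f.GetNumHeavyAtoms(), Chem.MolToSmiles(f)), reverse=True
        )
        frag = organic[0]
        Chem.SanitizeMol(frag)
        frag = _neutralise(frag)
        frag = Chem.RemoveHs(frag)
        if frag.GetNumHeavyAtoms() < 4:
            return Rejection(record.source_id, "too_small")
        inchi = Chem.MolToInchi(frag)
        if not inchi:
            return Rejection(record.source_id, "unparseable")
    except Exception:  # RDKit sanitisation failures count as unparseable
        return Rejection(record.source_id, "unparseable")
    return MoleculeRecord(
        structure=frag,
        inchi=inchi,
        labels=dict(record.labels),
        source_id=record.source_id,
    )


def _dedup_by_key(
    records: Sequence,
    keys: Sequence[str],
    endpoint: str,
) -> tuple[list, int, int]:
    """Generic conflict-aware dedup; returns (survivors, n_conflict, n_dup)."""
    by_key: dict[str, list[int]] = {}
    for i, k in enumerate(keys):
        by_key.setdefault(k, []).append(i)
    survivors, n_conflict, n_dup = [], 0, 0
    for k, idxs in by_key.items():
        labels = {records[i].labels.get(endpoint) for i in idxs} - {MISSING}
        if labels == {0, 1}:
            n_conflict += len(idxs)  # all copies of a conflicting InChI go
            continue
        survivors.append(idxs[0])  # first-seen record keeps its provenance
        n_dup += len(idxs) - 1
    survivors.sort()
    return [records[i] for i in survivors], n_conflict, n_dup


def deduplicate(
    records: Sequence[MoleculeRecord], endpoint: str
) -> list[MoleculeRecord]:
    """Drop all copies of InChIs carrying both labels; merge agreeing ones."""
    out, _, _ = _dedup_by_key(records, [r.inchi for r in records], endpoint)
    return out


def preprocess_dataset(
    raw: Iterable[RawRecord], endpoint: str
) -> tuple[list[MoleculeRecord], PreprocessReport]:
    """Full cleaning pipeline for one endpoint.

    dedup (raw InChIs) -> standardise -> dedup (standardised InChIs); the
    conflict check runs both before and after standardisation because salt
    stripping can merge distinct parents.  Records with a missing label for
    the endpoint are dropped first.  The report accounts for every removal.
    """
    report = PreprocessReport()
    labelled: list[RawRecord] = []
    for r in raw:
        if r.labels.get(endpoint) is MISSING:
            report.missing_label += 1
        else:
            labelled.append(r)

    # pre-standardisation conflict check on raw-structure InChIs; records
    # whose raw structure cannot be parsed skip this stage (rejected below)
    keys = []
    parseable = []
    unparseable_raw = []
    for r in labelled:
        inchi = Chem.MolToInchi(r.structure) if r.structure is not None else None
        if inchi:
            parseable.append(r)
            keys.append(inchi)
        else:
            unparseable_raw.append(r)
    kept, n_conf, n_dup = _dedup_by_key(parseable, keys, endpoint)
    report.conflict_pre += n_conf
    report.duplicate_pre += n_dup

    std: list[MoleculeRecord] = []
    for r in list(kept) + unparseable_raw:
        result = standardise(r)
        if isinstance(result, Rejection):
            setattr(report, result.reason, getattr(report, result.reason) + 1)
        else:
            std.append(result)

    out, n_conf, n_dup = _dedup_by_key(std, [r.inchi for r in std], endpoint)
    report.conflict_post += n_conf
    report.duplicate_post += n_dup
    return out, report


# ---------------------------------------------------------------------------
# readers / writers


def _parse_label(value) -> int | None:
    if value is None:
        return MISSING
    s = str(value).strip()
    if s in ("", "X", "x", "nan", "NaN"):
        return MISSING
    return int(float(s))


def read_sdf(path, endpoints: Sequence[str]) -> list[RawRecord]:
    """Read an SDF with one property block per endpoint ('X' = missing)."""
    supplier = Chem.SDMolSupplier(str(path), sanitize=False)
    records = []
    for i, mol in enumerate(supplier):
        labels: dict[str, int | None] = {}
        source_id = f"sdf:{i}"
        if mol is not None:
            if mol.HasProp("_Name") and mol.GetProp("_Name"):
                source_id = mol.GetProp("_Name")
            for ep in endpoints:
                labels[ep] = _parse_label(mol.GetProp(ep)) if mol.HasProp(ep) else MISSING
            try:
                Chem.SanitizeMol(mol)
            except Exception:
                mol = None
        else:
            labels = {ep: MISSING for ep in endpoints}
        records.append(RawRecord(structure=mol, labels=labels, source_id=source_id))
    return records


def read_smiles_csv(
    path, smiles_column: str = "smiles", endpoints: Sequence[str] | None = None
) -> list[RawRecord]:
    """Read a CSV with a SMILES column plus one label column per endpoint."""
    df = pd.read_csv(path, dtype=str)
    if smiles_column not in df.columns:
        raise ValueError(f"no column {smiles_column!r} in {path}")
    eps = list(endpoints) if endpoints is not None else [
        c for c in df.columns if c not in (smiles_column, "id")
    ]
    records = []
    for i, row in df.iterrows():
        smi = row[smiles_column]
        mol = Chem.MolFromSmiles(smi) if isinstance(smi, str) else None
        labels = {ep: _parse_label(row.get(ep)) for ep in eps}
        source_id = str(row["id"]) if "id" in df.columns else f"csv:{i}"
        records.append(RawRecord(structure=mol, labels=labels, source_id=source_id))
    return records


def records_from_smiles(
    pairs: Iterable[tuple[str, int | None]], endpoint: str = "endpoint"
) -> list[RawRecord]:
    """Convenience constructor from (SMILES, label) pairs."""
    return [
        RawRecord(
            structure=Chem.MolFromSmiles(smi),
            labels={endpoint: label},
            source_id=f"smi:{i}",
        )
        for i, (smi, label) in enumerate(pairs)
    ]


def write_records_csv(records: Sequence[MoleculeRecord], path, endpoints=None) -> None:
    eps = list(endpoints) if endpoints else sorted(
        {k for r in records for k in r.labels}
    )
    rows = []
    for r in records:
        row = {
            "inchi": r.inchi,
            "smiles": Chem.MolToSmiles(r.structure),
            "batch": r.provenance,
        }
        for ep in eps:
            v = r.labels.get(ep)
            row[ep] = "X" if v is MISSING else v
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_report_csv(report: PreprocessReport, path) -> None:
    pd.DataFrame([vars(report)]).to_csv(path, index=False)
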