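"""SMILES dataset preparation: parsing, canonicalization, structural and
activity filtering, fingerprint-based deduplication, and stereoisomer
enumeration.

The preprocessing contract for all downstream models is: keep only
molecules whose SMILES parse, whose raw string is shorter than 100
characters, and which encode a single fragment (no '.'); optionally drop
candidates too similar (Morgan/Tanimoto) to a reference set, molecules
below a potency floor (pChEMBL), and molecules above a molecular-weight
ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors
from rdkit.Chem.EnumerateStereoisomers import (
    EnumerateStereoisomers,
    StereoEnumerationOptions,
)
from rdkit.Chem import rdFingerprintGenerator
from rdkit import DataStructs

RDLogger.DisableLog("rdApp.*")  # parse failures are data, not console noise

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


class SmilesParseError(ValueError):
    """Raised when an operation requires a valid SMILES but parsing failed."""


@dataclass(frozen=True)
class MoleculeRecord:
    """One input molecule and its parse/canonicalization outcome."""

    raw_smiles: str
    parse_ok: bool
    canonical_smiles: Optional[str] = None
    label: Optional[str] = None  # "positive" | "negative" | None (unlabeled)
    meta: Optional[str] = None   # free-text second column (id or activity)

    @property
    def n_chars(self) -> int:
        return len(self.raw_smiles)

    @property
    def is_multi_fragment(self) -> bool:
        return "." in self.raw_smiles


@dataclass(frozen=True)
class FilterPolicy:
    """Thresholds of the dataset-cleaning pipeline.

    max_smiles_len is an exclusive bound on the raw string length;
    tanimoto_exclusion_threshold applies to Morgan(r=2, 2048 bit)
    fingerprints; pchembl_min only applies to records that carry an
    activity value; mw_max is an average-molecular-weight ceiling.
    """

    max_smiles_len: int = 100
    require_single_fragment: bool = True
    tanimoto_exclusion_threshold: float = 0.8
    pchembl_min: float = 5.85
    mw_max: float = 600.0

    def __post_init__(self):
        if not 0.0 <= self.tanimoto_exclusion_threshold <= 1.0:
            raise ValueError("tanimoto_exclusion_threshold must lie in [0, 1]")
        if self.max_smiles_len < 1:
            raise ValueError("max_smiles_len must be positive")


# --------------------------------------------------------------- parsing

def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"not a valid SMILES: {smiles!r}")
    return mol


def canonicalize(smiles: str) -> str:
    """Isomeric canonical SMILES (RDKit canonical form); idempotent."""
    return Chem.MolToSmiles(_mol_from_smiles(smiles), isomericSmiles=True)


def make_record(raw: str, label: Optional[str] = None,
                meta: Optional[str] = None) -> MoleculeRecord:
    mol = Chem.MolFromSmiles(raw)
    if mol is None:
        return MoleculeRecord(raw_smiles=raw, parse_ok=False, label=label, meta=meta)
    return MoleculeRecord(
        raw_smiles=raw, parse_ok=True,
        canonical_smiles=Chem.MolToSmiles(mol, isomericSmiles=True),
        label=label, meta=meta)


def parse_smiles_file(path: str | Path, label: Optional[str] = None
                      ) -> list[MoleculeRecord]:
    """Read one SMILES per line (optional tab/comma second column).

    Parse failures yield records with parse_ok=False rather than raising;
    empty lines are skipped; file order is preserved.
    """
    path = Path(path)
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise IOError(f"cannot read SMILES file {path}: {exc}") from exc
    records = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        for sep in ("\t", ","):
            if sep in line:
                smiles, meta = line.split(sep, 1)
                break
        else:
            smiles, meta = line, None
        records.append(make_record(smiles.strip(), label=label,
                                   meta=meta.strip() if meta else None))
    return records


# -------------------------------------------------------------- filtering

def passes_structural_filters(record: MoleculeRecord,
                              policy: FilterPolicy = FilterPolicy()) -> bool:
    if not record.parse_ok:
        return False
    if record.n_chars >= policy.max_smiles_len:
        return False
    if policy.require_single_fragment and record.is_multi_fragment:
        return False
    return True


def rejection_reason(record: MoleculeRecord,
                     policy: FilterPolicy = FilterPolicy()) -> Optional[str]:
    """Why a record fails the structural filters; None if it passes."""
    if not record.parse_ok:
        return "unparseable"
    if record.n_chars >= policy.max_smiles_len:
        return "too_long"
    if policy.require_single_fragment and record.is_multi_fragment:
        return "multi_fragment"
    return None


def molecular_weight(record: MoleculeRecord) -> float:
    if not record.parse_ok:
        raise SmilesParseError(f"not a valid SMILES: {record.raw_smiles!r}")
    return Descriptors.MolWt(_mol_from_smiles(record.canonical_smiles))


def apply_activity_filters(records: Sequence[MoleculeRecord],
                           activity: Sequence[Optional[float]] | None = None,
                           policy: FilterPolicy = FilterPolicy()
                           ) -> list[MoleculeRecord]:
    """Keep records with activity >= pchembl_min (where given) and
    molecular weight <= mw_max; order preserved."""
    if activity is None:
        activity = [None] * len(records)
    if len(activity) != len(records):
        raise ValueError("activity must align with records")
    kept = []
    for rec, act in zip(records, activity):
        if act is not None and act < policy.pchembl_min:
            continue
        if molecular_weight(rec) > policy.mw_max:
            continue
        kept.append(rec)
    return kept


# ---------------------------------------------------------- deduplication

def _fingerprint(record: MoleculeRecord):
    if not record.parse_ok:
        raise SmilesParseError(f"not a valid SMILES: {record.raw_smiles!r}")
    return _MORGAN.GetFingerprint(_mol_from_smiles(record.canonical_smiles))


def tanimoto_dedup(candidates: Sequence[MoleculeRecord],
                   reference: Sequence[MoleculeRecord],
                   threshold: float = 0.8) -> list[MoleculeRecord]:
    """Drop candidates whose max Tanimoto similarity to any reference
    molecule reaches `threshold`; candidate order preserved."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    ref_fps = [_fingerprint(r) for r in reference]
    if not ref_fps:
        return list(candidates)
    kept = []
    for cand in candidates:
        sims = DataStructs.BulkTanimotoSimilarity(_fingerprint(cand), ref_fps)
        if max(sims) < threshold:
            kept.append(cand)
    return kept


# --------------------------------------------------------- stereoisomers

def enumerate_stereoisomers(smiles: str, cap: int = 32) -> list[str]:
    """Canonical isomeric SMILES of the distinct stereoisomers obtained by
    assigning unspecified stereocenters/double-bond geometry.

    Returns at most `cap` strings in sorted (hence deterministic) order;
    a molecule with no unassigned stereo elements yields exactly its own
    canonical form.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    mol = _mol_from_smiles(smiles)
    opts = StereoEnumerationOptions(onlyUnassigned=True, unique=True,
                                    maxIsomers=cap, rand=0x5EED)
    isomers = {Chem.MolToSmiles(m, isomericSmiles=True)
               for m in EnumerateStereoisomers(mol, options=opts)}
    if not isomers:  # RDKit yields nothing for some fully-assigned inputs
        isomers = {Chem.MolToSmiles(mol, isomericSmiles=True)}
    return sorted(isomers)[:cap]


# -------------------------------------------------------------- pipeline

def preprocess(records: Iterable[MoleculeRecord],
               reference: Sequence[MoleculeRecord] = (),
               activity: Sequence[Optional[float]] | None = None,
               policy: FilterPolicy = FilterPolicy(),
               apply_activity: bool = False,
               ) -> tuple[list[MoleculeRecord], list[tuple[str, str]]]:
    """Full cleaning pipeline; returns (survivors, audit log).

    The audit log lists (raw_smiles, reason) for every rejected record.
    """
    records = list(records)
    audit: list[tuple[str, str]] = []
    structural: list[MoleculeRecord] = []
    struct_activity: list[Optional[float]] = []
    acts = list(activity) if activity is not None else [None] * len(records)
    if len(acts) != len(records):
        raise ValueError("activity must align with records")
    for rec, act in zip(records, acts):
        reason = rejection_reason(rec, policy)
        if reason is not None:
            audit.append((rec.raw_smiles, reason))
        else:
            structural.append(rec)
            struct_activity.append(act)
    survivors = structural
    if apply_activity:
        before = survivors
        survivors = apply_activity_filters(before, struct_activity, policy)
        kept = {id(r) for r in survivors}
        audit.extend((r.raw_smiles, "activity_or_mw")
                     for r in before if id(r) not in kept)
    if reference:
        before = survivors
        survivors = tanimoto_dedup(before, reference,
                                   policy.tanimoto_exclusion_threshold)
        kept = {id(r) for r in survivors}
        audit.extend((r.raw_smiles, "tanimoto_similar_to_reference")
                     for r in before if id(r) not in kept)
    return survivors, audit


def with_label(records: Iterable[MoleculeRecord], label: str) -> list[MoleculeRecord]:
    return [replace(r, label=label) for r in records]
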