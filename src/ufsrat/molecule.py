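"""Molecule representation and MDL SD/SDF input/output.

Molecules are lightweight heavy-atom point clouds with a bond graph:
exactly the information the shape/type descriptors consume.  RDKit does
the actual V2000 connection-table parsing and writing; this module wraps
it with fail-soft multi-record handling, stable record identifiers and
byte offsets into the source file (needed by the descriptor database
manifest).
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

_PT = Chem.GetPeriodicTable()

#: Proton mass used when adding attached hydrogens into the molecular weight.
_H_MASS = 1.008


@dataclass(frozen=True)
class Atom:
    """A single heavy atom (or an explicit hydrogen before stripping)."""

    index: int
    element: str
    coords: tuple[float, float, float]
    attached_hydrogens: int = 0
    formal_charge: int = 0

    def __post_init__(self) -> None:
        if not all(math.isfinite(c) for c in self.coords):
            raise ValueError(f"atom {self.index}: non-finite coordinates {self.coords}")
        if self.attached_hydrogens < 0:
            raise ValueError("attached_hydrogens must be >= 0")


@dataclass
class Molecule3D:
    """A named molecule: ordered atoms, 3D coordinates and a bond graph.

    ``bonds`` are ``(i, j, order)`` triples with 0-based endpoint indices;
    order uses the MDL convention (1, 2, 3, 4 = aromatic).  Atom order is
    preserved from the input file because reference-point tie-breaking
    depends on it.
    """

    id: str
    atoms: list[Atom]
    bonds: list[tuple[int, int, int]] = field(default_factory=list)
    #: True when the source record looked 2D (all z == 0 or a 2D dim flag).
    flagged_2d: bool = False
    #: byte offset of the record in its source SD file, if known
    source_offset: int | None = None

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"molecule {self.id!r} has no atoms")
        n = len(self.atoms)
        for i, j, _order in self.bonds:
            if i == j:
                raise ValueError(f"molecule {self.id!r}: self-bond on atom {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"molecule {self.id!r}: bond ({i},{j}) out of range")

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) float64 coordinate array in Angstrom."""
        return np.array([a.coords for a in self.atoms], dtype=np.float64)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def neighbours(self, index: int) -> list[int]:
        out = []
        for i, j, _ in self.bonds:
            if i == index:
                out.append(j)
            elif j == index:
                out.append(i)
        return sorted(out)


@dataclass(frozen=True)
class LipinskiProperties:
    """Rule-of-five descriptors; ``logp`` may be unavailable (None)."""

    molecular_weight: float
    hbd_count: int
    hba_count: int
    logp: float | None = None

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise ValueError("molecular_weight must be > 0")
        if self.hbd_count < 0 or self.hba_count < 0:
            raise ValueError("H-bond counts must be >= 0")

    def violations(self) -> int:
        v = 0
        if self.molecular_weight > 500:
            v += 1
        if self.hbd_count > 5:
            v += 1
        if self.hba_count > 10:
            v += 1
        if self.logp is not None and self.logp > 5:
            v += 1
        return v


@dataclass(frozen=True)
class RecordError:
    """One failed SD record: its ordinal and why it was rejected."""

    record_index: int
    reason: str


@dataclass
class SDParseResult:
    molecules: list[Molecule3D]
    errors: list[RecordError]


_MDL_BOND_ORDERS = {
    Chem.BondType.SINGLE: 1,
    Chem.BondType.DOUBLE: 2,
    Chem.BondType.TRIPLE: 3,
    Chem.BondType.AROMATIC: 4,
}
_RDKIT_BOND_TYPES = {v: k for k, v in _MDL_BOND_ORDERS.items()}


def _split_sd_records(text: str) -> list[tuple[int, str]]:
    """Split multi-record SD text into (byte_offset, record_text) pairs."""
    records: list[tuple[int, str]] = []
    offset = 0
    current: list[str] = []
    start = 0
    for line in text.splitlines(keepends=True):
        if not current:
            start = offset
        current.append(line)
        if line.rstrip("\r\n") == "$$$$":
            records.append((start, "".join(current)))
            current = []
        offset += len(line.encode("utf-8"))
    tail = "".join(current)
    if tail.strip():
        records.append((start, tail))
    return records


def _mol_from_rdkit(rdmol: Chem.Mol, mol_id: str, offset: int | None) -> Molecule3D:
    conf = rdmol.GetConformer()
    atoms = []
    for a in rdmol.GetAtoms():
        p = conf.GetAtomPosition(a.GetIdx())
        atoms.append(
            Atom(
                index=a.GetIdx(),
                element=a.GetSymbol(),
                coords=(p.x, p.y, p.z),
                attached_hydrogens=a.GetTotalNumHs(includeNeighbors=False),
                formal_charge=a.GetFormalCharge(),
            )
        )
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), _MDL_BOND_ORDERS.get(b.GetBondType(), 1))
        for b in rdmol.GetBonds()
    ]
    flagged_2d = not conf.Is3D() or all(abs(a.coords[2]) < 1e-12 for a in atoms)
    return Molecule3D(
        id=mol_id, atoms=atoms, bonds=bonds, flagged_2d=flagged_2d, source_offset=offset
    )


def _read_source(source) -> str:
    if hasattr(source, "read"):
        return source.read()
    if isinstance(source, Path):
        return source.read_text()
    text = str(source)
    if "\n" not in text:
        try:
            p = Path(text)
            if p.exists():
                return p.read_text()
        except OSError:
            pass
    return text


def parse_sd(source) -> SDParseResult:
    """Parse multi-record V2000 SD text, collecting per-record errors.

    ``source`` may be a path, raw SD text, or a file-like object.  Records
    that fail to parse are reported in ``errors`` and skipped; parsing
    continues (fail-soft).  V3000 connection tables are rejected.
    """
    text = _read_source(source)
    result = SDParseResult(molecules=[], errors=[])
    seen_ids: dict[str, int] = {}
    for ordinal, (offset, record) in enumerate(_split_sd_records(text)):
        lines = record.splitlines()
        if len(lines) >= 4 and "V3000" in lines[3]:
            result.errors.append(RecordError(ordinal, "V3000 connection tables are not supported"))
            continue
        rdmol = Chem.MolFromMolBlock(record, sanitize=True, removeHs=False)
        if rdmol is None:
            # salvage the hydrogen-count-free structure when only
            # sanitization (valence model) failed
            rdmol = Chem.MolFromMolBlock(record, sanitize=False, removeHs=False)
            if rdmol is not None:
                try:
                    rdmol.UpdatePropertyCache(strict=False)
                except Exception:
                    rdmol = None
        if rdmol is None or rdmol.GetNumConformers() == 0 or rdmol.GetNumAtoms() == 0:
            result.errors.append(RecordError(ordinal, "unparseable connection table"))
            continue
        name = lines[0].strip() if lines else ""
        mol_id = name if name else str(ordinal)
        if mol_id in seen_ids:
            mol_id = f"{mol_id}#{ordinal}"
        seen_ids[mol_id] = ordinal
        try:
            mol = _mol_from_rdkit(rdmol, mol_id, offset)
        except ValueError as exc:
            result.errors.append(RecordError(ordinal, str(exc)))
            continue
        if mol.flagged_2d:
            logger.warning("record %d (%s): no 3D coordinates; flagged as 2D", ordinal, mol_id)
        result.molecules.append(mol)
    for err in result.errors:
        logger.warning("SD record %d skipped: %s", err.record_index, err.reason)
    return result


def read_sd(source) -> list[Molecule3D]:
    """Read a multi-molecule SD file; parse errors are logged, not raised."""
    return parse_sd(source).molecules


def strip_hydrogens(mol: Molecule3D) -> Molecule3D:
    """Drop explicit hydrogen atoms, folding them into heavy-atom H counts.

    Heavy-atom order is unchanged; idempotent.  Raises ``ValueError`` on a
    molecule with no heavy atom.
    """
    extra_h = {i: 0 for i in range(len(mol.atoms))}
    for i, j, _ in mol.bonds:
        if mol.atoms[i].element == "H" and mol.atoms[j].element != "H":
            extra_h[j] += 1
        elif mol.atoms[j].element == "H" and mol.atoms[i].element != "H":
            extra_h[i] += 1

    keep = [a for a in mol.atoms if a.element != "H"]
    if not keep:
        raise ValueError(f"molecule {mol.id!r} has no heavy atoms")
    remap = {a.index: new for new, a in enumerate(keep)}
    atoms = [
        replace(
            a,
            index=remap[a.index],
            attached_hydrogens=a.attached_hydrogens + extra_h[a.index],
        )
        for a in keep
    ]
    bonds = [
        (remap[i], remap[j], order)
        for i, j, order in mol.bonds
        if i in remap and j in remap
    ]
    return Molecule3D(
        id=mol.id,
        atoms=atoms,
        bonds=bonds,
        flagged_2d=mol.flagged_2d,
        source_offset=mol.source_offset,
    )


def to_rdkit(mol: Molecule3D, sanitize: bool = True) -> Chem.Mol:
    """Build an RDKit molecule (used for SMARTS typing and SD output).

    Hydrogen counts are carried as explicit-H annotations so SMARTS ``H``
    primitives see them.  Sanitization is best-effort: valence errors in
    synthetic point-cloud molecules must not abort descriptor generation,
    so failures fall back to ring perception only.
    """
    rw = Chem.RWMol()
    for a in mol.atoms:
        ra = Chem.Atom(a.element)
        ra.SetNoImplicit(True)
        ra.SetNumExplicitHs(a.attached_hydrogens)
        ra.SetFormalCharge(a.formal_charge)
        rw.AddAtom(ra)
    for i, j, order in mol.bonds:
        rw.AddBond(i, j, _RDKIT_BOND_TYPES.get(order, Chem.BondType.SINGLE))
    conf = Chem.Conformer(len(mol.atoms))
    for a in mol.atoms:
        conf.SetAtomPosition(a.index, a.coords)
    rw.AddConformer(conf)
    out = rw.GetMol()
    if sanitize:
        try:
            Chem.SanitizeMol(
                out, Chem.SanitizeFlags.SANITIZE_ALL ^ Chem.SanitizeFlags.SANITIZE_PROPERTIES
            )
        except Exception:
            out.UpdatePropertyCache(strict=False)
            Chem.FastFindRings(out)
    else:
        out.UpdatePropertyCache(strict=False)
    # synthetic point clouds routinely under-fill valences; do not let the
    # electron bookkeeping surface as radical annotations in SD output
    for atom in out.GetAtoms():
        atom.SetNumRadicalElectrons(0)
    return out


def write_sd(
    mols: Sequence[Molecule3D],
    annotations: Mapping[str, float] | None = None,
    score_field: str = "UFSRAT_SCORE",
) -> str:
    """Serialize molecules as multi-record V2000 SD text.

    ``annotations`` maps molecule id to a similarity score, emitted as an
    SD data field (6 significant digits).  Every annotated id must exist.
    """
    annotations = dict(annotations or {})
    known = {m.id for m in mols}
    missing = sorted(set(annotations) - known)
    if missing:
        raise ValueError(f"annotated ids not present in molecules: {missing}")

    buf = io.StringIO()
    writer = Chem.SDWriter(buf)
    writer.SetKekulize(False)
    for mol in mols:
        rdmol = to_rdkit(mol, sanitize=True)
        rdmol.SetProp("_Name", mol.id)
        if mol.id in annotations:
            rdmol.SetProp(score_field, f"{annotations[mol.id]:.6g}")
        writer.write(rdmol)
    writer.close()
    return buf.getvalue()


def molecular_weight(mol: Molecule3D) -> float:
    return sum(
        _PT.GetAtomicWeight(a.element) + _H_MASS * a.attached_hydrogens for a in mol.atoms
    )


def lipinski_properties(mol: Molecule3D, logp: float | None = None) -> LipinskiProperties:
    """Rule-of-five properties from the heavy-atom graph.

    HBD counts N-H/O-H hydrogens, HBA counts nitrogen and oxygen atoms
    (the classic rule-of-five conventions).  logP is never computed from
    first principles here; pass a toolkit estimate or table value.
    """
    hbd = sum(a.attached_hydrogens for a in mol.atoms if a.element in ("N", "O"))
    hba = sum(1 for a in mol.atoms if a.element in ("N", "O"))
    return LipinskiProperties(
        molecular_weight=molecular_weight(mol), hbd_count=hbd, hba_count=hba, logp=logp
    )


def lipinski_filter(
    mols: Sequence[Molecule3D],
    props: Sequence[LipinskiProperties] | None = None,
    max_violations: int = 1,
) -> list[Molecule3D]:
    """Drug-likeness filter: keep molecules with <= ``max_violations``
    rule-of-five violations (MW <= 500, HBD <= 5, HBA <= 10, logP <= 5).

    ``max_violations=0`` selects the strict any-violation-fails policy.
    Output order follows input order.
    """
    if props is None:
        props = [lipinski_properties(m) for m in mols]
    if len(props) != len(mols):
        raise ValueError(
            f"props length {len(props)} does not match molecules length {len(mols)}"
        )
    return [m for m, p in zip(mols, props) if p.violations() <= max_violations]


def selection_fraction_pct(n_queries: int, top_n: int, library_size: int) -> float:
    """Percentage of a library selected by ``n_queries`` top-N screens.

    Three top-500 screens of a 3.8 million compound library select
    0.04 % of it; this is the reporting arithmetic behind that figure.
    """
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    return 100.0 * n_queries * top_n / library_size
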