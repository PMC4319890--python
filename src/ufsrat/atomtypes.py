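"""Pharmacophoric atom typing: hydrophobic / H-bond acceptor / H-bond donor.

Each heavy atom is assigned boolean membership in three channels by an
ordered, user-editable list of SMARTS rules (an "atomic mask").  Channels
are not mutually exclusive: a hydroxyl oxygen is donor and acceptor.
Typing depends only on the bond graph, hydrogen counts and formal
charges, never on coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem

from .molecule import Molecule3D, to_rdkit

CHANNELS = ("all", "hydrophobic", "acceptor", "donor")
TYPED_CHANNELS = ("hydrophobic", "acceptor", "donor")


@dataclass(frozen=True)
class TypingRule:
    pattern: str
    channel: str
    set_flag: bool
    query: Chem.Mol

    def __repr__(self) -> str:  # query object is noise
        sign = "+" if self.set_flag else "-"
        return f"TypingRule({self.pattern!r}, {self.channel}, {sign})"


@dataclass(frozen=True)
class TypingRules:
    """Ordered rule list; later rules override earlier ones."""

    rules: tuple[TypingRule, ...]

    @classmethod
    def from_lines(cls, lines: Sequence[str]) -> "TypingRules":
        parsed = []
        for lineno, raw in enumerate(lines, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(
                    f"typing rules line {lineno}: expected 'SMARTS<TAB>channel<TAB>+|-', got {raw!r}"
                )
            pattern, channel, flag = (p.strip() for p in parts)
            if channel not in TYPED_CHANNELS:
                raise ValueError(
                    f"typing rules line {lineno}: unknown channel {channel!r}"
                )
            if flag not in ("+", "-"):
                raise ValueError(f"typing rules line {lineno}: flag must be '+' or '-'")
            query = Chem.MolFromSmarts(pattern)
            if query is None:
                raise ValueError(
                    f"typing rules line {lineno}: invalid SMARTS pattern {pattern!r}"
                )
            parsed.append(TypingRule(pattern, channel, flag == "+", query))
        return cls(rules=tuple(parsed))

    @classmethod
    def from_file(cls, path: str | Path) -> "TypingRules":
        return cls.from_lines(Path(path).read_text().splitlines())


_DEFAULT_RULES: TypingRules | None = None


def default_rules() -> TypingRules:
    """The packaged default mask (cached after first load)."""
    global _DEFAULT_RULES
    if _DEFAULT_RULES is None:
        text = resources.files("ufsrat").joinpath("data/default_typing.rules").read_text()
        _DEFAULT_RULES = TypingRules.from_lines(text.splitlines())
    return _DEFAULT_RULES


@dataclass
class AtomTypeAssignment:
    """Per-atom channel membership for one molecule."""

    hydrophobic: np.ndarray
    acceptor: np.ndarray
    donor: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.hydrophobic)
        if not (len(self.acceptor) == len(self.donor) == n):
            raise ValueError("channel vectors must have equal length")

    def mask(self, channel: str) -> np.ndarray:
        if channel == "all":
            return np.ones(len(self.hydrophobic), dtype=bool)
        if channel not in TYPED_CHANNELS:
            raise ValueError(f"unknown channel {channel!r}; expected one of {CHANNELS}")
        return getattr(self, channel)


def assign_types(mol: Molecule3D, rules: TypingRules | None = None) -> AtomTypeAssignment:
    """Apply the typing mask to a hydrogen-stripped molecule.

    Deterministic: rules fire in file order, each setting or clearing its
    channel for every matching atom.
    """
    if any(a.element == "H" for a in mol.atoms):
        raise ValueError("assign_types requires a hydrogen-stripped molecule")
    if rules is None:
        rules = default_rules()
    n = len(mol.atoms)
    masks = {c: np.zeros(n, dtype=bool) for c in TYPED_CHANNELS}
    rdmol = to_rdkit(mol, sanitize=True)
    for rule in rules.rules:
        matches = rdmol.GetSubstructMatches(rule.query, uniquify=False, maxMatches=10 * n + 100)
        hits = {m[0] for m in matches}
        if not hits:
            continue
        idx = np.fromiter(hits, dtype=np.intp)
        masks[rule.channel][idx] = rule.set_flag
    return AtomTypeAssignment(
        hydrophobic=masks["hydrophobic"], acceptor=masks["acceptor"], donor=masks["donor"]
    )


def channel_atoms(mol: Molecule3D, assignment: AtomTypeAssignment, channel: str) -> list[int]:
    """Atom indices belonging to a channel, in ascending order."""
    if len(assignment.hydrophobic) != len(mol.atoms):
        raise ValueError("assignment does not match molecule atom count")
    return [int(i) for i in np.nonzero(assignment.mask(channel))[0]]
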