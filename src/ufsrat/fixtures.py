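"""Deterministic synthetic molecule and benchmark-set generation.

The generated structures are physically naive point clouds, not
chemically valid molecules: atoms are scattered uniformly in a box and
joined in a chain so that typing rules have a graph to act on.  That is
sufficient here because every computation in this package consumes only
elements, coordinates, hydrogen counts and the bond graph.  "Actives"
for a benchmark target are coordinate-jittered conformers of the
target's seed molecule — near-duplicates in shape space — while decoys
are independent random molecules.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .enrichment import LabeledLibrary, TargetSet
from .molecule import Atom, Molecule3D

#: default hydrogen counts by element for generated atoms; O and N carry
#: one H so donor/acceptor channels are populated, S is bare (thioether-like)
DEFAULT_HYDROGENS = {"C": 2, "N": 1, "O": 1, "S": 0}


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one random molecule family.

    ``composition`` gives element sampling probabilities; the defaults
    approximate a small organic molecule (mostly carbon with enough N/O
    that donor/acceptor channels are non-empty on average).  ``scale`` is
    the coordinate box edge in Angstrom, sized like a drug-like molecule.
    """

    n_atoms_range: tuple[int, int] = (8, 24)
    composition: dict = field(
        default_factory=lambda: {"C": 0.6, "N": 0.15, "O": 0.2, "S": 0.05}
    )
    scale: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.n_atoms_range
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid n_atoms_range {self.n_atoms_range}")
        if abs(sum(self.composition.values()) - 1.0) > 1e-9:
            raise ValueError("composition probabilities must sum to 1")


def random_molecule(
    spec: FixtureSpec,
    mol_id: str = "random",
    rng: np.random.Generator | None = None,
) -> Molecule3D:
    """One random chain molecule; same spec + seed gives identical output."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    lo, hi = spec.n_atoms_range
    n = int(rng.integers(lo, hi + 1))
    elements = list(spec.composition)
    probs = np.array([spec.composition[e] for e in elements])
    picks = rng.choice(len(elements), size=n, p=probs)
    coords = rng.uniform(0.0, spec.scale, size=(n, 3))
    atoms = [
        Atom(
            index=i,
            element=elements[picks[i]],
            coords=tuple(coords[i]),
            attached_hydrogens=DEFAULT_HYDROGENS.get(elements[picks[i]], 0),
        )
        for i in range(n)
    ]
    bonds = [(i - 1, i, 1) for i in range(1, n)]
    return Molecule3D(id=mol_id, atoms=atoms, bonds=bonds)


def jittered_conformers(
    seed_mol: Molecule3D,
    n: int,
    sigma: float,
    seed: int = 0,
    id_prefix: str | None = None,
) -> list[Molecule3D]:
    """``n`` copies with independent Gaussian coordinate noise.

    ``sigma`` is the per-axis standard deviation in Angstrom; 0 gives
    exact copies.  Element identity, hydrogen counts and bonding are
    untouched, so the copies emulate conformers of one compound.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    prefix = id_prefix if id_prefix is not None else seed_mol.id
    out = []
    for k in range(n):
        noise = rng.normal(0.0, sigma, size=(len(seed_mol.atoms), 3)) if sigma > 0 else 0.0
        coords = seed_mol.coords + noise
        atoms = [
            replace(a, coords=tuple(coords[a.index])) for a in seed_mol.atoms
        ]
        out.append(
            Molecule3D(id=f"{prefix}_conf{k}", atoms=atoms, bonds=list(seed_mol.bonds))
        )
    return out


def benchmark_set(
    n_targets: int = 10,
    n_actives: int = 10,
    n_decoys: int = 490,
    sigma: float = 0.05,
    seed: int = 0,
    spec: FixtureSpec | None = None,
) -> LabeledLibrary:
    """A labeled actives/decoys library with one query per target.

    Per target: a random seed molecule is the query, its jittered
    conformers (noise ``sigma`` Angstrom) are the actives, and
    independent random molecules are the decoys.  Id spaces are disjoint
    across targets.  Defaults give 10 targets of 500 candidates with 2%
    actives, a desk-scale analogue of a decoy-set benchmark.
    """
    if min(n_targets, n_actives, n_decoys) < 1:
        raise ValueError("n_targets, n_actives and n_decoys must all be >= 1")
    if spec is None:
        spec = FixtureSpec(seed=seed)
    rng = np.random.default_rng(seed)
    targets = []
    for t in range(n_targets):
        tname = f"target{t:02d}"
        query = random_molecule(spec, mol_id=f"{tname}_query", rng=rng)
        actives = jittered_conformers(
            query,
            n_actives,
            sigma,
            seed=int(rng.integers(0, 2**31)),
            id_prefix=f"{tname}_active",
        )
        decoys = [
            random_molecule(spec, mol_id=f"{tname}_decoy{d:04d}", rng=rng)
            for d in range(n_decoys)
        ]
        molecules = {m.id: m for m in actives + decoys}
        targets.append(
            TargetSet(
                name=tname,
                query=query,
                active_ids=frozenset(m.id for m in actives),
                decoy_ids=frozenset(m.id for m in decoys),
                molecules=molecules,
            )
        )
    return LabeledLibrary(targets=targets)
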