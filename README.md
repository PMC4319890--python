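# ufsrat

Ligand-based virtual screening with typed ultrafast shape descriptors.

Given one 3D query molecule, the goal is to pull, out of a library of
millions of candidate structures, the few hundred whose shape *and*
pharmacophoric make-up would let them form similar interactions with a
protein — including molecules whose chemical scaffold is completely
different from the query's (scaffold hopping). This package is for
computational chemists who want that screen to be alignment-free and
fast enough to run as a linear scan over a pre-computed descriptor
file.

## The descriptor and the score

A molecule's heavy atoms are split into four distributions: **all**
atoms (shape), **hydrophobic** atoms, hydrogen-bond **acceptor** atoms
and hydrogen-bond **donor** atoms, assigned by an ordered, user-editable
SMARTS mask. Four reference points are defined from the all-atom cloud:

* P1 — the geometric centre (unweighted centroid),
* P2 — the atom closest to P1,
* P3 — the atom furthest from P2,
* P4 — the atom furthest from P3.

For each distribution, the Euclidean distances of its atoms to each
reference point form a 1D distribution whose **mean**, **population
variance** and **skew** are recorded: 4 points × 3 moments = 12 values
per distribution, 48 per molecule (hydrogens are ignored throughout; an
empty channel contributes 12 zeros). The shape-only baseline (classic
USR) keeps just the 12 all-atom values, which are always identical to
the first 12 entries of the typed vector.

Two vectors *M*<sup>q</sup> and *M*<sup>c</sup> are compared with

&nbsp;&nbsp;&nbsp;&nbsp;*S*<sub>qc</sub> = 1 / (1 + Σ<sub>k</sub> *w*<sub>k</sub> *d*<sub>k</sub>),&nbsp;&nbsp;&nbsp;
*d*<sub>k</sub> = (1/12) Σ<sub>i∈k</sub> |*M*<sup>q</sup><sub>i</sub> − *M*<sup>c</sup><sub>i</sub>|

with channel weights *w*<sub>k</sub> ≥ 0 normalized to sum 1 (default
¼ each). *S* is symmetric, lies in (0, 1], equals 1 exactly for
identical vectors, and with *w* = (1,0,0,0) reduces to the classic
shape-only score 1/(1 + mean|Δ|). Because the descriptors are functions
of interatomic distances only, they are invariant under rotation,
translation — and reflection, so enantiomers are indistinguishable.

Screening never recomputes candidate descriptors: a library is compiled
once into a single binary file of 200-byte records (8-byte identifier +
48 × 4-byte float32 values; 3.8 million compounds ≈ 725 MiB) and each
query is a single sequential scan keeping a bounded top-N.

An enrichment harness measures ranking power on labeled actives/decoys:
EF(f) = (fraction of actives recovered in the top f) / f, so EF = 1 is
random picking and EF = 1/f is perfect.

## Worked example

```python
import numpy as np, pathlib
from ufsrat import (FixtureSpec, random_molecule, write_sd, build_db,
                    compute_descriptors, read_sd)

rng = np.random.default_rng(0)
spec = FixtureSpec(seed=0)
mols = [random_molecule(spec, f"mol{i:04d}", rng) for i in range(1000)]
pathlib.Path("library.sdf").write_text(write_sd(mols))

db = build_db("library.sdf", "library.ufsrat")
print(f"{db.count} records, {pathlib.Path('library.ufsrat').stat().st_size} bytes")

query = read_sd("library.sdf")[123]
for rank, h in enumerate(db.scan(compute_descriptors(query), n=5), 1):
    print(f"{rank}  id={h.id:4d}  S = {h.score:.4f}")
```

prints

```
1000 records, 200022 bytes
1  id= 123  S = 1.0000
2  id= 860  S = 0.5680
3  id= 507  S = 0.5637
4  id= 888  S = 0.5626
5  id= 232  S = 0.5598
```

The file holds a 22-byte header plus 1000 × 200-byte records. Molecule
123 retrieves itself with *S* = 1 (queries are compared at the
database's float32 storage precision), and the next hits score ≈ 0.56 —
unrelated random structures of broadly similar size.

The same pipeline from the shell, including the enrichment benchmark on
a generated actives/decoys library:

```
$ ufsrat fixtures --seed 7 --out bench --targets 3 --actives 5 --decoys 95
$ ufsrat benchmark --library bench --fractions 1,5
Mean enrichment factors across targets:
method    ufsrat   usr
fraction
0.01       20.00 20.00
0.05       20.00 20.00
```

Each target has 100 candidates, so the top 1% holds one compound and
the top 5% five; with actives that are tightly jittered conformers of
the query, both methods recover only actives there, saturating the
statistic at (5/5)/0.05 = 20. Other subcommands: `ufsrat describe`
(TSV descriptor table), `ufsrat build-db`, `ufsrat screen --query q.sdf
--db lib.ufsrat --top 500 [--lipinski]`.

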