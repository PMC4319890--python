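# Methods

## Model

A rigid 3D molecule is reduced to moment summaries of interatomic
distance distributions, measured from four reference points (geometric
centre; atom closest to it; atom furthest from that; atom furthest from
that again) and taken over four atom subsets (all heavy atoms,
hydrophobic, H-bond acceptor, H-bond donor). The method assumes the
supplied conformer is the biologically relevant one: no conformational
sampling is performed, and a database may simply hold one record per
supplied conformer of the same compound. Hydrogens never enter any
distance distribution; their counts are kept on heavy atoms because
donor typing needs them.

### Reference points

P1 is the unweighted centroid of heavy-atom positions ("centre of the
volume" is read as the centroid; no mass weighting). P2–P4 are actual
atoms selected by nearest/furthest criteria, with ties broken by lowest
atom index under exact floating-point comparison — no epsilon — so the
selection is deterministic across platforms for identical input
coordinates (which is also why input atom order is preserved).

By default all four channels share the reference points computed from
the *all*-atom cloud: this preserves spatial registration between
channels (a donor cluster far from the molecular centre looks different
from one at the centre). `DescriptorConfig(per_channel_refpoints=True)`
recomputes P1–P4 from each typed subset instead, for sensitivity
studies; the choice is recorded in the database header and mismatched
query/database conventions are refused rather than silently compared.

### Moments

Population (1/N) moments throughout; N = 1 is legal and gives
(d, 0, 0). Two skew conventions are available and recorded in the
database header:

* `standardized` (default): μ₃/σ³, with skew := 0 when the variance is
  below 10⁻¹² (degenerate distributions, single atoms). Unit-free and
  bounded for near-degenerate inputs.
* `cbrt-central`: signed ∛μ₃, in Ångström — the normalization used by
  early shape-moment work, kept for comparability.

An empty typed channel yields 12 zeros rather than an error: every
molecule must be representable in the database, and two molecules with
no donors are then maximally similar in the donor block, which is
chemically sensible.

## Atom typing

Typing is an ordered list of SMARTS rules (`pattern<TAB>channel<TAB>+|-`),
applied top to bottom with later rules overriding earlier ones; the
packaged default is `src/ufsrat/data/default_typing.rules` and users can
supply their own file. Defaults: donors are N/O/S bearing ≥ 1 hydrogen;
acceptors are neutral N or O plus fluorine, minus amide and
pyrrole-type nitrogens (lone pair delocalized); hydrophobic atoms are C
or S bonded only to C/S/halogen, plus halogens. These follow common
pharmacophore conventions; they are a documented, editable default, not
a claim about any particular reference implementation. Formal charges
are taken from the input record; protonation states are never
recomputed, keeping pre-calculation deterministic per record.

## Scoring and ranking

S = 1/(1 + Σₖ wₖ dₖ) with dₖ the mean absolute per-entry difference in
channel k and weights normalized to sum 1 (default ¼ each). The exact
functional form is the one implementation-defined equation in the
package; it is pinned by three constraints — it extends the classic
shape-only score, reduces to it exactly when all weight sits on the
all-atom channel, and maps [0, ∞) difference to (0, 1] similarity.
Scores are computed in double precision; stored float32 candidate
values are promoted on read, and the query is *quantized* through
float32 before a database scan so that a molecule compared against its
own stored record scores exactly 1.

Ranking keeps a bounded buffer (≤ 4N entries, compacted by sorting) —
O(N) memory over an arbitrarily long stream — and is tested to agree
exactly with a score-everything-and-sort oracle, including the
descending-score / ascending-id tie-break.

## Descriptor database

One binary file: a 22-byte self-describing header (magic, format
version, mode, skew convention, reference-point scope, record count)
followed by contiguous 200-byte records (little-endian uint64 id +
48 float32 values; shape-only databases zero-pad to the fixed width).
Builds assign ids sequentially in input order, skip unparseable records
with a logged reason without renumbering, and are byte-deterministic.
A sidecar TSV manifest (id, name, byte offset into the source SD file)
makes hit retrieval self-contained without a relational database. The
header is this package's addition — a raw record stream has no way to
refuse incompatibly built queries. Scans are chunked over a memory map,
so memory use is bounded by the chunk, not the file.

## SD input/output

V2000 only; V3000 is rejected with a per-record error. Parsing is
fail-soft: corrupt records are collected as errors and the rest of the
file is processed. Records whose coordinates are all z = 0 (or carry a
2D flag) are flagged but still usable if forced — the alternative,
silent rejection, loses data a user may knowingly supply. Molecule ids
come from the name line, falling back to the record ordinal, with
collisions disambiguated by appending the ordinal. Round-trips preserve
heavy-atom counts, elements and coordinates to the format's 4-decimal
precision. The rule-of-five filter defaults to the common "fail on ≥ 2
violations" policy (`max_violations=1`), with the strict variant
selectable; logP is accepted from a toolkit estimate or user table,
never computed here.

## Enrichment harness

EF(f) = (recovered actives / total actives) / f over the top
⌈f·N⌉ candidates. Ceiling rounding guarantees a non-empty selection at
small f; EF at small N is sensitive to this choice, hence it is fixed
and documented. Boundary ties inherit the ranker's ascending-id order;
no fractional attribution. Queries are not members of the ranked
library. A method failing on a target removes that target from all
means so cross-method averages stay comparable. Beyond per-target EFs,
cross-target means and strict-inequality win counts, a label-permutation
test is provided for calibration; no ROC/AUC-style metrics are
computed.

## Synthetic data

The fixture generator produces chain-bonded point clouds: 8–24 heavy
atoms drawn from {C 60%, N 15%, O 20%, S 5%} uniformly in an 8 Å box,
with per-element default hydrogen counts (C:2, N:1, O:1, S:0). These
are *not* chemically valid molecules — no valence model, no realistic
geometry — but every computation in this package consumes only
elements, coordinates, hydrogen counts and the bond graph, so they
exercise all code paths, including empty typed channels. Benchmark
"actives" are conformers of the target's query with Gaussian coordinate
jitter (default σ = 0.05 Å per axis), i.e. near-duplicates in shape
space; decoys are independent random molecules. Defaults (10 targets,
10 actives + 490 decoys each) give a desk-scale labeled library of
5 000 candidates at 2% actives.

Consequently a passing benchmark here shows that the pipeline separates
near-identical conformers from unrelated structures — a correctness
check of descriptors, scoring, ranking and the EF statistic — and *not*
that the method achieves any particular enrichment on real screening
decks, where actives share pharmacophores but not coordinates. On this
easy separation both the typed and shape-only methods typically
saturate the EF ceiling and their win counts tie.

## Numerical choices and limitations

* Exact float comparison for reference-point ties; determinism over
  robustness to coordinate noise is intentional for a pre-computed
  database.
* Reflection blindness: enantiomers receive identical descriptors.
* Descriptors are conformer-sensitive; a poor query conformer degrades
  retrieval and nothing in the package corrects for it.
* Typing quality is bounded by the SMARTS defaults and the input's
  recorded charges; aromaticity-dependent rules require the input to be
  sanitizable, and fall back to ring perception only otherwise.
* Problem sizes in the test suite and acceptance script (hundreds to a
  few thousand molecules, 10-target benchmarks) were chosen so the full
  pipeline — including brute-force oracles — runs comfortably on a
  single CPU; the statistics they compute are not scale-dependent.
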