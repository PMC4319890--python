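"""Recall-over-random enrichment evaluation on labeled actives/decoys.

The enrichment factor at fraction f of a ranked library is

    EF(f) = (actives recovered in the top ceil(f*N) / total actives) / f

so EF = 1 matches random picking, EF = 1/f is the ceiling, and EF = 0
means no active survives the cut.  The benchmark harness runs any number
of scoring methods over a labeled library (one query plus disjoint
active/decoy id sets per target), reporting per-target EFs, cross-target
means and pairwise win counts; score ties at the selection boundary are
resolved by ascending candidate id, the same tie-break the ranker uses.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .atomtypes import TypingRules
from .db import compute_descriptors
from .descriptors import DescriptorConfig, DescriptorVector, MODE_USR
from .molecule import Molecule3D, read_sd, write_sd
from .similarity import ChannelWeights, score

logger = logging.getLogger(__name__)

DEFAULT_FRACTIONS = (0.005, 0.01, 0.02, 0.05)

#: a scorer maps (query molecule, [(id, molecule), ...]) -> {id: score}
Scorer = Callable[[Molecule3D, Sequence[tuple[str, Molecule3D]]], dict]


@dataclass
class TargetSet:
    """One benchmark target: a query plus its labeled candidate library."""

    name: str
    query: Molecule3D
    active_ids: frozenset
    decoy_ids: frozenset
    molecules: dict

    def __post_init__(self) -> None:
        if self.active_ids & self.decoy_ids:
            raise ValueError(f"target {self.name}: active and decoy ids overlap")
        if not self.active_ids:
            raise ValueError(f"target {self.name}: at least one active required")
        if len(self.active_ids) + len(self.decoy_ids) < 2:
            raise ValueError(f"target {self.name}: at least two candidates required")
        missing = (self.active_ids | self.decoy_ids) - set(self.molecules)
        if missing:
            raise ValueError(f"target {self.name}: ids without molecules: {sorted(missing)[:5]}")

    @property
    def candidate_ids(self) -> list:
        return sorted(self.active_ids | self.decoy_ids)


@dataclass
class LabeledLibrary:
    targets: list[TargetSet]


def enrichment_factor(ranking: Sequence, actives: Iterable, fraction: float) -> float:
    """EF of one ranked id list at one top fraction.

    ``ranking`` is best-first; the top set has ceil(fraction * N) members
    (ceiling keeps the selection non-empty at small fractions).
    """
    actives = set(actives)
    if not actives:
        raise ValueError("actives must be non-empty")
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    ranked = list(ranking)
    if not actives <= set(ranked):
        raise ValueError("every active id must appear in the ranking")
    n_top = math.ceil(fraction * len(ranked))
    found = sum(1 for cid in ranked[:n_top] if cid in actives)
    return (found / len(actives)) / fraction


def random_ranking_ef(
    n_candidates: int,
    n_actives: int,
    fraction: float,
    n_shuffles: int = 1000,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """EF samples under random ranking — the EF ~ 1 null distribution."""
    if rng is None:
        rng = np.random.default_rng(0)
    ids = np.arange(n_candidates)
    out = np.empty(n_shuffles)
    for k in range(n_shuffles):
        order = rng.permutation(ids)
        out[k] = enrichment_factor(order.tolist(), range(n_actives), fraction)
    return out


def permutation_pvalue(
    ranking: Sequence,
    actives: Iterable,
    fraction: float,
    n_permutations: int = 999,
    rng: np.random.Generator | None = None,
) -> float:
    """One-sided p-value that the observed EF beats label-shuffled EFs."""
    if rng is None:
        rng = np.random.default_rng(0)
    actives = set(actives)
    ranked = list(ranking)
    observed = enrichment_factor(ranked, actives, fraction)
    n_actives = len(actives)
    at_least = 1  # the observed labeling counts itself
    for _ in range(n_permutations):
        shuffled = rng.choice(len(ranked), size=n_actives, replace=False)
        fake_actives = {ranked[i] for i in shuffled}
        if enrichment_factor(ranked, fake_actives, fraction) >= observed:
            at_least += 1
    return at_least / (n_permutations + 1)


def rank_candidates(scores: dict) -> list:
    """Best-first id order; ties broken by ascending id."""
    return [cid for cid, _ in sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))]


@dataclass
class EnrichmentReport:
    per_target: pd.DataFrame  # columns: target, method, fraction, ef
    means: pd.DataFrame  # columns: method, fraction, mean_ef
    win_counts: pd.DataFrame  # columns: method_a, method_b, fraction, wins_a
    failed_targets: list = field(default_factory=list)

    def to_tsv(self, prefix: str | Path) -> list[Path]:
        prefix = Path(prefix)
        paths = []
        for name, frame in (
            ("per_target", self.per_target),
            ("means", self.means),
            ("wins", self.win_counts),
        ):
            p = prefix.with_name(prefix.name + f".{name}.tsv")
            frame.to_csv(p, sep="\t", index=False)
            paths.append(p)
        return paths

    def pretty(self) -> str:
        lines = ["Mean enrichment factors across targets:"]
        pivot = self.means.pivot(index="fraction", columns="method", values="mean_ef")
        lines.append(pivot.to_string(float_format=lambda v: f"{v:.2f}"))
        if len(self.win_counts):
            lines.append("\nPairwise wins (EF strictly greater):")
            lines.append(self.win_counts.to_string(index=False))
        if self.failed_targets:
            lines.append(f"\nFailed targets: {', '.join(self.failed_targets)}")
        return "\n".join(lines)


def benchmark(
    methods: Sequence[tuple[str, Scorer]],
    library: LabeledLibrary,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
) -> EnrichmentReport:
    """Score every target with every method and tabulate enrichment.

    A method that fails on a target excludes that target from every
    method's means (targets stay comparable); the failure is logged.
    """
    rows = []
    failed = []
    for target in library.targets:
        candidates = [(cid, target.molecules[cid]) for cid in target.candidate_ids]
        per_method = {}
        try:
            for name, scorer in methods:
                scores = scorer(target.query, candidates)
                if set(scores) != set(target.candidate_ids):
                    raise ValueError(f"method {name} did not score every candidate")
                per_method[name] = rank_candidates(scores)
        except Exception as exc:
            logger.warning("benchmark: target %s failed: %s", target.name, exc)
            failed.append(target.name)
            continue
        for name, ranking in per_method.items():
            for f in fractions:
                rows.append(
                    {
                        "target": target.name,
                        "method": name,
                        "fraction": f,
                        "ef": enrichment_factor(ranking, target.active_ids, f),
                    }
                )

    per_target = pd.DataFrame(rows, columns=["target", "method", "fraction", "ef"])
    if len(per_target):
        means = (
            per_target.groupby(["method", "fraction"], as_index=False)["ef"]
            .mean()
            .rename(columns={"ef": "mean_ef"})
        )
    else:
        means = pd.DataFrame(columns=["method", "fraction", "mean_ef"])

    win_rows = []
    names = [name for name, _ in methods]
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            for f in fractions:
                sub = per_target[per_target["fraction"] == f]
                efs_a = sub[sub["method"] == a].set_index("target")["ef"]
                efs_b = sub[sub["method"] == b].set_index("target")["ef"]
                common = efs_a.index.intersection(efs_b.index)
                wins_a = int((efs_a[common] > efs_b[common]).sum())
                wins_b = int((efs_b[common] > efs_a[common]).sum())
                win_rows.append(
                    {"method_a": a, "method_b": b, "fraction": f, "wins_a": wins_a, "wins_b": wins_b}
                )
    win_counts = pd.DataFrame(
        win_rows, columns=["method_a", "method_b", "fraction", "wins_a", "wins_b"]
    )
    return EnrichmentReport(
        per_target=per_target, means=means, win_counts=win_counts, failed_targets=failed
    )


def descriptor_scorer(
    config: DescriptorConfig | None = None,
    weights: ChannelWeights | None = None,
    rules: TypingRules | None = None,
) -> Scorer:
    """Scorer backed by this package's descriptors (typed or shape-only)."""
    if config is None:
        config = DescriptorConfig()

    def _score(query: Molecule3D, candidates: Sequence[tuple[str, Molecule3D]]) -> dict:
        qv = compute_descriptors(query, rules, config)
        return {
            cid: score(qv, compute_descriptors(mol, rules, config), weights)
            for cid, mol in candidates
        }

    return _score


def usr_scorer() -> Scorer:
    """Shape-only (all-atom, 12-value) baseline scorer."""
    return descriptor_scorer(DescriptorConfig(mode=MODE_USR))


# ---------------------------------------------------------------------------
# on-disk layout: per-target directory with query.sdf, actives.ids,
# decoys.ids, next to a shared library.sdf holding every candidate


def save_library(library: LabeledLibrary, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    all_mols: dict = {}
    for target in library.targets:
        tdir = directory / target.name
        tdir.mkdir(exist_ok=True)
        (tdir / "query.sdf").write_text(write_sd([target.query]))
        (tdir / "actives.ids").write_text("\n".join(map(str, sorted(target.active_ids))) + "\n")
        (tdir / "decoys.ids").write_text("\n".join(map(str, sorted(target.decoy_ids))) + "\n")
        all_mols.update(target.molecules)
    lib_path = directory / "library.sdf"
    lib_path.write_text(write_sd([all_mols[k] for k in sorted(all_mols)]))
    return directory


def load_library(directory: str | Path) -> LabeledLibrary:
    directory = Path(directory)
    lib_path = directory / "library.sdf"
    molecules = {m.id: m for m in read_sd(lib_path)}
    targets = []
    for tdir in sorted(p for p in directory.iterdir() if p.is_dir()):
        queries = read_sd(tdir / "query.sdf")
        if not queries:
            raise ValueError(f"{tdir}: query.sdf holds no parseable molecule")
        active_ids = frozenset((tdir / "actives.ids").read_text().split())
        decoy_ids = frozenset((tdir / "decoys.ids").read_text().split())
        subset = {cid: molecules[cid] for cid in active_ids | decoy_ids}
        targets.append(
            TargetSet(
                name=tdir.name,
                query=queries[0],
                active_ids=active_ids,
                decoy_ids=decoy_ids,
                molecules=subset,
            )
        )
    return LabeledLibrary(targets=targets)
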