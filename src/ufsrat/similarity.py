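"""Descriptor similarity scoring and top-N ranking.

The score between query and candidate vectors is

    S_qc = 1 / (1 + sum_k w_k * d_k),      d_k = (1/12) * sum_i |q_i - c_i|

where k runs over the four typed channels and the weights w_k are
normalized to sum to 1 (default 1/4 each).  With all weight on the
all-atom channel this degenerates to the classic shape-only score
1/(1 + mean absolute descriptor difference).  S is symmetric, lies in
(0, 1], and equals 1 exactly when the vectors are identical.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .descriptors import MODE_UFSRAT, MODE_USR, DescriptorConfig, DescriptorVector


@dataclass(frozen=True)
class ChannelWeights:
    """Non-negative per-channel weights, normalized to sum 1 on creation."""

    w_all: float = 0.25
    w_hydrophobic: float = 0.25
    w_acceptor: float = 0.25
    w_donor: float = 0.25

    def __post_init__(self) -> None:
        raw = (self.w_all, self.w_hydrophobic, self.w_acceptor, self.w_donor)
        if any(w < 0 for w in raw):
            raise ValueError("channel weights must be non-negative")
        total = sum(raw)
        if total <= 0:
            raise ValueError("channel weights must sum to a positive value")
        for name, w in zip(("w_all", "w_hydrophobic", "w_acceptor", "w_donor"), raw):
            object.__setattr__(self, name, w / total)

    def as_array(self) -> np.ndarray:
        return np.array([self.w_all, self.w_hydrophobic, self.w_acceptor, self.w_donor])

    @classmethod
    def parse(cls, text: str) -> "ChannelWeights":
        """Parse ``a,h,acc,don`` comma-separated weights."""
        parts = [float(p) for p in text.split(",")]
        if len(parts) != 4:
            raise ValueError("expected four comma-separated weights: all,hydrophobic,acceptor,donor")
        return cls(*parts)


def entry_weights(config: DescriptorConfig, weights: ChannelWeights) -> np.ndarray:
    """Per-entry weight vector so that S = 1/(1 + |q - c| . w_entries)."""
    if config.mode == MODE_USR:
        return np.full(12, 1.0 / 12.0)
    return np.repeat(weights.as_array(), 12) / 12.0


def _check_compatible(q: DescriptorVector, c: DescriptorVector) -> None:
    if q.config != c.config:
        raise ValueError(
            "descriptor conventions differ between query and candidate: "
            f"{q.config} vs {c.config}; vectors built with different "
            "conventions are never comparable"
        )


def score(
    q: DescriptorVector, c: DescriptorVector, weights: ChannelWeights | None = None
) -> float:
    """Similarity in (0, 1] between two same-convention vectors."""
    _check_compatible(q, c)
    if weights is None:
        weights = ChannelWeights()
    w = entry_weights(q.config, weights)
    return float(1.0 / (1.0 + np.abs(q.values - c.values) @ w))


def score_matrix(
    q: DescriptorVector, candidate_values: np.ndarray, weights: ChannelWeights | None = None
) -> np.ndarray:
    """Vectorized scores of the query against an (m, L) value matrix."""
    if weights is None:
        weights = ChannelWeights()
    w = entry_weights(q.config, weights)
    values = np.asarray(candidate_values, dtype=np.float64)
    return 1.0 / (1.0 + np.abs(values - q.values) @ w)


@dataclass(frozen=True)
class Hit:
    id: object
    score: float


@dataclass
class RankedHits:
    """Hits sorted by descending score; ties broken by ascending id."""

    hits: list[Hit]

    def ids(self) -> list:
        return [h.id for h in self.hits]

    def __len__(self) -> int:
        return len(self.hits)

    def __iter__(self):
        return iter(self.hits)

    def __getitem__(self, i):
        return self.hits[i]


class TopN:
    """Bounded top-N accumulator: O(n) memory over an arbitrary stream.

    Keeps a buffer of at most ``4n`` scored ids, compacting with a sort
    whenever it fills; equivalent to scoring everything and full-sorting,
    including the (descending score, ascending id) tie-break.
    """

    def __init__(self, n: int):
        if n < 1:
            raise ValueError("n must be >= 1")
        self.n = n
        self._buffer: list[tuple[float, object]] = []
        #: score of the current provisional cut-off, for cheap rejection
        self._floor: float | None = None

    def _compact(self) -> None:
        self._buffer.sort(key=lambda t: (-t[0], t[1]))
        del self._buffer[self.n :]
        if len(self._buffer) == self.n:
            self._floor = self._buffer[-1][0]

    def push(self, candidate_id, candidate_score: float) -> None:
        if self._floor is not None and candidate_score < self._floor:
            return
        self._buffer.append((candidate_score, candidate_id))
        if len(self._buffer) >= 4 * self.n:
            self._compact()

    def result(self) -> RankedHits:
        self._compact()
        return RankedHits([Hit(id=i, score=s) for s, i in self._buffer])


def rank(
    q: DescriptorVector,
    candidates: Iterable[tuple[object, DescriptorVector | np.ndarray]],
    n: int = 500,
    weights: ChannelWeights | None = None,
) -> RankedHits:
    """Top-``n`` candidates from a (possibly huge) stream, single pass.

    Candidate vectors may be ``DescriptorVector`` (conventions are then
    checked against the query) or bare value arrays assumed compatible.
    """
    if weights is None:
        weights = ChannelWeights()
    top = TopN(n)
    w = entry_weights(q.config, weights)
    qv = q.values
    for candidate_id, vec in candidates:
        if isinstance(vec, DescriptorVector):
            _check_compatible(q, vec)
            values = vec.values
        else:
            values = np.asarray(vec, dtype=np.float64)
        s = float(1.0 / (1.0 + np.abs(qv - values) @ w))
        top.push(candidate_id, s)
    return top.result()
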