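"""Shape/type moment descriptors.

A molecule is reduced to four atom distributions (all, hydrophobic,
H-bond acceptor, H-bond donor).  For each distribution the Euclidean
distances to four reference points are summarized by mean, variance and
skewness, giving 4 points x 3 moments = 12 values per distribution and
48 per molecule.  The plain-shape baseline uses the all-atom
distribution only (12 values).

Reference points:
  P1  geometric centre (unweighted centroid of heavy atoms)
  P2  atom closest to P1
  P3  atom furthest from P2
  P4  atom furthest from P3

All distances are rigid-transform invariant by construction, so the
descriptors need no molecular alignment.  They are also blind to
chirality: a mirror image yields identical values (a known limitation of
moment-based shape methods).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .atomtypes import CHANNELS, AtomTypeAssignment
from .molecule import Molecule3D

#: zero-variance guard below which skew is defined as 0
_VAR_EPS = 1e-12

MODE_UFSRAT = "ufsrat"
MODE_USR = "usr"
SKEW_STANDARDIZED = "standardized"
SKEW_CBRT = "cbrt-central"


@dataclass(frozen=True)
class DescriptorConfig:
    """Build conventions; recorded in the database header so scans can
    refuse queries built differently.

    per_channel_refpoints
        Recompute P1-P4 from each typed subset instead of sharing the
        all-heavy-atom points (default off: shared points preserve the
        spatial registration between channels).
    skew
        ``standardized`` (mu3 / sigma^3, zero-guarded) or ``cbrt-central``
        (signed cube root of the third central moment, in Angstrom).
    """

    mode: str = MODE_UFSRAT
    per_channel_refpoints: bool = False
    skew: str = SKEW_STANDARDIZED

    def __post_init__(self) -> None:
        if self.mode not in (MODE_UFSRAT, MODE_USR):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.skew not in (SKEW_STANDARDIZED, SKEW_CBRT):
            raise ValueError(f"unknown skew convention {self.skew!r}")

    @property
    def length(self) -> int:
        return 48 if self.mode == MODE_UFSRAT else 12


@dataclass(frozen=True)
class ReferencePoints:
    p1: np.ndarray
    p2: np.ndarray
    p3: np.ndarray
    p4: np.ndarray
    p2_index: int
    p3_index: int
    p4_index: int

    def as_array(self) -> np.ndarray:
        return np.stack([self.p1, self.p2, self.p3, self.p4])


@dataclass(frozen=True)
class MomentTriple:
    mean: float
    variance: float
    skew: float


@dataclass(frozen=True)
class DescriptorVector:
    """Ordered descriptor values plus the conventions that built them.

    Channel-major layout: [all, hydrophobic, acceptor, donor] blocks of
    [P1, P2, P3, P4] x [mean, variance, skew].
    """

    values: np.ndarray
    config: DescriptorConfig = field(default_factory=DescriptorConfig)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        if values.shape != (self.config.length,):
            raise ValueError(
                f"mode {self.config.mode!r} requires {self.config.length} values, "
                f"got shape {values.shape}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("descriptor values must be finite")

    @property
    def mode(self) -> str:
        return self.config.mode

    def at_single_precision(self) -> "DescriptorVector":
        """Values rounded through float32 — the database storage precision.

        Scans quantize the query this way so a molecule compared against
        its own stored record scores exactly 1.
        """
        return DescriptorVector(
            values=self.values.astype(np.float32).astype(np.float64), config=self.config
        )

    def __len__(self) -> int:
        return len(self.values)


def reference_points(coords: np.ndarray) -> ReferencePoints:
    """Select P1-P4 from a coordinate array.

    Ties in the nearest/furthest criteria are broken by lowest atom
    index, with exact floating-point comparison — deterministic for
    identical input coordinates on any platform.
    """
    coords = np.asarray(coords, dtype=np.float64)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] == 0:
        raise ValueError("coords must be a non-empty (N, 3) array")
    p1 = coords.mean(axis=0)
    # np.argmin/argmax return the first (lowest-index) extremum
    d1 = np.linalg.norm(coords - p1, axis=1)
    i2 = int(np.argmin(d1))
    d2 = np.linalg.norm(coords - coords[i2], axis=1)
    i3 = int(np.argmax(d2))
    d3 = np.linalg.norm(coords - coords[i3], axis=1)
    i4 = int(np.argmax(d3))
    return ReferencePoints(
        p1=p1,
        p2=coords[i2].copy(),
        p3=coords[i3].copy(),
        p4=coords[i4].copy(),
        p2_index=i2,
        p3_index=i3,
        p4_index=i4,
    )


def moments(distances, skew_convention: str = SKEW_STANDARDIZED) -> MomentTriple:
    """Mean, population variance and skew of a distance distribution.

    Population (1/N) moments throughout; N may be 1.  Skew is zero when
    the variance vanishes (single-atom and other degenerate cases).
    """
    d = np.asarray(distances, dtype=np.float64)
    if d.size == 0:
        raise ValueError("moments of an empty distribution are undefined")
    mean = float(d.mean())
    centred = d - mean
    variance = float(np.mean(centred**2))
    mu3 = float(np.mean(centred**3))
    if skew_convention == SKEW_STANDARDIZED:
        skew = 0.0 if variance < _VAR_EPS else mu3 / variance**1.5
    elif skew_convention == SKEW_CBRT:
        skew = float(np.cbrt(mu3))
    else:
        raise ValueError(f"unknown skew convention {skew_convention!r}")
    return MomentTriple(mean=mean, variance=variance, skew=skew)


def _block(coords: np.ndarray, refs: ReferencePoints, skew_convention: str) -> np.ndarray:
    """12 moment values for one atom subset against four reference points."""
    out = np.empty(12)
    for k, point in enumerate(refs.as_array()):
        m = moments(np.linalg.norm(coords - point, axis=1), skew_convention)
        out[3 * k : 3 * k + 3] = (m.mean, m.variance, m.skew)
    return out


def ufsrat_descriptors(
    mol: Molecule3D,
    types: AtomTypeAssignment,
    config: DescriptorConfig | None = None,
) -> DescriptorVector:
    """The 48-value typed descriptor vector of a hydrogen-stripped molecule.

    An empty typed channel contributes 12 zeros, so molecules that both
    lack (say) donors are maximally similar in that block.
    """
    if config is None:
        config = DescriptorConfig()
    if config.mode == MODE_USR:
        return usr_descriptors(mol, config)
    if len(types.hydrophobic) != len(mol.atoms):
        raise ValueError("type assignment does not match molecule atom count")
    coords = mol.coords
    shared_refs = reference_points(coords)
    values = np.zeros(48)
    for c, channel in enumerate(CHANNELS):
        subset = coords[types.mask(channel)]
        if subset.shape[0] == 0:
            continue
        refs = reference_points(subset) if config.per_channel_refpoints else shared_refs
        values[12 * c : 12 * c + 12] = _block(subset, refs, config.skew)
    return DescriptorVector(values=values, config=config)


def usr_descriptors(mol: Molecule3D, config: DescriptorConfig | None = None) -> DescriptorVector:
    """The 12-value all-atom (shape only) descriptor vector.

    Equals the first 12 entries of the typed vector built with the same
    conventions.
    """
    if config is None:
        config = DescriptorConfig(mode=MODE_USR)
    coords = mol.coords
    refs = reference_points(coords)
    values = _block(coords, refs, config.skew)
    usr_config = DescriptorConfig(
        mode=MODE_USR, per_channel_refpoints=config.per_channel_refpoints, skew=config.skew
    )
    return DescriptorVector(values=values, config=usr_config)
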