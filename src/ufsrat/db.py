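"""One-file binary store of pre-calculated descriptors.

Each record is exactly 200 bytes: a little-endian 64-bit unsigned
identifier followed by 48 IEEE-754 single-precision values (8 + 192
bytes).  At that density 3.8 million compounds fit in ~725 MiB, which is
what makes whole-library linear scans practical: a screen only ever
computes descriptors for the query and streams the pre-computed records.

The file opens with a small self-describing header (magic, version, and
the build conventions: mode, skew, reference-point scope) so a scan can
refuse a query whose descriptors were built differently.  A sidecar TSV
manifest maps record ids back to molecule names and byte offsets in the
source SD file, keeping hit retrieval self-contained.
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .atomtypes import TypingRules, assign_types
from .descriptors import (
    MODE_UFSRAT,
    MODE_USR,
    SKEW_CBRT,
    SKEW_STANDARDIZED,
    DescriptorConfig,
    DescriptorVector,
    ufsrat_descriptors,
    usr_descriptors,
)
from .molecule import Molecule3D, parse_sd, strip_hydrogens
from .similarity import ChannelWeights, RankedHits, TopN, score_matrix

logger = logging.getLogger(__name__)

MAGIC = b"UFSRATDB"
FORMAT_VERSION = 1
RECORD_STRUCT = struct.Struct("<Q48f")
RECORD_BYTES = RECORD_STRUCT.size  # 200
HEADER_STRUCT = struct.Struct("<8sHBBBxQ")
HEADER_BYTES = HEADER_STRUCT.size

RECORD_DTYPE = np.dtype([("id", "<u8"), ("values", "<f4", (48,))])

_MODE_CODES = {MODE_UFSRAT: 0, MODE_USR: 1}
_SKEW_CODES = {SKEW_STANDARDIZED: 0, SKEW_CBRT: 1}
_MODE_NAMES = {v: k for k, v in _MODE_CODES.items()}
_SKEW_NAMES = {v: k for k, v in _SKEW_CODES.items()}


@dataclass(frozen=True)
class DbRecord:
    id: int
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) != 48:
            raise ValueError(f"a record holds exactly 48 values, got {len(self.values)}")
        if not 0 <= self.id < 2**64:
            raise ValueError("id must fit an unsigned 64-bit integer")


def pack_record(record: DbRecord) -> bytes:
    """200 bytes: little-endian u64 id + 48 little-endian float32 values."""
    return RECORD_STRUCT.pack(record.id, *record.values)


def unpack_record(data: bytes) -> DbRecord:
    if len(data) != RECORD_BYTES:
        raise ValueError(f"a packed record is {RECORD_BYTES} bytes, got {len(data)}")
    fields = RECORD_STRUCT.unpack(data)
    return DbRecord(id=fields[0], values=tuple(fields[1:]))


def _pack_header(config: DescriptorConfig, count: int) -> bytes:
    return HEADER_STRUCT.pack(
        MAGIC,
        FORMAT_VERSION,
        _MODE_CODES[config.mode],
        _SKEW_CODES[config.skew],
        int(config.per_channel_refpoints),
        count,
    )


def _unpack_header(data: bytes) -> tuple[DescriptorConfig, int]:
    magic, version, mode, skew, per_channel, count = HEADER_STRUCT.unpack(data)
    if magic != MAGIC:
        raise ValueError("not a descriptor database (bad magic)")
    if version != FORMAT_VERSION:
        raise ValueError(f"unsupported format version {version}")
    config = DescriptorConfig(
        mode=_MODE_NAMES[mode], skew=_SKEW_NAMES[skew], per_channel_refpoints=bool(per_channel)
    )
    return config, count


@dataclass
class ManifestEntry:
    id: int
    name: str
    offset: int


class DescriptorDatabase:
    """Read-side handle over a built database file and its manifest."""

    def __init__(self, path: str | Path):
        self.path = Path(path)
        size = self.path.stat().st_size
        if size < HEADER_BYTES:
            raise ValueError(f"{self.path}: too short to hold a header")
        with open(self.path, "rb") as fh:
            self.config, self.count = _unpack_header(fh.read(HEADER_BYTES))
        body = size - HEADER_BYTES
        if body != RECORD_BYTES * self.count:
            raise ValueError(
                f"{self.path}: body is {body} bytes, expected "
                f"{RECORD_BYTES} x {self.count} records"
            )
        # memory-mapped so scans stream the file instead of loading it
        self._records = np.memmap(
            self.path, dtype=RECORD_DTYPE, mode="r", offset=HEADER_BYTES, shape=(self.count,)
        )

    @property
    def manifest_path(self) -> Path:
        return self.path.with_suffix(self.path.suffix + ".manifest.tsv")

    def load_manifest(self) -> dict[int, ManifestEntry]:
        entries: dict[int, ManifestEntry] = {}
        self.source_path: Path | None = None
        for line in self.manifest_path.read_text().splitlines():
            if line.startswith("#"):
                if line.startswith("# source:"):
                    self.source_path = Path(line.split(":", 1)[1].strip())
                continue
            rec_id, name, offset = line.split("\t")
            entries[int(rec_id)] = ManifestEntry(int(rec_id), name, int(offset))
        return entries

    def iter_chunks(self, chunk_size: int = 65536) -> Iterator[np.ndarray]:
        for start in range(0, self.count, chunk_size):
            yield self._records[start : start + chunk_size]

    def records(self) -> Iterator[tuple[int, np.ndarray]]:
        """(id, float64 values) stream, e.g. for the generic ranker.

        Records are fixed-width on disk; shape-only (12-value) databases
        are zero-padded, so values are trimmed to the configured length.
        """
        width = self.config.length
        for chunk in self.iter_chunks():
            for row in chunk:
                yield int(row["id"]), row["values"][:width].astype(np.float64)

    def scan(
        self,
        query: DescriptorVector,
        n: int = 500,
        weights: ChannelWeights | None = None,
        chunk_size: int = 65536,
    ) -> RankedHits:
        """Top-``n`` records by similarity to the query, one sequential pass.

        Candidate descriptors are never recomputed; stored float32 values
        are promoted to float64 for scoring.  Raises if the query was
        built with conventions different from the database header.
        """
        if query.config != self.config:
            raise ValueError(
                "descriptor convention mismatch, refusing to scan:\n"
                f"  database: {self.config}\n  query:    {query.config}"
            )
        # compare at the storage precision so a molecule matches its own
        # stored record exactly
        query = query.at_single_precision()
        top = TopN(n)
        width = self.config.length
        for chunk in self.iter_chunks(chunk_size):
            scores = score_matrix(query, chunk["values"][:, :width].astype(np.float64), weights)
            for rec_id, s in zip(chunk["id"], scores):
                top.push(int(rec_id), float(s))
        return top.result()


def compute_descriptors(
    mol: Molecule3D,
    rules: TypingRules | None = None,
    config: DescriptorConfig | None = None,
) -> DescriptorVector:
    """Strip hydrogens, type and describe one molecule."""
    if config is None:
        config = DescriptorConfig()
    heavy = strip_hydrogens(mol)
    if config.mode == MODE_USR:
        return usr_descriptors(heavy, config)
    types = assign_types(heavy, rules)
    return ufsrat_descriptors(heavy, types, config)


def write_db(
    out_path: str | Path,
    ids: Sequence[int],
    values: np.ndarray,
    config: DescriptorConfig | None = None,
) -> None:
    """Write a database file from pre-computed descriptor values.

    ``values`` is an (m, L) array; vectors shorter than 48 entries (the
    shape-only mode) are zero-padded to the fixed record width.
    """
    if config is None:
        config = DescriptorConfig()
    values = np.asarray(values)
    if len(ids) != values.shape[0]:
        raise ValueError("ids and values must have matching lengths")
    if len(ids) == 0:
        raise ValueError("a database must hold at least one record")
    records = np.zeros(len(ids), dtype=RECORD_DTYPE)
    records["id"] = np.asarray(ids, dtype=np.uint64)
    records["values"][:, : values.shape[1]] = values.astype(np.float32)
    with open(Path(out_path), "wb") as fh:
        fh.write(_pack_header(config, len(ids)))
        fh.write(records.tobytes())


def build_db(
    sd_source,
    out_path: str | Path,
    rules: TypingRules | None = None,
    config: DescriptorConfig | None = None,
) -> DescriptorDatabase:
    """Pre-calculate descriptors for every molecule of an SD file.

    Ids are assigned sequentially in input order; records that fail to
    parse or describe are skipped with a logged reason and never cause
    renumbering of ids already assigned.  The build is deterministic:
    identical input and conventions give byte-identical files.
    """
    if config is None:
        config = DescriptorConfig()
    out_path = Path(out_path)
    parsed = parse_sd(sd_source)
    for err in parsed.errors:
        logger.warning("build_db: skipped record %d: %s", err.record_index, err.reason)

    values_f32 = []
    manifest: list[ManifestEntry] = []
    next_id = 0
    for mol in parsed.molecules:
        try:
            vec = compute_descriptors(mol, rules, config)
        except ValueError as exc:
            logger.warning("build_db: skipped molecule %s: %s", mol.id, exc)
            continue
        padded = np.zeros(48, dtype=np.float32)
        padded[: len(vec.values)] = vec.values.astype(np.float32)
        values_f32.append(padded)
        manifest.append(ManifestEntry(next_id, mol.id, mol.source_offset or 0))
        next_id += 1

    if not manifest:
        raise ValueError("build_db: no molecule could be processed")

    write_db(out_path, [e.id for e in manifest], np.stack(values_f32), config)

    db = DescriptorDatabase(out_path)
    source_line = ""
    if isinstance(sd_source, (str, Path)) and Path(str(sd_source)).exists():
        source_line = f"# source: {sd_source}\n"
    with open(db.manifest_path, "w") as fh:
        fh.write("# id\tname\toffset\n")
        fh.write(source_line)
        for e in manifest:
            fh.write(f"{e.id}\t{e.name}\t{e.offset}\n")
    return db


def fetch_hits(
    hits: RankedHits,
    manifest: dict[int, ManifestEntry],
    source_sd: str | Path,
) -> list[Molecule3D]:
    """Retrieve hit molecules from the source SD file, in hit order."""
    missing = [h.id for h in hits if h.id not in manifest]
    if missing:
        raise KeyError(f"ids missing from manifest: {missing}")
    if not len(hits):
        return []
    raw = Path(source_sd).read_bytes()
    out = []
    for h in hits:
        entry = manifest[h.id]
        end = raw.find(b"$$$$", entry.offset)
        block = raw[entry.offset : end if end >= 0 else len(raw)] + b"$$$$\n"
        parsed = parse_sd(block.decode("utf-8"))
        if not parsed.molecules:
            raise ValueError(
                f"manifest offset {entry.offset} for id {h.id} does not "
                f"address a parseable record in {source_sd}"
            )
        mol = parsed.molecules[0]
        mol.id = entry.name
        mol.source_offset = entry.offset
        out.append(mol)
    return out
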