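"""Plasmid sequence records, canonical k-mer sets and basic composition statistics.

Plasmid genomes are compared alignment-free: each sequence is decomposed into
its set of k-mers (k = 21 by default) and similarity downstream is set overlap.
Because plasmids are double-stranded, k-mers are canonicalized by default: each
window is replaced by the lexicographic minimum of itself and its reverse
complement, so the two strands of the same molecule yield the same set.

Sequences are treated as linear even though most plasmids are circular;
windows spanning the origin are not generated (the effect is at most k-1
k-mers per molecule). Windows containing any non-ACGT symbol are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import logging

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "TAXONOMY_RANKS",
    "PlasmidRecord",
    "KmerSet",
    "read_plasmids",
    "read_metadata",
    "extract_kmers",
    "gc_content",
]

#: Taxonomic ranks recognised in metadata, from broadest to narrowest.
TAXONOMY_RANKS = ("phylum", "class", "order", "family", "genus", "species")

_METADATA_COLUMNS = ("id",) + TAXONOMY_RANKS + ("replicon_types", "mob_types")


@dataclass
class PlasmidRecord:
    """One plasmid: identifier, nucleotide sequence and typing metadata.

    Parameters
    ----------
    id :
        Unique identifier within a dataset.
    sequence :
        Nucleotide string over the IUPAC alphabet (upper- or lower-case).
    host_lineage :
        Ordered rank -> taxon mapping (``phylum`` ... ``species``); ranks may
        be missing for poorly annotated hosts.
    replicon_types :
        Replicon (incompatibility-group) labels; empty when untyped. A plasmid
        may carry genes from more than one replication machinery and hence
        hold several labels.
    mob_types :
        Relaxase-based mobility (MOB) labels; empty when untyped.
    """

    id: str
    sequence: str
    host_lineage: dict[str, str] = field(default_factory=dict)
    replicon_types: set[str] = field(default_factory=set)
    mob_types: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("plasmid id must be nonempty")
        if len(self.sequence) < 1:
            raise ValueError(f"plasmid {self.id!r}: sequence must be nonempty")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def gc(self) -> float:
        """GC fraction of the sequence (non-ACGT symbols excluded)."""
        return gc_content(self)


@dataclass(frozen=True)
class KmerSet:
    """The set of canonical k-mers of one plasmid.

    ``kmers`` holds plain ``str`` k-mers over {A, C, G, T}; set semantics means
    multiplicities are discarded, which is what the Jaccard index requires.
    """

    plasmid_id: str
    k: int
    kmers: frozenset[str]

    @property
    def n_kmers(self) -> int:
        return len(self.kmers)


# --- FASTA + metadata reading -------------------------------------------------


def _parse_multivalue(cell: str) -> set[str]:
    cell = cell.strip()
    if not cell or cell in {"-", "NA", "na", "."}:
        return set()
    return {part.strip() for part in cell.split(";") if part.strip()}


def read_metadata(metadata_path: str | Path) -> dict[str, dict]:
    """Read the tab-separated plasmid metadata table.

    Expected header: ``id``, the six taxonomy ranks, ``replicon_types``,
    ``mob_types``. Multi-valued cells are ";"-separated. Empty cells, ``-``,
    ``.`` and ``NA`` denote missing values.

    Returns a mapping id -> {"host_lineage", "replicon_types", "mob_types"}.
    """
    path = Path(metadata_path)
    meta: dict[str, dict] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = [c for c in _METADATA_COLUMNS if c not in header]
        if missing:
            raise ValueError(f"metadata {path}: missing columns {missing}")
        col = {name: header.index(name) for name in _METADATA_COLUMNS}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise ValueError(
                    f"metadata {path} line {lineno}: expected "
                    f"{len(header)} fields, found {len(fields)}"
                )
            pid = fields[col["id"]].strip()
            if not pid:
                raise ValueError(f"metadata {path} line {lineno}: empty id")
            if pid in meta:
                raise ValueError(f"metadata {path} line {lineno}: duplicate id {pid!r}")
            lineage = {}
            for rank in TAXONOMY_RANKS:
                taxon = fields[col[rank]].strip()
                if taxon and taxon not in {"-", "NA", "na", "."}:
                    lineage[rank] = taxon
            meta[pid] = {
                "host_lineage": lineage,
                "replicon_types": _parse_multivalue(fields[col["replicon_types"]]),
                "mob_types": _parse_multivalue(fields[col["mob_types"]]),
            }
    return meta


def read_plasmids(
    fasta_path: str | Path,
    metadata_path: Optional[str | Path] = None,
) -> list[PlasmidRecord]:
    """Read plasmid sequences from FASTA, optionally joined with metadata.

    One record is returned per FASTA entry, in input order. Records absent
    from the metadata table get an empty lineage and empty typing sets.
    Metadata rows with no matching FASTA entry are tolerated (the table may
    describe a superset); any id mismatch in either direction is reported
    through the module logger so curation problems are visible.

    Raises
    ------
    ValueError
        On duplicated FASTA ids (naming the id) or malformed metadata rows
        (naming the line number).
    """
    meta = read_metadata(metadata_path) if metadata_path is not None else {}
    records: list[PlasmidRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(fasta_path), "fasta"):
        pid = entry.id
        if pid in seen:
            raise ValueError(f"duplicate FASTA id {pid!r} in {fasta_path}")
        seen.add(pid)
        info = meta.get(pid, None)
        records.append(
            PlasmidRecord(
                id=pid,
                sequence=str(entry.seq).upper(),
                host_lineage=dict(info["host_lineage"]) if info else {},
                replicon_types=set(info["replicon_types"]) if info else set(),
                mob_types=set(info["mob_types"]) if info else set(),
            )
        )
    if meta:
        fasta_only = seen - meta.keys()
        meta_only = meta.keys() - seen
        if fasta_only:
            logger.warning(
                "%d FASTA record(s) without metadata row (e.g. %s)",
                len(fasta_only), sorted(fasta_only)[0],
            )
        if meta_only:
            logger.warning(
                "%d metadata row(s) without FASTA record (e.g. %s)",
                len(meta_only), sorted(meta_only)[0],
            )
    return records


# --- k-mer extraction ---------------------------------------------------------

# 2-bit encoding; complement of code v is 3 - v.
_BASE_CODES = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODES[_b] = _i
    _BASE_CODES[_b + 32] = _i  # lower case
_CODE_TO_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)


def _decode_codes(codes: np.ndarray, k: int) -> frozenset[str]:
    """Turn packed base-4 k-mer codes back into length-k ACGT strings."""
    if codes.size == 0:
        return frozenset()
    digits = np.empty((codes.size, k), dtype=np.int64)
    rem = codes.copy()
    for pos in range(k - 1, -1, -1):
        digits[:, pos] = rem & 3
        rem >>= 2
    letters = _CODE_TO_BASE[digits]
    flat = letters.tobytes()
    return frozenset(
        flat[i * k : (i + 1) * k].decode("ascii") for i in range(codes.size)
    )


def extract_kmers(
    record: PlasmidRecord | str,
    k: int = 21,
    canonical: bool = True,
    plasmid_id: str = "",
) -> KmerSet:
    """Decompose a sequence into its set of (canonical) k-mers.

    Windows containing a non-ACGT symbol are skipped. With ``canonical=True``
    each window is replaced by min(window, reverse_complement(window)) before
    insertion, collapsing the two strands. Sequences shorter than ``k`` yield
    an empty set.

    Packed 2-bit integer codes are used internally so the sliding windows are
    computed vectorially; requires ``2*k`` bits to fit an int64 (k <= 31).
    """
    if isinstance(record, PlasmidRecord):
        seq, pid = record.sequence, record.id
    else:
        seq, pid = record, plasmid_id
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > 31:
        raise ValueError("k must be <= 31 (packed 2-bit encoding)")
    n = len(seq)
    if n < k:
        return KmerSet(plasmid_id=pid, k=k, kmers=frozenset())

    codes = _BASE_CODES[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    valid = codes != 255
    # windows of length k with all positions valid
    win_valid = (
        np.convolve(valid.astype(np.int64), np.ones(k, dtype=np.int64), "valid") == k
    )
    if not win_valid.any():
        return KmerSet(plasmid_id=pid, k=k, kmers=frozenset())

    vals = codes.astype(np.int64)
    vals[~valid] = 0  # placeholder; invalid windows are masked out below
    windows = np.lib.stride_tricks.sliding_window_view(vals, k)[win_valid]
    fwd_weights = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    fwd = windows @ fwd_weights
    if canonical:
        # reverse complement: complement each base (3 - v), reverse the order
        rev = (3 - windows) @ fwd_weights[::-1]
        packed = np.minimum(fwd, rev)
    else:
        packed = fwd
    return KmerSet(plasmid_id=pid, k=k, kmers=_decode_codes(np.unique(packed), k))


def gc_content(record: PlasmidRecord | str) -> float:
    """GC fraction: (#G + #C) / (#A + #C + #G + #T), non-ACGT symbols excluded.

    Raises
    ------
    ValueError
        If the sequence contains no ACGT symbol at all.
    """
    seq = record.sequence if isinstance(record, PlasmidRecord) else record
    up = seq.upper()
    gc = up.count("G") + up.count("C")
    at = up.count("A") + up.count("T")
    if gc + at == 0:
        raise ValueError("GC content undefined: sequence has no ACGT symbols")
    return gc / (gc + at)
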