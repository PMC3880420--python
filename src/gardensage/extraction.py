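"""Parse raw DeepSAGE reads into (library, mono-tag) assignments.

A valid read starts with the CATG anchoring-enzyme site, followed by the
17-base gene-specific tag, followed by the downstream adaptor that carries a
3-bp library key at a configurable offset. Reads failing any of these checks
are returned as typed rejections and counted, never silently dropped.
Matching is exact (no mismatch tolerance): downstream error control is
frequency-based filtering, not fuzzy matching.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Union

import pandas as pd

from .errors import InvalidConfigError
from .matrix import ANCHOR, KEY_LENGTH, NUCLEOTIDES, TAG_LENGTH, LibraryKey, TagCountMatrix

REJECTION_REASONS = ("too_short", "bad_anchor", "unknown_key", "ambiguous_tag")


@dataclass(frozen=True)
class AdaptorSpec:
    """Where to find the library key downstream of the tag.

    ``key_offset`` is the number of adaptor bases between the end of the
    17-base tag and the key (default 0: the key immediately follows the
    tag). ``scan_window`` > 0 permits the CATG anchor to start within the
    first ``scan_window`` + 1 read positions; the default requires it at
    position 0, matching libraries sequenced from the anchoring site.
    """

    key_offset: int = 0
    scan_window: int = 0

    def __post_init__(self):
        if self.key_offset < 0 or self.scan_window < 0:
            raise InvalidConfigError("key_offset and scan_window must be >= 0")

    @property
    def min_read_length(self) -> int:
        return len(ANCHOR) + TAG_LENGTH + self.key_offset + KEY_LENGTH


@dataclass(frozen=True)
class Rejection:
    reason: str


@dataclass(frozen=True)
class ParsedRead:
    library_id: str
    tag_sequence: str


def parse_read(
    read: str,
    keys: list[LibraryKey] | dict[str, str],
    spec: AdaptorSpec = AdaptorSpec(),
) -> Union[ParsedRead, Rejection]:
    """Assign one read to a library and extract its 17-base tag.

    ``keys`` maps 3-bp key -> library id (a list of LibraryKey is accepted).
    Returns a ParsedRead on success, otherwise a Rejection with reason
    ``too_short``, ``bad_anchor``, ``unknown_key`` or ``ambiguous_tag`` (tag
    containing non-ACGT bases, e.g. N calls).
    """
    if not isinstance(keys, dict):
        keys = {lk.key: lk.library_id for lk in keys}
    start = _find_anchor(read, spec)
    if start is None:
        # distinguish length failures from anchor failures
        if len(read) < spec.min_read_length:
            return Rejection("too_short")
        return Rejection("bad_anchor")
    if len(read) - start < spec.min_read_length:
        return Rejection("too_short")
    tag_start = start + len(ANCHOR)
    tag = read[tag_start:tag_start + TAG_LENGTH]
    key_start = tag_start + TAG_LENGTH + spec.key_offset
    key = read[key_start:key_start + KEY_LENGTH]
    if key not in keys:
        return Rejection("unknown_key")
    if not set(tag) <= NUCLEOTIDES:
        return Rejection("ambiguous_tag")
    return ParsedRead(keys[key], tag)


def _find_anchor(read: str, spec: AdaptorSpec):
    for start in range(spec.scan_window + 1):
        if read.startswith(ANCHOR, start):
            return start
    return None


def count_tags(
    reads: Iterable[str],
    keys: list[LibraryKey],
    spec: AdaptorSpec = AdaptorSpec(),
) -> tuple[TagCountMatrix, dict[str, int]]:
    """Aggregate reads into a raw tag-count matrix plus a rejection summary.

    Tag ids are assigned by lexicographic order of the 17-base sequence, so
    the result is independent of read order. The rejection summary has one
    entry per rejection reason plus ``accepted``; accepted + rejected always
    equals the number of input reads.
    """
    if not keys:
        raise InvalidConfigError("key list must be nonempty")
    key_map = {lk.key: lk.library_id for lk in keys}
    if len(key_map) != len(keys):
        raise InvalidConfigError("library keys are not unique")

    summary = {reason: 0 for reason in REJECTION_REASONS}
    summary["accepted"] = 0
    cell_counts: Counter[tuple[str, str]] = Counter()
    for read in reads:
        parsed = parse_read(read, key_map, spec)
        if isinstance(parsed, Rejection):
            summary[parsed.reason] += 1
        else:
            summary["accepted"] += 1
            cell_counts[(parsed.tag_sequence, parsed.library_id)] += 1

    sequences = sorted({seq for seq, _ in cell_counts})
    tag_ids = pd.Index(range(1, len(sequences) + 1), name="tag_id")
    lib_ids = [lk.library_id for lk in keys]
    counts = pd.DataFrame(0, index=tag_ids, columns=lib_ids, dtype=int)
    id_of = {seq: i for seq, i in zip(sequences, tag_ids)}
    for (seq, lib), n in cell_counts.items():
        counts.loc[id_of[seq], lib] = n
    matrix = TagCountMatrix(
        counts=counts,
        sequences=pd.Series(sequences, index=tag_ids, dtype=object),
        libraries=list(keys),
        state="raw",
    )
    return matrix, summary
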