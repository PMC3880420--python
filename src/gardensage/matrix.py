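"""Core containers for DeepSAGE mono-tags and tag-count matrices.

A mono-tag is the gene-specific part of a DeepSAGE read: the 4-bp anchoring
enzyme site CATG followed by a 17-bp unique sequence. Tags are stored
*without* the shared CATG (17 bases), matching the convention of published
tag tables; the 21-base form is reconstructed by prefixing CATG where a
genomic search needs it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DesignError, InvalidConfigError

ANCHOR = "CATG"
TAG_LENGTH = 17
KEY_LENGTH = 3
NUCLEOTIDES = frozenset("ACGT")

#: Garden sections compared by the differential-expression stage, in
#: top-to-bottom order of the decomposition gradient.
GARDEN_SECTIONS = ("top", "middle", "bottom")

RAW = "raw"
NORMALIZED = "normalized"


@dataclass(frozen=True)
class MonoTag:
    """A 17-base mono-tag (CATG anchor omitted) with a stable integer id."""

    tag_id: int
    sequence: str

    def __post_init__(self):
        if len(self.sequence) != TAG_LENGTH:
            raise InvalidConfigError(
                f"tag {self.tag_id}: sequence must be {TAG_LENGTH} bases, "
                f"got {len(self.sequence)}"
            )
        if not set(self.sequence) <= NUCLEOTIDES:
            raise InvalidConfigError(
                f"tag {self.tag_id}: sequence contains non-ACGT characters"
            )

    @property
    def anchored_sequence(self) -> str:
        """The full 21-base tag including the CATG anchor."""
        return ANCHOR + self.sequence


@dataclass(frozen=True)
class LibraryKey:
    """A sequencing library: its 3-bp demultiplexing key and section label.

    ``section`` is the garden section the RNA sample came from (``top``,
    ``middle``, ``bottom``) or another condition label (e.g. a pure-culture
    medium); libraries whose section is not among the tested sections are
    carried through filtering but excluded from section comparisons.
    """

    key: str
    library_id: str
    section: str

    def __post_init__(self):
        if len(self.key) != KEY_LENGTH or not set(self.key) <= NUCLEOTIDES:
            raise InvalidConfigError(
                f"library {self.library_id}: key must be {KEY_LENGTH} ACGT bases"
            )


@dataclass
class TagCountMatrix:
    """Tags x libraries count table with a raw/normalized state flag.

    ``counts`` is indexed by integer tag id with one column per library id;
    ``sequences`` maps tag id to the 17-base tag sequence; ``libraries``
    carries the demultiplexing key and section design for every column.
    """

    counts: pd.DataFrame
    sequences: pd.Series
    libraries: list[LibraryKey] = field(default_factory=list)
    state: str = RAW

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.state not in (RAW, NORMALIZED):
            raise InvalidConfigError(f"unknown matrix state {self.state!r}")
        lib_ids = [lk.library_id for lk in self.libraries]
        if len(set(lib_ids)) != len(lib_ids):
            raise InvalidConfigError("duplicate library ids")
        keys = [lk.key for lk in self.libraries]
        if len(set(keys)) != len(keys):
            raise InvalidConfigError("library keys are not unique")
        if list(self.counts.columns) != lib_ids:
            raise InvalidConfigError("count columns do not match library list")
        if not self.counts.index.equals(self.sequences.index):
            raise InvalidConfigError("counts and sequences index mismatch")
        if (np.asarray(self.counts) < 0).any():
            raise InvalidConfigError("negative counts")
        if self.state == RAW and len(self.counts):
            arr = np.asarray(self.counts)
            if not np.allclose(arr, np.round(arr)):
                raise InvalidConfigError("raw counts must be integers")

    # -- views ----------------------------------------------------------------

    @property
    def n_tags(self) -> int:
        return len(self.counts)

    @property
    def library_ids(self) -> list[str]:
        return [lk.library_id for lk in self.libraries]

    def section_of(self) -> dict[str, str]:
        """Mapping library id -> section label."""
        return {lk.library_id: lk.section for lk in self.libraries}

    def section_libraries(self, section: str) -> list[str]:
        libs = [lk.library_id for lk in self.libraries if lk.section == section]
        if not libs:
            raise DesignError(f"no libraries assigned to section {section!r}")
        return libs

    def library_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def tag_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    # -- manipulation ----------------------------------------------------------

    def subset(self, tag_ids) -> "TagCountMatrix":
        """A copy restricted to ``tag_ids`` (library set unchanged)."""
        idx = self.counts.index.intersection(pd.Index(tag_ids))
        return TagCountMatrix(
            counts=self.counts.loc[idx].copy(),
            sequences=self.sequences.loc[idx].copy(),
            libraries=list(self.libraries),
            state=self.state,
        )

    def copy(self) -> "TagCountMatrix":
        return TagCountMatrix(
            counts=self.counts.copy(),
            sequences=self.sequences.copy(),
            libraries=list(self.libraries),
            state=self.state,
        )

    def with_counts(self, counts: pd.DataFrame, state: str) -> "TagCountMatrix":
        return TagCountMatrix(
            counts=counts,
            sequences=self.sequences.loc[counts.index].copy(),
            libraries=list(self.libraries),
            state=state,
        )

    def tags(self) -> list[MonoTag]:
        return [MonoTag(int(i), s) for i, s in self.sequences.items()]


def auto_library_keys(n: int) -> list[str]:
    """Deterministic distinct 3-base keys: AAA, AAC, AAG, ... in lexicographic
    order. Raises if more than 64 are requested."""
    if n > 4 ** KEY_LENGTH:
        raise InvalidConfigError(f"cannot generate {n} distinct 3-base keys")
    keys = []
    alphabet = "ACGT"
    for i in range(n):
        a, rem = divmod(i, 16)
        b, c = divmod(rem, 4)
        keys.append(alphabet[a] + alphabet[b] + alphabet[c])
    return keys


def reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
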