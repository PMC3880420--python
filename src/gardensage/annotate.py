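"""Extend mono-tags into contig fragments for protein-level annotation.

A 17-base tag is re-anchored (CATG prefixed) and searched exactly against
both strands of an EST contig set; every occurrence is extended by up to 50
bases of flank on each side, giving the minimum 121-bp fragment used as a
BLASTX query when both flanks are complete. Fragments are reported on the
contig's forward strand with a strand flag; coordinates are 0-based,
half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .matrix import MonoTag, reverse_complement


@dataclass(frozen=True)
class ContigMatch:
    tag_id: int
    contig_id: str
    start: int            # 0-based start of the 21-base CATG+tag (forward coords)
    end: int              # half-open end of the 21-base match
    strand: str           # "+" or "-"
    fragment: str         # forward-strand fragment including flanks
    fragment_complete: bool
    ambiguous: bool = False


def _occurrences(haystack: str, needle: str):
    start = haystack.find(needle)
    while start != -1:
        yield start
        start = haystack.find(needle, start + 1)


def match_tag_to_contigs(
    tag: MonoTag,
    contigs: Mapping[str, str] | Iterable[tuple[str, str]],
    flank: int = 50,
) -> list[ContigMatch]:
    """Every exact placement of CATG+tag (either strand) with its fragment.

    ``fragment_complete`` is True when at least ``flank`` bases exist on
    both sides of the 21-base match. When the tag hits more than one place
    (multi-mapping), all matches are returned flagged ambiguous. No match
    returns an empty list.
    """
    if not isinstance(contigs, Mapping):
        contigs = dict(contigs)
    forward = tag.anchored_sequence
    reverse = reverse_complement(forward)
    matches: list[ContigMatch] = []
    for contig_id, seq in contigs.items():
        for strand, needle in (("+", forward), ("-", reverse)):
            for start in _occurrences(seq, needle):
                end = start + len(needle)
                frag_start = max(0, start - flank)
                frag_end = min(len(seq), end + flank)
                matches.append(ContigMatch(
                    tag_id=tag.tag_id, contig_id=contig_id,
                    start=start, end=end, strand=strand,
                    fragment=seq[frag_start:frag_end],
                    fragment_complete=(start >= flank
                                       and end + flank <= len(seq)),
                ))
    if len(matches) > 1:
        matches = [ContigMatch(**{**m.__dict__, "ambiguous": True})
                   for m in matches]
    return matches


def match_all(tags: Iterable[MonoTag], contigs, flank: int = 50) -> list[ContigMatch]:
    out = []
    for tag in tags:
        out.extend(match_tag_to_contigs(tag, contigs, flank=flank))
    return out


def export_blast_queries(
    matches: Sequence[ContigMatch],
    only_complete: bool = True,
) -> list[tuple[str, str]]:
    """FASTA-writable (id, fragment) pairs for the retained matches.

    Record ids are ``tagid|contigid|strand``; by default only matches with
    both flanks complete (the minimum-121-bp criterion) are exported. In the
    rare case of duplicate ids (one tag hitting one contig twice on the same
    strand) the match start is appended to keep ids unique.
    """
    retained = [m for m in matches if m.fragment_complete or not only_complete]
    ids = [f"{m.tag_id}|{m.contig_id}|{m.strand}" for m in retained]
    seen: dict[str, int] = {}
    records = []
    for rid, m in zip(ids, retained):
        if ids.count(rid) > 1:
            rid = f"{rid}|{m.start}"
        records.append((rid, m.fragment))
    return records


def matches_to_frame(matches: Sequence[ContigMatch]) -> pd.DataFrame:
    return pd.DataFrame(
        [(m.tag_id, m.contig_id, m.start, m.end, m.strand,
          m.fragment_complete, m.ambiguous) for m in matches],
        columns=["tag_id", "contig_id", "start", "end", "strand",
                 "complete", "ambiguous"],
    )
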