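"""Peptide pattern recognition: alignment-free enzyme-function assignment.

Protein families (e.g. glycoside hydrolase subgroups labelled by EC number)
are characterized by short conserved peptides: every overlapping 5-mer of
every member is scored by the fraction of class members containing it
(coverage) and by its enrichment over non-class members; peptides passing
both thresholds form the class's characteristic set. A query sequence is
decomposed into its overlapping 5-mers and assigned to the class holding
the strict majority of matched peptides; ties and zero matches are reported
as unclassified with all candidate counts.

This is a documented reconstruction of the published peptide-pattern-
recognition approach, not a port of the original program; thresholds are
this package's stated defaults.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .errors import InvalidConfigError, TooShortError
from .simulate import AMINO_ACIDS

_STANDARD_AA = frozenset(AMINO_ACIDS)


@dataclass
class PPRModel:
    """Per-class characteristic n-mer peptide sets with their scores.

    ``peptides[class][nmer] = (coverage, enrichment)`` where coverage is the
    fraction of class members containing the peptide and enrichment is that
    coverage divided by the fraction of non-class members containing it
    (inf when no outside member does). ``empty_classes`` lists classes whose
    characteristic set came out empty.
    """

    nmer: int
    classes: list[str]
    peptides: dict[str, dict[str, tuple[float, float]]]
    min_coverage: float = 0.5
    min_enrichment: float = 5.0
    empty_classes: list[str] = field(default_factory=list)

    def characteristic_set(self, label: str) -> frozenset[str]:
        return frozenset(self.peptides[label])

    def to_frame(self) -> pd.DataFrame:
        rows = [(label, pep, cov, enr)
                for label, peps in self.peptides.items()
                for pep, (cov, enr) in sorted(peps.items())]
        return pd.DataFrame(rows, columns=["class", "nmer", "coverage",
                                           "enrichment"])


@dataclass(frozen=True)
class PPRCall:
    query_id: str
    predicted: str | None            # None = unclassified
    counts: dict[str, int]           # matched-peptide count per class
    majority_fraction: float         # top count / total matched (0 if none)
    candidates: tuple[str, ...] = () # argmax classes (several on a tie)


def _valid_windows(sequence: str, n: int) -> list[str]:
    """All overlapping n-mers over the standard 20-letter alphabet; windows
    containing X, gaps or other symbols are skipped."""
    seq = sequence.upper()
    return [seq[i:i + n] for i in range(len(seq) - n + 1)
            if set(seq[i:i + n]) <= _STANDARD_AA]


def train_ppr(
    labeled_sequences: Iterable[tuple[str, str, str]],
    nmer: int = 5,
    min_coverage: float = 0.5,
    min_enrichment: float = 5.0,
) -> PPRModel:
    """Learn characteristic peptide sets from (id, class label, sequence)
    records. Needs at least two classes with at least two members each."""
    if not 0 < min_coverage <= 1:
        raise InvalidConfigError("min_coverage must be in (0, 1]")
    members: dict[str, list[frozenset[str]]] = {}
    for _, label, seq in labeled_sequences:
        members.setdefault(label, []).append(frozenset(_valid_windows(seq, nmer)))
    if len(members) < 2:
        raise InvalidConfigError("training needs at least 2 classes")
    for label, mem in members.items():
        if len(mem) < 2:
            raise InvalidConfigError(f"class {label!r} has fewer than 2 members")

    classes = sorted(members)
    presence = {label: Counter(pep for kmers in mem for pep in kmers)
                for label, mem in members.items()}
    n_members = {label: len(mem) for label, mem in members.items()}
    total_members = sum(n_members.values())
    total_presence: Counter[str] = Counter()
    for cnt in presence.values():
        total_presence.update(cnt)

    peptides: dict[str, dict[str, tuple[float, float]]] = {}
    empty = []
    for label in classes:
        n_in = n_members[label]
        n_out = total_members - n_in
        selected = {}
        for pep, count_in in presence[label].items():
            coverage = count_in / n_in
            if coverage < min_coverage:
                continue
            out_fraction = (total_presence[pep] - count_in) / n_out
            enrichment = float("inf") if out_fraction == 0 else coverage / out_fraction
            if enrichment >= min_enrichment:
                selected[pep] = (coverage, enrichment)
        peptides[label] = selected
        if not selected:
            empty.append(label)
    return PPRModel(nmer=nmer, classes=classes, peptides=peptides,
                    min_coverage=min_coverage, min_enrichment=min_enrichment,
                    empty_classes=empty)


def classify_sequence(query: str, model: PPRModel,
                      query_id: str = "query") -> PPRCall:
    """Assign a query to the class holding the strict majority of its
    matched peptides (each overlapping window counted once per class whose
    characteristic set contains it)."""
    if len(query) < model.nmer:
        raise TooShortError(
            f"query length {len(query)} < n-mer length {model.nmer}"
        )
    windows = _valid_windows(query, model.nmer)
    sets = {label: model.characteristic_set(label) for label in model.classes}
    counts = {label: sum(w in sets[label] for w in windows)
              for label in model.classes}
    total = sum(counts.values())
    if total == 0:
        return PPRCall(query_id, None, counts, 0.0)
    top = max(counts.values())
    winners = tuple(sorted(c for c, n in counts.items() if n == top))
    predicted = winners[0] if len(winners) == 1 else None
    return PPRCall(query_id, predicted, counts, top / total, winners)


def classify_all(queries: Iterable[tuple[str, str]],
                 model: PPRModel) -> list[PPRCall]:
    return [classify_sequence(seq, model, query_id=qid) for qid, seq in queries]


def calls_to_frame(calls: Sequence[PPRCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = {"query_id": c.query_id,
               "predicted": c.predicted if c.predicted else "unclassified",
               "majority_fraction": c.majority_fraction,
               "candidates": ",".join(c.candidates)}
        for label, n in c.counts.items():
            row[f"matched_{label}"] = n
        rows.append(row)
    return pd.DataFrame(rows)


def model_to_tsv(model: PPRModel, path) -> None:
    model.to_frame().to_csv(path, sep="\t", index=False)


def model_from_tsv(path, nmer: int | None = None,
                   min_coverage: float = 0.5,
                   min_enrichment: float = 5.0) -> PPRModel:
    df = pd.read_csv(path, sep="\t")
    peptides: dict[str, dict[str, tuple[float, float]]] = {}
    for _, row in df.iterrows():
        peptides.setdefault(str(row["class"]), {})[str(row["nmer"])] = (
            float(row["coverage"]), float(row["enrichment"]))
    lengths = {len(p) for peps in peptides.values() for p in peps}
    inferred = nmer or (lengths.pop() if len(lengths) == 1 else 5)
    return PPRModel(nmer=inferred, classes=sorted(peptides),
                    peptides=peptides, min_coverage=min_coverage,
                    min_enrichment=min_enrichment,
                    empty_classes=[c for c, p in peptides.items() if not p])
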