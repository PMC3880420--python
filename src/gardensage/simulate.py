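"""Synthetic-data generators with known ground truth.

Everything downstream of sequencing is testable against these generators:
reference contigs with planted tag placements, DeepSAGE reads carrying a
3-bp library key in the downstream adaptor, negative-binomial replicate
count matrices with designed per-section effects, and labelled protein
families carrying planted 5-mer peptide motifs.

The default design mirrors the fungus-garden study layout: three sections
(top, middle, bottom) with 5/4/5 biological replicate libraries. Replicate
counts are negative-binomial with variance mu + dispersion * mu^2;
dispersion 0 degenerates to Poisson. All generators are pure functions of
(config, seed).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, MissingTagError
from .matrix import (
    ANCHOR,
    GARDEN_SECTIONS,
    TAG_LENGTH,
    LibraryKey,
    TagCountMatrix,
    auto_library_keys,
    reverse_complement,
)

#: Constant downstream adaptor used in simulated reads. The 3-bp library key
#: is inserted into it at ``SimDesign.key_offset`` (default 0: the key
#: immediately follows the tag).
DEFAULT_ADAPTOR = "TCGTATGCCGTCTTCTGCTTG"

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

EFFECT_CLASSES = ("housekeeping", "bottom_up", "zero_in_top", "noise")


@dataclass(frozen=True)
class SimDesign:
    """Replicated multi-section experimental design for the simulator."""

    sections: tuple[str, ...] = GARDEN_SECTIONS
    replicates_per_section: tuple[int, ...] = (5, 4, 5)
    n_tags: int = 500
    seed: int = 0
    library_keys: tuple[str, ...] | None = None
    key_offset: int = 0
    adaptor: str = DEFAULT_ADAPTOR

    def __post_init__(self):
        if len(self.sections) != len(self.replicates_per_section):
            raise InvalidConfigError("sections and replicate counts differ in length")
        if any(r < 2 for r in self.replicates_per_section):
            raise InvalidConfigError("every section needs at least 2 replicates")
        if self.n_tags < 1:
            raise InvalidConfigError("n_tags must be >= 1")
        if self.key_offset < 0 or self.key_offset > len(self.adaptor):
            raise InvalidConfigError("key_offset outside the adaptor")
        if self.library_keys is not None:
            if len(self.library_keys) != self.n_libraries:
                raise InvalidConfigError("one key per library required")
            if len(set(self.library_keys)) != len(self.library_keys):
                raise InvalidConfigError("library keys must be unique")

    @property
    def n_libraries(self) -> int:
        return sum(self.replicates_per_section)

    def libraries(self) -> list[LibraryKey]:
        keys = (list(self.library_keys) if self.library_keys is not None
                else auto_library_keys(self.n_libraries))
        libs, i = [], 0
        for section, n in zip(self.sections, self.replicates_per_section):
            for r in range(n):
                libs.append(LibraryKey(keys[i], f"{section}-{r + 1}", section))
                i += 1
        return libs


@dataclass(frozen=True)
class EffectProfile:
    """Designed expression behaviour of one simulated tag.

    ``folds`` multiplies ``baseline_mean`` per section; housekeeping tags are
    flat (all folds 1), ``bottom_up`` tags are upregulated in the bottom
    section, ``zero_in_top`` tags have fold 0 in the top section (exercising
    the Kruskal-Wallis fallback of the test stage).
    """

    tag_id: int
    baseline_mean: float
    folds: dict[str, float]
    dispersion: float = 0.3
    klass: str = "noise"

    def __post_init__(self):
        if self.klass not in EFFECT_CLASSES:
            raise InvalidConfigError(f"unknown effect class {self.klass!r}")
        if self.dispersion < 0:
            raise InvalidConfigError("dispersion must be >= 0")
        if self.baseline_mean <= 0 and self.klass != "noise":
            raise InvalidConfigError("baseline_mean must be > 0")
        if any(f < 0 for f in self.folds.values()):
            raise InvalidConfigError("fold multipliers must be >= 0")
        if self.klass == "housekeeping" and any(f != 1 for f in self.folds.values()):
            raise InvalidConfigError("housekeeping profiles must be flat")
        if self.klass == "zero_in_top" and self.folds.get("top", 0) != 0:
            raise InvalidConfigError("zero_in_top profiles need top fold 0")


@dataclass(frozen=True)
class TagPlacement:
    tag_id: int
    contig_id: str
    start: int  # 0-based start of the 21-base CATG+tag on the forward strand
    strand: str  # "+" or "-"
    full_flanks: bool


@dataclass
class GroundTruth:
    """Everything the generators decided, for oracle-style assertions."""

    profiles: dict[int, EffectProfile] = field(default_factory=dict)
    sequences: dict[int, str] = field(default_factory=dict)
    placements: list[TagPlacement] = field(default_factory=list)
    motifs: dict[str, frozenset[str]] = field(default_factory=dict)
    expected_library_means: dict[str, float] = field(default_factory=dict)


def default_profiles(
    design: SimDesign,
    frac_housekeeping: float = 0.55,
    frac_bottom_up: float = 0.2,
    n_zero_in_top: int = 1,
    baseline_mean: float = 100.0,
    bottom_fold: float = 8.0,
    dispersion: float = 0.3,
) -> list[EffectProfile]:
    """The standard mixture of effect classes for a study-like simulation.

    Defaults: flat housekeeping tags, a contingent of 8-fold
    bottom-upregulated tags at baseline 100 and dispersion 0.3, one tag
    absent from the top section, and low-level noise tags for the rest.
    """
    n = design.n_tags
    n_up = int(round(frac_bottom_up * n))
    n_zero_in_top = min(n_zero_in_top, n - n_up)
    n_hk = min(int(round(frac_housekeeping * n)), n - n_up - n_zero_in_top)
    if n_up + n_zero_in_top > n or min(n_up, n_zero_in_top, n_hk) < 0:
        raise InvalidConfigError("effect class fractions exceed n_tags")
    flat = {s: 1.0 for s in design.sections}
    profiles = []
    for tag_id in range(1, n + 1):
        if tag_id <= n_hk:
            profiles.append(EffectProfile(tag_id, baseline_mean, dict(flat),
                                          dispersion, "housekeeping"))
        elif tag_id <= n_hk + n_up:
            folds = dict(flat)
            folds["bottom"] = bottom_fold
            profiles.append(EffectProfile(tag_id, baseline_mean, folds,
                                          dispersion, "bottom_up"))
        elif tag_id <= n_hk + n_up + n_zero_in_top:
            folds = dict(flat)
            folds["top"] = 0.0
            profiles.append(EffectProfile(tag_id, baseline_mean, folds,
                                          dispersion, "zero_in_top"))
        else:
            profiles.append(EffectProfile(tag_id, baseline_mean / 4, dict(flat),
                                          dispersion, "noise"))
    return profiles


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float, size: int):
    if mean == 0:
        return np.zeros(size, dtype=np.int64)
    if dispersion == 0:
        return rng.poisson(mean, size)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size)


def _random_tag_sequences(rng: np.random.Generator, n: int) -> list[str]:
    seqs: set[str] = set()
    out = []
    while len(out) < n:
        s = "".join(rng.choice(list("ACGT"), TAG_LENGTH))
        if s not in seqs:
            seqs.add(s)
            out.append(s)
    return out


def generate_count_matrix(
    design: SimDesign, profiles: list[EffectProfile] | None = None
) -> tuple[TagCountMatrix, GroundTruth]:
    """Draw a raw replicate count matrix from the designed effect profiles.

    Counts for tag t in a library of section s are negative-binomial with
    mean ``baseline_mean(t) * fold(t, s)`` and the profile's dispersion.
    """
    if profiles is None:
        profiles = default_profiles(design)
    if not profiles:
        raise InvalidConfigError("profiles must be nonempty")
    ids = [p.tag_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise InvalidConfigError("duplicate tag ids in profiles")

    rng = np.random.default_rng(design.seed)
    libraries = design.libraries()
    sequences = _random_tag_sequences(rng, len(profiles))
    counts = np.zeros((len(profiles), len(libraries)), dtype=np.int64)
    truth = GroundTruth()
    for i, prof in enumerate(profiles):
        truth.profiles[prof.tag_id] = prof
        truth.sequences[prof.tag_id] = sequences[i]
        for j, lib in enumerate(libraries):
            fold = prof.folds.get(lib.section, 1.0)
            counts[i, j] = _nb_draw(rng, prof.baseline_mean * fold,
                                    prof.dispersion, 1)[0]
    for j, lib in enumerate(libraries):
        truth.expected_library_means[lib.library_id] = float(
            sum(p.baseline_mean * p.folds.get(lib.section, 1.0) for p in profiles)
        )
    matrix = TagCountMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(ids, name="tag_id"),
                            columns=[lk.library_id for lk in libraries]),
        sequences=pd.Series(sequences, index=pd.Index(ids, name="tag_id")),
        libraries=libraries,
        state="raw",
    )
    return matrix, truth


def generate_reference(
    truth: GroundTruth,
    design: SimDesign,
    contig_length: int = 300,
    flank: int = 50,
    full_flank_fraction: float = 1.0,
    revcomp_fraction: float = 0.0,
) -> list[tuple[str, str]]:
    """Plant every tag (as CATG + 17 bases) into its own random contig.

    A deterministic ``round(full_flank_fraction * n_tags)`` prefix of tags
    (in tag-id order) is placed with at least ``flank`` bases on both sides;
    the rest are placed near the contig start so at least one flank is
    short. ``revcomp_fraction`` of tags (seeded choice) are planted on the
    minus strand. Placements are recorded in ``truth.placements``; returns
    FASTA-writable (contig_id, sequence) pairs.
    """
    anchored = TAG_LENGTH + len(ANCHOR)
    if contig_length < anchored:
        raise InvalidConfigError(
            f"contig_length {contig_length} cannot host a {anchored}-base tag"
        )
    if full_flank_fraction > 0 and contig_length < anchored + 2 * flank:
        raise InvalidConfigError(
            "contig too short for the requested full flanks"
        )
    if not 0 <= full_flank_fraction <= 1:
        raise InvalidConfigError("full_flank_fraction must be in [0, 1]")

    rng = np.random.default_rng((design.seed, 1))
    tag_ids = sorted(truth.sequences)
    n_full = int(round(full_flank_fraction * len(tag_ids)))
    rc = rng.random(len(tag_ids)) < revcomp_fraction
    truth.placements = []
    contigs = []
    for rank, tag_id in enumerate(tag_ids):
        full = rank < n_full
        if full:
            start = int(rng.integers(flank, contig_length - anchored - flank + 1))
        else:
            start = int(rng.integers(0, flank))  # left flank < ``flank``
        insert = ANCHOR + truth.sequences[tag_id]
        strand = "+"
        if rc[rank]:
            insert = reverse_complement(insert)
            strand = "-"
        background = "".join(rng.choice(list("ACGT"), contig_length))
        seq = background[:start] + insert + background[start + anchored:]
        contig_id = f"contig_{tag_id}"
        contigs.append((contig_id, seq))
        truth.placements.append(
            TagPlacement(tag_id, contig_id, start, strand, full)
        )
    return contigs


def generate_reads(
    truth: GroundTruth,
    design: SimDesign,
    counts: TagCountMatrix,
    shuffle: bool = True,
) -> list[str]:
    """Emit exactly ``counts[tag, library]`` reads per cell.

    Each read is CATG + 17-base tag + downstream adaptor carrying the
    library's 3-bp key at ``design.key_offset``. Order is shuffled by the
    design seed.
    """
    if counts.state != "raw":
        raise InvalidConfigError("read generation needs a raw count matrix")
    missing = [t for t in counts.counts.index if t not in truth.sequences]
    if missing:
        raise MissingTagError(f"tags absent from ground truth: {missing[:5]}")
    key_of = {lk.library_id: lk.key for lk in design.libraries()}
    adaptor, off = design.adaptor, design.key_offset
    reads = []
    for tag_id, row in counts.counts.iterrows():
        tag = truth.sequences[tag_id]
        for lib_id, n in row.items():
            key = key_of[lib_id]
            read = ANCHOR + tag + adaptor[:off] + key + adaptor[off:]
            reads.extend([read] * int(n))
    if shuffle:
        rng = np.random.default_rng((design.seed, 2))
        rng.shuffle(reads)
    return reads


def generate_protein_families(
    n_classes: int = 2,
    members_per_class: int = 20,
    motifs_per_class: int = 5,
    mutation_rate: float = 0.1,
    seed: int = 0,
    nmer: int = 5,
    motifs: dict[str, list[str]] | None = None,
    class_labels: list[str] | None = None,
    spacer_length: int = 20,
) -> tuple[list[tuple[str, str, str]], GroundTruth]:
    """Labelled protein families with planted class-specific peptide motifs.

    Each member embeds one copy of every motif of its class in a uniform
    random amino-acid background, separated by random spacers; each embedded
    motif copy receives independent point substitutions at ``mutation_rate``
    per residue (so a copy survives intact with probability
    ``(1 - mutation_rate) ** nmer``). Motif sets are disjoint between
    classes. Returns (member records, truth) where records are
    (sequence id, class label, sequence) and ``truth.motifs`` maps each
    class to its planted motif set.
    """
    if not 0 <= mutation_rate < 1:
        raise InvalidConfigError("mutation_rate must be in [0, 1)")
    if n_classes < 1 or members_per_class < 1:
        raise InvalidConfigError("need at least one class and one member")
    rng = np.random.default_rng(seed)
    aa = list(AMINO_ACIDS)
    if class_labels is None:
        class_labels = [f"class-{i + 1}" for i in range(n_classes)]
    if len(class_labels) != n_classes:
        raise InvalidConfigError("one label per class required")

    if motifs is None:
        used: set[str] = set()
        motifs = {}
        for label in class_labels:
            mset = []
            while len(mset) < motifs_per_class:
                m = "".join(rng.choice(aa, nmer))
                if m not in used:
                    used.add(m)
                    mset.append(m)
            motifs[label] = mset
    for label, mset in motifs.items():
        for m in mset:
            if len(m) != nmer:
                raise InvalidConfigError(
                    f"motif {m!r} has length {len(m)}, expected n-mer = {nmer}"
                )

    def mutate(motif: str) -> str:
        out = []
        for a in motif:
            if rng.random() < mutation_rate:
                alternatives = [x for x in aa if x != a]
                out.append(alternatives[rng.integers(0, len(alternatives))])
            else:
                out.append(a)
        return "".join(out)

    records = []
    truth = GroundTruth(motifs={lab: frozenset(m) for lab, m in motifs.items()})
    counter = itertools.count(1)
    for label in class_labels:
        for _ in range(members_per_class):
            parts = []
            for m in motifs[label]:
                parts.append("".join(rng.choice(aa, spacer_length)))
                parts.append(mutate(m))
            parts.append("".join(rng.choice(aa, spacer_length)))
            records.append((f"seq{next(counter)}", label, "".join(parts)))
    return records, truth
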