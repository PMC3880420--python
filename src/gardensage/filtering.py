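"""Abundance filtering and counts-per-million normalization.

The processing order is fixed: (1) remove tags whose summed raw count across
all libraries is 10 or less, (2) normalize each library column to counts per
million, (3) retain only tags present (nonzero) in at least three libraries
with a total of 22 or more across all libraries. The low-abundance cut is
interpreted dataset-wide (summed over every library, including any
pure-culture columns); the reproducibility filter runs on normalized counts
by default, with a flag to apply it to raw totals instead.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidConfigError, WrongStateError, ZeroTotalLibraryError
from .matrix import NORMALIZED, RAW, TagCountMatrix


@dataclass(frozen=True)
class FilterConfig:
    low_abundance_max: int = 10      # remove tags with total <= this, raw
    min_libraries: int = 3           # nonzero in at least this many libraries
    min_total: float = 22.0          # summed count across all libraries
    cpm_scale: float = 1_000_000.0

    def __post_init__(self):
        if min(self.low_abundance_max, self.min_libraries,
               self.min_total, self.cpm_scale) < 0:
            raise InvalidConfigError("filter thresholds must be >= 0")


def _require_state(matrix: TagCountMatrix, state: str, op: str) -> None:
    if matrix.state != state:
        raise WrongStateError(f"{op} requires a {state} matrix, got {matrix.state}")


def remove_low_abundance(matrix: TagCountMatrix,
                         cfg: FilterConfig = FilterConfig()) -> TagCountMatrix:
    """Drop tags whose summed raw count across all libraries is at most
    ``low_abundance_max`` (a total of exactly 10 is removed, 11 is kept)."""
    _require_state(matrix, RAW, "remove_low_abundance")
    keep = matrix.tag_totals() > cfg.low_abundance_max
    return matrix.subset(matrix.counts.index[keep])


def normalize_cpm(matrix: TagCountMatrix,
                  cfg: FilterConfig = FilterConfig()) -> TagCountMatrix:
    """Scale each library column to counts per million of its total."""
    _require_state(matrix, RAW, "normalize_cpm")
    totals = matrix.library_totals()
    zero = totals[totals == 0]
    if len(zero):
        raise ZeroTotalLibraryError(str(zero.index[0]))
    counts = matrix.counts.astype(float) / totals * cfg.cpm_scale
    return matrix.with_counts(counts, NORMALIZED)


def filter_reproducible(matrix: TagCountMatrix,
                        cfg: FilterConfig = FilterConfig(),
                        on_raw: bool = False) -> TagCountMatrix:
    """Retain tags seen in >= ``min_libraries`` libraries with a grand total
    >= ``min_total``. Runs on the normalized matrix unless ``on_raw``."""
    _require_state(matrix, RAW if on_raw else NORMALIZED, "filter_reproducible")
    n_libraries = (matrix.counts > 0).sum(axis=1)
    keep = (n_libraries >= cfg.min_libraries) & (matrix.tag_totals() >= cfg.min_total)
    return matrix.subset(matrix.counts.index[keep])


def apply_filters(
    matrix: TagCountMatrix,
    cfg: FilterConfig = FilterConfig(),
    reproducible_on_raw: bool = False,
) -> tuple[TagCountMatrix, dict[str, int]]:
    """Run the full processing chain on a raw matrix.

    Returns the filtered normalized matrix and a stage log of tag counts
    (input, after the low-abundance cut, after the reproducibility filter).
    """
    _require_state(matrix, RAW, "apply_filters")
    log = {"tags_in": matrix.n_tags}
    abundant = remove_low_abundance(matrix, cfg)
    log["tags_after_low_abundance"] = abundant.n_tags
    if reproducible_on_raw:
        reproducible = filter_reproducible(abundant, cfg, on_raw=True)
        out = normalize_cpm(reproducible, cfg)
    else:
        out = filter_reproducible(normalize_cpm(abundant, cfg), cfg)
    log["tags_after_reproducible"] = out.n_tags
    return out, log
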