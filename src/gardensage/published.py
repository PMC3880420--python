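"""Published per-section summary statistics and their replicate reconstruction.

The fungus-garden DeepSAGE study distributed its replicate-level counts as a
supplementary table that is not redistributable here; what the article
itself prints is, for each selected tag, the per-section mean normalized
count with a 95% t-confidence interval (5/4/5 replicate libraries), the
equal-expression P value, and the bottom/top fold. Those printed summaries
are packaged as plain TSV under ``data/``.

Because Welch's ANOVA and the ratio-of-means fold depend on the replicate
values only through each group's (mean, sd, n), a **synthetic** replicate
vector matching a printed (mean, CI, n) exactly reproduces every statistic
that the summaries determine. :func:`synthetic_replicates` builds such a
vector; :func:`replicate_matrix` assembles a full normalized TagCountMatrix
from a summary table. The within-section arrangement of values is synthetic
plumbing — only the per-section summaries are real.

Replicate-level counts for the housekeeping genes cannot be reconstructed:
the article prints their means and P values but no dispersion information,
so :func:`housekeeping_replicates` raises DataUnavailableError.
"""

from __future__ import annotations

import importlib.resources as resources
import math

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataUnavailableError, InvalidConfigError
from .matrix import LibraryKey, TagCountMatrix, auto_library_keys

#: Replicate libraries per garden section in the study design.
STUDY_REPLICATES = {"top": 5, "middle": 4, "bottom": 5}


def _load(name: str) -> pd.DataFrame:
    with resources.files("gardensage.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_enzyme_summary() -> pd.DataFrame:
    """Per-section summaries for the selected biomass-conversion enzyme tags
    (24 rows: means, 95% CI bounds, printed P and fold with its CI)."""
    return _load("garden_enzyme_expression_summary.tsv")


def load_top_expressed_summary() -> pd.DataFrame:
    """Per-section summaries for the most highly expressed tags (peak mean
    above ~1000 normalized counts; 12 rows)."""
    return _load("garden_top_expressed_summary.tsv")


def load_housekeeping_summary() -> pd.DataFrame:
    """Printed per-section means and P values of the housekeeping genes used
    to validate normalization (no dispersion information is printed)."""
    return _load("garden_housekeeping_summary.tsv")


def sd_from_ci(mean: float, ci_high: float, n: int, level: float = 0.95) -> float:
    """Invert a t-interval's upper bound to the sample sd.

    The upper margin is used because printed lower bounds are clipped at
    zero for low-count tags.
    """
    t = sps.t.ppf(0.5 + level / 2, n - 1)
    return (ci_high - mean) * math.sqrt(n) / t


def synthetic_replicates(mean: float, ci_high: float, n: int,
                         level: float = 0.95) -> np.ndarray:
    """A synthetic n-vector with exactly the given mean and t-CI.

    Construction: n - 1 values at mean - s/sqrt(n) and one at
    mean + s (n - 1)/sqrt(n), which has sample mean ``mean`` and sample sd
    ``s`` exactly. For every printed row of the packaged tables the low
    value is nonnegative. An all-zero section (mean 0) returns zeros.
    """
    if n < 2:
        raise InvalidConfigError("need n >= 2")
    if mean == 0:
        return np.zeros(n)
    s = sd_from_ci(mean, ci_high, n, level)
    low = mean - s / math.sqrt(n)
    high = mean + s * (n - 1) / math.sqrt(n)
    return np.array([low] * (n - 1) + [high])


def replicate_matrix(summary: pd.DataFrame | None = None) -> TagCountMatrix:
    """A normalized TagCountMatrix of synthetic replicates matching the
    printed per-section summaries (default: the enzyme table).

    Libraries are named ``top-1`` ... ``bottom-5`` with the study's 5/4/5
    design; every per-section sample mean, sd and hence every Welch/fold
    statistic computable from the summaries is reproduced exactly.
    """
    if summary is None:
        summary = load_enzyme_summary()
    sections = list(STUDY_REPLICATES)
    n_libs = sum(STUDY_REPLICATES.values())
    keys = auto_library_keys(n_libs)
    libraries, i = [], 0
    for section in sections:
        for r in range(STUDY_REPLICATES[section]):
            libraries.append(LibraryKey(keys[i], f"{section}-{r + 1}", section))
            i += 1

    rows = []
    for _, row in summary.iterrows():
        values = []
        for section in sections:
            values.extend(synthetic_replicates(
                float(row[f"{section}_mean"]), float(row[f"{section}_hi"]),
                STUDY_REPLICATES[section]))
        rows.append(values)
    index = pd.Index(summary["tag_id"].astype(int), name="tag_id")
    counts = pd.DataFrame(rows, index=index,
                          columns=[lk.library_id for lk in libraries])
    # Placeholder 17-mers: the article prints tag ids, not sequences, for
    # these tables; sequences are not used by the statistics stage.
    seqs = pd.Series([_placeholder_sequence(t) for t in index], index=index,
                     dtype=object)
    return TagCountMatrix(counts=counts, sequences=seqs,
                          libraries=libraries, state="normalized")


def _placeholder_sequence(tag_id: int) -> str:
    """A distinct synthetic 17-mer per tag id (base-4 encoding of the id)."""
    alphabet = "ACGT"
    digits = []
    x = int(tag_id)
    for _ in range(17):
        x, d = divmod(x, 4)
        digits.append(alphabet[d])
    return "".join(digits)


def housekeeping_replicates():
    """Replicate-level counts of the housekeeping genes.

    Always raises: the article prints only per-section means and P values
    for these genes (no CIs or SDs), and the replicate-level supplementary
    table is not redistributable, so the replicate values cannot be
    reconstructed without fabricating the dispersion.
    """
    raise DataUnavailableError(
        "replicate-level housekeeping counts are not available: the printed "
        "validation reports means and P values but no dispersion, and the "
        "supplementary per-library table is not distributed with this package"
    )
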