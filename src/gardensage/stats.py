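"""Per-tag differential-expression statistics across garden sections.

For every tag the three sections (5/4/5 replicate libraries) are compared on
normalized counts, untransformed. The primary test is Welch's
heteroscedastic one-way ANOVA, which does not assume equal variances; when
all replicate counts of some section are zero (and in the rarer degenerate
case of a zero-variance nonzero section) the tie-corrected Kruskal-Wallis
rank sum test is used instead, optionally as an exact permutation test.
Expression ratios bottom/top come with simulated confidence intervals: a
nonparametric percentile bootstrap resampling replicates within each
section (a normal-theory parametric variant is available behind a flag).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    DegenerateVarianceError,
    DesignError,
    InsufficientReplicatesError,
    InvalidConfigError,
)
from .matrix import NORMALIZED, GARDEN_SECTIONS, TagCountMatrix

logger = logging.getLogger(__name__)


# -- group summaries ----------------------------------------------------------

@dataclass(frozen=True)
class GroupSummary:
    """Mean normalized count of one section with a t-based 95% CI.

    The lower bound is clipped at zero: counts cannot be negative, and
    printed intervals in tag tables follow the same convention.
    """

    n: int
    mean: float
    ci_low: float
    ci_high: float
    section: str | None = None
    level: float = 0.95


def group_summary(values: Sequence[float], level: float = 0.95,
                  section: str | None = None) -> GroupSummary:
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise InsufficientReplicatesError(
            f"need >= 2 replicate values, got {x.size}"
        )
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    margin = sps.t.ppf(0.5 + level / 2, x.size - 1) * sd / math.sqrt(x.size)
    return GroupSummary(n=int(x.size), mean=mean,
                        ci_low=max(0.0, mean - margin),
                        ci_high=mean + margin, section=section, level=level)


# -- Welch ANOVA --------------------------------------------------------------

@dataclass(frozen=True)
class WelchResult:
    statistic: float
    df_num: float
    df_den: float
    p_value: float


def welch_anova(groups: Sequence[Sequence[float]]) -> WelchResult:
    """Welch's heteroscedastic one-way F test.

    With group means m_i, variances s_i^2 and sizes n_i, weights
    w_i = n_i / s_i^2 and W = sum w_i, the statistic is

        F = [sum w_i (m_i - m_w)^2 / (k - 1)]
            / [1 + 2 (k - 2) / (k^2 - 1) * Lambda],
        Lambda = sum (1 - w_i / W)^2 / (n_i - 1),

    with m_w the weighted grand mean, referred to an F distribution on
    (k - 1, (k^2 - 1) / (3 Lambda)) degrees of freedom (Welch-Satterthwaite
    denominator df). A zero-variance group makes the weights undefined and
    raises DegenerateVarianceError; the caller dispatches to the rank test.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrays)
    if k < 2:
        raise InvalidConfigError("welch_anova needs at least 2 groups")
    for g in arrays:
        if g.size < 2:
            raise InsufficientReplicatesError("every group needs n >= 2")
        if g.var(ddof=1) == 0:
            raise DegenerateVarianceError("a group has zero variance")
    n = np.array([g.size for g in arrays], dtype=float)
    m = np.array([g.mean() for g in arrays])
    v = np.array([g.var(ddof=1) for g in arrays])
    w = n / v
    W = w.sum()
    m_w = (w * m).sum() / W
    numerator = (w * (m - m_w) ** 2).sum() / (k - 1)
    lam = (((1 - w / W) ** 2) / (n - 1)).sum()
    statistic = numerator / (1 + 2 * (k - 2) / (k ** 2 - 1) * lam)
    df_num = float(k - 1)
    df_den = (k ** 2 - 1) / (3 * lam)
    p = float(sps.f.sf(statistic, df_num, df_den))
    return WelchResult(float(statistic), df_num, float(df_den), p)


# -- Kruskal-Wallis -----------------------------------------------------------

@dataclass(frozen=True)
class KruskalResult:
    statistic: float
    p_value: float
    exact: bool = False


#: Upper bound on the number of enumerated group assignments for the exact
#: permutation p-value (a 5/4/5 design enumerates 252,252 assignments).
MAX_EXACT_ASSIGNMENTS = 1_000_000


def _kw_h(ranks: np.ndarray, sizes: Sequence[int], tie_term: float) -> float:
    """Tie-corrected H from pooled ranks laid out group-by-group."""
    N = ranks.size
    h = 0.0
    start = 0
    for n in sizes:
        r = ranks[start:start + n].sum()
        h += r * r / n
        start += n
    h = 12.0 / (N * (N + 1)) * h - 3 * (N + 1)
    return h / tie_term if tie_term > 0 else 0.0


def kruskal_wallis(groups: Sequence[Sequence[float]],
                   exact: bool = False) -> KruskalResult:
    """Kruskal-Wallis rank sum test with tie correction.

    The default p-value uses the chi-square approximation; ``exact=True``
    enumerates every assignment of the pooled observations to groups of the
    observed sizes and reports the proportion with H at least as large
    (feasible for small designs; the 5/4/5 garden design is well within the
    enumeration cap). Identical observations across all groups give H = 0,
    p = 1 rather than an error.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise InvalidConfigError("kruskal_wallis needs at least 2 groups")
    pooled = np.concatenate(arrays)
    if pooled.size < 3:
        raise InsufficientReplicatesError("total n must be >= 3")
    if np.all(pooled == pooled[0]):
        return KruskalResult(0.0, 1.0, exact=False)
    if not exact:
        stat, p = sps.kruskal(*arrays)
        return KruskalResult(float(stat), float(p), exact=False)

    sizes = [g.size for g in arrays]
    n_assignments = math.factorial(pooled.size)
    for s in sizes:
        n_assignments //= math.factorial(s)
    if n_assignments > MAX_EXACT_ASSIGNMENTS:
        raise InvalidConfigError(
            f"{n_assignments} assignments exceed the exact-test cap; "
            "use the asymptotic test"
        )
    ranks = sps.rankdata(pooled)
    N = pooled.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = 1.0 - ((tie_counts ** 3 - tie_counts).sum()) / (N ** 3 - N)
    h_obs = _kw_h(ranks, sizes, tie_term)

    count = 0
    total = 0
    eps = 1e-9
    for assignment in _assignments(N, sizes):
        h = _kw_h(ranks[assignment], sizes, tie_term)
        if h >= h_obs - eps:
            count += 1
        total += 1
    return KruskalResult(float(h_obs), count / total, exact=True)


def _assignments(n: int, sizes: Sequence[int]):
    """Yield index arrays enumerating every split of range(n) into ordered
    groups of the given sizes."""
    indices = list(range(n))

    def rec(remaining: list[int], remaining_sizes: list[int], prefix: list[int]):
        if not remaining_sizes:
            yield np.array(prefix, dtype=int)
            return
        size = remaining_sizes[0]
        if len(remaining_sizes) == 1:
            yield np.array(prefix + remaining, dtype=int)
            return
        for combo in itertools.combinations(range(len(remaining)), size):
            chosen = [remaining[i] for i in combo]
            rest = [x for i, x in enumerate(remaining) if i not in set(combo)]
            yield from rec(rest, remaining_sizes[1:], prefix + chosen)

    yield from rec(indices, list(sizes), [])


# -- fold change --------------------------------------------------------------

@dataclass(frozen=True)
class FoldEstimate:
    """Ratio of mean normalized counts (bottom/top) with a simulated CI.

    ``point`` is NaN (rendered NA) when the denominator section mean is
    zero; the CI is then NaN as well.
    """

    point: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int | None
    level: float = 0.95
    method: str = "bootstrap"

    @property
    def is_na(self) -> bool:
        return math.isnan(self.point)


def fold_change_ci(
    top: Sequence[float],
    bottom: Sequence[float],
    n_boot: int = 10_000,
    level: float = 0.95,
    seed: int | np.random.Generator | None = None,
    method: str = "bootstrap",
) -> FoldEstimate:
    """Fold increase of ``bottom`` relative to ``top`` with a simulated CI.

    The point estimate is mean(bottom) / mean(top), regardless of the
    simulation settings. The interval is a percentile interval over
    ``n_boot`` simulated ratios: nonparametric resampling of replicates
    with replacement within each group (``method="bootstrap"``), or
    normal-theory sampling of the two group means (``method="parametric"``).
    Simulated ratios with a zero denominator count as +inf (upper mass);
    0/0 draws are dropped.
    """
    if n_boot < 100:
        raise InvalidConfigError("n_boot must be >= 100")
    if method not in ("bootstrap", "parametric"):
        raise InvalidConfigError(f"unknown CI method {method!r}")
    t = np.asarray(top, dtype=float)
    b = np.asarray(bottom, dtype=float)
    if t.size < 2 or b.size < 2:
        raise InsufficientReplicatesError("need >= 2 replicates per group")
    seed_int = seed if isinstance(seed, (int, np.integer)) else None
    if t.mean() == 0:
        nan = float("nan")
        return FoldEstimate(nan, nan, nan, n_boot, seed_int, level, method)
    point = float(b.mean() / t.mean())

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if method == "bootstrap":
        t_means = t[rng.integers(0, t.size, (n_boot, t.size))].mean(axis=1)
        b_means = b[rng.integers(0, b.size, (n_boot, b.size))].mean(axis=1)
    else:
        t_means = rng.normal(t.mean(), t.std(ddof=1) / math.sqrt(t.size), n_boot)
        b_means = rng.normal(b.mean(), b.std(ddof=1) / math.sqrt(b.size), n_boot)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = b_means / t_means
    ratios = np.where((t_means == 0) & (b_means > 0), np.inf, ratios)
    ratios = ratios[~np.isnan(ratios)]
    alpha = (1 - level) / 2
    lo = float(np.quantile(ratios, alpha))
    hi = float(np.quantile(ratios, 1 - alpha))
    return FoldEstimate(point, lo, hi, n_boot, seed_int, level, method)


# -- per-tag driver -----------------------------------------------------------

@dataclass
class TagTestResult:
    tag_id: int
    sequence: str
    summaries: dict[str, GroupSummary]
    method: str  # "welch" | "kruskal_wallis"
    statistic: float
    df_num: float
    df_den: float
    p_value: float
    fold: FoldEstimate | None
    q_value: float | None = None
    note: str = ""


def analyze_all(
    matrix: TagCountMatrix,
    sections: Sequence[str] = GARDEN_SECTIONS,
    fold_pair: tuple[str, str] = ("bottom", "top"),
    n_boot: int = 10_000,
    seed: int = 0,
    level: float = 0.95,
    exact_kw: bool = False,
    bh: bool = False,
) -> list[TagTestResult]:
    """One TagTestResult per tag of a filtered, normalized matrix.

    Only libraries assigned to ``sections`` enter the tests; other columns
    (e.g. pure-culture libraries) are ignored here. Dispatch: Welch ANOVA
    unless some section's replicates are all zero, in which case
    Kruskal-Wallis; a zero-variance nonzero section also falls back to
    Kruskal-Wallis (logged). The fold is ``fold_pair[0]`` over
    ``fold_pair[1]`` section means. Per-tag bootstrap streams are derived
    from (seed, tag id), so results do not depend on tag order. Results are
    sorted by p-value with a stable tie-break on tag id; ``bh=True`` adds
    Benjamini-Hochberg q-values.
    """
    if matrix.state != NORMALIZED:
        raise DesignError("analyze_all requires a normalized matrix")
    section_of = matrix.section_of()
    for lk in matrix.libraries:
        if lk.section is None or (isinstance(lk.section, float) and math.isnan(lk.section)):
            raise DesignError(f"library {lk.library_id} has no section")
    section_cols = {s: matrix.section_libraries(s) for s in sections}

    results = []
    for tag_id, row in matrix.counts.iterrows():
        groups = {s: row[cols].to_numpy(dtype=float)
                  for s, cols in section_cols.items()}
        summaries = {s: group_summary(g, level=level, section=s)
                     for s, g in groups.items()}
        values = list(groups.values())
        note = ""
        if any((g == 0).all() for g in values):
            method = "kruskal_wallis"
        elif any(g.var(ddof=1) == 0 for g in values):
            method = "kruskal_wallis"
            note = "zero-variance section; rank test used"
            logger.info("tag %s: %s", tag_id, note)
        else:
            method = "welch"
        if method == "welch":
            res = welch_anova(values)
            statistic, df_num, df_den, p = (res.statistic, res.df_num,
                                            res.df_den, res.p_value)
        else:
            res = kruskal_wallis(values, exact=exact_kw)
            statistic, p = res.statistic, res.p_value
            df_num, df_den = float(len(values) - 1), float("nan")
        rng = np.random.default_rng((seed, int(tag_id)))
        fold = fold_change_ci(groups[fold_pair[1]], groups[fold_pair[0]],
                              n_boot=n_boot, level=level, seed=rng)
        fold = replace(fold, seed=seed)
        results.append(TagTestResult(
            tag_id=int(tag_id), sequence=str(matrix.sequences.loc[tag_id]),
            summaries=summaries, method=method, statistic=float(statistic),
            df_num=df_num, df_den=df_den, p_value=float(p), fold=fold,
            note=note,
        ))

    results.sort(key=lambda r: (r.p_value, r.tag_id))
    if bh:
        q = sps.false_discovery_control([r.p_value for r in results], method="bh")
        for r, qv in zip(results, q):
            r.q_value = float(qv)
    return results


def results_to_frame(results: Sequence[TagTestResult]) -> pd.DataFrame:
    """Flatten test results into a TSV-writable table (full precision)."""
    rows = []
    for r in results:
        row = {"tag_id": r.tag_id, "sequence": r.sequence, "method": r.method,
               "statistic": r.statistic, "df_num": r.df_num, "df_den": r.df_den,
               "p_value": r.p_value}
        for s, g in r.summaries.items():
            row[f"{s}_n"] = g.n
            row[f"{s}_mean"] = g.mean
            row[f"{s}_ci_low"] = g.ci_low
            row[f"{s}_ci_high"] = g.ci_high
        if r.fold is not None:
            row["fold"] = r.fold.point
            row["fold_ci_low"] = r.fold.ci_low
            row["fold_ci_high"] = r.fold.ci_high
        if r.q_value is not None:
            row["q_value"] = r.q_value
        if r.note:
            row["note"] = r.note
        rows.append(row)
    return pd.DataFrame(rows)
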