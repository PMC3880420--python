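"""End-to-end orchestration and report rendering.

``run_pipeline`` chains extract (when reads are given) -> filter -> test ->
annotate (when contigs are given) -> report, writing every intermediate
table plus a run manifest (versions, seed, thresholds, input checksums and
per-stage tag counts). Re-running the same config and seed produces a
byte-identical bundle. ``render_expression_table`` is a pure view turning
test results into the familiar per-section "mean (CI)" / P / fold (CI)
layout.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import os
from dataclasses import dataclass, field
from importlib.metadata import version as pkg_version

import pandas as pd

from . import annotate as annotate_mod
from . import io as gio
from .errors import InvalidConfigError, StageError
from .filtering import FilterConfig, apply_filters
from .matrix import GARDEN_SECTIONS, TagCountMatrix
from .extraction import AdaptorSpec, count_tags
from .stats import TagTestResult, analyze_all, results_to_frame


@dataclass
class RunConfig:
    """Paths and parameters for a full pipeline run (flat key=value file)."""

    out_dir: str
    reads_path: str | None = None
    counts_path: str | None = None
    keys_path: str | None = None
    contigs_path: str | None = None
    counts_state: str = "raw"
    key_offset: int = 0
    low_abundance_max: int = 10
    min_libraries: int = 3
    min_total: float = 22.0
    reproducible_on_raw: bool = False
    sections: tuple[str, ...] = GARDEN_SECTIONS
    fold_pair: tuple[str, str] = ("bottom", "top")
    n_boot: int = 10_000
    seed: int = 0
    level: float = 0.95
    exact_kw: bool = False
    bh: bool = False
    flank: int = 50
    include_incomplete: bool = False
    highly_expressed_threshold: float = 1000.0

    def __post_init__(self):
        if self.reads_path is None and self.counts_path is None:
            raise InvalidConfigError("need reads_path or counts_path")
        if self.keys_path is None:
            raise InvalidConfigError("need a keys_path key table")
        for label, path in (("reads", self.reads_path),
                            ("counts", self.counts_path),
                            ("keys", self.keys_path),
                            ("contigs", self.contigs_path)):
            if path is not None and not os.path.exists(path):
                raise InvalidConfigError(f"{label} input {path!r} does not exist")

    @classmethod
    def from_file(cls, path: str, **overrides) -> "RunConfig":
        values: dict = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                values[key.strip()] = value.strip()
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in values:
                continue
            raw = values[f.name]
            if f.type in ("int", "int | None"):
                kwargs[f.name] = int(raw)
            elif f.type == "float":
                kwargs[f.name] = float(raw)
            elif f.type == "bool":
                kwargs[f.name] = raw.lower() in ("1", "true", "yes")
            elif f.type.startswith("tuple"):
                kwargs[f.name] = tuple(x.strip() for x in raw.split(","))
            else:
                kwargs[f.name] = raw
        kwargs.update(overrides)
        return cls(**kwargs)

    def filter_config(self) -> FilterConfig:
        return FilterConfig(low_abundance_max=self.low_abundance_max,
                            min_libraries=self.min_libraries,
                            min_total=self.min_total)


@dataclass
class RunResults:
    manifest: dict
    results: list[TagTestResult]
    matrix: TagCountMatrix
    paths: dict[str, str] = field(default_factory=dict)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> RunResults:
    """Execute every configured stage; any failure aborts with the stage
    name and cause (StageError)."""
    os.makedirs(config.out_dir, exist_ok=True)
    paths: dict[str, str] = {}
    manifest: dict = {
        "package": "gardensage",
        "version": pkg_version("gardensage"),
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(config).items()},
        "inputs": {},
        "stages": {},
    }
    for label, path in (("reads", config.reads_path),
                        ("counts", config.counts_path),
                        ("keys", config.keys_path),
                        ("contigs", config.contigs_path)):
        if path is not None:
            manifest["inputs"][label] = {"path": path, "sha256": _sha256(path)}

    def out(name: str) -> str:
        p = os.path.join(config.out_dir, name)
        paths[name] = p
        return p

    try:
        keys = gio.read_key_table(config.keys_path)
    except Exception as exc:  # noqa: BLE001 - rewrapped with stage name
        raise StageError("keys", exc) from exc

    if config.reads_path is not None:
        try:
            reads = gio.read_reads(config.reads_path)
            matrix, rejections = count_tags(
                reads, keys, AdaptorSpec(key_offset=config.key_offset))
            gio.write_count_matrix(matrix, out("counts_raw.tsv"))
            pd.Series(rejections).rename("reads").to_csv(
                out("rejections.tsv"), sep="\t", header=True,
                index_label="outcome")
            manifest["stages"]["extract"] = {
                "reads_in": len(reads), **rejections,
                "tags_out": matrix.n_tags}
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError("extract", exc) from exc
    else:
        try:
            matrix = gio.read_count_matrix(config.counts_path, keys,
                                           state=config.counts_state)
        except Exception as exc:  # noqa: BLE001
            raise StageError("load-counts", exc) from exc

    if matrix.state == "raw":
        try:
            matrix, log = apply_filters(matrix, config.filter_config(),
                                        config.reproducible_on_raw)
            manifest["stages"]["filter"] = log
            gio.write_count_matrix(matrix, out("counts_filtered.tsv"))
        except Exception as exc:  # noqa: BLE001
            raise StageError("filter", exc) from exc

    try:
        results = analyze_all(matrix, sections=config.sections,
                              fold_pair=config.fold_pair,
                              n_boot=config.n_boot, seed=config.seed,
                              level=config.level, exact_kw=config.exact_kw,
                              bh=config.bh)
        results_to_frame(results).to_csv(out("results.tsv"), sep="\t",
                                         index=False, float_format="%.10g")
        manifest["stages"]["test"] = {"tags_tested": len(results)}
    except Exception as exc:  # noqa: BLE001
        raise StageError("test", exc) from exc

    if config.contigs_path is not None:
        try:
            contigs = {cid: seq for cid, _, seq in
                       gio.read_fasta(config.contigs_path)}
            matches = annotate_mod.match_all(matrix.tags(), contigs,
                                             flank=config.flank)
            annotate_mod.matches_to_frame(matches).to_csv(
                out("matches.tsv"), sep="\t", index=False)
            queries = annotate_mod.export_blast_queries(
                matches, only_complete=not config.include_incomplete)
            gio.write_fasta(queries, out("blast_queries.fasta"))
            manifest["stages"]["annotate"] = {
                "matches": len(matches), "queries_exported": len(queries)}
        except Exception as exc:  # noqa: BLE001
            raise StageError("annotate", exc) from exc

    try:
        table, warnings = render_expression_table(results)
        table.to_csv(out("report.tsv"), sep="\t", index=False)
        manifest["stages"]["report"] = {"rows": len(table),
                                        "warnings": warnings}
    except Exception as exc:  # noqa: BLE001
        raise StageError("report", exc) from exc

    with open(out("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return RunResults(manifest=manifest, results=results, matrix=matrix,
                      paths=paths)


# -- rendering ----------------------------------------------------------------

def format_p(p: float) -> str:
    """P to 2 significant digits; scientific notation below 0.01."""
    if math.isnan(p):
        return "NA"
    if p < 0.01:
        return f"{p:.1e}"
    return f"{p:.2g}"


def _format_mean_ci(summary) -> str:
    return (f"{summary.mean:.0f} ({summary.ci_low:.0f}, {summary.ci_high:.0f})"
            if summary.ci_high != summary.ci_low or summary.mean
            else "0")


def _format_fold(fold) -> str:
    if fold is None or fold.is_na:
        return "NA"
    return f"{fold.point:.1f} ({fold.ci_low:.2f}, {fold.ci_high:.2f})"


def render_expression_table(
    results: list[TagTestResult],
    annotations: dict[int, str] | None = None,
    selection: list[int] | None = None,
    highly_expressed: float | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Format test results as a per-section expression table.

    ``selection`` restricts to the listed tag ids (unknown ids go to the
    warnings list, not fatal); ``highly_expressed`` instead keeps tags whose
    per-section mean peaks above the threshold. Fold is "NA" when the
    denominator-section mean is zero.
    """
    if not results:
        raise InvalidConfigError("no results to render")
    warnings: list[str] = []
    chosen = results
    if selection is not None:
        known = {r.tag_id for r in results}
        missing = [t for t in selection if t not in known]
        if missing:
            warnings.append(f"unknown tag ids in selection: {missing}")
        wanted = set(selection)
        chosen = [r for r in results if r.tag_id in wanted]
    if highly_expressed is not None:
        chosen = [r for r in chosen
                  if max(g.mean for g in r.summaries.values()) > highly_expressed]
    rows = []
    for r in chosen:
        row = {"tag_id": r.tag_id}
        if annotations:
            row["function"] = annotations.get(r.tag_id, "")
        for section, g in r.summaries.items():
            row[section] = _format_mean_ci(g)
        row["p"] = format_p(r.p_value)
        row["fold_bottom_vs_top"] = _format_fold(r.fold)
        rows.append(row)
    return pd.DataFrame(rows), warnings
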