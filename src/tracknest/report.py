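"""Analysis grids, effect tables and the end-to-end pipeline.

The *analysis grid* mirrors the standard presentation of a two-population
motility comparison: one row per analysis of the ladder, columns holding the
per-population estimate and the p-value for the population effect.  The
*effect table* reports the signed sum-to-zero offsets of the second
population level, the first dye level and their interaction, in response
units, with a significance marker.
"""

from __future__ import annotations

import io as _io
import json
import logging
from dataclasses import asdict, dataclass, field

import pandas as pd

from .io import Dialect, TrackSet, read_tracks, validate_hierarchy, write_steps
from .motility import FilterConfig, apply_track_filters, compute_steps
from .stats import FitResult, LadderRow, TestResult, analysis_ladder

__all__ = [
    "AnalysisGrid",
    "EffectTable",
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "render_grid",
    "render_effects",
    "format_p",
]

logger = logging.getLogger(__name__)


def format_p(p: float | None) -> str:
    """Display convention: values below 1e-4 print as 'p<.0001'."""
    if p is None:
        return ""
    if p < 1e-4:
        return "p<.0001"
    return f"p = {p:.4f}"


@dataclass
class AnalysisGrid:
    """Rows = ladder analyses; columns = per-population estimates, p-value."""

    response: str
    populations: tuple
    rows: list = field(default_factory=list)   # dicts: label, estimates, p, skipped, reason
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            rec = {"analysis": r["label"]}
            for pop in self.populations:
                rec[f"{pop} est."] = (r["estimates"] or {}).get(pop)
            rec["p-value"] = r["p"]
            rec["skipped"] = r["skipped"]
            rec["reason"] = r["reason"]
            recs.append(rec)
        return pd.DataFrame(recs)


@dataclass
class EffectTable:
    """Signed sum-to-zero effects (response units) with significance marks."""

    response: str
    rows: list = field(default_factory=list)   # dicts: term, label, effect, p
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"term": r["term"], "level": r["label"], "effect": r["effect"],
             "p": r["p"], "significant": r["p"] is not None and r["p"] < 1e-4}
            for r in self.rows
        ])


#: population labels treated as the reference (control) arm when present
_REFERENCE_POPULATIONS = frozenset({"WT", "SUB", "CONTROL", "CTRL"})


def grid_from_ladder(rows: list[LadderRow], response: str,
                     populations: tuple, metadata: dict | None = None) -> AnalysisGrid:
    grid = AnalysisGrid(response=response, populations=tuple(populations),
                        metadata=dict(metadata or {}))
    for row in rows:
        if row.skipped:
            grid.rows.append({"label": row.label, "estimates": None, "p": None,
                              "skipped": True, "reason": row.reason})
            continue
        res = row.result
        if isinstance(res, TestResult):
            est, p = res.group_estimates, res.p_value
        else:
            est, p = res.population_estimates, res.p_population
        grid.rows.append({"label": row.label, "estimates": dict(est), "p": p,
                          "skipped": False, "reason": None})
    return grid


def effects_from_fit(fit: FitResult, response: str,
                     metadata: dict | None = None) -> EffectTable:
    """Effect table from a factorial (or mixed) fit.

    Reports the offset of the *second* population level (the knockout /
    treated group by the package's sorted-label convention is whichever
    sorts second) and of the first dye level, matching the single-signed-
    number presentation of factorial effect sizes.
    """
    table = EffectTable(response=response, metadata=dict(metadata or {}))
    pops = sorted(fit.population_effects)
    dyes = sorted(fit.dye_effects) if fit.dye_effects else []
    # report the offset of the non-reference (knockout/treated) population
    reference = next((p for p in pops if p.upper() in _REFERENCE_POPULATIONS), pops[0])
    ko = next(p for p in pops if p != reference)
    table.metadata["reference_population"] = reference
    table.rows.append({
        "term": "population", "label": ko,
        "effect": fit.population_effects[ko], "p": fit.p_population,
    })
    if dyes:
        d0 = dyes[0]
        table.rows.append({
            "term": "dye", "label": d0,
            "effect": fit.dye_effects[d0], "p": fit.p_dye,
        })
        if fit.interaction_effects:
            table.rows.append({
                "term": "population x dye", "label": f"{ko} x {d0}",
                "effect": fit.interaction_effects[(ko, d0)],
                "p": fit.p_interaction,
            })
    return table


def render_grid(grid: AnalysisGrid, fmt: str = "text", path=None):
    """Render an AnalysisGrid as csv (lossless), json (lossless) or text
    (2-decimal estimates, 'p<.0001' convention)."""
    if fmt == "csv":
        out = grid.to_frame().to_csv(index=False)
    elif fmt == "json":
        out = json.dumps({
            "response": grid.response,
            "populations": list(grid.populations),
            "rows": grid.rows,
            "metadata": grid.metadata,
        }, indent=2)
    elif fmt == "text":
        buf = _io.StringIO()
        width = max(len(r["label"]) for r in grid.rows) + 2
        head = "Analysis".ljust(width) + "".join(
            f"{p + ' est.':>14}" for p in grid.populations) + f"{'p-value':>14}"
        print(head, file=buf)
        print("-" * len(head), file=buf)
        for r in grid.rows:
            if r["skipped"]:
                print(r["label"].ljust(width) + f"skipped: {r['reason']}", file=buf)
                continue
            line = r["label"].ljust(width)
            for p in grid.populations:
                line += f"{r['estimates'][p]:>14.2f}"
            line += f"{format_p(r['p']):>14}"
            print(line, file=buf)
        out = buf.getvalue()
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if path is not None:
        with open(path, "w") as fh:
            fh.write(out)
    return out


def render_effects(table: EffectTable, fmt: str = "text", path=None):
    if fmt == "csv":
        out = table.to_frame().to_csv(index=False)
    elif fmt == "json":
        out = json.dumps({
            "response": table.response,
            "rows": [
                {**r, "label": r["label"], "term": r["term"]} for r in table.rows
            ],
            "metadata": table.metadata,
        }, indent=2)
    elif fmt == "text":
        buf = _io.StringIO()
        for r in table.rows:
            mark = " ***" if (r["p"] is not None and r["p"] < 1e-4) else ""
            print(f"{r['term']:<18} {r['label']:<16} {r['effect']:+.2f}{mark}",
                  file=buf)
        out = buf.getvalue()
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if path is not None:
        with open(path, "w") as fh:
            fh.write(out)
    return out


@dataclass
class PipelineConfig:
    """End-to-end analysis settings."""

    dialect: Dialect = field(default_factory=Dialect)
    filters: FilterConfig = field(default_factory=FilterConfig)
    responses: tuple = ("speed", "angle")
    df_method: str = "satterthwaite"
    drop_aliased: bool = True
    out_dir: str | None = None
    persist_intermediates: bool = False


@dataclass
class PipelineResult:
    hierarchy: object
    filter_report: object
    grids: dict          # response -> AnalysisGrid
    effects: dict        # response -> EffectTable
    steps: pd.DataFrame


def run_pipeline(tracks, config: PipelineConfig | None = None) -> PipelineResult:
    """read -> validate -> filter -> steps -> ladder -> grids.

    ``tracks`` is a CSV path or an already constructed TrackSet.
    """
    config = config or PipelineConfig()
    if isinstance(tracks, TrackSet):
        ts = tracks
    else:
        ts = read_tracks(tracks, dialect=config.dialect)
    hierarchy = validate_hierarchy(ts)
    logger.info("hierarchy: %s aliased=%s", hierarchy.counts(),
                hierarchy.aliased_levels)
    ts, filter_report = apply_track_filters(ts, config.filters)
    logger.info("filters: removed %d of %d tracks (%s)",
                filter_report.n_removed, filter_report.n_input,
                filter_report.removed_by_rule)
    steps = compute_steps(ts)
    populations = tuple(sorted(steps["population"].unique()))

    grids, effects = {}, {}
    for response in config.responses:
        rows = analysis_ladder(steps, hierarchy, response=response,
                               df_method=config.df_method,
                               drop_aliased=config.drop_aliased)
        meta = {
            "response": response,
            "df_method": config.df_method,
            "filters": asdict(config.filters),
            "filter_report": asdict(filter_report),
            "provenance": ts.provenance,
        }
        factorial = next(
            (r.result for r in rows
             if r.label == "Factorial ANOVA" and not r.skipped), None)
        dropped = sorted({lev for r in rows if not r.skipped
                          and isinstance(r.result, FitResult)
                          for lev in r.result.dropped_random})
        meta["dropped_levels"] = dropped
        grids[response] = grid_from_ladder(rows, response, populations, meta)
        if factorial is not None:
            effects[response] = effects_from_fit(factorial, response, meta)

    if config.out_dir is not None:
        from pathlib import Path

        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for response, grid in grids.items():
            render_grid(grid, "csv", out / f"grid_{response}.csv")
            render_grid(grid, "json", out / f"grid_{response}.json")
            render_grid(grid, "text", out / f"grid_{response}.txt")
        for response, table in effects.items():
            render_effects(table, "csv", out / f"effects_{response}.csv")
            render_effects(table, "json", out / f"effects_{response}.json")
        if config.persist_intermediates:
            write_steps(steps, out / "steps.csv")
    return PipelineResult(hierarchy=hierarchy, filter_report=filter_report,
                          grids=grids, effects=effects, steps=steps)
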