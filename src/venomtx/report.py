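"""Aggregation and reporting: expression tiers per superfamily, the
precursor-count vs read-count regression, and the run report bundle."""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from scipy.stats import linregress

__all__ = ["AbundanceRegression", "regress_abundance", "build_report", "write_report"]


@dataclass(frozen=True)
class AbundanceRegression:
    """OLS fit of reads-per-superfamily against precursors-per-superfamily.

    Fitted both on the raw scale and (when all points are positive) on the
    log10-log10 scale, since read counts span orders of magnitude.
    """

    slope: float
    intercept: float
    r_squared: float
    log_slope: float | None
    log_intercept: float | None
    log_r_squared: float | None
    points: tuple[tuple[float, float], ...]


def regress_abundance(points: Sequence[tuple[float, float]]) -> AbundanceRegression:
    """Least-squares regression of (n_precursors, n_reads) points."""
    if len(points) < 2:
        raise ValueError("need at least 2 points")
    xs = [p[0] for p in points]
    ys = [p[1] for p in points]
    if len(set(xs)) < 2:
        raise ValueError("degenerate fit: all x values equal")
    fit = linregress(xs, ys)
    r2 = float(fit.rvalue**2)
    log_slope = log_intercept = log_r2 = None
    if all(x > 0 and y > 0 for x, y in points) and len({round(math.log10(x), 12) for x in xs}) > 1:
        lfit = linregress([math.log10(x) for x in xs], [math.log10(y) for y in ys])
        log_slope, log_intercept = float(lfit.slope), float(lfit.intercept)
        log_r2 = float(lfit.rvalue**2)
    return AbundanceRegression(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r2,
        log_slope=log_slope,
        log_intercept=log_intercept,
        log_r_squared=log_r2,
        points=tuple((float(x), float(y)) for x, y in points),
    )


def build_report(
    categories: Mapping[str, str],
    superfamily_of: Mapping[str, str],
    read_counts: Mapping[str, int],
    tiers: Mapping[str, str],
    framework_classes: Mapping[str, str],
    event_kinds: Sequence[str],
    selection_zones: Sequence[str],
    recovery: Mapping[str, float] | None = None,
) -> dict:
    """Assemble the run report: category proportions, per-superfamily
    precursor/read/tier tables, framework / variant-event / selection-zone
    censuses, the abundance regression, and optional ground-truth recovery
    metrics.  Deterministically ordered."""
    n = len(categories)
    if n == 0:
        raise ValueError("no transcripts to report on")
    cat_census = {}
    for cat in sorted(set(categories.values())):
        cat_census[cat] = sum(1 for c in categories.values() if c == cat)
    proportions = {k: v / n for k, v in cat_census.items()}

    superfamilies: dict[str, dict] = {}
    for pid, sf in sorted(superfamily_of.items()):
        row = superfamilies.setdefault(
            sf, {"n_precursors": 0, "n_reads": 0, "tiers": {"high": 0, "low": 0, "rare": 0}}
        )
        row["n_precursors"] += 1
        row["n_reads"] += int(read_counts.get(pid, 0))
        tier = tiers.get(pid)
        if tier in row["tiers"]:
            row["tiers"][tier] += 1

    tier_census = {t: sum(1 for v in tiers.values() if v == t) for t in ("high", "low", "rare")}
    fw_census: dict[str, int] = {}
    for cls in sorted(framework_classes.values()):
        fw_census[cls] = fw_census.get(cls, 0) + 1
    ev_census: dict[str, int] = {}
    for kind in sorted(event_kinds):
        ev_census[kind] = ev_census.get(kind, 0) + 1
    sel_census: dict[str, int] = {}
    for zone in sorted(selection_zones):
        sel_census[zone] = sel_census.get(zone, 0) + 1

    regression = None
    pts = [
        (row["n_precursors"], row["n_reads"])
        for sf, row in sorted(superfamilies.items())
        if not sf.startswith("NEW")
    ]
    if len(pts) >= 2 and len({p[0] for p in pts}) >= 2:
        reg = regress_abundance(pts)
        regression = {
            "slope": reg.slope,
            "intercept": reg.intercept,
            "r_squared": reg.r_squared,
            "log_slope": reg.log_slope,
            "log_intercept": reg.log_intercept,
            "log_r_squared": reg.log_r_squared,
            "n_points": len(pts),
        }

    report = {
        "n_transcripts": n,
        "category_census": cat_census,
        "category_proportions": proportions,
        "superfamilies": {k: superfamilies[k] for k in sorted(superfamilies)},
        "tier_census": tier_census,
        "framework_census": fw_census,
        "event_census": ev_census,
        "selection_census": sel_census,
        "regression": regression,
    }
    if recovery is not None:
        report["recovery"] = dict(sorted(recovery.items()))
    return report


def write_report(report: dict, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "superfamilies.tsv", "w") as fh:
        fh.write("superfamily\tn_precursors\tn_reads\thigh\tlow\trare\n")
        for sf, row in report["superfamilies"].items():
            t = row["tiers"]
            fh.write(
                f"{sf}\t{row['n_precursors']}\t{row['n_reads']}"
                f"\t{t['high']}\t{t['low']}\t{t['rare']}\n"
            )
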