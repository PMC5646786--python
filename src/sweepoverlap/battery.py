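"""Configured suites of intersection tests with reproducible reports.

A battery is a list of comparisons, each either size-driven (the published
(a, b, v) triple, for sources whose raw gene lists are not machine-readable)
or pool-driven (two gene-list TSVs whose overlap v is computed here). Every
row gets the exact upper-tail probability and, optionally, a seeded Monte
Carlo estimate.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import __version__
from .genelists import AliasTable, build_pool, filter_noncoding, read_genelist_tsv
from .hyperg import intersection_tail_ge
from .mc import MCResult, estimate_tail
from .overlap import pairwise_overlap

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (0.05, 0.01)


@dataclass(frozen=True)
class ComparisonSpec:
    """One configured comparison: sizes (a, b, v) or pool files per side."""

    label: str
    universe_n: int
    a: int | None = None
    b: int | None = None
    v: int | None = None
    pool_x: str | None = None
    pool_y: str | None = None
    mc_reps: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        if (self.a is None) == (self.pool_x is None):
            raise ValueError(
                f"{self.label}: exactly one of size a / pool_x must be given"
            )
        if (self.b is None) == (self.pool_y is None):
            raise ValueError(
                f"{self.label}: exactly one of size b / pool_y must be given"
            )
        if self.pool_x is None and self.pool_y is None and self.v is None:
            raise ValueError(
                f"{self.label}: size-only comparison needs an observed v"
            )
        for size in (self.a, self.b):
            if size is not None and size > self.universe_n:
                raise ValueError(
                    f"{self.label}: draw size {size} exceeds universe "
                    f"{self.universe_n}"
                )


@dataclass(frozen=True)
class BatteryRow:
    label: str
    n: int
    a: int
    b: int
    v: int
    p_exact: float
    mc: MCResult | None
    significant_at: tuple[float, ...]


@dataclass(frozen=True)
class BatteryResult:
    rows: list[BatteryRow]
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS


def load_config(path: str | Path) -> list[ComparisonSpec]:
    """Parse a battery YAML config into comparison specs.

    Top-level keys ``universe_n``, ``mc_reps``, ``seed`` set defaults;
    each entry of ``comparisons:`` may override them.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    defaults = {
        "universe_n": raw.get("universe_n"),
        "mc_reps": raw.get("mc_reps", 0),
        "seed": raw.get("seed"),
    }
    specs = []
    for entry in raw["comparisons"]:
        merged = {**defaults, **entry}
        specs.append(
            ComparisonSpec(
                label=merged["label"],
                universe_n=merged["universe_n"],
                a=merged.get("a"),
                b=merged.get("b"),
                v=merged.get("v"),
                pool_x=merged.get("pool_x"),
                pool_y=merged.get("pool_y"),
                mc_reps=merged.get("mc_reps", 0),
                seed=merged.get("seed"),
            )
        )
    config_hash = hashlib.sha256(path.read_bytes()).hexdigest()[:12]
    logger.info(
        "loaded battery config %s (sha256 %s, %d comparisons) with "
        "sweepoverlap %s",
        path,
        config_hash,
        len(specs),
        __version__,
    )
    return specs


def _load_pool(path: str, label: str, aliases: AliasTable | None):
    records = filter_noncoding(read_genelist_tsv(path, aliases=aliases))
    return build_pool(label, records)


def run_battery(
    specs: list[ComparisonSpec],
    aliases: AliasTable | None = None,
    base_dir: str | Path | None = None,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
) -> BatteryResult:
    """Run every comparison: resolve pools, compute v, exact p, optional MC."""
    base = Path(base_dir) if base_dir is not None else Path(".")
    rows = []
    for spec in specs:
        if spec.pool_x is not None:
            pool_x = _load_pool(str(base / spec.pool_x), f"{spec.label}:x", aliases)
            a = pool_x.size
        else:
            pool_x, a = None, spec.a
        if spec.pool_y is not None:
            pool_y = _load_pool(str(base / spec.pool_y), f"{spec.label}:y", aliases)
            b = pool_y.size
        else:
            pool_y, b = None, spec.b
        if pool_x is not None and pool_y is not None:
            _, v = pairwise_overlap(pool_x, pool_y)
        else:
            v = spec.v
        if v is None:
            raise ValueError(f"{spec.label}: observed v unavailable")
        p_exact = intersection_tail_ge(spec.universe_n, a, b, v)
        mc = (
            estimate_tail(spec.universe_n, a, b, v, spec.mc_reps, seed=spec.seed)
            if spec.mc_reps > 0
            else None
        )
        if mc is not None:
            logger.info("%s: MC seed=%s reps=%d", spec.label, spec.seed, spec.mc_reps)
        rows.append(
            BatteryRow(
                label=spec.label,
                n=spec.universe_n,
                a=a,
                b=b,
                v=v,
                p_exact=p_exact,
                mc=mc,
                significant_at=tuple(t for t in thresholds if p_exact < t),
            )
        )
    return BatteryResult(rows=rows, thresholds=thresholds)


def _fmt(x: float) -> str:
    return f"{x:.4g}"


def render_report(result: BatteryResult, format: str = "tsv") -> str:
    """Deterministic TSV or JSON rendering, rows in config order."""
    if format == "tsv":
        lines = [
            "label\tn\ta\tb\tv\tp_exact\tmc_fraction\tmc_ci95_low\tmc_ci95_high"
            "\tsignificant_at"
        ]
        for row in result.rows:
            mc_cols = (
                [_fmt(row.mc.fraction), _fmt(row.mc.ci95[0]), _fmt(row.mc.ci95[1])]
                if row.mc is not None
                else ["", "", ""]
            )
            sig = ";".join(str(t) for t in row.significant_at)
            lines.append(
                "\t".join(
                    [row.label, str(row.n), str(row.a), str(row.b), str(row.v),
                     _fmt(row.p_exact), *mc_cols, sig]
                )
            )
        return "\n".join(lines) + "\n"
    if format == "json":
        payload = []
        for row in result.rows:
            entry = {
                "label": row.label,
                "n": row.n,
                "a": row.a,
                "b": row.b,
                "v": row.v,
                "p_exact": float(_fmt(row.p_exact)),
                "significant_at": list(row.significant_at),
            }
            if row.mc is not None:
                entry.update(
                    {
                        "mc_reps": row.mc.reps,
                        "mc_seed": row.mc.seed,
                        "mc_fraction": float(_fmt(row.mc.fraction)),
                        "mc_ci95": [float(_fmt(c)) for c in row.mc.ci95],
                    }
                )
            payload.append(entry)
        return json.dumps(payload, indent=2, sort_keys=False) + "\n"
    raise ValueError(f"unknown report format {format!r}")
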