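"""Pairwise and multi-set overlaps between gene pools.

Overlap is computed on canonical symbols only: a gene contributes once per
pool regardless of how many source lists mention it, and once to an
intersection regardless of how many species share it (gene-level, not
gene-by-species counting).
"""

from __future__ import annotations

from typing import Iterable, Sequence

from .genelists import GenePool


def pairwise_overlap(pool_x: GenePool, pool_y: GenePool) -> tuple[frozenset[str], int]:
    """Intersection of two pools and its cardinality v."""
    shared = pool_x.symbols & pool_y.symbols
    return frozenset(shared), len(shared)


def overlap_table(pools: Sequence[GenePool]) -> dict[str, frozenset[str]]:
    """Map each symbol in the union of pools to the labels containing it."""
    table: dict[str, set[str]] = {}
    for pool in pools:
        for symbol in pool.symbols:
            table.setdefault(symbol, set()).add(pool.label)
    return {symbol: frozenset(labels) for symbol, labels in table.items()}


def venn_decompose(pools: Sequence[GenePool]) -> dict[frozenset[str], int]:
    """Count symbols by the exact subset of pools containing them.

    Every union symbol lands in exactly one cell, so cell counts sum to the
    size of the union. Cells with zero count are omitted.
    """
    if len(pools) < 2:
        raise ValueError("venn decomposition needs at least two pools")
    labels = [p.label for p in pools]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate pool labels: {labels}")
    cells: dict[frozenset[str], int] = {}
    for membership in overlap_table(pools).values():
        cells[membership] = cells.get(membership, 0) + 1
    return cells


def classify_convergent(
    amh: GenePool, domesticates: Iterable[GenePool]
) -> tuple[frozenset[str], frozenset[str]]:
    """Split union symbols into the two convergence classes of interest.

    Returns ``(amh_and_any_dom, multi_dom_not_amh)``: symbols under
    selection in AMH and at least one domesticate, and symbols under
    selection in two or more domesticates but not in AMH.
    """
    dom_pools = list(domesticates)
    amh_and_any: set[str] = set()
    multi_dom: set[str] = set()
    union: set[str] = set(amh.symbols)
    for pool in dom_pools:
        union |= pool.symbols
    for symbol in union:
        n_dom = sum(symbol in pool for pool in dom_pools)
        if symbol in amh and n_dom >= 1:
            amh_and_any.add(symbol)
        elif symbol not in amh and n_dom >= 2:
            multi_dom.add(symbol)
    return frozenset(amh_and_any), frozenset(multi_dom)


def multi_domesticate_symbols(
    pools: Sequence[GenePool], min_pools: int = 2
) -> frozenset[str]:
    """Symbols present in at least ``min_pools`` of the given pools."""
    counts: dict[str, int] = {}
    for pool in pools:
        for symbol in pool.symbols:
            counts[symbol] = counts.get(symbol, 0) + 1
    return frozenset(s for s, c in counts.items() if c >= min_pools)


def render_overlap_tsv(table: dict[str, frozenset[str]]) -> str:
    """Deterministic TSV rendering of an overlap table (sorted rows)."""
    lines = ["symbol\tpools"]
    for symbol in sorted(table):
        lines.append(f"{symbol}\t{';'.join(sorted(table[symbol]))}")
    return "\n".join(lines) + "\n"
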