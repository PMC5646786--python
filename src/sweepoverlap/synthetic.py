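"""Synthetic gene lists and neighborhoods with known ground truth.

The generator reproduces the statistical structure the analysis assumes —
candidate pools drawn uniformly without replacement from a fixed universe of
protein-coding symbols — and perturbs it in controlled ways: a planted
shared-overlap component (the alternative hypothesis), symbol-alias noise
(nomenclature drift between assemblies), non-coding contaminant records
(the rows the class filter must remove), and gene-neighborhood
rearrangements (insertions, inversions, shuffles, translocations) for the
synteny checks. Membership is fixed before noise is applied and recorded in
a truth table, so tests never re-derive ground truth from generator
internals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genelists import AliasTable, GeneRecord
from .synteny import SyntenyNeighborhood

#: Default pool labels, assigned in order to generated pools.
DEFAULT_POOL_LABELS = ("amh", "cat", "dog", "cattle", "horse", "chimp", "wolf", "wisent")

_CONTAMINANT_CLASSES = ("miRNA", "antisense", "other_noncoding")


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation parameters for a set of candidate pools.

    ``planted_overlap`` symbols are forced into every designated pool
    (default: all pools); remaining members are uniform draws without
    replacement. Rates are per emitted record.
    """

    universe_n: int
    pool_sizes: tuple[int, ...]
    planted_overlap: int = 0
    planted_pools: tuple[int, ...] | None = None  # indices into pool_sizes
    alias_noise_rate: float = 0.0
    noncoding_rate: float = 0.0
    seed: int | None = None
    pool_labels: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.pool_labels is None:
            object.__setattr__(
                self, "pool_labels", DEFAULT_POOL_LABELS[: len(self.pool_sizes)]
            )
        if len(self.pool_labels) != len(self.pool_sizes):
            raise ValueError("pool_labels and pool_sizes length mismatch")
        designated = self.planted_pools or tuple(range(len(self.pool_sizes)))
        if self.planted_overlap > min(self.pool_sizes[i] for i in designated):
            raise ValueError("planted_overlap exceeds a designated pool size")
        if any(size > self.universe_n for size in self.pool_sizes):
            raise ValueError("pool size exceeds universe size")
        for rate in (self.alias_noise_rate, self.noncoding_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


def universe_symbols(n: int) -> list[str]:
    """Synthetic universe: G00000..; disjoint from real gene nomenclature."""
    return [f"G{i:05d}" for i in range(n)]


def generate_pools(
    spec: SyntheticSpec,
) -> tuple[dict[str, list[GeneRecord]], pd.DataFrame, AliasTable]:
    """Generate per-pool record lists, the truth table, and the alias table.

    Returns ``(records_by_pool, truth, aliases)``. The truth table has one
    row per true pool membership (columns pool, symbol, planted); alias and
    contaminant noise are applied after membership is fixed, so filtering
    and harmonization must restore the truth table exactly.
    """
    rng = np.random.default_rng(spec.seed)
    universe = universe_symbols(spec.universe_n)
    designated = set(spec.planted_pools or range(len(spec.pool_sizes)))

    planted_idx = rng.choice(spec.universe_n, size=spec.planted_overlap, replace=False)
    planted = [universe[i] for i in planted_idx]
    rest = np.setdiff1d(np.arange(spec.universe_n), planted_idx, assume_unique=True)

    # phase 1: fix every pool's membership before any noise randomness, so
    # the same seed yields identical memberships at any noise setting
    members_by_pool: dict[str, list[str]] = {}
    for pool_i, (label, size) in enumerate(zip(spec.pool_labels, spec.pool_sizes)):
        members = list(planted) if pool_i in designated else []
        drawn = rng.choice(rest, size=size - len(members), replace=False)
        members_by_pool[label] = members + [universe[i] for i in drawn]

    # phase 2: emit records with alias/contaminant noise
    records_by_pool: dict[str, list[GeneRecord]] = {}
    truth_rows = []
    alias_entries: dict[str, str] = {}
    for pool_i, (label, size) in enumerate(zip(spec.pool_labels, spec.pool_sizes)):
        records = []
        for symbol in members_by_pool[label]:
            raw = symbol
            if spec.alias_noise_rate and rng.random() < spec.alias_noise_rate:
                raw = f"{symbol}-V1"  # variant spelling resolved by the alias table
                alias_entries[raw] = symbol
            records.append(
                GeneRecord(
                    symbol_raw=raw,
                    symbol=symbol,
                    species=label,
                    comparison="synthetic",
                    source="generator",
                    gene_class="protein_coding",
                )
            )
            truth_rows.append(
                {"pool": label, "symbol": symbol, "planted": symbol in planted}
            )
        n_contaminants = int(rng.binomial(size, spec.noncoding_rate))
        for k in range(n_contaminants):
            records.append(
                GeneRecord(
                    symbol_raw=f"NC{pool_i:02d}{k:04d}",
                    symbol=f"NC{pool_i:02d}{k:04d}",
                    species=label,
                    comparison="synthetic",
                    source="generator",
                    gene_class=_CONTAMINANT_CLASSES[k % len(_CONTAMINANT_CLASSES)],
                )
            )
        order = rng.permutation(len(records))
        records_by_pool[label] = [records[i] for i in order]
    truth = pd.DataFrame(truth_rows, columns=["pool", "symbol", "planted"])
    return records_by_pool, truth, AliasTable(alias_entries)


REARRANGEMENTS = ("none", "insertion", "inversion", "shuffle", "translocation")


def generate_neighborhoods(
    focal: str,
    species_list: Sequence[str],
    flanks_per_side: int = 4,
    rearrangement: str = "none",
    seed: int | None = None,
) -> tuple[list[SyntenyNeighborhood], bool]:
    """Replicate one neighborhood across species, perturbing the last one.

    Returns the neighborhoods and the expected conservation verdict under
    the default thresholds (min_shared=4, max_insertions=1):
    none/insertion/inversion keep the block conserved as long as enough
    shared flanks remain in the window; shuffle/translocation break it.
    """
    if rearrangement not in REARRANGEMENTS:
        raise ValueError(
            f"unknown rearrangement {rearrangement!r}; one of {REARRANGEMENTS}"
        )
    if not 1 <= flanks_per_side <= 8:
        raise ValueError("flanks_per_side must be in [1, 8]")
    if rearrangement == "shuffle" and flanks_per_side < 2:
        raise ValueError("shuffle needs >= 2 flanks per side to break order")
    default_min_shared = 4
    rng = np.random.default_rng(seed)
    n_flanks = 2 * flanks_per_side
    base = [f"FLK{i:03d}" for i in rng.choice(1000, size=n_flanks, replace=False)]
    upstream = tuple(base[:flanks_per_side])
    downstream = tuple(base[flanks_per_side:])

    def make(species: str, up: tuple[str, ...], down: tuple[str, ...]):
        return SyntenyNeighborhood(
            species=species, focal=focal, upstream=up, downstream=down
        )

    neighborhoods = [make(sp, upstream, downstream) for sp in species_list[:-1]]
    target = species_list[-1]
    if rearrangement == "none":
        neighborhoods.append(make(target, upstream, downstream))
        truth = n_flanks >= default_min_shared
    elif rearrangement == "insertion":
        # novel gene inserted next to the focal; outermost downstream flank
        # drops off the window
        down = ("INS999",) + downstream[:-1] if flanks_per_side > 1 else ("INS999",)
        neighborhoods.append(make(target, upstream, down))
        truth = n_flanks - 1 >= default_min_shared
    elif rearrangement == "inversion":
        neighborhoods.append(make(target, downstream, upstream))
        truth = n_flanks >= default_min_shared
    elif rearrangement == "shuffle":
        seq = list(base)
        # a flank assignment is order-consistent iff it equals the original
        # or its orientation swap (down block then up block); reject both
        swapped = seq[flanks_per_side:] + seq[:flanks_per_side]
        while True:
            perm = [seq[i] for i in rng.permutation(n_flanks)]
            if perm != seq and perm != swapped:
                break
        neighborhoods.append(
            make(target, tuple(perm[:flanks_per_side]), tuple(perm[flanks_per_side:]))
        )
        truth = False
    else:  # translocation: focal moved into an unrelated neighborhood
        fresh = [f"TRX{i:03d}" for i in range(n_flanks)]
        neighborhoods.append(
            make(target, tuple(fresh[:flanks_per_side]), tuple(fresh[flanks_per_side:]))
        )
        truth = False
    return neighborhoods, truth
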