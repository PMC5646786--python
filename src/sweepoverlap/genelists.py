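"""Reading, harmonizing, filtering, and pooling candidate-gene lists.

Selective-sweep screens publish their candidates as flat lists of gene
symbols, one list per species/comparison. Before any overlap statistic can
be computed the lists must be harmonized (same symbol for the same gene
across assemblies), purged of non-coding records (the intersection model is
defined over protein-coding genes), and deduplicated into species-level or
pooled symbol sets. Everything downstream operates on the canonical,
uppercase symbol.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

#: Controlled species vocabulary; validated at parse time so that a typo in a
#: species column cannot silently contaminate a pool.
SPECIES_LABELS = frozenset(
    {
        "amh",
        "dog",
        "cat",
        "cattle",
        "horse",
        "chimp",
        "orangutan",
        "gorilla",
        "wolf",
        "wisent",
        "rabbit",
        "bonobo",
        "fox",
        "pig",
        "rat",
    }
)

#: Controlled gene-class vocabulary.
GENE_CLASSES = frozenset(
    {"protein_coding", "miRNA", "antisense", "other_noncoding", "unknown"}
)

#: Gene-list TSV column order (the on-disk dialect).
GENELIST_COLUMNS = ("species", "comparison", "source", "symbol_raw", "gene_class")


class GenelistParseError(ValueError):
    """Raised when a gene-list or alias file violates the format contract."""


@dataclass(frozen=True)
class GeneRecord:
    """One harmonized candidate-gene entry with its provenance.

    ``symbol_raw`` is the spelling as printed in the source table;
    ``symbol`` is the canonical uppercase symbol used for all set
    operations.
    """

    symbol_raw: str
    symbol: str
    species: str
    comparison: str = ""
    source: str = ""
    gene_class: str = "unknown"

    def __post_init__(self) -> None:
        if not self.symbol or self.symbol != self.symbol.strip().upper():
            raise GenelistParseError(
                f"canonical symbol must be non-empty, stripped, uppercase: "
                f"{self.symbol!r}"
            )
        if self.species not in SPECIES_LABELS:
            raise GenelistParseError(
                f"unknown species label {self.species!r}; allowed: "
                f"{sorted(SPECIES_LABELS)}"
            )
        if self.gene_class not in GENE_CLASSES:
            raise GenelistParseError(
                f"unknown gene_class {self.gene_class!r}; allowed: "
                f"{sorted(GENE_CLASSES)}"
            )


class AliasTable:
    """Functional mapping from raw symbol variants to canonical symbols.

    Keys are matched case-insensitively. Canonical targets must be fixed
    points of the mapping (no chains), so a single lookup fully resolves
    any variant.
    """

    def __init__(self, entries: Mapping[str, str] | None = None) -> None:
        self.entries: dict[str, str] = {}
        for raw, canonical in (entries or {}).items():
            key = raw.strip().upper()
            value = canonical.strip().upper()
            if not key or not value:
                raise GenelistParseError("alias entries must be non-empty")
            if key in self.entries and self.entries[key] != value:
                raise GenelistParseError(
                    f"alias table maps {key!r} to both {self.entries[key]!r} "
                    f"and {value!r}"
                )
            self.entries[key] = value
        for value in self.entries.values():
            if value in self.entries and self.entries[value] != value:
                raise GenelistParseError(
                    f"canonical symbol {value!r} is itself remapped; aliases "
                    "must resolve in one step"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def resolve(self, symbol: str) -> str:
        return self.entries.get(symbol, symbol)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AliasTable":
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
        for col in ("raw", "canonical"):
            if col not in df.columns:
                raise GenelistParseError(
                    f"alias file {path} is missing required column {col!r}"
                )
        return cls(dict(zip(df["raw"], df["canonical"])))


@dataclass(frozen=True)
class GenePool:
    """A deduplicated set of canonical symbols from one or more lists."""

    label: str
    species_set: frozenset[str]
    symbols: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbols


def normalize_symbol(raw: str, aliases: AliasTable | None = None, row: object = None) -> str:
    """Canonicalize one symbol: strip, uppercase, then alias lookup.

    Deliberately minimal (no Greek-letter or hyphen rewriting): every
    harmonization decision beyond case and whitespace must be an explicit,
    versioned alias entry so it can be audited.
    """
    stripped = raw.strip() if isinstance(raw, str) else ""
    if not stripped:
        where = f" (row {row})" if row is not None else ""
        raise GenelistParseError(f"empty or whitespace-only gene symbol{where}")
    symbol = stripped.upper()
    if aliases is not None:
        symbol = aliases.resolve(symbol)
    return symbol


def filter_noncoding(records: Iterable[GeneRecord]) -> list[GeneRecord]:
    """Drop miRNA / antisense / other non-coding records.

    Records of unknown class are retained — published sweep tables rarely
    annotate gene class — and their count is reported through a logged
    warning so the retention is visible.
    """
    kept = [r for r in records if r.gene_class in ("protein_coding", "unknown")]
    n_unknown = sum(1 for r in kept if r.gene_class == "unknown")
    if n_unknown:
        logger.warning(
            "filter_noncoding retained %d record(s) of unknown gene class",
            n_unknown,
        )
    return kept


def build_pool(label: str, *record_lists: Iterable[GeneRecord]) -> GenePool:
    """Union one or more record lists into a deduplicated symbol pool.

    Order- and duplication-invariant: repeating a list or permuting the
    inputs never changes the resulting symbol set.
    """
    symbols: set[str] = set()
    species: set[str] = set()
    for records in record_lists:
        for record in records:
            symbols.add(record.symbol)
            species.add(record.species)
    return GenePool(label=label, species_set=frozenset(species), symbols=frozenset(symbols))


def pools_by_species(records: Iterable[GeneRecord]) -> dict[str, GenePool]:
    """Split records into one pool per species label."""
    grouped: dict[str, list[GeneRecord]] = {}
    for record in records:
        grouped.setdefault(record.species, []).append(record)
    return {sp: build_pool(sp, recs) for sp, recs in sorted(grouped.items())}


def read_genelist_tsv(
    path: str | Path, aliases: AliasTable | None = None
) -> list[GeneRecord]:
    """Read a gene-list TSV into normalized records.

    Required columns: species, comparison, source, symbol_raw; gene_class is
    optional and defaults to ``unknown``. Alias harmonization is opt-in via
    ``aliases`` so that verbatim transcriptions keep their printed symbols.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    for col in GENELIST_COLUMNS[:-1]:
        if col not in df.columns:
            raise GenelistParseError(
                f"gene list {path} is missing required column {col!r}"
            )
    if "gene_class" not in df.columns:
        df["gene_class"] = "unknown"
    df.loc[df["gene_class"] == "", "gene_class"] = "unknown"
    records = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        records.append(
            GeneRecord(
                symbol_raw=row.symbol_raw,
                symbol=normalize_symbol(row.symbol_raw, aliases, row=idx),
                species=row.species,
                comparison=row.comparison,
                source=row.source,
                gene_class=row.gene_class,
            )
        )
    return records


def write_genelist_tsv(records: Iterable[GeneRecord], path: str | Path) -> None:
    """Write records in the gene-list TSV dialect (round-trips with read)."""
    df = pd.DataFrame(
        [
            {
                "species": r.species,
                "comparison": r.comparison,
                "source": r.source,
                "symbol_raw": r.symbol_raw,
                "gene_class": r.gene_class,
            }
            for r in records
        ],
        columns=list(GENELIST_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False)


def _fixture_path(name: str) -> Path:
    return Path(resources.files("sweepoverlap") / "fixtures" / name)


def load_table1_records() -> list[GeneRecord]:
    """Load the packaged transcription of the 41-gene AMH/domesticate overlap.

    One record per (gene, overlapping domesticate) pair; a gene listed under
    two domesticates therefore yields two records but only one distinct
    symbol.
    """
    return read_genelist_tsv(_fixture_path("table1_overlap.tsv"))


def load_packaged_aliases() -> AliasTable:
    """Packaged alias fixture of legacy-to-current HGNC symbol renames."""
    return AliasTable.from_tsv(_fixture_path("aliases.tsv"))
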