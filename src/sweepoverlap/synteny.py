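"""Synteny-based orthology validation for shared candidate genes.

A gene symbol shared between two species' sweep lists is only evidence of
convergent selection if it names the same (orthologous) locus in both
genomes, not a same-named paralog. The check used here mirrors manual
synteny curation: take the ordered protein-coding genes flanking the focal
gene in each species and ask whether the flanking blocks agree — the same
neighbors, in a consistent relative order, allowing whole-block inversion
(strand/assembly orientation is arbitrary) and a bounded number of
interleaved insertions (lineage-specific gene gains or local duplications).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

MAX_FLANKS_PER_SIDE = 8

NEIGHBORHOOD_COLUMNS = ("species", "focal", "side", "rank", "symbol", "chrom")


@dataclass(frozen=True)
class SyntenyNeighborhood:
    """Ordered flanking protein-coding genes around a focal gene.

    ``upstream`` and ``downstream`` are nearest-first; the linear
    chromosomal order is therefore reversed(upstream) + focal + downstream.
    """

    species: str
    focal: str
    upstream: tuple[str, ...]
    downstream: tuple[str, ...]
    chrom: str | None = None

    def __post_init__(self) -> None:
        for side, flanks in (("upstream", self.upstream), ("downstream", self.downstream)):
            if not 1 <= len(flanks) <= MAX_FLANKS_PER_SIDE:
                raise ValueError(
                    f"{side} must have 1..{MAX_FLANKS_PER_SIDE} flanks, "
                    f"got {len(flanks)} for {self.focal} in {self.species}"
                )
        all_flanks = self.upstream + self.downstream
        if len(set(all_flanks)) != len(all_flanks):
            raise ValueError(f"repeated flank symbol around {self.focal}")
        if self.focal in all_flanks:
            raise ValueError(f"focal {self.focal} listed among its own flanks")

    @property
    def sequence(self) -> tuple[str, ...]:
        """Flanks and focal in linear chromosomal order."""
        return tuple(reversed(self.upstream)) + (self.focal,) + self.downstream

    @property
    def flank_set(self) -> frozenset[str]:
        return frozenset(self.upstream) | frozenset(self.downstream)

    def reversed_(self) -> "SyntenyNeighborhood":
        """The same neighborhood read from the opposite strand/orientation."""
        return SyntenyNeighborhood(
            species=self.species,
            focal=self.focal,
            upstream=self.downstream,
            downstream=self.upstream,
            chrom=self.chrom,
        )


@dataclass(frozen=True)
class SyntenyVerdict:
    focal: str
    species_pair: tuple[str, str]
    shared_flanks: int
    order_consistent: bool
    conserved: bool


def _project(sequence: Sequence[str], keep: frozenset[str]) -> list[str]:
    return [s for s in sequence if s in keep]


def _gaps_ok(sequence: Sequence[str], keep: frozenset[str], max_insertions: int) -> bool:
    # count non-shared symbols strictly between consecutive shared symbols
    gap = 0
    seen_first = False
    for symbol in sequence:
        if symbol in keep:
            if seen_first and gap > max_insertions:
                return False
            seen_first = True
            gap = 0
        elif seen_first:
            gap += 1
    return True


def compare_neighborhoods(
    nb_a: SyntenyNeighborhood,
    nb_b: SyntenyNeighborhood,
    min_shared: int = 4,
    max_insertions: int = 1,
) -> SyntenyVerdict:
    """Pairwise conservation verdict for one focal gene in two species.

    Shared flanks are counted on the union of both sides. Order consistency
    requires the shared symbols (plus the focal) to appear as the same
    sequence in both neighborhoods, in either the given orientation or the
    full reversal of one of them, with at most ``max_insertions``
    non-shared genes interleaved between consecutive shared ones.
    """
    if nb_a.focal != nb_b.focal:
        raise ValueError(
            f"cannot compare neighborhoods of different focal genes: "
            f"{nb_a.focal} vs {nb_b.focal}"
        )
    shared = nb_a.flank_set & nb_b.flank_set
    keep = frozenset(shared | {nb_a.focal})
    proj_a = _project(nb_a.sequence, keep)
    order_consistent = False
    for candidate in (nb_b, nb_b.reversed_()):
        if proj_a != _project(candidate.sequence, keep):
            continue
        if _gaps_ok(nb_a.sequence, keep, max_insertions) and _gaps_ok(
            candidate.sequence, keep, max_insertions
        ):
            order_consistent = True
            break
    conserved = len(shared) >= min_shared and order_consistent
    return SyntenyVerdict(
        focal=nb_a.focal,
        species_pair=(nb_a.species, nb_b.species),
        shared_flanks=len(shared),
        order_consistent=order_consistent,
        conserved=conserved,
    )


def confirm_orthology(
    focal: str,
    neighborhoods: Sequence[SyntenyNeighborhood],
    min_shared: int = 4,
    max_insertions: int = 1,
) -> tuple[bool, list[SyntenyVerdict]]:
    """Check one focal gene across species against a reference neighborhood.

    The reference is the AMH neighborhood when present, else the first
    listed; the gene is called orthologous across the panel only if every
    reference-vs-other pair is conserved.
    """
    nbs = [nb for nb in neighborhoods if nb.focal == focal]
    if len(nbs) < 2:
        raise ValueError(
            f"need neighborhoods from >= 2 species for {focal}, got {len(nbs)}"
        )
    reference = next((nb for nb in nbs if nb.species == "amh"), nbs[0])
    verdicts = [
        compare_neighborhoods(reference, nb, min_shared, max_insertions)
        for nb in nbs
        if nb is not reference
    ]
    return all(v.conserved for v in verdicts), verdicts


def read_neighborhoods_tsv(path: str | Path) -> list[SyntenyNeighborhood]:
    """Read neighborhoods from the TSV dialect (species/focal/side/rank/symbol/chrom)."""
    df = pd.read_csv(path, sep="\t", dtype={"rank": int}, comment="#").fillna("")
    for col in NEIGHBORHOOD_COLUMNS[:-1]:
        if col not in df.columns:
            raise ValueError(f"neighborhood file {path} is missing column {col!r}")
    if "chrom" not in df.columns:
        df["chrom"] = ""
    out = []
    for (species, focal), group in df.groupby(["species", "focal"], sort=True):
        sides = {}
        for side in ("up", "down"):
            rows = group[group["side"] == side].sort_values("rank")
            sides[side] = tuple(rows["symbol"])
        chroms = set(group["chrom"]) - {""}
        out.append(
            SyntenyNeighborhood(
                species=species,
                focal=focal,
                upstream=sides["up"],
                downstream=sides["down"],
                chrom=chroms.pop() if len(chroms) == 1 else None,
            )
        )
    return out


def write_neighborhoods_tsv(
    neighborhoods: Iterable[SyntenyNeighborhood], path: str | Path
) -> None:
    rows = []
    for nb in neighborhoods:
        for side, flanks in (("up", nb.upstream), ("down", nb.downstream)):
            for rank, symbol in enumerate(flanks, start=1):
                rows.append(
                    {
                        "species": nb.species,
                        "focal": nb.focal,
                        "side": side,
                        "rank": rank,
                        "symbol": symbol,
                        "chrom": nb.chrom or "",
                    }
                )
    pd.DataFrame(rows, columns=list(NEIGHBORHOOD_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def neighborhood_from_gff(
    gff_path: str | Path,
    focal: str,
    species: str,
    flanks_per_side: int = 4,
) -> SyntenyNeighborhood:
    """Extract a focal gene's neighborhood from a GFF3 annotation.

    Selects protein-coding gene features, orders them by start coordinate
    within each sequence region (coordinates handled 0-based half-open
    internally), and takes up to ``flanks_per_side`` genes on each side of
    the focal gene.
    """
    import gffutils

    db = gffutils.create_db(
        str(gff_path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )

    def gene_name(feature) -> str:
        for key in ("Name", "gene_name", "gene", "ID"):
            if key in feature.attributes:
                return feature.attributes[key][0]
        return feature.id

    def is_protein_coding(feature) -> bool:
        for key in ("gene_biotype", "biotype", "gene_type"):
            if key in feature.attributes:
                return feature.attributes[key][0] == "protein_coding"
        return True  # unannotated biotype: keep

    genes_by_seqid: dict[str, list] = {}
    for feature in db.features_of_type("gene"):
        if is_protein_coding(feature):
            # GFF3 is 1-based inclusive; convert to 0-based half-open
            genes_by_seqid.setdefault(feature.seqid, []).append(
                (feature.start - 1, feature.end, gene_name(feature))
            )
    for seqid, genes in genes_by_seqid.items():
        genes.sort()
        names = [name for _, _, name in genes]
        if focal in names:
            i = names.index(focal)
            upstream = tuple(reversed(names[max(0, i - flanks_per_side) : i]))
            downstream = tuple(names[i + 1 : i + 1 + flanks_per_side])
            return SyntenyNeighborhood(
                species=species,
                focal=focal,
                upstream=upstream,
                downstream=downstream,
                chrom=seqid,
            )
    raise ValueError(f"focal gene {focal!r} not found among protein-coding genes")


def render_verdicts_tsv(verdicts: Sequence[SyntenyVerdict]) -> str:
    lines = ["focal\tspecies_a\tspecies_b\tshared_flanks\torder_consistent\tconserved"]
    for v in verdicts:
        lines.append(
            f"{v.focal}\t{v.species_pair[0]}\t{v.species_pair[1]}\t"
            f"{v.shared_flanks}\t{v.order_consistent}\t{v.conserved}"
        )
    return "\n".join(lines) + "\n"
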