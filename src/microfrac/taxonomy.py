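"""Genome-size-annotated taxonomy.

Builds a rooted rank tree from a table of reference genomes in which every
node carries an average genome size (AGS) in base pairs:

* each genome's raw assembly size is corrected for its estimated
  completeness and contamination;
* a species node's AGS is the mean corrected size of its member genomes;
* every node above species takes the *unweighted mean of its immediate
  children* — e.g. a family's AGS is the mean of its genera's AGS values,
  not the mean over all descendant species — and the root takes the mean
  of the domains.

The level-wise propagation keeps a large, well-sampled genus from dominating
the estimate for its family, mirroring how rank-aggregated trait tables are
built for marker-based community profiling.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .lineage import RANKS, Lineage, LineageError


class MissingTaxonError(LookupError):
    """A queried lineage's domain is absent from the taxonomy."""


class MissingTaxonWarning(UserWarning):
    """A queried taxon was priced at its deepest present ancestor."""


class TaxonomyError(ValueError):
    """Structural problem in the input records or a taxonomy file."""


@dataclass(frozen=True)
class GenomeRecord:
    """One reference genome with taxonomy and assembly quality estimates.

    ``completeness`` and ``contamination`` are percentages as produced by
    single-copy-marker quality tools (CheckM-style): completeness in
    (0, 100], contamination >= 0 (and < 100 for a usable size estimate).
    """

    accession: str
    lineage: Lineage
    assembly_size: int
    completeness: float
    contamination: float

    def __post_init__(self) -> None:
        if not self.lineage.is_species:
            raise TaxonomyError(
                f"genome {self.accession}: lineage must resolve all 7 ranks "
                f"(got depth {self.lineage.depth})"
            )
        if self.assembly_size <= 0:
            raise TaxonomyError(f"genome {self.accession}: assembly_size must be > 0")
        if not 0 < self.completeness <= 100:
            raise TaxonomyError(
                f"genome {self.accession}: completeness must be in (0, 100]"
            )
        if self.contamination < 0:
            raise TaxonomyError(f"genome {self.accession}: contamination must be >= 0")

    @property
    def corrected_size(self) -> float:
        return corrected_genome_size(
            self.assembly_size, self.completeness, self.contamination
        )


def corrected_genome_size(
    assembly_size: float, completeness: float, contamination: float
) -> float:
    """Completeness/contamination-corrected genome size in bp.

    ``corrected = assembly_size * (1 - contamination/100) / (completeness/100)``:
    estimated contaminant bases are removed, then the remainder is rescaled
    to account for the unrecovered fraction of the genome.

    Raises
    ------
    ValueError
        If ``completeness`` is not in (0, 100] or ``contamination`` is
        outside [0, 100) (contamination of 100% or more would yield a
        non-positive size).
    """
    if not 0 < completeness <= 100:
        raise ValueError(f"completeness must be in (0, 100], got {completeness}")
    if not 0 <= contamination < 100:
        raise ValueError(f"contamination must be in [0, 100), got {contamination}")
    if assembly_size <= 0:
        raise ValueError(f"assembly_size must be > 0, got {assembly_size}")
    return assembly_size * (1.0 - contamination / 100.0) / (completeness / 100.0)


def species_ags(genomes: Iterable[GenomeRecord]) -> float:
    """Mean corrected genome size over all genomes of one species."""
    genomes = list(genomes)
    if not genomes:
        raise TaxonomyError("species_ags needs at least one genome")
    lineages = {g.lineage for g in genomes}
    if len(lineages) > 1:
        raise TaxonomyError(
            f"species_ags called with {len(lineages)} distinct lineages"
        )
    return sum(g.corrected_size for g in genomes) / len(genomes)


@dataclass
class TaxonNode:
    """One node of a size-annotated taxonomy tree."""

    rank: str
    name: str
    ags: float = math.nan
    children: dict[str, "TaxonNode"] = field(default_factory=dict)

    # genome sizes accumulated at species nodes during construction
    _member_sizes: list[float] = field(default_factory=list, repr=False)

    def walk(self, prefix: tuple[str, ...] = ()) -> Iterator[tuple[Lineage, "TaxonNode"]]:
        """Pre-order traversal yielding (lineage, node) pairs."""
        yield Lineage(prefix), self
        for label in sorted(self.children):
            yield from self.children[label].walk(prefix + (label,))


class SizeTaxonomy:
    """Rooted rank tree in which every node carries an AGS in base pairs."""

    def __init__(self, root: TaxonNode):
        if root.rank != "root":
            raise TaxonomyError("taxonomy root must have rank 'root'")
        self.root = root

    # -- queries -----------------------------------------------------------

    def find(self, lineage: Lineage) -> TaxonNode | None:
        """Exact node for ``lineage``, or None if absent."""
        node = self.root
        for label in lineage:
            child = node.children.get(label)
            if child is None:
                return None
            node = child
        return node

    def lookup_ags(self, lineage: Lineage) -> float:
        """AGS in bp of the deepest taxonomy node matching ``lineage``.

        If the exact taxon is absent, falls back to its deepest present
        ancestor and emits :class:`MissingTaxonWarning`; the root lineage
        returns the root AGS.  A lineage whose domain is unknown raises
        :class:`MissingTaxonError`.
        """
        node = self.root
        matched = 0
        for label in lineage:
            child = node.children.get(label)
            if child is None:
                break
            node = child
            matched += 1
        if matched < lineage.depth:
            if matched == 0 and lineage.depth > 0:
                raise MissingTaxonError(
                    f"domain {lineage.name_at(1)!r} absent from taxonomy"
                )
            warnings.warn(
                f"taxon {lineage} absent from taxonomy; using ancestor "
                f"{lineage.truncate(matched)} ({node.rank} AGS)",
                MissingTaxonWarning,
                stacklevel=2,
            )
        return node.ags

    def nodes(self) -> Iterator[tuple[Lineage, TaxonNode]]:
        return self.root.walk()

    def species(self) -> Iterator[tuple[Lineage, TaxonNode]]:
        """All species-rank (lineage, node) pairs."""
        for lin, node in self.nodes():
            if node.rank == "species":
                yield lin, node

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SizeTaxonomy):
            return NotImplemented
        mine = {str(lin): node.ags for lin, node in self.nodes()}
        theirs = {str(lin): node.ags for lin, node in other.nodes()}
        return mine == theirs


def build_taxonomy(records: Iterable[GenomeRecord]) -> SizeTaxonomy:
    """Build a :class:`SizeTaxonomy` from reference genome records.

    The tree contains exactly the taxa present in ``records``.  Species AGS
    is the mean corrected size of member genomes; every ancestor's AGS is
    the unweighted mean of its immediate children; the root's AGS is the
    mean over domains.  Input order does not affect the result.

    Raises
    ------
    TaxonomyError
        On empty input, or when the same taxon name at a rank appears under
        two different parents (inconsistent parentage).
    """
    records = list(records)
    if not records:
        raise TaxonomyError("cannot build a taxonomy from zero genomes")

    root = TaxonNode(rank="root", name="root")
    seen_parent: dict[tuple[str, str], str] = {}

    for rec in sorted(records, key=lambda r: (str(r.lineage), r.accession)):
        node = root
        parent_path = ""
        for depth, label in enumerate(rec.lineage, start=1):
            key = (RANKS[depth - 1], label)
            prev = seen_parent.setdefault(key, parent_path)
            if prev != parent_path:
                raise TaxonomyError(
                    f"inconsistent parentage: {label!r} appears under both "
                    f"{prev!r} and {parent_path!r}"
                )
            node = node.children.setdefault(
                label, TaxonNode(rank=RANKS[depth - 1], name=label)
            )
            parent_path = f"{parent_path}; {label}" if parent_path else label
        node._member_sizes.append(rec.corrected_size)

    _propagate(root)
    return SizeTaxonomy(root)


def _propagate(node: TaxonNode) -> float:
    if not node.children:  # species leaf
        node.ags = sum(node._member_sizes) / len(node._member_sizes)
    else:
        child_ags = [_propagate(c) for c in node.children.values()]
        node.ags = sum(child_ags) / len(child_ags)
    return node.ags


def lookup_ags(taxonomy: SizeTaxonomy, lineage: Lineage) -> float:
    """Functional form of :meth:`SizeTaxonomy.lookup_ags`."""
    return taxonomy.lookup_ags(lineage)


# -- genome table and taxonomy I/O ----------------------------------------

GENOME_COLUMNS = ("accession", "lineage", "assembly_size", "completeness", "contamination")
TAXONOMY_COLUMNS = ("lineage", "rank", "ags_bp")


def read_genome_table(path: str | Path) -> list[GenomeRecord]:
    """Read a tab-delimited genome metadata table.

    Required header: accession, lineage, assembly_size, completeness,
    contamination.  The lineage column holds the 7-rank prefixed string
    joined by ``"; "``.
    """
    path = Path(path)
    records: list[GenomeRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not set(GENOME_COLUMNS) <= set(reader.fieldnames):
            raise TaxonomyError(
                f"{path}: genome table must have columns {GENOME_COLUMNS}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(
                    GenomeRecord(
                        accession=row["accession"],
                        lineage=Lineage.parse(row["lineage"]),
                        assembly_size=int(row["assembly_size"]),
                        completeness=float(row["completeness"]),
                        contamination=float(row["contamination"]),
                    )
                )
            except (LineageError, TaxonomyError, ValueError) as exc:
                raise TaxonomyError(f"{path}:{lineno}: {exc}") from exc
    if not records:
        raise TaxonomyError(f"{path}: no genome records found")
    return records


def write_taxonomy(taxonomy: SizeTaxonomy, path: str | Path) -> None:
    """Write the taxonomy as a TSV of (lineage, rank, ags_bp), pre-order.

    The root row has an empty lineage field.  AGS values are written with
    ``repr`` precision so a read/write round-trip is exact.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(TAXONOMY_COLUMNS)
        for lin, node in taxonomy.nodes():
            writer.writerow([str(lin), node.rank, repr(node.ags)])


def read_taxonomy(path: str | Path) -> SizeTaxonomy:
    """Read a taxonomy TSV written by :func:`write_taxonomy`.

    Raises :class:`TaxonomyError` with the offending line number on
    malformed rows, duplicate lineages, orphan rows or a missing root.
    """
    path = Path(path)
    root: TaxonNode | None = None
    seen: set[str] = set()
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            raise TaxonomyError(f"{path}: empty taxonomy file")
        if tuple(header) != TAXONOMY_COLUMNS:
            raise TaxonomyError(
                f"{path}:1: expected header {TAXONOMY_COLUMNS}, got {tuple(header)}"
            )
        for lineno, row in enumerate(reader, start=2):
            if len(row) != 3:
                raise TaxonomyError(f"{path}:{lineno}: expected 3 fields, got {len(row)}")
            lineage_str, rank, ags_str = row
            try:
                lineage = Lineage.parse(lineage_str)
                ags = float(ags_str)
            except (LineageError, ValueError) as exc:
                raise TaxonomyError(f"{path}:{lineno}: {exc}") from exc
            if ags <= 0:
                raise TaxonomyError(f"{path}:{lineno}: ags_bp must be > 0")
            if str(lineage) in seen:
                raise TaxonomyError(f"{path}:{lineno}: duplicate lineage {lineage_str!r}")
            seen.add(str(lineage))
            if lineage.depth == 0:
                if rank != "root":
                    raise TaxonomyError(f"{path}:{lineno}: zero-depth row must have rank 'root'")
                root = TaxonNode(rank="root", name="root", ags=ags)
                continue
            if root is None:
                raise TaxonomyError(f"{path}:{lineno}: root row must precede taxon rows")
            if rank != RANKS[lineage.depth - 1]:
                raise TaxonomyError(
                    f"{path}:{lineno}: rank {rank!r} does not match lineage depth"
                )
            parent = root
            for label in lineage.parent:
                parent = parent.children.get(label)  # type: ignore[assignment]
                if parent is None:
                    raise TaxonomyError(
                        f"{path}:{lineno}: parent of {lineage_str!r} not yet defined"
                    )
            parent.children[lineage.labels[-1]] = TaxonNode(
                rank=rank, name=lineage.labels[-1], ags=ags
            )
    if root is None:
        raise TaxonomyError(f"{path}: no rows in taxonomy file")
    return SizeTaxonomy(root)
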