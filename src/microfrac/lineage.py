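"""GTDB-style rank-prefixed lineages.

A lineage is an ordered chain of taxon labels from domain downwards, each
carrying its canonical one-letter rank prefix (``d__``, ``p__``, ``c__``,
``o__``, ``f__``, ``g__``, ``s__``).  Lineages may be truncated at any depth:
a marker-based profiler assigns read coverage at the deepest rank it can
resolve confidently, so coverage routinely sits at genus, family or higher.
A zero-depth lineage denotes the taxonomy root (coverage that could not be
assigned below the root at all).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

RANKS: tuple[str, ...] = (
    "domain",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)
RANK_PREFIXES: tuple[str, ...] = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")
SEPARATOR = "; "

_PREFIX_TO_DEPTH = {p: i + 1 for i, p in enumerate(RANK_PREFIXES)}


class LineageError(ValueError):
    """Raised for malformed lineage strings or label sequences."""


@dataclass(frozen=True, order=True)
class Lineage:
    """An ordered, possibly truncated chain of rank-prefixed taxon labels.

    Parameters
    ----------
    labels :
        Tuple of prefixed labels in canonical rank order starting at domain,
        e.g. ``("d__Bacteria", "p__Pseudomonadota")``.  May be empty (root).
    """

    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.labels) > len(RANK_PREFIXES):
            raise LineageError(
                f"lineage has {len(self.labels)} ranks; at most "
                f"{len(RANK_PREFIXES)} (domain..species) are allowed"
            )
        for i, label in enumerate(self.labels):
            prefix = RANK_PREFIXES[i]
            if not label.startswith(prefix):
                raise LineageError(
                    f"label {label!r} at position {i} must carry the "
                    f"{RANKS[i]} prefix {prefix!r} (prefixes must appear in "
                    "canonical order with no gaps)"
                )
            if len(label) <= len(prefix):
                raise LineageError(f"empty taxon name in label {label!r}")

    # -- constructors ------------------------------------------------------

    @classmethod
    def parse(cls, text: str) -> "Lineage":
        """Parse a ``"; "``-separated prefixed lineage string.

        An empty or whitespace-only string parses to the root lineage.
        """
        text = text.strip()
        if not text:
            return cls(())
        parts = tuple(p.strip() for p in text.split(";"))
        if any(not p for p in parts):
            raise LineageError(f"empty rank field in lineage string {text!r}")
        return cls(parts)

    @classmethod
    def from_names(cls, *names: str) -> "Lineage":
        """Build a lineage from bare taxon names, adding rank prefixes."""
        if len(names) > len(RANK_PREFIXES):
            raise LineageError("too many ranks")
        return cls(tuple(p + n for p, n in zip(RANK_PREFIXES, names)))

    # -- basic accessors ---------------------------------------------------

    @property
    def depth(self) -> int:
        """Number of resolved ranks; 0 for the root, 7 for full species."""
        return len(self.labels)

    @property
    def rank(self) -> str:
        """Rank name of the deepest resolved label ('root' at depth 0)."""
        return "root" if not self.labels else RANKS[len(self.labels) - 1]

    @property
    def is_species(self) -> bool:
        return len(self.labels) == len(RANK_PREFIXES)

    def name_at(self, depth: int) -> str:
        """Prefixed label at 1-based ``depth``."""
        return self.labels[depth - 1]

    def truncate(self, depth: int) -> "Lineage":
        """Lineage cut to the first ``depth`` ranks."""
        if depth < 0:
            raise LineageError("depth must be >= 0")
        return Lineage(self.labels[:depth])

    @property
    def parent(self) -> "Lineage":
        if not self.labels:
            raise LineageError("root lineage has no parent")
        return Lineage(self.labels[:-1])

    def ancestors(self) -> Iterator["Lineage"]:
        """Yield proper ancestors from the root down to the parent."""
        for d in range(len(self.labels)):
            yield Lineage(self.labels[:d])

    def __str__(self) -> str:
        return SEPARATOR.join(self.labels)

    def __iter__(self) -> Iterator[str]:
        return iter(self.labels)

    def __len__(self) -> int:
        return len(self.labels)
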