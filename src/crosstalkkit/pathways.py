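"""Named gene-set collections (metabolic pathways, GO terms) and their filters.

A :class:`PathwayDB` maps a pathway (or term) name to its member genes, a
functional-class label (e.g. ``"Amino acid metabolism"``) and an optional
KEGG ``ko`` identifier.  It is the shared container for the enrichment and
cross-talk stages.
"""
from __future__ import annotations

import re
from collections.abc import Mapping
from dataclasses import dataclass
from typing import Iterable, Iterator

__all__ = ["PathwayEntry", "PathwayDB"]

_KO_RE = re.compile(r"^ko\d{5}$")


@dataclass(frozen=True)
class PathwayEntry:
    """One gene set: members, functional-class label, optional KEGG ko id."""

    genes: frozenset[str]
    functional_class: str = ""
    ko: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))
        if not self.genes:
            raise ValueError("pathway gene set must be nonempty")
        if self.ko is not None and not _KO_RE.match(self.ko):
            raise ValueError(f"malformed ko identifier: {self.ko!r}")


class PathwayDB(Mapping):
    """Immutable, order-preserving collection of named gene sets.

    Behaves like a mapping from pathway name to :class:`PathwayEntry`.
    Iteration order is insertion order (generation or file order), which
    keeps serialization deterministic.
    """

    def __init__(self, entries: Mapping[str, PathwayEntry] | Iterable[tuple[str, PathwayEntry]]):
        self._entries: dict[str, PathwayEntry] = dict(entries)
        for name, entry in self._entries.items():
            if not isinstance(entry, PathwayEntry):
                raise TypeError(f"entry for {name!r} is not a PathwayEntry")

    @classmethod
    def from_dict(
        cls,
        sets: Mapping[str, Iterable[str]],
        classes: Mapping[str, str] | None = None,
        kos: Mapping[str, str] | None = None,
    ) -> "PathwayDB":
        """Build a DB from plain ``{name: genes}`` mappings."""
        classes = classes or {}
        kos = kos or {}
        return cls(
            {
                name: PathwayEntry(frozenset(genes), classes.get(name, ""), kos.get(name))
                for name, genes in sets.items()
            }
        )

    # -- Mapping protocol ------------------------------------------------
    def __getitem__(self, name: str) -> PathwayEntry:
        return self._entries[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"PathwayDB({len(self)} pathways, {len(self.universe)} genes)"

    # -- accessors -------------------------------------------------------
    @property
    def names(self) -> list[str]:
        return list(self._entries)

    def genes(self, name: str) -> frozenset[str]:
        return self._entries[name].genes

    def functional_class(self, name: str) -> str:
        return self._entries[name].functional_class

    def ko(self, name: str) -> str | None:
        return self._entries[name].ko

    @property
    def universe(self) -> frozenset[str]:
        """Union of all member genes."""
        out: set[str] = set()
        for entry in self._entries.values():
            out |= entry.genes
        return frozenset(out)

    def sizes(self) -> dict[str, int]:
        return {name: len(entry.genes) for name, entry in self._entries.items()}

    # -- transforms ------------------------------------------------------
    def subset(self, names: Iterable[str]) -> "PathwayDB":
        """DB restricted to ``names``, preserving this DB's order."""
        keep = set(names)
        missing = keep - set(self._entries)
        if missing:
            raise KeyError(f"unknown pathway names: {sorted(missing)}")
        return PathwayDB({n: e for n, e in self._entries.items() if n in keep})

    def filter_min_genes(self, min_genes: int = 3) -> "PathwayDB":
        """Drop pathways with fewer than ``min_genes`` members (idempotent)."""
        if min_genes < 1:
            raise ValueError("min_genes must be >= 1")
        return PathwayDB(
            {n: e for n, e in self._entries.items() if len(e.genes) >= min_genes}
        )

    def restrict_to(self, genes: Iterable[str]) -> "PathwayDB":
        """Intersect every pathway with ``genes``; drop pathways left empty."""
        pool = frozenset(genes)
        out: dict[str, PathwayEntry] = {}
        for name, entry in self._entries.items():
            inter = entry.genes & pool
            if inter:
                out[name] = PathwayEntry(inter, entry.functional_class, entry.ko)
        return PathwayDB(out)
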