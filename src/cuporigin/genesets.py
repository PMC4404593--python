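"""Gene sets and GMT-format input/output.

A gene set is a named collection of unique gene symbols; collections of
sets are what overlap testing, GSEA and instability scoring consume.
The GMT dialect is the usual tab-delimited one: set name, description,
then one symbol per remaining column.
"""

from __future__ import annotations

import os
from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass, field


@dataclass(frozen=True)
class GeneSet:
    """A named set of unique gene symbols."""

    name: str
    description: str = ""
    genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set must have a non-empty name")
        if len(self.genes) == 0:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} contains duplicate symbols")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return symbol in set(self.genes)


class GeneSetCollection(Mapping[str, GeneSet]):
    """An ordered, name-indexed collection of :class:`GeneSet` objects."""

    def __init__(self, sets: Iterable[GeneSet] = ()) -> None:
        self._sets: dict[str, GeneSet] = {}
        for s in sets:
            self.add(s)

    def add(self, gene_set: GeneSet) -> None:
        if gene_set.name in self._sets:
            raise ValueError(f"duplicate gene set name {gene_set.name!r}")
        self._sets[gene_set.name] = gene_set

    def __getitem__(self, name: str) -> GeneSet:
        return self._sets[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def __repr__(self) -> str:
        return f"GeneSetCollection({len(self)} sets)"


def read_gmt(path: str | os.PathLike) -> GeneSetCollection:
    """Read a GMT file into a :class:`GeneSetCollection`."""
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT lines need name, description and at "
                    f"least one symbol (got {len(fields)} fields)"
                )
            name, description, *genes = fields
            genes = [g for g in genes if g]
            # preserve order, drop repeats introduced by sloppy files
            seen: dict[str, None] = dict.fromkeys(genes)
            sets.append(GeneSet(name, description, tuple(seen)))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | os.PathLike) -> None:
    """Write a collection in GMT format."""
    with open(path, "w") as fh:
        for gene_set in collection.values():
            fh.write(
                "\t".join([gene_set.name, gene_set.description, *gene_set.genes])
                + "\n"
            )
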