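"""Named gene sets and the plain-text one-identifier-per-line format.

Identifiers are matched case-sensitively after trimming surrounding whitespace;
no symbol aliasing is attempted (mapping between gene/protein namespaces would
require external dictionaries and is out of scope).
"""

from __future__ import annotations

from collections.abc import Iterable, Iterator
from dataclasses import dataclass, field
from pathlib import Path


@dataclass(frozen=True)
class GeneSet:
    """An immutable labelled set of gene identifiers."""

    label: str
    members: frozenset[str] = field(default_factory=frozenset)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: object) -> bool:
        return gene in self.members

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.members))

    @classmethod
    def from_iterable(cls, label: str, genes: Iterable[str]) -> "GeneSet":
        return cls(label, frozenset(g.strip() for g in genes if g.strip()))

    def intersection(self, other: Iterable[str]) -> "GeneSet":
        return GeneSet(self.label, self.members & frozenset(other))


def as_members(genes: "GeneSet | Iterable[str]") -> frozenset[str]:
    """Accept either a GeneSet or a plain iterable of identifiers."""
    if isinstance(genes, GeneSet):
        return genes.members
    return frozenset(str(g).strip() for g in genes)


def load_gene_list(path: str | Path, label: str | None = None) -> GeneSet:
    """Read a gene list: one identifier per line, ``#`` comments and blanks skipped."""
    path = Path(path)
    genes: list[str] = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            genes.append(line)
    return GeneSet.from_iterable(label or path.stem, genes)


def write_gene_list(genes: "GeneSet | Iterable[str]", path: str | Path) -> None:
    members = as_members(genes)
    Path(path).write_text("".join(f"{g}\n" for g in sorted(members)))
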