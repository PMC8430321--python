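"""ADME screening of herbal compounds and the compound–target bipartite network.

Compounds are filtered on two database-reported pharmacokinetic scores: oral
bioavailability (OB, percent of the dose reaching systemic circulation) and
drug-likeness (DL, structural similarity to approved drugs). The conventional
cut-offs OB >= 30% and DL >= 0.18 are applied inclusively — a compound at
exactly the boundary is retained. No ADME prediction is performed; scores are
taken as given in the input table.

A compound appearing under several herbs is attributed to each herb for the
per-herb tallies, while the deduplicated global compound list counts it once.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import ConsistencyError
from .genesets import GeneSet


@dataclass(frozen=True)
class CompoundRecord:
    """One compound row: TCMSP-style id, name, source herb, OB%, DL score."""

    mol_id: str
    name: str
    herb: str
    ob: float
    dl: float

    def __post_init__(self):
        if not self.mol_id:
            raise ValueError("mol_id must be non-empty")
        if self.ob < 0 or self.dl < 0:
            raise ValueError(f"OB/DL must be non-negative ({self.mol_id})")


@dataclass(frozen=True)
class BipartiteNetwork:
    """Compound→target bipartite graph with per-herb attribution."""

    compounds: frozenset[str]
    targets: frozenset[str]
    edges: frozenset[tuple[str, str]]
    herbs_of: dict[str, tuple[str, ...]]
    per_herb_compounds: dict[str, int]
    per_herb_targets: dict[str, int]


def filter_compounds(
    records: Sequence[CompoundRecord],
    ob_min: float = 30.0,
    dl_min: float = 0.18,
) -> list[CompoundRecord]:
    """Records with OB >= ob_min and DL >= dl_min, input order preserved."""
    if ob_min < 0 or dl_min < 0:
        raise ValueError("thresholds must be non-negative")
    return [r for r in records if r.ob >= ob_min and r.dl >= dl_min]


def dedup_targets(pairs: Iterable[tuple[str, str]]) -> GeneSet:
    """The set of distinct targets across all (compound, target) pairs."""
    return GeneSet.from_iterable("targets", (t for _, t in pairs))


def build_bipartite(
    records: Sequence[CompoundRecord],
    pairs: Iterable[tuple[str, str]],
) -> BipartiteNetwork:
    """Assemble the compound–target network and the per-herb tallies.

    A pair naming a compound absent from ``records`` is a consistency error.
    """
    herbs_of: dict[str, set[str]] = {}
    for r in records:
        herbs_of.setdefault(r.mol_id, set()).add(r.herb)
    edges = set()
    targets_of: dict[str, set[str]] = {}
    for mol_id, target in pairs:
        if mol_id not in herbs_of:
            raise ConsistencyError(f"pair references unknown compound {mol_id!r}")
        edges.add((mol_id, target))
        targets_of.setdefault(mol_id, set()).add(target)

    herbs = sorted({h for hs in herbs_of.values() for h in hs})
    per_herb_compounds = {
        h: sum(1 for hs in herbs_of.values() if h in hs) for h in herbs
    }
    per_herb_targets = {}
    for h in herbs:
        tset: set[str] = set()
        for mol_id, hs in herbs_of.items():
            if h in hs:
                tset |= targets_of.get(mol_id, set())
        per_herb_targets[h] = len(tset)

    return BipartiteNetwork(
        compounds=frozenset(herbs_of),
        targets=frozenset(t for _, t in edges),
        edges=frozenset(edges),
        herbs_of={m: tuple(sorted(hs)) for m, hs in herbs_of.items()},
        per_herb_compounds=per_herb_compounds,
        per_herb_targets=per_herb_targets,
    )


def read_compound_table(path: str | Path) -> list[CompoundRecord]:
    """TSV with header ``mol_id name herb ob dl``."""
    df = pd.read_csv(path, sep="\t", dtype={"mol_id": str, "name": str, "herb": str})
    required = {"mol_id", "name", "herb", "ob", "dl"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"compound table missing columns: {sorted(missing)}")
    return [
        CompoundRecord(
            mol_id=row.mol_id, name=row.name, herb=row.herb,
            ob=float(row.ob), dl=float(row.dl),
        )
        for row in df.itertuples(index=False)
    ]


def read_pairs(path: str | Path) -> list[tuple[str, str]]:
    """TSV with header ``mol_id target``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"mol_id", "target"} <= set(df.columns):
        raise ValueError("pairs table needs columns mol_id, target")
    return [(row.mol_id, row.target) for row in df.itertuples(index=False)]


def write_compound_table(records: Sequence[CompoundRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(r.mol_id, r.name, r.herb, r.ob, r.dl) for r in records],
        columns=["mol_id", "name", "herb", "ob", "dl"],
    ).to_csv(path, sep="\t", index=False)


def write_pairs(pairs: Sequence[tuple[str, str]], path: str | Path) -> None:
    pd.DataFrame(pairs, columns=["mol_id", "target"]).to_csv(path, sep="\t", index=False)


def write_bipartite(net: BipartiteNetwork, edge_path: str | Path, node_path: str | Path) -> None:
    """Edge-list TSV plus a node-attribute sidecar (type, semicolon-joined herbs)."""
    pd.DataFrame(sorted(net.edges), columns=["compound", "target"]).to_csv(
        edge_path, sep="\t", index=False
    )
    rows = [
        (c, "compound", ";".join(net.herbs_of.get(c, ())))
        for c in sorted(net.compounds)
    ] + [(t, "target", "") for t in sorted(net.targets)]
    pd.DataFrame(rows, columns=["node", "type", "herbs"]).to_csv(
        node_path, sep="\t", index=False
    )
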