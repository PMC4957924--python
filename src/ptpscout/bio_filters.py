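"""Biological plausibility filters for candidate substrate genes.

A candidate gene passes if it is a known substrate of the anchor phosphatase
or of a phosphatase sharing substrates with the anchor, or if it co-occurs
with the anchor's gene in at least one pathway of the supplied collections.
Tables are user-supplied (DEPOD-style substrate TSV, GMT pathway files);
nothing is fetched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "FilterError",
    "SubstrateTable",
    "PathwaySets",
    "FilterVerdict",
    "related_phosphatases",
    "passes_filters",
    "filter_report",
]


class FilterError(ValueError):
    pass


def _norm(gene: str) -> str:
    return gene.strip().upper()


@dataclass
class SubstrateTable:
    """Phosphatase id -> set of substrate gene ids (uppercased)."""

    substrates: dict[str, frozenset[str]]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SubstrateTable":
        # two columns: phosphatase \t substrate_gene; optional header
        frame = pd.read_csv(
            path, sep="\t", comment="#", names=["phosphatase", "substrate"], dtype=str
        )
        if len(frame) and frame.iloc[0]["phosphatase"] == "phosphatase":
            frame = frame.iloc[1:]
        table: dict[str, set[str]] = {}
        for row in frame.itertuples(index=False):
            table.setdefault(_norm(row.phosphatase), set()).add(_norm(row.substrate))
        return cls({k: frozenset(v) for k, v in table.items()})

    def __getitem__(self, phosphatase: str) -> frozenset[str]:
        return self.substrates[_norm(phosphatase)]

    def __contains__(self, phosphatase: str) -> bool:
        return _norm(phosphatase) in self.substrates


@dataclass
class PathwaySets:
    """Named pathway collections (e.g. KEGG, PID): pathway id -> gene set."""

    collections: dict[str, dict[str, frozenset[str]]] = field(default_factory=dict)

    def add_gmt(self, name: str, path: str | Path) -> "PathwaySets":
        # GMT: pathway \t description \t gene...
        pathways: dict[str, frozenset[str]] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FilterError(f"{path}: GMT line with <3 fields: {line[:60]!r}")
            genes = frozenset(_norm(g) for g in parts[2:] if g.strip())
            if not genes:
                raise FilterError(f"{path}: pathway {parts[0]!r} has no genes")
            pathways[parts[0]] = genes
        self.collections[name] = pathways
        return self

    def shared_pathways(self, gene_a: str, gene_b: str) -> dict[str, list[str]]:
        """Per collection, the pathways containing both genes."""
        a, b = _norm(gene_a), _norm(gene_b)
        return {
            name: [pid for pid, genes in pws.items() if a in genes and b in genes]
            for name, pws in self.collections.items()
        }


def related_phosphatases(table: SubstrateTable, anchor: str) -> set[str]:
    """Phosphatases whose substrate set intersects the anchor's (anchor excluded)."""
    if anchor not in table:
        raise FilterError(f"anchor phosphatase {anchor!r} not in substrate table")
    anchor_set = table[anchor]
    return {
        p
        for p, subs in table.substrates.items()
        if p != _norm(anchor) and subs & anchor_set
    }


@dataclass
class FilterVerdict:
    gene: str
    passed: bool
    reasons: list[str] = field(default_factory=list)


def passes_filters(
    gene: str,
    table: SubstrateTable,
    pathways: PathwaySets,
    anchor: str,
    anchor_gene: str,
    require_all_collections: bool = False,
) -> FilterVerdict:
    """Evaluate the substrate-or-pathway disjunction for one candidate gene.

    Passes iff the gene is a known substrate of the anchor or of a related
    phosphatase, OR it shares a pathway with ``anchor_gene`` (in at least one
    collection by default; in every collection with
    ``require_all_collections=True``).  ``reasons`` lists every satisfied
    clause; an unknown gene fails with reason "not found".
    """
    g = _norm(gene)
    reasons: list[str] = []
    if g in table[anchor]:
        reasons.append(f"substrate of anchor {_norm(anchor)}")
    for p in sorted(related_phosphatases(table, anchor)):
        if g in table.substrates[p]:
            reasons.append(f"substrate of related phosphatase {p}")
    shared = pathways.shared_pathways(g, anchor_gene)
    hit_collections = {name for name, pids in shared.items() if pids}
    for name in sorted(hit_collections):
        reasons.append(f"shares {name} pathway(s): {','.join(sorted(shared[name]))}")
    if require_all_collections:
        pathway_ok = bool(pathways.collections) and hit_collections == set(
            pathways.collections
        )
    else:
        pathway_ok = bool(hit_collections)
    passed = bool(reasons) and (
        any(r.startswith("substrate") for r in reasons) or pathway_ok
    )
    if not passed and not reasons:
        known = any(g in subs for subs in table.substrates.values()) or any(
            g in genes for pws in pathways.collections.values() for genes in pws.values()
        )
        reasons.append("no clause satisfied" if known else "not found")
    return FilterVerdict(gene=g, passed=passed, reasons=reasons)


def filter_report(
    genes: Iterable[str],
    table: SubstrateTable,
    pathways: PathwaySets,
    anchor: str,
    anchor_gene: str,
    require_all_collections: bool = False,
) -> pd.DataFrame:
    verdicts = [
        passes_filters(g, table, pathways, anchor, anchor_gene, require_all_collections)
        for g in genes
    ]
    return pd.DataFrame(
        {
            "gene": [v.gene for v in verdicts],
            "passed": [v.passed for v in verdicts],
            "reasons": ["; ".join(v.reasons) for v in verdicts],
        }
    )
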