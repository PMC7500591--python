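"""Cross-site comparison of significant annotation sets.

Maps significant UniProt IDs to Gene Ontology terms through a local
many-to-many mapping table, compares per-site term sets (Venn region
counts, shared and unique terms), and exports node/edge lists for network
visualization.  Semantic clustering and layout are out of scope; edges
are accepted as input, not computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import chain, combinations

import networkx as nx
import pandas as pd

VALID_NAMESPACES = ("process", "function")


@dataclass(frozen=True)
class GoMapping:
    """Many-to-many (uniprot_id, go_id, namespace) pairs.

    A UniProt ID may map to zero or many GO terms - the conversion is
    explicitly not one-to-one.
    """

    pairs: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"uniprot_id", "go_id", "namespace"}
        missing = required - set(self.pairs.columns)
        if missing:
            raise ValueError(f"mapping lacks columns {sorted(missing)}")
        if len(self.pairs) == 0:
            raise ValueError("empty mapping table")
        bad = set(self.pairs["namespace"]) - set(VALID_NAMESPACES)
        if bad:
            raise ValueError(f"unknown GO namespaces: {sorted(bad)}")
        if self.pairs.duplicated().any():
            object.__setattr__(self, "pairs", self.pairs.drop_duplicates())

    @classmethod
    def from_tsv(cls, path) -> "GoMapping":
        frame = pd.read_csv(path, sep="\t", dtype=str)
        return cls(frame)


def map_to_go(uniprot_ids, mapping: GoMapping, namespace: str) -> tuple[set[str], set[str]]:
    """Union of GO terms for the given IDs in one namespace.

    Returns ``(terms, unmapped_ids)``; IDs without any term in the
    namespace are reported, never silently dropped.  Idempotent under
    input duplication.
    """
    if namespace not in VALID_NAMESPACES:
        raise ValueError(f"namespace must be one of {VALID_NAMESPACES}")
    ids = set(uniprot_ids)
    sub = mapping.pairs[
        (mapping.pairs["namespace"] == namespace)
        & mapping.pairs["uniprot_id"].isin(ids)
    ]
    terms = set(sub["go_id"])
    unmapped = ids - set(sub["uniprot_id"])
    return terms, unmapped


@dataclass(frozen=True)
class TermSetComparison:
    """Venn decomposition of per-site term sets.

    ``regions`` maps each non-empty site combination (sorted tuple) to the
    set of terms found in exactly those sites; region counts therefore
    satisfy inclusion-exclusion against the raw sets by construction.
    """

    site_sets: dict[str, set[str]]
    regions: dict[tuple[str, ...], set[str]]

    def region_counts(self) -> dict[tuple[str, ...], int]:
        return {k: len(v) for k, v in self.regions.items()}

    def shared(self, *sites: str) -> set[str]:
        """Terms present in every one of the given sites (any others too)."""
        out = set.intersection(*(self.site_sets[s] for s in sites))
        return out

    def unique_to(self, site: str) -> set[str]:
        others = set().union(*(v for k, v in self.site_sets.items() if k != site))
        return self.site_sets[site] - others

    def to_dict(self) -> dict:
        return {
            "sites": {s: sorted(v) for s, v in self.site_sets.items()},
            "regions": {"+".join(k): sorted(v) for k, v in self.regions.items()},
            "region_counts": {"+".join(k): len(v) for k, v in self.regions.items()},
        }


def compare_sites(site_term_sets: dict) -> TermSetComparison:
    """All Venn region cardinalities and shared-term lists for >= 2 sites."""
    if len(site_term_sets) < 2:
        raise ValueError("need at least two sites to compare")
    sites = sorted(site_term_sets)
    sets = {s: set(site_term_sets[s]) for s in sites}
    regions: dict[tuple[str, ...], set[str]] = {}
    for r in range(1, len(sites) + 1):
        for combo in combinations(sites, r):
            inside = set.intersection(*(sets[s] for s in combo))
            outside = set().union(*(sets[s] for s in sites if s not in combo)) if len(combo) < len(sites) else set()
            regions[combo] = inside - outside
    return TermSetComparison(sets, regions)


def export_network(term_set, term_frequencies: dict, edges, path, fmt: str = "graphml") -> nx.Graph:
    """Write a term network with node sizes from supplied frequencies.

    ``edges`` is an iterable of (term, term) pairs; an edge naming an
    unknown node is an error.  ``fmt`` is ``"graphml"`` or ``"tsv"``
    (edge list with a node attribute sidecar section).  Returns the graph.
    """
    nodes = set(term_set)
    if not nodes:
        raise ValueError("node set must be non-empty")
    graph = nx.Graph()
    for t in sorted(nodes):
        graph.add_node(t, frequency=float(term_frequencies.get(t, 1.0)))
    for u, v in edges:
        if u not in nodes or v not in nodes:
            raise ValueError(f"edge ({u}, {v}) references an unknown node")
        graph.add_edge(u, v)
    if fmt == "graphml":
        nx.write_graphml(graph, path)
    elif fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("#node\tfrequency\n")
            for t in sorted(nodes):
                fh.write(f"{t}\t{graph.nodes[t]['frequency']}\n")
            fh.write("#source\ttarget\n")
            for u, v in graph.edges:
                fh.write(f"{u}\t{v}\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return graph
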