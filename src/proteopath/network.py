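"""Co-participation networks at gene, protein, or proteoform granularity.

Two entities are connected when they participate in the same reaction.
Node identity is the gene name, the protein accession, or the serialized
proteoform, depending on the chosen granularity; proteoforms of the same
protein collapse to a single node at gene/protein granularity but form
distinct, possibly interconnected nodes at proteoform granularity.

Edges are recorded per reaction (a multigraph on disk), annotated with
each endpoint's role and complex/set context in that reaction; degree
computation and subnetwork membership collapse this multiplicity.
Given an input node set, the *internal* subnetwork holds the edges with
both endpoints in the input and the *external* subnetwork those with
exactly one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .kb import KnowledgeBase
from .proteoforms import Proteoform, format_proteoform

NETWORK_GRANULARITIES = ("gene", "protein", "proteoform")


@dataclass(frozen=True)
class NetworkNode:
    """A network node: identity string plus canonical/specific category."""

    identity: str
    category: str  # "canonical" or "specific"


@dataclass(frozen=True)
class NetworkEdge:
    """One co-participation edge, annotated per reaction.

    ``node_a < node_b`` lexicographically.  ``role_a``/``context_a``
    aggregate the roles and contexts of every participant that projects
    to ``node_a`` in this reaction (sorted, ``|``-joined).  ``locality``
    is ``internal``/``external`` for extracted subnetworks and ``-``
    otherwise.
    """

    node_a: str
    node_b: str
    reaction_id: str
    role_a: str
    role_b: str
    context_a: str
    context_b: str
    locality: str = "-"


@dataclass
class Network:
    """Granularity-resolved node and edge collections."""

    granularity: str
    nodes: dict[str, NetworkNode]
    edges: list[NetworkEdge]


def project_identity(
    p: Proteoform, granularity: str, kb: KnowledgeBase
) -> str:
    """Project a proteoform to its node identity at a granularity."""
    if granularity == "proteoform":
        return format_proteoform(p)
    if granularity == "protein":
        return p.accession
    genes = kb.accession_to_genes.get(p.accession)
    if not genes:
        warnings.warn(
            f"no gene mapping for accession {p.accession}; keeping the "
            f"accession as node identity",
            stacklevel=2,
        )
        return p.accession
    return genes[0]


def build_network(kb: KnowledgeBase, granularity: str) -> Network:
    """Connect every pair of distinct projected identities per reaction.

    A node is *canonical* when it represents (at least) the unmodified
    canonical isoform of its protein, and *specific* otherwise.
    """
    if granularity not in NETWORK_GRANULARITIES:
        raise ValueError(
            f"granularity must be one of {NETWORK_GRANULARITIES}, "
            f"got {granularity!r}"
        )

    canonical: dict[str, bool] = {}
    for p in kb.proteoforms:
        if p not in kb.participants_by_proteoform:
            continue
        ident = project_identity(p, granularity, kb)
        canonical[ident] = canonical.get(ident, False) or p.is_canonical

    edges: list[NetworkEdge] = []
    for rid in sorted(kb.reactions):
        by_identity: dict[str, list] = {}
        for part in kb.reactions[rid].participants:
            ident = project_identity(part.proteoform, granularity, kb)
            by_identity.setdefault(ident, []).append(part)
        for a, b in combinations(sorted(by_identity), 2):
            edges.append(
                NetworkEdge(
                    node_a=a,
                    node_b=b,
                    reaction_id=rid,
                    role_a="|".join(sorted({p.role for p in by_identity[a]})),
                    role_b="|".join(sorted({p.role for p in by_identity[b]})),
                    context_a="|".join(
                        sorted({p.context for p in by_identity[a]})
                    ),
                    context_b="|".join(
                        sorted({p.context for p in by_identity[b]})
                    ),
                )
            )

    nodes = {
        ident: NetworkNode(ident, "canonical" if is_canon else "specific")
        for ident, is_canon in sorted(canonical.items())
    }
    return Network(granularity, nodes, edges)


def extract_subnetworks(
    network: Network, input_identities: Iterable[str]
) -> tuple[list[NetworkEdge], list[NetworkEdge]]:
    """Split input-incident edges into internal and external sets.

    Internal edges have both endpoints in the input identity set,
    external edges exactly one; edges touching no input node are dropped.
    """
    input_set = set(input_identities)
    internal, external = [], []
    for e in network.edges:
        inside = (e.node_a in input_set) + (e.node_b in input_set)
        if inside == 2:
            internal.append(replace(e, locality="internal"))
        elif inside == 1:
            external.append(replace(e, locality="external"))
    return internal, external


def degree_summary(network: Network) -> pd.DataFrame:
    """Per-node degree (distinct neighbours; reaction multiplicity collapsed)."""
    g = nx.Graph()
    g.add_nodes_from(network.nodes)
    g.add_edges_from((e.node_a, e.node_b) for e in network.edges)
    return pd.DataFrame(
        [
            (ident, network.nodes[ident].category, g.degree(ident))
            for ident in sorted(network.nodes)
        ],
        columns=["identity", "category", "degree"],
    )


# ---------------------------------------------------------------------------
# TSV / SIF serialization
# ---------------------------------------------------------------------------

EDGE_COLUMNS = (
    "node_a",
    "node_b",
    "reaction_id",
    "role_a",
    "role_b",
    "context_a",
    "context_b",
    "locality",
)


def _edge_tuple(e: NetworkEdge) -> tuple:
    return (
        e.node_a,
        e.node_b,
        e.reaction_id,
        e.role_a,
        e.role_b,
        e.context_a,
        e.context_b,
        e.locality,
    )


def write_edges_tsv(edges: Sequence[NetworkEdge], path: str | Path) -> None:
    rows = sorted(_edge_tuple(e) for e in edges)
    pd.DataFrame(rows, columns=list(EDGE_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def write_network(
    network: Network,
    directory: str | Path,
    name: str = "network",
    sif: bool = False,
) -> None:
    """Write ``<name>_nodes.tsv`` and ``<name>_edges.tsv`` (optionally SIF)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        sorted((n.identity, n.category) for n in network.nodes.values()),
        columns=["identity", "category"],
    ).to_csv(directory / f"{name}_nodes.tsv", sep="\t", index=False)
    write_edges_tsv(network.edges, directory / f"{name}_edges.tsv")
    if sif:
        with open(directory / f"{name}.sif", "w", encoding="utf-8") as fh:
            for row in sorted(_edge_tuple(e) for e in network.edges):
                fh.write(f"{row[0]}\treaction:{row[2]}\t{row[1]}\n")


def read_network(
    directory: str | Path, name: str = "network", granularity: str = "protein"
) -> Network:
    """Read a network written by :func:`write_network` (for round trips)."""
    directory = Path(directory)
    nodes_df = pd.read_csv(
        directory / f"{name}_nodes.tsv", sep="\t", dtype=str
    )
    edges_df = pd.read_csv(
        directory / f"{name}_edges.tsv", sep="\t", dtype=str,
        keep_default_na=False,
    )
    nodes = {
        row["identity"]: NetworkNode(row["identity"], row["category"])
        for _, row in nodes_df.iterrows()
    }
    edges = [
        NetworkEdge(*[row[c] for c in EDGE_COLUMNS])
        for _, row in edges_df.iterrows()
    ]
    return Network(granularity, nodes, edges)
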