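"""Functional-subnetwork perturbation scoring on an interactome.

A functional subnetwork is a connected fraction of the interactome whose
proteins share one annotation term.  A drug perturbs a subnetwork directly
(a target is a member) or peripherally (a target interacts with members).
With per-target affinities a_t in (0, 1] the perturbation score of a
subnetwork with node set V_f is

    S_net = ( sum_{t in T ∩ V_f} a_t
            + sum_{t in T \\ V_f} a_t * e(t, V_f) / deg(t) ) / |V_f|

where e(t, V_f) counts edges from the peripheral target t into V_f and
deg(t) is its total degree; direct membership supersedes the peripheral
term.  Normalizing by |V_f| makes scores comparable across subnetwork sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

__all__ = [
    "FunctionalSubnetwork",
    "SubnetworkScore",
    "extract_subnetworks",
    "s_net",
    "rank_perturbed",
    "interaction_overlap",
]


@dataclass(frozen=True)
class FunctionalSubnetwork:
    term: str
    nodes: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.nodes)


@dataclass(frozen=True)
class SubnetworkScore:
    term: str
    n_nodes: int
    n_targets: int  # targets touching the subnetwork, directly or peripherally
    s_net: float


def extract_subnetworks(
    graph: nx.Graph,
    term2nodes: Mapping[str, Iterable[str]],
    *,
    all_components: bool = False,
) -> list[FunctionalSubnetwork]:
    """Connected functional subnetworks induced by each term's annotation.

    By default keeps the largest connected component of the induced subgraph
    (ties broken by lexicographically smallest node set for determinism);
    with ``all_components=True`` each component becomes its own subnetwork.
    Terms annotating no graph node are dropped.
    """
    subnets = []
    for term in sorted(term2nodes):
        present = set(term2nodes[term]) & set(graph.nodes)
        if not present:
            continue
        induced = graph.subgraph(present)
        components = [frozenset(c) for c in nx.connected_components(induced)]
        components.sort(key=lambda c: (-len(c), tuple(sorted(c))))
        if all_components:
            subnets.extend(FunctionalSubnetwork(term, c) for c in components)
        else:
            subnets.append(FunctionalSubnetwork(term, components[0]))
    return subnets


def s_net(
    subnet: FunctionalSubnetwork,
    affinities: Mapping[str, float],
    graph: nx.Graph,
) -> SubnetworkScore:
    """Affinity-weighted perturbation score of one functional subnetwork."""
    for t, a in affinities.items():
        if not 0 < a <= 1:
            raise ValueError(f"affinity for {t} must be in (0, 1], got {a}")
    nodes = subnet.nodes
    direct = 0.0
    peripheral = 0.0
    n_touching = 0
    for target, affinity in affinities.items():
        if target in nodes:
            direct += affinity
            n_touching += 1
        elif target in graph:
            deg = graph.degree(target)
            if deg == 0:
                continue
            e_in = sum(1 for nb in graph.neighbors(target) if nb in nodes)
            if e_in:
                peripheral += affinity * e_in / deg
                n_touching += 1
    return SubnetworkScore(
        term=subnet.term,
        n_nodes=len(nodes),
        n_targets=n_touching,
        s_net=(direct + peripheral) / len(nodes),
    )


def rank_perturbed(
    subnets: Iterable[FunctionalSubnetwork],
    affinities: Mapping[str, float],
    graph: nx.Graph,
) -> pd.DataFrame:
    """Score every subnetwork and rank by S_net descending (ties by term id)."""
    subnets = list(subnets)
    if not subnets:
        raise ValueError("no subnetworks to rank")
    scores = [s_net(sn, affinities, graph) for sn in subnets]
    table = pd.DataFrame(
        {
            "term": [s.term for s in scores],
            "nodes": [s.n_nodes for s in scores],
            "targets": [s.n_targets for s in scores],
            "s_net": [s.s_net for s in scores],
        }
    )
    return (
        table.sort_values(["s_net", "term"], ascending=[False, True])
        .reset_index(drop=True)
    )


def interaction_overlap(
    targets: Iterable[str],
    de_proteins: Iterable[str],
    graph: nx.Graph,
) -> list[tuple[str, str]]:
    """Interactome edges linking the target profile to differential proteins.

    Returns deduplicated, sorted (target, de_protein) pairs; a protein in
    both sets yields (x, x) only if the graph has a self-edge on it.
    """
    target_set = set(targets)
    de_set = set(de_proteins)
    pairs = set()
    for u, v in graph.edges:
        if u in target_set and v in de_set:
            pairs.add((u, v))
        if v in target_set and u in de_set:
            pairs.add((v, u))
    return sorted(pairs)
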