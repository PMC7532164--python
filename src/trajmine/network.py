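"""Merge linear trajectories into a disease trajectory network and export it.

One disease may appear in many linear trajectories, so merging their
adjacent pairs yields a single directed graph: nodes are level-3 codes
annotated with chapter, unique-patient count and 5-year mortality; edges
carry the statistics of the underlying directional pair plus the
length-2 follower count and mean inter-diagnosis gap.  Exports
(Cytoscape JSON and delimited tables) apply a privacy suppression that
removes any node, edge or trajectory assigned to fewer than five
patients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .icd10 import chapter_of
from .registry import Registry, days_since_epoch
from .trajectories import (
    LinearTrajectory,
    count_followers,
    trajectories_to_table,
    trajectory_summary,
)

_DAYS_PER_YEAR = 365.25


@dataclass
class TrajectoryNetwork:
    """Directed multimorbidity graph with node/edge annotations."""

    graph: nx.DiGraph
    provenance: dict = field(default_factory=dict)

    @property
    def nodes(self) -> dict:
        return dict(self.graph.nodes(data=True))

    @property
    def edges(self) -> dict:
        return {(u, v): d for u, v, d in self.graph.edges(data=True)}

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"d1": u, "d2": v, **data} for u, v, data in self.graph.edges(data=True)
        ]
        frame = pd.DataFrame(
            rows,
            columns=[
                "d1",
                "d2",
                "n_followers",
                "rr",
                "p_direction",
                "p_cooccurrence",
                "mean_gap_years",
            ],
        )
        return frame.sort_values(["d1", "d2"]).reset_index(drop=True)


@dataclass(frozen=True)
class Selection:
    """A node/edge subset of a network (the browser's highlight set)."""

    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]


def _node_annotations(registry: Registry) -> pd.DataFrame:
    """Per-code unique patient count and 5-year mortality."""
    first = registry.first_occurrences()
    patients = registry.patients.set_index("patient_id")
    death = patients.loc[first.index, "death_date"]
    death_days = days_since_epoch(death.to_numpy())
    rows = {}
    for code in first.columns:
        days = days_since_epoch(first[code].to_numpy())
        has = ~np.isnan(days)
        with np.errstate(invalid="ignore"):
            dead = death_days <= days + 5.0 * _DAYS_PER_YEAR
        rows[code] = {
            "n_unique_patients": int(has.sum()),
            "mortality_5y": int(np.nansum(dead & has)),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def merge_network(
    trajectories: Sequence[LinearTrajectory],
    registry: Registry | None = None,
    provenance: dict | None = None,
) -> TrajectoryNetwork:
    """Union of all trajectory nodes and adjacent-pair edges.

    Each edge carries the statistics of its underlying directional pair,
    identical no matter how many trajectories contain it, so the result
    is independent of the input order.  Edge follower counts and gaps
    come from the length-2 trajectory when it is present in the input,
    otherwise they are recomputed from *registry* when given.
    """
    graph = nx.DiGraph()
    length2 = {t.codes: t for t in trajectories if t.length == 2}
    for trajectory in sorted(trajectories, key=lambda t: t.codes):
        for k, (a, b) in enumerate(zip(trajectory.codes, trajectory.codes[1:])):
            for code in (a, b):
                if code not in graph:
                    graph.add_node(code, chapter=chapter_of(code))
            if graph.has_edge(a, b):
                continue
            stats = trajectory.edge_stats[k] if trajectory.edge_stats else None
            pair_traj = length2.get((a, b))
            if pair_traj is not None:
                n_followers = pair_traj.n_followers
                gaps = pair_traj.inter_diagnosis_times
            elif registry is not None:
                two = LinearTrajectory((a, b), 0)
                two = trajectory_summary(registry, two)
                n_followers = two.n_followers
                gaps = two.inter_diagnosis_times
            else:
                n_followers, gaps = None, None
            graph.add_edge(
                a,
                b,
                n_followers=n_followers,
                rr=stats.rr if stats else None,
                p_direction=stats.p_direction if stats else None,
                p_cooccurrence=stats.p_cooccurrence if stats else None,
                mean_gap_years=(gaps[0] if gaps else None),
            )
    if registry is not None and len(graph):
        annotations = _node_annotations(registry)
        for code in graph.nodes:
            if code in annotations.index:
                graph.nodes[code]["n_unique_patients"] = int(
                    annotations.loc[code, "n_unique_patients"]
                )
                graph.nodes[code]["mortality_5y"] = int(
                    annotations.loc[code, "mortality_5y"]
                )
    return TrajectoryNetwork(graph, dict(provenance or {}))


def neighbourhood(
    network: TrajectoryNetwork, code: str, mode: str = "both"
) -> Selection:
    """Edges linking directly to *code* (and their endpoint nodes).

    Modes: ``incoming`` (edges ending at the code), ``outgoing`` (edges
    starting at it), ``both`` (their union) and ``inverse`` (the
    complement of the ``both`` selection).
    """
    graph = network.graph
    if code not in graph:
        raise ValueError(f"code {code!r} is not a node of the network")
    incoming = {(u, v) for u, v in graph.in_edges(code)}
    outgoing = {(u, v) for u, v in graph.out_edges(code)}
    if mode == "incoming":
        edges = incoming
    elif mode == "outgoing":
        edges = outgoing
    elif mode in ("both", "inverse"):
        edges = incoming | outgoing
    else:
        raise ValueError(f"unknown neighbourhood mode {mode!r}")
    nodes = {code} | {u for u, _ in edges} | {v for _, v in edges}
    if mode == "inverse":
        edges = set(graph.edges()) - edges
        nodes = set(graph.nodes()) - nodes
    return Selection(nodes=frozenset(nodes), edges=frozenset(edges))


def _in_range(value, rng: tuple[float, float] | None) -> bool:
    if rng is None:
        return True
    return value is not None and rng[0] <= value <= rng[1]


def _check_range(rng, name):
    if rng is not None and rng[0] > rng[1]:
        raise ValueError(f"{name} range is inverted: {rng}")


def apply_filters(
    obj,
    sex: str = "all",
    length_range: tuple[int, int] | None = None,
    rr_range: tuple[float, float] | None = None,
    follower_range: tuple[float, float] | None = None,
):
    """Browser-style search filters over trajectories or a network.

    All ranges are closed; filters compose commutatively.  For a
    trajectory list, the RR condition must hold for every edge of the
    trajectory; for a network the length filter does not apply.
    """
    _check_range(length_range, "length")
    _check_range(rr_range, "rr")
    _check_range(follower_range, "follower")
    if isinstance(obj, TrajectoryNetwork):
        graph = obj.graph.copy()
        for u, v, data in list(obj.graph.edges(data=True)):
            if not _in_range(data.get("rr"), rr_range) or not _in_range(
                data.get("n_followers"), follower_range
            ):
                graph.remove_edge(u, v)
        return TrajectoryNetwork(graph, dict(obj.provenance))
    kept = []
    for t in obj:
        if sex != "all" and t.sex not in (sex,):
            continue
        if not _in_range(t.length, length_range):
            continue
        if not _in_range(t.n_followers, follower_range):
            continue
        if rr_range is not None:
            rrs = [s.rr for s in t.edge_stats]
            if not rrs or not all(_in_range(r, rr_range) for r in rrs):
                continue
        kept.append(t)
    return kept


def suppress_small_counts(obj, min_patients: int = 5):
    """Privacy suppression: drop anything assigned to too few patients.

    Trajectories below *min_patients* followers are removed; network
    edges below the threshold (or with unknown counts) are removed, and
    nodes below it follow.  Applied by default to every serialised
    output.  ``min_patients = 0`` is the identity.
    """
    if min_patients <= 0:
        return obj
    if isinstance(obj, TrajectoryNetwork):
        graph = obj.graph.copy()
        for u, v, data in list(obj.graph.edges(data=True)):
            n = data.get("n_followers")
            if n is None or n < min_patients:
                graph.remove_edge(u, v)
        for node, data in list(graph.nodes(data=True)):
            n = data.get("n_unique_patients")
            if n is not None and n < min_patients:
                graph.remove_node(node)
            elif n is None and graph.degree(node) == 0:
                graph.remove_node(node)
        return TrajectoryNetwork(graph, dict(obj.provenance))
    return [t for t in obj if t.n_followers >= min_patients]


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------

def export_cyjs(
    network: TrajectoryNetwork, path, min_patients: int = 5
) -> None:
    """Write the network as Cytoscape JSON (elements format).

    Node data: id (the code), chapter, patient count, mortality; edge
    data: source, target, follower count, RR and P-values.  Loadable by
    the Cytoscape desktop data model; byte-stable for identical inputs.
    """
    suppressed = suppress_small_counts(network, min_patients)
    payload = nx.cytoscape_data(suppressed.graph)
    payload["data"] = {"provenance": network.provenance}
    with open(path, "w") as handle:
        json.dump(payload, handle, indent=2, sort_keys=True)
        handle.write("\n")


def read_cyjs(path) -> TrajectoryNetwork:
    """Re-import a Cytoscape JSON export written by :func:`export_cyjs`."""
    with open(path) as handle:
        payload = json.load(handle)
    graph = nx.cytoscape_graph(payload)
    if not graph.is_directed():
        graph = graph.to_directed()
    provenance = {}
    if isinstance(payload.get("data"), dict):
        provenance = payload["data"].get("provenance", {})
    graph.graph.pop("provenance", None)
    for node in graph.nodes:  # strip cytoscape display/identity fields
        for extra in ("name", "value", "id"):
            graph.nodes[node].pop(extra, None)
    for u, v in graph.edges:
        for extra in ("source", "target"):
            graph.edges[u, v].pop(extra, None)
    return TrajectoryNetwork(graph, provenance)


def _provenance_lines(provenance: dict) -> str:
    return "".join(f"# {key}={provenance[key]}\n" for key in sorted(provenance))


def export_edges_csv(
    network: TrajectoryNetwork, path, min_patients: int = 5
) -> None:
    """One edge per row with the full pair statistics columns."""
    suppressed = suppress_small_counts(network, min_patients)
    with open(path, "w") as handle:
        handle.write(_provenance_lines(network.provenance))
        suppressed.edge_table().to_csv(handle, index=False)


def export_trajectories_csv(
    trajectories: Sequence[LinearTrajectory], path, min_patients: int = 5
) -> None:
    """One trajectory per row (codes joined by '->'), suppressed."""
    kept = suppress_small_counts(list(trajectories), min_patients)
    with open(path, "w") as handle:
        trajectories_to_table(kept).to_csv(handle, index=False)


def read_edges_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
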