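"""Non-redundant dataset construction.

Structures are grouped by oligomeric state; within a group, two
structures are redundant when any pair of their chains exceeds the 0.9
similarity threshold (sequence identity by default, or externally
supplied structure-similarity scores).  The redundancy relation is
closed transitively; one representative is retained per cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx

from .partition import pairwise_identity

__all__ = [
    "RedundancyConfig",
    "RedundancyCluster",
    "StructureEntry",
    "cluster_chains",
    "deduplicate_structures",
]


@dataclass
class RedundancyConfig:
    mode: str = "sequence"  # sequence | structure
    threshold: float = 0.9
    structure_backend: str = "none"  # external_adapter | none

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold <= 1.0):
            raise ValueError(f"threshold {self.threshold} outside (0, 1]")
        if self.mode not in ("sequence", "structure"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "structure" and self.structure_backend == "none":
            raise ValueError(
                "structure mode requires an external similarity adapter "
                "(structure_backend='external_adapter' plus a score table)"
            )


@dataclass
class RedundancyCluster:
    representative: str
    members: list[str]
    oligomeric_state: int

    def __post_init__(self) -> None:
        if self.representative not in self.members:
            raise ValueError("representative must be a cluster member")


@dataclass
class StructureEntry:
    """Minimal structure description for redundancy removal."""

    structure_id: str
    chain_sequences: dict[str, str]  # chain_id -> one-letter sequence
    resolution: float | None = None

    @property
    def oligomeric_state(self) -> int:
        return len(self.chain_sequences)


def cluster_chains(
    sequences: dict[str, str], identity_threshold: float = 0.9
) -> list[list[str]]:
    """Greedy incremental chain clustering (cd-hit-style, exact identities).

    Sequences are visited by descending length (ties by ID); each joins
    the first existing cluster whose representative's pairwise identity
    exceeds the threshold, else founds a new cluster.  Deterministic.
    """
    if not sequences:
        raise ValueError("need at least one sequence")
    order = sorted(sequences, key=lambda k: (-len(sequences[k]), k))
    clusters: list[list[str]] = []
    for name in order:
        seq = sequences[name]
        for cluster in clusters:
            rep_seq = sequences[cluster[0]]
            if pairwise_identity(seq, rep_seq) > identity_threshold:
                cluster.append(name)
                break
        else:
            clusters.append([name])
    return clusters


def _chain_similarity(
    a: StructureEntry,
    b: StructureEntry,
    config: RedundancyConfig,
    score_lookup: dict[tuple[str, str], float] | None,
) -> float:
    best = 0.0
    for ca, sa in a.chain_sequences.items():
        for cb, sb in b.chain_sequences.items():
            if config.mode == "structure":
                key_a, key_b = f"{a.structure_id}:{ca}", f"{b.structure_id}:{cb}"
                sim = (score_lookup or {}).get(
                    (key_a, key_b), (score_lookup or {}).get((key_b, key_a), 0.0)
                )
            else:
                sim = pairwise_identity(sa, sb) if sa and sb else 0.0
            best = max(best, sim)
    return best


def deduplicate_structures(
    structures: list[StructureEntry],
    config: RedundancyConfig | None = None,
    score_lookup: dict[tuple[str, str], float] | None = None,
) -> tuple[list[RedundancyCluster], list[str]]:
    """Remove redundant structures within each oligomeric-state group.

    Two structures of the same oligomeric state are redundant when any
    chain pair across them has similarity strictly greater than the
    threshold.  Clusters are the connected components of that relation;
    the retained representative is the member with the best (lowest)
    resolution, ties and unknowns falling back to the lowest ID.
    Returns (clusters, retained structure IDs).
    """
    config = config or RedundancyConfig()
    by_state: dict[int, list[StructureEntry]] = {}
    for s in structures:
        by_state.setdefault(s.oligomeric_state, []).append(s)

    clusters: list[RedundancyCluster] = []
    retained: list[str] = []
    for state in sorted(by_state):
        group = sorted(by_state[state], key=lambda s: s.structure_id)
        graph = nx.Graph()
        graph.add_nodes_from(s.structure_id for s in group)
        for a, b in combinations(group, 2):
            if _chain_similarity(a, b, config, score_lookup) > config.threshold:
                graph.add_edge(a.structure_id, b.structure_id)
        by_id = {s.structure_id: s for s in group}
        for comp in nx.connected_components(graph):
            members = sorted(comp)
            rep = min(
                members,
                key=lambda sid: (
                    by_id[sid].resolution if by_id[sid].resolution is not None else float("inf"),
                    sid,
                ),
            )
            clusters.append(
                RedundancyCluster(representative=rep, members=members, oligomeric_state=state)
            )
            retained.append(rep)
    clusters.sort(key=lambda c: (c.oligomeric_state, c.representative))
    return clusters, sorted(retained)
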