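"""Base-pair detection and DNA/RNA chain grouping.

Chains are joined when they share at least three inter-chain base pairs;
a chain of one or two nucleotides is joined as long as every one of its
nucleotides is paired with the partner chain.  Multi-chain nucleic units
are the connected components of the resulting pairing graph.

Base pairs come either from the built-in geometric detector (default,
no external binary needed) or from a parsed DSSR output file.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .partition import PolymerChain

__all__ = [
    "BasePair",
    "PairingResult",
    "detect_base_pairs",
    "parse_dssr_pairs",
    "pair_chains",
]

# Watson-Crick edge donor/acceptor atoms considered for hydrogen bonds.
WC_EDGE_ATOMS = {"N1", "N3", "N6", "N4", "O6", "O4", "O2", "N2"}

HBOND_MAX = 3.5  # Å, donor-acceptor distance
C1_MIN, C1_MAX = 8.0, 11.5  # Å, C1'-C1' window for a paired geometry
MIN_EDGE_CONTACTS = 2  # distinct donor-acceptor pairs required


@dataclass(frozen=True)
class BasePair:
    partner_a: tuple[str, int, str]  # (chain_id, seq_id, comp_id)
    partner_b: tuple[str, int, str]
    source: str = "builtin_geometric"

    def __post_init__(self) -> None:
        if self.partner_a == self.partner_b:
            raise ValueError("a nucleotide cannot pair with itself")

    @property
    def inter_chain(self) -> bool:
        return self.partner_a[0] != self.partner_b[0]


@dataclass
class PairingResult:
    groups: list[set[str]]
    edge_evidence: dict[tuple[str, str], int]
    accepted_edges: set[tuple[str, str]]

    def group_of(self, chain_id: str) -> set[str]:
        for g in self.groups:
            if chain_id in g:
                return g
        raise KeyError(chain_id)


@dataclass
class _Nucleotide:
    chain_id: str
    seq_id: int
    comp_id: str
    edge_atoms: dict[str, np.ndarray]
    c1: np.ndarray | None


def _collect_nucleotides(chains: list[PolymerChain]) -> list[_Nucleotide]:
    nts = []
    for chain in chains:
        by_res: dict[tuple[int, str], dict[str, np.ndarray]] = {}
        for a in chain.atoms:
            by_res.setdefault((a.seq_id, a.comp_id), {})[a.name] = a.coords
        for (seq_id, comp_id), atoms in sorted(by_res.items()):
            edge = {n: xyz for n, xyz in atoms.items() if n in WC_EDGE_ATOMS}
            c1 = atoms.get("C1'")
            nts.append(_Nucleotide(chain.chain_id, seq_id, comp_id, edge, c1))
    return nts


def detect_base_pairs(
    chains: list[PolymerChain],
    hbond_max: float = HBOND_MAX,
    c1_window: tuple[float, float] = (C1_MIN, C1_MAX),
    min_contacts: int = MIN_EDGE_CONTACTS,
) -> list[BasePair]:
    """Geometric Watson-Crick base-pair detector.

    A nucleotide pair is accepted when (a) at least ``min_contacts``
    donor-acceptor atom pairs among the WC edge atoms lie within
    ``hbond_max``, (b) the C1'-C1' distance falls inside ``c1_window``,
    and (c) each nucleotide joins at most one pair (greedy by smallest
    mean hydrogen-bond distance).  Nucleotides missing base atoms are
    skipped, not fatal.
    """
    nts = [n for n in _collect_nucleotides(chains) if n.edge_atoms and n.c1 is not None]
    if len(nts) < 2:
        return []
    c1 = np.array([n.c1 for n in nts])
    tree = cKDTree(c1)
    candidates = []
    for i, j in tree.query_pairs(r=c1_window[1]):
        d_c1 = float(np.linalg.norm(c1[i] - c1[j]))
        if not (c1_window[0] <= d_c1 <= c1_window[1]):
            continue
        dists = sorted(
            float(np.linalg.norm(xa - xb))
            for xa in nts[i].edge_atoms.values()
            for xb in nts[j].edge_atoms.values()
        )
        close = [d for d in dists if d < hbond_max]
        if len(close) >= min_contacts:
            candidates.append((float(np.mean(close)), i, j))

    candidates.sort(key=lambda t: (t[0], t[1], t[2]))
    used: set[int] = set()
    pairs = []
    for _, i, j in candidates:
        if i in used or j in used:
            continue
        used.update((i, j))
        a = (nts[i].chain_id, nts[i].seq_id, nts[i].comp_id)
        b = (nts[j].chain_id, nts[j].seq_id, nts[j].comp_id)
        pairs.append(BasePair(partner_a=min(a, b), partner_b=max(a, b)))
    return sorted(pairs, key=lambda p: (p.partner_a, p.partner_b))


_DSSR_NT_RE = re.compile(r"^(?:\d+:)?(?P<chain>[^.]+)\.(?P<comp>[A-Za-z0-9]+?)(?P<seq>-?\d+)$")


def _parse_dssr_nt(nt_id: str) -> tuple[str, int, str]:
    m = _DSSR_NT_RE.match(nt_id.strip())
    if not m:
        raise ValueError(f"unrecognized DSSR nucleotide id {nt_id!r}")
    return (m.group("chain"), int(m.group("seq")), m.group("comp").upper())


def parse_dssr_pairs(
    path: str | Path, known_chains: list[str] | None = None
) -> list[BasePair]:
    """Parse base pairs from a DSSR output file (JSON or plain-text listing).

    JSON must carry a top-level ``pairs`` list with ``nt1``/``nt2``
    nucleotide IDs in DSSR notation (``chain.COMPseq``, optionally
    prefixed with a model number).  The plain-text fallback accepts one
    pair per line as two whitespace-separated DSSR nucleotide IDs.
    """
    path = Path(path)
    text = path.read_text()
    records: list[tuple[str, str]] = []
    stripped = text.lstrip()
    if stripped.startswith("{") or stripped.startswith("["):
        try:
            doc = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ValueError(f"{path}: invalid DSSR JSON: {exc}") from exc
        pairs = doc.get("pairs", doc) if isinstance(doc, dict) else doc
        if not isinstance(pairs, list):
            raise ValueError(f"{path}: DSSR JSON has no 'pairs' list")
        for p in pairs:
            try:
                records.append((p["nt1"], p["nt2"]))
            except (TypeError, KeyError) as exc:
                raise ValueError(f"{path}: malformed DSSR pair record {p!r}") from exc
    else:
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}: unparseable DSSR pair line {line!r}")
            records.append((fields[0], fields[1]))

    result = []
    for nt1, nt2 in records:
        a, b = _parse_dssr_nt(nt1), _parse_dssr_nt(nt2)
        if known_chains is not None:
            for part in (a, b):
                if part[0] not in known_chains:
                    raise ValueError(f"{path}: DSSR pair references unknown chain {part[0]!r}")
        result.append(BasePair(partner_a=min(a, b), partner_b=max(a, b), source="dssr_parsed"))
    return result


def pair_chains(
    base_pairs: list[BasePair],
    chains: list[PolymerChain],
    min_pairs: int = 3,
) -> PairingResult:
    """Group nucleic chains into intact multi-chain units.

    Chains i and j are linked when they share at least ``min_pairs``
    inter-chain base pairs, or when one of them has length <= 2 and all
    of its nucleotides are base-paired with nucleotides of chain j.
    Groups are connected components over the accepted links; unlinked
    chains form singleton groups.
    """
    inventory = {c.chain_id: c for c in chains}
    for bp in base_pairs:
        for part in (bp.partner_a, bp.partner_b):
            if part[0] not in inventory:
                raise ValueError(f"base pair references unknown chain {part[0]!r}")

    counts: dict[tuple[str, str], int] = {}
    # which chains each nucleotide of a short chain pairs with
    nt_partners: dict[tuple[str, int], set[str]] = {}
    for bp in base_pairs:
        if not bp.inter_chain:
            continue
        ca, cb = bp.partner_a[0], bp.partner_b[0]
        key = (min(ca, cb), max(ca, cb))
        counts[key] = counts.get(key, 0) + 1
        nt_partners.setdefault((ca, bp.partner_a[1]), set()).add(cb)
        nt_partners.setdefault((cb, bp.partner_b[1]), set()).add(ca)

    graph = nx.Graph()
    graph.add_nodes_from(inventory)
    accepted: set[tuple[str, str]] = set()
    for (ca, cb), n in counts.items():
        if n >= min_pairs:
            accepted.add((ca, cb))

    # 1-2-nt special case: every nucleotide of the short chain is paired
    # with the candidate partner chain
    for chain in chains:
        if chain.length > 2:
            continue
        nt_keys = [(chain.chain_id, seq_id) for seq_id, _ in chain.residues]
        partner_sets = [nt_partners.get(k, set()) for k in nt_keys]
        if not partner_sets or any(not s for s in partner_sets):
            continue
        common = set.intersection(*partner_sets)
        for partner in common:
            accepted.add((min(chain.chain_id, partner), max(chain.chain_id, partner)))

    graph.add_edges_from(accepted)
    groups = [set(comp) for comp in nx.connected_components(graph)]
    groups.sort(key=lambda g: sorted(g))
    return PairingResult(groups=groups, edge_evidence=counts, accepted_edges=accepted)
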