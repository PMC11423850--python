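"""Receptor/ligand extraction from assemblies.

An assembly is separated into one receptor (protein chains with >= 30
observed residues) and ligands: peptides (< 30 residues), paired DNA/RNA
chain groups, and per-residue non-polymer groups (small molecules and
metal ions).  Waters are never ligand candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from Bio import Align

from ._chemistry import (
    DNA_RES,
    METAL_ELEMENTS,
    RNA_RES,
    STANDARD_AA,
    WATER_RES,
    one_letter,
)
from .structure_io import Assembly, AtomRecord

__all__ = [
    "PolymerChain",
    "Receptor",
    "Ligand",
    "PartitionResult",
    "classify_chain",
    "extract_chains",
    "partition_assembly",
    "pairwise_identity",
    "stoichiometry",
]

RECEPTOR_MIN_RESIDUES = 30


@dataclass
class PolymerChain:
    """One polymer chain with its observed residues (hydrogen-only residues excluded)."""

    chain_id: str
    polymer_type: str  # protein | dna | rna | na_hybrid | other
    residues: list[tuple[int, str]]  # (seq_id, comp_id), ordered
    atoms: list[AtomRecord] = field(default_factory=list, repr=False)

    @property
    def length(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(one_letter(c) for _, c in self.residues)


@dataclass
class Receptor:
    chains: list[PolymerChain]
    stoichiometry: str = ""

    @property
    def oligomeric_state(self) -> int:
        return len(self.chains)

    @property
    def atoms(self) -> list[AtomRecord]:
        return [a for c in self.chains for a in c.atoms]

    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]


@dataclass
class Ligand:
    """A bound unit: small molecule, metal ion, peptide, or paired nucleic group."""

    kind: str  # small_molecule | metal_ion | peptide | nucleic
    ligand_id: str
    atoms: list[AtomRecord] = field(default_factory=list, repr=False)
    chains: list[PolymerChain] = field(default_factory=list)
    comp_id: str = ""
    seq_id: int | None = None
    source_chain: str = ""

    def __post_init__(self) -> None:
        if self.kind == "peptide":
            if not self.chains or not (1 <= self.chains[0].length < RECEPTOR_MIN_RESIDUES):
                raise ValueError("peptide ligand must hold one chain of 1-29 residues")
        if self.kind == "metal_ion" and len(self.atoms) != 1:
            raise ValueError("metal_ion ligand must have exactly one atom")

    @property
    def component_chain_ids(self) -> list[str]:
        if self.chains:
            return [c.chain_id for c in self.chains]
        return [self.source_chain]


@dataclass
class PartitionResult:
    receptor: Receptor | None
    ligands: list[Ligand]
    unassigned: list[PolymerChain] = field(default_factory=list)


def classify_chain(chain: PolymerChain) -> str:
    """Classify a polymer chain as protein / dna / rna / na_hybrid / other.

    Protein requires >= 80% standard (or parent-mapped) amino acids;
    nucleic classes use the same 80% threshold over nucleotides, with a
    mixed deoxy/ribo chain reported as na_hybrid.
    """
    if not chain.residues:
        raise ValueError(f"chain {chain.chain_id}: cannot classify an empty chain")
    n = chain.length
    comps = [c for _, c in chain.residues]
    n_aa = sum(1 for c in comps if c in STANDARD_AA)
    n_d = sum(1 for c in comps if c in DNA_RES)
    n_r = sum(1 for c in comps if c in RNA_RES)
    if n_aa / n >= 0.8:
        return "protein"
    if (n_d + n_r) / n >= 0.8:
        if n_d and n_r:
            return "na_hybrid"
        return "dna" if n_d else "rna"
    return "other"


def extract_chains(assembly: Assembly) -> tuple[list[PolymerChain], list[AtomRecord]]:
    """Group assembly atoms into typed polymer chains and non-polymer atoms."""
    poly_atoms: dict[str, list[AtomRecord]] = {}
    hetero: list[AtomRecord] = []
    for a in assembly.atoms:
        if a.is_polymer:
            poly_atoms.setdefault(a.asym_id, []).append(a)
        else:
            hetero.append(a)
    chains = []
    for chain_id, atoms in poly_atoms.items():
        residues: list[tuple[int, str]] = []
        seen: set[tuple[int, str]] = set()
        for a in atoms:
            if a.element in ("H", "D"):
                continue
            key = (a.seq_id, a.icode)
            if key not in seen:
                seen.add(key)
                residues.append((a.seq_id, a.comp_id))
        chain = PolymerChain(chain_id=chain_id, polymer_type="other", residues=residues, atoms=atoms)
        chain.polymer_type = classify_chain(chain) if residues else "other"
        chains.append(chain)
    return chains, hetero


def _hetero_groups(hetero: list[AtomRecord]) -> list[list[AtomRecord]]:
    groups: dict[tuple[str, int, str, str], list[AtomRecord]] = {}
    for a in hetero:
        groups.setdefault((a.asym_id, a.seq_id, a.icode, a.comp_id), []).append(a)
    return [groups[k] for k in sorted(groups)]


def partition_assembly(
    assembly: Assembly,
    nucleic_groups: list[list[str]] | None = None,
) -> PartitionResult:
    """Split an assembly into a receptor and ligand candidates.

    ``nucleic_groups`` is the chain partition produced by
    :func:`quatbind.nucleic_pairing.pair_chains` on this assembly's
    DNA/RNA chains; when omitted every nucleic chain forms its own group.
    """
    chains, hetero = extract_chains(assembly)
    by_id = {c.chain_id: c for c in chains}

    receptor_chains: list[PolymerChain] = []
    ligands: list[Ligand] = []
    unassigned: list[PolymerChain] = []

    nucleic_ids = [
        c.chain_id for c in chains if c.polymer_type in ("dna", "rna", "na_hybrid")
    ]
    if nucleic_groups is None:
        groups = [[cid] for cid in nucleic_ids]
    else:
        grouped = {cid for g in nucleic_groups for cid in g}
        groups = [list(g) for g in nucleic_groups]
        groups.extend([cid] for cid in nucleic_ids if cid not in grouped)

    for chain in sorted(chains, key=lambda c: c.chain_id):
        if chain.polymer_type == "protein":
            if chain.length >= RECEPTOR_MIN_RESIDUES:
                receptor_chains.append(chain)
            else:
                ligands.append(
                    Ligand(kind="peptide", ligand_id="peptide", chains=[chain],
                           atoms=list(chain.atoms), source_chain=chain.chain_id)
                )
        elif chain.polymer_type in ("dna", "rna", "na_hybrid"):
            pass  # handled via nucleic groups below
        else:
            # non-protein, non-nucleic polymers (e.g. polysaccharides):
            # treated as per-residue small-molecule ligands and flagged
            unassigned.append(chain)
            by_res: dict[tuple[int, str], list[AtomRecord]] = {}
            for a in chain.atoms:
                by_res.setdefault((a.seq_id, a.comp_id), []).append(a)
            for (seq_id, comp), res_atoms in sorted(by_res.items()):
                if comp in WATER_RES:
                    continue
                ligands.append(
                    Ligand(kind="small_molecule", ligand_id=comp, atoms=res_atoms,
                           comp_id=comp, seq_id=seq_id, source_chain=chain.chain_id)
                )

    for group in sorted(groups, key=lambda g: sorted(g)):
        members = [by_id[cid] for cid in sorted(group) if cid in by_id]
        if not members:
            continue
        kinds = {m.polymer_type for m in members}
        if kinds <= {"dna"}:
            tag = "dna"
        elif kinds <= {"rna"}:
            tag = "rna"
        else:
            tag = "dna-rna"
        ligands.append(
            Ligand(
                kind="nucleic",
                ligand_id=tag,
                chains=members,
                atoms=[a for m in members for a in m.atoms],
            )
        )

    for group_atoms in _hetero_groups(hetero):
        comp = group_atoms[0].comp_id
        if comp in WATER_RES:
            continue
        heavy = [a for a in group_atoms if a.element not in ("H", "D")]
        if not heavy:
            continue
        if len(heavy) == 1 and heavy[0].element in METAL_ELEMENTS:
            kind = "metal_ion"
        else:
            kind = "small_molecule"
        ligands.append(
            Ligand(
                kind=kind,
                ligand_id=comp,
                atoms=group_atoms,
                comp_id=comp,
                seq_id=group_atoms[0].seq_id,
                source_chain=group_atoms[0].asym_id,
            )
        )

    receptor = None
    if receptor_chains:
        receptor = Receptor(chains=receptor_chains)
        receptor.stoichiometry = stoichiometry(receptor)
    return PartitionResult(receptor=receptor, ligands=ligands, unassigned=unassigned)


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -0.5
    aligner.extend_gap_score = -0.5
    return aligner


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment sequence identity: matches / alignment length.

    Needleman-Wunsch with match +1, mismatch 0, gap -0.5 (open and
    extend).  Symmetric in its arguments.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    # the aligner returns one of possibly several co-optimal alignments;
    # canonicalize argument order so the result is symmetric
    if (len(seq_a), seq_a) > (len(seq_b), seq_b):
        seq_a, seq_b = seq_b, seq_a
    aln = _aligner().align(seq_a, seq_b)[0]
    counts = aln.counts()
    return counts.identities / aln.length


def stoichiometry(receptor: Receptor, identity_threshold: float = 0.95) -> str:
    """Compact composition string over chain-equivalence classes (A2, AB, ...).

    Chains are grouped by single linkage on pairwise identity strictly
    greater than ``identity_threshold``; groups are lettered by
    descending size (ties by smallest member chain ID).
    """
    if not receptor.chains:
        raise ValueError("receptor has no chains")
    chains = receptor.chains
    n = len(chains)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if pairwise_identity(chains[i].sequence, chains[j].sequence) > identity_threshold:
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    ordered = sorted(
        groups.values(), key=lambda g: (-len(g), min(chains[i].chain_id for i in g))
    )
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    parts = []
    for idx, grp in enumerate(ordered):
        letter = letters[idx] if idx < len(letters) else f"Z{idx}"
        parts.append(letter + (str(len(grp)) if len(grp) > 1 else ""))
    return "".join(parts)
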