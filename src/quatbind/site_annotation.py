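"""Binding-residue detection, SASA, and buried interface area.

A receptor residue is a binding residue when any of its heavy atoms lies
closer to a ligand heavy atom than the sum of the two van der Waals
radii plus a 0.5 Å margin (strict inequality).  Solvent-accessible
surface areas use a deterministic Shrake-Rupley implementation; the
interface area is half the SASA lost upon complexation,
S = (S_prot + S_lig - S_com) / 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from ._chemistry import DEFAULT_VDW_RADIUS, VDW_RADII
from .structure_io import AtomRecord

__all__ = [
    "RadiiTable",
    "BindingSite",
    "InterfaceReport",
    "find_binding_residues",
    "compute_sasa",
    "interface_area",
]


@dataclass
class RadiiTable:
    """Element -> van der Waals radius (Å), with a fallback default."""

    radii: dict[str, float] = field(default_factory=lambda: dict(VDW_RADII))
    default_radius: float = DEFAULT_VDW_RADIUS

    def __post_init__(self) -> None:
        for elem, r in self.radii.items():
            if not (0.5 < r < 3.0):
                raise ValueError(f"radius for {elem}: {r} outside (0.5, 3.0) Å")
        if not (0.5 < self.default_radius < 3.0):
            raise ValueError("default radius outside (0.5, 3.0) Å")

    def radius(self, element: str) -> float:
        return self.radii.get(element.upper(), self.default_radius)

    def for_atoms(self, atoms: list[AtomRecord]) -> np.ndarray:
        return np.array([self.radius(a.element) for a in atoms])


@dataclass
class BindingSite:
    """Binding residues sorted by (chain_id, seq_id) with min ligand distances."""

    residues: list[tuple[str, int, str, float]]  # (chain, seq_id, comp_id, min dist Å)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def n_chains_involved(self) -> int:
        return len({r[0] for r in self.residues})

    def chain_ids(self) -> set[str]:
        return {r[0] for r in self.residues}

    def restricted_to(self, chain_id: str) -> "BindingSite":
        return BindingSite([r for r in self.residues if r[0] == chain_id])


@dataclass
class InterfaceReport:
    S_prot: float
    S_lig: float
    S_com: float

    @property
    def S(self) -> float:
        return 0.5 * (self.S_prot + self.S_lig - self.S_com)


def _heavy(atoms: list[AtomRecord]) -> list[AtomRecord]:
    return [a for a in atoms if a.element not in ("H", "D")]


def find_binding_residues(
    receptor_atoms: list[AtomRecord],
    ligand_atoms: list[AtomRecord],
    radii: RadiiTable | None = None,
    margin: float = 0.5,
) -> BindingSite:
    """Receptor residues with a heavy atom within vdW-sum + margin of the ligand.

    Accelerated with a KD-tree capped at the largest possible contact
    threshold, then verified against each atom pair's exact vdW-sum
    threshold, so the result equals the all-pairs computation.
    """
    radii = radii or RadiiTable()
    rec = _heavy(receptor_atoms)
    lig = _heavy(ligand_atoms)
    if not rec or not lig:
        raise ValueError("receptor and ligand atom sets must both be non-empty")

    rec_xyz = np.array([a.coords for a in rec])
    lig_xyz = np.array([a.coords for a in lig])
    rec_r = radii.for_atoms(rec)
    lig_r = radii.for_atoms(lig)
    max_cut = float(rec_r.max() + lig_r.max() + margin)

    tree = cKDTree(lig_xyz)
    min_dist: dict[tuple[str, int, str], float] = {}
    is_binding: dict[tuple[str, int, str], bool] = {}
    comp_of: dict[tuple[str, int, str], str] = {}
    neighbor_lists = tree.query_ball_point(rec_xyz, r=max_cut)
    for i, neighbors in enumerate(neighbor_lists):
        if not neighbors:
            continue
        a = rec[i]
        d = np.linalg.norm(lig_xyz[neighbors] - rec_xyz[i], axis=1)
        thresholds = rec_r[i] + lig_r[np.array(neighbors)] + margin
        key = (a.asym_id, a.seq_id, a.icode)
        comp_of[key] = a.comp_id
        min_dist[key] = min(min_dist.get(key, np.inf), float(d.min()))
        is_binding[key] = is_binding.get(key, False) or bool((d < thresholds).any())

    residues = [
        (chain, seq, comp_of[(chain, seq, icode)], min_dist[(chain, seq, icode)])
        for (chain, seq, icode), hit in is_binding.items()
        if hit
    ]
    residues.sort(key=lambda r: (r[0], r[1]))
    return BindingSite(residues=residues)


def _golden_spiral(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def compute_sasa(
    atoms: list[AtomRecord],
    radii: RadiiTable | None = None,
    probe: float = 1.4,
    n_points: int = 960,
) -> tuple[np.ndarray, float]:
    """Shrake-Rupley SASA over heavy atoms.

    Returns (per-atom areas aligned with the heavy-atom subset, total
    area) in Å².  Sphere points come from a golden-spiral construction,
    so results are deterministic.
    """
    radii = radii or RadiiTable()
    heavy = _heavy(atoms)
    if not heavy:
        raise ValueError("no heavy atoms for SASA computation")
    xyz = np.array([a.coords for a in heavy])
    r_ext = radii.for_atoms(heavy) + probe
    sphere = _golden_spiral(n_points)

    tree = cKDTree(xyz)
    max_r = float(r_ext.max())
    areas = np.zeros(len(heavy))
    for i in range(len(heavy)):
        pts = xyz[i] + r_ext[i] * sphere
        neighbors = [j for j in tree.query_ball_point(xyz[i], r_ext[i] + max_r) if j != i]
        if neighbors:
            nb_xyz = xyz[neighbors]
            nb_r = r_ext[np.array(neighbors)]
            d2 = ((pts[:, None, :] - nb_xyz[None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (nb_r**2)[None, :]).any(axis=1)
            exposed = int((~buried).sum())
        else:
            exposed = n_points
        areas[i] = (exposed / n_points) * 4.0 * np.pi * r_ext[i] ** 2
    return areas, float(areas.sum())


def interface_area(
    receptor_atoms: list[AtomRecord],
    ligand_atoms: list[AtomRecord],
    radii: RadiiTable | None = None,
    probe: float = 1.4,
    n_points: int = 960,
) -> InterfaceReport:
    """Buried interface area S = (S_prot + S_lig - S_com) / 2.

    The three SASA terms are computed with identical parameters, the
    receptor and ligand in isolation (atoms extracted as-is).
    """
    radii = radii or RadiiTable()
    _, s_prot = compute_sasa(receptor_atoms, radii, probe, n_points)
    _, s_lig = compute_sasa(ligand_atoms, radii, probe, n_points)
    _, s_com = compute_sasa(list(receptor_atoms) + list(ligand_atoms), radii, probe, n_points)
    return InterfaceReport(S_prot=s_prot, S_lig=s_lig, S_com=s_com)
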