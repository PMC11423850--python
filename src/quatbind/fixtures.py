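"""Synthetic structure and dataset fixtures.

Every fixture is written to disk as a real mmCIF (or TSV) file together
with a JSON manifest of its construction ground truth, so the actual
parsers and detectors are always on the tested path.  Geometry is
idealized, not physically realistic: protein chains ride on a stylized
backbone, B-DNA duplexes use ideal helical parameters (rise 3.38 Å,
twist 36°) with a known base-pair registry, and the ion-in-pocket
fixture places a metal ion within contact range of two chains.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .structure_io import (
    AssemblyDefinition,
    AtomRecord,
    TransformOperator,
    write_mmcif,
)

__all__ = ["FixtureSpec", "make_structure_fixture", "make_affinity_dataset"]

FIXTURE_KINDS = {
    "protein_monomer",
    "protein_dimer_via_operator",
    "hetero_oligomer",
    "bdna_duplex",
    "rna_hairpin_plus_dinucleotide",
    "ion_in_pocket",
    "many_chain_giant",
    "affinity_linear_dataset",
}

AA_CODES = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
]


@dataclass
class FixtureSpec:
    kind: str
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in FIXTURE_KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}")


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

# backbone atom offsets relative to CA, Å
_BB_OFFSETS = {
    "N": np.array([0.0, 1.3, 0.3]),
    "C": np.array([1.0, -1.0, 0.0]),
    "O": np.array([1.6, -2.2, 0.0]),
}
_CA_STEP = 3.8


def _protein_chain_atoms(
    chain_id: str,
    comp_ids: list[str],
    origin: np.ndarray,
    direction: np.ndarray,
    start_serial: int = 1,
) -> list[AtomRecord]:
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    atoms = []
    serial = start_serial
    for i, comp in enumerate(comp_ids):
        ca = np.asarray(origin, dtype=float) + direction * (_CA_STEP * i)
        zig = np.array([0.0, 0.0, 0.4 if i % 2 else -0.4])
        for name, off in (("N", _BB_OFFSETS["N"]), ("CA", np.zeros(3)),
                          ("C", _BB_OFFSETS["C"]), ("O", _BB_OFFSETS["O"])):
            atoms.append(
                AtomRecord(
                    serial=serial, name=name, element=name[0], comp_id=comp,
                    asym_id=chain_id, seq_id=i + 1, icode="",
                    coords=ca + off + zig, is_polymer=True,
                )
            )
            serial += 1
    return atoms


def _random_protein_seq(rng: np.random.Generator, length: int) -> list[str]:
    return [AA_CODES[i] for i in rng.integers(0, len(AA_CODES), size=length)]


# Watson-Crick pair templates in the pair frame: left base (purine) has its
# C1' at x = -5.2, right base at x = +5.2; hydrogen-bond partner atoms sit
# near the pair axis so canonical contacts fall inside 3.5 Å while stacked
# neighbors (rise 3.38 Å, twist 36°) stay outside.
_PAIR_TEMPLATES = {
    # left comp: (atom name, x, y)
    "A": [("C1'", -5.2, 0.0), ("N1", -1.4, 0.5), ("N6", -1.5, 2.9)],
    "G": [("C1'", -5.2, 0.0), ("N1", -1.4, 0.5), ("O6", -1.5, 2.9), ("N2", -1.6, -1.9)],
    # right comp
    "T": [("C1'", 5.2, 0.0), ("N3", 1.4, 0.5), ("O4", 1.4, 2.9), ("O2", 1.6, -1.9)],
    "U": [("C1'", 5.2, 0.0), ("N3", 1.4, 0.5), ("O4", 1.4, 2.9), ("O2", 1.6, -1.9)],
    "C": [("C1'", 5.2, 0.0), ("N3", 1.4, 0.5), ("N4", 1.4, 2.9), ("O2", 1.6, -1.9)],
}
_RISE = 3.38
_TWIST = math.radians(36.0)


def _pair_slot_atoms(
    slot: int,
    left: tuple[str, str, int],  # (chain_id, comp_id, seq_id)
    right: tuple[str, str, int],
    origin: np.ndarray | None = None,
    start_serial: int = 1,
) -> list[AtomRecord]:
    origin = np.zeros(3) if origin is None else np.asarray(origin, dtype=float)
    angle = _TWIST * slot
    cos_a, sin_a = math.cos(angle), math.sin(angle)
    atoms = []
    serial = start_serial
    for (chain_id, comp_id, seq_id), template_key in ((left, left[1][-1:]), (right, right[1][-1:])):
        template = _PAIR_TEMPLATES[template_key.upper()]
        for name, x, y in template:
            xr = x * cos_a - y * sin_a
            yr = x * sin_a + y * cos_a
            elem = name[0]
            atoms.append(
                AtomRecord(
                    serial=serial, name=name, element=elem, comp_id=comp_id,
                    asym_id=chain_id, seq_id=seq_id, icode="",
                    coords=origin + np.array([xr, yr, _RISE * slot]),
                    is_polymer=True,
                )
            )
            serial += 1
    return atoms


def _chain_id_series(n: int) -> list[str]:
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    ids = []
    for i in range(n):
        if i < 26:
            ids.append(alphabet[i])
        else:
            ids.append(alphabet[(i // 26) - 1] + alphabet[i % 26])
    return ids


_IDENTITY_OP = {"1": TransformOperator("1", np.eye(3), np.zeros(3))}


def _identity_assembly(chain_ids: list[str]) -> list[AssemblyDefinition]:
    return [AssemblyDefinition(assembly_id="1", generators=[("1", list(chain_ids))])]


# ---------------------------------------------------------------------------
# fixture builders
# ---------------------------------------------------------------------------


def _build_protein_monomer(spec: FixtureSpec, rng: np.random.Generator):
    length = int(spec.params.get("length", 50))
    seq = spec.params.get("sequence") or _random_protein_seq(rng, length)
    atoms = _protein_chain_atoms("A", list(seq), np.zeros(3), [1, 0, 0])
    manifest = {
        "chains": {"A": {"type": "protein", "length": len(seq)}},
        "receptor_chains": ["A"] if len(seq) >= 30 else [],
        "expected_category": "structure_only",
        "stoichiometry": "A",
    }
    return atoms, _IDENTITY_OP, _identity_assembly(["A"]), manifest


def _build_protein_dimer_via_operator(spec: FixtureSpec, rng: np.random.Generator):
    length = int(spec.params.get("length", 100))
    seq = _random_protein_seq(rng, length)
    atoms = _protein_chain_atoms("A", seq, np.zeros(3), [1, 0, 0])
    ops = {
        "1": TransformOperator("1", np.eye(3), np.zeros(3)),
        "2": TransformOperator(
            "2",
            np.array([[-1.0, 0.0, 0.0], [0.0, -1.0, 0.0], [0.0, 0.0, 1.0]]),
            np.array([0.0, 12.0, 0.0]),
        ),
    }
    assemblies = [AssemblyDefinition(assembly_id="1", generators=[("1,2", ["A"])])]
    manifest = {
        "chains": {"A": {"type": "protein", "length": length}},
        "assembly_chain_count": 2,
        "assembly_chain_ids": ["A", "A-2"],
        "stoichiometry": "A2",
        "operator_ids": ["1", "2"],
    }
    return atoms, ops, assemblies, manifest


def _build_hetero_oligomer(spec: FixtureSpec, rng: np.random.Generator):
    length = int(spec.params.get("length", 60))
    n_chains = int(spec.params.get("n_chains", 2))
    mutate_every = int(spec.params.get("mutate_every", 2))
    base = _random_protein_seq(rng, length)
    chain_ids = _chain_id_series(n_chains)
    atoms: list[AtomRecord] = []
    seqs = {}
    for k, cid in enumerate(chain_ids):
        seq = list(base)
        if k > 0:
            for i in range(0, length, mutate_every):
                choices = [c for c in AA_CODES if c != seq[i]]
                seq[i] = choices[int(rng.integers(0, len(choices)))]
        seqs[cid] = seq
        atoms.extend(
            _protein_chain_atoms(
                cid, seq, np.array([0.0, 20.0 * k, 0.0]), [1, 0, 0],
                start_serial=len(atoms) + 1,
            )
        )
    manifest = {
        "chains": {c: {"type": "protein", "length": length} for c in chain_ids},
        "receptor_chains": chain_ids,
        "stoichiometry_distinct": n_chains,
    }
    return atoms, _IDENTITY_OP, _identity_assembly(chain_ids), manifest


def _build_bdna_duplex(spec: FixtureSpec, rng: np.random.Generator):
    n_bp = int(spec.params.get("n_bp", 8))
    if n_bp < 1:
        raise ValueError("bdna_duplex needs n_bp >= 1")
    pattern = ["A", "G"]  # left-strand bases alternate A/G
    complement = {"A": "T", "G": "C"}
    atoms: list[AtomRecord] = []
    pairs = []
    for i in range(n_bp):
        left_base = pattern[i % 2]
        right_base = complement[left_base]
        left = ("X", "D" + left_base, i + 1)
        right = ("Y", "D" + right_base, n_bp - i)  # antiparallel numbering
        atoms.extend(_pair_slot_atoms(i, left, right, start_serial=len(atoms) + 1))
        pairs.append([["X", i + 1, "D" + left_base], ["Y", n_bp - i, "D" + right_base]])
    manifest = {
        "chains": {
            "X": {"type": "dna", "length": n_bp},
            "Y": {"type": "dna", "length": n_bp},
        },
        "n_inter_chain_pairs": n_bp,
        "pairs": pairs,
        "expected_groups": [["X", "Y"]],
    }
    return atoms, _IDENTITY_OP, _identity_assembly(["X", "Y"]), manifest


def _build_rna_hairpin_plus_dinucleotide(spec: FixtureSpec, rng: np.random.Generator):
    """10-nt RNA chain R (6-nt intra-chain stem + loop + 2-nt overhang stem)
    plus a dinucleotide chain S whose two nucleotides both pair with R."""
    atoms: list[AtomRecord] = []
    pairs = []
    # stem slots: R1:R8, R2:R7, R3:R6 (intra-chain)
    stem = [(("R", "A", 1), ("R", "U", 8)), (("R", "A", 2), ("R", "U", 7)),
            (("R", "G", 3), ("R", "C", 6))]
    for slot, (left, right) in enumerate(stem):
        atoms.extend(_pair_slot_atoms(slot, left, right, start_serial=len(atoms) + 1))
        pairs.append([list(left), list(right)])
    # overhang slots pair R9/R10 with the dinucleotide S2/S1 (inter-chain)
    overhang = [(("R", "A", 9), ("S", "U", 2)), (("R", "G", 10), ("S", "C", 1))]
    for slot, (left, right) in enumerate(overhang, start=len(stem)):
        atoms.extend(_pair_slot_atoms(slot, left, right, start_serial=len(atoms) + 1))
        pairs.append([list(left), list(right)])
    # unpaired loop nucleotides R4, R5 placed far from every pair slot
    for j, seq_id in enumerate((4, 5)):
        for name, x, y in _PAIR_TEMPLATES["A"]:
            atoms.append(
                AtomRecord(
                    serial=len(atoms) + 1, name=name, element=name[0], comp_id="A",
                    asym_id="R", seq_id=seq_id, icode="",
                    coords=np.array([x + 40.0, y + 15.0 * j, 0.0]),
                    is_polymer=True,
                )
            )
    manifest = {
        "chains": {"R": {"type": "rna", "length": 10}, "S": {"type": "rna", "length": 2}},
        "n_inter_chain_pairs": 2,
        "n_intra_chain_pairs": 3,
        "pairs": pairs,
        "expected_groups": [["R", "S"]],
        "special_case": "dinucleotide fully paired with R but below the 3-pair rule",
    }
    return atoms, _IDENTITY_OP, _identity_assembly(["R", "S"]), manifest


def _build_ion_in_pocket(spec: FixtureSpec, rng: np.random.Generator):
    length = int(spec.params.get("length", 30))
    ion_comp = str(spec.params.get("ion", "K")).upper()
    if length < 30:
        raise ValueError("ion_in_pocket chains must be receptor-sized (>= 30 residues)")
    seq = _random_protein_seq(rng, length)
    atoms = _protein_chain_atoms("A", seq, np.array([3.2, 0.0, 0.0]), [1, 0, 0])
    atoms += _protein_chain_atoms(
        "B", seq, np.array([-3.2, 0.0, 0.0]), [-1, 0, 0], start_serial=len(atoms) + 1
    )
    atoms.append(
        AtomRecord(
            serial=len(atoms) + 1, name=ion_comp, element=ion_comp, comp_id=ion_comp,
            asym_id="C", seq_id=1, icode="", coords=np.zeros(3), is_polymer=False,
        )
    )
    manifest = {
        "chains": {"A": {"type": "protein", "length": length},
                   "B": {"type": "protein", "length": length}},
        "ligand": {"kind": "metal_ion", "comp_id": ion_comp},
        "expected_binding_chains": ["A", "B"],
        "expected_category": "relevant",
        "stoichiometry": "A2",
    }
    return atoms, _IDENTITY_OP, _identity_assembly(["A", "B", "C"]), manifest


def _build_many_chain_giant(spec: FixtureSpec, rng: np.random.Generator):
    n_chains = int(spec.params.get("n_chains", 100))
    length = int(spec.params.get("length", 4))
    chain_ids = _chain_id_series(n_chains)
    atoms: list[AtomRecord] = []
    seq = _random_protein_seq(rng, length)
    for k, cid in enumerate(chain_ids):
        origin = np.array([25.0 * (k % 10), 25.0 * (k // 10), 0.0])
        atoms.extend(
            _protein_chain_atoms(cid, seq, origin, [1, 0, 0], start_serial=len(atoms) + 1)
        )
    manifest = {
        "chains": {c: {"type": "protein", "length": length} for c in chain_ids},
        "n_chains": n_chains,
    }
    return atoms, _IDENTITY_OP, _identity_assembly(chain_ids), manifest


_BUILDERS = {
    "protein_monomer": _build_protein_monomer,
    "protein_dimer_via_operator": _build_protein_dimer_via_operator,
    "hetero_oligomer": _build_hetero_oligomer,
    "bdna_duplex": _build_bdna_duplex,
    "rna_hairpin_plus_dinucleotide": _build_rna_hairpin_plus_dinucleotide,
    "ion_in_pocket": _build_ion_in_pocket,
    "many_chain_giant": _build_many_chain_giant,
}


def make_structure_fixture(spec: FixtureSpec, out_dir: str | Path) -> tuple[Path, dict]:
    """Write one synthetic mmCIF fixture plus its ground-truth manifest.

    Returns (mmCIF path, manifest dict); the manifest is also written as
    ``<name>.manifest.json`` next to the structure.  The same spec and
    seed always produce byte-identical files.
    """
    if spec.kind == "affinity_linear_dataset":
        raise ValueError("use make_affinity_dataset for affinity_linear_dataset specs")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    atoms, operators, assemblies, manifest = _BUILDERS[spec.kind](spec, rng)
    name = f"{spec.kind}_{spec.seed}"
    cif_path = out_dir / f"{name}.cif"
    write_mmcif(atoms, cif_path, name=name, operators=operators, assemblies=assemblies)
    manifest = {"kind": spec.kind, "seed": spec.seed, "params": spec.params, **manifest}
    manifest_path = out_dir / f"{name}.manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return cif_path, manifest


def make_affinity_dataset(
    n: int,
    weights=(0.5, 0.3, -0.2),
    intercept: float = 1.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> dict:
    """Synthetic linear score/affinity dataset in the adapter TSV formats.

    Draws score triples from a seeded standard Gaussian and sets
    y = intercept + weights · x + N(0, noise_sigma).  When ``out_dir`` is
    given, writes ``scores.tsv`` and ``affinity.tsv``; always returns the
    arrays and generating parameters.
    """
    if n < 10:
        raise ValueError("need n >= 10")
    rng = np.random.default_rng(seed)
    w = np.asarray(weights, dtype=float).reshape(3)
    X = rng.standard_normal((n, 3))
    y = intercept + X @ w + noise_sigma * rng.standard_normal(n)
    ids = [f"fx{i:04d}" for i in range(n)]
    result = {
        "ids": ids, "X": X, "y": y,
        "weights": w.tolist(), "intercept": intercept,
        "noise_sigma": noise_sigma, "seed": seed,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "scores.tsv", "w") as fh:
            fh.write("pdb_id\tligand_id\tx_xscore\tx_itscore\tx_vina\n")
            for i, pid in enumerate(ids):
                fh.write(f"{pid}\tLIG\t{X[i, 0]:.6f}\t{X[i, 1]:.6f}\t{X[i, 2]:.6f}\n")
        with open(out_dir / "affinity.tsv", "w") as fh:
            fh.write("pdb_id\tligand_id\tchain\tmeasure\tvalue\tunit\tsource\n")
            for i, pid in enumerate(ids):
                kd_molar = 10.0 ** (-y[i])
                fh.write(f"{pid}\tLIG\tA\tKd\t{kd_molar:.6e}\tM\tsynthetic\n")
        result["scores_path"] = str(out_dir / "scores.tsv")
        result["affinity_path"] = str(out_dir / "affinity.tsv")
    return result
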