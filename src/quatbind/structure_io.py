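"""Structure parsing, biological-assembly generation and format conversion.

Reads mmCIF (via biotite's CIF reader) and legacy PDB files into a flat
atom table plus the metadata needed to build biological assemblies:
``pdbx_struct_assembly_gen`` generators, ``pdbx_struct_oper_list``
rotation/translation operators, and the ``pdbx_struct_mod_residue``
modified-residue map.  Assemblies are built by applying the stored
operators; oversized assemblies can be split into several legacy PDB
files with a chain-ID mapping table.
"""

from __future__ import annotations

import io
import math
import re
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from biotite.structure.io.pdbx import CIFBlock, CIFCategory, CIFFile

from ._chemistry import NUCLEOTIDE_RES, STANDARD_AA, WATER_RES

__all__ = [
    "AtomRecord",
    "TransformOperator",
    "AssemblyDefinition",
    "ModifiedResidueMap",
    "ParsedStructure",
    "ChainProvenance",
    "Assembly",
    "StructureParseError",
    "AssemblyBuildError",
    "PdbCapacityError",
    "parse_structure",
    "build_assemblies",
    "asu_as_assembly",
    "write_structure",
    "split_for_pdb",
    "parse_oper_expression",
]

# Alphabet used for single-character PDB chain IDs, in assignment order.
PDB_CHAIN_ALPHABET = string.ascii_uppercase + string.ascii_lowercase + string.digits
PDB_MAX_CHAINS = len(PDB_CHAIN_ALPHABET)  # 62


class StructureParseError(ValueError):
    """Raised when an input file cannot be parsed into a structure."""


class AssemblyBuildError(ValueError):
    """Raised when assembly generators reference unknown or invalid operators."""


class PdbCapacityError(ValueError):
    """Raised when a structure does not fit the legacy PDB format."""


@dataclass
class AtomRecord:
    """One atom of a parsed structure or built assembly."""

    serial: int
    name: str
    element: str
    comp_id: str
    asym_id: str
    seq_id: int
    icode: str
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    is_polymer: bool = True
    model_num: int = 1

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial}: coords must be a finite 3-vector")
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(f"atom {self.serial}: occupancy {self.occupancy} outside [0, 1]")
        if not self.element:
            raise ValueError(f"atom {self.serial}: empty element symbol")

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.asym_id, self.seq_id, self.icode)


@dataclass
class TransformOperator:
    """Rigid-body operator: x' = R @ x + t."""

    oper_id: str
    R: np.ndarray
    t: np.ndarray

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float).reshape(3, 3)
        self.t = np.asarray(self.t, dtype=float).reshape(3)
        det = float(np.linalg.det(self.R))
        if abs(det - 1.0) > 1e-3:
            raise AssemblyBuildError(
                f"operator {self.oper_id!r}: det(R) = {det:.6f}, not a proper rotation"
            )
        if not np.allclose(self.R @ self.R.T, np.eye(3), atol=1e-3):
            raise AssemblyBuildError(f"operator {self.oper_id!r}: R is not orthogonal")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.R.T + self.t

    @property
    def is_identity(self) -> bool:
        return np.allclose(self.R, np.eye(3), atol=1e-9) and np.allclose(self.t, 0.0, atol=1e-9)

    def compose(self, other: "TransformOperator") -> "TransformOperator":
        """Return self ∘ other (apply ``other`` first, then ``self``)."""
        return TransformOperator(
            oper_id=f"{self.oper_id}.{other.oper_id}",
            R=self.R @ other.R,
            t=self.R @ other.t + self.t,
        )


@dataclass
class AssemblyDefinition:
    """One ``pdbx_struct_assembly_gen`` record set for an assembly ID."""

    assembly_id: str
    generators: list[tuple[str, list[str]]]  # (oper_expression, asym_id list)


@dataclass
class ModifiedResidueMap:
    """(asym_id, seq_id, modified comp_id) -> parent standard comp_id."""

    entries: list[tuple[str, int, str, str]] = field(default_factory=list)

    def lookup(self) -> dict[tuple[str, int, str], str]:
        return {(a, s, m): p for a, s, m, p in self.entries}


@dataclass
class ParsedStructure:
    """Atom table plus assembly metadata parsed from one file."""

    pdb_id: str
    atoms: list[AtomRecord]
    polymer_types: dict[str, str]  # asym_id -> entity_poly type string
    assemblies: list[AssemblyDefinition]
    operators: dict[str, TransformOperator]
    mod_residues: ModifiedResidueMap
    resolution: float | None = None
    source_format: str = "mmcif"

    @property
    def model_numbers(self) -> list[int]:
        return sorted({a.model_num for a in self.atoms})

    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.asym_id, None)
        return list(seen)


@dataclass
class ChainProvenance:
    chain_id: str
    source_asym_id: str
    operator_ids: tuple[str, ...]


@dataclass
class Assembly:
    """A biological assembly: transformed atoms with per-chain provenance."""

    pdb_id: str
    assembly_id: str
    atoms: list[AtomRecord]
    provenance: list[ChainProvenance]
    resolution: float | None = None
    polymer_types: dict[str, str] = field(default_factory=dict)

    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.asym_id, None)
        return list(seen)

    def atoms_of_chain(self, chain_id: str) -> list[AtomRecord]:
        return [a for a in self.atoms if a.asym_id == chain_id]


# ---------------------------------------------------------------------------
# Operator-expression grammar
# ---------------------------------------------------------------------------

_RANGE_RE = re.compile(r"^(\d+)-(\d+)$")


def _expand_factor(factor: str) -> list[str]:
    ids: list[str] = []
    for token in factor.split(","):
        token = token.strip()
        if not token:
            continue
        m = _RANGE_RE.match(token)
        if m:
            lo, hi = int(m.group(1)), int(m.group(2))
            if hi < lo:
                raise AssemblyBuildError(f"invalid operator range {token!r}")
            ids.extend(str(i) for i in range(lo, hi + 1))
        else:
            ids.append(token)
    if not ids:
        raise AssemblyBuildError(f"empty operator selection in factor {factor!r}")
    return ids


def parse_oper_expression(expr: str) -> list[tuple[str, ...]]:
    """Expand an mmCIF oper_expression into operator-ID products.

    Supports comma lists (``"1,2"``), numeric ranges (``"1-60"``) and up to
    two parenthesized factors composed left-to-right as matrix products
    (``"(1-60)(61)"``).  Returns one tuple of operator IDs per output copy.
    """
    expr = expr.strip()
    if not expr:
        raise AssemblyBuildError("empty oper_expression")
    if "(" in expr:
        factors = re.findall(r"\(([^()]*)\)", expr)
        stripped = re.sub(r"\([^()]*\)", "", expr).strip()
        if stripped:
            raise AssemblyBuildError(
                f"unsupported oper_expression grammar: {expr!r} (text outside parentheses)"
            )
        if len(factors) > 2:
            raise AssemblyBuildError(
                f"unsupported oper_expression grammar: {expr!r} (more than two factors)"
            )
        expanded = [_expand_factor(f) for f in factors]
        if len(expanded) == 1:
            return [(i,) for i in expanded[0]]
        return [(i, j) for i in expanded[0] for j in expanded[1]]
    return [(i,) for i in _expand_factor(expr)]


# ---------------------------------------------------------------------------
# mmCIF parsing
# ---------------------------------------------------------------------------


def _col(category: CIFCategory, name: str, n: int, default: str | None = None) -> list[str]:
    if name in category:
        return [str(v) for v in category[name].as_array(str)]
    if default is None:
        raise StructureParseError(f"mmCIF category _atom_site is missing item {name!r}")
    return [default] * n


def _parse_mmcif(path: Path) -> ParsedStructure:
    try:
        cif = CIFFile.read(str(path))
        block = cif.block
    except Exception as exc:  # biotite raises several exception types
        raise StructureParseError(f"cannot parse mmCIF file {path}: {exc}") from exc

    if "atom_site" not in block:
        raise StructureParseError(f"{path}: no _atom_site records (missing coordinates)")
    site = block["atom_site"]
    n = site.row_count

    xs = site["Cartn_x"].as_array(float)
    ys = site["Cartn_y"].as_array(float)
    zs = site["Cartn_z"].as_array(float)
    names = _col(site, "label_atom_id", n)
    elements = _col(site, "type_symbol", n)
    comps = _col(site, "label_comp_id", n)
    asyms = _col(site, "label_asym_id", n)
    auth_seq = _col(site, "auth_seq_id", n, default=".")
    label_seq = _col(site, "label_seq_id", n, default=".")
    icodes = _col(site, "pdbx_PDB_ins_code", n, default="?")
    occ = _col(site, "occupancy", n, default="1.0")
    alt = _col(site, "label_alt_id", n, default=".")
    models = _col(site, "pdbx_PDB_model_num", n, default="1")
    groups = _col(site, "group_PDB", n, default="ATOM")
    entities = _col(site, "label_entity_id", n, default=".")

    # entity_poly gives authoritative polymer classification per entity
    poly_entities: dict[str, str] = {}
    if "entity_poly" in block:
        ep = block["entity_poly"]
        ids = [str(v) for v in ep["entity_id"].as_array(str)]
        types = [str(v) for v in ep["type"].as_array(str)] if "type" in ep else ["?"] * len(ids)
        poly_entities = dict(zip(ids, types))

    atoms: list[AtomRecord] = []
    polymer_types: dict[str, str] = {}
    for i in range(n):
        seq_raw = auth_seq[i]
        if seq_raw in (".", "?"):
            seq_raw = label_seq[i]
        try:
            seq_id = int(seq_raw)
        except ValueError:
            seq_id = 0
        if poly_entities:
            is_poly = entities[i] in poly_entities
        else:
            is_poly = groups[i] == "ATOM"
        try:
            atom = AtomRecord(
                serial=i + 1,
                name=names[i],
                element=elements[i].upper(),
                comp_id=comps[i].upper(),
                asym_id=asyms[i],
                seq_id=seq_id,
                icode="" if icodes[i] in (".", "?") else icodes[i],
                coords=np.array([xs[i], ys[i], zs[i]]),
                occupancy=float(occ[i]) if occ[i] not in (".", "?") else 1.0,
                altloc="" if alt[i] in (".", "?") else alt[i],
                is_polymer=is_poly,
                model_num=int(models[i]) if models[i] not in (".", "?") else 1,
            )
        except ValueError as exc:
            raise StructureParseError(f"{path}: bad _atom_site row {i + 1}: {exc}") from exc
        atoms.append(atom)
        if is_poly and asyms[i] not in polymer_types:
            polymer_types[asyms[i]] = poly_entities.get(entities[i], "?")

    operators = _parse_oper_list(block, path)
    assemblies = _parse_assembly_gen(block)
    mod_residues = _parse_mod_residues(block)
    resolution = _parse_resolution(block)

    pdb_id = str(block.name).lower() if block.name else path.stem.lower()
    atoms = _select_altloc(atoms)
    return ParsedStructure(
        pdb_id=pdb_id,
        atoms=atoms,
        polymer_types=polymer_types,
        assemblies=assemblies,
        operators=operators,
        mod_residues=mod_residues,
        resolution=resolution,
        source_format="mmcif",
    )


def _parse_oper_list(block: CIFBlock, path: Path) -> dict[str, TransformOperator]:
    if "pdbx_struct_oper_list" not in block:
        return {}
    cat = block["pdbx_struct_oper_list"]
    n = cat.row_count
    ids = [str(v) for v in cat["id"].as_array(str)]
    operators: dict[str, TransformOperator] = {}
    for i in range(n):
        try:
            R = np.array(
                [
                    [float(cat[f"matrix[{r}][{c}]"].as_array(str)[i]) for c in (1, 2, 3)]
                    for r in (1, 2, 3)
                ]
            )
            t = np.array([float(cat[f"vector[{r}]"].as_array(str)[i]) for r in (1, 2, 3)])
        except Exception as exc:
            raise StructureParseError(
                f"{path}: malformed pdbx_struct_oper_list row for id {ids[i]!r}"
            ) from exc
        operators[ids[i]] = TransformOperator(oper_id=ids[i], R=R, t=t)
    return operators


def _parse_assembly_gen(block: CIFBlock) -> list[AssemblyDefinition]:
    if "pdbx_struct_assembly_gen" not in block:
        return []
    cat = block["pdbx_struct_assembly_gen"]
    asm_ids = [str(v) for v in cat["assembly_id"].as_array(str)]
    exprs = [str(v) for v in cat["oper_expression"].as_array(str)]
    asym_lists = [str(v) for v in cat["asym_id_list"].as_array(str)]
    by_id: dict[str, AssemblyDefinition] = {}
    for asm_id, expr, asyms in zip(asm_ids, exprs, asym_lists):
        asym_ids = [a.strip() for a in asyms.split(",") if a.strip()]
        defn = by_id.setdefault(asm_id, AssemblyDefinition(assembly_id=asm_id, generators=[]))
        defn.generators.append((expr, asym_ids))
    return list(by_id.values())


def _parse_mod_residues(block: CIFBlock) -> ModifiedResidueMap:
    result = ModifiedResidueMap()
    if "pdbx_struct_mod_residue" not in block:
        return result
    cat = block["pdbx_struct_mod_residue"]
    n = cat.row_count

    def col(name: str, default: str = "?") -> list[str]:
        if name in cat:
            return [str(v) for v in cat[name].as_array(str)]
        return [default] * n

    asyms = col("label_asym_id")
    seqs = col("auth_seq_id")
    comps = col("label_comp_id")
    parents = col("parent_comp_id")
    for a, s, m, p in zip(asyms, seqs, comps, parents):
        if p in (".", "?") or m in (".", "?"):
            continue
        try:
            seq_id = int(s)
        except ValueError:
            continue
        result.entries.append((a, seq_id, m.upper(), p.upper()))
    return result


def _parse_resolution(block: CIFBlock) -> float | None:
    for cat_name, item in (("refine", "ls_d_res_high"), ("reflns", "d_resolution_high")):
        if cat_name in block and item in block[cat_name]:
            try:
                val = str(block[cat_name][item].as_array(str)[0])
                if val not in (".", "?"):
                    return float(val)
            except Exception:
                continue
    return None


def _select_altloc(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep one alternate per atom: highest occupancy, ties by altloc order."""
    best: dict[tuple, AtomRecord] = {}
    order: list[tuple] = []
    for a in atoms:
        key = (a.model_num, a.asym_id, a.seq_id, a.icode, a.name)
        cur = best.get(key)
        if cur is None:
            best[key] = a
            order.append(key)
        elif (a.occupancy, _altloc_rank(a.altloc)) > (cur.occupancy, _altloc_rank(cur.altloc)):
            best[key] = a
    return [best[k] for k in order]


def _altloc_rank(altloc: str) -> float:
    # empty altloc sorts first among ties; otherwise reverse character order
    # so that 'A' beats 'B' when occupancies tie
    if not altloc:
        return 1.0
    return -ord(altloc) / 1000.0


# ---------------------------------------------------------------------------
# PDB parsing
# ---------------------------------------------------------------------------


def _parse_pdb(path: Path) -> ParsedStructure:
    atoms: list[AtomRecord] = []
    model_num = 1
    seen_model_record = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                try:
                    model_num = int(line[6:].split()[0])
                except (ValueError, IndexError):
                    raise StructureParseError(f"{path}:{lineno}: malformed MODEL record")
                seen_model_record = True
            elif rec in ("ATOM", "HETATM"):
                try:
                    atoms.append(_parse_pdb_atom_line(line, model_num))
                except ValueError as exc:
                    raise StructureParseError(f"{path}:{lineno}: {exc}") from exc
    if not atoms:
        raise StructureParseError(f"{path}: no ATOM/HETATM records (missing coordinates)")
    if not seen_model_record:
        pass  # single implicit model
    atoms = _select_altloc(atoms)
    polymer_types: dict[str, str] = {}
    for a in atoms:
        if a.is_polymer and a.asym_id not in polymer_types:
            if a.comp_id in NUCLEOTIDE_RES:
                polymer_types[a.asym_id] = "polynucleotide"
            else:
                polymer_types[a.asym_id] = "polypeptide(L)"
    return ParsedStructure(
        pdb_id=path.stem.lower(),
        atoms=atoms,
        polymer_types=polymer_types,
        assemblies=[],
        operators={},
        mod_residues=ModifiedResidueMap(),
        resolution=None,
        source_format="pdb",
    )


def _parse_pdb_atom_line(line: str, model_num: int) -> AtomRecord:
    if len(line) < 54:
        raise ValueError(f"truncated coordinate record: {line.rstrip()!r}")
    comp_id = line[17:20].strip().upper()
    element = line[76:78].strip().upper() if len(line) >= 78 else ""
    if not element:
        # fall back on the atom-name convention: first alphabetic character
        element = next((c for c in line[12:16] if c.isalpha()), "C").upper()
    is_polymer = line[:6].strip() == "ATOM" and (
        comp_id in STANDARD_AA or comp_id in NUCLEOTIDE_RES
    )
    occ_str = line[54:60].strip() if len(line) >= 60 else ""
    return AtomRecord(
        serial=int(line[6:11]),
        name=line[12:16].strip(),
        element=element,
        comp_id=comp_id,
        asym_id=line[21].strip() or "A",
        seq_id=int(line[22:26]),
        icode=line[26].strip(),
        coords=np.array([float(line[30:38]), float(line[38:46]), float(line[46:54])]),
        occupancy=float(occ_str) if occ_str else 1.0,
        altloc=line[16].strip(),
        is_polymer=is_polymer,
        model_num=model_num,
    )


def parse_structure(path: str | Path, format: str = "auto") -> ParsedStructure:
    """Parse an mmCIF or legacy PDB file into a :class:`ParsedStructure`.

    ``format="auto"`` decides by extension (``.cif``/``.mmcif`` vs
    ``.pdb``/``.ent``), falling back to content sniffing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        suffix = path.suffix.lower()
        if suffix in (".cif", ".mmcif"):
            format = "mmcif"
        elif suffix in (".pdb", ".ent"):
            format = "pdb"
        else:
            head = path.read_text(errors="replace")[:4096]
            format = "mmcif" if head.lstrip().startswith("data_") or "_atom_site" in head else "pdb"
    if format == "mmcif":
        return _parse_mmcif(path)
    if format == "pdb":
        return _parse_pdb(path)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Assembly building
# ---------------------------------------------------------------------------


def _resolve_operator(
    product: tuple[str, ...], operators: dict[str, TransformOperator]
) -> TransformOperator:
    ops = []
    for oper_id in product:
        if oper_id not in operators:
            raise AssemblyBuildError(f"oper_expression references unknown operator id {oper_id!r}")
        ops.append(operators[oper_id])
    combined = ops[0]
    for op in ops[1:]:
        combined = combined.compose(op)
    return combined


def build_assemblies(
    parsed: ParsedStructure, model_policy: str = "first_model"
) -> list[Assembly]:
    """Build every biological assembly defined in the parsed structure.

    Only the first model is used when several are present.  The modified-
    residue map is applied (component IDs replaced by their standard
    parents; coordinates untouched).  Chain copies created by operator
    duplication are renamed ``<asym_id>-<oper_id>`` (composed products
    join IDs with ``.``); the first copy of each asym unit keeps its
    original ID.  Returns an empty list when the file defines no
    assemblies (caller decides the fallback, see :func:`asu_as_assembly`).
    """
    if model_policy != "first_model":
        raise ValueError(f"unknown model_policy {model_policy!r}")
    models = parsed.model_numbers
    first = models[0] if models else 1
    atoms = [a for a in parsed.atoms if a.model_num == first]
    mod_map = parsed.mod_residues.lookup()

    by_asym: dict[str, list[AtomRecord]] = {}
    for a in atoms:
        by_asym.setdefault(a.asym_id, []).append(a)

    result = []
    for defn in parsed.assemblies:
        out_atoms: list[AtomRecord] = []
        provenance: list[ChainProvenance] = []
        used_names: set[str] = set()
        serial = 0
        for expr, asym_ids in defn.generators:
            if not asym_ids:
                raise AssemblyBuildError(
                    f"assembly {defn.assembly_id}: empty asym_id selection for {expr!r}"
                )
            products = parse_oper_expression(expr)
            for product in products:
                op = _resolve_operator(product, parsed.operators)
                for asym_id in asym_ids:
                    if asym_id not in by_asym:
                        continue  # asym units without coordinates (e.g. waters removed upstream)
                    chain_name = _assembly_chain_name(asym_id, product, used_names)
                    used_names.add(chain_name)
                    provenance.append(
                        ChainProvenance(
                            chain_id=chain_name,
                            source_asym_id=asym_id,
                            operator_ids=product,
                        )
                    )
                    for a in by_asym[asym_id]:
                        serial += 1
                        comp = mod_map.get((a.asym_id, a.seq_id, a.comp_id), a.comp_id)
                        out_atoms.append(
                            AtomRecord(
                                serial=serial,
                                name=a.name,
                                element=a.element,
                                comp_id=comp,
                                asym_id=chain_name,
                                seq_id=a.seq_id,
                                icode=a.icode,
                                coords=op.apply(a.coords),
                                occupancy=a.occupancy,
                                altloc=a.altloc,
                                is_polymer=a.is_polymer,
                                model_num=a.model_num,
                            )
                        )
        polymer_types = {
            p.chain_id: parsed.polymer_types[p.source_asym_id]
            for p in provenance
            if p.source_asym_id in parsed.polymer_types
        }
        result.append(
            Assembly(
                pdb_id=parsed.pdb_id,
                assembly_id=defn.assembly_id,
                atoms=out_atoms,
                provenance=provenance,
                resolution=parsed.resolution,
                polymer_types=polymer_types,
            )
        )
    return result


def _assembly_chain_name(asym_id: str, product: tuple[str, ...], used: set[str]) -> str:
    if asym_id not in used:
        return asym_id
    name = f"{asym_id}-{'.'.join(product)}"
    while name in used:
        name += "x"
    return name


def asu_as_assembly(parsed: ParsedStructure) -> Assembly:
    """Treat the asymmetric unit itself as assembly "0" (identity operator)."""
    models = parsed.model_numbers
    first = models[0] if models else 1
    mod_map = parsed.mod_residues.lookup()
    atoms = []
    for a in parsed.atoms:
        if a.model_num != first:
            continue
        comp = mod_map.get((a.asym_id, a.seq_id, a.comp_id), a.comp_id)
        if comp != a.comp_id:
            a = AtomRecord(**{**a.__dict__, "comp_id": comp})
        atoms.append(a)
    provenance = [
        ChainProvenance(chain_id=c, source_asym_id=c, operator_ids=("identity",))
        for c in sorted({a.asym_id for a in atoms})
    ]
    return Assembly(
        pdb_id=parsed.pdb_id,
        assembly_id="0",
        atoms=atoms,
        provenance=provenance,
        resolution=parsed.resolution,
        polymer_types=dict(parsed.polymer_types),
    )


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------


def _poly_type_for_chain(comp_ids: Sequence[str]) -> str:
    n = len(comp_ids)
    n_aa = sum(1 for c in comp_ids if c in STANDARD_AA)
    n_nt = sum(1 for c in comp_ids if c in NUCLEOTIDE_RES)
    if n_nt > n_aa:
        deoxy = all(c.startswith("D") for c in comp_ids if c in NUCLEOTIDE_RES)
        return "polydeoxyribonucleotide" if deoxy else "polyribonucleotide"
    return "polypeptide(L)"


def _atoms_to_cif_block(
    atoms: Sequence[AtomRecord],
    name: str,
    operators: dict[str, TransformOperator] | None = None,
    assemblies: Sequence[AssemblyDefinition] | None = None,
    mod_residues: ModifiedResidueMap | None = None,
) -> CIFBlock:
    block = CIFBlock()

    # entity bookkeeping: one entity per polymer chain, one for all hetero
    chain_entity: dict[str, str] = {}
    entity_rows: list[tuple[str, str]] = []  # (entity_id, poly type)
    chain_residues: dict[str, list[str]] = {}
    for a in atoms:
        if a.is_polymer:
            chain_residues.setdefault(a.asym_id, [])
            if not chain_residues[a.asym_id] or chain_residues[a.asym_id][-1] != a.comp_id:
                chain_residues[a.asym_id].append(a.comp_id)
    next_entity = 1
    for chain, comps in chain_residues.items():
        chain_entity[chain] = str(next_entity)
        entity_rows.append((str(next_entity), _poly_type_for_chain(comps)))
        next_entity += 1
    het_entity = str(next_entity)

    cols: dict[str, list[str]] = {k: [] for k in (
        "group_PDB", "id", "type_symbol", "label_atom_id", "label_alt_id",
        "label_comp_id", "label_asym_id", "label_entity_id", "label_seq_id",
        "pdbx_PDB_ins_code", "Cartn_x", "Cartn_y", "Cartn_z", "occupancy",
        "B_iso_or_equiv", "auth_seq_id", "auth_comp_id", "auth_asym_id",
        "auth_atom_id", "pdbx_PDB_model_num",
    )}
    for i, a in enumerate(atoms, start=1):
        cols["group_PDB"].append("ATOM" if a.is_polymer else "HETATM")
        cols["id"].append(str(i))
        cols["type_symbol"].append(a.element)
        cols["label_atom_id"].append(a.name)
        cols["label_alt_id"].append(a.altloc or ".")
        cols["label_comp_id"].append(a.comp_id)
        cols["label_asym_id"].append(a.asym_id)
        cols["label_entity_id"].append(chain_entity.get(a.asym_id, het_entity))
        cols["label_seq_id"].append(str(a.seq_id) if a.is_polymer else ".")
        cols["pdbx_PDB_ins_code"].append(a.icode or "?")
        cols["Cartn_x"].append(f"{a.coords[0]:.4f}")
        cols["Cartn_y"].append(f"{a.coords[1]:.4f}")
        cols["Cartn_z"].append(f"{a.coords[2]:.4f}")
        cols["occupancy"].append(f"{a.occupancy:.2f}")
        cols["B_iso_or_equiv"].append("0.00")
        cols["auth_seq_id"].append(str(a.seq_id))
        cols["auth_comp_id"].append(a.comp_id)
        cols["auth_asym_id"].append(a.asym_id)
        cols["auth_atom_id"].append(a.name)
        cols["pdbx_PDB_model_num"].append(str(a.model_num))

    if entity_rows:
        block["entity_poly"] = CIFCategory(
            {
                "entity_id": [e for e, _ in entity_rows],
                "type": [t for _, t in entity_rows],
                "pdbx_strand_id": [c for c in chain_residues],
            }
        )
    if operators:
        ids = list(operators)
        cat: dict[str, list[str]] = {"id": ids, "type": ["point symmetry operation"] * len(ids)}
        for r in (1, 2, 3):
            for c in (1, 2, 3):
                cat[f"matrix[{r}][{c}]"] = [f"{operators[i].R[r - 1, c - 1]:.10f}" for i in ids]
            cat[f"vector[{r}]"] = [f"{operators[i].t[r - 1]:.10f}" for i in ids]
        block["pdbx_struct_oper_list"] = CIFCategory(cat)
    if assemblies:
        rows = [
            (d.assembly_id, expr, ",".join(asyms))
            for d in assemblies
            for expr, asyms in d.generators
        ]
        block["pdbx_struct_assembly"] = CIFCategory(
            {"id": sorted({r[0] for r in rows}), "details": ["?"] * len({r[0] for r in rows})}
        )
        block["pdbx_struct_assembly_gen"] = CIFCategory(
            {
                "assembly_id": [r[0] for r in rows],
                "oper_expression": [r[1] for r in rows],
                "asym_id_list": [r[2] for r in rows],
            }
        )
    if mod_residues and mod_residues.entries:
        block["pdbx_struct_mod_residue"] = CIFCategory(
            {
                "id": [str(i + 1) for i in range(len(mod_residues.entries))],
                "label_asym_id": [e[0] for e in mod_residues.entries],
                "auth_seq_id": [str(e[1]) for e in mod_residues.entries],
                "label_comp_id": [e[2] for e in mod_residues.entries],
                "parent_comp_id": [e[3] for e in mod_residues.entries],
            }
        )
    block["atom_site"] = CIFCategory(cols)
    return block


def write_mmcif(
    atoms: Sequence[AtomRecord],
    path: str | Path,
    name: str = "structure",
    operators: dict[str, TransformOperator] | None = None,
    assemblies: Sequence[AssemblyDefinition] | None = None,
    mod_residues: ModifiedResidueMap | None = None,
) -> None:
    cif = CIFFile()
    cif[name] = _atoms_to_cif_block(atoms, name, operators, assemblies, mod_residues)
    cif.write(str(path))


def _pdb_chain_map(chain_ids: Sequence[str]) -> dict[str, str]:
    if len(chain_ids) > PDB_MAX_CHAINS:
        raise PdbCapacityError(
            f"{len(chain_ids)} chains exceed the {PDB_MAX_CHAINS}-chain PDB limit; "
            "use split_for_pdb"
        )
    mapping = {}
    for i, cid in enumerate(chain_ids):
        if len(cid) == 1 and cid not in mapping.values():
            mapping[cid] = cid
    free = [c for c in PDB_CHAIN_ALPHABET if c not in mapping.values()]
    for cid in chain_ids:
        if cid not in mapping:
            mapping[cid] = free.pop(0)
    return mapping


def write_pdb(atoms: Sequence[AtomRecord], path: str | Path) -> dict[str, str]:
    """Write atoms as a single legacy PDB file; returns the chain-ID map."""
    chain_ids = []
    for a in atoms:
        if a.asym_id not in chain_ids:
            chain_ids.append(a.asym_id)
    mapping = _pdb_chain_map(chain_ids)
    with open(path, "w") as fh:
        prev_chain = None
        serial = 0
        for a in atoms:
            serial += 1
            if prev_chain is not None and a.asym_id != prev_chain:
                fh.write("TER\n")
            prev_chain = a.asym_id
            rec = "ATOM  " if a.is_polymer else "HETATM"
            name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
            fh.write(
                f"{rec}{serial % 100000:5d} {name:<4.4s}{a.altloc or ' ':1s}"
                f"{a.comp_id:>3.3s} {mapping[a.asym_id]}{a.seq_id:4d}{a.icode or ' ':1s}   "
                f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
                f"{a.occupancy:6.2f}{0.0:6.2f}          {a.element:>2.2s}\n"
            )
        fh.write("TER\nEND\n")
    return mapping


def write_structure(
    obj: Assembly | Sequence[AtomRecord],
    path: str | Path,
    format: str = "mmcif",
) -> None:
    """Write an assembly (or plain atom list) to mmCIF or legacy PDB.

    PDB output requires at most 62 chains; larger structures must go
    through :func:`split_for_pdb`.
    """
    atoms = obj.atoms if isinstance(obj, Assembly) else list(obj)
    name = obj.pdb_id if isinstance(obj, Assembly) else "structure"
    if format == "mmcif":
        write_mmcif(atoms, path, name=name)
    elif format == "pdb":
        write_pdb(atoms, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def split_for_pdb(
    assembly: Assembly, out_dir: str | Path, basename: str | None = None
) -> tuple[list[Path], list[tuple[str, int, str]]]:
    """Split an assembly into ≤62-chain PDB files plus a chain-ID map.

    Returns the written file paths and mapping rows
    ``(orig_chain, file_index, new_chain)``.  New IDs are assigned in
    ``A–Z a–z 0–9`` order within each file.  The mapping table is also
    written next to the PDB files as ``<basename>.chain_map.tsv``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    basename = basename or f"{assembly.pdb_id}_assembly{assembly.assembly_id}"
    chain_ids = assembly.chain_ids()
    chunks = [
        chain_ids[i : i + PDB_MAX_CHAINS] for i in range(0, len(chain_ids), PDB_MAX_CHAINS)
    ]
    by_chain: dict[str, list[AtomRecord]] = {c: [] for c in chain_ids}
    for a in assembly.atoms:
        by_chain[a.asym_id].append(a)

    paths: list[Path] = []
    mapping: list[tuple[str, int, str]] = []
    for file_index, chunk in enumerate(chunks, start=1):
        new_ids = {c: PDB_CHAIN_ALPHABET[i] for i, c in enumerate(chunk)}
        atoms = []
        for c in chunk:
            for a in by_chain[c]:
                atoms.append(AtomRecord(**{**a.__dict__, "asym_id": new_ids[c]}))
            mapping.append((c, file_index, new_ids[c]))
        path = out_dir / f"{basename}.part{file_index}.pdb"
        write_pdb(atoms, path)
        paths.append(path)

    map_path = out_dir / f"{basename}.chain_map.tsv"
    with open(map_path, "w") as fh:
        fh.write("orig_chain\tfile_index\tnew_chain\n")
        for orig, idx, new in mapping:
            fh.write(f"{orig}\t{idx}\t{new}\n")
    return paths, mapping
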