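"""End-to-end pipeline: assemblies -> annotated interaction entries.

For each input structure, every defined biological assembly is built
(falling back to the asymmetric unit when none is defined), partitioned
into receptor and ligands, and annotated: binding residues on the full
quaternary structure, biological relevance, optional interface area and
affinity.  Entries fall into three categories: relevant, irrelevant, and
structure_only (assemblies lacking a receptor or lacking ligands).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from . import nucleic_pairing, structure_io
from .partition import (
    Ligand,
    PartitionResult,
    Receptor,
    partition_assembly,
)
from .relevance_affinity import (
    AffinityRecord,
    ExclusionList,
    RelevanceVerdict,
    assess_relevance,
    predict_consensus,
)
from .site_annotation import (
    BindingSite,
    InterfaceReport,
    RadiiTable,
    find_binding_residues,
    interface_area,
)

__all__ = [
    "PipelineConfig",
    "InteractionEntry",
    "SingleChainEntry",
    "CorpusSummary",
    "PipelineResult",
    "run_pipeline",
    "process_assembly",
    "split_single_chain",
    "summarize_corpus",
    "export_entries",
]

KIND_ORDER = {"small_molecule": 0, "metal_ion": 1, "peptide": 2, "nucleic": 3}


@dataclass
class PipelineConfig:
    margin: float = 0.5  # Å added to the vdW sum for binding residues
    min_pairs: int = 3  # inter-chain base pairs to join nucleic chains
    identity_threshold: float = 0.95  # stoichiometry chain equivalence
    redundancy_threshold: float = 0.9
    probe_radius: float = 1.4
    n_points: int = 960
    min_site_residues: int = 6
    compute_interface: bool = False  # SASA is costly; opt in
    interface_all_kinds: bool = False  # default: small molecules and ions only
    exclusion_path: str | None = None

    def exclusion_list(self) -> ExclusionList:
        if self.exclusion_path:
            return ExclusionList.from_file(self.exclusion_path)
        from .data import default_exclusion_list

        return default_exclusion_list()

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class InteractionEntry:
    entry_id: str
    pdb_id: str
    assembly_id: str
    category: str  # relevant | irrelevant | structure_only
    receptor: Receptor | None = None
    ligand: Ligand | None = None
    site: BindingSite | None = None
    verdict: RelevanceVerdict | None = None
    interface: InterfaceReport | None = None
    affinities: list[AffinityRecord] = field(default_factory=list)
    resolution: float | None = None

    @property
    def stoichiometry(self) -> str:
        return self.receptor.stoichiometry if self.receptor else ""


@dataclass
class SingleChainEntry:
    parent_entry_id: str
    receptor_chain: str
    ligand_kind: str
    ligand_id: str
    ligand_component: str  # component chain for nucleic ligands, else ligand id
    site: BindingSite


@dataclass
class CorpusSummary:
    counts_by_category: dict[str, int]
    oligomeric_state_hist: dict[int, int]
    homo_hetero_by_state: dict[int, dict[str, int]]
    ligand_kind_counts: dict[str, int]
    multi_chain_ligand_fraction: float


@dataclass
class PipelineResult:
    entries: list[InteractionEntry]
    errors: list[dict] = field(default_factory=list)
    config: PipelineConfig | None = None


def process_assembly(
    assembly: structure_io.Assembly,
    config: PipelineConfig,
    exclusion: ExclusionList,
    radii: RadiiTable | None = None,
    abstract_text: str | None = None,
    dssr_pairs_path: str | None = None,
    score_lookup: dict | None = None,
    affinity_lookup: dict | None = None,
    consensus_model=None,
) -> list[InteractionEntry]:
    """Annotate one assembly into interaction entries."""
    radii = radii or RadiiTable()
    from .partition import extract_chains

    chains, _ = extract_chains(assembly)
    nucleic_chains = [c for c in chains if c.polymer_type in ("dna", "rna", "na_hybrid")]
    if nucleic_chains:
        if dssr_pairs_path:
            pairs = nucleic_pairing.parse_dssr_pairs(
                dssr_pairs_path, known_chains=[c.chain_id for c in nucleic_chains]
            )
        else:
            pairs = nucleic_pairing.detect_base_pairs(nucleic_chains)
        pairing = nucleic_pairing.pair_chains(pairs, nucleic_chains, min_pairs=config.min_pairs)
        groups = [sorted(g) for g in pairing.groups]
    else:
        groups = []

    part = partition_assembly(assembly, nucleic_groups=groups)
    receptor, ligands = part.receptor, part.ligands

    base = f"{assembly.pdb_id}_{assembly.assembly_id}"
    entries: list[InteractionEntry] = []
    if receptor is None or not ligands:
        entries.append(
            InteractionEntry(
                entry_id=f"{base}_0",
                pdb_id=assembly.pdb_id,
                assembly_id=assembly.assembly_id,
                category="structure_only",
                receptor=receptor,
                ligand=ligands[0] if ligands else None,
                resolution=assembly.resolution,
            )
        )
        return entries

    def sort_key(lig: Ligand):
        return (
            KIND_ORDER.get(lig.kind, 9),
            lig.source_chain or (lig.chains[0].chain_id if lig.chains else ""),
            lig.seq_id if lig.seq_id is not None else -1,
            lig.ligand_id,
        )

    serial = 0
    for ligand in sorted(ligands, key=sort_key):
        serial += 1
        site = find_binding_residues(receptor.atoms, ligand.atoms, radii, margin=config.margin)
        verdict = assess_relevance(
            ligand, site, exclusion,
            abstract_text=abstract_text,
            min_site_residues=config.min_site_residues,
        )
        category = "relevant" if verdict.status == "relevant" else "irrelevant"
        iface = None
        if config.compute_interface and (
            config.interface_all_kinds or ligand.kind in ("small_molecule", "metal_ion")
        ):
            iface = interface_area(
                receptor.atoms, ligand.atoms, radii,
                probe=config.probe_radius, n_points=config.n_points,
            )
        affinities = _attach_affinities(
            assembly.pdb_id, ligand, affinity_lookup, score_lookup, consensus_model
        )
        entries.append(
            InteractionEntry(
                entry_id=f"{base}_{serial}",
                pdb_id=assembly.pdb_id,
                assembly_id=assembly.assembly_id,
                category=category,
                receptor=receptor,
                ligand=ligand,
                site=site,
                verdict=verdict,
                interface=iface,
                affinities=affinities,
                resolution=assembly.resolution,
            )
        )
    return entries


def _attach_affinities(pdb_id, ligand, affinity_lookup, score_lookup, model):
    records: list[AffinityRecord] = []
    key = (pdb_id, ligand.ligand_id)
    if affinity_lookup and key in affinity_lookup:
        row = affinity_lookup[key]
        records.append(
            AffinityRecord(kind="experimental", value=row["pkd"],
                           raw=f"{row.get('measure', '?')}={row.get('value', '?')}{row.get('unit', '')}",
                           source=row.get("source", "")))
    if model is not None and score_lookup and key in score_lookup:
        comp = score_lookup[key]
        records.append(
            AffinityRecord(kind="predicted", value=predict_consensus(model, comp),
                           source="consensus", components=tuple(comp)))
    return records


def run_pipeline(
    paths: list[str | Path],
    config: PipelineConfig | None = None,
    **annotation_kwargs,
) -> PipelineResult:
    """Run the full pipeline over mmCIF/PDB inputs.

    Per-file failures are quarantined into the errors report; the run
    continues with the remaining inputs.
    """
    config = config or PipelineConfig()
    exclusion = config.exclusion_list()
    entries: list[InteractionEntry] = []
    errors: list[dict] = []
    for path in paths:
        try:
            parsed = structure_io.parse_structure(path)
            assemblies = structure_io.build_assemblies(parsed)
            if not assemblies:
                assemblies = [structure_io.asu_as_assembly(parsed)]
            for assembly in assemblies:
                entries.extend(
                    process_assembly(assembly, config, exclusion, **annotation_kwargs)
                )
        except Exception as exc:
            errors.append({"path": str(path), "error": f"{type(exc).__name__}: {exc}"})
    return PipelineResult(entries=entries, errors=errors, config=config)


def split_single_chain(entry: InteractionEntry) -> list[SingleChainEntry]:
    """Split a quaternary entry into single-chain (per-receptor-chain) entries.

    One entry per (receptor chain with binding residues x contacting
    ligand unit); nucleic ligands are decomposed into component chains
    and only chains contacting the given receptor chain are kept.  Small
    molecules, ions and peptides stay atomic units.
    """
    if entry.receptor is None or entry.ligand is None or entry.site is None:
        return []
    results: list[SingleChainEntry] = []
    ligand = entry.ligand
    for chain in entry.receptor.chains:
        if ligand.kind == "nucleic":
            for nchain in ligand.chains:
                sub_site = find_binding_residues(chain.atoms, nchain.atoms)
                if sub_site.n_residues:
                    results.append(
                        SingleChainEntry(
                            parent_entry_id=entry.entry_id,
                            receptor_chain=chain.chain_id,
                            ligand_kind="nucleic",
                            ligand_id=ligand.ligand_id,
                            ligand_component=nchain.chain_id,
                            site=sub_site,
                        )
                    )
        else:
            sub_site = entry.site.restricted_to(chain.chain_id)
            if sub_site.n_residues:
                results.append(
                    SingleChainEntry(
                        parent_entry_id=entry.entry_id,
                        receptor_chain=chain.chain_id,
                        ligand_kind=ligand.kind,
                        ligand_id=ligand.ligand_id,
                        ligand_component=ligand.ligand_id,
                        site=sub_site,
                    )
                )
    return results


def summarize_corpus(entries: list[InteractionEntry]) -> CorpusSummary:
    """Corpus statistics; oligomeric/ligand panels cover relevant entries only."""
    if not entries:
        raise ValueError("cannot summarize an empty corpus")
    counts = {"relevant": 0, "irrelevant": 0, "structure_only": 0}
    for e in entries:
        counts[e.category] = counts.get(e.category, 0) + 1

    relevant = [e for e in entries if e.category == "relevant"]
    state_hist: dict[int, int] = {}
    homo_hetero: dict[int, dict[str, int]] = {}
    seen_receptors: set[tuple[str, str]] = set()
    for e in relevant:
        if e.receptor is None:
            continue
        key = (e.pdb_id, e.assembly_id)
        if key in seen_receptors:
            continue
        seen_receptors.add(key)
        state = e.receptor.oligomeric_state
        state_hist[state] = state_hist.get(state, 0) + 1
        # homo when every chain falls in one equivalence group (single letter)
        is_homo = len([c for c in e.stoichiometry if c.isalpha()]) == 1
        bucket = homo_hetero.setdefault(state, {"homo": 0, "hetero": 0})
        bucket["homo" if is_homo else "hetero"] += 1

    kind_counts: dict[str, int] = {}
    multi, total_olig = 0, 0
    for e in relevant:
        if e.ligand is not None:
            kind_counts[e.ligand.kind] = kind_counts.get(e.ligand.kind, 0) + 1
        if e.receptor is not None and e.receptor.oligomeric_state > 1 and e.site is not None:
            total_olig += 1
            if e.site.n_chains_involved > 1:
                multi += 1
    fraction = multi / total_olig if total_olig else 0.0
    return CorpusSummary(
        counts_by_category=counts,
        oligomeric_state_hist=state_hist,
        homo_hetero_by_state=homo_hetero,
        ligand_kind_counts=kind_counts,
        multi_chain_ligand_fraction=fraction,
    )


TSV_COLUMNS = [
    "entry_id", "pdb_id", "assembly_id", "resolution", "stoichiometry",
    "ligand_id", "ligand_kind", "category", "n_binding_residues",
    "n_chains_involved", "interface_S", "affinity_kind", "affinity_value",
]


def _entry_row(e: InteractionEntry) -> dict:
    aff = e.affinities[0] if e.affinities else None
    for a in e.affinities:  # experimental takes precedence in the flat export
        if a.kind == "experimental":
            aff = a
            break
    return {
        "entry_id": e.entry_id,
        "pdb_id": e.pdb_id,
        "assembly_id": e.assembly_id,
        "resolution": f"{e.resolution:.2f}" if e.resolution is not None else "",
        "stoichiometry": e.stoichiometry,
        "ligand_id": e.ligand.ligand_id if e.ligand else "",
        "ligand_kind": e.ligand.kind if e.ligand else "",
        "category": e.category,
        "n_binding_residues": e.site.n_residues if e.site else 0,
        "n_chains_involved": e.site.n_chains_involved if e.site else 0,
        "interface_S": f"{e.interface.S:.2f}" if e.interface else "",
        "affinity_kind": aff.kind if aff else "",
        "affinity_value": f"{aff.value:.2f}" if aff else "",
    }


def export_entries(
    entries: list[InteractionEntry], path: str | Path, format: str = "tsv"
) -> Path:
    """Write entries as TSV (flat Browse-style table) or JSON (lossless superset)."""
    path = Path(path)
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(TSV_COLUMNS) + "\n")
            for e in entries:
                row = _entry_row(e)
                fh.write("\t".join(str(row[c]) for c in TSV_COLUMNS) + "\n")
    elif format == "json":
        payload = []
        for e in entries:
            row = _entry_row(e)
            row.update(
                {
                    "receptor_chains": e.receptor.chain_ids() if e.receptor else [],
                    "ligand_component_chains": (
                        e.ligand.component_chain_ids if e.ligand else []
                    ),
                    "binding_residues": e.site.residues if e.site else [],
                    "verdict": (
                        {"status": e.verdict.status, "rule_fired": e.verdict.rule_fired,
                         "evidence": e.verdict.evidence}
                        if e.verdict else None
                    ),
                    "interface": (
                        {"S": e.interface.S, "S_prot": e.interface.S_prot,
                         "S_lig": e.interface.S_lig, "S_com": e.interface.S_com}
                        if e.interface else None
                    ),
                    "affinities": [
                        {"kind": a.kind, "value": a.value, "raw": a.raw,
                         "source": a.source,
                         "components": list(a.components) if a.components else None}
                        for a in e.affinities
                    ],
                }
            )
            payload.append(row)
        path.write_text(json.dumps(payload, indent=2) + "\n")
    else:
        raise ValueError(f"unknown export format {format!r}")
    return path
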