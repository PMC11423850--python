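# quatbind

A toolkit for building quaternary-structure protein–ligand interaction
datasets from mmCIF asymmetric units:

- **structure_io** — mmCIF/PDB parsing, biological-assembly generation from
  `pdbx_struct_assembly_gen` / `pdbx_struct_oper_list` operators (comma
  lists, ranges, two-factor parenthesized products), modified-residue
  conversion, format conversion, and splitting of >62-chain structures into
  multiple PDB files with a chain-ID map.
- **partition** — receptor extraction (protein chains with ≥ 30 observed
  residues), ligand typing (small molecule / metal ion / peptide / paired
  nucleic group), stoichiometry strings (`A2`, `AB`, …) over >95%-identity
  chain classes.
- **nucleic_pairing** — geometric Watson–Crick base-pair detection (or a
  DSSR output parser), chain grouping by the ≥3 inter-chain base-pair rule
  with the 1–2-nucleotide special case, connected-component multi-chain units.
- **site_annotation** — binding residues by the vdW-sum + 0.5 Å criterion
  (KD-tree accelerated, exact), deterministic Shrake–Rupley SASA, and buried
  interface area S = ½(S_prot + S_lig − S_com).
- **relevance_affinity** — biological-relevance hierarchy over a replaceable
  crystallization-additive exclusion list, affinity normalization to pKd,
  OLS consensus prediction over three docking scores, bootstrap PCC
  comparison.
- **redundancy** — greedy chain clustering and oligomeric-state-aware
  structure deduplication under the any-chain-pair > 0.9 similarity rule.
- **pipeline** / **cli** — orchestration into relevant / irrelevant /
  structure-only entries, per-receptor-chain single-chain splits, corpus
  statistics, TSV/JSON export.
- **fixtures** — synthetic mmCIF structures (ideal B-DNA duplexes,
  operator-built dimers, ion-in-pocket dimers, 100-chain giants, …) and
  linear score/affinity datasets with ground-truth manifests, so the whole
  pipeline is testable offline.

## CLI

```sh
quatbind build input1.cif input2.cif --out entries.tsv    # run the pipeline
quatbind build --show-config                              # print thresholds
quatbind split input.cif --out single_chain.tsv           # single-chain entries
quatbind dedupe chains.fasta --threshold 0.9              # non-redundant sets
quatbind summarize input*.cif                             # corpus statistics
quatbind convert structure.cif --out structure.pdb        # format conversion
quatbind fixtures bdna_duplex --seed 1 --param n_bp=8     # synthetic fixtures
```

Thresholds (contact margin, minimum base pairs, identity and redundancy
thresholds, SASA probe/points, minimum site size) can be set in a TOML file
passed via `--config`.

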