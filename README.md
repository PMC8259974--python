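# unirenum

Renumber macromolecular structure files according to their UniProt sequences.

## The problem

Depositors to the structural archive may number the residues of a protein
chain any way they like: with or without the initiator methionine, with or
without a cleaved signal peptide, with negative numbers or insertion codes
for expression tags and inserted loops. The same kinase domain can therefore
carry its DFG motif at 1153–1155 in one entry and at 1123–1125 in another,
purely because one depositor counted the 30-residue signal peptide and the
other did not. Every residue-level annotation inside the file (secondary
structure, validation records, sites, connectivity) uses that same arbitrary
numbering, which breaks any analysis that compares structures of one protein
or maps sequence-level annotations onto coordinates.

`unirenum` fixes this by replacing the author numbering with the numbering
of the corresponding UniProt sequence, using the residue-by-residue
PDB↔UniProt correspondences distributed by the SIFTS resource at PDBe. It
processes both mmCIF (asymmetric units and PDBe biological assemblies) and
legacy fixed-column PDB files, rewriting every residue-numbered table, and
always keeps a record of the original numbering.

## The renumbering scheme

For each chain with UniProt content in SIFTS, the new number of residue *i*
(1-to-N position `label_seq_id = i`, author number `auth_seq_id`) is

* its UniProt residue number, when SIFTS provides one;
* `offset + i` otherwise (sequence tags, linkers) — `offset` is 50,000 for
  mmCIF output and 5,000 for legacy PDB output, guaranteeing no collision
  with genuine UniProt numbers;
* non-polymer groups (ligands, waters, branched sugars) get
  `60,000 + original number` in mmCIF; in legacy format, where numbers must
  fit four columns, they are instead reassigned the highest numbers still
  free in 1–9999, in descending order.

Chains with no UniProt rows in SIFTS are left untouched. Chimeric chains
mapping to several accessions keep all of them when the UniProt number
ranges do not clash (flag `+`); on a clash the accession covering the most
residues wins (flag `*`), unless it is a listed crystallization chaperone
(GFP_AEQVI, GCN4_YEAST, C562_ECOLX, ENLYS_BPT4, MALE_ECOLI), which defers
to the best non-chaperone accession. Mutated residues keep the structure's
residue type together with the UniProt number.

In mmCIF output the `_pdbx_poly_seq_scheme` table becomes a three-way
correspondence: `seq_id` (1-to-N) ↔ `pdb_seq_num` (new, UniProt-based) ↔
`auth_seq_num` (the numbering of the input file). A `_database_PDB_remark`
(mmCIF) or `REMARK 0` block (legacy) documents the transformation with the
offsets actually used.

## Worked example

The package ships a generator of synthetic SIFTS/mmCIF/legacy triples that
emulate the archive's numbering pathologies. A chain whose author numbering
runs 16 ahead of UniProt (author 18, 19, 20 ... for UniProt residues
2, 3, 4 ... of accession Q9PRK9) with an unobserved three-residue tag and a
zinc ion numbered 5:

```python
from unirenum import (ChainSpec, FixtureSpec, LigandSpec, make_fixture,
                      parse_sifts, resolve_chain_accession,
                      assign_target_numbers, build_replacement_map,
                      read_mmcif, renumber_document, rewrite_seq_scheme)

spec = FixtureSpec(pdb_id="9aa3", chains=(
    ChainSpec(label_chain="A", auth_chain="A", length=12, numbering="offset",
              accession="Q9PRK9", uniprot_start=2, offset=-16,
              tag_length=3, tag_observed=False),
), ligands=(LigandSpec("ZN", 5, "A"),))
triple = make_fixture(spec, seed=11)

records = parse_sifts(triple.sifts_xml.encode(), "9aa3")
chain_map = resolve_chain_accession(records)
plan = assign_target_numbers(records, chain_map, fmt="mmcif")
rmap = build_replacement_map(plan)
doc = read_mmcif(triple.mmcif_text.encode())
renumber_document(doc, rmap, plan)
rewrite_seq_scheme(doc, rmap)

scheme = doc.get_table("_pdbx_poly_seq_scheme")
print(scheme["pdb_seq_num"])   # new numbering
print(scheme["auth_seq_num"])  # original numbering, preserved
```

prints

```
['50001', '50002', '50003', '2', '3', '4', '5', '6', '7', '8', '9', '10']
['?', '?', '?', '-14', '-13', '-12', '-11', '-10', '-9', '-8', '-7', '-6']
```

The three unobserved tag residues got 50,000 + their 1-to-N position, the
mapped residues got their UniProt numbers 2–10, and the original author
numbers (here negative, as tags often are) moved into `auth_seq_num`. In the
coordinates the zinc becomes residue 60005.

## Command line

```bash
unirenum -rfla 1d5t 1bxw 2vl3 5e6h -mmCIF          # ids as arguments
unirenum -rftf input.txt -PDB                       # ids from a text file
unirenum -rfla 2aa3 -mmCIF_assembly -offz           # uncompressed output
```

Inputs are downloaded (three attempts per file, then the entry is skipped
with a log record) into `./mmCIF`, `./PDB`, `./mmCIF_assembly`,
`./PDB_assembly` and `./SIFTS`; outputs named `<id>_renum.cif.gz` /
`<id>_renum.pdb.gz` go to the matching `./output_*` directory, and a
per-chain log (`renumber_log.tsv`) reports, for every chain: the chosen
UniProt accession, chain length, residues in UniProt (`uni_len`), residues
renumbered to UniProt (`renum`), residues given offset numbers
(`5k_or_50k`), and the special-case flag (`+`/`*`). Directories, offsets
(`--set_default_mmCIF_num`, `--set_default_PDB_num`), gzip (`-offz`) and
worker count (`-nproc`) are configurable; `--offline` uses pre-placed files
only.

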