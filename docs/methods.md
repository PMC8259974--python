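# Methods

## Residue correspondence model

The unit of information is one SIFTS residue row (`ResidueRecord`): the
archive chain label (`label_asym_id`), the author chain label
(`auth_asym_id`), the canonical 1-to-N position within the chain construct
(`label_seq_id`), the author residue number with any insertion code, the
3-letter residue name, and — when SIFTS aligns the residue to UniProt — the
accession, UniProt residue number and 1-letter type. SIFTS reports residues
absent from the coordinates with a `null` author number; these are modelled
as *absent* (`None`), never as a sentinel integer, and a `Not_Observed`
annotation is what marks them unobserved. An annotation whose text contains
"mutation" or "conflict" marks the residue as mutated relative to UniProt
(real SIFTS uses strings such as "Engineered mutation" and "Conflict").
The parser matches XML elements by local name, so documents with or without
the SIFTS schema namespace parse identically.

Invariants enforced at construction: `seq_res_num >= 1`; insertion code is
empty or one uppercase letter; accession and UniProt number are present
together or not at all.

## Accession resolution for chimeric chains

Per author chain, candidate accessions are ranked by residue coverage, and
their UniProt number ranges (min..max) are tested pairwise for overlap:

* no overlap anywhere — all accessions are kept and each segment is
  renumbered by its own accession (special-case flag `+`);
* any overlap — the accession covering the most residues wins (flag `*`),
  unless it is in the crystallization-chaperone exception list, in which
  case the best-covering non-excepted accession wins. If *all* candidates
  are excepted, the rule falls back to the full candidate set.

"Collision" is implemented as overlap of the min..max UniProt intervals
(not merely sharing one integer); this is the conservative reading, flagged
here as a design choice. Coverage ties are broken by lexicographically
smallest accession so output is deterministic. The exception list is
configuration — a plain-text file of UniProt IDs, defaulting to the five
common chaperones (GFP_AEQVI, GCN4_YEAST, C562_ECOLX, ENLYS_BPT4,
MALE_ECOLI) — and matches either the accession or its SwissProt-style ID
through an optional accession→ID mapping (SIFTS residue rows do not carry
the ID form).

## Target numbering and offsets

For every residue of a chain with at least one chosen accession:

* UniProt number available under a chosen accession → that number
  (`source=uniprot`); mutated residues keep the structure's residue type;
* otherwise → `offset + seq_res_num` (`source=offset`), with
  `mmcif_offset = 50000` and `legacy_offset = 5000` by default.

A UniProt number `>= offset` raises a collision error instructing a larger
offset; the check uses `>=`, not `>`, so UniProt-derived and offset-derived
numbers are strictly separated in every plan. Chains with no UniProt content
are excluded from the plan and pass through every engine untouched.
Insertion codes are carried through unchanged in both formats; a duplicate
(new number, insertion code) pair within a chain is an error, never a silent
merge.

Non-polymer groups are not in SIFTS and are handled per format:
`ligand_offset_mmcif = 60000` added to the original number in mmCIF; in
legacy output, where numbers must fit four columns, non-polymer groups are
reassigned the highest numbers still free in 1..9999 in descending file
order, "free" meaning not assigned to any polymer residue of the legacy
plan. Waters follow the same non-polymer path (collision-free behaviour
preferred; the choice is otherwise open).

## mmCIF engine

Documents are held as ordered named tables of raw string columns (backed by
gemmi); untouched values round-trip exactly, and no numeric reformatting
ever occurs. A vetted static list of ~50 residue-number items — the children
of `_atom_site.auth_seq_id` in the PDBx dictionary, plus `pdb_seq_num` in
the three sequence-scheme tables and `_struct_ref_seq_dif.pdbx_auth_seq_num`
(which corresponds to `pdb_seq_num`, not the scheme's historical
`auth_seq_num`) — is intersected with the tables present in each document.
Chain-id and insertion-code companion columns are located among
dictionary-conformant variants (`auth_asym_id`, `pdb_strand_id`,
`pdbx_strand_id`; `pdbx_PDB_ins_code` and relatives) sharing the number
column's prefix/suffix; an item without a chain companion is skipped with a
warning. Columns that look like further `auth_seq_id` variants but are not
on the list are logged as novel and left alone — the list is authoritative,
discovery is only a tripwire.

Row rewriting is keyed on (chain id, author number, insertion code).
Keys in the polymer map take the planned number; keys identified as
non-polymer (rows of `_pdbx_nonpoly_scheme`/`_pdbx_branch_scheme`, or
HETATM coordinate rows with no `label_seq_id`) take the ligand offset;
everything else — including `.`/`?` placeholders and unmapped chains — is
untouched. The scheme tables are rewritten last: `pdb_seq_num` is
renumbered (unobserved rows are keyed by their `seq_id` since they have no
author number) and the *original* `pdb_seq_num` values are written into
`auth_seq_num`, discarding that column's historical content, so each row
links 1-to-N ↔ new ↔ original numbering.

A `_database_PDB_remark` entry documents the transformation; its offset
values are substituted from the active configuration so the remark can
never contradict behaviour. Re-running the tool on its own output is
detected through the remark marker and flagged (a second remark is
appended); idempotence is deliberately not claimed, because offset-derived
numbers would be offset again.

Assembly files from PDBe give every symmetry copy a unique `auth_asym_id`
absent from SIFTS. Each assembly chain is matched back to its source chain
by the identical ordered sequence of (author number, insertion code,
residue name); matched chains reuse the source chain's mapping under the
assembly chain id, unmatched chains are logged and left alone.

## Legacy engine

Lines are classified by their record name; ATOM/TER/ANISOU/SIGUIJ/HETATM
carry the residue key in 0-based columns 22:26 (number), 26 (insertion
code), 17:20 (name), 21 (chain); REMARK 465 missing-residue rows in columns
20:26, 26, 15:18, 19. HETATM is included in the classification so the
non-polymer reassignment is reachable. Substitution is key-targeted column
rewriting — never global string replacement, which could corrupt
coincidental matches elsewhere on a line — and a rendered number that would
not fit its column width is an error, never a truncation. The 9-character
replacement keys (number 4 + ins code 1 + name 3 + chain 1) are exposed as
`legacy_key`/`ReplacementMap.legacy_pairs` with values rendered at
identical width. Chains whose target numbers fall outside -999..9999 are
excluded from the legacy map with a warning. The legacy offset is
configurable but values above 9000 warn, since `offset + chain length` must
stay within 9999. The REMARK 0 provenance block, generated from the active
configuration, is inserted at the top of the output.

REMARK 465 rows are matched first by author key; rows for residues with no
author number at all are matched by 1-to-N position. (In the synthetic
fixtures such rows print the 1-to-N position in the number column — a
documented convention, since no author number exists to print.)

## Retrieval

All network access lives behind an injectable fetcher callable (default:
stdlib `urllib`). A download is attempted at most three times; transport
errors are absorbed into the retry count, and after the last failure the
file is assumed absent and the entry is skipped with a log record. Existing
files are reused without refetching. Endpoints (RCSB for asymmetric units,
PDBe for assemblies and SIFTS) are configuration with those defaults.
UniProt identifiers are classified by shape (4 characters with a leading
digit → PDB id; containing `_` → SwissProt-style ID; otherwise accession)
and expanded through a pluggable accession→entries index.

## Synthetic data generator

`fixtures.make_fixture` emits a mutually consistent triple — SIFTS XML,
mmCIF, legacy PDB — plus the ground-truth expectation table computed
directly from the generating rule, independently of the engines. Emulated
features: constant author/UniProt offsets (including the 30-residue
signal-peptide case), expression tags that are unobserved or negatively
numbered, insertion codes, chimeras with overlapping or disjoint accession
ranges, chains without UniProt content, non-polymer ligands, and mutation
annotations. Not emulated: realistic geometry (coordinates are random
points in a 50 Å box), occupancy/altloc complexity, multi-model files,
branched-sugar schemes, and SIFTS segment fragmentation. Passing tests
therefore demonstrate the numbering logic and file surgery, not robustness
to every formatting quirk of real archive files.

Default generator conditions used by the tests and the acceptance script:
chains of 5–150 residues, tags of 3 residues, a 16-position author offset
for the scheme-rewrite scenario, a 30-position offset for the
signal-peptide scenario, chimera segment lengths 80/20 (overlapping) and
35/25 (disjoint), and a single ligand for the reverse-order reassignment
scenario (150-residue chain, so the ligand must receive 9999). These sizes
keep every case hand-checkable while exercising each rule.

## Numerical and degenerate-input choices

* Values are strings end-to-end; only matched residue-number fields are
  rewritten, so untouched columns are byte-identical.
* `.`/`?` placeholders always pass through.
* Empty documents, chains with zero UniProt rows, and empty replacement
  maps are all no-ops rather than errors.
* Offsets must be positive; the collision check is strict (`>=`).
* Per-entry failures in batch mode are isolated; the exit status is 0 when
  at least one entry/format task succeeded, 2 when all failed.
* Parallel batch execution distributes whole entries; outputs are
  per-entry files, so serial and parallel runs are byte-identical.

## Known limitations

* Renumbering is only as good as SIFTS; alignments are trusted as given
  and never re-derived from sequence.
* Legacy output cannot represent UniProt numbers above 9999; such chains
  are left unrenumbered in legacy format (mmCIF is unaffected).
* `label_seq_id`, entity definitions and `_struct_ref` alignments are
  never edited.
* REMARK 470/480 residue lists in legacy files are not rewritten (only
  REMARK 465 is).
* Whole-archive statistics depend on a dated archive snapshot and are out
  of scope here.
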