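"""mmCIF renumbering engine.

Reads a PDBx/mmCIF document (gemmi-backed, values kept as raw strings),
rewrites every author-residue-number item per the replacement map, rewrites
the sequence-scheme tables so the original numbering is preserved in
``auth_seq_num``, inserts a provenance remark, and writes the result as
``<id>_renum.cif[.gz]``.

Which items are renumbered is governed by a vetted static list of mmCIF
items that are children of ``_atom_site.auth_seq_id`` in the PDBx dictionary
(coordinates, validation records, secondary structure, connectivity, sites,
TLS groups, NCS domains, sheet ranges, unobserved-residue lists, and the
``pdb_seq_num`` column of the three sequence-scheme tables).  Columns that
look like further ``auth_seq_id`` variants but are not on the list are
logged, never silently renumbered.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Set, Tuple, Union

import gemmi

from .model import OffsetConfig, RenumberError, RenumberPlan, ReplacementMap

logger = logging.getLogger(__name__)

REMARK_MARKER = "File processed by unirenum"

REMARK_TEMPLATE = """\
{marker}
Author sequence numbering is replaced with UniProt numbering according to
alignment by SIFTS (https://www.ebi.ac.uk/pdbe/docs/sifts/).
Only chains with UniProt sequences in SIFTS are renumbered.
Residues in UniProt chains without UniProt residue numbers in SIFTS
(e.g., sequence tags) are given residue numbers {tag_offset}+label_seq_id
(where label_seq_id is the 1-to-N residue numbering of each chain).
Ligands are numbered {ligand_offset}+their residue number in the original file.
The _pdbx_poly_seq_scheme table contains a correspondence between the
1-to-N sequence (seq_id), the new numbering based on UniProt (pdb_seq_num =
auth_seq_id in the _atom_site records), and the author numbering
in the original mmCIF file from the PDB (auth_seq_num)."""


class MmcifDocument:
    """Ordered named tables of named string columns over a gemmi document.

    Tables are addressed without the trailing dot (``"_atom_site"``); values
    are raw strings throughout (``.`` and ``?`` preserved), so a round trip
    with no edits reproduces every value.
    """

    def __init__(self, doc: gemmi.cif.Document, gzipped: bool = False):
        self._doc = doc
        self.gzipped = gzipped

    @property
    def block(self) -> gemmi.cif.Block:
        return self._doc.sole_block()

    @property
    def entry_id(self) -> str:
        val = self.block.find_value("_entry.id")
        return (val or self.block.name).strip("'\"").lower()

    def table_names(self) -> List[str]:
        return [n.rstrip(".") for n in self.block.get_mmcif_category_names()]

    def has_table(self, name: str) -> bool:
        return name in self.table_names()

    def get_table(self, name: str) -> Dict[str, List[str]]:
        return self.block.get_mmcif_category(name + ".", raw=True)

    def set_table(self, name: str, data: Dict[str, List[str]]) -> None:
        self.block.set_mmcif_category(name + ".", data, raw=True)

    def as_string(self) -> str:
        return self._doc.as_string()


def read_mmcif(source: Union[str, Path, bytes], gzipped: Optional[bool] = None
               ) -> MmcifDocument:
    """Read an mmCIF file (path or bytes, optionally gzipped)."""
    if isinstance(source, (str, Path)):
        data = Path(source).read_bytes()
    else:
        data = source
    was_gz = data[:2] == b"\x1f\x8b" if gzipped is None else gzipped
    if data[:2] == b"\x1f\x8b":
        data = gzip.decompress(data)
    try:
        doc = gemmi.cif.read_string(data.decode())
    except (ValueError, RuntimeError) as exc:
        raise RenumberError(f"mmCIF syntax error: {exc}") from exc
    return MmcifDocument(doc, gzipped=was_gz)


@dataclass(frozen=True)
class RenumberableItem:
    """One residue-number column together with its chain and insertion-code
    companion columns, as present in a concrete document."""

    table: str
    num_col: str
    chain_col: str
    ins_col: Optional[str]
    role: str  # coordinate | annotation | scheme | nonpoly-scheme | branch-scheme


# The vetted list of renumberable residue-number items: (table, column).
# Chain-id and ins-code companions are located among dictionary-conformant
# variants of auth_asym_id / pdb_strand_id / pdbx_strand_id and
# pdbx_PDB_ins_code at enumeration time.
RENUMBERABLE_ITEMS: List[Tuple[str, str, str]] = [
    ("_atom_site_anisotrop", "pdbx_auth_seq_id", "coordinate"),
    ("_atom_site", "auth_seq_id", "coordinate"),
    ("_pdbx_distant_solvent_atoms", "auth_seq_id", "annotation"),
    ("_pdbx_refine_tls_group", "beg_auth_seq_id", "annotation"),
    ("_pdbx_refine_tls_group", "end_auth_seq_id", "annotation"),
    ("_pdbx_struct_chem_comp_diagnostics", "auth_seq_id", "annotation"),
    ("_pdbx_struct_conn_angle", "ptnr1_auth_seq_id", "annotation"),
    ("_pdbx_struct_conn_angle", "ptnr2_auth_seq_id", "annotation"),
    ("_pdbx_struct_conn_angle", "ptnr3_auth_seq_id", "annotation"),
    ("_pdbx_struct_mod_residue", "auth_seq_id", "annotation"),
    ("_pdbx_struct_sheet_hbond", "range_1_auth_seq_id", "annotation"),
    ("_pdbx_struct_sheet_hbond", "range_2_auth_seq_id", "annotation"),
    ("_pdbx_struct_special_symmetry", "auth_seq_id", "annotation"),
    ("_pdbx_unobs_or_zero_occ_atoms", "auth_seq_id", "annotation"),
    ("_pdbx_unobs_or_zero_occ_residues", "auth_seq_id", "annotation"),
    ("_pdbx_validate_chiral", "auth_seq_id", "annotation"),
    ("_pdbx_validate_close_contact", "auth_seq_id_1", "annotation"),
    ("_pdbx_validate_close_contact", "auth_seq_id_2", "annotation"),
    ("_pdbx_validate_main_chain_plane", "auth_seq_id", "annotation"),
    ("_pdbx_validate_peptide_omega", "auth_seq_id_1", "annotation"),
    ("_pdbx_validate_peptide_omega", "auth_seq_id_2", "annotation"),
    ("_pdbx_validate_planes", "auth_seq_id", "annotation"),
    ("_pdbx_validate_polymer_linkage", "auth_seq_id_1", "annotation"),
    ("_pdbx_validate_polymer_linkage", "auth_seq_id_2", "annotation"),
    ("_pdbx_validate_rmsd_angle", "auth_seq_id_1", "annotation"),
    ("_pdbx_validate_rmsd_angle", "auth_seq_id_2", "annotation"),
    ("_pdbx_validate_rmsd_angle", "auth_seq_id_3", "annotation"),
    ("_pdbx_validate_rmsd_bond", "auth_seq_id_1", "annotation"),
    ("_pdbx_validate_rmsd_bond", "auth_seq_id_2", "annotation"),
    ("_pdbx_validate_symm_contact", "auth_seq_id_1", "annotation"),
    ("_pdbx_validate_symm_contact", "auth_seq_id_2", "annotation"),
    ("_pdbx_validate_torsion", "auth_seq_id", "annotation"),
    ("_struct_conf", "beg_auth_seq_id", "annotation"),
    ("_struct_conf", "end_auth_seq_id", "annotation"),
    ("_struct_conn", "ptnr1_auth_seq_id", "annotation"),
    ("_struct_conn", "ptnr2_auth_seq_id", "annotation"),
    ("_struct_mon_prot_cis", "auth_seq_id", "annotation"),
    ("_struct_mon_prot_cis", "pdbx_auth_seq_id_2", "annotation"),
    ("_struct_ncs_dom_lim", "beg_auth_seq_id", "annotation"),
    ("_struct_ncs_dom_lim", "end_auth_seq_id", "annotation"),
    ("_struct_sheet_range", "beg_auth_seq_id", "annotation"),
    ("_struct_sheet_range", "end_auth_seq_id", "annotation"),
    ("_struct_site_gen", "auth_seq_id", "annotation"),
    ("_struct_site", "pdbx_auth_seq_id", "annotation"),
    ("_pdbx_nonpoly_scheme", "pdb_seq_num", "nonpoly-scheme"),
    ("_pdbx_nonpoly_seq_scheme", "pdb_seq_num", "nonpoly-scheme"),
    ("_pdbx_poly_seq_scheme", "pdb_seq_num", "scheme"),
    ("_pdbx_branch_scheme", "pdb_seq_num", "branch-scheme"),
    ("_struct_ref_seq_dif", "pdbx_auth_seq_num", "annotation"),
    ("_struct_ref_seq", "pdbx_auth_seq_align_beg", "annotation"),
    ("_struct_ref_seq", "pdbx_auth_seq_align_end", "annotation"),
]

# Companion columns that do not follow the generic prefix/suffix pattern.
_EXPLICIT_COMPANIONS: Dict[Tuple[str, str], Tuple[List[str], List[str]]] = {
    ("_struct_ref_seq", "pdbx_auth_seq_align_beg"):
        (["pdbx_strand_id"], ["pdbx_seq_align_beg_ins_code"]),
    ("_struct_ref_seq", "pdbx_auth_seq_align_end"):
        (["pdbx_strand_id"], ["pdbx_seq_align_end_ins_code"]),
    ("_struct_ref_seq_dif", "pdbx_auth_seq_num"):
        (["pdbx_pdb_strand_id"], ["pdbx_pdb_ins_code"]),
    ("_struct_site", "pdbx_auth_seq_id"):
        (["pdbx_auth_asym_id"], ["pdbx_auth_ins_code"]),
}


def _companion_candidates(num_col: str) -> Tuple[List[str], List[str]]:
    """Derive chain-id and ins-code column candidates from a residue-number
    column name, reusing its prefix/suffix (e.g. ``beg_auth_seq_id`` ->
    ``beg_auth_asym_id`` / ``pdbx_beg_PDB_ins_code``)."""
    if num_col == "pdb_seq_num":
        return ["pdb_strand_id"], ["pdb_ins_code"]
    pre, _, suf = num_col.partition("auth_seq_id")
    chain = [
        pre + "auth_asym_id" + suf,
        "pdbx_" + pre + "auth_asym_id" + suf,
        pre + "pdbx_auth_asym_id" + suf,
        pre + "pdb_strand_id" + suf,
        pre + "pdbx_strand_id" + suf,
        "auth_asym_id", "pdbx_auth_asym_id", "pdb_strand_id", "pdbx_strand_id",
    ]
    ins = [
        pre + "pdbx_PDB_ins_code" + suf,
        "pdbx_" + pre + "PDB_ins_code" + suf,
        pre + "PDB_ins_code" + suf,
        pre + "pdbx_auth_ins_code" + suf,
        pre + "ins_code" + suf,
        "pdbx_PDB_ins_code", "PDB_ins_code", "pdb_ins_code",
    ]
    return chain, ins


def enumerate_renumberable_items(doc: MmcifDocument) -> List[RenumberableItem]:
    """Intersect the static item list with the tables present in ``doc``.

    Items whose chain-id companion cannot be located are skipped with a
    warning; columns resembling unlisted ``auth_seq_id`` variants are logged
    as novel and left alone.
    """
    items: List[RenumberableItem] = []
    present = set(doc.table_names())
    listed_cols: Set[Tuple[str, str]] = set()
    for table, num_col, role in RENUMBERABLE_ITEMS:
        listed_cols.add((table, num_col))
        if table not in present:
            continue
        data = doc.get_table(table)
        if num_col not in data:
            continue
        chain_cands, ins_cands = _EXPLICIT_COMPANIONS.get(
            (table, num_col)) or _companion_candidates(num_col)
        chain_col = next((c for c in chain_cands if c in data), None)
        if chain_col is None:
            logger.warning("%s.%s: no chain-id companion column; skipped",
                           table, num_col)
            continue
        ins_col = next((c for c in ins_cands if c in data), None)
        items.append(RenumberableItem(table, num_col, chain_col, ins_col, role))
    # dictionary-driven fallback: report novel auth_seq_id variants
    for table in present:
        for col in doc.get_table(table):
            if "auth_seq_id" in col and (table, col) not in listed_cols:
                logger.warning("novel residue-number item %s.%s is not on the "
                               "vetted list; left unrenumbered", table, col)
    return items


def _norm_ins(value: str) -> str:
    return "" if value in (".", "?", "") else value


def _ligand_keys(doc: MmcifDocument) -> Set[Tuple[str, int, str]]:
    """Author identities of non-polymer groups (ligands, waters, sugars):
    rows of the non-polymer/branch scheme tables plus HETATM coordinate rows
    with no 1-to-N position."""
    keys: Set[Tuple[str, int, str]] = set()
    for table in ("_pdbx_nonpoly_scheme", "_pdbx_nonpoly_seq_scheme",
                  "_pdbx_branch_scheme"):
        if not doc.has_table(table):
            continue
        data = doc.get_table(table)
        if "pdb_seq_num" not in data or "pdb_strand_id" not in data:
            continue
        ins_vals = data.get("pdb_ins_code")
        for i, num in enumerate(data["pdb_seq_num"]):
            try:
                n = int(num)
            except ValueError:
                continue
            ins = _norm_ins(ins_vals[i]) if ins_vals else ""
            keys.add((data["pdb_strand_id"][i], n, ins))
    if doc.has_table("_atom_site"):
        data = doc.get_table("_atom_site")
        if "group_PDB" in data and "auth_seq_id" in data and "auth_asym_id" in data:
            seq_vals = data.get("label_seq_id")
            ins_vals = data.get("pdbx_PDB_ins_code")
            for i, grp in enumerate(data["group_PDB"]):
                if grp != "HETATM":
                    continue
                if seq_vals is not None and seq_vals[i] not in (".", "?"):
                    continue  # polymer-linked het residue: handled by the plan
                try:
                    n = int(data["auth_seq_id"][i])
                except ValueError:
                    continue
                ins = _norm_ins(ins_vals[i]) if ins_vals else ""
                keys.add((data["auth_asym_id"][i], n, ins))
    return keys


def renumber_document(doc: MmcifDocument, rmap: ReplacementMap,
                      plan: RenumberPlan,
                      offsets: OffsetConfig = OffsetConfig()
                      ) -> MmcifDocument:
    """Rewrite every coordinate/annotation residue-number item in place.

    Polymer residues found in the replacement map take their planned number;
    non-polymer groups take ``ligand_offset_mmcif + original number``; all
    other rows (unmapped chains, ``.``/``?`` placeholders) pass through
    unchanged.  Scheme tables are handled by :func:`rewrite_seq_scheme`.
    """
    ligands = _ligand_keys(doc)
    plan_chains = set(plan.chains())
    unmatched = 0
    for item in enumerate_renumberable_items(doc):
        if item.role in ("scheme", "nonpoly-scheme", "branch-scheme"):
            continue
        data = doc.get_table(item.table)
        nums = data[item.num_col]
        chains = data[item.chain_col]
        ins_vals = data.get(item.ins_col) if item.ins_col else None
        changed = False
        for i, raw in enumerate(nums):
            if raw in (".", "?"):
                continue
            try:
                num = int(raw)
            except ValueError:
                continue
            ins = _norm_ins(ins_vals[i]) if ins_vals is not None else ""
            key = (chains[i], num, ins)
            entry = rmap.by_author.get(key)
            if entry is not None:
                nums[i] = str(entry.new_number)
                changed = True
            elif key in ligands:
                nums[i] = str(offsets.ligand_offset_mmcif + num)
                changed = True
            elif chains[i] in plan_chains:
                unmatched += 1
        if changed:
            doc.set_table(item.table, data)
    if unmatched:
        logger.info("%d residue references in mapped chains had no "
                    "replacement key", unmatched)
    return doc


def rewrite_seq_scheme(doc: MmcifDocument, rmap: ReplacementMap,
                       offsets: OffsetConfig = OffsetConfig()
                       ) -> MmcifDocument:
    """Renumber ``pdb_seq_num`` in the three scheme tables and preserve the
    original numbering in ``auth_seq_num``.

    After the rewrite each scheme row is a three-way correspondence between
    the 1-to-N position (``seq_id``), the new UniProt-based numbering
    (``pdb_seq_num``), and the numbering of the input file
    (``auth_seq_num``); the historical ``auth_seq_num`` content is discarded.
    """
    for table in ("_pdbx_poly_seq_scheme", "_pdbx_nonpoly_scheme",
                  "_pdbx_nonpoly_seq_scheme", "_pdbx_branch_scheme"):
        if not doc.has_table(table):
            continue
        data = doc.get_table(table)
        if "pdb_seq_num" not in data or "pdb_strand_id" not in data:
            continue
        nonpoly = table != "_pdbx_poly_seq_scheme"
        nums = data["pdb_seq_num"]
        chains = data["pdb_strand_id"]
        ins_vals = data.get("pdb_ins_code")
        seq_vals = data.get("seq_id")
        originals = list(nums)
        for i, raw in enumerate(nums):
            chain = chains[i]
            ins = _norm_ins(ins_vals[i]) if ins_vals else ""
            entry = None
            if raw not in (".", "?"):
                try:
                    entry = rmap.by_author.get((chain, int(raw), ins))
                except ValueError:
                    entry = None
            if entry is None and seq_vals is not None and raw in (".", "?"):
                try:
                    entry = rmap.by_seq.get((chain, int(seq_vals[i])))
                except ValueError:
                    entry = None
            if entry is not None:
                nums[i] = str(entry.new_number)
            elif nonpoly and raw not in (".", "?"):
                try:
                    nums[i] = str(offsets.ligand_offset_mmcif + int(raw))
                except ValueError:
                    pass
        if "auth_seq_num" in data:
            data["auth_seq_num"] = originals
        doc.set_table(table, data)
    return doc


def insert_remark(doc: MmcifDocument,
                  offsets: OffsetConfig = OffsetConfig()) -> bool:
    """Add the provenance remark to ``_database_PDB_remark``.

    Returns True when a remark from a previous run was already present (the
    new remark is still appended so the history is visible, and the repeat
    processing is flagged to the caller).
    """
    text = gemmi.cif.quote(REMARK_TEMPLATE.format(
        marker=REMARK_MARKER,
        tag_offset=offsets.mmcif_offset,
        ligand_offset=offsets.ligand_offset_mmcif))
    already = False
    if doc.has_table("_database_PDB_remark"):
        data = doc.get_table("_database_PDB_remark")
        ids = data.get("id", [])
        texts = data.get("text", [])
        already = any(REMARK_MARKER in t for t in texts)
        if already:
            logger.warning("document was already renumbered once; appending "
                           "a second remark")
        next_id = max((int(i) for i in ids if i.isdigit()), default=0) + 1
        ids.append(str(next_id))
        texts.append(text)
        doc.set_table("_database_PDB_remark", {"id": ids, "text": texts})
    else:
        doc.set_table("_database_PDB_remark", {"id": ["1"], "text": [text]})
    return already


def match_assembly_chains(doc: MmcifDocument, records) -> Dict[str, str]:
    """Match assembly chain ids back to asymmetric-unit author chains.

    PDBe assembly files give every symmetry copy its own unique
    ``auth_asym_id``, so a copy's chain id may not exist in SIFTS.  Each
    assembly chain is matched to the source chain with the identical ordered
    sequence of (author number, ins code, residue name); ambiguous or
    unmatched chains are logged and skipped.
    """
    source_sigs: Dict[tuple, str] = {}
    by_chain: Dict[str, List] = {}
    for rec in records:
        by_chain.setdefault(rec.auth_chain_id, []).append(rec)
    for chain, recs in by_chain.items():
        sig = tuple((r.auth_res_num, r.ins_code, r.res_name)
                    for r in recs if r.auth_res_num is not None)
        source_sigs.setdefault(sig, chain)

    mapping: Dict[str, str] = {}
    if not doc.has_table("_atom_site"):
        return mapping
    data = doc.get_table("_atom_site")
    needed = {"auth_asym_id", "auth_seq_id", "auth_comp_id"}
    if not needed <= set(data):
        return mapping
    ins_vals = data.get("pdbx_PDB_ins_code")
    seq_vals = data.get("label_seq_id")
    asm_sigs: Dict[str, List[tuple]] = {}
    for i, chain in enumerate(data["auth_asym_id"]):
        if seq_vals is not None and seq_vals[i] in (".", "?"):
            continue  # non-polymer
        try:
            num = int(data["auth_seq_id"][i])
        except ValueError:
            continue
        ins = _norm_ins(ins_vals[i]) if ins_vals else ""
        ident = (num, ins, data["auth_comp_id"][i])
        sig = asm_sigs.setdefault(chain, [])
        if not sig or sig[-1] != ident:
            sig.append(ident)
    for chain, sig in asm_sigs.items():
        src = source_sigs.get(tuple(sig))
        if src is None:
            logger.warning("assembly chain %s matches no source chain; "
                           "left unrenumbered", chain)
        else:
            mapping[chain] = src
    return mapping


def records_for_assembly(doc: MmcifDocument, records):
    """Clone SIFTS records under the assembly's chain ids so the standard
    planning path applies to assembly files."""
    from dataclasses import replace

    mapping = match_assembly_chains(doc, records)
    reverse: Dict[str, List[str]] = {}
    for asm, src in mapping.items():
        reverse.setdefault(src, []).append(asm)
    out = []
    for rec in records:
        for asm in reverse.get(rec.auth_chain_id, []):
            out.append(replace(rec, auth_chain_id=asm))
    return out


def output_name(entry_id: str, gzip_on: bool = True,
                assembly: Optional[int] = None) -> str:
    stem = f"{entry_id}-assembly-{assembly}" if assembly else entry_id
    return f"{stem}_renum.cif" + (".gz" if gzip_on else "")


def write_mmcif(doc: MmcifDocument, directory: Union[str, Path],
                entry_id: Optional[str] = None, gzip_on: bool = True,
                assembly: Optional[int] = None) -> Path:
    """Write the document as ``<id>_renum.cif[.gz]`` under ``directory``."""
    entry_id = entry_id or doc.entry_id
    path = Path(directory) / output_name(entry_id, gzip_on, assembly)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = doc.as_string().encode()
    if gzip_on:
        payload = gzip.compress(payload)
    path.write_bytes(payload)
    return path
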