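"""Small helpers to run the full pipeline on a fixture triple in memory."""

from unirenum import legacy as legacy_mod
from unirenum import mmcif as mmcif_mod
from unirenum.model import DEFAULT_CHAPERONE_IDS, OffsetConfig
from unirenum.sifts import (
    assign_target_numbers,
    build_replacement_map,
    parse_sifts,
    resolve_chain_accession,
)


def plan_for(triple, fmt, offsets=OffsetConfig()):
    records = parse_sifts(triple.sifts_xml.encode(), triple.spec.pdb_id)
    chain_map = resolve_chain_accession(records, DEFAULT_CHAPERONE_IDS,
                                        triple.swissprot_names)
    plan = assign_target_numbers(records, chain_map, offsets, fmt)
    return records, chain_map, plan


def run_mmcif(triple, offsets=OffsetConfig()):
    """Parse + resolve + plan + renumber the fixture's mmCIF document."""
    _, _, plan = plan_for(triple, "mmcif", offsets)
    rmap = build_replacement_map(plan, offsets)
    doc = mmcif_mod.read_mmcif(triple.mmcif_text.encode())
    mmcif_mod.renumber_document(doc, rmap, plan, offsets)
    mmcif_mod.rewrite_seq_scheme(doc, rmap, offsets)
    mmcif_mod.insert_remark(doc, offsets)
    return doc, plan


def run_legacy(triple, offsets=OffsetConfig()):
    """Parse + resolve + plan + renumber the fixture's legacy PDB lines."""
    _, _, plan = plan_for(triple, "legacy", offsets)
    rmap = build_replacement_map(plan, offsets)
    lines = legacy_mod.renumber_legacy_file(triple.legacy_lines, rmap, offsets)
    return lines, plan


def atom_site_numbers(doc):
    """(chain, old-row-index) -> auth_seq_id strings of the _atom_site table."""
    data = doc.get_table("_atom_site")
    return list(zip(data["auth_asym_id"], data["auth_comp_id"],
                    data["auth_seq_id"]))
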