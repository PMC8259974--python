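"""Synthetic test triples: SIFTS XML + mmCIF + legacy PDB, mutually consistent.

Real archive entries exhibit a zoo of numbering pathologies: signal-peptide
offsets (mature-protein numbering 30 short of the preprotein), expression
tags with negative or missing author numbers, insertion codes, chimeric
chains fusing two UniProt sequences, unobserved residues, and non-polymer
ligands.  This module generates minimal but schema-valid files exhibiting
any combination of these, together with the ground-truth renumbering
(the expectation table) computed directly from the generating rule, so the
whole pipeline can be exercised and verified without downloads.

Synthetic conventions (documented, deliberate):

* coordinates are random points in a 50 Å box — physically meaningless;
* one CA atom per residue;
* residues unobserved in the coordinates have no author number anywhere; the
  REMARK 465 number column of the legacy file prints their 1-to-N position
  (no author number exists to print).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .model import OffsetConfig, ResidueRecord

AMINO3 = ["ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS",
          "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP",
          "TYR", "VAL"]
AMINO1 = {"ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
          "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
          "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
          "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V"}

NUMBERING_RULES = ("identity", "offset", "signal_peptide", "negative_tag",
                   "insertion_codes", "chimera", "no_uniprot")


@dataclass(frozen=True)
class LigandSpec:
    name: str = "ZN"
    auth_number: int = 500
    chain: str = "A"


@dataclass(frozen=True)
class ChainSpec:
    """One synthetic chain and its author-numbering rule.

    ``offset`` is the amount by which author numbering falls short of
    UniProt numbering (author = UniProt - offset); 30 emulates a cleaved
    signal peptide.  ``tag_length`` N-terminal residues carry no UniProt
    number; unobserved tags (``tag_observed=False``) have no author number
    either, observed tags are numbered ... -1, 0 (the negative-tag case).
    ``chimera`` is (second accession, its residue count, ranges overlap?).
    """

    label_chain: str = "A"
    auth_chain: str = "A"
    length: int = 10
    numbering: str = "identity"
    accession: str = "P00001"
    swissprot_id: Optional[str] = None
    uniprot_start: int = 1
    offset: int = 0
    tag_length: int = 0
    tag_observed: bool = False
    insertion_positions: Tuple[int, ...] = ()
    mutation_positions: Tuple[int, ...] = ()
    chimera: Optional[Tuple[str, int, bool]] = None

    def __post_init__(self) -> None:
        if self.numbering not in NUMBERING_RULES:
            raise ValueError(f"unknown numbering rule {self.numbering!r}")
        if self.tag_length >= self.length:
            raise ValueError("tag longer than chain")
        if self.chimera and self.chimera[1] >= self.length:
            raise ValueError("chimera segment longer than chain")


@dataclass(frozen=True)
class FixtureSpec:
    pdb_id: str = "9abc"
    chains: Tuple[ChainSpec, ...] = (ChainSpec(),)
    ligands: Tuple[LigandSpec, ...] = ()


@dataclass
class SyntheticResidue:
    """Internal per-residue ground truth shared by the three emitted files."""

    label_chain: str
    auth_chain: str
    seq: int
    res_name: str
    auth_num: Optional[int]
    ins: str
    accession: Optional[str]
    uni_num: Optional[int]
    observed: bool
    is_mutation: bool = False
    expected_mmcif: Optional[int] = None   # None: left untouched
    expected_legacy: Optional[int] = None
    expected_source: str = ""


@dataclass
class FixtureTriple:
    """The generated files plus the expectation table for tests."""

    spec: FixtureSpec
    sifts_xml: str
    mmcif_text: str
    legacy_lines: List[str]
    residues: List[SyntheticResidue]
    ligand_expected_mmcif: Dict[Tuple[str, int, str], int] = field(default_factory=dict)
    ligand_expected_legacy: Dict[Tuple[str, int, str], int] = field(default_factory=dict)
    swissprot_names: Dict[str, str] = field(default_factory=dict)

    def records(self) -> List[ResidueRecord]:
        """The ResidueRecord rows an ideal SIFTS parse should yield."""
        out = []
        for r in self.residues:
            out.append(ResidueRecord(
                pdb_chain_id=r.label_chain, auth_chain_id=r.auth_chain,
                seq_res_num=r.seq, res_name=r.res_name,
                auth_res_num=r.auth_num, ins_code=r.ins,
                accession=r.accession, uniprot_res_num=r.uni_num,
                uniprot_res_name=AMINO1.get(r.res_name) if r.accession else None,
                is_mutation=r.is_mutation,
            ))
        return out


def _build_chain(spec: ChainSpec, rng: random.Random) -> List[SyntheticResidue]:
    residues: List[SyntheticResidue] = []
    chim_acc, chim_len, _ = spec.chimera or (None, 0, False)
    first_len = spec.length - chim_len
    ins_letter: Dict[int, int] = {}
    auth_counter = None
    uni = spec.uniprot_start - 1
    chim_uni = (spec.uniprot_start - 1 if spec.chimera and spec.chimera[2]
                else 1000 - 1)
    for seq in range(1, spec.length + 1):
        res_name = AMINO3[rng.randrange(len(AMINO3))]
        in_tag = seq <= spec.tag_length
        accession: Optional[str] = None
        uni_num: Optional[int] = None
        auth_num: Optional[int] = None
        ins = ""
        observed = True
        if spec.numbering == "no_uniprot":
            auth_num = seq
        elif in_tag:
            if spec.numbering == "negative_tag" or spec.tag_observed:
                auth_num = seq - spec.tag_length  # ..., -1, 0
            else:
                observed = False                  # tag absent from coordinates
        elif spec.chimera and seq > first_len:
            accession = chim_acc
            chim_uni += 1
            uni_num = chim_uni
            auth_num = seq  # chimera authors number the construct 1..N
        else:
            accession = spec.accession
            uni += 1
            uni_num = uni
            if spec.numbering == "chimera" or spec.chimera:
                auth_num = seq
            elif spec.numbering == "insertion_codes":
                if seq in spec.insertion_positions and auth_counter is not None:
                    n = ins_letter.get(auth_counter, 0)
                    ins = chr(ord("A") + n)
                    ins_letter[auth_counter] = n + 1
                    auth_num = auth_counter
                else:
                    auth_counter = uni_num if auth_counter is None else auth_counter + 1
                    auth_num = auth_counter
            elif spec.numbering in ("offset", "signal_peptide"):
                auth_num = uni_num - spec.offset
            else:  # identity
                auth_num = uni_num
        residues.append(SyntheticResidue(
            label_chain=spec.label_chain, auth_chain=spec.auth_chain,
            seq=seq, res_name=res_name, auth_num=auth_num, ins=ins,
            accession=accession, uni_num=uni_num, observed=observed,
            is_mutation=seq in spec.mutation_positions,
        ))
    return residues


def _fill_expectations(spec: ChainSpec, residues: List[SyntheticResidue],
                       offsets: OffsetConfig) -> None:
    """Apply the renumbering rule literally to produce the ground truth."""
    if spec.numbering == "no_uniprot":
        return  # chain untouched in both formats
    winners = {spec.accession}
    if spec.chimera:
        acc2, len2, overlap = spec.chimera
        if not overlap:
            winners.add(acc2)
        else:
            # best residue coverage wins; fixture lengths are always distinct
            if len2 > spec.length - len2:
                winners = {acc2}
    for r in residues:
        if r.accession in winners:
            r.expected_mmcif = r.uni_num
            r.expected_legacy = r.uni_num
            r.expected_source = "uniprot"
        else:
            r.expected_mmcif = offsets.mmcif_offset + r.seq
            r.expected_legacy = offsets.legacy_offset + r.seq
            r.expected_source = "offset"


# --- SIFTS XML -------------------------------------------------------------

_SIFTS_NS = "http://www.ebi.ac.uk/pdbe/docs/sifts/eFamily.xsd"


def _sifts_xml(spec: FixtureSpec, residues: Sequence[SyntheticResidue],
               swissprot_names: Dict[str, str]) -> str:
    from lxml import etree

    root = etree.Element(f"{{{_SIFTS_NS}}}entry", nsmap={None: _SIFTS_NS})
    root.set("dbAccessionId", spec.pdb_id)
    by_chain: Dict[str, List[SyntheticResidue]] = {}
    for r in residues:
        by_chain.setdefault(r.label_chain, []).append(r)
    for chain, recs in by_chain.items():
        entity = etree.SubElement(root, f"{{{_SIFTS_NS}}}entity",
                                  type="protein", entityId=chain)
        segment = etree.SubElement(
            entity, f"{{{_SIFTS_NS}}}segment",
            segId=f"{spec.pdb_id}_{chain}_1_{len(recs)}")
        listing = etree.SubElement(segment, f"{{{_SIFTS_NS}}}listResidue")
        for r in recs:
            el = etree.SubElement(listing, f"{{{_SIFTS_NS}}}residue",
                                  dbSource="PDBe", dbCoordSys="PDBe",
                                  dbResNum=str(r.seq), dbResName=r.res_name)
            auth = "null" if r.auth_num is None else f"{r.auth_num}{r.ins}"
            etree.SubElement(el, f"{{{_SIFTS_NS}}}crossRefDb",
                             dbSource="PDB", dbCoordSys="PDBresnum",
                             dbAccessionId=spec.pdb_id,
                             dbResNum=auth, dbResName=r.res_name,
                             dbChainId=r.auth_chain)
            if r.accession is not None:
                etree.SubElement(el, f"{{{_SIFTS_NS}}}crossRefDb",
                                 dbSource="UniProt", dbCoordSys="UniProt",
                                 dbAccessionId=r.accession,
                                 dbResNum=str(r.uni_num),
                                 dbResName=AMINO1[r.res_name])
            if not r.observed:
                detail = etree.SubElement(el, f"{{{_SIFTS_NS}}}residueDetail",
                                          dbSource="PDBe",
                                          property="Annotation")
                detail.text = "Not_Observed"
            if r.is_mutation:
                detail = etree.SubElement(el, f"{{{_SIFTS_NS}}}residueDetail",
                                          dbSource="PDBe",
                                          property="Annotation")
                detail.text = "Engineered mutation"
    return etree.tostring(root, pretty_print=True,
                          xml_declaration=True, encoding="UTF-8").decode()


# --- mmCIF -----------------------------------------------------------------

def _mmcif_text(spec: FixtureSpec, residues: Sequence[SyntheticResidue],
                rng: random.Random) -> str:
    lines = [f"data_{spec.pdb_id}", f"_entry.id   {spec.pdb_id.upper()}", ""]

    entity_of = {c.label_chain: i + 1 for i, c in enumerate(spec.chains)}
    lig_entity0 = len(spec.chains)

    atom_rows = []
    serial = 0
    for r in residues:
        if not r.observed:
            continue
        serial += 1
        x, y, z = (rng.uniform(0, 50) for _ in range(3))
        atom_rows.append(
            f"ATOM {serial} C CA {r.res_name} {r.label_chain} "
            f"{entity_of[r.label_chain]} {r.seq} {r.ins or '?'} "
            f"{x:.3f} {y:.3f} {z:.3f} 1.00 20.00 "
            f"{r.auth_num} {r.res_name} {r.auth_chain} 1")
    for i, lig in enumerate(spec.ligands):
        serial += 1
        x, y, z = (rng.uniform(0, 50) for _ in range(3))
        atom_rows.append(
            f"HETATM {serial} X X1 {lig.name} {chr(ord('a') + i)} "
            f"{lig_entity0 + i + 1} . ? "
            f"{x:.3f} {y:.3f} {z:.3f} 1.00 20.00 "
            f"{lig.auth_number} {lig.name} {lig.chain} 1")
    lines += ["loop_"] + [
        "_atom_site." + c for c in (
            "group_PDB", "id", "type_symbol", "label_atom_id",
            "label_comp_id", "label_asym_id", "label_entity_id",
            "label_seq_id", "pdbx_PDB_ins_code", "Cartn_x", "Cartn_y",
            "Cartn_z", "occupancy", "B_iso_or_equiv", "auth_seq_id",
            "auth_comp_id", "auth_asym_id", "pdbx_PDB_model_num")
    ] + atom_rows + [""]

    scheme_rows = []
    for r in residues:
        pdb_num = str(r.auth_num) if r.auth_num is not None else "?"
        # auth_seq_num deliberately carries historical junk (9000+seq) to
        # exercise the discard-and-preserve rewrite
        scheme_rows.append(
            f"{r.label_chain} {entity_of[r.label_chain]} {r.seq} {r.res_name} "
            f"{r.seq} {pdb_num} {9000 + r.seq} {r.res_name} {r.res_name} "
            f"{r.auth_chain} {r.ins or '.'}")
    lines += ["loop_"] + [
        "_pdbx_poly_seq_scheme." + c for c in (
            "asym_id", "entity_id", "seq_id", "mon_id", "ndb_seq_num",
            "pdb_seq_num", "auth_seq_num", "pdb_mon_id", "auth_mon_id",
            "pdb_strand_id", "pdb_ins_code")
    ] + scheme_rows + [""]

    if spec.ligands:
        lig_rows = []
        for i, lig in enumerate(spec.ligands):
            lig_rows.append(
                f"{chr(ord('a') + i)} {lig_entity0 + i + 1} {lig.name} 1 "
                f"{lig.auth_number} {lig.auth_number} {lig.name} {lig.name} "
                f"{lig.chain} .")
        lines += ["loop_"] + [
            "_pdbx_nonpoly_scheme." + c for c in (
                "asym_id", "entity_id", "mon_id", "ndb_seq_num",
                "pdb_seq_num", "auth_seq_num", "pdb_mon_id", "auth_mon_id",
                "pdb_strand_id", "pdb_ins_code")
        ] + lig_rows + [""]

    # a helix per mapped chain spanning its observed residues, to exercise
    # annotation-table consistency with the coordinates
    conf_rows = []
    for ci, chain in enumerate(spec.chains):
        obs = [r for r in residues
               if r.auth_chain == chain.auth_chain and r.observed
               and r.auth_num is not None]
        if len(obs) < 2:
            continue
        beg, end = obs[0], obs[-1]
        conf_rows.append(
            f"HELX_P HELX_P{ci + 1} {beg.res_name} {beg.auth_chain} "
            f"{beg.auth_num} {beg.ins or '?'} {end.res_name} "
            f"{end.auth_chain} {end.auth_num} {end.ins or '?'} 1")
    if conf_rows:
        lines += ["loop_"] + [
            "_struct_conf." + c for c in (
                "conf_type_id", "id", "beg_auth_comp_id", "beg_auth_asym_id",
                "beg_auth_seq_id", "pdbx_beg_PDB_ins_code",
                "end_auth_comp_id", "end_auth_asym_id", "end_auth_seq_id",
                "pdbx_end_PDB_ins_code", "pdbx_PDB_helix_class")
        ] + conf_rows + [""]

    unobs = [r for r in residues if not r.observed]
    if unobs:
        rows = [f"1 1 {r.auth_chain} {r.res_name} ? ? Y 1" for r in unobs]
        lines += ["loop_"] + [
            "_pdbx_unobs_or_zero_occ_residues." + c for c in (
                "id", "PDB_model_num", "auth_asym_id", "auth_comp_id",
                "auth_seq_id", "PDB_ins_code", "polymer_flag", "occupancy_flag")
        ] + rows + [""]
    return "\n".join(lines)


# --- legacy PDB ------------------------------------------------------------

def _legacy_lines(spec: FixtureSpec, residues: Sequence[SyntheticResidue],
                  rng: random.Random) -> List[str]:
    lines = [
        "HEADER    SYNTHETIC FIXTURE                       01-JAN-20   "
        + spec.pdb_id.upper(),
        "TITLE     SYNTHETIC RENUMBERING FIXTURE",
    ]
    unobs = [r for r in residues if not r.observed]
    if unobs:
        lines += [
            "REMARK 465",
            "REMARK 465 MISSING RESIDUES",
            "REMARK 465   M RES C SSSEQI",
        ]
        for r in unobs:
            # no author number exists; the 1-to-N position is printed
            lines.append(f"REMARK 465     {r.res_name:>3s} {r.auth_chain}"
                         f"{r.seq:>6d}")
    serial = 0
    by_chain: Dict[str, List[SyntheticResidue]] = {}
    for r in residues:
        by_chain.setdefault(r.auth_chain, []).append(r)
    for chain, recs in by_chain.items():
        last = None
        for r in recs:
            if not r.observed or r.auth_num is None:
                continue
            serial += 1
            x, y, z = (rng.uniform(0, 50) for _ in range(3))
            lines.append(
                f"ATOM  {serial:>5d}  CA  {r.res_name:>3s} {chain}"
                f"{r.auth_num:>4d}{r.ins or ' ':1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{20.00:6.2f}"
                f"          {'C':>2s}")
            last = r
        if last is not None:
            serial += 1
            lines.append(
                f"TER   {serial:>5d}      {last.res_name:>3s} {chain}"
                f"{last.auth_num:>4d}{last.ins or ' ':1s}")
    for lig in spec.ligands:
        serial += 1
        x, y, z = (rng.uniform(0, 50) for _ in range(3))
        lines.append(
            f"HETATM{serial:>5d}  X1  {lig.name:>3s} {lig.chain}"
            f"{lig.auth_number:>4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{20.00:6.2f}"
            f"          {'X':>2s}")
    lines.append("END")
    return lines


def make_fixture(spec: FixtureSpec, seed: int = 0,
                 offsets: OffsetConfig = OffsetConfig()) -> FixtureTriple:
    """Generate a consistent SIFTS/mmCIF/legacy triple plus ground truth.

    Deterministic for a given (spec, seed).  The expectation table is
    computed from the generating rule itself, independently of the
    renumbering engines.
    """
    rng = random.Random(seed)
    residues: List[SyntheticResidue] = []
    swissprot_names: Dict[str, str] = {}
    for chain in spec.chains:
        chain_res = _build_chain(chain, rng)
        _fill_expectations(chain, chain_res, offsets)
        residues.extend(chain_res)
        if chain.swissprot_id:
            swissprot_names[chain.accession] = chain.swissprot_id

    triple = FixtureTriple(
        spec=spec,
        sifts_xml=_sifts_xml(spec, residues, swissprot_names),
        mmcif_text=_mmcif_text(spec, residues, random.Random(seed + 1)),
        legacy_lines=_legacy_lines(spec, residues, random.Random(seed + 2)),
        residues=residues,
        swissprot_names=swissprot_names,
    )
    # ligand ground truth: +60,000 in mmCIF; highest free numbers descending
    # in legacy, where "used" numbers are those of renumbered polymers
    used = {r.expected_legacy for r in residues if r.expected_legacy is not None}
    candidate = offsets.legacy_number_cap
    for lig in spec.ligands:
        key = (lig.chain, lig.auth_number, lig.name)
        triple.ligand_expected_mmcif[key] = (offsets.ligand_offset_mmcif
                                             + lig.auth_number)
        while candidate in used:
            candidate -= 1
        triple.ligand_expected_legacy[key] = candidate
        used.add(candidate)
        candidate -= 1
    return triple
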