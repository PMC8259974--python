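"""Core domain types for UniProt-based renumbering of structure files.

The central objects are:

* :class:`ResidueRecord` — one row of the SIFTS residue-level correspondence
  between a PDB chain and (optionally) a UniProt sequence.
* :class:`OffsetConfig` — the collision-free offsets applied to residues that
  have no UniProt number (sequence tags, linkers) and to non-polymer groups.
* :class:`RenumberPlan` — the computed target numbering for every residue of
  every UniProt-bearing chain, with per-chain bookkeeping for the log report.
* :class:`ReplacementMap` — format-specific lookup from the author residue
  identifier to the new number.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

_INS_CODE_RE = re.compile(r"^[A-Z]?$")

#: UniProt IDs of proteins commonly fused as crystallization chaperones.
#: A chimeric chain is never renumbered by one of these when a non-chaperone
#: accession is also present.
DEFAULT_CHAPERONE_IDS = frozenset(
    {"GFP_AEQVI", "GCN4_YEAST", "C562_ECOLX", "ENLYS_BPT4", "MALE_ECOLI"}
)


class RenumberError(Exception):
    """Base class for errors raised by this package."""


class SiftsParseError(RenumberError):
    """The SIFTS XML document could not be parsed."""


class SiftsRecordError(RenumberError):
    """A single SIFTS residue row is malformed (names chain and position)."""


class NumberingCollisionError(RenumberError):
    """A UniProt residue number reaches the offset range; a larger offset is
    required to keep UniProt-derived and offset-derived numbers separated."""


@dataclass(frozen=True)
class ResidueRecord:
    """One SIFTS residue row.

    ``seq_res_num`` is the canonical 1-to-N position of the residue within its
    chain construct (``label_seq_id``).  ``auth_res_num`` is the author number
    from the coordinates; it is ``None`` for residues not observed in the
    coordinates.  ``accession``/``uniprot_res_num`` are present together or
    not at all.
    """

    pdb_chain_id: str
    auth_chain_id: str
    seq_res_num: int
    res_name: str
    auth_res_num: Optional[int] = None
    ins_code: str = ""
    accession: Optional[str] = None
    uniprot_res_num: Optional[int] = None
    uniprot_res_name: Optional[str] = None
    is_mutation: bool = False

    def __post_init__(self) -> None:
        if self.seq_res_num < 1:
            raise ValueError(f"seq_res_num must be >= 1, got {self.seq_res_num}")
        if not _INS_CODE_RE.match(self.ins_code):
            raise ValueError(f"invalid insertion code {self.ins_code!r}")
        if (self.accession is None) != (self.uniprot_res_num is None):
            raise ValueError(
                "accession and uniprot_res_num must be present together "
                f"(chain {self.auth_chain_id}, position {self.seq_res_num})"
            )


@dataclass(frozen=True)
class OffsetConfig:
    """Offsets applied to residues without a UniProt number.

    ``mmcif_offset`` (default 50,000) and ``legacy_offset`` (default 5,000)
    are added to the 1-to-N position of tag/linker residues in UniProt-bearing
    chains.  Non-polymer groups in mmCIF output get ``ligand_offset_mmcif``
    (default 60,000) added to their original number; in legacy output they are
    reassigned the highest free numbers below ``legacy_number_cap`` instead.
    """

    mmcif_offset: int = 50000
    legacy_offset: int = 5000
    ligand_offset_mmcif: int = 60000
    legacy_number_cap: int = 9999

    def __post_init__(self) -> None:
        for name in ("mmcif_offset", "legacy_offset", "ligand_offset_mmcif",
                     "legacy_number_cap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def offset_for(self, fmt: str) -> int:
        if fmt == "mmcif":
            return self.mmcif_offset
        if fmt == "legacy":
            return self.legacy_offset
        raise ValueError(f"unknown format {fmt!r}")


# Special-case flags used in the per-chain log (mirroring the log's SP column).
FLAG_NONE = ""
FLAG_NO_CLASH_MULTI = "+"   # several accessions, non-overlapping ranges: all kept
FLAG_LONGEST_TAKEN = "*"    # overlapping ranges: the best-covering accession kept


@dataclass
class ChainChoice:
    """Resolution outcome for one author chain: which accession(s) drive the
    renumbering, with per-candidate residue coverage."""

    accessions: Tuple[str, ...] = ()
    coverage: Dict[str, int] = field(default_factory=dict)
    flag: str = FLAG_NONE
    swissprot_id: Optional[str] = None

    @property
    def chosen(self) -> Optional[str]:
        """Primary accession (first chosen) or None for unmapped chains."""
        return self.accessions[0] if self.accessions else None


ChainAccessionMap = Dict[str, ChainChoice]

SOURCE_UNIPROT = "uniprot"
SOURCE_OFFSET = "offset"
SOURCE_LIGAND = "ligand"


@dataclass(frozen=True)
class PlanEntry:
    """Target number for one residue, with provenance."""

    pdb_chain_id: str
    auth_chain_id: str
    seq_res_num: int
    res_name: str
    new_number: int
    source: str  # SOURCE_UNIPROT | SOURCE_OFFSET | SOURCE_LIGAND
    auth_res_num: Optional[int] = None
    ins_code: str = ""


@dataclass
class ChainStats:
    """Per-chain accounting for the log report."""

    pdb_chain_id: str = ""
    auth_chain_id: str = ""
    accession: str = ""
    swissprot_id: str = ""
    uni_len: int = 0
    chain_len: int = 0
    count_renumbered: int = 0   # residues renumbered according to UniProt
    count_changed: int = 0      # residues whose number actually changed
    count_offset: int = 0       # residues given offset+seq (the 5k/50k column)
    flag: str = FLAG_NONE


@dataclass
class RenumberPlan:
    """Target numbering for every residue of every renumberable chain.

    Chains with no UniProt content are absent from the plan and left
    untouched downstream.
    """

    fmt: str  # "mmcif" | "legacy"
    entries: List[PlanEntry] = field(default_factory=list)
    chain_stats: Dict[str, ChainStats] = field(default_factory=dict)

    def chains(self) -> List[str]:
        return sorted({e.auth_chain_id for e in self.entries})

    def validate(self) -> None:
        """Assert per-chain injectivity and UniProt/offset range separation."""
        by_chain: Dict[str, List[PlanEntry]] = {}
        for e in self.entries:
            by_chain.setdefault(e.auth_chain_id, []).append(e)
        uni_max = None
        off_min = None
        for chain, entries in by_chain.items():
            seen: Dict[Tuple[int, str], int] = {}
            for e in entries:
                key = (e.new_number, e.ins_code)
                if key in seen:
                    raise RenumberError(
                        f"duplicate target number {key} in chain {chain}"
                    )
                seen[key] = e.seq_res_num
                if e.source == SOURCE_UNIPROT:
                    uni_max = e.new_number if uni_max is None else max(uni_max, e.new_number)
                elif e.source == SOURCE_OFFSET:
                    off_min = e.new_number if off_min is None else min(off_min, e.new_number)
        if uni_max is not None and off_min is not None and uni_max >= off_min:
            raise NumberingCollisionError(
                f"UniProt number {uni_max} reaches the offset range starting at "
                f"{off_min}; increase the offset"
            )


def legacy_key(auth_res_num: int, ins_code: str, res_name: str, chain_id: str) -> str:
    """Render the fixed-width 9-character legacy residue key.

    Layout: residue number (4 columns, right-justified, signed) + insertion
    code (1) + residue name (3, right-justified) + chain id (1).
    """
    if not (-999 <= auth_res_num <= 9999):
        raise ValueError(f"residue number {auth_res_num} not representable in 4 columns")
    return f"{auth_res_num:>4d}{ins_code or ' ':1.1s}{res_name:>3.3s}{chain_id:1.1s}"


@dataclass
class ReplacementMap:
    """Lookup from author residue identity to its target number.

    ``by_author`` keys are ``(auth_chain_id, auth_res_num, ins_code)``;
    ``by_seq`` keys are ``(auth_chain_id, seq_res_num)`` and cover residues
    with no author number (unobserved), used in sequence-scheme and
    REMARK 465 contexts.
    """

    fmt: str
    by_author: Dict[Tuple[str, int, str], PlanEntry] = field(default_factory=dict)
    by_seq: Dict[Tuple[str, int], PlanEntry] = field(default_factory=dict)
    dropped_chains: List[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.by_author) + len(self.by_seq)

    def lookup(self, chain: str, num: int, ins: str) -> Optional[PlanEntry]:
        return self.by_author.get((chain, num, ins))

    def legacy_pairs(self) -> Dict[str, str]:
        """The 9-character key -> 9-character value dictionary for legacy
        files (author identity mapped to the same identity with the new
        number rendered at identical width)."""
        if self.fmt != "legacy":
            raise ValueError("legacy_pairs is only defined for legacy maps")
        pairs: Dict[str, str] = {}
        for (chain, num, ins), entry in self.by_author.items():
            pairs[legacy_key(num, ins, entry.res_name, chain)] = legacy_key(
                entry.new_number, ins, entry.res_name, chain
            )
        return pairs
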