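"""Legacy PDB renumbering by fixed-column key substitution.

The legacy format is 80-column fixed-width text; the residue identity on a
coordinate line occupies columns 23-27 (number + insertion code), 18-20
(residue name) and 22 (chain id) in 1-based counting.  Renumbering rewrites
exactly those columns at identical width, so every output line has the same
length as its input line.

Residues without a UniProt number in a UniProt-bearing chain get
``5000 + seq position`` (configurable); non-polymeric groups (ligands,
waters) are reassigned the highest numbers still free in 1..9999, in
descending order, which cannot collide with any polymer number.
"""

from __future__ import annotations

import gzip
import logging
import re
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple, Union

from .model import (
    OffsetConfig,
    RenumberError,
    ReplacementMap,
)

logger = logging.getLogger(__name__)

KIND_ATOM = "ATOM"
KIND_TER = "TER"
KIND_ANISOU = "ANISOU"
KIND_SIGUIJ = "SIGUIJ"
KIND_HETATM = "HETATM"
KIND_REMARK465 = "REMARK465"
KIND_OTHER = "other"

#: record names whose residue identity sits in the coordinate columns
_COORD_KINDS = (KIND_ATOM, KIND_TER, KIND_ANISOU, KIND_SIGUIJ, KIND_HETATM)

_INT_RE = re.compile(r"^-?\d+$")

LEGACY_REMARK_TEMPLATE = """\
REMARK   0 File processed by unirenum
REMARK   0 Author sequence numbering is replaced with UniProt numbering
REMARK   0 according to alignment by SIFTS
REMARK   0 (https://www.ebi.ac.uk/pdbe/docs/sifts/).
REMARK   0 Only chains with UniProt sequences in SIFTS are renumbered.
REMARK   0 Residues in UniProt chains without UniProt residue numbers in SIFTS
REMARK   0 (e.g., sequence tags) are given residue numbers {tag_offset}+label_seq_id
REMARK   0 (where label_seq_id is the 1-to-N residue numbering of each chain).
REMARK   0 Non-polymeric groups (ligands, waters) are reassigned the highest
REMARK   0 residue numbers still unused in the range 1-{cap}, in descending
REMARK   0 order, so they cannot collide with any polymer residue number."""


def legacy_remark_lines(offsets: OffsetConfig = OffsetConfig()) -> List[str]:
    return LEGACY_REMARK_TEMPLATE.format(
        tag_offset=offsets.legacy_offset, cap=offsets.legacy_number_cap
    ).splitlines()


ResidueKey = Tuple[int, str, str, str]  # (number, ins code, res name, chain)


def classify_and_extract(line: str) -> Tuple[str, Optional[ResidueKey]]:
    """Classify a legacy line and extract its residue key, if any.

    Coordinate records (ATOM/TER/ANISOU/SIGUIJ/HETATM) carry the key in
    columns 22:26 (number), 26 (ins code), 17:20 (name), 21 (chain) of the
    0-based half-open slicing; REMARK 465 missing-residue lines in columns
    20:26, 26, 15:18, 19.  Header and other lines yield no key.
    """
    record = line[:6].strip()
    if record in _COORD_KINDS:
        num_txt = line[22:26].strip()
        if not _INT_RE.match(num_txt):
            return record, None
        ins = line[26:27].strip()
        return record, (int(num_txt), ins, line[17:20].strip(), line[21:22].strip())
    if line.startswith("REMARK 465"):
        num_txt = line[20:26].strip()
        if not _INT_RE.match(num_txt):
            return KIND_REMARK465, None
        ins = line[26:27].strip()
        return KIND_REMARK465, (int(num_txt), ins, line[15:18].strip(),
                                line[19:20].strip())
    return KIND_OTHER, None


def _rewrite_number(line: str, start: int, width: int, new: int) -> str:
    rendered = f"{new:>{width}d}"
    if len(rendered) > width:
        raise RenumberError(
            f"number {new} does not fit {width} columns; offset too large"
        )
    return line[:start] + rendered + line[start + width:]


def hetero_groups(lines: Iterable[str],
                  polymer_keys: Set[Tuple[str, int, str]]
                  ) -> List[ResidueKey]:
    """Distinct non-polymer residue groups (HETATM identity not claimed by
    the polymer plan), in file order."""
    seen: Set[ResidueKey] = set()
    groups: List[ResidueKey] = []
    for line in lines:
        kind, key = classify_and_extract(line)
        if kind != KIND_HETATM or key is None:
            continue
        num, ins, _name, chain = key
        if (chain, num, ins) in polymer_keys:
            continue
        if key not in seen:
            seen.add(key)
            groups.append(key)
    return groups


def reassign_hetero_numbers(groups: Sequence[ResidueKey],
                            used_numbers: Set[int],
                            cap: int = 9999) -> Dict[ResidueKey, int]:
    """Give each non-polymer group, in file order, the largest residue
    number still available in 1..cap (descending, skipping used ones)."""
    assignment: Dict[ResidueKey, int] = {}
    candidate = cap
    for key in groups:
        while candidate >= 1 and candidate in used_numbers:
            candidate -= 1
        if candidate < 1:
            raise RenumberError("no residue numbers left in 1..%d for "
                                "non-polymer groups" % cap)
        assignment[key] = candidate
        used_numbers.add(candidate)
    return assignment


def renumber_legacy(lines: Sequence[str], rmap: ReplacementMap,
                    hetero_map: Optional[Dict[ResidueKey, int]] = None,
                    remark_lines: Optional[Sequence[str]] = None,
                    offsets: OffsetConfig = OffsetConfig()) -> List[str]:
    """Rewrite the residue-number columns of every matched line.

    Polymer residues follow the replacement map; non-polymer groups follow
    ``hetero_map`` (see :func:`reassign_hetero_numbers`).  REMARK 465 rows
    are matched first by author key, then — for residues with no author
    number — by their 1-to-N position.  The provenance REMARK 0 block is
    inserted at the top.  Lines never change length.
    """
    if hetero_map is None:
        hetero_map = {}
    if remark_lines is None:
        remark_lines = legacy_remark_lines(offsets)
    out: List[str] = list(remark_lines)
    unmatched = 0
    for line in lines:
        kind, key = classify_and_extract(line)
        if key is not None:
            num, ins, name, chain = key
            new: Optional[int] = None
            entry = rmap.by_author.get((chain, num, ins))
            if entry is not None:
                new = entry.new_number
            elif kind == KIND_REMARK465:
                seq_entry = rmap.by_seq.get((chain, num))
                if seq_entry is not None and seq_entry.auth_res_num is None:
                    new = seq_entry.new_number
            elif key in hetero_map:
                new = hetero_map[key]
            if new is not None:
                start, width = (20, 6) if kind == KIND_REMARK465 else (22, 4)
                line = _rewrite_number(line, start, width, new)
            elif kind in _COORD_KINDS:
                unmatched += 1
        out.append(line)
    if unmatched:
        logger.debug("%d coordinate lines had no replacement key", unmatched)
    return out


def renumber_legacy_file(lines: Sequence[str], rmap: ReplacementMap,
                         offsets: OffsetConfig = OffsetConfig()) -> List[str]:
    """Full legacy pipeline for one file: scan non-polymer groups, reassign
    their numbers in reverse order, then rewrite every line."""
    polymer_keys = set(rmap.by_author)
    groups = hetero_groups(lines, polymer_keys)
    used = {e.new_number for e in rmap.by_author.values()}
    used |= {e.new_number for e in rmap.by_seq.values()}
    hetero_map = reassign_hetero_numbers(groups, used,
                                         cap=offsets.legacy_number_cap)
    return renumber_legacy(lines, rmap, hetero_map, offsets=offsets)


def output_name(entry_id: str, gzip_on: bool = True,
                assembly: Optional[int] = None) -> str:
    suffix = f".pdb{assembly}" if assembly else ".pdb"
    return f"{entry_id}_renum{suffix}" + (".gz" if gzip_on else "")


def read_legacy(source: Union[str, Path, bytes]) -> List[str]:
    """Read a legacy PDB file (path or bytes, optionally gzipped) into
    newline-stripped lines."""
    data = Path(source).read_bytes() if isinstance(source, (str, Path)) else source
    if data[:2] == b"\x1f\x8b":
        data = gzip.decompress(data)
    return data.decode().splitlines()


def write_legacy(lines: Sequence[str], directory: Union[str, Path],
                 entry_id: str, gzip_on: bool = True,
                 assembly: Optional[int] = None) -> Path:
    path = Path(directory) / output_name(entry_id, gzip_on, assembly)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = ("\n".join(lines) + "\n").encode()
    if gzip_on:
        payload = gzip.compress(payload)
    path.write_bytes(payload)
    return path
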