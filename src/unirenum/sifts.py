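"""SIFTS residue-level mapping: parsing, accession resolution, numbering plan.

SIFTS (https://www.ebi.ac.uk/pdbe/docs/sifts/) distributes one XML file per
PDB entry with a residue-by-residue correspondence between the deposited
coordinates and UniProt sequences.  This module turns that document into
:class:`~unirenum.model.ResidueRecord` rows, chooses which UniProt accession
drives the renumbering of each chain (chimeras, crystallization chaperones),
and computes the target number for every residue:

* residues with a UniProt number under the chosen accession keep that number;
* residues of UniProt-bearing chains without a UniProt number (sequence tags,
  linkers) get ``offset + seq_res_num`` — 50,000 for mmCIF output, 5,000 for
  legacy PDB output by default — which guarantees no collision with genuine
  UniProt numbers;
* chains with no UniProt content are excluded and left untouched downstream.
"""

from __future__ import annotations

import gzip
import logging
import re
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple, Union

from lxml import etree

from .model import (
    FLAG_LONGEST_TAKEN,
    FLAG_NO_CLASH_MULTI,
    FLAG_NONE,
    SOURCE_OFFSET,
    SOURCE_UNIPROT,
    ChainAccessionMap,
    ChainChoice,
    ChainStats,
    NumberingCollisionError,
    OffsetConfig,
    PlanEntry,
    RenumberError,
    RenumberPlan,
    ReplacementMap,
    ResidueRecord,
    SiftsParseError,
    SiftsRecordError,
)

logger = logging.getLogger(__name__)

_AUTH_NUM_RE = re.compile(r"^(-?\d+)([A-Z]?)$")
_MUTATION_RE = re.compile(r"mutation|conflict", re.IGNORECASE)


def _localname(element: etree._Element) -> str:
    return etree.QName(element).localname


def _parse_auth_number(text: Optional[str], chain: str, pos: int
                       ) -> Tuple[Optional[int], str]:
    """Split an author number like ``"100A"`` or ``"-2"`` into (number, ins
    code); ``"null"``/empty means the residue is not observed."""
    if text is None or text.lower() == "null" or text == "":
        return None, ""
    m = _AUTH_NUM_RE.match(text)
    if not m:
        raise SiftsRecordError(
            f"chain {chain}, position {pos}: author residue number {text!r} "
            "is neither an integer (with optional insertion letter) nor null"
        )
    return int(m.group(1)), m.group(2)


def parse_sifts(source: Union[str, Path, bytes], entry_id: str = "?"
                ) -> List[ResidueRecord]:
    """Parse a SIFTS per-entry residue-level XML document.

    ``source`` may be a path (optionally gzipped) or raw XML bytes.  Returns
    one record per polymer residue of every protein chain, in document order.
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        entry_id = entry_id if entry_id != "?" else path.name.split(".")[0]
        data = path.read_bytes()
    else:
        data = source
    if data[:2] == b"\x1f\x8b":
        data = gzip.decompress(data)
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise SiftsParseError(f"malformed SIFTS XML for entry {entry_id}: {exc}") from exc

    records: List[ResidueRecord] = []
    for entity in root.iter():
        if _localname(entity) != "entity":
            continue
        if entity.get("type") not in (None, "protein"):
            continue
        pdb_chain = entity.get("entityId", "?")
        for residue in entity.iter():
            if _localname(residue) != "residue":
                continue
            seq_txt = residue.get("dbResNum")
            res_name = residue.get("dbResName", "UNK")
            try:
                seq = int(seq_txt)
            except (TypeError, ValueError):
                raise SiftsRecordError(
                    f"chain {pdb_chain}: non-integer 1-to-N position {seq_txt!r}"
                )
            auth_chain = pdb_chain
            auth_num: Optional[int] = None
            ins = ""
            accession = uni_name = None
            uni_num: Optional[int] = None
            is_mut = False
            for child in residue:
                name = _localname(child)
                if name == "crossRefDb":
                    src = child.get("dbSource")
                    if src == "PDB":
                        auth_chain = child.get("dbChainId", auth_chain)
                        auth_num, ins = _parse_auth_number(
                            child.get("dbResNum"), pdb_chain, seq)
                        res_name = child.get("dbResName", res_name)
                    elif src == "UniProt":
                        accession = child.get("dbAccessionId")
                        num_txt = child.get("dbResNum")
                        uni_num = int(num_txt) if num_txt else None
                        uni_name = child.get("dbResName")
                elif name == "residueDetail":
                    text = child.text or ""
                    if child.get("property") == "Annotation":
                        if _MUTATION_RE.search(text):
                            is_mut = True
            if accession is not None and uni_num is None:
                accession = None  # incomplete UniProt row: treat as unmapped
                uni_name = None
            records.append(ResidueRecord(
                pdb_chain_id=pdb_chain,
                auth_chain_id=auth_chain,
                seq_res_num=seq,
                res_name=res_name,
                auth_res_num=auth_num,
                ins_code=ins,
                accession=accession,
                uniprot_res_num=uni_num,
                uniprot_res_name=uni_name,
                is_mutation=is_mut,
            ))
    return records


def load_exception_list(path: Union[str, Path]) -> Set[str]:
    """Read a plain-text chaperone exception list (one UniProt ID or
    accession per line; '#' comments allowed)."""
    ids: Set[str] = set()
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            ids.add(line)
    return ids


def _ranges_overlap(a: Tuple[int, int], b: Tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def resolve_chain_accession(
    records: Sequence[ResidueRecord],
    chaperone_exceptions: Iterable[str] = (),
    swissprot_names: Optional[Dict[str, str]] = None,
) -> ChainAccessionMap:
    """Choose the accession(s) that renumber each author chain.

    Chimeric chains carry residues from several accessions.  When the UniProt
    number ranges of the candidates do not overlap, all are kept and each
    segment is renumbered by its own accession (flag ``+``).  When ranges
    overlap, the accession covering the most residues wins (flag ``*``) —
    unless it is a listed crystallization chaperone, in which case the
    best-covering non-chaperone accession is taken.  Equal coverage is broken
    by lexicographic accession order so output is deterministic.
    """
    exceptions = set(chaperone_exceptions)
    names = swissprot_names or {}
    chain_map: ChainAccessionMap = {}
    by_chain: Dict[str, List[ResidueRecord]] = {}
    for rec in records:
        by_chain.setdefault(rec.auth_chain_id, []).append(rec)

    for chain, recs in by_chain.items():
        coverage: Dict[str, int] = {}
        ranges: Dict[str, Tuple[int, int]] = {}
        for rec in recs:
            if rec.accession is None:
                continue
            coverage[rec.accession] = coverage.get(rec.accession, 0) + 1
            lo, hi = ranges.get(rec.accession, (rec.uniprot_res_num,
                                                rec.uniprot_res_num))
            ranges[rec.accession] = (min(lo, rec.uniprot_res_num),
                                     max(hi, rec.uniprot_res_num))

        def _name(acc: str) -> Optional[str]:
            return names.get(acc)

        if not coverage:
            chain_map[chain] = ChainChoice()
            continue
        accs = sorted(coverage)
        if len(accs) == 1:
            acc = accs[0]
            chain_map[chain] = ChainChoice((acc,), coverage, FLAG_NONE, _name(acc))
            continue
        overlap = any(
            _ranges_overlap(ranges[a], ranges[b])
            for i, a in enumerate(accs) for b in accs[i + 1:]
        )
        if not overlap:
            chain_map[chain] = ChainChoice(tuple(accs), coverage,
                                           FLAG_NO_CLASH_MULTI)
            logger.info("chain %s: %d accessions with disjoint ranges kept",
                        chain, len(accs))
            continue

        def _is_chaperone(acc: str) -> bool:
            return acc in exceptions or names.get(acc) in exceptions

        pool = [a for a in accs if not _is_chaperone(a)] or accs
        # best coverage wins; coverage ties broken by lexicographic order
        best = min(pool, key=lambda a: (-coverage[a], a))
        chain_map[chain] = ChainChoice((best,), coverage, FLAG_LONGEST_TAKEN,
                                       _name(best))
        logger.info("chain %s: overlapping accessions %s -> %s taken",
                    chain, accs, best)
    return chain_map


def assign_target_numbers(
    records: Sequence[ResidueRecord],
    chain_map: ChainAccessionMap,
    offsets: OffsetConfig = OffsetConfig(),
    fmt: str = "mmcif",
) -> RenumberPlan:
    """Compute the target number for every residue of every mapped chain.

    Residues whose accession is among the chain's chosen accessions keep
    their UniProt number (mutated residues keep the structure's residue type
    with the UniProt number); all other residues of such chains get
    ``offset + seq_res_num``.  Unmapped chains are excluded from the plan.
    A UniProt number at or above the active offset raises
    :class:`NumberingCollisionError` (choose a larger offset).
    """
    offset = offsets.offset_for(fmt)
    plan = RenumberPlan(fmt=fmt)
    by_chain: Dict[str, List[ResidueRecord]] = {}
    for rec in records:
        by_chain.setdefault(rec.auth_chain_id, []).append(rec)

    for chain, recs in by_chain.items():
        choice = chain_map.get(chain)
        if choice is None:
            raise RenumberError(f"chain {chain} missing from accession map")
        if not choice.accessions:
            continue  # no UniProt content: chain is not renumbered
        chosen = set(choice.accessions)
        stats = ChainStats(
            pdb_chain_id=recs[0].pdb_chain_id,
            auth_chain_id=chain,
            accession=choice.chosen or "",
            swissprot_id=choice.swissprot_id or "",
            chain_len=len(recs),
            flag=choice.flag,
        )
        for rec in recs:
            if rec.accession in chosen and rec.uniprot_res_num is not None:
                new, source = rec.uniprot_res_num, SOURCE_UNIPROT
                if new >= offset:
                    raise NumberingCollisionError(
                        f"chain {chain}: UniProt number {new} >= offset "
                        f"{offset}; increase the offset"
                    )
                stats.uni_len += 1
                stats.count_renumbered += 1
                if rec.auth_res_num != new or rec.ins_code:
                    stats.count_changed += 1
            else:
                new, source = offset + rec.seq_res_num, SOURCE_OFFSET
                stats.count_offset += 1
                stats.count_changed += 1
            plan.entries.append(PlanEntry(
                pdb_chain_id=rec.pdb_chain_id,
                auth_chain_id=chain,
                seq_res_num=rec.seq_res_num,
                res_name=rec.res_name,
                new_number=new,
                source=source,
                auth_res_num=rec.auth_res_num,
                ins_code=rec.ins_code,
            ))
        plan.chain_stats[chain] = stats
    plan.validate()
    return plan


def build_replacement_map(plan: RenumberPlan,
                          offsets: OffsetConfig = OffsetConfig()
                          ) -> ReplacementMap:
    """Index the plan by author residue identity for the file editors.

    Observed residues are keyed by ``(chain, author number, ins code)``;
    unobserved residues (no author number) by ``(chain, seq position)`` for
    sequence-scheme and REMARK 465 contexts.  In legacy format, chains whose
    target numbers do not fit 4 columns are dropped with a warning.
    """
    rmap = ReplacementMap(fmt=plan.fmt)
    if plan.fmt == "legacy":
        bad = sorted({
            e.auth_chain_id for e in plan.entries
            if e.new_number > offsets.legacy_number_cap or e.new_number < -999
        })
        if bad:
            logger.warning(
                "chains %s have numbers outside the 4-column legacy range; "
                "left unrenumbered in legacy output", bad)
        rmap.dropped_chains = bad
    for e in plan.entries:
        if e.auth_chain_id in rmap.dropped_chains:
            continue
        if e.auth_res_num is not None:
            key = (e.auth_chain_id, e.auth_res_num, e.ins_code)
            if key in rmap.by_author:
                raise RenumberError(f"duplicate author key {key}")
            rmap.by_author[key] = e
        rmap.by_seq[(e.auth_chain_id, e.seq_res_num)] = e
    return rmap
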