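"""Batch renumbering driver: per-entry pipeline, per-chain log report.

Each requested entry is processed independently (a failing entry never
aborts the batch): locate/fetch the structure and SIFTS inputs, parse the
SIFTS mapping, resolve accessions, compute the plan for the requested
format, rewrite the file, and emit one report row per chain.  Work can be
distributed over processes; outputs are per-entry files, so parallel and
serial runs produce identical results.
"""

from __future__ import annotations

import logging
import multiprocessing
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from . import legacy as legacy_mod
from . import mmcif as mmcif_mod
from .model import DEFAULT_CHAPERONE_IDS, OffsetConfig
from .retrieval import (
    KIND_MMCIF,
    KIND_MMCIF_ASSEMBLY,
    KIND_PDB,
    KIND_PDB_ASSEMBLY,
    KIND_SIFTS,
    input_filename,
)
from .sifts import (
    assign_target_numbers,
    build_replacement_map,
    parse_sifts,
    resolve_chain_accession,
)

logger = logging.getLogger(__name__)

REPORT_COLUMNS = ["PDB_id", "chain_PDB", "chain_auth", "UniProt", "SwissProt",
                  "uni_len", "chain_len", "renum", "5k_or_50k", "SP"]

FORMAT_KINDS = (KIND_MMCIF, KIND_PDB, KIND_MMCIF_ASSEMBLY, KIND_PDB_ASSEMBLY)


@dataclass
class BatchConfig:
    """Paths, offsets and switches for one batch run."""

    input_paths: Dict[str, Path] = field(default_factory=dict)
    output_paths: Dict[str, Path] = field(default_factory=dict)
    offsets: OffsetConfig = field(default_factory=OffsetConfig)
    gzip_output: bool = True
    chaperone_exceptions: frozenset = DEFAULT_CHAPERONE_IDS
    swissprot_names: Dict[str, str] = field(default_factory=dict)
    nproc: int = 1

    @classmethod
    def with_root(cls, root: Path, **kwargs) -> "BatchConfig":
        """Default directory layout under ``root``: inputs in mmCIF/, PDB/,
        mmCIF_assembly/, PDB_assembly/, SIFTS/; outputs in output_<kind>/."""
        root = Path(root)
        input_paths = {k: root / k for k in FORMAT_KINDS + (KIND_SIFTS,)}
        output_paths = {k: root / f"output_{k}" for k in FORMAT_KINDS}
        return cls(input_paths=input_paths, output_paths=output_paths, **kwargs)


@dataclass
class EntryResult:
    pdb_id: str
    fmt_kind: str
    status: str                  # ok | no_sifts | no_uniprot | error
    outputs: List[Path] = field(default_factory=list)
    report_rows: List[Dict] = field(default_factory=list)
    message: str = ""


def _find_input(directory: Path, kind: str, pdb_id: str) -> Optional[Path]:
    name = input_filename(kind, pdb_id)
    for candidate in (directory / name, directory / name.removesuffix(".gz")):
        if candidate.exists():
            return candidate
    return None


def _report_rows(pdb_id: str, plan, chain_map, records) -> List[Dict]:
    rows = []
    seen = set()
    by_chain: Dict[str, List] = {}
    for rec in records:
        by_chain.setdefault(rec.auth_chain_id, []).append(rec)
    for chain, stats in plan.chain_stats.items():
        seen.add(chain)
        rows.append({
            "PDB_id": pdb_id, "chain_PDB": stats.pdb_chain_id,
            "chain_auth": chain, "UniProt": stats.accession,
            "SwissProt": stats.swissprot_id or "",
            "uni_len": stats.uni_len, "chain_len": stats.chain_len,
            "renum": stats.count_renumbered,
            "5k_or_50k": stats.count_offset, "SP": stats.flag,
        })
    for chain, recs in by_chain.items():
        if chain in seen:
            continue
        rows.append({
            "PDB_id": pdb_id, "chain_PDB": recs[0].pdb_chain_id,
            "chain_auth": chain, "UniProt": "", "SwissProt": "",
            "uni_len": 0, "chain_len": len(recs), "renum": 0,
            "5k_or_50k": 0, "SP": "",
        })
    return rows


def process_entry(pdb_id: str, fmt_kind: str, config: BatchConfig
                  ) -> EntryResult:
    """Renumber one entry in one output format.  Never raises; failures are
    reported in the result status."""
    try:
        return _process_entry(pdb_id, fmt_kind, config)
    except Exception as exc:  # per-entry isolation
        logger.exception("entry %s (%s) failed", pdb_id, fmt_kind)
        return EntryResult(pdb_id, fmt_kind, "error", message=str(exc))


def _process_entry(pdb_id: str, fmt_kind: str, config: BatchConfig
                   ) -> EntryResult:
    sifts_path = _find_input(config.input_paths[KIND_SIFTS], KIND_SIFTS, pdb_id)
    if sifts_path is None:
        logger.warning("entry %s: no SIFTS file; not renumbered", pdb_id)
        return EntryResult(pdb_id, fmt_kind, "no_sifts",
                           message="no SIFTS file")
    records = parse_sifts(sifts_path, entry_id=pdb_id)
    chain_map = resolve_chain_accession(records, config.chaperone_exceptions,
                                        config.swissprot_names)
    if not any(c.accessions for c in chain_map.values()):
        return EntryResult(pdb_id, fmt_kind, "no_uniprot",
                           message="no UniProt content in SIFTS",
                           report_rows=_report_rows(
                               pdb_id,
                               assign_target_numbers(records, chain_map,
                                                     config.offsets, "mmcif"),
                               chain_map, records))

    struct_path = _find_input(config.input_paths[fmt_kind], fmt_kind, pdb_id)
    if struct_path is None:
        return EntryResult(pdb_id, fmt_kind, "error",
                           message=f"no {fmt_kind} input file")
    out_dir = config.output_paths[fmt_kind]
    assembly = 1 if fmt_kind in (KIND_MMCIF_ASSEMBLY, KIND_PDB_ASSEMBLY) else None

    if fmt_kind in (KIND_MMCIF, KIND_MMCIF_ASSEMBLY):
        doc = mmcif_mod.read_mmcif(struct_path)
        eff_records = records
        if fmt_kind == KIND_MMCIF_ASSEMBLY:
            eff_records = mmcif_mod.records_for_assembly(doc, records)
            chain_map = resolve_chain_accession(
                eff_records, config.chaperone_exceptions,
                config.swissprot_names)
        plan = assign_target_numbers(eff_records, chain_map, config.offsets,
                                     "mmcif")
        rmap = build_replacement_map(plan, config.offsets)
        mmcif_mod.renumber_document(doc, rmap, plan, config.offsets)
        mmcif_mod.rewrite_seq_scheme(doc, rmap, config.offsets)
        mmcif_mod.insert_remark(doc, config.offsets)
        out = mmcif_mod.write_mmcif(doc, out_dir, pdb_id, config.gzip_output,
                                    assembly)
    else:
        lines = legacy_mod.read_legacy(struct_path)
        plan = assign_target_numbers(records, chain_map, config.offsets,
                                     "legacy")
        rmap = build_replacement_map(plan, config.offsets)
        new_lines = legacy_mod.renumber_legacy_file(lines, rmap, config.offsets)
        out = legacy_mod.write_legacy(new_lines, out_dir, pdb_id,
                                      config.gzip_output, assembly)
    rows = _report_rows(pdb_id, plan, chain_map, records)
    return EntryResult(pdb_id, fmt_kind, "ok", outputs=[out],
                       report_rows=rows)


def _worker(args: Tuple[str, str, BatchConfig]) -> EntryResult:
    return process_entry(*args)


def run_batch(pdb_ids: Sequence[str], fmt_kinds: Sequence[str],
              config: BatchConfig,
              log_path: Optional[Path] = None
              ) -> Tuple[List[EntryResult], pd.DataFrame]:
    """Process every (entry, format) pair and write the per-chain log TSV.

    With ``config.nproc > 1`` entries are distributed over a process pool;
    results are ordered as submitted, so outputs and the log are identical
    to a serial run.
    """
    tasks = [(pdb_id, kind, config) for pdb_id in pdb_ids
             for kind in fmt_kinds]
    if config.nproc > 1 and len(tasks) > 1:
        with multiprocessing.Pool(config.nproc) as pool:
            results = pool.map(_worker, tasks)
    else:
        results = [process_entry(*t) for t in tasks]

    rows: List[Dict] = []
    seen_rows = set()
    for res in results:
        for row in res.report_rows:
            key = (row["PDB_id"], row["chain_auth"])
            if key not in seen_rows:
                seen_rows.add(key)
                rows.append(row)
    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    if log_path is not None:
        log_path = Path(log_path)
        log_path.parent.mkdir(parents=True, exist_ok=True)
        report.to_csv(log_path, sep="\t", index=False)
    return results, report
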