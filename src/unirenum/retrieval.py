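"""Acquisition of structure and SIFTS files with bounded retry.

All network access in the package goes through this module, behind an
injectable ``fetcher`` callable, so every other module is testable offline.
A download is attempted at most three times; after three failures the file
is assumed not to exist and the entry is skipped downstream with a log
record.
"""

from __future__ import annotations

import logging
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Union

logger = logging.getLogger(__name__)

Fetcher = Callable[[str], bytes]

KIND_MMCIF = "mmCIF"
KIND_MMCIF_ASSEMBLY = "mmCIF_assembly"
KIND_PDB = "PDB"
KIND_PDB_ASSEMBLY = "PDB_assembly"
KIND_SIFTS = "SIFTS"

OUT_OK = "ok"
OUT_ABSENT = "absent"
OUT_FAILED = "failed"


@dataclass(frozen=True)
class Endpoints:
    """Download URL templates; asymmetric units from RCSB, assemblies and
    SIFTS from PDBe.  Configuration, because URLs drift."""

    mmcif: str = "https://files.rcsb.org/download/{pdb_id}.cif.gz"
    pdb: str = "https://files.rcsb.org/download/{pdb_id}.pdb.gz"
    mmcif_assembly: str = ("https://www.ebi.ac.uk/pdbe/static/entry/"
                           "{pdb_id}-assembly-{n}.cif.gz")
    pdb_assembly: str = "https://files.rcsb.org/download/{pdb_id}.pdb{n}.gz"
    sifts: str = ("https://ftp.ebi.ac.uk/pub/databases/msd/sifts/xml/"
                  "{pdb_id}.xml.gz")

    def url_for(self, kind: str, pdb_id: str, n: int = 1) -> str:
        template = {
            KIND_MMCIF: self.mmcif,
            KIND_PDB: self.pdb,
            KIND_MMCIF_ASSEMBLY: self.mmcif_assembly,
            KIND_PDB_ASSEMBLY: self.pdb_assembly,
            KIND_SIFTS: self.sifts,
        }[kind]
        return template.format(pdb_id=pdb_id, n=n)


@dataclass
class FetchResult:
    identifier: str
    kind: str
    outcome: str          # ok | absent | failed
    path: Optional[Path] = None
    attempts: int = 0


def _default_fetcher(url: str, timeout: float = 30.0) -> bytes:
    with urllib.request.urlopen(url, timeout=timeout) as resp:
        return resp.read()


def fetch_with_retry(url: str, dest: Union[str, Path], identifier: str = "",
                     kind: str = "", attempts: int = 3,
                     fetcher: Optional[Fetcher] = None) -> FetchResult:
    """Download ``url`` to ``dest``, trying at most ``attempts`` times.

    Network-layer errors are absorbed into the retry count; after the last
    failure the resource is reported absent, never raised.
    """
    fetcher = fetcher or _default_fetcher
    dest = Path(dest)
    for attempt in range(1, attempts + 1):
        try:
            data = fetcher(url)
        except Exception as exc:  # any transport failure counts one attempt
            logger.info("attempt %d/%d for %s failed: %s",
                        attempt, attempts, url, exc)
            continue
        dest.parent.mkdir(parents=True, exist_ok=True)
        dest.write_bytes(data)
        return FetchResult(identifier, kind, OUT_OK, dest, attempt)
    logger.warning("no success in %d attempts for %s; assuming the file "
                   "does not exist", attempts, url)
    return FetchResult(identifier, kind, OUT_ABSENT, None, attempts)


def classify_identifier(ident: str) -> str:
    """Shape-based classification: 4 characters with a leading digit is a
    PDB id; an underscore marks a SwissProt-style ID; anything else is
    treated as a UniProt accession."""
    if len(ident) == 4 and ident[0].isdigit():
        return "pdb"
    if "_" in ident:
        return "swissprot"
    return "accession"


def resolve_identifiers(ids: Sequence[str],
                        index: Optional[Dict[str, Sequence[str]]] = None
                        ) -> List[str]:
    """Expand UniProt identifiers to PDB entries via ``index`` (a mapping
    from accession or SwissProt ID to PDB ids); PDB ids pass through.
    Duplicates are removed, input order preserved; unresolvable identifiers
    are reported and skipped."""
    index = index or {}
    out: List[str] = []
    seen = set()
    for ident in ids:
        kind = classify_identifier(ident)
        if kind == "pdb":
            expansion: Iterable[str] = [ident.lower()]
        else:
            hits = index.get(ident)
            if not hits:
                logger.warning("identifier %s not found in the UniProt->PDB "
                               "index; skipped", ident)
                continue
            expansion = [h.lower() for h in hits]
        for pdb_id in expansion:
            if pdb_id not in seen:
                seen.add(pdb_id)
                out.append(pdb_id)
    return out


_FILENAMES = {
    KIND_MMCIF: "{pdb_id}.cif.gz",
    KIND_PDB: "{pdb_id}.pdb.gz",
    KIND_MMCIF_ASSEMBLY: "{pdb_id}-assembly-{n}.cif.gz",
    KIND_PDB_ASSEMBLY: "{pdb_id}.pdb{n}.gz",
    KIND_SIFTS: "{pdb_id}.xml.gz",
}


def input_filename(kind: str, pdb_id: str, n: int = 1) -> str:
    return _FILENAMES[kind].format(pdb_id=pdb_id, n=n)


def gather_inputs(pdb_ids: Sequence[str], kinds: Sequence[str],
                  paths: Dict[str, Union[str, Path]],
                  endpoints: Endpoints = Endpoints(),
                  fetcher: Optional[Fetcher] = None,
                  attempts: int = 3) -> List[FetchResult]:
    """Ensure the structure files for every requested format, plus the SIFTS
    file, exist under the per-kind input directories.

    Existing files are reused without refetching (attempts=0).  No entry
    leaves this function without either a SIFTS file or an explicit absent
    record for it.
    """
    results: List[FetchResult] = []
    wanted = list(dict.fromkeys(list(kinds) + [KIND_SIFTS]))
    for pdb_id in pdb_ids:
        for kind in wanted:
            directory = Path(paths[kind])
            dest = directory / input_filename(kind, pdb_id)
            alt = directory / input_filename(kind, pdb_id).removesuffix(".gz")
            if dest.exists():
                results.append(FetchResult(pdb_id, kind, OUT_OK, dest, 0))
                continue
            if alt.exists():  # pre-placed uncompressed input
                results.append(FetchResult(pdb_id, kind, OUT_OK, alt, 0))
                continue
            url = endpoints.url_for(kind, pdb_id)
            results.append(fetch_with_retry(url, dest, pdb_id, kind,
                                            attempts, fetcher))
    return results
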