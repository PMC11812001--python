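"""Protein sequence catalog and annotation tracks.

All UniProt interaction is file-based: sequences come from FASTA (UniProt
``>sp|ACC|NAME`` headers or bare ``>ACC``), annotation features from a
tab-separated track file (columns ``accession, kind, start, end,
description``).  The library never touches the network, so analyses are
reproducible from the files on disk.

Isoform accessions (``P12345-2``) are distinct proteins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

from Bio import SeqIO

from .errors import FormatError, RowError
from .records import ModificationSite

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnnotationFeature:
    """One annotation track feature (domain, binding site, known modified
    residue, ...) with 1-based inclusive coordinates."""

    kind: str
    start: int
    end: int
    description: str = ""

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid feature span {self.start}..{self.end}")


@dataclass
class ProteinEntry:
    accession: str
    sequence: str
    name: Optional[str] = None
    tracks: list[AnnotationFeature] = field(default_factory=list)

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        self.sequence = self.sequence.upper()

    @property
    def length(self) -> int:
        return len(self.sequence)

    def residue_at(self, position: int) -> str:
        """Residue letter at a 1-based position."""
        return self.sequence[position - 1]


class ProteinCatalog:
    """Mapping-like container of ProteinEntry keyed by accession."""

    def __init__(self, entries: Sequence[ProteinEntry] = ()):
        self.proteins: dict[str, ProteinEntry] = {}
        for entry in entries:
            self.add(entry)

    def add(self, entry: ProteinEntry) -> None:
        if entry.accession in self.proteins:
            logger.warning("duplicate accession %s: last record wins", entry.accession)
        self.proteins[entry.accession] = entry

    def __contains__(self, accession: str) -> bool:
        return accession in self.proteins

    def __getitem__(self, accession: str) -> ProteinEntry:
        return self.proteins[accession]

    def __iter__(self) -> Iterator[ProteinEntry]:
        return iter(self.proteins.values())

    def __len__(self) -> int:
        return len(self.proteins)

    def get(self, accession: str, default=None):
        return self.proteins.get(accession, default)

    def accessions(self) -> list[str]:
        return list(self.proteins)


def _parse_header(header: str) -> tuple[str, Optional[str]]:
    """Accession and name from a FASTA header token.

    ``sp|P0A6F5|CH60_ECOLI`` -> (``P0A6F5``, ``CH60_ECOLI``); a bare token is
    the accession itself."""
    token = header.split()[0]
    parts = token.split("|")
    if len(parts) >= 3 and parts[0] in {"sp", "tr"}:
        return parts[1], parts[2]
    return token, None


def load_fasta(path: str | Path) -> ProteinCatalog:
    """Load a FASTA file into a :class:`ProteinCatalog`.

    Sequences are uppercased; on duplicate accessions the last record wins
    with a warning; an empty file yields an empty catalog with a warning.
    """
    path = Path(path)
    catalog = ProteinCatalog()
    for record in SeqIO.parse(str(path), "fasta"):
        accession, name = _parse_header(record.description or record.id)
        catalog.add(ProteinEntry(accession=accession, sequence=str(record.seq), name=name))
    if len(catalog) == 0:
        logger.warning("%s: no FASTA records found", path)
    return catalog


def load_annotation_tracks(path: str | Path, catalog: ProteinCatalog) -> int:
    """Attach features from a tab-separated track file to catalog proteins.

    Columns: ``accession, kind, start, end, description``.  Features for
    unknown accessions or outside the sequence are tallied, logged and
    skipped; the number of attached features is returned.  ``end < start``
    is a row error.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        return 0
    header = [h.strip().lower() for h in lines[0].split("\t")]
    required = ["accession", "kind", "start", "end", "description"]
    for column in required[:4]:
        if column not in header:
            raise FormatError(f"{path}: missing required column '{column}'")
    idx = {column: header.index(column) for column in header}
    attached = skipped = 0
    for line_number, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        try:
            start, end = int(fields[idx["start"]]), int(fields[idx["end"]])
        except (ValueError, IndexError):
            raise RowError("non-integer start/end", line_number)
        if end < start:
            raise RowError(f"end {end} < start {start}", line_number)
        accession = fields[idx["accession"]].strip()
        entry = catalog.get(accession)
        if entry is None:
            skipped += 1
            continue
        if end > entry.length:
            logger.warning("%s line %d: feature %d..%d out of bounds for %s (length %d)",
                           path, line_number, start, end, accession, entry.length)
            skipped += 1
            continue
        description = fields[idx["description"]] if "description" in idx and len(fields) > idx["description"] else ""
        entry.tracks.append(
            AnnotationFeature(kind=fields[idx["kind"]].strip(), start=start,
                              end=end, description=description.strip())
        )
        attached += 1
    if skipped:
        logger.warning("%s: %d features skipped (unknown accession or out of bounds)",
                       path, skipped)
    return attached


@dataclass
class ValidationReport:
    """Tally of sites rejected during coordinate validation."""

    unknown_protein: int = 0
    out_of_bounds: int = 0
    valid: int = 0

    def to_dict(self) -> dict:
        return {"unknown_protein": self.unknown_protein,
                "out_of_bounds": self.out_of_bounds, "valid": self.valid}


def validate_sites(
    sites: Sequence[ModificationSite], catalog: ProteinCatalog
) -> tuple[list[ModificationSite], ValidationReport]:
    """Check site coordinates against the catalog and attach residue letters.

    Sites on unknown proteins or beyond the sequence length are rejected and
    tallied — never silently dropped.  Valid sites get ``site.residue`` set
    to the sequence letter at their position.
    """
    report = ValidationReport()
    valid: list[ModificationSite] = []
    for site in sites:
        entry = catalog.get(site.protein_accession)
        if entry is None:
            report.unknown_protein += 1
            continue
        if site.position > entry.length:
            report.out_of_bounds += 1
            continue
        site.residue = entry.residue_at(site.position)
        valid.append(site)
    report.valid = len(valid)
    return valid, report


def write_fasta(catalog: ProteinCatalog, path: str | Path, width: int = 60) -> None:
    """Write the catalog as UniProt-style FASTA (deterministic ordering)."""
    lines = []
    for accession in catalog.accessions():
        entry = catalog[accession]
        name = entry.name or f"{accession}_SYN"
        lines.append(f">sp|{accession}|{name}")
        seq = entry.sequence
        lines.extend(seq[i:i + width] for i in range(0, len(seq), width))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
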