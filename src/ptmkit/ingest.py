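"""Parsers for site-level and PSM-level input tables.

Three PSM dialects are supported natively:

* ``msfragger`` — the FragPipe/MSFragger ``psm.tsv`` layout (tab-separated;
  assigned modifications like ``4S(79.9663), N-term(42.0106)``, open mass
  shift in ``Delta Mass`` with its explanation in ``Observed Modifications``).
* ``sage`` — the Sage ``results.sage.tsv`` layout (tab-separated; peptide in
  ProForma bracket notation like ``PEPT[+79.9663]IDEK``; ``label`` -1 marks
  decoys).
* ``normalized`` — a one-to-one tab-separated serialization of
  :class:`~ptmkit.records.PSMRecord`, used as the lossless interchange format.

Additional engines are admitted through :func:`register_dialect`, which takes
a declarative column mapping rather than code.  The site-level generic CSV
(``uniprot_id,position,modification_unimod_name[,mass_shift]``) is handled by
:func:`read_generic_csv`.

Decoy PSMs are recognized by the accession prefixes ``rev_`` and ``DECOY_``
(case-insensitive) or, in the normalized dialect, an explicit boolean column.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

from pyteomics import proforma

from .errors import DialectAmbiguityError, FormatError, RowError, UsageError
from .records import Modification, PSMRecord, SiteRecord

logger = logging.getLogger(__name__)

DECOY_PREFIXES = ("rev_", "decoy_")

GENERIC_CSV_DIALECT = "generic_csv"

NORMALIZED_HEADER = [
    "spectrum_id",
    "peptide",
    "proteins",
    "score",
    "q_value",
    "is_decoy",
    "modifications",
]


def is_decoy_accession(accession: str) -> bool:
    return accession.lower().startswith(DECOY_PREFIXES)


def strip_decoy_prefix(accession: str) -> str:
    low = accession.lower()
    for prefix in DECOY_PREFIXES:
        if low.startswith(prefix):
            return accession[len(prefix):]
    return accession


# ---------------------------------------------------------------------------
# generic site-level CSV
# ---------------------------------------------------------------------------

_GENERIC_REQUIRED = ("uniprot_id", "position", "modification_unimod_name")


def read_generic_csv(path: str | Path) -> list[SiteRecord]:
    """Read the generic site-level CSV into :class:`SiteRecord` objects.

    Required columns (case-insensitive): ``uniprot_id``, ``position``,
    ``modification_unimod_name``; optional ``mass_shift``.  Rows are returned
    in file order.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file, expected a header row")
        columns = {name.strip().lower(): i for i, name in enumerate(header)}
        for required in _GENERIC_REQUIRED:
            if required not in columns:
                raise FormatError(f"{path}: missing required column '{required}'")
        acc_i = columns["uniprot_id"]
        pos_i = columns["position"]
        name_i = columns["modification_unimod_name"]
        mass_i = columns.get("mass_shift")

        records: list[SiteRecord] = []
        for line_number, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            try:
                position = int(row[pos_i].strip())
            except (ValueError, IndexError):
                raise RowError(
                    f"non-integer position {row[pos_i]!r}" if len(row) > pos_i
                    else "missing position field",
                    line_number,
                )
            mass_shift = None
            if mass_i is not None and len(row) > mass_i and row[mass_i].strip():
                try:
                    mass_shift = float(row[mass_i])
                except ValueError:
                    raise RowError(f"non-numeric mass_shift {row[mass_i]!r}", line_number)
            try:
                records.append(
                    SiteRecord(
                        protein_accession=row[acc_i].strip(),
                        position=position,
                        mod_name=row[name_i].strip(),
                        mass_shift=mass_shift,
                    )
                )
            except ValueError as exc:
                raise RowError(str(exc), line_number)
    return records


# ---------------------------------------------------------------------------
# PSM dialects
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Dialect:
    """Declarative description of one tabular PSM dialect.

    ``required_headers`` identifies the dialect during auto-detection;
    ``parse_row`` maps one row dict to a PSMRecord.
    """

    name: str
    separator: str
    required_headers: frozenset[str]
    parse_row: Callable[[dict, int], PSMRecord]


_MSFRAGGER_ASSIGNED_RE = re.compile(
    r"^(?:(?P<pos>\d+)(?P<aa>[A-Z])|(?P<term>[NC])-term)\((?P<mass>-?\d+\.?\d*)\)$"
)


def _parse_msfragger_assigned(text: str, peptide: str, line_number: int) -> list[Modification]:
    mods: list[Modification] = []
    for chunk in filter(None, (c.strip() for c in text.split(","))):
        m = _MSFRAGGER_ASSIGNED_RE.match(chunk)
        if not m:
            raise RowError(f"unparseable assigned modification {chunk!r}", line_number)
        if m.group("term") == "N":
            pos = 0
        elif m.group("term") == "C":
            pos = len(peptide)
        else:
            pos = int(m.group("pos"))
        mods.append(Modification(peptide_position=pos, mass_shift=float(m.group("mass"))))
    return mods


def _count_observed_components(text: str) -> int:
    """Number of named modifications used to explain an open mass shift.

    MSFragger/PTM-Shepherd annotations list combinations with ``;`` or
    ``" + "`` separators, e.g. ``Phospho + Oxidation``.
    """
    text = text.strip()
    if not text or text.lower() in {"none", "unannotated"}:
        return 0
    parts = re.split(r";|\s\+\s", text)
    return len([p for p in parts if p.strip()])


def _parse_msfragger_row(row: dict, line_number: int) -> PSMRecord:
    peptide = row["Peptide"].strip().upper()
    protein = row["Protein"].strip()
    mapped = row.get("Mapped Proteins", "").strip()
    accessions = [protein] + [p.strip() for p in mapped.split(",") if p.strip()]
    mods = _parse_msfragger_assigned(row.get("Assigned Modifications", ""), peptide, line_number)

    # The open-search mass shift lives in Delta Mass; its explanation in
    # Observed Modifications, its candidate positions (lowercase letters) in
    # MSFragger Localization.
    delta_text = row.get("Delta Mass", "").strip()
    delta = float(delta_text) if delta_text else 0.0
    if abs(delta) > 0.01:
        observed = row.get("Observed Modifications", "").strip()
        localization = row.get("MSFragger Localization", "").strip()
        candidates = [i for i, ch in enumerate(localization, start=1) if ch.islower()]
        n_loc = len(candidates) if candidates else 1
        pos = candidates[0] if len(candidates) == 1 else (candidates[0] if candidates else 1)
        n_comp = _count_observed_components(observed)
        mods.append(
            Modification(
                peptide_position=min(pos, len(peptide)),
                mass_shift=delta,
                name=observed or None,
                n_localizations=n_loc,
                n_components=max(1, n_comp),
            )
        )

    score_text = row.get("Hyperscore", "").strip()
    return PSMRecord(
        spectrum_id=row.get("Spectrum", f"row{line_number}").strip(),
        peptide=peptide,
        protein_accessions=tuple(accessions),
        score=float(score_text) if score_text else None,
        q_value=None,
        is_decoy=any(is_decoy_accession(a) for a in accessions),
        modifications=tuple(mods),
    )


def _parse_sage_row(row: dict, line_number: int) -> PSMRecord:
    try:
        parsed, _ = proforma.parse(row["peptide"].strip())
    except Exception as exc:
        raise RowError(f"unparseable ProForma peptide {row['peptide']!r}: {exc}", line_number)
    peptide = "".join(aa for aa, _mods in parsed)
    mods: list[Modification] = []
    for position, (_aa, aamods) in enumerate(parsed, start=1):
        for tag in aamods or ():
            mass = getattr(tag, "mass", None)
            if mass is None:
                raise RowError(f"modification tag without mass at position {position}", line_number)
            name = getattr(tag, "name", None) if not isinstance(tag, proforma.MassModification) else None
            mods.append(Modification(peptide_position=position, mass_shift=float(mass), name=name))
    accessions = tuple(p.strip() for p in row["proteins"].split(";") if p.strip())
    label = row.get("label", "1").strip()
    q_text = row.get("spectrum_q", "").strip()
    return PSMRecord(
        spectrum_id=f"{row.get('filename', '')}:{row.get('scannr', line_number)}".strip(":"),
        peptide=peptide.upper(),
        protein_accessions=accessions,
        score=float(row["sage_discriminant_score"]) if row.get("sage_discriminant_score", "").strip() else None,
        q_value=float(q_text) if q_text else None,
        is_decoy=(label == "-1") or any(is_decoy_accession(a) for a in accessions),
        modifications=tuple(mods),
    )


def format_normalized_modifications(mods: tuple[Modification, ...]) -> str:
    return ";".join(
        f"{m.peptide_position}:{m.mass_shift!r}:{m.name or ''}:{m.n_localizations}"
        for m in mods
    )


def _parse_normalized_modifications(text: str, line_number: int) -> tuple[Modification, ...]:
    mods = []
    for chunk in filter(None, (c.strip() for c in text.split(";"))):
        parts = chunk.split(":")
        if len(parts) < 4:
            raise RowError(f"unparseable modification {chunk!r}", line_number)
        try:
            mods.append(
                Modification(
                    peptide_position=int(parts[0]),
                    mass_shift=float(parts[1]),
                    name=":".join(parts[2:-1]) or None,
                    n_localizations=int(parts[-1]),
                )
            )
        except ValueError:
            raise RowError(f"unparseable modification {chunk!r}", line_number)
    return tuple(mods)


def _parse_normalized_row(row: dict, line_number: int) -> PSMRecord:
    try:
        return PSMRecord(
            spectrum_id=row["spectrum_id"],
            peptide=row["peptide"].strip().upper(),
            protein_accessions=tuple(p for p in row["proteins"].split(";") if p),
            score=float(row["score"]) if row["score"].strip() else None,
            q_value=float(row["q_value"]) if row["q_value"].strip() else None,
            is_decoy=row["is_decoy"].strip().lower() in {"true", "1", "yes"},
            modifications=_parse_normalized_modifications(row["modifications"], line_number),
        )
    except (ValueError, KeyError) as exc:
        raise RowError(str(exc), line_number)


DIALECTS: dict[str, Dialect] = {}


def register_dialect(dialect: Dialect) -> None:
    """Register a PSM dialect; the plugin hook for engines not built in."""
    DIALECTS[dialect.name] = dialect


register_dialect(
    Dialect(
        name="msfragger",
        separator="\t",
        required_headers=frozenset(
            {"Spectrum", "Peptide", "Protein", "Hyperscore",
             "Assigned Modifications", "Observed Modifications"}
        ),
        parse_row=_parse_msfragger_row,
    )
)
register_dialect(
    Dialect(
        name="sage",
        separator="\t",
        required_headers=frozenset(
            {"psm_id", "peptide", "proteins", "scannr",
             "sage_discriminant_score", "spectrum_q", "label"}
        ),
        parse_row=_parse_sage_row,
    )
)
register_dialect(
    Dialect(
        name="normalized",
        separator="\t",
        required_headers=frozenset(NORMALIZED_HEADER),
        parse_row=_parse_normalized_row,
    )
)


def read_psm_table(path: str | Path, dialect: str) -> list[PSMRecord]:
    """Read a PSM table in the given dialect into PSMRecords, in file order."""
    if dialect not in DIALECTS:
        raise UsageError(
            f"unknown dialect {dialect!r}; available: {sorted(DIALECTS)}"
        )
    spec = DIALECTS[dialect]
    path = Path(path)
    records: list[PSMRecord] = []
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter=spec.separator)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file, expected a header row")
        missing = spec.required_headers - set(reader.fieldnames)
        if missing:
            raise FormatError(
                f"{path}: not a {dialect} table, missing columns {sorted(missing)}"
            )
        for line_number, row in enumerate(reader, start=2):
            records.append(spec.parse_row(row, line_number))
    return records


def write_normalized_psm_table(psms: list[PSMRecord], path: str | Path) -> None:
    """Write PSMRecords as a normalized-dialect TSV (lossless round-trip)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(NORMALIZED_HEADER)
        for psm in psms:
            writer.writerow(
                [
                    psm.spectrum_id,
                    psm.peptide,
                    ";".join(psm.protein_accessions),
                    "" if psm.score is None else repr(psm.score),
                    "" if psm.q_value is None else repr(psm.q_value),
                    str(psm.is_decoy).lower(),
                    format_normalized_modifications(psm.modifications),
                ]
            )


def detect_dialect(path: str | Path) -> str:
    """Identify the dialect of a tabular input from its header row.

    Returns the unique registered dialect whose required headers are all
    present, or ``generic_csv`` for the site-level CSV format.  Raises
    :class:`DialectAmbiguityError` when zero or several dialects match.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as handle:
        first_line = handle.readline()
    if not first_line.strip():
        raise FormatError(f"{path}: empty file, expected a header row")

    candidates = []
    tab_headers = set(h.strip() for h in first_line.rstrip("\n").split("\t"))
    for name, spec in DIALECTS.items():
        if spec.required_headers <= tab_headers:
            candidates.append(name)
    comma_headers = set(h.strip().lower() for h in first_line.rstrip("\n").split(","))
    if set(_GENERIC_REQUIRED) <= comma_headers:
        candidates.append(GENERIC_CSV_DIALECT)

    if len(candidates) == 1:
        return candidates[0]
    if not candidates:
        raise DialectAmbiguityError(
            f"{path}: header matches no known dialect "
            f"(known: {sorted(DIALECTS) + [GENERIC_CSV_DIALECT]})",
            [],
        )
    raise DialectAmbiguityError(
        f"{path}: header matches several dialects: {sorted(candidates)}", candidates
    )
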