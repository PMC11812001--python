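"""UniMod mass-shift annotation.

Maps observed mass shifts (and, when present, modification names) to UniMod
entries at a configurable mass tolerance (default 0.001 Da).  A mass shift
that matches exactly one entry takes that entry's name as display label and
its per-residue classification; a shift matching zero or several entries
keeps the formatted mass shift as label under the class
``"Ambiguous mass shift"``.  Pairs of modification types whose mass shifts
differ by less than a user threshold — and are therefore hard to tell apart
by MS — can be flagged with :func:`flag_ambiguous_pairs`.

A modification's class depends on the modified residue (oxidation of Met is
an artefact of sample handling; oxidation of Pro is hydroxylation, a genuine
PTM), so classes are always resolved per (entry, residue).

The bundled reference table is a curated subset of UniMod shipped as TSV;
:func:`convert_unimod_xml` converts the official ``unimod.xml`` for users who
need full coverage.
"""

from __future__ import annotations

import bisect
import logging
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .errors import FormatError
from .records import (
    AMBIGUOUS_CLASS,
    UNDEFINED_CLASS,
    AmbiguousPair,
    ModificationSite,
    ModificationType,
    format_mass_shift,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class UnimodEntry:
    """One UniMod modification: id, name, monoisotopic mass shift, and the
    class assigned per residue or terminus (``N-term``/``C-term``)."""

    unimod_id: int
    name: str
    mono_mass: float
    classifications: dict[str, str]

    def class_for(self, residue: Optional[str]) -> str:
        """Class for the given residue letter, falling back to ``Undefined``."""
        if residue is not None and residue in self.classifications:
            return self.classifications[residue]
        return UNDEFINED_CLASS


@dataclass(frozen=True)
class MatchConfig:
    """Tolerances for mass-shift matching and ambiguity flagging.

    mass_tolerance
        Half-width, in Da, of the window for matching an observed shift to a
        UniMod monoisotopic mass (default 0.001 Da).
    ambiguity_flag_threshold
        Two modification types closer than this (Da) are flagged as hard to
        distinguish (default 0.02 Da).
    excluded_classes
        UniMod classes removed from the analysis after labeling.
    """

    mass_tolerance: float = 0.001
    ambiguity_flag_threshold: float = 0.02
    excluded_classes: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.mass_tolerance <= 0:
            raise ValueError("mass_tolerance must be > 0")
        if self.ambiguity_flag_threshold <= 0:
            raise ValueError("ambiguity_flag_threshold must be > 0")


class UnimodTable:
    """In-memory UniMod table indexed by id, by name, and by mass."""

    def __init__(self, entries: Iterable[UnimodEntry]):
        self.entries: list[UnimodEntry] = list(entries)
        self.by_id: dict[int, UnimodEntry] = {}
        self.by_name: dict[str, UnimodEntry] = {}
        for entry in self.entries:
            if entry.unimod_id in self.by_id:
                raise FormatError(f"duplicate UniMod id {entry.unimod_id}")
            if entry.name.casefold() in self.by_name:
                raise FormatError(f"duplicate UniMod name {entry.name!r}")
            self.by_id[entry.unimod_id] = entry
            self.by_name[entry.name.casefold()] = entry
        self._sorted = sorted(self.entries, key=lambda e: e.mono_mass)
        self._masses = [e.mono_mass for e in self._sorted]

    def __len__(self) -> int:
        return len(self.entries)

    def lookup_name(self, name: str) -> Optional[UnimodEntry]:
        return self.by_name.get(name.casefold())

    def range_query(self, lo: float, hi: float) -> list[UnimodEntry]:
        """All entries with mono_mass in the closed interval [lo, hi]."""
        i = bisect.bisect_left(self._masses, lo)
        j = bisect.bisect_right(self._masses, hi)
        return self._sorted[i:j]


def _parse_classifications(text: str, line_number: int) -> dict[str, str]:
    classes: dict[str, str] = {}
    for chunk in filter(None, (c.strip() for c in text.split(";"))):
        if "=" not in chunk:
            raise FormatError(f"line {line_number}: bad classification {chunk!r}")
        residue, cls = chunk.split("=", 1)
        classes[residue.strip()] = cls.strip()
    return classes


def load_unimod_table(path: str | Path) -> UnimodTable:
    """Load a UniMod reference table from TSV.

    Columns: ``id``, ``name``, ``mono_mass``, ``classifications`` (the last
    as ``residue=class`` pairs joined by ``;``).
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        return UnimodTable([])
    header = [h.strip() for h in lines[0].split("\t")]
    required = ["id", "name", "mono_mass", "classifications"]
    for column in required:
        if column not in header:
            raise FormatError(f"{path}: missing required column '{column}'")
    idx = {column: header.index(column) for column in required}
    entries = []
    for line_number, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        try:
            entries.append(
                UnimodEntry(
                    unimod_id=int(fields[idx["id"]]),
                    name=fields[idx["name"]].strip(),
                    mono_mass=float(fields[idx["mono_mass"]]),
                    classifications=_parse_classifications(
                        fields[idx["classifications"]], line_number
                    ),
                )
            )
        except (ValueError, IndexError) as exc:
            raise FormatError(f"{path}: line {line_number}: {exc}")
    return UnimodTable(entries)


def load_bundled_table() -> UnimodTable:
    """Load the curated UniMod subset shipped with the package."""
    with resources.as_file(
        resources.files("ptmkit").joinpath("data/unimod_subset.tsv")
    ) as path:
        return load_unimod_table(path)


def match_mass_shift(
    delta: float, cfg: MatchConfig, table: UnimodTable
) -> list[UnimodEntry]:
    """All entries with ``|mono_mass - delta| <= mass_tolerance``, nearest
    first; ties broken by ascending UniMod id."""
    hits = table.range_query(delta - cfg.mass_tolerance, delta + cfg.mass_tolerance)
    return sorted(hits, key=lambda e: (abs(e.mono_mass - delta), e.unimod_id))


def assign_label(
    site: ModificationSite, matches: Sequence[UnimodEntry]
) -> ModificationSite:
    """Choose the display label for a site from its UniMod candidates.

    Exactly one candidate: the entry's name, id, and per-residue class.
    Zero or several: the formatted mass shift becomes the label, class
    ``Ambiguous mass shift``.  A named site with no mass shift and no match
    keeps its input name under class ``Undefined``.
    """
    site.candidates = tuple(e.unimod_id for e in matches)
    if len(matches) == 1:
        entry = matches[0]
        site.label = entry.name
        site.unimod_id = entry.unimod_id
        key = "N-term" if site.is_nterm else site.residue
        site.mod_class = entry.class_for(key)
        return site
    if site.mass_shift is not None:
        site.label = format_mass_shift(site.mass_shift)
        site.mod_class = AMBIGUOUS_CLASS
    else:
        site.label = site.source_name or UNDEFINED_CLASS
        site.mod_class = UNDEFINED_CLASS
    site.unimod_id = None
    return site


def label_sites(
    sites: list[ModificationSite], table: UnimodTable, cfg: MatchConfig = MatchConfig()
) -> list[ModificationSite]:
    """Label every site: exact (case-insensitive) name lookup first when the
    input carried a modification name, mass matching otherwise."""
    out = []
    for site in sites:
        matches: list[UnimodEntry] = []
        if site.source_name:
            entry = table.lookup_name(site.source_name)
            if entry is not None:
                matches = [entry]
        if not matches and site.mass_shift is not None:
            matches = match_mass_shift(site.mass_shift, cfg, table)
        out.append(assign_label(site, matches))
    return out


def flag_ambiguous_pairs(
    types: Sequence[ModificationType], threshold: float
) -> list[AmbiguousPair]:
    """All unordered pairs of types with ``|mass_a - mass_b| < threshold``.

    Types without a numeric mass shift are skipped.  The scan sorts by mass
    and only compares neighbors within the threshold window, so it is
    near-linear for well-separated tables.
    """
    typed = sorted(
        (t for t in types if t.mass_shift is not None), key=lambda t: t.mass_shift
    )
    pairs: list[AmbiguousPair] = []
    for i, a in enumerate(typed):
        for b in typed[i + 1:]:
            diff = b.mass_shift - a.mass_shift
            if diff >= threshold:
                break
            if a.label != b.label:
                pairs.append(AmbiguousPair(a.label, b.label, abs(diff)))
    pairs.sort(key=lambda p: (p.difference, p.label_a, p.label_b))
    return pairs


def exclude_classes(
    sites: Sequence[ModificationSite], excluded: set[str]
) -> list[ModificationSite]:
    """Drop sites whose resolved class is in ``excluded``; order preserved.

    Unknown class names in ``excluded`` produce a warning, not an error."""
    known = {s.mod_class for s in sites if s.mod_class} | {
        AMBIGUOUS_CLASS, UNDEFINED_CLASS,
        "Post-translational", "Artefact", "Chemical derivative",
        "AA substitution", "Multiple",
    }
    for name in excluded:
        if name not in known:
            warnings.warn(f"excluded class {name!r} matches no known class")
    return [s for s in sites if s.mod_class not in excluded]


def convert_unimod_xml(xml_path: str | Path, out_path: str | Path) -> int:
    """Convert the official ``unimod.xml`` into the TSV layout this package
    reads.  Provided for users with full-UniMod needs; the bundled subset is
    sufficient for the shipped workflows.  Returns the number of entries."""
    from pyteomics import mass as _mass  # local import; optional path

    from lxml import etree

    ns = {"u": "http://www.unimod.org/xmlns/schema/unimod_2"}
    tree = etree.parse(str(xml_path))
    lines = ["id\tname\tmono_mass\tclassifications"]
    count = 0
    for mod in tree.findall(".//u:modifications/u:mod", ns):
        uid = int(mod.get("record_id"))
        name = mod.get("title")
        delta = mod.find("u:delta", ns)
        mono = float(delta.get("mono_mass"))
        classes = []
        for spec in mod.findall("u:specificity", ns):
            classes.append(f"{spec.get('site')}={spec.get('classification')}")
        lines.append(f"{uid}\t{name}\t{mono:.6f}\t{';'.join(classes)}")
        count += 1
    Path(out_path).write_text("\n".join(lines) + "\n", encoding="utf-8")
    return count
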