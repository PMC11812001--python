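"""Residue contact maps with modification-state overlay.

A contact is a pair of residues whose representative atoms — Cβ, or Cα for
glycine — lie strictly closer than a cutoff (default 4.69 Å, an empirical
estimate for physical interaction between modified residues).  Trivially
adjacent backbone neighbors are excluded through a minimum sequence
separation (default 2).  Each contact carries a modification state:

* ``highlighted`` — a highlight label is set and at least one residue of the
  pair carries it;
* ``any_modified`` — at least one residue carries any modification;
* ``both_unmodified`` — otherwise.

States form a strict priority (highlighted > any_modified >
both_unmodified); exactly one state per pair.

Structures are read from PDB or mmCIF with gemmi.  Residue numbering must
align with the sequence numbering of the protein catalog (true for AlphaFold
models); an optional cross-check against the catalog reports mismatched
residue letters at load time.  Non-glycine residues missing a Cβ (truncated
models) fall back to Cα and are flagged rather than dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

import gemmi

from .errors import FormatError, PtmkitError
from .records import ModificationSite

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 4.69  # Angstrom
DEFAULT_MIN_SEPARATION = 2

STATE_HIGHLIGHTED = "highlighted"
STATE_ANY_MODIFIED = "any_modified"
STATE_BOTH_UNMODIFIED = "both_unmodified"

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass(frozen=True)
class ResidueRecord:
    """One residue with its representative-atom coordinate."""

    position: int
    name: str  # three-letter code
    coord: tuple[float, float, float]
    used_fallback: bool = False  # Ca used although the residue is not glycine

    @property
    def letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")


@dataclass
class StructureModel:
    """Ordered representative-atom model of one chain."""

    accession: str
    residues: list[ResidueRecord]
    skipped: int = 0
    #: all heavy-atom coordinates per residue position, for the optional
    #: closest-atom distance
    heavy_atoms: dict[int, list[tuple[float, float, float]]] = field(default_factory=dict)

    def positions(self) -> list[int]:
        return [r.position for r in self.residues]

    def coords(self) -> np.ndarray:
        return np.array([r.coord for r in self.residues], dtype=float)

    def residue(self, position: int) -> ResidueRecord:
        for r in self.residues:
            if r.position == position:
                return r
        raise KeyError(position)


def representative_atom(residue: "gemmi.Residue") -> Optional[tuple[np.ndarray, bool]]:
    """Representative-atom coordinate of a gemmi residue.

    Cβ for everything but glycine, Cα for glycine; Cα fallback (flagged) for
    non-glycine residues without a Cβ.  Returns ``None`` when neither atom is
    present.
    """
    ca = cb = None
    for atom in residue:
        if atom.name == "CB" and cb is None:
            cb = atom.pos
        elif atom.name == "CA" and ca is None:
            ca = atom.pos
    is_glycine = residue.name.strip().upper() == "GLY"
    if not is_glycine and cb is not None:
        return np.array([cb.x, cb.y, cb.z]), False
    if ca is not None:
        return np.array([ca.x, ca.y, ca.z]), (not is_glycine)
    return None


def load_structure(
    path: str | Path, accession: str, catalog=None
) -> StructureModel:
    """Read a PDB or mmCIF file into a representative-atom model.

    Only the first chain of the first model is used (with a warning if more
    exist).  Residues without Cα and Cβ are skipped and tallied.  When a
    catalog is given, residue letters are cross-checked against the protein
    sequence and mismatches logged.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"{path}: unparseable structure file: {exc}")
    if len(st) == 0 or len(st[0]) == 0:
        logger.warning("%s: no chains found", path)
        return StructureModel(accession=accession, residues=[])
    model = st[0]
    if len(st) > 1 or len(model) > 1:
        logger.warning("%s: multiple models/chains; using first chain", path)
    chain = model[0]

    residues: list[ResidueRecord] = []
    heavy: dict[int, list[tuple[float, float, float]]] = {}
    skipped = 0
    for residue in chain:
        if residue.name.strip().upper() not in THREE_TO_ONE:
            continue
        rep = representative_atom(residue)
        if rep is None:
            skipped += 1
            continue
        coord, fallback = rep
        position = residue.seqid.num
        residues.append(
            ResidueRecord(
                position=position,
                name=residue.name.strip().upper(),
                coord=tuple(float(x) for x in coord),
                used_fallback=fallback,
            )
        )
        heavy[position] = [
            (a.pos.x, a.pos.y, a.pos.z) for a in residue if not a.name.startswith("H")
        ]
    if not residues:
        logger.warning("%s: no standard residues with usable atoms", path)
    seen = set()
    ordered = []
    for r in residues:
        if r.position in seen:
            logger.warning("%s: duplicate residue number %d skipped", path, r.position)
            skipped += 1
            continue
        seen.add(r.position)
        ordered.append(r)
    ordered.sort(key=lambda r: r.position)

    if catalog is not None:
        entry = catalog.get(accession)
        if entry is not None:
            mismatches = [
                r.position for r in ordered
                if r.position <= entry.length and r.letter != entry.residue_at(r.position)
            ]
            if mismatches:
                logger.warning(
                    "%s: %d residue letters disagree with catalog sequence of %s "
                    "(first at %d)", path, len(mismatches), accession, mismatches[0]
                )
    return StructureModel(accession=accession, residues=ordered, skipped=skipped,
                          heavy_atoms=heavy)


@dataclass
class ContactMap:
    """Symmetric set of residue contacts under the representative-atom rule."""

    accession: str
    cutoff: float
    min_separation: int
    #: unordered pairs keyed as (i, j) with i < j -> distance in Angstrom
    distances: dict[tuple[int, int], float]
    states: dict[tuple[int, int], str] = field(default_factory=dict)
    highlight_label: Optional[str] = None

    @staticmethod
    def _key(i: int, j: int) -> tuple[int, int]:
        if i == j:
            raise KeyError("no self-contacts")
        return (i, j) if i < j else (j, i)

    def __contains__(self, pair: tuple[int, int]) -> bool:
        try:
            return self._key(*pair) in self.distances
        except KeyError:
            return False

    def distance(self, i: int, j: int) -> float:
        return self.distances[self._key(i, j)]

    def state(self, i: int, j: int) -> str:
        return self.states[self._key(i, j)]

    def pairs(self) -> list[tuple[int, int]]:
        return sorted(self.distances)

    def __len__(self) -> int:
        return len(self.distances)

    def to_records(self) -> list[dict]:
        return [
            {
                "i": i,
                "j": j,
                "distance": self.distances[(i, j)],
                "state": self.states.get((i, j), STATE_BOTH_UNMODIFIED),
            }
            for i, j in self.pairs()
        ]

    def to_tsv(self) -> str:
        lines = ["i\tj\tdistance\tstate"]
        for rec in self.to_records():
            lines.append(f"{rec['i']}\t{rec['j']}\t{rec['distance']:.6f}\t{rec['state']}")
        return "\n".join(lines) + "\n"


def contact_map(
    model: StructureModel,
    cutoff: float = DEFAULT_CUTOFF,
    min_separation: int = DEFAULT_MIN_SEPARATION,
) -> ContactMap:
    """All residue pairs with representative-atom distance strictly below
    ``cutoff`` and sequence separation ``|i - j| >= min_separation``."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    distances: dict[tuple[int, int], float] = {}
    n = len(model.residues)
    if n >= 2:
        coords = model.coords()
        positions = np.array(model.positions())
        dist = squareform(pdist(coords))
        ii, jj = np.nonzero(np.triu(dist < cutoff, k=1))
        for a, b in zip(ii, jj):
            pi, pj = int(positions[a]), int(positions[b])
            if abs(pi - pj) >= min_separation:
                distances[(min(pi, pj), max(pi, pj))] = float(dist[a, b])
    return ContactMap(
        accession=model.accession,
        cutoff=cutoff,
        min_separation=min_separation,
        distances=distances,
    )


def classify_contacts(
    cmap: ContactMap,
    sites: Sequence[ModificationSite],
    highlight: Optional[str] = None,
) -> ContactMap:
    """Assign a modification state to every contact (in place; returns map).

    ``sites`` are the validated sites of the map's protein.  If ``highlight``
    names a label absent from those sites, a warning is logged and no pair is
    highlighted.
    """
    mine = [s for s in sites if s.protein_accession == cmap.accession]
    modified = {s.position for s in mine}
    highlighted_positions = set()
    if highlight is not None:
        highlighted_positions = {s.position for s in mine if s.label == highlight}
        if not highlighted_positions:
            logger.warning("highlight label %r not found on %s; nothing highlighted",
                           highlight, cmap.accession)
    cmap.highlight_label = highlight
    cmap.states = {}
    for i, j in cmap.distances:
        if highlighted_positions & {i, j}:
            cmap.states[(i, j)] = STATE_HIGHLIGHTED
        elif modified & {i, j}:
            cmap.states[(i, j)] = STATE_ANY_MODIFIED
        else:
            cmap.states[(i, j)] = STATE_BOTH_UNMODIFIED
    return cmap


@dataclass
class ResiduePairDetail:
    """Everything known about one contact: its distance and the
    modifications carried by each residue."""

    i: int
    j: int
    distance: float
    mods_i: list[tuple[str, Optional[float], Optional[str]]]
    mods_j: list[tuple[str, Optional[float], Optional[str]]]


def residue_pair_detail(
    cmap: ContactMap, pair: tuple[int, int], sites: Sequence[ModificationSite]
) -> ResiduePairDetail:
    """Distance plus per-residue (label, mass shift, class) lists for a pair
    present in the map; raises ``KeyError`` otherwise."""
    i, j = min(pair), max(pair)
    if (i, j) not in cmap.distances:
        raise KeyError(f"pair ({i}, {j}) is not a contact")
    mine = [s for s in sites if s.protein_accession == cmap.accession]

    def mods_at(position: int):
        return sorted(
            (s.label or "", s.display_mass(), s.mod_class)
            for s in mine if s.position == position
        )

    return ResiduePairDetail(
        i=i, j=j, distance=cmap.distances[(i, j)],
        mods_i=mods_at(i), mods_j=mods_at(j),
    )


def modified_contact_filter(cmap: ContactMap) -> ContactMap:
    """Sub-map retaining only contacts involving at least one modified
    residue (state != both_unmodified); states must be assigned."""
    if set(cmap.states) != set(cmap.distances):
        raise PtmkitError("classify_contacts must run before modified_contact_filter")
    keep = {
        pair: d for pair, d in cmap.distances.items()
        if cmap.states[pair] != STATE_BOTH_UNMODIFIED
    }
    return ContactMap(
        accession=cmap.accession,
        cutoff=cmap.cutoff,
        min_separation=cmap.min_separation,
        distances=keep,
        states={pair: cmap.states[pair] for pair in keep},
        highlight_label=cmap.highlight_label,
    )


def closest_atom_distance(model: StructureModel, i: int, j: int) -> float:
    """Closest heavy-atom distance between residues i and j, for comparison
    with the representative-atom contact-rule distance."""
    a = np.array(model.heavy_atoms[i], dtype=float)
    b = np.array(model.heavy_atoms[j], dtype=float)
    return float(np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(-1)).min())
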