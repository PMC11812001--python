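"""Synthetic inputs with machine-readable ground truth.

Every pipeline stage is testable offline: this module generates random
proteomes (FASTA), PSM tables with planted modifications and target/decoy
score distributions (normalized dialect), annotation tracks, and toy protein
structures (PDB) with analytically known contact sets.  Each generator is
deterministic given its seed and emits the ground truth the pipeline is
expected to recover.

The ground truth for the PSM generator is computed with its own inline
target-decoy bookkeeping (a plain loop, independent of the postprocess
module), and lists exactly the sites that survive 1% FDR filtering plus the
decoy/multi-protein/localization drop rules.  Expected display labels are
derived by a linear scan over the UniMod table at the matching tolerance —
again independent of the indexed matcher it is used to test.

The default generation conditions emulate a well-behaved open search on a
small proteome: ten proteins of 120-400 residues, 400 PSMs with 30% decoys,
and clearly separated target/decoy score distributions (Gaussians at 25 +- 3
versus 12 +- 3), under which every confidently planted site survives the 1%
FDR filter.  The ``nonenriched`` preset instead mimics a non-enriched
bacterial sample in miniature: a dominant oxidation-type label, a cation
adduct trio with two nearly indistinguishable mass shifts (0.0089 Da apart),
and a long tail of rare labels.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .annotation import ProteinCatalog, ProteinEntry, write_fasta
from .errors import PtmkitError
from .records import Modification, ModificationSite, PSMRecord, format_mass_shift
from .unimod import UnimodTable, load_bundled_table

AA = "ACDEFGHIKLMNPQRSTVWY"

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


@dataclass(frozen=True)
class PlantedMod:
    """One modification type in the planting palette."""

    name: str
    mass_shift: float
    residues: str  # residue letters the modification prefers
    weight: float = 1.0


DEFAULT_PALETTE = (
    PlantedMod("Phospho", 79.966331, "STY", 3.0),
    PlantedMod("Oxidation", 15.994915, "M", 3.0),
    PlantedMod("Acetyl", 42.010565, "K", 2.0),
    PlantedMod("Cation:K", 37.955882, "DE", 1.0),
    PlantedMod("unannotated", 103.0684, "S", 1.0),
)

NONENRICHED_PALETTE = (
    PlantedMod("Oxidation", 15.994915, "M", 10.0),
    PlantedMod("Cation:K", 37.955882, "DE", 4.0),
    PlantedMod("Cation:Ca[II]", 37.946941, "DE", 4.0),
    PlantedMod("Cation:Na", 21.981944, "DE", 3.0),
    PlantedMod("Phospho", 79.966331, "STY", 1.0),
    PlantedMod("Acetyl", 42.010565, "K", 1.0),
    PlantedMod("GG", 114.042927, "K", 0.5),
    PlantedMod("Formyl", 27.994915, "S", 0.5),
    PlantedMod("unannotated", 103.0684, "S", 0.5),
)


@dataclass(frozen=True)
class FixtureSpec:
    """Conditions for one synthetic dataset; the seed fixes all randomness."""

    n_proteins: int = 10
    length_range: tuple[int, int] = (120, 400)
    n_psms: int = 400
    decoy_fraction: float = 0.3
    palette: tuple[PlantedMod, ...] = DEFAULT_PALETTE
    target_score: tuple[float, float] = (25.0, 3.0)  # mean, sd
    decoy_score: tuple[float, float] = (12.0, 3.0)
    multi_protein_fraction: float = 0.05
    multi_localization_fraction: float = 0.05
    fdr_threshold: float = 0.01
    mass_tolerance: float = 0.001
    seed: int = 0

    def __post_init__(self):
        for name in ("decoy_fraction", "multi_protein_fraction",
                     "multi_localization_fraction"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {value}")


def nonenriched_spec(seed: int = 0, n_psms: int = 600) -> FixtureSpec:
    """Preset mimicking a non-enriched bacterial open search in miniature."""
    return FixtureSpec(palette=NONENRICHED_PALETTE, n_psms=n_psms, seed=seed)


def generate_proteome(spec: FixtureSpec) -> ProteinCatalog:
    """Random protein catalog: uniform sequences over the 20 amino acids,
    lengths uniform in ``spec.length_range``, accessions ``SYNP001``...

    Deterministic given ``spec.seed``; writing with
    :func:`ptmkit.annotation.write_fasta` is byte-stable.
    """
    rng = np.random.default_rng([spec.seed, 0])
    lo, hi = spec.length_range
    entries = []
    for index in range(spec.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        sequence = "".join(rng.choice(list(AA), size=length))
        accession = f"SYNP{index + 1:03d}"
        entries.append(ProteinEntry(accession=accession, sequence=sequence,
                                    name=f"{accession}_SYN"))
    return ProteinCatalog(entries)


def _expected_label(delta: float, table: UnimodTable, tolerance: float) -> tuple[str, Optional[str], Optional[int]]:
    """(label, class-key entry, unimod id) by brute-force linear scan."""
    hits = [e for e in table.entries if abs(e.mono_mass - delta) <= tolerance]
    if len(hits) == 1:
        return hits[0].name, None, hits[0].unimod_id
    return format_mass_shift(delta), "Ambiguous mass shift", None


def generate_synthetic_psms(
    spec: FixtureSpec, catalog: ProteinCatalog, table: Optional[UnimodTable] = None
) -> tuple[list[PSMRecord], dict]:
    """PSM list plus ground truth for the filtered pipeline output.

    Target peptides are unique substrings of their protein; each carries one
    planted modification on a palette-preferred residue.  Decoys get
    ``rev_``-prefixed accessions and scores from the decoy distribution.
    The returned truth dict lists the sites (and their expected labels and
    classes) that survive FDR filtering, decoy and multi-protein removal and
    the localization rule, together with the expected per-label site counts.
    """
    if table is None:
        table = load_bundled_table()
    rng = np.random.default_rng([spec.seed, 1])
    accessions = catalog.accessions()
    if not accessions and spec.n_psms:
        raise PtmkitError("cannot generate PSMs against an empty proteome")

    n_targets = round(spec.n_psms * (1.0 - spec.decoy_fraction))
    n_decoys = spec.n_psms - n_targets
    psms: list[PSMRecord] = []
    planted: list[dict] = []  # one entry per target PSM

    for index in range(n_targets):
        mod = rng.choice(
            spec.palette,
            p=np.array([m.weight for m in spec.palette])
            / sum(m.weight for m in spec.palette),
        )
        placed = None
        for _attempt in range(200):
            accession = str(rng.choice(accessions))
            sequence = catalog[accession].sequence
            length = int(rng.integers(8, 16))
            if len(sequence) <= length:
                continue
            start = int(rng.integers(0, len(sequence) - length))
            peptide = sequence[start:start + length]
            if sequence.count(peptide) != 1:
                continue
            residue_positions = [
                k + 1 for k, aa in enumerate(peptide) if aa in mod.residues
            ]
            if not residue_positions:
                continue
            pep_pos = int(rng.choice(residue_positions))
            placed = (accession, peptide, start + 1, pep_pos)
            break
        if placed is None:
            raise PtmkitError(
                "proteome does not support the requested number of distinct "
                "modified peptides; enlarge the proteome or shrink n_psms"
            )
        accession, peptide, pep_start, pep_pos = placed
        multi_protein = bool(rng.random() < spec.multi_protein_fraction)
        multi_loc = bool(rng.random() < spec.multi_localization_fraction)
        accs = (accession,)
        if multi_protein:
            other = str(rng.choice([a for a in accessions if a != accession])) \
                if len(accessions) > 1 else accession + "b"
            accs = (accession, other)
        score = float(rng.normal(*spec.target_score))
        psms.append(
            PSMRecord(
                spectrum_id=f"T{index:05d}",
                peptide=peptide,
                protein_accessions=accs,
                score=score,
                is_decoy=False,
                modifications=(
                    Modification(
                        peptide_position=pep_pos,
                        mass_shift=mod.mass_shift,
                        n_localizations=2 if multi_loc else 1,
                    ),
                ),
            )
        )
        planted.append(
            {
                "accession": accession,
                "position": pep_start + pep_pos - 1,
                "mass_shift": mod.mass_shift,
                "residue": peptide[pep_pos - 1],
                "score": score,
                "clean": not (multi_protein or multi_loc),
            }
        )

    for index in range(n_decoys):
        length = int(rng.integers(8, 16))
        peptide = "".join(rng.choice(list(AA), size=length))
        base = str(rng.choice(accessions)) if accessions else "SYNP000"
        psms.append(
            PSMRecord(
                spectrum_id=f"D{index:05d}",
                peptide=peptide,
                protein_accessions=(f"rev_{base}",),
                score=float(rng.normal(*spec.decoy_score)),
                is_decoy=True,
            )
        )

    order = rng.permutation(len(psms))
    psms = [psms[i] for i in order]

    # --- ground truth: inline target-decoy competition ------------------
    scored = sorted(psms, key=lambda p: p.score, reverse=True)
    survivors: set[int] = set()  # indices into `planted` via spectrum id
    n_dec = n_tar = 0
    raw = []
    for psm in scored:
        if psm.is_decoy:
            n_dec += 1
        else:
            n_tar += 1
        raw.append(n_dec / max(1, n_tar))
    q = raw[:]
    for k in range(len(q) - 2, -1, -1):
        q[k] = min(q[k], q[k + 1])
    passing_ids = {
        psm.spectrum_id
        for psm, qv in zip(scored, q)
        if not psm.is_decoy and qv <= spec.fdr_threshold
    }

    truth_sites: dict[tuple, dict] = {}
    for index, info in enumerate(planted):
        if not info["clean"] or f"T{index:05d}" not in passing_ids:
            continue
        label, forced_class, unimod_id = _expected_label(
            info["mass_shift"], table, spec.mass_tolerance
        )
        if forced_class is not None:
            mod_class = forced_class
        elif unimod_id is not None:
            entry = table.by_id[unimod_id]
            mod_class = entry.classifications.get(info["residue"], "Undefined")
        else:
            mod_class = "Undefined"
        key = (info["accession"], info["position"], label)
        truth_sites.setdefault(
            key, {"accession": info["accession"], "position": info["position"],
                  "label": label, "class": mod_class}
        )

    site_counts: dict[str, int] = {}
    class_counts: dict[str, int] = {}
    site_positions: dict[str, set] = {}
    for info in truth_sites.values():
        site_positions.setdefault(info["label"], set()).add(
            (info["accession"], info["position"])
        )
        class_counts[info["class"]] = class_counts.get(info["class"], 0) + 1
    site_counts = {label: len(v) for label, v in site_positions.items()}

    truth = {
        "sites": sorted(
            ([s["accession"], s["position"], s["label"], s["class"]]
             for s in truth_sites.values()),
        ),
        "site_counts": dict(sorted(site_counts.items())),
        "class_counts": dict(sorted(class_counts.items())),
        "n_target_psms": n_targets,
        "n_decoy_psms": n_decoys,
    }
    return psms, truth


# ---------------------------------------------------------------------------
# toy structures
# ---------------------------------------------------------------------------

def _pdb_atom(serial: int, name: str, resname: str, resseq: int,
              x: float, y: float, z: float) -> str:
    element = name[0]
    # strict PDB columns: name 13-16, altLoc 17, resName 18-20, chain 22
    return (
        f"ATOM  {serial:5d} {name:^4s} {resname:>3s} A{resseq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          {element:>2s}"
    )


def _write_chain(sequence: str, rep_points: Sequence[tuple[float, float, float]],
                 start_position: int = 1) -> str:
    """PDB text with the representative atom of each residue at the given
    point: Cβ there (Cα offset above) for non-glycine, Cα there for glycine."""
    lines = []
    serial = 1
    for offset, (aa, point) in enumerate(zip(sequence, rep_points)):
        resseq = start_position + offset
        resname = ONE_TO_THREE[aa]
        x, y, z = point
        if aa == "G":
            lines.append(_pdb_atom(serial, "CA", resname, resseq, x, y, z))
            serial += 1
        else:
            lines.append(_pdb_atom(serial, "CA", resname, resseq, x, y, z + 1.5))
            serial += 1
            lines.append(_pdb_atom(serial, "CB", resname, resseq, x, y, z))
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def _contacts_from_points(points, cutoff: float, min_separation: int,
                          positions: Optional[Sequence[int]] = None):
    if positions is None:
        positions = range(1, len(points) + 1)
    positions = list(positions)
    contacts = []
    for a in range(len(points)):
        for b in range(a + 1, len(points)):
            if abs(positions[a] - positions[b]) < min_separation:
                continue
            d = math.dist(points[a], points[b])
            if d < cutoff:
                contacts.append((positions[a], positions[b]))
    return sorted(contacts)


@dataclass
class ToyStructure:
    """A generated structure plus its expected contact set (the generator's
    ground truth, computed directly from the coordinates it placed)."""

    sequence: str
    geometry: str
    pdb_text: str
    rep_points: list[tuple[float, float, float]]
    expected_contacts: list[tuple[int, int]]
    cutoff: float
    min_separation: int

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.pdb_text, encoding="utf-8")


def generate_toy_structure(
    sequence: str,
    geometry: str = "hairpin",
    seed: int = 0,
    cutoff: float = 4.69,
    min_separation: int = 2,
    pairing_distance: float = 4.5,
) -> ToyStructure:
    """Ideal-geometry chain whose contact set is known in closed form.

    ``extended``: residues on a straight line, 3.8 Å apart — no contacts at
    separation >= 2.  ``hairpin``: two antiparallel strands; residue i pairs
    with residue L+1-i at ``pairing_distance`` (< cutoff), so the expected
    contacts are exactly the cross-strand pairs that clear the minimum
    separation.  ``helix``: an ideal alpha-helical arrangement (contacts as
    produced by the geometry; the ground truth is computed from the placed
    coordinates).  ``seed`` jitters nothing by default and is kept for
    interface stability.
    """
    L = len(sequence)
    if L < 3:
        raise ValueError("sequence must have at least 3 residues")
    spacing = 3.8
    if geometry == "extended":
        points = [(spacing * i, 0.0, 0.0) for i in range(L)]
    elif geometry == "hairpin":
        if L % 2:
            raise ValueError("hairpin needs an even-length sequence")
        half = L // 2
        points = [(spacing * i, 0.0, 0.0) for i in range(half)]
        points += [(spacing * (L - j - 1), pairing_distance, 0.0)
                   for j in range(half, L)]
    elif geometry == "helix":
        rise, turn, radius = 1.5, math.radians(100.0), 3.3
        points = [
            (radius * math.cos(turn * i), radius * math.sin(turn * i), rise * i)
            for i in range(L)
        ]
    elif geometry == "coil":
        # seeded self-avoiding-ish random walk with 3.8 A steps; produces
        # rich, irregular contact sets for oracle comparisons
        rng = np.random.default_rng(seed)
        pts = [np.zeros(3)]
        while len(pts) < L:
            step = rng.normal(size=3)
            step *= spacing / np.linalg.norm(step)
            candidate = pts[-1] + step
            if all(np.linalg.norm(candidate - q) > 2.0 for q in pts[-20:]):
                pts.append(candidate)
        points = [tuple(map(float, p)) for p in pts]
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    # PDB coordinates carry 3 decimals; the ground truth must use exactly
    # the coordinates the file stores
    points = [tuple(round(v, 3) for v in p) for p in points]
    return ToyStructure(
        sequence=sequence,
        geometry=geometry,
        pdb_text=_write_chain(sequence, points),
        rep_points=list(points),
        expected_contacts=_contacts_from_points(points, cutoff, min_separation),
        cutoff=cutoff,
        min_separation=min_separation,
    )


def hairpin_closed_form(L: int, min_separation: int = 2) -> list[tuple[int, int]]:
    """The analytic hairpin contact set: pairs (i, L+1-i) for i = 1..L/2 with
    separation |L+1-2i| >= min_separation."""
    return sorted(
        (i, L + 1 - i)
        for i in range(1, L // 2 + 1)
        if abs(L + 1 - 2 * i) >= min_separation
    )


# ---------------------------------------------------------------------------
# synthetic chaperonin scenario
# ---------------------------------------------------------------------------

def synthetic_groel_scenario(
    phospho_position: int = 506,
    contact_position: int = 80,
    contact_distance: float = 4.41,
    length: int = 548,
) -> tuple[ProteinCatalog, list[ModificationSite], ToyStructure]:
    """SYNTHETIC stand-in for the GroEL phosphosite-contact scenario.

    Builds a synthetic 548-residue chaperonin-like protein with a lysine at
    position 80 and a phosphorylated tyrosine at position 506, plus a
    structure in which the Cβ atoms of those two residues sit exactly
    ``contact_distance`` Å apart (all other non-neighbor pairs are far).
    This exercises the structure machinery end-to-end on a fold-back loop
    geometry; it is generated, not the AlphaFold model.
    """
    rng = np.random.default_rng(80506)
    sequence = list("".join(rng.choice(list(AA), size=length)))
    sequence[contact_position - 1] = "K"
    sequence[phospho_position - 1] = "Y"
    sequence = "".join(sequence)

    spacing = 3.8
    points = [(spacing * i, 0.0, 0.0) for i in range(length)]
    # fold position `phospho_position` back next to `contact_position`
    anchor = points[contact_position - 1]
    points[phospho_position - 1] = (anchor[0], contact_distance, 0.0)

    toy = ToyStructure(
        sequence=sequence,
        geometry="synthetic-groel-loop",
        pdb_text=_write_chain(sequence, points),
        rep_points=points,
        expected_contacts=_contacts_from_points(points, 4.69, 2),
        cutoff=4.69,
        min_separation=2,
    )
    entry = ProteinEntry(accession="SYNGROEL", sequence=sequence,
                         name="CH60_SYNTH")
    site = ModificationSite(
        protein_accession="SYNGROEL",
        position=phospho_position,
        mass_shift=79.966331,
        residue="Y",
    )
    return ProteinCatalog([entry]), [site], toy


def write_fixture_files(spec: FixtureSpec, outdir: str | Path) -> dict[str, Path]:
    """Emit a complete fixture dataset (FASTA, normalized PSM TSV, truth
    JSON) into ``outdir``; returns the paths."""
    from .ingest import write_normalized_psm_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    catalog = generate_proteome(spec)
    psms, truth = generate_synthetic_psms(spec, catalog)
    paths = {
        "fasta": outdir / "proteome.fasta",
        "psms": outdir / "psms.tsv",
        "truth": outdir / "psms.truth.json",
    }
    write_fasta(catalog, paths["fasta"])
    write_normalized_psm_table(psms, paths["psms"])
    paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True),
                              encoding="utf-8")
    return paths
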