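"""Sample-level and protein-level summary structures.

A *site* for counting purposes is a distinct (protein accession, position)
pair; spectral multiplicity never inflates counts.  Sample-level summaries
cover: sites per modification type, the symmetric shared-site matrix (how
many sites carry both of two types), the per-type mass shifts, the UniMod
class distribution, and the pairs of types flagged as hard to distinguish
by mass.  Protein-level summaries cover: the presence/absence matrix (types
x positions, rows ordered by ascending mass shift), per-position counts
partitioned by class, and the amino-acid x modification heatmap normalized
per amino acid (each residue row is divided by its row sum, so rows sum to
1 where the residue has any site, and stay all-zero otherwise; raw counts
are kept alongside).

All summaries are permutation-invariant in the input site order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import UsageError
from .records import AmbiguousPair, ModificationSite, ModificationType
from .unimod import flag_ambiguous_pairs

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")


def _label(site: ModificationSite) -> str:
    if site.label is None:
        raise ValueError(f"site {site.protein_accession}:{site.position} is unlabeled")
    return site.label


def _distinct(sites: Sequence[ModificationSite]) -> list[ModificationSite]:
    """One representative per (protein, position, label)."""
    seen: dict[tuple, ModificationSite] = {}
    for site in sites:
        seen.setdefault((site.protein_accession, site.position, _label(site)), site)
    return list(seen.values())


def site_counts(sites: Sequence[ModificationSite]) -> dict[str, int]:
    """Number of distinct (protein, position) sites per modification label."""
    counts: dict[str, set] = {}
    for site in sites:
        counts.setdefault(_label(site), set()).add(
            (site.protein_accession, site.position)
        )
    return {label: len(positions) for label, positions in counts.items()}


def mass_shifts(sites: Sequence[ModificationSite]) -> dict[str, Optional[float]]:
    """Representative numeric mass shift per label (None when unavailable)."""
    shifts: dict[str, Optional[float]] = {}
    for site in sites:
        label = _label(site)
        if shifts.get(label) is None:
            shifts[label] = site.display_mass()
    return shifts


def modification_types(sites: Sequence[ModificationSite]) -> list[ModificationType]:
    counts = site_counts(sites)
    shifts = mass_shifts(sites)
    return [
        ModificationType(label=label, mass_shift=shifts[label], count=counts[label])
        for label in sorted(counts)
    ]


def modification_axis(
    types: Sequence[ModificationType], sort_key: str = "mass_shift"
) -> list[str]:
    """Order labels for plotting axes.

    ``mass_shift``: ascending mass, ties and missing masses lexicographic;
    ``count``: descending site count, ties lexicographic.
    """
    if sort_key == "mass_shift":
        ordered = sorted(
            types,
            key=lambda t: (t.mass_shift is None,
                           t.mass_shift if t.mass_shift is not None else 0.0,
                           t.label),
        )
    elif sort_key == "count":
        ordered = sorted(types, key=lambda t: (-t.count, t.label))
    else:
        raise UsageError(f"unknown sort_key {sort_key!r}; use 'mass_shift' or 'count'")
    return [t.label for t in ordered]


def shared_site_matrix(sites: Sequence[ModificationSite]) -> pd.DataFrame:
    """Symmetric label x label matrix of shared sites.

    Cell (a, b) counts distinct (protein, position) pairs carrying both label
    a and label b; the diagonal equals :func:`site_counts`.
    """
    per_site_labels: dict[tuple, set] = {}
    for site in sites:
        per_site_labels.setdefault(
            (site.protein_accession, site.position), set()
        ).add(_label(site))
    labels = sorted({l for ls in per_site_labels.values() for l in ls})
    index = {label: i for i, label in enumerate(labels)}
    matrix = np.zeros((len(labels), len(labels)), dtype=int)
    for site_labels in per_site_labels.values():
        for a, b in itertools.combinations_with_replacement(sorted(site_labels), 2):
            matrix[index[a], index[b]] += 1
            if a != b:
                matrix[index[b], index[a]] += 1
    return pd.DataFrame(matrix, index=labels, columns=labels)


def class_distribution(sites: Sequence[ModificationSite]) -> dict[str, int]:
    """Site counts per resolved UniMod class (one count per distinct
    (protein, position, label) event)."""
    counts: dict[str, int] = {}
    for site in _distinct(sites):
        cls = site.mod_class or "Undefined"
        counts[cls] = counts.get(cls, 0) + 1
    return counts


def presence_absence(
    protein, sites: Sequence[ModificationSite]
) -> pd.DataFrame:
    """Boolean matrix: rows = labels sorted by ascending mass shift (ties
    lexicographic), columns = positions 1..L of ``protein``."""
    accession = getattr(protein, "accession", None)
    length = getattr(protein, "length", None) or len(protein.sequence)
    mine = [s for s in sites
            if accession is None or s.protein_accession == accession]
    types = modification_types(mine)
    labels = modification_axis(types, "mass_shift")
    matrix = pd.DataFrame(
        False, index=labels, columns=pd.RangeIndex(1, length + 1)
    )
    for site in mine:
        if site.position <= length:
            matrix.loc[_label(site), site.position] = True
    return matrix


def per_position_counts(
    protein, sites: Sequence[ModificationSite]
) -> pd.DataFrame:
    """Distinct modification labels per position, partitioned by class.

    Returns a positions x classes count frame whose row totals equal the
    column sums of :func:`presence_absence`.
    """
    accession = getattr(protein, "accession", None)
    length = getattr(protein, "length", None) or len(protein.sequence)
    mine = _distinct(
        s for s in sites
        if accession is None or s.protein_accession == accession
    )
    classes = sorted({s.mod_class or "Undefined" for s in mine})
    frame = pd.DataFrame(
        0, index=pd.RangeIndex(1, length + 1), columns=classes, dtype=int
    )
    for site in mine:
        if site.position <= length:
            frame.loc[site.position, site.mod_class or "Undefined"] += 1
    return frame


@dataclass
class AAModHeatmap:
    """Amino-acid x modification heatmap; ``normalized`` rows are the raw
    rows divided by their row sum (zero rows stay zero)."""

    raw: pd.DataFrame
    normalized: pd.DataFrame


def aa_mod_heatmap(sites: Sequence[ModificationSite], catalog=None) -> AAModHeatmap:
    """Distinct sites per (residue letter, label), normalized per amino acid.

    Sites must carry residue letters (run annotation validation first);
    sites without one are ignored.
    """
    mine = [s for s in _distinct(sites) if s.residue]
    labels = modification_axis(modification_types(mine), "mass_shift") if mine else []
    raw = pd.DataFrame(0, index=list(AMINO_ACIDS), columns=labels, dtype=int)
    for site in mine:
        if site.residue in raw.index:
            raw.loc[site.residue, _label(site)] += 1
    sums = raw.sum(axis=1)
    normalized = raw.astype(float)
    nonzero = sums > 0
    normalized.loc[nonzero] = normalized.loc[nonzero].div(sums[nonzero], axis=0)
    return AAModHeatmap(raw=raw, normalized=normalized)


@dataclass
class SampleSummary:
    """The sample-level overview: what was modified, how often, how
    ambiguously."""

    types: list[ModificationType]
    site_counts: dict[str, int]
    mass_shifts: dict[str, Optional[float]]
    shared: pd.DataFrame
    class_counts: dict[str, int]
    ambiguous_pairs: list[AmbiguousPair]

    def to_dict(self) -> dict:
        labels = list(self.shared.index)
        cells = []
        for i, a in enumerate(labels):
            for j in range(i, len(labels)):
                value = int(self.shared.iat[i, j])
                if value:
                    cells.append([a, labels[j], value])
        return {
            "types": [
                {"label": t.label, "mass_shift": t.mass_shift, "count": t.count}
                for t in self.types
            ],
            "site_counts": dict(sorted(self.site_counts.items())),
            "mass_shifts": dict(sorted(self.mass_shifts.items())),
            "shared": {"labels": labels, "cells": cells},
            "class_counts": dict(sorted(self.class_counts.items())),
            "ambiguous_pairs": [
                {"a": p.label_a, "b": p.label_b, "difference": p.difference}
                for p in self.ambiguous_pairs
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SampleSummary":
        labels = d["shared"]["labels"]
        shared = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
        for a, b, value in d["shared"]["cells"]:
            shared.loc[a, b] = value
            shared.loc[b, a] = value
        return cls(
            types=[ModificationType(t["label"], t["mass_shift"], t["count"])
                   for t in d["types"]],
            site_counts=dict(d["site_counts"]),
            mass_shifts=dict(d["mass_shifts"]),
            shared=shared,
            class_counts=dict(d["class_counts"]),
            ambiguous_pairs=[
                AmbiguousPair(p["a"], p["b"], p["difference"])
                for p in d["ambiguous_pairs"]
            ],
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, SampleSummary):
            return NotImplemented
        return self.to_dict() == other.to_dict()


def build_sample_summary(
    sites: Sequence[ModificationSite], ambiguity_threshold: float = 0.02
) -> SampleSummary:
    types = modification_types(sites)
    return SampleSummary(
        types=types,
        site_counts=site_counts(sites),
        mass_shifts=mass_shifts(sites),
        shared=shared_site_matrix(sites),
        class_counts=class_distribution(sites),
        ambiguous_pairs=flag_ambiguous_pairs(types, ambiguity_threshold),
    )


@dataclass
class ProteinSummary:
    """The per-protein view: where each modification type sits on the
    sequence, and how types distribute over amino acids."""

    accession: str
    length: int
    presence: pd.DataFrame
    per_position: pd.DataFrame
    site_counts: dict[str, int]
    heatmap: AAModHeatmap

    def to_dict(self) -> dict:
        presence_cells = [
            [str(label), int(position)]
            for label in self.presence.index
            for position in self.presence.columns[self.presence.loc[label].to_numpy()]
        ]
        pp_cells = [
            [int(position), str(cls), int(self.per_position.loc[position, cls])]
            for position in self.per_position.index
            for cls in self.per_position.columns
            if self.per_position.loc[position, cls]
        ]
        hm_cells = [
            [aa, str(label), int(self.heatmap.raw.loc[aa, label])]
            for aa in self.heatmap.raw.index
            for label in self.heatmap.raw.columns
            if self.heatmap.raw.loc[aa, label]
        ]
        return {
            "accession": self.accession,
            "length": self.length,
            "presence": {"labels": list(self.presence.index), "cells": presence_cells},
            "per_position": pp_cells,
            "site_counts": dict(sorted(self.site_counts.items())),
            "heatmap_raw": hm_cells,
        }


def build_protein_summary(protein, sites: Sequence[ModificationSite]) -> ProteinSummary:
    accession = protein.accession
    mine = [s for s in sites if s.protein_accession == accession]
    return ProteinSummary(
        accession=accession,
        length=protein.length,
        presence=presence_absence(protein, mine),
        per_position=per_position_counts(protein, mine),
        site_counts=site_counts(mine),
        heatmap=aa_mod_heatmap(mine),
    )


def long_format_tsv(frame: pd.DataFrame, value_name: str = "value") -> str:
    """Serialize a matrix as long-format TSV, one line per nonzero cell."""
    lines = [f"row\tcolumn\t{value_name}"]
    for row in frame.index:
        for column in frame.columns:
            value = frame.loc[row, column]
            if value:
                lines.append(f"{row}\t{column}\t{value}")
    return "\n".join(lines) + "\n"
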