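"""Core domain records shared across the pipeline.

The pipeline normalizes every supported input into two record kinds:

* :class:`PSMRecord` — one peptide-spectrum match, the unit on which
  confidence filtering (target-decoy FDR) operates.
* :class:`ModificationSite` — one (protein, residue position, modification)
  event in protein coordinates, the unit on which all summaries operate.

Positions are 1-based and inclusive throughout, matching UniProt and the
outputs of the supported search engines.  An N-terminal modification is
encoded as peptide position 0 and, once mapped onto the protein, lands on the
peptide's first residue with ``is_nterm`` set.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Optional

_PEPTIDE_RE = re.compile(r"^[A-Z]+$")

#: Display label used for sites whose mass shift matches zero or several
#: UniMod entries at the configured tolerance.
AMBIGUOUS_CLASS = "Ambiguous mass shift"

#: Class assigned when a UniMod entry does not classify the site's residue,
#: or when a named modification cannot be resolved at all.
UNDEFINED_CLASS = "Undefined"


def format_mass_shift(delta: float) -> str:
    """Signed fixed-point label for an unresolved mass shift, e.g. ``+103.0684``."""
    return f"{delta:+.4f}"


@dataclass(frozen=True)
class SiteRecord:
    """A site-level input row: (protein accession, position, modification name)."""

    protein_accession: str
    position: int
    mod_name: str
    mass_shift: Optional[float] = None

    def __post_init__(self):
        if not self.protein_accession:
            raise ValueError("protein_accession must be non-empty")
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")


@dataclass(frozen=True)
class Modification:
    """One modification on a peptide.

    ``peptide_position`` is 1-based within the peptide; 0 denotes the peptide
    N-terminus.  ``n_localizations`` counts the candidate positions the search
    engine reported for this mass shift (1 = confidently localized).
    ``n_components`` counts the named modifications the engine used to explain
    the mass shift (>1 = a combination, removed under the MSFragger rules).
    """

    peptide_position: int
    mass_shift: float
    name: Optional[str] = None
    n_localizations: int = 1
    n_components: int = 1


@dataclass(frozen=True)
class PSMRecord:
    """A normalized peptide-spectrum match."""

    spectrum_id: str
    peptide: str
    protein_accessions: tuple[str, ...]
    score: Optional[float] = None
    q_value: Optional[float] = None
    is_decoy: bool = False
    modifications: tuple[Modification, ...] = ()

    def __post_init__(self):
        if not _PEPTIDE_RE.match(self.peptide):
            raise ValueError(f"peptide must match [A-Z]+, got {self.peptide!r}")
        if self.q_value is not None and not (0.0 <= self.q_value <= 1.0):
            raise ValueError(f"q_value must be in [0, 1], got {self.q_value}")
        for mod in self.modifications:
            if mod.peptide_position > len(self.peptide):
                raise ValueError(
                    f"modification position {mod.peptide_position} beyond "
                    f"peptide of length {len(self.peptide)}"
                )

    def with_q_value(self, q: float) -> "PSMRecord":
        return replace(self, q_value=q)


@dataclass
class ModificationSite:
    """A modification event in protein coordinates.

    ``label`` is the display label (UniMod name for a unique match, the
    formatted mass shift otherwise) and is ``None`` until UniMod assignment.
    ``candidates`` keeps the full UniMod candidate list so ambiguity stays
    queryable after a label was chosen.
    """

    protein_accession: str
    position: int
    mass_shift: Optional[float] = None
    source_name: Optional[str] = None
    label: Optional[str] = None
    unimod_id: Optional[int] = None
    mod_class: Optional[str] = None
    candidates: tuple[int, ...] = ()
    residue: Optional[str] = None
    spectral_count: int = 1
    is_nterm: bool = False

    def display_mass(self) -> Optional[float]:
        """Numeric mass shift for sorting; parses ambiguous labels like ``+103.0684``."""
        if self.mass_shift is not None:
            return self.mass_shift
        if self.label is not None:
            try:
                return float(self.label)
            except ValueError:
                return None
        return None


@dataclass(frozen=True)
class ModificationType:
    """A modification type as it appears in sample-level summaries."""

    label: str
    mass_shift: Optional[float]
    count: int = 0


@dataclass(frozen=True)
class AmbiguousPair:
    """Two modification types whose mass shifts are closer than a threshold."""

    label_a: str
    label_b: str
    difference: float

    def __post_init__(self):
        # canonical order so pairs compare equal regardless of input order
        if self.label_b < self.label_a:
            a, b = self.label_a, self.label_b
            object.__setattr__(self, "label_a", b)
            object.__setattr__(self, "label_b", a)


@dataclass
class FilterReport:
    """Tally of PSMs removed per filtering rule; removed + retained = input."""

    fdr: int = 0
    decoy: int = 0
    multi_protein: int = 0
    msfragger_combination: int = 0
    msfragger_localization: int = 0
    unmapped_peptide: int = 0
    missing_protein: int = 0
    retained: int = 0

    RULES = (
        "fdr",
        "decoy",
        "multi_protein",
        "msfragger_combination",
        "msfragger_localization",
        "unmapped_peptide",
        "missing_protein",
    )

    @property
    def removed(self) -> int:
        return sum(getattr(self, rule) for rule in self.RULES)

    def to_dict(self) -> dict:
        d = {rule: getattr(self, rule) for rule in self.RULES}
        d["retained"] = self.retained
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FilterReport":
        return cls(**{k: int(v) for k, v in d.items()})


__all__ = [
    "AMBIGUOUS_CLASS",
    "UNDEFINED_CLASS",
    "AmbiguousPair",
    "FilterReport",
    "Modification",
    "ModificationSite",
    "ModificationType",
    "PSMRecord",
    "SiteRecord",
    "format_mass_shift",
]
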