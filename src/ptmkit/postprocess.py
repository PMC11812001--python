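"""Confidence filtering and protein-coordinate site extraction.

Filtering follows the standard open-search postprocessing recipe: PSMs are
kept at a q-value threshold (default 1% FDR via target-decoy competition),
decoy matches and peptides mapping to multiple proteins are removed, and —
for MSFragger-style open results — PSMs whose mass shift is explained by a
combination of modifications or localized to more than one candidate
position are dropped as unreliable.

The filter order is fixed (fdr, decoy, multi_protein, msfragger_combination,
msfragger_localization) so the :class:`~ptmkit.records.FilterReport` tallies
are reproducible: a PSM failing several rules is charged to the first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional

from .errors import UnfilterableError
from .records import FilterReport, Modification, ModificationSite, PSMRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterConfig:
    """Configuration for :func:`apply_filters`.

    fdr_threshold
        q-value cutoff as a fraction (0.01 = 1% FDR).
    drop_decoys, drop_multi_protein
        Remove decoy matches / peptides mapping to more than one protein.
    msfragger_rules
        Apply the open-search combination and multi-localization drop rules.
    """

    fdr_threshold: float = 0.01
    drop_decoys: bool = True
    drop_multi_protein: bool = True
    msfragger_rules: bool = True

    def __post_init__(self):
        if not (0.0 < self.fdr_threshold <= 1.0):
            raise ValueError(f"fdr_threshold must be in (0, 1], got {self.fdr_threshold}")


def compute_qvalues(psms: list[PSMRecord]) -> list[PSMRecord]:
    """Assign target-decoy q-values to PSMs that do not already carry one.

    At each score ``s`` the raw FDR is ``#decoys(score >= s) / max(1,
    #targets(score >= s))``; the q-value is the running minimum of the raw
    FDR taken from the worst score upward, so q-values are non-decreasing as
    the score decreases.  PSMs with an engine-provided q-value keep it.
    Output order equals input order.
    """
    if not psms:
        return []
    if all(p.q_value is not None for p in psms):
        return list(psms)
    if any(p.score is None for p in psms if p.q_value is None):
        raise UnfilterableError(
            "PSMs carry neither scores nor q-values; disable FDR filtering "
            "(FilterConfig(fdr_threshold=1.0)) or provide scores"
        )

    order = sorted(range(len(psms)), key=lambda i: psms[i].score, reverse=True)
    raw: list[float] = []
    n_decoys = n_targets = 0
    for rank, i in enumerate(order):
        if psms[i].is_decoy:
            n_decoys += 1
        else:
            n_targets += 1
        # PSMs tied on score share counts; defer the ratio to the last of a tie run
        raw.append(0.0)
        raw[rank] = (n_decoys, n_targets)
    # resolve ties: counts at a score = counts at the last PSM with that score
    for rank in range(len(order) - 2, -1, -1):
        if psms[order[rank]].score == psms[order[rank + 1]].score:
            raw[rank] = raw[rank + 1]
    fdrs = [d / max(1, t) for d, t in raw]
    qvals = fdrs[:]
    for rank in range(len(order) - 2, -1, -1):
        qvals[rank] = min(qvals[rank], qvals[rank + 1])

    out = list(psms)
    for rank, i in enumerate(order):
        if out[i].q_value is None:
            out[i] = out[i].with_q_value(min(1.0, qvals[rank]))
    return out


def _has_combination(psm: PSMRecord) -> bool:
    return any(m.n_components > 1 for m in psm.modifications)


def _has_multi_localization(psm: PSMRecord) -> bool:
    return any(m.n_localizations > 1 for m in psm.modifications)


def apply_filters(
    psms: list[PSMRecord], cfg: FilterConfig = FilterConfig()
) -> tuple[list[PSMRecord], FilterReport]:
    """Apply the confidence and disambiguation filters, tallying removals."""
    report = FilterReport()
    kept: list[PSMRecord] = []
    for psm in psms:
        if psm.q_value is not None and psm.q_value > cfg.fdr_threshold:
            report.fdr += 1
        elif cfg.drop_decoys and psm.is_decoy:
            report.decoy += 1
        elif cfg.drop_multi_protein and len(psm.protein_accessions) > 1:
            report.multi_protein += 1
        elif cfg.msfragger_rules and _has_combination(psm):
            report.msfragger_combination += 1
        elif cfg.msfragger_rules and _has_multi_localization(psm):
            report.msfragger_localization += 1
        else:
            kept.append(psm)
    report.retained = len(kept)
    return kept, report


def _sequence_of(entry) -> str:
    return entry if isinstance(entry, str) else entry.sequence


def extract_sites(
    psms: list[PSMRecord],
    proteome: Mapping[str, object],
    report: Optional[FilterReport] = None,
) -> list[ModificationSite]:
    """Map peptide-level modifications onto protein coordinates.

    ``proteome`` maps accession to either a plain sequence string or an
    object with a ``sequence`` attribute (a
    :class:`~ptmkit.annotation.ProteinEntry`).  The peptide must occur
    exactly once in its protein; ambiguous or absent peptides are dropped and
    tallied as ``unmapped_peptide`` in ``report``.  Duplicate (protein,
    position, modification) events are collapsed with a spectral count.
    Site position = peptide start (1-based) + peptide position - 1; an
    N-terminal modification (peptide position 0) lands on the peptide's first
    residue with ``is_nterm`` set.
    """
    if report is None:
        report = FilterReport(retained=len(psms))

    def drop(rule: str) -> None:
        setattr(report, rule, getattr(report, rule) + 1)
        report.retained = max(0, report.retained - 1)

    collapsed: dict[tuple, ModificationSite] = {}
    for psm in psms:
        if len(psm.protein_accessions) != 1:
            drop("multi_protein")
            continue
        accession = psm.protein_accessions[0]
        entry = proteome.get(accession)
        if entry is None:
            drop("missing_protein")
            logger.warning("protein %s absent from catalog; PSM %s dropped",
                           accession, psm.spectrum_id)
            continue
        sequence = _sequence_of(entry)
        first = sequence.find(psm.peptide)
        if first < 0 or sequence.find(psm.peptide, first + 1) >= 0:
            drop("unmapped_peptide")
            continue
        start = first + 1  # 1-based
        for mod in psm.modifications:
            is_nterm = mod.peptide_position == 0
            position = start + max(mod.peptide_position, 1) - 1
            key = (
                accession,
                position,
                mod.name,
                None if mod.mass_shift is None else round(mod.mass_shift, 6),
            )
            site = collapsed.get(key)
            if site is None:
                collapsed[key] = ModificationSite(
                    protein_accession=accession,
                    position=position,
                    mass_shift=mod.mass_shift,
                    source_name=mod.name,
                    is_nterm=is_nterm,
                )
            else:
                site.spectral_count += 1
    return list(collapsed.values())


def sites_from_records(records) -> list[ModificationSite]:
    """Convert generic-CSV :class:`SiteRecord` rows into modification sites,
    collapsing duplicates with a spectral count."""
    collapsed: dict[tuple, ModificationSite] = {}
    for rec in records:
        key = (rec.protein_accession, rec.position, rec.mod_name,
               None if rec.mass_shift is None else round(rec.mass_shift, 6))
        site = collapsed.get(key)
        if site is None:
            collapsed[key] = ModificationSite(
                protein_accession=rec.protein_accession,
                position=rec.position,
                mass_shift=rec.mass_shift,
                source_name=rec.mod_name,
            )
        else:
            site.spectral_count += 1
    return list(collapsed.values())
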