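"""Session persistence and the end-to-end processing pipeline.

A :class:`Session` is the fully processed dataset: configuration echo,
protein catalog, labeled modification sites, the sample-level summary and
the filter report.  Protein-level summaries are computed on demand from the
stored sites.

Sessions serialize as canonical JSON (sorted keys, no whitespace) compressed
with zlib, so saving is deterministic — identical inputs and configs yield
byte-identical files — and the format stays portable across implementations.
The payload carries a format version that is checked on load.

:func:`run_pipeline` drives the fixed stage order: ingest -> q-value
computation -> confidence filters -> site extraction -> coordinate
validation -> UniMod labeling -> class exclusion -> summaries.  Site-level
(generic CSV) inputs skip the PSM-only stages.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from . import ingest
from .annotation import (
    ProteinCatalog,
    ProteinEntry,
    AnnotationFeature,
    load_annotation_tracks,
    load_fasta,
    validate_sites,
)
from .errors import IntegrityError, PipelineError, PtmkitError, UsageError, VersionError
from .postprocess import (
    FilterConfig,
    apply_filters,
    compute_qvalues,
    extract_sites,
    sites_from_records,
)
from .records import FilterReport, ModificationSite
from .summaries import (
    SampleSummary,
    build_protein_summary,
    build_sample_summary,
)
from .unimod import (
    MatchConfig,
    UnimodTable,
    exclude_classes,
    label_sites,
    load_bundled_table,
    load_unimod_table,
)

logger = logging.getLogger(__name__)

FORMAT_VERSION = 1

STAGE_ORDER = (
    "ingest",
    "qvalues",
    "filters",
    "extract_sites",
    "validate",
    "label",
    "exclude_classes",
    "summaries",
)


def _site_to_dict(site: ModificationSite) -> dict:
    return {
        "protein_accession": site.protein_accession,
        "position": site.position,
        "mass_shift": site.mass_shift,
        "source_name": site.source_name,
        "label": site.label,
        "unimod_id": site.unimod_id,
        "mod_class": site.mod_class,
        "candidates": list(site.candidates),
        "residue": site.residue,
        "spectral_count": site.spectral_count,
        "is_nterm": site.is_nterm,
    }


def _site_from_dict(d: dict) -> ModificationSite:
    return ModificationSite(
        protein_accession=d["protein_accession"],
        position=d["position"],
        mass_shift=d["mass_shift"],
        source_name=d["source_name"],
        label=d["label"],
        unimod_id=d["unimod_id"],
        mod_class=d["mod_class"],
        candidates=tuple(d["candidates"]),
        residue=d["residue"],
        spectral_count=d["spectral_count"],
        is_nterm=d["is_nterm"],
    )


def _catalog_to_dict(catalog: ProteinCatalog) -> dict:
    return {
        entry.accession: {
            "name": entry.name,
            "sequence": entry.sequence,
            "tracks": [
                {"kind": f.kind, "start": f.start, "end": f.end,
                 "description": f.description}
                for f in entry.tracks
            ],
        }
        for entry in catalog
    }


def _catalog_from_dict(d: dict) -> ProteinCatalog:
    catalog = ProteinCatalog()
    for accession in sorted(d):
        info = d[accession]
        entry = ProteinEntry(accession=accession, sequence=info["sequence"],
                             name=info["name"])
        entry.tracks = [
            AnnotationFeature(kind=t["kind"], start=t["start"], end=t["end"],
                              description=t["description"])
            for t in info["tracks"]
        ]
        catalog.add(entry)
    return catalog


@dataclass
class Session:
    """The processed dataset, ready to query, summarize, and persist."""

    filter_cfg: FilterConfig
    match_cfg: MatchConfig
    contact_cutoff: float
    min_separation: int
    catalog: ProteinCatalog
    sites: list[ModificationSite]
    sample_summary: SampleSummary
    filter_report: FilterReport
    format_version: int = FORMAT_VERSION

    def protein_summary(self, accession: str):
        """Protein-level summary for one accession, computed on demand."""
        entry = self.catalog.get(accession)
        if entry is None:
            raise UsageError(f"accession {accession!r} not in catalog")
        return build_protein_summary(entry, self.sites)

    def sites_for(self, accession: str) -> list[ModificationSite]:
        return [s for s in self.sites if s.protein_accession == accession]

    def to_dict(self) -> dict:
        return {
            "format_version": self.format_version,
            "configs": {
                "filter": {
                    "fdr_threshold": self.filter_cfg.fdr_threshold,
                    "drop_decoys": self.filter_cfg.drop_decoys,
                    "drop_multi_protein": self.filter_cfg.drop_multi_protein,
                    "msfragger_rules": self.filter_cfg.msfragger_rules,
                },
                "match": {
                    "mass_tolerance": self.match_cfg.mass_tolerance,
                    "ambiguity_flag_threshold": self.match_cfg.ambiguity_flag_threshold,
                    "excluded_classes": sorted(self.match_cfg.excluded_classes),
                },
                "contact_cutoff": self.contact_cutoff,
                "min_separation": self.min_separation,
            },
            "catalog": _catalog_to_dict(self.catalog),
            "sites": sorted(
                (_site_to_dict(s) for s in self.sites),
                key=lambda d: (d["protein_accession"], d["position"],
                               d["label"] or "", d["mass_shift"] or 0.0),
            ),
            "sample_summary": self.sample_summary.to_dict(),
            "filter_report": self.filter_report.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Session":
        version = d.get("format_version")
        if version != FORMAT_VERSION:
            raise VersionError(
                f"session format version {version!r} is not supported "
                f"(this reader handles version {FORMAT_VERSION})"
            )
        cfg = d["configs"]
        return cls(
            format_version=version,
            filter_cfg=FilterConfig(**cfg["filter"]),
            match_cfg=MatchConfig(
                mass_tolerance=cfg["match"]["mass_tolerance"],
                ambiguity_flag_threshold=cfg["match"]["ambiguity_flag_threshold"],
                excluded_classes=frozenset(cfg["match"]["excluded_classes"]),
            ),
            contact_cutoff=cfg["contact_cutoff"],
            min_separation=cfg["min_separation"],
            catalog=_catalog_from_dict(d["catalog"]),
            sites=[_site_from_dict(s) for s in d["sites"]],
            sample_summary=SampleSummary.from_dict(d["sample_summary"]),
            filter_report=FilterReport.from_dict(d["filter_report"]),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, Session):
            return NotImplemented
        return self.to_dict() == other.to_dict()


def save_session(session: Session, path: str | Path) -> None:
    """Serialize as canonical JSON, deflate-compress, write to ``path``.

    Saving the same session twice yields byte-identical files."""
    payload = json.dumps(
        session.to_dict(), sort_keys=True, separators=(",", ":"), allow_nan=False
    ).encode("utf-8")
    Path(path).write_bytes(zlib.compress(payload, level=9))


def load_session(path: str | Path) -> Session:
    """Reload a session file written by :func:`save_session`.

    Corrupt or truncated streams raise :class:`IntegrityError`; an
    unsupported format version raises :class:`VersionError`."""
    blob = Path(path).read_bytes()
    try:
        payload = zlib.decompress(blob)
        data = json.loads(payload.decode("utf-8"))
    except (zlib.error, ValueError, UnicodeDecodeError) as exc:
        raise IntegrityError(f"{path}: not a valid session file: {exc}")
    if not isinstance(data, dict):
        raise IntegrityError(f"{path}: not a valid session payload")
    return Session.from_dict(data)


def run_pipeline(
    input_path: str | Path,
    *,
    dialect: str = "auto",
    fasta: Optional[str | Path] = None,
    features: Optional[str | Path] = None,
    unimod_table: Optional[str | Path | UnimodTable] = None,
    filter_cfg: FilterConfig = FilterConfig(),
    match_cfg: MatchConfig = MatchConfig(),
    contact_cutoff: float = 4.69,
    min_separation: int = 2,
) -> Session:
    """Run the full processing pipeline over one input file.

    ``dialect='auto'`` detects the input format from its header.  PSM-level
    inputs require ``fasta`` for peptide-to-protein mapping; site-level
    (generic CSV) inputs use it only for residue validation when provided.
    Stage failures are re-raised as :class:`PipelineError` naming the stage.
    """
    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc)
        return wrap

    logger.info("stage order: %s", " -> ".join(STAGE_ORDER))
    if dialect == "auto":
        dialect = stage("ingest")(ingest.detect_dialect, input_path)
        logger.info("detected dialect: %s", dialect)

    if isinstance(unimod_table, UnimodTable):
        table = unimod_table
    elif unimod_table is not None:
        table = stage("label")(load_unimod_table, unimod_table)
    else:
        table = load_bundled_table()

    catalog = ProteinCatalog()
    if fasta is not None:
        catalog = stage("validate")(load_fasta, fasta)
        if features is not None:
            stage("validate")(load_annotation_tracks, features, catalog)

    report = FilterReport()
    if dialect == ingest.GENERIC_CSV_DIALECT:
        records = stage("ingest")(ingest.read_generic_csv, input_path)
        sites = sites_from_records(records)
        logger.info("ingest: %d site rows -> %d distinct sites",
                    len(records), len(sites))
    else:
        psms = stage("ingest")(ingest.read_psm_table, input_path, dialect)
        if fasta is None:
            raise PipelineError(
                "extract_sites",
                PtmkitError("PSM-level input needs --fasta for peptide mapping"),
            )
        try:
            psms = stage("qvalues")(compute_qvalues, psms)
        except PipelineError:
            if filter_cfg.fdr_threshold < 1.0:
                raise
            logger.warning("no scores or q-values; FDR filtering disabled")
        psms, report = stage("filters")(apply_filters, psms, filter_cfg)
        sites = stage("extract_sites")(extract_sites, psms, catalog.proteins, report)
        logger.info("filters: %s", report.to_dict())

    if len(catalog):
        sites, validation = stage("validate")(validate_sites, sites, catalog)
        if validation.unknown_protein or validation.out_of_bounds:
            logger.warning("validation rejected sites: %s", validation.to_dict())

    sites = stage("label")(label_sites, sites, table, match_cfg)
    if match_cfg.excluded_classes:
        sites = stage("exclude_classes")(
            exclude_classes, sites, set(match_cfg.excluded_classes)
        )
    summary = stage("summaries")(
        build_sample_summary, sites, match_cfg.ambiguity_flag_threshold
    )
    return Session(
        filter_cfg=filter_cfg,
        match_cfg=match_cfg,
        contact_cutoff=contact_cutoff,
        min_separation=min_separation,
        catalog=catalog,
        sites=sites,
        sample_summary=summary,
        filter_report=report,
    )
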