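# Methods

This note records the models, conventions and numerical choices behind
ptmkit, and what the synthetic-data tests do and do not demonstrate.

## Processing model

The pipeline has a fixed stage order: ingest → q-value estimation →
confidence filters → peptide-to-protein site extraction → coordinate
validation → UniMod labeling → class exclusion → summaries. The order is
part of the contract: the `FilterReport` charges each removed PSM to the
*first* rule it fails (fdr, decoy, multi_protein, msfragger_combination,
msfragger_localization, then unmapped_peptide / missing_protein during
extraction), so tallies are reproducible, and removed + retained always
equals the input count.

### Target-decoy q-values

When the search engine supplies q-values they are trusted and never
overwritten. Otherwise q-values are estimated by target-decoy competition:
sort PSMs by decreasing score, compute at each score the ratio of decoys to
targets at or above it, and monotonize with a running minimum from the worst
score upward. Ties in score share counts (the counts at the last PSM of a
tie run), so tied PSMs receive equal q-values. With zero decoys every
q-value is 0 — the estimator has no evidence of false matches; the result is
a pass-through, not an error. PSMs with neither scores nor q-values cannot
be FDR-filtered and raise an explicit error suggesting to disable the filter
(threshold 1.0). Protein-level FDR is out of scope; filtering is strictly
PSM-level.

### Site extraction conventions

* Positions are 1-based and inclusive everywhere (UniProt convention).
* A peptide must occur **exactly once** in its assigned protein; zero or
  multiple occurrences drop the PSM (tallied `unmapped_peptide`). Matching
  is exact string equality — Leu/Ile are *not* equated — so localization is
  deterministic.
* An N-terminal modification (peptide position 0) is mapped to the
  peptide's first residue and flagged `is_nterm`; the classification lookup
  then uses the `N-term` specificity rather than the residue letter. This
  is a convention choice; upstream tools differ and none documents it.
* Identical (protein, position, modification) events collapse into one site
  with a spectral count. Collapsing happens after filtering and before
  UniMod labeling; counting "sites" always means distinct
  (protein, position) pairs, never spectra.

### UniMod matching and labels

The matcher returns every table entry within ±`mass_tolerance` (default
0.001 Da, closed interval) of the observed shift, nearest first, ties by
ascending UniMod id. Exactly one candidate: the site takes the entry's name,
id, and the class the entry assigns to the site's residue (fallback
`Undefined` when the residue is not listed — classes are *always* resolved
per residue, since one modification can be an artefact on one amino acid
and a biological PTM on another). Zero or several candidates: the label is
the signed fixed-point mass shift with 4 decimals (`+103.0684`) under class
`Ambiguous mass shift`. The full candidate list stays on the site, so
ambiguity remains queryable after labeling. Only the configured tolerance is
applied; no second pass at a tighter tolerance is attempted when it would
disambiguate — the tolerance is a statement about instrument accuracy, not
a knob to tune per site.

Inputs that carry a modification *name* are resolved by case-insensitive
exact name lookup first; mass matching is the fallback. A named site with no
mass and no table entry keeps its input name under class `Undefined`.

Ambiguity flagging compares type pairs, not table entries against a shift:
all unordered pairs with mass difference strictly below the threshold
(default 0.02 Da — configurable; chosen as a generous bound above typical
fragment-level accuracy) are reported with their exact difference.

### Summaries

* The shared-site matrix counts distinct (protein, position) pairs carrying
  both labels; its diagonal equals the per-type site counts by construction.
* The per-amino-acid heatmap normalizes each amino-acid row by its **row
  sum** (proportions), not its maximum; raw counts are retained alongside so
  a max-normalized view can be derived. Rows with no sites stay all-zero.
* The presence/absence matrix orders rows by ascending mass shift
  (ambiguous labels sort by their numeric value), ties lexicographic; the
  axis helper also offers count-descending ordering.
* The class distribution counts (site, label) events: a site carrying two
  labels contributes to two classes.
* All summaries are permutation-invariant in input order; truncation to
  "top N" views is left to consumers.

### Contact maps

A contact is a residue pair whose representative atoms — Cβ, or Cα for
glycine — are **strictly** closer than the cutoff (default 4.69 Å, an
empirical estimate for physical interaction between modified residues);
pairs exactly at the cutoff are excluded. A minimum sequence separation
(default 2) removes trivially adjacent backbone neighbors; the parameter is
configurable since no standard value exists. Non-glycine residues missing a
Cβ (truncated models) fall back to Cα with a per-residue flag instead of
being dropped, keeping map coverage complete on imperfect files. Residue
numbering must align with the catalog sequence (true for AlphaFold models);
a letter-by-letter cross-check at load time reports mismatches. Contact
states form a strict priority — highlighted ⊃ any_modified ⊃
both_unmodified — and the pair detail view reports the contact-rule
(representative-atom) distance; a closest-heavy-atom distance is exposed
separately for comparison, since viewers may display either.

### Sessions

Sessions serialize as canonical JSON (sorted keys, fixed separators)
compressed with zlib. Canonical JSON rather than a language-native pickle
makes the format portable and the files byte-stable: identical inputs and
configurations produce byte-identical session files, which the tests assert.
The payload embeds a format version checked on load; truncated or corrupt
streams raise an integrity error rather than misparsing.

## Input dialects

Three PSM dialects are built in — an MSFragger-style `psm.tsv`, a Sage-style
`results.tsv` (ProForma bracket peptides, parsed with pyteomics), and a
lossless `normalized` TSV mirroring the internal PSM record — plus the
site-level generic CSV. Other engines are admitted through a declarative
column-mapping hook (`ptmkit.ingest.register_dialect`) rather than code
forks. Decoys are recognized by the `rev_` / `DECOY_` accession prefixes
(case-insensitive), the Sage `label = -1` convention, or the normalized
dialect's explicit boolean. The MSFragger "combination of modifications"
rule is operationalized as: the observed-modification annotation for the
open shift lists more than one named component (separators `;` or ` + `);
multi-localization as: more than one lowercase candidate position in the
localization column.

## Synthetic data: what it emulates, what it does not

The fixtures module generates proteomes (uniform random sequences),
open-search PSM tables with planted modifications, and toy structures, all
deterministic given a seed. Default conditions model a well-behaved small
experiment: 10 proteins of 120–400 residues, 400 PSMs, 30% decoys, target
scores N(25, 3) vs decoy scores N(12, 3) (cleanly separable at 1% FDR), 5%
multi-protein peptides and 5% ambiguous localizations. The `nonenriched`
preset mimics a non-enriched bacterial sample in miniature: a dominant
oxidation-type label, a cation-adduct trio with two masses 0.0089 Da apart,
and a long tail of rare types, so ambiguity flagging and shared-site
structure are exercised realistically.

Ground truth is computed by independent inline code (a plain linear UniMod
scan and a plain target-decoy loop), not by the modules under test. Toy
structures place representative atoms on ideal geometries; the hairpin's
contact set is known in closed form, the random coil's by direct
enumeration over the coordinates written to file (PDB stores 3 decimals, so
truth is computed from the rounded values).

What passing these tests shows: the bookkeeping — filtering, mapping,
counting, matching, serialization — is exact under known conditions. What
it does not show: behavior on real spectra (no chimeric spectra, no
retention-time structure, no engine-specific score pathologies), realistic
amino-acid composition, or real protein folds. The synthetic
chaperonin-like contact scenario (`synthetic_groel_scenario`) is a
*generated* structure built to contain a lysine–phosphotyrosine contact at
4.41 Å; it validates the contact machinery, not any database model.

## Known limitations

* Two engine dialects plus the normalized format; mzIdentML and further
  engines are out of scope (the plugin hook is the extension point).
* The bundled UniMod table is a curated subset (25 entries, masses computed
  from elemental compositions); analyses of shifts outside it will label
  them as ambiguous/unannotated. Use the XML converter for full coverage.
* No network access anywhere: sequences, annotations and structures come
  from files. No protein-level FDR; no combinatorial explanation of one
  shift as a sum of modifications (such annotations are consumed, not
  computed); single-chain structures only.
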