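"""Summarize a hand-written site-level CSV.

The generic CSV format is the simplest input: one row per modification site
(UniProt accession, 1-based position, modification name, optional mass
shift).  The pipeline validates positions against the FASTA, resolves names
and mass shifts against the bundled UniMod subset, and builds the
sample-level summary.
"""

import tempfile
from pathlib import Path

from ptmkit import run_pipeline

workdir = Path(tempfile.mkdtemp())

(workdir / "sites.csv").write_text(
    "uniprot_id,position,modification_unimod_name,mass_shift\n"
    "P0A6F5,12,Phospho,79.966331\n"     # named, resolves to UniMod 21
    "P0A6F5,12,,103.0684\n"             # no name, unmatched mass shift
    "P0A6F5,19,,15.994915\n"            # oxidation-type mass, 3 candidates
    "P0A6F5,23,Acetyl,\n"
)
(workdir / "proteome.fasta").write_text(
    ">sp|P0A6F5|CH60_SYN synthetic chaperonin fragment\n"
    "MKAPEPTIDEKSTYWQRLMNHGKCDEF\n"
)

session = run_pipeline(workdir / "sites.csv", fasta=workdir / "proteome.fasta")
summary = session.sample_summary

print("sites per modification type:")
for label, count in sorted(summary.site_counts.items()):
    print(f"  {label:>12s}: {count}")
print("classes:", dict(sorted(summary.class_counts.items())))
print("shared sites Phospho/+103.0684:",
      int(summary.shared.loc["Phospho", "+103.0684"]))

# The unnamed 103.0684 Da shift matches no UniMod entry, so its formatted
# mass shift becomes the label and it is classed "Ambiguous mass shift";
# it co-occurs with Phospho at position 12, hence one shared site.  The
# 15.994915 Da shift matches oxidation AND two amino-acid substitutions at
# the 0.001 Da tolerance, so it too keeps its mass-shift label.
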