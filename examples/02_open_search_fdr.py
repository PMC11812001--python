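"""FDR filtering and planted-site recovery on synthetic open-search PSMs.

Generates a proteome and a PSM table with known planted modification sites,
target scores ~ N(25, 3) and decoy scores ~ N(12, 3), then runs the full
pipeline at 1% FDR and compares the recovered sites to the generator's
ground truth.
"""

import json
import tempfile
from pathlib import Path

from ptmkit import run_pipeline
from ptmkit.fixtures import FixtureSpec, write_fixture_files

workdir = Path(tempfile.mkdtemp())
spec = FixtureSpec(seed=42, n_proteins=6, n_psms=200)
paths = write_fixture_files(spec, workdir)
truth = json.loads(paths["truth"].read_text())

session = run_pipeline(paths["psms"], fasta=paths["fasta"])

report = session.filter_report
print("filter report:", report.to_dict())
got = {(s.protein_accession, s.position, s.label) for s in session.sites}
want = {(acc, pos, label) for acc, pos, label, _cls in truth["sites"]}
print(f"planted sites surviving the filters: {len(want)}")
print(f"recovered by the pipeline:           {len(got & want)}")
print(f"spurious:                            {len(got - want)}")

# With well-separated score distributions every planted site that passes
# the filters is recovered exactly and no decoy survives; the report shows
# where the removed PSMs went (FDR, decoy, multi-protein mapping,
# ambiguous localization).
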