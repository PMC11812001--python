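"""Persist a processed dataset and reload it byte-stably.

Sessions serialize as canonical JSON compressed with zlib: saving the same
processed dataset twice yields byte-identical files, and a reload restores
every field.
"""

import tempfile
from pathlib import Path

from ptmkit import load_session, run_pipeline, save_session
from ptmkit.fixtures import FixtureSpec, write_fixture_files

workdir = Path(tempfile.mkdtemp())
paths = write_fixture_files(FixtureSpec(seed=11, n_proteins=4, n_psms=120),
                            workdir)
session = run_pipeline(paths["psms"], fasta=paths["fasta"])

a, b = workdir / "a.session.zlib", workdir / "b.session.zlib"
save_session(session, a)
save_session(session, b)
print(f"session file size: {a.stat().st_size} bytes")
print(f"two saves byte-identical: {a.read_bytes() == b.read_bytes()}")

reloaded = load_session(a)
print(f"reload equals original: {reloaded == session}")
accession = reloaded.sites[0].protein_accession
print(f"protein summary on demand for {accession}: "
      f"{reloaded.protein_summary(accession).presence.shape} "
      f"(types x positions)")

# The same works from the shell:
#   ptmkit process --input psms.tsv --fasta proteome.fasta --out s.zlib
#   ptmkit summary --session s.zlib --out tables/
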