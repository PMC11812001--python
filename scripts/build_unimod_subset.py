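"""Regenerate the bundled UniMod subset table (src/ptmkit/data/unimod_subset.tsv).

Monoisotopic mass shifts are computed from elemental compositions with
pyteomics, so the table is reproducible offline.  The subset covers the
modifications the package's documentation and fixtures discuss: common PTMs,
sample-preparation artefacts, cation adducts, and the amino-acid
substitutions that collide in mass with carbamidomethylation and oxidation.

Ids for the well-known entries are the public UniMod ids.  Ids for the
amino-acid-substitution block and for rare entries (Carbofuran, Pyrophospho)
are best-effort placements in the UniMod error-tolerant range; regenerate
from the official unimod.xml via ``ptmkit.unimod.convert_unimod_xml`` for
production use.
"""

from pathlib import Path

from pyteomics.mass import calculate_mass

OUT = Path(__file__).resolve().parents[1] / "src" / "ptmkit" / "data" / "unimod_subset.tsv"

PT = "Post-translational"
ART = "Artefact"
CHD = "Chemical derivative"
SUB = "AA substitution"
MUL = "Multiple"


def m(formula: str) -> float:
    return calculate_mass(formula=formula)


# residue monoisotopic masses for substitution deltas
R = {aa: calculate_mass(sequence=aa) - calculate_mass(formula="H2O")
     for aa in "ACDEFGHIKLMNPQRSTVWY"}

# (id, name, mono_mass, {residue_or_terminus: class})
ENTRIES = [
    (1, "Acetyl", m("C2H2O"), {"K": PT, "S": PT, "T": PT, "C": PT, "N-term": MUL}),
    (2, "Amidated", m("NH2") - m("OH"), {"C-term": PT}),
    (4, "Carbamidomethyl", m("C2H3NO"),
     {"C": CHD, "K": ART, "H": ART, "D": ART, "E": ART, "S": ART, "T": ART,
      "Y": ART, "M": ART, "N-term": ART}),
    (5, "Carbamyl", m("CHNO"), {"K": MUL, "N-term": MUL, "R": ART, "C": ART}),
    (7, "Deamidated", m("O") - m("HN"), {"N": ART, "Q": ART}),
    (21, "Phospho", m("HPO3"), {"S": PT, "T": PT, "Y": PT, "D": PT, "H": PT,
                                "C": PT, "R": PT, "K": PT}),
    (30, "Cation:Na", m("Na") - m("H"), {"D": ART, "E": ART, "C-term": ART}),
    (34, "Methyl", m("CH2"), {"K": PT, "R": PT, "C-term": MUL, "N-term": MUL}),
    (35, "Oxidation", m("O"), {"M": ART, "W": ART, "H": ART, "F": ART,
                               "Y": ART, "P": PT, "K": PT, "R": PT, "N": PT,
                               "D": PT, "C": PT}),
    (36, "Dimethyl", m("C2H4"), {"K": PT, "R": PT, "N-term": MUL}),
    (37, "Trimethyl", m("C3H6"), {"K": PT, "R": PT}),
    (40, "Sulfo", m("SO3"), {"S": PT, "T": PT, "Y": PT}),
    (121, "GG", m("C4H6N2O2"), {"K": PT, "S": PT, "T": PT, "C": PT}),
    (122, "Formyl", m("CHO") - m("H"), {"K": ART, "S": ART, "T": ART, "N-term": ART}),
    (345, "Trioxidation", m("O3"), {"C": PT, "W": ART, "Y": ART, "F": ART}),
    (425, "Dioxidation", m("O2"), {"M": ART, "W": ART, "F": ART, "Y": ART,
                                   "C": PT, "P": PT, "K": PT}),
    (530, "Cation:K", m("K") - m("H"), {"D": ART, "E": ART, "C-term": ART}),
    (951, "Cation:Ca[II]", m("Ca") - m("H2"), {"D": ART, "E": ART, "C-term": ART}),
    (977, "Carbofuran", m("C2H3NO"), {"S": CHD}),
    # error-tolerant substitution block (ids best-effort; see module docstring)
    (540, "Ala->Ser", R["S"] - R["A"], {"A": SUB}),
    (544, "Ala->Gln", R["Q"] - R["A"], {"A": SUB}),
    (560, "Gly->Asn", R["N"] - R["G"], {"G": SUB}),
    (567, "Phe->Tyr", R["Y"] - R["F"], {"F": SUB}),
    (1330, "Glycyl", R["G"], {"K": PT, "S": PT, "T": PT, "C": PT}),
    (1356, "Pyrophospho", 2 * m("HPO3"), {"S": PT, "T": PT}),
]


def main() -> None:
    lines = ["id\tname\tmono_mass\tclassifications"]
    for uid, name, mass, classes in ENTRIES:
        cls = ";".join(f"{res}={c}" for res, c in classes.items())
        lines.append(f"{uid}\t{name}\t{mass:.6f}\t{cls}")
    OUT.parent.mkdir(parents=True, exist_ok=True)
    OUT.write_text("\n".join(lines) + "\n", encoding="utf-8")
    print(f"wrote {OUT} ({len(ENTRIES)} entries)")


if __name__ == "__main__":
    main()
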