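"""Bundled reference data: the printed 34-member screen table, a toy
codon-usage table, and a synthetic stand-in CDS for library-design demos.

The screen table transcribes the published initial library of RepB point
mutants with their growth calls at 48°C and 58°C, exactly as printed.
One printed row is internally inconsistent: the member named ``770-I51C``
lists Gln as the new residue.  It is kept as printed (new residue Gln)
and flagged in :data:`SCREEN_TABLE_NOTES`.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd
from Bio.SeqUtils import seq1

from .library import CodonUsageTable, GrowthCall, ScreenRecord

__all__ = [
    "load_codon_usage",
    "repb_screen_records",
    "repb_screen_table",
    "REPB_SITES",
    "SCREEN_TABLE_NOTES",
    "synthetic_repb_like_cds",
]

# name, position, old residue, new residue (three-letter, as printed),
# growth at 48°C, growth at 58°C
_SCREEN_ROWS = [
    ("770-M8C", 8, "Met", "Cys", "-", "-"),
    ("770-M8E", 8, "Met", "Glu", "-", "-"),
    ("770-M8G", 8, "Met", "Gly", "-", "-"),
    ("770-M8Y", 8, "Met", "Tyr", "-", "-"),
    ("770-I51E", 51, "Ile", "Glu", "+", "-"),
    ("770-I51W", 51, "Ile", "Trp", "-", "-"),
    ("770-I51L", 51, "Ile", "Leu", "+", "+"),
    ("770-I51C", 51, "Ile", "Gln", "-", "-"),
    ("770-V83A", 83, "Val", "Ala", "+", "+"),
    ("770-V83L", 83, "Val", "Leu", "-", "-"),
    ("770-V83R", 83, "Val", "Arg", "-", "-"),
    ("770-F124W", 124, "Phe", "Trp", "+/-", "-"),
    ("770-F124S", 124, "Phe", "Ser", "-", "-"),
    ("770-F124G", 124, "Phe", "Gly", "-", "-"),
    ("770-G148M", 148, "Gly", "Met", "-", "-"),
    ("770-G148P", 148, "Gly", "Pro", "-", "-"),
    ("770-G148T", 148, "Gly", "Thr", "-", "-"),
    ("770-G148Y", 148, "Gly", "Tyr", "-", "-"),
    ("770-M166A", 166, "Met", "Ala", "+", "-"),
    ("770-M166H", 166, "Met", "His", "-", "-"),
    ("770-M166G", 166, "Met", "Gly", "-", "-"),
    ("770-L187A", 187, "Leu", "Ala", "-", "-"),
    ("770-L187R", 187, "Leu", "Arg", "-", "-"),
    ("770-L187T", 187, "Leu", "Thr", "-", "-"),
    ("770-W211D", 211, "Trp", "Asp", "-", "-"),
    ("770-W211T", 211, "Trp", "Thr", "-", "-"),
    ("770-W211V", 211, "Trp", "Val", "-", "-"),
    ("770-I289W", 289, "Ile", "Trp", "+", "-"),
    ("770-I289L", 289, "Ile", "Leu", "+", "+/-"),
    ("770-I289Y", 289, "Ile", "Tyr", "+", "-"),
    ("770-I289D", 289, "Ile", "Asp", "-", "-"),
    ("770-I320T", 320, "Ile", "Thr", "+", "-"),
    ("770-I320F", 320, "Ile", "Phe", "+", "+"),
    ("770-I320Y", 320, "Ile", "Tyr", "+", "+"),
]

SCREEN_TABLE_NOTES = {
    "770-I51C": "printed row names Cys but lists Gln as the new residue; kept as printed",
}

# the ten mutagenised sites with each site's wild-type residue
REPB_SITES = {
    8: "M", 51: "I", 83: "V", 124: "F", 148: "G",
    166: "M", 187: "L", 211: "W", 289: "I", 320: "I",
}


def repb_screen_table() -> pd.DataFrame:
    """The printed screen as a DataFrame (one-letter residues)."""
    return pd.DataFrame(
        [
            {
                "name": name,
                "position": pos,
                "old_aa": seq1(old),
                "new_aa": seq1(new),
                "growth48": g48,
                "growth58": g58,
            }
            for name, pos, old, new, g48, g58 in _SCREEN_ROWS
        ]
    )


def repb_screen_records() -> list[ScreenRecord]:
    """The printed screen as :class:`~tsplasmid.library.ScreenRecord`s."""
    return [
        ScreenRecord(
            name=name,
            growth48=GrowthCall.parse(g48),
            growth58=GrowthCall.parse(g58),
            position=pos,
            old_aa=seq1(old),
            new_aa=seq1(new),
        )
        for name, pos, old, new, g48, g58 in _SCREEN_ROWS
    ]


def load_codon_usage() -> CodonUsageTable:
    """Bundled toy codon-usage table (AT-rich, thermophile-flavoured).

    Illustrative relative synonymous codon frequencies in the Kazusa TSV
    dialect; adequate for choosing a deterministic most-frequent codon in
    tests and demos, not a measured genomic table.
    """
    path = resources.files("tsplasmid.data") / "codon_usage_cthermocellum.tsv"
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t")
    freq = dict(zip(df["codon"], df["fraction"]))
    return CodonUsageTable(organism="C. thermocellum (toy)", freq=freq)


def synthetic_repb_like_cds(length_aa: int = 340, seed: int = 77) -> str:
    """Synthetic stand-in CDS with the screen table's wild-type residues
    at the ten mutagenised positions.

    The true RepB sequence is not bundled; this stand-in has the right
    residue at every site in :data:`REPB_SITES` (so the printed library
    can be rebuilt codon-exactly) and a random polar-biased background
    elsewhere.  Back-translated with the bundled usage table's
    most-frequent codons; starts with Met, ends with a stop codon.
    """
    if length_aa < max(REPB_SITES):
        raise ValueError(f"length_aa must be >= {max(REPB_SITES)}")
    rng = np.random.default_rng(seed)
    background = list("ADEFGHIKLNPQRSTVWY")  # no Met/Cys to keep sites unambiguous
    protein = [str(rng.choice(background)) for _ in range(length_aa)]
    protein[0] = "M"
    for pos, aa in REPB_SITES.items():
        protein[pos - 1] = aa
    usage = load_codon_usage()
    codons = [usage.best_codon(aa) for aa in protein]
    return "".join(codons) + "TAA"
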