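"""Rebuild the printed 34-member mutant library and classify the screen.

Uses the bundled screen table (10 sites, 3-4 substitutions each) with a
synthetic stand-in CDS carrying the correct wild-type residue at every
site, then applies the two-temperature Ts rule to the printed growth
calls.
"""

from tsplasmid import build_library, screen_summary
from tsplasmid.datasets import (
    load_codon_usage,
    repb_screen_records,
    repb_screen_table,
    synthetic_repb_like_cds,
)

cds = synthetic_repb_like_cds()
table = repb_screen_table()
sites = [(pos, grp["new_aa"].tolist()) for pos, grp in table.groupby("position")]
library = build_library(cds, sites, load_codon_usage())
print(f"library members: {len(library)} (one codon-exact CDS each)")
print("first three:", ", ".join(library.names()[:3]))

summary = screen_summary(repb_screen_records())
print(f"screen phenotypes: {summary['by_phenotype']}")
print("Ts mutants:", ", ".join(n.replace("770-", "") for n in summary["ts_names"]))
print(
    "A mutant is Ts when it grows at 48 C but not (or only weakly) at "
    "58 C; these are the candidates for a temperature-sensitive plasmid."
)
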