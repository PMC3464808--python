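"""Mutant-library design and Ts-screen phenotype calls.

Given a wild-type CDS and a set of predicted buried sites, this module
produces a codon-exact library of single-substitution mutants (each mutant
carries the organism's most-frequent codon for the new amino acid) and
classifies the outcome of a two-temperature growth screen into
temperature-sensitive (Ts) and non-Ts phenotypes.

The screen logic: growth at the permissive temperature (48°C) combined
with absent or impaired growth at the restrictive temperature (58°C) marks
a mutant Ts; growth at both marks it active; growth at neither, inactive;
anything resting on an intermediate call at the permissive temperature is
ambiguous and never counted as Ts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum

from Bio.Seq import Seq

__all__ = [
    "GrowthCall",
    "Phenotype",
    "CodonUsageTable",
    "MutantSpec",
    "MutantRecord",
    "MutantLibrary",
    "ScreenRecord",
    "design_substitutions",
    "mutate_cds",
    "build_library",
    "classify_ts_phenotype",
    "screen_summary",
    "translate_cds",
]

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


class GrowthCall(str, Enum):
    """Plate/liquid-culture growth call at one temperature."""

    PLUS = "+"
    INTERMEDIATE = "+/-"
    MINUS = "-"

    @classmethod
    def parse(cls, text: str) -> "GrowthCall":
        # tolerate the unicode minus the printed table uses
        norm = text.strip().replace("−", "-").replace("–", "-")
        try:
            return cls(norm)
        except ValueError:
            raise ValueError(f"invalid growth call {text!r}; expected one of +, +/-, -") from None


class Phenotype(str, Enum):
    TS = "Ts"
    ACTIVE = "active"
    INACTIVE = "inactive"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class CodonUsageTable:
    """Relative synonymous codon frequencies for one organism.

    ``freq`` maps a DNA codon to its relative frequency *within its amino
    acid's synonymous family*; families therefore sum to 1.
    """

    organism: str
    freq: dict[str, float]

    def __post_init__(self) -> None:
        sums: dict[str, float] = {}
        for codon, f in self.freq.items():
            if len(codon) != 3 or any(b not in "ACGT" for b in codon):
                raise ValueError(f"invalid DNA codon {codon!r}")
            aa = str(Seq(codon).translate())
            sums[aa] = sums.get(aa, 0.0) + f
        bad = {aa: s for aa, s in sums.items() if abs(s - 1.0) > 1e-6}
        if bad:
            raise ValueError(f"per-amino-acid frequencies do not sum to 1: {bad}")

    def best_codon(self, aa: str) -> str:
        """Most-frequent codon for ``aa``; ties break alphabetically."""
        aa = aa.upper()
        candidates = [
            c for c in self.freq if str(Seq(c).translate()) == aa
        ]
        if not candidates:
            raise ValueError(f"no codon for amino acid {aa!r} in usage table")
        return max(sorted(candidates), key=lambda c: (self.freq[c], ))

    def codons_for(self, aa: str) -> dict[str, float]:
        return {c: f for c, f in self.freq.items() if str(Seq(c).translate()) == aa.upper()}


@dataclass(frozen=True)
class MutantSpec:
    """One designed amino-acid substitution with its codon edit."""

    position: int  # 1-based residue index
    old_aa: str
    new_aa: str
    codon_old: str
    codon_new: str

    def __post_init__(self) -> None:
        if self.old_aa == self.new_aa:
            raise ValueError("substitution must change the residue")
        if str(Seq(self.codon_old).translate()) != self.old_aa:
            raise ValueError(f"codon_old {self.codon_old} does not encode {self.old_aa}")
        if str(Seq(self.codon_new).translate()) != self.new_aa:
            raise ValueError(f"codon_new {self.codon_new} does not encode {self.new_aa}")

    @property
    def name(self) -> str:
        return f"{self.old_aa}{self.position}{self.new_aa}"


@dataclass(frozen=True)
class MutantRecord:
    spec: MutantSpec
    cds: str


@dataclass
class MutantLibrary:
    wild_cds: str
    members: list[MutantRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.members)

    def names(self) -> list[str]:
        return [m.spec.name for m in self.members]


@dataclass(frozen=True)
class ScreenRecord:
    """One library member's screen outcome at 48°C and 58°C."""

    name: str
    growth48: GrowthCall
    growth58: GrowthCall
    position: int | None = None
    old_aa: str | None = None
    new_aa: str | None = None

    @property
    def phenotype(self) -> Phenotype:
        return classify_ts_phenotype(self.growth48, self.growth58)


_KSTW = ["K", "S", "A", "W"]  # positively charged, polar, small, large hydrophobic


def design_substitutions(
    wild_aa: str,
    strategy: str = "kstw",
    n: int = 4,
    seed: int = 0,
) -> list[str]:
    """Choose replacement residues for one buried site.

    Strategies:

    * ``asp_probe`` — the single Asp probe: Asp is small, rigid and charged,
      hence poorly tolerated at buried positions.
    * ``kstw`` — the fixed panel Lys, Ser, Ala, Trp (a charged, a polar, a
      small and a large hydrophobic residue), minus the wild type.
    * ``random_all`` — ``n`` distinct residues drawn uniformly without
      replacement from the 19 non-wild standard residues (seeded).
    """
    wild_aa = wild_aa.upper()
    if wild_aa not in _STANDARD_AA:
        raise ValueError(f"non-standard wild-type residue {wild_aa!r}")
    if strategy == "asp_probe":
        if wild_aa == "D":
            raise ValueError("asp_probe undefined for wild-type Asp")
        return ["D"]
    if strategy == "kstw":
        return [aa for aa in _KSTW if aa != wild_aa]
    if strategy == "random_all":
        pool = sorted(_STANDARD_AA - {wild_aa})
        if not 1 <= n <= len(pool):
            raise ValueError(f"n must be in [1, {len(pool)}], got {n}")
        import numpy as np

        rng = np.random.default_rng(seed)
        return [pool[i] for i in rng.choice(len(pool), size=n, replace=False)]
    raise ValueError(f"unknown strategy {strategy!r}")


def translate_cds(cds: str) -> str:
    """Translate a CDS, validating length and characters."""
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    if any(b not in "ACGT" for b in cds):
        raise ValueError("CDS contains non-ACGT characters")
    return str(Seq(cds).translate())


def mutate_cds(
    cds: str,
    position: int,
    new_aa: str,
    usage: CodonUsageTable,
) -> tuple[str, MutantSpec]:
    """Swap the codon at ``position`` (1-based residue index) for the
    most-frequent codon of ``new_aa``.

    The output differs from the input in exactly one codon; its translation
    differs from the wild type at exactly ``position``.
    """
    protein = translate_cds(cds)
    if not 1 <= position <= len(protein):
        raise ValueError(f"position {position} outside translated length {len(protein)}")
    new_aa = new_aa.upper()
    if new_aa == "*" or new_aa not in _STANDARD_AA:
        raise ValueError(f"invalid replacement residue {new_aa!r}")
    if "*" in protein[: position - 1]:
        stop_at = protein.index("*") + 1
        raise ValueError(f"premature stop codon at residue {stop_at}, before position {position}")
    old_aa = protein[position - 1]
    if old_aa == "*":
        raise ValueError(f"position {position} is a stop codon")
    if old_aa == new_aa:
        raise ValueError(f"substitution at {position} would be silent ({old_aa} -> {new_aa})")
    cds = cds.upper()
    start = (position - 1) * 3
    codon_old = cds[start : start + 3]
    codon_new = usage.best_codon(new_aa)
    spec = MutantSpec(
        position=position,
        old_aa=old_aa,
        new_aa=new_aa,
        codon_old=codon_old,
        codon_new=codon_new,
    )
    return cds[:start] + codon_new + cds[start + 3 :], spec


def build_library(
    cds: str,
    sites: list[tuple[int, list[str]]],
    usage: CodonUsageTable,
) -> MutantLibrary:
    """One mutant per (site, substitution); names in Table-1 style
    ``<old><pos><new>`` (e.g. ``M166A``)."""
    lib = MutantLibrary(wild_cds=cds.upper())
    seen: set[tuple[int, str]] = set()
    for position, subs in sites:
        for new_aa in subs:
            key = (position, new_aa.upper())
            if key in seen:
                raise ValueError(f"duplicate library member at site {position} -> {new_aa}")
            seen.add(key)
            try:
                mutant_cds, spec = mutate_cds(cds, position, new_aa, usage)
            except ValueError as exc:
                raise ValueError(f"site {position}: {exc}") from exc
            lib.members.append(MutantRecord(spec=spec, cds=mutant_cds))
    return lib


def classify_ts_phenotype(growth48: GrowthCall, growth58: GrowthCall) -> Phenotype:
    """Phenotype from the two-temperature screen.

    Growth at 48°C but not (or only weakly) at 58°C is Ts.  An intermediate
    call at 48°C is never counted Ts — the permissive-temperature evidence
    is itself equivocal — and growth only at the restrictive temperature is
    anomalous; both map to ambiguous.
    """
    g48 = GrowthCall(growth48)
    g58 = GrowthCall(growth58)
    if g48 is GrowthCall.PLUS:
        return Phenotype.ACTIVE if g58 is GrowthCall.PLUS else Phenotype.TS
    if g48 is GrowthCall.INTERMEDIATE:
        return Phenotype.AMBIGUOUS
    # no growth at permissive temperature
    return Phenotype.INACTIVE if g58 is GrowthCall.MINUS else Phenotype.AMBIGUOUS


def screen_summary(records: list[ScreenRecord]) -> dict:
    """Counts per phenotype and per site; totals are conserved."""
    by_phenotype = Counter(r.phenotype.value for r in records)
    by_site: dict[int | None, Counter] = {}
    for r in records:
        by_site.setdefault(r.position, Counter())[r.phenotype.value] += 1
    for ph in Phenotype:
        by_phenotype.setdefault(ph.value, 0)
    return {
        "n": len(records),
        "by_phenotype": dict(by_phenotype),
        "by_site": {site: dict(c) for site, c in by_site.items()},
        "ts_names": [r.name for r in records if r.phenotype is Phenotype.TS],
    }
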