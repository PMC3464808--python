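"""Plasmid segregational stability from CFU counts (plasmid stability ratio).

A culture carrying a selectable plasmid is grown without selection and
plated on selective (antibiotic) and non-selective media at an initial and
a final timepoint.  The plasmid stability ratio compares the log10 gain in
plasmid-bearing cells to the log10 gain in total cells:

    PSR = [log10(CFU_ab,t1) - log10(CFU_ab,t0)]
        / [log10(CFU_no,t1) - log10(CFU_no,t0)]

PSR = 1: the plasmid replicates stably (plasmid-bearing cells keep pace
with the population).  0 < PSR < 1: segregational loss.  PSR = 0: no
replication, existing copies diluted but maintained.  PSR < 0:
plasmid-bearing cells are being removed from the population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CfuExperiment",
    "PsrResult",
    "compute_psr",
    "classify_psr",
    "psr_result",
    "summarize_replicates",
]


@dataclass
class CfuExperiment:
    """Four CFU/ml counts: (selective x non-selective) x (t0 x t1)."""

    cfu_ab_t0: float
    cfu_ab_t1: float
    cfu_no_t0: float
    cfu_no_t1: float
    temperature: float | None = None  # °C, metadata only

    def __post_init__(self) -> None:
        for name in ("cfu_ab_t0", "cfu_ab_t1", "cfu_no_t0", "cfu_no_t1"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"{name} must be a positive finite count, got {v}")


@dataclass(frozen=True)
class PsrResult:
    psr: float
    regime: str  # stable | unstable | non_replicating | lost


def compute_psr(exp: CfuExperiment) -> float:
    """Plasmid stability ratio from one experiment's four counts.

    Invariant under a common multiplicative rescaling of all counts, so
    dilution factors cancel as long as they are applied consistently.
    """
    den = math.log10(exp.cfu_no_t1) - math.log10(exp.cfu_no_t0)
    if den == 0:
        raise ValueError("culture did not grow: non-selective counts unchanged")
    num = math.log10(exp.cfu_ab_t1) - math.log10(exp.cfu_ab_t0)
    return num / den


def classify_psr(psr: float, zero_band: float = 0.05) -> str:
    """Replication regime with a tolerance band around the 0 and 1 anchors.

    The exact boundaries (PSR = 1 stable, PSR = 0 non-replicating) are
    unusable on noisy plate counts; ``zero_band`` widens each anchor into
    an interval.
    """
    if zero_band < 0:
        raise ValueError("zero_band must be >= 0")
    if psr >= 1.0 - zero_band:
        return "stable"
    if psr > zero_band:
        return "unstable"
    if psr >= -zero_band:
        return "non_replicating"
    return "lost"


def psr_result(exp: CfuExperiment, zero_band: float = 0.05) -> PsrResult:
    psr = compute_psr(exp)
    return PsrResult(psr=psr, regime=classify_psr(psr, zero_band))


def summarize_replicates(experiments: list[CfuExperiment], zero_band: float = 0.05) -> dict:
    """Per-replicate PSRs with their mean and sample sd.

    Uncertainty is reported as the dispersion of per-replicate PSRs; no
    within-replicate error propagation is attempted.
    """
    psrs = np.array([compute_psr(e) for e in experiments])
    if psrs.size == 0:
        raise ValueError("no replicates")
    mean = float(psrs.mean())
    return {
        "psr_values": psrs.tolist(),
        "mean": mean,
        "sd": float(psrs.std(ddof=1)) if psrs.size > 1 else 0.0,
        "n": int(psrs.size),
        "regime": classify_psr(mean, zero_band),
    }
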