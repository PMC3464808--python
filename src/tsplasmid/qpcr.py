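"""Efficiency-corrected qPCR plasmid copy number (PCN).

Plasmid copy number is measured as the abundance ratio of a plasmid-borne
single-copy target gene (*cat*) to a chromosomal single-copy reference
gene (*celS*), each quantified by its quantification cycle Cq.  A
single-copy control construct carrying one copy of each amplicon serves
as the calibrator, and per-primer amplification efficiencies estimated
from a serial-dilution standard curve correct for non-ideal doubling
(Pfaffl-style ratio):

    PCN = (1 + E_target)^(Cq_target,cal - Cq_target,sample)
        / (1 + E_ref)^(Cq_ref,cal - Cq_ref,sample)

With both efficiencies at 100% this reduces to the textbook 2^-ddCq.
The assay's limit of detection follows from how many cycles separate the
reference gene from the no-template control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "DilutionSeries",
    "EfficiencyFit",
    "QpcrPanel",
    "CopyNumberResult",
    "CqAggregate",
    "fit_efficiency",
    "copy_number",
    "limit_of_detection",
    "aggregate_cq",
    "panel_from_table",
]


@dataclass
class DilutionSeries:
    """Standard curve data: relative log10 template amount vs Cq.

    Replicates are simply repeated ``log10_conc`` entries.
    """

    log10_conc: np.ndarray
    cq: np.ndarray

    def __post_init__(self) -> None:
        self.log10_conc = np.asarray(self.log10_conc, dtype=float)
        self.cq = np.asarray(self.cq, dtype=float)
        if self.log10_conc.shape != self.cq.shape:
            raise ValueError("log10_conc and cq must be aligned")
        if len(np.unique(self.log10_conc)) < 3:
            raise ValueError("need >= 3 distinct dilution levels")
        if not np.all(np.isfinite(self.cq)):
            raise ValueError("Cq values must be finite")


@dataclass(frozen=True)
class EfficiencyFit:
    efficiency: float  # fraction; 1.0 == 100%
    slope: float       # cycles per log10 template
    intercept: float
    r_squared: float

    @property
    def percent(self) -> float:
        return 100.0 * self.efficiency


def fit_efficiency(series: DilutionSeries) -> EfficiencyFit:
    """Amplification efficiency from the standard-curve slope.

    OLS fit of Cq on log10 template amount; a perfect doubling per cycle
    gives slope -1/log10(2) = -3.3219 and efficiency 1.0.  Efficiency is
    ``10^(-1/slope) - 1``.
    """
    res = stats.linregress(series.log10_conc, series.cq)
    if res.slope >= 0:
        raise ValueError(
            f"standard-curve slope {res.slope:.3f} is non-negative: no amplification signal"
        )
    eff = 10.0 ** (-1.0 / res.slope) - 1.0
    return EfficiencyFit(
        efficiency=float(eff),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


@dataclass
class QpcrPanel:
    """Mean Cq values for target/reference in sample and calibrator, plus
    the per-primer efficiencies (fractions)."""

    cq_target_sample: float
    cq_ref_sample: float
    cq_target_cal: float
    cq_ref_cal: float
    eff_target: float = 1.0
    eff_ref: float = 1.0

    def __post_init__(self) -> None:
        for name in ("cq_target_sample", "cq_ref_sample", "cq_target_cal", "cq_ref_cal"):
            v = getattr(self, name)
            if v is None or not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be a positive finite Cq, got {v}")
        for name in ("eff_target", "eff_ref"):
            e = getattr(self, name)
            if not 0.0 < e <= 1.5:
                raise ValueError(f"{name} must be in (0, 1.5], got {e}")


@dataclass(frozen=True)
class CopyNumberResult:
    pcn: float  # plasmid copies per chromosome
    below_lod: bool = False

    def __post_init__(self) -> None:
        if self.pcn < 0:
            raise ValueError("pcn must be >= 0")


def copy_number(
    panel: QpcrPanel,
    calibrator_ratio: float = 1.0,
    lod: float | None = None,
) -> CopyNumberResult:
    """Efficiency-corrected ddCq ratio of target to reference.

    ``calibrator_ratio`` is the known target:reference copy ratio of the
    calibrator construct (1 for a single-copy control plasmid).  Passing a
    limit of detection flags results below it.
    """
    num = (1.0 + panel.eff_target) ** (panel.cq_target_cal - panel.cq_target_sample)
    den = (1.0 + panel.eff_ref) ** (panel.cq_ref_cal - panel.cq_ref_sample)
    pcn = calibrator_ratio * num / den
    return CopyNumberResult(
        pcn=float(pcn),
        below_lod=bool(lod is not None and pcn < lod),
    )


def limit_of_detection(
    cq_ref: float,
    cq_ntc: float,
    eff_target: float | None = None,
) -> float:
    """Minimal detectable plasmid:chromosome ratio.

    The no-template control (NTC) Cq of the target assay bounds the lowest
    signal distinguishable from background; relative to the reference-gene
    Cq this is ``2^-(cq_ntc - cq_ref)`` assuming perfect doubling.  Passing
    ``eff_target`` switches to the efficiency-corrected base
    ``(1 + E)^-(cq_ntc - cq_ref)``.
    """
    if cq_ntc <= cq_ref:
        raise ValueError(f"NTC Cq ({cq_ntc}) must exceed reference Cq ({cq_ref})")
    base = 2.0 if eff_target is None else 1.0 + eff_target
    return float(base ** -(cq_ntc - cq_ref))


@dataclass(frozen=True)
class CqAggregate:
    mean: float
    sd: float
    n: int
    outliers: tuple[int, ...] = ()  # indices deviating from the median


def aggregate_cq(cqs, outlier_cycles: float = 0.5) -> CqAggregate:
    """Mean and sample sd of replicate Cqs, flagging replicates more than
    ``outlier_cycles`` from the median."""
    arr = np.asarray(list(cqs), dtype=float)
    if arr.size == 0:
        raise ValueError("no replicates")
    if arr.size == 1:
        warnings.warn("single Cq replicate: sd undefined, reported as 0", stacklevel=2)
        return CqAggregate(mean=float(arr[0]), sd=0.0, n=1)
    med = float(np.median(arr))
    outliers = tuple(int(i) for i in np.flatnonzero(np.abs(arr - med) > outlier_cycles))
    return CqAggregate(
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)),
        n=int(arr.size),
        outliers=outliers,
    )


def panel_from_table(df, eff_target: float, eff_ref: float) -> QpcrPanel:
    """Assemble a :class:`QpcrPanel` from a tidy replicate table.

    Expects columns ``sample`` ('sample' | 'calibrator'), ``target``
    ('target' | 'reference') and ``cq``; replicates are averaged with
    :func:`aggregate_cq`.
    """
    means = {}
    for (who, gene), grp in df.groupby(["sample", "target"]):
        means[(who, gene)] = aggregate_cq(grp["cq"]).mean
    try:
        return QpcrPanel(
            cq_target_sample=means[("sample", "target")],
            cq_ref_sample=means[("sample", "reference")],
            cq_target_cal=means[("calibrator", "target")],
            cq_ref_cal=means[("calibrator", "reference")],
            eff_target=eff_target,
            eff_ref=eff_ref,
        )
    except KeyError as exc:
        raise ValueError(f"replicate table missing rows for {exc.args[0]}") from exc
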