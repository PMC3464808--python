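"""Synthetic inputs with known ground truth for every analysis stage.

Each generator is a pure function of its arguments (including the seed):
calling it twice with the same configuration yields identical output, and
with noise switched off it composes with its analysis counterpart into an
exact round trip (growth curve -> muMax, dilution series -> efficiency,
Cq panel -> copy number, CFU counts -> PSR, designed protein -> predicted
regions).

Noise models: multiplicative lognormal for OD readings and plate counts
(measurement error scales with the signal), additive Gaussian for Cq
values (cycle-threshold jitter).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .growth import GrowthCurve
from .qpcr import DilutionSeries
from .stability import CfuExperiment

__all__ = [
    "gen_growth_curve",
    "gen_dilution_series",
    "gen_qpcr_panel",
    "gen_cfu_experiment",
    "gen_test_protein",
]

# one cell doubling per generation; ~7 generations per curing passage
DEFAULT_GENERATIONS = 7


def _lognormal_factor(rng: np.random.Generator, sd: float, size) -> np.ndarray:
    """Multiplicative noise with the given coefficient of variation."""
    if sd == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(sd**2))
    return rng.lognormal(mean=-(sigma**2) / 2, sigma=sigma, size=size)


def gen_growth_curve(
    mu: float,
    od0: float = 0.01,
    lag: float = 0.0,
    capacity: float | None = None,
    interval_min: float = 3.0,
    duration_h: float = 6.0,
    noise_sd: float = 0.0,
    blank: float = 0.0,
    seed: int = 0,
) -> GrowthCurve:
    """Logistic-with-lag OD600 trajectory sampled at a fixed interval.

    ``capacity=None`` removes the carrying-capacity limit (pure
    exponential).  ``noise_sd`` is the coefficient of variation of
    multiplicative lognormal reading noise; 0 gives a deterministic curve.
    """
    if mu < 0:
        raise ValueError("mu must be >= 0")
    if interval_min <= 0:
        raise ValueError("interval_min must be > 0")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration_h + 1e-9, interval_min / 60.0)
    t_eff = np.maximum(times - lag, 0.0)
    if capacity is None:
        od = od0 * np.exp(mu * t_eff)
    else:
        if capacity <= od0:
            raise ValueError("capacity must exceed od0")
        a = (capacity - od0) / od0
        od = capacity / (1.0 + a * np.exp(-mu * t_eff))
    od = od * _lognormal_factor(rng, noise_sd, od.shape)
    return GrowthCurve(times=times, od=od + blank, blank=blank, pathlength_factor=1.0)


def gen_dilution_series(
    eff: float,
    levels: int = 9,
    fold: float = 10.0,
    cq_top: float = 12.0,
    replicates: int = 1,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> DilutionSeries:
    """Serial-dilution standard curve at a known amplification efficiency.

    Each ``fold``-fold dilution step delays the quantification cycle by
    ``log(fold)/log(1+eff)`` cycles (3.32 cycles for a 10-fold step at
    100% efficiency).
    """
    if levels < 3:
        raise ValueError("levels must be >= 3")
    if not 0.0 < eff <= 1.5:
        raise ValueError("eff must be in (0, 1.5]")
    rng = np.random.default_rng(seed)
    step = np.log(fold) / np.log(1.0 + eff)
    log10_conc = np.repeat(-np.arange(levels) * np.log10(fold), replicates)
    cq = cq_top + np.repeat(np.arange(levels) * step, replicates)
    cq = cq + (rng.normal(0.0, noise_sd, cq.shape) if noise_sd > 0 else 0.0)
    return DilutionSeries(log10_conc=log10_conc, cq=cq)


def gen_qpcr_panel(
    pcn_true: float,
    eff_target: float = 1.008,
    eff_ref: float = 0.971,
    cq_ref_base: float = 19.12,
    cq_target_cal: float | None = None,
    replicates: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Tidy replicate Cq table for a sample at a known copy number.

    The calibrator carries the target and reference at a 1:1 ratio; the
    sample's target Cq is advanced by ``log(pcn)/log(1+eff_target)``
    cycles relative to the calibrator.  Columns: sample, target,
    replicate, cq.
    """
    if pcn_true <= 0:
        raise ValueError("pcn_true must be > 0")
    rng = np.random.default_rng(seed)
    if cq_target_cal is None:
        cq_target_cal = cq_ref_base
    shift = np.log(pcn_true) / np.log(1.0 + eff_target)
    ideal = {
        ("sample", "target"): cq_target_cal - shift,
        ("sample", "reference"): cq_ref_base,
        ("calibrator", "target"): cq_target_cal,
        ("calibrator", "reference"): cq_ref_base,
    }
    rows = []
    for (who, gene), cq0 in ideal.items():
        noise = rng.normal(0.0, noise_sd, replicates) if noise_sd > 0 else np.zeros(replicates)
        for r in range(replicates):
            rows.append(
                {"sample": who, "target": gene, "replicate": r + 1, "cq": cq0 + noise[r]}
            )
    return pd.DataFrame(rows)


def gen_cfu_experiment(
    loss_prob: float,
    generations: int = DEFAULT_GENERATIONS,
    cfu0: float = 1e3,
    plating_cv: float = 0.0,
    seed: int = 0,
) -> CfuExperiment:
    """CFU counts for a culture losing its plasmid at a per-generation rate.

    All cells double each generation; a plasmid-bearing cell produces a
    plasmid-free daughter with probability ``loss_prob``, so selective
    counts grow as ``2^g (1 - loss_prob)^g`` against ``2^g`` overall.
    ``plating_cv`` applies multiplicative lognormal plating noise.
    """
    if not 0.0 <= loss_prob < 1.0:
        raise ValueError("loss_prob must be in [0, 1)")
    rng = np.random.default_rng(seed)
    growth = 2.0**generations
    expected = np.array(
        [cfu0, cfu0 * growth * (1.0 - loss_prob) ** generations, cfu0, cfu0 * growth]
    )
    noisy = expected * _lognormal_factor(rng, plating_cv, 4)
    return CfuExperiment(
        cfu_ab_t0=noisy[0], cfu_ab_t1=noisy[1], cfu_no_t0=noisy[2], cfu_no_t1=noisy[3]
    )


_HYDROPHOBIC = "ILVF"
# small-|H| polar residues: a background that is hydrophilic without the
# large-magnitude charged residues whose chance periodicity would mimic an
# amphipathic face
_POLAR = "STNQG"


def gen_test_protein(
    length: int,
    buried_blocks: list[tuple[int, int]] = (),
    amphipathic: bool = False,
    period: float = 3.6,
    seed: int = 0,
) -> tuple[str, np.ndarray]:
    """Designed protein with known buried blocks, plus a boolean truth mask.

    Blocks (1-based inclusive) are filled with strongly hydrophobic
    residues; with ``amphipathic=True`` hydrophobics are instead placed
    every ``period`` residues inside each block, mimicking the buried face
    of a helix (period 3.6 pairs with a 100°/residue moment scan).  The
    background is polar.
    """
    rng = np.random.default_rng(seed)
    blocks = sorted((int(s), int(e)) for s, e in buried_blocks)
    prev_end = 0
    for s, e in blocks:
        if not 1 <= s <= e <= length:
            raise ValueError(f"block ({s}, {e}) outside sequence of length {length}")
        if s <= prev_end:
            raise ValueError(f"block ({s}, {e}) overlaps a previous block")
        prev_end = e
    seq = list(rng.choice(list(_POLAR), size=length))
    mask = np.zeros(length, dtype=bool)
    for s, e in blocks:
        mask[s - 1 : e] = True
        for offset, pos in enumerate(range(s - 1, e)):
            if amphipathic:
                if (offset % period) < 1.0:
                    seq[pos] = str(rng.choice(list(_HYDROPHOBIC)))
            else:
                seq[pos] = str(rng.choice(list(_HYDROPHOBIC)))
    return "".join(seq), mask
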