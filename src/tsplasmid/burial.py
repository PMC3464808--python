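"""Sequence-only prediction of buried residues.

Buried, hydrophobic residues stabilise a protein's core; substituting them
is the classic route to temperature-sensitive (Ts) variants.  This module
locates candidate buried positions from the amino-acid sequence alone using
two windowed tracks:

* **average hydrophobicity** — the mean hydrophobicity over a short window,
  which flags buried stretches that need not adopt regular secondary
  structure;
* **hydrophobic moment** (``muH``) — the magnitude of the vector sum of
  per-residue hydrophobicities placed at successive angular increments
  ``delta``, which flags the buried face of an amphipathic helix
  (``delta = 100°``) or strand (``delta = 160°``).

Both raw tracks are mapped to a probability of burial through a logistic
calibration, and positions exceeding a probability threshold on either
track are merged into contiguous candidate regions, one suggested
mutagenesis site (the probability peak) per region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HydrophobicityScale",
    "BurialProfile",
    "BuriedRegion",
    "EISENBERG_CONSENSUS",
    "windowed_hydrophobicity",
    "hydrophobic_moment",
    "moment_of_window",
    "calibrate_probability",
    "find_buried_regions",
    "predict_profile",
]

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class HydrophobicityScale:
    """A named per-residue hydrophobicity scale (unitless)."""

    name: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        missing = sorted(set(STANDARD_AA) - set(self.values))
        if missing:
            raise ValueError(f"scale {self.name!r} missing residues: {missing}")
        for aa, v in self.values.items():
            if not math.isfinite(v):
                raise ValueError(f"scale {self.name!r}: non-finite value for {aa}")

    def __getitem__(self, aa: str) -> float:
        return self.values[aa]

    def encode(self, sequence: str) -> np.ndarray:
        """Map a protein sequence to its hydrophobicity vector.

        Raises ``ValueError`` naming the 1-based position of the first
        non-standard residue.
        """
        if not sequence:
            raise ValueError("empty sequence")
        seq = sequence.upper()
        for i, aa in enumerate(seq, start=1):
            if aa not in self.values:
                raise ValueError(
                    f"non-standard residue {aa!r} at position {i}"
                )
        return np.array([self.values[aa] for aa in seq], dtype=float)


# Eisenberg consensus scale -- the standard scale for hydrophobic-moment work.
EISENBERG_CONSENSUS = HydrophobicityScale(
    name="eisenberg-consensus",
    values={
        "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29,
        "Q": -0.85, "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38,
        "L": 1.06, "K": -1.50, "M": 0.64, "F": 1.19, "P": 0.12,
        "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.08,
    },
)


def _check_window(window: int, length: int) -> None:
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be a positive odd integer, got {window}")
    if window > length:
        raise ValueError(f"window {window} exceeds sequence length {length}")


def windowed_hydrophobicity(
    sequence: str,
    scale: HydrophobicityScale = EISENBERG_CONSENSUS,
    window: int = 7,
) -> np.ndarray:
    """Per-residue mean hydrophobicity over a centred sliding window.

    At the termini the window is truncated to the residues that exist; no
    padding is invented.  Returns an array of the same length as
    ``sequence``.
    """
    h = scale.encode(sequence)
    _check_window(window, len(h))
    half = window // 2
    # prefix sums give O(n) truncated-window means
    csum = np.concatenate([[0.0], np.cumsum(h)])
    n = len(h)
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def moment_of_window(values: np.ndarray, delta_deg: float) -> float:
    """Hydrophobic moment of one window, normalised per residue.

    Residues ``n = 0..w-1`` contribute vectors of length ``H_n`` at angles
    ``n * delta``; the moment is the magnitude of their sum divided by the
    window size.  Invariant under a global rotation of all angles.
    """
    values = np.asarray(values, dtype=float)
    w = len(values)
    if w == 0:
        raise ValueError("empty window")
    ang = np.deg2rad(delta_deg) * np.arange(w)
    s = np.dot(values, np.sin(ang))
    c = np.dot(values, np.cos(ang))
    return math.hypot(s, c) / w


def hydrophobic_moment(
    sequence: str,
    scale: HydrophobicityScale = EISENBERG_CONSENSUS,
    window: int = 11,
    delta: float = 100.0,
) -> np.ndarray:
    """Per-residue hydrophobic moment ``muH`` over a centred sliding window.

    ``delta`` is the angular increment per residue in degrees: 100° probes
    an alpha-helix periodicity, 160° a beta-strand.  Terminal windows are
    truncated like :func:`windowed_hydrophobicity`.
    """
    h = scale.encode(sequence)
    _check_window(window, len(h))
    if not 0.0 < delta < 360.0:
        raise ValueError(f"delta must be in (0, 360) degrees, got {delta}")
    half = window // 2
    n = len(h)
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(i - half, 0), min(i + half + 1, n)
        out[i] = moment_of_window(h[lo:hi], delta)
    return out


def calibrate_probability(track: np.ndarray, s0: float, k: float) -> np.ndarray:
    """Logistic map from a raw track to a burial probability in [0, 1].

    ``p = 1 / (1 + exp(-(x - s0)/k))`` — midpoint at ``s0``, steepness set
    by ``k > 0``; strictly increasing in the raw score.
    """
    if k <= 0:
        raise ValueError(f"calibration steepness k must be > 0, got {k}")
    from scipy.special import expit  # overflow-safe logistic

    x = np.asarray(track, dtype=float)
    return expit((x - s0) / k)


# Defaults chosen so that, under the Eisenberg scale, a poly-Ile window maps
# to p >= 0.99 and a poly-Asp window to p <= 0.01 (average track), and an
# ideal helical hydrophobic face scores high while a uniformly polar stretch
# scores near zero (moment track).  A stand-in calibration: the original
# burial predictor's score-to-probability mapping is unpublished.
DEFAULT_CALIB_AVG = (0.24, 0.20)
DEFAULT_CALIB_MOMENT = (0.35, 0.08)


@dataclass
class BurialProfile:
    """All per-residue tracks for one protein (1-based positions)."""

    sequence: str
    avg_hydro: np.ndarray
    moment: np.ndarray
    p_avg: np.ndarray
    p_moment: np.ndarray
    window_avg: int = 7
    window_moment: int = 11
    delta: float = 100.0

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for name in ("avg_hydro", "moment", "p_avg", "p_moment"):
            track = getattr(self, name)
            if len(track) != n:
                raise ValueError(f"track {name} length {len(track)} != sequence length {n}")
        if np.any(self.moment < 0):
            raise ValueError("hydrophobic moment must be non-negative")
        for name in ("p_avg", "p_moment"):
            p = getattr(self, name)
            if np.any((p < 0) | (p > 1)):
                raise ValueError(f"{name} outside [0, 1]")

    def to_frame(self):
        """Tabular export: position, residue, and the four tracks."""
        import pandas as pd

        return pd.DataFrame(
            {
                "position": np.arange(1, len(self.sequence) + 1),
                "residue": list(self.sequence),
                "avg_hydro": self.avg_hydro,
                "moment": self.moment,
                "p_avg": self.p_avg,
                "p_moment": self.p_moment,
            }
        )


@dataclass(frozen=True)
class BuriedRegion:
    """A contiguous run of predicted-buried residues (1-based, inclusive)."""

    start: int
    end: int
    peak: int
    criterion: str  # "average-hydrophobicity" | "moment"
    peak_probability: float

    def __post_init__(self) -> None:
        if not self.start <= self.peak <= self.end:
            raise ValueError("peak must lie within [start, end]")


def predict_profile(
    sequence: str,
    scale: HydrophobicityScale = EISENBERG_CONSENSUS,
    window_avg: int = 7,
    window_moment: int = 11,
    delta: float = 100.0,
    calib_avg: tuple[float, float] = DEFAULT_CALIB_AVG,
    calib_moment: tuple[float, float] = DEFAULT_CALIB_MOMENT,
) -> BurialProfile:
    """Compute both tracks and their burial probabilities for one protein."""
    avg = windowed_hydrophobicity(sequence, scale, window_avg)
    mom = hydrophobic_moment(sequence, scale, window_moment, delta)
    return BurialProfile(
        sequence=sequence.upper(),
        avg_hydro=avg,
        moment=mom,
        p_avg=calibrate_probability(avg, *calib_avg),
        p_moment=calibrate_probability(mom, *calib_moment),
        window_avg=window_avg,
        window_moment=window_moment,
        delta=delta,
    )


def find_buried_regions(
    profile: BurialProfile,
    threshold_avg: float = 0.90,
    threshold_moment: float = 0.80,
) -> list[BuriedRegion]:
    """Merge above-threshold residues into regions and pick one site each.

    A residue is a candidate iff ``p_avg > threshold_avg`` or
    ``p_moment > threshold_moment``.  Maximal runs of consecutive candidates
    become regions; the region's site is the position with the highest
    triggering probability (ties resolved toward the average-hydrophobicity
    track, then toward the lowest position).
    """
    for t in (threshold_avg, threshold_moment):
        if not 0.0 < t < 1.0:
            raise ValueError(f"thresholds must be in (0, 1), got {t}")
    hit_avg = profile.p_avg > threshold_avg
    hit_mom = profile.p_moment > threshold_moment
    cand = hit_avg | hit_mom
    regions: list[BuriedRegion] = []
    i, n = 0, len(cand)
    while i < n:
        if not cand[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and cand[j + 1]:
            j += 1
        best_p, best_pos, best_crit = -1.0, -1, ""
        for pos in range(i, j + 1):
            # average-hydrophobicity considered first so it wins exact ties
            if hit_avg[pos] and profile.p_avg[pos] > best_p:
                best_p, best_pos, best_crit = profile.p_avg[pos], pos, "average-hydrophobicity"
            if hit_mom[pos] and profile.p_moment[pos] > best_p:
                best_p, best_pos, best_crit = profile.p_moment[pos], pos, "moment"
        regions.append(
            BuriedRegion(
                start=i + 1,
                end=j + 1,
                peak=best_pos + 1,
                criterion=best_crit,
                peak_probability=float(best_p),
            )
        )
        i = j + 1
    return regions
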