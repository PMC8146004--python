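"""Amplitude thresholding: droplets → per-well positive/negative tallies.

The instrument software usually places the cut-off line automatically, but
not always (the RHc assay needed a manual line), so every cutoff here
records whether it was set automatically or manually and classification
accepts manual overrides.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .droplets import DropletTable

__all__ = [
    "AutoThreshold",
    "ChannelCutoffs",
    "ClassifiedCounts",
    "auto_threshold",
    "auto_cutoffs",
    "classify",
]

#: minimum droplets for a meaningful threshold fit
MIN_DROPLETS = 100


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class AutoThreshold:
    """Outcome of automatic thresholding on one channel."""

    cutoff: float
    bimodal: bool
    lower_mean: float
    upper_mean: float
    variance_ratio: float  # total SS / best two-cluster within SS

    def __post_init__(self) -> None:
        if not math.isfinite(self.cutoff):
            raise ValueError("cutoff must be finite")


@dataclass(frozen=True)
class ChannelCutoffs:
    """Per-channel amplitude cutoffs and their provenance (auto/manual)."""

    ch1_cutoff: float
    ch2_cutoff: float
    ch1_method: str = "auto"
    ch2_method: str = "auto"

    def __post_init__(self) -> None:
        for name in ("ch1_cutoff", "ch2_cutoff"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and positive, got {v}")
        for name in ("ch1_method", "ch2_method"):
            if getattr(self, name) not in ("auto", "manual"):
                raise ValueError(f"{name} must be 'auto' or 'manual'")


@dataclass(frozen=True)
class ClassifiedCounts:
    """Per-well positive/negative droplet tallies.

    A double-positive droplet counts in BOTH per-channel positive tallies
    (instrument convention) and is also reported separately, so the
    conservation identity is
    ``n_ch1_pos + n_ch2_pos − n_double_pos + n_neg = n_total``.
    """

    well_id: str
    n_total: int
    n_ch1_pos: int
    n_ch2_pos: int
    n_double_pos: int
    n_neg: int
    cutoffs: ChannelCutoffs | None = None

    def __post_init__(self) -> None:
        for name in ("n_total", "n_ch1_pos", "n_ch2_pos", "n_double_pos", "n_neg"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"well {self.well_id!r}: {name} must be a non-negative integer")
        if self.n_ch1_pos + self.n_ch2_pos - self.n_double_pos + self.n_neg != self.n_total:
            raise ValueError(
                f"well {self.well_id!r}: droplet conservation violated: "
                f"{self.n_ch1_pos} + {self.n_ch2_pos} - {self.n_double_pos} "
                f"+ {self.n_neg} != {self.n_total}"
            )
        if self.n_double_pos > min(self.n_ch1_pos, self.n_ch2_pos):
            raise ValueError(
                f"well {self.well_id!r}: n_double_pos exceeds a per-channel tally"
            )

    def positives(self, channel) -> int:
        key = getattr(channel, "value", channel)
        if key == "FAM":
            return self.n_ch1_pos
        if key == "HEX":
            return self.n_ch2_pos
        raise KeyError(f"unknown channel {channel!r}")


def auto_threshold(
    amplitudes,
    *,
    bimodal_factor: float = 4.0,
    fallback_k: float = 7.0,
    trim: float = 0.05,
) -> AutoThreshold:
    """Set a cutoff for one channel from its amplitude distribution.

    An exact 1-D two-means split (all n−1 ordered split points, prefix
    sums) finds the best two-cluster partition.  If it reduces the total
    sum of squares by at least ``bimodal_factor``, the channel is bimodal
    and the cutoff is the midpoint of the two cluster means.  Otherwise
    the distribution is a single (negative) cloud and the cutoff falls
    back to trimmed mean + ``fallback_k`` · trimmed SD, which places the
    line above every droplet of a clean NTC.
    """
    x = np.sort(np.asarray(amplitudes, dtype=float))
    n = len(x)
    if n < MIN_DROPLETS:
        raise InsufficientDataError(
            f"need at least {MIN_DROPLETS} droplets to set a threshold, got {n}"
        )

    s1 = np.cumsum(x)
    s2 = np.cumsum(x * x)
    total_ss = max(s2[-1] - s1[-1] ** 2 / n, 0.0)

    k = np.arange(1, n)  # left cluster sizes
    left_ss = s2[k - 1] - s1[k - 1] ** 2 / k
    right_n = n - k
    right_s1 = s1[-1] - s1[k - 1]
    right_ss = (s2[-1] - s2[k - 1]) - right_s1**2 / right_n
    within = np.clip(left_ss, 0, None) + np.clip(right_ss, 0, None)
    best = int(np.argmin(within))
    within_best = within[best]
    lower_mean = s1[best] / (best + 1)
    upper_mean = right_s1[best] / right_n[best]

    if total_ss == 0.0:
        ratio = 1.0
    elif within_best == 0.0:
        ratio = np.inf
    else:
        ratio = total_ss / within_best

    bimodal = total_ss > 0 and ratio >= bimodal_factor
    if bimodal:
        cutoff = 0.5 * (lower_mean + upper_mean)
    else:
        tmean = stats.trim_mean(x, trim)
        lo, hi = int(n * trim), n - int(n * trim)
        trimmed = x[lo:hi]
        tsd = float(trimmed.std(ddof=1)) if len(trimmed) > 1 else 0.0
        cutoff = float(tmean + fallback_k * tsd)
    return AutoThreshold(
        cutoff=float(cutoff),
        bimodal=bool(bimodal),
        lower_mean=float(lower_mean),
        upper_mean=float(upper_mean),
        variance_ratio=float(ratio),
    )


def auto_cutoffs(
    table: DropletTable, **kwargs
) -> tuple[ChannelCutoffs, dict[str, AutoThreshold]]:
    """Automatic cutoffs for both channels of a well, with diagnostics."""
    d1 = auto_threshold(table.ch1_amplitude, **kwargs)
    d2 = auto_threshold(table.ch2_amplitude, **kwargs)
    cutoffs = ChannelCutoffs(
        ch1_cutoff=d1.cutoff, ch2_cutoff=d2.cutoff, ch1_method="auto", ch2_method="auto"
    )
    return cutoffs, {"FAM": d1, "HEX": d2}


def classify(table: DropletTable, cutoffs: ChannelCutoffs) -> ClassifiedCounts:
    """Tally positives per channel: positive iff amplitude strictly exceeds
    the channel cutoff (ties classify negative — conservative for fetal
    calls).  Deterministic and droplet-order invariant."""
    pos1 = table.ch1_amplitude > cutoffs.ch1_cutoff
    pos2 = table.ch2_amplitude > cutoffs.ch2_cutoff
    n_double = int(np.sum(pos1 & pos2))
    n_neg = int(np.sum(~pos1 & ~pos2))
    return ClassifiedCounts(
        well_id=table.well_id,
        n_total=table.n_droplets,
        n_ch1_pos=int(pos1.sum()),
        n_ch2_pos=int(pos2.sum()),
        n_double_pos=n_double,
        n_neg=n_neg,
        cutoffs=cutoffs,
    )
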