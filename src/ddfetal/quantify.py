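"""Molecular quantification for digital PCR wells.

Covers the standard Poisson occupancy machinery (λ = −ln(1 − p), copies
per microliter) and the cell-free fetal DNA fraction statistic

    FF = FSP / ((MSP − FSP) / 2),

where FSP are fetus-specific positive droplets (the allele the homozygous
mother lacks) and MSP maternal-specific positives.  The raw-count form
assumes each positive droplet holds a single molecule, justified at the
low occupancies typical of plasma cfDNA wells; the Poisson-corrected form
replaces each count by the estimated molecule number n·λ and is the
appropriate choice at higher loads.

The denominator (MSP − FSP)/2 is the number of maternal genomes: the
mother contributes two copies of her allele per genome while the fetus,
necessarily heterozygous when detectable, contributes one copy to each
channel — subtracting FSP removes the fetal contribution from the
maternal channel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "SaturationError",
    "FetalFractionResult",
    "lambda_estimate",
    "lambda_ci",
    "copies_per_microliter",
    "fetal_fraction",
    "fetal_fraction_ci",
    "format_percent",
]

#: default droplet volume (nL), the generator-instrument convention
DEFAULT_DROPLET_VOLUME_NL = 0.85


class SaturationError(ValueError):
    """All droplets positive: occupancy is unbounded."""


def lambda_estimate(n_pos: int, n_total: int) -> float:
    """Mean target molecules per droplet, λ = −ln(1 − n_pos/n_total)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_pos <= n_total:
        raise ValueError(f"n_pos must lie in [0, n_total], got {n_pos}/{n_total}")
    if n_pos == n_total:
        raise SaturationError(
            f"all {n_total} droplets positive: occupancy cannot be estimated"
        )
    return float(-np.log1p(-n_pos / n_total))


def lambda_ci(n_pos: int, n_total: int, conf: float = 0.95) -> tuple[float, float]:
    """Confidence interval on λ via a Wilson interval on the positive
    fraction, transformed through λ = −ln(1 − p)."""
    lambda_estimate(n_pos, n_total)  # validation incl. saturation
    alpha = 1.0 - conf
    p_lo, p_hi = proportion_confint(n_pos, n_total, alpha=alpha, method="wilson")
    return (float(-np.log1p(-p_lo)), float(-np.log1p(-min(p_hi, 1.0 - 1e-12))))


def copies_per_microliter(
    lam: float, droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL
) -> float:
    """Absolute concentration: λ molecules per droplet over droplet volume."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if droplet_volume_nl <= 0:
        raise ValueError("droplet volume must be positive")
    return lam / (droplet_volume_nl * 1e-3)


def format_percent(fraction: float) -> str:
    """Report a fetal fraction in the mixed-precision house style:
    whole percent at ≥10%, one decimal below 10% (e.g. "26%", "3.5%")."""
    pct = fraction * 100.0
    if pct >= 10:
        return f"{math.floor(pct + 0.5):.0f}%"
    return f"{pct:.1f}%"


def reported_percent(fraction: float) -> float:
    """Numeric form of :func:`format_percent` (26.0 or 3.5)."""
    pct = fraction * 100.0
    return float(math.floor(pct + 0.5)) if pct >= 10 else round(pct, 1)


@dataclass(frozen=True)
class FetalFractionResult:
    """Point estimate (and optional CI) of the cffDNA fraction of a well."""

    fsp: int
    msp: int
    fraction: float
    method: str  # "raw-count" | "poisson-corrected"
    reference: str = "maternal-specific"
    ci: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.fraction < 0:
            raise ValueError("fetal fraction must be non-negative")
        if self.fsp >= self.msp:
            raise ValueError("fraction defined only for fsp < msp")
        if self.ci is not None:
            lo, hi = self.ci
            if not lo <= self.fraction <= hi:
                raise ValueError("CI must contain the point estimate")

    @property
    def percent(self) -> float:
        return self.fraction * 100.0

    @property
    def percent_rounded(self) -> float:
        return reported_percent(self.fraction)

    @property
    def percent_display(self) -> str:
        return format_percent(self.fraction)


def _molecule_counts(fsp: float, msp: float, n_total: int) -> tuple[float, float]:
    return (
        n_total * lambda_estimate(int(fsp), n_total),
        n_total * lambda_estimate(int(msp), n_total),
    )


def _apply_ff_formula(a: float, b: float, reference: str) -> float:
    """FF from (fetus-specific, reference) molecule or droplet numbers.

    reference semantics:
    ``"maternal-specific"``
        b counts the maternal allele; maternal genomes = (b − a)/2 (the
        detectable fetus is heterozygous, so a of b's copies are fetal).
    ``"total-dna"``
        b is a total-DNA control (β-globin) counting 2 copies per genome,
        maternal and fetal alike; maternal genomes = (b − 2a)/2.
    ``"total-dna-ratio"``
        the simple ratio 2a/b — fetal per *total* genomes, a different
        (smaller) quantity than the fetal/maternal ratio; kept for
        comparison with total-DNA-normalised reports.
    """
    if reference == "maternal-specific":
        denom = (b - a) / 2.0
    elif reference == "total-dna":
        denom = (b - 2.0 * a) / 2.0
    elif reference == "total-dna-ratio":
        return 2.0 * a / b
    else:
        raise ValueError(f"unknown reference {reference!r}")
    if denom <= 0:
        raise ValueError(
            f"fetal fraction undefined: no maternal excess on the reference "
            f"channel (fsp-like {a:.1f}, reference {b:.1f}, {reference})"
        )
    return a / denom


def fetal_fraction(
    fsp: int,
    msp: int,
    method: str = "raw-count",
    n_total: int | None = None,
    *,
    reference: str = "maternal-specific",
    ci: bool = False,
    conf: float = 0.95,
    n_boot: int = 4000,
    random_state: int | None = None,
) -> FetalFractionResult:
    """Cell-free fetal DNA fraction, FF = FSP/((MSP − FSP)/2).

    Parameters
    ----------
    fsp, msp
        Fetus-specific and maternal-specific positive droplet counts.
    method
        ``"raw-count"`` (default; one molecule per droplet) or
        ``"poisson-corrected"`` (counts replaced by n_total·λ estimates,
        requires ``n_total``).
    reference
        What the MSP channel counts.  The default applies the printed
        formula above.  ``"total-dna"`` treats MSP as a β-globin total-DNA
        control (2 copies from every genome, fetal included) and uses
        maternal genomes = (MSP − 2·FSP)/2; ``"total-dna-ratio"`` is the
        simple 2·FSP/MSP ratio (fetal per total genomes).
    ci
        If True, attach a bootstrap confidence interval
        (see :func:`fetal_fraction_ci`).
    """
    if fsp < 0 or msp < 0:
        raise ValueError("droplet counts must be non-negative")
    if msp <= fsp:
        raise ValueError(
            f"fetal fraction undefined for fsp={fsp} >= msp={msp} "
            "(no maternal excess on the reference channel)"
        )
    if method == "raw-count":
        a, b = float(fsp), float(msp)
    elif method == "poisson-corrected":
        if n_total is None:
            raise ValueError("poisson-corrected method requires n_total")
        a, b = _molecule_counts(fsp, msp, n_total)
    else:
        raise ValueError(f"unknown method {method!r}")
    fraction = _apply_ff_formula(a, b, reference)
    interval = (
        fetal_fraction_ci(
            fsp, msp, method=method, n_total=n_total, reference=reference,
            conf=conf, n_boot=n_boot, random_state=random_state,
        )
        if ci
        else None
    )
    return FetalFractionResult(
        fsp=fsp, msp=msp, fraction=fraction, method=method,
        reference=reference, ci=interval,
    )


def fetal_fraction_ci(
    fsp: int,
    msp: int,
    n_total: int | None = None,
    method: str = "raw-count",
    reference: str = "maternal-specific",
    conf: float = 0.95,
    n_boot: int = 4000,
    random_state: int | None = None,
) -> tuple[float, float]:
    """Bootstrap confidence interval on the fetal fraction.

    The two droplet counts are treated as independent Poisson
    observations; their means are resampled from Gamma(count + 1/2)
    (the Jeffreys posterior for a Poisson mean, which remains proper at
    fsp = 0) and the FF formula is applied to every draw.  The percentile
    interval is widened, if necessary, to contain the point estimate, and
    the lower bound is 0 when fsp = 0.

    The bootstrap is deterministic: when ``random_state`` is omitted a
    seed is derived from (fsp, msp).
    """
    point = fetal_fraction(fsp, msp, method=method, n_total=n_total,
                           reference=reference).fraction
    if random_state is None:
        random_state = (1_000_003 * int(fsp) + int(msp) + 17) % (2**31 - 1)
    rng = np.random.default_rng(random_state)
    a = rng.gamma(fsp + 0.5, size=n_boot)
    b = rng.gamma(msp + 0.5, size=n_boot)
    if method == "poisson-corrected":
        assert n_total is not None
        cap = n_total * (1.0 - 1e-9)
        a = -n_total * np.log1p(-np.minimum(a, cap) / n_total)
        b = -n_total * np.log1p(-np.minimum(b, cap) / n_total)
    valid = b > (2.0 * a if reference == "total-dna" else a)
    a, b = a[valid], b[valid]
    if len(a) == 0:
        return (0.0 if fsp == 0 else point, point)
    if reference == "maternal-specific":
        fr = a / ((b - a) / 2.0)
    elif reference == "total-dna":
        fr = a / ((b - 2.0 * a) / 2.0)
    else:
        fr = 2.0 * a / b
    alpha = (1.0 - conf) / 2.0
    lo, hi = np.quantile(fr, [alpha, 1.0 - alpha])
    lo, hi = float(min(lo, point)), float(max(hi, point))
    if fsp == 0:
        lo = 0.0
    return (lo, hi)
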