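"""Synthetic ddPCR well generator: Poisson partitioning of cfDNA into droplets.

A maternal plasma sample contains maternal genomes at a mean occupancy of
``maternal_genomes_per_droplet`` genome-equivalents per droplet and fetal
genomes at a fraction ``fetal_fraction_true`` of that (fetal/maternal
ratio).  Each genotype contributes allele copies to the channel that
detects the allele (homozygote 2 per genome, heterozygote 1 per channel;
the β-globin total-DNA control sees 2 copies from *every* genome).
Molecule counts per droplet are then independent Poisson draws per channel,
so droplet co-occupancy arises naturally — the common "one molecule per
droplet" reading of low-occupancy wells becomes an approximation whose
failure modes the simulator can probe.

A droplet is latently positive on a channel if at least one molecule
survives ``detection_dropout``, or, failing that, with probability
``false_positive_rate`` (spurious amplification).  Amplitudes are drawn
from Gaussian negative/positive clouds, with a small ``rain_prob`` chance
that a positive droplet lands uniformly between the clouds ("rain").
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .assays import Channel, MaternalContext, parse_genotype
from .droplets import DropletTable

__all__ = [
    "AmplitudeModel",
    "SimulationParams",
    "channel_lambdas",
    "expected_counts",
    "simulate_well",
    "simulate_ntc",
]


@dataclass(frozen=True)
class AmplitudeModel:
    """Gaussian negative/positive fluorescence clouds for one channel.

    Defaults (negative 1000 ± 150, positive 8000 ± 400 arbitrary units)
    give cleanly separable clouds with visible rain, the morphology of a
    well-optimised duplex TaqMan assay.
    """

    neg_mean: float = 1000.0
    neg_sd: float = 150.0
    pos_mean: float = 8000.0
    pos_sd: float = 400.0

    def __post_init__(self) -> None:
        if self.pos_mean <= self.neg_mean:
            raise ValueError("positive-cloud mean must exceed negative-cloud mean")
        if self.neg_sd < 0 or self.pos_sd < 0:
            raise ValueError("cloud SDs must be non-negative")


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of one simulated duplex well.

    ``fetal_fraction_true`` is the fetal/maternal genome-equivalent ratio
    (not fetal/total), matching the FSP/((MSP−FSP)/2) fetal-fraction
    statistic this package estimates.
    """

    ctx: MaternalContext
    fetal_genotype: tuple[str, str]
    n_droplets: int = 14_000
    maternal_genomes_per_droplet: float = 0.035
    fetal_fraction_true: float = 0.10
    fam_amplitudes: AmplitudeModel = field(default_factory=AmplitudeModel)
    hex_amplitudes: AmplitudeModel = field(default_factory=AmplitudeModel)
    rain_prob: float = 0.01
    false_positive_rate: float = 2e-5
    detection_dropout: float = 0.0
    seed: int = 0
    well_id: str = "sim"

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "fetal_genotype", parse_genotype(self.ctx.assay, self.fetal_genotype)
        )
        if self.n_droplets < 1:
            raise ValueError("n_droplets must be >= 1")
        if self.maternal_genomes_per_droplet <= 0:
            raise ValueError("maternal_genomes_per_droplet must be > 0")
        if self.fetal_fraction_true < 0:
            raise ValueError("fetal_fraction_true must be >= 0")
        for name in ("rain_prob", "false_positive_rate", "detection_dropout"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not set(self.fetal_genotype) & set(self.ctx.maternal_genotype):
            raise ValueError(
                f"fetal genotype {self.fetal_genotype} shares no allele with the "
                f"maternal genotype {self.ctx.maternal_genotype}; impossible "
                "under Mendelian inheritance"
            )

    def with_(self, **changes) -> "SimulationParams":
        return replace(self, **changes)

    def amplitude_model(self, channel: Channel) -> AmplitudeModel:
        return self.fam_amplitudes if channel is Channel.FAM else self.hex_amplitudes


def _allele_copies(genotype: tuple[str, str], allele: str) -> int:
    return sum(1 for a in genotype if a == allele)


def channel_lambdas(params: SimulationParams) -> dict[Channel, float]:
    """Mean molecules per droplet on each channel.

    λ_c = (maternal copies/genome on c)·λ_m + (fetal copies/genome on c)·f·λ_m.
    The β-globin control channel sees 2 copies from every genome, maternal
    and fetal alike.
    """
    assay = params.ctx.assay
    lam_m = params.maternal_genomes_per_droplet
    f = params.fetal_fraction_true
    out: dict[Channel, float] = {}
    for channel, allele in ((Channel.FAM, assay.fam_allele), (Channel.HEX, assay.hex_allele)):
        if channel is Channel.HEX and assay.reference_channel_is_total_dna:
            out[channel] = 2.0 * lam_m * (1.0 + f)
        else:
            m = _allele_copies(params.ctx.maternal_genotype, allele)
            k = _allele_copies(params.fetal_genotype, allele)
            out[channel] = lam_m * (m + f * k)
    return out


def expected_counts(params: SimulationParams) -> dict[str, float]:
    """Analytic expected positive-droplet count per channel.

    E[positives_c] = n · [(1 − e^{−λ_c(1−d)}) + e^{−λ_c(1−d)} · fp],
    i.e. a droplet is positive if at least one molecule survives dropout,
    or spuriously with probability fp otherwise.
    """
    lams = channel_lambdas(params)
    out = {}
    for channel, lam in lams.items():
        p_neg = np.exp(-lam * (1.0 - params.detection_dropout))
        out[channel.value] = params.n_droplets * ((1.0 - p_neg) + p_neg * params.false_positive_rate)
    return out


def _draw_amplitudes(
    rng: np.random.Generator,
    positive: np.ndarray,
    model: AmplitudeModel,
    rain_prob: float,
) -> np.ndarray:
    n = len(positive)
    amp = rng.normal(model.neg_mean, model.neg_sd, size=n)
    n_pos = int(positive.sum())
    if n_pos:
        pos_amp = rng.normal(model.pos_mean, model.pos_sd, size=n_pos)
        rain = rng.random(n_pos) < rain_prob
        n_rain = int(rain.sum())
        if n_rain:
            pos_amp[rain] = rng.uniform(model.neg_mean, model.pos_mean, size=n_rain)
        amp[positive] = pos_amp
    return np.clip(amp, 0.0, None)


def simulate_well(params: SimulationParams) -> DropletTable:
    """Simulate one duplex well; reproducible for a fixed ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    lams = channel_lambdas(params)
    n = params.n_droplets
    cols: dict[str, np.ndarray] = {}
    for i, channel in enumerate((Channel.FAM, Channel.HEX), start=1):
        mol = rng.poisson(lams[channel], size=n)
        if params.detection_dropout > 0:
            mol = rng.binomial(mol, 1.0 - params.detection_dropout)
        latent = mol >= 1
        if params.false_positive_rate > 0:
            fp = (~latent) & (rng.random(n) < params.false_positive_rate)
            latent = latent | fp
        amp = _draw_amplitudes(rng, latent, params.amplitude_model(channel), params.rain_prob)
        cols[f"ch{i}_molecules"] = mol
        cols[f"ch{i}_latent_pos"] = latent
        cols[f"ch{i}_amplitude"] = amp
    return DropletTable(
        ch1_amplitude=cols["ch1_amplitude"],
        ch2_amplitude=cols["ch2_amplitude"],
        well_id=params.well_id,
        ch1_molecules=cols["ch1_molecules"],
        ch2_molecules=cols["ch2_molecules"],
        ch1_latent_pos=cols["ch1_latent_pos"],
        ch2_latent_pos=cols["ch2_latent_pos"],
        meta={"seed": params.seed, "fetal_fraction_true": params.fetal_fraction_true},
    )


def simulate_ntc(
    n_droplets: int = 15_000,
    false_positive_rate: float = 2e-5,
    fam_amplitudes: AmplitudeModel | None = None,
    hex_amplitudes: AmplitudeModel | None = None,
    rain_prob: float = 0.01,
    seed: int = 0,
    well_id: str = "NTC",
) -> DropletTable:
    """Simulate a no-template control: positives arise only from noise."""
    if n_droplets < 1:
        raise ValueError("n_droplets must be >= 1")
    if not 0 <= false_positive_rate <= 1:
        raise ValueError("false_positive_rate must lie in [0, 1]")
    fam_amplitudes = fam_amplitudes or AmplitudeModel()
    hex_amplitudes = hex_amplitudes or AmplitudeModel()
    rng = np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {}
    for i, model in enumerate((fam_amplitudes, hex_amplitudes), start=1):
        latent = rng.random(n_droplets) < false_positive_rate
        out[f"ch{i}_latent_pos"] = latent
        out[f"ch{i}_amplitude"] = _draw_amplitudes(rng, latent, model, rain_prob)
    zero = np.zeros(n_droplets, dtype=int)
    return DropletTable(
        ch1_amplitude=out["ch1_amplitude"],
        ch2_amplitude=out["ch2_amplitude"],
        well_id=well_id,
        ch1_molecules=zero,
        ch2_molecules=zero.copy(),
        ch1_latent_pos=out["ch1_latent_pos"],
        ch2_latent_pos=out["ch2_latent_pos"],
        meta={"seed": seed, "ntc": True},
    )
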