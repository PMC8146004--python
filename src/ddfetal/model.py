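"""Model/Results interface for per-well fetal genotyping.

`FetalGenotypeModel` bundles one sample well, its no-template control and
the maternal context; `fit()` runs classification (when starting from
amplitudes), quantification and the decision rules, returning a
`FetalGenotypeResults` that carries the call, the fetal-fraction estimate
with its confidence interval, QC diagnostics and a printable summary.
"""

from __future__ import annotations

from typing import Mapping

from .assays import MaternalContext, fetus_specific_channel
from .caller import CallStatus, DecisionThresholds, FetalCallResult, call_fetal_genotype, ntc_qc
from .classify import AutoThreshold, ChannelCutoffs, ClassifiedCounts, auto_cutoffs, classify
from .droplets import DropletTable
from .quantify import copies_per_microliter, lambda_ci, lambda_estimate

__all__ = ["FetalGenotypeModel", "FetalGenotypeResults"]


class FetalGenotypeModel:
    """Fetal blood-group genotype model for one ddPCR well.

    Parameters
    ----------
    sample_counts, ntc_counts
        Classified droplet tallies of the sample well and its NTC.
    ctx
        Assay plus homozygous maternal genotype.
    thresholds
        Decision limits; defaults to the validated limits
        (NTC ≤ 4, FSP ≥ 5, repeat zone [3, 7], MSP ≥ 200).

    Use :meth:`from_amplitudes` to start from raw droplet amplitude
    tables; cutoffs are then set automatically per channel unless
    supplied manually.
    """

    def __init__(
        self,
        sample_counts: ClassifiedCounts,
        ntc_counts: ClassifiedCounts,
        ctx: MaternalContext,
        thresholds: DecisionThresholds | None = None,
    ) -> None:
        self.sample_counts = sample_counts
        self.ntc_counts = ntc_counts
        self.ctx = ctx
        self.thresholds = thresholds or DecisionThresholds()
        self.sample_table: DropletTable | None = None
        self.ntc_table: DropletTable | None = None
        self.threshold_diagnostics: Mapping[str, AutoThreshold] | None = None

    @classmethod
    def from_amplitudes(
        cls,
        sample_table: DropletTable,
        ntc_table: DropletTable,
        ctx: MaternalContext,
        cutoffs: ChannelCutoffs | None = None,
        ntc_cutoffs: ChannelCutoffs | None = None,
        thresholds: DecisionThresholds | None = None,
        **auto_kwargs,
    ) -> "FetalGenotypeModel":
        """Build the model from per-droplet amplitudes.

        Manual ``cutoffs`` override the automatic two-cluster threshold
        (needed e.g. when the software cannot place the line on a channel);
        the NTC well gets its own cutoffs because it normally lacks a
        positive cloud to split on.
        """
        diagnostics = None
        if cutoffs is None:
            cutoffs, diagnostics = auto_cutoffs(sample_table, **auto_kwargs)
        if ntc_cutoffs is None:
            ntc_cutoffs, _ = auto_cutoffs(ntc_table, **auto_kwargs)
        model = cls(
            sample_counts=classify(sample_table, cutoffs),
            ntc_counts=classify(ntc_table, ntc_cutoffs),
            ctx=ctx,
            thresholds=thresholds,
        )
        model.sample_table = sample_table
        model.ntc_table = ntc_table
        model.threshold_diagnostics = diagnostics
        return model

    @classmethod
    def from_counts(
        cls,
        sample_counts: ClassifiedCounts,
        ntc_counts: ClassifiedCounts,
        ctx: MaternalContext,
        thresholds: DecisionThresholds | None = None,
    ) -> "FetalGenotypeModel":
        return cls(sample_counts, ntc_counts, ctx, thresholds)

    def fit(
        self,
        ff_method: str = "auto",
        ci: bool = True,
    ) -> "FetalGenotypeResults":
        """Apply the decision rules and estimate the fetal fraction.

        ``ff_method`` "auto" uses raw droplet counts at low occupancy and
        Poisson-corrected molecule numbers above (see
        :func:`ddfetal.caller.call_fetal_genotype`); "raw-count" or
        "poisson-corrected" force one estimator.
        """
        call = call_fetal_genotype(
            self.sample_counts,
            self.ntc_counts,
            self.ctx,
            self.thresholds,
            ff_method=ff_method,
            compute_ci=ci,
        )
        return FetalGenotypeResults(self, call)


class FetalGenotypeResults:
    """Fitted per-well genotyping result.

    Attributes
    ----------
    call : FetalCallResult
        Genotype call, status and QC flags.
    """

    def __init__(self, model: FetalGenotypeModel, call: FetalCallResult) -> None:
        self.model = model
        self.call = call

    # -- convenience accessors -------------------------------------------
    @property
    def status(self) -> CallStatus:
        return self.call.status

    @property
    def fetal_genotype(self) -> str:
        return self.call.fetal_genotype_call

    @property
    def fetal_fraction(self) -> float | None:
        ff = self.call.fetal_fraction
        return None if ff is None else ff.fraction

    def conf_int(self) -> tuple[float, float] | None:
        """95% interval on the fetal fraction (positive calls only)."""
        ff = self.call.fetal_fraction
        return None if ff is None or ff.ci is None else ff.ci

    @property
    def qc_flags(self) -> tuple[str, ...]:
        return self.call.qc_flags

    def lambda_(self, channel: str = "MSP") -> float:
        """Poisson occupancy of a channel (``"FSP"``, ``"MSP"``, ``"FAM"``,
        ``"HEX"``)."""
        return lambda_estimate(self._channel_positives(channel), self.model.sample_counts.n_total)

    def lambda_conf_int(self, channel: str = "MSP") -> tuple[float, float]:
        return lambda_ci(self._channel_positives(channel), self.model.sample_counts.n_total)

    def concentration(self, channel: str = "MSP", droplet_volume_nl: float = 0.85) -> float:
        """Absolute concentration of a channel's target, copies/µL."""
        return copies_per_microliter(self.lambda_(channel), droplet_volume_nl)

    def _channel_positives(self, channel: str) -> int:
        fs_ch, _ = fetus_specific_channel(self.model.ctx)
        key = {"FSP": fs_ch.value, "MSP": fs_ch.other().value}.get(channel, channel)
        return self.model.sample_counts.positives(key)

    def to_dict(self) -> dict:
        return self.call.to_dict()

    def plot(self, ax=None):
        """One-dimensional amplitude plot of the sample well, if the model
        was built from amplitudes."""
        if self.model.sample_table is None:
            raise ValueError("model was built from counts; no amplitudes to plot")
        from .plotting import plot_droplets_1d

        return plot_droplets_1d(self.model.sample_table, self.model.sample_counts.cutoffs, ax=ax)

    # -- reporting -------------------------------------------------------
    def summary(self) -> str:
        c = self.call
        m = self.model
        ntc = ntc_qc(m.ntc_counts, m.thresholds)
        width = 58
        lines = [
            "Fetal blood-group genotype call (duplex ddPCR)".center(width),
            "=" * width,
            f"{'Well:':<24}{c.well_id}",
            f"{'Assay:':<24}{c.assay_name}",
            f"{'Maternal genotype:':<24}{'/'.join(c.maternal_genotype)}",
            f"{'Fetus-specific channel:':<24}{c.fs_channel.value} ({c.fs_allele})",
            "-" * width,
            f"{'Droplets (total):':<24}{m.sample_counts.n_total}",
            f"{'FSP:':<24}{c.fsp}",
            f"{'MSP:':<24}{c.msp}",
            f"{'NTC positives:':<24}FAM {ntc.ch1_pos}, HEX {ntc.ch2_pos} (limit {ntc.limit})",
        ]
        if m.sample_counts.cutoffs is not None:
            cut = m.sample_counts.cutoffs
            lines.append(
                f"{'Cutoffs:':<24}ch1 {cut.ch1_cutoff:.0f} ({cut.ch1_method}), "
                f"ch2 {cut.ch2_cutoff:.0f} ({cut.ch2_method})"
            )
        lines += [
            "-" * width,
            f"{'Fetal genotype call:':<24}{c.fetal_genotype_call}",
            f"{'Status:':<24}{c.status.value}",
        ]
        ff = c.fetal_fraction
        if ff is not None:
            ci = ""
            if ff.ci is not None:
                ci = f"  (95% CI {ff.ci[0] * 100:.1f}%-{ff.ci[1] * 100:.1f}%)"
            lines.append(f"{'Fetal fraction:':<24}{ff.percent_display}{ci}")
        lines += [
            f"{'QC flags:':<24}{', '.join(c.qc_flags) if c.qc_flags else 'none'}",
            f"{'Thresholds:':<24}NTC<={m.thresholds.ntc_max_false_pos}, "
            f"FSP>={m.thresholds.min_fetal_pos}, "
            f"repeat {list(m.thresholds.repeat_zone)}, MSP>={m.thresholds.min_msp}",
            "=" * width,
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<FetalGenotypeResults well={self.call.well_id!r} "
            f"call={self.fetal_genotype!r} status={self.status.value}>"
        )
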