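"""File formats: amplitude CSV, counts CSV, and report JSON.

Two entry points mirror the two places a user may start from: raw
per-droplet amplitude exports (QuantaSoft-style, one droplet per row) or
already-classified per-well droplet tallies, which lets published count
tables be replayed without amplitude data.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from . import __version__ as _pkg_version
from .caller import FetalCallResult
from .classify import ChannelCutoffs, ClassifiedCounts
from .droplets import CH1_COL, CH2_COL, DropletTable

__all__ = [
    "FormatError",
    "WellRecord",
    "read_amplitude_csv",
    "write_amplitude_csv",
    "read_counts_csv",
    "write_counts_csv",
    "write_report",
    "read_report",
    "render_summary",
]

logger = logging.getLogger("ddfetal")


class FormatError(ValueError):
    pass


#: accepted header aliases per channel (instrument exports vary)
CH1_ALIASES = (CH1_COL, "Ch1 Amplitude", "Ch1Amplitude", "ch1", "FAM", "fam_amplitude")
CH2_ALIASES = (CH2_COL, "Ch2 Amplitude", "Ch2Amplitude", "ch2", "HEX", "VIC", "hex_amplitude")

COUNTS_COLUMNS = ("well_id", "n_total", "n_ch1_pos", "n_ch2_pos", "n_double_pos", "n_neg")


@dataclass(frozen=True)
class WellRecord:
    """One well of a run manifest: its kind, assay and data location."""

    well_id: str
    kind: str  # sample | ntc | positive-control | negative-control
    assay_name: str
    maternal_genotype: str | None = None
    path: str | None = None

    def __post_init__(self) -> None:
        kinds = ("sample", "ntc", "positive-control", "negative-control")
        if self.kind not in kinds:
            raise ValueError(f"well {self.well_id!r}: kind must be one of {kinds}")
        if self.kind == "ntc" and self.maternal_genotype is not None:
            raise ValueError(f"NTC well {self.well_id!r} must not carry a maternal genotype")
        if self.kind == "sample" and self.maternal_genotype is None:
            raise ValueError(f"sample well {self.well_id!r} requires a maternal genotype")


def _resolve_column(columns: Sequence[str], aliases: Sequence[str], what: str) -> str:
    lowered = {c.lower().strip(): c for c in columns}
    for alias in aliases:
        hit = lowered.get(alias.lower())
        if hit is not None:
            return hit
    raise FormatError(
        f"no {what} column found; expected one of {list(aliases)}, got {list(columns)}"
    )


def read_amplitude_csv(
    source,
    well_id: str | None = None,
    ch1_aliases: Sequence[str] = CH1_ALIASES,
    ch2_aliases: Sequence[str] = CH2_ALIASES,
) -> DropletTable:
    """Read a per-droplet amplitude table (comma-separated, header row).

    Extra columns (pre-assigned cluster labels etc.) are ignored; row
    order is preserved.
    """
    try:
        frame = pd.read_csv(source, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty amplitude file: {source}") from exc
    if frame.empty:
        raise FormatError(f"amplitude file has a header but no droplets: {source}")
    c1 = _resolve_column(frame.columns, ch1_aliases, "channel-1 (FAM) amplitude")
    c2 = _resolve_column(frame.columns, ch2_aliases, "channel-2 (HEX) amplitude")
    for col in (c1, c2):
        values = pd.to_numeric(frame[col], errors="coerce")
        bad = values.isna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise FormatError(f"non-numeric amplitude in column {col!r} at line {line}")
        frame[col] = values
    if well_id is None:
        name = getattr(source, "name", source)
        well_id = os.path.splitext(os.path.basename(str(name)))[0]
    logger.info("read %d droplets for well %s", len(frame), well_id)
    renamed = frame.rename(columns={c1: CH1_COL, c2: CH2_COL})
    return DropletTable.from_frame(renamed, well_id=well_id)


def write_amplitude_csv(table: DropletTable, destination, include_truth: bool = True) -> None:
    table.to_frame(include_truth=include_truth).to_csv(destination, index=False)


def read_counts_csv(source) -> list[ClassifiedCounts]:
    """Read per-well classified tallies; the droplet conservation identity
    is enforced on load and a violation names the offending well."""
    try:
        frame = pd.read_csv(source)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty counts file: {source}") from exc
    if frame.empty:
        raise FormatError(f"counts file has a header but no wells: {source}")
    missing = [c for c in COUNTS_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"counts file missing column(s): {missing}")
    records = []
    for _, row in frame.iterrows():
        try:
            records.append(
                ClassifiedCounts(
                    well_id=str(row["well_id"]),
                    n_total=int(row["n_total"]),
                    n_ch1_pos=int(row["n_ch1_pos"]),
                    n_ch2_pos=int(row["n_ch2_pos"]),
                    n_double_pos=int(row["n_double_pos"]),
                    n_neg=int(row["n_neg"]),
                )
            )
        except ValueError as exc:
            raise FormatError(str(exc)) from exc
    return records


def write_counts_csv(records: Iterable[ClassifiedCounts], destination) -> None:
    rows = []
    for r in records:
        row = {c: getattr(r, c) for c in COUNTS_COLUMNS}
        if r.cutoffs is not None:
            row.update(
                ch1_cutoff=r.cutoffs.ch1_cutoff,
                ch2_cutoff=r.cutoffs.ch2_cutoff,
                ch1_method=r.cutoffs.ch1_method,
                ch2_method=r.cutoffs.ch2_method,
            )
        rows.append(row)
    pd.DataFrame(rows).to_csv(destination, index=False)


def _cutoffs_dict(cutoffs: ChannelCutoffs | None) -> dict | None:
    if cutoffs is None:
        return None
    return {
        "ch1_cutoff": cutoffs.ch1_cutoff,
        "ch2_cutoff": cutoffs.ch2_cutoff,
        "ch1_method": cutoffs.ch1_method,
        "ch2_method": cutoffs.ch2_method,
    }


def write_report(
    results: Sequence[FetalCallResult],
    destination,
    *,
    cutoffs: dict[str, ChannelCutoffs] | None = None,
    seed: int | None = None,
) -> dict:
    """Write the machine-readable run report (JSON, one record per well).

    Every record carries full provenance: the exact thresholds, the
    cutoffs used and how they were set, the software version and, for
    simulated wells, the seed.
    """
    if not results:
        raise ValueError("cannot write a report with no results")
    doc = {
        "software": {"name": "ddfetal", "version": _pkg_version},
        "seed": seed,
        "wells": [],
    }
    for r in results:
        rec = r.to_dict()
        if cutoffs and r.well_id in cutoffs:
            rec["cutoffs"] = _cutoffs_dict(cutoffs[r.well_id])
        doc["wells"].append(rec)
    doc["status_counts"] = _status_counts(results)
    if hasattr(destination, "write"):
        json.dump(doc, destination, indent=2)
    else:
        with open(destination, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=2)
    logger.info("wrote report for %d wells", len(results))
    return doc


def read_report(source) -> dict:
    if hasattr(source, "read"):
        return json.load(source)
    with open(source, "r", encoding="utf-8") as fh:
        return json.load(fh)


def _status_counts(results: Sequence[FetalCallResult]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for r in results:
        counts[r.status.value] = counts.get(r.status.value, 0) + 1
    return counts


def render_summary(results: Sequence[FetalCallResult]) -> str:
    """Human-readable summary table (well, genotypes, tallies, FF, status)."""
    header = (
        f"{'well':<14}{'assay':<16}{'maternal':<12}{'fetal call':<14}"
        f"{'FSP':>6}{'MSP':>7}  {'FF':<8}{'status'}"
    )
    lines = [header, "-" * len(header)]
    for r in results:
        ff = r.fetal_fraction.percent_display if r.fetal_fraction else "-"
        lines.append(
            f"{r.well_id:<14}{r.assay_name:<16}{'/'.join(r.maternal_genotype):<12}"
            f"{r.fetal_genotype_call:<14}{r.fsp:>6}{r.msp:>7}  {ff:<8}{r.status.value}"
        )
    counts = _status_counts(results)
    lines.append("-" * len(header))
    lines.append("status counts: " + ", ".join(f"{k}={v}" for k, v in sorted(counts.items())))
    return "\n".join(lines)
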