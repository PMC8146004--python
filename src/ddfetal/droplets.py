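"""Per-droplet two-channel amplitude tables (one ddPCR well)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DropletTable"]

#: canonical amplitude column names (channel 1 = FAM, channel 2 = HEX)
CH1_COL = "ch1_amplitude"
CH2_COL = "ch2_amplitude"


@dataclass
class DropletTable:
    """Two-channel fluorescence amplitudes for every droplet of one well.

    Amplitudes are in arbitrary instrument fluorescence units; channel 1 is
    FAM (blue) and channel 2 is HEX/VIC (green).  Simulated wells may carry
    the latent truth alongside: per-droplet surviving molecule counts and
    the latent positive flags (which include false-positive droplets).
    """

    ch1_amplitude: np.ndarray
    ch2_amplitude: np.ndarray
    well_id: str = "well"
    ch1_molecules: np.ndarray | None = None
    ch2_molecules: np.ndarray | None = None
    ch1_latent_pos: np.ndarray | None = None
    ch2_latent_pos: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ch1_amplitude = np.asarray(self.ch1_amplitude, dtype=float)
        self.ch2_amplitude = np.asarray(self.ch2_amplitude, dtype=float)
        if self.ch1_amplitude.ndim != 1 or self.ch2_amplitude.ndim != 1:
            raise ValueError("amplitude arrays must be one-dimensional")
        if len(self.ch1_amplitude) != len(self.ch2_amplitude):
            raise ValueError(
                "channel amplitude arrays differ in length "
                f"({len(self.ch1_amplitude)} vs {len(self.ch2_amplitude)})"
            )
        if len(self.ch1_amplitude) == 0:
            raise ValueError(f"well {self.well_id!r}: droplet table is empty")
        for name, arr in ((CH1_COL, self.ch1_amplitude), (CH2_COL, self.ch2_amplitude)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"well {self.well_id!r}: non-finite values in {name}")
            if np.any(arr < 0):
                raise ValueError(f"well {self.well_id!r}: negative amplitude in {name}")
        for name in ("ch1_molecules", "ch2_molecules", "ch1_latent_pos", "ch2_latent_pos"):
            arr = getattr(self, name)
            if arr is not None and len(arr) != len(self.ch1_amplitude):
                raise ValueError(f"well {self.well_id!r}: {name} length mismatch")

    @property
    def n_droplets(self) -> int:
        return len(self.ch1_amplitude)

    def amplitudes(self, channel: str) -> np.ndarray:
        """Amplitude vector for ``"FAM"`` (ch1) or ``"HEX"`` (ch2)."""
        key = getattr(channel, "value", channel)
        if key == "FAM":
            return self.ch1_amplitude
        if key == "HEX":
            return self.ch2_amplitude
        raise KeyError(f"unknown channel {channel!r}")

    def to_frame(self, include_truth: bool = True) -> pd.DataFrame:
        """Export as a DataFrame in the amplitude CSV column layout."""
        data: dict[str, np.ndarray] = {
            CH1_COL: self.ch1_amplitude,
            CH2_COL: self.ch2_amplitude,
        }
        if include_truth:
            if self.ch1_molecules is not None:
                data["ch1_molecules"] = self.ch1_molecules
            if self.ch2_molecules is not None:
                data["ch2_molecules"] = self.ch2_molecules
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, well_id: str = "well") -> "DropletTable":
        kwargs = {}
        for col in ("ch1_molecules", "ch2_molecules"):
            if col in frame.columns:
                kwargs[col] = frame[col].to_numpy()
        return cls(
            ch1_amplitude=frame[CH1_COL].to_numpy(dtype=float),
            ch2_amplitude=frame[CH2_COL].to_numpy(dtype=float),
            well_id=well_id,
            **kwargs,
        )
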