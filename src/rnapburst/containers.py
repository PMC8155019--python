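"""Shared in-memory containers for trace, correlation and count data.

Traces are multi-channel transcription-site intensity time series, one
record per cell, all channels sharing one uniform time grid.  Intensities
are background-subtracted and in arbitrary units; optional centroid
positions are in nanometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

CHANNELS = ("ctd", "ser5ph", "mrna")

#: the six signal pairs used throughout: three autos then three crosses.
AUTO_PAIRS = (("ctd", "ctd"), ("ser5ph", "ser5ph"), ("mrna", "mrna"))
CROSS_PAIRS = (("ctd", "ser5ph"), ("ctd", "mrna"), ("ser5ph", "mrna"))
ALL_PAIRS = AUTO_PAIRS + CROSS_PAIRS


@dataclass
class CellTrace:
    """Intensity (and optional position) time series of one cell."""

    cell_id: str
    time: np.ndarray  # minutes, uniform
    intensities: dict[str, np.ndarray]  # channel -> (n_t,)
    positions: dict[str, np.ndarray] | None = None  # channel -> (n_t, 2) nm
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if self.time.size < 2:
            raise ValueError("a trace needs at least 2 time points")
        dt = np.diff(self.time)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("time grid must be uniform")
        n = self.time.size
        for ch, v in self.intensities.items():
            self.intensities[ch] = np.asarray(v, dtype=float)
            if self.intensities[ch].shape != (n,):
                raise ValueError(f"channel {ch!r} does not share the time grid")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


@dataclass
class TraceSet:
    """A collection of per-cell traces from one experiment/condition."""

    cells: list[CellTrace]
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.cells)

    def __iter__(self):
        return iter(self.cells)

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(self.cells[0].intensities)

    def channel_matrix(self, channel: str) -> np.ndarray:
        """Stack one channel over cells; requires equal trace lengths."""
        return np.vstack([c.intensities[channel] for c in self.cells])

    def to_frame(self) -> pd.DataFrame:
        """Long format: cell_id, time_min, channel, intensity, x_nm, y_nm."""
        rows = []
        for cell in self.cells:
            for ch, inten in cell.intensities.items():
                df = pd.DataFrame(
                    {
                        "cell_id": cell.cell_id,
                        "time_min": cell.time,
                        "channel": ch,
                        "intensity": inten,
                    }
                )
                if cell.positions is not None and ch in cell.positions:
                    df["x_nm"] = cell.positions[ch][:, 0]
                    df["y_nm"] = cell.positions[ch][:, 1]
                else:
                    df["x_nm"] = np.nan
                    df["y_nm"] = np.nan
                rows.append(df)
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, meta: dict | None = None) -> "TraceSet":
        cells = []
        for cell_id, g in frame.groupby("cell_id", sort=False):
            intensities: dict[str, np.ndarray] = {}
            positions: dict[str, np.ndarray] = {}
            time = None
            for ch, gc in g.groupby("channel", sort=False):
                gc = gc.sort_values("time_min")
                time = gc["time_min"].to_numpy()
                intensities[ch] = gc["intensity"].to_numpy()
                if gc["x_nm"].notna().any():
                    positions[ch] = gc[["x_nm", "y_nm"]].to_numpy()
            cells.append(
                CellTrace(
                    cell_id=str(cell_id),
                    time=time,
                    intensities=intensities,
                    positions=positions or None,
                )
            )
        return cls(cells=cells, meta=meta or {})


@dataclass
class CorrelationSet:
    """Replica-averaged normalized auto/cross-covariances with SEM.

    ``curves[(a, b)]`` holds the mean of G_ab(tau)/Gbar(0) over cells, where
    G_ab(tau) = <da(t) db(t+tau)> and Gbar(0) is the zero-lag covariance of
    that pair averaged over replicas (shot-noise corrected for autos).
    Auto pairs are tabulated on ``lags >= 0``; cross pairs on symmetric lags.
    """

    auto_lags: np.ndarray  # minutes, >= 0
    cross_lags: np.ndarray  # minutes, symmetric about 0
    curves: dict[tuple[str, str], np.ndarray]
    sem: dict[tuple[str, str], np.ndarray]
    gbar0: dict[tuple[str, str], float]
    shot_noise_var: dict[str, float]  # per channel, intensity units^2
    n_cells: int
    dt: float
    meta: dict = field(default_factory=dict)

    def lags_for(self, pair: tuple[str, str]) -> np.ndarray:
        return self.auto_lags if pair[0] == pair[1] else self.cross_lags

    def shot_noise_ratio(self, channel: str) -> float:
        """Shot-noise SD as a multiple of the (corrected) signal SD."""
        g0 = self.gbar0[(channel, channel)]
        return float(np.sqrt(self.shot_noise_var[channel] / g0))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pair, curve in self.curves.items():
            lags = self.lags_for(pair)
            rows.append(
                pd.DataFrame(
                    {
                        "channel_a": pair[0],
                        "channel_b": pair[1],
                        "lag_min": lags,
                        "g_norm": curve,
                        "sem": self.sem[pair],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


@dataclass
class MRNACountSample:
    """Per-transcription-site nascent mRNA counts in mature-mRNA units."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)

    @property
    def n(self) -> int:
        return self.counts.size

    @property
    def mean(self) -> float:
        return float(np.mean(self.counts))

    @property
    def sd(self) -> float:
        return float(np.std(self.counts, ddof=1))

    @property
    def var(self) -> float:
        return float(np.var(self.counts, ddof=1))

    @property
    def sem(self) -> float:
        return self.sd / np.sqrt(self.n)

    @property
    def var_sem(self) -> float:
        # Gaussian approximation for the SE of a sample variance.
        return self.var * np.sqrt(2.0 / (self.n - 1))

    @property
    def fano(self) -> float:
        return self.var / self.mean

    def summary(self) -> Mapping[str, float]:
        return {
            "n": self.n,
            "mean": self.mean,
            "sd": self.sd,
            "sem": self.sem,
            "var": self.var,
            "var_sem": self.var_sem,
            "fano": self.fano,
        }
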