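"""Interval extraction and logarithmically binned density estimation.

Bins follow a fixed logarithmic grid: edges at ``10**(j/M)`` ms for
``j = 0..4M``, i.e. four decades from 1 ms to 10^4 ms, with the j-th bin
width ``(1 - 10**(-1/M)) * 10**(j/M)`` ms. Event counts are normalized
by bin width and by the number of in-range intervals, so the densities
integrate to the in-range fraction. Intervals outside the grid are not
silently discarded: they are tallied in ``n_below`` / ``n_above``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .errors import DegenerateInputError, ValidationError
from .simulate import SpikeTrain

__all__ = [
    "ISISample",
    "LogBinnedHistogram",
    "CellTypeCall",
    "compute_isis",
    "log_binned_histogram",
    "split_halves",
    "classify_cell_type",
]

MS_PER_S = 1000.0
DECADES = 4  # grid always spans [1, 10**DECADES] ms


@dataclass(frozen=True)
class ISISample:
    """Inter-spike intervals in milliseconds, in recording order."""

    intervals_ms: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals_ms, dtype=float)
        object.__setattr__(self, "intervals_ms", iv)
        if iv.ndim != 1 or iv.size == 0:
            raise ValidationError("interval sample must be a nonempty 1-d array")
        if np.any(iv <= 0):
            raise ValidationError("all intervals must be positive")


@dataclass(frozen=True)
class LogBinnedHistogram:
    """Normalized interval density on the fixed logarithmic grid.

    ``counts`` may be floats when the histogram holds an exact tabulated
    density (see :meth:`from_density`) rather than event counts.
    """

    M: int
    edges_ms: np.ndarray
    counts: np.ndarray
    densities: np.ndarray  # per ms, normalized by in-range count
    n_below: int = 0
    n_above: int = 0
    source_id: str = ""

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges_ms, dtype=float)
        object.__setattr__(self, "edges_ms", edges)
        object.__setattr__(self, "counts", np.asarray(self.counts))
        object.__setattr__(self, "densities", np.asarray(self.densities, dtype=float))
        if edges.size != DECADES * self.M + 1:
            raise ValidationError("edge array does not match the bin grid")

    @property
    def n_bins(self) -> int:
        return DECADES * self.M

    @property
    def widths_ms(self) -> np.ndarray:
        return np.diff(self.edges_ms)

    @property
    def centers_ms(self) -> np.ndarray:
        """Geometric bin centers (the natural abscissa on a log grid)."""
        return np.sqrt(self.edges_ms[:-1] * self.edges_ms[1:])

    @property
    def n_in_range(self) -> float:
        return float(self.counts.sum())

    def to_tsv(self, path) -> None:
        header = (
            f"# isilaw log-binned histogram  M={self.M}  "
            f"n_below={self.n_below}  n_above={self.n_above}  "
            f"source_id={self.source_id}\n"
            "bin_left_ms\tbin_right_ms\tcount\tdensity\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            for lo, hi, c, d in zip(
                self.edges_ms[:-1], self.edges_ms[1:], self.counts, self.densities
            ):
                fh.write(f"{lo:.10g}\t{hi:.10g}\t{c:.10g}\t{d:.12g}\n")

    @classmethod
    def from_tsv(cls, path) -> "LogBinnedHistogram":
        meta = {"M": None, "n_below": 0, "n_above": 0, "source_id": ""}
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    for tok in line.lstrip("#").split():
                        if "=" in tok:
                            key, val = tok.split("=", 1)
                            if key in meta:
                                meta[key] = val
                    continue
                if line.startswith("bin_left_ms"):
                    continue
                rows.append([float(x) for x in line.split("\t")])
        if meta["M"] is None:
            raise ValidationError(f"{path}: missing M in histogram header")
        arr = np.asarray(rows)
        edges = np.concatenate([arr[:, 0], [arr[-1, 1]]])
        return cls(
            M=int(meta["M"]),
            edges_ms=edges,
            counts=arr[:, 2],
            densities=arr[:, 3],
            n_below=int(meta["n_below"]),
            n_above=int(meta["n_above"]),
            source_id=str(meta["source_id"]),
        )

    @classmethod
    def from_density(
        cls,
        pdf: Callable[[np.ndarray], np.ndarray],
        M: int = 20,
        n_effective: float = 1e12,
        source_id: str = "tabulated",
    ) -> "LogBinnedHistogram":
        """Tabulate an exact density at the bin centers (zero-noise
        histogram for self-consistency and oracle tests)."""
        edges = bin_edges(M)
        centers = np.sqrt(edges[:-1] * edges[1:])
        dens = np.asarray(pdf(centers), dtype=float)
        widths = np.diff(edges)
        counts = dens * widths * n_effective
        return cls(
            M=M,
            edges_ms=edges,
            counts=counts,
            densities=dens,
            source_id=source_id,
        )


def bin_edges(M: int) -> np.ndarray:
    """Edges ``10**(j/M)`` ms, j = 0..4M."""
    j = np.arange(DECADES * M + 1)
    return 10.0 ** (j / M)


def compute_isis(train: SpikeTrain, source_id: str = "") -> ISISample:
    """Successive spike-time differences, converted to milliseconds."""
    if train.n_spikes < 2:
        raise ValidationError("need at least 2 spikes to form an interval")
    iv = np.diff(train.times) * MS_PER_S
    return ISISample(intervals_ms=iv, source_id=source_id)


def log_binned_histogram(isis: ISISample, M: int = 20) -> LogBinnedHistogram:
    """Bin intervals on the logarithmic grid and normalize to a density."""
    if M < 2:
        raise ValidationError(f"M must be >= 2, got {M}")
    edges = bin_edges(M)
    iv = isis.intervals_ms
    counts, _ = np.histogram(iv, bins=edges)
    n_below = int(np.sum(iv < edges[0]))
    n_above = int(np.sum(iv >= edges[-1]))
    n_in = int(counts.sum())
    if n_in == 0:
        raise DegenerateInputError(
            f"all {iv.size} intervals fall outside [{edges[0]:g}, {edges[-1]:g}] ms"
        )
    densities = counts / (np.diff(edges) * n_in)
    return LogBinnedHistogram(
        M=M,
        edges_ms=edges,
        counts=counts,
        densities=densities,
        n_below=n_below,
        n_above=n_above,
        source_id=isis.source_id,
    )


def split_halves(train: SpikeTrain) -> tuple[SpikeTrain, SpikeTrain]:
    """Early and late halves with (nearly) the same number of spikes, for
    stationarity checks. Odd counts give the extra spike to the first half."""
    n = train.n_spikes
    if n < 4:
        raise ValidationError("need at least 4 spikes to split")
    cut = math.ceil(n / 2)
    first = SpikeTrain(times=train.times[:cut], metadata=dict(train.metadata))
    second = SpikeTrain(times=train.times[cut:], metadata=dict(train.metadata))
    return first, second


@dataclass(frozen=True)
class CellTypeCall:
    label: str  # "pyramidal" | "fast-spiking"
    mean_rate_hz: float
    spike_width_ms: float


def classify_cell_type(mean_rate_hz: float, spike_width_ms: float) -> CellTypeCall:
    """Putative cell type from mean rate and spike width.

    Pyramidal iff rate < 30 spikes/s (strict) and width > 0.2 ms (strict);
    otherwise fast-spiking. A missing width is refused, not defaulted.
    """
    if spike_width_ms is None:
        raise ValidationError("spike width required for cell-type classification")
    if not (mean_rate_hz > 0 and spike_width_ms > 0):
        raise ValidationError("rate and spike width must be positive")
    label = "pyramidal" if (mean_rate_hz < 30.0 and spike_width_ms > 0.2) else "fast-spiking"
    return CellTypeCall(label=label, mean_rate_hz=mean_rate_hz, spike_width_ms=spike_width_ms)
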