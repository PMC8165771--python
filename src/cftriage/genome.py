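"""Genome bin/segment grid used by the copy-number workflow.

Coverage is tabulated on a fixed grid of bins (0-based, half-open
coordinates), each assigned to exactly one segment. For real genomes the
segments would be chromosome arms; the default toy grid uses 20 autosomal
segments of 50 one-megabase bins each, enough structure for the z-score
statistic to behave like it does on a real bin grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cftriage.errors import ConfigurationError

BIN_COLUMNS = ["bin_id", "segment_id", "chrom", "start", "end", "gc"]


@dataclass(frozen=True)
class GenomeDef:
    """Ordered bin grid with segment assignment and GC content.

    Parameters
    ----------
    bins
        DataFrame with columns ``bin_id, segment_id, chrom, start, end, gc``;
        bins within a segment must be disjoint, sorted, half-open, and GC
        fractions must lie in [0, 1].
    """

    bins: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in BIN_COLUMNS if c not in self.bins.columns]
        if missing:
            raise ConfigurationError(f"GenomeDef bins missing columns: {missing}")
        b = self.bins
        if (b["start"] >= b["end"]).any():
            bad = b.loc[b["start"] >= b["end"], "bin_id"].iloc[0]
            raise ConfigurationError(f"bin {bad!r} has start >= end (0-based half-open expected)")
        if ((b["gc"] < 0) | (b["gc"] > 1)).any():
            raise ConfigurationError("gc fraction outside [0, 1]")
        for seg, grp in b.groupby("segment_id", sort=False):
            grp = grp.sort_index()
            if not grp["start"].is_monotonic_increasing:
                raise ConfigurationError(f"bins of segment {seg!r} are not sorted")
            if (grp["start"].to_numpy()[1:] < grp["end"].to_numpy()[:-1]).any():
                raise ConfigurationError(f"bins of segment {seg!r} overlap")

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def segment_ids(self) -> list:
        """Segment identifiers in grid order."""
        return list(dict.fromkeys(self.bins["segment_id"]))

    @property
    def n_segments(self) -> int:
        return len(self.segment_ids)

    @property
    def gc(self) -> np.ndarray:
        return self.bins["gc"].to_numpy(dtype=float)

    @property
    def bin_lengths(self) -> np.ndarray:
        return (self.bins["end"] - self.bins["start"]).to_numpy(dtype=float)

    def segment_index(self) -> np.ndarray:
        """Integer segment index per bin, following grid order."""
        order = {s: i for i, s in enumerate(self.segment_ids)}
        return self.bins["segment_id"].map(order).to_numpy(dtype=int)

    def segment_means(self, per_bin: np.ndarray) -> np.ndarray:
        """Mean of a per-bin vector within each segment (grid order)."""
        values = np.asarray(per_bin, dtype=float)
        if values.shape[-1] != self.n_bins:
            raise ConfigurationError(
                f"per-bin vector of length {values.shape[-1]} does not match {self.n_bins} bins"
            )
        idx = self.segment_index()
        sums = np.zeros(values.shape[:-1] + (self.n_segments,))
        for s in range(self.n_segments):
            sums[..., s] = values[..., idx == s].mean(axis=-1)
        return sums

    @classmethod
    def toy(cls, n_segments: int = 20, bins_per_segment: int = 50, bin_size: int = 1_000_000) -> "GenomeDef":
        """Deterministic toy autosome grid with smoothly varying GC.

        GC varies between roughly 0.28 and 0.52 through two superimposed
        sinusoids, mimicking the isochore-like structure that makes GC
        correction non-trivial.
        """
        n = n_segments * bins_per_segment
        i = np.arange(n)
        gc = 0.40 + 0.08 * np.sin(2 * np.pi * i / 137.0) + 0.04 * np.sin(2 * np.pi * i / 23.0)
        rows = {
            "bin_id": [f"bin{j:04d}" for j in i],
            "segment_id": [f"seg{j // bins_per_segment:02d}" for j in i],
            "chrom": [f"chr{1 + j // bins_per_segment}" for j in i],
            "start": (i % bins_per_segment) * bin_size,
            "end": (i % bins_per_segment + 1) * bin_size,
            "gc": gc,
        }
        return cls(pd.DataFrame(rows))

    def to_tsv(self, path) -> None:
        self.bins.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GenomeDef":
        return cls(pd.read_csv(path, sep="\t"))
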