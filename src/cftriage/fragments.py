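"""cfDNA fragment-length features.

Tumor-derived cfDNA fragments are on average shorter than fragments shed
by normal (mostly hematopoietic) cells, so the proportion of short
fragments carries tumor-fraction signal that is independent of the
tumor's copy-number state. The features computed here are the short/long
count ratio — short fragments are 1-150 bp, long fragments 151-500 bp,
closed bounds — and the fraction of fragments falling in configurable
length windows (the defaults 40-140, 163-169 and 210-330 bp bracket the
sub-nucleosomal, mono-nucleosomal-peak and di-nucleosomal regions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from cftriage.errors import ComputationError, ConfigurationError, DegenerateInputError

log = logging.getLogger(__name__)

MAX_LEN = 500
SHORT_RANGE = (1, 150)
LONG_RANGE = (151, 500)
DEFAULT_WINDOWS = ((40, 140), (163, 169), (210, 330))


@dataclass
class FragmentLengthHistogram:
    """Exact tabulation of fragment lengths on 1..500 bp.

    ``counts[L]`` holds the number of fragments of length ``L`` (index 0 is
    unused and always zero). Lengths outside [1, 500] are excluded at
    ingest and counted in ``n_excluded``.
    """

    sample_id: str
    counts: np.ndarray = field(repr=False)
    n_excluded: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (MAX_LEN + 1,):
            raise ConfigurationError(f"histogram must have {MAX_LEN + 1} slots (index = length)")
        if (self.counts < 0).any() or self.counts[0] != 0:
            raise ConfigurationError("histogram counts must be >= 0 with no length-0 fragments")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_lengths(cls, sample_id: str, lengths) -> "FragmentLengthHistogram":
        """Tabulate a multiset of integer lengths; out-of-range lengths are logged."""
        arr = np.asarray(list(lengths), dtype=np.int64)
        if arr.size == 0:
            raise DegenerateInputError("no fragment lengths supplied")
        if (arr <= 0).any():
            raise ConfigurationError("fragment lengths must be positive integers")
        keep = arr <= MAX_LEN
        excluded = int((~keep).sum())
        if excluded:
            log.info("%s: excluded %d fragments longer than %d bp", sample_id, excluded, MAX_LEN)
        counts = np.bincount(arr[keep], minlength=MAX_LEN + 1)[: MAX_LEN + 1]
        return cls(sample_id=sample_id, counts=counts, n_excluded=excluded)

    @classmethod
    def from_counts(cls, sample_id: str, length_counts: pd.DataFrame) -> "FragmentLengthHistogram":
        """Build from a (length, count) table, excluding out-of-range lengths."""
        counts = np.zeros(MAX_LEN + 1, dtype=np.int64)
        lengths = length_counts["length"].to_numpy(np.int64)
        values = length_counts["count"].to_numpy(np.int64)
        keep = (lengths >= 1) & (lengths <= MAX_LEN)
        np.add.at(counts, lengths[keep], values[keep])
        return cls(sample_id=sample_id, counts=counts, n_excluded=int(values[~keep].sum()))

    def range_count(self, lo: int, hi: int) -> int:
        """Fragments with length in the closed interval [lo, hi]."""
        return int(self.counts[lo : hi + 1].sum())

    def to_frame(self) -> pd.DataFrame:
        nz = np.nonzero(self.counts)[0]
        return pd.DataFrame({"length": nz, "count": self.counts[nz]})


def short_long_ratio(h: FragmentLengthHistogram) -> float:
    """(count in 1-150 bp) / (count in 151-500 bp), closed bounds.

    A zero short count gives 0.0; a zero long count is an error (no
    pseudocount is applied — the denominator spans the mono-nucleosomal
    peak and is empty only for degenerate input).
    """
    short = h.range_count(*SHORT_RANGE)
    long_ = h.range_count(*LONG_RANGE)
    if long_ == 0:
        raise ComputationError(f"{h.sample_id}: no fragments in the long range {LONG_RANGE}")
    return short / long_


def window_fraction(h: FragmentLengthHistogram, windows=DEFAULT_WINDOWS) -> dict[tuple[int, int], float]:
    """Fraction of all in-range fragments within each closed window.

    Windows are evaluated independently and may overlap.
    """
    total = h.total
    if total == 0:
        raise DegenerateInputError(f"{h.sample_id}: empty histogram")
    out = {}
    for lo, hi in windows:
        if lo > hi or lo < 1 or hi > MAX_LEN:
            raise ConfigurationError(f"malformed window [{lo}, {hi}]")
        out[(lo, hi)] = h.range_count(lo, hi) / total
    return out


class FragmentSizeFeaturizer(BaseEstimator, TransformerMixin):
    """Stateless transformer mapping histograms to size-feature rows.

    ``transform`` accepts a list of :class:`FragmentLengthHistogram` and
    returns a DataFrame with ``ratio_short_long`` plus one
    ``frac_{lo}_{hi}`` column per window, indexed by sample id. Being
    stateless, ``fit`` only validates the window configuration, so the
    transformer composes with sklearn pipelines.
    """

    def __init__(self, windows=DEFAULT_WINDOWS):
        self.windows = windows

    def fit(self, X=None, y=None):
        for lo, hi in self.windows:
            if lo > hi or lo < 1 or hi > MAX_LEN:
                raise ConfigurationError(f"malformed window [{lo}, {hi}]")
        return self

    def transform(self, X) -> pd.DataFrame:
        self.fit()
        rows = {}
        for h in X:
            fracs = window_fraction(h, self.windows)
            row = {"ratio_short_long": short_long_ratio(h)}
            row.update({f"frac_{lo}_{hi}": v for (lo, hi), v in fracs.items()})
            rows[h.sample_id] = row
        out = pd.DataFrame.from_dict(rows, orient="index")
        out.index.name = "sample"
        return out


def parse_windows(text: str) -> tuple[tuple[int, int], ...]:
    """Parse a CLI window spec like ``"40-140,163-169,210-330"``."""
    windows = []
    for part in text.split(","):
        lo, _, hi = part.strip().partition("-")
        try:
            windows.append((int(lo), int(hi)))
        except ValueError as exc:
            raise ConfigurationError(f"bad window {part!r}") from exc
    return tuple(windows)
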