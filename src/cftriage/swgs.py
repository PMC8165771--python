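"""Genome-wide z-score tumor-fraction estimation from shallow WGS coverage.

The statistic compares the binned, GC-corrected coverage profile of a
plasma sample to a panel of healthy donors. Per segment, the mean
normalized bin ratio is standardized against the panel (z_i); the
instability score S = sum(z_i^2) aggregates deviations over the genome;
and S is itself standardized against the leave-one-out distribution of S
within the healthy panel, giving the genome-wide z-score Z. Z >= 5 labels
a sample high tumor fraction (empirically ~>=10% tumor DNA), Z in
[2.5, 5) corresponds to roughly 5-10%. Z may be negative for samples even
more panel-like than a typical panel member.

The construction is deterministic: GC correction divides each bin's count
rate by the median rate of its GC decile, and segmentation comes from the
fixed genome grid rather than data-driven changepoints, so identical
inputs give identical scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from cftriage.errors import (
    ComputationError,
    ConfigurationError,
    DegenerateInputError,
    DomainError,
)
from cftriage.genome import GenomeDef

Z_HIGH_CUT = 5.0
Z_MID_CUT = 2.5
MIN_PANEL = 4
MIN_BINS_PER_DECILE = 5


@dataclass
class GenomeWideZ:
    """Per-sample copy-number-instability result."""

    sample_id: str
    z_segments: np.ndarray = field(repr=False)
    s: float = 0.0
    z: float = 0.0
    tf_class: str = "low"
    tf_band: str = ""


def classify_tf(z: float, threshold: float = Z_HIGH_CUT) -> tuple[str, str]:
    """High/low tumor-fraction class plus the approximate TF band annotation.

    Z >= 5 -> high (~>=10% tumor fraction); 2.5 <= Z < 5 -> low but ~5-10%;
    Z < 2.5 -> low, below ~5%.
    """
    if not np.isfinite(z):
        raise DomainError(f"non-finite genome-wide z-score: {z}")
    cls = "high" if z >= threshold else "low"
    if z >= Z_HIGH_CUT:
        band = "~>=10% tumor fraction"
    elif z >= Z_MID_CUT:
        band = "~5-10% tumor fraction"
    else:
        band = "~<5% tumor fraction"
    return cls, band


def gc_correct(
    counts: np.ndarray,
    genome: GenomeDef,
    n_deciles: int = 10,
    min_bins: int = MIN_BINS_PER_DECILE,
) -> np.ndarray:
    """Normalize bin counts to GC-corrected coverage ratios.

    Each bin's count rate (count / total) is divided by the median rate of
    the bins in the same GC decile, removing smooth multiplicative GC bias
    while leaving copy-number signal intact (the genome-wide median of the
    corrected ratios is 1 by construction). Deciles are quantile bins of
    the genome's GC values, so the grouping is a property of the genome,
    not of the sample. A decile with fewer than ``min_bins`` bins falls
    back to the global median, with a warning.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (genome.n_bins,):
        raise ConfigurationError(
            f"count vector of length {counts.shape} does not match {genome.n_bins} bins"
        )
    if (counts < 0).any():
        raise DomainError("negative bin counts")
    total = counts.sum()
    if total <= 0:
        raise DegenerateInputError("all-zero coverage")
    rate = counts / total
    gc = genome.gc
    edges = np.quantile(gc, np.linspace(0, 1, n_deciles + 1))
    # interior edges only; right-closed so every gc value lands in a decile
    decile = np.searchsorted(edges[1:-1], gc, side="left")
    global_median = np.median(rate)
    if global_median <= 0:
        raise DegenerateInputError("median bin rate is zero")
    ratios = np.empty_like(rate)
    for d in np.unique(decile):
        mask = decile == d
        if mask.sum() < min_bins:
            warnings.warn(
                f"GC decile {d} has only {int(mask.sum())} bins; using global median",
                stacklevel=2,
            )
            med = global_median
        else:
            med = np.median(rate[mask])
            if med <= 0:
                med = global_median
        ratios[mask] = rate[mask] / med
    return ratios


class GenomeWideZScorer(BaseEstimator):
    """Healthy-panel-calibrated genome-wide z-score estimator.

    Fit on a (n_controls, n_bins) matrix of healthy-donor bin counts;
    transform plasma samples into genome-wide z-scores.

    Fitted attributes
    -----------------
    segment_mean_, segment_sd_ : per-segment mean/SD of panel segment ratios
    loo_s_ : leave-one-out instability scores S of the panel members
    s_mean_, s_sd_ : mean and SD of ``loo_s_`` used to standardize S into Z
    """

    def __init__(self, genome: GenomeDef, z_threshold: float = Z_HIGH_CUT, n_gc_deciles: int = 10):
        self.genome = genome
        self.z_threshold = z_threshold
        self.n_gc_deciles = n_gc_deciles

    # -- internals -----------------------------------------------------
    def _segment_ratios(self, counts: np.ndarray) -> np.ndarray:
        ratios = gc_correct(counts, self.genome, self.n_gc_deciles)
        return self.genome.segment_means(ratios)

    @staticmethod
    def _zvec(seg_ratios: np.ndarray, mean: np.ndarray, sd: np.ndarray, segment_ids) -> np.ndarray:
        zero = sd <= 0
        if zero.any():
            seg = segment_ids[int(np.argmax(zero))]
            raise ComputationError(f"panel SD is zero for segment {seg!r}")
        return (seg_ratios - mean) / sd

    # -- sklearn API ---------------------------------------------------
    def fit(self, X, y=None):
        """Build panel statistics from healthy-control bin counts (rows)."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.genome.n_bins:
            raise ConfigurationError("X must be (n_controls, n_bins) on the scorer's genome")
        n = X.shape[0]
        if n < MIN_PANEL:
            raise ConfigurationError(f"panel needs >= {MIN_PANEL} controls, got {n}")
        seg = np.stack([self._segment_ratios(X[i]) for i in range(n)])
        self.panel_segment_ratios_ = seg
        self.segment_mean_ = seg.mean(axis=0)
        self.segment_sd_ = seg.std(axis=0, ddof=1)
        ids = np.asarray(self.genome.segment_ids)
        if (self.segment_sd_ <= 0).any():
            bad = ids[int(np.argmax(self.segment_sd_ <= 0))]
            raise ComputationError(f"panel SD is zero for segment {bad!r}")
        loo_s = np.empty(n)
        for j in range(n):
            rest = np.delete(seg, j, axis=0)
            z = self._zvec(seg[j], rest.mean(axis=0), rest.std(axis=0, ddof=1), ids)
            loo_s[j] = float((z**2).sum())
        self.loo_s_ = loo_s
        self.s_mean_ = float(loo_s.mean())
        self.s_sd_ = float(loo_s.std(ddof=1))
        if self.s_sd_ <= 0:
            raise ComputationError("leave-one-out S has zero variance across the panel")
        self.n_controls_ = n
        return self

    def score_sample(self, counts: np.ndarray, sample_id: str = "sample") -> GenomeWideZ:
        """Full per-sample result: z vector, S, Z and the class label."""
        self._check_fitted()
        seg_ratios = self._segment_ratios(np.asarray(counts, dtype=float))
        zvec = self._zvec(
            seg_ratios, self.segment_mean_, self.segment_sd_, np.asarray(self.genome.segment_ids)
        )
        s = float((zvec**2).sum())
        z = (s - self.s_mean_) / self.s_sd_
        cls, band = classify_tf(z, self.z_threshold)
        return GenomeWideZ(sample_id=sample_id, z_segments=zvec, s=s, z=z, tf_class=cls, tf_band=band)

    def transform(self, X) -> np.ndarray:
        """Genome-wide z-scores, one per row of bin counts."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        return np.array([self.score_sample(row).z for row in X])

    def fit_transform(self, X, y=None):  # leave-one-out is NOT applied here
        return self.fit(X).transform(X)

    def score_table(self, X, sample_ids=None) -> pd.DataFrame:
        """Per-sample TSV-ready table (sample, S, Z, tf_class, tf_band)."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if sample_ids is None:
            sample_ids = [f"sample{i}" for i in range(X.shape[0])]
        rows = []
        for sid, row in zip(sample_ids, X):
            gz = self.score_sample(row, sid)
            rows.append(
                {"sample": sid, "S": gz.s, "Z": gz.z, "tf_class": gz.tf_class, "tf_band": gz.tf_band}
            )
        return pd.DataFrame(rows)

    def segment_z_table(self, X, sample_ids=None) -> pd.DataFrame:
        """Long-format per-segment z values for each sample."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if sample_ids is None:
            sample_ids = [f"sample{i}" for i in range(X.shape[0])]
        rows = []
        for sid, row in zip(sample_ids, X):
            gz = self.score_sample(row, sid)
            for seg, zi in zip(self.genome.segment_ids, gz.z_segments):
                rows.append({"sample": sid, "segment_id": seg, "z": zi})
        return pd.DataFrame(rows)

    def _check_fitted(self) -> None:
        if not hasattr(self, "s_sd_"):
            raise ComputationError("scorer is not fitted; call fit(panel_counts) first")
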