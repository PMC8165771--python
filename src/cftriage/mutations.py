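"""Assay detection limits, per-sample mutation profiles, mVAF and TMB.

Detection is threshold-based on allele counts rather than statistical
calling: a variant is reported when its VAF clears the limit of the assay
mode in play and it has minimal read support. The limits mirror clinical
cfDNA panel behavior: 1% VAF when genotyping loci already known from tumor
sequencing, 2% for de novo hotspot calls, 5% for de novo non-hotspot
calls, and 0.1% for the UMI-error-corrected ultra-deep assay.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cftriage.errors import ConfigurationError, DomainError

log = logging.getLogger(__name__)

TMB_PANEL_BP = 1_016_478  # territory over which mutations/Mb is computed
TMB_HIGH_CUT = 10.0
MVAF_HIGH_CUT = 0.10
CCF_CLONAL_CUT = 0.75

MODES = ("genotyping", "de_novo", "ultradeep")


@dataclass(frozen=True)
class AssayLimits:
    """VAF detection limits and read-support floor for one assay mode.

    ``min_alt_reads`` is a support floor on the variant-allele read count:
    the published limits are pure VAF thresholds, but a handful of reads is
    required in practice to exclude single-read artifacts, so the default
    is 3 for the targeted modes and 2 for the ultra-deep mode (where a
    0.1% VAF at >12,000x still implies ~12 consensus reads).
    """

    mode: str = "de_novo"
    vaf_genotyping: float = 0.01
    vaf_hotspot: float = 0.02
    vaf_nonhotspot: float = 0.05
    vaf_ultradeep: float = 0.001
    min_alt_reads: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigurationError(f"unknown assay mode {self.mode!r}; expected one of {MODES}")
        if not (0 < self.vaf_ultradeep < self.vaf_genotyping < self.vaf_hotspot < self.vaf_nonhotspot):
            raise ConfigurationError(
                "detection limits must satisfy 0 < ultradeep < genotyping < hotspot < non-hotspot"
            )
        if self.min_alt_reads is None:
            object.__setattr__(self, "min_alt_reads", 2 if self.mode == "ultradeep" else 3)
        if self.min_alt_reads < 1:
            raise ConfigurationError("min_alt_reads must be >= 1")

    def threshold(self, known: bool, hotspot: bool) -> float:
        """Applicable VAF limit for one locus under this mode."""
        if self.mode == "ultradeep":
            return self.vaf_ultradeep
        if self.mode == "genotyping" and known:
            return self.vaf_genotyping
        return self.vaf_hotspot if hotspot else self.vaf_nonhotspot


def call_mutations(
    calls: pd.DataFrame,
    limits: AssayLimits,
    known: set | None = None,
    hotspots: set | None = None,
) -> pd.DataFrame:
    """Apply detection limits to per-locus allele counts.

    Parameters
    ----------
    calls
        Table with ``locus, alt_count, depth`` and optionally boolean
        ``hotspot`` / ``known_in_tumor`` / panel-membership columns
        (``in_panel`` for the ultra-deep panel, ``in_targeted`` for the
        targeted panel). Loci outside the mode's panel are dropped with a
        log message, mirroring how a capture assay simply does not see them.
    known, hotspots
        Optional sets of locus ids overriding/augmenting the flag columns.

    Returns a copy with ``vaf``, ``applied_threshold`` and boolean
    ``detected`` columns for the loci visible to the assay.
    """
    if (calls["depth"] <= 0).any():
        bad = calls.loc[calls["depth"] <= 0].index[0]
        raise DomainError(f"non-positive depth at row {bad}")
    df = calls.copy()
    panel_col = "in_panel" if limits.mode == "ultradeep" else "in_targeted"
    if panel_col in df.columns:
        outside = ~df[panel_col].astype(bool)
        if outside.any():
            log.info("%s mode: skipping %d loci outside panel", limits.mode, int(outside.sum()))
            df = df.loc[~outside].copy()
    is_known = df.get("known_in_tumor", pd.Series(False, index=df.index)).astype(bool)
    is_hot = df.get("hotspot", pd.Series(False, index=df.index)).astype(bool)
    if known is not None:
        is_known = is_known | df["locus"].isin(known)
    if hotspots is not None:
        is_hot = is_hot | df["locus"].isin(hotspots)
    df["vaf"] = df["alt_count"] / df["depth"]
    df["applied_threshold"] = [
        limits.threshold(k, h) for k, h in zip(is_known.to_numpy(), is_hot.to_numpy())
    ]
    df["detected"] = (df["alt_count"] >= limits.min_alt_reads) & (df["vaf"] >= df["applied_threshold"])
    return df


def mvaf(vafs, use_mean: bool = False) -> float | None:
    """Median (default) or mean VAF of the detected mutations.

    Returns ``None`` when no mutation was detected — an absent mVAF is
    not the same as an mVAF of zero.
    """
    arr = np.asarray(list(vafs), dtype=float)
    if arr.size == 0:
        return None
    return float(arr.mean() if use_mean else np.median(arr))


def is_high_tf(mvaf_value: float | None, cut: float = MVAF_HIGH_CUT) -> bool | None:
    """High-tumor-fraction label from mVAF (>= 10%); None when mVAF absent."""
    if mvaf_value is None:
        return None
    return bool(mvaf_value >= cut)


def tmb(nonsynonymous_count: int, panel_bp: int = TMB_PANEL_BP) -> tuple[float, bool]:
    """Mutations per megabase over the panel territory, and the >=10/Mb flag."""
    if panel_bp <= 0:
        raise ConfigurationError("panel_bp must be positive")
    if nonsynonymous_count < 0:
        raise DomainError("mutation count must be >= 0")
    value = nonsynonymous_count / (panel_bp / 1e6)
    return value, value >= TMB_HIGH_CUT


def classify_clonality(ccf: float | None, cut: float = CCF_CLONAL_CUT) -> str:
    """clonal (CCF >= 0.75), subclonal (< 0.75) or unknown (CCF absent)."""
    if ccf is None or (isinstance(ccf, float) and np.isnan(ccf)):
        return "unknown"
    if not (0 < ccf <= 1):
        raise DomainError(f"CCF {ccf} outside (0, 1]")
    return "clonal" if ccf >= cut else "subclonal"


@dataclass
class SampleMutationProfile:
    """Detection summary of one plasma (or tumor) sample under one assay."""

    sample_id: str
    assay: str
    calls: pd.DataFrame = field(repr=False)
    mvaf: float | None = None
    high_tf: bool | None = None
    tmb: float = 0.0
    tmb_high: bool = False
    n_detected: int = 0

    @classmethod
    def from_calls(
        cls,
        sample_id: str,
        calls: pd.DataFrame,
        limits: AssayLimits,
        panel_bp: int = TMB_PANEL_BP,
        use_mean: bool = False,
    ) -> "SampleMutationProfile":
        called = call_mutations(calls, limits)
        detected = called.loc[called["detected"]]
        m = mvaf(detected["vaf"], use_mean=use_mean)
        if "synonymous" in detected.columns:
            nonsyn = int((~detected["synonymous"].astype(bool)).sum())
        else:
            nonsyn = len(detected)
        tmb_value, tmb_flag = tmb(nonsyn, panel_bp)
        return cls(
            sample_id=sample_id,
            assay=limits.mode,
            calls=called,
            mvaf=m,
            high_tf=is_high_tf(m),
            tmb=tmb_value,
            tmb_high=tmb_flag,
            n_detected=int(detected.shape[0]),
        )

    def as_row(self) -> dict:
        return {
            "sample": self.sample_id,
            "assay": self.assay,
            "n_detected": self.n_detected,
            "mvaf": np.nan if self.mvaf is None else self.mvaf,
            "tmb": self.tmb,
            "tmb_high": self.tmb_high,
        }
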