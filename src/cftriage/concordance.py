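"""Tumor-plasma mutational concordance and the study's statistical tests.

The accounting partitions each patient's mutations into shared,
tumor-only and plasma-only sets keyed by ``chrom:pos:ref:alt``. The
association tests operate on 2x2 contingency tables (Fisher's exact test
with the two-sided minimum-likelihood rule, Pearson's chi-squared with
Yates continuity correction) or on two score distributions (Mann-Whitney
U). They are implemented here in full — log-space hypergeometric
enumeration for Fisher, exact rank-configuration enumeration for small
Mann-Whitney samples — because the detection-limit structure of the
workflow makes the tail conventions load-bearing: the minimum-likelihood
two-sided rule reproduces the published p-values, the doubling rule does
not always.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln

from cftriage.errors import DomainError, InputError

MATCH_KEY = ["chrom", "pos", "ref", "alt"]

#: relative slack when deciding whether another table is "as extreme":
#: wide enough to absorb float error in log-space pmfs, narrow enough
#: never to swallow a genuinely distinct hypergeometric probability.
_TIE_EPS = 2e-12


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]], all non-negative, N > 0."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in cells):
            raise DomainError(f"negative cell in 2x2 table: {cells}")
        if sum(cells) == 0:
            raise DomainError("empty 2x2 table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def _as_table(table) -> ContingencyTable2x2:
    if isinstance(table, ContingencyTable2x2):
        return table
    (a, b), (c, d) = table
    return ContingencyTable2x2(int(a), int(b), int(c), int(d))


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 table.

    Conditions on both margins (central hypergeometric) and applies the
    minimum-likelihood rule: the p-value sums the probabilities of every
    table with the same margins whose probability does not exceed that of
    the observed table. Probabilities are evaluated in log space so tables
    with N in the hundreds remain exact to double precision.

    Returns
    -------
    (odds_ratio, p_value)
        ``odds_ratio`` is the sample odds ratio a*d/(b*c), ``inf`` when
        b*c == 0 and a*d > 0, ``nan`` when both products vanish.
    """
    t = _as_table(table)
    r1, r2 = t.a + t.b, t.c + t.d
    c1 = t.a + t.c
    n = t.n
    # support of the (1,1) cell given fixed margins
    k_lo = max(0, c1 - r2)
    k_hi = min(c1, r1)
    k = np.arange(k_lo, k_hi + 1)
    logpmf = (
        gammaln(r1 + 1)
        - gammaln(k + 1)
        - gammaln(r1 - k + 1)
        + gammaln(r2 + 1)
        - gammaln(c1 - k + 1)
        - gammaln(r2 - c1 + k + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )
    log_obs = logpmf[t.a - k_lo]
    include = logpmf <= log_obs + _TIE_EPS
    p = float(np.exp(logpmf[include]).sum())
    p = min(1.0, p)
    ad, bc = t.a * t.d, t.b * t.c
    if bc == 0:
        odds = math.nan if ad == 0 else math.inf
    else:
        odds = ad / bc
    return odds, p


def chi2_yates(table) -> tuple[float, float]:
    """Pearson chi-squared test with Yates continuity correction (1 df).

    chi2 = N * (max(0, |ad - bc| - N/2))^2 / ((a+b)(c+d)(a+c)(b+d)).
    """
    t = _as_table(table)
    margins = [(t.a + t.b), (t.c + t.d), (t.a + t.c), (t.b + t.d)]
    if any(m == 0 for m in margins):
        raise DomainError("chi-squared with a zero margin is undefined")
    num = max(0.0, abs(t.a * t.d - t.b * t.c) - t.n / 2.0)
    chi2 = t.n * num * num / math.prod(margins)
    p = float(sps.chi2.sf(chi2, df=1))
    return chi2, p


def _mwu_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U statistic for x versus y; ties count one half."""
    diff = x[:, None] - y[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Uses exact enumeration over all rank configurations when
    ``min(n_x, n_y) <= 8`` and the pooled sample has no ties, otherwise the
    normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DomainError("Mann-Whitney requires two non-empty groups")
    nx, ny = x.size, y.size
    u = _mwu_statistic(x, y)

    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if min(nx, ny) <= 8 and not has_ties:
        # exact: without ties U depends only on which pooled ranks belong to x
        total = 0
        at_most = 0
        at_least = 0
        n = nx + ny
        for combo in itertools.combinations(range(n), nx):
            # U for this assignment = sum of x ranks - nx(nx-1)/2 (0-based)
            u_k = sum(combo) - nx * (nx - 1) // 2
            total += 1
            if u_k <= u + 1e-9:
                at_most += 1
            if u_k >= u - 1e-9:
                at_least += 1
        p = min(1.0, 2.0 * min(at_most, at_least) / total)
        return u, p

    mu = nx * ny / 2.0
    n = nx + ny
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1))
    sigma2 = nx * ny / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return u, 1.0
    z = (abs(u - mu) - 0.5) / math.sqrt(sigma2)
    z = max(z, 0.0)
    p = 2.0 * float(sps.norm.sf(z))
    return u, min(1.0, p)


def partition_mutations(
    tumor: pd.DataFrame,
    plasma: pd.DataFrame,
    sample_col: str = "sample",
    key_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Partition per-sample mutation sets into shared / tumor-only / plasma-only.

    Both inputs are MAF-like tables carrying ``sample_col`` and the matching
    key columns (default ``chrom, pos, ref, alt``). Returns one row per
    sample plus a pooled ``__all__`` row; shared + tumor_only equals the
    tumor total and shared + plasma_only equals the plasma total by
    construction.
    """
    key_cols = key_cols or MATCH_KEY
    for name, df in (("tumor", tumor), ("plasma", plasma)):
        missing = [c for c in [sample_col] + key_cols if c not in df.columns]
        if missing:
            raise InputError(f"{name} calls missing columns {missing}")
        keys = df[sample_col].astype(str) + "|" + df[key_cols].astype(str).agg(":".join, axis=1)
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0]
            raise InputError(f"duplicate mutation key within one {name} sample: {dup}")

    def _sets(df):
        out = {}
        for s, grp in df.groupby(sample_col):
            out[s] = set(grp[key_cols].astype(str).agg(":".join, axis=1))
        return out

    tsets, psets = _sets(tumor), _sets(plasma)
    rows = []
    pooled = {"shared": 0, "tumor_only": 0, "plasma_only": 0}
    for s in sorted(set(tsets) | set(psets), key=str):
        tk = tsets.get(s, set())
        pk = psets.get(s, set())
        row = {
            sample_col: s,
            "shared": len(tk & pk),
            "tumor_only": len(tk - pk),
            "plasma_only": len(pk - tk),
        }
        row["tumor_total"] = row["shared"] + row["tumor_only"]
        row["plasma_total"] = row["shared"] + row["plasma_only"]
        for k in pooled:
            pooled[k] += row[k]
        rows.append(row)
    pooled_row = {
        sample_col: "__all__",
        **pooled,
        "tumor_total": pooled["shared"] + pooled["tumor_only"],
        "plasma_total": pooled["shared"] + pooled["plasma_only"],
    }
    return pd.DataFrame(rows + [pooled_row])


def tmb_concordance(df: pd.DataFrame, stratify: str = "tf_class") -> pd.DataFrame:
    """Tumor-vs-plasma TMB agreement per tumor-fraction stratum.

    Expects columns ``tumor_tmb``, ``plasma_tmb`` and a stratification
    column. For each stratum with at least 3 samples and non-degenerate
    variance, reports the Pearson correlation, the least-squares slope of
    plasma on tumor, and the correlation t-test p-value; strata where the
    statistic is undefined are reported with NaN.
    """
    rows = []
    groups = [("overall", df)] + [(str(k), g) for k, g in df.groupby(stratify)]
    for name, g in groups:
        row = {"stratum": name, "n": len(g), "r": np.nan, "slope": np.nan, "p": np.nan}
        if len(g) >= 3:
            t = g["tumor_tmb"].to_numpy(float)
            p = g["plasma_tmb"].to_numpy(float)
            if np.std(t) > 0 and np.std(p) > 0:
                res = sps.linregress(t, p)
                row.update(r=float(res.rvalue), slope=float(res.slope), p=float(res.pvalue))
        rows.append(row)
    return pd.DataFrame(rows)
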