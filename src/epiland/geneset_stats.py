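"""Sign tests, two-gene-set comparisons, and fold-change correlation.

Small exact statistics used throughout the landscape analysis: the
binomial sign test on fold-change direction (e.g. 14 of 15 mitochondrial
genes higher in SH, or 9 of 9 activity-regulated genes higher in GH),
two-sample comparisons of a signal between two gene sets (e.g. genes
repressed vs activated by the TF Cabut), and the Pearson correlation of
fold changes against an external dataset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .signal_io import DeltaMatrix


@dataclass
class SignTestResult:
    successes: int
    trials: int
    sidedness: str
    p: float

    def __post_init__(self) -> None:
        if not 0 < self.p <= 1:
            raise ValueError("p must lie in (0, 1]")


def sign_test(successes: int, trials: int, sidedness: str = "two") -> SignTestResult:
    """Exact binomial sign test at p = 0.5.

    One-sided: upper tail P(X >= successes). Two-sided: min(1, 2 * the
    smaller tail). Sidedness is an explicit argument because published
    sign tests mix conventions; 14/15 one-sided gives 0.000488 (printed
    as 0.0005) and 9/9 two-sided gives 0.00391 (printed as 0.004).
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not 0 <= successes <= trials:
        raise ValueError(f"successes must be in [0, trials], got {successes}/{trials}")
    if sidedness not in ("one", "two"):
        raise ValueError("sidedness must be 'one' or 'two'")
    upper = float(stats.binom.sf(successes - 1, trials, 0.5))
    lower = float(stats.binom.cdf(successes, trials, 0.5))
    p = upper if sidedness == "one" else min(1.0, 2.0 * min(upper, lower))
    return SignTestResult(successes=successes, trials=trials, sidedness=sidedness, p=p)


@dataclass
class SetComparison:
    """Two-sample comparison of one signal between disjoint gene sets."""

    signal: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    statistic: float
    p: float
    test: str

    @property
    def direction(self) -> int:
        """Sign of mean(A) - mean(B); matches the statistic's sign."""
        return int(np.sign(self.mean_a - self.mean_b))


def compare_sets(
    values: pd.Series,
    set_a: Sequence[str],
    set_b: Sequence[str],
    test: str = "welch_t",
    signal: str = "",
) -> SetComparison:
    """Compare a per-gene value vector between two disjoint gene sets.

    ``welch_t`` (unequal-variance t, the default) or ``wilcoxon``
    (Mann-Whitney rank-sum). Identical constant vectors return statistic
    0 with p = 1 rather than an undefined ratio.
    """
    a_genes, b_genes = list(set_a), list(set_b)
    if set(a_genes) & set(b_genes):
        raise ValueError("gene sets must be disjoint")
    if not a_genes or not b_genes:
        raise ValueError("both gene sets must be non-empty")
    if test not in ("welch_t", "wilcoxon"):
        raise ValueError("test must be 'welch_t' or 'wilcoxon'")
    a = values.loc[a_genes].to_numpy(dtype=float)
    b = values.loc[b_genes].to_numpy(dtype=float)
    if test == "welch_t" and (len(a) < 2 or len(b) < 2):
        raise ValueError("welch_t needs >= 2 genes per set; try test='wilcoxon'")
    if np.ptp(np.concatenate([a, b])) == 0.0:
        return SetComparison(signal=signal, n_a=len(a), n_b=len(b),
                             mean_a=float(a.mean()), mean_b=float(b.mean()),
                             statistic=0.0, p=1.0, test=test)
    if test == "welch_t":
        res = stats.ttest_ind(a, b, equal_var=False)
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        # center the U statistic so its sign tracks the direction
        stat = float(res.statistic - len(a) * len(b) / 2.0)
        p = float(res.pvalue)
    return SetComparison(signal=signal, n_a=len(a), n_b=len(b),
                         mean_a=float(a.mean()), mean_b=float(b.mean()),
                         statistic=stat, p=p, test=test)


def compare_sets_by_signal(
    delta: DeltaMatrix,
    set_a: Sequence[str],
    set_b: Sequence[str],
    test: str = "welch_t",
) -> pd.DataFrame:
    """Per-signal rows of `compare_sets` (no cross-signal adjustment)."""
    rows = []
    for signal in delta.signals:
        c = compare_sets(delta.z[signal], set_a, set_b, test=test, signal=signal)
        rows.append(
            {
                "signal": signal, "n_a": c.n_a, "n_b": c.n_b,
                "mean_a": c.mean_a, "mean_b": c.mean_b,
                "statistic": c.statistic, "p": c.p, "direction": c.direction,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int


def correlate_fc(fc_self: pd.Series, fc_external: pd.Series) -> CorrelationResult:
    """Pearson correlation of two fold-change vectors joined on gene id."""
    a, b = fc_self.align(fc_external, join="inner")
    if len(a) < 3:
        raise ValueError(f"need >= 3 shared genes, got {len(a)}")
    r, p = stats.pearsonr(a.to_numpy(dtype=float), b.to_numpy(dtype=float))
    return CorrelationResult(r=float(r), p=float(p), n=len(a))
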