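"""Gene-level signal tables and the GH-SH delta matrix.

The pipeline consumes per-gene quantifications of six histone marks
(H3K4me3, H3K27ac, H3K9/K14ac, H3K36me3, H3K9me3, H3K27me3) and mRNA
expression, each measured in two housing conditions: group-housed (GH,
social enrichment) and single-housed (SH, social isolation) male flies.
This module reads and writes those tables, restricts the analysis to
expressed genes (top fraction by mRNA expression), and builds the
z-score-normalized GH-SH difference matrix ("delta matrix") that the
clustering stage operates on.

Coordinates are 0-based half-open everywhere internally; tables are
tab-delimited text with a header row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CONDITIONS = ("GH", "SH")

#: The seven signals clustered together, mRNA first by convention.
SIGNALS = (
    "mRNA",
    "H3K4me3",
    "H3K27ac",
    "H3K9K14ac",
    "H3K36me3",
    "H3K9me3",
    "H3K27me3",
)


class SignalTableError(ValueError):
    """Raised for malformed signal tables (duplicates, non-numeric cells...)."""


@dataclass
class SignalMatrix:
    """One signal (a histone mark or mRNA) in one condition.

    Parameters
    ----------
    signal_name:
        Mark name or ``"mRNA"``.
    condition:
        ``"GH"`` or ``"SH"``.
    data:
        genes x replicates DataFrame of non-negative, finite values on a
        normalized coverage / TPM scale. The index is the gene id.
    """

    signal_name: str
    condition: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise SignalTableError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        if self.data.shape[1] < 1:
            raise SignalTableError(
                f"{self.signal_name}/{self.condition}: need at least 1 replicate column"
            )
        dup = self.data.index[self.data.index.duplicated()]
        if len(dup):
            raise SignalTableError(
                f"{self.signal_name}/{self.condition}: duplicate gene id {dup[0]!r}"
            )
        values = self.data.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            g, r = np.argwhere(~np.isfinite(values))[0]
            raise SignalTableError(
                f"{self.signal_name}/{self.condition}: non-finite value at gene "
                f"{self.data.index[g]!r}, column {self.data.columns[r]!r}"
            )
        if (values < 0).any():
            g, r = np.argwhere(values < 0)[0]
            raise SignalTableError(
                f"{self.signal_name}/{self.condition}: negative value at gene "
                f"{self.data.index[g]!r}, column {self.data.columns[r]!r}"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_replicates(self) -> int:
        return self.data.shape[1]

    def replicate_means(self) -> pd.Series:
        return self.data.mean(axis=1)


def read_signal_table(path: str | Path, signal_name: str, condition: str) -> SignalMatrix:
    """Read a TSV with a header row, gene ids in the first column.

    Rejects duplicated gene ids (naming the offender) and non-numeric
    cells (naming row and column).
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if raw.shape[1] < 2:
        raise SignalTableError(f"{path}: expected gene-id column plus >=1 replicate")
    gene_col = raw.columns[0]
    genes = raw[gene_col]
    dup = genes[genes.duplicated()]
    if len(dup):
        raise SignalTableError(f"{path}: duplicate gene id {dup.iloc[0]!r}")
    cols = {}
    for col in raw.columns[1:]:
        try:
            # exact strtod parsing so write -> read is bit-identical
            cols[col] = np.asarray(raw[col].to_numpy(), dtype=float)
        except (TypeError, ValueError):
            for g, cell in zip(genes, raw[col]):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise SignalTableError(
                        f"{path}: non-numeric cell at gene {g!r}, column {col!r}"
                    ) from None
            raise
    numeric = pd.DataFrame(cols, index=pd.Index(genes, name=gene_col))
    return SignalMatrix(signal_name=signal_name, condition=condition, data=numeric)


def write_signal_table(matrix: SignalMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label=matrix.data.index.name or "gene")


def median_scale(matrix: SignalMatrix) -> SignalMatrix:
    """Per-column median scaling: an optional fallback normalizer.

    Replicate columns are rescaled so that each column's median matches
    the global median of column medians. Upstream pipelines normally
    deliver already-normalized signals (e.g. TMM-normalized coverage);
    this helper is only for inputs that skipped that step.
    """
    med = matrix.data.median(axis=0)
    target = float(np.median(med))
    if (med <= 0).any():
        raise SignalTableError(
            f"{matrix.signal_name}/{matrix.condition}: non-positive column median, "
            "cannot median-scale"
        )
    scaled = matrix.data * (target / med)
    return SignalMatrix(matrix.signal_name, matrix.condition, scaled)


@dataclass
class ExpressionTable:
    """Per-gene mRNA summary used for the expressed-gene filter.

    ``tpm_mean`` holds mean expression per condition (columns GH, SH);
    ``cv`` holds the within-treatment coefficient of variation (sd/mean),
    NaN where fewer than 2 replicates or zero mean.
    """

    tpm_mean: pd.DataFrame
    cv: pd.DataFrame

    def __post_init__(self) -> None:
        for c in CONDITIONS:
            if c not in self.tpm_mean.columns:
                raise SignalTableError(f"ExpressionTable missing condition column {c}")
        if (self.tpm_mean[list(CONDITIONS)].to_numpy() < 0).any():
            raise SignalTableError("ExpressionTable: negative mean expression")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.cv.to_numpy(dtype=float), initial=0.0) < 0:
                raise SignalTableError("ExpressionTable: negative CV")

    @property
    def genes(self) -> list[str]:
        return list(self.tpm_mean.index)

    @classmethod
    def from_signal_matrices(cls, gh: SignalMatrix, sh: SignalMatrix) -> "ExpressionTable":
        if set(gh.genes) != set(sh.genes):
            raise SignalTableError("GH and SH expression tables cover different genes")
        sh_data = sh.data.loc[gh.data.index]
        tpm = pd.DataFrame({"GH": gh.replicate_means(), "SH": sh_data.mean(axis=1)})
        cv = {}
        for cond, d in (("GH", gh.data), ("SH", sh_data)):
            if d.shape[1] >= 2:
                mean = d.mean(axis=1)
                sd = d.std(axis=1, ddof=1)
                with np.errstate(divide="ignore", invalid="ignore"):
                    c = np.where(mean > 0, sd / mean, np.nan)
            else:
                c = np.full(len(d), np.nan)
            cv[cond] = pd.Series(c, index=d.index)
        return cls(tpm_mean=tpm, cv=pd.DataFrame(cv))


def pooled_mean_expression(expr: ExpressionTable, rank_on: str = "pooled") -> pd.Series:
    if rank_on == "pooled":
        return expr.tpm_mean[list(CONDITIONS)].mean(axis=1)
    if rank_on in CONDITIONS:
        return expr.tpm_mean[rank_on]
    raise ValueError(f"rank_on must be 'pooled', 'GH' or 'SH', got {rank_on!r}")


def select_expressed(
    expr: ExpressionTable, fraction: float = 0.4, rank_on: str = "pooled"
) -> list[str]:
    """Top ``ceil(fraction * G)`` genes by mean expression.

    Ranking uses the pooled mean over the two conditions by default; ties
    break lexicographically by gene id so the selection is deterministic.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if len(expr.genes) == 0:
        raise SignalTableError("select_expressed: empty expression table")
    mean = pooled_mean_expression(expr, rank_on)
    n_keep = math.ceil(fraction * len(mean))
    order = (
        pd.DataFrame({"tpm": mean.to_numpy(), "gene_id": list(mean.index)})
        .sort_values(["tpm", "gene_id"], ascending=[False, True], kind="mergesort")
    )
    return list(order["gene_id"].iloc[:n_keep])


@dataclass
class SignalToNoiseReport:
    """Advisory summary of replicate signal-to-noise below the expression cutoff.

    Signal-to-noise per gene is mean/sd averaged across the two
    treatments (the reciprocal of the within-treatment CV); genes with
    zero replicate variance have infinite SNR and count as >= 1.
    """

    applicable: bool
    n_below_cutoff: int
    share_snr_below_1: float | None
    cv_defined: bool
    note: str = ""


def signal_to_noise_report(
    expr: ExpressionTable, fraction: float = 0.4, rank_on: str = "pooled"
) -> SignalToNoiseReport:
    expressed = set(select_expressed(expr, fraction, rank_on))
    below = [g for g in expr.genes if g not in expressed]
    if not below:
        return SignalToNoiseReport(
            applicable=False, n_below_cutoff=0, share_snr_below_1=None,
            cv_defined=True, note="no genes below the cutoff (fraction=1?)",
        )
    cv = expr.cv.loc[below]
    if cv.isna().to_numpy().all():
        return SignalToNoiseReport(
            applicable=False, n_below_cutoff=len(below), share_snr_below_1=None,
            cv_defined=False,
            note="CV undefined: fewer than 2 replicates per condition",
        )
    with np.errstate(divide="ignore"):
        snr = 1.0 / cv.to_numpy(dtype=float)  # inf where sd == 0
    snr_gene = np.nanmean(snr, axis=1)
    share = float(np.mean(snr_gene < 1.0))
    return SignalToNoiseReport(
        applicable=True, n_below_cutoff=len(below),
        share_snr_below_1=share, cv_defined=True,
    )


@dataclass
class DeltaMatrix:
    """Genes x signals matrix of z-score-normalized GH-SH differences.

    Each column has mean 0 and sample standard deviation 1 (ddof=1) over
    the expressed genes; this is the substrate the clustering stage uses.
    """

    z: pd.DataFrame  # genes x signals

    def __post_init__(self) -> None:
        col_mean = self.z.mean(axis=0).to_numpy()
        col_sd = self.z.std(axis=0, ddof=1).to_numpy()
        if not np.allclose(col_mean, 0.0, atol=1e-9):
            raise SignalTableError("DeltaMatrix columns must have mean 0")
        if not np.allclose(col_sd, 1.0, atol=1e-9):
            raise SignalTableError("DeltaMatrix columns must have sample sd 1")

    @property
    def genes(self) -> list[str]:
        return list(self.z.index)

    @property
    def signals(self) -> list[str]:
        return list(self.z.columns)

    def values(self) -> np.ndarray:
        return self.z.to_numpy(dtype=float)


def make_delta(
    gh: Mapping[str, SignalMatrix],
    sh: Mapping[str, SignalMatrix],
    expressed: Sequence[str],
) -> DeltaMatrix:
    """Build the delta matrix from per-signal GH and SH tables.

    For each signal the GH-SH difference of replicate means is taken per
    gene (on that signal's normalized scale) and then z-scored across the
    expressed genes with sample standard deviation (ddof=1). A signal
    whose differences are constant across genes has no z-scale and is
    rejected by name.
    """
    if set(gh) != set(sh):
        raise SignalTableError(
            f"GH and SH signal sets differ: {sorted(set(gh) ^ set(sh))}"
        )
    expressed = list(expressed)
    if len(expressed) < 2:
        raise SignalTableError("make_delta: need at least 2 expressed genes")
    cols = {}
    for name in gh:
        g, s = gh[name], sh[name]
        if set(g.genes) != set(s.genes):
            raise SignalTableError(f"signal {name}: GH/SH gene universes differ")
        missing = set(expressed) - set(g.genes)
        if missing:
            raise SignalTableError(
                f"signal {name}: expressed genes missing from table: "
                f"{sorted(missing)[:5]}"
            )
        diff = (g.replicate_means() - s.replicate_means()).loc[expressed]
        sd = float(diff.std(ddof=1))
        if sd == 0.0:
            raise SignalTableError(f"signal {name}: zero variance across genes")
        cols[name] = (diff - diff.mean()) / sd
    z = pd.DataFrame(cols, index=pd.Index(expressed, name="gene"))
    # preserve caller-supplied signal ordering
    z = z[[name for name in gh]]
    return DeltaMatrix(z=z)


@dataclass
class FoldChangeTable:
    """Per-gene log2 fold change (GH over SH) and symmetric percent change."""

    table: pd.DataFrame  # columns: log2fc, pct_change

    def __post_init__(self) -> None:
        if (self.table["pct_change"].to_numpy() < 0).any():
            raise SignalTableError("pct_change must be >= 0")

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    @property
    def log2fc(self) -> pd.Series:
        return self.table["log2fc"]

    @property
    def pct_change(self) -> pd.Series:
        return self.table["pct_change"]


def fold_changes(
    gh_mean: pd.Series, sh_mean: pd.Series, pseudocount: float = 0.5
) -> FoldChangeTable:
    """Fold changes of GH over SH mean expression with a pseudocount.

    log2fc = log2((GH + pc) / (SH + pc)); pct_change is direction-free:
    100 * (max(ratio, 1/ratio) - 1), so a 4/3 ratio in either direction
    is a 33.33% change. Direction lives only in the sign of log2fc.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    gh_mean, sh_mean = gh_mean.align(sh_mean, join="inner")
    if (gh_mean < 0).any() or (sh_mean < 0).any():
        raise SignalTableError("fold_changes: negative expression values")
    ratio = (gh_mean + pseudocount) / (sh_mean + pseudocount)
    log2fc = np.log2(ratio)
    pct = 100.0 * (np.maximum(ratio, 1.0 / ratio) - 1.0)
    table = pd.DataFrame({"log2fc": log2fc, "pct_change": pct})
    return FoldChangeTable(table=table)


def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line; blank lines ignored."""
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def read_fold_change_tsv(path: str | Path) -> pd.Series:
    """External fold-change table: columns (gene, log_fc)."""
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df.iloc[:, 1].to_numpy(dtype=float), index=df.iloc[:, 0], name="log_fc")
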