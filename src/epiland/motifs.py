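"""PWM scanning of promoter windows, enrichment, and motif-count regression.

Transcription-factor binding motifs are modelled as position weight
matrices (PWMs) read from MEME minimal format. A promoter-proximal
window (1001 bp centered on the TSS) is scanned on both strands with the
log-odds score log2(P_motif / P_background); a position is a predicted
site when its score reaches the threshold whose *exact* null p-value
(the probability that a random background-distributed L-mer scores at
least as high) is the largest p not exceeding the requested threshold.
The exact null distribution is computed by dynamic programming over PWM
columns with score discretization.

Downstream, per-cluster motif enrichment is a one-sided hypergeometric
test of gene-level site presence against an equally sized random control
gene set, Bonferroni-adjusted over motifs with the enrichment call at
adjusted p < 1e-10. Enriched TFs are filtered to expressed genes with at
least a 33.3% housing-driven change in transcript level, and per-gene
mRNA log fold change is regressed on motif counts with backward stepwise
elimination (`StepwiseLinearRegression`).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .signal_io import FoldChangeTable

ALPHABET = "ACGT"
_CODE = {c: i for i, c in enumerate(ALPHABET)}
_CODE["N"] = 4
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: symmetric percent-change threshold for the TF filter (ratio 4/3)
TF_PCT_CHANGE_THRESHOLD = 100.0 / 3.0
ENRICHMENT_ALPHA = 1e-10


class MotifError(ValueError):
    pass


@dataclass
class MotifModel:
    """A PWM over ACGT with a background model.

    ``matrix`` is L x 4 of per-position letter probabilities. On
    construction a pseudocount is mixed in, row by row, as
    (p + pc * background) / (1 + pc), so every cell is strictly positive
    whenever the background is; rows then renormalize to 1.
    """

    motif_id: str
    tf_gene: str | None
    matrix: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    pseudocount: float = 0.1

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise MotifError(f"{self.motif_id}: matrix must be L x 4")
        if self.matrix.shape[0] < 4:
            raise MotifError(f"{self.motif_id}: motif length must be >= 4")
        if abs(self.background.sum() - 1.0) > 1e-6 or (self.background <= 0).any():
            raise MotifError(f"{self.motif_id}: invalid background")
        adj = (self.matrix + self.pseudocount * self.background) / (1.0 + self.pseudocount)
        self.matrix = adj / adj.sum(axis=1, keepdims=True)
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise MotifError(f"{self.motif_id}: rows do not sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    def log_odds(self) -> np.ndarray:
        """L x 4 log2(p / background); N (code 4) maps to -inf at scan time."""
        return np.log2(self.matrix / self.background)

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=1))


def read_meme(path: str | Path) -> list[MotifModel]:
    """Parse MEME minimal format (letter-probability matrix blocks)."""
    text = Path(path).read_text()
    background = np.full(4, 0.25)
    m = re.search(
        r"Background letter frequencies.*?\n((?:[ACGT]\s+[\d.eE+-]+\s*)+)", text
    )
    if m:
        pairs = m.group(1).split()
        freq = {pairs[i]: float(pairs[i + 1]) for i in range(0, len(pairs), 2)}
        background = np.array([freq.get(c, 0.25) for c in ALPHABET])
        background = background / background.sum()
    motifs = []
    for block in re.finditer(
        r"MOTIF\s+(\S+)(?:[ \t]+(\S+))?\s*\n.*?letter-probability matrix:[^\n]*\n"
        r"((?:\s*[\d.eE+-]+[ \t]+[\d.eE+-]+[ \t]+[\d.eE+-]+[ \t]+[\d.eE+-]+\s*\n)+)",
        text,
        re.DOTALL,
    ):
        motif_id, alt, rows = block.group(1), block.group(2), block.group(3)
        matrix = np.array(
            [[float(x) for x in ln.split()] for ln in rows.strip().splitlines()]
        )
        motifs.append(
            MotifModel(
                motif_id=motif_id, tf_gene=alt, matrix=matrix,
                background=background,
                # file already holds probabilities; only guard exact zeros
                pseudocount=1e-4,
            )
        )
    if not motifs:
        raise MotifError(f"{path}: no motifs found (MEME minimal format expected)")
    return motifs


def write_meme(motifs: Sequence[MotifModel], path: str | Path) -> None:
    lines = ["MEME version 4", "", "ALPHABET= ACGT", "", "strands: + -", ""]
    bg = motifs[0].background
    lines.append("Background letter frequencies")
    lines.append(" ".join(f"{c} {b:.6f}" for c, b in zip(ALPHABET, bg)))
    lines.append("")
    for mm in motifs:
        name = f"MOTIF {mm.motif_id}"
        if mm.tf_gene:
            name += f" {mm.tf_gene}"
        lines.append(name)
        lines.append(
            f"letter-probability matrix: alength= 4 w= {mm.length} nsites= 20 E= 0"
        )
        for row in mm.matrix:
            lines.append(" ".join(f"{p:.6f}" for p in row))
        lines.append("")
    Path(path).write_text("\n".join(lines))


@dataclass
class ScoreDistribution:
    """Exact null distribution of the log-odds score of a background L-mer.

    Scores are discretized to integer multiples of ``granularity``;
    probabilities are exact (products of background letter probabilities
    summed per score bin) and sum to 1.
    """

    scores: np.ndarray  # ascending, bin centers (bin_index * granularity)
    probs: np.ndarray
    granularity: float

    def tail_p(self, score: float) -> float:
        """P(binned score >= binned ``score``) under the background."""
        k = int(round(score / self.granularity))
        bins = np.round(self.scores / self.granularity).astype(np.int64)
        return float(self.probs[bins >= k].sum())

    def threshold_for_p(self, p_threshold: float) -> tuple[float, float]:
        """Smallest score whose exact tail p is <= p_threshold.

        Returns (score_threshold, attained_p); attained_p is the largest
        achievable p not exceeding p_threshold, or 0 with a threshold
        above the maximum score when no tail qualifies.
        """
        tail = np.cumsum(self.probs[::-1])[::-1]
        ok = tail <= p_threshold
        if not ok.any():
            return float(self.scores[-1] + self.granularity), 0.0
        i = int(np.argmax(ok))
        return float(self.scores[i]), float(tail[i])


def pwm_score_distribution(
    motif: MotifModel,
    granularity: float = 1e-3,
    max_rounding_error: float = 0.5,
) -> ScoreDistribution:
    """Exact score distribution by DP over columns with binned scores.

    The accumulated score discretization error is bounded by
    L * granularity / 2; if that exceeds ``max_rounding_error`` (in bits)
    the binning is too coarse and an error asks for finer bins.
    """
    if granularity <= 0:
        raise MotifError("granularity must be > 0")
    L = motif.length
    if L * granularity / 2.0 > max_rounding_error:
        raise MotifError(
            f"granularity {granularity} too coarse for motif length {L} "
            f"(worst-case rounding error {L * granularity / 2:.3g} bits > "
            f"{max_rounding_error}); use finer bins"
        )
    lo = motif.log_odds()
    col_bins = np.round(lo / granularity).astype(np.int64)  # L x 4
    offset = 0  # current minimum achievable bin
    probs = np.array([1.0])
    bg = motif.background
    for i in range(L):
        b = col_bins[i]
        lo_b, hi_b = int(b.min()), int(b.max())
        new = np.zeros(len(probs) + (hi_b - lo_b), dtype=float)
        for letter in range(4):
            shift = int(b[letter]) - lo_b
            new[shift : shift + len(probs)] += probs * bg[letter]
        probs = new
        offset += lo_b
    nz = probs > 0
    bins = np.arange(len(probs))[nz] + offset
    return ScoreDistribution(
        scores=bins * granularity, probs=probs[nz], granularity=granularity
    )


def encode_sequence(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    table = np.full(256, 4, dtype=np.int8)
    for c, i in _CODE.items():
        table[ord(c)] = i
    codes = table[arr]
    bad = set(seq.upper()) - set("ACGTN")
    if bad:
        raise MotifError(f"sequence contains letters outside ACGTN: {sorted(bad)}")
    return codes


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MotifHit:
    """One predicted site: forward-strand start, strand, score, exact p."""

    start: int
    strand: str
    score: float
    p: float


def _strand_scores(codes: np.ndarray, lo_bins: np.ndarray) -> np.ndarray:
    """Binned window scores; windows containing N score minimum (skipped)."""
    L = lo_bins.shape[0]
    n_win = len(codes) - L + 1
    if n_win <= 0:
        return np.zeros(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes, L)
    padded = np.concatenate(
        [lo_bins, np.full((L, 1), np.iinfo(np.int64).min // (2 * L), dtype=np.int64)],
        axis=1,
    )
    return padded[np.arange(L)[None, :], win].sum(axis=1)


def pwm_scan(
    sequence: str,
    motif: MotifModel,
    p_threshold: float = 1e-4,
    granularity: float = 1e-3,
    dist: ScoreDistribution | None = None,
) -> list[MotifHit]:
    """Log-odds scan of both strands at an exact p-value threshold.

    A window is a hit when its binned score reaches the threshold score
    from `ScoreDistribution.threshold_for_p`, so the per-window hit
    probability under the background equals the attained p exactly.
    Windows containing N never match; sequences shorter than the motif
    return no hits. Reverse-strand hits report the forward-strand start
    of the covered window.
    """
    if not 0 < p_threshold < 1:
        raise MotifError("p_threshold must be in (0, 1)")
    if dist is None:
        dist = pwm_score_distribution(motif, granularity=granularity)
    thr_score, attained = dist.threshold_for_p(p_threshold)
    thr_bin = int(round(thr_score / dist.granularity))
    lo_bins = np.round(motif.log_odds() / dist.granularity).astype(np.int64)
    L = motif.length
    hits: list[MotifHit] = []
    for strand, seq in (("+", sequence), ("-", reverse_complement(sequence))):
        codes = encode_sequence(seq)
        scores = _strand_scores(codes, lo_bins)
        for pos in np.nonzero(scores >= thr_bin)[0]:
            start = int(pos) if strand == "+" else len(sequence) - L - int(pos)
            score_bits = float(scores[pos] * dist.granularity)
            hits.append(
                MotifHit(start=start, strand=strand, score=score_bits,
                         p=dist.tail_p(score_bits))
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


@dataclass
class PromoterWindow:
    """TSS +/- 500 bp window, 0-based half-open, possibly clipped at an edge."""

    gene: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    clipped: bool = False

    def __post_init__(self) -> None:
        if self.end - self.start != 1001 and not self.clipped:
            raise MotifError(
                f"{self.gene}: window must span 1001 bp unless clipped "
                f"(got {self.end - self.start})"
            )


def tss_windows(
    bed: pd.DataFrame, half_width: int = 500, contig_sizes: Mapping[str, int] | None = None
) -> list[PromoterWindow]:
    """Promoter windows from BED6 gene annotation (0-based half-open).

    The TSS is ``start`` on + strand and ``end - 1`` on - strand; the
    window is [TSS - half_width, TSS + half_width + 1), clipped (and
    flagged) at contig edges.
    """
    windows = []
    for row in bed.itertuples(index=False):
        chrom, start, end, name, _score, strand = row[:6]
        tss = int(start) if strand == "+" else int(end) - 1
        lo, hi = tss - half_width, tss + half_width + 1
        clipped = False
        if lo < 0:
            lo, clipped = 0, True
        if contig_sizes and chrom in contig_sizes and hi > contig_sizes[chrom]:
            hi, clipped = contig_sizes[chrom], True
        windows.append(
            PromoterWindow(gene=str(name), chrom=str(chrom), start=lo, end=hi,
                           strand=str(strand), clipped=clipped)
        )
    return windows


def read_bed6(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )


def _window_sequence(window: PromoterWindow, sequences: Mapping[str, str]) -> str | None:
    if window.gene in sequences:
        return sequences[window.gene]
    if window.chrom in sequences:
        return sequences[window.chrom][window.start : window.end]
    return None


def count_motifs(
    windows: Sequence[PromoterWindow] | Mapping[str, str],
    sequences: Mapping[str, str] | None,
    motifs: Sequence[MotifModel],
    p_threshold: float = 1e-4,
    granularity: float = 1e-3,
) -> pd.DataFrame:
    """Predicted-site counts per gene per motif in the promoter window.

    Both strands are scanned and overlapping hits each count, so a
    palindromic site contributes 2 (once per strand). Accepts either
    windows + a sequence source (per-gene promoter FASTA or per-contig
    genome FASTA) or a plain gene -> promoter-sequence mapping.
    """
    if isinstance(windows, Mapping):
        seq_by_gene = dict(windows)
    else:
        if sequences is None:
            raise MotifError("sequences required when windows are coordinates")
        seq_by_gene = {}
        missing = []
        for w in windows:
            s = _window_sequence(w, sequences)
            if s is None:
                missing.append(w.gene)
            else:
                seq_by_gene[w.gene] = s
        if missing:
            raise MotifError(f"no sequence for windows of genes: {missing}")
    dists = {m.motif_id: pwm_score_distribution(m, granularity) for m in motifs}
    counts = pd.DataFrame(
        0,
        index=pd.Index(list(seq_by_gene), name="gene"),
        columns=[m.motif_id for m in motifs],
        dtype=int,
    )
    for m in motifs:
        for gene, seq in seq_by_gene.items():
            counts.loc[gene, m.motif_id] = len(
                pwm_scan(seq, m, p_threshold, dist=dists[m.motif_id])
            )
    return counts


@dataclass
class EnrichmentResult:
    cluster: str | int
    motif_id: str
    test_genes_with_site: int
    control_genes_with_site: int
    test_total_sites: int
    control_total_sites: int
    n_test: int
    n_control: int
    raw_p: float
    adjusted_p: float

    @property
    def enriched(self) -> bool:
        return self.adjusted_p < ENRICHMENT_ALPHA


def enrich_cluster_motifs(
    cluster_genes: Sequence[str],
    universe_genes: Sequence[str],
    counts: pd.DataFrame,
    seed: int = 0,
    cluster_id: str | int = "",
) -> list[EnrichmentResult]:
    """Motif enrichment of a cluster against a random control gene set.

    The control is |cluster| genes sampled without replacement (seeded)
    from the universe outside the cluster. Per motif, a one-sided
    hypergeometric test compares the number of genes carrying >= 1
    predicted site in the cluster versus the control; p-values are
    Bonferroni-adjusted over motifs and a motif is enriched when the
    adjusted p is below 1e-10. Total site counts are reported alongside
    the gene-level presence statistic.
    """
    cluster = list(dict.fromkeys(cluster_genes))
    universe = list(dict.fromkeys(universe_genes))
    if not set(cluster) <= set(universe):
        raise MotifError("cluster genes must be a subset of the universe")
    outside = [g for g in universe if g not in set(cluster)]
    if len(outside) < len(cluster):
        raise MotifError(
            "universe minus cluster is smaller than the cluster; cannot draw "
            "an equal-size control set"
        )
    rng = np.random.default_rng(seed)
    control = list(rng.choice(outside, size=len(cluster), replace=False))
    test_counts = counts.loc[cluster]
    ctrl_counts = counts.loc[control]
    n_motifs = counts.shape[1]
    results = []
    for motif_id in counts.columns:
        a = int((test_counts[motif_id] >= 1).sum())
        b = int((ctrl_counts[motif_id] >= 1).sum())
        M = len(cluster) + len(control)
        K = a + b
        raw = float(stats.hypergeom.sf(a - 1, M, K, len(cluster)))
        results.append(
            EnrichmentResult(
                cluster=cluster_id, motif_id=str(motif_id),
                test_genes_with_site=a, control_genes_with_site=b,
                test_total_sites=int(test_counts[motif_id].sum()),
                control_total_sites=int(ctrl_counts[motif_id].sum()),
                n_test=len(cluster), n_control=len(control),
                raw_p=raw, adjusted_p=min(1.0, raw * n_motifs),
            )
        )
    return results


@dataclass
class TFShortlist:
    """Enriched motifs collapsed to TF level and filtered.

    A TF survives when its gene is in the expressed set and shows at
    least a 33.3% symmetric change in transcript level between housing
    conditions. Motifs whose TF gene is unknown land in ``unmapped``.
    """

    kept: dict[str, list[str]]  # tf_gene -> motif ids
    dropped_not_expressed: list[str]
    dropped_low_change: list[str]
    unmapped: list[str]

    @property
    def tf_genes(self) -> list[str]:
        return sorted(self.kept)


def filter_tfs(
    enriched_motifs: Sequence[MotifModel],
    expressed_genes: Iterable[str],
    fc: FoldChangeTable,
    min_pct_change: float = TF_PCT_CHANGE_THRESHOLD,
) -> TFShortlist:
    expressed = set(expressed_genes)
    kept: dict[str, list[str]] = {}
    not_expr, low, unmapped = [], [], []
    for m in enriched_motifs:
        tf = m.tf_gene
        if not tf:
            unmapped.append(m.motif_id)
            continue
        if tf not in expressed:
            not_expr.append(m.motif_id)
            continue
        if tf not in fc.genes or fc.pct_change.loc[tf] < min_pct_change:
            low.append(m.motif_id)
            continue
        kept.setdefault(tf, []).append(m.motif_id)
    return TFShortlist(
        kept=kept, dropped_not_expressed=not_expr,
        dropped_low_change=low, unmapped=unmapped,
    )


class StepwiseLinearRegression(RegressorMixin, BaseEstimator):
    """OLS with backward stepwise elimination of non-significant predictors.

    The model (with intercept) is refit repeatedly, dropping the
    predictor with the largest coefficient p-value while any p is at or
    above the elimination threshold. Predictors whose final p lies in
    [alpha, drop_alpha) are retained but flagged marginal — rendered as
    "(+)" / "(-)" in reports, matching the convention of printing a
    parenthesised sign for marginally significant coefficients.

    Parameters
    ----------
    alpha:
        Significance level for an unqualified +/- sign (default 0.05).
    drop_alpha:
        Elimination threshold; defaults to ``alpha``. Set it to 0.10 to
        retain marginally significant predictors.
    criterion:
        "pvalue" (drop largest-p while >= drop threshold) or "aic"
        (drop the least significant predictor while AIC improves).

    Attributes
    ----------
    retained_ : list of predictor names in the final model
    coef_, tvalues_, pvalues_ : aligned with ``retained_``
    signs_ : dict name -> "+", "-", "(+)" or "(-)"
    r_ : float, sqrt of the final model's R^2
    fstat_, f_pvalue_ : overall F test of the final model
    dropped_collinear_ : predictors removed for perfect collinearity
    """

    def __init__(self, alpha: float = 0.05, drop_alpha: float | None = None,
                 criterion: str = "pvalue"):
        self.alpha = alpha
        self.drop_alpha = drop_alpha
        self.criterion = criterion

    def _drop_threshold(self) -> float:
        return self.alpha if self.drop_alpha is None else self.drop_alpha

    def fit(self, X, y, feature_names: Sequence[str] | None = None):
        if self.criterion not in ("pvalue", "aic"):
            raise ValueError("criterion must be 'pvalue' or 'aic'")
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            Xv = X.to_numpy(dtype=float)
        else:
            Xv = np.asarray(X, dtype=float)
            names = list(feature_names) if feature_names is not None else [
                f"x{i}" for i in range(Xv.shape[1])
            ]
        yv = np.asarray(y, dtype=float)
        if Xv.ndim != 2 or len(yv) != Xv.shape[0]:
            raise ValueError("X must be 2-D with one row per response value")
        if len(yv) <= Xv.shape[1] + 2:
            raise ValueError(
                f"need more than n_predictors + 2 = {Xv.shape[1] + 2} observations, "
                f"got {len(yv)}"
            )
        frame = pd.DataFrame(Xv, columns=names)

        # perfectly collinear pairs: keep the earlier-listed predictor
        self.dropped_collinear_ = []
        keep = list(frame.columns)
        with np.errstate(invalid="ignore"):
            corr = frame.corr().to_numpy()
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                if names[j] in keep and names[i] in keep and np.isclose(
                    abs(corr[i, j]), 1.0, atol=1e-10
                ):
                    keep.remove(names[j])
                    self.dropped_collinear_.append(names[j])
                    warnings.warn(
                        f"dropping {names[j]}: perfectly collinear with {names[i]}",
                        stacklevel=2,
                    )
        frame = frame[keep]

        thr = self._drop_threshold()
        current = list(frame.columns)
        res = None
        while True:
            design = sm.add_constant(frame[current], has_constant="add")
            res = sm.OLS(yv, design).fit()
            if not current:
                break
            pvals = res.pvalues.drop("const")
            if self.criterion == "pvalue":
                if pvals.max() < thr or np.isnan(pvals.max()):
                    break
                current.remove(pvals.idxmax())
            else:  # aic: drop least significant first while AIC improves
                worst = pvals.idxmax()
                reduced = [c for c in current if c != worst]
                res_red = sm.OLS(
                    yv, sm.add_constant(frame[reduced], has_constant="add")
                ).fit()
                if res_red.aic < res.aic:
                    current = reduced
                else:
                    break

        self.retained_ = current
        self.results_ = res
        if current:
            self.coef_ = res.params[current].to_numpy()
            self.tvalues_ = res.tvalues[current].to_numpy()
            self.pvalues_ = res.pvalues[current].to_numpy()
            self.r_ = float(np.sqrt(max(res.rsquared, 0.0)))
            self.fstat_ = float(res.fvalue)
            self.f_pvalue_ = float(res.f_pvalue)
        else:
            self.coef_ = np.zeros(0)
            self.tvalues_ = np.zeros(0)
            self.pvalues_ = np.zeros(0)
            self.r_ = 0.0
            self.fstat_ = float("nan")
            self.f_pvalue_ = float("nan")
        self.intercept_ = float(res.params["const"])
        self.signs_ = {}
        for name, c, p in zip(current, self.coef_, self.pvalues_):
            sign = "+" if c > 0 else "-"
            if p >= self.alpha:
                sign = f"({sign})"
            self.signs_[name] = sign
        self.n_obs_ = len(yv)
        self.feature_names_in_ = np.asarray(names, dtype=object)
        return self

    def predict(self, X):
        check_is_fitted(self, "retained_")
        if isinstance(X, pd.DataFrame):
            Xv = X[self.retained_].to_numpy(dtype=float)
        else:
            Xv = np.asarray(X, dtype=float)
            idx = [list(self.feature_names_in_).index(n) for n in self.retained_]
            Xv = Xv[:, idx]
        return self.intercept_ + Xv @ self.coef_


@dataclass
class RegressionResult:
    """Stepwise fit summary for one functional gene group."""

    group: str
    n_genes: int
    retained: pd.DataFrame  # motif/tf, coef, t, p, sign
    r: float
    fstat: float
    f_pvalue: float
    dropped_collinear: list[str]


def stepwise_fit(
    log_fc: pd.Series,
    counts: pd.DataFrame,
    gene_group: Sequence[str] | None = None,
    group_name: str = "",
    alpha: float = 0.05,
    drop_alpha: float | None = None,
    criterion: str = "pvalue",
) -> RegressionResult:
    """Regress mRNA log fold change on motif counts for one gene group."""
    genes = list(gene_group) if gene_group is not None else list(counts.index)
    missing = [g for g in genes if g not in counts.index or g not in log_fc.index]
    if missing:
        raise MotifError(f"genes missing from counts or fold changes: {missing[:5]}")
    est = StepwiseLinearRegression(alpha=alpha, drop_alpha=drop_alpha,
                                   criterion=criterion)
    est.fit(counts.loc[genes], log_fc.loc[genes])
    retained = pd.DataFrame(
        {
            "predictor": est.retained_,
            "coef": est.coef_,
            "t": est.tvalues_,
            "p": est.pvalues_,
            "sign": [est.signs_[n] for n in est.retained_],
        }
    )
    return RegressionResult(
        group=group_name, n_genes=len(genes), retained=retained,
        r=est.r_, fstat=est.fstat_, f_pvalue=est.f_pvalue_,
        dropped_collinear=est.dropped_collinear_,
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
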