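"""Synthetic inputs with planted ground truth for every pipeline stage.

Three generators emulate the study's data at desk scale:

* `gen_landscape` — per-gene signals for six marks + mRNA in two housing
  conditions, with cluster-structured GH-SH differences: each expressed
  gene belongs to one of K planted clusters whose mean delta vector over
  the 7 signals is a scaled, mutually orthogonal +/-1 pattern. A pool of
  low-expression genes without structure makes the expressed-gene filter
  meaningful (defaults reproduce the study scale: 5372 expressed of
  13430 total, K=8).
* `gen_promoters` — 1001-bp promoter sequences with planted motif sites
  whose per-gene counts drive a linear model for mRNA log fold change
  (negative coefficients for repressor-acting TFs), plus the truth table
  of counts and coefficients.
* `gen_activity` — per-fly activity traces from a two-state (awake /
  asleep) per-minute Markov chain with housing- and genotype-dependent
  day rates; awake minutes emit Poisson(lambda > 0) counts so zero-count
  minutes only rarely occur awake. The *planted* delta-sleep is computed
  exactly (`expected_scored_daytime_sleep`) by a hidden-Markov
  run-length dynamic program that accounts for the 5-minute bout rule,
  so recovery tests compare against the true expectation of the scoring
  pipeline, not the raw state occupancy.

Every generator is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import hadamard

from .motifs import MotifModel, reverse_complement
from .signal_io import SIGNALS, ExpressionTable, SignalMatrix
from .sleep import DAY_MINUTES, MINUTES_PER_DAY, ActivityTrace

ALPHABET = "ACGT"


# ---------------------------------------------------------------------------
# Landscape
# ---------------------------------------------------------------------------

@dataclass
class LandscapeSpec:
    """Planted cluster structure for the 7-signal delta landscape.

    ``separation`` scales the cluster mean vectors in units of
    ``within_sd``; at the default 5 the clusters are well separated and
    both k-selection criteria recover K.
    """

    n_genes: int = 5372          # expressed genes carrying cluster structure
    n_unexpressed: int = 8058    # structureless low-expression pool
    n_clusters: int = 8
    cluster_props: tuple[float, ...] | None = None
    separation: float = 5.0
    within_sd: float = 1.0
    n_replicates: int = 3
    replicate_noise_sd: float = 0.5
    baseline_low: float = 30.0
    baseline_high: float = 80.0
    signals: tuple[str, ...] = SIGNALS

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.cluster_props is not None:
            if len(self.cluster_props) != self.n_clusters:
                raise ValueError("cluster_props length must equal n_clusters")
            if abs(sum(self.cluster_props) - 1.0) > 1e-9:
                raise ValueError("cluster proportions must sum to 1")

    def cluster_means(self) -> np.ndarray:
        """K x n_signals planted delta means: orthogonal +/-1 patterns
        (Hadamard rows, first column dropped), unit-normalized and scaled
        by separation * within_sd."""
        d = len(self.signals)
        size = 1
        while size < max(self.n_clusters, d + 1):
            size *= 2
        H = hadamard(size)[: self.n_clusters, 1 : d + 1].astype(float)
        H = H / np.linalg.norm(H, axis=1, keepdims=True)
        return H * self.separation * self.within_sd


@dataclass
class LandscapeData:
    gh: dict[str, SignalMatrix]
    sh: dict[str, SignalMatrix]
    expression: ExpressionTable
    true_labels: pd.Series          # expressed genes only, 1..K
    true_means: np.ndarray          # K x n_signals
    true_delta: pd.DataFrame        # expressed genes x signals (pre-noise)

    @property
    def expressed_genes(self) -> list[str]:
        return list(self.true_labels.index)


def gen_landscape(spec: LandscapeSpec, seed: int = 0) -> LandscapeData:
    rng = np.random.default_rng(seed)
    K, d = spec.n_clusters, len(spec.signals)
    n_expr, n_low = spec.n_genes, spec.n_unexpressed
    genes_expr = [f"g{i:05d}" for i in range(n_expr)]
    genes_low = [f"lo{i:05d}" for i in range(n_low)]
    props = (
        np.asarray(spec.cluster_props)
        if spec.cluster_props is not None
        else np.full(K, 1.0 / K)
    )
    labels = rng.choice(K, size=n_expr, p=props) + 1
    means = spec.cluster_means()
    delta = means[labels - 1] + rng.normal(0.0, spec.within_sd, size=(n_expr, d))

    base_expr = rng.uniform(spec.baseline_low, spec.baseline_high, size=(n_expr, d))
    gh, sh = {}, {}
    rep_cols = [f"rep{r + 1}" for r in range(spec.n_replicates)]
    for j, signal in enumerate(spec.signals):
        gh_mean = base_expr[:, j] + delta[:, j] / 2.0
        sh_mean = base_expr[:, j] - delta[:, j] / 2.0
        if signal == "mRNA":
            # low-expression pool: mean ~1 with replicate CV > 1 so the
            # advisory signal-to-noise report mirrors real bottom-60% genes
            low_gh = rng.gamma(0.4, 2.5, size=(n_low, spec.n_replicates))
            low_sh = rng.gamma(0.4, 2.5, size=(n_low, spec.n_replicates))
        else:
            low_gh = rng.uniform(0.5, 3.0, size=(n_low, spec.n_replicates))
            low_sh = rng.uniform(0.5, 3.0, size=(n_low, spec.n_replicates))
        noise = rng.normal(0.0, spec.replicate_noise_sd,
                           size=(2, n_expr, spec.n_replicates))
        gh_vals = np.clip(gh_mean[:, None] + noise[0], 0.0, None)
        sh_vals = np.clip(sh_mean[:, None] + noise[1], 0.0, None)
        idx = pd.Index(genes_expr + genes_low, name="gene")
        gh[signal] = SignalMatrix(
            signal, "GH",
            pd.DataFrame(np.vstack([gh_vals, low_gh]), index=idx, columns=rep_cols),
        )
        sh[signal] = SignalMatrix(
            signal, "SH",
            pd.DataFrame(np.vstack([sh_vals, low_sh]), index=idx, columns=rep_cols),
        )
    expression = ExpressionTable.from_signal_matrices(gh["mRNA"], sh["mRNA"])
    return LandscapeData(
        gh=gh, sh=sh, expression=expression,
        true_labels=pd.Series(labels, index=pd.Index(genes_expr, name="gene"),
                              name="cluster"),
        true_means=means,
        true_delta=pd.DataFrame(delta, index=pd.Index(genes_expr, name="gene"),
                                columns=list(spec.signals)),
    )


# ---------------------------------------------------------------------------
# Promoters and motif counts
# ---------------------------------------------------------------------------

@dataclass
class PlantedMotif:
    motif_id: str
    tf_gene: str
    consensus: str
    coefficient: float          # effect of one site on log2 fold change
    dominant_prob: float = 0.85

    def pwm(self, background: np.ndarray) -> MotifModel:
        L = len(self.consensus)
        mat = np.full((L, 4), (1.0 - self.dominant_prob) / 3.0)
        for i, c in enumerate(self.consensus):
            mat[i, ALPHABET.index(c)] = self.dominant_prob
        return MotifModel(
            motif_id=self.motif_id, tf_gene=self.tf_gene, matrix=mat,
            background=background, pseudocount=0.0001,
        )


def default_motif_set() -> list[PlantedMotif]:
    """Synthetic stand-ins for the five shortlisted TFs.

    Consensi are invented (CrebA gets a CRE-like palindrome on purpose,
    to exercise double-strand counting); coefficients mirror the
    dominant repressor signs for Hr38/cbt/CrebA and the positive effect
    of pho.
    """
    return [
        PlantedMotif("M_Hr38", "Hr38", "TGACCTTG", -0.30),
        PlantedMotif("M_cbt", "cbt", "GGGTGTGA", -0.30),
        PlantedMotif("M_CrebA", "CrebA", "TGACGTCA", -0.20),
        PlantedMotif("M_sr", "sr", "GCGTGGGCG", +0.20),
        PlantedMotif("M_pho", "pho", "GCCATCTT", +0.25),
    ]


@dataclass
class MotifSpec:
    """Planted promoter/motif structure feeding the regression stage."""

    motifs: list[PlantedMotif] = field(default_factory=default_motif_set)
    promoter_length: int = 1001
    background: tuple[float, float, float, float] = (0.3, 0.2, 0.2, 0.3)
    site_mean: float = 1.2      # Poisson mean of planted sites per gene
    site_max: int = 6
    noise_sd: float = 0.3       # residual sd of log2 fold change
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if self.promoter_length % 2 == 0:
            raise ValueError("promoter length must be odd (TSS centered)")
        if abs(sum(self.background) - 1.0) > 1e-9:
            raise ValueError("background must sum to 1")
        for m in self.motifs:
            if not np.isfinite(m.coefficient):
                raise ValueError(f"{m.motif_id}: coefficient must be finite")


def gen_motif_counts(
    spec: MotifSpec, n_genes: int, seed: int = 0
) -> tuple[pd.DataFrame, pd.Series]:
    """Planted site counts and the log fold changes they generate.

    counts ~ Poisson(site_mean) capped at site_max, per gene per motif;
    log2 fc = intercept + sum_m coefficient_m * count_m + N(0, noise_sd).
    """
    rng = np.random.default_rng(seed)
    genes = pd.Index([f"g{i:05d}" for i in range(n_genes)], name="gene")
    counts = pd.DataFrame(
        np.minimum(
            rng.poisson(spec.site_mean, size=(n_genes, len(spec.motifs))),
            spec.site_max,
        ),
        index=genes, columns=[m.motif_id for m in spec.motifs],
    )
    beta = np.array([m.coefficient for m in spec.motifs])
    log_fc = pd.Series(
        spec.intercept + counts.to_numpy() @ beta
        + rng.normal(0.0, spec.noise_sd, size=n_genes),
        index=genes, name="log_fc",
    )
    return counts, log_fc


@dataclass
class PromoterSet:
    sequences: dict[str, str]
    true_counts: pd.DataFrame
    log_fc: pd.Series
    motifs: list[MotifModel]


def gen_promoters(spec: MotifSpec, n_genes: int, seed: int = 0) -> PromoterSet:
    """Background promoters with planted, non-overlapping consensus sites.

    Sites are inserted at random positions on a random strand; the scan
    may add chance background sites, so scanned counts are >= the truth
    table counts for every gene.
    """
    rng = np.random.default_rng(seed)
    counts, log_fc = gen_motif_counts(spec, n_genes, seed=int(rng.integers(2**31)))
    bg = np.asarray(spec.background)
    sequences: dict[str, str] = {}
    for gene in counts.index:
        seq = list(
            "".join(rng.choice(list(ALPHABET), p=bg, size=spec.promoter_length))
        )
        occupied: list[tuple[int, int]] = []
        for m in spec.motifs:
            site = m.consensus
            for _ in range(int(counts.loc[gene, m.motif_id])):
                placed = False
                for _attempt in range(200):
                    start = int(rng.integers(0, spec.promoter_length - len(site) + 1))
                    span = (start, start + len(site))
                    if all(span[1] <= a or span[0] >= b for a, b in occupied):
                        placed = True
                        break
                if not placed:  # pragma: no cover - promoter essentially full
                    raise RuntimeError("could not place all planted sites")
                occupied.append(span)
                inserted = site if rng.random() < 0.5 else reverse_complement(site)
                seq[span[0] : span[1]] = list(inserted)
        sequences[gene] = "".join(seq)
    models = [m.pwm(bg) for m in spec.motifs]
    return PromoterSet(sequences=sequences, true_counts=counts, log_fc=log_fc,
                       motifs=models)


# ---------------------------------------------------------------------------
# Activity traces
# ---------------------------------------------------------------------------

@dataclass
class GroupRates:
    """Per-minute sleep-state transition probabilities for one phase."""

    p_fall_asleep: float
    p_wake_up: float

    def __post_init__(self) -> None:
        for p in (self.p_fall_asleep, self.p_wake_up):
            if not 0.0 < p < 1.0:
                raise ValueError("transition probabilities must lie in (0, 1)")

    def stationary_sleep(self) -> float:
        return self.p_fall_asleep / (self.p_fall_asleep + self.p_wake_up)


@dataclass
class BehaviorSpec:
    """Planted sleep behavior: housing effect on daytime sleep, modifiable
    by genotype.

    Day rates make GH flies sleepier than SH flies; an RNAi genotype
    shrinks the GH-SH rate gap by ``delta_reduction`` (0.5 halves it).
    Awake minutes emit Poisson(awake_lambda) beam-break counts; asleep
    minutes emit 0. Traces cover ``n_days`` starting at lights-on; the
    first day is the acclimation period.
    """

    n_flies: int = 32
    genotypes: tuple[str, ...] = ("control", "rnai")
    delta_reduction: Mapping[str, float] = field(
        default_factory=lambda: {"control": 0.0, "rnai": 0.5}
    )
    day_rates: Mapping[str, GroupRates] = field(
        default_factory=lambda: {
            "GH": GroupRates(0.06, 0.04),
            "SH": GroupRates(0.03, 0.07),
        }
    )
    night_rates: GroupRates = field(default_factory=lambda: GroupRates(0.15, 0.01))
    awake_lambda: float = 2.0
    n_days: int = 2
    lights_on_index: int = 0

    def __post_init__(self) -> None:
        if self.awake_lambda <= 0:
            raise ValueError("awake_lambda must be > 0 (zero-activity awake "
                             "state is disallowed)")
        for g in self.genotypes:
            if g not in self.delta_reduction:
                raise ValueError(f"no delta_reduction for genotype {g!r}")

    def rates(self, housing: str, genotype: str) -> GroupRates:
        """Day rates after the genotype's gap reduction toward the midpoint."""
        base = self.day_rates[housing]
        other = self.day_rates["SH" if housing == "GH" else "GH"]
        r = float(self.delta_reduction[genotype])
        mid_f = (base.p_fall_asleep + other.p_fall_asleep) / 2.0
        mid_w = (base.p_wake_up + other.p_wake_up) / 2.0
        return GroupRates(
            mid_f + (base.p_fall_asleep - mid_f) * (1.0 - r),
            mid_w + (base.p_wake_up - mid_w) * (1.0 - r),
        )


AWAKE, ASLEEP = 0, 1


def _minute_rates(spec: BehaviorSpec, housing: str, genotype: str,
                  minute: int) -> GroupRates:
    phase_day = (minute % MINUTES_PER_DAY) < DAY_MINUTES
    return spec.rates(housing, genotype) if phase_day else spec.night_rates


def simulate_group(
    spec: BehaviorSpec, housing: str, genotype: str, n_flies: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """States and counts for one group, vectorized over flies.

    Returns (states, counts), each n_flies x total_minutes; states are
    0 = awake, 1 = asleep.
    """
    total = spec.n_days * MINUTES_PER_DAY
    p_fall = np.empty(total)
    p_wake = np.empty(total)
    for t in range(total):
        r = _minute_rates(spec, housing, genotype, t)
        p_fall[t], p_wake[t] = r.p_fall_asleep, r.p_wake_up
    asleep = rng.random(n_flies) < spec.night_rates.stationary_sleep()
    states = np.zeros((n_flies, total), dtype=np.int8)
    for t in range(total):
        u = rng.random(n_flies)
        asleep = np.where(asleep, u >= p_wake[t], u < p_fall[t])
        states[:, t] = asleep
    counts = np.where(
        states == ASLEEP, 0, rng.poisson(spec.awake_lambda, size=states.shape)
    )
    return states, counts


def gen_activity(spec: BehaviorSpec, seed: int = 0) -> list[ActivityTrace]:
    """Simulate traces for every (housing, genotype) group."""
    rng = np.random.default_rng(seed)
    traces = []
    for genotype in spec.genotypes:
        for housing in ("GH", "SH"):
            _, counts = simulate_group(spec, housing, genotype, spec.n_flies, rng)
            for fly in range(spec.n_flies):
                traces.append(
                    ActivityTrace(
                        fly_id=f"{genotype}_{housing}_{fly:03d}",
                        genotype=genotype, housing=housing, counts=counts[fly],
                        lights_on_index=spec.lights_on_index,
                    )
                )
    return traces


# --- exact expectation of scored daytime sleep -----------------------------

def _transition_matrix(r: GroupRates) -> np.ndarray:
    return np.array(
        [[1.0 - r.p_fall_asleep, r.p_fall_asleep],
         [r.p_wake_up, 1.0 - r.p_wake_up]]
    )


def expected_scored_daytime_sleep(
    spec: BehaviorSpec, housing: str, genotype: str, analysis_day: int = 1
) -> float:
    """Exact E[daytime sleep minutes] under the 5-minute bout scorer.

    The trace is a hidden Markov chain (states awake/asleep) emitting a
    zero count with probability exp(-lambda) awake and 1 asleep; the
    scorer marks minutes inside zero-runs of length >= 5. Using

        E[scored] = sum_t P(count_t = 0) - P(t in a zero-run of length <= 4)

    each run probability P(nonzero, 0^l, nonzero) is an exact product of
    transition matrices and emission diagonals, evaluated per position of
    the analysis day (the trace is trimmed to start at that day, exactly
    as the pipeline scores it).
    """
    q0 = np.array([np.exp(-spec.awake_lambda), 1.0])  # P(zero | state)
    q_pos = 1.0 - q0

    total = spec.n_days * MINUTES_PER_DAY
    mats = [
        _transition_matrix(_minute_rates(spec, housing, genotype, t))
        for t in range(total)
    ]
    # marginal state distribution at each minute of the full trace
    night = spec.night_rates.stationary_sleep()
    mu = np.array([1.0 - night, night])
    marginals = []
    for t in range(total):
        mu = mu @ mats[t]
        marginals.append(mu.copy())

    start = analysis_day * MINUTES_PER_DAY  # trim boundary: scoring restarts here
    horizon = total - start

    def run_prob(s: int, l: int) -> float:
        """P(zero-run of exactly length l starting at trimmed position s)."""
        if s + l > horizon:
            return 0.0
        t0 = start + s
        if s == 0:
            v = marginals[t0 - 1] if t0 > 0 else np.array([1.0 - night, night])
            # trimmed trace has no left neighbor: only require zeros then nonzero
            v = v.copy()
        else:
            v = marginals[t0 - 1] * q_pos  # left delimiter: nonzero at s-1
        for u in range(l):
            v = (v @ mats[t0 + u]) * q0
        if s + l < horizon:
            v = (v @ mats[t0 + l]) * q_pos
        return float(v.sum())

    expected = 0.0
    for t in range(DAY_MINUTES):
        p_zero = float((marginals[start + t] * q0).sum())
        p_short = 0.0
        for l in range(1, 5):
            for offset in range(l):
                s = t - offset
                if s >= 0:
                    p_short += run_prob(s, l)
        expected += p_zero - p_short
    return expected


def planted_delta_sleep(spec: BehaviorSpec, genotype: str = "control") -> float:
    """True expected delta-sleep (GH minus SH) for one genotype."""
    return expected_scored_daytime_sleep(spec, "GH", genotype) - \
        expected_scored_daytime_sleep(spec, "SH", genotype)
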