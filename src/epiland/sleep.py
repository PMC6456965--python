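"""Sleep scoring from activity-monitor traces and the housing effect on sleep.

Drosophila locomotor activity is recorded by beam-break monitors in
1-minute bins under a 12/12 light/dark cycle. A sleep bout is a maximal
run of >= 5 consecutive minutes with zero activity counts; daytime sleep
is the number of bout minutes falling in [ZT0, ZT12) (lights-on to
lights-off, 720 minutes). The behavioral readout of social experience is
delta-sleep: mean daytime sleep of group-housed (GH) flies minus that of
single-housed (SH) flies. Whether an RNAi genotype blunts the housing
effect is tested as a genotype x housing interaction on per-fly daytime
sleep with a Type III ANOVA (sum-to-zero contrasts), which on balanced
designs coincides with the classical two-way decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

MINUTES_PER_DAY = 1440
DAY_MINUTES = 720
MIN_BOUT = 5


class SleepDataError(ValueError):
    pass


@dataclass
class ActivityTrace:
    """Per-fly activity counts in 1-minute bins.

    ``lights_on_index`` is the minute index of ZT0 for the first scored
    day. Counts must be dense (monitors emit every minute; traces with
    gaps are rejected upstream, no imputation).
    """

    fly_id: str
    genotype: str
    housing: str
    counts: np.ndarray
    lights_on_index: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 1:
            raise SleepDataError(f"{self.fly_id}: counts must be 1-D")
        if (self.counts < 0).any():
            raise SleepDataError(f"{self.fly_id}: negative activity count")
        if self.housing not in ("GH", "SH"):
            raise SleepDataError(f"{self.fly_id}: housing must be GH or SH")
        if not 0 <= self.lights_on_index < max(len(self.counts), 1):
            raise SleepDataError(f"{self.fly_id}: lights_on_index out of range")


@dataclass
class SleepBout:
    start: int
    length: int


def score_sleep(trace: ActivityTrace) -> tuple[np.ndarray, list[SleepBout]]:
    """Sleep mask and bout list under the 5-minute rule.

    Maximal runs of consecutive zero-count minutes with length >= 5 are
    sleep; the mask marks every minute inside such a run. Idempotent and
    unaffected by appending awake minutes.
    """
    zero = trace.counts == 0
    mask = np.zeros_like(zero, dtype=bool)
    bouts: list[SleepBout] = []
    if not zero.any():
        return mask, bouts
    padded = np.concatenate([[False], zero, [False]])
    starts = np.nonzero(padded[1:].astype(int) - padded[:-1].astype(int) == 1)[0]
    ends = np.nonzero(padded[1:].astype(int) - padded[:-1].astype(int) == -1)[0]
    for s, e in zip(starts, ends):
        if e - s >= MIN_BOUT:
            mask[s:e] = True
            bouts.append(SleepBout(start=int(s), length=int(e - s)))
    return mask, bouts


def total_sleep(trace: ActivityTrace) -> int:
    mask, bouts = score_sleep(trace)
    assert int(mask.sum()) == sum(b.length for b in bouts)
    return int(mask.sum())


def daytime_sleep(
    trace: ActivityTrace, mask: np.ndarray | None = None, day: int = 0
) -> int:
    """Sleep-mask minutes in [ZT0, ZT12) of the given scored day.

    Bouts spanning the lights-off boundary contribute only their daytime
    minutes. The full day window must be covered by the trace.
    """
    if mask is None:
        mask, _ = score_sleep(trace)
    start = trace.lights_on_index + day * MINUTES_PER_DAY
    end = start + DAY_MINUTES
    if end > len(trace.counts):
        raise SleepDataError(
            f"{trace.fly_id}: day window [{start}, {end}) not fully covered "
            f"by a {len(trace.counts)}-minute trace"
        )
    return int(mask[start:end].sum())


def trim_acclimation(trace: ActivityTrace, minutes: int = MINUTES_PER_DAY) -> ActivityTrace:
    """Drop the acclimation period (default: the first recorded day).

    Scoring happens after trimming, so a bout spanning the trim boundary
    is truncated at the new trace start.
    """
    if minutes >= len(trace.counts):
        raise SleepDataError(f"{trace.fly_id}: trim removes the whole trace")
    if minutes % MINUTES_PER_DAY != 0 and (len(trace.counts) - minutes) % MINUTES_PER_DAY:
        pass  # non-day-multiple trims are allowed; the day window check guards use
    return replace(trace, counts=trace.counts[minutes:].copy())


@dataclass
class SleepSummary:
    """Group daytime-sleep means +/- SEM and their difference (minutes)."""

    gh_sleep: list[float]
    sh_sleep: list[float]

    def __post_init__(self) -> None:
        if not self.gh_sleep or not self.sh_sleep:
            raise SleepDataError("both housing groups must be non-empty")
        for v in (*self.gh_sleep, *self.sh_sleep):
            if not 0 <= v <= DAY_MINUTES:
                raise SleepDataError(f"daytime sleep {v} outside [0, {DAY_MINUTES}]")

    @property
    def gh_mean(self) -> float:
        return float(np.mean(self.gh_sleep))

    @property
    def sh_mean(self) -> float:
        return float(np.mean(self.sh_sleep))

    @property
    def gh_sem(self) -> float:
        return _sem(self.gh_sleep)

    @property
    def sh_sem(self) -> float:
        return _sem(self.sh_sleep)

    @property
    def delta_sleep(self) -> float:
        return self.gh_mean - self.sh_mean

    @property
    def delta_sem(self) -> float:
        return float(np.hypot(self.gh_sem, self.sh_sem))


def _sem(values: Sequence[float]) -> float:
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        return float("nan")
    return float(v.std(ddof=1) / np.sqrt(len(v)))


def delta_sleep(gh_sleep: Sequence[float], sh_sleep: Sequence[float]) -> SleepSummary:
    """Group means, SEMs and delta-sleep = mean(GH) - mean(SH)."""
    return SleepSummary(gh_sleep=list(map(float, gh_sleep)),
                        sh_sleep=list(map(float, sh_sleep)))


@dataclass
class InteractionAnova:
    """Type III ANOVA table plus the fitted model."""

    table: pd.DataFrame  # index: terms; columns: sum_sq, df, F, PR(>F)
    formula: str
    n_obs: int

    def p(self, term: str) -> float:
        return float(self.table.loc[term, "PR(>F)"])

    @property
    def interaction_term(self) -> str:
        cand = [t for t in self.table.index if ":" in t]
        if not cand:
            raise SleepDataError("no interaction term in the model")
        return cand[0]

    @property
    def interaction_p(self) -> float:
        return self.p(self.interaction_term)


def interaction_anova(
    data: pd.DataFrame,
    response: str = "daytime_sleep",
    factors: Sequence[str] = ("genotype", "housing"),
    typ: int = 3,
) -> InteractionAnova:
    """Factorial ANOVA with full interaction, Type III sums of squares.

    Uses sum-to-zero contrasts so Type III SS are well defined; every
    design cell must hold >= 2 replicates (an empty cell is rejected by
    name). On balanced designs the decomposition equals the classical
    (Type I) two-way ANOVA.
    """
    factors = list(factors)
    if len(factors) < 2:
        raise SleepDataError("need at least two crossed factors")
    for col in (response, *factors):
        if col not in data.columns:
            raise SleepDataError(f"column {col!r} missing from data")
    cell_sizes = data.groupby(factors, observed=True).size()
    levels = [sorted(data[f].unique()) for f in factors]
    full_index = pd.MultiIndex.from_product(levels, names=factors)
    cell_sizes = cell_sizes.reindex(full_index, fill_value=0)
    bad = cell_sizes[cell_sizes < 2]
    if len(bad):
        cell = dict(zip(factors, np.atleast_1d(bad.index[0])))
        raise SleepDataError(
            f"design cell {cell} has {int(bad.iloc[0])} replicates (need >= 2)"
        )
    terms = " * ".join(f"C({f}, Sum)" for f in factors)
    formula = f"{response} ~ {terms}"
    fit = smf.ols(formula, data=data).fit()
    table = sm.stats.anova_lm(fit, typ=typ)
    return InteractionAnova(table=table, formula=formula, n_obs=int(fit.nobs))


# ---------------------------------------------------------------------------
# Trikinetics-style monitor files
# ---------------------------------------------------------------------------

N_CHANNELS = 32
_META_COLS = 10  # reading index, date, time, status, then six unused fields


def write_monitor(counts: np.ndarray, path: str | Path, start_minute: int = 0) -> None:
    """Write a minutes x 32 count matrix in DAM-style TSV.

    Ten metadata columns (index, date, HH:MM:SS time, status flag, six
    zeros) followed by one count column per channel.
    """
    counts = np.asarray(counts, dtype=int)
    if counts.ndim != 2 or counts.shape[1] != N_CHANNELS:
        raise SleepDataError(f"counts must be minutes x {N_CHANNELS}")
    with open(path, "w") as fh:
        for i, row in enumerate(counts):
            minute = start_minute + i
            hh, mm = (minute // 60) % 24, minute % 60
            meta = [str(i + 1), "1 Jan 00", f"{hh:02d}:{mm:02d}:00", "1"] + ["0"] * 6
            fh.write("\t".join(meta + [str(int(c)) for c in row]) + "\n")


def read_monitor(path: str | Path) -> pd.DataFrame:
    """Read a DAM-style monitor TSV into a minutes x 32 count table."""
    df = pd.read_csv(path, sep="\t", header=None)
    if df.shape[1] != _META_COLS + N_CHANNELS:
        raise SleepDataError(
            f"{path}: expected {_META_COLS + N_CHANNELS} columns, got {df.shape[1]}"
        )
    counts = df.iloc[:, _META_COLS:].to_numpy(dtype=int)
    status = df.iloc[:, 3].to_numpy()
    if (status != 1).any():
        raise SleepDataError(f"{path}: monitor reports an error status; trace rejected")
    idx = df.iloc[:, 0].to_numpy(dtype=int)
    if not np.array_equal(idx, np.arange(idx[0], idx[0] + len(idx))):
        raise SleepDataError(f"{path}: gap in monitor readings; traces rejected")
    return pd.DataFrame(counts, columns=[f"ch{c + 1}" for c in range(N_CHANNELS)])


def read_channel_metadata(path: str | Path) -> pd.DataFrame:
    """CSV mapping channel -> fly id, genotype, housing."""
    meta = pd.read_csv(path)
    required = {"channel", "fly_id", "genotype", "housing"}
    if not required <= set(meta.columns):
        raise SleepDataError(f"{path}: metadata needs columns {sorted(required)}")
    return meta


def assemble_traces(
    counts: pd.DataFrame, metadata: pd.DataFrame, lights_on_index: int = 0
) -> list[ActivityTrace]:
    traces = []
    for row in metadata.itertuples(index=False):
        col = f"ch{int(row.channel)}"
        if col not in counts.columns:
            raise SleepDataError(f"channel {row.channel} not present in monitor file")
        traces.append(
            ActivityTrace(
                fly_id=str(row.fly_id), genotype=str(row.genotype),
                housing=str(row.housing),
                counts=counts[col].to_numpy(dtype=int),
                lights_on_index=lights_on_index,
            )
        )
    return traces


def sleep_table(traces: Sequence[ActivityTrace], day: int = 0) -> pd.DataFrame:
    """Per-fly daytime sleep with genotype/housing factors."""
    rows = []
    for t in traces:
        rows.append(
            {
                "fly_id": t.fly_id, "genotype": t.genotype, "housing": t.housing,
                "daytime_sleep": daytime_sleep(t, day=day),
            }
        )
    return pd.DataFrame(rows)
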