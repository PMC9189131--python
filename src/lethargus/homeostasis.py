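"""Sleep-homeostasis quantification.

Sleep during lethargus is homeostatically regulated: the duration of a
sleep bout increases with the duration of the immediately preceding
motion bout.  This module pairs each sleep bout with its prior motion
bout, regresses sleep duration on prior motion duration, compares sleep
durations binned by prior motion duration (across genotypes when
labels are present), and summarizes lethargus architecture (bout
durations, transition counts, quiescence in vs out of lethargus).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bout_segmentation import MOTION, SLEEP, BoutSeries, QuiescenceSeries
from .errors import AnalysisError
from .event_analysis import RegressionSummary, linear_fit


@dataclass(frozen=True)
class HomeostasisPair:
    """One sleep bout paired with its immediately preceding motion bout."""

    prior_motion_s: float
    sleep_s: float
    animal: Optional[str] = None
    genotype: Optional[str] = None


@dataclass(frozen=True)
class ArchitectureSummary:
    """Summary statistics of the sleep architecture within lethargus."""

    mean_motion_duration_s: float
    mean_sleep_duration_s: float
    lethargus_length_s: float
    transition_count: int
    quiescence_in: float
    quiescence_out: float
    whole_recording: bool = False  # True when no lethargus was detected


@dataclass(frozen=True)
class BinnedHomeostasisResult:
    """Sleep durations grouped by prior-motion-duration bin."""

    table: pd.DataFrame = field(repr=False)  # pair table with bin labels
    bin_edges: np.ndarray = field(repr=False)
    bin_means: pd.Series = field(repr=False)
    across_bin_p: dict = field(repr=False)  # per genotype
    interaction_p: float = math.nan  # genotype x bin, two-way ANOVA
    pairwise: pd.DataFrame = field(repr=False, default=None)  # Sidak-corrected
    empty_bins: tuple = ()


def pair_sleep_with_prior_motion(
    series: BoutSeries,
    animal: Optional[str] = None,
    genotype: Optional[str] = None,
    exclude_edges: bool = True,
) -> list[HomeostasisPair]:
    """Pair every eligible sleep bout with its preceding motion bout.

    A sleep bout yields a pair when a motion bout immediately precedes it;
    with ``exclude_edges`` pairs involving a bout that touches the start
    or end of the recording are dropped (edge bouts are truncated, so
    their durations are not trustworthy).
    """
    pairs = []
    for prev, cur in zip(series.bouts[:-1], series.bouts[1:]):
        if prev.kind != MOTION or cur.kind != SLEEP:
            continue
        if exclude_edges and (prev.at_edge or cur.at_edge):
            continue
        pairs.append(
            HomeostasisPair(
                prior_motion_s=prev.duration,
                sleep_s=cur.duration,
                animal=animal,
                genotype=genotype,
            )
        )
    if not pairs:
        raise AnalysisError("no motion->sleep pairs in the series")
    return pairs


def pairs_to_frame(pairs: Sequence[HomeostasisPair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "animal": [p.animal for p in pairs],
            "genotype": [p.genotype for p in pairs],
            "prior_motion_s": [p.prior_motion_s for p in pairs],
            "sleep_s": [p.sleep_s for p in pairs],
        }
    )


def homeostasis_regression(pairs: Sequence[HomeostasisPair]) -> RegressionSummary:
    """OLS of sleep duration on prior motion duration (the homeostatic gain)."""
    if len(pairs) < 3:
        raise AnalysisError("need at least 3 pairs for a regression")
    x = [p.prior_motion_s for p in pairs]
    y = [p.sleep_s for p in pairs]
    return linear_fit(x, y)


def binned_homeostasis_test(
    pairs: Sequence[HomeostasisPair],
    bin_edges: Optional[Sequence[float]] = None,
) -> BinnedHomeostasisResult:
    """Compare sleep-bout durations across prior-motion-duration bins.

    With no ``bin_edges``, pairs are split into two bins at the pooled
    median of prior motion durations (values equal to the median fall in
    the upper bin).  Within each genotype, an across-bin one-way ANOVA
    p-value is reported (equivalent to a two-sample t test for two bins);
    with two or more genotypes, the genotype x bin interaction from a
    two-way ANOVA and Sidak-corrected pairwise between-genotype contrasts
    per bin are added.  Empty bins are reported and excluded.
    """
    df = pairs_to_frame(pairs)
    if bin_edges is None:
        bin_edges = [float(df["prior_motion_s"].median())]
    edges = np.asarray(sorted(bin_edges), dtype=float)
    df = df.assign(bin=np.digitize(df["prior_motion_s"], edges))

    n_bins = edges.size + 1
    counts = df["bin"].value_counts()
    empty = tuple(b for b in range(n_bins) if counts.get(b, 0) == 0)
    df = df[~df["bin"].isin(empty)]
    if df["bin"].nunique() < 2:
        raise AnalysisError("need at least 2 non-empty bins")

    genotypes = [g for g in df["genotype"].unique()]
    across = {}
    for g in genotypes:
        sub = df if g is None else df[df["genotype"] == g]
        groups = [grp["sleep_s"].to_numpy() for _, grp in sub.groupby("bin")]
        if len(groups) < 2 or any(len(v) < 2 for v in groups):
            across[g] = math.nan
        elif np.ptp(np.concatenate(groups)) == 0:
            across[g] = 1.0  # identical constant durations in every bin
        else:
            across[g] = float(stats.f_oneway(*groups).pvalue)

    interaction_p = math.nan
    pairwise = None
    if len([g for g in genotypes if g is not None]) >= 2:
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        model = ols("sleep_s ~ C(genotype) * C(bin)", data=df).fit()
        table = sm.stats.anova_lm(model, typ=2)
        interaction_p = float(table.loc["C(genotype):C(bin)", "PR(>F)"])

        rows = []
        contrasts = []
        for b, grp in df.groupby("bin"):
            gs = grp["genotype"].unique()
            for i in range(len(gs)):
                for j in range(i + 1, len(gs)):
                    a = grp.loc[grp["genotype"] == gs[i], "sleep_s"]
                    c = grp.loc[grp["genotype"] == gs[j], "sleep_s"]
                    if len(a) >= 2 and len(c) >= 2:
                        p = float(stats.ttest_ind(a, c).pvalue)
                        contrasts.append((b, gs[i], gs[j], p))
        m = len(contrasts)
        for b, g1, g2, p in contrasts:
            rows.append(
                {
                    "bin": b,
                    "genotype_1": g1,
                    "genotype_2": g2,
                    "p_raw": p,
                    # Sidak 1-(1-p)^m, computed stably for tiny p
                    "p_sidak": float(-np.expm1(m * np.log1p(-min(p, 1.0 - 1e-16)))),
                }
            )
        pairwise = pd.DataFrame(rows)

    return BinnedHomeostasisResult(
        table=df,
        bin_edges=edges,
        bin_means=df.groupby("bin")["sleep_s"].mean(),
        across_bin_p=across,
        interaction_p=interaction_p,
        pairwise=pairwise,
        empty_bins=empty,
    )


def summarize_architecture(
    series: BoutSeries,
    lethargus: Optional[tuple],
    q: QuiescenceSeries,
) -> ArchitectureSummary:
    """Summarize bout durations, transitions, and quiescence in lethargus.

    Bout-duration means use bouts fully contained in the lethargus
    interval; the transition count is the number of bout boundaries
    strictly inside it.  Quiescence fractions average the windows whose
    start lies inside vs outside the interval.  When no lethargus was
    detected the summary covers the whole recording and is flagged.
    """
    if lethargus is None:
        start, end = 0.0, series.total_duration
        whole = True
    else:
        start, end = lethargus
        if not (0.0 <= start < end <= series.total_duration + 1e-9):
            raise ValueError("lethargus interval must lie within the recording")
        whole = False

    inside = [b for b in series if b.start >= start and b.end <= end]
    motion = [b.duration for b in inside if b.kind == MOTION]
    sleep = [b.duration for b in inside if b.kind == SLEEP]
    boundaries = [b.start for b in series.bouts[1:]]
    transitions = sum(1 for t in boundaries if start < t < end)

    win_start = np.asarray(q.window_starts)
    in_mask = (win_start >= start) & (win_start < end)
    q_in = float(np.mean(q.fraction[in_mask])) if in_mask.any() else math.nan
    q_out = float(np.mean(q.fraction[~in_mask])) if (~in_mask).any() else math.nan

    return ArchitectureSummary(
        mean_motion_duration_s=float(np.mean(motion)) if motion else math.nan,
        mean_sleep_duration_s=float(np.mean(sleep)) if sleep else math.nan,
        lethargus_length_s=end - start,
        transition_count=transitions,
        quiescence_in=q_in,
        quiescence_out=q_out,
        whole_recording=whole,
    )
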