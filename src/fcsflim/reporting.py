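"""Population statistics in the study's reporting conventions.

Distributions are summarised as mean with a 2xSEM box (95.4% confidence for
a normal sampling distribution) and whiskers spanning the central 80% of the
population (10th-90th percentiles, linear interpolation); pairwise group
comparisons use the two-sided Mann-Whitney rank test with mid-rank tie
handling, exact by enumeration for small samples and a tie- and
continuity-corrected normal approximation otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy.stats import rankdata, norm

EXACT_CUTOFF = 12  # n1 + n2 at or below which the exact enumeration runs


@dataclass
class PopulationSummary:
    mean: float
    sem: float
    box: tuple[float, float]  # mean -/+ 2 SEM
    whiskers: tuple[float, float]  # P10, P90
    n: int


@dataclass
class TestResult:
    u: float
    p_value: float
    method: str  # "exact" | "normal-approx"
    n1: int
    n2: int


def summarize_population(values) -> PopulationSummary:
    """Mean, SEM (sample sd, n-1), 2xSEM box and P10/P90 whiskers."""
    v = np.asarray(list(values), dtype=float)
    if v.size < 2:
        raise ValueError("SEM undefined for n < 2")
    mean = float(v.mean())
    sem = float(v.std(ddof=1) / np.sqrt(v.size))
    p10, p90 = np.percentile(v, [10, 90], method="linear")
    return PopulationSummary(mean=mean, sem=sem,
                             box=(mean - 2 * sem, mean + 2 * sem),
                             whiskers=(float(p10), float(p90)), n=int(v.size))


def _u_statistic(ranks: np.ndarray, idx_a: np.ndarray, n1: int) -> float:
    return float(ranks[idx_a].sum() - n1 * (n1 + 1) / 2.0)


def mann_whitney(a, b) -> TestResult:
    """Two-sided Mann-Whitney rank test with mid-rank ties.

    Exact two-sided p by full enumeration of the ``C(n1+n2, n1)`` label
    assignments when ``n1 + n2 <= 12`` (p is the probability of a U at
    least as far from its null mean n1*n2/2 as the observed one); otherwise
    the normal approximation with tie correction and a continuity
    correction of 1/2 toward the mean.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    n1, n2 = a.size, b.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)  # mid-ranks
    u_obs = _u_statistic(ranks, np.arange(n1), n1)
    mu = n1 * n2 / 2.0
    n = n1 + n2

    if n <= EXACT_CUTOFF:
        dev = abs(u_obs - mu) - 1e-9
        hits = 0
        for idx in combinations(range(n), n1):
            if abs(_u_statistic(ranks, np.asarray(idx), n1) - mu) >= dev:
                hits += 1
        p = hits / comb(n, n1)
        return TestResult(u=u_obs, p_value=p, method="exact", n1=n1, n2=n2)

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return TestResult(u=u_obs, p_value=1.0, method="normal-approx", n1=n1, n2=n2)
    shift = 0.5 if u_obs > mu else (-0.5 if u_obs < mu else 0.0)
    z = (u_obs - mu - shift) / np.sqrt(var)
    p = min(1.0, 2.0 * norm.sf(abs(z)))
    return TestResult(u=u_obs, p_value=p, method="normal-approx", n1=n1, n2=n2)


def plot_population(groups: dict, path) -> None:
    """Box (2xSEM) and whisker (P10-P90) summary figure of named groups."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.2 + 0.9 * len(groups), 3.2))
    for i, (name, values) in enumerate(groups.items()):
        s = summarize_population(values)
        ax.scatter(np.full(s.n, i), list(values), s=8, color="0.6", zorder=1)
        ax.add_patch(plt.Rectangle((i - 0.22, s.box[0]), 0.44, s.box[1] - s.box[0],
                                   fill=False, edgecolor="k", zorder=3))
        ax.hlines(s.mean, i - 0.22, i + 0.22, color="k", zorder=3)
        ax.vlines(i, s.whiskers[0], s.whiskers[1], color="k", lw=0.8, zorder=2)
    ax.set_xticks(range(len(groups)), list(groups))
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
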