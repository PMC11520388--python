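"""Nonparametric statistics relating gene usage, locus zone, and RSS quality.

Group comparisons use the Kruskal-Wallis H test (tie-corrected, chi-square
p-value on k-1 df) and the Mann-Whitney U test (exact p by enumeration for
small tie-free samples, normal approximation with continuity correction
otherwise).  Rank correlation is Spearman's rho with a seeded permutation
p-value at small n.  Per-zone comparisons treat each gene as one
observation, its frequency averaged over samples.

Significance stars follow the convention * p<0.05, ** p<0.01, *** p<0.001;
p-values are reported raw (no multiple-testing correction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .clonotypes import UsageProfile
from .locus import ZoneAssignment
from .ric import VERY_LOW_THRESHOLD, classify_rss

Alternative = Literal["two_sided", "less", "greater"]

ZONE_LETTER = {"distal": "D", "middle": "M", "proximal": "P"}


class StatsError(ValueError):
    """Invalid statistical input (empty group, constant vector, ...)."""


@dataclass(frozen=True)
class GroupTestResult:
    statistic: float
    p_value: float
    n_per_group: tuple[int, ...]
    test: str
    stars: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "stars", significance_stars(self.p_value))


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def kruskal_wallis(*groups: Sequence[float]) -> GroupTestResult:
    """Tie-corrected Kruskal-Wallis H with chi-square (k-1 df) p-value."""
    if len(groups) < 2:
        raise StatsError("Kruskal-Wallis needs at least two groups")
    if any(len(g) == 0 for g in groups):
        raise StatsError("Kruskal-Wallis groups must be non-empty")
    if sum(len(g) for g in groups) < 3:
        raise StatsError("Kruskal-Wallis needs total n >= 3")
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(flat == flat[0]):
        # no variation at all: H = 0 after tie correction, p = 1
        return GroupTestResult(0.0, 1.0, tuple(len(g) for g in groups), "kruskal_wallis")
    h, p = sps.kruskal(*groups)
    return GroupTestResult(float(h), float(p), tuple(len(g) for g in groups), "kruskal_wallis")


def mann_whitney(
    a: Sequence[float], b: Sequence[float], alternative: Alternative = "two_sided"
) -> GroupTestResult:
    """Mann-Whitney U (U of the first sample).

    Exact p by full enumeration of rank assignments when n1+n2 <= 12 and
    the pooled sample is tie-free; otherwise the normal approximation with
    tie correction and continuity correction.
    """
    if len(a) == 0 or len(b) == 0:
        raise StatsError("Mann-Whitney samples must be non-empty")
    alt = {"two_sided": "two-sided", "less": "less", "greater": "greater"}[alternative]
    pooled = list(a) + list(b)
    tie_free = len(set(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= 12 and tie_free) else "asymptotic"
    u, p = sps.mannwhitneyu(a, b, alternative=alt, method=method, use_continuity=True)
    return GroupTestResult(float(u), float(p), (len(a), len(b)), f"mann_whitney_{method}")


def rank_correlation(
    x: Sequence[float],
    y: Sequence[float],
    n_permutations: int = 10_000,
    seed: int = 0,
    method: Literal["spearman", "pearson"] = "spearman",
) -> tuple[float, float]:
    """Rank (Spearman) correlation with a seeded permutation p at n < 30.

    For n >= 30 the t-approximation p-value is used.  Constant input is an
    error (the correlation is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise StatsError("x and y must have equal length")
    if len(x) < 3:
        raise StatsError("rank correlation needs n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise StatsError("correlation is undefined for a constant vector")
    if method == "pearson":
        rho, p = sps.pearsonr(x, y)
        return float(rho), float(p)
    rho, p_t = sps.spearmanr(x, y)
    if len(x) >= 30:
        return float(rho), float(p_t)
    rng = np.random.default_rng(seed)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    norm = np.linalg.norm(rxc) * np.linalg.norm(ryc)
    obs = abs(float(rxc @ ryc) / norm)
    perms = np.argsort(rng.random((n_permutations, len(ry))), axis=1)
    perm_r = (ry[perms] - ry.mean()) @ rxc / norm
    hits = int((np.abs(perm_r) >= obs - 1e-12).sum())
    return float(rho), (hits + 1) / (n_permutations + 1)


# ---------------------------------------------------------------------------
# Zone-level bias summaries


@dataclass
class BiasSummary:
    """Per-zone frequency/RIC means, orderings, and tests for one analysis.

    Orderings are 3-letter strings over {D, M, P} like "P>D>M", listing
    zones by decreasing per-zone mean.
    """

    analysis: str
    segment: str
    zone_mean_frequency: dict[str, float]
    zone_mean_ric: dict[str, float]
    frequency_ordering: str
    ric_ordering: str
    kruskal: GroupTestResult | None
    pairwise: dict[str, GroupTestResult]
    correlation_rho: float | None
    correlation_p: float | None
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        def _test(t: GroupTestResult | None):
            if t is None:
                return None
            return {
                "test": t.test,
                "statistic": t.statistic,
                "p_value": t.p_value,
                "n_per_group": list(t.n_per_group),
                "stars": t.stars,
            }

        return {
            "analysis": self.analysis,
            "segment": self.segment,
            "zone_mean_frequency": self.zone_mean_frequency,
            "zone_mean_ric": self.zone_mean_ric,
            "frequency_ordering": self.frequency_ordering,
            "ric_ordering": self.ric_ordering,
            "kruskal": _test(self.kruskal),
            "pairwise": {k: _test(v) for k, v in self.pairwise.items()},
            "correlation_rho": self.correlation_rho,
            "correlation_p": self.correlation_p,
            "flags": self.flags,
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for zone in ("distal", "middle", "proximal"):
            if zone in self.zone_mean_frequency:
                rows.append(
                    {
                        "analysis": self.analysis,
                        "segment": self.segment,
                        "zone": zone,
                        "mean_frequency": self.zone_mean_frequency[zone],
                        "mean_ric": self.zone_mean_ric.get(zone, float("nan")),
                        "frequency_ordering": self.frequency_ordering,
                        "ric_ordering": self.ric_ordering,
                    }
                )
        return pd.DataFrame(rows)


def _ordering(means: Mapping[str, float]) -> str:
    ranked = sorted(means, key=lambda z: (-means[z], z))
    return ">".join(ZONE_LETTER[z] for z in ranked)


def zone_bias_report(
    usage: UsageProfile,
    zones: ZoneAssignment,
    scores: Mapping[str, float],
    segment: str = "V",
    correlation_seed: int = 0,
) -> BiasSummary:
    """Summarize frequency and RIC by zone for one D-cluster analysis.

    Each zoned gene contributes one observation: its usage frequency
    averaged over samples (0 if unused) and its RIC score.  Reports
    per-zone means, decreasing orderings, Kruskal-Wallis across zones,
    pairwise Mann-Whitney tests, and the Spearman correlation between RIC
    and frequency over the full zoned gene set.
    """
    genes = sorted(zones.zones)
    missing = [g for g in genes if g not in scores]
    if missing:
        raise StatsError(f"no RIC score for zoned gene(s) {missing}")
    mean_freq = usage.mean_frequencies(segment, genes=genes)
    flags = list(zones.flags)
    by_zone_freq: dict[str, list[float]] = {}
    by_zone_ric: dict[str, list[float]] = {}
    for g in genes:
        z = zones.zones[g]
        by_zone_freq.setdefault(z, []).append(mean_freq[g])
        by_zone_ric.setdefault(z, []).append(float(scores[g]))
    present = [z for z in ("distal", "middle", "proximal") if z in by_zone_freq]
    if len(present) < 3:
        flags.append(f"only zones {present} populated")
    zone_mean_frequency = {z: float(np.mean(by_zone_freq[z])) for z in present}
    zone_mean_ric = {z: float(np.mean(by_zone_ric[z])) for z in present}

    kw = None
    if len(present) >= 2:
        kw = kruskal_wallis(*[by_zone_freq[z] for z in present])
        if kw.p_value >= 0.05:
            flags.append("zone frequency ordering not significant (KW p >= 0.05)")
    pairwise: dict[str, GroupTestResult] = {}
    for i in range(len(present)):
        for j in range(i + 1, len(present)):
            a, b = present[i], present[j]
            key = f"{ZONE_LETTER[a]}-vs-{ZONE_LETTER[b]}"
            pairwise[key] = mann_whitney(by_zone_freq[a], by_zone_freq[b])

    rho = p = None
    freqs = [mean_freq[g] for g in genes]
    rics = [float(scores[g]) for g in genes]
    try:
        rho, p = rank_correlation(rics, freqs, seed=correlation_seed)
    except StatsError:
        flags.append("RIC-frequency correlation undefined (constant input)")

    return BiasSummary(
        analysis=zones.analysis,
        segment=segment,
        zone_mean_frequency=zone_mean_frequency,
        zone_mean_ric=zone_mean_ric,
        frequency_ordering=_ordering(zone_mean_frequency),
        ric_ordering=_ordering(zone_mean_ric),
        kruskal=kw,
        pairwise=pairwise,
        correlation_rho=rho,
        correlation_p=p,
        flags=flags,
    )


@dataclass
class LowRICResult:
    """Effect of very-low RSS quality on usage frequency."""

    testable: bool
    test: GroupTestResult | None
    mean_frequency_very_low: float | None
    mean_frequency_normal: float | None
    n_very_low: int
    n_normal: int

    def to_dict(self) -> dict:
        return {
            "testable": self.testable,
            "p_value": self.test.p_value if self.test else None,
            "statistic": self.test.statistic if self.test else None,
            "mean_frequency_very_low": self.mean_frequency_very_low,
            "mean_frequency_normal": self.mean_frequency_normal,
            "n_very_low": self.n_very_low,
            "n_normal": self.n_normal,
        }


def low_ric_effect(
    usage: UsageProfile,
    scores: Mapping[str, float],
    threshold: float = VERY_LOW_THRESHOLD,
    segment: str = "V",
) -> LowRICResult:
    """Test whether very-low-RIC genes are used less than normal-RIC genes.

    One-sided Mann-Whitney ("less": very-low frequencies shifted below
    normal) on per-gene, sample-averaged frequencies.  Not testable when
    either side of the threshold is empty.
    """
    genes = sorted(scores)
    mean_freq = usage.mean_frequencies(segment, genes=genes)
    low = [mean_freq[g] for g in genes if classify_rss(scores[g], threshold) == "very_low"]
    normal = [mean_freq[g] for g in genes if classify_rss(scores[g], threshold) == "normal"]
    if not low or not normal:
        return LowRICResult(False, None, None, None, len(low), len(normal))
    test = mann_whitney(low, normal, alternative="less")
    return LowRICResult(
        testable=True,
        test=test,
        mean_frequency_very_low=float(np.mean(low)),
        mean_frequency_normal=float(np.mean(normal)),
        n_very_low=len(low),
        n_normal=len(normal),
    )
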