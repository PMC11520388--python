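import math
from itertools import combinations

import numpy as np
import pytest

from vdjbias.locus import GeneRecord, LocusModel


def human_like_locus() -> LocusModel:
    """A miniature human-style TRB locus: 9 functional V genes in three
    blocks, one pseudogene V, two D-J-C clusters with 6 + 7 J genes."""
    genes = [
        GeneRecord("TRBV1", "V", "F", 0),
        GeneRecord("TRBV2", "V", "F", 5_000),
        GeneRecord("TRBV3", "V", "F", 10_000),
        GeneRecord("TRBV4P", "V", "P", 12_000),
        GeneRecord("TRBV5", "V", "F", 210_000),
        GeneRecord("TRBV6", "V", "F", 215_000),
        GeneRecord("TRBV7", "V", "F", 220_000),
        GeneRecord("TRBV28", "V", "F", 420_000),
        GeneRecord("TRBV29", "V", "F", 425_000),
        GeneRecord("TRBV30", "V", "F", 430_000),
        GeneRecord("TRBD1", "D", "F", 530_000, cluster_id=1),
    ]
    pos = 530_700
    for i in range(1, 7):
        genes.append(GeneRecord(f"TRBJ1-{i}", "J", "F", pos, cluster_id=1))
        pos += 600
    genes.append(GeneRecord("TRBC1", "C", "F", pos, cluster_id=1))
    genes.append(GeneRecord("TRBD2", "D", "F", pos + 3_000, cluster_id=2))
    pos += 3_700
    for i in range(1, 8):
        genes.append(GeneRecord(f"TRBJ2-{i}", "J", "F", pos, cluster_id=2))
        pos += 600
    genes.append(GeneRecord("TRBC2", "C", "F", pos, cluster_id=2))
    return LocusModel(species="human-like", genes=genes)


@pytest.fixture
def locus() -> LocusModel:
    return human_like_locus()


# ---------------------------------------------------------------------------
# Independent oracles (coded from first principles, no vdjbias internals)


def brute_force_ric(training_seqs, groups, pseudocount, query):
    """Explicit count -> probability -> sum-of-logs RIC recomputation."""
    n = len(training_seqs)
    total = 0.0
    for group in groups:
        tup = "".join(query[p - 1] for p in group)
        count = sum(
            1 for s in training_seqs if "".join(s[p - 1] for p in group) == tup
        )
        p = (count + pseudocount) / (n + pseudocount * 4 ** len(group))
        if p == 0.0:
            return -math.inf
        total += math.log(p)
    return total


def ranks(values):
    """Tie-averaged ranks (1-based)."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    out = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            out[order[k]] = avg
        i = j + 1
    return out


def enumerate_mwu(a, b, alternative="two_sided"):
    """Exact Mann-Whitney p by enumerating all rank assignments (tie-free)."""
    n1, n2 = len(a), len(b)
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free input"
    rank_of = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(rank_of[v] for v in a) - n1 * (n1 + 1) / 2
    us = []
    all_ranks = list(range(1, n1 + n2 + 1))
    for combo in combinations(all_ranks, n1):
        us.append(sum(combo) - n1 * (n1 + 1) / 2)
    us = np.array(us)
    if alternative == "less":
        p = np.mean(us <= u_obs)
    elif alternative == "greater":
        p = np.mean(us >= u_obs)
    else:
        lo, hi = min(u_obs, n1 * n2 - u_obs), max(u_obs, n1 * n2 - u_obs)
        p = np.mean((us <= lo) | (us >= hi))
    return float(u_obs), float(p)


def kw_h_formula(groups):
    """Tie-corrected Kruskal-Wallis H from the rank-sum formula."""
    flat = [v for g in groups for v in g]
    n = len(flat)
    r = ranks(flat)
    h = 0.0
    i = 0
    for g in groups:
        rsum = sum(r[i : i + len(g)])
        h += rsum**2 / len(g)
        i += len(g)
    h = 12 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    from collections import Counter

    ties = Counter(flat)
    correction = 1 - sum(t**3 - t for t in ties.values()) / (n**3 - n)
    return h / correction if correction > 0 else 0.0
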