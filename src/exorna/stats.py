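"""Enrichment and validation statistics.

* EASE-score Fisher test: the one-sided hypergeometric upper tail with
  one gene removed from the list-hit cell (a deliberately conservative
  variant of Fisher's exact test used for category enrichment), with
  Benjamini-Hochberg correction across tested categories.
* Wilcoxon rank-sum comparison of two expression distributions, with an
  exact small-sample branch and a tie/continuity-corrected normal
  approximation otherwise.
* Relative qPCR quantification as 2^-ddCt against a calibrator sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps


# ---------------------------------------------------------------------------
# EASE-score Fisher test


def ease_fisher(k: int, n: int, K: int, N: int) -> float:
    """EASE-adjusted one-sided Fisher p for a 2x2 enrichment table.

    ``k`` list hits, ``n`` list size, ``K`` background hits, ``N``
    universe size. The list-hit count is reduced by one before taking the
    hypergeometric upper tail: p = P(X >= k-1), X ~ Hypergeom(N, K, n).
    k <= 1 gives p = 1 by construction.
    """
    if not (0 <= k <= min(n, K) and 0 <= n <= N and 0 <= K <= N):
        raise ValueError(f"inconsistent table k={k} n={n} K={K} N={N}")
    return float(ease_fisher_many([k], [n], [K], [N])[0])


def ease_fisher_many(k, n, K, N) -> np.ndarray:
    """Vectorized :func:`ease_fisher` over parallel arrays."""
    k = np.asarray(k, dtype=int)
    n = np.asarray(n, dtype=int)
    K = np.asarray(K, dtype=int)
    N = np.asarray(N, dtype=int)
    ka = np.maximum(k - 1, 0)
    p = np.ones(np.broadcast(k, n, K, N).shape, dtype=float)
    mask = ka >= 1
    if mask.any():
        # sf(ka - 1) = P(X >= ka)
        p[mask] = sps.hypergeom.sf(ka[mask] - 1, N[mask], K[mask], n[mask])
    return p


def fisher_exact_onesided(k: int, n: int, K: int, N: int) -> float:
    """Ordinary one-sided Fisher p = P(X >= k) for the same table."""
    if not (0 <= k <= min(n, K) and 0 <= n <= N and 0 <= K <= N):
        raise ValueError(f"inconsistent table k={k} n={n} K={K} N={N}")
    if k == 0:
        return 1.0
    return float(sps.hypergeom.sf(k - 1, N, K, n))


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Step-up FDR adjustment: q_(i) = min_{j>=i} (m p_(j) / j), clipped
    at 1, returned in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# category enrichment


@dataclass
class CategoryAnnotation:
    """Category membership over a background gene universe."""

    members: Dict[str, Set[str]]  # category id -> gene symbols
    names: Dict[str, str]  # category id -> display name
    universe: Set[str]

    def validate(self) -> None:
        if not self.universe:
            raise ValueError("empty background universe")
        for cat, genes in self.members.items():
            if not genes <= self.universe:
                raise ValueError(f"category {cat} has members outside the universe")


def read_annotation_table(path: str, universe: Set[str] | None = None) -> CategoryAnnotation:
    """TSV with columns category_id, category_name, gene; the universe
    defaults to the union of all member sets."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    members: Dict[str, Set[str]] = {}
    names: Dict[str, str] = {}
    for _, row in df.iterrows():
        members.setdefault(row["category_id"], set()).add(row["gene"])
        names[row["category_id"]] = row.get("category_name", row["category_id"])
    if universe is None:
        universe = set().union(*members.values()) if members else set()
    ann = CategoryAnnotation(members, names, universe)
    ann.validate()
    return ann


def enrich_categories(
    gene_list: Iterable[str],
    annotation: CategoryAnnotation,
    min_count: int = 5,
    ease_cutoff: float = 0.1,
    q_cutoff: float = 0.05,
) -> pd.DataFrame:
    """EASE-Fisher enrichment of ``gene_list`` against the annotation.

    Genes outside the universe are dropped with a warning. Categories with
    fewer than ``min_count`` list hits are excluded before testing; BH
    runs across the surviving categories only. The result carries the 2x2
    counts, p, q, an EASE-score pass flag (p <= ease_cutoff) and the
    significance call (q < q_cutoff).
    """
    annotation.validate()
    genes = set(gene_list)
    outside = genes - annotation.universe
    if outside:
        warnings.warn(
            f"{len(outside)} gene(s) outside the background universe dropped"
        )
        genes &= annotation.universe
    if not genes:
        return pd.DataFrame(
            columns=[
                "category_id", "category_name", "k", "n", "K", "N",
                "p", "q", "ease_pass", "significant",
            ]
        )
    n = len(genes)
    N = len(annotation.universe)
    rows = []
    for cat in sorted(annotation.members):
        K = len(annotation.members[cat])
        k = len(genes & annotation.members[cat])
        if k < min_count:
            continue
        rows.append(
            {
                "category_id": cat,
                "category_name": annotation.names.get(cat, cat),
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "p": ease_fisher(k, n, K, N),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["category_id", "category_name", "k", "n", "K", "N", "p"],
    )
    if len(df):
        df["q"] = bh_adjust(df["p"].to_numpy())
        df["ease_pass"] = df["p"] <= ease_cutoff
        df["significant"] = df["q"] < q_cutoff
        df = df.sort_values(["p", "category_id"]).reset_index(drop=True)
    else:
        df["q"] = pd.Series(dtype=float)
        df["ease_pass"] = pd.Series(dtype=bool)
        df["significant"] = pd.Series(dtype=bool)
    return df


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum


@lru_cache(maxsize=None)
def _ranksum_distribution(n_a: int, n_b: int) -> np.ndarray:
    """Exact distribution of the rank sum of sample A over all C(N, n_a)
    equally likely rank assignments (no ties). Index i is the probability
    of rank sum = min_sum + i."""
    total = n_a + n_b
    min_sum = n_a * (n_a + 1) // 2
    width = n_a * n_b + 1
    dp = np.zeros((n_a + 1, width), dtype=float)
    dp[0][0] = 1.0
    # classic Mann-Whitney recursion: f(j, u) with u = rank_sum - min_sum
    for rank in range(1, total + 1):
        for j in range(min(rank, n_a), 0, -1):
            u_shift = rank - j  # adding `rank` as the j-th smallest pick
            if u_shift == 0:
                dp[j] += dp[j - 1]
            else:
                dp[j][u_shift:] += dp[j - 1][: width - u_shift]
    dist = dp[n_a]
    return dist / dist.sum()


def rank_sum_test(
    values_a: Sequence[float], values_b: Sequence[float]
) -> Tuple[float, float]:
    """Two-sample Wilcoxon rank-sum test.

    Returns (rank-sum statistic of sample A with midranks, two-sided p).
    Exact enumeration when n_a + n_b <= 12 and there are no ties;
    otherwise a normal approximation with tie and continuity corrections.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    w = float(ranks[: a.size].sum())
    n_a, n_b = a.size, b.size
    total = n_a + n_b
    has_ties = np.unique(pooled).size < total

    if total <= 12 and not has_ties:
        dist = _ranksum_distribution(n_a, n_b)
        min_sum = n_a * (n_a + 1) // 2
        idx = int(round(w)) - min_sum
        p_low = float(dist[: idx + 1].sum())
        p_high = float(dist[idx:].sum())
        return w, min(1.0, 2.0 * min(p_low, p_high))

    mu = n_a * (total + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (total * (total - 1)))
    var = n_a * n_b / 12.0 * ((total + 1) - tie_term)
    if var <= 0:
        return w, 1.0
    z = (abs(w - mu) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    return w, float(min(1.0, 2.0 * sps.norm.sf(z)))


# ---------------------------------------------------------------------------
# qPCR relative quantification


@dataclass(frozen=True)
class QpcrRecord:
    """Ct values for one gene in one sample plus the calibrator sample.

    dCt = Ct(gene) - Ct(endogenous control); the fold change relative to
    the calibrator is 2^-(dCt_sample - dCt_calibrator).
    """

    gene: str
    sample: str
    ct_gene: float
    ct_control: float
    calibrator_ct_gene: float
    calibrator_ct_control: float

    def __post_init__(self) -> None:
        for name in ("ct_gene", "ct_control", "calibrator_ct_gene", "calibrator_ct_control"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{self.gene}/{self.sample}: {name} must be positive and finite")


def ddct_fold_change(record: QpcrRecord) -> float:
    dct_sample = record.ct_gene - record.ct_control
    dct_cal = record.calibrator_ct_gene - record.calibrator_ct_control
    return float(2.0 ** -(dct_sample - dct_cal))


def qpcr_table(records: Iterable[QpcrRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "gene": r.gene,
                "sample": r.sample,
                "ct_gene": r.ct_gene,
                "ct_control": r.ct_control,
                "ddct": (r.ct_gene - r.ct_control)
                - (r.calibrator_ct_gene - r.calibrator_ct_control),
                "fold_change": ddct_fold_change(r),
            }
        )
    return pd.DataFrame(rows)
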