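"""Gene-level RSA statistics and sensitizer/resistance hit calling.

The Redundant siRNA Activity (RSA) score asks: given where a gene's guides
land in the library-wide ranking of robust z-scores, how surprising is it
that so many of them sit so high? For a gene with n guides at ranks
r_1 < ... < r_n within a library of N guides, the score is

    P = min over i in 1..n of  P(X >= i),   X ~ Hypergeometric(N, n, r_i)

i.e. the smallest upper-tail probability that a random placement of the
gene's n guides would put at least i of them in the top r_i. It is
reported as log10 P; the minimum over cutoffs rewards consistent activity
across a gene's guides and tolerates inactive ones. Both directions are
scored: "down" ranks the most negative z first (depletion/sensitization),
"up" ranks the most positive z first (enrichment/resistance).

Hits are called with dual gates, stringent (RSA <= -4) or lenient
(RSA <= -3), combined with a quartile z-score gate: Q1 z <= -1 for
sensitizers, Q3 z >= +1 for resistance genes. All comparisons inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

DIRECTIONS = ("down", "up")

HIT_CLASSES = (
    "sensitizer_stringent",
    "sensitizer_lenient",
    "resistance_stringent",
    "resistance_lenient",
    "none",
)


@dataclass(frozen=True)
class HitThresholds:
    """Dual-gate hit-calling thresholds (log10 P and z units)."""

    rsa_stringent: float = -4.0
    rsa_lenient: float = -3.0
    q1_max: float = -1.0
    q3_min: float = 1.0

    def __post_init__(self) -> None:
        if not self.rsa_stringent <= self.rsa_lenient <= 0:
            raise ValueError("require rsa_stringent <= rsa_lenient <= 0")


def rank_guides(stats: pd.DataFrame, direction: str) -> pd.Series:
    """Dense 1..N ranks of guides by robust z in the given direction.

    ``down`` ranks the most negative z first, ``up`` the most positive.
    Ties are broken deterministically by guide_id so the RSA P values are
    reproducible.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    z = stats["z"].to_numpy(dtype=float)
    if not np.isfinite(z).all():
        raise ValueError("non-finite z-scores cannot be ranked")
    key = z if direction == "down" else -z
    ids = stats.index.to_numpy(dtype=object)
    order = np.lexsort((ids, key))
    ranks = np.empty(len(order), dtype=np.int64)
    ranks[order] = np.arange(1, len(order) + 1)
    return pd.Series(ranks, index=stats.index, name=f"rank_{direction}")


def _hypergeom_logsf(k_min, N, n, r) -> np.ndarray:
    """log P(X >= k_min) for X ~ Hypergeometric(N, n, r), vectorized.

    Natural-log upper tail summed term-by-term through gammaln; exact to
    floating precision because the sum has at most n terms (guides per
    gene are few).
    """
    k_min = np.atleast_1d(np.asarray(k_min, dtype=np.int64))
    n = np.broadcast_to(np.asarray(n, dtype=np.int64), k_min.shape)
    r = np.broadcast_to(np.asarray(r, dtype=np.int64), k_min.shape)
    k_max = np.minimum(n, r)
    width = int((k_max - k_min).max()) + 1 if k_min.size else 1
    # term matrix: k = k_min + offset, masked where k exceeds the support
    offsets = np.arange(width)
    k = k_min[:, None] + offsets[None, :]
    valid = k <= k_max[:, None]
    k = np.where(valid, k, 0)
    n2 = n[:, None]
    r2 = r[:, None]
    logpmf = (
        gammaln(n2 + 1)
        - gammaln(k + 1)
        - gammaln(n2 - k + 1)
        + gammaln(N - n2 + 1)
        - gammaln(r2 - k + 1)
        - gammaln(N - n2 - (r2 - k) + 1)
        - (gammaln(N + 1) - gammaln(r2 + 1) - gammaln(N - r2 + 1))
    )
    logpmf = np.where(valid, logpmf, -np.inf)
    out = logsumexp(logpmf, axis=1)
    return np.minimum(out, 0.0)


def rsa_logp(ranks, n: int, N: int) -> float:
    """RSA score (log10 P) for one gene.

    Parameters
    ----------
    ranks
        The gene's guide ranks within the full library ranking, distinct
        integers in 1..N.
    n
        Number of guides for the gene (must equal ``len(ranks)``).
    N
        Library size (total guides ranked).
    """
    r = np.sort(np.asarray(ranks, dtype=np.int64))
    if len(r) != n:
        raise ValueError("n must equal the number of ranks")
    if not 1 <= n <= N:
        raise ValueError("require 1 <= n <= N")
    if len(np.unique(r)) != n or r[0] < 1 or r[-1] > N:
        raise ValueError("ranks must be distinct integers in 1..N")
    i = np.arange(1, n + 1)
    logp = _hypergeom_logsf(i, N, n, r).min()
    return float(logp / np.log(10.0))


def gene_quartiles(z_values) -> tuple[float, float]:
    """(Q1, Q3) of a gene's guide z-scores.

    Linear interpolation between order statistics: quantile q of sorted
    x_1..x_m sits at position 1 + (m - 1) q.
    """
    values = np.asarray(z_values, dtype=float)
    if values.size == 0:
        raise ValueError("gene_quartiles: empty z vector")
    if not np.isfinite(values).all():
        raise ValueError("gene_quartiles: non-finite z")
    q1, q3 = np.percentile(values, [25, 75])
    return float(q1), float(q3)


def _direction_logp(stats: pd.DataFrame, direction: str) -> pd.Series:
    """Per-gene RSA log10 P for one direction, vectorized over the library."""
    ranks = rank_guides(stats, direction)
    N = len(stats)
    frame = pd.DataFrame({"gene": stats["gene"], "rank": ranks})
    frame = frame.sort_values(["gene", "rank"], kind="mergesort")
    n_per_gene = frame.groupby("gene", sort=False)["rank"].transform("size")
    i = frame.groupby("gene", sort=False).cumcount() + 1
    logsf = _hypergeom_logsf(
        i.to_numpy(), N, n_per_gene.to_numpy(), frame["rank"].to_numpy()
    )
    per_guide = pd.Series(logsf / np.log(10.0), index=frame.index)
    return per_guide.groupby(frame["gene"]).min()


def build_gene_stats(stats: pd.DataFrame, library=None) -> pd.DataFrame:
    """Aggregate per-guide z-scores into gene-level statistics.

    Requires a guide-stats table with ``gene`` and ``z`` columns (a
    GuideLibrary may be passed to supply the gene mapping instead). Both
    RSA directions are evaluated on the full library ranking.

    Returns a table indexed by gene: n_guides, q1_z, q3_z, logp_down,
    logp_up, plus Benjamini-Hochberg FDR columns (informational only;
    hit calling uses the fixed gates).
    """
    stats = stats.copy()
    if "gene" not in stats.columns:
        if library is None:
            raise ValueError("guide stats lack a gene column and no library given")
        stats["gene"] = library.guide_to_gene.reindex(stats.index)
    if stats["gene"].isna().any():
        orphans = stats.index[stats["gene"].isna()][:3].tolist()
        raise ValueError(f"guides with no gene mapping, e.g. {orphans}")
    if not np.isfinite(stats["z"].to_numpy(dtype=float)).all():
        raise ValueError("non-finite z-scores")

    grouped = stats.groupby("gene")["z"]
    genes = pd.DataFrame(
        {
            "n_guides": grouped.size(),
            "q1_z": grouped.quantile(0.25),
            "q3_z": grouped.quantile(0.75),
        }
    )
    genes["logp_down"] = _direction_logp(stats, "down")
    genes["logp_up"] = _direction_logp(stats, "up")
    for direction in DIRECTIONS:
        p = np.power(10.0, genes[f"logp_{direction}"].to_numpy())
        genes[f"fdr_{direction}"] = _benjamini_hochberg(p)
    genes["low_confidence"] = genes["n_guides"] == 1
    genes.index.name = "gene"
    return genes


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    adjusted = np.empty(m)
    adjusted[order] = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    return np.minimum(adjusted, 1.0)


def call_hits(
    genes: pd.DataFrame, thresholds: HitThresholds = HitThresholds()
) -> pd.DataFrame:
    """Fill ``hit_class`` with dual-threshold sensitizer/resistance calls.

    A gene is a stringent sensitizer when logp_down <= rsa_stringent and
    Q1 z <= q1_max, lenient when only the lenient RSA gate holds;
    resistance calls mirror this with logp_up and Q3 z >= q3_min. A gene
    passing both directions is flagged in ``both_directions`` and assigned
    the direction with the smaller log10 P.
    """
    genes = genes.copy()
    sens_gate = genes["q1_z"] <= thresholds.q1_max
    res_gate = genes["q3_z"] >= thresholds.q3_min
    sens_str = (genes["logp_down"] <= thresholds.rsa_stringent) & sens_gate
    sens_len = (genes["logp_down"] <= thresholds.rsa_lenient) & sens_gate
    res_str = (genes["logp_up"] <= thresholds.rsa_stringent) & res_gate
    res_len = (genes["logp_up"] <= thresholds.rsa_lenient) & res_gate

    both = sens_len & res_len
    prefer_down = genes["logp_down"] <= genes["logp_up"]
    keep_sens = ~both | prefer_down
    keep_res = ~both | ~prefer_down

    hit_class = np.full(len(genes), "none", dtype=object)
    hit_class[(res_len & keep_res).to_numpy()] = "resistance_lenient"
    hit_class[(res_str & keep_res).to_numpy()] = "resistance_stringent"
    hit_class[(sens_len & keep_sens).to_numpy()] = "sensitizer_lenient"
    hit_class[(sens_str & keep_sens).to_numpy()] = "sensitizer_stringent"

    genes["hit_class"] = hit_class
    genes["both_directions"] = both
    return genes


def permutation_null_hits(
    z,
    guides_per_gene: int,
    thresholds: HitThresholds = HitThresholds(),
    n_permutations: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Stringent-hit counts under random guide->gene label permutations.

    Shuffling which guides belong to which gene destroys any gene-level
    signal while keeping the library's z distribution fixed, so the
    returned per-permutation counts of stringent calls (both directions)
    estimate the null hit rate of the dual-threshold caller. Requires a
    uniform library layout (same number of guides per gene).

    Implemented with a precomputed (cutoff, rank) tail table so thousands
    of permutations cost seconds at genome scale.
    """
    z = np.asarray(z, dtype=float)
    N = len(z)
    if N % guides_per_gene:
        raise ValueError("library size not divisible by guides_per_gene")
    n_genes = N // guides_per_gene
    n = guides_per_gene

    ranks = {}
    for direction, key in (("down", z), ("up", -z)):
        order = np.argsort(key, kind="stable")
        rk = np.empty(N, dtype=np.int64)
        rk[order] = np.arange(1, N + 1)
        ranks[direction] = rk

    # tail table: log10 P(X >= i) for i = 1..n at every possible rank r
    i_grid, r_grid = np.meshgrid(
        np.arange(1, n + 1), np.arange(1, N + 1), indexing="ij"
    )
    table = (
        _hypergeom_logsf(i_grid.ravel(), N, n, r_grid.ravel()).reshape(n, N)
        / np.log(10.0)
    )

    rng = np.random.default_rng(seed)
    row_i = np.arange(n)
    hits = np.empty(n_permutations, dtype=np.int64)
    for b in range(n_permutations):
        perm = rng.permutation(N)
        zg = z[perm].reshape(n_genes, n)
        q1 = np.percentile(zg, 25, axis=1)
        q3 = np.percentile(zg, 75, axis=1)
        called = np.zeros(n_genes, dtype=bool)
        for direction, gate in (("down", q1 <= thresholds.q1_max),
                                ("up", q3 >= thresholds.q3_min)):
            rg = np.sort(ranks[direction][perm].reshape(n_genes, n), axis=1)
            logp = table[row_i[None, :], rg - 1].min(axis=1)
            called |= (logp <= thresholds.rsa_stringent) & gate
        hits[b] = int(called.sum())
    return hits


def write_gene_stats(genes: pd.DataFrame, path, sep: str = "\t") -> None:
    genes.to_csv(path, sep=sep, index_label="gene")


def read_gene_stats(path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, index_col="gene")
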