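"""Gene-set over-representation statistics.

Implements the two-sided hypergeometric test (doubling the smaller
tail), Holm's step-down multiple-testing correction (the procedure
usually labelled "Bonferroni step-down"), Cohen's kappa on binary term
membership with connected-component grouping at kappa >= 0.4,
majority-direction term labelling, and the MAPPFinder-style pathway
Z-score with one-sided cutoff 1.6449 (the 5% standard-normal critical
value).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from fabrymeta.errors import ConfigError, ValidationError
from fabrymeta.io_formats import GeneSet

logger = logging.getLogger(__name__)

#: One-sided 5% standard-normal critical value, Phi^-1(0.95).
Z_CUTOFF_DEFAULT = 1.6449

RESULT_COLUMNS = ("term_id", "N", "K", "n", "k", "p_two_sided",
                  "p_adjusted", "hit_genes", "n_up", "n_down",
                  "regulation_label")


@dataclass(frozen=True)
class EnrichmentConfig:
    """Parameters of the over-representation analysis.

    kappa_threshold is the minimum pairwise kappa for two significant
    terms to join one functional group; alpha is the adjusted-p
    significance level; z_cutoff the pathway Z-score critical value.
    """

    kappa_threshold: float = 0.4
    alpha: float = 0.05
    z_cutoff: float = Z_CUTOFF_DEFAULT
    universe_policy: str = "geneset_union"
    two_sided_policy: str = "double_min"
    z_two_sided: bool = False

    def __post_init__(self) -> None:
        if not -1.0 <= self.kappa_threshold <= 1.0:
            raise ConfigError("kappa_threshold must lie in [-1, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.z_cutoff <= 0:
            raise ConfigError("z_cutoff must be positive")
        if self.universe_policy not in ("geneset_union", "explicit_list"):
            raise ConfigError("universe_policy must be 'geneset_union' or "
                              "'explicit_list'")
        if self.two_sided_policy not in ("double_min", "min_likelihood"):
            raise ConfigError("two_sided_policy must be 'double_min' or "
                              "'min_likelihood'")


def hypergeom_two_sided(k: int, n: int, K: int, N: int,
                        policy: str = "double_min") -> float:
    """Two-sided hypergeometric p-value of an overlap of k.

    X ~ Hypergeometric(N, K, n) counts how many of the n query genes fall
    in a term of size K within a universe of N. The default two-sided
    construction doubles the smaller of P[X >= k] and P[X <= k], capped
    at 1; ``policy="min_likelihood"`` instead sums the probabilities of
    all outcomes no more likely than k.
    """
    for name, v in (("k", k), ("n", n), ("K", K), ("N", N)):
        if int(v) != v or v < 0:
            raise ValidationError(f"{name} must be a nonnegative integer")
    if K > N or n > N:
        raise ValidationError("require K <= N and n <= N")
    lo, hi = max(0, n + K - N), min(n, K)
    if not lo <= k <= hi:
        raise ValidationError(
            f"k={k} outside hypergeometric support [{lo}, {hi}]")
    dist = stats.hypergeom(N, K, n)
    if policy == "double_min":
        upper = float(dist.sf(k - 1))
        lower = float(dist.cdf(k))
        p = min(1.0, 2.0 * min(upper, lower))
    elif policy == "min_likelihood":
        support = np.arange(lo, hi + 1)
        pmf = dist.pmf(support)
        p = float(pmf[pmf <= dist.pmf(k) * (1 + 1e-10)].sum())
        p = min(1.0, p)
    else:
        raise ConfigError(f"unknown two-sided policy {policy!r}")
    return max(p, np.finfo(float).tiny)


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values, in the input order.

    Equivalent to sorting ascending, taking the running maximum of
    min(1, (m - j + 1) * p(j)), and mapping back. Adjusted values never
    fall below the raw ones and preserve their ranking.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def term_kappa(members_a, members_b, universe) -> float:
    """Cohen's kappa between two terms on binary gene membership.

    Agreement is scored over every gene of the universe (member of both
    or of neither counts as agreement); kappa = (Po - Pe) / (1 - Pe)
    with Pe the chance agreement from the marginals. When Pe = 1 (both
    marginals degenerate) the result is 1 for identical sets, else 0.
    """
    uni = frozenset(universe)
    if not uni:
        raise ValidationError("universe must be nonempty")
    a, b = frozenset(members_a), frozenset(members_b)
    if not a <= uni or not b <= uni:
        stray = sorted((a | b) - uni)
        raise ValidationError(f"members outside the universe: {stray}")
    N = len(uni)
    n11 = len(a & b)
    n10 = len(a - b)
    n01 = len(b - a)
    n00 = N - n11 - n10 - n01
    po = (n11 + n00) / N
    pe = (len(a) * len(b) + (N - len(a)) * (N - len(b))) / (N * N)
    if pe == 1.0:
        return 1.0 if po == 1.0 else 0.0
    return (po - pe) / (1.0 - pe)


def term_direction(hit_genes, directions) -> str:
    """Majority regulation label of a term's hit genes.

    ``up`` if more hits are up-regulated than down, ``down`` for the
    converse, ``mixed`` on an exact tie. Raises when there is no hit.
    """
    hits = list(hit_genes)
    if not hits:
        raise ValidationError("cannot label a term with zero hits")
    n_up = sum(1 for g in hits if directions[g] == "up")
    n_down = len(hits) - n_up
    if n_up > n_down:
        return "up"
    if n_down > n_up:
        return "down"
    return "mixed"


def enrich(
    query,
    gene_sets: list[GeneSet],
    directions: dict | None = None,
    config: EnrichmentConfig | None = None,
    universe=None,
) -> pd.DataFrame:
    """Over-representation of a query gene list in each gene set.

    The universe defaults to the union of all genes in the collection;
    an explicit background list may be supplied instead. Query genes
    absent from the universe are dropped with a logged count. Adjusted
    p-values are Holm step-down across the collection.
    """
    config = config or EnrichmentConfig()
    if config.universe_policy == "explicit_list":
        if universe is None:
            raise ConfigError("universe_policy='explicit_list' requires a "
                              "universe argument")
        uni = frozenset(universe)
    else:
        uni = frozenset().union(*(gs.member_set for gs in gene_sets)) \
            if gene_sets else frozenset()
    query = list(dict.fromkeys(query))
    q = frozenset(query) & uni
    dropped = len(set(query)) - len(q)
    if dropped:
        logger.info("enrichment: dropped %d query gene(s) outside the "
                    "universe of %d", dropped, len(uni))
    N, n = len(uni), len(q)

    rows = []
    for gs in sorted(gene_sets, key=lambda g: g.name):
        members = gs.member_set & uni
        K = len(members)
        hits = sorted(q & members)
        k = len(hits)
        p = hypergeom_two_sided(k, n, K, N, policy=config.two_sided_policy)
        if directions is not None and k > 0:
            n_up = sum(1 for g in hits if directions[g] == "up")
            n_down = k - n_up
            label = term_direction(hits, directions)
        else:
            n_up = n_down = 0
            label = ""
        rows.append((gs.name, N, K, n, k, p, np.nan,
                     ",".join(hits), n_up, n_down, label))
    out = pd.DataFrame(rows, columns=list(RESULT_COLUMNS))
    if len(out):
        out["p_adjusted"] = holm_adjust(out["p_two_sided"].to_numpy())
    return out


@dataclass(frozen=True)
class TermGroup:
    """A connected component of significant terms under the kappa graph."""

    representative: str
    members: tuple[str, ...]
    mean_kappa: float


def group_terms(
    results: pd.DataFrame,
    gene_sets: list[GeneSet],
    config: EnrichmentConfig | None = None,
) -> list[TermGroup]:
    """Group significant terms by membership similarity.

    An edge joins two terms whose kappa, computed over the universe
    restricted to the query's hit genes, reaches the threshold; groups
    are the connected components. The representative is the member with
    the smallest adjusted p (ties broken lexicographically). Groups are
    returned sorted by (representative adjusted p, representative id).
    """
    config = config or EnrichmentConfig()
    sig = results[results["p_adjusted"] < config.alpha]
    if sig.empty:
        return []
    hit_lists = {r.term_id: frozenset(r.hit_genes.split(","))
                 if r.hit_genes else frozenset()
                 for r in sig.itertuples(index=False)}
    universe = frozenset().union(*hit_lists.values())
    if not universe:
        return []
    terms = sorted(hit_lists)
    graph = nx.Graph()
    graph.add_nodes_from(terms)
    kappas: dict[tuple[str, str], float] = {}
    for i, t1 in enumerate(terms):
        for t2 in terms[i + 1:]:
            kap = term_kappa(hit_lists[t1], hit_lists[t2], universe)
            kappas[(t1, t2)] = kap
            if kap >= config.kappa_threshold:
                graph.add_edge(t1, t2)

    padj = sig.set_index("term_id")["p_adjusted"]
    groups = []
    for comp in nx.connected_components(graph):
        members = tuple(sorted(comp))
        rep = min(members, key=lambda t: (padj[t], t))
        if len(members) == 1:
            mean_kappa = 1.0
        else:
            pair_k = [kappas[(a, b)] for ai, a in enumerate(members)
                      for b in members[ai + 1:]]
            mean_kappa = float(np.mean(pair_k))
        groups.append(TermGroup(rep, members, mean_kappa))
    groups.sort(key=lambda g: (padj[g.representative], g.representative))
    return groups


@dataclass(frozen=True)
class ZScoreResult:
    """MAPPFinder-style pathway over-representation Z-score.

    r of the R measured query hits fall on a pathway of n measured
    members within a measured universe of N; z standardizes r against
    its hypergeometric mean and variance.
    """

    pathway_id: str
    r: int
    n: int
    R: int
    N: int
    z: float
    significant: bool


def pathway_zscore(
    r: int, n: int, R: int, N: int,
    pathway_id: str = "",
    z_cutoff: float = Z_CUTOFF_DEFAULT,
    two_sided: bool = False,
) -> ZScoreResult:
    """Standardized pathway hit count.

    z = (r - nR/N) / sqrt(n (R/N)(1 - R/N)(1 - (n-1)/(N-1))), the exact
    hypergeometric standardization. A zero variance (R = 0, R = N or
    n = N) yields z = 0 with a warning. Significance is one-sided
    (over-representation) by default.
    """
    for name, v in (("r", r), ("n", n), ("R", R), ("N", N)):
        if int(v) != v or v < 0:
            raise ValidationError(f"{name} must be a nonnegative integer")
    if not (0 <= r <= n <= N and r <= R <= N):
        raise ValidationError("require 0 <= r <= n <= N and r <= R <= N")
    if N < 2 or n < 1:
        raise ValidationError("require N >= 2 and n >= 1")
    frac = R / N
    var = n * frac * (1.0 - frac) * (1.0 - (n - 1) / (N - 1))
    if var == 0.0:
        logger.warning("pathway %s: degenerate variance (R=%d, n=%d, N=%d); "
                       "z set to 0", pathway_id or "<unnamed>", R, n, N)
        z = 0.0
    else:
        z = (r - n * frac) / math.sqrt(var)
    significant = abs(z) >= z_cutoff if two_sided else z >= z_cutoff
    return ZScoreResult(pathway_id, int(r), int(n), int(R), int(N), z,
                        bool(significant))


def pathway_zscores(
    query,
    gene_sets: list[GeneSet],
    config: EnrichmentConfig | None = None,
    universe=None,
) -> pd.DataFrame:
    """Z-score every pathway of a collection against one query list."""
    config = config or EnrichmentConfig()
    if universe is not None:
        uni = frozenset(universe)
    else:
        uni = frozenset().union(*(gs.member_set for gs in gene_sets)) \
            if gene_sets else frozenset()
    q = frozenset(query) & uni
    N, R = len(uni), len(q)
    rows = []
    for gs in sorted(gene_sets, key=lambda g: g.name):
        members = gs.member_set & uni
        n = len(members)
        if n == 0 or N < 2:
            continue
        res = pathway_zscore(len(q & members), n, R, N, pathway_id=gs.name,
                             z_cutoff=config.z_cutoff,
                             two_sided=config.z_two_sided)
        rows.append((res.pathway_id, res.r, res.n, res.R, res.N, res.z,
                     res.significant))
    return pd.DataFrame(rows, columns=["pathway_id", "r", "n", "R", "N",
                                       "z", "significant"])
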