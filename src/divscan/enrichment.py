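"""Rank-based (Mann-Whitney U) functional enrichment on binary gene scores.

Each gene in the background (genes whose protein was detected in larvae)
carries a binary score: 1 if it maps to an outlier window of the tail and
condition under analysis, 0 otherwise.  Every qualifying GO category is
tested for enrichment of score-1 genes with a one-sided Mann-Whitney U test
(category vs rest of background).  With binary scores the test reduces to a
rank test dominated by ties, so tie handling is explicit: midranks with a
tie-corrected normal approximation and continuity correction for large
samples, and full enumeration of the permutation distribution for small ones.
Raw p-values are Benjamini-Hochberg adjusted within each GO namespace.
"""

from __future__ import annotations

import logging
import warnings
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)

EXACT_LIMIT = 20  # combined sample size up to which enumeration is used


def _rank_u(pooled_ranks: np.ndarray, idx: tuple[int, ...], n1: int) -> float:
    return float(sum(pooled_ranks[i] for i in idx) - n1 * (n1 + 1) / 2.0)


def exact_mwu_p(
    x: np.ndarray, y: np.ndarray, alternative: str = "greater"
) -> float:
    """Exact Mann-Whitney p by enumerating all group assignments (ties allowed).

    Every partition of the pooled values into groups of the observed sizes is
    equally likely under the null; the p-value is the fraction of partitions
    with a U statistic at least as extreme as observed.  Intended for small
    samples (combined n up to ~20).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n = len(x), len(x) + len(y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u_obs = _rank_u(ranks, tuple(range(n1)), n1)

    eps = 1e-9
    total = comb(n, n1)
    n_ge = n_le = 0
    for idx in combinations(range(n), n1):
        u = _rank_u(ranks, idx, n1)
        if u >= u_obs - eps:
            n_ge += 1
        if u <= u_obs + eps:
            n_le += 1
    if alternative == "greater":
        return n_ge / total
    if alternative == "less":
        return n_le / total
    if alternative == "two-sided":
        return min(1.0, 2.0 * min(n_ge, n_le) / total)
    raise ValueError(f"unknown alternative {alternative!r}")


def mann_whitney_u(
    scores_in_category: np.ndarray,
    scores_outside: np.ndarray,
    exact_limit: int = EXACT_LIMIT,
) -> tuple[float, float]:
    """One-sided MWU (category scores greater) with explicit tie handling.

    Returns ``(U, p)`` where U is the category-side statistic with midrank
    ties.  Exact enumeration when the combined sample size is at most
    ``exact_limit``; otherwise the normal approximation with tie-corrected
    variance and continuity correction.  Identical values across both groups
    give p = 1.
    """
    x = np.asarray(scores_in_category, dtype=float)
    y = np.asarray(scores_outside, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be nonempty")

    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u = float(ranks[: len(x)].sum() - len(x) * (len(x) + 1) / 2.0)
    if np.all(pooled == pooled[0]):
        return u, 1.0
    if len(pooled) <= exact_limit:
        return u, exact_mwu_p(x, y, alternative="greater")
    res = sps.mannwhitneyu(x, y, alternative="greater", method="asymptotic")
    return u, float(res.pvalue)


def build_gene_scores(
    mapped_genes: pd.DataFrame | set[str],
    proteome: pd.DataFrame,
) -> pd.DataFrame:
    """Binary score table over the larval-protein background.

    ``mapped_genes`` is the window-to-gene table of the tail/condition under
    analysis (or simply a set of gene ids); genes in it score 1, all other
    background genes 0.  Background = genes with ``in_larva`` true.
    """
    if isinstance(mapped_genes, pd.DataFrame):
        hit = set(mapped_genes["gene_id"])
    else:
        hit = set(mapped_genes)
    background = proteome.loc[proteome["in_larva"].astype(bool), "gene_id"]
    outside = hit - set(background)
    if outside:
        log.info("%d scored genes outside the larval background ignored", len(outside))
    return pd.DataFrame(
        {
            "gene_id": background.to_numpy(),
            "score": background.isin(hit).astype(int).to_numpy(),
        }
    )


def run_enrichment(
    scores: pd.DataFrame,
    go_map: pd.DataFrame,
    min_category: int = 5,
    max_category_frac: float = 0.5,
) -> pd.DataFrame:
    """One MWU enrichment test per qualifying GO term, BH-adjusted per namespace.

    ``scores`` has columns ``gene_id, score`` (binary) covering the
    background; ``go_map`` has ``gene_id, go_id, namespace``.  Categories
    smaller than ``min_category`` background genes or larger than
    ``max_category_frac`` of the background are skipped (logged).  Returns a
    frame with ``go_id, namespace, n_category, n_scored, u, p, p_adj``
    sortable by raw p.
    """
    from statsmodels.stats.multitest import multipletests

    if scores.empty:
        raise ValueError("empty score table")
    score_by_gene = scores.set_index("gene_id")["score"]
    background = set(score_by_gene.index)
    gomap = go_map[go_map["gene_id"].isin(background)]
    if gomap.empty:
        warnings.warn("GO map covers no background gene; empty result", stacklevel=2)
        return pd.DataFrame(
            columns=["go_id", "namespace", "n_category", "n_scored", "u", "p", "p_adj"]
        )

    max_size = max_category_frac * len(background)
    rows, n_skipped = [], 0
    for (ns, term), members in gomap.groupby(["namespace", "go_id"])["gene_id"]:
        genes = sorted(set(members))
        if len(genes) < min_category or len(genes) > max_size:
            n_skipped += 1
            continue
        in_cat = score_by_gene.loc[genes].to_numpy(dtype=float)
        out_genes = sorted(background - set(genes))
        outside = score_by_gene.loc[out_genes].to_numpy(dtype=float)
        u, p = mann_whitney_u(in_cat, outside)
        rows.append((term, ns, len(genes), int(in_cat.sum()), u, p))
    if n_skipped:
        log.info("%d GO categories outside size bounds skipped", n_skipped)
    if not rows:
        warnings.warn("no qualifying GO category", stacklevel=2)
        return pd.DataFrame(
            columns=["go_id", "namespace", "n_category", "n_scored", "u", "p", "p_adj"]
        )

    result = pd.DataFrame(
        rows, columns=["go_id", "namespace", "n_category", "n_scored", "u", "p"]
    )
    result["p_adj"] = np.nan
    for ns, idx in result.groupby("namespace").groups.items():
        result.loc[idx, "p_adj"] = multipletests(
            result.loc[idx, "p"].to_numpy(), method="fdr_bh"
        )[1]
    return result.sort_values("p", kind="mergesort").reset_index(drop=True)


def overlap_summary(
    results: dict[str, pd.DataFrame], alpha: float | None = None
) -> dict[str, object]:
    """Venn-style GO-term overlaps across condition x tail result sets.

    ``results`` maps a set label (e.g. ``control_balancing``) to an
    enrichment result frame.  With ``alpha`` set, only terms with raw
    p < alpha are included; otherwise all tested terms.
    """
    if len(results) < 2:
        raise ValueError("need at least 2 result sets")
    term_sets = {}
    for name, df in results.items():
        if alpha is None:
            term_sets[name] = set(df["go_id"])
        else:
            term_sets[name] = set(df.loc[df["p"] < alpha, "go_id"])

    names = sorted(term_sets)
    pairwise = {
        f"{a}&{b}": len(term_sets[a] & term_sets[b]) for a, b in combinations(names, 2)
    }
    common = set.intersection(*term_sets.values())
    return {
        "sizes": {name: len(term_sets[name]) for name in names},
        "pairwise_intersections": pairwise,
        "common_to_all": len(common),
        "union": len(set.union(*term_sets.values())),
        "unique": {
            name: len(
                term_sets[name]
                - set.union(*(term_sets[o] for o in names if o != name))
            )
            for name in names
        },
    }
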