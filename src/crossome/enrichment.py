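"""Fisher's-exact cluster enrichment with BH control, and the rank-skew test.

Enrichment of a cluster in an annotation term is scored with the one-sided
(upper-tail) Fisher exact test: with background size N, term size K and
cluster size n, the p-value of observing a or more term members inside the
cluster is the hypergeometric tail

    p = sum_{k >= a} C(K, k) C(N-K, n-k) / C(N, n).

q-values are Benjamini-Hochberg adjusted across all (cluster, term) pairs of
one run. The rank-skew test asks whether a lipid class sits toward the upper
end of the per-genotype log2FC ranking, via a one-sided Wilcoxon rank-sum
(exact for small groups, normal approximation with continuity correction
otherwise).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cluster import ClusterModel
from .io import AnnotationSets, DifferentialMatrix, ValidationError

__all__ = ["fisher_enrich", "bh_adjust", "class_rank_test"]

#: switch to the normal approximation above these exact-test sizes
EXACT_MAX_GROUP = 10
EXACT_MAX_TOTAL = 30


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values for a family of p-values."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_enrich(
    clusters: ClusterModel,
    annotations: AnnotationSets,
    background: Iterable[str],
) -> pd.DataFrame:
    """One-sided Fisher enrichment of every cluster against every term.

    The background must contain all cluster members; annotation terms are
    restricted to the background before testing, and terms emptied by that
    restriction are skipped. Returns one row per tested (cluster, term) with
    the 2x2 table (a, b, c, d), odds ratio, p and BH q.
    """
    bg = sorted(set(background))
    if not bg:
        raise ValidationError("empty background")
    bg_set = set(bg)
    stray = set(clusters.feature_ids) - bg_set
    if stray:
        raise ValidationError(
            f"cluster member {sorted(stray)[0]!r} missing from background"
        )
    ann = annotations.restricted_to(bg_set)
    n_bg = len(bg)
    rows = []
    for cid in range(1, clusters.k + 1):
        members = set(clusters.members(cid))
        n_clu = len(members)
        for term in ann.term_ids:
            term_set = ann.member_set(term)
            a = len(members & term_set)
            b = n_clu - a
            c = len(term_set) - a
            d = n_bg - n_clu - c
            # upper-tail hypergeometric: P(X >= a)
            p = float(stats.hypergeom.sf(a - 1, n_bg, len(term_set), n_clu))
            p = min(p, 1.0)
            odds = (a * d) / (b * c) if b * c > 0 else float("inf")
            rows.append(
                {
                    "cluster": cid,
                    "term_id": term,
                    "a": a,
                    "b": b,
                    "c": c,
                    "d": d,
                    "odds_ratio": odds,
                    "p_value": p,
                    "term_description": ann.descriptions.get(term, ""),
                }
            )
    result = pd.DataFrame(
        rows,
        columns=[
            "cluster", "term_id", "a", "b", "c", "d",
            "odds_ratio", "p_value", "term_description",
        ],
    )
    if len(result):
        result["q_value"] = bh_adjust(result["p_value"].to_numpy())
    else:
        result["q_value"] = pd.Series(dtype=float)
    cols = [
        "cluster", "term_id", "a", "b", "c", "d",
        "odds_ratio", "p_value", "q_value", "term_description",
    ]
    return result[cols]


def class_rank_test(
    diff: DifferentialMatrix,
    genotype: str,
    class_members: Iterable[str],
) -> tuple[float, float]:
    """Skew of a feature class toward the top of one genotype's log2FC ranking.

    Features are ranked by log2FC descending (rank 1 = largest fold change);
    the one-sided Wilcoxon rank-sum tests whether class members occupy
    higher-than-random positions. Returns ``(p_value, members_mean_rank)``.
    """
    if genotype not in diff.log2fc.columns:
        raise ValidationError(f"genotype {genotype!r} not in differential matrix")
    col = diff.log2fc[genotype].dropna()
    member_ids = set(class_members)
    in_class = col.index.isin(member_ids)
    x = col[in_class].to_numpy()
    y = col[~in_class].to_numpy()
    if x.size == 0:
        raise ValidationError("no class member has a non-missing log2fc")
    if y.size == 0:
        raise ValidationError("no non-member has a non-missing log2fc")
    n_total = x.size + y.size
    method = (
        "exact"
        if min(x.size, y.size) <= EXACT_MAX_GROUP and n_total <= EXACT_MAX_TOTAL
        else "asymptotic"
    )
    res = stats.mannwhitneyu(x, y, alternative="greater", method=method)
    # descending ranks with average ties: rank 1 is the largest value
    desc_ranks = pd.Series(-col.to_numpy(), index=col.index).rank(method="average")
    mean_rank = float(desc_ranks[in_class].mean())
    return float(res.pvalue), mean_rank
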