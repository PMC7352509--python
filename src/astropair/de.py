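"""Two-group differential expression with empirical-Bayes variance
moderation, BH-FDR, Venn set comparisons, and Fisher category enrichment.

The per-gene test contrasts two sample groups on a log2 expression matrix.
Gene-wise sample variances are shrunk toward a common prior fitted across
genes: the pooled variance s_g^2 is modeled as s0^2 * F(d, d0), the prior
(d0, s0^2) is estimated by matching the first two moments of s_g^2 across
genes, and the moderated statistic

    t_g = (meanA - meanB) / sqrt(s~_g^2 (1/nA + 1/nB)),
    s~_g^2 = (d0 s0^2 + d s_g^2) / (d0 + d)

is referred to a t distribution on d0 + d degrees of freedom. As d0 -> inf
this approaches a pooled-variance z-like test; at d0 = 0 it is the ordinary
two-sample t-test.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def fit_variance_prior(s2: np.ndarray, d: float) -> tuple[float, float]:
    """Moment fit of the scaled inverse-chi-square variance prior.

    Under the hierarchical model s_g^2 ~ s0^2 F(d, d0). Matching the mean and
    variance of the F distribution to the observed moments of s_g^2 gives

        v / m^2 = 2 (d + d0 - 2) / (d (d0 - 4))

    solved for d0 (infinite when the observed spread is at or below the
    pure-sampling spread). Returns (d0, s0_squared).
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2)]
    m = float(np.mean(s2))
    v = float(np.var(s2, ddof=1)) if s2.size > 1 else 0.0
    if m <= 0:
        return np.inf, max(m, 1e-12)
    r = v / m**2
    denom = r * d - 2.0
    if denom <= 0:
        return np.inf, m
    d0 = (4.0 * r * d + 2.0 * d - 4.0) / denom
    if d0 <= 4.0:  # moment solution outside its validity region
        d0 = 4.0 + 1e-6
    s0_sq = m * (d0 - 2.0) / d0
    return d0, s0_sq


def moderated_two_group_test(
    logexpr: pd.DataFrame,
    group_a,
    group_b,
    q_threshold: float = 0.01,
    d0: float | None = None,
    s0_sq: float | None = None,
) -> pd.DataFrame:
    """Moderated t-test of group A versus group B per gene.

    ``d0``/``s0_sq`` override the moment-fitted prior (d0=0 gives the
    ordinary t-test, d0=inf the pooled-variance z-like test).

    Returns a DataFrame indexed by gene with columns log2_fc, t, p, q and
    direction in {under, over, unchanged} (A relative to B at the q cut).
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    A = logexpr[group_a].to_numpy(float)
    B = logexpr[group_b].to_numpy(float)
    na, nb = A.shape[1], B.shape[1]
    d = na + nb - 2
    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    ss = A.var(axis=1, ddof=1) * (na - 1) + B.var(axis=1, ddof=1) * (nb - 1)
    s2 = ss / d
    if d0 is None:
        d0, s0_fit = fit_variance_prior(s2, d)
        s0_sq = s0_fit if s0_sq is None else s0_sq
    elif s0_sq is None:
        s0_sq = float(np.mean(s2))
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df = np.inf
    else:
        s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
        df = d0 + d
    lfc = mean_a - mean_b
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    t = np.where(np.isfinite(t), t, 0.0)
    p = 2.0 * (stats.t.sf(np.abs(t), df) if np.isfinite(df)
               else stats.norm.sf(np.abs(t)))
    q = bh_adjust(p)
    direction = np.where(
        q <= q_threshold, np.where(lfc > 0, "over", "under"), "unchanged"
    )
    return pd.DataFrame(
        {"log2_fc": lfc, "t": t, "p": p, "q": q, "direction": direction},
        index=logexpr.index,
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def de_sets(result: pd.DataFrame, threshold: float = 0.01) -> dict[str, set]:
    """Under/over gene sets of one DE result at a q cut."""
    sig = result[result["q"] <= threshold]
    return {
        "under": set(sig.index[sig["log2_fc"] < 0]),
        "over": set(sig.index[sig["log2_fc"] > 0]),
    }


def venn_counts(sets: dict[str, set]) -> dict[str, int]:
    """Counts for every region of the Venn partition of named sets.

    Region keys are '&'-joined sorted member names, e.g. 'A&C' is the region
    inside A and C but outside every other set.
    """
    names = sorted(sets)
    universe = set().union(*sets.values()) if sets else set()
    counts: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set(universe)
            for n in combo:
                inside &= sets[n]
            for n in names:
                if n not in combo:
                    inside -= sets[n]
            counts["&".join(combo)] = len(inside)
    return counts


def de_sets_and_venn(
    results: dict[str, pd.DataFrame], threshold: float = 0.01
) -> dict:
    """Per-result under/over gene lists plus all Venn intersection counts."""
    universes = {frozenset(r.index) for r in results.values()}
    if len(universes) > 1:
        raise ValueError("DE results do not share a gene universe")
    split = {name: de_sets(res, threshold) for name, res in results.items()}
    return {
        "sets": split,
        "venn": {
            direction: venn_counts(
                {name: s[direction] for name, s in split.items()}
            )
            for direction in ("under", "over")
        },
    }


def category_enrichment(
    geneset, universe, annotations: dict[str, set], alternative: str = "greater"
) -> pd.DataFrame:
    """Fisher's exact over-representation test per annotation category.

    ``annotations`` maps category name -> gene set. The 2x2 table counts
    (in geneset & in category) against the rest of the universe.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    geneset = set(geneset)
    if not geneset <= universe:
        raise ValueError("gene set is not a subset of the universe")
    rows = []
    for cat, members in annotations.items():
        members = set(members) & universe
        k = len(geneset & members)
        table = [
            [k, len(geneset) - k],
            [len(members) - k, len(universe) - len(members) - len(geneset) + k],
        ]
        odds, p = stats.fisher_exact(table, alternative=alternative)
        rows.append((cat, k, len(members), odds, p))
    return pd.DataFrame(
        rows, columns=["category", "n_overlap", "n_category", "odds_ratio", "p"]
    ).set_index("category")
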