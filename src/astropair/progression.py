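"""Aggregation of per-pair expression-state calls into progression groups.

Decoded per-gene states (-1 under, 0 unchanged, +1 over) of each
patient-matched pair are tallied within progression groups (A2->A3, A2->G4,
A3->G4). A gene belongs to a group's frequent under-set (resp. over-set) if
it is called in that direction in at least ``min_fraction`` of the group's
pairs — "at least 50%" is inclusive, so exactly half qualifies. Frequent
sets are compared across groups by Venn regions, averaged into genome-wide
alteration profiles, and summarized per pathway.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .de import category_enrichment, venn_counts

PROGRESSION_LABELS = ("A2->A3", "A2->G4", "A3->G4")


def group_alteration_counts(
    labels: pd.DataFrame, groups: dict[str, list[str]]
) -> pd.DataFrame:
    """Per-group per-gene counts of under/over calls.

    Parameters
    ----------
    labels : genes x pairs DataFrame of decoded state codes (-1/0/+1).
    groups : progression-group label -> list of pair (patient) ids; the
        listed pairs must partition the decoded columns they reference.

    Returns a DataFrame indexed by gene with MultiIndex columns
    (group, {n_under, n_over, n_pairs}).
    """
    seen: set[str] = set()
    for g, members in groups.items():
        if not members:
            raise ValueError(f"progression group {g!r} has no pairs")
        missing = [m for m in members if m not in labels.columns]
        if missing:
            raise KeyError(f"pairs {missing} of group {g!r} not decoded")
        overlap = seen & set(members)
        if overlap:
            raise ValueError(f"pairs {sorted(overlap)} appear in two groups")
        seen |= set(members)
    blocks = {}
    for g, members in groups.items():
        sub = labels[members]
        blocks[(g, "n_under")] = (sub == -1).sum(axis=1)
        blocks[(g, "n_over")] = (sub == 1).sum(axis=1)
        blocks[(g, "n_pairs")] = len(members)
    out = pd.DataFrame(blocks)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["group", "stat"])
    return out


def frequent_sets(
    summary: pd.DataFrame, min_fraction: float = 0.5
) -> dict:
    """Frequent under/over gene sets per group plus cross-group Venn counts.

    A gene enters a set iff count / n_pairs >= min_fraction (inclusive).
    Venn regions are computed separately per direction; opposite-direction
    pairwise overlaps are reported under 'opposite'.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must lie in (0, 1]")
    group_names = summary.columns.get_level_values("group").unique()
    sets: dict[str, dict[str, set]] = {}
    for g in group_names:
        n = int(summary[(g, "n_pairs")].iloc[0])
        sets[g] = {
            "under": set(summary.index[summary[(g, "n_under")] / n >= min_fraction]),
            "over": set(summary.index[summary[(g, "n_over")] / n >= min_fraction]),
        }
    venn = {
        d: venn_counts({g: sets[g][d] for g in group_names})
        for d in ("under", "over")
    }
    opposite = {
        f"{g1}:under&{g2}:over": len(sets[g1]["under"] & sets[g2]["over"])
        for g1 in group_names
        for g2 in group_names
    }
    return {"sets": sets, "venn": venn, "opposite": opposite}


def average_alteration_profile(
    profiles: pd.DataFrame,
    labels: pd.DataFrame,
    members: list[str],
    genes,
    direction: str,
) -> pd.Series:
    """Mean log-ratio per frequent gene over the pairs carrying the call.

    For each gene of ``genes``, averages the log2(recurrent/initial) values
    of exactly those group members whose decoded label matches ``direction``
    ('under' or 'over'); genes with no contributing pair are omitted. The
    result keeps the chromosomal row order of ``profiles``.
    """
    code = {"under": -1, "over": 1}[direction]
    genes = [g for g in profiles.index if g in set(genes)]
    out = {}
    for g in genes:
        mask = labels.loc[g, members] == code
        if mask.any():
            contrib = profiles.loc[g, members][mask.to_numpy()]
            out[g] = float(contrib.mean())
    return pd.Series(out, name=f"mean_log2_ratio_{direction}", dtype=float)


def pathway_alteration_profile(
    sets: dict[str, dict[str, set]],
    pathways: dict[str, set],
    universe,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Per-pathway altered-gene proportions and Fisher enrichment p-values.

    For each group and direction: the fraction of the pathway's (measured)
    genes that are in the frequent set, and the enrichment p of the frequent
    set in the pathway.
    """
    universe = set(universe)
    rows = []
    for name, members in pathways.items():
        measured = set(members) & universe
        if not measured:
            warnings.warn(f"pathway {name!r} has no measured genes; skipped")
            continue
        for g, dirsets in sets.items():
            for d in ("under", "over"):
                fs = dirsets[d] & universe
                frac = len(measured & fs) / len(measured)
                p = category_enrichment(
                    fs, universe, {name: measured}, alternative=alternative
                ).loc[name, "p"]
                rows.append((name, g, d, len(measured), frac, p))
    return pd.DataFrame(
        rows,
        columns=["pathway", "group", "direction", "n_measured", "proportion", "p"],
    )
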