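"""Copy-number segment handling: gene-level profiles, subgroup averages,
and whole-chromosome / arm event calls.

Coordinates are 0-based half-open internally; SEG files on disk are treated
as 1-based inclusive and converted at the I/O boundary (see astropair.io).

A gene map is a DataFrame with columns gene, chrom, start, end, sorted by
(chrom, start) with a total order index. Segment sets are DataFrames with
columns sample, chrom, start, end, seg_mean.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_LOSS_CUT = -0.3
DEFAULT_GAIN_CUT = 0.3
DEFAULT_MIN_FRACTION = 0.7


def segments_to_genes(segments: pd.DataFrame, gene_map: pd.DataFrame) -> pd.DataFrame:
    """Gene-level log2-ratio profiles from per-sample segment sets.

    Each gene receives the mean log2-ratio of the segment containing its
    midpoint; genes covered by no segment (or on chromosomes absent from a
    sample's segments) are NaN.

    Returns a genes x samples DataFrame indexed like ``gene_map``.
    """
    mid = (gene_map["start"].to_numpy() + gene_map["end"].to_numpy()) / 2.0
    samples = list(dict.fromkeys(segments["sample"]))
    out = pd.DataFrame(
        np.nan, index=gene_map["gene"].to_numpy(), columns=samples, dtype=float
    )
    for sample, segs in segments.groupby("sample", sort=False):
        values = np.full(len(gene_map), np.nan)
        for chrom, csegs in segs.groupby("chrom", sort=False):
            gmask = (gene_map["chrom"] == chrom).to_numpy()
            if not gmask.any():
                continue
            csegs = csegs.sort_values("start")
            starts = csegs["start"].to_numpy(float)
            ends = csegs["end"].to_numpy(float)
            means = csegs["seg_mean"].to_numpy(float)
            m = mid[gmask]
            idx = np.searchsorted(starts, m, side="right") - 1
            ok = (idx >= 0) & (m < ends[np.clip(idx, 0, None)])
            vals = np.full(m.size, np.nan)
            vals[ok] = means[idx[ok]]
            values[gmask] = vals
        out[sample] = values
    return out


def average_profile(profiles: pd.DataFrame) -> pd.Series:
    """Per-gene arithmetic mean log2-ratio across samples (NaNs excluded)."""
    if profiles.shape[1] < 1:
        raise ValueError("need at least one profile")
    return profiles.mean(axis=1, skipna=True).rename("mean_log2_ratio")


def chromosome_event_call(
    values: np.ndarray,
    loss_cut: float = DEFAULT_LOSS_CUT,
    gain_cut: float = DEFAULT_GAIN_CUT,
    min_fraction: float = DEFAULT_MIN_FRACTION,
) -> str:
    """Call one scope (chromosome or arm) as loss / gain / neutral.

    Loss if at least ``min_fraction`` of genes sit at or below ``loss_cut``;
    gain symmetrically at or above ``gain_cut``. If both qualify the larger
    fraction wins; an exact tie is neutral.
    """
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise ValueError("empty scope: no genes with copy-number values")
    f_loss = float(np.mean(values <= loss_cut))
    f_gain = float(np.mean(values >= gain_cut))
    loss_ok = f_loss >= min_fraction
    gain_ok = f_gain >= min_fraction
    if loss_ok and (not gain_ok or f_loss > f_gain):
        return "loss"
    if gain_ok and (not loss_ok or f_gain > f_loss):
        return "gain"
    return "neutral"


def call_events(
    profiles: pd.DataFrame,
    gene_map: pd.DataFrame,
    level: str = "chromosome",
    loss_cut: float = DEFAULT_LOSS_CUT,
    gain_cut: float = DEFAULT_GAIN_CUT,
    min_fraction: float = DEFAULT_MIN_FRACTION,
    arm_boundaries: dict | None = None,
) -> pd.DataFrame:
    """Event calls per sample per chromosome (or arm).

    ``arm_boundaries`` maps chromosome -> centromere coordinate; when absent
    the chromosome's coordinate midpoint splits p from q.

    Returns a long DataFrame (sample, scope, n_genes, call).
    """
    if level not in ("chromosome", "arm"):
        raise ValueError("level must be 'chromosome' or 'arm'")
    chrom = gene_map["chrom"].to_numpy()
    mid = (gene_map["start"].to_numpy() + gene_map["end"].to_numpy()) / 2.0
    scopes: list[tuple[str, np.ndarray]] = []
    for c in dict.fromkeys(chrom):
        cmask = chrom == c
        if level == "chromosome":
            scopes.append((str(c), cmask))
        else:
            if arm_boundaries and c in arm_boundaries:
                cut = arm_boundaries[c]
            else:
                cut = (gene_map.loc[cmask, "start"].min()
                       + gene_map.loc[cmask, "end"].max()) / 2.0
            scopes.append((f"{c}p", cmask & (mid < cut)))
            scopes.append((f"{c}q", cmask & (mid >= cut)))
    rows = []
    for sample in profiles.columns:
        vals = profiles[sample].to_numpy(float)
        for name, mask in scopes:
            if not mask.any():
                continue
            call = chromosome_event_call(
                vals[mask], loss_cut=loss_cut, gain_cut=gain_cut,
                min_fraction=min_fraction,
            )
            rows.append((sample, name, int(mask.sum()), call))
    return pd.DataFrame(rows, columns=["sample", "scope", "n_genes", "call"])
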