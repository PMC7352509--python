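"""Somatic-variant summaries for patient-matched tumor pairs.

A variant call set is a DataFrame with columns sample, chrom, pos, ref, alt,
gene, func_class, vaf. Variant identity is the (chrom, pos, ref, alt) key;
gene-level recurrence supports two scopes because pairs may carry mutations
in the same gene at different positions: 'shared-in-pair' requires an
identical key in both tumors of a pair, 'any-sample' counts a pair if either
tumor carries any variant in the gene.
"""

from __future__ import annotations

import warnings

import pandas as pd

FUNCTIONAL_CLASSES = ("nonsynonymous", "stop", "synonymous", "intronic", "other")
EXONIC_CLASSES = ("nonsynonymous", "stop", "synonymous")
KEY = ["chrom", "pos", "ref", "alt"]


def _keys(calls: pd.DataFrame) -> set[tuple]:
    keys = list(map(tuple, calls[KEY].itertuples(index=False)))
    if len(keys) != len(set(keys)):
        raise ValueError("duplicate variant keys within a sample")
    return set(keys)


def shared_private(
    initial: pd.DataFrame, recurrent: pd.DataFrame
) -> tuple[int, int, int]:
    """(n_shared, n_initial_private, n_recurrent_private) by variant key."""
    ki, kr = _keys(initial), _keys(recurrent)
    return len(ki & kr), len(ki - kr), len(kr - ki)


def functional_tally(calls: pd.DataFrame) -> dict[str, int]:
    """Counts per functional class plus the derived 'exonic' total."""
    tally = {c: 0 for c in FUNCTIONAL_CLASSES}
    for c, n in calls["func_class"].value_counts().items():
        if c not in tally:
            warnings.warn(f"unknown functional class {c!r}; counted as 'other'")
            c = "other"
        tally[c] += int(n)
    tally["exonic"] = sum(tally[c] for c in EXONIC_CLASSES)
    return tally


def gene_frequency(
    pairs: dict[str, tuple[pd.DataFrame, pd.DataFrame]],
    scope: str = "shared-in-pair",
    groups: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Fraction of pairs mutated per gene.

    Parameters
    ----------
    pairs : patient id -> (initial calls, recurrent calls).
    scope : 'any-sample' or 'shared-in-pair' (see module docstring).
    groups : optional progression-group label -> patient ids for
        stratified frequencies (an extra column per group).

    Returns a DataFrame indexed by gene, sorted by descending overall
    fraction then gene name, with columns n_pairs, frequency (and one
    frequency column per group when given).
    """
    if scope not in ("any-sample", "shared-in-pair"):
        raise ValueError("scope must be 'any-sample' or 'shared-in-pair'")
    mutated: dict[str, set[str]] = {}
    for patient, (initial, recurrent) in pairs.items():
        if scope == "any-sample":
            genes = set(initial["gene"]) | set(recurrent["gene"])
        else:
            shared_keys = _keys(initial) & _keys(recurrent)
            idx = initial.set_index(KEY)["gene"]
            genes = {idx.loc[k] for k in shared_keys}
        for g in genes:
            mutated.setdefault(g, set()).add(patient)
    n_pairs = len(pairs)
    rows = {
        gene: {"n_pairs": n_pairs, "frequency": len(members) / n_pairs}
        for gene, members in mutated.items()
    }
    out = pd.DataFrame.from_dict(rows, orient="index")
    if out.empty:
        return pd.DataFrame(columns=["n_pairs", "frequency"])
    if groups:
        for label, patients in groups.items():
            denom = len(patients)
            out[f"frequency_{label}"] = [
                len(mutated[g] & set(patients)) / denom for g in out.index
            ]
    out = out.sort_values(
        ["frequency"], ascending=False, kind="mergesort"
    )
    # stable tie-break by gene name
    out["_name"] = out.index
    out = (
        out.sort_values(["frequency", "_name"], ascending=[False, True])
        .drop(columns="_name")
    )
    out.index.name = "gene"
    return out
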