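"""Expression-subtype assignment by centroid correlation.

Tumor expression is first reduced to a per-gene log2 ratio against the mean
of the normal brain references. A tumor is G-CIMP positive iff its log-ratio
profile correlates positively (Pearson) with the G-CIMP signature centroid
over the shared genes. Four-class (neural / proneural / classical /
mesenchymal) assignment picks the class centroid with the greatest positive
correlation; tumors whose best correlation is not positive are reported as
unclassifiable, mirroring the exclusion of tumors that do not correlate well
with any class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

UNCLASSIFIABLE = "unclassifiable"


@dataclass
class SubtypeSignature:
    """One class centroid: name plus per-gene log-ratio weights."""

    name: str
    centroid: pd.Series  # gene -> log2-ratio weight

    def shared_genes(self, genes) -> pd.Index:
        return self.centroid.index.intersection(pd.Index(genes))


def tumor_logratio_vs_normal(
    logexpr: pd.DataFrame, normals
) -> pd.DataFrame:
    """Per-gene tumor log2 ratio relative to the mean of the normals."""
    normals = list(normals)
    if not normals:
        raise ValueError("at least one normal reference sample is required")
    reference = logexpr[normals].mean(axis=1)
    tumors = [c for c in logexpr.columns if c not in set(normals)]
    return logexpr[tumors].sub(reference, axis=0)


def _signature_correlation(logratio: pd.Series, sig: SubtypeSignature) -> float:
    shared = sig.shared_genes(logratio.index)
    if len(shared) < 3:
        return np.nan
    r, _ = stats.pearsonr(logratio[shared], sig.centroid[shared])
    return float(r)


def gcimp_call(logratio: pd.Series, sig: SubtypeSignature) -> tuple[float, bool]:
    """(Pearson r, positivity flag); positivity requires strictly r > 0."""
    r = _signature_correlation(logratio, sig)
    if np.isnan(r):
        warnings.warn("fewer than 3 shared signature genes; call unavailable")
        return np.nan, False
    return r, r > 0


def verhaak_assign(
    logratio: pd.Series, sigs: list[SubtypeSignature], min_r: float = 0.0
) -> tuple[str, dict[str, float]]:
    """Assign the class with the greatest correlation above ``min_r``.

    Exact ties between the top classes, or no class exceeding ``min_r``,
    yield 'unclassifiable'. Returns (class, per-class r).
    """
    if len(sigs) < 2:
        raise ValueError("need at least two class signatures")
    corr = {s.name: _signature_correlation(logratio, s) for s in sigs}
    finite = {k: v for k, v in corr.items() if np.isfinite(v)}
    if not finite:
        return UNCLASSIFIABLE, corr
    best = max(finite.values())
    if best <= min_r:
        return UNCLASSIFIABLE, corr
    winners = [k for k, v in finite.items() if v == best]
    return (winners[0] if len(winners) == 1 else UNCLASSIFIABLE), corr


class CentroidSubtypeClassifier(BaseEstimator):
    """Nearest-centroid-by-correlation classifier over signature panels.

    Parameters
    ----------
    signatures : list of :class:`SubtypeSignature`, one per class.
    min_r : minimal correlation for a confident assignment (default 0:
        the best correlation must be strictly positive).
    """

    def __init__(self, signatures: list[SubtypeSignature] | None = None,
                 min_r: float = 0.0):
        self.signatures = signatures
        self.min_r = min_r

    def fit(self, X=None, y=None):
        if not self.signatures:
            raise ValueError("no class signatures supplied")
        self.classes_ = [s.name for s in self.signatures]
        return self

    def predict(self, logratios: pd.DataFrame) -> pd.Series:
        """Class per sample of a genes x samples log-ratio matrix."""
        self.fit()
        calls = {
            s: verhaak_assign(logratios[s], self.signatures, self.min_r)[0]
            for s in logratios.columns
        }
        return pd.Series(calls, name="subtype")

    def correlations(self, logratios: pd.DataFrame) -> pd.DataFrame:
        """Per-sample, per-class Pearson correlations."""
        self.fit()
        rows = {
            s: verhaak_assign(logratios[s], self.signatures, self.min_r)[1]
            for s in logratios.columns
        }
        return pd.DataFrame(rows).T[self.classes_]


def transition_table(
    calls: pd.Series, pairs: pd.DataFrame
) -> tuple[pd.DataFrame, list[str]]:
    """Initial-class x recurrent-class counts over patient-matched pairs.

    Pairs with an unclassifiable member are excluded and their patient ids
    returned alongside the count matrix.
    """
    classes = sorted(
        {c for c in calls.unique() if c != UNCLASSIFIABLE}
    )
    table = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    excluded: list[str] = []
    for row in pairs.itertuples(index=False):
        ci, cr = calls.get(row.initial), calls.get(row.recurrent)
        if ci in (None, UNCLASSIFIABLE) or cr in (None, UNCLASSIFIABLE):
            excluded.append(row.patient)
            continue
        table.loc[ci, cr] += 1
    return table, excluded
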