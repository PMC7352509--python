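"""Three-state Gaussian HMM over chromosomally ordered expression log-ratios.

Each patient-matched tumor pair yields one log2(recurrent/initial) profile in
chromosomal gene order. Segmental DNA gains and losses shift the expression of
runs of neighboring genes coherently, so hidden expression states (under-,
un-, overexpressed) are locally persistent along the chromosome. A first-order
HMM with Gaussian emissions captures exactly this persistence: one model is
trained by Baum-Welch across all profiles (each chromosome an independent
sequence restarting from the initial distribution) and each gene is assigned
its maximum-posterior state by forward-backward decoding.

All recursions run in log-space for numerical stability on long sequences.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .params import HMMParams, STATE_CODES, STATE_LABELS

VAR_FLOOR = 1e-4


# ---------------------------------------------------------------------------
# low-level log-space recursions
# ---------------------------------------------------------------------------

def _log_gaussian(x: np.ndarray, means: np.ndarray, variances: np.ndarray) -> np.ndarray:
    """(T, K) log emission densities for a 1-D observation sequence."""
    x = np.asarray(x, dtype=float)[:, None]
    return -0.5 * (
        np.log(2.0 * np.pi * variances)[None, :]
        + (x - means[None, :]) ** 2 / variances[None, :]
    )

def _forward(logb: np.ndarray, log_pi: np.ndarray, log_a: np.ndarray) -> np.ndarray:
    T, K = logb.shape
    alpha = np.empty((T, K))
    alpha[0] = log_pi + logb[0]
    for t in range(1, T):
        alpha[t] = logb[t] + logsumexp(alpha[t - 1][:, None] + log_a, axis=0)
    return alpha

def _backward(logb: np.ndarray, log_a: np.ndarray) -> np.ndarray:
    T, K = logb.shape
    beta = np.zeros((T, K))
    for t in range(T - 2, -1, -1):
        beta[t] = logsumexp(log_a + (logb[t + 1] + beta[t + 1])[None, :], axis=1)
    return beta


def _split_chromosomes(values: np.ndarray, chrom: np.ndarray) -> list[np.ndarray]:
    """Split a gene-ordered vector into per-chromosome sequences (input order)."""
    seqs = []
    # preserve first-appearance order, not sorted order
    _, idx = np.unique(chrom, return_index=True)
    for c in chrom[np.sort(idx)]:
        seqs.append(values[chrom == c])
    return seqs


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class GaussianChainHMM(BaseEstimator):
    """First-order Gaussian HMM with ordered states, trained by Baum-Welch.

    Parameters
    ----------
    n_states : number of hidden states (3: under / unchanged / over).
    means_init : initial emission means; default (-3, 0, 3) log2 units.
    self_transition : initial self-transition probability (default 0.9).
    variances_init : initial emission variances (default 1).
    tied_variance : if True a single variance is shared across states.
    update_startprob, update_transmat : whether pi and A are re-estimated.
    tol : stop when the log-likelihood gain per iteration falls below this.
    max_iter : Baum-Welch iteration cap.

    Attributes (after :meth:`fit`)
    ------------------------------
    params_ : fitted :class:`HMMParams`.
    loglik_trace_ : per-iteration total log-likelihood (non-decreasing).
    n_iter_ : iterations actually run.
    """

    def __init__(
        self,
        n_states: int = 3,
        means_init=(-3.0, 0.0, 3.0),
        self_transition: float = 0.9,
        variances_init=None,
        tied_variance: bool = False,
        update_startprob: bool = True,
        update_transmat: bool = True,
        tol: float = 1e-4,
        max_iter: int = 200,
    ):
        self.n_states = n_states
        self.means_init = means_init
        self.self_transition = self_transition
        self.variances_init = variances_init
        self.tied_variance = tied_variance
        self.update_startprob = update_startprob
        self.update_transmat = update_transmat
        self.tol = tol
        self.max_iter = max_iter

    # -- initialization -----------------------------------------------------

    def _init_params(self) -> HMMParams:
        k = self.n_states
        means = np.asarray(self.means_init, dtype=float)
        if means.size != k:
            raise ValueError("means_init length must equal n_states")
        off = (1.0 - self.self_transition) / (k - 1) if k > 1 else 0.0
        transmat = np.full((k, k), off) + np.eye(k) * (self.self_transition - off)
        variances = (
            np.ones(k)
            if self.variances_init is None
            else np.broadcast_to(np.asarray(self.variances_init, float), (k,)).copy()
        )
        return HMMParams(
            startprob=np.full(k, 1.0 / k),
            transmat=transmat,
            means=means,
            variances=variances,
        ).validate()

    # -- public API ----------------------------------------------------------

    def fit(self, X, lengths=None, init: HMMParams | None = None):
        """Pooled multi-sequence Baum-Welch.

        Parameters
        ----------
        X : list of 1-D arrays (one per independent sequence), or a single
            1-D array with ``lengths`` giving the per-sequence lengths.
        init : optional explicit initial parameters overriding the
            constructor's initialization.
        """
        seqs = _as_sequences(X, lengths)
        params = (init or self._init_params()).validate()
        trace: list[float] = []
        for it in range(self.max_iter):
            ll, params = self._em_step(seqs, params)
            trace.append(ll)
            if len(trace) >= 2 and trace[-1] - trace[-2] < self.tol:
                break
        self.params_ = params
        self.loglik_trace_ = np.asarray(trace)
        self.n_iter_ = len(trace)
        return self

    def score(self, X, lengths=None, params: HMMParams | None = None) -> float:
        """Total log-likelihood of the sequences under the (fitted) model."""
        p = params if params is not None else self.params_
        p.validate()
        log_pi = _safe_log(p.startprob)
        log_a = _safe_log(p.transmat)
        total = 0.0
        for seq in _as_sequences(X, lengths):
            logb = _log_gaussian(seq, p.means, p.variances)
            total += float(logsumexp(_forward(logb, log_pi, log_a)[-1]))
        return total

    def predict_proba(self, X, lengths=None, params: HMMParams | None = None):
        """Per-position posterior state probabilities (forward-backward).

        Sequences are batched by length internally; the returned array
        concatenates the per-sequence posteriors in input order.
        """
        p = params if params is not None else self.params_
        p.validate()
        seqs = _as_sequences(X, lengths)
        by_length: dict[int, list[int]] = {}
        for i, seq in enumerate(seqs):
            by_length.setdefault(seq.size, []).append(i)
        results: dict[int, np.ndarray] = {}
        for T, idxs in by_length.items():
            gamma = _batched_posteriors(
                np.stack([seqs[i] for i in idxs]), p
            )
            for j, i in enumerate(idxs):
                results[i] = gamma[j]
        return np.concatenate([results[i] for i in range(len(seqs))], axis=0)

    def predict(self, X, lengths=None, params: HMMParams | None = None):
        """Maximum-posterior state per position; ties resolved to 'unchanged'."""
        gamma = self.predict_proba(X, lengths, params=params)
        return decode_labels(gamma)

    # -- EM internals ---------------------------------------------------------

    def _em_step(self, seqs, params: HMMParams):
        k = params.n_states
        log_pi = _safe_log(params.startprob)
        log_a = _safe_log(params.transmat)

        total_ll = 0.0
        start_acc = np.zeros(k)
        trans_acc = np.zeros((k, k))
        w_acc = np.zeros(k)
        wx_acc = np.zeros(k)
        wxx_acc = np.zeros(k)

        # batch equal-length sequences so the time recursion vectorizes
        by_length: dict[int, list[np.ndarray]] = {}
        for seq in seqs:
            by_length.setdefault(seq.size, []).append(seq)

        for T, group in by_length.items():
            S = np.stack(group)  # (m, T)
            m = S.shape[0]
            logb = -0.5 * (
                np.log(2.0 * np.pi * params.variances)[None, None, :]
                + (S[:, :, None] - params.means[None, None, :]) ** 2
                / params.variances[None, None, :]
            )  # (m, T, k)
            la = np.empty((m, T, k))
            la[:, 0] = log_pi[None, :] + logb[:, 0]
            for t in range(1, T):
                la[:, t] = logb[:, t] + logsumexp(
                    la[:, t - 1][:, :, None] + log_a[None, :, :], axis=1
                )
            lb = np.zeros((m, T, k))
            for t in range(T - 2, -1, -1):
                lb[:, t] = logsumexp(
                    log_a[None, :, :]
                    + (logb[:, t + 1] + lb[:, t + 1])[:, None, :],
                    axis=2,
                )
            ll = logsumexp(la[:, -1], axis=1)  # (m,)
            total_ll += float(ll.sum())
            gamma = np.exp(la + lb - ll[:, None, None])
            start_acc += gamma[:, 0].sum(axis=0)
            if T > 1:
                lx = (
                    la[:, :-1, :, None]
                    + log_a[None, None, :, :]
                    + (logb[:, 1:] + lb[:, 1:])[:, :, None, :]
                    - ll[:, None, None, None]
                )
                trans_acc += np.exp(logsumexp(lx, axis=(0, 1)))
            w_acc += gamma.sum(axis=(0, 1))
            wx_acc += np.einsum("mtk,mt->k", gamma, S)
            wxx_acc += np.einsum("mtk,mt->k", gamma, S**2)

        new = HMMParams(
            startprob=params.startprob.copy(),
            transmat=params.transmat.copy(),
            means=params.means.copy(),
            variances=params.variances.copy(),
        )
        if self.update_startprob:
            new.startprob = start_acc / start_acc.sum()
        if self.update_transmat:
            rows = trans_acc.sum(axis=1, keepdims=True)
            nz = rows[:, 0] > 0
            new.transmat[nz] = trans_acc[nz] / rows[nz]
        new.means = wx_acc / w_acc
        var = wxx_acc / w_acc - new.means**2
        if self.tied_variance:
            var[:] = np.sum(w_acc * var) / w_acc.sum()
        if np.any(var < VAR_FLOOR):
            warnings.warn("emission variance collapsed; clamped to floor")
            var = np.maximum(var, VAR_FLOOR)
        new.variances = var

        # enforce the under < unchanged < over labeling after each M-step
        order = np.argsort(new.means)
        if not np.array_equal(order, np.arange(k)):
            new.startprob = new.startprob[order]
            new.transmat = new.transmat[np.ix_(order, order)]
            new.means = new.means[order]
            new.variances = new.variances[order]
        return total_ll, new


def _batched_posteriors(S: np.ndarray, params: HMMParams) -> np.ndarray:
    """Forward-backward posteriors for a (m, T) stack of sequences."""
    m, T = S.shape
    k = params.n_states
    log_pi = _safe_log(params.startprob)
    log_a = _safe_log(params.transmat)
    logb = -0.5 * (
        np.log(2.0 * np.pi * params.variances)[None, None, :]
        + (S[:, :, None] - params.means[None, None, :]) ** 2
        / params.variances[None, None, :]
    )
    la = np.empty((m, T, k))
    la[:, 0] = log_pi[None, :] + logb[:, 0]
    for t in range(1, T):
        la[:, t] = logb[:, t] + logsumexp(
            la[:, t - 1][:, :, None] + log_a[None, :, :], axis=1
        )
    lb = np.zeros((m, T, k))
    for t in range(T - 2, -1, -1):
        lb[:, t] = logsumexp(
            log_a[None, :, :] + (logb[:, t + 1] + lb[:, t + 1])[:, None, :],
            axis=2,
        )
    lg = la + lb
    lg -= logsumexp(lg, axis=2, keepdims=True)
    return np.exp(lg)


def _safe_log(x: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(x)


def _as_sequences(X, lengths=None) -> list[np.ndarray]:
    if isinstance(X, np.ndarray) and X.ndim == 1:
        if lengths is None:
            return [np.asarray(X, float)]
        bounds = np.cumsum(lengths)
        if bounds[-1] != X.size:
            raise ValueError("lengths do not sum to the sequence length")
        return [np.asarray(s, float) for s in np.split(X, bounds[:-1])]
    seqs = [np.asarray(s, dtype=float).ravel() for s in X]
    if any(s.size == 0 for s in seqs):
        raise ValueError("empty sequence")
    return seqs


def decode_labels(gamma: np.ndarray) -> np.ndarray:
    """Argmax state codes (-1/0/+1) with exact ties resolved to 0 (unchanged)."""
    arg = np.argmax(gamma, axis=1)
    maxv = gamma[np.arange(gamma.shape[0]), arg]
    tie_unchanged = gamma[:, 1] >= maxv
    arg[tie_unchanged] = 1
    return np.asarray(STATE_CODES)[arg]


# ---------------------------------------------------------------------------
# profile-level interface
# ---------------------------------------------------------------------------

def pair_logratio(logexpr: pd.DataFrame, pairs: pd.DataFrame) -> pd.DataFrame:
    """Per-gene log2(recurrent/initial) profiles for each patient.

    Parameters
    ----------
    logexpr : genes x samples log2 expression, rows in chromosomal order.
    pairs : DataFrame with columns patient, initial, recurrent (sample ids).

    Returns genes x patients DataFrame of differences recurrent - initial.
    """
    out = {}
    for row in pairs.itertuples(index=False):
        for member in (row.initial, row.recurrent):
            if member not in logexpr.columns:
                raise KeyError(
                    f"sample {member!r} for patient {row.patient!r} missing "
                    "from the expression matrix"
                )
        out[row.patient] = logexpr[row.recurrent] - logexpr[row.initial]
    return pd.DataFrame(out, index=logexpr.index)


def profile_sequences(profiles: pd.DataFrame, chrom: np.ndarray) -> list[np.ndarray]:
    """Flatten genes x pairs profiles into per-chromosome training sequences."""
    chrom = np.asarray(chrom)
    if chrom.size != profiles.shape[0]:
        raise ValueError("chromosome vector length must match gene count")
    seqs = []
    for col in profiles.columns:
        seqs.extend(_split_chromosomes(profiles[col].to_numpy(float), chrom))
    return seqs


def fit_hmm(
    profiles: pd.DataFrame,
    chrom: np.ndarray,
    init: HMMParams | None = None,
    max_iter: int = 200,
    tol: float = 1e-4,
    **kwargs,
) -> tuple[HMMParams, np.ndarray]:
    """Train one pooled HMM across all pair profiles; returns (params, trace)."""
    model = GaussianChainHMM(max_iter=max_iter, tol=tol, **kwargs)
    model.fit(profile_sequences(profiles, chrom), init=init)
    return model.params_, model.loglik_trace_


def posterior_decode(
    profiles: pd.DataFrame, chrom: np.ndarray, params: HMMParams
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Forward-backward decoding of every pair profile.

    Returns
    -------
    posteriors : dict patient -> genes x 3 DataFrame of state posteriors.
    labels : genes x patients DataFrame of state codes (-1, 0, +1).
    """
    params.validate()
    model = GaussianChainHMM(n_states=params.n_states)
    chrom = np.asarray(chrom)
    seqs: list[np.ndarray] = []
    counts: list[int] = []
    for col in profiles.columns:
        parts = _split_chromosomes(profiles[col].to_numpy(float), chrom)
        seqs.extend(parts)
        counts.append(sum(p.size for p in parts))
    gamma_all = model.predict_proba(seqs, params=params)
    posteriors: dict[str, pd.DataFrame] = {}
    labels = {}
    offset = 0
    for col, n in zip(profiles.columns, counts):
        gamma = gamma_all[offset : offset + n]
        offset += n
        posteriors[col] = pd.DataFrame(
            gamma, index=profiles.index, columns=list(STATE_LABELS)
        )
        labels[col] = decode_labels(gamma)
    return posteriors, pd.DataFrame(labels, index=profiles.index)
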