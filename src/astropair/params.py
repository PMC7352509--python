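"""Parameter containers shared across modules."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

STATE_LABELS = ("under", "unchanged", "over")
STATE_CODES = (-1, 0, 1)


@dataclass
class HMMParams:
    """Parameters of a three-state first-order Gaussian HMM.

    States are ordered under < unchanged < over by their emission means.

    Attributes
    ----------
    startprob : (3,) initial state distribution.
    transmat : (3, 3) row-stochastic transition matrix.
    means : (3,) state emission means in log2 units, strictly increasing.
    variances : (3,) state emission variances, positive.
    """

    startprob: np.ndarray = field(
        default_factory=lambda: np.full(3, 1.0 / 3.0)
    )
    transmat: np.ndarray = field(
        default_factory=lambda: np.full((3, 3), 0.05) + np.eye(3) * 0.85
    )
    means: np.ndarray = field(default_factory=lambda: np.array([-3.0, 0.0, 3.0]))
    variances: np.ndarray = field(default_factory=lambda: np.ones(3))

    def __post_init__(self) -> None:
        self.startprob = np.asarray(self.startprob, dtype=float)
        self.transmat = np.asarray(self.transmat, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)

    @property
    def n_states(self) -> int:
        return self.means.size

    def validate(self, atol: float = 1e-10) -> "HMMParams":
        k = self.n_states
        if self.startprob.shape != (k,) or self.transmat.shape != (k, k):
            raise ValueError("inconsistent HMM parameter shapes")
        if not np.isclose(self.startprob.sum(), 1.0, atol=atol):
            raise ValueError("initial state probabilities must sum to 1")
        if np.any(self.startprob < -atol):
            raise ValueError("initial state probabilities must be non-negative")
        rows = self.transmat.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=atol):
            raise ValueError("transition matrix rows must sum to 1")
        if np.any(self.transmat < -atol):
            raise ValueError("transition probabilities must be non-negative")
        if np.any(self.variances <= 0):
            raise ValueError("emission variances must be positive")
        if np.any(np.diff(self.means) <= 0):
            raise ValueError("emission means must be strictly increasing")
        return self

    def stationary(self) -> np.ndarray:
        """Stationary distribution of the transition matrix (left eigenvector)."""
        vals, vecs = np.linalg.eig(self.transmat.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, i])
        return pi / pi.sum()

    def to_dict(self) -> dict:
        return {
            "startprob": self.startprob.tolist(),
            "transmat": self.transmat.tolist(),
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "HMMParams":
        return cls(
            startprob=np.asarray(d["startprob"], dtype=float),
            transmat=np.asarray(d["transmat"], dtype=float),
            means=np.asarray(d["means"], dtype=float),
            variances=np.asarray(d["variances"], dtype=float),
        )

    @classmethod
    def from_json(cls, path) -> "HMMParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
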