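"""General time-reversible (GTR) nucleotide substitution model.

State order is A, C, G, T.  Exchangeabilities follow the conventional pair
order (AC, AG, AT, CG, CT, GT).  The rate matrix is scaled so the expected
number of substitutions per site per unit branch length is one, i.e.
-sum_i pi_i Q_ii = 1; branch lengths are therefore expected substitutions
per site.  Transition probabilities P(t) = exp(Qt) are computed from the
symmetrised eigendecomposition, which is exact for any reversible Q.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

STATES = "ACGT"
STATE_INDEX = {b: i for i, b in enumerate(STATES)}
PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


@dataclass(frozen=True)
class GTRParams:
    """Exchangeabilities (6, normalised to sum 1) and stationary frequencies."""

    rates: tuple[float, ...]
    freqs: tuple[float, ...]

    def __post_init__(self) -> None:
        rates = np.asarray(self.rates, dtype=float)
        freqs = np.asarray(self.freqs, dtype=float)
        if rates.shape != (6,) or np.any(rates < 0) or rates.sum() <= 0:
            raise ValueError("need 6 non-negative exchangeabilities, not all zero")
        if freqs.shape != (4,) or np.any(freqs <= 0) or abs(freqs.sum() - 1) > 1e-8:
            raise ValueError("frequencies must be positive and sum to 1")
        object.__setattr__(self, "rates", tuple(rates / rates.sum()))
        object.__setattr__(self, "freqs", tuple(freqs / freqs.sum()))

    @classmethod
    def jukes_cantor(cls) -> "GTRParams":
        return cls(rates=(1 / 6,) * 6, freqs=(0.25,) * 4)

    def rate_matrix(self) -> np.ndarray:
        """Q scaled to mean rate 1; rows sum to zero."""
        pi = np.asarray(self.freqs)
        Q = np.zeros((4, 4))
        for r, (i, j) in zip(self.rates, PAIRS):
            Q[i, j] = r * pi[j]
            Q[j, i] = r * pi[i]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mean_rate = -float(np.dot(pi, np.diag(Q)))
        return Q / mean_rate

    def detailed_balance_residual(self) -> float:
        """max |pi_i Q_ij - pi_j Q_ji|; zero for a reversible model."""
        pi = np.asarray(self.freqs)
        Q = self.rate_matrix()
        F = pi[:, None] * Q
        return float(np.max(np.abs(F - F.T)))


class TransitionCalculator:
    """Caches the eigendecomposition of one Q to evaluate P(t) cheaply."""

    def __init__(self, params: GTRParams):
        self.params = params
        pi = np.asarray(params.freqs)
        Q = params.rate_matrix()
        sqrt_pi = np.sqrt(pi)
        B = (sqrt_pi[:, None] * Q) / sqrt_pi[None, :]  # symmetric
        eigval, eigvec = np.linalg.eigh((B + B.T) / 2)
        self._eigval = eigval
        self._left = eigvec / sqrt_pi[:, None]  # D^-1/2 V
        self._right = eigvec.T * sqrt_pi[None, :]  # V^T D^1/2

    def probability_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to one for any t >= 0."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        P = (self._left * np.exp(self._eigval * t)) @ self._right
        np.clip(P, 0.0, None, out=P)
        return P / P.sum(axis=1, keepdims=True)

    def probability_matrices(self, ts: np.ndarray) -> np.ndarray:
        """Stacked P(t) for an array of branch lengths, shape (len(ts), 4, 4)."""
        ts = np.asarray(ts, dtype=float)
        if np.any(ts < 0):
            raise ValueError("branch lengths must be non-negative")
        expo = np.exp(self._eigval[None, :] * ts[:, None])  # (T, 4)
        P = np.einsum("ik,tk,kj->tij", self._left, expo, self._right)
        np.clip(P, 0.0, None, out=P)
        return P / P.sum(axis=2, keepdims=True)


def jc_p_same(t: float) -> float:
    """Jukes-Cantor closed form: P(no observed change) on one branch of
    length t under the mean-rate-1 scaling."""
    return 0.25 + 0.75 * np.exp(-4.0 * t / 3.0)


def encode_bases(bases: str) -> np.ndarray:
    """Map a base string to state indices; anything not ACGT becomes -1
    (fully ambiguous, integrates to one in likelihoods)."""
    out = np.full(len(bases), -1, dtype=np.int8)
    for i, b in enumerate(bases.upper()):
        out[i] = STATE_INDEX.get(b, -1)
    return out
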