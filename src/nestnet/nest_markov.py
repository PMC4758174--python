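"""Markov-chain model of daytime nest-site switching.

A squirrel with ``n`` nest sites is modelled as a discrete-time Markov chain
over those sites, one step per day.  The transition matrix comes from a
multinomial (row-softmax) regression on the nest network:

    L = b_I * I + (1 - I) * (b_D * D + b_C * C)
    P_ij = exp(L_ij) / sum_j exp(L_ij)

where ``I`` is the identity (staying put), ``D`` the log inter-nest distance
matrix and ``C`` a binary connectivity matrix; the ``(1 - I)`` factor makes
distance and connectivity act only conditional on switching.  Between
observations ``dt`` days apart the state evolves as ``z(t + dt) = z(t) P^dt``,
so irregular observation gaps are handled exactly by matrix powers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

LOG_FLOOR = 1e-300  # guards log() against exact underflow; unreachable for finite L


@dataclass(frozen=True)
class IndividualParams:
    """Regression coefficients (b_I, b_D, b_C) for one individual."""

    beta_I: float
    beta_D: float = 0.0
    beta_C: float = 0.0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.as_array())):
            raise ValueError("beta parameters must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.beta_I, self.beta_D, self.beta_C])

    @classmethod
    def from_array(cls, beta: np.ndarray) -> "IndividualParams":
        return cls(*(float(v) for v in beta))


@dataclass(frozen=True)
class NestSequence:
    """Chronological daytime nest observations for one individual.

    ``observations`` is an ordered list of (day, nest_index) with strictly
    increasing integer days and 0-based nest indices.  Same-day duplicates
    must be collapsed upstream (see :func:`sequence_from_records`).
    """

    individual_id: str
    observations: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        days = [d for d, _ in self.observations]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("observation days must be strictly increasing")
        if any(j < 0 for _, j in self.observations):
            raise ValueError("nest indices must be non-negative")

    @property
    def n_obs(self) -> int:
        return len(self.observations)

    def transition_counts(self, n_nests: int) -> dict[int, np.ndarray]:
        """Aggregate transitions into per-gap count matrices.

        Returns {dt: n x n matrix of counts of (i at t, j at t+dt)}.  The
        log-likelihood is a sufficient-statistics sum over these counts, so
        they are precomputed once per individual and reused by the sampler.
        """
        if any(j >= n_nests for _, j in self.observations):
            raise IndexError("nest_index out of range for this nest network")
        counts: dict[int, np.ndarray] = {}
        obs = self.observations
        for (d0, i), (d1, j) in zip(obs, obs[1:]):
            dt = d1 - d0
            if dt not in counts:
                counts[dt] = np.zeros((n_nests, n_nests))
            counts[dt][i, j] += 1
        return counts


def sequence_from_records(individual_id: str, days, nest_indices) -> NestSequence:
    """Build a NestSequence, collapsing same-day duplicate records."""
    seen: dict[int, int] = {}
    for d, j in zip(days, nest_indices):
        seen[int(d)] = int(j)
    obs = tuple(sorted(seen.items()))
    return NestSequence(individual_id=individual_id, observations=obs)


def linear_predictor(beta: IndividualParams | np.ndarray, D: np.ndarray, C: np.ndarray | None) -> np.ndarray:
    """Build L = b_I*I + (1-I)*(b_D*D + b_C*C).

    ``C=None`` (or ``D=None``) drops that term structurally (its coefficient
    contributes 0 regardless of the stored beta value).
    """
    b = beta.as_array() if isinstance(beta, IndividualParams) else np.asarray(beta, float)
    if D is None and C is None:
        raise ValueError("at least one of D, C must be given")
    ref = D if D is not None else C
    n = ref.shape[0]
    if ref.shape != (n, n) or (D is not None and C is not None and D.shape != C.shape):
        raise ValueError(f"D and C must be square and same shape, got {np.shape(D)} vs {np.shape(C)}")
    off = np.zeros((n, n))
    if D is not None:
        off += b[1] * D
    if C is not None:
        off += b[2] * C
    L = (1.0 - np.eye(n)) * off
    L[np.diag_indices(n)] = b[0]
    return L


def transition_matrix(L: np.ndarray) -> np.ndarray:
    """Row-wise softmax of the linear predictor (max-subtracted for safety)."""
    L = np.asarray(L, dtype=float)
    if not np.all(np.isfinite(L)):
        raise ValueError("linear predictor must be finite")
    shifted = L - L.max(axis=1, keepdims=True)
    E = np.exp(shifted)
    return E / E.sum(axis=1, keepdims=True)


def evolve(P: np.ndarray, delta_t: int) -> np.ndarray:
    """P^dt by repeated squaring; dt must be a positive integer (days)."""
    if int(delta_t) != delta_t or delta_t < 1:
        raise ValueError(f"delta_t must be a positive integer, got {delta_t}")
    return np.linalg.matrix_power(P, int(delta_t))


def sequence_loglik(
    seq: NestSequence,
    beta: IndividualParams | np.ndarray,
    D: np.ndarray | None,
    C: np.ndarray | None,
) -> float:
    """Log-likelihood of an observed nest sequence under the chain.

    Sum over consecutive observation pairs of ``log [P^dt]_{ij}``; a single
    observation carries no transition information and scores 0.
    """
    ref = D if D is not None else C
    counts = seq.transition_counts(ref.shape[0])
    L = linear_predictor(beta, D, C)
    P = transition_matrix(L)
    return _loglik_from_counts(counts, P)


def _loglik_from_counts(counts: dict[int, np.ndarray], P: np.ndarray) -> float:
    total = 0.0
    for dt, N in counts.items():
        Pdt = np.linalg.matrix_power(P, dt)
        total += float(np.sum(N * np.log(np.maximum(Pdt, LOG_FLOOR))))
    return total


def simulate_sequence(
    beta: IndividualParams | np.ndarray,
    D: np.ndarray | None,
    C: np.ndarray | None,
    start_index: int,
    observation_days,
    rng: np.random.Generator | int,
) -> NestSequence:
    """Forward-simulate a nest sequence on a given observation schedule.

    Each next nest is drawn from the row of ``P^dt`` for the current nest,
    where ``dt`` is the gap to the next observation day.  Reproducible under
    a fixed seed or Generator.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    days = [int(d) for d in observation_days]
    if any(b <= a for a, b in zip(days, days[1:])):
        raise ValueError("observation_days must be strictly increasing")
    L = linear_predictor(beta, D, C)
    P = transition_matrix(L)
    powers: dict[int, np.ndarray] = {}
    obs = [(days[0], start_index)]
    current = start_index
    for d0, d1 in zip(days, days[1:]):
        dt = d1 - d0
        if dt not in powers:
            powers[dt] = np.linalg.matrix_power(P, dt)
        row = powers[dt][current]
        current = int(rng.choice(len(row), p=row / row.sum()))
        obs.append((d1, current))
    return NestSequence(individual_id="sim", observations=tuple(obs))
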