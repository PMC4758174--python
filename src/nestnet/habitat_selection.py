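"""Compositional analysis of habitat selection (used vs. available).

Habitat use during movement bursts is compared with habitat availability
within the home range over the four terrestrial classes H1-H4, following
the log-ratio compositional approach: for each individual the vector of
differences

    d_i = ln(used_i / used_ref) - ln(avail_i / avail_ref)

is computed against a reference habitat, the multivariate null "no
selection" (mean d = 0) is tested with Wilks Lambda evaluated by a
sign-randomization of individuals, and pairwise habitat ranking comes from
the antisymmetric matrix of mean log-ratio differences.

Zero handling mirrors common practice with small samples: zero *used*
proportions are replaced by 0.01 (without renormalizing), and log-ratios
undefined because a habitat was *unavailable* to an individual are imputed
with the mean of that log-ratio over the other individuals.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

HABITATS = ("H1", "H2", "H3", "H4")
ZERO_USE_REPLACEMENT = 0.01


class ImputationError(ValueError):
    pass


class SingularityError(np.linalg.LinAlgError):
    pass


@dataclass(frozen=True)
class CompositionTable:
    """Used and available habitat proportions per individual (rows x H1-H4)."""

    individual_ids: tuple[str, ...]
    sexes: tuple[str, ...]
    used: np.ndarray       # (n, 4) proportions
    available: np.ndarray  # (n, 4) proportions

    def __post_init__(self) -> None:
        n = len(self.individual_ids)
        for arr, label in ((self.used, "used"), (self.available, "available")):
            if arr.shape != (n, len(HABITATS)):
                raise ValueError(f"{label} must be (n_individuals, 4)")
            if (arr < 0).any():
                raise ValueError(f"{label} proportions must be non-negative")

    @property
    def n(self) -> int:
        return len(self.individual_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CompositionTable":
        """Build from a long table (individual_id, sex, habitat, used_prop,
        avail_prop)."""
        wide_u = df.pivot(index="individual_id", columns="habitat", values="used_prop")
        wide_a = df.pivot(index="individual_id", columns="habitat", values="avail_prop")
        sexes = df.drop_duplicates("individual_id").set_index("individual_id")["sex"]
        ids = tuple(wide_u.index)
        return cls(
            individual_ids=ids,
            sexes=tuple(sexes.loc[list(ids)]),
            used=wide_u[list(HABITATS)].to_numpy(float),
            available=wide_a[list(HABITATS)].to_numpy(float),
        )

    def subset(self, sex: str) -> "CompositionTable":
        keep = [k for k, s in enumerate(self.sexes) if s == sex]
        return CompositionTable(
            tuple(self.individual_ids[k] for k in keep),
            tuple(self.sexes[k] for k in keep),
            self.used[keep], self.available[keep],
        )


@dataclass(frozen=True)
class SelectionResult:
    ranking_matrix: pd.DataFrame  # 4x4 mean log-ratio differences
    ranks: dict[str, int]         # habitat -> rank (1 = most used)
    wilks_lambda: float
    p_value: float
    pairwise_p: pd.DataFrame      # 4x4 randomization p per cell
    n_individuals: int
    exhaustive: bool              # whether the sign-flip test was exhaustive


def prepare_compositions(table: CompositionTable) -> tuple[np.ndarray, np.ndarray]:
    """Zero-adjusted used proportions and the imputed log-ratio cube.

    Returns ``(used_adj, lr)`` where ``lr[l, i, j]`` is individual ``l``'s
    log-ratio difference between habitats i and j, with entries that were
    undefined because of zero availability imputed by the cross-individual
    mean of that same log-ratio.
    """
    if table.n < 2:
        raise ValueError("compositional analysis needs >= 2 individuals")
    used = table.used.copy()
    used[used == 0] = ZERO_USE_REPLACEMENT
    avail = table.available
    h = len(HABITATS)
    with np.errstate(divide="ignore", invalid="ignore"):
        lu = np.log(used)
        la = np.log(avail)
    la[~np.isfinite(la)] = np.nan
    lr = (lu[:, :, None] - lu[:, None, :]) - (la[:, :, None] - la[:, None, :])
    for i, j in product(range(h), range(h)):
        col = lr[:, i, j]
        bad = ~np.isfinite(col)
        if bad.all() and i != j:
            raise ImputationError(
                f"habitat pair ({HABITATS[i]}, {HABITATS[j]}): unavailable for "
                "every individual; imputation impossible"
            )
        if bad.any():
            col[bad] = np.nanmean(col[~bad]) if (~bad).any() else 0.0
    return used, lr


def _wilks_lambda(d: np.ndarray) -> float:
    """Lambda = |residual cross-products| / |total cross-products| for H0:
    mean(d) = 0."""
    total = d.T @ d
    if np.trace(total) < 1e-12:
        return 1.0  # used == available for everyone: no selection signal
    centered = d - d.mean(axis=0)
    resid = centered.T @ centered
    det_total = np.linalg.det(total)
    if det_total <= 0 or not np.isfinite(det_total):
        raise SingularityError(
            "singular cross-product matrix; consider pooling habitat classes"
        )
    return float(np.linalg.det(resid) / det_total)


def _sign_patterns(n: int, n_randomizations: int, rng: np.random.Generator, exhaustive_limit: int = 12):
    """Sign-flip patterns: exhaustive 2^n when n is small, else Monte-Carlo."""
    if n <= exhaustive_limit:
        signs = np.array(list(product((1.0, -1.0), repeat=n)))
        return signs, True
    signs = rng.choice([1.0, -1.0], size=(n_randomizations, n))
    signs[0] = 1.0  # the observed labelling is always included
    return signs, False


def compositional_analysis(
    table: CompositionTable,
    n_randomizations: int = 999,
    seed: int | np.random.Generator = 0,
    reference: str = "H1",
    exhaustive_limit: int = 12,
) -> SelectionResult:
    """Full compositional habitat-selection analysis.

    Wilks Lambda tests the overall departure from "use == availability";
    its p-value comes from sign-randomization of individuals' log-ratio
    difference vectors (exhaustive over all 2^n flips when n <= 12, else
    ``n_randomizations`` Monte-Carlo flips including the observed one).
    The ranking matrix holds mean pairwise log-ratio differences, each cell
    with its own univariate sign-randomization p-value.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    _, lr = prepare_compositions(table)
    h = len(HABITATS)
    ref = HABITATS.index(reference)
    others = [k for k in range(h) if k != ref]
    d = lr[:, others, ref]  # (n, 3)
    n = table.n

    lam_obs = _wilks_lambda(d)
    signs, exhaustive = _sign_patterns(n, n_randomizations + 1, rng, exhaustive_limit)
    lam_rand = np.array([_wilks_lambda(d * s[:, None]) for s in signs])
    p_value = float(np.mean(lam_rand <= lam_obs + 1e-12))

    M = lr.mean(axis=0)  # antisymmetric by construction
    pairwise_p = np.ones((h, h))
    obs_means = np.abs(M)
    for i in range(h):
        for j in range(i + 1, h):
            col = lr[:, i, j]
            rand_means = np.abs(signs @ col) / n
            pairwise_p[i, j] = pairwise_p[j, i] = float(
                np.mean(rand_means >= obs_means[i, j] - 1e-12)
            )

    order = np.argsort(-(M > 0).sum(axis=1), kind="stable")
    ranks = {HABITATS[k]: r + 1 for r, k in enumerate(order)}
    idx = list(HABITATS)
    return SelectionResult(
        ranking_matrix=pd.DataFrame(M, index=idx, columns=idx),
        ranks=ranks,
        wilks_lambda=lam_obs,
        p_value=p_value,
        pairwise_p=pd.DataFrame(pairwise_p, index=idx, columns=idx),
        n_individuals=n,
        exhaustive=exhaustive,
    )


def format_ranking(result: SelectionResult, alpha: float = 0.05) -> str:
    """Human-readable ranking summary (matrix, significance marks, ranks)."""
    lines = ["Ranking matrix (mean log-ratio differences, row vs column):"]
    M, P = result.ranking_matrix, result.pairwise_p
    header = "          " + "".join(f"{h:>12}" for h in HABITATS) + "   rank"
    lines.append(header)
    for hrow in HABITATS:
        cells = []
        for hcol in HABITATS:
            mark = "*" if (hrow != hcol and P.loc[hrow, hcol] < alpha) else " "
            cells.append(f"{M.loc[hrow, hcol]:>11.3f}{mark}")
        lines.append(f"{hrow:>6}    " + "".join(cells) + f"   {result.ranks[hrow]}")
    lines.append(
        f"Wilks lambda = {result.wilks_lambda:.3f}, randomization p = "
        f"{result.p_value:.4f} ({'exhaustive' if result.exhaustive else 'Monte-Carlo'}, "
        f"n = {result.n_individuals})"
    )
    return "\n".join(lines)
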