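"""Exact and Monte-Carlo test of Mendelian segregation across N2 families.

A dominant suppressor transmitted in Mendelian fashion passes to each N2
with probability 1/2, and a carrier N2 passes it to each assessed N3
offspring with probability 1/2 — so 25% of all N3 offspring are expected
to show trait improvement, arriving in a characteristic family pattern:
roughly half of N2 families contribute no improved offspring at all,
while the other half contribute improved offspring at rate 1/2.

The null for one family of n assessed Mecp2/Y N3 offspring is therefore
a hierarchical Bernoulli mixture:

    P(K = k) = (1 - p_c) * 1{k = 0} + p_c * C(n, k) p_t^k (1 - p_t)^(n-k)

with p_c = P(N2 carrier) = 0.5 and p_t = P(improved | carrier parent)
= 0.5.  Families are independent, and the test conditions on the observed
family sizes.  Extremeness is probability ordering: the p-value sums the
null probabilities of every per-family count configuration whose null
probability does not exceed that of the observed configuration — the
standard construction for exact multinomial-style tests, two-sided and
parameter-free.  When the configuration space is too large to enumerate,
a Monte-Carlo version with the add-one correction is used instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .scoring import InvalidInputError

# relative tolerance when comparing configuration probabilities, so that
# configurations tied with the observed one (up to float error) count as
# "as extreme"
_TIE_RTOL = 1e-9


class EnumerationLimitError(RuntimeError):
    """Raised when the exact test's configuration space exceeds the cap."""


@dataclass(frozen=True)
class FamilyCount:
    """Improved / total assessed Mecp2/Y N3 offspring of one N2 family."""

    n_offspring: int
    n_improved: int

    def __post_init__(self) -> None:
        if self.n_offspring < 1:
            raise InvalidInputError(
                f"n_offspring must be >= 1, got {self.n_offspring}"
            )
        if not 0 <= self.n_improved <= self.n_offspring:
            raise InvalidInputError(
                f"n_improved must be in 0..{self.n_offspring}, got {self.n_improved}"
            )


@dataclass(frozen=True)
class LineSegregation:
    """Per-family improvement counts for one founder line."""

    line_id: str
    families: Tuple[FamilyCount, ...]

    def __post_init__(self) -> None:
        if not self.families:
            raise InvalidInputError("at least one family required")
        object.__setattr__(self, "families", tuple(self.families))

    @property
    def family_sizes(self) -> Tuple[int, ...]:
        return tuple(f.n_offspring for f in self.families)

    @property
    def observed_counts(self) -> Tuple[int, ...]:
        return tuple(f.n_improved for f in self.families)


@dataclass(frozen=True)
class MendelianNull:
    """Hierarchical Bernoulli null: carrier and transmission probabilities."""

    p_carrier: float = 0.5
    p_transmit: float = 0.5

    def __post_init__(self) -> None:
        for name in ("p_carrier", "p_transmit"):
            p = getattr(self, name)
            if not 0 < p < 1:
                raise InvalidInputError(f"{name} must be in (0, 1), got {p}")


DEFAULT_NULL = MendelianNull()


@dataclass(frozen=True)
class MendelianTestResult:
    p_value: float
    method: str  # "exact" or "monte_carlo"
    observed_config_probability: float
    n_replicates: Optional[int] = None


def family_pmf(n: int, k: int, null: MendelianNull = DEFAULT_NULL) -> float:
    """Null probability of k improved among n offspring of one N2 family."""
    if n < 1:
        raise InvalidInputError(f"n must be >= 1, got {n}")
    if not 0 <= k <= n:
        raise InvalidInputError(f"k must be in 0..{n}, got {k}")
    binom = (
        math.comb(n, k)
        * null.p_transmit**k
        * (1.0 - null.p_transmit) ** (n - k)
    )
    point = (1.0 - null.p_carrier) if k == 0 else 0.0
    return point + null.p_carrier * binom


def _pmf_table(n: int, null: MendelianNull) -> np.ndarray:
    return np.array([family_pmf(n, k, null) for k in range(n + 1)])


def expected_improved_fraction(null: MendelianNull = DEFAULT_NULL) -> float:
    """Expected fraction of improved N3 offspring: p_carrier * p_transmit."""
    return null.p_carrier * null.p_transmit


def observed_config_probability(
    line: LineSegregation, null: MendelianNull = DEFAULT_NULL
) -> float:
    """Null probability of the observed per-family count configuration."""
    return math.prod(
        family_pmf(f.n_offspring, f.n_improved, null) for f in line.families
    )


def exact_test(
    line: LineSegregation,
    null: MendelianNull = DEFAULT_NULL,
    max_configs: int = 10**7,
) -> MendelianTestResult:
    """Exact probability-ordering p-value by full configuration enumeration.

    Enumerates every per-family count vector (conditioning on the observed
    family sizes) and sums the probabilities of configurations no more
    probable than the observed one.
    """
    sizes = line.family_sizes
    n_configs = math.prod(n + 1 for n in sizes)
    if n_configs > max_configs:
        raise EnumerationLimitError(
            f"{n_configs} configurations exceed the cap of {max_configs}; "
            "use monte_carlo_test"
        )
    probs = np.array([1.0])
    for n in sizes:
        probs = np.multiply.outer(probs, _pmf_table(n, null)).ravel()
    p_obs = observed_config_probability(line, null)
    p = float(probs[probs <= p_obs * (1.0 + _TIE_RTOL)].sum())
    return MendelianTestResult(
        p_value=min(p, 1.0),
        method="exact",
        observed_config_probability=p_obs,
    )


def _simulate_null_counts(
    sizes: Sequence[int],
    null: MendelianNull,
    reps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """(reps, n_families) matrix of improved counts drawn from the null."""
    sizes = np.asarray(sizes)
    carrier = rng.random((reps, len(sizes))) < null.p_carrier
    counts = rng.binomial(sizes[None, :], null.p_transmit, size=(reps, len(sizes)))
    counts[~carrier] = 0
    return counts


def monte_carlo_test(
    line: LineSegregation,
    null: MendelianNull = DEFAULT_NULL,
    reps: int = 10_000,
    seed: int = 0,
) -> MendelianTestResult:
    """Monte-Carlo probability-ordering p-value.

    Simulates ``reps`` lines from the null conditional on the observed
    family sizes and reports (1 + #{prob <= prob_obs}) / (reps + 1); the
    add-one correction keeps the p-value strictly positive and valid.
    """
    if reps < 1:
        raise InvalidInputError(f"reps must be >= 1, got {reps}")
    rng = np.random.default_rng(seed)
    sizes = line.family_sizes
    tables = [np.log(_pmf_table(n, null)) for n in sizes]
    counts = _simulate_null_counts(sizes, null, reps, rng)
    log_probs = np.zeros(reps)
    for j, table in enumerate(tables):
        log_probs += table[counts[:, j]]
    log_p_obs = math.log(observed_config_probability(line, null))
    hits = int(np.sum(log_probs <= log_p_obs + math.log1p(_TIE_RTOL)))
    return MendelianTestResult(
        p_value=(1 + hits) / (reps + 1),
        method="monte_carlo",
        observed_config_probability=math.exp(log_p_obs),
        n_replicates=reps,
    )


def segregation_test(
    line: LineSegregation,
    null: MendelianNull = DEFAULT_NULL,
    max_configs: int = 10**7,
    mc_reps: int = 100_000,
    seed: int = 0,
) -> MendelianTestResult:
    """Exact test when enumerable, Monte-Carlo fallback otherwise."""
    try:
        return exact_test(line, null, max_configs=max_configs)
    except EnumerationLimitError:
        return monte_carlo_test(line, null, reps=mc_reps, seed=seed)


def simulate_null_lines(
    family_sizes: Sequence[int],
    n_lines: int,
    null: MendelianNull = DEFAULT_NULL,
    seed: int = 0,
) -> List[LineSegregation]:
    """Draw whole lines from the null — for calibration and power studies."""
    rng = np.random.default_rng(seed)
    counts = _simulate_null_counts(family_sizes, null, n_lines, rng)
    return [
        LineSegregation(
            line_id=f"null_{i}",
            families=tuple(
                FamilyCount(n, int(k)) for n, k in zip(family_sizes, row)
            ),
        )
        for i, row in enumerate(counts)
    ]


def exact_pvalues_for_sizes(
    family_sizes: Sequence[int],
    observed_matrix: np.ndarray,
    null: MendelianNull = DEFAULT_NULL,
    max_configs: int = 10**7,
) -> np.ndarray:
    """Vectorized exact p-values for many lines sharing one family structure.

    Enumerates the configuration space once, then maps each row of
    ``observed_matrix`` (improved counts per family) to its p-value via a
    sorted cumulative sum — used for null-calibration simulations where
    re-enumerating per line would be wasteful.
    """
    sizes = tuple(family_sizes)
    n_configs = math.prod(n + 1 for n in sizes)
    if n_configs > max_configs:
        raise EnumerationLimitError(f"{n_configs} configurations exceed the cap")
    probs = np.array([1.0])
    tables = [_pmf_table(n, null) for n in sizes]
    for table in tables:
        probs = np.multiply.outer(probs, table).ravel()
    order = np.argsort(probs)
    sorted_probs = probs[order]
    cum = np.cumsum(sorted_probs)
    observed_matrix = np.asarray(observed_matrix)
    p_obs = np.ones(observed_matrix.shape[0])
    for j, table in enumerate(tables):
        p_obs *= table[observed_matrix[:, j]]
    idx = np.searchsorted(sorted_probs, p_obs * (1.0 + _TIE_RTOL), side="right")
    return np.minimum(cum[np.maximum(idx - 1, 0)], 1.0)
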