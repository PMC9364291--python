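"""Two-high-threshold MPT model of source monitoring.

The model describes responses in a three-alternative forced-choice (3AFC)
source-monitoring test in which studied items were presented with either a
schema-expected or a schema-unexpected source, and distractor ("new") items
were never presented.  Each of the three trial types (expected-source,
unexpected-source, new) has its own processing tree built from seven
probability parameters:

- ``D_E`` / ``D_U``: probability that an item from the expected / unexpected
  source is recognized as old (item memory),
- ``D_N``: probability that a participant knows that a new item is new,
- ``d_E`` / ``d_U``: probability of remembering the expected / unexpected
  source given the item was recognized (source memory),
- ``b``: probability of guessing "old" for an unrecognized item,
- ``g``: probability of guessing the schema-expected source when source
  memory fails (schema-consistent guessing bias; g > .5 means a bias toward
  the expected source).

With one aggregate 3x3 frequency table the full model is not identifiable;
an equality restriction ties ``D_N`` to ``D_U`` (default) or to ``D_E``,
leaving six free parameters for six data degrees of freedom, so the
restricted aggregate model is exactly identified and typically fits the
observed proportions perfectly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import optimize
from scipy.special import expit, logit

TRIAL_TYPES = ("expected", "unexpected", "new")
RESPONSES = ("expected", "unexpected", "new")
PARAM_NAMES = ("D_E", "D_U", "D_N", "d_E", "d_U", "b", "g")
#: order of the six free parameters under an identifiability restriction
FREE_PARAM_NAMES = ("D_E", "D_U", "d_E", "d_U", "b", "g")

Restriction = Literal["D_N=D_U", "D_N=D_E", "none"]


class MPTDomainError(ValueError):
    """A parameter or table violates the model's domain contract."""


@dataclass(frozen=True)
class MPTParameters:
    """The seven tree probabilities with an identifiability restriction tag.

    When ``restriction`` is ``"D_N=D_U"`` (or ``"D_N=D_E"``) the tied fields
    must be exactly equal; :meth:`from_free` constructs a consistent instance
    from the six free parameters.
    """

    D_E: float
    D_U: float
    D_N: float
    d_E: float
    d_U: float
    b: float
    g: float
    restriction: Restriction = "D_N=D_U"

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v) or not (0.0 <= v <= 1.0):
                raise MPTDomainError(f"parameter {name}={v!r} outside [0, 1]")
        if self.restriction == "D_N=D_U" and self.D_N != self.D_U:
            raise MPTDomainError("restriction D_N=D_U but D_N != D_U")
        if self.restriction == "D_N=D_E" and self.D_N != self.D_E:
            raise MPTDomainError("restriction D_N=D_E but D_N != D_E")
        if self.restriction not in ("D_N=D_U", "D_N=D_E", "none"):
            raise MPTDomainError(f"unknown restriction {self.restriction!r}")

    @classmethod
    def from_free(
        cls, free: Sequence[float], restriction: Restriction = "D_N=D_U"
    ) -> "MPTParameters":
        """Build parameters from the free vector (D_E, D_U, d_E, d_U, b, g)."""
        D_E, D_U, d_E, d_U, b, g = (float(v) for v in free)
        if restriction == "D_N=D_U":
            D_N = D_U
        elif restriction == "D_N=D_E":
            D_N = D_E
        else:
            raise MPTDomainError(
                "from_free requires a tie restriction (D_N=D_U or D_N=D_E)"
            )
        return cls(D_E, D_U, D_N, d_E, d_U, b, g, restriction)

    def free_vector(self) -> np.ndarray:
        """The six free parameters in :data:`FREE_PARAM_NAMES` order."""
        return np.array([self.D_E, self.D_U, self.d_E, self.d_U, self.b, self.g])

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAM_NAMES}


@dataclass(frozen=True)
class CategoryDistribution:
    """P(response | trial type) as a 3x3 row-stochastic array.

    Rows follow :data:`TRIAL_TYPES`, columns :data:`RESPONSES`.
    """

    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (3, 3):
            raise MPTDomainError(f"expected a 3x3 array, got shape {p.shape}")
        if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
            raise MPTDomainError("category probabilities outside [0, 1]")
        if np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-12):
            raise MPTDomainError("category probability rows must sum to 1")
        object.__setattr__(self, "probs", p)

    def __getitem__(self, key):
        return self.probs[key]


@dataclass(frozen=True)
class FrequencyTable:
    """Aggregated response counts: 3x3 (3AFC) or 2x2 (2AFC) layout.

    Rows are trial types, columns responses.  2AFC tables (source
    attributions without a "new" option) have no third row/column.
    """

    counts: np.ndarray
    label: str = ""
    task: Literal["3afc", "2afc"] = "3afc"

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if not np.issubdtype(c.dtype, np.integer):
            if not np.allclose(c, np.round(c)):
                raise MPTDomainError("counts must be integers")
            c = np.round(c).astype(np.int64)
        else:
            c = c.astype(np.int64)
        expected_shape = (3, 3) if self.task == "3afc" else (2, 2)
        if c.shape != expected_shape:
            raise MPTDomainError(
                f"{self.task} table must be {expected_shape}, got {c.shape}"
            )
        if np.any(c < 0):
            raise MPTDomainError("counts must be non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def proportions(self) -> np.ndarray:
        totals = self.row_totals.astype(float)
        if np.any(totals == 0):
            raise MPTDomainError(f"table {self.label!r} has an empty row")
        return self.counts / totals[:, None]


@dataclass(frozen=True)
class MLFitResult:
    """Aggregate maximum-likelihood fit of the restricted model."""

    params: MPTParameters
    log_likelihood: float
    g_squared: float
    df: int
    converged: bool
    boundary: bool
    method: str = "closed_form"


def _free_to_probs(free: np.ndarray, restriction: Restriction) -> np.ndarray:
    """Category probabilities from free-vector(s); broadcasts over leading axes."""
    free = np.asarray(free, dtype=float)
    D_E, D_U, d_E, d_U, b, g = (free[..., i] for i in range(6))
    D_N = D_E if restriction == "D_N=D_E" else D_U
    P = np.empty(free.shape[:-1] + (3, 3))
    # expected-source tree
    P[..., 0, 0] = D_E * d_E + D_E * (1 - d_E) * g + (1 - D_E) * b * g
    P[..., 0, 1] = D_E * (1 - d_E) * (1 - g) + (1 - D_E) * b * (1 - g)
    P[..., 0, 2] = (1 - D_E) * (1 - b)
    # unexpected-source tree
    P[..., 1, 0] = D_U * (1 - d_U) * g + (1 - D_U) * b * g
    P[..., 1, 1] = D_U * d_U + D_U * (1 - d_U) * (1 - g) + (1 - D_U) * b * (1 - g)
    P[..., 1, 2] = (1 - D_U) * (1 - b)
    # new-item tree
    P[..., 2, 0] = (1 - D_N) * b * g
    P[..., 2, 1] = (1 - D_N) * b * (1 - g)
    P[..., 2, 2] = D_N + (1 - D_N) * (1 - b)
    return P


def category_probabilities(params: MPTParameters) -> CategoryDistribution:
    """Category probabilities P(response | trial type) implied by the trees.

    Recognized-but-source-forgotten items never receive a "new" response
    (standard two-high-threshold assumption): detection of oldness is
    above-threshold, so only unrecognized items can be called new.
    """
    if params.restriction == "none":
        # evaluate the full 7-parameter tree directly
        free = params.free_vector()
        P = _free_to_probs(free, "D_N=D_U")
        D_N, b, g = params.D_N, params.b, params.g
        P[2, 0] = (1 - D_N) * b * g
        P[2, 1] = (1 - D_N) * b * (1 - g)
        P[2, 2] = D_N + (1 - D_N) * (1 - b)
    else:
        P = _free_to_probs(params.free_vector(), params.restriction)
    return CategoryDistribution(P)


def log_likelihood(params: MPTParameters, freq: FrequencyTable) -> float:
    """Multinomial log-likelihood of a 3x3 table under the tree model.

    Returns ``-inf`` when any cell with a positive count has probability 0.
    """
    if freq.task != "3afc":
        raise MPTDomainError("log_likelihood requires a 3AFC (3x3) table")
    P = category_probabilities(params).probs
    counts = freq.counts.astype(float)
    with np.errstate(divide="ignore"):
        logp = np.log(P)
    mask = counts > 0
    if np.any(np.isneginf(logp[mask])):
        return float("-inf")
    return float(np.sum(counts[mask] * logp[mask]))


def _g_squared(counts: np.ndarray, P: np.ndarray) -> float:
    """Likelihood-ratio statistic vs the saturated multinomial, 0*log(0)=0."""
    counts = counts.astype(float)
    totals = counts.sum(axis=1, keepdims=True)
    expected = totals * P
    mask = counts > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = counts[mask] * np.log(counts[mask] / expected[mask])
    return float(max(2.0 * terms.sum(), 0.0))


def _closed_form_inversion(
    p: np.ndarray, restriction: Restriction
) -> dict[str, float]:
    """Moment inversion of the 3x3 proportion table under a tie restriction.

    Solves, in order: the tied detection parameter D from the "new"-response
    proportions, b from the new-response rate of the tied studied row, g from
    the new-item false-alarm split, the other D from its "new" response rate,
    and finally d_E, d_U from the correct-response cells.
    """
    if restriction == "D_N=D_U":
        tied_row = 1  # unexpected-source row shares D with the new-item row
    else:
        tied_row = 0
    D = p[2, 2] - p[tied_row, 2]  # D_N + (1-D_N)(1-b) - (1-D)(1-b)
    b = 1.0 - p[tied_row, 2] / (1.0 - D) if D < 1.0 else 1.0
    fa = p[2, 0] + p[2, 1]
    g = p[2, 0] / fa if fa > 0 else 0.5
    other_row = 1 - tied_row
    D_other = 1.0 - p[other_row, 2] / (1.0 - b) if b < 1.0 else 1.0
    if restriction == "D_N=D_U":
        D_E, D_U = D_other, D
    else:
        D_E, D_U = D, D_other
    # correct-response cells:  P(E|E) = D_E d_E (1-g) + D_E g + (1-D_E) b g
    d_E = (
        (p[0, 0] - D_E * g - (1 - D_E) * b * g) / (D_E * (1 - g))
        if D_E * (1 - g) > 0
        else 0.5
    )
    d_U = (
        (p[1, 1] - D_U * (1 - g) - (1 - D_U) * b * (1 - g)) / (D_U * g)
        if D_U * g > 0
        else 0.5
    )
    return {"D_E": D_E, "D_U": D_U, "d_E": d_E, "d_U": d_U, "b": b, "g": g}


def _fit_numeric(
    freq: FrequencyTable, restriction: Restriction
) -> tuple[MPTParameters, float]:
    """Bounded likelihood maximization on logit-transformed free parameters."""
    counts = freq.counts.astype(float)

    def neg_ll(x: np.ndarray) -> float:
        free = expit(x)
        P = _free_to_probs(free, restriction)
        return -float(np.sum(counts * np.log(np.maximum(P, 1e-300))))

    starts = [np.zeros(6)]
    cf = _closed_form_inversion(freq.proportions(), restriction)
    clipped = np.clip(
        [cf["D_E"], cf["D_U"], cf["d_E"], cf["d_U"], cf["b"], cf["g"]],
        1e-4,
        1 - 1e-4,
    )
    starts.append(logit(clipped))
    best = None
    for x0 in starts:
        res = optimize.minimize(neg_ll, x0, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12,
                                         "maxiter": 20000})
        if best is None or res.fun < best.fun:
            best = res
    free = expit(best.x)
    params = MPTParameters.from_free(free, restriction)
    return params, -float(best.fun)


def fit_ml(
    freq: FrequencyTable, restriction: Restriction = "D_N=D_U"
) -> MLFitResult:
    """Maximum-likelihood fit of the restricted model to one aggregate table.

    The restricted model has six parameters and the 3x3 table six free data
    degrees of freedom, so an interior solution reproduces the observed
    proportions exactly (G-squared 0).  The closed-form moment inversion is
    attempted first; if any solved value leaves [0, 1] the fit falls back to
    bounded numerical likelihood maximization on the logit scale, and the
    boundary flag is set.
    """
    if restriction not in ("D_N=D_U", "D_N=D_E"):
        raise MPTDomainError("fit_ml requires restriction D_N=D_U or D_N=D_E")
    if freq.task != "3afc":
        raise MPTDomainError("fit_ml requires a 3AFC (3x3) table")
    p = freq.proportions()  # raises on empty rows
    sol = _closed_form_inversion(p, restriction)
    interior = all(0.0 <= v <= 1.0 for v in sol.values())
    if interior:
        params = MPTParameters.from_free(
            [sol["D_E"], sol["D_U"], sol["d_E"], sol["d_U"], sol["b"], sol["g"]],
            restriction,
        )
        ll = log_likelihood(params, freq)
        method = "closed_form"
        converged = True
    else:
        params, ll = _fit_numeric(freq, restriction)
        method = "numeric"
        converged = True
    P = category_probabilities(params).probs
    g2 = _g_squared(freq.counts, P)
    eps = 1e-7
    boundary = bool(
        np.any(params.free_vector() < eps) or np.any(params.free_vector() > 1 - eps)
    ) or not interior
    return MLFitResult(
        params=params,
        log_likelihood=ll,
        g_squared=g2,
        df=0,
        converged=converged,
        boundary=boundary,
        method=method,
    )


def simulate_frequencies(
    params: MPTParameters,
    n_per_type: int,
    n_participants: int = 1,
    seed: int | np.random.Generator = 0,
) -> FrequencyTable:
    """Multinomial sample of a 3x3 table with row totals n_per_type x n_participants."""
    if n_per_type < 1:
        raise MPTDomainError("n_per_type must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    P = category_probabilities(params).probs
    n_row = n_per_type * n_participants
    counts = np.stack([rng.multinomial(n_row, P[t]) for t in range(3)])
    return FrequencyTable(counts, label="simulated", task="3afc")
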