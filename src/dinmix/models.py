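"""Response-probability functions for Q-matrix restricted latent class models.

This module implements the deterministic-input noisy models built from the
three classical condensation rules — conjunctive ("and"-gate, DINA),
disjunctive ("or"-gate, DINO) and ratio (DINR) — together with the DINMix
model, which mixes the rules within an item through a simplex of item-level
mixing proportions, and the additive models (ACDM and the saturated GDINA)
used as comparison points.

Notation
--------
A test measures K binary attributes.  The Q-matrix ``Q`` is an I x K binary
incidence matrix: ``Q[i, k] = 1`` when item i requires attribute k.  A
respondent's attribute profile ``alpha`` is a length-K binary vector of
mastery indicators.  For an item with guessing parameter ``g``, slip
parameter ``s`` and latent response ``psi`` in [0, 1], the correct-response
probability is ``g + (1 - s - g) * psi``, so the probability runs from g
(latent response 0) to 1 - s (latent response 1); the monotonicity
restriction g < 1 - s is enforced throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np

__all__ = [
    "MODELS",
    "QMatrix",
    "AttributeMatrix",
    "DinmixItemParams",
    "AdditiveItemParams",
    "latent_conjunctive",
    "latent_disjunctive",
    "latent_ratio",
    "mixed_latent_response",
    "response_probability",
    "dinmix_probability",
    "additive_probability",
    "pattern_probabilities",
    "probability_matrix",
    "log_likelihood",
    "all_profiles",
    "required_subsets",
]

#: recognised model tags
MODELS = ("dina", "dino", "dinr", "dinmix", "acdm", "gdina")

#: clipping bound keeping Bernoulli log-likelihoods finite when additive
#: parameters sit exactly on the 0/1 boundary
LIKELIHOOD_EPS = 1e-12


def _as_binary_matrix(x, name: str) -> np.ndarray:
    arr = np.asarray(x)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be two-dimensional, got shape {arr.shape}")
    if not np.isin(arr, (0, 1)).all():
        bad = np.argwhere(~np.isin(arr, (0, 1)))[0]
        raise ValueError(
            f"{name} must be binary; entry at row {bad[0]}, column {bad[1]} "
            f"is {arr[bad[0], bad[1]]!r}"
        )
    return arr.astype(np.int8)


@dataclass(frozen=True)
class QMatrix:
    """Item-by-attribute incidence matrix (I items x K attributes).

    Every entry is 0/1 and every item requires at least one attribute.
    """

    entries: np.ndarray

    def __post_init__(self):
        arr = _as_binary_matrix(self.entries, "Q-matrix")
        if (arr.sum(axis=1) == 0).any():
            row = int(np.argwhere(arr.sum(axis=1) == 0)[0, 0])
            raise ValueError(f"Q-matrix row {row} requires no attribute")
        object.__setattr__(self, "entries", arr)

    @property
    def n_items(self) -> int:
        return self.entries.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.entries.shape[1]

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.entries, dtype=dtype)


@dataclass(frozen=True)
class AttributeMatrix:
    """Binary mastery profiles, one row per respondent (N x K)."""

    entries: np.ndarray

    def __post_init__(self):
        object.__setattr__(
            self, "entries", _as_binary_matrix(self.entries, "attribute matrix")
        )

    @property
    def n_persons(self) -> int:
        return self.entries.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.entries.shape[1]

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.entries, dtype=dtype)


def _check_gs(g: float, s: float) -> None:
    if not (0.0 < g < 1.0 and 0.0 < s < 1.0):
        raise ValueError(f"g and s must lie strictly in (0, 1); got g={g}, s={s}")
    if g >= 1.0 - s:
        raise ValueError(f"monotonicity g < 1 - s violated: g={g}, 1-s={1 - s}")


def _check_simplex(tau, atol: float = 1e-10) -> np.ndarray:
    tau = np.asarray(tau, dtype=float)
    if (tau < 0).any() or abs(tau.sum() - 1.0) > atol:
        raise ValueError(f"mixing proportions must lie on the simplex; got {tau}")
    return tau


@dataclass(frozen=True)
class DinmixItemParams:
    """Item parameters of the mixed-rule model: (g, s) and simplex weights tau.

    ``tau`` is ordered (conjunctive, disjunctive, ratio).  For an item that
    requires a single attribute all condensation rules coincide, so tau is
    pinned at (1, 0, 0) at construction time via :meth:`for_item`.
    """

    g: float
    s: float
    tau: tuple = (1.0, 0.0, 0.0)

    def __post_init__(self):
        _check_gs(self.g, self.s)
        tau = _check_simplex(self.tau)
        object.__setattr__(self, "tau", tuple(float(t) for t in tau))

    @classmethod
    def for_item(cls, g: float, s: float, tau, q_row) -> "DinmixItemParams":
        """Build parameters for a specific item, pinning tau on unidimensional items."""
        q_row = np.asarray(q_row)
        if q_row.sum() == 1:
            return cls(g, s, (1.0, 0.0, 0.0))
        return cls(g, s, tuple(np.asarray(tau, dtype=float)))


@dataclass(frozen=True)
class AdditiveItemParams:
    """Identity-link additive item parameters (ACDM / GDINA).

    ``main_effects`` holds one value per required attribute, in Q-row order.
    ``interaction_effects`` holds one value per required-attribute subset of
    size >= 2 in the canonical order of :func:`required_subsets`; it is empty
    for the ACDM.  Every implied reduced-pattern probability must lie in
    [0, 1].
    """

    intercept: float
    main_effects: tuple
    interaction_effects: tuple = field(default_factory=tuple)

    def __post_init__(self):
        mains = tuple(float(m) for m in np.atleast_1d(self.main_effects))
        inters = tuple(float(v) for v in np.atleast_1d(self.interaction_effects)) if (
            np.size(self.interaction_effects)
        ) else ()
        object.__setattr__(self, "main_effects", mains)
        object.__setattr__(self, "interaction_effects", inters)
        kstar = len(mains)
        n_sub = len(required_subsets(kstar))
        if inters and len(inters) != n_sub:
            raise ValueError(
                f"expected {n_sub} interaction effects for {kstar} required "
                f"attributes, got {len(inters)}"
            )
        probs = self.reduced_pattern_probabilities()
        if (probs < -1e-12).any() or (probs > 1 + 1e-12).any():
            raise ValueError(
                f"implied pattern probabilities outside [0, 1]: {probs}"
            )

    @property
    def kstar(self) -> int:
        return len(self.main_effects)

    def reduced_pattern_probabilities(self) -> np.ndarray:
        """Probabilities for all 2^K* reduced mastery patterns (LSB = first required attribute)."""
        kstar = self.kstar
        patterns = all_profiles(kstar)
        probs = self.intercept + patterns @ np.asarray(self.main_effects)
        if self.interaction_effects:
            for subset, effect in zip(required_subsets(kstar), self.interaction_effects):
                probs = probs + effect * patterns[:, subset].all(axis=1)
        return probs


def required_subsets(kstar: int) -> list[tuple[int, ...]]:
    """Canonical ordering of required-attribute subsets of size >= 2.

    Subsets are listed by increasing size, lexicographically within size,
    using positions 0..kstar-1 within the item's required attributes.
    """
    out: list[tuple[int, ...]] = []
    for size in range(2, kstar + 1):
        out.extend(combinations(range(kstar), size))
    return out


def all_profiles(k: int) -> np.ndarray:
    """All 2^k binary profiles; the first attribute is the least significant bit."""
    idx = np.arange(2**k)
    return ((idx[:, None] >> np.arange(k)) & 1).astype(np.int8)


def _check_pair(alpha_row, q_row):
    alpha = np.asarray(alpha_row, dtype=float)
    q = np.asarray(q_row, dtype=float)
    if alpha.shape != q.shape or alpha.ndim != 1:
        raise ValueError(
            f"profile and Q-row must be vectors of equal length; "
            f"got {alpha.shape} and {q.shape}"
        )
    if q.sum() == 0:
        raise ValueError("item requires no attribute (all-zero Q-row)")
    return alpha, q


def latent_conjunctive(alpha_row, q_row) -> float:
    """Conjunctive ("and"-gate) latent response: 1 iff all required attributes mastered."""
    alpha, q = _check_pair(alpha_row, q_row)
    return float(np.all(alpha[q == 1] == 1))


def latent_disjunctive(alpha_row, q_row) -> float:
    """Disjunctive ("or"-gate) latent response: 1 iff any required attribute mastered."""
    alpha, q = _check_pair(alpha_row, q_row)
    return float(np.any(alpha[q == 1] == 1))


def latent_ratio(alpha_row, q_row) -> float:
    """Ratio latent response: fraction of required attributes mastered."""
    alpha, q = _check_pair(alpha_row, q_row)
    return float(alpha[q == 1].sum() / q.sum())


_RULES = (latent_conjunctive, latent_disjunctive, latent_ratio)


def mixed_latent_response(alpha_row, q_row, tau) -> float:
    """Convex combination of the conjunctive, disjunctive and ratio latent responses."""
    tau = _check_simplex(tau)
    if tau.shape != (3,):
        raise ValueError(f"tau must have three components, got {tau.shape}")
    psi = float(sum(t * rule(alpha_row, q_row) for t, rule in zip(tau, _RULES)))
    return min(max(psi, 0.0), 1.0)  # guard float round-off at the corners


def response_probability(g: float, s: float, psi: float) -> float:
    """Map a latent response through the guessing/slip noise layer."""
    _check_gs(g, s)
    if not -1e-9 <= psi <= 1.0 + 1e-9:
        raise ValueError(f"latent response must lie in [0, 1], got {psi}")
    return g + (1.0 - s - g) * min(max(psi, 0.0), 1.0)


def dinmix_probability(params: DinmixItemParams, alpha_row, q_row) -> float:
    """Correct-response probability under the mixed-rule (DINMix) model."""
    psi = mixed_latent_response(alpha_row, q_row, params.tau)
    return response_probability(params.g, params.s, psi)


def additive_probability(params: AdditiveItemParams, alpha_row, q_row) -> float:
    """Correct-response probability under the identity-link additive model.

    Intercept plus main effects of mastered required attributes plus (for
    GDINA) interaction effects of fully mastered required subsets.
    """
    alpha, q = _check_pair(alpha_row, q_row)
    required = np.flatnonzero(q == 1)
    if len(required) != params.kstar:
        raise ValueError(
            f"item requires {len(required)} attributes but parameters "
            f"describe {params.kstar}"
        )
    mastered = alpha[required] == 1
    p = params.intercept + float(np.asarray(params.main_effects)[mastered].sum())
    for subset, effect in zip(required_subsets(params.kstar), params.interaction_effects):
        if mastered[list(subset)].all():
            p += effect
    return p


def _reduced_index(profiles: np.ndarray, q_row: np.ndarray) -> np.ndarray:
    """Index of each full profile's reduced pattern (first required attr = LSB)."""
    required = np.flatnonzero(np.asarray(q_row) == 1)
    bits = profiles[:, required].astype(np.int64)
    return bits @ (1 << np.arange(len(required)))


def pattern_probabilities(model: str, item_params, q_row) -> np.ndarray:
    """Correct-response probability for every reduced attribute pattern.

    Returns a vector of length 2^K*, K* being the number of required
    attributes, enumerating reduced patterns in binary order with the first
    required attribute as the least significant bit.  This is the
    saturated-model (GDINA-style) representation of any of the supported
    models; for DINMix it shows that four free parameters (g, s, tau1, tau2)
    generate all 2^K* entries.
    """
    model = model.lower()
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    q = np.asarray(q_row, dtype=np.int8)
    kstar = int(q.sum())
    if kstar < 1:
        raise ValueError("item requires no attribute (all-zero Q-row)")
    patterns = all_profiles(kstar)
    q_reduced = np.ones(kstar, dtype=np.int8)
    if model in ("dina", "dino", "dinr", "dinmix"):
        p = item_params
        if model == "dina":
            tau = (1.0, 0.0, 0.0)
        elif model == "dino":
            tau = (0.0, 1.0, 0.0)
        elif model == "dinr":
            tau = (0.0, 0.0, 1.0)
        else:
            tau = p.tau if kstar > 1 else (1.0, 0.0, 0.0)
        return np.array(
            [
                response_probability(
                    p.g, p.s, mixed_latent_response(row, q_reduced, tau)
                )
                for row in patterns
            ]
        )
    return item_params.reduced_pattern_probabilities()


def probability_matrix(model, item_params: Sequence, Q, profiles=None) -> np.ndarray:
    """Correct-response probabilities for every profile x item pair.

    Parameters
    ----------
    model : str or sequence of str
        A single model tag applied to all items, or one tag per item.
    item_params : sequence
        One parameter object per item (:class:`DinmixItemParams` or
        :class:`AdditiveItemParams` as appropriate).
    Q : array-like or QMatrix
    profiles : array-like, optional
        Rows of binary profiles to evaluate; defaults to all 2^K profiles.

    Returns
    -------
    ndarray of shape (len(profiles), I)
    """
    Qarr = np.asarray(Q, dtype=np.int8)
    I, K = Qarr.shape
    if isinstance(model, str):
        tags = [model] * I
    else:
        tags = list(model)
        if len(tags) != I:
            raise ValueError(f"expected {I} model tags, got {len(tags)}")
    if profiles is None:
        profiles = all_profiles(K)
    profiles = np.asarray(profiles, dtype=np.int8)
    P = np.empty((profiles.shape[0], I), dtype=float)
    for i in range(I):
        pat = pattern_probabilities(tags[i], item_params[i], Qarr[i])
        P[:, i] = pat[_reduced_index(profiles, Qarr[i])]
    return P


def log_likelihood(Y, Q, params: Sequence, alphas, model) -> float:
    """Bernoulli log-likelihood of a response matrix given attribute profiles.

    ``Y`` is the N x I binary response matrix, ``alphas`` the N x K profile
    matrix.  Probabilities are clipped away from {0, 1} so the result stays
    finite even when additive parameters sit on the boundary.
    """
    Y = np.asarray(Y, dtype=float)
    A = np.asarray(alphas, dtype=np.int8)
    Qarr = np.asarray(Q, dtype=np.int8)
    if Y.ndim != 2 or Y.shape != (A.shape[0], Qarr.shape[0]):
        raise ValueError(
            f"dimension mismatch: Y {Y.shape}, alphas {A.shape}, Q {Qarr.shape}"
        )
    P = probability_matrix(model, params, Qarr, profiles=A)
    P = np.clip(P, LIKELIHOOD_EPS, 1.0 - LIKELIHOOD_EPS)
    return float((Y * np.log(P) + (1.0 - Y) * np.log1p(-P)).sum())
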