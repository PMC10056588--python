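"""Synthetic data generation for the two simulation study designs.

Study 1 simulates data from the mixed-rule (DINMix) model itself: item
guessing/slip parameters drawn from a bivariate normal on the logit scale
(negatively correlated, matching higher- or lower-quality tests), item-level
mixing proportions assigned in fixed blocks (uniform or skew), and attribute
profiles drawn either equiprobably over all 2^K patterns ("unstructured") or
by thresholding a correlated multivariate normal at zero ("mvn").

Study 2 simulates six test situations in which items follow fixed,
non-random parameter sets under pure condensation rules (DINA / DINO /
DINR), the additive ACDM, the saturated GDINA, or a per-item allocation of
all five generating models ("separately").  Correct-response probabilities
are bounded in [0.1, 0.9] in every situation.

All randomness flows through a single master seed: per-stage / per-
replication substreams are spawned deterministically so any replication is
reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.special import expit, logit

from .models import (
    AdditiveItemParams,
    AttributeMatrix,
    DinmixItemParams,
    QMatrix,
    probability_matrix,
)

__all__ = [
    "Study1Design",
    "Study2Design",
    "STUDY2_SITUATIONS",
    "build_qmatrix",
    "draw_item_quality",
    "assign_mixing_proportions",
    "draw_attributes",
    "simulate_responses",
    "study2_item_params",
    "simulate_study1",
    "simulate_study2",
    "SimulatedDataset",
]

#: logit-scale means of the (g, s) distribution: logistic(-2.197) ~ 0.10
#: for higher-quality items, logistic(-1.386) ~ 0.20 for lower-quality.
ITEM_QUALITY_LOGIT_MEAN = {"higher": -2.197, "lower": -1.386}
#: correlation of logit(g) and logit(s); negative, g and s trade off
ITEM_LOGIT_CORRELATION = -0.6
#: pairwise latent correlation of attributes under the mvn structure
ATTRIBUTE_CORRELATION = 0.6

STUDY2_SITUATIONS = (
    "conjunctive",
    "disjunctive",
    "ratio",
    "compensatory",
    "fuzzily",
    "separately",
)

_SITUATION_MODEL = {
    "conjunctive": "dina",
    "disjunctive": "dino",
    "ratio": "dinr",
    "compensatory": "acdm",
    "fuzzily": "gdina",
}


@dataclass(frozen=True)
class Study1Design:
    """One cell of the first simulation study's 2x2x2x2x2 factorial design."""

    N: int = 500
    I: int = 15
    item_quality: Literal["higher", "lower"] = "higher"
    mixing_type: Literal["uniform", "skew"] = "uniform"
    lsm: Literal["unstructured", "mvn"] = "unstructured"
    K: int = 5
    seed: int | None = None

    def __post_init__(self):
        if self.I % 15 != 0:
            raise ValueError(
                f"test length must be divisible by 15 for the mixing-proportion "
                f"block boundaries; got I={self.I}"
            )
        if self.item_quality not in ITEM_QUALITY_LOGIT_MEAN:
            raise ValueError(f"unknown item quality {self.item_quality!r}")
        if self.mixing_type not in ("uniform", "skew"):
            raise ValueError(f"unknown mixing type {self.mixing_type!r}")
        if self.lsm not in ("unstructured", "mvn"):
            raise ValueError(f"unknown latent structural model {self.lsm!r}")


@dataclass(frozen=True)
class Study2Design:
    """One test situation of the second simulation study (fixed item parameters)."""

    situation: str = "conjunctive"
    N: int = 1000
    I: int = 30
    K: int = 5
    seed: int | None = None

    def __post_init__(self):
        if self.situation not in STUDY2_SITUATIONS:
            raise ValueError(
                f"unknown situation {self.situation!r}; expected one of "
                f"{STUDY2_SITUATIONS}"
            )


@dataclass
class SimulatedDataset:
    """A generated dataset plus the truth that produced it."""

    Y: np.ndarray
    Q: QMatrix
    alphas: AttributeMatrix
    model_tags: list[str]
    item_params: list
    design: object = None

    @property
    def true_profile_proportions(self) -> np.ndarray:
        """Empirical frequency of each of the 2^K profiles among respondents."""
        K = self.Q.n_attributes
        idx = np.asarray(self.alphas.entries, dtype=np.int64) @ (1 << np.arange(K))
        return np.bincount(idx, minlength=2**K) / self.alphas.n_persons


# ---------------------------------------------------------------------------
# Q-matrix construction
# ---------------------------------------------------------------------------

# multidimensional row blocks used by the canonical study-1 Q-matrix: five
# two-dimensional items cycling adjacent attribute pairs, then five
# three-dimensional items cycling attribute triples
_STUDY1_TWODIM = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 0)]
_STUDY1_THREEDIM = [(0, 1, 2), (1, 2, 3), (2, 3, 4), (3, 4, 0), (4, 0, 1)]

# study-2 multidimensional q-vectors; the same four vectors are reused for
# each generating-model block so only the model differs between blocks
_STUDY2_QVECTORS = [(0, 1), (2, 3), (0, 1, 2), (2, 3, 4)]


def build_qmatrix(I: int, K: int, design_tag: str = "study1") -> QMatrix:
    """Canonical Q-matrix for a shipped simulation design.

    ``study1``: the first I/3 items are unidimensional (starting with a K x K
    identity block), the remainder alternate two- and three-dimensional
    items; every attribute is measured at least three times.

    ``study2``: the first 10 items are two stacked K x K identity blocks;
    items 11..I cycle through four fixed multidimensional q-vectors in
    blocks of four (one block per generating model in the "separately"
    situation).
    """
    if K != 5:
        raise ValueError(f"shipped designs use K = 5 attributes, got K={K}")
    rows = []
    if design_tag == "study1":
        if I % 15 != 0 or I < 2 * K:
            raise ValueError(f"study1 design needs I divisible by 15 and >= {2*K}")
        n_uni = I // 3
        for j in range(n_uni):
            row = np.zeros(K, dtype=np.int8)
            row[j % K] = 1
            rows.append(row)
        n_multi = I - n_uni
        blocks = []
        # alternate 2-dim and 3-dim cycles until enough rows exist
        while len(blocks) < n_multi:
            blocks.extend(_STUDY1_TWODIM)
            blocks.extend(_STUDY1_THREEDIM)
        for attrs in blocks[:n_multi]:
            row = np.zeros(K, dtype=np.int8)
            row[list(attrs)] = 1
            rows.append(row)
    elif design_tag == "study2":
        if I < 3 * K:
            raise ValueError(f"study2 design needs I >= {3*K}")
        if I != 30:
            raise ValueError("the study2 design is defined for I = 30 items")
        for j in range(10):
            row = np.zeros(K, dtype=np.int8)
            row[j % K] = 1
            rows.append(row)
        for _block in range(5):
            for attrs in _STUDY2_QVECTORS:
                row = np.zeros(K, dtype=np.int8)
                row[list(attrs)] = 1
                rows.append(row)
    else:
        raise ValueError(f"unknown design tag {design_tag!r}")
    Q = QMatrix(np.vstack(rows))
    assert (Q.entries.sum(axis=0) >= 3).all()
    return Q


# ---------------------------------------------------------------------------
# item parameters
# ---------------------------------------------------------------------------


def draw_item_quality(I: int, quality: str, rng) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-item (g, s) from the bivariate normal on the logit scale.

    ``logit(g), logit(s)`` have mean -2.197 ("higher" quality, mean
    probability ~ 0.1) or -1.386 ("lower", ~ 0.2), unit variances and
    correlation -0.6.  Pairs violating the monotonicity restriction
    g < 1 - s are redrawn wholesale, which preserves the marginal shape.
    """
    rng = np.random.default_rng(rng)
    mu = ITEM_QUALITY_LOGIT_MEAN[quality]
    cov = np.array([[1.0, ITEM_LOGIT_CORRELATION], [ITEM_LOGIT_CORRELATION, 1.0]])
    g = np.empty(I)
    s = np.empty(I)
    todo = np.arange(I)
    while todo.size:
        z = rng.multivariate_normal([mu, mu], cov, size=todo.size)
        g[todo], s[todo] = expit(z[:, 0]), expit(z[:, 1])
        todo = todo[g[todo] >= 1.0 - s[todo]]
    return g, s


def assign_mixing_proportions(I: int, mixing_type: str) -> np.ndarray:
    """Block-wise true mixing proportions (I x 3), ordered (conj, disj, ratio).

    Items 1..I/3 are unidimensional and pinned at (1, 0, 0).  Under uniform
    mixing all remaining items get (1/3, 1/3, 1/3); under skew mixing the
    remaining items split into three blocks dominated in turn by the
    conjunctive, disjunctive and ratio rule.
    """
    if I % 15 != 0:
        raise ValueError(f"I must be divisible by 15, got {I}")
    tau = np.empty((I, 3))
    n_uni = I // 3
    tau[:n_uni] = (1.0, 0.0, 0.0)
    if mixing_type == "uniform":
        tau[n_uni:] = (1 / 3, 1 / 3, 1 / 3)
    elif mixing_type == "skew":
        b1, b2 = 8 * I // 15, 11 * I // 15
        tau[n_uni:b1] = (0.6, 0.2, 0.2)
        tau[b1:b2] = (0.2, 0.6, 0.2)
        tau[b2:] = (0.2, 0.2, 0.6)
    else:
        raise ValueError(f"unknown mixing type {mixing_type!r}")
    return tau


# ---------------------------------------------------------------------------
# attribute profiles
# ---------------------------------------------------------------------------


def draw_attributes(
    N: int, K: int, lsm: str = "unstructured", rng=None, rho: float = ATTRIBUTE_CORRELATION
) -> AttributeMatrix:
    """Draw N binary attribute profiles.

    ``unstructured`` picks each profile uniformly from all 2^K patterns
    (pairwise tetrachoric correlations ~ 0).  ``mvn`` thresholds a latent
    multivariate normal with unit variances and pairwise correlation ``rho``
    at zero, giving marginal mastery probability 0.5 and tetrachoric
    correlation ~ rho.
    """
    rng = np.random.default_rng(rng)
    if lsm == "unstructured":
        alphas = rng.integers(0, 2, size=(N, K), dtype=np.int8)
    elif lsm == "mvn":
        cov = np.full((K, K), rho)
        np.fill_diagonal(cov, 1.0)
        theta = rng.multivariate_normal(np.zeros(K), cov, size=N, method="cholesky")
        alphas = (theta >= 0.0).astype(np.int8)
    else:
        raise ValueError(f"unknown latent structural model {lsm!r}")
    return AttributeMatrix(alphas)


# ---------------------------------------------------------------------------
# responses
# ---------------------------------------------------------------------------


def simulate_responses(model_per_item, params_per_item, Q, alphas, rng=None) -> np.ndarray:
    """Draw the N x I binary response matrix, y_ni ~ Bernoulli(p_ni)."""
    rng = np.random.default_rng(rng)
    A = np.asarray(alphas, dtype=np.int8)
    P = probability_matrix(model_per_item, params_per_item, Q, profiles=A)
    return (rng.random(P.shape) < P).astype(np.int8)


# ---------------------------------------------------------------------------
# study-2 fixed parameter sets
# ---------------------------------------------------------------------------

# fixed additive effects; every parameter set sums to the 0.9 upper limit
_ACDM_MAINS = {2: (0.5, 0.3), 3: (0.35, 0.25, 0.2)}
_GDINA_EFFECTS = {
    2: {"mains": (0.35, 0.25), "inters": (0.2,)},
    3: {"mains": (0.15, 0.1, 0.05), "inters": (0.05, 0.1, 0.15, 0.2)},
}
_BOUNDED_G = 0.1  # lower limit of correct-response probability
_BOUNDED_S = 0.1  # one minus the upper limit


def _fixed_params_for(model: str, kstar: int):
    if model in ("dina", "dino", "dinr"):
        return DinmixItemParams(_BOUNDED_G, _BOUNDED_S)
    if model == "acdm":
        return AdditiveItemParams(0.1, _ACDM_MAINS[kstar])
    if model == "gdina":
        eff = _GDINA_EFFECTS[kstar]
        return AdditiveItemParams(0.1, eff["mains"], eff["inters"])
    raise ValueError(f"unknown model {model!r}")


def study2_item_params(situation: str) -> tuple[list[str], list]:
    """Model tag and fixed parameter object for each of the 30 study-2 items.

    The first 10 items are unidimensional, where all condensation rules
    coincide, and are generated as DINA items with g = s = 0.1.  In the five
    pure situations all multidimensional items follow one generating model;
    in "separately" they follow DINA, DINO, DINR, ACDM and GDINA in blocks
    of four items sharing the same q-vectors.
    """
    if situation not in STUDY2_SITUATIONS:
        raise ValueError(f"unknown situation {situation!r}")
    Q = build_qmatrix(30, 5, "study2")
    kstars = Q.entries.sum(axis=1)
    tags: list[str] = []
    params: list = []
    if situation == "separately":
        block_models = ["dina", "dino", "dinr", "acdm", "gdina"]
        multi_tags = [m for m in block_models for _ in range(4)]
    else:
        multi_tags = [_SITUATION_MODEL[situation]] * 20
    for i in range(30):
        tag = "dina" if i < 10 else multi_tags[i - 10]
        tags.append(tag)
        params.append(_fixed_params_for(tag, int(kstars[i])))
    return tags, params


# ---------------------------------------------------------------------------
# full study generators
# ---------------------------------------------------------------------------


def _spawn(seed, n):
    return np.random.SeedSequence(seed).spawn(n)


def simulate_study1(design: Study1Design) -> SimulatedDataset:
    """Generate one replication of a study-1 cell from the DINMix model."""
    ss_items, ss_alpha, ss_resp = _spawn(design.seed, 3)
    Q = build_qmatrix(design.I, design.K, "study1")
    g, s = draw_item_quality(design.I, design.item_quality, np.random.default_rng(ss_items))
    tau = assign_mixing_proportions(design.I, design.mixing_type)
    params = [
        DinmixItemParams.for_item(g[i], s[i], tau[i], Q.entries[i])
        for i in range(design.I)
    ]
    alphas = draw_attributes(design.N, design.K, design.lsm, np.random.default_rng(ss_alpha))
    Y = simulate_responses(
        ["dinmix"] * design.I, params, Q, alphas, np.random.default_rng(ss_resp)
    )
    return SimulatedDataset(Y, Q, alphas, ["dinmix"] * design.I, params, design)


def simulate_study2(design: Study2Design) -> SimulatedDataset:
    """Generate one replication of a study-2 test situation (fixed parameters)."""
    ss_alpha, ss_resp = _spawn(design.seed, 2)
    Q = build_qmatrix(design.I, design.K, "study2")
    tags, params = study2_item_params(design.situation)
    alphas = draw_attributes(design.N, design.K, "unstructured", np.random.default_rng(ss_alpha))
    Y = simulate_responses(tags, params, Q, alphas, np.random.default_rng(ss_resp))
    return SimulatedDataset(Y, Q, alphas, tags, params, design)
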