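"""Bayesian MCMC estimation via an explicit Metropolis-within-Gibbs sampler.

One sweep of the sampler:

1. each respondent's attribute profile is drawn from its full conditional
   over all 2^K latent classes given the item parameters and the class
   proportions (Gumbel-max categorical sampling, vectorised over persons);
2. the class-proportion vector pi is drawn from its conjugate Dirichlet
   full conditional (saturated / unstructured latent structural model);
3. item parameters are updated model by model:

   * guessing/slip pairs by joint random-walk Metropolis on the logit
     scale, rejecting proposals that violate the monotonicity restriction
     g < 1 - s (flat prior on the truncated unit square);
   * mixing proportions tau by random-walk Metropolis on the additive
     log-ratio transform of the simplex (flat Dirichlet(1,1,1) prior);
     unidimensional items keep tau pinned at (1, 0, 0);
   * saturated-model (GDINA) reduced-pattern probabilities by exact
     conjugate Beta Gibbs draws (Beta(1,1) priors, unconstrained);
   * additive (ACDM) intercept/main effects by blocked random-walk
     Metropolis with a flat prior on the polytope where every implied
     pattern probability lies in [0, 1].

Proposal scales adapt toward a 20-45% acceptance rate during burn-in and
are frozen afterwards.  Convergence is diagnosed with the split-chain
potential scale reduction factor (PSRF).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, logit

from .models import LIKELIHOOD_EPS, MODELS, QMatrix, all_profiles

__all__ = [
    "McmcConfig",
    "PosteriorDraws",
    "PosteriorSummary",
    "fit",
    "psrf",
    "estimate_attributes",
]

_TARGET_ACCEPT = 0.3  # middle of the 20-45% band


def _dirichlet_logpdf(x: np.ndarray, alpha: np.ndarray) -> float:
    return float(
        ((alpha - 1.0) * np.log(x)).sum() + gammaln(alpha.sum()) - gammaln(alpha).sum()
    )


@dataclass(frozen=True)
class McmcConfig:
    """Sampler run configuration.

    Defaults follow common practice for these models: two chains of 10,000
    iterations with the first 5,000 discarded as burn-in.
    """

    chains: int = 2
    iterations: int = 10_000
    burn_in: int = 5_000
    thin: int = 1
    seed: int | None = None
    #: Metropolis refreshes of the item-parameter block per sweep; the item
    #: updates are cheap relative to the latent-class update, so repeating
    #: them sharpens mixing of weakly identified parameters (e.g. the mixing
    #: proportions of two-attribute items) at little cost
    param_refreshes: int = 1
    #: every this many sweeps, guessing/slip/mixing parameters are also
    #: updated against the class-marginalised likelihood (a partially
    #: collapsed move; the latent classes are redrawn from their exact full
    #: conditional at the start of the next sweep).  The conditional
    #: posterior given sampled classes is much narrower than the marginal
    #: posterior, so purely conditional updates mix slowly; the collapsed
    #: move removes that bottleneck at modest cost.  Set to 0 to disable
    #: (cheaper sweeps, slower mixing).
    marginal_interval: int = 1
    marginal_refreshes: int = 2
    adapt_interval: int = 50
    initial_scale_gs: float = 0.3
    initial_scale_tau: float = 0.6
    initial_scale_additive: float = 0.04

    def __post_init__(self):
        if not 0 <= self.burn_in < self.iterations:
            raise ValueError("burn_in must satisfy 0 <= burn_in < iterations")
        if self.chains < 1:
            raise ValueError("at least one chain is required")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class PosteriorDraws:
    """Retained posterior draws for all chains.

    ``params`` maps parameter-block names to arrays with leading axes
    (chain, draw): ``g``/``s`` -> (C, T, I), ``tau`` -> (C, T, I, 3),
    ``patp`` -> (C, T, I, R) padded reduced-pattern probabilities,
    ``delta`` -> (C, T, I, 1 + max K*) additive effects.  ``alpha`` holds
    per-person latent-class indices (C, T, N) and ``pi`` the class
    proportions (C, T, 2^K).
    """

    model: str
    Q: np.ndarray
    profiles: np.ndarray
    params: dict[str, np.ndarray]
    alpha: np.ndarray
    pi: np.ndarray
    acceptance: dict[str, np.ndarray]
    config: McmcConfig = None

    @property
    def n_chains(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_draws(self) -> int:
        return self.alpha.shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """A parameter block with chains concatenated along the draw axis."""
        arr = self.params[name] if name in self.params else getattr(self, name)
        return arr.reshape(-1, *arr.shape[2:])

    def scalar_blocks(self, item_only: bool = False):
        """Yield (name, (chains, T) array) for every monitored scalar parameter."""
        kstar = self.Q.sum(axis=1)
        for i in range(self.Q.shape[0]):
            if self.model in ("dina", "dino", "dinr", "dinmix"):
                yield f"g[{i}]", self.params["g"][:, :, i]
                yield f"s[{i}]", self.params["s"][:, :, i]
                if self.model == "dinmix" and kstar[i] > 1:
                    for m, rule in enumerate(("conj", "disj", "ratio")):
                        yield f"tau_{rule}[{i}]", self.params["tau"][:, :, i, m]
            elif self.model == "gdina":
                for r in range(int(2 ** kstar[i])):
                    yield f"p[{i},{r}]", self.params["patp"][:, :, i, r]
            elif self.model == "acdm":
                for j in range(int(kstar[i]) + 1):
                    name = "intercept" if j == 0 else f"main{j}"
                    yield f"{name}[{i}]", self.params["delta"][:, :, i, j]
        if not item_only:
            for c in range(self.pi.shape[-1]):
                yield f"pi[{c}]", self.pi[:, :, c]

    def to_frame(self) -> pd.DataFrame:
        """Long-format draws table (chain, iteration, parameter, value)."""
        rows = []
        for name, arr in self.scalar_blocks():
            for ch in range(arr.shape[0]):
                rows.append(
                    pd.DataFrame(
                        {
                            "chain": ch,
                            "iteration": np.arange(arr.shape[1]),
                            "parameter": name,
                            "value": arr[ch],
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)


@dataclass
class PosteriorSummary:
    """Posterior means, standard deviations and PSRF per parameter, plus
    per-person attribute classification."""

    params: pd.DataFrame
    attribute_marginals: np.ndarray
    attribute_estimates: np.ndarray
    modal_profiles: np.ndarray
    max_psrf_item_params: float
    acceptance: dict[str, float]


# ---------------------------------------------------------------------------
# convergence diagnostic
# ---------------------------------------------------------------------------


def psrf(draws) -> float:
    """Split-chain Gelman-Rubin potential scale reduction factor.

    ``draws`` has shape (chains, T); each chain is split in half so
    within-chain drift also inflates the statistic.  Returns a value >= 1
    up to numerical tolerance; identical constant chains give exactly 1.
    """
    x = np.asarray(draws, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("PSRF needs draws with shape (chains >= 2, T)")
    if x.shape[1] < 10:
        raise ValueError("PSRF needs at least 10 retained draws per chain")
    n = x.shape[1] // 2
    halves = np.concatenate([x[:, :n], x[:, n : 2 * n]], axis=0)
    W = halves.var(axis=1, ddof=1).mean()
    B_over_n = halves.mean(axis=1).var(ddof=1)
    if W <= 1e-300:
        return 1.0 if B_over_n <= 1e-300 else np.inf
    var_plus = (n - 1) / n * W + B_over_n
    # the estimator can dip fractionally below 1 by sampling noise; report
    # the clamped value so converged chains read exactly >= 1
    return float(max(1.0, np.sqrt(var_plus / W)))


# ---------------------------------------------------------------------------
# sampler internals
# ---------------------------------------------------------------------------


class _Precomp:
    """Quantities fixed by the Q-matrix, shared by every chain."""

    def __init__(self, Q: np.ndarray):
        self.Q = Q
        self.I, self.K = Q.shape
        self.C = 2**self.K
        self.profiles = all_profiles(self.K)
        self.kstar = Q.sum(axis=1).astype(int)
        self.multidim = self.kstar > 1
        A = self.profiles.astype(float)
        Qf = Q.astype(float)
        req = Qf.sum(axis=1)
        mastered = A @ Qf.T  # (C, I) count of mastered required attrs
        self.omega = np.stack(
            [
                (mastered == req).astype(float),
                (mastered > 0).astype(float),
                mastered / req,
            ]
        )  # (3, C, I): conjunctive, disjunctive, ratio
        # reduced-pattern index of each class for each item (LSB = first
        # required attribute)
        self.maxk = int(self.kstar.max())
        self.R = 2**self.maxk
        Mred = np.zeros((self.C, self.I), dtype=np.int64)
        for i in range(self.I):
            required = np.flatnonzero(Q[i] == 1)
            Mred[:, i] = self.profiles[:, required].astype(np.int64) @ (
                1 << np.arange(len(required))
            )
        self.Mred = Mred
        self.valid_pattern = (
            np.arange(self.R)[None, :] < (2 ** self.kstar)[:, None]
        )  # (I, R)
        # additive-model bit masks: which mains are active in reduced pattern r
        self.bits = ((np.arange(self.R)[:, None] >> np.arange(self.maxk)) & 1).astype(
            float
        )  # (R, maxk)
        # reduced-pattern latent responses per rule, (3, R, I): every class
        # sharing a reduced pattern shares its latent response, which lets the
        # collapsed updates work on R <= 8 values instead of 2^K classes
        mastered_red = self.bits.sum(axis=1)[:, None]  # (R, 1) bit count
        kst = self.kstar[None, :].astype(float)
        self.omega_red = np.stack(
            [
                (mastered_red == kst).astype(float),
                np.broadcast_to(mastered_red > 0, (self.R, self.I)).astype(float),
                np.minimum(mastered_red / kst, 1.0),
            ]
        )
        # class -> reduced-pattern indicator per item, (I, C, R), for BLAS
        self.onehot = np.zeros((self.I, self.C, self.R))
        for i in range(self.I):
            self.onehot[i, np.arange(self.C), Mred[:, i]] = 1.0


class _ChainState:
    def __init__(self, pre: _Precomp, model: str, Y: np.ndarray, rng, cfg: McmcConfig):
        self.pre = pre
        self.model = model
        self.rng = rng
        N = Y.shape[0]
        I, C = pre.I, pre.C
        self.Y = Y.astype(float)
        self.Yc = 1.0 - self.Y
        self.c = rng.integers(0, C, size=N)
        self.pi = rng.dirichlet(np.ones(C))
        if model in ("dina", "dino", "dinr", "dinmix"):
            while True:
                self.g = rng.uniform(0.05, 0.35, size=I)
                self.s = rng.uniform(0.05, 0.35, size=I)
                if (self.g < 1 - self.s).all():
                    break
            self.tau = np.tile([1.0, 0.0, 0.0], (I, 1))
            if model == "dinmix":
                self.tau[pre.multidim] = rng.dirichlet(
                    np.ones(3), size=int(pre.multidim.sum())
                )
        elif model == "gdina":
            # noisy monotone ramp in the number of mastered required
            # attributes: random starts that avoid seeding chains in
            # spurious non-monotone modes of the saturated likelihood
            frac = pre.bits.sum(axis=1)[None, :] / np.maximum(
                pre.kstar[:, None], 1
            )  # (I, R) fraction of required attributes mastered
            ramp = 0.2 + 0.6 * np.minimum(frac, 1.0)
            self.patp = np.clip(
                ramp + rng.uniform(-0.15, 0.15, size=(I, pre.R)), 0.02, 0.98
            )
        elif model == "acdm":
            self.delta = np.zeros((I, 1 + pre.maxk))
            self.delta[:, 0] = rng.uniform(0.05, 0.2, size=I)
            for i in range(I):
                k = pre.kstar[i]
                self.delta[i, 1 : 1 + k] = rng.dirichlet(np.ones(k)) * (
                    0.85 - self.delta[i, 0]
                )
        else:
            raise ValueError(f"unknown model {model!r}")
        # adaptive proposal scales and acceptance accounting, per item block;
        # *_m blocks belong to the class-marginalised (collapsed) updates
        self.log_scale = {
            "gs": np.full(I, np.log(cfg.initial_scale_gs)),
            "tau": np.full(I, np.log(cfg.initial_scale_tau)),
            "delta": np.full(I, np.log(cfg.initial_scale_additive)),
            "gs_m": np.full(I, np.log(cfg.initial_scale_gs)),
            "tau_m": np.full(I, np.log(cfg.initial_scale_tau)),
        }
        blocks = list(self.log_scale) + ["gs_i", "tau_i"]  # _i: independence
        self.acc = {k: np.zeros(I) for k in blocks}
        self.tries = {k: np.zeros(I) for k in blocks}
        self.acc_total = {k: np.zeros(I) for k in blocks}
        self.tries_total = {k: np.zeros(I) for k in blocks}
        # collapsed pi move: Dirichlet proposal concentration (adapted)
        self.log_kappa = np.log(4.0 * Y.shape[0])
        self.pi_acc = np.zeros(2)  # accepts, tries
        # moment accumulators for the fitted independence proposals (second
        # half of burn-in); frozen at the end of burn-in.  "joint" couples
        # (logit g, logit s, alr tau) within an item, capturing the strong
        # within-item posterior correlation between noise and mixing levels.
        self._fit_acc = {
            "gs": [np.zeros((I, 2)), np.zeros((I, 2, 2)), 0],
            "tau": [np.zeros((I, 2)), np.zeros((I, 2, 2)), 0],
            "joint": [np.zeros((I, 4)), np.zeros((I, 4, 4)), 0],
        }
        # separate first/second moments of tau itself for the moment-matched
        # Dirichlet independence proposal (handles posteriors piled against
        # the simplex boundary better than a Gaussian in log-ratio space)
        self._tau_acc = [np.zeros((I, 3)), np.zeros((I, 3)), 0]
        self.tau_dir_alpha: np.ndarray | None = None
        self.indep_prop: dict[str, tuple] | None = None

    # -- adaptive independence proposals --------------------------------------

    def _alr(self, tau: np.ndarray) -> np.ndarray:
        """Additive log-ratio coordinates of tau rows (reference: ratio)."""
        return np.log(np.clip(tau[:, :2], 1e-12, None)) - np.log(
            np.clip(tau[:, 2:3], 1e-12, None)
        )

    def collect_proposal_moments(self):
        if self.model not in ("dina", "dino", "dinr", "dinmix"):
            return
        z = np.column_stack([logit(self.g), logit(self.s)])
        acc = self._fit_acc["gs"]
        acc[0] += z
        acc[1] += z[:, :, None] * z[:, None, :]
        acc[2] += 1
        if self.model == "dinmix":
            t = self._alr(self.tau)
            acc = self._fit_acc["tau"]
            acc[0] += t
            acc[1] += t[:, :, None] * t[:, None, :]
            acc[2] += 1
            z4 = np.column_stack([z, t])
            acc = self._fit_acc["joint"]
            acc[0] += z4
            acc[1] += z4[:, :, None] * z4[:, None, :]
            acc[2] += 1
            self._tau_acc[0] += self.tau
            self._tau_acc[1] += self.tau**2
            self._tau_acc[2] += 1

    def freeze_proposals(self):
        """Fit per-item bivariate Gaussians to the burn-in draws.

        The fitted distributions (inflated 1.5x for robustness) serve as
        independence proposals after burn-in; the Metropolis-Hastings ratio
        corrects for the approximation, so validity does not depend on the
        fit quality.
        """
        if self.model not in ("dina", "dino", "dinr", "dinmix"):
            return
        out = {}
        for block, (zs, zz, n) in self._fit_acc.items():
            if n < 20:
                continue
            d = zs.shape[1]
            m = zs / n
            cov = zz / n - m[:, :, None] * m[:, None, :]
            cov *= 1.2
            cov[:, np.arange(d), np.arange(d)] += 1e-4
            try:
                chol = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                continue
            inv = np.linalg.inv(cov)
            _, logdet = np.linalg.slogdet(cov)
            out[block] = (m, chol, inv, 0.5 * logdet)
        self.indep_prop = out or None
        n = self._tau_acc[2]
        if n >= 20:
            m = np.clip(self._tau_acc[0] / n, 1e-4, 1.0)
            m /= m.sum(axis=1, keepdims=True)
            v = np.clip(self._tau_acc[1] / n - m**2, 1e-8, None)
            # Dirichlet strength from each component's mean/variance relation,
            # damped for fatter-than-posterior tails
            s = np.median(m * (1.0 - m) / v - 1.0, axis=1)
            s = np.clip(0.7 * s, 2.0, 2000.0)
            self.tau_dir_alpha = np.clip(m * s[:, None], 0.05, None)

    def _indep_logq(self, block: str, i: int, z: np.ndarray) -> float:
        m, _, inv, half_logdet = self.indep_prop[block]
        d = z - m[i]
        return float(-0.5 * d @ inv[i] @ d - half_logdet[i])

    def _indep_draw(self, block: str, i: int) -> np.ndarray:
        m, chol, _, _ = self.indep_prop[block]
        return m[i] + chol[i] @ self.rng.standard_normal(m.shape[1])

    def reset_proposal_moments(self):
        for acc in self._fit_acc.values():
            acc[0][:] = 0.0
            acc[1][:] = 0.0
            acc[2] = 0
        self._tau_acc[0][:] = 0.0
        self._tau_acc[1][:] = 0.0
        self._tau_acc[2] = 0

    # -- probability table ---------------------------------------------------

    def psi(self) -> np.ndarray:
        om = self.pre.omega
        if self.model == "dina":
            return om[0]
        if self.model == "dino":
            return om[1]
        if self.model == "dinr":
            return om[2]
        return np.einsum("im,mci->ci", self.tau, om)

    def prob_table(self) -> np.ndarray:
        """Correct-response probability for every (class, item) pair."""
        if self.model in ("dina", "dino", "dinr", "dinmix"):
            return self.g + (1.0 - self.s - self.g) * self.psi()
        if self.model == "gdina":
            return self.patp[np.arange(self.pre.I)[None, :], self.pre.Mred]
        # acdm: bits (R, maxk) @ mains.T (maxk, I) -> (R, I), plus intercepts
        P_red = self.delta[:, 0][None, :] + self.pre.bits @ self.delta[:, 1:].T
        return P_red[self.pre.Mred, np.arange(self.pre.I)[None, :]]

    # -- Gibbs steps ---------------------------------------------------------

    def update_alpha_pi(self, P: np.ndarray):
        logP = np.log(np.clip(P, LIKELIHOOD_EPS, None))
        log1mP = np.log(np.clip(1.0 - P, LIKELIHOOD_EPS, None))
        L = self.Y @ logP.T + self.Yc @ log1mP.T  # (N, C)
        L += np.log(self.pi)[None, :]
        gumbel = self.rng.gumbel(size=L.shape)
        self.c = np.argmax(L + gumbel, axis=1)
        counts = np.bincount(self.c, minlength=self.pre.C)
        self.pi = self.rng.dirichlet(1.0 + counts)
        # per-(class, item) sufficient statistics for the item updates
        Z = np.zeros((self.Y.shape[0], self.pre.C))
        Z[np.arange(self.Y.shape[0]), self.c] = 1.0
        self.n1 = Z.T @ self.Y  # successes
        self.n0 = counts[:, None] - self.n1  # failures
        self.counts = counts

    # -- item-parameter updates ----------------------------------------------

    @staticmethod
    def _item_loglik(P: np.ndarray, n1: np.ndarray, n0: np.ndarray) -> np.ndarray:
        Pc = np.clip(P, LIKELIHOOD_EPS, 1.0 - LIKELIHOOD_EPS)
        return (n1 * np.log(Pc) + n0 * np.log1p(-Pc)).sum(axis=0)  # per item

    def _metropolis(self, block: str, ll_old, ll_new, extra_old, extra_new, valid, count=None):
        """Vectorised per-item accept/reject; returns the accept mask.

        ``count`` restricts acceptance-rate accounting (hence scale
        adaptation) to a subset of items, e.g. excluding independence
        proposals whose acceptance says nothing about the walk scale.
        """
        log_ratio = (ll_new + extra_new) - (ll_old + extra_old)
        u = self.rng.random(log_ratio.shape)
        accept = valid & (np.log(u) < log_ratio)
        counted = 1.0 if count is None else count
        self.tries[block] += counted
        self.acc[block] += accept * counted
        self.tries_total[block] += counted
        self.acc_total[block] += accept * counted
        return accept

    def update_gs(self):
        sig = np.exp(self.log_scale["gs"])
        zg = logit(self.g) + sig * self.rng.standard_normal(self.pre.I)
        zs = logit(self.s) + sig * self.rng.standard_normal(self.pre.I)
        g_new, s_new = expit(zg), expit(zs)
        valid = g_new < 1.0 - s_new
        psi = self.psi()
        P_old = self.g + (1.0 - self.s - self.g) * psi
        P_new = g_new + (1.0 - s_new - g_new) * psi
        ll_old = self._item_loglik(P_old, self.n1, self.n0)
        ll_new = self._item_loglik(P_new, self.n1, self.n0)
        # flat prior on (g, s); logit random walk needs the log-Jacobian
        jac_old = np.log(self.g * (1 - self.g)) + np.log(self.s * (1 - self.s))
        jac_new = np.where(
            valid, np.log(g_new * (1 - g_new)) + np.log(s_new * (1 - s_new)), -np.inf
        )
        accept = self._metropolis("gs", ll_old, ll_new, jac_old, jac_new, valid)
        self.g = np.where(accept, g_new, self.g)
        self.s = np.where(accept, s_new, self.s)

    def update_tau(self):
        multi = self.pre.multidim
        if not multi.any():
            return
        sig = np.exp(self.log_scale["tau"])
        tau = self.tau
        # additive log-ratio transform with the ratio component as reference
        t = np.log(np.clip(tau[:, :2], 1e-300, None)) - np.log(
            np.clip(tau[:, 2:3], 1e-300, None)
        )
        t_new = t + sig[:, None] * self.rng.standard_normal((self.pre.I, 2))
        m = np.maximum(t_new.max(axis=1), 0.0)  # reference component has t = 0
        e = np.exp(t_new - m[:, None])
        ref = np.exp(-m)
        denom = e.sum(axis=1) + ref
        tau_new = np.column_stack([e / denom[:, None], ref / denom])
        # flat Dirichlet prior; ALR inverse Jacobian is prod(tau)
        jac_old = np.log(np.clip(tau, 1e-300, None)).sum(axis=1)
        jac_new = np.log(np.clip(tau_new, 1e-300, None)).sum(axis=1)
        # half the moves are independence proposals from the uniform prior:
        # they decorrelate successive draws wherever the posterior is
        # diffuse (common for mixing proportions), while the random walk
        # handles sharply identified items
        indep = self.rng.random(self.pre.I) < 0.5
        tau_ind = self.rng.dirichlet(np.ones(3), size=self.pre.I)
        tau_new = np.where(indep[:, None], tau_ind, tau_new)
        jac_old = np.where(indep, 0.0, jac_old)
        jac_new = np.where(indep, 0.0, jac_new)
        om = self.pre.omega
        psi_old = np.einsum("im,mci->ci", tau, om)
        psi_new = np.einsum("im,mci->ci", tau_new, om)
        slope = 1.0 - self.s - self.g
        P_old = self.g + slope * psi_old
        P_new = self.g + slope * psi_new
        ll_old = self._item_loglik(P_old, self.n1, self.n0)
        ll_new = self._item_loglik(P_new, self.n1, self.n0)
        accept = self._metropolis(
            "tau", ll_old, ll_new, jac_old, jac_new, multi, count=~indep
        )
        self.tau = np.where(accept[:, None], tau_new, tau)
        self.gibbs_tau_ridge()

    def gibbs_tau_ridge(self):
        """Exact Gibbs move along the flat direction of two-attribute items.

        For an item requiring exactly two attributes the likelihood depends
        on tau only through u = tau2 + tau3/2 (both single-mastery patterns
        share the same latent response), so the posterior is flat along a
        line segment of the simplex.  With the uniform Dirichlet prior the
        conditional over that segment is uniform; drawing from it directly
        removes the slow random-walk diffusion along the ridge.
        """
        two = self.pre.kstar == 2
        if not two.any():
            return
        tau = self.tau[two]
        u = tau[:, 1] + 0.5 * tau[:, 2]
        w_max = np.minimum(2.0 * u, 2.0 * (1.0 - u))
        w = self.rng.uniform(0.0, w_max)
        new = np.column_stack([1.0 - u - 0.5 * w, u - 0.5 * w, w])
        np.clip(new, 0.0, None, out=new)  # guard float round-off at segment ends
        self.tau[two] = new / new.sum(axis=1, keepdims=True)

    def update_gdina(self):
        """Exact conjugate Beta draws for every reduced-pattern probability.

        Unidimensional items are order-constrained (mastery probability
        above non-mastery) by truncated conjugate draws; without this the
        posterior has an exact per-attribute reflection symmetry (invert an
        attribute's coding and swap the two pattern probabilities of its
        unidimensional items), and chains land in different mirrored modes.
        """
        from scipy.stats import beta as _beta

        I, R = self.pre.I, self.pre.R
        succ = np.zeros((I, R))
        tot = np.zeros((I, R))
        for r in range(R):
            mask = self.pre.Mred == r  # (C, I)
            succ[:, r] = (self.n1 * mask).sum(axis=0)
            tot[:, r] = (self.counts[:, None] * mask).sum(axis=0)
        draw = self.rng.beta(1.0 + succ, 1.0 + tot - succ)
        self.patp = np.where(self.pre.valid_pattern, draw, 0.5)
        uni = np.flatnonzero(self.pre.kstar == 1)
        if uni.size:
            a0, b0 = 1.0 + succ[uni, 0], 1.0 + tot[uni, 0] - succ[uni, 0]
            a1, b1 = 1.0 + succ[uni, 1], 1.0 + tot[uni, 1] - succ[uni, 1]
            p1 = self.patp[uni, 1]
            # one Gibbs scan of (p0 | p1 < .), (p1 | p0 > .)
            hi = np.clip(_beta.cdf(p1, a0, b0), 1e-12, 1.0)
            p0 = _beta.ppf(self.rng.uniform(0.0, hi), a0, b0)
            lo = np.clip(_beta.cdf(p0, a1, b1), None, 1.0 - 1e-12)
            p1 = _beta.ppf(self.rng.uniform(lo, 1.0), a1, b1)
            self.patp[uni, 0] = np.clip(p0, 1e-9, 1.0 - 1e-9)
            self.patp[uni, 1] = np.clip(p1, 1e-9, 1.0 - 1e-9)

    def update_acdm(self):
        sig = np.exp(self.log_scale["delta"])
        ncol = 1 + self.pre.maxk
        step = sig[:, None] * self.rng.standard_normal((self.pre.I, ncol))
        # zero out steps for mains beyond the item's K*
        active = np.arange(ncol)[None, :] <= self.pre.kstar[:, None]
        delta_new = self.delta + np.where(active, step, 0.0)
        P_red_old = self.delta[:, 0][None, :] + self.pre.bits @ self.delta[:, 1:].T
        P_red_new = delta_new[:, 0][None, :] + self.pre.bits @ delta_new[:, 1:].T
        vp = self.pre.valid_pattern.T  # (R, I)
        # pattern probabilities in [0, 1] and nonnegative main effects (the
        # monotone additive model; also removes the attribute-reflection
        # symmetry that would otherwise let chains settle in mirrored modes)
        valid = (
            np.where(vp, P_red_new >= 0.0, True).all(axis=0)
            & np.where(vp, P_red_new <= 1.0, True).all(axis=0)
            & np.where(active[:, 1:], delta_new[:, 1:] >= 0.0, True).all(axis=1)
        )
        idx = np.arange(self.pre.I)[None, :]
        P_old = P_red_old[self.pre.Mred, idx]
        P_new = P_red_new[self.pre.Mred, idx]
        ll_old = self._item_loglik(P_old, self.n1, self.n0)
        ll_new = self._item_loglik(P_new, self.n1, self.n0)
        zero = np.zeros(self.pre.I)
        accept = self._metropolis("delta", ll_old, ll_new, zero, zero, valid)
        self.delta = np.where(accept[:, None], delta_new, self.delta)

    def _item_pattern(self, i: int, g=None, s=None, tau=None) -> np.ndarray:
        """Reduced-pattern success probabilities of item i for candidate parameters."""
        g = self.g[i] if g is None else g
        s = self.s[i] if s is None else s
        if self.model == "dinmix":
            t = self.tau[i] if tau is None else tau
            psi = t @ self.pre.omega_red[:, :, i]
        else:
            psi = self.pre.omega_red[("dina", "dino", "dinr").index(self.model), :, i]
        return np.clip(
            g + (1.0 - s - g) * psi, LIKELIHOOD_EPS, 1.0 - LIKELIHOOD_EPS
        )

    def update_items_marginal(self, refreshes: int = 1):
        """Partially collapsed item update: Metropolis against the likelihood
        with the latent classes summed out (weights pi).

        Valid because the classes are redrawn from their exact full
        conditional immediately afterwards.  Only the guessing/slip and
        mixing-proportion models use this move; the additive models'
        conditional updates mix adequately (GDINA's are exact conjugate
        draws).

        The implementation tracks per-person class weights E (normalised so
        the per-person marginal likelihood is absorbed into a log-scale
        offset ``b``) and aggregates them over each item's reduced patterns,
        so a proposal costs two (N x R) products rather than an exponential
        over all N x 2^K class weights.
        """
        if self.model not in ("dina", "dino", "dinr", "dinmix"):
            return
        pre = self.pre
        rng = self.rng
        P = np.clip(self.prob_table(), LIKELIHOOD_EPS, 1.0 - LIKELIHOOD_EPS)
        base = (
            np.log(self.pi)[None, :]
            + self.Y @ np.log(P).T
            + self.Yc @ np.log1p(-P).T
        )
        b = base.max(axis=1)
        E = np.exp(base - b[:, None])  # (N, C) un-normalised class weights
        S = E.sum(axis=1)
        b += np.log(S)
        E /= S[:, None]
        # per-person marginal log-likelihood sums to b.sum() throughout

        def attempt(i, W, y_i, cur, pnew, extra):
            """Metropolis accept/reject for new pattern probabilities of item i."""
            e1 = pnew / cur
            e0 = (1.0 - pnew) / (1.0 - cur)
            S_new = np.where(y_i, W @ e1, W @ e0)
            log_ratio = np.log(S_new).sum() + extra
            if np.log(rng.random()) >= log_ratio:
                return W, False
            # fold the accepted factors into the weights and renormalise
            col1 = e1[pre.Mred[:, i]]
            col0 = e0[pre.Mred[:, i]]
            np.multiply(E, np.where(y_i[:, None], col1[None, :], col0[None, :]), out=E)
            W = W * np.where(y_i[:, None], e1[None, :], e0[None, :])
            nonlocal_b[0] += np.log(S_new)
            np.divide(E, S_new[:, None], out=E)
            W /= S_new[:, None]
            return W, True

        def pi_attempt(pi_new, extra):
            rho = pi_new / self.pi
            S_new = E @ rho
            log_ratio = np.log(S_new).sum() + extra
            if np.log(rng.random()) >= log_ratio:
                return False
            np.multiply(E, rho[None, :], out=E)
            nonlocal_b[0] += np.log(S_new)
            np.divide(E, S_new[:, None], out=E)
            self.pi = pi_new
            return True

        def pi_phase():
            """Collapsed class-proportion moves: pi given parameters with the
            classes summed out.  Alternated with the collapsed item updates
            inside each refresh, which breaks the slow coupling between
            attribute prevalence and item parameters that the conjugate
            pi | classes draw alone cannot traverse."""
            for _ in range(4):
                kappa = np.exp(self.log_kappa)
                a_fwd = kappa * self.pi + 1.0
                pi_new = np.clip(rng.dirichlet(a_fwd), 1e-12, None)
                pi_new /= pi_new.sum()
                a_rev = kappa * pi_new + 1.0
                extra = _dirichlet_logpdf(self.pi, a_rev) - _dirichlet_logpdf(
                    pi_new, a_fwd
                )
                self.pi_acc[1] += 1
                if pi_attempt(pi_new, extra):
                    self.pi_acc[0] += 1
            # attribute-prevalence tilt: multiplicative reweighting of the
            # classes mastering one attribute -- a one-dimensional move along
            # the slowly mixing direction trading prevalence against
            # guessing/slip levels.  Jacobian of the simplex tilt
            # pi -> pi*w/S is prod(w)/S^C.
            C = pre.C
            for k in range(pre.K):
                log_r = 0.25 * rng.standard_normal()
                w = np.where(pre.profiles[:, k] == 1, np.exp(log_r), 1.0)
                Sw = float(self.pi @ w)
                pi_new = self.pi * w / Sw
                log_jac = (C / 2) * log_r - C * np.log(Sw)
                pi_attempt(pi_new, log_jac)

        nonlocal_b = [b]
        for _ in range(refreshes):
            for i in range(pre.I):
                W = E @ pre.onehot[i]  # (N, R) reduced-pattern weights
                y_i = self.Y[:, i] > 0.5
                # ---- joint (g, s, tau) fitted move --------------------------
                if (
                    self.model == "dinmix"
                    and pre.multidim[i]
                    and self.indep_prop is not None
                    and "joint" in self.indep_prop
                ):
                    z_old4 = np.concatenate(
                        [
                            [logit(self.g[i]), logit(self.s[i])],
                            self._alr(self.tau[i : i + 1])[0],
                        ]
                    )
                    z_new4 = self._indep_draw("joint", i)
                    g_new, s_new = expit(z_new4[:2])
                    if g_new < 1.0 - s_new:
                        t_new = z_new4[2:]
                        mm = max(t_new.max(), 0.0)
                        e = np.exp(t_new - mm)
                        ref = np.exp(-mm)
                        tau_new = np.append(e, ref) / (e.sum() + ref)
                        jac4 = (
                            np.log(g_new * (1 - g_new) * s_new * (1 - s_new))
                            + np.log(np.clip(tau_new, 1e-300, None)).sum()
                            - np.log(
                                self.g[i]
                                * (1 - self.g[i])
                                * self.s[i]
                                * (1 - self.s[i])
                            )
                            - np.log(np.clip(self.tau[i], 1e-300, None)).sum()
                        )
                        hast4 = self._indep_logq(
                            "joint", i, z_old4
                        ) - self._indep_logq("joint", i, z_new4)
                        W, ok = attempt(
                            i,
                            W,
                            y_i,
                            self._item_pattern(i),
                            self._item_pattern(i, g=g_new, s=s_new, tau=tau_new),
                            jac4 + hast4,
                        )
                        if ok:
                            self.g[i], self.s[i] = g_new, s_new
                            self.tau[i] = tau_new
                # ---- guessing/slip moves ------------------------------------
                # one fitted independence attempt (the main regenerator once
                # burn-in has produced a fit) plus one random-walk attempt,
                # which keeps local exploration alive even when a chain's
                # frozen fit is poor
                have_fit = self.indep_prop is not None and "gs" in self.indep_prop
                for indep_move in ((True, False) if have_fit else (False,)):
                    z_old = np.array([logit(self.g[i]), logit(self.s[i])])
                    if indep_move:
                        z_new = self._indep_draw("gs", i)
                        hastings = self._indep_logq(
                            "gs", i, z_old
                        ) - self._indep_logq("gs", i, z_new)
                        self.tries_total["gs_i"][i] += 1
                    else:
                        sig = np.exp(self.log_scale["gs_m"][i])
                        z_new = z_old + sig * rng.standard_normal(2)
                        hastings = 0.0
                        self.tries["gs_m"][i] += 1
                        self.tries_total["gs_m"][i] += 1
                    g_new, s_new = expit(z_new)
                    if g_new < 1.0 - s_new:
                        # flat prior on (g, s); logit moves need the Jacobian
                        jac = np.log(
                            g_new * (1 - g_new) * s_new * (1 - s_new)
                        ) - np.log(
                            self.g[i] * (1 - self.g[i]) * self.s[i] * (1 - self.s[i])
                        )
                        W, ok = attempt(
                            i,
                            W,
                            y_i,
                            self._item_pattern(i),
                            self._item_pattern(i, g=g_new, s=s_new),
                            jac + hastings,
                        )
                        if ok:
                            self.g[i], self.s[i] = g_new, s_new
                            if indep_move:
                                self.acc_total["gs_i"][i] += 1
                            else:
                                self.acc["gs_m"][i] += 1
                                self.acc_total["gs_m"][i] += 1
                # ---- mixing-proportion moves --------------------------------
                # two attempts per phase: a fitted independence draw (the
                # main regenerator once burn-in has produced a fit) plus an
                # exploratory prior/walk move
                if self.model != "dinmix" or not pre.multidim[i]:
                    continue
                have_fit = self.tau_dir_alpha is not None
                for attempt_no in range(2):
                    if attempt_no == 0 and have_fit:
                        kind = "fitted"
                    else:
                        kind = "prior" if rng.random() < 0.5 else "walk"
                    if kind == "fitted":
                        # moment-matched Dirichlet independence proposal
                        a = self.tau_dir_alpha[i]
                        tau_new = np.clip(rng.dirichlet(a), 1e-12, None)
                        tau_new /= tau_new.sum()
                        jac_t = _dirichlet_logpdf(
                            np.clip(self.tau[i], 1e-12, None), a
                        ) - _dirichlet_logpdf(tau_new, a)
                    elif kind == "prior":
                        # uniform proposal in tau space: likelihood ratio only
                        tau_new = rng.dirichlet(np.ones(3))
                        jac_t = 0.0
                    else:
                        t_old = self._alr(self.tau[i : i + 1])[0]
                        sig = np.exp(self.log_scale["tau_m"][i])
                        t_new = t_old + sig * rng.standard_normal(2)
                        m = max(t_new.max(), 0.0)
                        e = np.exp(t_new - m)
                        ref = np.exp(-m)
                        tau_new = np.append(e, ref) / (e.sum() + ref)
                        jac_t = np.log(
                            np.clip(tau_new, 1e-300, None)
                        ).sum() - np.log(np.clip(self.tau[i], 1e-300, None)).sum()
                    if kind == "walk":
                        self.tries["tau_m"][i] += 1
                        self.tries_total["tau_m"][i] += 1
                    elif kind == "fitted":
                        self.tries_total["tau_i"][i] += 1
                    W, ok = attempt(
                        i,
                        W,
                        y_i,
                        self._item_pattern(i),
                        self._item_pattern(i, tau=tau_new),
                        jac_t,
                    )
                    if ok:
                        self.tau[i] = tau_new
                        if kind == "walk":
                            self.acc["tau_m"][i] += 1
                            self.acc_total["tau_m"][i] += 1
                        elif kind == "fitted":
                            self.acc_total["tau_i"][i] += 1
            pi_phase()

    def update_items(self, refreshes: int = 1):
        if self.model == "gdina":
            self.update_gdina()  # exact conjugate draw; once is enough
            return
        for _ in range(refreshes):
            if self.model in ("dina", "dino", "dinr", "dinmix"):
                self.update_gs()
                if self.model == "dinmix":
                    self.update_tau()
            else:
                self.update_acdm()

    def adapt(self, batch: int):
        gamma = min(0.5, 2.0 / np.sqrt(batch + 1.0))
        if self.pi_acc[1] > 0:
            rate = self.pi_acc[0] / self.pi_acc[1]
            # larger kappa -> tighter Dirichlet proposal -> higher acceptance
            self.log_kappa += gamma * (_TARGET_ACCEPT - rate)
            self.log_kappa = float(np.clip(self.log_kappa, 2.0, 20.0))
            self.pi_acc[:] = 0.0
        for block in self.log_scale:
            tries = self.tries[block]
            if tries.max() == 0:
                continue
            rate = self.acc[block] / np.maximum(tries, 1.0)
            self.log_scale[block] += gamma * (rate - _TARGET_ACCEPT)
            np.clip(self.log_scale[block], -8.0, 3.0, out=self.log_scale[block])
            self.acc[block][:] = 0.0
            self.tries[block][:] = 0.0


def _run_chain(Y, pre: _Precomp, model: str, cfg: McmcConfig, seed):
    rng = np.random.default_rng(seed)
    state = _ChainState(pre, model, Y, rng, cfg)
    n_ret = (cfg.iterations - cfg.burn_in + cfg.thin - 1) // cfg.thin
    N = Y.shape[0]
    store = {"alpha": np.empty((n_ret, N), dtype=np.uint8), "pi": np.empty((n_ret, pre.C))}
    if model in ("dina", "dino", "dinr", "dinmix"):
        store["g"] = np.empty((n_ret, pre.I))
        store["s"] = np.empty((n_ret, pre.I))
        if model == "dinmix":
            store["tau"] = np.empty((n_ret, pre.I, 3))
    elif model == "gdina":
        store["patp"] = np.empty((n_ret, pre.I, pre.R))
    else:
        store["delta"] = np.empty((n_ret, pre.I, 1 + pre.maxk))
    t = 0
    for it in range(cfg.iterations):
        # collapsed moves first, then the exact conditional class/proportion
        # draws, so every stored (params, alpha, pi) triple is jointly
        # consistent
        if cfg.marginal_interval and it and it % cfg.marginal_interval == 0:
            state.update_items_marginal(cfg.marginal_refreshes)
        P = state.prob_table()
        state.update_alpha_pi(P)
        state.update_items(cfg.param_refreshes)
        if it < cfg.burn_in and (it + 1) % cfg.adapt_interval == 0:
            state.adapt((it + 1) // cfg.adapt_interval)
        # two-stage fitting of the independence proposals: a first fit halfway
        # through burn-in already speeds mixing, so the second-stage moments
        # (and hence the frozen proposals) come from a better-mixed chain
        if cfg.burn_in // 4 <= it < cfg.burn_in:
            state.collect_proposal_moments()
            if it == cfg.burn_in // 2 - 1 or it == cfg.burn_in - 1:
                state.freeze_proposals()
                state.reset_proposal_moments()
        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
            store["alpha"][t] = state.c
            store["pi"][t] = state.pi
            if model in ("dina", "dino", "dinr", "dinmix"):
                store["g"][t] = state.g
                store["s"][t] = state.s
                if model == "dinmix":
                    store["tau"][t] = state.tau
            elif model == "gdina":
                store["patp"][t] = state.patp
            else:
                store["delta"][t] = state.delta
            t += 1
    rates = {
        block: np.divide(
            state.acc_total[block],
            np.maximum(state.tries_total[block], 1.0),
        )
        for block in state.tries_total
        if state.tries_total[block].max() > 0
    }
    return store, rates


# ---------------------------------------------------------------------------
# public entry points
# ---------------------------------------------------------------------------


def fit(Y, Q, model: str, config: McmcConfig | None = None):
    """Fit one model to a response matrix by MCMC.

    Parameters
    ----------
    Y : array-like, N x I binary responses
    Q : array-like or QMatrix, I x K
    model : one of ``dina``, ``dino``, ``dinr``, ``dinmix``, ``acdm``,
        ``gdina``
    config : McmcConfig, optional

    Returns
    -------
    (PosteriorDraws, PosteriorSummary)
    """
    model = model.lower()
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    cfg = config or McmcConfig()
    if isinstance(Q, QMatrix):
        Qarr = Q.entries
    else:
        Qarr = QMatrix(np.asarray(Q)).entries
    Y = np.asarray(Y)
    if Y.ndim != 2 or Y.shape[1] != Qarr.shape[0]:
        raise ValueError(
            f"Y has shape {Y.shape} but Q describes {Qarr.shape[0]} items"
        )
    if not np.isin(Y, (0, 1)).all():
        raise ValueError("responses must be binary (0/1)")
    pre = _Precomp(Qarr)
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.chains)
    stores, rates_all = [], []
    for ch in range(cfg.chains):
        store, rates = _run_chain(Y, pre, model, cfg, seeds[ch])
        stores.append(store)
        rates_all.append(rates)
    params = {
        key: np.stack([st[key] for st in stores])
        for key in stores[0]
        if key not in ("alpha", "pi")
    }
    draws = PosteriorDraws(
        model=model,
        Q=Qarr,
        profiles=pre.profiles,
        params=params,
        alpha=np.stack([st["alpha"] for st in stores]),
        pi=np.stack([st["pi"] for st in stores]),
        acceptance={
            block: np.mean([r[block] for r in rates_all], axis=0)
            for block in rates_all[0]
        },
        config=cfg,
    )
    return draws, summarize(draws)


def summarize(draws: PosteriorDraws) -> PosteriorSummary:
    """Posterior means, SDs and split-chain PSRF for every monitored parameter."""
    rows = []
    max_item_psrf = 0.0
    can_psrf = draws.n_chains >= 2 and draws.n_draws >= 10
    for name, arr in draws.scalar_blocks():
        r = psrf(arr) if can_psrf else np.nan
        is_item = not name.startswith("pi[")
        if is_item and can_psrf and np.isfinite(r):
            max_item_psrf = max(max_item_psrf, r)
        rows.append(
            {
                "parameter": name,
                "mean": float(arr.mean()),
                "sd": float(arr.std(ddof=1)),
                "psrf": r,
                "group": "item" if is_item else "structural",
            }
        )
    table = pd.DataFrame(rows).set_index("parameter")
    marginals, estimates, modal = estimate_attributes(draws)
    return PosteriorSummary(
        params=table,
        attribute_marginals=marginals,
        attribute_estimates=estimates,
        modal_profiles=modal,
        max_psrf_item_params=max_item_psrf,
        acceptance={k: float(v.mean()) for k, v in draws.acceptance.items()},
    )


def estimate_attributes(draws: PosteriorDraws):
    """Point estimates of respondent attribute profiles.

    Returns ``(marginal means, binary estimates, modal profiles)``.  The
    binary estimate sets mastery when the marginal posterior mean is >= 0.5
    (ties count as mastery); the modal profile is the most frequently
    sampled latent class per person (smallest class index on ties).
    """
    classes = draws.stacked("alpha")  # (T_total, N)
    profiles = draws.profiles.astype(float)
    T, N = classes.shape
    C = profiles.shape[0]
    counts = np.zeros((N, C), dtype=np.int64)
    for t in range(T):
        counts[np.arange(N), classes[t]] += 1
    marginals = (counts / T) @ profiles  # (N, K)
    estimates = (marginals >= 0.5).astype(np.int8)
    modal = draws.profiles[np.argmax(counts, axis=1)]
    return marginals, estimates, modal
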