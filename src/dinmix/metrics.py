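"""Recovery metrics and model-comparison indices.

Recovery metrics summarise simulation replications against known truth:
bias and RMSE of item parameters, attribute-level (ACCR) and whole-profile
(PCCR) correct classification rates, and RMSE of the 2^K attribute-profile
proportions.

Model comparison uses the deviance information criterion (DIC) and minus
twice the summed log conditional predictive ordinates (-2LCPO), both
computed from retained posterior draws.  The deviance is evaluated
conditional on the per-draw sampled attribute profiles (the convention of
general-purpose Gibbs samplers); the plug-in deviance uses posterior-mean
item parameters with per-person modal profiles.  CPOs use the harmonic-mean
identity evaluated stably in log space.  Smaller DIC / -2LCPO indicates
better model-data fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mcmc import PosteriorDraws, estimate_attributes
from .models import LIKELIHOOD_EPS

__all__ = [
    "bias_rmse",
    "accr",
    "pccr",
    "profile_proportion_rmse",
    "dic",
    "lcpo",
    "fit_indices",
    "FitIndices",
]


def bias_rmse(estimates, truths):
    """Bias and RMSE of estimates over replications.

    ``estimates`` has replications along the first axis; ``truths`` is
    either one truth shared by all replications or one truth per
    replication with the same shape.
    """
    est = np.asarray(estimates, dtype=float)
    tru = np.asarray(truths, dtype=float)
    if tru.shape == est.shape:
        err = est - tru
    elif tru.shape == est.shape[1:]:
        err = est - tru[None]
    else:
        raise ValueError(
            f"truths shape {tru.shape} matches neither {est.shape} nor "
            f"{est.shape[1:]}"
        )
    return err.mean(axis=0), np.sqrt((err**2).mean(axis=0))


def _stack_reps(est, tru):
    est = np.asarray(est)
    tru = np.asarray(tru)
    if est.shape != tru.shape:
        raise ValueError(f"shape mismatch: {est.shape} vs {tru.shape}")
    if est.ndim == 2:  # single replication
        est, tru = est[None], tru[None]
    return est, tru


def accr(estimated, true):
    """Attribute-level correct classification rate, per attribute.

    Accepts (N, K) matrices for one replication or (R, N, K) stacks.
    """
    est, tru = _stack_reps(estimated, true)
    return (est == tru).mean(axis=(0, 1))


def pccr(estimated, true) -> float:
    """Whole-profile correct classification rate."""
    est, tru = _stack_reps(estimated, true)
    return float((est == tru).all(axis=2).mean())


def profile_proportion_rmse(estimated, true, atol: float = 1e-6):
    """RMSE of each attribute-profile proportion over replications.

    ``estimated`` is (R, 2^K) with each row on the simplex; ``true`` is the
    length-2^K truth.  Returns (per-profile RMSE, mean across profiles).
    """
    est = np.atleast_2d(np.asarray(estimated, dtype=float))
    tru = np.asarray(true, dtype=float)
    for name, arr in (("estimated", est), ("true", tru[None])):
        if (arr < -atol).any() or (np.abs(arr.sum(axis=1) - 1.0) > atol).any():
            raise ValueError(f"{name} proportions must lie on the simplex")
    per_profile = np.sqrt(((est - tru[None]) ** 2).mean(axis=0))
    return per_profile, float(per_profile.mean())


# ---------------------------------------------------------------------------
# model-comparison indices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FitIndices:
    """DIC and conditional-predictive-ordinate summaries for one fitted model."""

    dic: float
    posterior_mean_deviance: float
    plugin_deviance: float
    effective_parameters: float
    test_lcpo2: float
    item_lcpo2: np.ndarray
    n_underflow: int = 0


def _prob_table_from_params(draws: PosteriorDraws, params: dict) -> np.ndarray:
    """Class-by-item probability table for one parameter draw (or a mean)."""
    from .mcmc import _Precomp  # local import to avoid cycle at module load

    pre = _Precomp(draws.Q)
    if draws.model in ("dina", "dino", "dinr", "dinmix"):
        g, s = params["g"], params["s"]
        if draws.model == "dina":
            psi = pre.omega[0]
        elif draws.model == "dino":
            psi = pre.omega[1]
        elif draws.model == "dinr":
            psi = pre.omega[2]
        else:
            psi = np.einsum("im,mci->ci", params["tau"], pre.omega)
        P = g + (1.0 - s - g) * psi
    elif draws.model == "gdina":
        P = params["patp"][np.arange(pre.I)[None, :], pre.Mred]
    else:
        P_red = params["delta"][:, 0][None, :] + pre.bits @ params["delta"][:, 1:].T
        P = P_red[pre.Mred, np.arange(pre.I)[None, :]]
    return np.clip(P, LIKELIHOOD_EPS, 1.0 - LIKELIHOOD_EPS)


def _per_draw_tables(draws: PosteriorDraws):
    """Yield (class-by-item probability table, class index per person) per draw."""
    keys = list(draws.params)
    stacked = {k: draws.stacked(k) for k in keys}
    classes = draws.stacked("alpha")
    for t in range(classes.shape[0]):
        yield _prob_table_from_params(
            draws, {k: stacked[k][t] for k in keys}
        ), classes[t]


def _posterior_mean_params(draws: PosteriorDraws) -> dict:
    return {k: draws.stacked(k).mean(axis=0) for k in draws.params}


def fit_indices(draws: PosteriorDraws, Y, thin: int = 1) -> FitIndices:
    """DIC and test-/item-level -2LCPO in one pass over the retained draws.

    ``thin`` subsamples the retained draws (every ``thin``-th) to bound the
    cost of the per-response CPO accumulation on long runs.
    """
    Y = np.asarray(Y, dtype=float)
    N, I = Y.shape
    logA = np.full((N, I), -np.inf)  # running logsumexp of -loglik per response
    deviances = []
    T_used = 0
    rows = np.arange(N)
    for t, (P, c) in enumerate(_per_draw_tables(draws)):
        if t % thin:
            continue
        probs = P[c]  # (N, I)
        ll = Y * np.log(probs) + (1.0 - Y) * np.log1p(-probs)
        deviances.append(-2.0 * ll.sum())
        np.logaddexp(logA, -ll, out=logA)
        T_used += 1
    if T_used == 0:
        raise ValueError("no retained draws available")
    dbar = float(np.mean(deviances))
    # plug-in deviance: posterior-mean item parameters, modal profiles
    mean_params = _posterior_mean_params(draws)
    P_hat = _prob_table_from_params(draws, mean_params)
    _, _, modal = estimate_attributes(draws)
    K = draws.profiles.shape[1]
    modal_class = modal.astype(np.int64) @ (1 << np.arange(K))
    probs_hat = P_hat[modal_class]
    d_hat = float(
        -2.0 * (Y * np.log(probs_hat) + (1.0 - Y) * np.log1p(-probs_hat)).sum()
    )
    p_d = dbar - d_hat
    # CPO_ni = harmonic mean of per-draw likelihoods = T / sum(1 / L_ni)
    log_cpo = np.log(T_used) - logA
    n_underflow = int(np.isinf(logA).sum())
    item_lcpo2 = -2.0 * log_cpo.sum(axis=0)
    return FitIndices(
        dic=dbar + p_d,
        posterior_mean_deviance=dbar,
        plugin_deviance=d_hat,
        effective_parameters=p_d,
        test_lcpo2=float(item_lcpo2.sum()),
        item_lcpo2=item_lcpo2,
        n_underflow=n_underflow,
    )


def dic(draws: PosteriorDraws, Y, thin: int = 1) -> float:
    """Deviance information criterion; smaller indicates better fit."""
    return fit_indices(draws, Y, thin=thin).dic


def lcpo(draws: PosteriorDraws, Y, thin: int = 1) -> FitIndices:
    """Test- and item-level -2LCPO (with the DIC computed alongside)."""
    return fit_indices(draws, Y, thin=thin)
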