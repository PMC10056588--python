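"""dinmix: cognitive diagnosis with item-level mixtures of condensation rules.

The package implements the DINMix model — a Q-matrix restricted latent
class model in which each item mixes the conjunctive, disjunctive and
ratio condensation rules through a simplex of item-level mixing
proportions — together with the classical DINA/DINO/DINR models, the
additive ACDM and the saturated GDINA, simulation designs for recovery and
model-comparison studies, Bayesian MCMC estimation, convergence
diagnostics, model-fit indices (DIC, -2LCPO) and condensation-rule
identification.
"""

from .models import (
    MODELS,
    AdditiveItemParams,
    AttributeMatrix,
    DinmixItemParams,
    QMatrix,
    additive_probability,
    all_profiles,
    dinmix_probability,
    latent_conjunctive,
    latent_disjunctive,
    latent_ratio,
    log_likelihood,
    mixed_latent_response,
    pattern_probabilities,
    probability_matrix,
    response_probability,
)
from .simulate import (
    Study1Design,
    Study2Design,
    assign_mixing_proportions,
    build_qmatrix,
    draw_attributes,
    draw_item_quality,
    simulate_responses,
    simulate_study1,
    simulate_study2,
    study2_item_params,
)
from .mcmc import McmcConfig, PosteriorDraws, PosteriorSummary, estimate_attributes, fit, psrf
from .metrics import (
    FitIndices,
    accr,
    bias_rmse,
    dic,
    fit_indices,
    lcpo,
    pccr,
    profile_proportion_rmse,
)
from .rules import RuleVerdict, classify_item, classify_items, revision_report

__version__ = "0.1.0"
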