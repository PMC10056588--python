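"""Condensation-rule identification from estimated mixing proportions.

An item's operative rule is read off the posterior means of its mixing
proportions tau = (tau1, tau2, tau3): a dominant tau1 (> threshold,
default 0.9) marks the conjunctive rule and a dominant tau2 the disjunctive
rule; the ratio/compensatory rule has no reliable single cut-point, so it
is flagged whenever tau3 is strictly largest.  Anything else is reported
as coexisting rules — a signal to test developers that the item may need
revision.  Unidimensional items are skipped (all rules coincide there).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["RuleVerdict", "classify_item", "classify_items", "revision_report"]

VERDICTS = (
    "conjunctive",
    "disjunctive",
    "ratio_compensatory",
    "coexisting",
    "unidimensional_na",
)


@dataclass(frozen=True)
class RuleVerdict:
    item: int
    verdict: str
    tau: tuple
    threshold: float


def classify_item(tau_hat, q_row, threshold: float = 0.9, item: int = 0) -> RuleVerdict:
    """Classify one item's operative condensation rule.

    ``tau_hat`` are the (conjunctive, disjunctive, ratio) posterior-mean
    mixing proportions; ``threshold`` is the dominance cut-point for the
    conjunctive/disjunctive verdicts and must exceed 1/3 (below that a
    component can be "dominant" without even being the largest).
    """
    tau = np.asarray(tau_hat, dtype=float)
    if tau.shape != (3,) or (tau < 0).any() or abs(tau.sum() - 1.0) > 1e-6:
        raise ValueError(f"tau must be a 3-simplex vector, got {tau_hat}")
    if not 1.0 / 3.0 < threshold <= 1.0:
        raise ValueError(f"threshold must lie in (1/3, 1], got {threshold}")
    q = np.asarray(q_row)
    if q.sum() == 1:
        verdict = "unidimensional_na"
    elif tau[0] > threshold:
        verdict = "conjunctive"
    elif tau[1] > threshold:
        verdict = "disjunctive"
    elif tau[2] > tau[0] and tau[2] > tau[1]:
        verdict = "ratio_compensatory"
    else:
        verdict = "coexisting"
    return RuleVerdict(item=item, verdict=verdict, tau=tuple(tau), threshold=threshold)


def classify_items(tau_hat, Q, threshold: float = 0.9) -> list[RuleVerdict]:
    """Classify every item; ``tau_hat`` is (I, 3), ``Q`` the Q-matrix."""
    tau_hat = np.asarray(tau_hat, dtype=float)
    Qarr = np.asarray(Q)
    if tau_hat.shape[0] != Qarr.shape[0]:
        raise ValueError("one tau vector per Q-matrix row is required")
    return [
        classify_item(tau_hat[i], Qarr[i], threshold=threshold, item=i)
        for i in range(Qarr.shape[0])
    ]


def revision_report(verdicts, expert_expected_rules) -> pd.DataFrame:
    """Compare identified rules with expert expectations item by item.

    Returns a table with one row per item (columns: item, tau estimates,
    verdict, expected, flagged).  An item is flagged for revision when its
    identified rule differs from the expert's expectation; unidimensional
    items are never flagged.  ``report.attrs['n_flagged']`` holds the count.
    """
    expected = list(expert_expected_rules)
    if len(expected) != len(verdicts):
        raise ValueError(
            f"{len(verdicts)} verdicts but {len(expected)} expected rules"
        )
    rows = []
    for v, exp in zip(verdicts, expected):
        flagged = v.verdict != "unidimensional_na" and v.verdict != exp
        rows.append(
            {
                "item": v.item,
                "tau_conj": v.tau[0],
                "tau_disj": v.tau[1],
                "tau_ratio": v.tau[2],
                "verdict": v.verdict,
                "expected": exp,
                "flagged": flagged,
            }
        )
    report = pd.DataFrame(rows)
    report.attrs["n_flagged"] = int(report["flagged"].sum())
    return report
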