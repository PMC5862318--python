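"""Marketplace plan-payment formulas: premiums, transfers, unprofitability.

Under community rating with competitive pricing, every enrollee pays the
same premium M_i = C-bar (the market-average cost).  Risk adjustment then
moves money between plans in proportion to relative risk:
A_i = (S_i / S-bar - 1) * C-bar.  Revenue is R_i = M_i + A_i, profit is
F_i = R_i - C_i, and unprofitability is its negation

    U_i = C_i - C-bar * S_i / S-bar,

which is mean-zero over the cohort by construction: the plan breaks even
in aggregate, and prediction targets *which* enrollees lose money.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PaymentComponents",
    "compute_premium",
    "compute_transfers",
    "compute_unprofitability",
]


@dataclass(frozen=True)
class PaymentComponents:
    """Per-enrollee payment quantities ($) and the cohort scalars."""

    premium: np.ndarray      # M_i, constant at mean cost
    transfer: np.ndarray     # A_i, signed, sums to zero
    revenue: np.ndarray      # R_i = M_i + A_i
    profit: np.ndarray       # F_i = R_i - C_i
    unprofitability: np.ndarray  # U_i = -F_i
    mean_cost: float         # C-bar
    mean_risk: float         # S-bar


def compute_premium(costs: np.ndarray) -> float:
    """The competitive community-rated premium: the mean cost C-bar."""
    costs = np.asarray(costs, dtype=float)
    if costs.size == 0:
        raise ValueError("empty cost vector")
    if np.any(costs < 0):
        raise ValueError("costs must be non-negative")
    return float(np.mean(costs))


def compute_transfers(risk_scores: np.ndarray, premium: float) -> np.ndarray:
    """Risk-adjustment transfers A_i = (S_i / S-bar - 1) * C-bar.

    Budget neutral by construction: the transfers sum to zero.
    """
    s = np.asarray(risk_scores, dtype=float)
    if s.size == 0:
        raise ValueError("empty risk-score vector")
    if np.any(s <= 0):
        raise ValueError("risk scores must be strictly positive")
    return (s / s.mean() - 1.0) * float(premium)


def compute_unprofitability(costs: np.ndarray, risk_scores: np.ndarray) -> PaymentComponents:
    """Derive all payment components, including U_i = C_i - C-bar * S_i / S-bar."""
    costs = np.asarray(costs, dtype=float)
    s = np.asarray(risk_scores, dtype=float)
    if costs.shape != s.shape:
        raise ValueError("costs and risk scores must have equal length")
    if costs.size == 1:
        warnings.warn("single-enrollee cohort: unprofitability is identically zero")
    premium = compute_premium(costs)
    transfer = compute_transfers(s, premium)
    revenue = premium + transfer
    profit = revenue - costs
    return PaymentComponents(
        premium=np.full_like(costs, premium),
        transfer=transfer,
        revenue=revenue,
        profit=profit,
        unprofitability=-profit,
        mean_cost=premium,
        mean_risk=float(s.mean()),
    )
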