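"""Baseline hazard, individual risk prediction and risk-group
stratification for the federated Cox models.

The cumulative baseline hazard uses the Breslow estimator evaluated
from node aggregates only:

    dLambda0(t_k) = d_k / sum_nodes S0_k(beta_hat),

anchored at the encoded-zero covariate vector. Individual predictions
follow the proportional-hazards identity S(t|x) = S0(t)^exp(beta' x),
and "reference outcome rates" evaluate this at the reference covariate
vector (all categoricals at baseline, age 35, GTV at the published
log10 value, dose 40 EQD2) at 2, 3 and 5 years.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_model import CentreDataset, ModelConfig, reference_covariates
from .errors import ContractError, InvalidInputError
from .fedcox import (
    CoxModelFit,
    EncodedCentre,
    encode_centre,
    local_sufficient_statistics,
)
from .messages import AuditLog

__all__ = [
    "BaselineHazard",
    "RiskPrediction",
    "ReferenceRates",
    "breslow_baseline",
    "breslow_baseline_encoded",
    "predict_survival",
    "reference_outcome_rates",
    "stratify_risk_groups",
    "federated_mean",
    "sample_times_from_baseline",
    "PREDICTION_HORIZONS_MONTHS",
]

#: Reporting horizons: 2, 3 and 5 years in months.
PREDICTION_HORIZONS_MONTHS = (24.0, 36.0, 60.0)


@dataclass(frozen=True)
class BaselineHazard:
    """Breslow cumulative baseline hazard: a right-continuous step
    function with increments at the global event times."""

    times: np.ndarray  # (K,) sorted event times
    increments: np.ndarray  # (K,) dLambda0(t_k) >= 0

    def __post_init__(self) -> None:
        if len(self.times) != len(self.increments):
            raise ContractError("times and increments differ in length")
        if np.any(self.increments < 0):
            raise InvalidInputError("baseline hazard increments must be >= 0")

    def cumulative_hazard(self, t) -> np.ndarray:
        """Lambda0(t), right-continuous in t."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise InvalidInputError("t must be >= 0")
        cum = np.concatenate([[0.0], np.cumsum(self.increments)])
        idx = np.searchsorted(self.times, t, side="right")
        return cum[idx]

    def survival(self, t) -> np.ndarray:
        """Baseline survival S0(t) = exp(-Lambda0(t)); S0(0) = 1."""
        return np.exp(-self.cumulative_hazard(t))


@dataclass(frozen=True)
class RiskPrediction:
    """One patient's prediction: linear predictor, survival at the
    reporting horizons, and risk-group label."""

    patient_id: str
    eta: float
    survival: dict  # horizon (months) -> S(t|x)
    risk_group: str | None = None


@dataclass(frozen=True)
class ReferenceRates:
    """Outcome rates at 2/3/5 years for the reference covariate
    vector; ``extrapolated`` flags horizons beyond the last observed
    event time (reported at the last step's value)."""

    outcome: str
    rates: dict
    extrapolated: dict

    def __post_init__(self) -> None:
        values = [self.rates[h] for h in sorted(self.rates)]
        if any(not 0.0 <= v <= 1.0 for v in values):
            raise InvalidInputError("rates must lie in [0, 1]")


def breslow_baseline_encoded(
    encoded: Sequence[EncodedCentre],
    fit: CoxModelFit,
    audit: AuditLog | None = None,
) -> BaselineHazard:
    """Breslow baseline from already-encoded nodes: one more audited
    node round at beta_hat supplies the global d_k and S0_k sums."""
    grid = fit.event_times
    d = np.zeros(len(grid))
    S0 = np.zeros(len(grid))
    for enc in encoded:
        st = local_sufficient_statistics(enc, fit.beta, grid, audit=audit)
        d += st.d
        S0 += st.S0
    if np.any((d > 0) & (S0 <= 0)):
        raise ContractError("empty global risk set at an event time")
    increments = np.where(S0 > 0, d / np.where(S0 > 0, S0, 1.0), 0.0)
    return BaselineHazard(times=grid, increments=increments)


def breslow_baseline(
    nodes: Sequence[CentreDataset],
    fit: CoxModelFit,
    config: ModelConfig,
    audit: AuditLog | None = None,
) -> BaselineHazard:
    """Federated Breslow baseline on the same grid the model was fitted
    on. Raises if the nodes' event times disagree with the fit's grid."""
    encoded = [encode_centre(node, config) for node in nodes]
    all_events = np.unique(
        np.concatenate([e.time[e.event == 1] for e in encoded])
        if encoded
        else np.array([])
    )
    if len(all_events) != len(fit.event_times) or not np.array_equal(
        all_events, fit.event_times
    ):
        raise ContractError(
            "event-time grid mismatch: baseline must be evaluated on the "
            "nodes the model was fitted on"
        )
    return breslow_baseline_encoded(encoded, fit, audit=audit)


def predict_survival(
    x: np.ndarray, fit: CoxModelFit, baseline: BaselineHazard, t
) -> np.ndarray:
    """S(t | x) = S0(t)^exp(beta' x), right-continuous in t."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidInputError("t must be >= 0")
    eta = float(np.asarray(x, dtype=float) @ fit.beta)
    return baseline.survival(t) ** np.exp(eta)


def reference_outcome_rates(
    fit: CoxModelFit, baseline: BaselineHazard, config: ModelConfig
) -> ReferenceRates:
    """Evaluate the model at the reference covariate vector at 24, 36
    and 60 months. Horizons beyond the last event time return the last
    step's value and are flagged (with a warning) as extrapolated."""
    x_ref = reference_covariates(config)
    last_event = float(baseline.times[-1]) if len(baseline.times) else 0.0
    rates = {}
    extrapolated = {}
    for h in PREDICTION_HORIZONS_MONTHS:
        rates[h] = float(predict_survival(x_ref, fit, baseline, h))
        extrapolated[h] = h > last_event
        if extrapolated[h]:
            warnings.warn(
                f"{config.outcome}: horizon {h} months exceeds the last "
                f"event time ({last_event:.1f}); reporting the last step's "
                "value",
                stacklevel=2,
            )
    return ReferenceRates(outcome=config.outcome, rates=rates, extrapolated=extrapolated)


def federated_mean(
    node_values: Sequence[np.ndarray],
    node_ids: Sequence[str] | None = None,
    audit: AuditLog | None = None,
) -> float:
    """Global mean of per-patient values held at different nodes, via
    exchange of (sum, count) aggregates only."""
    total = 0.0
    count = 0
    for i, values in enumerate(node_values):
        values = np.asarray(values, dtype=float)
        s, n = float(values.sum()), int(values.size)
        total += s
        count += n
        if audit is not None:
            audit.record(
                kind="rate_aggregate",
                sender=node_ids[i] if node_ids else f"node{i}",
                payload={"sum_rates": s, "n": n},
            )
    if count == 0:
        raise InvalidInputError("no values to average")
    return total / count


def stratify_risk_groups(
    predicted_rates: np.ndarray, global_mean: float | None = None
) -> tuple[np.ndarray, float]:
    """Allocate patients to 'high' / 'low' risk by comparing each
    predicted 3-year outcome rate with the global predicted mean:
    below the mean -> high risk, at or above -> low risk.

    Returns (labels, threshold). If every prediction is identical the
    split is degenerate: all patients are labelled low risk and a
    warning is emitted.
    """
    rates = np.asarray(predicted_rates, dtype=float)
    if rates.size < 2:
        raise InvalidInputError("need at least two patients to stratify")
    if not np.all(np.isfinite(rates)):
        raise InvalidInputError("predicted rates must be finite")
    threshold = float(np.mean(rates)) if global_mean is None else float(global_mean)
    if np.all(rates == rates[0]):
        warnings.warn("all predicted rates identical: degenerate risk split",
                      stacklevel=2)
        return np.full(rates.shape, "low", dtype=object), threshold
    labels = np.where(rates < threshold, "high", "low").astype(object)
    return labels, threshold


def sample_times_from_baseline(
    baseline: BaselineHazard, eta: np.ndarray, u: np.ndarray
) -> np.ndarray:
    """Inverse-transform sampling from a fitted step-function model:
    the smallest grid time with Lambda0(t) * exp(eta) >= -ln(u), or
    +inf when the target exceeds the total observed hazard (the
    sampled time lies beyond follow-up). Used for model-based
    self-consistency simulations."""
    eta = np.asarray(eta, dtype=float)
    u = np.asarray(u, dtype=float)
    if np.any(u <= 0) or np.any(u >= 1):
        raise InvalidInputError("u must lie strictly inside (0, 1)")
    cum = np.cumsum(baseline.increments)
    target = -np.log(u) * np.exp(-eta)  # required Lambda0
    idx = np.searchsorted(cum, target, side="left")
    out = np.where(idx < len(cum), baseline.times[np.minimum(idx, len(cum) - 1)],
                   np.inf)
    return out
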