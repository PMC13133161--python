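"""Model validation: Kaplan-Meier summaries, potential follow-up via
the reverse Kaplan-Meier estimator, Harrell's concordance index,
leave-one-centre-out (internal-external) cross-validation, external
validation, and risk-group calibration at three years.

Discrimination is summarised per centre and combined as a mean
weighted by centre cohort size; held-out centres score their own
patients locally and emit only (c-index, n) aggregates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from lifelines import KaplanMeierFitter

from .data_model import CentreDataset, ModelConfig, OutcomeRecord
from .errors import InvalidInputError, SeparationError
from .fedcox import (
    ConvergenceSpec,
    CoxModelFit,
    EncodedCentre,
    encode_centre,
    fit_federated_cox_encoded,
)
from .messages import AuditLog
from .prediction import (
    BaselineHazard,
    federated_mean,
    stratify_risk_groups,
)

__all__ = [
    "KMCurve",
    "CentrePerformance",
    "CalibrationPoint",
    "LocoResult",
    "km_estimate",
    "reverse_km_followup",
    "harrell_cindex",
    "count_comparable_pairs",
    "weighted_mean_by_size",
    "centre_cindex_summary",
    "loco_validation",
    "external_validation",
    "calibration_3yr",
]


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate with Greenwood-type 95% bands."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray

    def survival_at(self, t) -> np.ndarray:
        """Right-continuous step lookup of S(t)."""
        t = np.asarray(t, dtype=float)
        s = np.concatenate([[1.0], self.survival])
        idx = np.searchsorted(self.times, t, side="right")
        return s[idx]

    def ci_at(self, t) -> tuple[float, float]:
        t = float(t)
        lo = np.concatenate([[1.0], self.ci_low])
        hi = np.concatenate([[1.0], self.ci_high])
        idx = int(np.searchsorted(self.times, t, side="right"))
        return float(lo[idx]), float(hi[idx])


@dataclass(frozen=True)
class CentrePerformance:
    centre_id: str
    c_index: float
    n: int
    n_comparable: int


@dataclass(frozen=True)
class CalibrationPoint:
    centre_id: str
    group: str  # "high" | "low"
    predicted_mean: float
    observed_km: float
    km_ci_low: float
    km_ci_high: float
    n_group: int


@dataclass(frozen=True)
class LocoResult:
    per_centre: tuple[CentrePerformance, ...]
    weighted_mean: float


def _to_arrays(outcomes: Sequence[OutcomeRecord]) -> tuple[np.ndarray, np.ndarray]:
    if len(outcomes) == 0:
        raise InvalidInputError("no outcome records")
    t = np.array([o.time_months for o in outcomes], dtype=float)
    e = np.array([o.event for o in outcomes], dtype=int)
    return t, e


def km_estimate(outcomes: Sequence[OutcomeRecord]) -> KMCurve:
    """Kaplan-Meier product-limit estimator; with no censoring it
    coincides with the empirical survival function."""
    t, e = _to_arrays(outcomes)
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    event_table = kmf.event_table
    mask = event_table["observed"] > 0
    times = event_table.index.values[mask].astype(float)
    surv = kmf.survival_function_at_times(times).values
    ci = kmf.confidence_interval_survival_function_.sort_index()
    ci_step = ci.reindex(ci.index.union(times)).ffill().loc[times]
    lo = ci_step.iloc[:, 0].to_numpy(dtype=float)
    hi = ci_step.iloc[:, 1].to_numpy(dtype=float)
    return KMCurve(
        times=times,
        survival=surv,
        at_risk=event_table["at_risk"].values[mask].astype(int),
        events=event_table["observed"].values[mask].astype(int),
        ci_low=lo,
        ci_high=hi,
    )


def reverse_km_followup(
    outcomes: Sequence[OutcomeRecord],
) -> tuple[float, float]:
    """Potential follow-up by the reverse Kaplan-Meier estimator: KM
    applied with the censoring indicator as the event. Returns
    (median, restricted mean) potential follow-up in months."""
    t, e = _to_arrays(outcomes)
    kmf = KaplanMeierFitter()
    kmf.fit(t, 1 - e)
    median = float(kmf.median_survival_time_)
    if not np.isfinite(median):
        median = float(np.max(t))
    from lifelines.utils import restricted_mean_survival_time

    rmst = float(restricted_mean_survival_time(kmf, t=float(np.max(t))))
    return median, rmst


def _pair_matrices(
    t: np.ndarray, e: np.ndarray
) -> np.ndarray:
    # comparable (i, j): i fails strictly earlier and i is an event
    return (t[:, None] < t[None, :]) & (e[:, None] == 1)


def count_comparable_pairs(outcomes: Sequence[OutcomeRecord]) -> int:
    t, e = _to_arrays(outcomes)
    return int(np.sum(_pair_matrices(t, e)))


def harrell_cindex(
    outcomes: Sequence[OutcomeRecord], risk_scores: Sequence[float]
) -> float:
    """Harrell's concordance index: over comparable pairs (the earlier
    time is an event), the fraction in which the earlier-failing
    patient has the higher risk score, counting tied scores 1/2.
    Computed by full pair enumeration (vectorised O(n^2))."""
    t, e = _to_arrays(outcomes)
    scores = np.asarray(risk_scores, dtype=float)
    if scores.shape != t.shape:
        raise InvalidInputError("risk_scores must align with outcomes")
    comparable = _pair_matrices(t, e)
    n_pairs = int(np.sum(comparable))
    if n_pairs == 0:
        raise InvalidInputError("no comparable pairs: c-index undefined")
    concordant = comparable & (scores[:, None] > scores[None, :])
    tied = comparable & (scores[:, None] == scores[None, :])
    return float((np.sum(concordant) + 0.5 * np.sum(tied)) / n_pairs)


def weighted_mean_by_size(
    values: Sequence[float], weights: Sequence[float]
) -> float:
    """Mean of per-centre values weighted by centre cohort size."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.size == 0 or values.shape != weights.shape:
        raise InvalidInputError("values and weights must be equal-length, non-empty")
    if np.any(weights <= 0):
        raise InvalidInputError("weights must be positive")
    return float(np.sum(values * weights) / np.sum(weights))


def _score_centre(
    enc: EncodedCentre, fit: CoxModelFit, audit: AuditLog | None
) -> CentrePerformance | None:
    """Node-side scoring: c-index of the model's linear predictor on
    this centre's own patients; only the summary leaves the node."""
    if enc.event.sum() == 0:
        warnings.warn(
            f"centre {enc.centre_id}: no events, discrimination undefined",
            stacklevel=3,
        )
        return None
    eta = enc.x @ fit.beta
    comparable = _pair_matrices(enc.time, enc.event)
    n_pairs = int(np.sum(comparable))
    if n_pairs == 0:
        warnings.warn(
            f"centre {enc.centre_id}: no comparable pairs", stacklevel=3
        )
        return None
    concordant = comparable & (eta[:, None] > eta[None, :])
    tied = comparable & (eta[:, None] == eta[None, :])
    c = float((np.sum(concordant) + 0.5 * np.sum(tied)) / n_pairs)
    if audit is not None:
        audit.record(
            kind="centre_performance",
            sender=enc.centre_id,
            payload={"c_index": c, "n": enc.n, "n_comparable_pairs": n_pairs},
        )
    return CentrePerformance(
        centre_id=enc.centre_id, c_index=c, n=enc.n, n_comparable=n_pairs
    )


def centre_cindex_summary(
    nodes: Sequence[CentreDataset],
    fit: CoxModelFit,
    config: ModelConfig,
    audit: AuditLog | None = None,
) -> LocoResult:
    """Per-centre c-indices of one fitted model (apparent performance
    when the nodes are the training centres; external validation when
    they are held-out cohorts), with the size-weighted mean."""
    perf = []
    for node in nodes:
        enc = encode_centre(node, config)
        if enc.n == 0:
            continue
        p = _score_centre(enc, fit, audit)
        if p is not None:
            perf.append(p)
    if not perf:
        raise InvalidInputError("no centre produced a defined c-index")
    wm = weighted_mean_by_size([p.c_index for p in perf], [p.n for p in perf])
    return LocoResult(per_centre=tuple(perf), weighted_mean=wm)


def loco_validation(
    nodes: Sequence[CentreDataset],
    config: ModelConfig,
    spec: ConvergenceSpec = ConvergenceSpec(),
    audit: AuditLog | None = None,
) -> LocoResult:
    """Leave-one-centre-out internal-external validation: for each
    centre, refit the federated model on all other centres and score
    the held-out centre's patients with the refitted linear predictor.
    Folds whose held-out centre has no events (or no comparable pairs)
    are skipped with a warning."""
    if len(nodes) < 2:
        raise InvalidInputError("leave-one-centre-out needs at least 2 centres")
    encoded = [encode_centre(node, config) for node in nodes]
    perf = []
    for i, held_out in enumerate(encoded):
        if held_out.n == 0:
            continue
        training = [e for j, e in enumerate(encoded) if j != i and e.n > 0]
        try:
            fit = fit_federated_cox_encoded(
                training, spec, term_names=tuple(config.covariates), audit=audit
            )
        except SeparationError as exc:
            warnings.warn(
                f"fold holding out {held_out.centre_id}: training model has "
                f"no finite maximum ({exc}); fold skipped",
                stacklevel=2,
            )
            continue
        p = _score_centre(held_out, fit, audit)
        if p is not None:
            perf.append(p)
    if not perf:
        raise InvalidInputError("no fold produced a defined c-index")
    wm = weighted_mean_by_size([p.c_index for p in perf], [p.n for p in perf])
    return LocoResult(per_centre=tuple(perf), weighted_mean=wm)


def external_validation(
    training_nodes: Sequence[CentreDataset],
    validation_nodes: Sequence[CentreDataset],
    config: ModelConfig,
    spec: ConvergenceSpec = ConvergenceSpec(),
    audit: AuditLog | None = None,
) -> tuple[CoxModelFit, LocoResult]:
    """Fit once on all training centres, then score each validation
    centre with the frozen model (no refitting)."""
    from .fedcox import fit_federated_cox

    fit = fit_federated_cox(training_nodes, config, spec, audit=audit)
    result = centre_cindex_summary(validation_nodes, fit, config, audit=audit)
    return fit, result


def calibration_3yr(
    nodes: Sequence[CentreDataset],
    fit: CoxModelFit,
    baseline: BaselineHazard,
    config: ModelConfig,
    horizon: float = 36.0,
    audit: AuditLog | None = None,
) -> list[CalibrationPoint]:
    """Risk-group calibration at a fixed horizon (default 3 years).

    Patients are split into high/low risk by the global mean of the
    predicted horizon outcome rates (aggregate exchange only); each
    centre then reports, per group, the mean predicted rate and the
    observed Kaplan-Meier rate with its 95% band. Empty groups are
    omitted with a warning.
    """
    encoded = [encode_centre(node, config) for node in nodes]
    encoded = [e for e in encoded if e.n > 0]
    s0_h = float(baseline.survival(horizon))
    pred_per_node = [s0_h ** np.exp(e.x @ fit.beta) for e in encoded]
    global_mean = federated_mean(
        pred_per_node, [e.centre_id for e in encoded], audit=audit
    )

    points: list[CalibrationPoint] = []
    for enc, pred in zip(encoded, pred_per_node):
        labels, _ = stratify_risk_groups(pred, global_mean=global_mean)
        for group in ("high", "low"):
            mask = labels == group
            if not np.any(mask):
                warnings.warn(
                    f"centre {enc.centre_id}: no {group}-risk patients, "
                    "calibration point omitted",
                    stacklevel=2,
                )
                continue
            outcomes = [
                OutcomeRecord(float(t), int(ev), config.outcome)
                for t, ev in zip(enc.time[mask], enc.event[mask])
            ]
            km = km_estimate(outcomes)
            observed = float(km.survival_at(horizon))
            lo, hi = km.ci_at(horizon)
            point = CalibrationPoint(
                centre_id=enc.centre_id,
                group=group,
                predicted_mean=float(np.mean(pred[mask])),
                observed_km=observed,
                km_ci_low=lo,
                km_ci_high=hi,
                n_group=int(np.sum(mask)),
            )
            if audit is not None:
                audit.record(
                    kind="calibration_point",
                    sender=enc.centre_id,
                    payload={
                        "group": group,
                        "predicted_mean": point.predicted_mean,
                        "observed_km": observed,
                        "km_ci_low": lo,
                        "km_ci_high": hi,
                        "n_group": point.n_group,
                    },
                )
            points.append(point)
    return points
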