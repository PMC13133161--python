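"""Federated Cox proportional-hazards engine.

Fits a Cox model across centres by exchanging only aggregate
statistics. Each node evaluates, on a shared grid of global event
times, its local Breslow sufficient statistics

    d_k   — number of local events at grid time t_k,
    s_k   — covariate sum over those events,
    S0_k  = sum_{i in R_k} w_i,        w_i = exp(beta' x_i),
    S1_k  = sum_{i in R_k} w_i x_i,
    S2_k  = sum_{i in R_k} w_i x_i x_i',

over its local risk set R_k = {i : t_i >= t_k}. Because the Breslow
partial log-likelihood, its score and its observed information are sums
of per-event-time terms built from these quantities, the server can run
exact Newton–Raphson on the *pooled* likelihood while seeing only the
aggregated sums — the federated fit is mathematically identical to a
centralised Breslow fit on the concatenated data, for any partition of
patients into centres.

Ties are handled with the Breslow approximation throughout; an Efron
variant is not offered here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    CentreDataset,
    ModelConfig,
    PatientRecord,
    derive_outcome,
    encode_covariates,
)
from .errors import (
    ContractError,
    ConvergenceError,
    InvalidInputError,
    NoEventsError,
    SeparationError,
)
from .messages import AuditLog

__all__ = [
    "EncodedCentre",
    "LocalSufficientStatistics",
    "ConvergenceSpec",
    "CoxModelFit",
    "HazardRatioTable",
    "encode_centre",
    "collect_event_times",
    "local_sufficient_statistics",
    "server_update",
    "ServerUpdate",
    "fit_federated_cox",
    "fit_federated_cox_encoded",
    "fit_pooled_cox_oracle",
    "hazard_ratios",
    "breslow_loglik_pooled",
]

#: |beta_j| beyond which, with a non-vanishing score, we declare
#: monotone likelihood (separation).
_SEPARATION_BETA_BOUND = 10.0
_SEPARATION_SCORE_FLOOR = 1e-3


@dataclass(frozen=True)
class EncodedCentre:
    """A node's design matrix and derived outcome, kept node-side."""

    centre_id: str
    x: np.ndarray  # (n, p)
    time: np.ndarray  # (n,)
    event: np.ndarray  # (n,) 0/1

    def __post_init__(self) -> None:
        if self.x.ndim != 2 or len(self.time) != self.x.shape[0]:
            raise ContractError("EncodedCentre: inconsistent shapes")
        if len(self.event) != len(self.time):
            raise ContractError("EncodedCentre: inconsistent shapes")

    @property
    def n(self) -> int:
        return self.x.shape[0]

    @property
    def p(self) -> int:
        return self.x.shape[1]


def encode_centre(node: CentreDataset, config: ModelConfig) -> EncodedCentre:
    """Derive the configured outcome and encode covariates for one
    centre. FFDM-style configs drop patients metastatic at baseline."""
    records = node.records
    if config.exclude_m1:
        records = tuple(r for r in records if r.m_stage != "M1")
    outcomes = [derive_outcome(r, config.outcome) for r in records]
    x = (
        np.array([encode_covariates(r, config) for r in records])
        if records
        else np.empty((0, config.n_parameters))
    )
    return EncodedCentre(
        centre_id=node.centre_id,
        x=x,
        time=np.array([o.time_months for o in outcomes]),
        event=np.array([o.event for o in outcomes], dtype=int),
    )


@dataclass(frozen=True)
class LocalSufficientStatistics:
    """One node's Breslow aggregates on the shared event-time grid, at a
    given coefficient vector. This object is the *only* model-fitting
    payload a node emits."""

    centre_id: str
    d: np.ndarray  # (K,) local event counts
    s: np.ndarray  # (K, p) covariate sums over local events
    S0: np.ndarray  # (K,)
    S1: np.ndarray  # (K, p)
    S2: np.ndarray  # (K, p, p)
    loglik_term: float  # sum over local events of beta' x_i
    n_local: int


@dataclass(frozen=True)
class ConvergenceSpec:
    """Newton–Raphson stopping rules. Defaults are strict enough that
    the federated and pooled optima agree well below test tolerances."""

    max_iterations: int = 50
    tol_beta: float = 1e-8
    tol_loglik: float = 1e-10
    step_halving_max: int = 20

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise InvalidInputError("max_iterations must be >= 1")
        if self.tol_beta <= 0 or self.tol_loglik <= 0:
            raise InvalidInputError("tolerances must be > 0")


@dataclass(frozen=True)
class CoxModelFit:
    """A fitted Cox model: coefficients, covariance (inverse observed
    information), maximised Breslow partial log-likelihood, score at the
    optimum, and convergence metadata."""

    beta: np.ndarray
    covariance: np.ndarray
    loglik: float
    score: np.ndarray
    n_iterations: int
    converged: bool
    event_times: np.ndarray
    term_names: tuple[str, ...]
    n_total: int
    n_events: int

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))

    def linear_predictor(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return x @ self.beta


@dataclass(frozen=True)
class HazardRatioTable:
    """Per-covariate hazard ratios with Wald 95% CIs; a factor is
    flagged prognostic when its CI excludes 1."""

    terms: tuple[str, ...]
    hr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    se_log: np.ndarray
    prognostic: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "hr": self.hr,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "se_log_hr": self.se_log,
                "prognostic": self.prognostic,
            }
        )


# ---------------------------------------------------------------------------
# Node-side operations
# ---------------------------------------------------------------------------


def _as_encoded(
    node: CentreDataset | EncodedCentre, config: ModelConfig | None
) -> EncodedCentre:
    if isinstance(node, EncodedCentre):
        return node
    if config is None:
        raise ContractError("a ModelConfig is required to encode a CentreDataset")
    return encode_centre(node, config)


def collect_event_times(
    nodes: Sequence[CentreDataset | EncodedCentre],
    config: ModelConfig | None = None,
    audit: AuditLog | None = None,
) -> np.ndarray:
    """Shared grid: the sorted union of distinct event times across all
    nodes. Each node contributes only its own distinct event times
    (grid sharing is the explicit privacy/utility trade-off of this
    scheme: exact pooled equivalence requires a common grid)."""
    per_node = []
    for node in nodes:
        enc = _as_encoded(node, config)
        local = np.unique(enc.time[enc.event == 1])
        per_node.append(local)
        if audit is not None:
            audit.record(
                kind="event_times", sender=enc.centre_id, payload={"event_times": local}
            )
    grid = np.unique(np.concatenate(per_node)) if per_node else np.array([])
    if grid.size == 0:
        raise NoEventsError("no events in any centre")
    return grid


def local_sufficient_statistics(
    node: CentreDataset | EncodedCentre,
    beta: np.ndarray,
    grid: np.ndarray,
    config: ModelConfig | None = None,
    audit: AuditLog | None = None,
) -> LocalSufficientStatistics:
    """Evaluate one node's Breslow sums at ``beta`` on the shared grid.

    At beta = 0, S0_k is the local risk-set size and S1_k the plain
    covariate sum over the risk set.
    """
    enc = _as_encoded(node, config)
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (enc.p,):
        raise ContractError(
            f"beta has shape {beta.shape}, design has {enc.p} columns"
        )
    K, p = len(grid), enc.p

    w = np.exp(enc.x @ beta)  # (n,)
    order = np.argsort(enc.time, kind="stable")
    t_sorted = enc.time[order]
    x_sorted = enc.x[order]
    w_sorted = w[order]

    # suffix sums: risk set at grid time t_k is {i : t_i >= t_k}
    wx = w_sorted[:, None] * x_sorted  # (n, p)
    wxx = wx[:, :, None] * x_sorted[:, None, :]  # (n, p, p)
    suf0 = np.concatenate([np.cumsum(w_sorted[::-1])[::-1], [0.0]])
    suf1 = np.concatenate([np.cumsum(wx[::-1], axis=0)[::-1], np.zeros((1, p))])
    suf2 = np.concatenate([np.cumsum(wxx[::-1], axis=0)[::-1], np.zeros((1, p, p))])
    idx = np.searchsorted(t_sorted, grid, side="left")
    S0 = suf0[idx]
    S1 = suf1[idx]
    S2 = suf2[idx]

    # local events on the grid
    d = np.zeros(K)
    s = np.zeros((K, p))
    ev_mask = enc.event == 1
    ev_times = enc.time[ev_mask]
    ev_x = enc.x[ev_mask]
    pos = np.searchsorted(grid, ev_times)
    on_grid = (pos < K) & np.isclose(
        grid[np.minimum(pos, K - 1)], ev_times, rtol=0, atol=0
    )
    if not np.all(on_grid):
        raise ContractError(
            f"centre {enc.centre_id}: event time not on the shared grid"
        )
    np.add.at(d, pos, 1.0)
    np.add.at(s, pos, ev_x)
    loglik_term = float(np.sum(ev_x @ beta)) if ev_x.size else 0.0

    stats = LocalSufficientStatistics(
        centre_id=enc.centre_id,
        d=d,
        s=s,
        S0=S0,
        S1=S1,
        S2=S2,
        loglik_term=loglik_term,
        n_local=enc.n,
    )
    if audit is not None:
        audit.record(
            kind="sufficient_statistics",
            sender=enc.centre_id,
            payload={
                "d": d,
                "s": s,
                "S0": S0,
                "S1": S1,
                "S2": S2,
                "loglik_term": loglik_term,
                "n_local": enc.n,
            },
        )
    return stats


# ---------------------------------------------------------------------------
# Server-side aggregation and Newton step
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _GlobalState:
    d: np.ndarray
    s: np.ndarray
    S0: np.ndarray
    S1: np.ndarray
    S2: np.ndarray
    loglik: float
    n_total: int


def _aggregate(stats: Sequence[LocalSufficientStatistics]) -> _GlobalState:
    if not stats:
        raise ContractError("no node statistics to aggregate")
    K, p = stats[0].d.shape[0], stats[0].s.shape[1]
    for st in stats:
        if st.d.shape[0] != K or st.s.shape[1] != p:
            raise ContractError("nodes reported on inconsistent grids")
    d = np.sum([st.d for st in stats], axis=0)
    s = np.sum([st.s for st in stats], axis=0)
    S0 = np.sum([st.S0 for st in stats], axis=0)
    S1 = np.sum([st.S1 for st in stats], axis=0)
    S2 = np.sum([st.S2 for st in stats], axis=0)
    has_event = d > 0
    loglik = float(
        sum(st.loglik_term for st in stats)
        - np.sum(d[has_event] * np.log(S0[has_event]))
    )
    return _GlobalState(
        d=d, s=s, S0=S0, S1=S1, S2=S2, loglik=loglik,
        n_total=int(sum(st.n_local for st in stats)),
    )


def _score_information(state: _GlobalState) -> tuple[np.ndarray, np.ndarray]:
    mask = state.d > 0
    d = state.d[mask]
    s = state.s[mask]
    S0 = state.S0[mask]
    S1 = state.S1[mask]
    S2 = state.S2[mask]
    m = S1 / S0[:, None]  # (K, p)
    U = np.sum(s - d[:, None] * m, axis=0)
    V = S2 / S0[:, None, None] - m[:, :, None] * m[:, None, :]
    I = np.einsum("k,kij->ij", d, V)
    return U, I


def _newton_direction(U: np.ndarray, I: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.solve(I, U)
    except np.linalg.LinAlgError:
        # ridge-regularised retry on a singular information matrix
        p = len(U)
        ridge = 1e-8 * (np.trace(I) / p if np.trace(I) > 0 else 1.0)
        try:
            return np.linalg.solve(I + ridge * np.eye(p), U)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("information matrix is singular") from exc


@dataclass(frozen=True)
class ServerUpdate:
    """Result of one server-side Newton step."""

    beta: np.ndarray  # accepted new coefficients
    loglik: float  # global Breslow loglik at the *input* beta
    score: np.ndarray  # U at the input beta
    information: np.ndarray  # I at the input beta
    loglik_new: float | None  # loglik at the accepted beta (if evaluated)
    step_halvings: int


def server_update(
    stats: Sequence[LocalSufficientStatistics],
    beta: np.ndarray,
    spec: ConvergenceSpec = ConvergenceSpec(),
    evaluate: Callable[[np.ndarray], float] | None = None,
) -> ServerUpdate:
    """Aggregate node statistics (reported at ``beta``) and take one
    Newton–Raphson step on the global Breslow partial likelihood.

    ``evaluate``, when provided, maps a candidate beta to the global
    log-likelihood (triggering a fresh audited node round); the step is
    then halved until the log-likelihood does not decrease. Without it
    the full Newton step is returned.
    """
    beta = np.asarray(beta, dtype=float)
    state = _aggregate(stats)
    if not np.isfinite(state.loglik):
        raise ConvergenceError("non-finite partial log-likelihood")
    U, I = _score_information(state)
    delta = _newton_direction(U, I)

    halvings = 0
    step = 1.0
    beta_new = beta + delta
    loglik_new = None
    if evaluate is not None:
        loglik_new = evaluate(beta_new)
        while (
            (not np.isfinite(loglik_new) or loglik_new < state.loglik - 1e-12)
            and halvings < spec.step_halving_max
        ):
            step *= 0.5
            halvings += 1
            beta_new = beta + step * delta
            loglik_new = evaluate(beta_new)
        if not np.isfinite(loglik_new):
            raise ConvergenceError("divergent likelihood during step-halving")
    return ServerUpdate(
        beta=beta_new,
        loglik=state.loglik,
        score=U,
        information=I,
        loglik_new=loglik_new,
        step_halvings=halvings,
    )


# ---------------------------------------------------------------------------
# Full fitting loops
# ---------------------------------------------------------------------------


def _check_separation(beta: np.ndarray, U: np.ndarray) -> None:
    if np.any(np.abs(beta) > _SEPARATION_BETA_BOUND) and (
        np.max(np.abs(U)) > _SEPARATION_SCORE_FLOOR
    ):
        j = int(np.argmax(np.abs(beta)))
        raise SeparationError(
            f"monotone likelihood suspected: |beta[{j}]| > "
            f"{_SEPARATION_BETA_BOUND} with non-vanishing score"
        )


def fit_federated_cox_encoded(
    encoded: Sequence[EncodedCentre],
    spec: ConvergenceSpec = ConvergenceSpec(),
    term_names: tuple[str, ...] | None = None,
    audit: AuditLog | None = None,
) -> CoxModelFit:
    """Fit the federated Cox model on already-encoded nodes.

    Iterates node rounds (local Breslow sums) and server Newton updates
    from beta = 0 until both the max coefficient change and the relative
    log-likelihood change fall below tolerance.
    """
    if not encoded:
        raise InvalidInputError("no nodes")
    p = encoded[0].p
    for enc in encoded:
        if enc.p != p:
            raise ContractError("nodes have inconsistent design dimensions")
    grid = collect_event_times(encoded, audit=audit)

    def node_round(beta: np.ndarray) -> list[LocalSufficientStatistics]:
        if audit is not None:
            for enc in encoded:
                audit.record(
                    kind="model_broadcast",
                    sender="server",
                    recipient=enc.centre_id,
                    payload={"beta": beta, "grid": grid},
                )
        return [
            local_sufficient_statistics(enc, beta, grid, audit=audit)
            for enc in encoded
        ]

    # cache: step-halving evaluates candidate betas whose stats we reuse
    cache: dict[bytes, list[LocalSufficientStatistics]] = {}

    def stats_at(beta: np.ndarray) -> list[LocalSufficientStatistics]:
        key = np.ascontiguousarray(beta).tobytes()
        if key not in cache:
            cache[key] = node_round(beta)
        return cache[key]

    def loglik_at(beta: np.ndarray) -> float:
        return _aggregate(stats_at(beta)).loglik

    beta = np.zeros(p)
    stats = stats_at(beta)
    state = _aggregate(stats)
    converged = False
    n_iter = 0
    last_U = _score_information(state)[0]
    last_I = _score_information(state)[1]

    for n_iter in range(1, spec.max_iterations + 1):
        upd = server_update(stats, beta, spec, evaluate=loglik_at)
        d_beta = float(np.max(np.abs(upd.beta - beta)))
        rel = abs(upd.loglik_new - upd.loglik) / (abs(upd.loglik) + 1e-12)
        beta = upd.beta
        stats = stats_at(beta)
        state = _aggregate(stats)
        last_U, last_I = _score_information(state)
        cache.clear()
        cache[np.ascontiguousarray(beta).tobytes()] = stats
        _check_separation(beta, last_U)
        if d_beta < spec.tol_beta and rel < spec.tol_loglik:
            converged = True
            break

    covariance = np.linalg.inv(last_I)
    # monotone likelihood can also surface as a numeric plateau: the
    # relative hazard underflows, the score vanishes and the "optimum"
    # sits at an absurd magnitude with an essentially flat likelihood
    big = np.abs(beta) > _SEPARATION_BETA_BOUND
    if np.any(big):
        flat = np.sqrt(np.abs(np.diag(covariance))) > 5.0
        if np.any(big & flat):
            j = int(np.argmax(np.abs(beta)))
            raise SeparationError(
                f"monotone likelihood: beta[{j}] = {beta[j]:.2f} with a "
                "flat likelihood (no finite maximum)"
            )
    names = term_names or tuple(f"x{j}" for j in range(p))
    return CoxModelFit(
        beta=beta,
        covariance=covariance,
        loglik=state.loglik,
        score=last_U,
        n_iterations=n_iter,
        converged=converged,
        event_times=grid,
        term_names=names,
        n_total=state.n_total,
        n_events=int(np.sum(state.d)),
    )


def fit_federated_cox(
    nodes: Sequence[CentreDataset],
    config: ModelConfig,
    spec: ConvergenceSpec = ConvergenceSpec(),
    audit: AuditLog | None = None,
) -> CoxModelFit:
    """Fit one endpoint's Cox model across centres, exchanging only
    aggregate statistics (see module docstring)."""
    encoded = [encode_centre(node, config) for node in nodes]
    encoded = [enc for enc in encoded if enc.n > 0]
    if not encoded:
        raise InvalidInputError("no patients after model-level exclusions")
    x_all = np.vstack([enc.x for enc in encoded])
    if np.any(np.ptp(x_all, axis=0) == 0):
        j = int(np.argmin(np.ptp(x_all, axis=0)))
        raise InvalidInputError(
            f"covariate {config.covariates[j]!r} is constant across the cohort"
        )
    return fit_federated_cox_encoded(
        encoded, spec, term_names=tuple(config.covariates), audit=audit
    )


def breslow_loglik_pooled(
    time: np.ndarray, event: np.ndarray, x: np.ndarray, beta: np.ndarray
) -> float:
    """Breslow partial log-likelihood evaluated directly on pooled
    arrays (no federation machinery); used by the pooled oracle."""
    enc = EncodedCentre("pooled", np.asarray(x, float), np.asarray(time, float),
                        np.asarray(event, int))
    grid = np.unique(enc.time[enc.event == 1])
    if grid.size == 0:
        raise NoEventsError("no events")
    st = local_sufficient_statistics(enc, np.asarray(beta, float), grid)
    return _aggregate([st]).loglik


def fit_pooled_cox_oracle(
    records: Sequence[PatientRecord] | Sequence[CentreDataset] | EncodedCentre,
    config: ModelConfig | None = None,
    spec: ConvergenceSpec = ConvergenceSpec(),
) -> CoxModelFit:
    """Centralised Breslow Cox fit on the pooled rows, via an
    established survival library (scikit-survival), for equivalence
    testing against the federated path.

    The coefficient estimate comes from the external optimiser; the
    log-likelihood, score and covariance reported in the returned fit
    are evaluated at that estimate with the standard Breslow formulas.
    """
    from sksurv.linear_model import CoxPHSurvivalAnalysis

    if isinstance(records, EncodedCentre):
        enc = records
        names = tuple(f"x{j}" for j in range(enc.p))
    else:
        records = list(records)
        if records and isinstance(records[0], CentreDataset):
            pooled: list[PatientRecord] = []
            for node in records:
                pooled.extend(node.records)
            records = pooled
        if config is None:
            raise ContractError("a ModelConfig is required for raw records")
        node = CentreDataset("pooled", tuple(records), role="training")
        enc = encode_centre(node, config)
        names = tuple(config.covariates)

    y = np.empty(enc.n, dtype=[("event", "?"), ("time", "<f8")])
    y["event"] = enc.event.astype(bool)
    y["time"] = enc.time
    model = CoxPHSurvivalAnalysis(ties="breslow", n_iter=200, tol=1e-12)
    model.fit(enc.x, y)
    beta = np.asarray(model.coef_, dtype=float)

    grid = np.unique(enc.time[enc.event == 1])
    st = local_sufficient_statistics(enc, beta, grid)
    state = _aggregate([st])
    U, I = _score_information(state)
    return CoxModelFit(
        beta=beta,
        covariance=np.linalg.inv(I),
        loglik=state.loglik,
        score=U,
        n_iterations=-1,
        converged=True,
        event_times=grid,
        term_names=names,
        n_total=enc.n,
        n_events=int(enc.event.sum()),
    )


def hazard_ratios(fit: CoxModelFit, z: float = 1.96) -> HazardRatioTable:
    """Hazard ratios exp(beta) with Wald 95% CIs on the log scale; the
    prognostic flag marks CIs excluding 1."""
    if not fit.converged:
        raise ConvergenceError(
            "refusing to report hazard ratios for a non-converged fit "
            f"(n_iterations={fit.n_iterations}, max|score|="
            f"{np.max(np.abs(fit.score)):.3g})"
        )
    se = fit.se
    hr = np.exp(fit.beta)
    ci_low = np.exp(fit.beta - z * se)
    ci_high = np.exp(fit.beta + z * se)
    prognostic = (ci_low > 1.0) | (ci_high < 1.0)
    return HazardRatioTable(
        terms=fit.term_names,
        hr=hr,
        ci_low=ci_low,
        ci_high=ci_high,
        se_log=se,
        prognostic=prognostic,
    )
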