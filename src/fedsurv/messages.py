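"""Cross-node message schemas and the payload audit log.

The federation is simulated in-process, but every quantity that would
cross a node boundary in a deployed system is funnelled through
:class:`AuditLog.record`, which validates the payload against a
versioned schema whitelist. The schemas admit only aggregate
statistics — event-time grids, per-event-time counts and Breslow sums,
scalar means, log-likelihood terms, performance summaries — so a patient
row (or any field outside the schema) raises immediately. Tests and the
pipeline assert on the log to certify that no patient-level data was
exchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .errors import AuditViolationError

__all__ = ["AuditLog", "AuditEntry", "PAYLOAD_SCHEMAS", "SCHEMA_VERSION"]

SCHEMA_VERSION = "1"

#: kind -> (required keys, optional keys). Values must be scalars,
#: strings, or numeric ndarrays; nothing resembling a patient table is
#: representable.
PAYLOAD_SCHEMAS: dict[str, tuple[frozenset, frozenset]] = {
    # federated GTV imputation: one scalar mean per donor centre
    "gtv_mean": (frozenset({"gtv_mean_cm3"}), frozenset()),
    # node -> server: the node's distinct event times
    "event_times": (frozenset({"event_times"}), frozenset()),
    # server -> nodes: current coefficients and the shared grid
    "model_broadcast": (frozenset({"beta", "grid"}), frozenset()),
    # node -> server: Breslow sufficient statistics on the shared grid
    "sufficient_statistics": (
        frozenset({"d", "s", "S0", "S1", "S2", "loglik_term", "n_local"}),
        frozenset(),
    ),
    # node -> server: sum and count of predicted rates (risk-group split)
    "rate_aggregate": (frozenset({"sum_rates", "n"}), frozenset()),
    # node -> server: per-centre discrimination summary
    "centre_performance": (
        frozenset({"c_index", "n"}),
        frozenset({"n_comparable_pairs"}),
    ),
    # node -> server: one calibration point (group-level aggregates)
    "calibration_point": (
        frozenset({"group", "predicted_mean", "observed_km", "n_group"}),
        frozenset({"km_ci_low", "km_ci_high"}),
    ),
}

_SCALAR_TYPES = (int, float, str, bool, np.integer, np.floating)


def _validate_value(kind: str, key: str, value: Any) -> None:
    if isinstance(value, _SCALAR_TYPES):
        return
    if isinstance(value, np.ndarray):
        if value.dtype == object:
            raise AuditViolationError(
                f"payload {kind}.{key}: object-dtype array not allowed"
            )
        if value.ndim > 3:
            raise AuditViolationError(
                f"payload {kind}.{key}: array rank {value.ndim} not allowed"
            )
        return
    raise AuditViolationError(
        f"payload {kind}.{key}: type {type(value).__name__} not allowed "
        "(only scalars and numeric arrays may cross node boundaries)"
    )


def validate_payload(kind: str, payload: dict[str, Any]) -> None:
    """Raise :class:`AuditViolationError` unless the payload matches the
    schema for its kind exactly."""
    if kind not in PAYLOAD_SCHEMAS:
        raise AuditViolationError(f"unknown payload kind {kind!r}")
    required, optional = PAYLOAD_SCHEMAS[kind]
    keys = set(payload)
    missing = required - keys
    extra = keys - required - optional
    if missing:
        raise AuditViolationError(f"payload {kind}: missing keys {sorted(missing)}")
    if extra:
        raise AuditViolationError(f"payload {kind}: unexpected keys {sorted(extra)}")
    for key, value in payload.items():
        _validate_value(kind, key, value)


@dataclass(frozen=True)
class AuditEntry:
    kind: str
    sender: str
    recipient: str
    payload: dict[str, Any]
    version: str = SCHEMA_VERSION


@dataclass
class AuditLog:
    """Append-only record of every cross-node payload in a run."""

    entries: list[AuditEntry] = field(default_factory=list)

    def record(
        self,
        kind: str,
        sender: str,
        payload: dict[str, Any],
        recipient: str = "server",
    ) -> None:
        validate_payload(kind, payload)
        self.entries.append(
            AuditEntry(kind=kind, sender=sender, recipient=recipient, payload=payload)
        )

    def assert_clean(self) -> None:
        """Re-validate every logged payload (idempotent safety check)."""
        for entry in self.entries:
            validate_payload(entry.kind, entry.payload)

    def counts_by_kind(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for entry in self.entries:
            out[entry.kind] = out.get(entry.kind, 0) + 1
        return out

    def to_jsonl(self, path) -> None:
        """Serialise the log (arrays summarised by shape, to keep the
        audit trail readable and small)."""
        with open(path, "w", encoding="utf-8") as fh:
            for entry in self.entries:
                summary = {}
                for key, value in entry.payload.items():
                    if isinstance(value, np.ndarray):
                        summary[key] = {"array_shape": list(value.shape)}
                    elif isinstance(value, (np.integer, np.floating)):
                        summary[key] = value.item()
                    else:
                        summary[key] = value
                fh.write(
                    json.dumps(
                        {
                            "version": entry.version,
                            "kind": entry.kind,
                            "sender": entry.sender,
                            "recipient": entry.recipient,
                            "payload": summary,
                        }
                    )
                    + "\n"
                )
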