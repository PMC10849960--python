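"""Threshold-gate filtering and ranking of design metric tables.

Applies the computational gates used in binder-design campaigns (for
example interface pAE < 10, mean pLDDT > 92, pTM > 0.8, RMSD < 1.75 Å) to
records of named numeric metrics.  Comparisons are strict or non-strict
exactly as written: a record sitting on a strict boundary fails.
Metrics may be computed locally or supplied externally (network/Rosetta
scores consumed as numbers); each metric can carry a provenance tag.
"""

from __future__ import annotations

import operator
from dataclasses import dataclass, field

COMPARATORS = {
    "<": operator.lt,
    ">": operator.gt,
    "<=": operator.le,
    ">=": operator.ge,
}


class SchemaError(KeyError):
    """A gated metric is missing from a record."""


@dataclass
class MetricRecord:
    """One design's named numeric metrics.

    ``provenance`` optionally tags each metric as computed-here or
    external; units are free-form strings keyed by metric name.
    """
    design_id: str
    metrics: dict[str, float]
    provenance: dict[str, str] = field(default_factory=dict)
    units: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, key: str) -> float:
        return self.metrics[key]


@dataclass(frozen=True)
class Gate:
    """One threshold test, e.g. Gate('interface_pae', '<', 10.0)."""
    metric: str
    comparator: str
    threshold: float

    def __post_init__(self) -> None:
        if self.comparator not in COMPARATORS:
            raise ValueError(
                f"comparator {self.comparator!r} not in {sorted(COMPARATORS)}")

    def passes(self, value: float) -> bool:
        return COMPARATORS[self.comparator](value, self.threshold)

    def __str__(self) -> str:
        return f"{self.metric} {self.comparator} {self.threshold}"


@dataclass
class FailedRecord:
    record: MetricRecord
    violated: list[Gate]


def apply_gates(records: list[MetricRecord], gates: list[Gate]
                ) -> tuple[list[MetricRecord], list[FailedRecord]]:
    """Split records into passing and failing, preserving input order.

    Every failed record lists *all* gates it violates.  A record missing
    a gated metric raises :class:`SchemaError` naming record and metric.
    """
    passed: list[MetricRecord] = []
    failed: list[FailedRecord] = []
    for rec in records:
        for g in gates:
            if g.metric not in rec.metrics:
                raise SchemaError(
                    f"record {rec.design_id!r} lacks metric {g.metric!r}")
        violated = [g for g in gates if not g.passes(rec.metrics[g.metric])]
        if violated:
            failed.append(FailedRecord(record=rec, violated=violated))
        else:
            passed.append(rec)
    return passed, failed


def rank_and_take(records: list[MetricRecord], key: str, n: int,
                  ascending: bool = True) -> list[MetricRecord]:
    """Top-n records by a key metric (stable; ties broken by design id).

    ``ascending=True`` treats smaller as better (energies, errors);
    set False for confidence-like metrics.  Returns min(n, len) records.
    """
    for rec in records:
        if key not in rec.metrics:
            raise SchemaError(f"record {rec.design_id!r} lacks metric {key!r}")
    sign = 1.0 if ascending else -1.0
    ranked = sorted(records, key=lambda r: (sign * r.metrics[key], r.design_id))
    return ranked[:max(n, 0)]


# Common binder-design campaign gate sets (thresholds are strict).
THREADING_GATES = [
    Gate("interface_pae", "<", 10.0),
    Gate("plddt", ">", 92.0),
    Gate("ptm", ">", 0.8),
    Gate("rmsd", "<", 1.75),
]
CAMPAIGN_GATES = [
    Gate("interface_pae", "<", 10.0),
    Gate("plddt", ">", 80.0),
    Gate("ddg", "<", -40.0),
]
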