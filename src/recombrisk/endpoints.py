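"""Assay endpoint computation.

Converts raw assay measurements into the four defined cellular endpoints:

* ``H`` — hyper-recombination rate: percentage of neo-resistant colonies
  that are also hyg-resistant in the pTPSN plasmid assay.
* ``F`` — HPRT mutation frequency: percentage of seeded cells forming
  colonies under 6-thioguanine selection.
* ``E`` — cellular evasion after 2 Gy: summed irradiated-minus-control
  change of the S and G2/M fractions (may be negative).
* ``G`` — G2/M escape after 2 Gy: irradiated-minus-control change of the
  G2/M fraction alone.

plus the G1 escape difference, and summarizes replicates as mean ± SEM.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from statistics import mean as _mean, stdev as _stdev
from typing import Sequence

from .panel import (
    AssayKind,
    CellLineRecord,
    CytometryCounts,
    Endpoint,
    EndpointSet,
    HprtCounts,
    PlasmidCounts,
    ScalarMeasurement,
)

__all__ = [
    "Condition",
    "CytometrySnapshot",
    "UndefinedRateError",
    "LowColonyCountWarning",
    "hyper_recombination_rate",
    "hprt_mutation_frequency",
    "evasion_percent",
    "g2m_escape_percent",
    "g1_escape_percent",
    "summarize_endpoint",
    "compute_endpoints",
    "MIN_NEO_COLONIES",
]

#: Experimental practice: plasmid experiments are repeated until at least
#: 20 neo-resistant colonies are counted.
MIN_NEO_COLONIES = 20


class UndefinedRateError(ZeroDivisionError):
    """A rate with a zero denominator."""


class LowColonyCountWarning(UserWarning):
    """Fewer neo-resistant colonies than the recommended minimum."""


class Condition(str, Enum):
    IRRADIATED_2GY = "IRRADIATED_2GY"
    UNIRRADIATED = "UNIRRADIATED"


@dataclass(frozen=True)
class CytometrySnapshot:
    """Cell-cycle phase percentages of one sample under one condition."""

    g1: float
    s: float
    g2m: float
    condition: Condition

    def __post_init__(self):
        for name in ("g1", "s", "g2m"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must lie in [0, 100], got {v}")
        if self.g1 + self.s + self.g2m > 100.0 + 1e-9:
            raise ValueError(
                f"phase percentages sum to {self.g1 + self.s + self.g2m:.3f} > 100"
            )
        object.__setattr__(self, "condition", Condition(self.condition))


def hyper_recombination_rate(
    hyg_colonies: int,
    neo_colonies: int,
    *,
    min_neo: int = MIN_NEO_COLONIES,
    strict: bool = False,
) -> float:
    """Hyper-recombination rate H = hyg+ / neo+ x 100, in percent.

    ``neo_colonies`` below ``min_neo`` triggers :class:`LowColonyCountWarning`
    (or a ``ValueError`` when ``strict``), reflecting the practice of
    accumulating at least 20 neo-resistant colonies before quoting a rate.
    """
    if hyg_colonies < 0 or neo_colonies < 0:
        raise ValueError("colony counts must be >= 0")
    if neo_colonies == 0:
        raise UndefinedRateError("H undefined: no neo-resistant colonies counted")
    if hyg_colonies > neo_colonies:
        raise ValueError(
            f"hyg_colonies ({hyg_colonies}) cannot exceed neo_colonies ({neo_colonies})"
        )
    if neo_colonies < min_neo:
        msg = f"only {neo_colonies} neo-resistant colonies (< {min_neo} recommended)"
        if strict:
            raise ValueError(msg)
        warnings.warn(msg, LowColonyCountWarning, stacklevel=2)
    return hyg_colonies / neo_colonies * 100.0


def hprt_mutation_frequency(colonies_6tg: int, colonies_seeded: int) -> float:
    """HPRT mutation frequency F = 6TG-resistant / seeded x 100, in percent."""
    if colonies_6tg < 0 or colonies_seeded < 0:
        raise ValueError("colony counts must be >= 0")
    if colonies_seeded == 0:
        raise UndefinedRateError("F undefined: no cells seeded")
    if colonies_6tg > colonies_seeded:
        raise ValueError(
            f"colonies_6tg ({colonies_6tg}) cannot exceed colonies_seeded ({colonies_seeded})"
        )
    return colonies_6tg / colonies_seeded * 100.0


def _check_conditions(irr: CytometrySnapshot, ctrl: CytometrySnapshot) -> None:
    if irr.condition is not Condition.IRRADIATED_2GY:
        raise ValueError(f"first snapshot must be IRRADIATED_2GY, got {irr.condition.value}")
    if ctrl.condition is not Condition.UNIRRADIATED:
        raise ValueError(f"second snapshot must be UNIRRADIATED, got {ctrl.condition.value}")


def evasion_percent(irr: CytometrySnapshot, ctrl: CytometrySnapshot) -> float:
    """Cellular evasion E = (ΔG2/M) + (ΔS) after 2 Gy; may be negative."""
    _check_conditions(irr, ctrl)
    return (irr.g2m - ctrl.g2m) + (irr.s - ctrl.s)


def g2m_escape_percent(irr: CytometrySnapshot, ctrl: CytometrySnapshot) -> float:
    """G2/M escape G = ΔG2/M after 2 Gy."""
    _check_conditions(irr, ctrl)
    return irr.g2m - ctrl.g2m


def g1_escape_percent(irr: CytometrySnapshot, ctrl: CytometrySnapshot) -> float:
    """G1 escape = ΔG1 after 2 Gy; may be negative."""
    _check_conditions(irr, ctrl)
    return irr.g1 - ctrl.g1


def summarize_endpoint(
    values: Sequence[float],
    endpoint: Endpoint | str,
    line_id: str = "",
) -> EndpointSet:
    """Summarize replicate endpoint values as mean ± SEM.

    SEM uses the sample standard deviation (n−1 denominator) divided by
    √n; a single replicate reports SEM 0.
    """
    if len(values) == 0:
        raise ValueError("cannot summarize an empty list of replicate values")
    n = len(values)
    m = _mean(values)
    sem = _stdev(values) / math.sqrt(n) if n > 1 else 0.0
    return EndpointSet(line_id=line_id, endpoint=Endpoint(endpoint), mean=m, sem=sem, n=n)


def _snapshots(c: CytometryCounts) -> tuple[CytometrySnapshot, CytometrySnapshot]:
    irr = CytometrySnapshot(c.g1_irr, c.s_irr, c.g2m_irr, Condition.IRRADIATED_2GY)
    ctrl = CytometrySnapshot(c.g1_ctrl, c.s_ctrl, c.g2m_ctrl, Condition.UNIRRADIATED)
    return irr, ctrl


def compute_endpoints(record: CellLineRecord, *, strict: bool = False) -> list[EndpointSet]:
    """Compute every available endpoint summary for one cell line.

    Groups the record's raw assays by kind, evaluates the per-replicate
    endpoint formulas, and summarizes each endpoint over replicates.
    Endpoints whose assay is absent from the record are simply omitted.
    """
    out: list[EndpointSet] = []

    plasmid = record.assays(AssayKind.PLASMID)
    if plasmid:
        h_vals = [
            hyper_recombination_rate(a.payload.hyg_colonies, a.payload.neo_colonies, strict=strict)
            for a in plasmid
            if isinstance(a.payload, PlasmidCounts)
        ]
        out.append(summarize_endpoint(h_vals, Endpoint.H, record.line_id))

    hprt = record.assays(AssayKind.HPRT)
    if hprt:
        f_vals = [
            hprt_mutation_frequency(a.payload.colonies_6tg, a.payload.colonies_seeded)
            for a in hprt
            if isinstance(a.payload, HprtCounts)
        ]
        out.append(summarize_endpoint(f_vals, Endpoint.F, record.line_id))

    cyto = record.assays(AssayKind.CYTOMETRY)
    if cyto:
        e_vals, g_vals, g1_vals = [], [], []
        for a in cyto:
            if not isinstance(a.payload, CytometryCounts):
                continue
            irr, ctrl = _snapshots(a.payload)
            e_vals.append(evasion_percent(irr, ctrl))
            g_vals.append(g2m_escape_percent(irr, ctrl))
            g1_vals.append(g1_escape_percent(irr, ctrl))
        out.append(summarize_endpoint(e_vals, Endpoint.E, record.line_id))
        out.append(summarize_endpoint(g_vals, Endpoint.G, record.line_id))
        out.append(summarize_endpoint(g1_vals, Endpoint.G1, record.line_id))

    for kind, ep in (
        (AssayKind.FDR, Endpoint.FDR),
        (AssayKind.MRE11MAX, Endpoint.MRE11MAX),
        (AssayKind.SF2, Endpoint.SF2),
    ):
        assays = record.assays(kind)
        if assays:
            vals = [a.payload.value for a in assays if isinstance(a.payload, ScalarMeasurement)]
            out.append(summarize_endpoint(vals, ep, record.line_id))

    return out
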