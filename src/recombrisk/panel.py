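"""Domain types and tabular I/O for fibroblast syndrome panels.

A *panel* is a collection of skin-fibroblast cell lines, each derived from a
patient with one of the eight major hereditary cancer syndromes (or from an
apparently healthy control donor), together with the raw measurements of the
assays run on each line: the pTPSN recombination plasmid assay (hyg+/neo+
colony counts), the HPRT 6-thioguanine mutation assay, flow-cytometry cell
cycle phase fractions with and without a 2 Gy X-ray challenge, and three
scalar endpoints measured externally (fraction of DNA released, maximal
MRE11 focus count, surviving fraction at 2 Gy).

Each syndrome carries a literature excess relative cancer risk (ERR); the
reference table of this module is the panel-wide ERR axis every downstream
fit uses.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Union

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Syndrome",
    "AssayKind",
    "Endpoint",
    "PlasmidCounts",
    "HprtCounts",
    "CytometryCounts",
    "ScalarMeasurement",
    "RawAssay",
    "CellLineRecord",
    "SyndromeERR",
    "EndpointSet",
    "PanelFormatError",
    "PanelValidationError",
    "read_panel",
    "write_panel",
    "reference_err_table",
    "read_err_table",
    "write_err_table",
    "REPRESENTATIVE_LINES",
]


class PanelFormatError(ValueError):
    """The input table does not conform to the assay_csv dialect."""


class PanelValidationError(ValueError):
    """A row violates a domain invariant (e.g. negative colony count)."""


class Syndrome(str, Enum):
    """Cancer-proneness syndromes represented in the panel.

    CONTROL denotes apparently healthy donors (1BR3, MRC5), used as the
    zero-excess-risk reference.
    """

    CONTROL = "CONTROL"
    AT = "AT"
    NBS = "NBS"
    NF1 = "NF1"
    FANC = "FANC"
    BLM = "BLM"
    RB = "RB"
    BRCA1 = "BRCA1"
    BRCA2 = "BRCA2"


class AssayKind(str, Enum):
    PLASMID = "PLASMID"
    HPRT = "HPRT"
    CYTOMETRY = "CYTOMETRY"
    FDR = "FDR"
    MRE11MAX = "MRE11MAX"
    SF2 = "SF2"


class Endpoint(str, Enum):
    """Computed per-line endpoints.

    H  -- hyper-recombination rate (% hyg+/neo+ colonies)
    F  -- HPRT mutation frequency (% 6TG-resistant/seeded)
    E  -- cellular evasion (Δ%G2/M + Δ%S after 2 Gy; may be negative)
    G  -- G2/M escape (Δ%G2/M after 2 Gy)
    G1 -- G1 escape (Δ%G1 after 2 Gy; may be negative)
    FDR, MRE11MAX, SF2 -- externally measured scalars
    """

    H = "H"
    F = "F"
    E = "E"
    G = "G"
    G1 = "G1"
    FDR = "FDR"
    MRE11MAX = "MRE11MAX"
    SF2 = "SF2"


def _check_count(name: str, value: int) -> int:
    if not isinstance(value, (int,)) or isinstance(value, bool):
        if isinstance(value, float) and value.is_integer():
            value = int(value)
        else:
            raise PanelValidationError(f"{name} must be an integer, got {value!r}")
    if value < 0:
        raise PanelValidationError(f"{name} must be >= 0, got {value}")
    return int(value)


def _check_pct(name: str, value: float) -> float:
    value = float(value)
    if not 0.0 <= value <= 100.0:
        raise PanelValidationError(f"{name} must lie in [0, 100], got {value}")
    return value


@dataclass(frozen=True)
class PlasmidCounts:
    """Colony counts from the pTPSN recombination plasmid assay."""

    hyg_colonies: int
    neo_colonies: int

    def __post_init__(self):
        object.__setattr__(self, "hyg_colonies", _check_count("hyg_colonies", self.hyg_colonies))
        object.__setattr__(self, "neo_colonies", _check_count("neo_colonies", self.neo_colonies))


@dataclass(frozen=True)
class HprtCounts:
    """Colony counts from the HPRT / 6-thioguanine selection assay."""

    colonies_6tg: int
    colonies_seeded: int

    def __post_init__(self):
        object.__setattr__(self, "colonies_6tg", _check_count("colonies_6tg", self.colonies_6tg))
        object.__setattr__(self, "colonies_seeded", _check_count("colonies_seeded", self.colonies_seeded))


@dataclass(frozen=True)
class CytometryCounts:
    """Cell-cycle phase percentages for one replicate, both conditions.

    Percentages within each condition may sum to < 100; the remainder is
    sub-G1 debris. Flat layout mirrors the assay_csv key names
    (g1_irr, s_irr, g2m_irr, g1_ctrl, s_ctrl, g2m_ctrl).
    """

    g1_irr: float
    s_irr: float
    g2m_irr: float
    g1_ctrl: float
    s_ctrl: float
    g2m_ctrl: float

    def __post_init__(self):
        for name in ("g1_irr", "s_irr", "g2m_irr", "g1_ctrl", "s_ctrl", "g2m_ctrl"):
            object.__setattr__(self, name, _check_pct(name, getattr(self, name)))
        for cond, (a, b, c) in {
            "irradiated": (self.g1_irr, self.s_irr, self.g2m_irr),
            "unirradiated": (self.g1_ctrl, self.s_ctrl, self.g2m_ctrl),
        }.items():
            if a + b + c > 100.0 + 1e-9:
                raise PanelValidationError(
                    f"{cond} phase percentages sum to {a + b + c:.3f} > 100"
                )


@dataclass(frozen=True)
class ScalarMeasurement:
    """A single externally measured non-negative value (FDR, MRE11max, SF2)."""

    value: float

    def __post_init__(self):
        if not math.isfinite(self.value) or self.value < 0:
            raise PanelValidationError(f"scalar measurement must be finite and >= 0, got {self.value}")


Payload = Union[PlasmidCounts, HprtCounts, CytometryCounts, ScalarMeasurement]

_PAYLOAD_TYPES = {
    AssayKind.PLASMID: PlasmidCounts,
    AssayKind.HPRT: HprtCounts,
    AssayKind.CYTOMETRY: CytometryCounts,
    AssayKind.FDR: ScalarMeasurement,
    AssayKind.MRE11MAX: ScalarMeasurement,
    AssayKind.SF2: ScalarMeasurement,
}


@dataclass(frozen=True)
class RawAssay:
    kind: AssayKind
    replicate_index: int
    payload: Payload

    def __post_init__(self):
        if self.replicate_index < 1:
            raise PanelValidationError(f"replicate_index must be >= 1, got {self.replicate_index}")
        expected = _PAYLOAD_TYPES[AssayKind(self.kind)]
        if not isinstance(self.payload, expected):
            raise PanelValidationError(
                f"payload for {self.kind} must be {expected.__name__}, got {type(self.payload).__name__}"
            )


@dataclass
class CellLineRecord:
    """One fibroblast cell line with its raw assay replicates."""

    line_id: str
    syndrome: Syndrome
    genotype: str = ""
    source: str = ""
    raw_assays: list[RawAssay] = field(default_factory=list)

    def __post_init__(self):
        if not self.line_id:
            raise PanelValidationError("line_id must be non-empty")
        self.syndrome = Syndrome(self.syndrome)

    def assays(self, kind: AssayKind) -> list[RawAssay]:
        return [a for a in self.raw_assays if a.kind is AssayKind(kind)]


@dataclass(frozen=True)
class SyndromeERR:
    """Literature excess relative cancer risk for one syndrome.

    ERR is dimensionless; ``rel_error`` is the systematic relative error
    band of the literature value (default 15%).
    """

    syndrome: Syndrome
    err: float
    rel_error: float = 0.15

    def __post_init__(self):
        object.__setattr__(self, "syndrome", Syndrome(self.syndrome))
        if self.err < 0:
            raise PanelValidationError(f"err must be >= 0, got {self.err}")
        if not 0.0 <= self.rel_error < 1.0:
            raise PanelValidationError(f"rel_error must lie in [0, 1), got {self.rel_error}")


@dataclass(frozen=True)
class EndpointSet:
    """Replicate summary (mean ± SEM, n) for one endpoint of one line."""

    line_id: str
    endpoint: Endpoint
    mean: float
    sem: float
    n: int

    def __post_init__(self):
        object.__setattr__(self, "endpoint", Endpoint(self.endpoint))
        if self.sem < 0:
            raise PanelValidationError(f"sem must be >= 0, got {self.sem}")
        if self.n < 1:
            raise PanelValidationError(f"n must be >= 1, got {self.n}")
        ep = self.endpoint
        if ep in (Endpoint.H, Endpoint.F, Endpoint.G) and not -1e-9 <= self.mean <= 100 + 1e-9:
            raise PanelValidationError(f"{ep.value} mean must lie in [0, 100], got {self.mean}")


# Representative line per syndrome (one line per syndrome in the reference
# panel; additional lines per syndrome exist but are averaged only on request).
REPRESENTATIVE_LINES: dict[Syndrome, tuple[str, str, str]] = {
    Syndrome.CONTROL: ("1BR3", "wild-type", "ECACC"),
    Syndrome.AT: ("AT4BI", "ATM-/-", "COPERNIC"),
    Syndrome.NBS: ("GM07166", "NBS1-/-", "CORIELL"),
    Syndrome.NF1: ("Rackham 37", "NF1+/-", "COPERNIC"),
    Syndrome.FANC: ("GM00369", "FANCA+/-", "CORIELL"),
    Syndrome.BLM: ("GM02520", "BLM-/-", "CORIELL"),
    Syndrome.RB: ("GM02718", "Rb-/-", "CORIELL"),
    Syndrome.BRCA1: ("202CLB", "BRCA1+/-", "COPERNIC"),
    Syndrome.BRCA2: ("201CLB", "BRCA2+/-", "COPERNIC"),
}

_REFERENCE_ERR: dict[Syndrome, float] = {
    Syndrome.CONTROL: 0.0,
    Syndrome.BRCA1: 0.4,
    Syndrome.BRCA2: 1.0,
    Syndrome.FANC: 1.4,
    Syndrome.BLM: 2.4,
    Syndrome.RB: 3.2,
    Syndrome.NF1: 3.6,
    Syndrome.NBS: 7.0,
    Syndrome.AT: 9.0,
}


def reference_err_table(rel_error: float = 0.15) -> list[SyndromeERR]:
    """Literature ERR values for the nine panel syndromes.

    Controls are assigned ERR = 0 by convention (zero *excess* risk for
    apparently healthy donors). Every entry carries the systematic 15%
    relative error band of the literature risk estimates.
    """
    return [SyndromeERR(s, e, rel_error) for s, e in _REFERENCE_ERR.items()]


# ---------------------------------------------------------------------------
# assay_csv dialect
#
# Long format, one row per (replicate, key): columns
#   line_id, syndrome, genotype, source, assay_kind, replicate, key, value
# Keys per assay kind:
#   PLASMID   : hyg_colonies, neo_colonies
#   HPRT      : colonies_6tg, colonies_seeded
#   CYTOMETRY : g1_irr, s_irr, g2m_irr, g1_ctrl, s_ctrl, g2m_ctrl
#   FDR/MRE11MAX/SF2 : value
# ---------------------------------------------------------------------------

_COLUMNS = ["line_id", "syndrome", "genotype", "source", "assay_kind", "replicate", "key", "value"]

_KEYS: dict[AssayKind, list[str]] = {
    AssayKind.PLASMID: ["hyg_colonies", "neo_colonies"],
    AssayKind.HPRT: ["colonies_6tg", "colonies_seeded"],
    AssayKind.CYTOMETRY: ["g1_irr", "s_irr", "g2m_irr", "g1_ctrl", "s_ctrl", "g2m_ctrl"],
    AssayKind.FDR: ["value"],
    AssayKind.MRE11MAX: ["value"],
    AssayKind.SF2: ["value"],
}


def read_panel(path: str | Path, format: str = "assay_csv") -> list[CellLineRecord]:
    """Read a long-format assay CSV into one record per cell line.

    Raises :class:`PanelFormatError` for missing columns or unknown
    keys/kinds, and :class:`PanelValidationError` (citing the 1-based data
    row) for invariant violations such as negative colony counts.
    """
    if format != "assay_csv":
        raise PanelFormatError(f"unknown panel format {format!r}")
    path = Path(path)
    df = pd.read_csv(path, dtype={"line_id": str, "key": str}, float_precision="round_trip")
    missing = [c for c in _COLUMNS if c not in df.columns and c != "source"]
    if missing:
        raise PanelFormatError(f"{path}: missing mandatory column(s) {missing}")
    if "source" not in df.columns:
        df["source"] = ""
    if df.empty:
        logger.warning("%s: empty panel (header only)", path)
        return []

    records: list[CellLineRecord] = []
    for line_id, grp in df.groupby("line_id", sort=False):
        syndromes = grp["syndrome"].unique()
        if len(syndromes) > 1:
            raise PanelValidationError(f"line {line_id!r} maps to multiple syndromes: {list(syndromes)}")
        try:
            syndrome = Syndrome(str(syndromes[0]))
        except ValueError as exc:
            raise PanelValidationError(f"line {line_id!r}: unknown syndrome {syndromes[0]!r}") from exc
        genotype = str(grp["genotype"].iloc[0]) if pd.notna(grp["genotype"].iloc[0]) else ""
        source = str(grp["source"].iloc[0]) if pd.notna(grp["source"].iloc[0]) else ""
        assays: list[RawAssay] = []
        for (kind_str, rep), sub in grp.groupby(["assay_kind", "replicate"], sort=False):
            try:
                kind = AssayKind(str(kind_str))
            except ValueError as exc:
                raise PanelFormatError(
                    f"row {int(sub.index[0]) + 2}: unknown assay_kind {kind_str!r}"
                ) from exc
            kv: dict[str, float] = {}
            for idx, row in sub.iterrows():
                key = row["key"]
                if key not in _KEYS[kind]:
                    raise PanelFormatError(f"row {int(idx) + 2}: key {key!r} invalid for {kind.value}")
                kv[key] = float(row["value"])
            missing_keys = [k for k in _KEYS[kind] if k not in kv]
            if missing_keys:
                raise PanelFormatError(
                    f"line {line_id!r} {kind.value} replicate {rep}: missing key(s) {missing_keys}"
                )
            try:
                payload = _payload_from_kv(kind, kv)
            except PanelValidationError as exc:
                rows = ", ".join(str(int(i) + 2) for i in sub.index)
                raise PanelValidationError(f"line {line_id!r}, CSV row(s) {rows}: {exc}") from exc
            assays.append(RawAssay(kind, int(rep), payload))
        records.append(CellLineRecord(str(line_id), syndrome, genotype, source, assays))
    return records


def _payload_from_kv(kind: AssayKind, kv: dict[str, float]) -> Payload:
    if kind is AssayKind.PLASMID:
        return PlasmidCounts(kv["hyg_colonies"], kv["neo_colonies"])
    if kind is AssayKind.HPRT:
        return HprtCounts(kv["colonies_6tg"], kv["colonies_seeded"])
    if kind is AssayKind.CYTOMETRY:
        return CytometryCounts(**kv)
    return ScalarMeasurement(kv["value"])


def _payload_to_kv(assay: RawAssay) -> dict[str, float]:
    p = assay.payload
    if isinstance(p, PlasmidCounts):
        return {"hyg_colonies": p.hyg_colonies, "neo_colonies": p.neo_colonies}
    if isinstance(p, HprtCounts):
        return {"colonies_6tg": p.colonies_6tg, "colonies_seeded": p.colonies_seeded}
    if isinstance(p, CytometryCounts):
        return {k: getattr(p, k) for k in _KEYS[AssayKind.CYTOMETRY]}
    return {"value": p.value}


def write_panel(records: Iterable[CellLineRecord], path: str | Path) -> None:
    """Write records back to the assay_csv dialect (inverse of read_panel)."""
    rows = []
    for rec in records:
        for assay in rec.raw_assays:
            for key, value in _payload_to_kv(assay).items():
                rows.append(
                    {
                        "line_id": rec.line_id,
                        "syndrome": rec.syndrome.value,
                        "genotype": rec.genotype,
                        "source": rec.source,
                        "assay_kind": assay.kind.value,
                        "replicate": assay.replicate_index,
                        "key": key,
                        "value": value,
                    }
                )
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)


def read_err_table(path: str | Path) -> list[SyndromeERR]:
    """Read a syndrome→ERR reference CSV (columns syndrome, err, rel_error)."""
    df = pd.read_csv(path)
    for col in ("syndrome", "err"):
        if col not in df.columns:
            raise PanelFormatError(f"{path}: missing mandatory column {col!r}")
    if "rel_error" not in df.columns:
        df["rel_error"] = 0.15
    return [
        SyndromeERR(Syndrome(str(r.syndrome)), float(r.err), float(r.rel_error))
        for r in df.itertuples()
    ]


def write_err_table(table: Iterable[SyndromeERR], path: str | Path) -> None:
    pd.DataFrame(
        [{"syndrome": t.syndrome.value, "err": t.err, "rel_error": t.rel_error} for t in table]
    ).to_csv(path, index=False)
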