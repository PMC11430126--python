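"""Synthetic syndrome-panel generator.

Produces raw assay tables with the statistical structure the analysis
assumes: nine cell lines (eight cancer syndromes plus a healthy control),
each with replicated plasmid, HPRT, cytometry and scalar assays whose
expected endpoints follow the panel-calibrated models at the syndrome's
true ERR:

* H follows the constrained mechanistic cubic;
* G follows the logistic escape model;
* F follows the panel's empirical quadratic, E its empirical cubic;
* G1 escape is targeted as pure noise around 0;
* FDR follows a weak linear trend dominated by line-to-line scatter (so
  a correlation screen at n = 9 is typically not significant);
* MRE11max decreases linearly with ERR; SF2 decays exponentially.

Two noise models: ``gaussian_sem`` perturbs replicate endpoint values with
Gaussian noise whose scale is anchored to the published SEM magnitudes;
``count_level`` draws physically grounded binomial/multinomial counts.
Panels are byte-identical for a fixed config and seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .endpoints import Condition, CytometrySnapshot
from .models import (
    DEFAULT_G_PARAMS,
    DEFAULT_H_PARAMS,
    GModelParams,
    HModelParams,
    g_of_err,
    h_of_err,
)
from .panel import (
    AssayKind,
    CellLineRecord,
    CytometryCounts,
    Endpoint,
    HprtCounts,
    PlasmidCounts,
    RawAssay,
    REPRESENTATIVE_LINES,
    ScalarMeasurement,
    SyndromeERR,
    reference_err_table,
)

__all__ = [
    "GeneratorConfig",
    "make_panel",
    "true_endpoint_means",
    "simulate_plasmid_counts",
    "simulate_hprt_counts",
    "simulate_cytometry",
    "perturb_err",
    "observed_err_table",
    "write_ground_truth",
]

#: Denominator used to encode real-valued rates as integer colony counts
#: under the gaussian_sem noise model (preserves the draw to 1e-4 %).
_ENCODING_DENOMINATOR = 1_000_000

#: Per-replicate Gaussian sd = floor + rel·|mean|, anchored so the sd at the
#: anchor endpoints equals the published SEM magnitudes: H 3.5±2 (control)
#: vs 56±8 (highest-risk line); F 10±3 vs 82±10; FDR 21±3 vs 61±10.
#: Endpoints with no published SEM use ~8-10% relative scales with small
#: floors (cytometry phase fractions replicate tightly).
DEFAULT_SEM_TABLE: dict[Endpoint, tuple[float, float]] = {
    Endpoint.H: (1.6, 0.11),
    Endpoint.F: (2.0, 0.10),
    Endpoint.E: (1.2, 0.10),
    Endpoint.G: (0.10, 0.10),
    Endpoint.G1: (1.2, 0.0),
    Endpoint.FDR: (0.5, 0.17),
    Endpoint.MRE11MAX: (1.2, 0.10),
    Endpoint.SF2: (0.015, 0.08),
}

#: Empirical mean curves for endpoints outside the mechanistic pair.
_F_QUAD = (13.8, 15.95, -1.1)           # F(ERR), percent
_E_CUBIC = (-4.2, 19.88, -5.38, 0.43)   # E(ERR), percent-difference
_FDR_LINE = (21.0, 40.0 / 9.0)          # arbitrary units, 21 -> 61 over ERR 0..9
_FDR_LINE_SCATTER_SD = 18.0             # line-to-line biological scatter, a.u.
_MRE11_LINE = (40.0, -30.0 / 9.0)       # foci, 40 -> 10 over ERR 0..9
_SF2_DECAY = (0.6, 0.25)                # SF2 = 0.6·exp(-0.25·ERR)

#: Unirradiated plateau-phase baseline (G0/G1 within the 95-99% band).
_CTRL_PHASES = (95.0, 3.2, 1.5)  # g1, s, g2m; remainder is sub-G1 debris


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic panel.

    ``noise_scale`` is a global multiplier on every Gaussian scale
    (0 gives a noiseless panel); it does not alter count-level sampling.
    ``baseline_h`` adds a constant to the H mean curve, emulating the
    measured nonzero control hyper-recombination (default off: the
    mechanistic model has H(0) = 0).
    """

    seed: int = 0
    n_replicates: int = 3
    err_noise: float = 0.15
    endpoint_noise_model: str = "gaussian_sem"  # or "count_level"
    noise_scale: float = 1.0
    sem_table: dict = field(default_factory=lambda: dict(DEFAULT_SEM_TABLE))
    n_neo_target: int = 20
    n_seeded: int = 500
    n_cells_cytometry: int = 10_000
    baseline_h: float = 0.0
    h_params: HModelParams = DEFAULT_H_PARAMS
    g_params: GModelParams = DEFAULT_G_PARAMS

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.endpoint_noise_model not in ("gaussian_sem", "count_level"):
            raise ValueError(f"unknown noise model {self.endpoint_noise_model!r}")
        if self.err_noise < 0 or self.noise_scale < 0:
            raise ValueError("noise scales must be >= 0")


def true_endpoint_means(
    err: float,
    cfg: GeneratorConfig | None = None,
) -> dict[Endpoint, float]:
    """Expected endpoint values at a given true ERR (no noise, no scatter)."""
    cfg = cfg or GeneratorConfig()
    h = float(np.clip(h_of_err(err, cfg.h_params) + cfg.baseline_h, 0.0, 100.0))
    g = float(np.clip(g_of_err(err, cfg.g_params), 0.0, 100.0))
    a0, a1, a2 = _F_QUAD
    f = float(np.clip(a0 + a1 * err + a2 * err**2, 0.0, 100.0))
    b0, b1, b2, b3 = _E_CUBIC
    e = b0 + b1 * err + b2 * err**2 + b3 * err**3
    return {
        Endpoint.H: h,
        Endpoint.F: f,
        Endpoint.E: e,
        Endpoint.G: g,
        Endpoint.G1: 0.0,
        Endpoint.FDR: max(_FDR_LINE[0] + _FDR_LINE[1] * err, 0.0),
        Endpoint.MRE11MAX: max(_MRE11_LINE[0] + _MRE11_LINE[1] * err, 0.0),
        Endpoint.SF2: _SF2_DECAY[0] * float(np.exp(-_SF2_DECAY[1] * err)),
    }


def simulate_plasmid_counts(
    h_true: float, n_neo: int, rng: np.random.Generator
) -> tuple[int, int]:
    """Binomial colony counts for a true hyper-recombination rate (percent)."""
    if not 0.0 <= h_true <= 100.0:
        raise ValueError(f"h_true must lie in [0, 100], got {h_true}")
    hyg = int(rng.binomial(n_neo, h_true / 100.0))
    return hyg, int(n_neo)


def simulate_hprt_counts(
    f_true: float, n_seeded: int, rng: np.random.Generator
) -> tuple[int, int]:
    """Binomial colony counts for a true HPRT mutation frequency (percent)."""
    if not 0.0 <= f_true <= 100.0:
        raise ValueError(f"f_true must lie in [0, 100], got {f_true}")
    return int(rng.binomial(n_seeded, f_true / 100.0)), int(n_seeded)


def simulate_cytometry(
    g1: float,
    s: float,
    g2m: float,
    n_cells: int,
    rng: np.random.Generator,
    condition: Condition = Condition.UNIRRADIATED,
) -> CytometrySnapshot:
    """Multinomial phase percentages over {G1, S, G2/M, other} for n_cells."""
    for name, v in (("g1", g1), ("s", s), ("g2m", g2m)):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"{name} must lie in [0, 100], got {v}")
    other = 100.0 - g1 - s - g2m
    if other < -1e-9:
        raise ValueError("phase percentages sum to more than 100")
    p = np.array([g1, s, g2m, max(other, 0.0)]) / 100.0
    p = p / p.sum()
    counts = rng.multinomial(n_cells, p)
    pct = counts / n_cells * 100.0
    return CytometrySnapshot(g1=pct[0], s=pct[1], g2m=pct[2], condition=condition)


def perturb_err(err_true: float, rel_sd: float, rng: np.random.Generator) -> float:
    """Multiplicative Gaussian perturbation of a true ERR, truncated at 0."""
    if err_true < 0 or rel_sd < 0:
        raise ValueError("err_true and rel_sd must be >= 0")
    if rel_sd == 0 or err_true == 0:
        return float(err_true)
    return float(max(err_true * (1.0 + rel_sd * rng.standard_normal()), 0.0))


def observed_err_table(
    truth: list[SyndromeERR],
    rel_sd: float,
    rng: np.random.Generator | int,
) -> list[SyndromeERR]:
    """Literature-style noisy ERR table: each true value perturbed by rel_sd."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return [SyndromeERR(t.syndrome, perturb_err(t.err, rel_sd, rng), t.rel_error) for t in truth]


def _gauss(rng: np.random.Generator, mean: float, sd: float) -> float:
    return float(mean + sd * rng.standard_normal())


def _sd(cfg: GeneratorConfig, ep: Endpoint, mean: float) -> float:
    floor, rel = cfg.sem_table[ep]
    return cfg.noise_scale * (floor + rel * abs(mean))


def _irradiated_phases(
    e_target: float, g_target: float, g1_target: float
) -> tuple[float, float, float]:
    """Build irradiated phase percentages realizing the endpoint targets.

    Compositional closure caps the result: the S fraction cannot drop below
    zero (truncating very negative evasion near ERR 0) and G1 + S + G2/M
    cannot exceed 100 (capping G1 for high-evasion lines).
    """
    g1c, sc, g2mc = _CTRL_PHASES
    g2m_irr = float(np.clip(g2mc + g_target, 0.0, 100.0))
    s_irr = float(np.clip(sc + (e_target - g_target), 0.0, 100.0 - g2m_irr))
    g1_irr = float(np.clip(g1c + g1_target, 0.0, 100.0 - g2m_irr - s_irr))
    return g1_irr, s_irr, g2m_irr


def make_panel(cfg: GeneratorConfig) -> tuple[list[CellLineRecord], list[SyndromeERR]]:
    """Generate one synthetic panel plus its ground-truth ERR table.

    One representative cell line per syndrome; per-replicate raw assays
    whose expected endpoints follow the model mean curves at the
    syndrome's true ERR. The returned ground truth carries the *true*
    ERRs; a literature-style noisy axis is obtained separately with
    :func:`observed_err_table`.
    """
    rng = np.random.default_rng(cfg.seed)
    truth = reference_err_table()
    records: list[CellLineRecord] = []
    gaussian = cfg.endpoint_noise_model == "gaussian_sem"

    for entry in truth:
        line_id, genotype, source = REPRESENTATIVE_LINES[entry.syndrome]
        means = true_endpoint_means(entry.err, cfg)
        # line-level biological scatter for FDR (dominates its weak trend)
        fdr_line_mean = max(
            means[Endpoint.FDR]
            + cfg.noise_scale * _FDR_LINE_SCATTER_SD * rng.standard_normal(),
            0.0,
        )
        assays: list[RawAssay] = []
        for rep in range(1, cfg.n_replicates + 1):
            # --- plasmid (H) ---
            if gaussian:
                h_rep = float(np.clip(_gauss(rng, means[Endpoint.H], _sd(cfg, Endpoint.H, means[Endpoint.H])), 0, 100))
                hyg = round(h_rep / 100.0 * _ENCODING_DENOMINATOR)
                payload = PlasmidCounts(hyg, _ENCODING_DENOMINATOR)
            else:
                hyg, neo = simulate_plasmid_counts(means[Endpoint.H], cfg.n_neo_target, rng)
                payload = PlasmidCounts(hyg, neo)
            assays.append(RawAssay(AssayKind.PLASMID, rep, payload))
            # --- HPRT (F) ---
            if gaussian:
                f_rep = float(np.clip(_gauss(rng, means[Endpoint.F], _sd(cfg, Endpoint.F, means[Endpoint.F])), 0, 100))
                n6 = round(f_rep / 100.0 * _ENCODING_DENOMINATOR)
                payload = HprtCounts(n6, _ENCODING_DENOMINATOR)
            else:
                n6, nseed = simulate_hprt_counts(means[Endpoint.F], cfg.n_seeded, rng)
                payload = HprtCounts(n6, nseed)
            assays.append(RawAssay(AssayKind.HPRT, rep, payload))
            # --- cytometry (E, G, G1) ---
            g_rep = max(_gauss(rng, means[Endpoint.G], _sd(cfg, Endpoint.G, means[Endpoint.G])), 0.0)
            e_rep = _gauss(rng, means[Endpoint.E], _sd(cfg, Endpoint.E, means[Endpoint.E]))
            g1_rep = _gauss(rng, 0.0, _sd(cfg, Endpoint.G1, 0.0))
            g1_irr, s_irr, g2m_irr = _irradiated_phases(e_rep, g_rep, g1_rep)
            g1c, sc, g2mc = _CTRL_PHASES
            if not gaussian:
                irr = simulate_cytometry(g1_irr, s_irr, g2m_irr, cfg.n_cells_cytometry, rng, Condition.IRRADIATED_2GY)
                ctrl = simulate_cytometry(g1c, sc, g2mc, cfg.n_cells_cytometry, rng, Condition.UNIRRADIATED)
                payload = CytometryCounts(irr.g1, irr.s, irr.g2m, ctrl.g1, ctrl.s, ctrl.g2m)
            else:
                payload = CytometryCounts(g1_irr, s_irr, g2m_irr, g1c, sc, g2mc)
            assays.append(RawAssay(AssayKind.CYTOMETRY, rep, payload))
            # --- scalar endpoints ---
            for kind, ep, mean in (
                (AssayKind.FDR, Endpoint.FDR, fdr_line_mean),
                (AssayKind.MRE11MAX, Endpoint.MRE11MAX, means[Endpoint.MRE11MAX]),
                (AssayKind.SF2, Endpoint.SF2, means[Endpoint.SF2]),
            ):
                v = max(_gauss(rng, mean, _sd(cfg, ep, mean)), 0.0)
                assays.append(RawAssay(kind, rep, ScalarMeasurement(v)))
        records.append(CellLineRecord(line_id, entry.syndrome, genotype, source, assays))
    return records, truth


def write_ground_truth(
    cfg: GeneratorConfig, truth: list[SyndromeERR], path: str | Path
) -> None:
    """Write per-syndrome true ERRs and endpoint means plus a config echo."""
    doc = {
        "config": {
            **{k: v for k, v in asdict(cfg).items() if k not in ("sem_table", "h_params", "g_params")},
            "sem_table": {ep.value: list(v) for ep, v in cfg.sem_table.items()},
            "h_params": {"k1": cfg.h_params.k1, "err_max": cfg.h_params.err_max},
            "g_params": {
                "c0": cfg.g_params.c0,
                "g_max": cfg.g_params.g_max,
                "g_min": cfg.g_params.g_min,
            },
        },
        "syndromes": {
            t.syndrome.value: {
                "err_true": t.err,
                "rel_error": t.rel_error,
                "endpoint_means": {
                    ep.value: m for ep, m in true_endpoint_means(t.err, cfg).items()
                },
            }
            for t in truth
        },
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")
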