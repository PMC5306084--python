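"""Seeded generators with planted truth for every pipeline stage.

The expression generator emulates an HG-U133-Plus-2.0-like study: log2
baseline intensities ~ Normal(7, 2^2) over (by default) 20,000 probe sets,
a planted developmental programme (D-genes shifting between day 0 and the
end-stage control), per-compound toxicant responses (T-genes shifting
treated samples against the end-stage control) with a configurable overlap
and antagonism structure, additive + multiplicative batch effects, and
replicate noise.  Planted |log2FC| spans the gate-relevant range (1.5- to
10-fold) so both significant and sub-threshold probes exist.

Each generator returns the exact planted truth alongside the data, so the
expected value of every downstream statistic is known without re-running
the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_model import (
    ExpressionMatrix,
    ProbeAnnotation,
    SampleDesign,
    ValidationError,
)


@dataclass
class PlantedCompound:
    """Planted toxicant response for one compound at one concentration."""

    name: str = "toxA"
    compound_class: str = "HDACi"
    concentration: float = 1.0
    conc_unit: str = "uM"
    t_up: int = 50
    t_down: int = 50
    overlap: int = 50  # T probes drawn from the D set
    antagonism_fraction: float = 0.8  # of overlap probes opposing development

    @property
    def t_total(self) -> int:
        return self.t_up + self.t_down


@dataclass
class SynthConfig:
    """Study conditions for the expression generator."""

    n_probes: int = 20_000
    n_replicates: int = 4
    d_up: int = 500
    d_down: int = 500
    compounds: list[PlantedCompound] = field(
        default_factory=lambda: [PlantedCompound()]
    )
    log2fc_range: tuple[float, float] = (0.8, 3.3)  # up to ~tenfold
    noise_sd: float = 0.25  # replicate noise, log2 units
    baseline_mean: float = 7.0
    baseline_sd: float = 2.0
    batch_effects: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"B1": (0.0, 1.0)}
    )  # batch -> (additive log2 shift, multiplicative noise scale)
    probes_per_gene: int = 2
    multi_map_rate: float = 0.05
    system: str = "UKN1"
    seed: int = 0

    @property
    def d_total(self) -> int:
        return self.d_up + self.d_down

    def validate(self) -> None:
        if self.d_total > self.n_probes:
            raise ValidationError("planted D exceeds n_probes")
        for comp in self.compounds:
            if comp.overlap > min(self.d_total, comp.t_total):
                raise ValidationError(
                    f"{comp.name}: planted overlap exceeds min(D, T)"
                )
            if comp.t_total - comp.overlap > self.n_probes - self.d_total:
                raise ValidationError(
                    f"{comp.name}: not enough non-developmental probes for T"
                )
            if not 0.0 <= comp.antagonism_fraction <= 1.0:
                raise ValidationError("antagonism fraction must be in [0, 1]")
        for batch, (_, mult) in self.batch_effects.items():
            if mult <= 0:
                raise ValidationError(f"batch {batch}: multiplicative effect <= 0")


@dataclass
class SyntheticTruth:
    """Exact planted membership and effects implied by one generated dataset."""

    d_up: frozenset[str]
    d_down: frozenset[str]
    t_up: dict[str, frozenset[str]]
    t_down: dict[str, frozenset[str]]
    overlap: dict[str, frozenset[str]]
    d_effects: np.ndarray  # per-probe developmental log2 shift
    t_effects: dict[str, np.ndarray]
    batch_effects: dict[str, tuple[float, float]]
    n_probes: int

    def true_dp(self, compound: str) -> float:
        return len(self.overlap[compound]) / (len(self.d_up) + len(self.d_down))

    def true_di(self, compound: str) -> float:
        T = len(self.t_up[compound]) + len(self.t_down[compound])
        D = len(self.d_up) + len(self.d_down)
        return (len(self.overlap[compound]) / T) / (D / self.n_probes)


def _probe_id(i: int) -> str:
    return f"PS{i:06d}_at"


def generate_dataset(
    config: SynthConfig,
) -> tuple[ExpressionMatrix, SampleDesign, ProbeAnnotation, SyntheticTruth]:
    """Generate a complete study: matrix, design, annotation, planted truth.

    Sample layout: n_replicates day-0 controls, n_replicates end-stage
    differentiation controls, and n_replicates treated samples per planted
    compound.  Replicates are spread round-robin over the configured
    batches so batch is never confounded with a biological group.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    P = config.n_probes
    probe_ids = [_probe_id(i) for i in range(P)]

    lo, hi = config.log2fc_range
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=P)

    # developmental programme
    d_idx = rng.choice(P, size=config.d_total, replace=False)
    d_up_idx = d_idx[: config.d_up]
    d_down_idx = d_idx[config.d_up:]
    d_effects = np.zeros(P)
    d_effects[d_up_idx] = rng.uniform(lo, hi, size=config.d_up)
    d_effects[d_down_idx] = -rng.uniform(lo, hi, size=config.d_down)

    # toxicant responses
    non_d = np.setdiff1d(np.arange(P), d_idx)
    t_effects: dict[str, np.ndarray] = {}
    truth_tu: dict[str, frozenset[str]] = {}
    truth_td: dict[str, frozenset[str]] = {}
    truth_ov: dict[str, frozenset[str]] = {}
    for comp in config.compounds:
        eff = np.zeros(P)
        ov_idx = rng.choice(d_idx, size=comp.overlap, replace=False)
        n_ant = int(round(comp.antagonism_fraction * comp.overlap))
        ant = ov_idx[:n_ant]
        co = ov_idx[n_ant:]
        # antagonists oppose the developmental direction, the rest reinforce it
        eff[ant] = -np.sign(d_effects[ant]) * rng.uniform(lo, hi, size=ant.size)
        eff[co] = np.sign(d_effects[co]) * rng.uniform(lo, hi, size=co.size)
        n_extra = comp.t_total - comp.overlap
        extra = rng.choice(non_d, size=n_extra, replace=False)
        up_have = int((eff[ov_idx] > 0).sum())
        n_extra_up = min(max(comp.t_up - up_have, 0), n_extra)
        eff[extra[:n_extra_up]] = rng.uniform(lo, hi, size=n_extra_up)
        eff[extra[n_extra_up:]] = -rng.uniform(lo, hi, size=n_extra - n_extra_up)
        t_effects[comp.name] = eff
        t_idx = np.concatenate([ov_idx, extra])
        truth_tu[comp.name] = frozenset(probe_ids[i] for i in t_idx if eff[i] > 0)
        truth_td[comp.name] = frozenset(probe_ids[i] for i in t_idx if eff[i] < 0)
        truth_ov[comp.name] = frozenset(probe_ids[i] for i in ov_idx)

    # sample table
    batches = list(config.batch_effects)
    rows = []
    sample_defs: list[tuple[str, str, str | None]] = []  # (sample_id, role, compound)
    for r in range(config.n_replicates):
        sample_defs.append((f"day0_r{r + 1}", "day0_control", None))
    for r in range(config.n_replicates):
        sample_defs.append((f"ctrl_r{r + 1}", "diff_control", None))
    for comp in config.compounds:
        for r in range(config.n_replicates):
            sample_defs.append((f"{comp.name}_r{r + 1}", "treated", comp.name))

    comp_by_name = {c.name: c for c in config.compounds}
    values = np.empty((P, len(sample_defs)))
    for j, (sid, role, comp_name) in enumerate(sample_defs):
        rep = int(sid.rsplit("_r", 1)[1])
        batch = batches[(rep - 1) % len(batches)]
        add, mult = config.batch_effects[batch]
        mean = baseline.copy()
        if role != "day0_control":
            mean = mean + d_effects
        if comp_name is not None:
            mean = mean + t_effects[comp_name]
        values[:, j] = mean + add + mult * rng.normal(0.0, config.noise_sd, size=P)
        comp = comp_by_name.get(comp_name) if comp_name else None
        rows.append(
            {
                "sample_id": sid,
                "role": role,
                "compound": comp.name if comp else None,
                "compound_class": comp.compound_class if comp else None,
                "concentration": comp.concentration if comp else None,
                "conc_unit": comp.conc_unit if comp else None,
                "system": config.system,
                "batch": batch,
                "replicate": rep,
            }
        )

    matrix = ExpressionMatrix(
        probe_ids=probe_ids,
        sample_ids=[sid for sid, _, _ in sample_defs],
        values=values,
    )
    design = SampleDesign(pd.DataFrame(rows))

    # annotation: probes_per_gene consecutive probes share a gene symbol;
    # a configurable fraction of probes additionally map to a second gene
    mapping: dict[str, set[str]] = {}
    n_genes = P // config.probes_per_gene + 1
    for i, probe in enumerate(probe_ids):
        mapping[probe] = {f"G{i // config.probes_per_gene:05d}"}
    n_multi = int(config.multi_map_rate * P)
    if n_multi:
        multi = rng.choice(P, size=n_multi, replace=False)
        for i in multi:
            mapping[probe_ids[i]].add(f"G{int(rng.integers(n_genes)):05d}")
    annotation = ProbeAnnotation({p: frozenset(s) for p, s in mapping.items()})

    truth = SyntheticTruth(
        d_up=frozenset(probe_ids[i] for i in d_up_idx),
        d_down=frozenset(probe_ids[i] for i in d_down_idx),
        t_up=truth_tu,
        t_down=truth_td,
        overlap=truth_ov,
        d_effects=d_effects,
        t_effects=t_effects,
        batch_effects=dict(config.batch_effects),
        n_probes=P,
    )
    return matrix, design, annotation, truth


def generate_batch_effect_matrix(
    n_probes: int,
    per_batch: int,
    additive: float = 2.0,
    scale: float = 2.0,
    noise_sd: float = 0.3,
    group_delta: float = 0.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SampleDesign, np.ndarray]:
    """Two-batch matrix with planted additive/multiplicative batch effects.

    Batch B2 receives an ``additive`` log2 shift and ``scale``-inflated
    replicate noise.  When ``group_delta`` is nonzero, samples alternate
    between day-0 and end-stage control roles within each batch and the
    first half of the probes carry the group difference; otherwise all
    samples share one biological group.  Returns the per-probe planted
    group effect alongside matrix and design.
    """
    rng = np.random.default_rng(seed)
    n = 2 * per_batch
    base = rng.normal(7, 1, size=n_probes)
    batch = ["B1"] * per_batch + ["B2"] * per_batch
    if group_delta:
        roles = [("day0_control" if j % 2 else "diff_control") for j in range(n)]
    else:
        roles = ["diff_control"] * n
    effect = np.zeros(n_probes)
    effect[: n_probes // 2] = group_delta
    values = np.empty((n_probes, n))
    for j in range(n):
        mult = scale if batch[j] == "B2" else 1.0
        add = additive if batch[j] == "B2" else 0.0
        shift = effect if roles[j] == "day0_control" else 0.0
        values[:, j] = base + shift + add + mult * rng.normal(0, noise_sd, n_probes)
    matrix = ExpressionMatrix(
        [f"p{i}" for i in range(n_probes)], [f"s{j}" for j in range(n)], values
    )
    rows = [
        {
            "sample_id": f"s{j}",
            "role": roles[j],
            "compound": None,
            "compound_class": None,
            "concentration": None,
            "conc_unit": None,
            "system": "UKN1",
            "batch": batch[j],
            "replicate": j + 1,
        }
        for j in range(n)
    ]
    return matrix, SampleDesign(pd.DataFrame(rows)), effect


# ---------------------------------------------------------------------------
# Co-expression modules (for the TF network stage)
# ---------------------------------------------------------------------------


@dataclass
class CoexpressionConfig:
    n_modules: int = 3
    module_size: int = 10
    rho: float = 0.8  # within-module correlation; cross-module ~ 0
    n_samples: int = 200
    seed: int = 0


def generate_coexpression(
    config: CoexpressionConfig,
) -> tuple[ExpressionMatrix, dict[str, int]]:
    """Latent-factor co-expression data over synthetic TF symbols.

    Each module shares one latent factor: x = sqrt(rho) * f + sqrt(1-rho) * e,
    giving within-module correlation rho and ~0 across modules.  Returns the
    genes × samples matrix and the gene -> module-id truth map.
    """
    if config.n_modules < 2:
        raise ValidationError("need >= 2 modules")
    if not 0.0 <= config.rho < 1.0:
        raise ValidationError("rho must be in [0, 1)")
    rng = np.random.default_rng(config.seed)
    genes: list[str] = []
    module_of: dict[str, int] = {}
    rows = []
    for m in range(config.n_modules):
        factor = rng.standard_normal(config.n_samples)
        for g in range(config.module_size):
            name = f"TF{m:02d}_{g:02d}"
            genes.append(name)
            module_of[name] = m
            noise = rng.standard_normal(config.n_samples)
            rows.append(np.sqrt(config.rho) * factor + np.sqrt(1 - config.rho) * noise)
    matrix = ExpressionMatrix(
        probe_ids=genes,
        sample_ids=[f"s{j + 1}" for j in range(config.n_samples)],
        values=np.vstack(rows),
    )
    return matrix, module_of


# ---------------------------------------------------------------------------
# Viability plates (for the BMC stage)
# ---------------------------------------------------------------------------


@dataclass
class ViabilityConfig:
    concentrations: tuple[float, ...] = (0.3, 1.0, 3.0, 10.0, 30.0, 100.0)
    conc_unit: str = "uM"
    top: float = 100.0
    bottom: float = 5.0
    log_ec50: float = 1.0  # 10 uM
    hill: float = 1.5
    noise_sd: float = 0.0  # fluorescence noise as a fraction of the span
    n_bio: int = 3
    n_tech: int = 5
    blank: float = 500.0
    span: float = 10_000.0  # vehicle fluorescence minus blank
    seed: int = 0


def generate_viability(
    config: ViabilityConfig,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Simulated resazurin plate readouts from a 4PL ground truth.

    fluorescence = blank + span * 4PL(conc)/100 + Normal noise; vehicle and
    blank wells are included per biological replicate.
    """
    from .bmc import four_pl  # local import to avoid a cycle

    if len(config.concentrations) < 4:
        raise ValidationError("need >= 4 concentrations")
    rng = np.random.default_rng(config.seed)
    rows = []
    well = 0
    for b in range(1, config.n_bio + 1):
        for _ in range(config.n_tech):
            well += 1
            rows.append(
                {
                    "well": f"W{well:03d}",
                    "concentration": np.nan,
                    "conc_unit": config.conc_unit,
                    "role": "blank",
                    "bio_replicate": b,
                    "fluorescence": config.blank
                    + config.noise_sd * config.span * rng.standard_normal() * 0.1,
                }
            )
            well += 1
            rows.append(
                {
                    "well": f"W{well:03d}",
                    "concentration": np.nan,
                    "conc_unit": config.conc_unit,
                    "role": "vehicle_control",
                    "bio_replicate": b,
                    "fluorescence": config.blank
                    + config.span
                    + config.noise_sd * config.span * rng.standard_normal(),
                }
            )
        for conc in config.concentrations:
            true_v = four_pl(
                np.log10(conc),
                config.top,
                config.bottom,
                config.log_ec50,
                config.hill,
            )
            for _ in range(config.n_tech):
                well += 1
                rows.append(
                    {
                        "well": f"W{well:03d}",
                        "concentration": conc,
                        "conc_unit": config.conc_unit,
                        "role": "treated",
                        "bio_replicate": b,
                        "fluorescence": config.blank
                        + config.span * true_v / 100.0
                        + config.noise_sd * config.span * rng.standard_normal(),
                    }
                )
    truth = {
        "top": config.top,
        "bottom": config.bottom,
        "log_ec50": config.log_ec50,
        "hill": config.hill,
    }
    return pd.DataFrame(rows), truth
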