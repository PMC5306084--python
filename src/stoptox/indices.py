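"""Developmental potency and developmental index for disturbed differentiation.

Given the D-genes (probe sets deregulated during unperturbed differentiation)
and a compound's T-genes (probe sets deregulated by the compound versus the
end-stage control) on an array of N probe sets, the overlap O = |D ∩ T|
yields

    D_p = O / D          fraction of the developmental programme hit
    D_i = (O/T) / (D/N)  enrichment of D-genes among T-genes; 1.0 = random

Overlap significance is the one-sided Fisher exact (hypergeometric upper
tail) test.  Directional quadrant counts quantify antagonism: toxicants
typically suppress developmentally up-regulated genes and induce
down-regulated ones.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .dge import DEGTable, RegulonSets, call_regulons
from .io_model import (
    ExpressionMatrix,
    GeneSetCollection,
    SampleDesign,
    ValidationError,
)

log = logging.getLogger(__name__)


@dataclass
class IndexResult:
    """All scores for one compound/concentration against one D-gene set."""

    D: int
    T: int
    O: int
    N: int
    Dp: float
    Di: float  # NaN when T == 0 (no deregulated genes: negative test)
    fisher_p: float
    quadrants: dict[str, int]
    antagonistic_fraction: float
    t_fraction: float  # O/T: fraction of T-genes that are developmental
    label: str = ""
    di_undefined_reason: str | None = None

    def to_record(self) -> dict:
        return {
            "label": self.label,
            "D": self.D,
            "T": self.T,
            "O": self.O,
            "N": self.N,
            "Dp": self.Dp,
            "Di": self.Di,
            "fisher_p": self.fisher_p,
            "quadrants": dict(self.quadrants),
            "antagonistic_fraction": self.antagonistic_fraction,
            "t_fraction": self.t_fraction,
            "di_undefined_reason": self.di_undefined_reason,
        }


QUADRANTS = ("Tup_Dup", "Tup_Ddown", "Tdown_Dup", "Tdown_Ddown")


def _check_namespace(d: RegulonSets, t: RegulonSets) -> None:
    if d.namespace != t.namespace:
        raise ValidationError(
            f"identifier namespace mismatch: D is {d.namespace!r}, "
            f"T is {t.namespace!r}"
        )


def compute_overlap(d: RegulonSets, t: RegulonSets) -> tuple[int, dict[str, int]]:
    """O = |(D.up ∪ D.down) ∩ (T.up ∪ T.down)| plus the four directional
    intersection counts."""
    _check_namespace(d, t)
    overlap = d.all & t.all
    quadrants = {
        "Tup_Dup": len(t.up & d.up),
        "Tup_Ddown": len(t.up & d.down),
        "Tdown_Dup": len(t.down & d.up),
        "Tdown_Ddown": len(t.down & d.down),
    }
    return len(overlap), quadrants


def compute_dp(O: int, D: int) -> float:
    """Developmental potency: the fraction of all D-genes altered."""
    if D < 1:
        raise ValidationError("D = 0: no developmental signal defined")
    if not 0 <= O <= D:
        raise ValidationError(f"O = {O} outside [0, D = {D}]")
    return O / D


def compute_di(O: int, T: int, D: int, N: int) -> float:
    """Developmental index: (O/T)/(D/N); 1.0 means random expectation.

    Returns NaN when T = 0 (a compound with no deregulated genes is a
    negative test, not a zero enrichment).
    """
    if D < 1:
        raise ValidationError("D must be >= 1")
    if N < max(D, T):
        raise ValidationError(f"N = {N} smaller than max(D, T)")
    if T == 0:
        return float("nan")
    if O > min(D, T):
        raise ValidationError(f"O = {O} exceeds min(D, T)")
    return (O / T) / (D / N)


def overlap_significance(O: int, T: int, D: int, N: int) -> float:
    """One-sided Fisher exact p for the D/T overlap: P(X >= O) with
    X ~ Hypergeometric(N, D, T)."""
    if O > min(D, T):
        raise ValidationError(f"O = {O} exceeds min(D, T)")
    if N < max(D, T):
        raise ValidationError(f"N = {N} smaller than max(D, T)")
    return float(hypergeom.sf(O - 1, N, D, T))


def index_result(
    d: RegulonSets, t: RegulonSets, N: int, label: str = ""
) -> IndexResult:
    """Assemble the full score set for one (D, T) pairing."""
    O, quadrants = compute_overlap(d, t)
    D, T = len(d), len(t)
    Dp = compute_dp(O, D)
    reason = None
    if T == 0:
        Di = float("nan")
        fisher_p = 1.0
        t_fraction = float("nan")
        reason = "no T-genes"
    else:
        Di = compute_di(O, T, D, N)
        fisher_p = overlap_significance(O, T, D, N)
        t_fraction = O / T
    antagonistic = quadrants["Tup_Ddown"] + quadrants["Tdown_Dup"]
    return IndexResult(
        D=D,
        T=T,
        O=O,
        N=N,
        Dp=Dp,
        Di=Di,
        fisher_p=fisher_p,
        quadrants=quadrants,
        antagonistic_fraction=antagonistic / O if O else 0.0,
        t_fraction=t_fraction,
        label=label,
        di_undefined_reason=reason,
    )


def antagonism_fractions(
    d: RegulonSets, t: RegulonSets
) -> dict[str, dict[str, float | int]]:
    """Fractions of D-genes affected per (T-direction, D-direction) pair.

    Each entry reports |t.dir ∩ d.dir'| / |d.dir'| plus the absolute count;
    the fraction is NaN for an empty D direction set.
    """
    _check_namespace(d, t)
    out: dict[str, dict[str, float | int]] = {}
    pairs = {
        "Tup_Dup": (t.up, d.up),
        "Tup_Ddown": (t.up, d.down),
        "Tdown_Dup": (t.down, d.up),
        "Tdown_Ddown": (t.down, d.down),
    }
    for name, (tset, dset) in pairs.items():
        count = len(tset & dset)
        frac = count / len(dset) if dset else float("nan")
        out[name] = {"count": count, "fraction": frac}
    return out


def category_indices(
    d: RegulonSets,
    t: RegulonSets,
    categories: GeneSetCollection,
    N: int,
) -> dict[str, IndexResult]:
    """D_p and D_i restricted to specific differentiation processes.

    For each category c: D_c = |D ∩ c| and O_c = |D ∩ T ∩ c|; T and the
    background N stay global.  Categories with no developmental members are
    skipped with a log entry.
    """
    if len(categories) == 0:
        raise ValidationError("empty category collection")
    if categories.namespace != d.namespace:
        raise ValidationError(
            f"category namespace {categories.namespace!r} does not match "
            f"regulon namespace {d.namespace!r}"
        )
    _check_namespace(d, t)
    results: dict[str, IndexResult] = {}
    for name in categories.names():
        members = categories.members(name)
        d_c = RegulonSets(
            up=d.up & members,
            down=d.down & members,
            label=f"{d.label}|{name}",
            namespace=d.namespace,
        )
        if len(d_c) == 0:
            log.info("category %r has no developmental members: skipped", name)
            continue
        results[name] = index_result(d_c, t, N, label=name)
    return results


def baseline_stratify(
    regulons: RegulonSets,
    matrix: ExpressionMatrix,
    design: SampleDesign,
    threshold_log2: float = 6.0,
) -> pd.DataFrame:
    """Partition regulon members by baseline expression at day 0 / end stage.

    A probe is "high" if its mean over day-0 controls OR over end-stage
    differentiation controls exceeds the threshold (strictly) on the log2
    scale.  Returns per-probe means and the high/low flag.
    """
    day0 = design.samples_with_role("day0_control")
    end = design.samples_with_role("diff_control")
    if not day0 or not end:
        raise ValidationError(
            "baseline stratification needs day0_control and diff_control samples"
        )
    frame = matrix.to_frame()
    members = sorted(regulons.all)
    missing = [m for m in members if m not in frame.index]
    if missing:
        raise ValidationError(f"regulon members absent from matrix: {missing[:5]}")
    mean_day0 = frame.loc[members, day0].mean(axis=1)
    mean_end = frame.loc[members, end].mean(axis=1)
    high = (mean_day0 > threshold_log2) | (mean_end > threshold_log2)
    return pd.DataFrame(
        {
            "mean_day0": mean_day0,
            "mean_end": mean_end,
            "high_baseline": high,
            "direction": [
                "up" if m in regulons.up else "down" for m in members
            ],
        },
        index=pd.Index(members, name=regulons.namespace + "_id"),
    )


def concentration_profile(
    per_concentration: list[tuple[float, DEGTable]],
    d: RegulonSets,
    N: int,
    label: str = "",
) -> pd.DataFrame:
    """One IndexResult row per tested concentration, sorted ascending.

    Concentrations with no deregulated probes carry D_p = 0 and an
    undefined D_i (negative test at that concentration).
    """
    if not per_concentration:
        raise ValidationError("no concentrations supplied")
    concs = [c for c, _ in per_concentration]
    if len(set(concs)) != len(concs):
        raise ValidationError("duplicate concentrations in profile")
    rows = []
    for conc, deg in sorted(per_concentration, key=lambda x: x[0]):
        t = call_regulons(deg, label=f"T@{conc}")
        res = index_result(d, t, N, label=f"{label}@{conc}")
        rows.append(
            {
                "concentration": conc,
                "T": res.T,
                "O": res.O,
                "Dp": res.Dp,
                "Di": res.Di,
                "fisher_p": res.fisher_p,
                "antagonistic_fraction": res.antagonistic_fraction,
            }
        )
    return pd.DataFrame(rows)
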