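"""Per-probe two-group differential expression and D-/T-gene calling.

The statistical model is the classical one-way ANOVA with two levels
(equivalently a pooled-variance two-sample t-test, F = t^2), with
Benjamini-Hochberg FDR control over all probes of the array and a
significance gate combining the FDR-adjusted p-value with an absolute
linear fold-change threshold (defaults: q <= 0.05, |FC| >= 1.5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_model import ExpressionMatrix, PROBE, ValidationError

log = logging.getLogger(__name__)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped at 1,
    mapped back to the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValidationError("empty p-value vector")
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def signed_fold_change(log2fc: np.ndarray) -> np.ndarray:
    """Signed linear fold change: 2^log2FC when >= 1, else -2^-log2FC."""
    log2fc = np.asarray(log2fc, dtype=float)
    return np.where(log2fc >= 0, 2.0**log2fc, -(2.0 ** (-log2fc)))


@dataclass
class DEGTable:
    """Per-probe differential-expression results for one contrast."""

    table: pd.DataFrame  # index: probe_id; columns below
    contrast: str
    fc_threshold: float
    q_threshold: float
    namespace: str = PROBE

    COLUMNS = (
        "mean_a",
        "mean_b",
        "log2fc",
        "fold_change",
        "p",
        "q",
        "direction",
        "significant",
    )

    def significant_probes(self) -> pd.Index:
        return self.table.index[self.table["significant"]]


def differential_expression(
    matrix: ExpressionMatrix,
    group_a: list[str],
    group_b: list[str],
    fc_threshold: float = 1.5,
    q_threshold: float = 0.05,
    welch: bool = False,
    contrast: str = "",
) -> DEGTable:
    """Two-group test per probe: B vs A (log2FC = mean_B - mean_A).

    Pooled-variance by default (two-level one-way ANOVA); Welch optional.
    Probes with zero variance in both groups and equal means get p = 1 by
    convention.
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValidationError("each group needs >= 2 samples")
    if set(group_a) & set(group_b):
        raise ValidationError("groups overlap")
    a = matrix.subset_samples(group_a).values
    b = matrix.subset_samples(group_b).values
    na, nb = a.shape[1], b.shape[1]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    diff = mean_b - mean_a

    with np.errstate(divide="ignore", invalid="ignore"):
        if welch:
            se2 = var_a / na + var_b / nb
            t = diff / np.sqrt(se2)
            df = se2**2 / (
                (var_a / na) ** 2 / (na - 1) + (var_b / nb) ** 2 / (nb - 1)
            )
        else:
            sp2 = ((na - 1) * var_a + (nb - 1) * var_b) / (na + nb - 2)
            t = diff / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
            df = np.full_like(t, na + nb - 2, dtype=float)
        p = 2.0 * stats.t.sf(np.abs(t), df)

    degenerate = ~np.isfinite(p)
    zero_sd_equal = degenerate & (diff == 0)
    if zero_sd_equal.any():
        log.info(
            "%d probe(s) with zero variance and equal means: p = 1 by convention",
            int(zero_sd_equal.sum()),
        )
    p = np.where(zero_sd_equal, 1.0, p)
    # zero pooled variance but nonzero difference: infinitely strong evidence
    p = np.where(degenerate & (diff != 0), 0.0, p)

    q = bh_fdr(p)
    fc = signed_fold_change(diff)
    significant = (np.abs(fc) >= fc_threshold) & (q <= q_threshold)
    direction = np.where(
        significant & (diff > 0), "up", np.where(significant & (diff < 0), "down", "none")
    )
    table = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": diff,
            "fold_change": fc,
            "p": p,
            "q": q,
            "direction": direction,
            "significant": significant,
        },
        index=pd.Index(matrix.probe_ids, name="probe_id"),
    )
    return DEGTable(
        table=table,
        contrast=contrast,
        fc_threshold=fc_threshold,
        q_threshold=q_threshold,
    )


@dataclass
class RegulonSets:
    """Up/down identifier sets for one contrast (D-genes or a compound's
    T-genes).  ``up`` and ``down`` are disjoint by construction."""

    up: frozenset[str]
    down: frozenset[str]
    label: str
    namespace: str = PROBE
    provenance: str = ""

    def __post_init__(self) -> None:
        self.up = frozenset(self.up)
        self.down = frozenset(self.down)
        if self.up & self.down:
            raise ValidationError(f"{self.label}: up and down sets overlap")

    @property
    def all(self) -> frozenset[str]:
        return self.up | self.down

    def __len__(self) -> int:
        return len(self.up) + len(self.down)


def call_regulons(deg: DEGTable, label: str) -> RegulonSets:
    """Split significant probes into up/down sets by sign of log2FC."""
    tab = deg.table
    sig = tab["significant"]
    up = frozenset(tab.index[sig & (tab["log2fc"] > 0)])
    down = frozenset(tab.index[sig & (tab["log2fc"] < 0)])
    return RegulonSets(
        up=up,
        down=down,
        label=label,
        namespace=deg.namespace,
        provenance=deg.contrast,
    )


def fold_change_tiers(
    regulons: RegulonSets, deg: DEGTable, tiers: tuple[float, ...] = (2.0, 5.0, 10.0)
) -> dict[float, dict[str, int]]:
    """Counts of up/down regulon members with linear |FC| >= each tier."""
    for tau in tiers:
        if tau < 1:
            raise ValidationError(f"tier {tau} < 1")
    fc = deg.table["fold_change"]
    out: dict[float, dict[str, int]] = {}
    for tau in tiers:
        up = int((fc.loc[list(regulons.up)].abs() >= tau).sum()) if regulons.up else 0
        down = (
            int((fc.loc[list(regulons.down)].abs() >= tau).sum())
            if regulons.down
            else 0
        )
        out[float(tau)] = {"up": up, "down": down}
    return out


def top_k_by_fdr(deg: DEGTable, k: int = 50, significant_only: bool = True) -> list[str]:
    """The k most regulated probes by lowest FDR-adjusted p.

    Ties on q break by ascending raw p, then probe id.  When fewer than k
    significant probes exist, all of them are returned.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    tab = deg.table
    if significant_only:
        tab = tab[tab["significant"]]
    order = np.lexsort(
        (tab.index.to_numpy(), tab["p"].to_numpy(), tab["q"].to_numpy())
    )
    return list(tab.index[order][:k])
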