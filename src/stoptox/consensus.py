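"""Probe-to-gene collapse, class consensus genes, and diagnostic-gene ranking.

A gene counts as deregulated by a compound if at least one annotated probe
set passes the significance gate; genes with significant probes in both
directions are "inconsistent" and count toward neither direction.  A
consensus gene is one called in the same direction by at least ``min_count``
compounds of a class (per-system presets from the source study: UKK
mercurials 3, UKN1 mercurials 4, UKK HDACi 4, UKN1 HDACi 5).  Diagnostic
candidates are consensus genes passing six further criteria (multi-compound
support, high fold change, developmental membership, antagonism of the
spontaneous development, baseline log2 expression > 6, and — optionally,
via a curated allow-list — understood function).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dge import DEGTable, RegulonSets
from .io_model import GENE, ProbeAnnotation, ValidationError

log = logging.getLogger(__name__)

CONSENSUS_PRESETS = {
    ("UKK", "mercurial"): 3,
    ("UKN1", "mercurial"): 4,
    ("UKK", "HDACi"): 4,
    ("UKN1", "HDACi"): 5,
}


@dataclass
class GeneRegulation:
    """Per-gene regulation state for one compound."""

    gene: str
    status: str  # up | down | inconsistent | none
    probes: list[tuple[str, float]] = field(default_factory=list)  # (probe, signed FC)
    best_abs_fc: float = 0.0


def collapse_to_genes(
    deg: DEGTable, annotation: ProbeAnnotation
) -> dict[str, GeneRegulation]:
    """Collapse probe-level calls to gene level.

    Unannotated probes are dropped; a probe mapping to several genes
    contributes to each of them.  Gene status: up/down if all significant
    probes agree, inconsistent if both directions occur, none otherwise.
    """
    if not annotation.mapping:
        raise ValidationError("annotation covers no probes")
    tab = deg.table
    per_gene: dict[str, GeneRegulation] = {}
    sig = tab[tab["significant"]]
    for probe, row in sig.iterrows():
        for gene in annotation.genes_for(str(probe)):
            reg = per_gene.setdefault(gene, GeneRegulation(gene=gene, status="none"))
            reg.probes.append((str(probe), float(row["fold_change"])))
    for gene, reg in per_gene.items():
        dirs = {"up" if fc > 0 else "down" for _, fc in reg.probes}
        if dirs == {"up"}:
            reg.status = "up"
        elif dirs == {"down"}:
            reg.status = "down"
        elif dirs:
            reg.status = "inconsistent"
        reg.best_abs_fc = max((abs(fc) for _, fc in reg.probes), default=0.0)
    return per_gene


def gene_level_regulons(
    regulation: dict[str, GeneRegulation], label: str
) -> RegulonSets:
    """Gene-level up/down sets from a collapse; inconsistent genes excluded."""
    up = frozenset(g for g, r in regulation.items() if r.status == "up")
    down = frozenset(g for g, r in regulation.items() if r.status == "down")
    return RegulonSets(up=up, down=down, label=label, namespace=GENE)


def consensus_genes(
    per_compound: dict[str, dict[str, GeneRegulation]], min_count: int
) -> pd.DataFrame:
    """Count, per gene and direction, how many compounds call it.

    Inconsistent-status compounds count toward neither direction.  A gene is
    a consensus gene when max(n_up, n_down) >= min_count.  Returns one row
    per gene with columns n_up, n_down, mean_fc (mean of per-compound best
    signed FC in the consensus direction), consensus (bool), direction.
    """
    if min_count < 1:
        raise ValidationError("min_count must be >= 1")
    if not per_compound:
        raise ValidationError("no compounds supplied")
    if min_count > len(per_compound):
        raise ValidationError(
            f"min_count = {min_count} exceeds number of compounds "
            f"({len(per_compound)})"
        )
    genes = sorted({g for regs in per_compound.values() for g in regs})
    rows = []
    for gene in genes:
        n_up = n_down = 0
        fcs_up, fcs_down = [], []
        for regs in per_compound.values():
            reg = regs.get(gene)
            if reg is None:
                continue
            if reg.status == "up":
                n_up += 1
                fcs_up.append(max(fc for _, fc in reg.probes))
            elif reg.status == "down":
                n_down += 1
                fcs_down.append(min(fc for _, fc in reg.probes))
        if n_up >= n_down and n_up > 0:
            direction, fcs, support = "up", fcs_up, n_up
        elif n_down > 0:
            direction, fcs, support = "down", fcs_down, n_down
        else:
            direction, fcs, support = "none", [], 0
        rows.append(
            {
                "gene": gene,
                "n_up": n_up,
                "n_down": n_down,
                "direction": direction,
                "n_compounds": support,
                "mean_fc": float(np.mean(fcs)) if fcs else 0.0,
                "consensus": max(n_up, n_down) >= min_count,
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def compound_hit_crosstab(
    per_compound: dict[str, dict[str, GeneRegulation]]
) -> pd.DataFrame:
    """How many genes are hit by exactly 1..n compounds, per direction
    (the cross-table of class-consensus counting)."""
    table = consensus_genes(per_compound, min_count=1)
    n = len(per_compound)
    rows = []
    for k in range(1, n + 1):
        rows.append(
            {
                "n_compounds": k,
                "up": int((table["n_up"] == k).sum()),
                "down": int((table["n_down"] == k).sum()),
            }
        )
    return pd.DataFrame(rows).set_index("n_compounds")


@dataclass
class DiagnosticCandidate:
    gene: str
    direction: str
    n_compounds: int
    mean_fc: float
    criteria: dict[str, bool]
    rank: int


def rank_diagnostic_genes(
    consensus: pd.DataFrame,
    d_genes: RegulonSets,
    baseline: pd.DataFrame,
    min_count: int,
    top_k: int | None = None,
    known_function: frozenset[str] | None = None,
) -> list[DiagnosticCandidate]:
    """Filter and rank consensus genes by the six diagnostic criteria.

    c1: supported by >= min_count compounds of the class;
    c2: higher fold changes preferred (the ranking key);
    c3: developmental gene (member of the gene-level D set);
    c4: compound direction antagonizes the developmental direction;
    c5: baseline log2 expression > threshold at day 0 or end stage;
    c6: function understood — an external curated allow-list, applied only
        when provided.

    Ranking: n_compounds desc, mean |FC| desc, gene id asc.
    """
    if d_genes.namespace != GENE:
        raise ValidationError("diagnostic ranking needs gene-level D regulons")
    if consensus.empty:
        return []
    high_baseline = set(baseline.index[baseline["high_baseline"]])
    if known_function is None:
        log.info("no curated function list supplied: criterion 6 skipped")
    candidates = []
    for gene, row in consensus.iterrows():
        direction = row["direction"]
        if direction == "none":
            continue
        c1 = bool(row["n_compounds"] >= min_count)
        c3 = gene in d_genes.all
        dev_dir = "up" if gene in d_genes.up else ("down" if gene in d_genes.down else None)
        c4 = dev_dir is not None and direction != dev_dir
        c5 = gene in high_baseline
        c6 = True if known_function is None else gene in known_function
        criteria = {"c1": c1, "c2": True, "c3": c3, "c4": c4, "c5": c5, "c6": c6}
        if all(criteria.values()):
            candidates.append(
                DiagnosticCandidate(
                    gene=str(gene),
                    direction=str(direction),
                    n_compounds=int(row["n_compounds"]),
                    mean_fc=float(row["mean_fc"]),
                    criteria=criteria,
                    rank=0,
                )
            )
    candidates.sort(key=lambda c: (-c.n_compounds, -abs(c.mean_fc), c.gene))
    for i, cand in enumerate(candidates, 1):
        cand.rank = i
    if top_k is not None:
        candidates = candidates[:top_k]
    return candidates
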