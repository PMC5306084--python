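"""Config-driven orchestration: preprocess -> dge -> indices -> consensus
-> tfnet, with a machine-readable run manifest.

The run directory receives one output file per stage plus ``manifest.json``
recording the package version, seeds, thresholds and SHA-256 hashes of all
inputs; re-running with the same config reproduces every deterministic
output byte-identically.  Any stage error aborts the run with the failing
stage named and a FAILED marker left next to the partial outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .consensus import collapse_to_genes, consensus_genes, gene_level_regulons
from .dge import call_regulons, differential_expression
from .indices import concentration_profile, index_result
from .io_model import (
    ValidationError,
    read_expression_matrix,
    read_gmt,
    read_probe_annotation,
    read_sample_design,
    write_expression_matrix,
    write_report,
)
from .preprocess import combat_correct, quantile_normalize
from .tfnet import (
    build_network,
    clr_scores,
    detect_communities,
    enrich_communities,
    knn_mutual_information,
    overlay_regulation,
)

log = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = {
    "fc": 1.5,
    "q": 0.05,
    "baseline": 6.0,
    "min_count": 3,
    "edge_quantile": 0.001,
    "mi_k": 9,
}


@dataclass
class RunConfig:
    matrix: Path
    design: Path
    out_dir: Path
    annotation: Path | None = None
    tf_list: Path | None = None
    categories: Path | None = None
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    seed: int = 0
    quantile: bool = True
    combat: str = "off"  # off | nonparametric | parametric
    stages: dict = field(
        default_factory=lambda: {"consensus": False, "tfnet": False}
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh)
        thresholds = dict(DEFAULT_THRESHOLDS)
        thresholds.update(raw.get("thresholds", {}))
        cfg = cls(
            matrix=Path(raw["matrix"]),
            design=Path(raw["design"]),
            out_dir=Path(raw["out_dir"]),
            annotation=Path(raw["annotation"]) if raw.get("annotation") else None,
            tf_list=Path(raw["tf_list"]) if raw.get("tf_list") else None,
            categories=Path(raw["categories"]) if raw.get("categories") else None,
            thresholds=thresholds,
            seed=int(raw.get("seed", 0)),
            quantile=bool(raw.get("quantile", True)),
            combat=str(raw.get("combat", "off")),
            stages={
                "consensus": bool(raw.get("stages", {}).get("consensus", False)),
                "tfnet": bool(raw.get("stages", {}).get("tfnet", False)),
            },
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for name in ("matrix", "design"):
            path = getattr(self, name)
            if not Path(path).exists():
                raise ValidationError(f"config: {name} file does not exist: {path}")
        for name in ("annotation", "tf_list", "categories"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise ValidationError(f"config: {name} file does not exist: {path}")
        if self.stages.get("consensus") and self.annotation is None:
            raise ValidationError(
                "config: consensus stage enabled but no annotation supplied"
            )
        if self.stages.get("tfnet") and (
            self.tf_list is None or self.annotation is None
        ):
            raise ValidationError(
                "config: tfnet stage enabled but tf_list/annotation missing"
            )
        th = self.thresholds
        if not (th["fc"] >= 1 and 0 < th["q"] <= 1 and 0 < th["edge_quantile"] <= 1):
            raise ValidationError("config: thresholds outside documented ranges")
        if self.combat not in ("off", "nonparametric", "parametric"):
            raise ValidationError(f"config: unknown combat mode {self.combat!r}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all enabled stages in dependency order; returns the manifest."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    failed_marker = out_dir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": dict(config.thresholds),
        "quantile": config.quantile,
        "combat": config.combat,
        "stages": dict(config.stages),
        "inputs": {},
        "outputs": [],
    }
    for name in ("matrix", "design", "annotation", "tf_list", "categories"):
        path = getattr(config, name)
        if path is not None:
            manifest["inputs"][name] = {
                "path": str(path),
                "sha256": _sha256(Path(path)),
            }
    stage = "io"
    try:
        matrix = read_expression_matrix(config.matrix)
        design = read_sample_design(config.design)
        design.validate_against(matrix)
        th = config.thresholds

        stage = "preprocess"
        if config.quantile:
            matrix = quantile_normalize(matrix)
        if config.combat != "off":
            matrix = combat_correct(matrix, design, mode=config.combat)
        norm_path = out_dir / "matrix.norm.tsv"
        write_expression_matrix(matrix, norm_path)
        manifest["outputs"].append(norm_path.name)

        stage = "dge"
        day0 = design.samples_with_role("day0_control")
        ctrl = design.samples_with_role("diff_control")
        deg_d = differential_expression(
            matrix,
            day0,
            ctrl,
            fc_threshold=th["fc"],
            q_threshold=th["q"],
            contrast="day0_control vs diff_control",
        )
        d_regulons = call_regulons(deg_d, label="D-genes")
        deg_dir = out_dir / "deg"
        deg_dir.mkdir(exist_ok=True)
        deg_d.table.to_csv(deg_dir / "D.tsv", sep="\t", float_format="%.10g")
        manifest["outputs"].append("deg/D.tsv")

        treated = design.table[design.table["role"] == "treated"]
        conditions = sorted(
            {
                (str(r["compound"]), float(r["concentration"]))
                for _, r in treated.iterrows()
            }
        )
        deg_t = {}
        for compound, conc in conditions:
            samples = design.samples_for_compound(compound, conc)
            deg = differential_expression(
                matrix,
                ctrl,
                samples,
                fc_threshold=th["fc"],
                q_threshold=th["q"],
                contrast=f"{compound}@{conc} vs diff_control",
            )
            deg_t[(compound, conc)] = deg
            fname = f"T_{compound}_{conc:g}.tsv"
            deg.table.to_csv(deg_dir / fname, sep="\t", float_format="%.10g")
            manifest["outputs"].append(f"deg/{fname}")

        stage = "indices"
        N = matrix.n_probes
        results = {}
        for (compound, conc), deg in deg_t.items():
            t_reg = call_regulons(deg, label=f"T({compound}@{conc:g})")
            results[f"{compound}@{conc:g}"] = index_result(
                d_regulons, t_reg, N, label=f"{compound}@{conc:g}"
            )
        write_report(
            {k: v.to_record() for k, v in results.items()},
            out_dir / "indices.json",
        )
        manifest["outputs"].append("indices.json")

        per_compound_concs: dict[str, list] = {}
        for (compound, conc), deg in deg_t.items():
            per_compound_concs.setdefault(compound, []).append((conc, deg))
        for compound, series in per_compound_concs.items():
            if len(series) > 1:
                profile = concentration_profile(series, d_regulons, N, label=compound)
                fname = f"profile_{compound}.tsv"
                profile.to_csv(out_dir / fname, sep="\t", index=False,
                               float_format="%.10g")
                manifest["outputs"].append(fname)

        collapsed = {}
        if config.annotation is not None:
            annotation = read_probe_annotation(config.annotation)
            for (compound, conc), deg in deg_t.items():
                collapsed[f"{compound}@{conc:g}"] = collapse_to_genes(deg, annotation)

        if config.stages.get("consensus"):
            stage = "consensus"
            per_class: dict[str, dict] = {}
            class_of = dict(
                zip(
                    treated["compound"].astype(str),
                    treated["compound_class"].astype(str),
                )
            )
            for key, regs in collapsed.items():
                compound = key.split("@")[0]
                per_class.setdefault(class_of.get(compound, "all"), {})[key] = regs
            for cls, per_comp in per_class.items():
                min_count = min(int(th["min_count"]), len(per_comp))
                table = consensus_genes(per_comp, min_count=min_count)
                fname = f"consensus_{cls}.tsv"
                table.to_csv(out_dir / fname, sep="\t", float_format="%.10g")
                manifest["outputs"].append(fname)

        if config.stages.get("tfnet"):
            stage = "tfnet"
            annotation = read_probe_annotation(config.annotation)
            tf_sets = read_gmt(config.tf_list)
            tfs: set[str] = set()
            for name in tf_sets.names():
                tfs |= set(tf_sets.members(name))
            # collapse probes to gene symbols (mean over mapped probes)
            frame = matrix.to_frame()
            gene_rows, gene_names = [], []
            for gene in sorted(tfs):
                probes = [
                    p for p in matrix.probe_ids if gene in annotation.genes_for(p)
                ]
                if probes:
                    gene_rows.append(frame.loc[probes].mean(axis=0).to_numpy())
                    gene_names.append(gene)
            if not gene_names:
                raise ValidationError("no TF symbols present in annotation")
            expr = np.vstack(gene_rows)
            mi = knn_mutual_information(
                expr, gene_names, k=int(th["mi_k"]), seed=config.seed
            )
            scores = clr_scores(mi)
            network = build_network(
                scores, gene_names, frozenset(tfs),
                edge_quantile=th["edge_quantile"],
            )
            network = detect_communities(network)
            edges = sorted(network.edges)
            with (out_dir / "tf_edges.tsv").open("w") as fh:
                fh.write("gene_i\tgene_j\tclr_score\n")
                for u, v, s in edges:
                    fh.write(f"{u}\t{v}\t{s:.10g}\n")
            manifest["outputs"].append("tf_edges.tsv")
            comm_report = {
                "communities": [sorted(c) for c in network.communities],
                "retained": network.retained_communities,
            }
            if config.categories is not None:
                cats = read_gmt(config.categories)
                comm_report["enrichment"] = {
                    str(ci): terms
                    for ci, terms in enrich_communities(network, cats).items()
                }
            if collapsed:
                first = sorted(collapsed)[0]
                comm_report["overlay"] = overlay_regulation(
                    network, collapsed[first]
                )
            write_report(comm_report, out_dir / "tf_communities.json")
            manifest["outputs"].append("tf_communities.json")

        stage = "manifest"
        write_report(manifest, out_dir / "manifest.json")
        return manifest
    except Exception as exc:
        failed_marker.write_text(f"stage {stage} failed: {exc}\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
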