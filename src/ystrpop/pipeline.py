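"""End-to-end orchestration: parse -> forensic stats -> census -> Rst/MDS
-> DA/NJ tree -> median-joining network + TMRCA -> haplogroups.

Each stage writes its table(s) under the output directory and records
itself in ``manifest.json``; a stage failure leaves a ``FAILED`` marker
naming the stage and cause but keeps the outputs already written. One
global seed fans out deterministically to the per-stage seeds, so two runs
with the same config are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .core import PopulationDataset, combine
from .datree import bootstrap_njtree
from .forensic import allele_frequencies, forensic_summary, variant_census
from .haplogroups import HaplogroupRefTable, PredictorConfig, batch_predict_with_thresholds
from .io import parse_haplotype_table
from .mds import classical_mds
from .mjnet import MJNetwork, MutationModel, NetworkConfig, build_mj_network, rho_tmrca, suggest_ancestral_node
from .panel import LocusPanel, YFILER_17
from .rst import RstConfig, rst_matrix_with_bonferroni, yhrd_filter

__all__ = ["RunConfig", "run_full_analysis"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    input_path: Path
    output_dir: Path
    panel: LocusPanel = YFILER_17
    rst: RstConfig = field(default_factory=RstConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    mutation_model: MutationModel = field(default_factory=MutationModel)
    predictor: PredictorConfig = field(default_factory=PredictorConfig)
    haplogroup_ref_path: Optional[Path] = None
    n_bootstrap: int = 1000
    ancestral_node: Optional[tuple] = None
    seed: int = 0

    def stage_seed(self, k: int) -> int:
        return int((self.seed * 1009 + k) % (2 ** 31))


def run_full_analysis(config: RunConfig) -> Dict[str, str]:
    """Run every stage; returns the manifest's stage-status mapping."""
    if not Path(config.input_path).exists():
        raise FileNotFoundError(f"input path {config.input_path} does not exist")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: Dict[str, object] = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
    }
    stages: Dict[str, str] = manifest["stages"]

    def fail(stage: str, exc: Exception):
        stages[stage] = f"FAILED: {exc}"
        (out / "FAILED").write_text(f"stage {stage}: {exc}\n", encoding="utf-8")
        _write_manifest(out, manifest)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # parse
    try:
        datasets = parse_haplotype_table(config.input_path, config.panel)
        if not datasets:
            raise ValueError("input table holds no haplotypes")
        stages["parse"] = "ok"
    except Exception as exc:  # noqa: BLE001
        fail("parse", exc)

    pooled = combine(datasets)

    # forensic summaries
    try:
        rows = [forensic_summary(ds, config.panel).to_series() for ds in datasets]
        rows.append(forensic_summary(pooled, config.panel).to_series())
        pd.DataFrame(rows).to_csv(out / "forensic_summary.csv", index=False)
        stages["forensic"] = "ok"
    except Exception as exc:  # noqa: BLE001
        fail("forensic", exc)

    # variant census
    try:
        census = variant_census(datasets, config.panel)
        census.table.to_csv(out / "variant_census.csv", index=False)
        stages["census"] = "ok"
    except Exception as exc:  # noqa: BLE001
        fail("census", exc)

    # Rst + permutation P + Bonferroni
    try:
        rst_cfg = RstConfig(
            excluded_loci=config.rst.excluded_loci,
            n_permutations=config.rst.n_permutations,
            alpha=config.rst.alpha,
            bonferroni_m=config.rst.bonferroni_m,
            rng_seed=config.stage_seed(1),
            p_estimator=config.rst.p_estimator,
        )
        filtered = []
        removal_lines = []
        for ds in datasets:
            res = yhrd_filter(ds, rst_cfg, config.panel)
            filtered.append(res.dataset)
            removal_lines += [f"{ds.name}\t{sid}\t{why}" for sid, why in res.removed]
        (out / "yhrd_removals.txt").write_text(
            "\n".join(removal_lines) + ("\n" if removal_lines else ""),
            encoding="utf-8",
        )
        matrix, results = rst_matrix_with_bonferroni(filtered, rst_cfg)
        matrix.to_frame().to_csv(out / "rst_matrix.csv")
        tidy = pd.DataFrame(
            [
                {
                    "pop_a": r.pop_a,
                    "pop_b": r.pop_b,
                    "rst": r.rst,
                    "p_value": r.p_value,
                    "significant_raw": r.significant_raw,
                    "significant_bonferroni": r.significant_bonferroni,
                }
                for r in results.values()
            ]
        )
        tidy.to_csv(out / "rst_pairs.csv", index=False)
        stages["rst"] = "ok"
    except Exception as exc:  # noqa: BLE001
        fail("rst", exc)

    # MDS of the Rst matrix
    try:
        emb = classical_mds(matrix)
        emb.to_frame().to_csv(out / "mds_coordinates.csv")
        stages["mds"] = "ok"
    except Exception as exc:  # noqa: BLE001
        fail("mds", exc)

    # DA distances + NJ tree with locus bootstrap
    try:
        tables = {
            ds.name: allele_frequencies(ds, config.panel) for ds in datasets
        }
        from .datree import da_matrix

        da = da_matrix(tables)
        da.to_frame().to_csv(out / "da_matrix.csv")
        tree = bootstrap_njtree(
            tables, n_replicates=config.n_bootstrap, rng_seed=config.stage_seed(2)
        )
        (out / "nj_tree.nwk").write_text(tree.newick + "\n", encoding="utf-8")
        stages["datree"] = "ok"
    except Exception as exc:  # noqa: BLE001
        fail("datree", exc)

    # median-joining network + TMRCA (both mutation rates)
    try:
        net = build_mj_network(list(pooled), config.network)
        _write_network(net, out)
        anc = config.ancestral_node or suggest_ancestral_node(net)
        if config.ancestral_node is None:
            log.warning(
                "no ancestral node supplied; using centrality heuristic %s", anc
            )
        tmrca_rows = []
        for rate_label in ("genealogical", "evolutionary"):
            est = rho_tmrca(net, anc, config.mutation_model, rate_label)
            tmrca_rows.append(
                {
                    "rate": rate_label,
                    "rho": est.rho,
                    "se_rho": est.se_rho,
                    "n_descendants": est.n_descendants,
                    "n_loci": est.n_loci,
                    "t_generations": est.t_generations,
                    "t_years": est.t_years,
                    "se_years": est.se_years,
                }
            )
        pd.DataFrame(tmrca_rows).to_csv(out / "tmrca.csv", index=False)
        stages["network"] = "ok"
    except Exception as exc:  # noqa: BLE001
        fail("network", exc)

    # haplogroup prediction (optional)
    if config.haplogroup_ref_path is not None:
        try:
            ref = HaplogroupRefTable.from_csv(config.haplogroup_ref_path)
            calls, dist = batch_predict_with_thresholds(
                pooled, ref, config.predictor
            )
            calls.to_csv(out / "haplogroup_calls.csv", index=False)
            dist.to_csv(out / "haplogroup_distribution.csv", index=False)
            stages["haplogroups"] = "ok"
        except Exception as exc:  # noqa: BLE001
            fail("haplogroups", exc)
    else:
        stages["haplogroups"] = "skipped (no reference table)"
        log.info("haplogroup stage skipped: no reference table supplied")

    _write_manifest(out, manifest)
    return stages


def _write_network(net: MJNetwork, out: Path) -> None:
    node_rows = []
    ids = {}
    for i, (vec, data) in enumerate(sorted(net.graph.nodes(data=True))):
        ids[vec] = f"N{i}"
        node_rows.append(
            {
                "id": ids[vec],
                "haplotype": " ".join(str(v) for v in vec),
                "multiplicity": data["multiplicity"],
                "is_median": data["is_median"],
                "populations": ";".join(
                    f"{p}:{c}" for p, c in sorted(data["populations"].items())
                ),
            }
        )
    pd.DataFrame(node_rows).to_csv(out / "network_nodes.csv", index=False)
    edge_rows = [
        {"a": ids[u], "b": ids[v], "length": d["length"]}
        for u, v, d in net.graph.edges(data=True)
    ]
    pd.DataFrame(edge_rows).to_csv(out / "network_edges.csv", index=False)


def _write_manifest(out: Path, manifest: Dict[str, object]) -> None:
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
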