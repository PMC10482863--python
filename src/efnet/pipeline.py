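"""End-to-end orchestration: validate -> classify -> build -> stats -> layout -> stitch.

A run is described by a :class:`RunConfig` (either input table paths or a
synthetic-data configuration), executes each stage in order, and writes a
run directory containing the classification table, network edge lists, a
per-event statistics table (degrees, power-law fit, all six modularity
indices per event), pairwise modularity matrices with Ward dendrograms,
layouts/exports, and a JSON manifest recording inputs, seeds and versions.
A single global seed fans out to per-stage seeds by fixed offsets so each
stage is independently reproducible; reruns with the same config are
bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import efnet
from efnet.age_classify import assign_loop_ages, classify_prototypes, loop_age_map, venn_domains
from efnet.io_formats import (
    Chronology,
    MappingTable,
    read_chronology,
    read_mapping_table,
    validate_inputs,
)
from efnet.netbuild import build_bipartite, event_series, graph_density, project
from efnet.netstats import (
    DegenerateDistributionError,
    dendrogram_to_newick,
    degree_vectors,
    fit_power_law,
    modularity_report,
    pairwise_modularity_matrix,
    ward_dendrogram,
)
from efnet.synthdata import SynthConfig, generate_dataset
from efnet.waterfall import export_graph, waterfall_layout

logger = logging.getLogger(__name__)

# fixed per-stage seed offsets from the global seed
STAGE_SEED_OFFSETS = {"synth": 0, "project": 1, "stats": 2, "layout": 3}


@dataclass
class RunConfig:
    mapping_path: str | None = None
    chronology_path: str | None = None
    synth: SynthConfig | None = None
    evalue_max: float | None = 0.001
    scheme: int = 2
    subset: str = "M"
    seed: int = 0
    bootstrap_reps: int = 20
    hub_percentile: float = 99.0
    n_bins: int = 10
    out_dir: str = "efnet_run"

    def stage_seed(self, stage: str) -> int:
        return (self.seed + STAGE_SEED_OFFSETS[stage]) % (2**31)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _load_inputs(cfg: RunConfig) -> tuple[MappingTable, Chronology]:
    if cfg.synth is not None:
        synth_cfg = dataclasses.replace(cfg.synth, seed=cfg.stage_seed("synth"))
        mapping, chronology, _ = generate_dataset(synth_cfg)
        return mapping, chronology
    if not cfg.mapping_path or not cfg.chronology_path:
        raise ValueError("RunConfig needs either table paths or a synth config")
    for p in (cfg.mapping_path, cfg.chronology_path):
        if not Path(p).exists():
            raise FileNotFoundError(p)
    return read_mapping_table(cfg.mapping_path, cfg.evalue_max), read_chronology(
        cfg.chronology_path
    )


def per_event_stats(series, bootstrap_reps: int, seed: int) -> pd.DataFrame:
    """One row per event: size, density, degrees, power-law fit, modularity indices."""
    rows = []
    for event, g in series:
        row: dict = {
            "event": event,
            "n_nodes": g.number_of_nodes(),
            "n_edges": g.number_of_edges(),
        }
        try:
            row["density"] = graph_density(g)
        except ValueError:
            row["density"] = np.nan
        degs = (
            [din + dout for (_, din), (_, dout) in zip(g.in_degree(weight="weight"), g.out_degree(weight="weight"))]
            if g.is_directed()
            else [d for _, d in g.degree(weight="weight")]
        )
        degs = np.asarray(degs, dtype=float)
        row["mean_degree"] = degs.mean() if len(degs) else np.nan
        row["max_degree"] = degs.max() if len(degs) else np.nan
        for key in ("gamma", "r_squared", "alpha", "ks_stat", "ks_p"):
            row[key] = np.nan
        nonzero = degs[degs > 0]
        if len(nonzero) >= 10 and not np.all(nonzero == nonzero[0]):
            try:
                fit = fit_power_law(nonzero, bootstrap_reps=bootstrap_reps, seed=seed)
                row.update(
                    gamma=fit.gamma, r_squared=fit.r_squared, alpha=fit.alpha,
                    ks_stat=fit.ks_stat, ks_p=fit.ks_p,
                )
            except DegenerateDistributionError:
                pass
        for key in ("vq", "c", "c_ratio", "fgc", "ng_age", "ng_vos", "n_communities"):
            row[key] = np.nan
        if g.number_of_edges() > 0:
            try:
                rep = modularity_report(g, seed=seed)
                row.update(dataclasses.asdict(rep))
            except ValueError:
                pass
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the full analysis; returns the run directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "efnet_version": efnet.__version__,
        "seed": cfg.seed,
        "stage_seeds": {s: cfg.stage_seed(s) for s in STAGE_SEED_OFFSETS},
        "config": {
            k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
            for k, v in dataclasses.asdict(cfg).items()
        },
        "stages": {},
    }

    def stage(name):
        logger.info("stage %s", name)
        return name

    try:
        name = stage("validate")
        mapping, chronology = _load_inputs(cfg)
        summary = validate_inputs(mapping, chronology)
        manifest["stages"][name] = summary
        mapping.write(out / "mapping.tsv")
        chronology.write(out / "chronology.tsv")

        name = stage("classify")
        assignments = assign_loop_ages(mapping, chronology, scheme=cfg.scheme)
        classification = classify_prototypes(mapping, chronology)
        venn = venn_domains(mapping, classification, chronology)
        pd.DataFrame(
            {
                "loop": [str(a.loop) for a in assignments],
                "scheme1_age": [a.scheme1_age for a in assignments],
                "scheme2_age": [a.scheme2_age for a in assignments],
                "label": [classification.partition[a.loop] for a in assignments],
            }
        ).to_csv(out / "classification.tsv", sep="\t", index=False)
        venn_counts = {
            "m_only": len(venn.m_only), "nm_only": len(venn.nm_only),
            "both": len(venn.both), "unmapped": len(venn.unmapped),
        }
        pd.DataFrame([venn_counts]).to_csv(out / "venn.tsv", sep="\t", index=False)
        manifest["stages"][name] = {**classification.counts(), **venn_counts}

        name = stage("build")
        ages = loop_age_map(assignments, scheme=cfg.scheme)
        bip = build_bipartite(mapping, chronology, ages, subset=cfg.subset,
                              classification=classification)
        loops_proj = project(bip, side="loop", seed=cfg.stage_seed("project"))
        domains_proj = project(bip, side="domain", seed=cfg.stage_seed("project"))
        nets = {"bipartite": bip, "loop_projection": loops_proj, "domain_projection": domains_proj}
        series = {k: event_series(g) for k, g in nets.items() if g.number_of_nodes()}
        for key, g in nets.items():
            export_graph(g, out / key, fmt="edgelist")
        pd.DataFrame(
            [
                {"network": k, "n_events": len(s), "n_nodes": s.final.number_of_nodes(),
                 "n_edges": s.final.number_of_edges()}
                for k, s in series.items()
            ]
        ).to_csv(out / "events_index.tsv", sep="\t", index=False)
        manifest["stages"][name] = {
            k: {"nodes": g.number_of_nodes(), "edges": g.number_of_edges()}
            for k, g in nets.items()
        }

        name = stage("stats")
        stats_seed = cfg.stage_seed("stats")
        for key, s in series.items():
            df = per_event_stats(s, cfg.bootstrap_reps, stats_seed)
            df.to_csv(out / f"stats_{key}.tsv", sep="\t", index=False, float_format="%.6g")
            _, curve = degree_vectors(s, mode="all", weighted=True)
            curve.to_csv(out / f"degree_curve_{key}.tsv", sep="\t", index=False,
                         float_format="%.6g")
        if bip.number_of_edges() > 0:
            pm = pairwise_modularity_matrix(bip)
            pm.to_frame().to_csv(out / "pairwise_modularity.tsv", sep="\t",
                                 float_format="%.6g")
            if len(pm.nodes) >= 2:
                z, labels = ward_dendrogram(pm)
                (out / "dendrogram.nwk").write_text(dendrogram_to_newick(z, labels) + "\n")
        manifest["stages"][name] = {"networks": sorted(series)}

        name = stage("layout")
        layout_seed = cfg.stage_seed("layout")
        for key in ("loop_projection", "domain_projection"):
            g = nets[key]
            if g.number_of_nodes() == 0 or g.number_of_edges() == 0:
                continue
            from efnet.netstats import detect_communities

            part, _ = detect_communities(g, method="vos_like", seed=layout_seed)
            lay = waterfall_layout(g, part, seed=layout_seed)
            export_graph(g, out / key, fmt="pajek", layout=lay)
            export_graph(g, out / key, fmt="graphml")
        manifest["stages"][name] = {"seed": layout_seed}
    except StageError:
        raise
    except Exception as exc:  # annotate with the failing stage
        raise StageError(name, exc) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out
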