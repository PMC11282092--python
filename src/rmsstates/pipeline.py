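"""End-to-end orchestration: simulate -> preprocess -> consensus -> score ->
states -> devmap -> shift tests, from a single config with one global seed.

Per-stage randomness is derived from the global seed by hashing the stage
name, so toggling one stage never perturbs another's random stream.  Each
run writes per-stage outputs plus a manifest recording seeds, input hashes
and cell/gene counts entering and leaving every step.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import devmap as dm
from . import io as rio
from . import preprocess as pp
from . import scoring as sc
from . import signatures as sg
from . import simulate as sim
from . import states as st

__all__ = ["RunConfig", "run_pipeline", "stage_seed", "load_run_config"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (< 2^31)."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).hexdigest()
    return int(h[:8], 16) % (2**31)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


@dataclass
class RunConfig:
    """Everything a pipeline run needs; serializable to/from YAML."""

    outdir: str = "rms_run"
    seed: int = 0
    simulate: dict = field(default_factory=dict)       # SimConfig overrides
    n_per_sample: int | None = None                    # subsampling cap
    qc_preset: str | None = None
    n_hvg: int = 2000
    n_pcs: int = 15
    n_neighbors: int = 20
    resolution: float = 0.3
    cluster_method: str = "louvain"
    batch_center: bool = True
    n_ctrl: int = 100
    n_bins: int = 24
    scale_scores: bool = True
    tau: float = 0.0
    tau_hi: float = 1.0
    stages: dict = field(
        default_factory=lambda: {
            "preprocess": True,
            "consensus": True,
            "score": True,
            "states": True,
            "devmap": True,
            "shift_test": True,
        }
    )
    devmap_labels: list = field(
        default_factory=lambda: ["SkM.Mesen", "MP", "MB", "MC", "MB-MC", "satellite"]
    )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_run_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def _pseudo_source_lists(
    truth: sim.GroundTruth, rng: np.random.Generator, n_sources: int = 3,
    keep_fraction: float = 0.8,
) -> dict[str, dict[str, sg.GeneSignature]]:
    """Jittered per-study marker lists from the planted markers, emulating
    independently derived publications feeding the consensus rule."""
    out: dict[str, dict[str, sg.GeneSignature]] = {}
    for state, genes in truth.marker_assignment.items():
        sources = {}
        for k in range(n_sources):
            n_keep = max(2, int(round(keep_fraction * len(genes))))
            kept = sorted(rng.choice(genes, size=n_keep, replace=False))
            sources[f"study{k + 1}"] = sg.GeneSignature(
                f"{state}_study{k + 1}", list(kept), source=f"study{k + 1}"
            )
        out[state] = sources
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order; returns (and writes) the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "run_config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    manifest: dict = {"seed": config.seed, "stages": {}, "inputs": {}}

    def record(stage: str, **info) -> None:
        manifest["stages"][stage] = {"seed": stage_seed(config.seed, stage), **info}

    try:
        # ---- simulate -------------------------------------------------
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("seed", stage_seed(config.seed, "simulate"))
        cfg = sim.SimConfig(**sim_kwargs)
        adata, truth = sim.generate_cohort(cfg)
        rio.write_10x(adata, outdir / "counts")
        truth.to_frame().to_csv(outdir / "ground_truth.tsv", sep="\t")
        record("simulate", n_cells=int(adata.n_obs), n_genes=int(adata.n_vars))
        manifest["inputs"]["counts/matrix.mtx"] = _hash_file(
            outdir / "counts" / "matrix.mtx"
        )

        clusters = markers = None
        # ---- preprocess -----------------------------------------------
        if config.stages.get("preprocess", True):
            if config.qc_preset:
                adata = pp.qc_filter(adata, config.qc_preset)
                with open(outdir / "qc_report.json", "w") as fh:
                    json.dump(adata.uns["qc_report"], fh, indent=2)
            if config.n_per_sample:
                adata = pp.subsample_cells(
                    adata, config.n_per_sample, stage_seed(config.seed, "subsample")
                )
            pp.lognormalize(adata)
            hvg = pp.select_hvg(adata, min(config.n_hvg, adata.n_vars))
            if config.batch_center:
                pp.center_batches(adata)
                pp.scale_genes(adata, layer="lognorm_centered")
            else:
                pp.scale_genes(adata)
            emb = pp.pca(adata, config.n_pcs, genes=hvg)
            clusters = pp.cluster_cells(
                emb,
                n_neighbors=config.n_neighbors,
                resolution=config.resolution,
                seed=stage_seed(config.seed, "cluster"),
                method=config.cluster_method,
                cell_names=adata.obs_names,
            )
            clusters.labels.to_frame().to_csv(outdir / "clusters.tsv", sep="\t")
            markers = pp.find_markers(adata, clusters)
            markers.to_csv(outdir / "markers.tsv", sep="\t", index=False)
            record(
                "preprocess",
                n_cells=int(adata.n_obs),
                n_hvg=len(hvg),
                n_clusters=len(clusters.labels.cat.categories),
                modularity=clusters.modularity,
            )
        else:
            pp.lognormalize(adata)
            record("preprocess", skipped=True)

        # ---- consensus -------------------------------------------------
        if config.stages.get("consensus", True):
            rng = np.random.default_rng(stage_seed(config.seed, "consensus"))
            families = _pseudo_source_lists(truth, rng)
            signatures = {}
            for state, sources in families.items():
                atlas_sig = sg.GeneSignature(
                    f"{state}_atlas", truth.marker_assignment[state], source="atlas"
                )
                signatures[state] = sg.build_consensus(
                    sources, atlas_markers=atlas_sig, name=state
                )
            rio.write_gmt(
                {s.name: s.genes for s in signatures.values()},
                outdir / "consensus_signatures.gmt",
            )
            record(
                "consensus",
                sizes={name: len(s) for name, s in signatures.items()},
            )
        else:
            signatures = {
                state: sg.GeneSignature(state, genes)
                for state, genes in truth.marker_assignment.items()
            }
            record("consensus", skipped=True)

        # ---- score -----------------------------------------------------
        scores = None
        if config.stages.get("score", True):
            params = sc.ScoreParams(
                n_ctrl=config.n_ctrl,
                n_bins=config.n_bins,
                seed=stage_seed(config.seed, "score"),
                scale_scores=config.scale_scores,
            )
            s_sig = sg.GeneSignature("S", truth.cycle_genes["S"])
            g2m_sig = sg.GeneSignature("G2M", truth.cycle_genes["G2M"])
            scores = sc.score_states(
                adata, signatures, params, s_genes=s_sig, g2m_genes=g2m_sig
            )
            out = scores.scores.copy()
            out["cycling_class"] = scores.cycling_class
            out["sample_id"] = adata.obs["sample_id"]
            out.to_csv(outdir / "cell_scores.tsv", sep="\t")
            record("score", columns=list(scores.scores.columns))

        # ---- states ----------------------------------------------------
        table = None
        if config.stages.get("states", True) and scores is not None:
            table = st.assign_cell_states(
                scores, tau=config.tau, tau_hi=config.tau_hi,
                sample_ids=adata.obs["sample_id"],
            )
            st.composition(table)
            table.cell_state.to_frame().to_csv(outdir / "cell_states.tsv", sep="\t")
            table.composition_counts.to_csv(outdir / "composition_counts.tsv", sep="\t")
            table.composition_fractions.to_csv(
                outdir / "composition_fractions.tsv", sep="\t"
            )
            record(
                "states",
                states={
                    k: int(v) for k, v in table.cell_state.value_counts().items()
                },
            )

        # ---- devmap ----------------------------------------------------
        if config.stages.get("devmap", True) and table is not None:
            ref_cfg = dataclasses.replace(
                cfg, seed=stage_seed(config.seed, "reference"),
                n_genes=cfg.n_genes, marker_log_fold_change=cfg.marker_log_fold_change,
            )
            atlas = sim.generate_reference(ref_cfg, config.devmap_labels)
            pp.lognormalize(atlas)
            result = dm.transfer_labels(
                adata, atlas, seed=stage_seed(config.seed, "devmap")
            )
            summary = dm.summarize_mapping(result, table.cell_state)
            result.fine_label.to_frame().to_csv(outdir / "devmap_labels.tsv", sep="\t")
            summary.to_csv(outdir / "devmap_summary.tsv", sep="\t")
            record("devmap", labels=list(summary.columns))
        elif not config.stages.get("devmap", True):
            record("devmap", skipped=True)

        # ---- shift test ------------------------------------------------
        if (
            config.stages.get("shift_test", True)
            and scores is not None
            and (adata.obs["treatment_status"] == "on").any()
        ):
            psb = sc.pseudobulk_scores(scores, adata.obs["sample_id"])
            status = adata.obs.groupby("sample_id", observed=True)[
                "treatment_status"
            ].first()
            pre_samples = status[status == "pre"].index
            on_samples = status[status == "on"].index
            n = min(len(pre_samples), len(on_samples))
            results = {}
            for col in ("progenitor", "differentiated", "proliferative", "MLS"):
                if col not in psb.columns:
                    continue
                r = st.paired_shift_test(
                    psb.loc[pre_samples[:n], col].reset_index(drop=True),
                    psb.loc[on_samples[:n], col].reset_index(drop=True),
                    score_name=col,
                )
                results[col] = {
                    "statistic": r.statistic,
                    "p_value": r.p_value,
                    "direction": r.direction,
                    "n_pairs": r.n_pairs,
                }
            with open(outdir / "shift_tests.json", "w") as fh:
                json.dump(results, fh, indent=2)
            record("shift_test", scores=list(results))
        elif not config.stages.get("shift_test", True):
            record("shift_test", skipped=True)

    except Exception as exc:  # mark partial outputs, re-raise with stage context
        (outdir / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        raise

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    _write_report(outdir, manifest)
    return manifest


def _write_report(outdir: Path, manifest: dict) -> None:
    lines = ["# Pipeline run report", ""]
    for stage, info in manifest["stages"].items():
        lines.append(f"## {stage}")
        for k, v in info.items():
            lines.append(f"- {k}: {v}")
        lines.append("")
    (outdir / "report.md").write_text("\n".join(lines))
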