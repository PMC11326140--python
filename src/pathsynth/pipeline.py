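"""End-to-end pipeline runner.

Chains simulate -> preprocess -> extract -> synthesize -> compare ->
validate -> nullmodel, writing every intermediate artifact to an output
directory. Stages re-use supplied files when paths are given in the
configuration; otherwise the synthetic generator provides them. One global
seed is expanded into per-stage seeds (see ``seeds``).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

from . import io
from .comparison import kinase_network_from_edges, overlap_stats
from .errors import StageError
from .model import TemporalPathwayModel
from .nullmodels import (
    TrekingNullConfig,
    ensemble_summary,
    random_treking_ensemble,
)
from .preprocess import DEFAULT_THRESHOLD
from .seeds import stage_seed
from .subnetwork import PCSFParams
from .synthesis import DEFAULT_MAX_PATH_LEN
from .synthetic import SimulationConfig, simulate_study
from .validation import ValidationConfig, validate_treking_arm


@dataclass
class PipelineConfig:
    """Everything one run needs; file paths override synthetic inputs."""

    outdir: str = "pathsynth_out"
    seed: int = 0
    source: str | None = None  # default: the synthetic receptor
    threshold: float = DEFAULT_THRESHOLD
    max_path_len: int = DEFAULT_MAX_PATH_LEN
    n_null: int = 100
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    pcsf: PCSFParams = field(default_factory=PCSFParams)
    validation: ValidationConfig = field(default_factory=ValidationConfig)
    treking_null: TrekingNullConfig = field(default_factory=TrekingNullConfig)
    timeseries_path: str | None = None
    interactome_path: str | None = None
    partial_model_path: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                continue
            val = raw[f.name]
            if f.name == "simulation":
                val = SimulationConfig(**val)
            elif f.name == "pcsf":
                val = PCSFParams(**val)
            elif f.name == "validation":
                val = ValidationConfig(**val)
            elif f.name == "treking_null":
                val = TrekingNullConfig(**val)
            kwargs[f.name] = val
        return cls(**kwargs)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the final report dict."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed}

    # ---- simulate (always runs: supplies ground truth and validation data)
    sim_cfg = dataclasses.replace(
        cfg.simulation, seed=stage_seed(cfg.seed, "simulate")
    )
    study = simulate_study(sim_cfg)
    source = cfg.source or study.source

    data = study.dataset
    interactome = study.interactome
    pm = study.partial_model
    if cfg.timeseries_path:
        data = io.read_timeseries(cfg.timeseries_path,
                                  expect_grid=sim_cfg.time_grid)
    if cfg.interactome_path:
        interactome = io.read_interactome(cfg.interactome_path)
    if cfg.partial_model_path:
        pm = io.read_partial_model(cfg.partial_model_path)

    io.write_timeseries(data, out / "timeseries.tsv", seed=sim_cfg.seed)
    io.write_interactome(interactome, out / "interactome.tsv", seed=sim_cfg.seed)
    io.write_partial_model(pm, out / "partial_model.tsv", seed=sim_cfg.seed)
    io.write_inhibition_matrix(study.inhibition, out / "inhibition.tsv",
                               seed=sim_cfg.seed)
    io.write_screen(study.screen, out / "screen.tsv", seed=sim_cfg.seed)
    io.write_treking_model(study.treking, out / "treking_model.json")

    # ---- fit: preprocess + extract + synthesize
    try:
        model = TemporalPathwayModel(
            data, interactome, source, pm,
            threshold=cfg.threshold,
            pcsf_params=cfg.pcsf,
            max_path_len=cfg.max_path_len,
        )
        res = model.fit(seed=stage_seed(cfg.seed, "extract"))
    except Exception as e:  # noqa: BLE001 - stage boundary
        raise StageError(f"fit stage failed: {e}") from e

    io.write_scores(res.scores, out / "scores.tsv", seed=cfg.seed)
    io.write_subnetwork(res.subnetwork, out / "subnetwork.tsv", seed=cfg.seed)
    io.write_summary(res.summary, out / "summary_network.tsv", seed=cfg.seed)
    io.write_windows(res.windows, out / "activity_windows.tsv", seed=cfg.seed)

    report["fit"] = {
        "n_directed_edges": res.n_directed_edges(),
        "n_signed_edges": res.n_signed_edges(),
        "n_network_kinases": len(res.network_kinases()),
    }
    report["recovery"] = res.recovery(study.truth)

    # ---- compare against the functional kinase network fixture
    kn = res.kinase_network()
    treking_edges = [
        (u, v, "none") for u, v in study.treking.background.edges
        if u in study.truth.barrier_kinases and v in study.truth.barrier_kinases
    ]
    treking_net = kinase_network_from_edges(treking_edges) if treking_edges else None
    if treking_net is not None:
        report["comparison"] = overlap_stats(kn, treking_net)
    io.write_kinase_network(
        ((u, v, "none") for u, v in kn.edges()),
        out / "kinase_network.tsv", seed=cfg.seed,
    )

    # ---- validate both arms
    report["validation_tps"] = res.validate(
        study.inhibition, study.screen, cfg.validation
    )
    report["validation_treking"] = validate_treking_arm(
        study.treking, data, cfg.validation
    )

    # ---- null ensembles
    tps_null = res.null_ensemble(
        study.inhibition, study.screen,
        n=cfg.n_null, base_seed=stage_seed(cfg.seed, "null-tps"),
        cfg=cfg.validation,
    )
    trk_null = random_treking_ensemble(
        cfg.treking_null, study.treking, study.treking.background, data,
        n=cfg.n_null, base_seed=stage_seed(cfg.seed, "null-treking"),
        vcfg=cfg.validation, kinase_pool=sorted(interactome.kinases()),
    )
    io.write_ensemble(tps_null, out / "null_tps.tsv", seed=cfg.seed)
    io.write_ensemble(trk_null, out / "null_treking.tsv", seed=cfg.seed)
    report["null_tps"] = ensemble_summary(
        tps_null, report["validation_tps"]["accuracy"]
    )
    report["null_treking"] = ensemble_summary(
        trk_null, report["validation_treking"]["accuracy"]
    )

    io.write_report(report, out / "report.json")
    return report
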