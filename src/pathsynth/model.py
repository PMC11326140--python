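"""Model/Results interface over the reconstruction pipeline.

``TemporalPathwayModel`` bundles the inputs of one reconstruction — the
replicate fold-change time courses, the background interactome, the source
receptor and the optional directed prior — and ``fit()`` runs significance
scoring, prize-collecting subnetwork extraction and temporal pathway
synthesis, returning a ``TemporalPathwayResults`` that carries the summary
network, activity windows, scores and diagnostics. Validation, comparison
and null ensembles hang off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .comparison import kinase_subnetwork, overlap_stats
from .containers import (
    ActivityWindows,
    Interactome,
    PartialModel,
    PhosphoDataset,
    PhosphoTimeSeries,
    SubNetwork,
    SummaryNetwork,
)
from .errors import ConfigError
from .nullmodels import random_tps_ensemble
from .preprocess import DEFAULT_THRESHOLD, preprocess_dataset
from .subnetwork import PCSFParams, extract_subnetwork
from .synthesis import DEFAULT_MAX_PATH_LEN, synthesize
from .validation import ValidationConfig, validate_tps_arm


class TemporalPathwayModel:
    """Temporal pathway synthesis model for one stimulation experiment.

    Parameters
    ----------
    data : PhosphoDataset
        Replicate fold-change trajectories of the measured proteins.
    interactome : Interactome
        Background PPI + kinase-substrate network.
    source : str
        The receptor node where the stimulus enters.
    partial_model : PartialModel, optional
        Directed (optionally signed) kinase-substrate priors.
    threshold : float
        Significance threshold for the paired t-tests (default 0.05).
    pcsf_params : PCSFParams
        Subnetwork-extraction parameters.
    max_path_len : int
        Maximum edges per candidate pathway during synthesis.
    """

    def __init__(
        self,
        data: PhosphoDataset,
        interactome: Interactome,
        source: str,
        partial_model: PartialModel | None = None,
        threshold: float = DEFAULT_THRESHOLD,
        pcsf_params: PCSFParams | None = None,
        max_path_len: int = DEFAULT_MAX_PATH_LEN,
    ) -> None:
        if source not in interactome.ppi:
            raise ConfigError(f"source {source} not in interactome")
        self.data = data
        self.interactome = interactome
        self.source = source
        self.partial_model = partial_model or PartialModel()
        self.threshold = threshold
        self.pcsf_params = pcsf_params or PCSFParams()
        self.max_path_len = max_path_len

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        interactome: Interactome,
        source: str,
        **kwargs,
    ) -> "TemporalPathwayModel":
        """Build from a long DataFrame with columns
        (protein, replicate, <minute columns...>)."""
        grid = tuple(int(c) for c in frame.columns[2:])
        series = {}
        for prot, block in frame.groupby(frame.columns[0], sort=True):
            vals = block.iloc[:, 2:].to_numpy(dtype=float)
            series[prot] = PhosphoTimeSeries(str(prot), grid, vals)
        data = PhosphoDataset(grid, series)
        return cls(data, interactome, source, **kwargs)

    def fit(self, seed: int = 0) -> "TemporalPathwayResults":
        """Run scoring, extraction, and synthesis; deterministic per seed."""
        scores, profiles, prizes = preprocess_dataset(self.data, self.threshold)
        sub = extract_subnetwork(
            self.interactome, prizes, self.source, self.pcsf_params, seed
        )
        summary, windows = synthesize(
            sub, self.partial_model, profiles, self.source, self.max_path_len
        )
        return TemporalPathwayResults(
            model=self,
            seed=seed,
            scores=scores,
            profiles=profiles,
            prizes=prizes,
            subnetwork=sub,
            summary=summary,
            windows=windows,
        )


@dataclass
class TemporalPathwayResults:
    """Fitted reconstruction: networks, scores, and diagnostics."""

    model: TemporalPathwayModel
    seed: int
    scores: dict
    profiles: dict
    prizes: dict
    subnetwork: SubNetwork
    summary: SummaryNetwork
    windows: ActivityWindows

    # ------------------------------------------------------------- accessors

    def network_kinases(self) -> set[str]:
        return self.summary.nodes() & self.model.interactome.kinases()

    def n_directed_edges(self) -> int:
        return self.summary.n_edges()

    def n_signed_edges(self) -> int:
        return len(self.summary.signed_edges())

    # ------------------------------------------------------------ operations

    def kinase_network(self):
        return kinase_subnetwork(self.summary, self.model.interactome.kinases())

    def compare(self, other) -> dict:
        """Overlap statistics against a functional kinase network."""
        return overlap_stats(self.kinase_network(), other)

    def validate(self, matrix, screen, cfg: ValidationConfig | None = None) -> dict:
        """Inhibitor-based validation of the fitted network."""
        return validate_tps_arm(self.network_kinases(), matrix, screen, cfg)

    def null_ensemble(
        self,
        matrix,
        screen,
        n: int = 100,
        base_seed: int = 0,
        cfg: ValidationConfig | None = None,
    ):
        """Randomization null for the fitted network's validation accuracy."""
        return random_tps_ensemble(
            self.subnetwork,
            self.model.partial_model,
            self.model.data,
            self.scores,
            matrix,
            screen,
            self.model.interactome.kinases(),
            self.model.source,
            n=n,
            base_seed=base_seed,
            cfg=cfg,
            max_path_len=self.model.max_path_len,
            universe=sorted(self.model.interactome.nodes()),
        )

    # ------------------------------------------------------------ reporting

    def recovery(self, truth) -> dict:
        """Recall/precision of the summary against a planted cascade."""
        true_edges = {(u, v) for u, v, _ in truth.cascade_edges}
        found = set(self.summary.edges())
        tp = true_edges & found
        signed = {(u, v): s for u, v, s in self.summary.signed_edges()}
        true_signs = {(u, v): s for u, v, s in truth.cascade_edges}
        sign_errors = sum(
            1 for e, s in signed.items() if e in true_signs and true_signs[e] != s
        )
        return {
            "recall": len(tp) / len(true_edges) if true_edges else None,
            "precision": len(tp) / len(found) if found else None,
            "n_true_edges": len(true_edges),
            "n_summary_edges": len(found),
            "n_signed_edges": len(signed),
            "sign_errors": sign_errors,
        }

    def summary_table(self) -> str:
        """Human-readable fit summary."""
        measured = len(self.model.data)
        changing = sum(
            1 for p in self.profiles.values() if p.first_change() < float("inf")
        )
        lines = [
            "Temporal Pathway Synthesis Results",
            "=" * 42,
            f"source node:            {self.model.source}",
            f"measured proteins:      {measured}",
            f"responding proteins:    {changing}",
            f"subnetwork nodes:       {len(self.subnetwork.nodes())}",
            f"subnetwork edges:       {len(self.subnetwork.edges())}",
            f"summary directed edges: {self.n_directed_edges()}",
            f"summary signed edges:   {self.n_signed_edges()}",
            f"network kinases:        {len(self.network_kinases())}",
            f"significance threshold: {self.model.threshold}",
            f"max path length:        {self.model.max_path_len}",
            f"seed:                   {self.seed}",
        ]
        return "\n".join(lines)

    def plot_profiles(self, proteins=None, ax=None):
        """Mean fold-change trajectories (log2 scale) for selected proteins."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        proteins = proteins or self.model.data.proteins()[:8]
        grid = self.model.data.time_grid
        for p in proteins:
            mean = self.model.data[p].values.mean(axis=0)
            ax.plot(grid, np.log2(mean), marker="o", label=p)
        ax.axhline(0.0, color="gray", lw=0.5)
        ax.set_xlabel("minutes after stimulation")
        ax.set_ylabel("log2 fold change")
        ax.legend(fontsize=7)
        return ax
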