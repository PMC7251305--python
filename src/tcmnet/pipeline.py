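"""End-to-end pipeline: block series -> states -> networks -> comparisons.

Given per-dyad block-series tables (or a simulation section generating them),
the pipeline pools each role's features across subjects, z-scores them, fits
one K-means state model per role, prunes scarce states, estimates per-subject
transition matrices, and produces the comparison tables: pairwise matrix
correlations and DeltaCorr class summaries, per-subject transition-law
regressions with a cohort summary, occupancy-drift screens, and network
exports.  A JSON manifest records the configuration and seeds so any run is
reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coding import WordBlockSeries, load_block_series
from .compare import class_summary, correlation_panel, pair_records, records_frame
from .drift import drift_screen
from .markov import dyad_sequence, export_network, mtm, mtm_from_pairs, state_frequencies
from .regression import (
    build_design,
    centroid_distances,
    cohort_summary,
    fit_model,
    results_frame,
)
from .simulate import simulate_cohort
from .states import assign, fit_states, prune_outlier_states, standardize

log = logging.getLogger("tcmnet")

ROLES = ("patient", "therapist")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Reproducible configuration of one pipeline run."""

    out_dir: str = "tcmnet_out"
    inputs: dict | None = None  # subject_id -> {path, outcome, [delimiter]}
    simulation: dict | None = None  # kwargs of simulate.simulate_cohort
    k: int = 8
    n_restarts: int = 50
    seed: int = 0
    min_share: float = 0.01
    cell_policy: str = "both_defined"
    include_diagonal: bool = True
    drift_correction: str = "yates"
    network_format: str = "graphml"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_dict(self) -> dict:
        return {
            "out_dir": self.out_dir,
            "inputs": self.inputs,
            "simulation": self.simulation,
            "k": self.k,
            "n_restarts": self.n_restarts,
            "seed": self.seed,
            "min_share": self.min_share,
            "cell_policy": self.cell_policy,
            "include_diagonal": self.include_diagonal,
            "drift_correction": self.drift_correction,
            "network_format": self.network_format,
        }


def _load_inputs(config: RunConfig) -> list[tuple[str, str, WordBlockSeries]]:
    """Return (subject_id, outcome_class, series) per dyad."""
    if config.simulation is not None:
        sim_kwargs = dict(config.simulation)
        sim_kwargs.setdefault("seed", config.seed)
        dyads = simulate_cohort(**sim_kwargs)
        return [(d.subject_id, d.outcome, d.sim.series) for d in dyads]
    if config.inputs:
        out = []
        for subject_id, spec in config.inputs.items():
            series = load_block_series(spec["path"], spec.get("delimiter", ","))
            out.append((subject_id, spec.get("outcome", "unknown"), series))
        return out
    raise PipelineError("configuration error: neither 'inputs' nor 'simulation' given")


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the output bundle; returns a results dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        subjects = _load_inputs(config)
        results: dict = {"subjects": [s[0] for s in subjects]}

        # --- per-role pooled clustering ------------------------------------
        stage = "cluster"
        models = {}
        sequences: dict[tuple[str, str], object] = {}
        for role in ROLES:
            pooled = np.vstack([series.features(role) for _, _, series in subjects])
            Z, constants = standardize(pooled)
            model, _ = fit_states(
                Z, k=config.k, n_restarts=config.n_restarts, seed=config.seed,
                role=role, constants=constants,
            )
            offsets = np.cumsum([0] + [len(series) for _, _, series in subjects])
            for (subject_id, outcome, series), lo, hi in zip(
                subjects, offsets[:-1], offsets[1:]
            ):
                labels = assign(Z[lo:hi], model, standardized=True)
                pruned_model, seq = prune_outlier_states(
                    model, labels, min_share=config.min_share,
                    role=role, subject_id=subject_id,
                )
                sequences[(subject_id, role)] = seq
            models[role] = pruned_model
            pruned_model.to_json(out / f"model_{role}.json")
        results["active_states"] = {
            role: list(models[role].active_states) for role in ROLES
        }
        results["variance_explained"] = {
            role: models[role].variance_explained for role in ROLES
        }

        label_rows = []
        for (subject_id, role), seq in sequences.items():
            for t, s in zip(seq.block_indices, seq.labels):
                label_rows.append(
                    {"t": int(t), "subject_id": subject_id, "role": role, "state": int(s)}
                )
        pd.DataFrame(label_rows).to_csv(out / "state_sequences.csv", index=False)

        # --- per-subject transition matrices -------------------------------
        stage = "mtm"
        mtms = {}
        for subject_id, outcome, _ in subjects:
            for role in ROLES:
                T = mtm(sequences[(subject_id, role)], k=config.k)
                mtms[(subject_id, role)] = T
                T.to_csv(out / f"mtm_{subject_id}_{role}.csv")
                export_network(
                    T,
                    out / f"network_{subject_id}_{role}.{config.network_format}",
                    fmt=config.network_format,
                )
            p2t = mtm_from_pairs(
                dyad_sequence(
                    sequences[(subject_id, "patient")],
                    sequences[(subject_id, "therapist")],
                    "P2T",
                ),
                k=config.k,
                subject_id=subject_id,
                direction="P2T",
            )
            mtms[(subject_id, "P2T")] = p2t
            p2t.to_csv(out / f"mtm_{subject_id}_P2T.csv")

        # --- direct comparison ---------------------------------------------
        stage = "compare"
        panels = {}
        for key in ("patient", "therapist", "P2T"):
            mats = [mtms[(sid, key)] for sid, _, _ in subjects]
            panel, summary = correlation_panel(
                mats, ids=[sid for sid, _, _ in subjects], cell_policy=config.cell_policy
            )
            panel.to_csv(out / f"correlation_panel_{key}.csv")
            panels[key] = summary
        results["correlation"] = panels

        recs = pair_records(
            [
                (sid, outcome, mtms[(sid, "patient")], mtms[(sid, "therapist")])
                for sid, outcome, _ in subjects
            ],
            cell_policy=config.cell_policy,
        )
        records_frame(recs).to_csv(out / "deltacorr_records.csv", index=False)
        summaries = []
        results["deltacorr"] = {}
        for label in ("poor-poor", "good-good", "poor-good"):
            if sum(r.class_label == label for r in recs) >= 2:
                s = class_summary(recs, label)
                summaries.append(s)
                results["deltacorr"][label] = {
                    "n": s.n, "mean": s.mean, "sd": s.sd,
                    "min": s.minimum, "max": s.maximum,
                    "ci_low": s.ci95[0], "ci_high": s.ci95[1],
                }
        pd.DataFrame(
            [
                {
                    "class": s.class_label, "n": s.n, "mean": s.mean, "sd": s.sd,
                    "minimum": s.minimum, "maximum": s.maximum,
                    "ci_low": s.ci95[0], "ci_high": s.ci95[1],
                }
                for s in summaries
            ]
        ).to_csv(out / "deltacorr_classes.csv", index=False)

        # --- transition-law regression --------------------------------------
        stage = "fit-model"
        reg_results = {role: [] for role in ROLES}
        for subject_id, outcome, _ in subjects:
            for role in ROLES:
                seq = sequences[(subject_id, role)]
                T = mtms[(subject_id, role)]
                design = build_design(
                    T,
                    centroid_distances(models[role]),
                    state_frequencies(seq, config.k),
                    include_diagonal=config.include_diagonal,
                )
                reg_results[role].append(
                    fit_model(design, "full", subject_id=subject_id, role=role)
                )
        all_results = reg_results["patient"] + reg_results["therapist"]
        results_frame(all_results).to_csv(out / "transition_model.csv", index=False)
        summary = cohort_summary(reg_results)
        results["regression"] = {
            "by_role": summary.by_role,
            "distance_dependence_ratio": summary.distance_dependence_ratio,
        }
        pd.DataFrame(summary.by_role).T.to_csv(out / "transition_model_summary.csv")

        # --- drift screens ---------------------------------------------------
        stage = "drift"
        drift_frames = [
            drift_screen(sequences[(sid, role)], correction=config.drift_correction)
            for sid, _, _ in subjects
            for role in ROLES
        ]
        drift_all = pd.concat(drift_frames, ignore_index=True)
        drift_all.to_csv(out / "drift.csv", index=False)
        results["drift_significant"] = int(drift_all["significant"].sum())
        results["drift_tests"] = int(len(drift_all))

        stage = "manifest"
        manifest = {
            "tcmnet_version": __version__,
            "config": config.to_dict(),
            "results": results,
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=float)
        return results
    except Exception as exc:  # noqa: BLE001 — re-raise with stage context
        raise PipelineError(f"pipeline stage {stage!r} failed: {exc}") from exc
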