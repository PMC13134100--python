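"""End-to-end pipeline: simulate/load -> rotate -> contrast -> permute -> report.

Every stage derives its own seed from the master seed with a documented
counter scheme (``derive_seed``), so stages can be rerun independently and
two runs with the same config and seed produce byte-identical artifacts.
A JSON manifest records the config, seeds, stage wall times and a SHA-256
hash of every artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .accounting import scaled_group_sizes
from .cohort import CohortTable, load_cohort_csv
from .contrasts import all_contrasts, contrasts_frame, rotate_references
from .estimator import EstimatorSettings
from .panel import default_panel
from .permutation import PermutationSettings, edge_count_chisq, null_distribution
from .report import (
    demographics_table,
    group_difference_ranking,
    heatmap_matrix,
    proportion_table,
    proportion_table_markdown,
)
from .synthetic import build_truth, sample_cohort

log = logging.getLogger(__name__)

# stage counters for seed derivation (fixed; part of the reproducibility contract)
STAGE_COUNTERS = {"truth": 0, "cohort": 1, "permute": 2}


def derive_seed(master: int, stage: str) -> int:
    """Deterministic per-stage sub-seed: SeedSequence([master, counter])."""
    counter = STAGE_COUNTERS[stage]
    state = np.random.SeedSequence([int(master), counter]).generate_state(1)[0]
    return int(state) & 0x7FFFFFFF


@dataclass
class SyntheticSpec:
    """Synthetic-cohort scenario: groups, sizes, planted effects."""

    G: int = 11
    total_n: int = 4000  # split into unbalanced groups mirroring the template
    group_sizes: dict | None = None  # explicit sizes override total_n
    n_planted_mean: int = 6
    n_planted_edge: int = 4
    effect_mean: float = 0.4
    effect_edge: float = 0.2
    density: float = 0.15
    ordinal: bool = True

    def sizes(self) -> list[int]:
        if self.group_sizes is not None:
            return [int(v) for v in self.group_sizes.values()]
        if self.G == 11:
            return list(scaled_group_sizes(self.total_n).values())
        # unbalanced split: proportional to a geometric taper, min 2
        weights = np.geomspace(1.0, 0.25, self.G)
        raw = weights / weights.sum() * self.total_n
        return [max(2, int(round(v))) for v in raw]


@dataclass
class RunConfig:
    """Everything one run needs; nested settings validate themselves."""

    outdir: str = "results/run"
    seed: int = 0
    cohort_csv: str | None = None  # when set, synthetic is ignored
    synthetic: SyntheticSpec = field(default_factory=SyntheticSpec)
    estimator: EstimatorSettings = field(default_factory=EstimatorSettings)
    permutation: PermutationSettings | None = field(
        default_factory=lambda: PermutationSettings(B=100)
    )
    alpha: float = 0.05

    @classmethod
    def from_dict(cls, obj: dict) -> "RunConfig":
        kwargs = dict(obj)
        if "synthetic" in kwargs and isinstance(kwargs["synthetic"], dict):
            kwargs["synthetic"] = SyntheticSpec(**kwargs["synthetic"])
        if "estimator" in kwargs and isinstance(kwargs["estimator"], dict):
            est = dict(kwargs["estimator"])
            if est.get("lambda_path") is not None:
                est["lambda_path"] = tuple(est["lambda_path"])
            kwargs["estimator"] = EstimatorSettings(**est)
        if "permutation" in kwargs and isinstance(kwargs["permutation"], dict):
            kwargs["permutation"] = PermutationSettings(**kwargs["permutation"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class PipelineRun:
    """Holds the run directory and accumulates the manifest."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest = {
            "config": config.to_dict(),
            "seed": config.seed,
            "stage_seeds": {s: derive_seed(config.seed, s) for s in STAGE_COUNTERS},
            "stages": {},
            "artifacts": {},
        }

    def record(self, stage: str, seconds: float, info: dict | None = None) -> None:
        self.manifest["stages"][stage] = {"wall_s": round(seconds, 3), **(info or {})}

    def add_artifact(self, path: Path) -> None:
        self.manifest["artifacts"][path.name] = _sha256(path)

    def write_manifest(self) -> Path:
        path = self.outdir / "manifest.json"
        with open(path, "w") as fh:
            json.dump(self.manifest, fh, indent=1, default=str)
        return path


def get_cohort(config: RunConfig, run: PipelineRun | None = None) -> CohortTable:
    """Simulate (or load) the cohort; writes cohort.csv and truth.json."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    if config.cohort_csv:
        cohort = load_cohort_csv(config.cohort_csv, default_panel())
        truth = None
    else:
        spec = config.synthetic
        truth = build_truth(
            G=spec.G,
            n_planted_mean=spec.n_planted_mean,
            n_planted_edge=spec.n_planted_edge,
            effect_mean=spec.effect_mean,
            effect_edge=spec.effect_edge,
            density=spec.density,
            seed=derive_seed(config.seed, "truth"),
        )
        cohort = sample_cohort(
            truth,
            spec.sizes(),
            ordinal=spec.ordinal,
            seed=derive_seed(config.seed, "cohort"),
        )
        truth.to_json(outdir / "truth.json")
    cohort.to_csv(outdir / "cohort.csv")
    if run is not None:
        run.record(
            "cohort", time.time() - t0,
            {"n": cohort.n, "group_sizes": cohort.group_sizes},
        )
        run.add_artifact(outdir / "cohort.csv")
        if truth is not None:
            run.add_artifact(outdir / "truth.json")
    return cohort


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the manifest (also written to disk)."""
    run = PipelineRun(config)
    outdir = run.outdir

    cohort = get_cohort(config, run)

    # rotation ensemble
    t0 = time.time()
    ensemble = rotate_references(cohort, config.estimator)
    fits_summary = {
        g: {
            "selected_lambdas": [f.selected_lambda for f in fit.node_fits],
            "edge_counts": fit.edge_counts().tolist(),
        }
        for g, fit in ensemble.fits.items()
    }
    with open(outdir / "fits.json", "w") as fh:
        json.dump(fits_summary, fh, indent=1)
    edges = pd.concat(
        [pd.DataFrame(ensemble.fits[g].edge_list()) for g in ensemble.groups],
        ignore_index=True,
    )
    edges.to_csv(outdir / "edges.csv", index=False)
    run.record("fit", time.time() - t0, {"groups": ensemble.groups})
    run.add_artifact(outdir / "fits.json")
    run.add_artifact(outdir / "edges.csv")

    # contrasts
    t0 = time.time()
    contrasts = all_contrasts(ensemble)
    run.record("contrast", time.time() - t0, {"n_pairs": len(contrasts)})

    # permutation inference
    if config.permutation is not None:
        t0 = time.time()
        psettings = PermutationSettings(
            B=config.permutation.B,
            seed=derive_seed(config.seed, "permute"),
            alpha=config.alpha,
        )
        contrasts, dist = null_distribution(
            cohort, config.estimator, psettings, ensemble=ensemble, contrasts=contrasts
        )
        dist.aggregate_pvalues.to_csv(outdir / "aggregate_pvalues.csv")
        perm_manifest = {
            "B": psettings.B,
            "seed": psettings.seed,
            "alpha": psettings.alpha,
            "statuses": dist.statuses,
        }
        with open(outdir / "permutation_manifest.json", "w") as fh:
            json.dump(perm_manifest, fh, indent=1)
        run.record("permute", time.time() - t0, {"B": psettings.B})
        run.add_artifact(outdir / "aggregate_pvalues.csv")
        run.add_artifact(outdir / "permutation_manifest.json")

    contrasts_frame(contrasts).to_csv(outdir / "contrasts.csv", index=False)
    run.add_artifact(outdir / "contrasts.csv")

    # reports
    t0 = time.time()
    for kind in ("intercept", "edge"):
        table = proportion_table(contrasts, kind, alpha=config.alpha)
        table.proportions.to_csv(outdir / f"proportions_{kind}.csv")
        table.counts.to_csv(outdir / f"counts_{kind}.csv")
        with open(outdir / f"proportions_{kind}.md", "w") as fh:
            fh.write(proportion_table_markdown(table))
        heat = heatmap_matrix(contrasts, kind, alpha=config.alpha)
        heat.to_csv(outdir / f"heatmap_{kind}.csv")
        for name in (
            f"proportions_{kind}.csv",
            f"counts_{kind}.csv",
            f"proportions_{kind}.md",
            f"heatmap_{kind}.csv",
        ):
            run.add_artifact(outdir / name)
    ranking = group_difference_ranking(proportion_table(contrasts, "intercept", config.alpha))
    ranking.to_csv(outdir / "ranking_intercept.csv", index=False)
    demographics_table(cohort).to_csv(outdir / "demographics.csv", index=False)
    chisq = edge_count_chisq(ensemble)
    with open(outdir / "edge_count_chisq.json", "w") as fh:
        json.dump(chisq, fh, indent=1)
    run.record("report", time.time() - t0)
    for name in ("ranking_intercept.csv", "demographics.csv", "edge_count_chisq.json"):
        run.add_artifact(outdir / name)

    run.write_manifest()
    run.add_artifact(outdir / "manifest.json")  # hash of everything else
    return run.manifest
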