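"""End-to-end orchestration: phantoms -> metrics -> cohort -> survival report.

A run is fully described by one JSON config plus a global seed; the emitted
manifest (config hash, seed, package version, file list) suffices to
reproduce every output byte-for-byte (CSV) or to floating tolerance (fits).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort_sim import CohortSpec, generate_cohort, write_cohort_csv
from .errors import PetHeteroError
from .io import write_parameters_csv
from .pet_metrics import BoundingBox, compute_all_parameters
from .phantom import PhantomSpec, make_phantom
from .survival_stats import (
    compare_groups,
    cox_fit,
    km_estimate,
    optimal_cutoff_roc,
)

logger = logging.getLogger(__name__)

COVARIATES = ["n_positive", "nerve_invasion", "tumor_thrombus", "hi_1"]


@dataclass(frozen=True)
class RunConfig:
    """Parameters of one pipeline run; everything has a reproducible default."""

    seed: int = 0
    out_dir: str = "pet_hetero_run"
    log_level: str = "INFO"
    n_phantoms: int = 20
    phantom: dict = field(default_factory=dict)  # PhantomSpec overrides
    cohort: dict = field(default_factory=dict)  # CohortSpec overrides
    multivariate_alpha: float = 0.05  # univariate gate into the multivariate model

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def canonical_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


def _phantom_stage(config: RunConfig, out: Path) -> Path:
    """Randomized linear-decay phantoms measured by the metrics pipeline."""
    rng = np.random.default_rng(config.seed)
    params, ids = [], []
    for i in range(config.n_phantoms):
        overrides = dict(config.phantom)
        spec = PhantomSpec(
            radius_mm=float(rng.uniform(10.0, 24.0)),
            profile="linear_decay",
            s_peak=float(rng.uniform(6.0, 15.0)),
            spacing_mm=(2.0, 2.0, 2.0),
            extent_mm=(64.0, 64.0, 64.0),
            seed=int(rng.integers(0, 2**31 - 1)),
            **overrides,
        )
        volume = make_phantom(spec)
        params.append(compute_all_parameters(volume, BoundingBox.whole(volume)))
        ids.append(i + 1)
    path = out / "phantom_parameters.csv"
    write_parameters_csv(params, path, ids=ids)
    return path


def _survival_stage(config: RunConfig, cohort: pd.DataFrame, out: Path) -> list[Path]:
    paths = []

    comparisons = compare_groups(cohort, COVARIATES, group_flag="event")
    comp_frame = pd.DataFrame(
        [
            {
                "variable": c.variable,
                "test_used": c.test_used,
                "statistic": c.statistic,
                "p": c.p,
                "normality_p": c.normality_p,
            }
            for c in comparisons
        ]
    )
    paths.append(out / "group_comparisons.csv")
    comp_frame.to_csv(paths[-1], index=False)

    uni_rows, significant = [], []
    for name in COVARIATES:
        res = cox_fit(cohort, [name])
        cov = res[name]
        uni_rows.append(
            {"covariate": name, "hr": cov.hr, "ci_low": cov.ci95[0],
             "ci_high": cov.ci95[1], "p": cov.p}
        )
        if cov.p < config.multivariate_alpha:
            significant.append(name)
    paths.append(out / "cox_univariate.csv")
    pd.DataFrame(uni_rows).to_csv(paths[-1], index=False)

    # covariates significant in univariate analysis enter the multivariate model
    multi_covs = significant if len(significant) >= 1 else COVARIATES
    multi = cox_fit(cohort, multi_covs)
    multi_frame = pd.DataFrame(
        [
            {"covariate": c.name, "hr": c.hr, "ci_low": c.ci95[0],
             "ci_high": c.ci95[1], "p": c.p}
            for c in multi.covariates
        ]
    )
    paths.append(out / "cox_multivariate.csv")
    multi_frame.to_csv(paths[-1], index=False)

    cut = optimal_cutoff_roc(cohort["hi_1"], cohort["event"])
    paths.append(out / "hi1_cutoff.csv")
    pd.DataFrame(
        [{"marker": "hi_1", "cutoff": cut.cutoff, "sensitivity": cut.sensitivity,
          "specificity": cut.specificity, "youden_j": cut.youden_j, "auc": cut.auc}]
    ).to_csv(paths[-1], index=False)

    km_rows = []
    for label, mask in [
        ("hi_1_high", cohort["hi_1"] >= cut.cutoff),
        ("hi_1_low", cohort["hi_1"] < cut.cutoff),
        ("n_positive", cohort["n_positive"] == 1),
        ("n_negative", cohort["n_positive"] == 0),
    ]:
        sub = cohort[mask]
        if len(sub) == 0 or sub["event"].sum() == 0:
            continue
        curve = km_estimate(sub["dfs_months"], sub["event"])
        for t, r, d, s in zip(curve.event_times, curve.at_risk, curve.events,
                              curve.survival):
            km_rows.append({"group": label, "time_months": t, "at_risk": r,
                            "events": d, "survival": s})
    paths.append(out / "km_curves.csv")
    pd.DataFrame(km_rows).to_csv(paths[-1], index=False)
    return paths


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest written to the output dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    handler = logging.FileHandler(out / "run.log", mode="w")
    logging.getLogger("pet_hetero").addHandler(handler)
    outputs = []
    try:
        outputs.append(_phantom_stage(config, out))

        cohort_spec = CohortSpec(seed=config.seed, **config.cohort)
        cohort = generate_cohort(cohort_spec)
        cohort_path = out / "cohort.csv"
        write_cohort_csv(cohort, cohort_path)
        outputs.append(cohort_path)

        outputs.extend(_survival_stage(config, cohort, out))
    except PetHeteroError as err:
        logger.error("STAGE_FAILURE %s: %s", type(err).__name__, err)
        raise
    finally:
        logging.getLogger("pet_hetero").removeHandler(handler)
        handler.close()

    manifest = {
        "config": json.loads(config.canonical_json()),
        "config_sha256": hashlib.sha256(config.canonical_json().encode()).hexdigest(),
        "seed": config.seed,
        "version": __version__,
        "outputs": [p.name for p in outputs],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
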