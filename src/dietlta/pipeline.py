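"""End-to-end orchestration: prepare -> fit -> select -> usual prevalence -> report.

The pipeline mirrors the two-branch analysis design: (a) a latent class
model on day-averaged intake and (b) a latent transition model on the two
recall days, both with age and sex as concomitant variables, followed by
the Markov usual-prevalence step on the fitted transition probabilities.
Every run writes a manifest with the exact configuration and seeds so the
outputs can be regenerated.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import data_prep
from .latent_class import FitResult, LCAParams, class_profile_table, lca_posterior
from .latent_transition import (LTAParams, aggregate_transition_matrix,
                                membership_odds_ratios, transition_matrix_grid)
from .markov import propagate, usual_prevalence
from .model_selection import fit_grid

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a pipeline run depends on; serialized into the manifest."""

    recalls_csv: str
    covariates_csv: str
    out_dir: str
    nil_threshold: float = 0.95
    lca_k_range: list[int] = field(default_factory=lambda: [1, 2, 3, 4, 5, 6, 7])
    lta_k_range: list[int] = field(default_factory=lambda: [2, 3])
    n_starts: int = 20
    seed: int = 1
    tol: float = 1e-8
    max_iter: int = 1000
    constrain_covariates: bool = True
    compute_odds_ratios: bool = True
    age_grid: list[float] = field(default_factory=lambda: list(range(18, 85, 2)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs and logs are preserved."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def save_fit(fit: FitResult, path: str | Path) -> None:
    """Persist a fit as JSON: parameters, indices, per-start bookkeeping."""
    payload = {
        "params": fit.params.to_dict(),
        "loglik": fit.loglik, "aic": fit.aic, "bic": fit.bic,
        "relative_entropy": fit.relative_entropy, "n_params": fit.n_params,
        "converged": fit.converged, "n_iter": fit.n_iter, "seed": fit.seed,
        "start_logliks": fit.start_logliks, "best_start": fit.best_start,
        "warnings": fit.warnings,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_params(path: str | Path):
    """Reload fitted parameters from a fit JSON."""
    d = json.loads(Path(path).read_text())["params"]
    return LCAParams.from_dict(d) if d["model"] == "lca" else LTAParams.from_dict(d)


def load_recalls(path: str | Path) -> pd.DataFrame:
    """Read a recalls CSV in either long or wide layout."""
    df = pd.read_csv(path)
    if set(data_prep.INTAKE_COLUMNS) <= set(df.columns):
        return df[data_prep.INTAKE_COLUMNS]
    return data_prep.wide_to_long(df)


def _write_matrix_csv(P: np.ndarray, path: Path, labels: list[str]) -> None:
    pd.DataFrame(P, index=labels, columns=labels).rename_axis("from").to_csv(path)


def prepare_stage(recalls: pd.DataFrame, nil_threshold: float, out: Path) -> dict:
    """Filtering, ICC, and ordinal coding for both analysis branches."""
    recalls = data_prep.require_complete_cases(recalls)
    filtered, report = data_prep.filter_rare_food_groups(recalls, nil_threshold)
    icc = data_prep.compute_icc(filtered)
    ordinal_both, median_map = data_prep.categorize_intake(filtered)
    averaged = data_prep.average_days(filtered)
    ordinal_avg, median_map_avg = data_prep.categorize_intake(averaged)

    out.mkdir(parents=True, exist_ok=True)
    ordinal_both.to_csv(out / "ordinal_two_day.csv", index=False)
    ordinal_avg.to_csv(out / "ordinal_averaged.csv", index=False)
    icc.to_csv(out / "icc.csv")
    (out / "prepare_report.json").write_text(json.dumps({
        "exclusion": report.to_dict(),
        "median_map_two_day": median_map,
        "median_map_averaged": median_map_avg,
    }, indent=2))
    return {"ordinal_two_day": ordinal_both, "ordinal_averaged": ordinal_avg,
            "icc": icc, "exclusion": report}


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis and write all report tables.

    Returns the run directory. Any stage failure raises :class:`StageError`
    naming the stage; whatever was written before the failure remains on
    disk together with the manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "manifest.json").write_text(json.dumps(config.to_dict(), indent=2))

    stage = "prepare"
    try:
        recalls = load_recalls(config.recalls_csv)
        covariates = pd.read_csv(config.covariates_csv)
        prep = prepare_stage(recalls, config.nil_threshold, out)

        stage = "fit_lca"
        lca_table, lca_fit = fit_grid(
            prep["ordinal_averaged"], covariates, "lca", config.lca_k_range,
            n_starts=config.n_starts, seed=config.seed, tol=config.tol,
            max_iter=config.max_iter)
        lca_table.to_csv(out / "selection_lca.csv", index=False)
        save_fit(lca_fit, out / "fit_lca.json")
        class_profile_table(prep["ordinal_averaged"], lca_fit.posterior).to_csv(
            out / "profile_lca.csv", index=False)

        stage = "fit_lta"
        lta_table, lta_fit = fit_grid(
            prep["ordinal_two_day"], covariates, "lta", config.lta_k_range,
            n_starts=config.n_starts, seed=config.seed, tol=config.tol,
            max_iter=config.max_iter,
            constrain_covariate_effects=config.constrain_covariates)
        lta_table.to_csv(out / "selection_lta.csv", index=False)
        save_fit(lta_fit, out / "fit_lta.json")
        class_profile_table(prep["ordinal_two_day"], lta_fit.posterior, day=1).to_csv(
            out / "profile_lta.csv", index=False)

        stage = "prevalence"
        K = lta_fit.K
        labels = [f"DP{k + 1}" for k in range(K)]
        P_agg = aggregate_transition_matrix(lta_fit, covariates)
        _write_matrix_csv(P_agg, out / "transition_aggregate.csv", labels)

        prev = usual_prevalence(lta_fit, covariates, mode="individual")
        prev_agg = usual_prevalence(lta_fit, covariates, mode="aggregate")
        # report S2 by one-step propagation of S1 through the aggregate matrix
        s2_prop = propagate(prev.s1, P_agg, 2)
        prev_frame = prev.to_frame()
        prev_frame["day2_propagated"] = s2_prop
        prev_frame["usual_aggregate_mode"] = prev_agg.usual
        prev_frame.to_csv(out / "prevalence.csv", index=False)

        stage = "transition_curves"
        curves = []
        for sex in (0, 1):
            grid = transition_matrix_grid(lta_fit.params, config.age_grid,
                                          [sex] * len(config.age_grid))
            for a_idx, age in enumerate(config.age_grid):
                for k in range(K):
                    for l in range(K):
                        curves.append({"age": age, "sex": sex,
                                       "from": labels[k], "to": labels[l],
                                       "probability": grid[a_idx, k, l]})
        pd.DataFrame(curves).to_csv(out / "transition_curves.csv", index=False)

        or_table = None
        if config.compute_odds_ratios:
            stage = "odds_ratios"
            or_table = membership_odds_ratios(lta_fit, prep["ordinal_two_day"],
                                              covariates, seed=config.seed)
            or_table.to_csv(out / "odds_ratios.csv", index=False)

        stage = "report"
        _write_summary(out, config, lca_table, lta_table, lca_fit, lta_fit,
                       P_agg, prev_frame, or_table)
    except StageError:
        raise
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        raise StageError(stage, exc) from exc
    return out


def _write_summary(out, config, lca_table, lta_table, lca_fit, lta_fit,
                   P_agg, prev_frame, or_table) -> None:
    K = lta_fit.K
    lines = [
        "# Dietary-pattern run summary", "",
        f"Seed: {config.seed}; starts per fit: {config.n_starts}", "",
        "## Model selection (latent class, averaged days)", "",
        lca_table.to_string(index=False), "",
        "## Model selection (latent transition, two days)", "",
        lta_table.to_string(index=False), "",
        f"Selected: {lca_fit.K}-class latent class model, "
        f"{K}-class latent transition model.", "",
        "## Aggregate day-to-day transition matrix", "",
        pd.DataFrame(P_agg,
                     index=[f"DP{k + 1}" for k in range(K)],
                     columns=[f"DP{k + 1}" for k in range(K)]).to_string(), "",
        "Diagonal entries are the probabilities of following the same",
        "dietary pattern on both recall days.", "",
        "## Prevalence (day 1, day 2, usual)", "",
        prev_frame.to_string(index=False), "",
        "Usual prevalence is the covariate-averaged stationary distribution",
        "of the fitted transition probabilities (individual mode).", "",
    ]
    if or_table is not None:
        lines += ["## Membership odds ratios (day-1 logit, vs last class)", "",
                  or_table.to_string(index=False), ""]
    (out / "summary.md").write_text("\n".join(lines))
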