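"""Model-recovery and parameter-recovery simulation harnesses.

Model recovery: simulate cohorts with each candidate model as generator,
fit all candidates to each cohort, run random-effects model selection, and
assemble the model-frequency rows into a confusion matrix. The minimal
recovery criterion is that every generating model is the most frequently
selected model on its own data (row argmax on the diagonal).

Parameter recovery: simulate a cohort from one model with known parameter
draws, re-fit that model, and correlate generating against recovered
values; same-parameter correlations should be strongly positive and
cross-parameter correlations near zero. For the test phase, learning
behavior is generated first (by the winning learning model), beliefs are
frozen, and only test choices are fitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bms import rfx_bms
from .cohort import (
    BehaviorDataset,
    ParameterSampler,
    decider_sampler,
    default_sampler,
    generate_cohort,
)
from .designs import ExperimentDesign
from .fitting import fit_dataset
from .models import MODEL_IDS, model_param_names

WINNING_LEARNING_MODEL = "kalman:qu"


@dataclass
class ConfusionMatrix:
    """Rows: generating model; columns: fitted model; entries: frequencies."""

    table: pd.DataFrame
    n_virtual: int
    phase: str

    def row_argmax_on_diagonal(self) -> bool:
        return all(self.table.loc[m].idxmax() == m for m in self.table.index)


@dataclass
class RecoveryReport:
    model_id: str
    phase: str
    params: pd.DataFrame  # per subject: generating + recovered values
    correlations: pd.DataFrame  # generating (rows) x recovered (cols), Pearson r
    sampler_spec: dict

    def diagonal(self) -> dict:
        return {
            n: float(self.correlations.loc[n, n]) for n in self.correlations.index
        }


def run_model_recovery(
    models=MODEL_IDS,
    n_virtual: int = 50,
    design: ExperimentDesign | None = None,
    phase: str = "learning",
    seed: int = 0,
    n_restarts: int = 10,
) -> ConfusionMatrix:
    """Confusion matrix of model frequencies, generating x fitted."""
    from .designs import make_main_design

    design = design or make_main_design()
    models = list(models)
    rows = {}
    for g_idx, gen_model in enumerate(models):
        cohort_seed = int(np.random.default_rng([seed, 101, g_idx]).integers(2**31))
        if phase == "test":
            # learning behavior comes from the winning learning model; the
            # candidate generating model produces the test choices only
            cohort = generate_cohort(
                n_virtual,
                WINNING_LEARNING_MODEL,
                design,
                seed=cohort_seed,
                test_sampler=decider_sampler(default_sampler(gen_model), gen_model),
                test_model_id=gen_model,
            )
        else:
            cohort = generate_cohort(n_virtual, gen_model, design, seed=cohort_seed)
        lme = np.empty((n_virtual, len(models)))
        for f_idx, fit_model in enumerate(models):
            fits = fit_dataset(
                cohort,
                fit_model,
                phase=phase,
                n_restarts=n_restarts,
                seed=int(np.random.default_rng([seed, 202, g_idx, f_idx]).integers(2**31)),
            )
            lme[:, f_idx] = fits["log_evidence"].to_numpy()
        result = rfx_bms(lme, model_ids=models, seed=int(seed) + g_idx)
        rows[gen_model] = result.model_frequencies
    table = pd.DataFrame.from_dict(rows, orient="index", columns=models)
    table.index.name = "generating"
    table.columns.name = "fitted"
    return ConfusionMatrix(table=table, n_virtual=n_virtual, phase=phase)


def run_parameter_recovery(
    model_id: str,
    n_virtual: int = 50,
    design: ExperimentDesign | None = None,
    phase: str = "learning",
    seed: int = 0,
    sampler: ParameterSampler | None = None,
    n_restarts: int = 10,
    learning_model: str = WINNING_LEARNING_MODEL,
) -> RecoveryReport:
    """Generating-vs-recovered parameter correlations for one model.

    For ``phase='test'`` the learning behavior is generated by
    ``learning_model`` and only the test choices are re-fitted; the
    recovered parameters are then the model's free parameters of the
    test-phase fit (decision weights, plus any learner parameters).
    """
    from .designs import make_main_design

    design = design or make_main_design()
    if not model_param_names(model_id):
        raise ValueError(f"{model_id} has no free parameters to recover")
    sampler = sampler or default_sampler(model_id)

    if phase == "learning":
        cohort = generate_cohort(
            n_virtual, model_id, design, seed=seed, sampler=sampler, include_test=False
        )
        truth_key = "learning"
    elif phase == "test":
        cohort = generate_cohort(
            n_virtual,
            learning_model,
            design,
            seed=seed,
            sampler=default_sampler(learning_model),
            test_sampler=decider_sampler(sampler, model_id),
            test_model_id=model_id,
        )
        truth_key = "test"
    else:
        raise ValueError(f"unknown phase {phase!r}")

    fits = fit_dataset(
        cohort,
        model_id,
        phase=phase,
        n_restarts=n_restarts,
        seed=int(np.random.default_rng([seed, 303]).integers(2**31)),
    )

    names = list(model_param_names(model_id))
    truth = cohort.manifest["true_params"]
    recovered_names = [n for n in names if f"param_{n}" in fits.columns]
    gen_names = [n for n in names if n in next(iter(truth.values()))[truth_key]]

    records = []
    for _, row in fits.iterrows():
        rec = {"subject": row["subject"]}
        for n in gen_names:
            rec[f"gen_{n}"] = truth[row["subject"]][truth_key][n]
        for n in recovered_names:
            rec[f"rec_{n}"] = row[f"param_{n}"]
        records.append(rec)
    params = pd.DataFrame(records)

    corr = pd.DataFrame(index=gen_names, columns=recovered_names, dtype=float)
    for g in gen_names:
        for r in recovered_names:
            corr.loc[g, r] = float(
                np.corrcoef(params[f"gen_{g}"], params[f"rec_{r}"])[0, 1]
            )
    corr.index.name = "generating"
    corr.columns.name = "recovered"
    return RecoveryReport(
        model_id=model_id,
        phase=phase,
        params=params,
        correlations=corr,
        sampler_spec=sampler.to_dict(),
    )
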