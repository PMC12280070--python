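"""Model-agnostic behavioral analyses.

Learning performance (proportion of Good choices per pair/condition),
sampling rates (which, under partial feedback, equal learning performance
for Good options and its complement for Bad options), test-phase selection
rates per pair type and pairwise comparison, performance-selection
correlations, and a permutation test for differences between correlation
coefficients with a standardized effect size:

    SES = (dr_actual - mean(dr_permuted)) / std(dr_permuted)

where dr = r(actual, fitted_A) - r(actual, fitted_B) and the null is built
by shuffling the actual-behavior vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import BehaviorDataset


# ---------------------------------------------------------------------------
# learning phase
# ---------------------------------------------------------------------------

def learning_performance(dataset: BehaviorDataset) -> pd.DataFrame:
    """Proportion of Good choices per subject x pair (with condition labels)."""
    design = dataset.design
    df = dataset.trials[dataset.trials["phase"] == "learning"]
    if df.empty:
        raise ValueError("no learning-phase trials")
    good = {p.pair_id: p.good_id for p in design.learning_pairs}
    cond = {p.pair_id: p.condition_id for p in design.learning_pairs}
    out = (
        df.assign(is_good=df["choice"] == df["pair_id"].map(good))
        .groupby(["subject", "pair_id"], as_index=False)
        .agg(n_trials=("is_good", "size"), performance=("is_good", "mean"))
    )
    out["condition"] = out["pair_id"].map(cond)
    return out


def condition_performance(dataset: BehaviorDataset) -> pd.DataFrame:
    """Mean learning performance per subject x condition."""
    per_pair = learning_performance(dataset)
    return per_pair.groupby(["subject", "condition"], as_index=False).agg(
        performance=("performance", "mean")
    )


def sampling_rates(dataset: BehaviorDataset) -> pd.DataFrame:
    """Per subject x pair: sampling rate of the Good and the Bad option.

    Exactly performance and 1 - performance, by the definition of
    learning performance under partial feedback.
    """
    per_pair = learning_performance(dataset)
    per_pair = per_pair.rename(columns={"performance": "rate_good"})
    per_pair["rate_bad"] = 1.0 - per_pair["rate_good"]
    return per_pair


# ---------------------------------------------------------------------------
# test phase
# ---------------------------------------------------------------------------

def _pair_reference(design, option_a: str, option_b: str) -> str:
    """The designated reference option of a test pair: the higher-EV one."""
    ev_a = design.option_expected_value(option_a)
    ev_b = design.option_expected_value(option_b)
    return option_a if ev_a >= ev_b else option_b


def test_selection_rates(dataset: BehaviorDataset) -> pd.DataFrame:
    """Selection rate of the reference option per subject x unique test pair.

    The reference is the Good option in Good-vs-Bad pairs and the option
    from the higher-expected-value condition in Good-vs-Good and
    Bad-vs-Bad pairs (the same rule: highest true expected value).
    Columns identify the pair type and the two options' conditions.
    """
    design = dataset.design
    df = dataset.trials[dataset.trials["phase"] == "test"]
    if df.empty:
        raise ValueError("no test-phase trials")
    rows = []
    grouped = df.groupby(["subject", "pair_id"])
    for (subject, pair_id), g in grouped:
        a = g["option_left"].iloc[0]
        b = g["option_right"].iloc[0]
        ref = _pair_reference(design, a, b)
        other = b if ref == a else a
        rows.append(
            {
                "subject": subject,
                "pair_id": pair_id,
                "pair_type": g["pair_type"].iloc[0],
                "reference": ref,
                "other": other,
                "condition_ref": design.option_condition(ref).condition_id,
                "condition_other": design.option_condition(other).condition_id,
                "block": design.option_pair(ref).block,
                "n_trials": len(g),
                "rate": float((g["choice"] == ref).mean()),
            }
        )
    return pd.DataFrame(rows)


def pairwise_selection_table(dataset: BehaviorDataset) -> pd.DataFrame:
    """GvG/BvB pairwise comparisons joined with performance differences.

    One row per subject x condition pair x pair type, averaging over
    blocks: the selection rate of the higher-value condition's option and
    the subject's difference in learning performance between the two
    conditions (higher minus lower).
    """
    design = dataset.design
    rates = test_selection_rates(dataset)
    rates = rates[rates["pair_type"].isin(["GvG", "BvB"])]
    perf = condition_performance(dataset).set_index(["subject", "condition"])["performance"]
    agg = rates.groupby(
        ["subject", "pair_type", "condition_ref", "condition_other"], as_index=False
    ).agg(rate=("rate", "mean"))
    agg["perf_ref"] = [
        perf[(s, c)] for s, c in zip(agg["subject"], agg["condition_ref"])
    ]
    agg["perf_other"] = [
        perf[(s, c)] for s, c in zip(agg["subject"], agg["condition_other"])
    ]
    agg["delta_performance"] = agg["perf_ref"] - agg["perf_other"]
    return agg


def perf_selection_correlations(dataset: BehaviorDataset) -> pd.DataFrame:
    """Correlations between learning performance and test-phase selection.

    Per condition for Good-vs-Bad pairs (performance vs Good-selection
    rate) and per pairwise comparison for Good-vs-Good / Bad-vs-Bad pairs
    (performance difference vs selection rate of the higher-value
    condition's option), plus rows pooled by pair type. Both Pearson and
    Spearman coefficients are reported; zero-variance cells are flagged.
    """
    rows = []

    def corr_row(x, y, **labels):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        degenerate = bool(np.std(x) == 0 or np.std(y) == 0 or len(x) < 3)
        if degenerate:
            pearson = spearman = p_pearson = p_spearman = np.nan
        else:
            pearson, p_pearson = stats.pearsonr(x, y)
            spearman, p_spearman = stats.spearmanr(x, y)
        rows.append(
            dict(
                labels,
                n=len(x),
                pearson=pearson,
                p_pearson=p_pearson,
                spearman=spearman,
                p_spearman=p_spearman,
                degenerate=degenerate,
            )
        )

    # GvB: performance vs Good selection rate, per condition
    rates = test_selection_rates(dataset)
    gvb = rates[rates["pair_type"] == "GvB"]
    if not gvb.empty:
        perf = condition_performance(dataset)
        agg = gvb.groupby(["subject", "condition_ref"], as_index=False).agg(
            rate=("rate", "mean")
        )
        merged = agg.merge(
            perf, left_on=["subject", "condition_ref"], right_on=["subject", "condition"]
        )
        for cond, g in merged.groupby("condition_ref"):
            corr_row(g["performance"], g["rate"], pair_type="GvB", comparison=cond)

    # GvG / BvB: per pairwise comparison and pooled
    table = pairwise_selection_table(dataset)
    for (ptype, c_ref, c_other), g in table.groupby(
        ["pair_type", "condition_ref", "condition_other"]
    ):
        corr_row(
            g["delta_performance"],
            g["rate"],
            pair_type=ptype,
            comparison=f"{c_ref}|{c_other}",
        )
    for ptype, g in table.groupby("pair_type"):
        corr_row(g["delta_performance"], g["rate"], pair_type=ptype, comparison="pooled")
    return pd.DataFrame(rows)


def bias_vs_value_entropy(dataset: BehaviorDataset) -> pd.DataFrame:
    """Group-level pairwise selection bias against delta-EV and delta-entropy.

    For each GvG/BvB condition pair: the cohort-mean selection rate of the
    higher-value option, the difference in true expected values, and the
    difference in outcome entropies (nats) of the compared options.
    """
    from .designs import expected_value, outcome_entropy

    design = dataset.design
    table = pairwise_selection_table(dataset)
    role = {"GvG": "good", "BvB": "bad"}
    rows = []
    for (ptype, c_ref, c_other), g in table.groupby(
        ["pair_type", "condition_ref", "condition_other"]
    ):
        cond_ref = design.conditions[c_ref]
        cond_other = design.conditions[c_other]
        r = role[ptype]
        rows.append(
            {
                "pair_type": ptype,
                "comparison": f"{c_ref}|{c_other}",
                "mean_rate": float(g["rate"].mean()),
                "delta_ev": expected_value(cond_ref, r) - expected_value(cond_other, r),
                "delta_entropy": outcome_entropy(cond_ref, r)
                - outcome_entropy(cond_other, r),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# permutation test for correlation differences
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    delta_r_actual: float
    p_value: float
    ci95: tuple
    ses: float
    n_permutations: int
    null_mean: float
    null_std: float

    def as_dict(self) -> dict:
        return {
            "delta_r_actual": self.delta_r_actual,
            "p_value": self.p_value,
            "ci95": list(self.ci95),
            "ses": self.ses,
            "n_permutations": self.n_permutations,
            "null_mean": self.null_mean,
            "null_std": self.null_std,
        }


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ValueError("constant input vector")
    return (x - x.mean()) / sd


def permutation_delta_r(
    actual,
    fitted_a,
    fitted_b,
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Permutation test for dr = r(actual, A) - r(actual, B).

    The null distribution shuffles the actual vector; the two-tailed
    p-value is the proportion of |dr_permuted| exceeding |dr_actual|, the
    CI95 is the [2.5, 97.5] percentile band of the null, and SES is the
    actual dr standardized against the null.
    """
    actual = np.asarray(actual, dtype=float)
    a = np.asarray(fitted_a, dtype=float)
    b = np.asarray(fitted_b, dtype=float)
    if not (len(actual) == len(a) == len(b)):
        raise ValueError("input vectors must have equal length")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    n = len(actual)
    za = _standardize(a)
    zb = _standardize(b)
    z_act = _standardize(actual)

    delta_actual = float(np.dot(z_act, za) / n - np.dot(z_act, zb) / n)

    rng = np.random.default_rng(seed)
    perm = np.empty((n_perm, n))
    for i in range(n_perm):
        perm[i] = z_act[rng.permutation(n)]
    null = (perm @ za) / n - (perm @ zb) / n

    # ties count toward the null, so identical comparands yield p = 1
    p = float(np.mean(np.abs(null) >= np.abs(delta_actual)))
    lo, hi = np.percentile(null, [2.5, 97.5])
    null_std = float(null.std())
    if null_std > 0:
        ses = float((delta_actual - null.mean()) / null_std)
    else:
        ses = 0.0 if delta_actual == null.mean() else float("nan")
    return PermutationResult(
        delta_r_actual=delta_actual,
        p_value=p,
        ci95=(float(lo), float(hi)),
        ses=ses,
        n_permutations=n_perm,
        null_mean=float(null.mean()),
        null_std=null_std,
    )
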