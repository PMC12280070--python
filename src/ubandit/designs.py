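"""Experiment designs for the two-phase probabilistic bandit tasks.

The main task has five conditions. Each condition is a pair of one Good
option (positive feedback with probability 0.75) and one Bad option
(positive feedback with probability 0.25). Conditions differ in
``p_appetitive``, the probability that a given feedback is drawn from an
appetitive context (positive/negative feedback = +1/0 currency units)
rather than an aversive context (positive/negative feedback = 0/-1).
Learning uses partial feedback (only the chosen option's outcome is
shown); the subsequent test phase recombines options into new pairs and
gives no feedback at all.

Two validation designs use four pairs with a single reward magnitude per
pair (+10 or +1 versus 0) and a fixed set of four test pairs.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

MAIN_MAGNITUDES = {
    "appetitive": {"pos": 1.0, "neg": 0.0},
    "aversive": {"pos": 0.0, "neg": -1.0},
}


@dataclass(frozen=True)
class ConditionSpec:
    """One learning condition: feedback contingencies for a Good/Bad pair.

    On each feedback, a context is drawn (appetitive with probability
    ``p_appetitive``) and a valence (positive with the role's feedback
    probability); the (context, valence) cell indexes ``magnitudes``.
    """

    condition_id: str
    p_appetitive: float
    p_positive_good: float = 0.75
    p_positive_bad: float = 0.25
    magnitudes: dict = field(default_factory=lambda: MAIN_MAGNITUDES)

    def __post_init__(self):
        for p in (self.p_appetitive, self.p_positive_good, self.p_positive_bad):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0,1]: {p}")

    def p_positive(self, role: str) -> float:
        if role == "good":
            return self.p_positive_good
        if role == "bad":
            return self.p_positive_bad
        raise ValueError(f"unknown role {role!r}")


def outcome_distribution(cond: ConditionSpec, role: str) -> dict:
    """Categorical outcome distribution {currency value: probability}.

    Enumerates the four (context, valence) leaves of the feedback tree and
    aggregates leaves that map to the same currency value.
    """
    p = cond.p_appetitive
    q = cond.p_positive(role)
    leaves = [
        (cond.magnitudes["appetitive"]["pos"], p * q),
        (cond.magnitudes["appetitive"]["neg"], p * (1.0 - q)),
        (cond.magnitudes["aversive"]["pos"], (1.0 - p) * q),
        (cond.magnitudes["aversive"]["neg"], (1.0 - p) * (1.0 - q)),
    ]
    dist: dict = {}
    for value, prob in leaves:
        if prob > 0.0:
            dist[value] = dist.get(value, 0.0) + prob
    return dist


def expected_value(cond: ConditionSpec, role: str) -> float:
    """Expected currency value of the option, by enumeration of the tree."""
    return sum(v * p for v, p in outcome_distribution(cond, role).items())


def outcome_entropy(cond: ConditionSpec, role: str, base: str = "nats") -> float:
    """Shannon entropy of the option's outcome distribution.

    ``base='nats'`` (natural log, default) or ``'bits'`` (log2).
    """
    dist = outcome_distribution(cond, role)
    h = -sum(p * math.log(p) for p in dist.values() if p > 0.0)
    if base == "bits":
        return h / math.log(2.0)
    if base != "nats":
        raise ValueError(f"unknown base {base!r}")
    return h


def sample_outcome(cond: ConditionSpec, role: str, rng: np.random.Generator) -> float:
    """Draw one feedback: context ~ Bernoulli(p_appetitive), valence ~ Bernoulli(q_role)."""
    context = "appetitive" if rng.random() < cond.p_appetitive else "aversive"
    valence = "pos" if rng.random() < cond.p_positive(role) else "neg"
    return float(cond.magnitudes[context][valence])


@dataclass(frozen=True)
class LearningPair:
    """One Good/Bad pair as it appears in a learning block."""

    pair_id: str
    block: int
    condition_id: str
    good_id: str
    bad_id: str


@dataclass
class ExperimentDesign:
    """Declarative description of one experiment.

    ``kind`` selects the test-pair construction rule: ``'main'`` builds
    within-block Good-vs-Good / Bad-vs-Bad recombinations plus cross-block
    Good-vs-Bad pairs; ``'validation'`` uses the four fixed pairs.
    """

    name: str
    conditions: dict
    n_blocks: int
    trials_per_pair: int
    test_repeats: int
    presentation_mode: str  # "interleaved" | "blocked"
    kind: str  # "main" | "validation"
    learning_pairs: list = field(default_factory=list)

    # ---- derived quantities -------------------------------------------------
    @property
    def outcome_alphabet(self) -> tuple:
        values = set()
        for cond in self.conditions.values():
            for role in ("good", "bad"):
                values.update(outcome_distribution(cond, role))
        return tuple(sorted(values))

    @property
    def n_learning_trials(self) -> int:
        return len(self.learning_pairs) * self.trials_per_pair

    def option_ids(self) -> list:
        out = []
        for pair in self.learning_pairs:
            out.extend([pair.good_id, pair.bad_id])
        return out

    def option_role(self, option_id: str) -> str:
        for pair in self.learning_pairs:
            if option_id == pair.good_id:
                return "good"
            if option_id == pair.bad_id:
                return "bad"
        raise KeyError(f"unknown option {option_id!r}")

    def option_condition(self, option_id: str) -> ConditionSpec:
        for pair in self.learning_pairs:
            if option_id in (pair.good_id, pair.bad_id):
                return self.conditions[pair.condition_id]
        raise KeyError(f"unknown option {option_id!r}")

    def option_pair(self, option_id: str) -> LearningPair:
        for pair in self.learning_pairs:
            if option_id in (pair.good_id, pair.bad_id):
                return pair
        raise KeyError(f"unknown option {option_id!r}")

    def option_expected_value(self, option_id: str) -> float:
        return expected_value(self.option_condition(option_id), self.option_role(option_id))

    # ---- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentDesign":
        d = dict(d)
        d["conditions"] = {k: ConditionSpec(**v) for k, v in d["conditions"].items()}
        d["learning_pairs"] = [LearningPair(**p) for p in d["learning_pairs"]]
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, s: str) -> "ExperimentDesign":
        return cls.from_dict(json.loads(s))


MAIN_P_APPETITIVE = (1.0, 0.75, 0.5, 0.25, 0.0)


def _cond_id(p_app: float) -> str:
    return f"p{p_app:.2f}"


def make_main_design() -> ExperimentDesign:
    """The five-condition appetitive/aversive design.

    3 blocks x 5 conditions x 16 trials = 240 learning trials; the test
    phase recombines the 30 options into 90 unique pairs, each shown twice.
    """
    conditions = {
        _cond_id(p): ConditionSpec(condition_id=_cond_id(p), p_appetitive=p)
        for p in MAIN_P_APPETITIVE
    }
    n_blocks = 3
    pairs = []
    for block in range(1, n_blocks + 1):
        for cid in conditions:
            pairs.append(
                LearningPair(
                    pair_id=f"{block}_{cid}",
                    block=block,
                    condition_id=cid,
                    good_id=f"{block}_{cid}_G",
                    bad_id=f"{block}_{cid}_B",
                )
            )
    return ExperimentDesign(
        name="main",
        conditions=conditions,
        n_blocks=n_blocks,
        trials_per_pair=16,
        test_repeats=2,
        presentation_mode="blocked",
        kind="main",
        learning_pairs=pairs,
    )


# Validation pairs: (pair options, condition id, reward magnitude)
_VALIDATION_PAIRS = [
    ("A1", "B1", "big1", 10.0),
    ("A2", "B2", "big2", 10.0),
    ("C1", "D1", "small1", 1.0),
    ("C2", "D2", "small2", 1.0),
]
VALIDATION_TEST_PAIRS = [("A1", "C1"), ("B1", "D1"), ("A2", "D2"), ("B2", "C2")]


def make_validation_design(variant: str = "interleaved") -> ExperimentDesign:
    """Four-pair validation design (+10 or +1 point rewards versus 0).

    ``variant='interleaved'`` presents the four pairs inter-mixed;
    ``'blocked'`` presents them block-wise. Contingencies are identical:
    Good rewarded with probability 0.75, Bad with 0.25; test pairs are
    A1C1, B1D1, A2D2 and B2C2, each presented 30 times.
    """
    if variant not in ("interleaved", "blocked"):
        raise ValueError(f"unknown variant {variant!r}")
    conditions = {}
    pairs = []
    for i, (good, bad, cid, magnitude) in enumerate(_VALIDATION_PAIRS):
        conditions[cid] = ConditionSpec(
            condition_id=cid,
            p_appetitive=1.0,
            magnitudes={
                "appetitive": {"pos": magnitude, "neg": 0.0},
                "aversive": {"pos": magnitude, "neg": 0.0},
            },
        )
        block = i + 1 if variant == "blocked" else 1
        pairs.append(
            LearningPair(
                pair_id=good + bad, block=block, condition_id=cid, good_id=good, bad_id=bad
            )
        )
    return ExperimentDesign(
        name=f"validation_{variant}",
        conditions=conditions,
        n_blocks=4 if variant == "blocked" else 1,
        trials_per_pair=30,
        test_repeats=30,
        presentation_mode=variant,
        kind="validation",
        learning_pairs=pairs,
    )


def get_design(name: str) -> ExperimentDesign:
    if name == "main":
        return make_main_design()
    if name in ("validation_interleaved", "validation_blocked"):
        return make_validation_design(name.split("_", 1)[1])
    raise ValueError(f"unknown design {name!r}")


SCHEDULE_COLUMNS = [
    "phase",
    "block",
    "trial",
    "pair_id",
    "pair_type",
    "condition",
    "option_left",
    "option_right",
]


def _randomize_sides(rows: list, rng: np.random.Generator) -> None:
    # Screen position is uniform per trial and has no model effect.
    for row in rows:
        if rng.random() < 0.5:
            row["option_left"], row["option_right"] = row["option_right"], row["option_left"]


def build_learning_schedule(design: ExperimentDesign, seed: int) -> pd.DataFrame:
    """Trial-level learning schedule; deterministic given (design, seed).

    Main design: each block presents its five pairs in 16-trial streaks;
    the condition order of block 3 is the reverse of block 1, block 2 is
    randomized independently. Validation designs present the four pairs
    interleaved or in blocks of 30.
    """
    rng = np.random.default_rng(seed)
    rows = []

    if design.kind == "main":
        cids = list(design.conditions)
        order1 = [cids[i] for i in rng.permutation(len(cids))]
        order2 = [cids[i] for i in rng.permutation(len(cids))]
        block_orders = {1: order1, 2: order2, 3: order1[::-1]}
        by_block = {}
        for pair in design.learning_pairs:
            by_block.setdefault(pair.block, {})[pair.condition_id] = pair
        trial = 0
        for block in sorted(by_block):
            for cid in block_orders[block]:
                pair = by_block[block][cid]
                for _ in range(design.trials_per_pair):
                    rows.append(
                        {
                            "phase": "learning",
                            "block": block,
                            "trial": trial,
                            "pair_id": pair.pair_id,
                            "pair_type": "learning",
                            "condition": cid,
                            "option_left": pair.good_id,
                            "option_right": pair.bad_id,
                        }
                    )
                    trial += 1
    else:
        if design.presentation_mode == "interleaved":
            seq = [p for p in design.learning_pairs for _ in range(design.trials_per_pair)]
            seq = [seq[i] for i in rng.permutation(len(seq))]
        else:
            order = [design.learning_pairs[i] for i in rng.permutation(len(design.learning_pairs))]
            seq = [p for p in order for _ in range(design.trials_per_pair)]
        for trial, pair in enumerate(seq):
            rows.append(
                {
                    "phase": "learning",
                    "block": pair.block,
                    "trial": trial,
                    "pair_id": pair.pair_id,
                    "pair_type": "learning",
                    "condition": pair.condition_id,
                    "option_left": pair.good_id,
                    "option_right": pair.bad_id,
                }
            )

    _randomize_sides(rows, rng)
    return pd.DataFrame(rows, columns=SCHEDULE_COLUMNS)


def unique_test_pairs(design: ExperimentDesign) -> list:
    """Unique test pairs as (pair_id, pair_type, option_a, option_b).

    Main design: per block all C(5,2) Good-vs-Good and Bad-vs-Bad
    combinations (10 + 10 per block), plus Good-vs-Bad pairs combining a
    Good option with the Bad option of the same condition from each other
    block (5 conditions x 6 ordered block pairs = 30).
    """
    out = []
    if design.kind == "main":
        by_block = {}
        for pair in design.learning_pairs:
            by_block.setdefault(pair.block, []).append(pair)
        for block in sorted(by_block):
            pairs = by_block[block]
            for a, b in itertools.combinations(pairs, 2):
                out.append((f"GvG_{a.good_id}|{b.good_id}", "GvG", a.good_id, b.good_id))
            for a, b in itertools.combinations(pairs, 2):
                out.append((f"BvB_{a.bad_id}|{b.bad_id}", "BvB", a.bad_id, b.bad_id))
        for pair in design.learning_pairs:
            for other_block in sorted(by_block):
                if other_block == pair.block:
                    continue
                bad = next(
                    p.bad_id
                    for p in by_block[other_block]
                    if p.condition_id == pair.condition_id
                )
                out.append((f"GvB_{pair.good_id}|{bad}", "GvB", pair.good_id, bad))
    else:
        roles = {oid: design.option_role(oid) for oid in design.option_ids()}
        for a, b in VALIDATION_TEST_PAIRS:
            ra, rb = roles[a][0].upper(), roles[b][0].upper()
            out.append((f"{a}{b}", f"{ra}v{rb}", a, b))
    return out


def build_test_schedule(
    design: ExperimentDesign, learning_schedule: pd.DataFrame, seed: int
) -> pd.DataFrame:
    """Feedback-free test schedule over recombined pairs, randomized order."""
    known = set(learning_schedule["option_left"]) | set(learning_schedule["option_right"])
    rng = np.random.default_rng(seed)
    pairs = unique_test_pairs(design)
    for _, _, a, b in pairs:
        if a not in known or b not in known:
            raise ValueError(f"test option {a!r}/{b!r} absent from learning schedule")
    reps = [p for p in pairs for _ in range(design.test_repeats)]
    reps = [reps[i] for i in rng.permutation(len(reps))]
    start = int(learning_schedule["trial"].max()) + 1
    rows = []
    for trial, (pid, ptype, a, b) in enumerate(reps, start=start):
        rows.append(
            {
                "phase": "test",
                "block": 0,
                "trial": trial,
                "pair_id": pid,
                "pair_type": ptype,
                "condition": ptype,
                "option_left": a,
                "option_right": b,
            }
        )
    _randomize_sides(rows, rng)
    return pd.DataFrame(rows, columns=SCHEDULE_COLUMNS)
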