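"""Monte-Carlo simulation of IHC/molecular diagnostic workflows for Spitz tumors.

The simulated department receives genetically confirmed Spitz cases whose
driver aberration is one of ALK, ROS1, NTRK (fusions with an available IHC
stain) or "other" (no stain available). Every case starts with one H&E
examination at day 0 and must end with the aberration identified, either by
a positive IHC stain or by molecular diagnostics (which always resolves).

Workflow variants
-----------------
``parallel``
    All three Spitz stains in one round; molecular only if none is positive.
``sequential_prevalence``
    Stains one at a time, ordered from high to low aberration prevalence;
    stop at the first positive; molecular after three negatives.
``parallel_ai`` / ``sequential_prevalence_ai``
    As above, but IHC is skipped entirely (straight to molecular) when the
    model's predicted probability for the "other" class exceeds threshold T.
``sequential_predprob_ai``
    Skip rule as above; otherwise stains ordered by descending predicted
    probability instead of prevalence.

A stain is positive only for the matching aberration, and even then fails
(false-negative or too ambiguous to call) with a per-stain probability.
Accounting: each stain costs ``stain_cost`` and takes ``stain_days``; a
parallel round counts as one re-examination, each sequential stain result as
one, and a molecular result as one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "STAINED_CLASSES",
    "ABERRATION_CLASSES",
    "WorkflowConfig",
    "SimCase",
    "CaseOutcome",
    "SimSummary",
    "perfect_oracle",
    "noisy_oracle",
    "simulate_case",
    "run_simulation",
    "expected_outcome",
]

ABERRATION_CLASSES = ("ALK", "ROS1", "NTRK", "other")
STAINED_CLASSES = ("ALK", "ROS1", "NTRK")

VARIANTS = (
    "parallel",
    "sequential_prevalence",
    "parallel_ai",
    "sequential_prevalence_ai",
    "sequential_predprob_ai",
)
AI_VARIANTS = ("parallel_ai", "sequential_prevalence_ai", "sequential_predprob_ai")


@dataclass(frozen=True)
class WorkflowConfig:
    stain_cost: float = 100.0
    molecular_cost: float = 1000.0
    stain_days: float = 1.0
    molecular_days: float = 10.0
    # Probability that the matching stain is false-negative/ambiguous.
    fn_prob: dict = field(
        default_factory=lambda: {"ALK": 0.055, "ROS1": 0.448, "NTRK": 0.255}
    )
    threshold_t: float = 0.5
    variant: str = "parallel"
    # Dataset prevalence order NTRK > ROS1 > ALK.
    prevalence_order: tuple = ("NTRK", "ROS1", "ALK")
    iterations: int = 10_000
    cases_per_iteration: int = 100
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if sorted(self.prevalence_order) != sorted(STAINED_CLASSES):
            raise ValueError("prevalence_order must be a permutation of the stains")
        if self.stain_cost < 0 or self.molecular_cost < 0:
            raise ValueError("costs must be nonnegative")
        for k, v in self.fn_prob.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"fn_prob[{k}] outside [0, 1]")


class SimCase(NamedTuple):
    true_aberration: str
    pred_probs: tuple | None = None  # 4-vector over ABERRATION_CLASSES


class CaseOutcome(NamedTuple):
    cost: float
    turnaround: float
    examinations: int
    stains_performed: tuple
    molecular_performed: bool
    resolved_by: str  # "ihc" or "molecular"


@dataclass(frozen=True)
class SimSummary:
    variant: str
    iterations: int
    cases_per_iteration: int
    mean_cost: float  # mean total cost per iteration (accumulated over cases)
    cost_ci_low: float
    cost_ci_high: float
    mean_turnaround: float  # per case
    mean_examinations: float  # per case


def perfect_oracle(true_aberration: str) -> tuple:
    """One-hot predicted probabilities on the true class."""
    if true_aberration not in ABERRATION_CLASSES:
        raise ValueError(f"unknown aberration {true_aberration!r}")
    return tuple(1.0 if c == true_aberration else 0.0 for c in ABERRATION_CLASSES)


def noisy_oracle(
    true_aberration: str, confidence: float, rng: np.random.Generator
) -> tuple:
    """Synthetic recommendation policy: correct class with prob ``confidence``.

    The predicted distribution puts ``confidence`` mass on a class drawn to
    be correct with probability ``confidence`` and spreads the rest
    uniformly, emulating a calibrated-but-imperfect model for testing the
    AI-variant plumbing without a trained ensemble.
    """
    if true_aberration not in ABERRATION_CLASSES:
        raise ValueError(f"unknown aberration {true_aberration!r}")
    if rng.random() < confidence:
        top = true_aberration
    else:
        others = [c for c in ABERRATION_CLASSES if c != true_aberration]
        top = others[rng.integers(len(others))]
    rest = (1.0 - confidence) / 3.0
    return tuple(confidence if c == top else rest for c in ABERRATION_CLASSES)


def _stain_order(case: SimCase, config: WorkflowConfig) -> tuple:
    if config.variant == "sequential_predprob_ai":
        probs = case.pred_probs
        # Descending predicted probability; ties broken by prevalence order.
        rank = {c: i for i, c in enumerate(config.prevalence_order)}
        return tuple(
            sorted(
                STAINED_CLASSES,
                key=lambda c: (-probs[ABERRATION_CLASSES.index(c)], rank[c]),
            )
        )
    return config.prevalence_order


def simulate_case(
    case: SimCase, config: WorkflowConfig, rng: np.random.Generator
) -> CaseOutcome:
    """Simulate one case through the configured workflow variant."""
    if config.variant in AI_VARIANTS and case.pred_probs is None:
        raise ValueError(f"variant {config.variant!r} requires pred_probs")
    if case.true_aberration not in ABERRATION_CLASSES:
        raise ValueError(f"unknown aberration {case.true_aberration!r}")

    cost = 0.0
    days = 0.0
    exams = 1  # initial H&E review
    stains: tuple = ()
    truth = case.true_aberration

    skip_ihc = (
        config.variant in AI_VARIANTS
        and case.pred_probs[ABERRATION_CLASSES.index("other")] > config.threshold_t
    )

    resolved = False
    if not skip_ihc:
        if config.variant in ("parallel", "parallel_ai"):
            stains = tuple(STAINED_CLASSES)
            cost += 3 * config.stain_cost
            days += config.stain_days
            exams += 1  # one review of the whole round
            if truth in config.fn_prob and rng.random() >= config.fn_prob[truth]:
                resolved = True
        else:  # sequential variants
            performed = []
            for stain in _stain_order(case, config):
                performed.append(stain)
                cost += config.stain_cost
                days += config.stain_days
                exams += 1
                if stain == truth and rng.random() >= config.fn_prob[truth]:
                    resolved = True
                    break
            stains = tuple(performed)

    if not resolved:
        cost += config.molecular_cost
        days += config.molecular_days
        exams += 1

    return CaseOutcome(
        cost=cost,
        turnaround=days,
        examinations=exams,
        stains_performed=stains,
        molecular_performed=not resolved,
        resolved_by="ihc" if resolved else "molecular",
    )


def run_simulation(cases: Sequence[SimCase], config: WorkflowConfig) -> SimSummary:
    """Monte-Carlo summary over ``iterations`` resampled annual caseloads.

    Each iteration draws ``cases_per_iteration`` cases from the pool with
    replacement, simulates them, and records the accumulated cost and the
    per-case means; the 95% CI on cost is the (2.5, 97.5) percentile of the
    per-iteration totals.
    """
    if len(cases) == 0:
        raise ValueError("case pool must be non-empty")
    rng = np.random.default_rng(config.seed)
    n_it, n_cases = config.iterations, config.cases_per_iteration
    costs = np.empty(n_it)
    days = np.empty(n_it)
    exams = np.empty(n_it)
    pool = list(cases)
    for i in range(n_it):
        idx = rng.integers(len(pool), size=n_cases)
        c = d = e = 0.0
        for j in idx:
            out = simulate_case(pool[j], config, rng)
            c += out.cost
            d += out.turnaround
            e += out.examinations
        costs[i] = c
        days[i] = d / n_cases
        exams[i] = e / n_cases
    lo, hi = np.percentile(costs, [2.5, 97.5])
    return SimSummary(
        variant=config.variant,
        iterations=n_it,
        cases_per_iteration=n_cases,
        mean_cost=float(costs.mean()),
        cost_ci_low=float(lo),
        cost_ci_high=float(hi),
        mean_turnaround=float(days.mean()),
        mean_examinations=float(exams.mean()),
    )


def expected_outcome(
    class_probs: Sequence[float], config: WorkflowConfig
) -> tuple[float, float, float]:
    """Closed-form per-case expectations (cost, turnaround, examinations).

    Supported for the non-AI variants with any class mix, and for the AI
    variants under a perfect recommendation oracle (one-hot predictions, so
    "other" cases skip IHC and stain order puts the true class first for
    the predicted-probability variant). Enumerates the outcome paths per
    class exactly.
    """
    p = np.asarray(class_probs, dtype=float)
    if p.shape != (4,) or not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise ValueError("class_probs must be a 4-vector summing to 1")
    sc, mc = config.stain_cost, config.molecular_cost
    sd, md = config.stain_days, config.molecular_days
    fn = config.fn_prob
    variant = config.variant

    # Expected (cost, days, exams) per class, initial H&E exam included.
    per_class: dict[str, tuple[float, float, float]] = {}

    def seq_class(c: str, position: int) -> tuple[float, float, float]:
        # position: 1-based index of the matching stain in the order used.
        q = fn[c]
        hit = (position * sc, position * sd, 1 + position)
        miss = (3 * sc + mc, 3 * sd + md, 1 + 3 + 1)
        return tuple((1 - q) * h + q * m for h, m in zip(hit, miss))

    if variant == "parallel":
        for c in STAINED_CLASSES:
            q = fn[c]
            per_class[c] = (
                3 * sc + q * mc,
                sd + q * md,
                2 + q,
            )
        per_class["other"] = (3 * sc + mc, sd + md, 3)
    elif variant == "sequential_prevalence":
        for i, c in enumerate(config.prevalence_order, start=1):
            per_class[c] = seq_class(c, i)
        per_class["other"] = (3 * sc + mc, 3 * sd + md, 5)
    elif variant == "parallel_ai":
        for c in STAINED_CLASSES:
            q = fn[c]
            per_class[c] = (3 * sc + q * mc, sd + q * md, 2 + q)
        per_class["other"] = (mc, md, 2)  # perfect oracle -> skip IHC
    elif variant == "sequential_prevalence_ai":
        for i, c in enumerate(config.prevalence_order, start=1):
            per_class[c] = seq_class(c, i)
        per_class["other"] = (mc, md, 2)
    elif variant == "sequential_predprob_ai":
        for c in STAINED_CLASSES:
            per_class[c] = seq_class(c, 1)  # oracle puts the true stain first
        per_class["other"] = (mc, md, 2)
    else:  # pragma: no cover
        raise ValueError(f"unsupported variant {variant!r}")

    totals = np.zeros(3)
    for prob, c in zip(p, ABERRATION_CLASSES):
        totals += prob * np.asarray(per_class[c])
    return tuple(float(t) for t in totals)
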