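"""Splitting, cross-validated training, ensembling and comparator models.

The development protocol: a patient-level 75/25 development/test split
(stratified by pathway), five patient-level folds over the development
side, and per-fold training of the bag aggregator with the study schedule —
cross-entropy minimised with AdamW (beta1 0.9, beta2 0.999) for 32,000
iterations at batch size one, gradients accumulated over every 32
iterations, learning rate 5e-5 halved after every 6,400 iterations,
validation loss evaluated after every 320 iterations with the best
checkpoint kept. Diagnostic-category training uses balancing class weights.
Inference averages probabilities over 10 random subsets for bags above the
25,000-feature cap, and over the five fold models for the ensemble. The
binary decision threshold is fitted on each validation fold; the ensemble
uses the mean of the five fitted thresholds.

Comparators: multinomial logistic regression on clinical covariates
(standardized age, sex, one-hot anatomical site), optionally concatenated
with the aggregator's pre-head case embedding.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression

from .cohort import ABERRATIONS, CATEGORIES, LOCATIONS, LesionRecord
from .model import (
    AggregatorState,
    ModelConfig,
    case_loss,
    forward,
    init_model,
    loss_and_grads,
    softmax,
)

__all__ = [
    "TASKS",
    "TrainConfig",
    "SplitPlan",
    "FoldModel",
    "EnsemblePrediction",
    "split_dataset",
    "lr_at",
    "class_weights",
    "train_fold",
    "predict_case",
    "ensemble_predict",
    "fit_threshold",
    "classify",
    "fit_clinical_lr",
    "fit_combined_lr",
    "group_aberration",
    "group_category",
    "task_label",
    "train_ensemble",
]

TASKS = ("pathway", "aberration", "category")
_TASK_CLASSES = {
    "pathway": ("melanoma", "spitz"),
    "aberration": ABERRATIONS,
    "category": CATEGORIES,
}


@dataclass(frozen=True)
class TrainConfig:
    iterations: int = 32_000
    lr0: float = 5e-5
    halve_every: int = 6_400
    accum_every: int = 32
    eval_every: int = 320
    beta1: float = 0.9
    beta2: float = 0.999
    weight_decay: float = 0.01
    use_class_weights: bool = False
    max_features: int = 25_000
    n_subsets_infer: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations % self.eval_every != 0:
            raise ValueError("eval_every must divide iterations")
        if self.halve_every <= 0:
            raise ValueError("halve_every must be positive")


@dataclass(frozen=True)
class SplitPlan:
    assignment: dict  # lesion_id -> "test" | "dev_fold_1".."dev_fold_5"
    test_fraction: float = 0.25
    k_folds: int = 5
    seed: int = 0

    def lesions(self, part: str) -> list[str]:
        return [lid for lid, a in self.assignment.items() if a == part]


@dataclass
class FoldModel:
    state: AggregatorState
    val_trace: list  # [(iteration, val_loss), ...]
    fold_index: int
    threshold: float | None = None  # binary task only

    @property
    def best_val_loss(self) -> float:
        return min(loss for _, loss in self.val_trace)


@dataclass(frozen=True)
class EnsemblePrediction:
    mean_probs: np.ndarray  # (n_classes,)
    per_model_probs: np.ndarray  # (n_models, n_classes)
    decision: int


def lr_at(iteration: int, config: TrainConfig) -> float:
    """Step-decay schedule: lr0 halved after every ``halve_every`` iterations."""
    if not (0 <= iteration < config.iterations):
        raise ValueError("iteration outside the training schedule")
    return config.lr0 * 0.5 ** (iteration // config.halve_every)


def class_weights(labels, n_classes: int | None = None) -> np.ndarray:
    """Balancing weights w_c = n / (k * n_c); mean weight over examples is 1."""
    y = np.asarray(labels)
    if n_classes is None:
        n_classes = int(y.max()) + 1
    counts = np.bincount(y, minlength=n_classes)
    if np.count_nonzero(counts) < 2:
        raise ValueError("need at least two classes present")
    if np.any(counts == 0):
        raise ValueError("every class must have at least one example")
    return y.size / (n_classes * counts.astype(float))


def split_dataset(
    cohort: list[LesionRecord],
    seed: int = 0,
    test_fraction: float = 0.25,
    k_folds: int = 5,
) -> SplitPlan:
    """Patient-level stratified 75/25 split plus patient-level folds.

    All lesions of a patient land on the same side and in the same fold.
    Stratification is by pathway; fold assignment greedily balances lesion
    counts within each stratum.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    patients: dict[str, list[LesionRecord]] = {}
    for r in cohort:
        patients.setdefault(r.patient_id, []).append(r)
    if len(patients) < k_folds:
        raise ValueError("fewer patients than folds")
    rng = np.random.default_rng(seed)

    assignment: dict[str, str] = {}
    strata: dict[str, list[str]] = {}
    for pid, recs in patients.items():
        strata.setdefault(recs[0].pathway, []).append(pid)

    fold_sizes = np.zeros(k_folds, dtype=int)
    for pathway in sorted(strata):
        pids = sorted(strata[pathway])
        rng.shuffle(pids)
        total = sum(len(patients[p]) for p in pids)
        target_test = test_fraction * total
        cum = 0
        test_pids, dev_pids = [], []
        for pid in pids:
            if cum < target_test:
                test_pids.append(pid)
                cum += len(patients[pid])
            else:
                dev_pids.append(pid)
        for pid in test_pids:
            for r in patients[pid]:
                assignment[r.lesion_id] = "test"
        # Greedy balancing: largest patients first into the lightest fold.
        dev_pids.sort(key=lambda p: -len(patients[p]))
        for pid in dev_pids:
            k = int(np.argmin(fold_sizes))
            fold_sizes[k] += len(patients[pid])
            for r in patients[pid]:
                assignment[r.lesion_id] = f"dev_fold_{k + 1}"

    return SplitPlan(
        assignment=assignment, test_fraction=test_fraction, k_folds=k_folds, seed=seed
    )


# ---------------------------------------------------------------------------
# Optimizer and the per-fold training loop.


class _AdamW:
    """Decoupled weight decay; decay applies to 2-D weight matrices only."""

    def __init__(self, params: dict, config: TrainConfig, eps: float = 1e-8):
        self.params = params
        self.cfg = config
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict, lr: float) -> None:
        b1, b2, wd = self.cfg.beta1, self.cfg.beta2, self.cfg.weight_decay
        self.t += 1
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            update = (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)
            if p.ndim == 2:
                update = update + wd * p
            p -= np.float32(lr) * update


def train_fold(
    config: TrainConfig,
    model_config: ModelConfig,
    train_cases: list,
    val_cases: list,
    fold_index: int = 0,
) -> FoldModel:
    """Train one fold model; ``*_cases`` are (features, label) pairs.

    One case per iteration, cycled in a fresh random order each epoch;
    a gradient step every ``accum_every`` iterations; validation loss every
    ``eval_every`` iterations; the parameters at the minimum validation
    loss are returned. Deterministic given ``config.seed``.
    """
    if not train_cases or not val_cases:
        raise ValueError("train and validation sets must be non-empty")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, fold_index]))
    state = init_model(model_config, seed=int(rng.integers(2**31)))

    labels = [y for _, y in train_cases]
    if config.use_class_weights:
        weights = class_weights(labels, n_classes=model_config.n_classes)
    else:
        weights = np.ones(model_config.n_classes)

    opt = _AdamW(state.params, config)
    accum = {k: np.zeros_like(v) for k, v in state.params.items()}
    order = rng.permutation(len(train_cases))
    pos = 0
    trace: list[tuple[int, float]] = []
    best_loss = np.inf
    best_params = copy.deepcopy(state.params)

    for it in range(config.iterations):
        if pos == len(order):
            order = rng.permutation(len(train_cases))
            pos = 0
        x, y = train_cases[order[pos]]
        pos += 1
        loss, grads = loss_and_grads(
            state, x, y, rng=rng, training=True, class_weight=float(weights[y])
        )
        for k in accum:
            accum[k] += grads[k]
        if (it + 1) % config.accum_every == 0:
            for k in accum:
                accum[k] /= config.accum_every
            opt.step(accum, lr_at(it, config))
            for k in accum:
                accum[k][:] = 0.0
        if (it + 1) % config.eval_every == 0:
            val_loss = float(
                np.mean(
                    [case_loss(state, x, y, float(weights[y])) for x, y in val_cases]
                )
            )
            trace.append((it + 1, val_loss))
            if val_loss < best_loss:
                best_loss = val_loss
                best_params = copy.deepcopy(state.params)

    best_state = AggregatorState(
        params=best_params, config=model_config, seed=state.seed
    )
    return FoldModel(state=best_state, val_trace=trace, fold_index=fold_index)


def predict_case(
    fold_model: FoldModel | AggregatorState,
    bag,
    n_subsets: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Evaluation-mode class probabilities for one bag.

    Bags above the feature cap are scored as the mean over ``n_subsets``
    random subsets of the maximum size (seeded, reproducible).
    """
    state = fold_model.state if isinstance(fold_model, FoldModel) else fold_model
    feats = np.asarray(getattr(bag, "features", bag), dtype=np.float32)
    if feats.shape[0] == 0:
        raise ValueError("empty bag")
    cap = state.config.max_features
    if feats.shape[0] <= cap:
        return forward(state, feats).probabilities
    rng = np.random.default_rng(seed)
    probs = np.zeros(state.config.n_classes)
    for _ in range(n_subsets):
        idx = rng.choice(feats.shape[0], size=cap, replace=False)
        probs += forward(state, feats[idx]).probabilities
    return probs / n_subsets


def ensemble_predict(
    fold_models: list,
    bag,
    n_subsets: int = 10,
    seed: int = 0,
    threshold: float | None = None,
) -> EnsemblePrediction:
    """Average the fold models' probabilities; decide by threshold/argmax.

    For the binary task the decision threshold defaults to the mean of the
    per-fold fitted thresholds when they are available.
    """
    n_classes = {m.state.config.n_classes for m in fold_models}
    if len(n_classes) != 1:
        raise ValueError("fold models disagree on the number of classes")
    per_model = np.stack(
        [predict_case(m, bag, n_subsets=n_subsets, seed=seed) for m in fold_models]
    )
    mean = per_model.mean(axis=0)
    if threshold is None:
        fitted = [m.threshold for m in fold_models if getattr(m, "threshold", None) is not None]
        if fitted and mean.size == 2:
            threshold = float(np.mean(fitted))
    decision = classify(mean, threshold=threshold)
    return EnsemblePrediction(mean_probs=mean, per_model_probs=per_model, decision=decision)


def fit_threshold(val_probs, val_labels) -> float:
    """Probability threshold maximizing validation accuracy (binary task).

    Candidates are the midpoints of the intervals between consecutive
    distinct scores (with 0 and 1 as the outer edges); among maximizing
    intervals the lowest one wins.
    """
    p = np.asarray(val_probs, dtype=float)
    y = np.asarray(val_labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to fit a threshold")
    edges = np.concatenate([[0.0], np.unique(p), [1.0]])
    candidates = (edges[:-1] + edges[1:]) / 2.0
    best_t, best_acc = candidates[0], -1.0
    for t in candidates:
        acc = float(np.mean((p >= t).astype(int) == y))
        if acc > best_acc:
            best_acc, best_t = acc, t
    return float(best_t)


def classify(probabilities, threshold: float | None = None) -> int:
    """Decision rule: thresholded positive class for binary, else argmax.

    Binary with a threshold: predict class 1 iff p1 >= threshold. Ties in
    the argmax go to the lowest class index.
    """
    p = np.asarray(probabilities, dtype=float)
    if abs(p.sum() - 1.0) > 1e-3:
        raise ValueError("probability vector must sum to 1")
    if threshold is not None:
        if p.size != 2:
            raise ValueError("threshold rule applies to binary tasks only")
        return int(p[1] >= threshold)
    return int(np.argmax(p))


# ---------------------------------------------------------------------------
# Clinical and combined logistic-regression comparators.


def _clinical_matrix(records, age_mean=None, age_sd=None):
    age = np.array([r.age for r in records], dtype=float)
    if age_mean is None:
        age_mean = age.mean()
        age_sd = age.std() or 1.0
    x_age = (age - age_mean) / age_sd
    x_sex = np.array([1.0 if r.sex == "male" else 0.0 for r in records])
    onehot = np.zeros((len(records), len(LOCATIONS)))
    loc_idx = {loc: i for i, loc in enumerate(LOCATIONS)}
    for i, r in enumerate(records):
        onehot[i, loc_idx[r.location]] = 1.0
    return np.column_stack([x_age, x_sex, onehot]), age_mean, age_sd


@dataclass
class ClinicalModel:
    lr: LogisticRegression
    age_mean: float
    age_sd: float

    def predict_proba(self, records) -> np.ndarray:
        x, _, _ = _clinical_matrix(records, self.age_mean, self.age_sd)
        return self.lr.predict_proba(x)


@dataclass
class CombinedModel:
    lr: LogisticRegression
    age_mean: float
    age_sd: float
    embed_dim: int

    def predict_proba(self, records, embeddings) -> np.ndarray:
        emb = np.asarray(embeddings, dtype=float)
        if emb.shape != (len(records), self.embed_dim):
            raise ValueError("embeddings misaligned with records")
        x, _, _ = _clinical_matrix(records, self.age_mean, self.age_sd)
        return self.lr.predict_proba(np.column_stack([x, emb]))


def fit_clinical_lr(records, labels, seed: int = 0) -> ClinicalModel:
    """Logistic regression on standardized age, sex and one-hot location."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two classes")
    x, mu, sd = _clinical_matrix(records)
    lr = LogisticRegression(max_iter=2000, random_state=seed).fit(x, y)
    return ClinicalModel(lr=lr, age_mean=mu, age_sd=sd)


def fit_combined_lr(records, embeddings, labels, seed: int = 0) -> CombinedModel:
    """Logistic regression on [clinical encoding || case embedding]."""
    emb = np.asarray(embeddings, dtype=float)
    if emb.ndim != 2 or emb.shape[0] != len(records):
        raise ValueError("embeddings must be (n_records, embed_dim)")
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two classes")
    x, mu, sd = _clinical_matrix(records)
    lr = LogisticRegression(max_iter=2000, random_state=seed).fit(
        np.column_stack([x, emb]), y
    )
    return CombinedModel(lr=lr, age_mean=mu, age_sd=sd, embed_dim=emb.shape[1])


# ---------------------------------------------------------------------------
# Label grouping rules.

_OTHER_GENES = {"HRAS", "MAP3K8", "BRAF", "RET", "MET", "RASGFR1"}


def group_aberration(raw_label: str) -> str:
    """Group a raw aberration label into {ALK, ROS1, NTRK, other}.

    ALK/ROS1 map by gene (mutation or fusion alike); any NTRK1/2/3 or
    unspecified NTRK fusion maps to NTRK; the remaining Spitz-associated
    genes map to "other".
    """
    gene = raw_label.strip().split()[0].upper().rstrip("*")
    if gene in ("ALK", "ROS1"):
        return gene
    if gene.startswith("NTRK"):
        return "NTRK"
    if gene in _OTHER_GENES:
        return "other"
    raise ValueError(f"unknown aberration label {raw_label!r}")


_CATEGORY_MAP = {
    "benign": "benign",
    "benign/intermediate": "intermediate",
    "intermediate": "intermediate",
    "intermediate/malignant": "malignant",
    "malignant": "malignant",
}


def group_category(raw_label: str) -> str:
    """Group a differential diagnostic category with the more severe side."""
    key = raw_label.strip().lower()
    if key not in _CATEGORY_MAP:
        raise ValueError(f"unknown category label {raw_label!r}")
    return _CATEGORY_MAP[key]


# ---------------------------------------------------------------------------
# High-level helpers tying the pieces together.


def task_label(record: LesionRecord, task: str) -> int | None:
    """Integer label of a lesion for a task; None if not applicable."""
    if task == "pathway":
        return _TASK_CLASSES["pathway"].index(record.pathway)
    if record.pathway != "spitz":
        return None
    if task == "aberration":
        return ABERRATIONS.index(record.aberration)
    if task == "category":
        return CATEGORIES.index(record.category)
    raise ValueError(f"unknown task {task!r}")


def train_ensemble(
    records: list[LesionRecord],
    bags: dict,
    task: str,
    plan: SplitPlan,
    train_config: TrainConfig,
    model_config: ModelConfig,
) -> list[FoldModel]:
    """Train the five cross-validation fold models for one task.

    ``bags`` maps lesion_id to a FeatureBag or feature matrix. For the
    binary task each fold's decision threshold is fitted on its own
    validation fold.
    """
    by_id = {r.lesion_id: r for r in records}
    dev_cases: dict[int, list] = {k: [] for k in range(1, plan.k_folds + 1)}
    for lid, part in plan.assignment.items():
        if part == "test" or lid not in bags:
            continue
        y = task_label(by_id[lid], task)
        if y is None:
            continue
        fold = int(part.rsplit("_", 1)[1])
        dev_cases[fold].append((bags[lid], y))

    models = []
    for k in range(1, plan.k_folds + 1):
        train_cases = [c for f, cs in dev_cases.items() if f != k for c in cs]
        val_cases = dev_cases[k]
        fm = train_fold(train_config, model_config, train_cases, val_cases, fold_index=k)
        if task == "pathway":
            val_probs = [predict_case(fm, x, train_config.n_subsets_infer)[1] for x, _ in val_cases]
            val_labels = [y for _, y in val_cases]
            if len(set(val_labels)) == 2:
                fm.threshold = fit_threshold(val_probs, val_labels)
        models.append(fm)
    return models
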