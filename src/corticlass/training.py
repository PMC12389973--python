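"""Focal adversarial domain-adaptation training and evaluation.

Losses
------
focal:       L = -sum_i beta_{t_i} (1 - p_{t_i})^gamma log p_{t_i}
adversarial: L = -sum_i log D(f(x_i))_{d_i}   (cross-entropy over K domains)
center:      L = sum_i ||f(x_i) - c_{t_i}||^2
joint:       L = L_focal + gamma_center * L_center - lambda * L_adv

as seen by the feature extractor; the sign flip on the adversarial term is
realized by the gradient-reversal layer, so the discriminator itself
minimizes its cross-entropy while the extractor receives -lambda times that
gradient. Sums are taken as batch means by default (the sum convention is
available via ``reduction="sum"``; they coincide for single samples).

Class centers are updated by an exponential moving average of the batch
class means (momentum 0.9). Splits are subject-wise and stratified so no
subject contributes epochs to two partitions. The positive class for the
confusion-matrix metrics is depressed (label 0).
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .autograd import Tensor
from .model import DepressionClassifier, ModelConfig
from .optim import SGD, Adam
from .pipeline import Sample

PROB_CLAMP = 1e-12


# ---------------------------------------------------------------------------
# losses (numpy reference forms)


def _beta_for(labels: np.ndarray, beta) -> np.ndarray:
    if beta is None:
        return np.ones(labels.shape[0])
    beta = np.asarray(beta, dtype=float)
    if beta.ndim == 0:
        return np.full(labels.shape[0], float(beta))
    return beta[labels]


def focal_loss(p_true, labels=None, gamma: float = 2.0, beta=None,
               reduction: str = "sum") -> float:
    """Focal loss from per-sample true-class probabilities.

    ``beta`` may be None, a scalar, or a per-class array indexed by
    ``labels``. Probabilities of 0 are clamped at 1e-12 with a warning.
    Reduces to (weighted) cross-entropy at gamma = 0.
    """
    p = np.atleast_1d(np.asarray(p_true, dtype=float))
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if np.any(p == 0):
        warnings.warn("zero probability clamped at 1e-12", stacklevel=2)
        p = np.clip(p, PROB_CLAMP, 1.0)
    labels = np.zeros(p.shape[0], dtype=np.int64) if labels is None \
        else np.asarray(labels, dtype=np.int64)
    b = _beta_for(labels, beta)
    terms = -b * (1.0 - p) ** gamma * np.log(p)
    return float(terms.mean() if reduction == "mean" else terms.sum())


def adversarial_loss(domain_probs, domain_labels, reduction: str = "sum") -> float:
    """Cross-entropy of the domain discriminator over K source domains."""
    probs = np.atleast_2d(np.asarray(domain_probs, dtype=float))
    labels = np.asarray(domain_labels, dtype=np.int64)
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("domain probability rows must sum to 1")
    p = np.clip(probs[np.arange(labels.size), labels], PROB_CLAMP, 1.0)
    terms = -np.log(p)
    return float(terms.mean() if reduction == "mean" else terms.sum())


def center_loss(features, labels, centers) -> float:
    """Sum of squared distances of features to their class centers."""
    f = np.atleast_2d(np.asarray(features, dtype=float))
    c = np.asarray(centers, dtype=float)[np.asarray(labels, dtype=np.int64)]
    return float(((f - c) ** 2).sum())


def joint_loss(l_focal: float, l_center: float, l_adv: float,
               gamma_center: float, lambda_adv: float) -> float:
    """The extractor's objective: L_focal + gamma_c L_center - lambda L_adv."""
    return l_focal + gamma_center * l_center - lambda_adv * l_adv


# ---------------------------------------------------------------------------
# losses (autograd forms used in the training graph)


def focal_loss_logits(logits: Tensor, labels: np.ndarray, gamma: float,
                      beta_vec: np.ndarray, reduction: str = "mean") -> Tensor:
    labels = np.asarray(labels, dtype=np.int64)
    lp = logits.log_softmax(axis=-1).gather_rows(labels)
    if gamma != 0:
        p = lp.exp()
        mod = (1.0 - p + PROB_CLAMP).powi(gamma)
        terms = -1.0 * Tensor(_beta_for(labels, beta_vec)) * mod * lp
    else:
        terms = -1.0 * Tensor(_beta_for(labels, beta_vec)) * lp
    return terms.mean() if reduction == "mean" else terms.sum()


def cross_entropy_logits(logits: Tensor, labels: np.ndarray,
                         reduction: str = "mean") -> Tensor:
    lp = logits.log_softmax(axis=-1).gather_rows(np.asarray(labels, dtype=np.int64))
    return (-1.0 * lp).mean() if reduction == "mean" else (-1.0 * lp).sum()


def center_loss_features(features: Tensor, labels: np.ndarray,
                         centers: np.ndarray, reduction: str = "mean") -> Tensor:
    c = np.asarray(centers)[np.asarray(labels, dtype=np.int64)]
    sq = (features - Tensor(c)).powi(2.0).sum(axis=1)
    return sq.mean() if reduction == "mean" else sq.sum()


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class EvalReport:
    tp: int
    tn: int
    fp: int
    fn: int
    acc: float
    pre: float
    rec: float
    f1: float
    confusion: np.ndarray
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {"TP": self.tp, "TN": self.tn, "FP": self.fp, "FN": self.fn,
                "ACC": self.acc, "PRE": self.pre, "REC": self.rec, "F1": self.f1}


def evaluate(predictions, labels) -> EvalReport:
    """Confusion-matrix metrics with positive class = depressed (label 0)."""
    pred = np.asarray(predictions, dtype=np.int64)
    true = np.asarray(labels, dtype=np.int64)
    if pred.shape != true.shape:
        raise ValueError("predictions and labels differ in length")
    tp = int(np.sum((pred == 0) & (true == 0)))
    tn = int(np.sum((pred == 1) & (true == 1)))
    fp = int(np.sum((pred == 0) & (true == 1)))
    fn = int(np.sum((pred == 1) & (true == 0)))
    m = tp + tn + fp + fn
    acc = 100.0 * (tp + tn) / m
    degenerate = False
    if tp + fp == 0:
        pre, degenerate = 0.0, True
    else:
        pre = 100.0 * tp / (tp + fp)
    if tp + fn == 0:
        rec, degenerate = 0.0, True
    else:
        rec = 100.0 * tp / (tp + fn)
    f1 = 0.0 if pre + rec == 0 else 2 * pre * rec / (pre + rec)
    confusion = np.array([[tp, fn], [fp, tn]])
    return EvalReport(tp=tp, tn=tn, fp=fp, fn=fn,
                      acc=round(acc, 2), pre=round(pre, 2),
                      rec=round(rec, 2), f1=round(f1, 2),
                      confusion=confusion, degenerate=degenerate)


# ---------------------------------------------------------------------------
# training


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 16
    learning_rate: float = 5e-5
    epochs: int = 70
    patience: int = 15
    optimizer: str = "adam"
    gamma_focal: float = 2.0
    class_balanced_beta: bool = True
    lambda_adv: float = 0.1
    gamma_center: float = 0.01
    center_momentum: float = 0.9
    lambda_rampup: bool = True
    use_fada: bool = True
    reduction: str = "mean"
    val_fraction: float = 0.15
    test_fraction: float = 0.15
    standardize_features: bool = True
    seed: int = 0
    model: ModelConfig = field(default_factory=ModelConfig)


@dataclass
class TrainState:
    model: DepressionClassifier
    centers: np.ndarray  # [2 x hidden]
    config: TrainConfig
    feature_mean: np.ndarray | None
    feature_sd: np.ndarray | None
    beta: np.ndarray
    domain_index: dict[str, int]


@dataclass
class TrainResult:
    state: TrainState
    history: list[dict]
    split: dict[str, list[str]]
    best_val_acc: float
    test_report: EvalReport | None


def _subject_split(samples: list[Sample], config: TrainConfig,
                   rng: np.random.Generator) -> dict[str, list[str]]:
    by_class: dict[int, list[str]] = {}
    for s in samples:
        by_class.setdefault(s.label, [])
        if s.subject_id not in by_class[s.label]:
            by_class[s.label].append(s.subject_id)
    if len(by_class) < 2:
        raise ValueError("dataset contains a single class")
    split = {"train": [], "val": [], "test": []}
    for label in sorted(by_class):
        subs = sorted(by_class[label])
        if len(subs) < 2:
            raise ValueError("need at least 2 subjects per class")
        rng.shuffle(subs)
        n = len(subs)
        n_test = int(round(config.test_fraction * n))
        n_val = int(round(config.val_fraction * n))
        if config.val_fraction > 0:
            n_val = max(1, n_val)
        if config.test_fraction > 0:
            n_test = max(1, n_test)
        if n - n_val - n_test < 1:
            raise ValueError("not enough subjects for the requested split")
        split["test"].extend(subs[:n_test])
        split["val"].extend(subs[n_test:n_test + n_val])
        split["train"].extend(subs[n_test + n_val:])
    return split


def _standardizer(samples: list[Sample]):
    stack = np.concatenate([s.x for s in samples], axis=0)
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0)
    sd[sd == 0] = 1.0
    return mean, sd


def _forward_batch(model: DepressionClassifier, batch: list[Sample],
                   mean, sd, training: bool, rng) -> tuple[Tensor, Tensor]:
    pooled = []
    for s in batch:
        x = s.x if mean is None else (s.x - mean) / sd
        pooled.append(model.extract(x, s.a_hat, training=training, rng=rng))
    feats = Tensor.concat(pooled, axis=0)
    logits = model.classify(feats)
    return logits, feats


def predict(state: TrainState, samples: list[Sample]) -> np.ndarray:
    """Deterministic class predictions (argmax of the logits)."""
    logits, _ = _forward_batch(state.model, samples, state.feature_mean,
                               state.feature_sd, training=False, rng=None)
    return np.argmax(logits.data, axis=1)


def extract_features(state: TrainState, samples: list[Sample]) -> np.ndarray:
    """Pooled extractor features (for e.g. domain-classifiability probes)."""
    _, feats = _forward_batch(state.model, samples, state.feature_mean,
                              state.feature_sd, training=False, rng=None)
    return feats.data.copy()


def lambda_schedule(epoch: int, total: int, lambda_max: float,
                    rampup: bool) -> float:
    if not rampup or total <= 1:
        return lambda_max
    p = epoch / (total - 1)
    return lambda_max * (2.0 / (1.0 + np.exp(-10.0 * p)) - 1.0)


def train(samples: list[Sample], config: TrainConfig = TrainConfig()) -> TrainResult:
    """Full adversarial training loop with subject-wise early stopping."""
    rng = np.random.default_rng(config.seed)
    split = _subject_split(samples, config, rng)
    train_s = [s for s in samples if s.subject_id in split["train"]]
    val_s = [s for s in samples if s.subject_id in split["val"]]
    test_s = [s for s in samples if s.subject_id in split["test"]]
    if not val_s:
        val_s = train_s

    mean = sd = None
    if config.standardize_features:
        mean, sd = _standardizer(train_s)

    domains = sorted({s.subject_id for s in train_s})
    domain_index = {d: i for i, d in enumerate(domains)}
    n_domains = len(domains)

    model_cfg = config.model
    d_in = train_s[0].x.shape[1]
    if model_cfg.d_in != d_in:
        model_cfg = replace(model_cfg, d_in=d_in)
    model = DepressionClassifier(model_cfg, n_domains=n_domains, seed=config.seed)

    # FADA off -> plain cross-entropy (gamma = 0, uniform beta)
    gamma = config.gamma_focal if config.use_fada else 0.0
    labels_train = np.array([s.label for s in train_s])
    if config.use_fada and config.class_balanced_beta:
        freq = np.bincount(labels_train, minlength=2) / labels_train.size
        beta = 1.0 / np.maximum(freq, 1e-9)
        beta = beta / beta.mean()
    else:
        beta = np.ones(2)

    centers = np.zeros((2, model_cfg.hidden_dim))
    params = model.parameters() if config.use_fada else (
        model.extractor_parameters() + model.classifier.parameters())
    opt = Adam(params, lr=config.learning_rate) if config.optimizer == "adam" \
        else SGD(params, lr=config.learning_rate)

    history: list[dict] = []
    best_state = model.state_dict()
    best_val = -np.inf
    best_epoch = 0
    order = np.arange(len(train_s))
    val_labels = np.array([s.label for s in val_s])

    for epoch in range(config.epochs):
        rng.shuffle(order)
        lam = lambda_schedule(epoch, config.epochs, config.lambda_adv,
                              config.lambda_rampup) if config.use_fada else 0.0
        ep_focal = ep_adv = ep_center = 0.0
        n_batches = 0
        for start in range(0, len(order), config.batch_size):
            batch = [train_s[i] for i in order[start:start + config.batch_size]]
            labels = np.array([s.label for s in batch])
            opt.zero_grad()
            logits, feats = _forward_batch(model, batch, mean, sd,
                                           training=True, rng=rng)
            loss = focal_loss_logits(logits, labels, gamma, beta,
                                     config.reduction)
            l_focal = float(loss.data)
            l_center = l_adv = 0.0
            if config.use_fada:
                lc = center_loss_features(feats, labels, centers,
                                          config.reduction)
                l_center = float(lc.data)
                loss = loss + config.gamma_center * lc
                if n_domains > 1:
                    dlabels = np.array([domain_index[s.subject_id] for s in batch])
                    la = cross_entropy_logits(
                        model.discriminate(feats, lam), dlabels, config.reduction)
                    l_adv = float(la.data)
                    # GRL inside discriminate() realizes the -lambda sign for
                    # the extractor; the discriminator minimizes l_adv itself.
                    loss = loss + la
            loss.backward()
            opt.step()
            if config.use_fada:
                m = config.center_momentum
                for cls in (0, 1):
                    sel = labels == cls
                    if sel.any():
                        centers[cls] = m * centers[cls] + (1 - m) * feats.data[sel].mean(axis=0)
            ep_focal += l_focal
            ep_adv += l_adv
            ep_center += l_center
            n_batches += 1

        state = TrainState(model=model, centers=centers, config=config,
                           feature_mean=mean, feature_sd=sd, beta=beta,
                           domain_index=domain_index)
        val_acc = float(np.mean(predict(state, val_s) == val_labels))
        ep_focal /= n_batches
        ep_adv /= n_batches
        ep_center /= n_batches
        history.append({
            "epoch": epoch,
            "l_focal": ep_focal,
            "l_adv": ep_adv,
            "l_center": ep_center,
            "l_fada": joint_loss(ep_focal, ep_center, ep_adv,
                                 config.gamma_center, lam),
            "lambda": lam,
            "val_acc": val_acc,
        })
        if val_acc > best_val:
            best_val = val_acc
            best_state = model.state_dict()
            best_epoch = epoch
        if epoch - best_epoch >= config.patience:
            break

    model.load_state_dict(best_state)
    state = TrainState(model=model, centers=centers, config=config,
                       feature_mean=mean, feature_sd=sd, beta=beta,
                       domain_index=domain_index)
    test_report = None
    if test_s:
        test_labels = np.array([s.label for s in test_s])
        test_report = evaluate(predict(state, test_s), test_labels)
    return TrainResult(state=state, history=history, split=split,
                       best_val_acc=best_val, test_report=test_report)


# ---------------------------------------------------------------------------
# ablation


ABLATION_GRID: tuple[tuple[str, bool, bool, bool], ...] = (
    ("S1", False, False, False),
    ("S2", True, False, False),
    ("S3", False, True, False),
    ("S4", False, False, True),
    ("S5", True, True, False),
    ("S6", True, False, True),
    ("S7", False, True, True),
    ("S8", True, True, True),
)


def ablation_run(cortical_samples: list[Sample], scalp_samples: list[Sample],
                 config: TrainConfig,
                 grid=ABLATION_GRID) -> list[dict]:
    """Run the S1-S8 toggle grid (CFE, FA, FADA) with a shared seed.

    Returns one row per configuration with the toggle flags and the
    subject-wise test metrics.
    """
    rows = []
    for name, cfe, fa, fada in grid:
        cfg = replace(config, use_fada=fada,
                      model=replace(config.model, use_fa=fa))
        samples = cortical_samples if cfe else scalp_samples
        result = train(samples, cfg)
        report = result.test_report
        rows.append({
            "index": name, "CFE": cfe, "FA": fa, "FADA": fada,
            **(report.as_dict() if report else {}),
        })
    return rows
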