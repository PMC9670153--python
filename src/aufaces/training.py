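"""Supervised training of the FC head: splits, batching, schedule, multi-run.

Identities are partitioned 40/8/12 (train/validation/test, scaled to the
database size); every augmented variant of a training identity's images is
a training sample, so a full-protocol epoch holds 40 x 7 x 50 = 14,000
training and 8 x 7 x 50 = 2,800 validation samples.  Optimization is plain
mini-batch SGD (batch 32, remainder batch allowed) on the softmax
cross-entropy, under a piecewise-constant learning-rate schedule, stopping
exactly at the iteration cap even mid-epoch.  Each experiment repeats the
run with fresh split/init/batch/dropout seeds drawn from a master seed
through a SeedSequence hierarchy.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .network import ExpressionNet, NetConfig, build_network

#: Full-protocol learning-rate schedule: (start iteration, rate).
FULL_LR_SCHEDULE: tuple[tuple[int, float], ...] = ((0, 1e-4), (4000, 1e-5), (8000, 1e-6))


@dataclass(frozen=True)
class SplitAssignment:
    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    seed: int

    def __post_init__(self):
        sets = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        if sum(len(s) for s in sets) != len(set.union(*sets)):
            raise ValueError("split sets must be disjoint")


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 32
    total_iterations: int = 12_000
    lr_schedule: tuple[tuple[int, float], ...] = FULL_LR_SCHEDULE
    runs: int = 40
    split_proportions: tuple[int, int, int] = (40, 8, 12)

    def __post_init__(self):
        starts = [s for s, _ in self.lr_schedule]
        if starts != sorted(set(starts)):
            raise ValueError("lr schedule breakpoints must be strictly increasing")
        if self.runs < 1:
            raise ValueError("runs must be >= 1")


@dataclass
class RunRecord:
    """Everything logged for one training run.

    `feat_mean`/`feat_sd` are the feature-standardization statistics
    computed from this run's augmented training pool; they are part of the
    trained model and must be applied to any features fed to its head.
    """

    run_index: int
    split: SplitAssignment
    losses: np.ndarray                 # per-iteration training loss
    epoch_train_acc: np.ndarray        # correct rate on augmented samples as encountered
    epoch_val_acc: np.ndarray
    fc_params: list[np.ndarray]        # final head parameters
    backbone_checksum: str
    init_seed: int
    feat_mean: np.ndarray | None = None
    feat_sd: np.ndarray | None = None

    def standardize(self, feats: np.ndarray) -> np.ndarray:
        if self.feat_mean is None:
            return feats
        return (feats - self.feat_mean) / self.feat_sd


@dataclass
class PreparedDatabase:
    """A database after preprocessing, augmentation and feature extraction.

    `feats`/`labels`/`identity` describe the augmented sample pool used for
    training and validation; `eval_feats`/... hold the single centered
    un-augmented variant per (identity, label) used for test evaluation.
    """

    name: str
    identities: tuple[str, ...]
    feats: np.ndarray
    labels: np.ndarray
    identity: np.ndarray      # identity string per augmented sample
    eval_feats: np.ndarray
    eval_labels: np.ndarray
    eval_identity: np.ndarray


def split_identities(
    ids: list[str] | tuple[str, ...],
    proportions: tuple[int, int, int] = (40, 8, 12),
    seed: int = 0,
) -> SplitAssignment:
    """Uniform random identity-disjoint partition with the given proportions."""
    n, total = len(ids), sum(proportions)
    if any((n * p) % total for p in proportions):
        raise ValueError(f"{n} identities cannot be split in proportions {proportions}")
    sizes = [n * p // total for p in proportions]
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    perm = [ids[i] for i in rng.permutation(n)]
    a, b = sizes[0], sizes[0] + sizes[1]
    return SplitAssignment(tuple(perm[:a]), tuple(perm[a:b]), tuple(perm[b:]), seed)


def batch_iterator(n_samples: int, batch_size: int, epoch_seed: int | np.random.Generator):
    """Shuffled index batches: full batches then one remainder batch (if any)."""
    rng = (epoch_seed if isinstance(epoch_seed, np.random.Generator)
           else np.random.default_rng(np.random.SeedSequence(epoch_seed)))
    perm = rng.permutation(n_samples)
    return [perm[i:i + batch_size] for i in range(0, n_samples, batch_size)]


def learning_rate_at(iteration: int, schedule=FULL_LR_SCHEDULE) -> float:
    """Piecewise-constant lookup; a breakpoint takes its new rate immediately."""
    if iteration < 0:
        raise ValueError("iteration must be >= 0")
    lr = schedule[0][1]
    for start, rate in schedule:
        if iteration >= start:
            lr = rate
    return lr


def _sgd_step(net: ExpressionNet, X: np.ndarray, y: np.ndarray, lr: float,
              dropout_rng: np.random.Generator) -> tuple[float, float]:
    """One mini-batch update; returns (loss, batch correct rate before update)."""
    scores, probs, cache = net.head_forward(X, train=True, dropout_rng=dropout_rng,
                                            return_cache=True)
    B = X.shape[0]
    loss = float(-np.mean(np.log(probs[np.arange(B), y] + 1e-300)))
    if not np.isfinite(loss):
        raise RuntimeError(f"non-finite training loss ({loss}); aborting run")
    acc = float(np.mean(np.argmax(scores, axis=1) == y))

    dscores = probs.copy()
    dscores[np.arange(B), y] -= 1.0
    dscores /= B
    dW3 = cache["h2"].T @ dscores
    db3 = dscores.sum(0)
    dh2 = dscores @ net.W3.T
    dz2 = dh2 * (cache["z2"] > 0)
    dW2 = cache["x1"].T @ dz2
    db2 = dz2.sum(0)
    dx1 = dz2 @ net.W2.T
    if "m1" in cache:
        dx1 = dx1 * cache["m1"]
    dz1 = dx1 * (cache["z1"] > 0)
    dW1 = cache["x0"].T @ dz1
    db1 = dz1.sum(0)

    net.W3 -= lr * dW3
    net.b3 -= lr * db3
    net.W2 -= lr * dW2
    net.b2 -= lr * db2
    net.W1 -= lr * dW1
    net.b1 -= lr * db1
    return loss, acc


def _accuracy(net: ExpressionNet, X: np.ndarray, y: np.ndarray) -> float:
    scores, _ = net.head_forward(X)
    return float(np.mean(np.argmax(scores, axis=1) == y))


def train_run(
    net: ExpressionNet,
    prepared: PreparedDatabase,
    split: SplitAssignment,
    config: TrainConfig,
    batch_seed: int = 0,
    dropout_seed: int = 0,
    run_index: int = 0,
) -> RunRecord:
    """Train the FC head of `net` in place under the given split and config."""
    train_mask = np.isin(prepared.identity, split.train_ids)
    val_mask = np.isin(prepared.identity, split.val_ids)
    Xtr, ytr = prepared.feats[train_mask], prepared.labels[train_mask]
    Xva, yva = prepared.feats[val_mask], prepared.labels[val_mask]
    if len(ytr) == 0:
        raise ValueError("empty training set")
    # feature standardization from the training pool; fixed for the run.
    # The sd floor (1% of the median feature sd) keeps rarely-active
    # features from exploding on out-of-distribution probe stimuli.
    feat_mean = Xtr.mean(axis=0)
    feat_sd = Xtr.std(axis=0)
    feat_sd = np.maximum(feat_sd, 0.01 * np.median(feat_sd) + 1e-12)
    Xtr = (Xtr - feat_mean) / feat_sd
    Xva = (Xva - feat_mean) / feat_sd if len(yva) else Xva

    batch_rng = np.random.default_rng(np.random.SeedSequence(batch_seed))
    drop_rng = np.random.default_rng(np.random.SeedSequence(dropout_seed))
    losses, epoch_train, epoch_val = [], [], []
    it = 0
    while it < config.total_iterations:
        epoch_accs = []
        for batch in batch_iterator(len(ytr), config.batch_size, batch_rng):
            lr = learning_rate_at(it, config.lr_schedule)
            loss, acc = _sgd_step(net, Xtr[batch], ytr[batch], lr, drop_rng)
            losses.append(loss)
            epoch_accs.append(acc)
            it += 1
            if it >= config.total_iterations:
                break
        epoch_train.append(float(np.mean(epoch_accs)))
        epoch_val.append(_accuracy(net, Xva, yva) if len(yva) else np.nan)

    return RunRecord(
        run_index=run_index,
        split=split,
        losses=np.asarray(losses),
        epoch_train_acc=np.asarray(epoch_train),
        epoch_val_acc=np.asarray(epoch_val),
        fc_params=[p.copy() for p in net.fc_params()],
        backbone_checksum=net.backbone_checksum(),
        init_seed=net.config.init_seed,
        feat_mean=feat_mean,
        feat_sd=feat_sd,
    )


def run_experiment(
    prepared: PreparedDatabase,
    net_config: NetConfig,
    config: TrainConfig,
    master_seed: int = 0,
) -> list[RunRecord]:
    """`config.runs` independent runs with per-run seeds spawned from the master."""
    records = []
    children = np.random.SeedSequence(master_seed).spawn(config.runs)
    for r, child in enumerate(children):
        split_s, init_s, batch_s, drop_s = (int(s.generate_state(1)[0] % 2**31)
                                            for s in child.spawn(4))
        split = split_identities(list(prepared.identities), config.split_proportions, split_s)
        net = build_network(dataclasses.replace(net_config, init_seed=init_s))
        records.append(
            train_run(net, prepared, split, config,
                      batch_seed=batch_s, dropout_seed=drop_s, run_index=r)
        )
    return records
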