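"""Training protocols: source pretraining, freeze-and-fine-tune, scratch
baselines, leakage-safe cross-validation and the epoch-budget sweep.

The experiment this module runs is subject transfer: a network pretrained
on a pool of source subjects is fine-tuned per target subject with part of
its parameters frozen (the "control" condition), and compared with an
identically configured network trained from random initialization on the
same target data (the "baseline" condition), across a grid of training
epoch budgets.

Cross-validation folds by series (the 9 recording blocks per subject), not
by window, so temporally adjacent windows never land on both sides of a
fold.  Window-level folding is available for completeness but is not the
default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, LeaveOneGroupOut, StratifiedGroupKFold

from .exceptions import ConfigurationError, ValidationError
from .model import CnnSpec, build_network
from .preprocess import EpochSet, normalize_examples
from ._network import GROUPS, Network

logger = logging.getLogger(__name__)

_SEED_MASK = 0x7FFFFFFF

#: Default epoch-budget grid of the sweep.
DEFAULT_BUDGETS: tuple[int, ...] = (10, 20, 30, 40, 50, 60)


def derive_seed(*entropy: int) -> int:
    """Deterministic child seed from a tuple of integers (subject, budget, ...)."""
    return int(np.random.SeedSequence(list(entropy)).generate_state(1)[0]) & _SEED_MASK


# ---------------------------------------------------------------------------
# Freeze plans
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FreezePlan:
    """Which parameter groups stay fixed during fine-tuning.

    Trainable groups must form a contiguous block ending at the output
    layer, matching the ablation order of unfreezing from the top down.
    """

    trainable: tuple[bool, bool, bool, bool]  # (conv1, conv2, dense, output)
    name: str = "custom"

    def __post_init__(self):
        if not any(self.trainable):
            raise ValidationError("at least one parameter group must stay trainable")
        flags = list(self.trainable)
        # contiguous from the output backwards: once trainable, stays trainable
        for a, b in zip(flags, flags[1:]):
            if a and not b:
                raise ValidationError(
                    "trainable groups must be contiguous from the output backwards"
                )

    def as_dict(self) -> dict[str, bool]:
        return dict(zip(GROUPS, self.trainable))


#: Named presets, ordered from most to least frozen.
FREEZE_PRESETS: dict[str, FreezePlan] = {
    "only-output": FreezePlan((False, False, False, True), "only-output"),
    "last-two-dense": FreezePlan((False, False, True, True), "last-two-dense"),
    "unfreeze-through-conv2": FreezePlan((False, True, True, True), "unfreeze-through-conv2"),
    "unfreeze-through-conv1": FreezePlan((True, True, True, True), "unfreeze-through-conv1"),
}

#: The preset that wins the freezing ablation and is used by default.
DEFAULT_FREEZE_PLAN = "last-two-dense"


def apply_freeze(net: Network, plan: FreezePlan | str) -> Network:
    """Mark parameter groups frozen/trainable on the handle, in place."""
    if isinstance(plan, str):
        try:
            plan = FREEZE_PRESETS[plan]
        except KeyError:
            raise ValidationError(
                f"unknown freeze plan {plan!r}; presets: {sorted(FREEZE_PRESETS)}"
            ) from None
    for group, flag in plan.as_dict().items():
        if group not in net.trainable:
            raise ValidationError(f"unknown parameter group {group!r}")
        net.trainable[group] = flag
    return net


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitScheme:
    """How a target subject's examples are split for evaluation.

    ``grouping='series'`` keeps all windows of a series on one side of any
    fold; ``'window'`` folds over raw windows (provided for comparison with
    protocols that do so, at the cost of adjacent-window leakage).
    """

    kind: str = "holdout_70_30"  # holdout_70_30 | leave_one_out | kfold
    k: int = 10
    grouping: str = "series"  # series | window
    rng_seed: int = 0

    def __post_init__(self):
        if self.kind not in ("holdout_70_30", "leave_one_out", "kfold"):
            raise ValidationError(f"unknown split kind {self.kind!r}")
        if self.grouping not in ("series", "window"):
            raise ValidationError(f"unknown grouping {self.grouping!r}")


def iter_splits(epochs: EpochSet, scheme: SplitScheme):
    """Yield (train_idx, test_idx) pairs honoring the scheme's grouping.

    Series-level k-fold with more folds than series degrades to
    leave-one-series-out with a logged note.  The series-level holdout is
    stratified by class: ~30% of each class's series go to the test side,
    so every fold sees all classes.
    """
    n = epochs.n_examples
    groups = epochs.groups
    uniq = pd.unique(groups)
    if scheme.grouping == "window":
        if scheme.kind == "holdout_70_30":
            rng = np.random.default_rng(scheme.rng_seed)
            order = rng.permutation(n)
            cut = int(round(0.7 * n))
            yield np.sort(order[:cut]), np.sort(order[cut:])
        elif scheme.kind == "leave_one_out":
            for i in range(n):
                yield np.delete(np.arange(n), i), np.array([i])
        else:
            kf = KFold(n_splits=scheme.k, shuffle=True, random_state=scheme.rng_seed)
            yield from kf.split(np.arange(n))
        return

    if scheme.kind == "holdout_70_30":
        rng = np.random.default_rng(scheme.rng_seed)
        # stratify series by their (single) label
        label_of = {g: int(epochs.y[groups == g][0]) for g in uniq}
        test_groups = []
        for lab in sorted(set(label_of.values())):
            members = [g for g in uniq if label_of[g] == lab]
            n_test = max(1, int(round(0.3 * len(members))))
            test_groups += list(rng.choice(members, size=n_test, replace=False))
        mask = np.isin(groups, test_groups)
        yield np.where(~mask)[0], np.where(mask)[0]
    elif scheme.kind == "leave_one_out":
        for tr, te in LeaveOneGroupOut().split(np.arange(n), groups=groups):
            yield tr, te
    else:
        k = scheme.k
        if k > len(uniq):
            logger.info(
                "k=%d exceeds the %d series groups; degrading to leave-one-series-out",
                k, len(uniq),
            )
            for tr, te in LeaveOneGroupOut().split(np.arange(n), groups=groups):
                yield tr, te
            return
        skf = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=scheme.rng_seed)
        for tr, te in skf.split(np.arange(n), y=epochs.y, groups=groups):
            yield tr, te


# ---------------------------------------------------------------------------
# Training configuration and pretraining
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    """Optimizer and normalization settings shared by all protocols.

    Target-subject training (fine-tuning and the scratch baseline alike)
    uses ``learning_rate``; source pretraining, which sees 16 subjects of
    pooled data, uses the larger ``source_learning_rate``.  Both groups
    share the identical target-training setting, so the comparison between
    them is fair.
    """

    learning_rate: float = 1e-4
    source_learning_rate: float = 1e-3
    batch_size: int = 32
    source_epochs: int = 20
    normalization: str = "zscore"


@dataclass
class Checkpoint:
    """Learned parameters plus the spec and training log they came from."""

    spec: CnnSpec
    params: dict
    loss_log: list[float] = field(default_factory=list)
    seed: int = 0


def concat_epochsets(epochsets: list[EpochSet]) -> EpochSet:
    """Concatenate per-subject epoch sets into one pooled set."""
    if not epochsets:
        raise ValidationError("no epoch sets to concatenate")
    first = epochsets[0]
    return replace(
        first,
        X=np.concatenate([e.X for e in epochsets]),
        y=np.concatenate([e.y for e in epochsets]),
        subject_ids=np.concatenate([e.subject_ids for e in epochsets]),
        series_idx=np.concatenate([e.series_idx for e in epochsets]),
    )


def pretrain_source(
    epochsets: list[EpochSet],
    spec: CnnSpec,
    config: TrainConfig = TrainConfig(),
    seed: int = 0,
) -> Checkpoint:
    """Train the network on pooled source-subject data from scratch.

    Each subject's examples are z-scored on their own statistics before
    pooling, so the network sees comparably scaled inputs from every
    subject — the same convention later applied to target subjects.
    """
    if not epochsets:
        raise ValidationError("source subset must be non-empty")
    normed = [normalize_examples(e, config.normalization) for e in epochsets]
    pooled = concat_epochsets(normed)
    net = build_network(spec, rng_seed=seed)
    log = net.train(
        pooled.X,
        pooled.y,
        epochs=config.source_epochs,
        batch_size=config.batch_size,
        lr=config.source_learning_rate,
        seed=derive_seed(seed, 1),
    )
    return Checkpoint(spec=spec, params=net.get_params(), loss_log=log, seed=seed)


# ---------------------------------------------------------------------------
# Per-subject evaluation protocols
# ---------------------------------------------------------------------------

def _accuracy_percent(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    return float(np.mean(y_true == y_pred) * 100.0)


def _run_folds(
    make_net,
    epochs: EpochSet,
    budget: int,
    scheme: SplitScheme,
    seed: int,
    config: TrainConfig,
) -> float:
    """Shared fold loop: normalize on train stats, train, pool predictions.

    Accuracy is micro-averaged over the pooled test predictions of all
    folds: correct / total * 100.
    """
    correct = total = 0
    n_folds = 0
    for fold_i, (tr, te) in enumerate(iter_splits(epochs, scheme)):
        if len(set(epochs.y[tr])) < epochs.n_classes:
            warnings.warn(f"fold {fold_i}: training side is missing a class; fold skipped")
            continue
        normed = normalize_examples(epochs, config.normalization, train_idx=tr)
        net = make_net(derive_seed(seed, fold_i))
        if budget > 0:
            net.train(
                normed.X[tr],
                normed.y[tr],
                epochs=budget,
                batch_size=config.batch_size,
                lr=config.learning_rate,
                seed=derive_seed(seed, fold_i, 1),
            )
        pred = net.predict(normed.X[te])
        correct += int(np.sum(pred == normed.y[te]))
        total += len(te)
        n_folds += 1
    if total == 0:
        raise ConfigurationError("every fold was skipped; cannot compute accuracy")
    return correct / total * 100.0


def _run_folds_milestones(
    make_net,
    epochs: EpochSet,
    budgets: tuple[int, ...],
    scheme: SplitScheme,
    seed: int,
    config: TrainConfig,
) -> dict[int, float]:
    """Learning-curve variant of the fold loop: one continuous training run
    per fold, with held-out accuracy recorded at each budget milestone."""
    budgets = tuple(sorted(budgets))
    correct = {b: 0 for b in budgets}
    total = 0
    for fold_i, (tr, te) in enumerate(iter_splits(epochs, scheme)):
        if len(set(epochs.y[tr])) < epochs.n_classes:
            warnings.warn(f"fold {fold_i}: training side is missing a class; fold skipped")
            continue
        normed = normalize_examples(epochs, config.normalization, train_idx=tr)
        net = make_net(derive_seed(seed, fold_i))

        def record(done, te=te, net=net, normed=normed):
            pred = net.predict(normed.X[te])
            correct[done] += int(np.sum(pred == normed.y[te]))

        net.train(
            normed.X[tr],
            normed.y[tr],
            epochs=budgets[-1],
            batch_size=config.batch_size,
            lr=config.learning_rate,
            seed=derive_seed(seed, fold_i, 1),
            milestones=budgets,
            on_milestone=record,
        )
        total += len(te)
    if total == 0:
        raise ConfigurationError("every fold was skipped; cannot compute accuracy")
    return {b: correct[b] / total * 100.0 for b in budgets}


def finetune_target(
    checkpoint: Checkpoint,
    epochs: EpochSet,
    budget_epochs: int,
    plan: FreezePlan | str = DEFAULT_FREEZE_PLAN,
    scheme: SplitScheme = SplitScheme(),
    seed: int = 0,
    config: TrainConfig = TrainConfig(),
) -> float:
    """Fine-tune the pretrained network on one target subject; accuracy %.

    Per fold: parameters are restored from the checkpoint, the freeze plan
    applied, and only the trainable groups updated for ``budget_epochs``.
    """

    def make_net(fold_seed: int) -> Network:
        net = build_network(checkpoint.spec, rng_seed=fold_seed)
        net.set_params(checkpoint.params)
        return apply_freeze(net, plan)

    return _run_folds(make_net, epochs, budget_epochs, scheme, seed, config)


def train_scratch(
    spec: CnnSpec,
    epochs: EpochSet,
    budget_epochs: int,
    scheme: SplitScheme = SplitScheme(),
    seed: int = 0,
    config: TrainConfig = TrainConfig(),
) -> float:
    """Train a freshly initialized network on one target subject; accuracy %."""

    def make_net(fold_seed: int) -> Network:
        return build_network(spec, rng_seed=fold_seed)

    return _run_folds(make_net, epochs, budget_epochs, scheme, seed, config)


# ---------------------------------------------------------------------------
# Accuracy tables and the sweep
# ---------------------------------------------------------------------------

class AccuracyTable:
    """Subject x epoch-budget accuracy grid (percent), with a group tag.

    The CSV layout is a header row of budgets and a first column of subject
    ids, the shared codec for generated tables and packaged reference
    tables alike.
    """

    def __init__(self, df: pd.DataFrame, group: str = ""):
        df = df.copy()
        df.columns = [int(c) for c in df.columns]
        if df.isna().any().any():
            raise ValidationError("accuracy table has missing cells")
        vals = df.to_numpy(dtype=float)
        if vals.size and (vals.min() < 0 or vals.max() > 100):
            raise ValidationError("accuracies must lie in [0, 100]")
        self.df = df.astype(float)
        self.group = group

    @property
    def subjects(self) -> list[str]:
        return [str(s) for s in self.df.index]

    @property
    def budgets(self) -> list[int]:
        return [int(c) for c in self.df.columns]

    def values(self) -> np.ndarray:
        return self.df.to_numpy(dtype=float)

    def column(self, budget: int) -> np.ndarray:
        return self.df[int(budget)].to_numpy(dtype=float)

    def max_cell(self) -> float:
        return float(self.values().max())

    def to_csv(self, path) -> None:
        out = self.df.copy()
        out.insert(0, "subject", self.subjects)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, group: str = "") -> "AccuracyTable":
        df = pd.read_csv(path)
        df = df.set_index(df.columns[0])
        return cls(df, group=group)

    def __repr__(self) -> str:
        return f"AccuracyTable(group={self.group!r}, {len(self.df)}x{len(self.df.columns)})"


@dataclass
class SweepResult:
    """Output of the epoch-budget sweep: one table per group, plus logs."""

    control: AccuracyTable
    baseline: AccuracyTable
    checkpoint: Checkpoint
    cell_log: pd.DataFrame  # group, subject, budget, seed, accuracy


def epoch_budget_sweep(
    epochsets: list[EpochSet],
    spec: CnnSpec,
    budgets: tuple[int, ...] = DEFAULT_BUDGETS,
    group_sizes: tuple[int, int, int] | None = None,
    master_seed: int = 0,
    plan: FreezePlan | str = DEFAULT_FREEZE_PLAN,
    scheme: SplitScheme = SplitScheme(),
    config: TrainConfig = TrainConfig(),
    budget_mode: str = "independent",
) -> SweepResult:
    """Run the full protocol: pretrain, then fill both accuracy grids.

    Subjects split (in cohort order) into source / control / baseline
    groups — by default 16/5/5 for a 26-subject cohort, i.e. roughly
    60:20:20.  Control subjects are fine-tuned from the shared checkpoint
    under ``plan``; baseline subjects train from random initialization.

    ``budget_mode='independent'`` trains every (group, subject, budget)
    cell from its own fresh seed — budgets are fully independent
    experiments.  ``budget_mode='milestones'`` trains each subject once
    per fold up to the largest budget and records held-out accuracy at
    every budget milestone — the standard learning-curve protocol, about
    3x cheaper, with budget columns correlated along one trajectory.
    """
    if budget_mode not in ("independent", "milestones"):
        raise ConfigurationError(f"unknown budget_mode {budget_mode!r}")
    n = len(epochsets)
    if n < 3:
        raise ConfigurationError("sweep needs at least 3 subjects (one per group)")
    if group_sizes is None:
        n_source = int(round(0.6 * n))
        n_ctrl = (n - n_source + 1) // 2
        group_sizes = (n_source, n_ctrl, n - n_source - n_ctrl)
    n_source, n_ctrl, n_base = group_sizes
    if min(group_sizes) < 1 or sum(group_sizes) > n:
        raise ConfigurationError(f"invalid group sizes {group_sizes} for {n} subjects")
    source = epochsets[:n_source]
    control = epochsets[n_source : n_source + n_ctrl]
    baseline = epochsets[n_source + n_ctrl : n_source + n_ctrl + n_base]

    checkpoint = pretrain_source(source, spec, config, seed=derive_seed(master_seed, 0))

    rows = []
    tables = {}
    for gcode, (gname, members) in enumerate([("control", control), ("baseline", baseline)]):
        grid = {}
        for si, eps in enumerate(members):
            subject = eps.subject_ids[0]
            if budget_mode == "milestones":
                cell_seed = derive_seed(master_seed, gcode + 1, si, 0)
                cell_scheme = replace(scheme, rng_seed=derive_seed(cell_seed, 7))
                if gname == "control":
                    def make_net(fold_seed, _ck=checkpoint):
                        net = build_network(_ck.spec, rng_seed=fold_seed)
                        net.set_params(_ck.params)
                        return apply_freeze(net, plan)
                else:
                    def make_net(fold_seed, _spec=spec):
                        return build_network(_spec, rng_seed=fold_seed)
                accs = _run_folds_milestones(
                    make_net, eps, budgets, cell_scheme, cell_seed, config
                )
                for budget in budgets:
                    rows.append(
                        {"group": gname, "subject": subject, "budget": budget,
                         "seed": cell_seed, "accuracy": accs[budget]}
                    )
            else:
                accs = {}
                for budget in budgets:
                    cell_seed = derive_seed(master_seed, gcode + 1, si, budget)
                    cell_scheme = replace(scheme, rng_seed=derive_seed(cell_seed, 7))
                    if gname == "control":
                        acc = finetune_target(
                            checkpoint, eps, budget, plan, cell_scheme, cell_seed, config
                        )
                    else:
                        acc = train_scratch(spec, eps, budget, cell_scheme, cell_seed, config)
                    accs[budget] = acc
                    rows.append(
                        {"group": gname, "subject": subject, "budget": budget,
                         "seed": cell_seed, "accuracy": acc}
                    )
            grid[subject] = accs
        table = AccuracyTable(pd.DataFrame(grid).T, group=gname)
        means = table.values().mean(axis=0)
        drops = [b1 for m_prev, m_next, b1 in zip(means, means[1:], budgets[1:]) if m_next < m_prev]
        if drops:
            logger.info("%s group mean accuracy declines past budget(s) %s "
                        "(possible over-fitting)", gname, drops)
        tables[gname] = table
    return SweepResult(
        control=tables["control"],
        baseline=tables["baseline"],
        checkpoint=checkpoint,
        cell_log=pd.DataFrame(rows),
    )


def freezing_ablation(
    checkpoint: Checkpoint,
    target_epochsets: list[EpochSet],
    budget_epochs: int = 20,
    scheme: SplitScheme = SplitScheme(),
    seed: int = 0,
    config: TrainConfig = TrainConfig(),
) -> pd.DataFrame:
    """Mean fine-tuning accuracy per freeze preset, ranked best first.

    Repeats the fine-tuning protocol for each preset (from only-output to
    fully unfrozen) over the given target subjects.
    """
    if not target_epochsets:
        raise ValidationError("freezing ablation needs at least one target subject")
    rows = []
    for pname, plan in FREEZE_PRESETS.items():
        accs = [
            finetune_target(
                checkpoint, eps, budget_epochs, plan,
                replace(scheme, rng_seed=derive_seed(seed, i)),
                derive_seed(seed, i), config,
            )
            for i, eps in enumerate(target_epochsets)
        ]
        rows.append({"plan": pname, "mean_accuracy": float(np.mean(accs))})
    out = pd.DataFrame(rows).sort_values("mean_accuracy", ascending=False, ignore_index=True)
    out.attrs["winner"] = out.loc[0, "plan"]
    return out
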