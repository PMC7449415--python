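"""Stratified partitions, network ensembles and performance-weighted classification.

Because both the initial weights and the train/test split of a single network
are random, classification is averaged over an ensemble (1,000 networks in
the published analyses). Each network gets a fresh stratified partition —
85% of each class for training, 15% for testing (three-way: 26/26/25 train,
5/5/5 test; two-way: 26/52 train, 5/9 test on the published class sizes) —
and a fresh random initialization. Every trained network is then evaluated
on *all* assemblages; its overall proportion correct is its weight in the
ensemble's weighted-mean class probabilities, and the weighted-mean argmax is
the ensemble classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assemblages import ClassScheme, TechnologyMatrix
from .mlp import class_probabilities, rescale_inputs
from .training import TrainedNetwork, TrainingConfig, train_network


@dataclass(frozen=True)
class Partition:
    """Disjoint train/test index sets covering all assemblages exactly once."""

    train_indices: np.ndarray
    test_indices: np.ndarray

    def __post_init__(self) -> None:
        tr = np.asarray(self.train_indices)
        te = np.asarray(self.test_indices)
        object.__setattr__(self, "train_indices", tr)
        object.__setattr__(self, "test_indices", te)
        combined = np.concatenate([tr, te])
        if len(np.unique(combined)) != combined.size:
            raise ValueError("train and test indices overlap or repeat")


def class_test_size(n_class: int, test_fraction: float = 0.15) -> int:
    """Per-class test-set size: the test fraction rounded half-up.

    Reproduces the published quotas exactly: 31 → 5, 30 → 5, 61 → 9.
    """
    return int(np.floor(test_fraction * n_class + 0.5))


def make_partition(
    labels: list[str],
    scheme: ClassScheme,
    rng: np.random.Generator,
    test_fraction: float = 0.15,
) -> Partition:
    """Randomized stratified split with exact per-class counts."""
    labels = list(labels)
    train: list[int] = []
    test: list[int] = []
    for cls in scheme.classes:
        idx = np.flatnonzero(np.array(labels) == cls)
        if idx.size == 0:
            raise ValueError(f"class {cls!r} has no members")
        q = class_test_size(idx.size, test_fraction)
        if q < 1 or q >= idx.size:
            raise ValueError(f"class {cls!r} too small for a stratified split")
        perm = rng.permutation(idx)
        test.extend(perm[:q].tolist())
        train.extend(perm[q:].tolist())
    return Partition(np.sort(np.array(train)), np.sort(np.array(test)))


@dataclass
class EnsembleResult:
    """Everything the downstream reports need from one ensemble run."""

    scheme: ClassScheme
    networks: list[TrainedNetwork]
    prob_tensor: np.ndarray          # (n_networks, n_assemblages, n_classes)
    weights: np.ndarray              # normalized per-network accuracy weights
    weighted_probs: np.ndarray       # (n_assemblages, n_classes)
    predicted: list[str]
    correct_rate: np.ndarray         # per-assemblage % of networks correct
    truth: list[str] = field(default_factory=list)

    @property
    def n_networks(self) -> int:
        return len(self.networks)

    def accuracies(self) -> np.ndarray:
        return np.array([net.accuracy_all for net in self.networks])


def weighted_mean_classify(
    prob_tensor: np.ndarray,
    accuracies: np.ndarray,
    scheme: ClassScheme,
) -> tuple[np.ndarray, list[str]]:
    """Performance-weighted mean probabilities and the resulting classes.

    Weights are the per-network accuracies normalized to sum to one (the
    normalization leaves the argmax unchanged but makes the reported weighted
    probabilities proper probabilities). Argmax ties break to the lowest
    class index in the scheme's declared order.
    """
    acc = np.asarray(accuracies, dtype=float)
    if (acc < 0).any():
        raise ValueError("accuracies must be nonnegative")
    total = acc.sum()
    if total == 0:
        raise ValueError("all-zero accuracies cannot weight an ensemble")
    weights = acc / total
    weighted = np.einsum("w,wnk->nk", weights, np.asarray(prob_tensor, dtype=float))
    predicted = [scheme.classes[i] for i in weighted.argmax(axis=1)]
    return weighted, predicted


def per_assemblage_correct_rate(prob_tensor: np.ndarray, truth_idx: np.ndarray) -> np.ndarray:
    """Percentage of networks whose argmax matches the true class, per assemblage."""
    tensor = np.asarray(prob_tensor, dtype=float)
    winners = tensor.argmax(axis=2)                    # (n_networks, n_assemblages)
    return (winners == np.asarray(truth_idx)[None, :]).mean(axis=0) * 100.0


def spawn_network_seeds(master_seed: int, n_networks: int) -> list[np.random.Generator]:
    """Child generators for an ensemble: ``SeedSequence(master).spawn(n)``.

    Network *i* always receives the *i*-th child stream, so any single
    network can be re-run in isolation from the master seed and its index.
    """
    return [np.random.default_rng(s) for s in np.random.SeedSequence(master_seed).spawn(n_networks)]


def train_ensemble(
    matrix: TechnologyMatrix,
    scheme: ClassScheme,
    n_networks: int,
    config: TrainingConfig | None = None,
    seed: int = 0,
    n_hidden: int = 10,
) -> EnsembleResult:
    """Train ``n_networks`` independent networks and pool their classifications.

    Each network draws a fresh stratified partition and fresh initial weights
    from its own child stream of the master seed, trains on its training
    subset, and is evaluated on the full assemblage table.
    """
    if n_networks < 1:
        raise ValueError("n_networks must be at least 1")
    cfg = config or TrainingConfig()
    labels = scheme.labels_for(matrix.labels3)
    truth_idx = np.array([scheme.class_index(lab) for lab in labels])
    X_all = rescale_inputs(matrix.presence)
    rngs = spawn_network_seeds(seed, n_networks)

    networks: list[TrainedNetwork] = []
    tensor = np.empty((n_networks, matrix.n_assemblages, scheme.n_classes))
    for i, rng in enumerate(rngs):
        try:
            part = make_partition(labels, scheme, rng)
            net = train_network(matrix, scheme, part, cfg, rng, n_hidden=n_hidden)
        except Exception as exc:
            raise RuntimeError(f"training aborted at network {i}: {exc}") from exc
        networks.append(net)
        tensor[i] = class_probabilities(net.params, X_all)

    acc = np.array([net.accuracy_all for net in networks])
    weighted, predicted = weighted_mean_classify(tensor, acc, scheme)
    return EnsembleResult(
        scheme=scheme,
        networks=networks,
        prob_tensor=tensor,
        weights=acc / acc.sum(),
        weighted_probs=weighted,
        predicted=predicted,
        correct_rate=per_assemblage_correct_rate(tensor, truth_idx),
        truth=labels,
    )


@dataclass
class ConfusionReport:
    """K×K confusion counts (output class × target class) with the derived
    percentage metrics, all reported to two decimals."""

    scheme: ClassScheme
    counts: np.ndarray
    sensitivity: np.ndarray           # per target class, % (diagonal / column sum)
    row_predictive_value: np.ndarray  # per output class, % (diagonal / row sum)
    accuracy: float                   # overall %, trace / total

    def to_frame(self) -> pd.DataFrame:
        """Confusion-table layout: output classes as rows, targets as columns,
        with the predictive-value column (printed as 'Specificity (TN%)' in
        report output) and a sensitivity row."""
        cls = list(self.scheme.classes)
        df = pd.DataFrame(self.counts, index=cls, columns=cls, dtype=object)
        df["Specificity (TN%)"] = [round(v, 2) for v in self.row_predictive_value]
        sens = {c: round(v, 2) for c, v in zip(cls, self.sensitivity)}
        sens["Specificity (TN%)"] = ""
        df.loc["Sensitivity (TP%)"] = pd.Series(sens)
        df.index.name = "Output Class"
        return df


def confusion_metrics(
    predicted: list[str],
    truth: list[str],
    scheme: ClassScheme,
) -> ConfusionReport:
    """Confusion counts and percentage metrics for a set of classifications.

    ``counts[i, j]`` is the number of assemblages output as class *i* whose
    target is class *j*. Sensitivity (TP%) is the column-wise diagonal share;
    the row-wise diagonal share is a predictive value (the published tables
    label it specificity/TN%, and report output preserves that label).
    """
    if len(predicted) != len(truth):
        raise ValueError("predicted and truth must have equal length")
    K = scheme.n_classes
    counts = np.zeros((K, K), dtype=int)
    for p, t in zip(predicted, truth):
        counts[scheme.class_index(p), scheme.class_index(t)] += 1
    total = counts.sum()
    diag = np.diag(counts).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        sens = np.where(counts.sum(axis=0) > 0, diag / counts.sum(axis=0) * 100.0, np.nan)
        rpv = np.where(counts.sum(axis=1) > 0, diag / counts.sum(axis=1) * 100.0, np.nan)
    return ConfusionReport(
        scheme=scheme,
        counts=counts,
        sensitivity=sens,
        row_predictive_value=rpv,
        accuracy=float(diag.sum() / total * 100.0),
    )


def confusion_from_counts(counts: np.ndarray, scheme: ClassScheme) -> ConfusionReport:
    """Metrics computed directly from a printed confusion-count table."""
    counts = np.asarray(counts, dtype=int)
    K = scheme.n_classes
    if counts.shape != (K, K):
        raise ValueError("counts shape does not match the scheme")
    labels: list[str] = []
    truths: list[str] = []
    for i in range(K):
        for j in range(K):
            labels.extend([scheme.classes[i]] * counts[i, j])
            truths.extend([scheme.classes[j]] * counts[i, j])
    return confusion_metrics(labels, truths, scheme)
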