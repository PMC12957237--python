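"""End-to-end decoding experiment orchestration.

Splits windows by run (training runs never mix with test runs and the
validation fraction is drawn trial-wise from the training windows only),
trains one binary attention classifier per finger pair, aggregates
window predictions to trials by majority voting, and combines the
C(5,2) = 10 pairwise classifiers into a five-class decoder with a
one-vs-one vote and two-stage tie-breaking: a sub-vote among the tied
candidates first, then the summed softmax probability over every
classifier involving a tied class, and finally the smallest label.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from itertools import combinations

import numpy as np

from .core import Recording
from .evalstats import (
    accuracy,
    cohens_kappa,
    confusion_matrix,
    permutation_test,
    roc_points,
)
from .exceptions import InvalidArgumentError
from .fbcsp import BandSpec, FBCSPModel, FeatureMap
from .model import ScbamConfig, ScbamNet, build_model
from .nn import Adam, softmax_cross_entropy
from .preprocess import (
    WindowSet,
    detect_artifacts,
    fit_normalizer,
    preprocess_run,
    reject_run,
    window_trials,
)

__all__ = [
    "TrainConfig", "FoldPlan", "ExperimentConfig", "OvOEnsemble",
    "split_by_runs", "train_binary", "vote_trial", "ovo_vote", "ovo_predict",
    "run_experiment", "report_to_json",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol for each binary classifier."""

    epochs: int = 150
    batch_size: int = 32
    learning_rate: float = 0.001
    val_fraction: float = 0.10
    optimizer_name: str = "adam"
    shuffle: bool = True
    seed: int = 0

    def validate(self):
        if not 0 < self.val_fraction < 1:
            raise InvalidArgumentError("val_fraction must be in (0, 1)")
        if self.epochs < 0:
            raise InvalidArgumentError("epochs must be >= 0")


@dataclass(frozen=True)
class FoldPlan:
    """Run-wise train/test assignment (default: runs 1-8 train, 9-10 test)."""

    train_runs: tuple = (1, 2, 3, 4, 5, 6, 7, 8)
    test_runs: tuple = (9, 10)

    def validate(self):
        if set(self.train_runs) & set(self.test_runs):
            raise InvalidArgumentError("train and test run sets must be disjoint")
        if not self.train_runs or not self.test_runs:
            raise InvalidArgumentError("both run sets must be nonempty")


def split_by_runs(windows: WindowSet, plan: FoldPlan,
                  val_fraction: float = 0.10, seed: int = 0):
    """Partition windows into (train, val, test) by their parent run.

    Validation is carved trial-wise out of the training windows so no
    trial ever spans two partitions; the test partition is untouched.
    """
    plan.validate()
    if not 0 <= val_fraction < 1:
        raise InvalidArgumentError("val_fraction must be in [0, 1)")
    train_mask = np.isin(windows.run_ids, plan.train_runs)
    test_mask = np.isin(windows.run_ids, plan.test_runs)
    train_all = windows.subset(train_mask, "train")
    test = windows.subset(test_mask, "test")

    trials = np.unique(train_all.trial_ids)
    n_val = int(round(val_fraction * trials.size))
    rng = np.random.default_rng(seed)
    val_trials = rng.choice(trials, size=n_val, replace=False) if n_val else []
    val_mask = np.isin(train_all.trial_ids, val_trials)
    return (train_all.subset(~val_mask, "train"),
            train_all.subset(val_mask, "val"), test)


def carve_validation(windows: WindowSet, fraction: float, seed: int = 0):
    """Split a training window set into (train, val) trial-wise, stratified
    by class so every class present keeps at least one validation trial
    (when it has more than one trial). Returns (train, val)."""
    if not 0 < fraction < 1:
        raise InvalidArgumentError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    val_trials = []
    for lab in np.unique(windows.labels):
        trials = np.unique(windows.trial_ids[windows.labels == lab])
        n_val = int(round(fraction * trials.size))
        if trials.size > 1:
            n_val = min(max(n_val, 1), trials.size - 1)
        if n_val:
            val_trials.extend(rng.choice(trials, size=n_val, replace=False))
    mask = np.isin(windows.trial_ids, val_trials)
    return windows.subset(~mask, "train"), windows.subset(mask, "val")


class _FeatureScaler:
    """Per-(component, rhythm) standardization fitted on training features."""

    def fit(self, values: np.ndarray) -> "_FeatureScaler":
        self.mean = values.mean(axis=0)
        sd = values.std(axis=0)
        sd[sd == 0] = 1.0
        self.sd = sd
        return self

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (values - self.mean) / self.sd


def _as_batches(n, batch_size, order):
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def train_binary(train_features: FeatureMap, val_features: FeatureMap,
                 model_config: ScbamConfig, train_config: TrainConfig,
                 scaler: _FeatureScaler | None = None):
    """Train one pairwise classifier; returns (ScbamNet, learning curves).

    Labels in the feature maps are the original finger labels; the lower
    label maps to network class 0. The returned model carries the weights
    of the final epoch; curves hold per-epoch train/val loss and accuracy.
    """
    train_config.validate()
    classes = np.unique(train_features.labels)
    if classes.size != 2:
        raise InvalidArgumentError("training features must contain exactly 2 classes")
    if np.unique(val_features.labels).size != 2 and train_config.epochs > 0:
        raise InvalidArgumentError("validation features must contain both classes")

    def prep(fm):
        v = fm.values if scaler is None else scaler.transform(fm.values)
        x = v[:, None, :, :]
        y = (fm.labels == classes[1]).astype(int)
        return x, y

    x_tr, y_tr = prep(train_features)
    x_va, y_va = prep(val_features)

    net = build_model(model_config, seed=train_config.seed)
    opt = Adam(net.network, learning_rate=train_config.learning_rate)
    rng = np.random.default_rng(train_config.seed + 7919)
    curves = {"train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []}

    for _ in range(train_config.epochs):
        order = np.arange(x_tr.shape[0])
        if train_config.shuffle:
            rng.shuffle(order)
        losses, correct = [], 0
        for batch in _as_batches(x_tr.shape[0], train_config.batch_size, order):
            logits = net.forward(x_tr[batch], train=True)
            loss, dlogits = softmax_cross_entropy(logits, y_tr[batch])
            net.network.backward(dlogits)
            opt.step()
            losses.append(loss * batch.size)
            correct += int(np.sum(logits.argmax(axis=1) == y_tr[batch]))
        curves["train_loss"].append(float(np.sum(losses) / x_tr.shape[0]))
        curves["train_acc"].append(correct / x_tr.shape[0])
        val_logits = net.forward(x_va, train=False)
        val_loss, _ = softmax_cross_entropy(val_logits, y_va)
        curves["val_loss"].append(float(val_loss))
        curves["val_acc"].append(float(np.mean(val_logits.argmax(axis=1) == y_va)))
    return net, curves


def vote_trial(window_predictions) -> int:
    """Majority vote over a trial's window labels; ties -> smallest label."""
    preds = list(window_predictions)
    if not preds:
        raise InvalidArgumentError("empty prediction list")
    labels, counts = np.unique(preds, return_counts=True)
    return int(labels[counts == counts.max()].min())


@dataclass
class PairModel:
    """Everything one binary comparison needs at prediction time."""

    pair: tuple
    featurizer: FBCSPModel
    scaler: _FeatureScaler
    net: ScbamNet
    curves: dict = field(default_factory=dict)

    def window_probs(self, windows: WindowSet) -> np.ndarray:
        """(n_windows, 2) probabilities in (lower label, higher label) order."""
        fm = self.featurizer.transform(windows)
        x = self.scaler.transform(fm.values)[:, None, :, :]
        return self.net.predict_proba(x)


@dataclass
class OvOEnsemble:
    """One trained binary classifier per unordered finger pair."""

    classifiers: dict
    class_set: tuple

    def __post_init__(self):
        expected = {frozenset(p) for p in combinations(self.class_set, 2)}
        present = set(self.classifiers.keys())
        if present != expected:
            raise InvalidArgumentError(
                f"need exactly one classifier per pair; missing "
                f"{sorted(map(sorted, expected - present))}"
            )

    @property
    def n_classifiers(self) -> int:
        return len(self.classifiers)

    def window_probability_tables(self, windows: WindowSet):
        """Per-pair (n, 2) probability arrays for a whole window set."""
        return {key: pm.window_probs(windows)
                for key, pm in sorted(self.classifiers.items(),
                                      key=lambda kv: sorted(kv[0]))}


def ovo_vote(probability_table: dict, class_set) -> tuple:
    """Resolve one window's one-vs-one vote.

    ``probability_table`` maps frozenset({a, b}) -> (p_a, p_b) with a < b.
    Stage 1: plain vote count. Stage 2 (tie): recount only classifiers
    whose pair lies inside the tied set. Stage 3 (still tied): for each
    remaining candidate, sum its probabilities over every classifier
    involving it; exact ties fall back to the smallest label.
    Returns (label, vote_tally dict).
    """
    tally = {c: 0 for c in class_set}
    pair_winner = {}
    for key, (p_a, p_b) in probability_table.items():
        a, b = sorted(key)
        winner = a if p_a >= p_b else b
        pair_winner[key] = winner
        tally[winner] += 1
    top = max(tally.values())
    tied = sorted(c for c, v in tally.items() if v == top)
    if len(tied) == 1:
        return tied[0], tally

    sub = {c: 0 for c in tied}
    for key, winner in pair_winner.items():
        if key <= frozenset(tied) and winner in sub:
            sub[winner] += 1
    sub_top = max(sub.values())
    tied = sorted(c for c, v in sub.items() if v == sub_top)
    if len(tied) == 1:
        return tied[0], tally

    cumulative = {c: 0.0 for c in tied}
    for key, (p_a, p_b) in probability_table.items():
        a, b = sorted(key)
        if a in cumulative:
            cumulative[a] += p_a
        if b in cumulative:
            cumulative[b] += p_b
    best = max(cumulative.values())
    winner = min(c for c, v in cumulative.items() if v == best)
    return winner, tally


def ovo_predict(ensemble: OvOEnsemble, windows: WindowSet):
    """Per-window five-class labels plus vote tallies and probability tables."""
    tables = ensemble.window_probability_tables(windows)
    n = windows.n_windows
    labels = np.empty(n, dtype=int)
    tallies = []
    for i in range(n):
        table = {key: tuple(prob[i]) for key, prob in tables.items()}
        labels[i], tally = ovo_vote(table, ensemble.class_set)
        tallies.append(tally)
    return labels, tallies, tables


@dataclass(frozen=True)
class ExperimentConfig:
    """Full experiment description (architecture, training, split, features)."""

    model: ScbamConfig = ScbamConfig()
    train: TrainConfig = TrainConfig()
    plan: FoldPlan = FoldPlan()
    bands: BandSpec = BandSpec()
    n_csp_components: int = 12
    band_first: bool = False
    window_len: int = 600
    step: int = 300
    artifact_z_thresh: float = 6.0
    artifact_channel_frac: float = 0.10
    n_perm: int = 5000
    seed: int = 0


def _config_hash(config: ExperimentConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _trial_votes(window_labels, trial_ids):
    """Aggregate window labels to per-trial majority votes.

    Returns (trial_id array, voted label array) in ascending trial order.
    """
    trials = np.unique(trial_ids)
    voted = np.array([vote_trial(window_labels[trial_ids == t]) for t in trials])
    return trials, voted


def run_experiment(session, config: ExperimentConfig) -> dict:
    """Run the full decoding workflow on one subject's session.

    ``session`` is a list of (Recording, EventTable) pairs, one per run
    (e.g. from :func:`scbam.synthgen.simulate_session`). Returns a
    JSON-serializable report with per-pair binary results, the five-class
    one-vs-one result, learning curves, and provenance. Byte-identical
    across repeated calls with the same inputs and seed.
    """
    config.plan.validate()
    runs = {rec.run_id: (rec, ev) for rec, ev in session}
    missing = [r for r in (*config.plan.train_runs, *config.plan.test_runs)
               if r not in runs]
    if missing:
        raise InvalidArgumentError(f"session is missing runs {missing}")

    seeds = np.random.SeedSequence(config.seed).generate_state(64)

    # --- preprocessing: fit the normalizer on training runs only ----------
    train_recs = [runs[r][0] for r in config.plan.train_runs]
    stats = fit_normalizer(train_recs)

    kept, rejected = {}, []
    for run_id in (*config.plan.train_runs, *config.plan.test_runs):
        rec, events = runs[run_id]
        normalized = rec.copy_with(
            (rec.signal - stats.mean[:, None]) / stats.sd[:, None])
        flags = detect_artifacts(normalized, config.artifact_z_thresh)
        if reject_run(flags, rec.n_channels, config.artifact_channel_frac):
            rejected.append(int(run_id))
            continue
        kept[run_id] = (preprocess_run(rec, stats), events)

    window_sets = [
        window_trials(rec, events, config.window_len, config.step)
        for rec, events in kept.values()
    ]
    if not window_sets:
        raise InvalidArgumentError("all runs were rejected by artifact screening")
    all_windows = WindowSet(
        np.concatenate([w.data for w in window_sets]),
        np.concatenate([w.labels for w in window_sets]),
        np.concatenate([w.trial_ids for w in window_sets]),
        np.concatenate([w.run_ids for w in window_sets]),
        config.window_len, config.step,
    )
    plan = FoldPlan(
        tuple(r for r in config.plan.train_runs if r in kept),
        tuple(r for r in config.plan.test_runs if r in kept),
    )
    train_w, _, test_w = split_by_runs(all_windows, plan, 0.0,
                                       seed=int(seeds[0]))

    class_set = tuple(sorted(np.unique(all_windows.labels).tolist()))
    pairs = list(combinations(class_set, 2))

    # --- per-pair feature extraction and training --------------------------
    # validation is carved per pair (stratified by class) from the training
    # windows, so both classes of every comparison appear in its val set
    classifiers = {}
    binary_reports = {}
    n_val_total = 0
    fs = next(iter(kept.values()))[0].fs
    for k, (a, b) in enumerate(pairs):
        pair_w = train_w.subset(np.isin(train_w.labels, (a, b)))
        tr, va = carve_validation(pair_w, config.train.val_fraction,
                                  seed=int(seeds[0]) ^ (k + 1))
        n_val_total += va.n_windows
        featurizer = FBCSPModel(config.bands, fs, config.n_csp_components,
                                config.band_first).fit(tr, (a, b))
        fm_tr = featurizer.transform(tr)
        fm_va = featurizer.transform(va)
        scaler = _FeatureScaler().fit(fm_tr.values)
        pair_train_cfg = TrainConfig(
            epochs=config.train.epochs, batch_size=config.train.batch_size,
            learning_rate=config.train.learning_rate,
            val_fraction=config.train.val_fraction,
            optimizer_name=config.train.optimizer_name,
            shuffle=config.train.shuffle, seed=int(seeds[1 + k]),
        )
        net, curves = train_binary(fm_tr, fm_va, config.model, pair_train_cfg,
                                   scaler=scaler)
        pm = PairModel((a, b), featurizer, scaler, net, curves)
        classifiers[frozenset((a, b))] = pm

        # binary evaluation on the pair's test windows
        te = test_w.subset(np.isin(test_w.labels, (a, b)))
        probs = pm.window_probs(te)
        win_pred = np.where(probs[:, 1] >= 0.5, b, a)
        trials, voted = _trial_votes(win_pred, te.trial_ids)
        truth = np.array([te.labels[te.trial_ids == t][0] for t in trials])
        cm = confusion_matrix(truth, voted, class_labels=[a, b])
        perm = permutation_test(truth, voted, config.n_perm,
                                rng=int(seeds[20 + k]))
        roc, auc_value = roc_points(probs[:, 1], te.labels, positive_label=b)
        binary_reports[f"{a}v{b}"] = {
            "pair": [a, b],
            "trial_accuracy": accuracy(cm),
            "window_accuracy": float(np.mean(win_pred == te.labels)),
            "kappa": cohens_kappa(cm),
            "confusion": cm.counts.tolist(),
            "n_test_trials": int(trials.size),
            "permutation_p": perm["p_value"],
            "permutation_null_mean": perm["null_mean"],
            "auc": auc_value,
            "learning_curves": curves,
        }

    ensemble = OvOEnsemble(classifiers, class_set)

    # --- five-class one-vs-one evaluation ----------------------------------
    win_labels, _, _ = ovo_predict(ensemble, test_w)
    trials, voted = _trial_votes(win_labels, test_w.trial_ids)
    truth = np.array([test_w.labels[test_w.trial_ids == t][0] for t in trials])
    cm5 = confusion_matrix(truth, voted, class_labels=list(class_set))
    perm5 = permutation_test(truth, voted, config.n_perm, rng=int(seeds[40]))

    report = {
        "provenance": {
            "seed": config.seed,
            "config_hash": _config_hash(config),
            "rejected_runs": rejected,
            "n_train_windows": int(train_w.n_windows),
            "n_val_windows_total": int(n_val_total),
            "n_test_windows": int(test_w.n_windows),
        },
        "binary": binary_reports,
        "five_class": {
            "trial_accuracy": accuracy(cm5),
            "window_accuracy": float(
                np.mean(win_labels == test_w.labels)),
            "kappa": cohens_kappa(cm5),
            "confusion": cm5.counts.tolist(),
            "n_test_trials": int(trials.size),
            "permutation_p": perm5["p_value"],
            "permutation_null_mean": perm5["null_mean"],
            "permutation_null_band": [perm5["null_quantiles"]["q025"],
                                      perm5["null_quantiles"]["q975"]],
        },
    }
    return report


def report_to_json(report: dict) -> str:
    """Canonical JSON serialization (sorted keys) of an experiment report."""
    return json.dumps(report, sort_keys=True, indent=2)
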