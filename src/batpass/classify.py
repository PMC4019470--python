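"""Random-forest species classification of bat passes.

A 100-tree random forest (three features drawn per split, trees fully
grown) is trained on 80% of a labeled reference call library, stratified by
species.  Per-call species probabilities are the ensemble vote fractions;
pass-level assignment sums these probabilities over the high-quality calls
of a pass and takes the species with the highest sum.  The winner's summed
probability divided by the number of calls ("mean call probability") feeds
an optional inclusion threshold for species-level analysis.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from . import zc

__all__ = [
    "ClassifierModel",
    "EvalReport",
    "LabeledCall",
    "PassAssignment",
    "ReferenceLibrary",
    "apply_threshold",
    "classify_pass",
    "evaluate",
    "load_model",
    "replicate_accuracy",
    "save_model",
    "stratified_split",
    "train_classifier",
]


@dataclass
class LabeledCall:
    """One reference call with its known species label."""

    species: str
    call: zc.Call

    @property
    def features(self) -> zc.CallFeatures:
        if self.call.features is None:
            zc.featurize_call(self.call)
        if self.call.features is None:
            raise zc.DegenerateCallError("labeled call cannot be featurized")
        return self.call.features


@dataclass
class ReferenceLibrary:
    """A labeled reference call set for classifier training."""

    entries: list[LabeledCall]
    species_list: tuple[str, ...]

    def __post_init__(self) -> None:
        known = set(self.species_list)
        for e in self.entries:
            if e.species not in known:
                raise ValueError(f"label {e.species!r} not in species_list")

    def __len__(self) -> int:
        return len(self.entries)

    def counts(self) -> dict[str, int]:
        out = {s: 0 for s in self.species_list}
        for e in self.entries:
            out[e.species] += 1
        return out

    def feature_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, labels) over entries with extractable features."""
        X, labels = [], []
        for e in self.entries:
            try:
                ft = e.features
            except zc.DegenerateCallError:
                continue
            X.append(ft.as_array())
            labels.append(e.species)
        return np.array(X), np.array(labels)


def stratified_split(
    library: ReferenceLibrary,
    train_frac: float = 0.8,
    seed: int | np.random.Generator = 0,
) -> tuple[list[int], list[int]]:
    """Split library entry indices into train/test sets, per species.

    Per species the train count is floor(train_frac * n), with the
    fractional remainder promoted by a seeded Bernoulli draw, so expected
    proportions are exact and the realized split is within one call of the
    target.  Returns (train_indices, test_indices); disjoint, exhaustive.
    """
    if not (0.0 < train_frac < 1.0):
        raise ValueError("train_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    counts = library.counts()
    for s, n in counts.items():
        if 0 < n < 2:
            raise ValueError(f"species {s!r} has {n} call(s); cannot stratify")
    by_species: dict[str, list[int]] = {s: [] for s in library.species_list}
    for i, e in enumerate(library.entries):
        by_species[e.species].append(i)
    train: list[int] = []
    test: list[int] = []
    for s in library.species_list:
        idx = np.array(by_species[s], dtype=int)
        if idx.size == 0:
            continue
        exact = train_frac * idx.size
        n_train = int(np.floor(exact))
        if rng.random() < exact - n_train:
            n_train += 1
        n_train = min(max(n_train, 1), idx.size - 1)
        perm = rng.permutation(idx)
        train.extend(perm[:n_train].tolist())
        test.extend(perm[n_train:].tolist())
    return sorted(train), sorted(test)


@dataclass
class ClassifierModel:
    """A fitted random-forest species classifier."""

    forest: RandomForestClassifier
    species_list: tuple[str, ...]
    train_indices: list[int]
    test_indices: list[int]
    seed: int

    def predict_proba_calls(self, calls) -> np.ndarray:
        """Per-call species probability vectors (rows sum to 1).

        ``calls`` may be :class:`~batpass.zc.Call` objects, CallFeatures,
        or raw 11-feature rows.  Columns follow ``species_list``.
        """
        X = _feature_rows(calls)
        raw = self.forest.predict_proba(X)
        # map sklearn's class order onto species_list order
        out = np.zeros((X.shape[0], len(self.species_list)))
        for j, cls in enumerate(self.forest.classes_):
            out[:, self.species_list.index(cls)] = raw[:, j]
        return out


def _feature_rows(calls) -> np.ndarray:
    rows = []
    for c in calls:
        if isinstance(c, zc.Call):
            zc.featurize_call(c)
            if c.features is None:
                raise zc.DegenerateCallError("call cannot be featurized")
            rows.append(c.features.as_array())
        elif isinstance(c, zc.CallFeatures):
            rows.append(c.as_array())
        else:
            rows.append(np.asarray(c, dtype=float))
    return np.array(rows)


def train_classifier(
    library: ReferenceLibrary,
    train_indices: list[int] | None = None,
    n_trees: int = 100,
    features_per_split: int = 3,
    seed: int = 0,
) -> ClassifierModel:
    """Train the random forest on the (stratified) training subset.

    Trees are fully grown; each node considers ``features_per_split``
    randomly drawn features.  Per-call probabilities are the fraction of
    trees voting for each species.  Deterministic for a fixed seed.
    """
    if train_indices is None:
        train_indices, test_indices = stratified_split(library, seed=seed)
    else:
        test_indices = sorted(
            set(range(len(library.entries))) - set(train_indices)
        )
    X, labels = [], []
    for i in train_indices:
        e = library.entries[i]
        try:
            X.append(e.features.as_array())
            labels.append(e.species)
        except zc.DegenerateCallError:
            continue
    X = np.array(X)
    labels = np.array(labels)
    if np.unique(labels).size < 2:
        raise ValueError("training set has fewer than 2 species")
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=features_per_split,
        bootstrap=True,
        random_state=seed,
    )
    forest.fit(X, labels)
    return ClassifierModel(
        forest=forest,
        species_list=library.species_list,
        train_indices=list(train_indices),
        test_indices=list(test_indices),
        seed=seed,
    )


@dataclass
class EvalReport:
    """Held-out evaluation of a classifier."""

    accuracy: float
    per_species: pd.DataFrame       # precision, recall, n_test per species
    confusion: pd.DataFrame         # rows = true, columns = predicted
    undefined_recall: tuple[str, ...] = ()
    n_replicates: int = 1
    accuracy_mean: float | None = None
    accuracy_sd: float | None = None


def evaluate(model: ClassifierModel, library: ReferenceLibrary,
             test_indices: list[int] | None = None) -> EvalReport:
    """Evaluate on held-out calls: confusion matrix, precision, recall.

    Precision P_s = TP_s / (TP_s + FP_s), recall R_s = TP_s / (TP_s + FN_s),
    accuracy = trace / total.  Species absent from the test set are flagged
    (recall undefined) rather than silently scored 0.
    """
    idx = model.test_indices if test_indices is None else test_indices
    entries = [library.entries[i] for i in idx]
    X = _feature_rows([e.call for e in entries])
    truth = np.array([e.species for e in entries])
    pred_raw = model.forest.predict(X)

    species = list(model.species_list)
    k = len(species)
    conf = np.zeros((k, k), dtype=int)
    pos = {s: i for i, s in enumerate(species)}
    for t, p in zip(truth, pred_raw):
        conf[pos[t], pos[p]] += 1
    total = conf.sum()
    accuracy = float(np.trace(conf) / total) if total else float("nan")

    tp = np.diag(conf).astype(float)
    pred_tot = conf.sum(axis=0).astype(float)
    true_tot = conf.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(pred_tot > 0, tp / pred_tot, np.nan)
        recall = np.where(true_tot > 0, tp / true_tot, np.nan)
    undefined = tuple(s for i, s in enumerate(species) if true_tot[i] == 0)
    per_species = pd.DataFrame(
        {"precision": precision, "recall": recall,
         "n_test": true_tot.astype(int)},
        index=species,
    )
    confusion = pd.DataFrame(conf, index=species, columns=species)
    return EvalReport(
        accuracy=accuracy,
        per_species=per_species,
        confusion=confusion,
        undefined_recall=undefined,
    )


def replicate_accuracy(
    library: ReferenceLibrary,
    n_replicates: int = 10,
    seed: int = 0,
    **train_kw,
) -> EvalReport:
    """Mean and SD of held-out accuracy over replicate split+fit cycles.

    Replicate r uses seed ``seed + r`` for both the stratified split and the
    forest, mirroring a replicate-fit evaluation protocol.
    """
    accs = []
    last = None
    for r in range(n_replicates):
        s = seed + r
        train_idx, _test_idx = stratified_split(library, seed=s)
        model = train_classifier(
            library, train_indices=train_idx, seed=s, **train_kw
        )
        last = evaluate(model, library)
        accs.append(last.accuracy)
    accs = np.array(accs)
    last.n_replicates = n_replicates
    last.accuracy_mean = float(accs.mean())
    last.accuracy_sd = float(accs.std(ddof=1)) if n_replicates > 1 else 0.0
    return last


@dataclass
class PassAssignment:
    """Species assignment of one pass by the probability-summation rule."""

    pass_id: str
    summed_probs: pd.Series         # per-species summed call probabilities
    n_calls: int                    # high-quality calls contributing
    winner: str
    mean_prob: float
    detector_night_id: str | None = None
    true_species: str | None = None


def classify_pass(model: ClassifierModel, pass_: zc.Pass) -> PassAssignment:
    """Assign a species to a pass by summing per-call probabilities.

    Only high-quality calls contribute; their probability vectors are
    summed over calls, so the species-sum equals the number of quality
    calls.  The winner is the argmax, with ties broken deterministically in
    ``species_list`` order; ``mean_prob`` is the winner's summed
    probability divided by the number of quality calls.
    """
    quality = pass_.quality_calls
    if not quality:
        raise ValueError(
            f"pass {pass_.pass_id} has no high-quality calls; "
            "apply quality_filter and drop_empty_passes first"
        )
    probs = model.predict_proba_calls(quality)
    summed = probs.sum(axis=0)
    winner_i = int(np.argmax(summed))       # first max = species_list order
    summed_series = pd.Series(summed, index=list(model.species_list))
    n = len(quality)
    return PassAssignment(
        pass_id=pass_.pass_id,
        summed_probs=summed_series,
        n_calls=n,
        winner=model.species_list[winner_i],
        mean_prob=float(summed[winner_i] / n),
        detector_night_id=pass_.detector_night_id,
        true_species=pass_.species,
    )


def apply_threshold(
    assignments: list[PassAssignment], threshold: float = 0.45
) -> tuple[list[PassAssignment], float]:
    """Retain passes with mean call probability >= threshold.

    Returns (retained assignments, retained fraction).
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must be within [0, 1]")
    kept = [a for a in assignments if a.mean_prob >= threshold]
    frac = len(kept) / len(assignments) if assignments else float("nan")
    return kept, frac


def save_model(model: ClassifierModel, path) -> None:
    """Persist a fitted classifier (opaque payload + metadata) to one file."""
    payload = {
        "forest": model.forest,
        "species_list": model.species_list,
        "train_indices": model.train_indices,
        "test_indices": model.test_indices,
        "seed": model.seed,
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_model(path) -> ClassifierModel:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    return ClassifierModel(**payload)
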