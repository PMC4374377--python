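"""Under-sampling ensemble of extreme learning machines with a
vote-fraction risk score.

This is the study's machine-learning method. The training data are
imbalanced (1 case : 4 controls), so each of T base classifiers is
trained on a balanced subset: the full positive set P plus a random
under-sample N_t of the negative set with |N_t| = |P|. Each base
classifier is a single-hidden-layer feed-forward network trained by
extreme learning machine (ELM): input weights and hidden biases are
random and never updated; only the output weights are fitted, by
least squares. The ensemble's hard votes are combined into a risk score

    RS(x) = 100 * (number of positive votes) / T,

an integer-granular score on [0, 100] (multiples of 100/T).

Defaults follow the study: T = 100 classifiers, 30 hidden neurons,
sigmoid activation. Input weights are uniform on [-1, 1] and biases
uniform on [0, 1] (the common ELM convention; both configurable).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .synthetic_data import MODEL_PREDICTORS, Cohort

__all__ = [
    "ElmClassifier",
    "TrainingSet",
    "EnsembleModel",
    "undersample",
    "train_elm",
    "classify",
    "build_ensemble",
    "risk_score",
    "score_cohort",
    "ensemble_to_json",
    "ensemble_from_json",
]


@dataclass
class TrainingSet:
    """One balanced under-sample: features, 0/1 labels, and which draw."""

    X: np.ndarray
    y: np.ndarray
    provenance: str = ""


@dataclass
class ElmClassifier:
    """A single-hidden-layer network with random, fixed hidden layer.

    ``input_weights`` is (n_features, n_hidden); ``biases`` (n_hidden,);
    ``output_weights`` (n_hidden,) is the least-squares solution of the
    hidden activations against the 0/1 targets. The continuous output is
    H(x) @ output_weights, thresholded at ``threshold`` for a hard vote.
    """

    input_weights: np.ndarray
    biases: np.ndarray
    output_weights: np.ndarray
    threshold: float = 0.5

    @property
    def n_hidden(self) -> int:
        return self.input_weights.shape[1]

    def hidden(self, X: np.ndarray) -> np.ndarray:
        return expit(X @ self.input_weights + self.biases)

    def decision(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.input_weights.shape[0]:
            raise ValueError(
                f"feature dimension {X.shape[1]} != "
                f"trained dimension {self.input_weights.shape[0]}")
        return self.hidden(X) @ self.output_weights


def undersample(P: np.ndarray, N: np.ndarray,
                seed: int | np.random.Generator = 0) -> TrainingSet:
    """Balanced subset: all of P plus |P| negatives drawn uniformly
    without replacement from N. Undefined (raises) when |P| > |N|."""
    P = np.atleast_2d(np.asarray(P, dtype=float))
    N = np.atleast_2d(np.asarray(N, dtype=float))
    if len(P) < 1:
        raise ValueError("positive set is empty")
    if len(P) > len(N):
        raise ValueError("under-sampling undefined: |P| > |N|")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.choice(len(N), size=len(P), replace=False)
    X = np.vstack([P, N[idx]])
    y = np.concatenate([np.ones(len(P)), np.zeros(len(P))])
    return TrainingSet(X=X, y=y, provenance=f"undersample:{len(P)}/{len(N)}")


def train_elm(ts: TrainingSet, n_hidden: int = 30,
              rng: int | np.random.Generator = 0,
              weight_range: tuple[float, float] = (-1.0, 1.0),
              bias_range: tuple[float, float] = (0.0, 1.0),
              ridge: float = 1e-8) -> ElmClassifier:
    """Train one ELM: draw the hidden layer at random, then solve the
    minimum-norm least-squares problem for the output weights.

    A rank-deficient hidden design (30 hidden units can exceed the rank
    spanned by few distinct binary rows) is handled by the minimum-norm
    solution itself; if the solver fails, a small ridge is the fallback —
    never an exception.
    """
    if len(ts.y) < 2 or len(np.unique(ts.y)) < 2:
        raise ValueError("training set needs >= 2 samples from both classes")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    d = ts.X.shape[1]
    W = rng.uniform(*weight_range, size=(d, n_hidden))
    b = rng.uniform(*bias_range, size=n_hidden)
    H = expit(ts.X @ W + b)
    try:
        beta, *_ = np.linalg.lstsq(H, ts.y, rcond=None)
    except np.linalg.LinAlgError:
        beta = np.linalg.solve(H.T @ H + ridge * np.eye(n_hidden), H.T @ ts.y)
    return ElmClassifier(input_weights=W, biases=b, output_weights=beta)


def classify(clf: ElmClassifier, x) -> np.ndarray:
    """Hard vote(s): 1 iff the continuous output is >= the threshold."""
    return (clf.decision(x) >= clf.threshold).astype(int)


@dataclass
class EnsembleModel:
    """T trained ELM classifiers sharing one feature order."""

    classifiers: list[ElmClassifier]
    feature_names: list[str]
    seed: int

    @property
    def T(self) -> int:
        return len(self.classifiers)


def build_ensemble(P: np.ndarray, N: np.ndarray, T: int = 100,
                   n_hidden: int = 30, seed: int = 0,
                   feature_names: list[str] | None = None) -> EnsembleModel:
    """Create the decision ensemble: T independent under-samples, each
    training one ELM with its own random hidden layer.

    One master seed spawns an independent substream per classifier, so
    growing T extends the ensemble without reshuffling earlier members.
    """
    P = np.atleast_2d(np.asarray(P, dtype=float))
    if feature_names is None:
        feature_names = [f"x{i}" for i in range(P.shape[1])]
    streams = np.random.SeedSequence(seed).spawn(T)
    classifiers = []
    for t in range(T):
        rng = np.random.default_rng(streams[t])
        ts = undersample(P, N, seed=rng)
        classifiers.append(train_elm(ts, n_hidden=n_hidden, rng=rng))
    return EnsembleModel(classifiers=classifiers,
                         feature_names=list(feature_names), seed=seed)


def risk_score(ens: EnsembleModel, x) -> float:
    """The vote-fraction risk score: 100 * (positive votes) / T."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] != 1:
        raise ValueError("risk_score takes a single record; use score_cohort")
    votes = sum(int(classify(clf, x)[0]) for clf in ens.classifiers)
    return 100.0 * votes / ens.T


def score_cohort(ens: EnsembleModel, cohort: Cohort | np.ndarray) -> np.ndarray:
    """Risk scores for every record, order-preserving."""
    if isinstance(cohort, Cohort):
        X = cohort.data[ens.feature_names].to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(cohort, dtype=float))
    votes = np.zeros(len(X))
    for clf in ens.classifiers:
        votes += classify(clf, X)
    return 100.0 * votes / ens.T


def features_matrix(cohort: Cohort,
                    names: list[str] = list(MODEL_PREDICTORS)) -> np.ndarray:
    """Binary feature matrix in the ensemble's order (age is not a
    feature; the model uses the seven binary items only)."""
    X = cohort.data[list(names)].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing values in model features")
    return X


def ensemble_to_json(ens: EnsembleModel, path=None) -> dict:
    obj = {
        "T": ens.T,
        "n_hidden": ens.classifiers[0].n_hidden if ens.classifiers else 0,
        "feature_names": ens.feature_names,
        "seed": ens.seed,
        "classifiers": [
            {"input_weights": c.input_weights.tolist(),
             "biases": c.biases.tolist(),
             "output_weights": c.output_weights.tolist(),
             "threshold": c.threshold}
            for c in ens.classifiers
        ],
    }
    if path is not None:
        with open(path, "w") as fh:
            json.dump(obj, fh)
    return obj


def ensemble_from_json(obj_or_path) -> EnsembleModel:
    if isinstance(obj_or_path, dict):
        obj = obj_or_path
    else:
        with open(obj_or_path) as fh:
            obj = json.load(fh)
    clfs = [ElmClassifier(np.array(c["input_weights"]), np.array(c["biases"]),
                          np.array(c["output_weights"]), c["threshold"])
            for c in obj["classifiers"]]
    return EnsembleModel(classifiers=clfs, feature_names=obj["feature_names"],
                         seed=obj["seed"])
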