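"""Learned and feature-guided cherry pickers.

The supervised signal imitates an oracle for "good" cherries: a candidate
pair (x, y) of the tree set is labelled by its role in the (known, simulated)
generating network N —

* class 1: (x, y) is a cherry of N;
* class 2: (x, y) is a reticulated cherry of N;
* class 3: (x, y) is not reducible in N but (y, x) is a reticulated cherry;
* class 4: neither order is reducible in N.

Training walks random reducible pairs of N: at every step each current
ordered cherry of the tree set contributes one data point (19 features +
class), then the picked pair is reduced in both the trees and N, until N is
fully reduced.  Classes are balanced by downsampling before fitting a
random forest with library-default settings.

Pickers:

* ``MLPicker`` — scores every candidate by P(class 1) + P(class 2); takes
  the argmax when it reaches the threshold tau, else a uniform random pair.
  With tau = 0 the heuristic is fully deterministic (lexicographic ties).
* ``TrivialMLPicker`` — a random trivial pair when one exists, else ML.
* ``FeatImpPicker`` — no model: filters candidates through the four most
  important features (trivialness f4, topological leaf distance f8t, LCA
  distance ratio f11d, topological depth ratio f12t), keeping the top
  alpha% at each stage and returning the top scorer of the final stage.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .cps import Picker, PickerContractError, TreeSetState
from .features import FEATURE_NAMES, FeatureIndex
from .phylo import Pair, PairKind, PhyloNetwork
from .simgen import exhaustive_trees

CLASSES = (1, 2, 3, 4)

_SCHEMA_VERSION = 1


def label_pair(net: PhyloNetwork, pair: Pair) -> int:
    """The 4-class label of an ordered pair w.r.t. the reference network."""
    kind = net.classify_pair(pair)
    if kind is PairKind.CHERRY:
        return 1
    if kind is PairKind.RETICULATED_CHERRY:
        return 2
    if net.classify_pair((pair[1], pair[0])) is PairKind.RETICULATED_CHERRY:
        return 3
    return 4


def make_training_set(
    networks: Sequence[PhyloNetwork],
    seed: int = 0,
    balance: bool = True,
) -> pd.DataFrame:
    """Labelled cherry features from reference networks and their trees.

    Every network must be orchard (fully reducible); its exhaustive displayed
    trees form the tree set.  Returns a DataFrame with the 19 feature columns
    plus ``label``.
    """
    rng = random.Random(seed)
    rows: List[np.ndarray] = []
    labels: List[int] = []
    for net in networks:
        work = net.copy()
        trees = exhaustive_trees(work)
        state = TreeSetState(trees, seed=rng.randrange(2**31))
        index = FeatureIndex(state)
        while not work.is_fully_reduced():
            candidates = list(state.cherry_trees)
            if candidates:
                _, mat = index.table(candidates)
                for pair, vec in zip(candidates, mat):
                    rows.append(vec)
                    labels.append(label_pair(work, pair))
            from .phylo import reducible_pairs

            options = reducible_pairs(work)
            if not options:
                raise ValueError("reference network is not orchard")
            pick = options[rng.randrange(len(options))]
            work.reduce_pair(pick)
            state.reduce(pick)
    df = pd.DataFrame(np.vstack(rows), columns=FEATURE_NAMES)
    df["label"] = labels
    if balance:
        df = balance_classes(df, seed=seed)
    return df


def balance_classes(df: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Downsample so every present class has the size of the smallest."""
    counts = df["label"].value_counts()
    n = int(counts.min())
    parts = [
        g.sample(n=n, random_state=seed, replace=False)
        for _, g in df.groupby("label")
    ]
    return pd.concat(parts).sample(frac=1.0, random_state=seed).reset_index(drop=True)


@dataclass
class CherryClassifier:
    """A fitted 4-class random forest over the 19 cherry features."""

    model: RandomForestClassifier
    columns: List[str] = field(default_factory=lambda: list(FEATURE_NAMES))
    metadata: Dict = field(default_factory=dict)

    def predict_proba(self, mat: np.ndarray) -> np.ndarray:
        """(n, 4) class-probability matrix aligned to classes 1..4."""
        raw = self.model.predict_proba(mat)
        out = np.zeros((mat.shape[0], len(CLASSES)))
        for j, cls in enumerate(self.model.classes_):
            out[:, CLASSES.index(int(cls))] = raw[:, j]
        return out

    def reducible_score(self, mat: np.ndarray) -> np.ndarray:
        """P(class 1) + P(class 2): predicted probability of reducibility."""
        probs = self.predict_proba(mat)
        return probs[:, 0] + probs[:, 1]

    def feature_importances(self) -> pd.Series:
        """Impurity importances mapped to feature names (sum to 1)."""
        imp = pd.Series(self.model.feature_importances_, index=self.columns)
        return imp.sort_values(ascending=False)

    def save(self, path: str) -> None:
        joblib.dump(
            {
                "schema_version": _SCHEMA_VERSION,
                "columns": self.columns,
                "metadata": self.metadata,
                "model": self.model,
            },
            path,
        )

    @classmethod
    def load(cls, path: str) -> "CherryClassifier":
        bundle = joblib.load(path)
        if (
            bundle.get("schema_version") != _SCHEMA_VERSION
            or bundle.get("columns") != list(FEATURE_NAMES)
        ):
            raise ValueError("incompatible classifier bundle")
        return cls(bundle["model"], bundle["columns"], bundle["metadata"])


def train_classifier(
    data: pd.DataFrame,
    holdout_frac: float = 0.1,
    seed: int = 0,
    metadata: Optional[Dict] = None,
) -> Tuple[CherryClassifier, Dict]:
    """Fit a random forest (library defaults) with a holdout accuracy report."""
    if data["label"].nunique() < 2:
        raise ValueError("training data must contain at least two classes")
    X = data[list(FEATURE_NAMES)].to_numpy()
    y = data["label"].to_numpy()
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=holdout_frac, random_state=seed, stratify=y
    )
    model = RandomForestClassifier(random_state=seed)
    model.fit(X_tr, y_tr)
    acc = float((model.predict(X_te) == y_te).mean())
    clf = CherryClassifier(model, metadata=dict(metadata or {}))
    report = {
        "holdout_accuracy": acc,
        "n_train": int(len(y_tr)),
        "n_holdout": int(len(y_te)),
        "importances": clf.feature_importances().to_dict(),
    }
    return clf, report


def feature_importances(clf: CherryClassifier) -> pd.Series:
    return clf.feature_importances()


# ------------------------------------------------------------------- pickers
class MLPicker(Picker):
    """Argmax of the predicted reducibility probability, thresholded by tau."""

    wants_expansion = True

    def __init__(
        self,
        classifier: CherryClassifier,
        tau: float = 0.0,
        rng: Optional[random.Random] = None,
    ) -> None:
        if not 0.0 <= tau < 1.0:
            raise ValueError("tau must be in [0, 1)")
        self.classifier = classifier
        self.tau = tau
        self.rng = rng
        self.index: Optional[FeatureIndex] = None

    def reset(self, state: TreeSetState) -> None:
        self.index = FeatureIndex(state)

    def _rng(self, state: TreeSetState) -> random.Random:
        return self.rng if self.rng is not None else state.rng

    def _scored_pick(self, state: TreeSetState) -> Pair:
        if self.index is None or self.index.state is not state:
            self.index = FeatureIndex(state)
        candidates = list(state.cherry_trees)
        if not candidates:
            raise PickerContractError("no reducible pair available")
        _, mat = self.index.table(candidates)
        scores = self.classifier.reducible_score(mat)
        best = float(scores.max())
        if best >= self.tau:
            winners = sorted(
                c for c, s in zip(candidates, scores) if s == best
            )
            return winners[0]
        return candidates[self._rng(state).randrange(len(candidates))]

    def pick(self, state: TreeSetState) -> Pair:
        return self._scored_pick(state)


class TrivialMLPicker(MLPicker):
    """A uniformly random trivial pair if any; otherwise the ML rule."""

    def pick(self, state: TreeSetState) -> Pair:
        trivial = state.trivial_pairs()
        if trivial:
            return trivial[self._rng(state).randrange(len(trivial))]
        return self._scored_pick(state)


# FeatImp filter stages: (feature name, higher-is-better)
FEATIMP_STAGES: Tuple[Tuple[str, bool], ...] = (
    ("f4", True),    # trivialness — higher means closer to a safe pick
    ("f8t", False),  # leaf distance — cherries of the target have distance 0
    ("f11d", True),  # x much farther from the LCA suggests a reticulated cherry
    ("f12t", False), # x relatively shallow is preferred
)


class FeatImpPicker(Picker):
    """Sequential top-alpha% filter on the most important features."""

    wants_expansion = True

    def __init__(self, alpha: float = 20.0) -> None:
        if not 0 < alpha <= 100:
            raise ValueError("alpha must be in (0, 100]")
        self.alpha = alpha
        self.index: Optional[FeatureIndex] = None

    def reset(self, state: TreeSetState) -> None:
        self.index = FeatureIndex(state)

    def pick(self, state: TreeSetState) -> Pair:
        if self.index is None or self.index.state is not state:
            self.index = FeatureIndex(state)
        candidates = list(state.cherry_trees)
        if not candidates:
            raise PickerContractError("no reducible pair available")
        _, mat = self.index.table(candidates)
        cols = {name: i for i, name in enumerate(FEATURE_NAMES)}
        survivors = list(range(len(candidates)))
        for stage, (feat, hi) in enumerate(FEATIMP_STAGES):
            vals = mat[survivors, cols[feat]]
            order = sorted(
                range(len(survivors)),
                key=lambda i: ((-vals[i]) if hi else vals[i], candidates[survivors[i]]),
            )
            if stage < len(FEATIMP_STAGES) - 1:
                k = max(1, math.ceil(self.alpha / 100.0 * len(survivors)))
                survivors = [survivors[i] for i in order[:k]]
            else:
                return candidates[survivors[order[0]]]
        raise AssertionError("unreachable")
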