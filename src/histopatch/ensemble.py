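"""Five-classifier patch ensemble with average/product/max fusion.

Concatenated patch features are classified by k-nearest neighbours, an
RBF support-vector machine (probability-calibrated), a random forest,
AdaBoost, and gradient-boosted trees. The five per-patch probability
vectors are fused classwise by the arithmetic mean, the product, or the
elementwise maximum, and the fused scores pass through a softmax to yield
the final per-patch class probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from histopatch.io_dataset import CLASSES, CLASS_TO_INDEX
from histopatch.features import FeatureVector, features_to_matrix
from histopatch.nn import softmax

#: Member order is fixed; fusion is equivariant to it anyway.
CLASSIFIER_NAMES = ("knn", "svm", "random_forest", "adaboost", "xgb")

FUSION_RULES = ("average", "product", "maximum")


@dataclass
class PatchClassProbabilities:
    """A per-patch probability vector over the four classes."""

    patch_ref: str
    probs: np.ndarray
    source: str

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if abs(self.probs.sum() - 1.0) > 1e-6:
            raise ValueError(f"patch {self.patch_ref}: probabilities sum to {self.probs.sum()}")

    @property
    def predicted_index(self) -> int:
        return int(self.probs.argmax())  # ties break to lowest class index

    @property
    def predicted_label(self) -> str:
        return CLASSES[self.predicted_index]


class _HardProbWrapper:
    """predict_proba as one-hot of predict; only used at degenerate sample
    counts where the SVM's internal probability calibration cannot run."""

    def __init__(self, base) -> None:
        self._base = base

    def fit(self, x, y):
        self._base.fit(x, y)
        self.classes_ = self._base.classes_
        return self

    def predict_proba(self, x):
        pred = self._base.predict(x)
        out = np.zeros((len(pred), len(self.classes_)))
        for i, p in enumerate(pred):
            out[i, list(self.classes_).index(p)] = 1.0
        return out


@dataclass
class ClassifierBank:
    """The five fitted members plus the label set they were fitted on."""

    members: dict[str, object]
    classes_: np.ndarray
    seed: int
    fitted: bool = False

    def member_probs(self, name: str, x: np.ndarray) -> np.ndarray:
        """Probabilities over the full 4-class simplex, in canonical order."""
        if not self.fitted:
            raise RuntimeError("classifier bank is not fitted")
        member = self.members[name]
        raw = member.predict_proba(x)
        out = np.zeros((x.shape[0], len(CLASSES)))
        for j, cls in enumerate(member.classes_):
            out[:, int(cls)] = raw[:, j]
        return out


def _as_matrix_and_refs(features) -> tuple[np.ndarray, list[str]]:
    if isinstance(features, np.ndarray):
        return features, [str(i) for i in range(len(features))]
    if features and isinstance(features[0], FeatureVector):
        return features_to_matrix(features), [f.patch_ref for f in features]
    x = np.asarray(features, dtype=float)
    return x, [str(i) for i in range(len(x))]


def _label_indices(labels) -> np.ndarray:
    return np.array([CLASS_TO_INDEX[l] if isinstance(l, str) else int(l) for l in labels])


def make_members(seed: int, n_samples: int, min_class_count: int) -> dict[str, object]:
    """Default hyperparameters: k=5 neighbours (clamped to n), RBF SVM with
    probability calibration, 200 trees for the forest and both boosted
    members, all seeded."""
    if min_class_count >= 2:
        svm: object = CalibratedClassifierCV(
            SVC(kernel="rbf", random_state=seed), ensemble=False, cv=min(3, min_class_count)
        )
    else:
        svm = _HardProbWrapper(SVC(kernel="rbf", random_state=seed))
    return {
        "knn": KNeighborsClassifier(n_neighbors=min(5, n_samples)),
        "svm": svm,
        "random_forest": RandomForestClassifier(n_estimators=200, random_state=seed),
        # depth-2 base trees: four-class boosting with axis-aligned stumps
        # cannot separate grid-arranged classes
        "adaboost": AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=2, random_state=seed),
            n_estimators=200,
            random_state=seed,
        ),
        "xgb": XGBClassifier(
            n_estimators=200,
            random_state=seed,
            n_jobs=1,
            verbosity=0,
            eval_metric="mlogloss",
        ),
    }


def fit_bank(features, labels, seed: int = 0) -> ClassifierBank:
    """Fit all five members on aligned features and class labels."""
    x, _ = _as_matrix_and_refs(features)
    y = _label_indices(labels)
    if len(x) != len(y):
        raise ValueError(f"features ({len(x)}) and labels ({len(y)}) are misaligned")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to fit the classifier bank")
    members = make_members(seed, len(y), int(counts.min()))
    for member in members.values():
        member.fit(x, y)
    return ClassifierBank(members=members, classes_=classes, seed=seed, fitted=True)


def predict_bank(bank: ClassifierBank, features) -> dict[str, list[PatchClassProbabilities]]:
    """Aligned probability lists, one per member, in ``CLASSIFIER_NAMES`` order."""
    x, refs = _as_matrix_and_refs(features)
    out: dict[str, list[PatchClassProbabilities]] = {}
    for name in CLASSIFIER_NAMES:
        probs = bank.member_probs(name, x)
        probs = probs / probs.sum(axis=1, keepdims=True)
        out[name] = [PatchClassProbabilities(refs[i], probs[i], name) for i in range(len(refs))]
    return out


def fuse(per_classifier, rule: str = "average") -> list[PatchClassProbabilities]:
    """Fuse the five members' probability vectors patchwise, then softmax.

    ``rule``: "average" (classwise arithmetic mean), "product", or
    "maximum" (elementwise max).
    """
    if rule not in FUSION_RULES:
        raise ValueError(f"unknown fusion rule {rule!r}; options: {FUSION_RULES}")
    if isinstance(per_classifier, dict):
        lists = [per_classifier[name] for name in sorted(per_classifier)]
    else:
        lists = list(per_classifier)
    n = len(lists[0])
    for lst in lists:
        if len(lst) != n:
            raise ValueError("classifier probability lists are misaligned")
    fused = []
    for i in range(n):
        refs = {lst[i].patch_ref for lst in lists}
        if len(refs) != 1:
            raise ValueError(f"misaligned patch refs at position {i}: {refs}")
        stack = np.stack([lst[i].probs for lst in lists])
        if rule == "average":
            score = stack.mean(axis=0)
        elif rule == "product":
            score = stack.prod(axis=0)
        else:
            score = stack.max(axis=0)
        fused.append(PatchClassProbabilities(refs.pop(), softmax(score), "ensemble"))
    return fused


def predictions_table(preds: list[PatchClassProbabilities], patch_meta: dict[str, tuple] | None = None) -> pd.DataFrame:
    """Tabulate patch predictions as
    ``patch_id,parent_id,row,col,p_normal,p_benign,p_insitu,p_invasive,pred``."""
    rows = []
    for p in preds:
        parent, row, col = (patch_meta or {}).get(p.patch_ref, ("", -1, -1))
        rows.append((p.patch_ref, parent, row, col, *p.probs, p.predicted_label))
    return pd.DataFrame(
        rows,
        columns=["patch_id", "parent_id", "row", "col"] + [f"p_{c}" for c in CLASSES] + ["pred"],
    )
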