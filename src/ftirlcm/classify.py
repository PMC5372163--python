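"""Hierarchical random-forest classification of corrected tissue spectra.

Tissue annotation proceeds as a cascade of classifiers: the first level
separates the pathologic regions from other tissue, the second resolves the
tumour class within pathologic pixels, and the third provides the
differential diagnosis of tumour subtypes (for pleural mesothelioma:
epithelioid vs sarcomatoid).  Each level is an independent random forest
trained on the fingerprint region (1800-950 cm^-1) of quality-controlled,
EMSC-corrected absorbance spectra; a level only ever refines pixels whose
previous-level label is one of its declared parents.

The hierarchy is configuration, not code: :class:`CascadeSpec` expresses any
tissue taxonomy (the mesothelioma cascade or, e.g., a colorectal one) as an
ordered list of levels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .errors import ParameterError, StructuralError, ValidationError
from .hyperspec_io import LabelMap, SpectralImage

__all__ = [
    "FINGERPRINT_RANGE",
    "CascadeLevel",
    "CascadeSpec",
    "TrainedCascade",
    "EvalReport",
    "SampleCall",
    "extract_features",
    "train_cascade",
    "predict_cascade",
    "evaluate",
    "majority_sample_call",
    "dmm_cascade_spec",
]

FINGERPRINT_RANGE = (950.0, 1800.0)

# display colors for generated legends, cycled per class
_PALETTE = [
    "#1f77b4", "#2ca02c", "#d62728", "#ff7f0e", "#9467bd",
    "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf",
]


@dataclass(frozen=True)
class CascadeLevel:
    """One classifier level: its classes and which parent labels it refines.

    ``parents`` maps each class of this level to its parent class at the
    previous level; ``None`` parents (level 1) mean the level applies to all
    pixels.
    """

    name: str
    classes: tuple[str, ...]
    parents: dict[str, str] | None = None
    n_trees: int = 200
    max_depth: int | None = None

    def parent_set(self) -> set[str]:
        return set() if self.parents is None else set(self.parents.values())


@dataclass(frozen=True)
class CascadeSpec:
    """Ordered classifier hierarchy plus the shared feature range."""

    levels: tuple[CascadeLevel, ...]
    feature_range: tuple[float, float] = FINGERPRINT_RANGE
    min_train_pixels: int = 100

    def __post_init__(self) -> None:
        if not self.levels:
            raise ParameterError("cascade needs at least one level")
        if self.levels[0].parents is not None:
            raise ParameterError("level 1 must not declare parents")
        for i, level in enumerate(self.levels):
            if len(set(level.classes)) != len(level.classes):
                raise ParameterError(f"duplicate class names in level '{level.name}'")
            if i > 0:
                if level.parents is None:
                    raise ParameterError(
                        f"level '{level.name}' must declare parent classes"
                    )
                prev = set(self.levels[i - 1].classes)
                bad = level.parent_set() - prev
                if bad:
                    raise ParameterError(
                        f"level '{level.name}' refines unknown parent(s) {sorted(bad)}"
                    )

    def leaf_classes(self) -> list[str]:
        """Classes that are never refined by a deeper level, shallow-first."""
        refined: set[str] = set()
        for level in self.levels[1:]:
            refined |= level.parent_set()
        leaves = []
        for level in self.levels:
            leaves.extend(c for c in level.classes if c not in refined)
        return leaves

    def ancestor_at_level(self, leaf: str, level_index: int) -> str | None:
        """Label a leaf class carries at an earlier level (None if deeper)."""
        # walk upward through parent links
        current = leaf
        current_level = self._level_of(leaf)
        if current_level < level_index:
            return None
        while current_level > level_index:
            parents = self.levels[current_level].parents or {}
            current = parents[current]
            current_level -= 1
        return current

    def _level_of(self, cls: str) -> int:
        for i, level in enumerate(self.levels):
            if cls in level.classes:
                return i
        raise ValidationError(f"class '{cls}' not found in cascade")


def dmm_cascade_spec() -> CascadeSpec:
    """Default three-level cascade for pleural tissue annotation.

    Level 1 finds pathologic regions, level 2 the tumour class within them,
    level 3 the mesothelioma subtype.
    """
    return CascadeSpec(
        levels=(
            CascadeLevel("region", ("normal", "pathologic")),
            CascadeLevel(
                "tumour-class",
                ("mesothelioma", "other-neoplasm"),
                parents={"mesothelioma": "pathologic", "other-neoplasm": "pathologic"},
            ),
            CascadeLevel(
                "dmm-subtype",
                ("epithelioid", "sarcomatoid"),
                parents={"epithelioid": "mesothelioma", "sarcomatoid": "mesothelioma"},
            ),
        )
    )


def extract_features(
    image: SpectralImage, feature_range: tuple[float, float] = FINGERPRINT_RANGE
) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix (QC-passing pixels x fingerprint bands) + back-map.

    Rows are QC-passing pixels in row-major order; ``back_map`` holds their
    flat indices so row k corresponds to pixel ``divmod(back_map[k], cols)``.
    Columns follow the stored band order (descending wavenumber).
    """
    idx = image.axis.window_indices(*feature_range)
    mask_flat = image.qc_mask.reshape(-1)
    if not mask_flat.any():
        raise ValidationError("no usable pixels: QC mask is empty")
    flat = image.cube.reshape(-1, image.cube.shape[2])
    back_map = np.nonzero(mask_flat)[0]
    return flat[np.ix_(back_map, idx)], back_map


@dataclass
class TrainedCascade:
    """Fitted per-level forests plus the grid they were trained on."""

    spec: CascadeSpec
    forests: list[RandomForestClassifier]
    feature_wavenumbers: np.ndarray
    seed: int
    train_counts: dict[str, int] = field(default_factory=dict)

    def legend(self) -> dict[int, tuple[str, str]]:
        leaves = self.spec.leaf_classes()
        return {
            i + 1: (name, _PALETTE[i % len(_PALETTE)])
            for i, name in enumerate(leaves)
        }


def _balanced_subsample(
    labels: np.ndarray, rng: np.random.Generator, cap: int | None = None
) -> np.ndarray:
    """Indices of a per-class balanced subsample (size = min class count)."""
    classes, counts = np.unique(labels, return_counts=True)
    per_class = counts.min() if cap is None else min(counts.min(), cap)
    keep = []
    for cls in classes:
        idx = np.nonzero(labels == cls)[0]
        keep.append(rng.choice(idx, size=per_class, replace=False))
    return np.sort(np.concatenate(keep))


def train_cascade(
    training: list[tuple[np.ndarray, np.ndarray]],
    spec: CascadeSpec,
    feature_wavenumbers: np.ndarray,
    seed: int = 0,
    balance: bool = True,
) -> TrainedCascade:
    """Fit one random forest per cascade level.

    ``training`` is a list of (feature matrix, per-pixel leaf labels as
    strings).  A level-L forest sees only pixels whose level-(L-1) ancestor
    is one of its parents; classes are balanced by subsampling to the
    smallest class (tissue-class prevalences are not equalizable in practice).
    Deterministic for a fixed seed.
    """
    features = np.vstack([f for f, _ in training])
    leaf_labels = np.concatenate([np.asarray(l, dtype=object) for _, l in training])
    if features.shape[0] != leaf_labels.shape[0]:
        raise StructuralError("feature rows and label count differ")
    known = set()
    for level in spec.levels:
        known |= set(level.classes)
    unknown = set(leaf_labels.tolist()) - known
    if unknown:
        raise ValidationError(f"training labels absent from cascade spec: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    forests: list[RandomForestClassifier] = []
    train_counts: dict[str, int] = {}
    for li, level in enumerate(spec.levels):
        # label each pixel at this level (None = pixel's leaf is shallower
        # or belongs to a branch this level does not refine)
        lvl_labels = np.array(
            [spec.ancestor_at_level(l, li) for l in leaf_labels], dtype=object
        )
        in_level = np.array([l in level.classes for l in lvl_labels])
        if li > 0:
            prev = np.array(
                [spec.ancestor_at_level(l, li - 1) for l in leaf_labels], dtype=object
            )
            in_level &= np.array([p in level.parent_set() for p in prev])
        sel = np.nonzero(in_level)[0]
        sub_labels = lvl_labels[sel].astype(str)
        for cls in level.classes:
            count = int(np.sum(sub_labels == cls))
            train_counts[cls] = count
            if count < spec.min_train_pixels:
                raise ValidationError(
                    f"class '{cls}' has {count} training pixels "
                    f"(minimum {spec.min_train_pixels})"
                )
        if balance:
            bal = _balanced_subsample(sub_labels, rng)
            sel, sub_labels = sel[bal], sub_labels[bal]
        forest = RandomForestClassifier(
            n_estimators=level.n_trees,
            max_features="sqrt",
            max_depth=level.max_depth,
            oob_score=True,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        forest.fit(features[sel], sub_labels)
        forests.append(forest)
    return TrainedCascade(
        spec=spec,
        forests=forests,
        feature_wavenumbers=np.asarray(feature_wavenumbers, dtype=float),
        seed=seed,
        train_counts=train_counts,
    )


def predict_cascade(image: SpectralImage, cascade: TrainedCascade) -> LabelMap:
    """Descend the cascade per pixel and return the leaf-level label map.

    QC-failed pixels get label 0.  A deeper level re-labels only pixels whose
    current label is one of its parents, so no pixel can carry a leaf label
    whose ancestor was never assigned.
    """
    features, back_map = extract_features(image, cascade.spec.feature_range)
    grid = image.axis.values[image.axis.window_indices(*cascade.spec.feature_range)]
    if grid.shape != cascade.feature_wavenumbers.shape or not np.allclose(
        grid, cascade.feature_wavenumbers, atol=1e-9
    ):
        raise StructuralError(
            "image wavenumber grid does not match the training grid "
            "(resampling is not performed implicitly)"
        )

    current = cascade.forests[0].predict(features).astype(object)
    for level, forest in zip(cascade.spec.levels[1:], cascade.forests[1:]):
        refinable = np.array([c in level.parent_set() for c in current])
        if refinable.any():
            current[refinable] = forest.predict(features[refinable]).astype(object)

    legend = cascade.legend()
    name_to_label = {name: lbl for lbl, (name, _) in legend.items()}
    labels = np.zeros(image.shape[0] * image.shape[1], dtype=np.int32)
    labels[back_map] = [name_to_label[c] for c in current]
    return LabelMap(labels=labels.reshape(image.shape), legend=legend)


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class EvalReport:
    """Binary diagnostic performance in percent, full precision retained."""

    tp: int
    tn: int
    fp: int
    fn: int
    positive_class: str

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        return 100.0 * (self.tp + self.tn) / self.n

    @property
    def sensitivity(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fp)

    def confusion_matrix(self) -> np.ndarray:
        """[[TP, FN], [FP, TN]] with rows = truth (positive first)."""
        return np.array([[self.tp, self.fn], [self.fp, self.tn]])

    def summary(self) -> dict[str, float]:
        return {
            "accuracy_pct": round(self.accuracy),
            "sensitivity_pct": round(self.sensitivity),
            "specificity_pct": round(self.specificity),
        }


def evaluate(
    predicted: list[str], truth: list[str], positive_class: str
) -> EvalReport:
    """Sample-level accuracy / sensitivity / specificity against diagnoses."""
    if len(predicted) == 0:
        raise ValidationError("no calls to evaluate")
    if len(predicted) != len(truth):
        raise ValidationError("predicted and truth call lists differ in length")
    tp = tn = fp = fn = 0
    for pred, actual in zip(predicted, truth):
        pos_pred = pred == positive_class
        pos_true = actual == positive_class
        if pos_true and pos_pred:
            tp += 1
        elif pos_true:
            fn += 1
        elif pos_pred:
            fp += 1
        else:
            tn += 1
    return EvalReport(tp=tp, tn=tn, fp=fp, fn=fn, positive_class=positive_class)


@dataclass(frozen=True)
class SampleCall:
    """Per-sample diagnosis derived from a pixel-level label map."""

    call: str
    majority_class: str
    majority_fraction: float
    fractions: dict[str, float]


def majority_sample_call(
    label_map: LabelMap,
    candidate_classes: tuple[str, str] = ("epithelioid", "sarcomatoid"),
    mixed_label: str = "biphasic",
    mixed_threshold: float = 0.20,
) -> SampleCall:
    """Diagnose a sample from its pixel fractions of two candidate classes.

    Returns the majority class and its fraction of candidate pixels; the
    call is ``mixed_label`` (biphasic) when both candidates each hold at
    least ``mixed_threshold`` of the candidate pixels.
    """
    name_to_label = {name: lbl for lbl, (name, _) in label_map.legend.items()}
    counts = {}
    for cls in candidate_classes:
        lbl = name_to_label.get(cls)
        counts[cls] = 0 if lbl is None else int(np.sum(label_map.labels == lbl))
    total = sum(counts.values())
    if total == 0:
        raise ValidationError(
            f"no pixels of candidate classes {candidate_classes} in label map"
        )
    fractions = {cls: counts[cls] / total for cls in candidate_classes}
    majority = max(candidate_classes, key=lambda c: (counts[c], c))
    if all(fractions[c] >= mixed_threshold for c in candidate_classes):
        call = mixed_label
    else:
        call = majority
    return SampleCall(
        call=call,
        majority_class=majority,
        majority_fraction=fractions[majority],
        fractions=fractions,
    )
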