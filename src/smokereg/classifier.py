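"""Five-class smoking-status classification over appended hotspot windows.

The learner is a multi-class linear-kernel SVM with inverse-class-frequency
("balanced") weighting, trained on unigram counts of the hotspot-window text
of each note.  Notes without any hotspot never reach the learner: they are
labelled *unknown* by rule.  Notes *with* hotspots can still be gold-unknown
(e.g. "smoke detector"), so *unknown* remains a learnable class.

Features are plain unigram counts — no tf-idf, no n-grams — so the fitted
weight vector stays human-readable: a clinician can be shown exactly which
window tokens drive a classification.

Stop words are removed from windows before counting, except the five
negation tokens ``neither, never, no, nor, not``, which are kept because
they carry the never-smoker signal ("no tobacco use").
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import scipy.sparse as sp
from sklearn.svm import LinearSVC

from .corpus import STATUS_ORDER, ClinicalNote, Corpus, SmokingStatus
from .hotspots import BOUNDARY_TOKEN, HotspotConfig, note_window_text, tokenize

#: negation tokens retained as features despite being standard stop words
NEGATION_TOKENS = frozenset({"neither", "never", "no", "nor", "not"})

_STOPWORD_RESOURCE = "stopwords_en_v1.txt"


def load_stopwords() -> frozenset[str]:
    """The shipped English stop-word list minus the five negation tokens."""
    text = resources.files("smokereg.data").joinpath(_STOPWORD_RESOURCE).read_text("utf-8")
    words = {
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    }
    return frozenset(words - NEGATION_TOKENS)


def stopword_list_hash() -> str:
    """SHA-256 of the shipped stop-word file, for model provenance."""
    raw = resources.files("smokereg.data").joinpath(_STOPWORD_RESOURCE).read_bytes()
    return hashlib.sha256(raw).hexdigest()


@dataclass(frozen=True)
class FeatureSpace:
    """An ordered unigram vocabulary plus the active stop-word set."""

    vocabulary: tuple[str, ...]
    stopwords: frozenset[str] = field(default_factory=load_stopwords)

    def __post_init__(self) -> None:
        if NEGATION_TOKENS & self.stopwords:
            raise ValueError("negation tokens must not be stop words")
        if BOUNDARY_TOKEN in self.vocabulary:
            raise ValueError("window-boundary marker must not enter the vocabulary")

    @classmethod
    def fit(cls, window_texts: Iterable[str], stopwords: frozenset[str] | None = None) -> "FeatureSpace":
        """Build a sorted vocabulary from training window texts."""
        sw = load_stopwords() if stopwords is None else stopwords
        vocab: set[str] = set()
        for text in window_texts:
            for tok in tokenize(text):
                if tok not in sw and tok != BOUNDARY_TOKEN:
                    vocab.add(tok)
        return cls(vocabulary=tuple(sorted(vocab)), stopwords=sw)

    @property
    def index(self) -> dict[str, int]:
        # small vocabularies: rebuild on demand rather than caching in a frozen dataclass
        return {t: i for i, t in enumerate(self.vocabulary)}


def vectorize(window_text: str, space: FeatureSpace) -> sp.csr_matrix:
    """Unigram counts of ``window_text`` over the fitted vocabulary.

    Stop words and out-of-vocabulary tokens are ignored; the boundary marker
    never counts.  Deterministic: equal text gives equal vectors.
    """
    idx = space.index
    counts: dict[int, int] = {}
    for tok in tokenize(window_text):
        j = idx.get(tok)
        if j is not None:
            counts[j] = counts.get(j, 0) + 1
    if not counts:
        return sp.csr_matrix((1, len(space.vocabulary)), dtype=np.float64)
    cols = sorted(counts)
    data = [float(counts[c]) for c in cols]
    return sp.csr_matrix(
        (data, (np.zeros(len(cols), dtype=int), cols)),
        shape=(1, len(space.vocabulary)),
        dtype=np.float64,
    )


def _vectorize_many(texts: list[str], space: FeatureSpace) -> sp.csr_matrix:
    if not texts:
        return sp.csr_matrix((0, len(space.vocabulary)), dtype=np.float64)
    return sp.vstack([vectorize(t, space) for t in texts], format="csr")


@dataclass(frozen=True)
class StatusPrediction:
    """One note's predicted status with decision provenance.

    ``via_hotspot_rule`` is true exactly when the note had no hotspot and the
    status was assigned without the learner, in which case
    ``decision_scores`` is absent.
    """

    note_id: str
    status: SmokingStatus
    decision_scores: Optional[dict[str, float]] = None
    via_hotspot_rule: bool = False
    pack_year_finding: Optional[object] = None  # PackYearFinding
    cessation_finding: Optional[object] = None  # CessationFinding

    def __post_init__(self) -> None:
        if self.via_hotspot_rule != (self.decision_scores is None):
            raise ValueError(
                "via_hotspot_rule must hold exactly when decision_scores is absent"
            )

    def to_dict(self) -> dict:
        out: dict = {
            "note_id": self.note_id,
            "status": self.status.value,
            "via_hotspot_rule": self.via_hotspot_rule,
            "decision_scores": self.decision_scores,
        }
        out["pack_year_finding"] = (
            self.pack_year_finding.to_dict() if self.pack_year_finding else None
        )
        out["cessation_finding"] = (
            self.cessation_finding.to_dict() if self.cessation_finding else None
        )
        return out

    @classmethod
    def from_dict(cls, obj: dict) -> "StatusPrediction":
        from .extraction import CessationFinding, PackYearFinding

        return cls(
            note_id=obj["note_id"],
            status=SmokingStatus.parse(obj["status"]),
            decision_scores=obj.get("decision_scores"),
            via_hotspot_rule=obj.get("via_hotspot_rule", False),
            pack_year_finding=PackYearFinding.from_dict(obj["pack_year_finding"])
            if obj.get("pack_year_finding")
            else None,
            cessation_finding=CessationFinding.from_dict(obj["cessation_finding"])
            if obj.get("cessation_finding")
            else None,
        )

    def with_findings(self, pack_year_finding=None, cessation_finding=None) -> "StatusPrediction":
        return StatusPrediction(
            note_id=self.note_id,
            status=self.status,
            decision_scores=self.decision_scores,
            via_hotspot_rule=self.via_hotspot_rule,
            pack_year_finding=pack_year_finding,
            cessation_finding=cessation_finding,
        )


@dataclass(frozen=True)
class TrainConfig:
    """Learner hyperparameters; the defaults are conventional and fixed."""

    hotspot: HotspotConfig = HotspotConfig()
    C: float = 1.0
    seed: int = 0
    max_iter: int = 10000


class StatusModel:
    """A fitted feature space + linear SVM, plus the no-hotspot rule."""

    def __init__(
        self,
        feature_space: FeatureSpace,
        learner: LinearSVC,
        classes: tuple[SmokingStatus, ...],
        train_config: TrainConfig,
    ) -> None:
        self.feature_space = feature_space
        self.learner = learner
        self.classes = classes
        self.train_config = train_config

    # -- persistence: a self-describing JSON archive --------------------
    def save(self, path: str | Path) -> None:
        obj = {
            "format": "smokereg-status-model-v1",
            "vocabulary": list(self.feature_space.vocabulary),
            "stopword_list_hash": stopword_list_hash(),
            "classes": [c.value for c in self.classes],
            "coef": np.asarray(self.learner.coef_).tolist(),
            "intercept": np.asarray(self.learner.intercept_).tolist(),
            "learner_classes": np.asarray(self.learner.classes_).tolist(),
            "train_config": {
                "C": self.train_config.C,
                "seed": self.train_config.seed,
                "max_iter": self.train_config.max_iter,
                "hotspot": {
                    "stems": list(self.train_config.hotspot.stems),
                    "mode": self.train_config.hotspot.mode,
                    "window_size": self.train_config.hotspot.window_size,
                },
            },
        }
        Path(path).write_text(json.dumps(obj), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "StatusModel":
        obj = json.loads(Path(path).read_text(encoding="utf-8"))
        if obj.get("format") != "smokereg-status-model-v1":
            raise ValueError(f"{path}: not a smokereg status-model archive")
        tc = obj["train_config"]
        config = TrainConfig(
            hotspot=HotspotConfig(
                stems=tuple(tc["hotspot"]["stems"]),
                mode=tc["hotspot"]["mode"],
                window_size=tc["hotspot"]["window_size"],
            ),
            C=tc["C"],
            seed=tc["seed"],
            max_iter=tc["max_iter"],
        )
        space = FeatureSpace(vocabulary=tuple(obj["vocabulary"]))
        learner = LinearSVC(
            C=config.C, class_weight="balanced", random_state=config.seed,
            max_iter=config.max_iter,
        )
        learner.coef_ = np.asarray(obj["coef"], dtype=np.float64)
        learner.intercept_ = np.asarray(obj["intercept"], dtype=np.float64)
        learner.classes_ = np.asarray(obj["learner_classes"])
        return cls(
            feature_space=space,
            learner=learner,
            classes=tuple(SmokingStatus.parse(c) for c in obj["classes"]),
            train_config=config,
        )


def fit(corpus: Corpus, config: TrainConfig = TrainConfig()) -> StatusModel:
    """Train the status classifier on the hotspot-bearing notes of ``corpus``.

    Notes without hotspots are excluded — they are covered by the unknown
    rule at prediction time.  Training rows are put in canonical note-id
    order, so permuting the corpus does not change the fitted model.
    """
    if not corpus.notes:
        raise ValueError("empty corpus")
    rows: list[tuple[str, str, int]] = []  # (note_id, window_text, class index)
    for note in corpus.notes:
        gold = corpus.annotations.get(note.note_id)
        if gold is None:
            continue
        wt = note_window_text(note, config.hotspot)
        if wt is None:
            continue
        rows.append((note.note_id, wt, STATUS_ORDER.index(gold.status)))
    if not rows:
        raise ValueError("no labelled hotspot-bearing notes to train on")
    rows.sort(key=lambda r: r[0])
    labels = sorted({y for _, _, y in rows})
    if len(labels) < 2:
        raise ValueError(
            "training requires >= 2 classes among hotspot-bearing notes "
            f"(got only {STATUS_ORDER[labels[0]].value!r})"
        )
    space = FeatureSpace.fit(wt for _, wt, _ in rows)
    X = _vectorize_many([wt for _, wt, _ in rows], space)
    y = np.array([y for _, _, y in rows], dtype=int)
    learner = LinearSVC(
        C=config.C,
        class_weight="balanced",
        random_state=config.seed,
        max_iter=config.max_iter,
    )
    learner.fit(X, y)
    return StatusModel(
        feature_space=space,
        learner=learner,
        classes=tuple(STATUS_ORDER[i] for i in labels),
        train_config=config,
    )


def predict(model: StatusModel, note: ClinicalNote) -> StatusPrediction:
    """Classify one note; no-hotspot notes are *unknown* by rule.

    Ties in the decision scores break by the fixed class order
    never < former < current < smoker < unknown.
    """
    wt = note_window_text(note, model.train_config.hotspot)
    if wt is None:
        return StatusPrediction(
            note_id=note.note_id,
            status=SmokingStatus.UNKNOWN,
            decision_scores=None,
            via_hotspot_rule=True,
        )
    x = vectorize(wt, model.feature_space)
    raw = model.learner.decision_function(x)[0]
    cls_idx = np.asarray(model.learner.classes_, dtype=int)
    if cls_idx.size == 2:
        # binary decision: positive favours the second class
        scores = np.array([-float(raw), float(raw)])
    else:
        scores = np.asarray(raw, dtype=float)
    # classes_ is sorted by class index, which is the canonical status
    # order, so argmax's first-wins behaviour is the required tie-break
    best = int(cls_idx[int(np.argmax(scores))])
    return StatusPrediction(
        note_id=note.note_id,
        status=STATUS_ORDER[best],
        decision_scores={
            STATUS_ORDER[int(c)].value: float(s) for c, s in zip(cls_idx, scores)
        },
        via_hotspot_rule=False,
    )


def predict_corpus(model: StatusModel, corpus: Corpus) -> list[StatusPrediction]:
    return [predict(model, note) for note in corpus.notes]


def cross_validate(corpus: Corpus, k: int = 5, config: TrainConfig = TrainConfig()):
    """Stratified k-fold cross-validation of the full rule+learner pipeline.

    Folds are dealt per class, round-robin after a seeded shuffle, so
    classes with fewer than ``k`` members degrade gracefully (they simply
    appear in fewer folds).  Returns ``(fold_reports, pooled_report)`` where
    the pooled report scores all out-of-fold predictions together.
    """
    from .metrics import ConfusionMatrix, per_class_report

    if k < 2:
        raise ValueError("k must be >= 2")
    labelled = [n for n in corpus.notes if n.note_id in corpus.annotations]
    if len(labelled) < k:
        raise ValueError(f"need at least k={k} labelled notes")
    rng = np.random.default_rng(config.seed)
    by_class: dict[SmokingStatus, list[ClinicalNote]] = {}
    for n in sorted(labelled, key=lambda n: n.note_id):
        by_class.setdefault(corpus.annotations[n.note_id].status, []).append(n)
    folds: list[list[ClinicalNote]] = [[] for _ in range(k)]
    offset = 0
    for status in STATUS_ORDER:
        members = by_class.get(status, [])
        order = rng.permutation(len(members))
        for j, idx in enumerate(order):
            folds[(offset + j) % k].append(members[idx])
        offset += len(members)

    fold_reports = []
    pooled_gold: list[SmokingStatus] = []
    pooled_pred: list[SmokingStatus] = []
    for i in range(k):
        test_notes = folds[i]
        train_notes = [n for j in range(k) if j != i for n in folds[j]]
        train = Corpus(
            notes=train_notes,
            annotations={n.note_id: corpus.annotations[n.note_id] for n in train_notes},
        )
        model = fit(train, config)
        gold = [corpus.annotations[n.note_id].status for n in test_notes]
        pred = [predict(model, n).status for n in test_notes]
        cm = ConfusionMatrix.from_pairs(gold, pred)
        fold_reports.append(per_class_report(cm))
        pooled_gold.extend(gold)
        pooled_pred.extend(pred)
    pooled = per_class_report(ConfusionMatrix.from_pairs(pooled_gold, pooled_pred))
    return fold_reports, pooled
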