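"""Two-layer random-forest classifier with out-of-bag error tracking.

Layer 1 separates enhancers from non-enhancers on the full table; layer 2
separates strong from weak enhancers and is trained on true enhancers with
a known strength only.  Each layer is a bootstrap random forest (100 trees
by default, sqrt-of-feature-count subsetting at each split) whose
generalization error is estimated out-of-bag: every sample is scored by
the trees whose bootstrap draw excluded it.

The tree count can be tuned by successive halving over a candidate range
(5-500 by default): candidates are evaluated on growing training
fractions, the worse half is eliminated at each rung, and the survivor of
the final full-data rung wins.  The elimination criterion is the OOB error
(a seeded stratified validation split is available as an alternative).

Prediction supports two modes: per-layer (mirroring how such models are
evaluated) and a cascade that consults layer 2 only for layer-1 positives,
yielding one of non_enhancer / weak_enhancer / strong_enhancer.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from . import __version__
from .features import FEATURE_NAMES, FeatureTable
from .sequence_io import ENHANCER, NON_ENHANCER, STRONG, UNKNOWN, WEAK

logger = logging.getLogger(__name__)

POSITIVE_CLASS = {1: ENHANCER, 2: STRONG}
LAYER_CLASSES = {1: (ENHANCER, NON_ENHANCER), 2: (STRONG, WEAK)}


@dataclass(frozen=True)
class ForestConfig:
    """Forest hyper-parameters; defaults follow the published configuration."""

    n_trees: int = 100
    search_space: tuple[int, int] = (5, 500)
    max_features: str | float = "sqrt"
    random_seed: int = 7

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.search_space[0] < 1 or self.search_space[0] > self.search_space[1]:
            raise ValueError("invalid tree-count search space")


@dataclass
class FittedLayer:
    layer: int
    model: RandomForestClassifier
    oob_error: float
    n_oob_uncovered: int  # samples never out-of-bag (possible for tiny forests)
    provenance: dict[str, str]

    def scores(self, X: np.ndarray) -> np.ndarray:
        """Vote fraction for the layer's positive class, in [0, 1]."""
        pos = list(self.model.classes_).index(POSITIVE_CLASS[self.layer])
        return self.model.predict_proba(X)[:, pos]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict(X)


@dataclass
class CascadeModel:
    layer1: FittedLayer
    layer2: FittedLayer


def _layer_training_data(
    table: FeatureTable, layer: int
) -> tuple[np.ndarray, np.ndarray]:
    if layer == 1:
        return table.X, np.asarray(table.layer1)
    if layer == 2:
        mask = np.array(
            [l1 == ENHANCER and l2 in (STRONG, WEAK)
             for l1, l2 in zip(table.layer1, table.layer2)]
        )
        n_unknown = sum(
            1 for l1, l2 in zip(table.layer1, table.layer2)
            if l1 == ENHANCER and l2 == UNKNOWN
        )
        if n_unknown:
            logger.warning(
                "layer 2: excluded %d enhancer(s) of unknown strength", n_unknown
            )
        y = np.asarray([l for l in table.layer2 if l in (STRONG, WEAK)])
        return table.X[mask], y
    raise ValueError(f"layer must be 1 or 2, got {layer}")


def _oob_error(model: RandomForestClassifier, y: np.ndarray) -> tuple[float, int]:
    """OOB misclassification rate from the vote matrix, tolerating uncovered rows."""
    votes = model.oob_decision_function_
    # rows never out-of-bag carry NaN or all-zero votes depending on version
    covered = ~(np.isnan(votes).any(axis=1) | (np.nansum(votes, axis=1) == 0))
    if not covered.any():
        return float("nan"), int(len(y))
    pred = model.classes_[np.argmax(votes[covered], axis=1)]
    err = float(np.mean(pred != y[covered]))
    return err, int((~covered).sum())


def train_layer(
    table: FeatureTable,
    layer: Literal[1, 2],
    config: ForestConfig | None = None,
) -> FittedLayer:
    """Fit one forest layer with bootstrap sampling and record its OOB error."""
    config = config or ForestConfig()
    X, y = _layer_training_data(table, layer)
    if len(np.unique(y)) < 2:
        raise ValueError(f"layer-{layer} training data contains a single class")
    model = RandomForestClassifier(
        n_estimators=config.n_trees,
        bootstrap=True,
        oob_score=True,
        max_features=config.max_features,
        random_state=config.random_seed,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        # tiny forests legitimately leave some samples never out-of-bag
        warnings.filterwarnings("ignore", message="Some inputs do not have OOB")
        model.fit(X, y)
    oob_err, uncovered = _oob_error(model, y)
    if uncovered:
        logger.warning(
            "layer %d: %d sample(s) never out-of-bag with %d tree(s)",
            layer, uncovered, config.n_trees,
        )
    provenance = {
        "software": f"enhmom {__version__}",
        "layer": str(layer),
        "n_trees": str(config.n_trees),
        "max_features": str(config.max_features),
        "random_seed": str(config.random_seed),
        "feature_layout": ",".join(FEATURE_NAMES),
        **table.provenance,
    }
    return FittedLayer(layer, model, oob_err, uncovered, provenance)


def oob_curve(
    table: FeatureTable,
    layer: Literal[1, 2],
    tree_counts: Sequence[int],
    config: ForestConfig | None = None,
) -> list[tuple[int, float]]:
    """OOB error at each tree count (ascending), same seed throughout.

    Supports the visual check that the error stabilizes near 100 trees.
    """
    if list(tree_counts) != sorted(tree_counts):
        raise ValueError("tree_counts must be ascending")
    config = config or ForestConfig()
    out = []
    for n in tree_counts:
        fitted = train_layer(table, layer, replace(config, n_trees=int(n)))
        out.append((int(n), fitted.oob_error))
    return out


def _halving_candidates(space: tuple[int, int], n_candidates: int = 8) -> list[int]:
    lo, hi = space
    grid = np.unique(np.round(np.geomspace(lo, hi, n_candidates)).astype(int))
    return [int(g) for g in grid]


def tune_n_estimators(
    table: FeatureTable,
    layer: Literal[1, 2],
    config: ForestConfig | None = None,
    criterion: Literal["oob", "validation"] = "oob",
) -> int:
    """Successive-halving search for the tree count within the configured space.

    Rungs evaluate the surviving candidates on doubling training fractions
    (final rung = full data) and eliminate the worse half each time.
    Deterministic given the seed.
    """
    config = config or ForestConfig()
    lo, hi = config.search_space
    if lo > hi:
        raise ValueError("empty search space")
    candidates = _halving_candidates(config.search_space)
    if len(candidates) == 1:
        return candidates[0]

    X, y = _layer_training_data(table, layer)
    rng = np.random.RandomState(config.random_seed)
    n_rungs = max(1, int(np.ceil(np.log2(len(candidates)))))
    fractions = [1.0 / (2 ** (n_rungs - 1 - r)) for r in range(n_rungs)]

    for frac in fractions:
        if len(candidates) == 1:
            break
        if frac < 1.0:
            idx, _ = train_test_split(
                np.arange(len(y)),
                train_size=frac,
                stratify=y,
                random_state=rng.randint(2**31 - 1),
            )
        else:
            idx = np.arange(len(y))
        Xr, yr = X[idx], y[idx]
        losses = []
        for n in candidates:
            if criterion == "oob":
                model = RandomForestClassifier(
                    n_estimators=n, bootstrap=True, oob_score=True,
                    max_features=config.max_features,
                    random_state=config.random_seed, n_jobs=1,
                )
                with warnings.catch_warnings():
                    warnings.filterwarnings(
                        "ignore", message="Some inputs do not have OOB"
                    )
                    model.fit(Xr, yr)
                loss, _ = _oob_error(model, yr)
            else:
                tr, va = train_test_split(
                    np.arange(len(yr)), test_size=0.25, stratify=yr,
                    random_state=config.random_seed,
                )
                model = RandomForestClassifier(
                    n_estimators=n, bootstrap=True,
                    max_features=config.max_features,
                    random_state=config.random_seed, n_jobs=1,
                )
                model.fit(Xr[tr], yr[tr])
                loss = float(np.mean(model.predict(Xr[va]) != yr[va]))
            losses.append(loss)
        order = np.argsort(losses, kind="stable")
        keep = max(1, len(candidates) // 2)
        candidates = sorted(candidates[i] for i in order[:keep])
    winner = candidates[0]
    logger.info("successive halving selected n_estimators = %d", winner)
    return winner


def train_cascade(
    table: FeatureTable, config: ForestConfig | None = None
) -> CascadeModel:
    return CascadeModel(
        layer1=train_layer(table, 1, config),
        layer2=train_layer(table, 2, config),
    )


def predict(
    model: CascadeModel,
    X: np.ndarray,
    mode: Literal["layers_separate", "cascade"] = "layers_separate",
    threshold: float = 0.5,
) -> dict[str, np.ndarray]:
    """Apply the two-layer model to feature rows.

    ``layers_separate`` returns each layer's labels and positive-class
    scores for every row (layer 2 is meaningful only for enhancers).
    ``cascade`` consults layer 2 only where layer 1 votes enhancer and
    returns one combined label per row.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != len(FEATURE_NAMES):
        raise ValueError(
            f"feature layout mismatch: expected {len(FEATURE_NAMES)} columns "
            f"(blocks seq/prim/rprim/fdv/aapiv/raapiv), got {X.shape[1]}"
        )
    s1 = model.layer1.scores(X)
    s2 = model.layer2.scores(X)
    if mode == "layers_separate":
        return {
            "layer1_label": model.layer1.predict(X),
            "layer1_score": s1,
            "layer2_label": model.layer2.predict(X),
            "layer2_score": s2,
        }
    if mode == "cascade":
        labels = np.where(
            s1 > threshold,
            np.where(s2 > threshold, "strong_enhancer", "weak_enhancer"),
            "non_enhancer",
        )
        return {"label": labels, "layer1_score": s1, "layer2_score": s2}
    raise ValueError(f"unknown mode {mode!r}")


def save_model(model: CascadeModel, directory: str | Path) -> None:
    """Persist both layers plus a JSON provenance sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for layer in (model.layer1, model.layer2):
        joblib.dump(layer.model, directory / f"layer{layer.layer}.joblib")
        sidecar = {
            "oob_error": layer.oob_error,
            "n_oob_uncovered": layer.n_oob_uncovered,
            "provenance": layer.provenance,
        }
        (directory / f"layer{layer.layer}.json").write_text(
            json.dumps(sidecar, indent=2)
        )


def load_model(directory: str | Path) -> CascadeModel:
    directory = Path(directory)
    layers = {}
    for n in (1, 2):
        meta = json.loads((directory / f"layer{n}.json").read_text())
        layers[n] = FittedLayer(
            layer=n,
            model=joblib.load(directory / f"layer{n}.joblib"),
            oob_error=meta["oob_error"],
            n_oob_uncovered=meta["n_oob_uncovered"],
            provenance=meta["provenance"],
        )
    return CascadeModel(layer1=layers[1], layer2=layers[2])
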