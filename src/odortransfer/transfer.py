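"""The six cross-lexicon prediction models.

Given a *source* study (few general descriptors, e.g. 19 rated 0-100) and a
*target* study (many fine-grained descriptors, e.g. 131 rated 0-5), the
models predict each molecule's target-descriptor profile:

* ``baseline`` -- the per-descriptor mean rating over training molecules
  (the zero vector when no training molecules exist);
* ``dirsem`` -- zero-shot: a map ``S`` learned purely between the two
  descriptor sets' *word embeddings* is applied to the molecule's source
  ratings, ``p_hat = S p_src + baseline``.  No target ratings are touched
  during training;
* ``dirrat`` -- supervised: a map ``R`` learned from molecules rated in both
  studies, fit on baseline residuals so the baseline added at predict time
  is not double-counted;
* ``impsem`` / ``imprat`` -- the same two models with the source ratings
  replaced by the output of a chemoinformatics-to-perception map ``C``
  (so molecules never rated in the source study can be scored);
* ``mixed`` -- the elementwise mean of the semantic and ratings predictions.

All maps are elastic-net fits (see :mod:`odortransfer.regression`).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .containers import ChemFeatureTable, DescriptorLexicon, RatingsTable, SemanticSpace
from .io import align_tables
from .regression import ElasticNetConfig, ElasticNetMap, LinearMap

logger = logging.getLogger(__name__)

__all__ = [
    "MODEL_KINDS",
    "TransferModel",
    "compute_baseline",
    "fit_semantic_transfer",
    "fit_ratings_transfer",
    "fit_chem_to_perception",
    "predict",
    "fit_transfer_model",
    "save_model",
    "load_model",
]

MODEL_KINDS = ("baseline", "dirsem", "dirrat", "impsem", "imprat", "mixed")
_SEMANTIC_KINDS = ("dirsem", "impsem")
_RATINGS_KINDS = ("dirrat", "imprat")
_IMPUTED_KINDS = ("impsem", "imprat")


@dataclass(frozen=True)
class TransferModel:
    """A fitted prediction model: its kind plus the linear maps it needs."""

    kind: str
    target_lexicon: DescriptorLexicon
    S: LinearMap | None = None
    R: LinearMap | None = None
    C: LinearMap | None = None
    baseline_vector: np.ndarray | None = None
    source_lexicon: DescriptorLexicon | None = None
    target_scale: tuple[float, float] | None = None
    clip: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind: {self.kind!r}")
        need = {
            "baseline": (),
            "dirsem": ("S",),
            "dirrat": ("R",),
            "impsem": ("S", "C"),
            "imprat": ("R", "C"),
            "mixed": ("S", "R"),
        }[self.kind]
        for name in need:
            if getattr(self, name) is None:
                raise ValueError(f"model kind {self.kind!r} requires map {name}")
        baseline = self.baseline_vector
        if baseline is None:
            baseline = np.zeros(len(self.target_lexicon))
        baseline = np.asarray(baseline, dtype=float).ravel()
        if baseline.shape[0] != len(self.target_lexicon):
            raise ValueError("baseline_vector length must match the target lexicon")
        object.__setattr__(self, "baseline_vector", baseline)

    def with_baseline(self, baseline_vector: np.ndarray) -> "TransferModel":
        return replace(self, baseline_vector=baseline_vector)

    def predict(self, source_input: RatingsTable | ChemFeatureTable) -> RatingsTable:
        return predict(self, source_input)


def compute_baseline(
    train_target_ratings: RatingsTable | None,
    lexicon: DescriptorLexicon | None = None,
) -> np.ndarray:
    """Per-descriptor mean rating over training molecules.

    With no training molecules at all (``None`` or an empty table) the
    baseline is the constant zero vector.
    """
    if train_target_ratings is None or train_target_ratings.n_molecules == 0:
        if train_target_ratings is not None:
            lexicon = train_target_ratings.lexicon
        if lexicon is None:
            raise ValueError("need a lexicon to build an empty baseline")
        return np.zeros(len(lexicon))
    return np.nanmean(train_target_ratings.values, axis=0)


def fit_semantic_transfer(
    space_source: SemanticSpace,
    space_target: SemanticSpace,
    config: ElasticNetConfig | None = None,
) -> LinearMap:
    """Learn the semantic map ``S`` sending source-descriptor space to target space.

    For each target descriptor, its embedding components (across the shared
    embedding dimensions) are regressed on the source descriptors'
    components; the result is a [n_target x n_source] weight matrix
    applicable to any source-length vector.  No molecules, and no ratings,
    are involved: this is what makes the semantic models zero-shot.

    No intercept is fit: the map is purely linear, exactly as it is applied
    to ratings at predict time.
    """
    if len(space_source.lexicon) < 2:
        raise ValueError("need at least 2 source descriptors")
    return _fit_semantic(space_source, space_target, config)


def _fit_semantic(
    space_source: SemanticSpace,
    space_target: SemanticSpace,
    config: ElasticNetConfig | None,
) -> LinearMap:
    if space_source.dim != space_target.dim:
        raise ValueError("source and target spaces must share the embedding dimension")
    config = config or ElasticNetConfig()
    config = replace(config, fit_intercept=False)
    X = space_source.vectors.T  # [dim x n_source]: one sample per embedding dim
    Y = space_target.vectors.T  # [dim x n_target]
    est = ElasticNetMap.from_config(config)
    est.fit(X, Y)
    return est.to_linear_map()


def fit_ratings_transfer(
    source_ratings: RatingsTable,
    target_ratings: RatingsTable,
    baseline_vector: np.ndarray | None = None,
    config: ElasticNetConfig | None = None,
    residualize: bool = True,
) -> LinearMap:
    """Learn the ratings map ``R`` from row-aligned shared molecules.

    The fit target is the residual ``target - baseline_vector`` so that the
    baseline added back at predict time is not double-counted
    (``residualize=False`` fits raw targets instead, for sensitivity
    analysis).
    """
    if source_ratings.n_molecules != target_ratings.n_molecules or list(
        source_ratings.molecule_ids
    ) != list(target_ratings.molecule_ids):
        raise ValueError("source and target ratings must be row-aligned; use align_tables")
    if source_ratings.n_molecules < 2:
        raise ValueError("need at least 2 training molecules")
    Y = target_ratings.values
    if residualize and baseline_vector is not None:
        Y = Y - np.asarray(baseline_vector, dtype=float).ravel()
    config = config or ElasticNetConfig()
    est = ElasticNetMap.from_config(config)
    est.fit(source_ratings.values, Y)
    return est.to_linear_map()


def fit_chem_to_perception(
    features: ChemFeatureTable,
    source_ratings: RatingsTable,
    config: ElasticNetConfig | None = None,
) -> LinearMap:
    """Learn the map ``C`` predicting source-descriptor ratings from molecular features.

    NaN features are imputed with per-feature medians of the training
    molecules before fitting.
    """
    if list(features.molecule_ids) != list(source_ratings.molecule_ids):
        raise ValueError("features and ratings must be row-aligned; use align_tables")
    features, medians = features.impute_median()
    config = config or ElasticNetConfig()
    est = ElasticNetMap.from_config(config)
    est.fit(features.values, source_ratings.values)
    linmap = est.to_linear_map()
    diagnostics = dict(linmap.fit_diagnostics)
    diagnostics["feature_medians"] = medians
    return LinearMap(linmap.weights, linmap.offset, linmap.chosen_lambdas, diagnostics)


def _source_profile(
    model: TransferModel, source_input: RatingsTable | ChemFeatureTable
) -> np.ndarray:
    imputed = model.kind in _IMPUTED_KINDS
    if imputed:
        if not isinstance(source_input, ChemFeatureTable):
            raise TypeError(f"{model.kind} predicts from a ChemFeatureTable")
        if model.C is None:
            raise ValueError(f"{model.kind} requires the chem-to-perception map C")
        medians = model.C.fit_diagnostics.get("feature_medians")
        source_input, _ = source_input.impute_median(medians)
        return model.C.predict(source_input.values)
    if not isinstance(source_input, RatingsTable):
        raise TypeError(f"{model.kind} predicts from a source RatingsTable")
    return source_input.values


def predict(
    model: TransferModel, source_input: RatingsTable | ChemFeatureTable
) -> RatingsTable:
    """Predict target-descriptor ratings for every molecule of ``source_input``.

    ``mixed`` is computed as the exact elementwise mean of the semantic and
    ratings predictions (algebraically ``(S + R)/2`` applied to the source
    profile, plus the baseline).
    """
    n = source_input.n_molecules
    baseline = model.baseline_vector
    if model.kind == "baseline":
        values = np.tile(baseline, (n, 1))
    elif model.kind == "mixed":
        imputed_input = isinstance(source_input, ChemFeatureTable)
        sem_kind = "impsem" if imputed_input else "dirsem"
        rat_kind = "imprat" if imputed_input else "dirrat"
        sem = predict(replace(model, kind=sem_kind), source_input)
        rat = predict(replace(model, kind=rat_kind), source_input)
        values = 0.5 * (sem.values + rat.values)
    else:
        p_src = _source_profile(model, source_input)
        linmap = model.S if model.kind in _SEMANTIC_KINDS else model.R
        assert linmap is not None
        values = linmap.predict(p_src) + baseline
    if model.clip and model.target_scale is not None:
        values = np.clip(values, *model.target_scale)
    return RatingsTable(
        source_input.molecule_ids,
        model.target_lexicon,
        values,
        scale=model.target_scale,
        check_bounds=False,
    )


def fit_transfer_model(
    kind: str,
    space_source: SemanticSpace | None = None,
    space_target: SemanticSpace | None = None,
    source_ratings: RatingsTable | None = None,
    target_ratings: RatingsTable | None = None,
    features: ChemFeatureTable | None = None,
    config: ElasticNetConfig | None = None,
    use_baseline: bool = True,
) -> TransferModel:
    """Fit any of the six model kinds from the pieces it actually needs.

    The zero-shot property is enforced structurally: the semantic kinds
    consume ``target_ratings`` only to form the baseline vector (set
    ``use_baseline=False`` for the pure zero-shot variant with a zero
    baseline).  The imputed kinds train ``C`` on molecules having both
    features and source ratings; ``imprat`` then trains ``R`` on *imputed*
    source ratings paired with the real target ratings of its training
    molecules.
    """
    if kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind: {kind!r}")
    # a mixed model given chem features is the imputed-task mixed model
    imputed = kind in _IMPUTED_KINDS or (kind == "mixed" and features is not None)

    if kind == "baseline":
        if target_ratings is None:
            raise ValueError("baseline model needs target ratings (or their lexicon)")
        return TransferModel(
            kind,
            target_ratings.lexicon,
            baseline_vector=compute_baseline(target_ratings if use_baseline else None,
                                             target_ratings.lexicon),
            target_scale=target_ratings.scale,
        )

    S = R = C = None
    target_lexicon: DescriptorLexicon | None = None
    source_lexicon: DescriptorLexicon | None = None
    target_scale = target_ratings.scale if target_ratings is not None else None

    if imputed:
        if features is None or source_ratings is None:
            raise ValueError(f"{kind} needs chem features and source ratings to train C")
        _, feat_aligned, src_aligned = align_tables(features, source_ratings)
        C = fit_chem_to_perception(feat_aligned, src_aligned, config)
        source_lexicon = source_ratings.lexicon

    if kind in _SEMANTIC_KINDS or kind == "mixed":
        if space_source is None or space_target is None:
            raise ValueError(f"{kind} needs source and target semantic spaces")
        S = fit_semantic_transfer(space_source, space_target, config)
        target_lexicon = space_target.lexicon
        source_lexicon = source_lexicon or space_source.lexicon

    baseline = None
    if target_ratings is not None and use_baseline:
        baseline = compute_baseline(target_ratings)
        target_lexicon = target_lexicon or target_ratings.lexicon

    if kind in _RATINGS_KINDS or kind == "mixed":
        if source_ratings is None or target_ratings is None:
            raise ValueError(f"{kind} needs source and target ratings on shared molecules")
        if imputed:
            assert C is not None and features is not None
            _, feat_aligned, tgt_aligned = align_tables(features, target_ratings)
            feat_imp, _ = feat_aligned.impute_median(
                C.fit_diagnostics.get("feature_medians")
            )
            imputed_src = RatingsTable(
                feat_aligned.molecule_ids,
                source_ratings.lexicon,
                C.predict(feat_imp.values),
                scale=source_ratings.scale,
                check_bounds=False,
            )
            R = fit_ratings_transfer(imputed_src, tgt_aligned, baseline, config)
        else:
            _, src_aligned, tgt_aligned = align_tables(source_ratings, target_ratings)
            R = fit_ratings_transfer(src_aligned, tgt_aligned, baseline, config)
        target_lexicon = target_ratings.lexicon
        source_lexicon = source_lexicon or source_ratings.lexicon

    if target_lexicon is None:
        raise ValueError("could not determine the target lexicon from the inputs")
    return TransferModel(
        kind,
        target_lexicon,
        S=S,
        R=R,
        C=C,
        baseline_vector=baseline,
        source_lexicon=source_lexicon,
        target_scale=target_scale,
    )


def _map_to_json(linmap: LinearMap | None) -> dict | None:
    if linmap is None:
        return None
    out = {
        "weights": linmap.weights.tolist(),
        "offset": linmap.offset.tolist(),
        "chosen_lambdas": list(linmap.chosen_lambdas),
    }
    medians = linmap.fit_diagnostics.get("feature_medians")
    if medians is not None:
        out["feature_medians"] = np.asarray(medians).tolist()
    return out


def _map_from_json(obj: dict | None) -> LinearMap | None:
    if obj is None:
        return None
    diagnostics = {}
    if "feature_medians" in obj:
        diagnostics["feature_medians"] = np.asarray(obj["feature_medians"])
    return LinearMap(
        np.asarray(obj["weights"]),
        np.asarray(obj["offset"]),
        tuple(obj.get("chosen_lambdas", (0.0, 0.0))),
        diagnostics,
    )


def save_model(model: TransferModel, path: str | Path) -> None:
    """Serialize a fitted model as a single JSON bundle."""
    payload = {
        "kind": model.kind,
        "target_lexicon": list(model.target_lexicon),
        "source_lexicon": list(model.source_lexicon) if model.source_lexicon else None,
        "baseline_vector": model.baseline_vector.tolist(),
        "target_scale": list(model.target_scale) if model.target_scale else None,
        "S": _map_to_json(model.S),
        "R": _map_to_json(model.R),
        "C": _map_to_json(model.C),
    }
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


def load_model(path: str | Path) -> TransferModel:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return TransferModel(
        payload["kind"],
        DescriptorLexicon(payload["target_lexicon"]),
        S=_map_from_json(payload.get("S")),
        R=_map_from_json(payload.get("R")),
        C=_map_from_json(payload.get("C")),
        baseline_vector=np.asarray(payload["baseline_vector"]),
        source_lexicon=(
            DescriptorLexicon(payload["source_lexicon"])
            if payload.get("source_lexicon")
            else None
        ),
        target_scale=(
            tuple(payload["target_scale"]) if payload.get("target_scale") else None
        ),
    )
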