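"""Seeded generators of coupled semantic / ratings / chem-feature data.

The generator plants a single ground-truth linear map ``true_S`` that ties
the two descriptor sets together in *both* views, mirroring the premise
that makes zero-shot transfer possible on real data:

* target embeddings are (noisy) images of the source embeddings under
  ``true_S``, so the semantic map is identifiable from word vectors alone;
* target ratings are images of the latent molecule loadings under the same
  ``true_S``, so the map learned from semantics genuinely predicts ratings;
* latent loadings are themselves a (noisy) sparse linear image ``true_C``
  of non-negative molecular features, so the chemistry-to-perception leg is
  identifiable too.

Loadings are built from sparse non-negative features and non-negative
coefficients, which gives them the positive skew of real odor profiles
(most descriptors near zero, a few strong ones) and lets the bounded rating
scales (0-100 source, 0-5 target) be reached by pure rescaling.  Noise
levels are expressed as fractions: of a unit-norm embedding row for the
semantic noise, of the scale width for the rating noise, and of the latent
loading spread for the chemistry noise.  Ratings are clipped to their scale
after noise so that generated tables always satisfy the observed-data
bounds invariant.

The default noise levels encode the regime the method is designed for: a
semantic relation that is real but rough (word use only loosely tracks
perception, so the zero-shot model is far from perfect and a supervised
ratings map can eventually overtake it), and comparatively clean averaged
ratings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .containers import ChemFeatureTable, DescriptorLexicon, RatingsTable, SemanticSpace

logger = logging.getLogger(__name__)

__all__ = [
    "ScenarioConfig",
    "PlantedTruth",
    "Scenario",
    "make_scenario",
    "make_paradigm_fixture",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """Dimensions and noise levels of a generated scenario.

    Defaults mirror the motivating data sets: 19 source descriptors rated
    0-100, 131 target descriptors rated 0-5, 300-dimensional embeddings, 58
    molecules rated in both studies plus 70 rated only in the target study,
    and a few hundred molecular features standing in for a full
    physicochemical descriptor block.
    """

    n_source_desc: int = 19
    n_target_desc: int = 131
    dim: int = 300
    n_shared_mol: int = 58
    n_extra_mol: int = 70
    n_features: int = 500
    noise_semantic: float = 2.0
    noise_ratings: float = 0.02
    noise_chem: float = 0.1
    chem_sparsity: float = 0.04
    source_scale: tuple[float, float] = (0.0, 100.0)
    target_scale: tuple[float, float] = (0.0, 5.0)
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_source_desc, self.n_target_desc, self.dim,
            self.n_shared_mol, self.n_features,
        )
        if any(c <= 0 for c in counts) or self.n_extra_mol < 0:
            raise ValueError("all dimension counts must be positive")
        if any(s < 0 for s in (self.noise_semantic, self.noise_ratings, self.noise_chem)):
            raise ValueError("noise levels must be non-negative")
        if not 0 < self.chem_sparsity <= 1:
            raise ValueError("chem_sparsity must lie in (0, 1]")


@dataclass(frozen=True)
class PlantedTruth:
    """The ground-truth maps and latent loadings behind a scenario."""

    true_S: np.ndarray  # [n_target_desc x n_source_desc]
    true_C: np.ndarray  # [n_source_desc x n_features]
    loadings: np.ndarray  # [n_molecules x n_source_desc]


@dataclass(frozen=True)
class Scenario:
    config: ScenarioConfig
    space_source: SemanticSpace
    space_target: SemanticSpace
    source_ratings: RatingsTable  # shared molecules only
    target_ratings: RatingsTable  # shared + target-only molecules
    features: ChemFeatureTable  # all molecules
    truth: PlantedTruth = field(compare=False)

    @property
    def shared_ids(self) -> tuple[str, ...]:
        return self.source_ratings.molecule_ids


def _clip_with_log(x: np.ndarray, lo: float, hi: float, what: str) -> np.ndarray:
    frac = float(np.mean((x < lo) | (x > hi)))
    if frac > 0:
        level = logging.WARNING if frac > 0.05 else logging.DEBUG
        logger.log(level, "clipping %.1f%% of %s to [%g, %g]", 100 * frac, what, lo, hi)
    return np.clip(x, lo, hi)


def make_scenario(config: ScenarioConfig | None = None, **overrides) -> Scenario:
    """Generate one coupled scenario; deterministic given ``config.seed``."""
    if config is None:
        config = ScenarioConfig(**overrides)
    elif overrides:
        config = replace(config, **overrides)
    c = config
    rng = np.random.default_rng(c.seed)

    src_lex = DescriptorLexicon([f"s{i:02d}" for i in range(1, c.n_source_desc + 1)])
    tgt_lex = DescriptorLexicon([f"t{i:03d}" for i in range(1, c.n_target_desc + 1)])
    n_mol = c.n_shared_mol + c.n_extra_mol
    mol_ids = tuple(f"M{i:04d}" for i in range(1, n_mol + 1))
    shared_ids = mol_ids[: c.n_shared_mol]

    # source embeddings with ~unit row norms
    E_src = rng.normal(0.0, 1.0 / np.sqrt(c.dim), size=(c.n_source_desc, c.dim))

    # planted semantic/perceptual map: each target descriptor is a dense
    # signed blend of the source descriptors; rows are l2-normalized so the
    # cross-correlation structure of both views directly reads off true_S
    true_S = rng.normal(size=(c.n_target_desc, c.n_source_desc))
    true_S /= np.linalg.norm(true_S, axis=1, keepdims=True)

    E_tgt = true_S @ E_src + c.noise_semantic * rng.normal(
        0.0, 1.0 / np.sqrt(c.dim), size=(c.n_target_desc, c.dim)
    )

    # sparse non-negative chemistry: each source descriptor reads its own
    # disjoint block of features, so loading columns are independent with
    # equal variances (no common molecule-activity factor)
    feat_mask = rng.random((n_mol, c.n_features)) < 0.1
    features = feat_mask * rng.exponential(1.0, size=(n_mol, c.n_features))
    block = max(1, c.n_features // c.n_source_desc)
    n_active_feat = max(1, min(block, round(c.chem_sparsity * c.n_features)))
    true_C = np.zeros((c.n_source_desc, c.n_features))
    for k in range(c.n_source_desc):
        lo = (k * block) % c.n_features
        cols = lo + rng.choice(min(block, c.n_features - lo), size=min(
            n_active_feat, c.n_features - lo), replace=False)
        true_C[k, cols] = rng.exponential(1.0, size=cols.size)

    loadings_clean = features @ true_C.T  # non-negative, positively skewed
    spread = float(loadings_clean.std()) or 1.0
    loadings = loadings_clean + c.noise_chem * spread * rng.normal(
        size=loadings_clean.shape
    )
    loadings = np.maximum(loadings, 0.0)

    src_lo, src_hi = c.source_scale
    tgt_lo, tgt_hi = c.target_scale
    # source scale: pure gain (loadings are non-negative with minimum ~0)
    src_gain = (src_hi - src_lo) / (float(loadings.max()) or 1.0)
    src_vals = loadings * src_gain + c.noise_ratings * (src_hi - src_lo) * rng.normal(
        size=loadings.shape
    )
    src_vals = _clip_with_log(src_vals, src_lo, src_hi, "source ratings")

    # target scale: affine onto [lo, hi] (signed map gives signed raw values;
    # evaluation correlations are affine-invariant, so this is benign)
    tgt_clean = loadings @ true_S.T
    t_min, t_max = float(tgt_clean.min()), float(tgt_clean.max())
    tgt_gain = (tgt_hi - tgt_lo) / ((t_max - t_min) or 1.0)
    tgt_vals = (
        (tgt_clean - t_min) * tgt_gain
        + tgt_lo
        + c.noise_ratings * (tgt_hi - tgt_lo) * rng.normal(size=tgt_clean.shape)
    )
    tgt_vals = _clip_with_log(tgt_vals, tgt_lo, tgt_hi, "target ratings")

    return Scenario(
        config=c,
        space_source=SemanticSpace(src_lex, E_src),
        space_target=SemanticSpace(tgt_lex, E_tgt),
        source_ratings=RatingsTable(
            shared_ids, src_lex, src_vals[: c.n_shared_mol], scale=c.source_scale
        ),
        target_ratings=RatingsTable(mol_ids, tgt_lex, tgt_vals, scale=c.target_scale),
        features=ChemFeatureTable(
            mol_ids, tuple(f"f{j:04d}" for j in range(1, c.n_features + 1)), features
        ),
        truth=PlantedTruth(true_S=true_S, true_C=true_C, loadings=loadings),
    )


def make_paradigm_fixture(
    n_desc: int = 80,
    n_mol: int = 35,
    signal: float = 1.0,
    seed: int = 0,
    min_positives: int = 3,
    max_positives: int = 12,
):
    """Scores and paradigm-descriptor sets for the family-AUC analysis.

    Each molecule gets a random set of "paradigm" descriptors; its score for
    descriptor d is ``signal * 1[d is a paradigm descriptor] + N(0, 1)``
    noise.  Returns ``(scores, positives)`` where ``scores`` is an
    [n_mol x n_desc] array and ``positives`` a list of per-molecule frozen
    index sets.
    """
    rng = np.random.default_rng(seed)
    max_positives = min(max_positives, n_desc - 1)
    positives = []
    indicator = np.zeros((n_mol, n_desc))
    for i in range(n_mol):
        size = int(rng.integers(min_positives, max_positives + 1))
        idx = rng.choice(n_desc, size=size, replace=False)
        positives.append(frozenset(int(j) for j in idx))
        indicator[i, idx] = 1.0
    scores = signal * indicator + rng.normal(size=(n_mol, n_desc))
    return scores, positives
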