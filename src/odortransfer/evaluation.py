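"""Performance metrics and cross-validation harness.

Per-molecule performance is the Pearson correlation, across target
descriptors, between a molecule's predicted and observed profile.  To decide
whether a model beats the baseline (the per-descriptor training mean, whose
own per-molecule correlation with the truth is substantial because odor
profiles share structure across molecules), correlations are compared with a
dependent-correlation Z statistic: the two correlations r(truth, model) and
r(truth, baseline) share the truth variable, so their dependence -- carried
by r(model, baseline) -- must enter the test.  We use the classical
Fisher-z comparison for dependent correlations sharing one variable
(Pearson-Filon covariance, Steiger's form):

    Z = sqrt(N-3) * (z(r_GM) - z(r_GB)) / sqrt(2 (1 - s)),

with s the estimated correlation between the two z-transformed correlations
and N the number of target descriptors.  Positive Z means the model beats
the baseline.  When no baseline exists (pure zero-shot, no training
molecules) the baseline correlation is zero and Z reduces to the plain
Fisher transform of r(truth, model).

The cross-validation harness repeats k-fold splits of the shared molecules,
subsampling the training side to a prescribed size, refitting each model
where applicable, and reporting median r and median Z across molecules and
repetitions -- the learning-curve view of how many co-rated molecules a
supervised transfer needs before it overtakes the zero-shot semantic one.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import RatingsTable, SemanticSpace
from .regression import ElasticNetConfig
from .transfer import (
    _fit_semantic,
    compute_baseline,
    fit_ratings_transfer,
    fit_semantic_transfer,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Z_CAP",
    "EvalReport",
    "CurvePoint",
    "per_molecule_correlation",
    "fisher_z",
    "dependent_z",
    "evaluate_model",
    "cv_curves",
    "curve_points",
    "descriptor_sweep",
    "auc_paradigm",
    "paradigm_family_test",
    "ks_uniformity",
]

#: cap applied to infinite Fisher z at |r| = 1 (double-precision atanh guard)
Z_CAP = 38.0


def per_molecule_correlation(pred: np.ndarray, truth: np.ndarray) -> float:
    """Pearson r across target descriptors for one molecule.

    Returns NaN (with a logged warning) when either profile has zero
    variance; NaN correlations are excluded from medians downstream.
    """
    pred = np.asarray(pred, dtype=float).ravel()
    truth = np.asarray(truth, dtype=float).ravel()
    if pred.shape != truth.shape:
        raise ValueError("profiles must have equal length")
    if pred.size < 3:
        raise ValueError("need at least 3 descriptors")
    if np.std(pred) == 0.0 or np.std(truth) == 0.0:
        logger.warning("zero-variance profile: correlation undefined (NaN)")
        return float("nan")
    return float(np.corrcoef(pred, truth)[0, 1])


def fisher_z(r: float) -> float:
    """The Fisher r-to-z transform, 0.5 * ln((1+r)/(1-r))."""
    r = float(r)
    if abs(r) >= 1.0:
        raise ValueError("fisher_z requires |r| < 1")
    return math.atanh(r)


def _fisher_z_capped(r: float) -> float:
    if not np.isfinite(r):
        return float("nan")
    if abs(r) >= 1.0:
        logger.warning("|r| >= 1: Fisher z capped at %g", Z_CAP)
        return math.copysign(Z_CAP, r)
    return min(max(math.atanh(r), -Z_CAP), Z_CAP)


def dependent_z(
    r_gm: float,
    r_gb: float,
    r_mb: float,
    n: int,
    as_printed: bool = False,
) -> float:
    """Z statistic comparing r(truth, model) with r(truth, baseline).

    Parameters are the three pairwise correlations among truth G, model
    prediction M and baseline prediction B, and the number of observations N
    (here, target descriptors) behind each correlation.  The sign convention
    is fixed so that positive Z means the model beats the baseline; the
    statistic always agrees in sign with ``r_gm - r_gb``.

    ``as_printed=True`` evaluates a literal transcription of an alternative
    (typographically inconsistent) form of the formula, kept for comparison;
    the default is the standard dependent-correlation statistic, whose null
    calibration is verified by simulation in the test-suite.
    """
    if n < 4:
        raise ValueError("need N >= 4 observations")
    for r in (r_gm, r_gb, r_mb):
        if abs(r) >= 1.0:
            raise ValueError("correlations must satisfy |r| < 1")
    corr = np.array([[1.0, r_gm, r_gb], [r_gm, 1.0, r_mb], [r_gb, r_mb, 1.0]])
    if np.linalg.det(corr) < -1e-10:
        raise ValueError("correlation triple is not positive semi-definite")
    if as_printed:
        s = (
            r_gb * (1 - r_gm**2 - r_mb**2)
            - 0.5 * (r_gm * r_mb) * (1 - r_gm**2 - r_mb**2 - r_gb**2)
        ) / ((1 - r_gm**2) * (1 - r_mb**2))
        num = fisher_z(r_gb) - fisher_z(r_mb)
    else:
        s = (
            r_mb * (1 - r_gm**2 - r_gb**2)
            - 0.5 * (r_gm * r_gb) * (1 - r_gm**2 - r_gb**2 - r_mb**2)
        ) / ((1 - r_gm**2) * (1 - r_gb**2))
        num = fisher_z(r_gm) - fisher_z(r_gb)
    if num == 0.0:
        return 0.0
    if s >= 1.0:
        raise ValueError("degenerate correlation triple (s >= 1)")
    return math.sqrt(n - 3) * num / math.sqrt(2.0 * (1.0 - s))


@dataclass(frozen=True)
class EvalReport:
    """Per-molecule and per-descriptor correlations with their medians."""

    per_molecule_r: np.ndarray
    per_molecule_z: np.ndarray
    per_descriptor_r: np.ndarray
    median_r: float
    median_z: float
    n_eff: int
    n_nan_molecules: int = 0
    molecule_ids: tuple[str, ...] = ()
    descriptor_names: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "median_r": self.median_r,
            "median_z": self.median_z,
            "n_eff": self.n_eff,
            "n_nan_molecules": self.n_nan_molecules,
            "per_molecule": {
                m: {"r": float(r), "z": float(z)}
                for m, r, z in zip(
                    self.molecule_ids, self.per_molecule_r, self.per_molecule_z
                )
            },
            "per_descriptor_r": {
                d: float(r)
                for d, r in zip(self.descriptor_names, self.per_descriptor_r)
            },
        }


def _nanmedian(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    good = x[np.isfinite(x)]
    return float(np.median(good)) if good.size else float("nan")


def evaluate_model(
    preds: RatingsTable,
    truth: RatingsTable,
    baseline_preds: RatingsTable | None = None,
    no_baseline: bool = False,
    n_eff: int | None = None,
) -> EvalReport:
    """Score predictions against ground truth, molecule by molecule.

    With a baseline, each molecule's Z is the dependent-correlation
    statistic; without one (``no_baseline=True``) it is the Fisher transform
    of the molecule's correlation.  N defaults to the number of target
    descriptors.  Molecules with undefined correlations (constant profiles,
    degenerate correlation triples) are excluded from the medians and
    counted.
    """
    if list(preds.molecule_ids) != list(truth.molecule_ids):
        raise ValueError("preds and truth must be row-aligned")
    if preds.n_descriptors != truth.n_descriptors:
        raise ValueError("preds and truth must share the descriptor set")
    if preds.n_descriptors < 3:
        raise ValueError("need at least 3 descriptors")
    if not no_baseline and baseline_preds is None:
        raise ValueError("provide baseline_preds or set no_baseline=True")
    n_desc = preds.n_descriptors
    n_eff = n_eff if n_eff is not None else n_desc

    r_gm = np.empty(preds.n_molecules)
    z = np.empty(preds.n_molecules)
    for i in range(preds.n_molecules):
        p, g = preds.values[i], truth.values[i]
        r = _safe_corr(p, g)
        r_gm[i] = r
        if not np.isfinite(r):
            z[i] = float("nan")
            continue
        if no_baseline:
            z[i] = _fisher_z_capped(r)
            continue
        b = baseline_preds.values[i]  # type: ignore[union-attr]
        rb = _safe_corr(g, b)
        rm = _safe_corr(p, b)
        if not (np.isfinite(rb) and np.isfinite(rm)):
            z[i] = float("nan")
            continue
        if r == rb:
            z[i] = 0.0
            continue
        try:
            z[i] = dependent_z(
                _clip_r(r), _clip_r(rb), _clip_r(rm), n_eff
            )
        except ValueError:
            logger.warning("degenerate correlation triple for molecule %s",
                           preds.molecule_ids[i])
            z[i] = float("nan")

    per_desc = np.array(
        [
            _safe_corr(preds.values[:, j], truth.values[:, j])
            for j in range(n_desc)
        ]
    )
    n_nan = int(np.sum(~np.isfinite(r_gm)))
    if n_nan:
        logger.warning("%d molecules had undefined correlations", n_nan)
    return EvalReport(
        per_molecule_r=r_gm,
        per_molecule_z=z,
        per_descriptor_r=per_desc,
        median_r=_nanmedian(r_gm),
        median_z=_nanmedian(z),
        n_eff=n_eff,
        n_nan_molecules=n_nan,
        molecule_ids=preds.molecule_ids,
        descriptor_names=tuple(preds.lexicon),
    )


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def _clip_r(r: float, eps: float = 1e-12) -> float:
    return min(max(r, -1.0 + eps), 1.0 - eps)


@dataclass(frozen=True)
class CurvePoint:
    """One point of a learning curve: a model's medians at one training size."""

    n_train: int
    model_kind: str
    median_z: float
    median_r: float
    n_reps: int

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


def cv_curves(
    source_ratings: RatingsTable,
    target_ratings: RatingsTable,
    space_source: SemanticSpace | None = None,
    space_target: SemanticSpace | None = None,
    kinds: Sequence[str] = ("baseline", "dirsem", "dirrat", "mixed"),
    n_train_grid: Sequence[int] = (2, 5, 10, 20, 40),
    reps: int = 100,
    folds: int = 10,
    seed: int = 0,
    config: ElasticNetConfig | None = None,
    harmonize_scales: bool = True,
) -> pd.DataFrame:
    """Learning curves over repeated k-fold cross-validation.

    Requires ``source_ratings`` and ``target_ratings`` row-aligned on the
    shared molecules.  For each repetition, molecules are split into
    ``folds`` folds; for each fold and each requested training-set size, the
    train side is subsampled (without replacement), the baseline and ratings
    maps are refit, and every model is scored on the fold's test molecules
    against the baseline.  The semantic map is fit once -- it involves no
    molecules.  ``n_train = 0`` is allowed only for the semantic and
    baseline models and scores them with the zero baseline (Fisher-z
    statistic).

    ``harmonize_scales`` multiplies the source ratings by one positive
    scalar gain mapping the source scale width onto the target's (0-100 to
    0-5 by default).  A common gain leaves every individual model's
    per-molecule correlation exactly unchanged, but it is what makes the
    mixed model's plain average meaningful: without it the semantic
    stream, whose raw output inherits the source scale, numerically
    swamps the ratings stream.  Source-side information only, so the
    semantic model remains zero-shot.

    Returns a tidy frame with one row per (model, n_train, repetition):
    columns ``model, n_train, rep, median_r, median_z``.  Deterministic
    given ``seed``.
    """
    if list(source_ratings.molecule_ids) != list(target_ratings.molecule_ids):
        raise ValueError("source and target ratings must be row-aligned")
    kinds = tuple(kinds)
    needs_s = any(k in ("dirsem", "mixed") for k in kinds)
    if needs_s and (space_source is None or space_target is None):
        raise ValueError("semantic models need both semantic spaces")
    config = config or ElasticNetConfig()
    n_mol = source_ratings.n_molecules
    folds = min(folds, n_mol)
    max_pool = n_mol - math.ceil(n_mol / folds)
    for nt in n_train_grid:
        if nt > max_pool:
            raise ValueError(
                f"n_train={nt} exceeds the available training pool ({max_pool})"
            )
        if nt == 0 and any(k in ("dirrat", "imprat", "mixed") for k in kinds):
            raise ValueError("n_train=0 is only valid for semantic and baseline models")

    S = (
        fit_semantic_transfer(space_source, space_target, config)
        if needs_s
        else None
    )
    if harmonize_scales:
        if source_ratings.scale is not None and target_ratings.scale is not None:
            s_lo, s_hi = source_ratings.scale
            t_lo, t_hi = target_ratings.scale
            gain = (t_hi - t_lo) / (s_hi - s_lo)
        else:
            src_sd = float(source_ratings.values.std()) or 1.0
            gain = (float(target_ratings.values.std()) or 1.0) / src_sd
        source_ratings = RatingsTable(
            source_ratings.molecule_ids,
            source_ratings.lexicon,
            source_ratings.values * gain,
            scale=None,
            check_bounds=False,
        )
    lexicon = target_ratings.lexicon
    scale = target_ratings.scale

    rows = []
    root = np.random.SeedSequence(seed)
    for rep, child in enumerate(root.spawn(reps)):
        rng = np.random.default_rng(child)
        order = rng.permutation(n_mol)
        fold_ids = np.array_split(order, folds)
        # per-(kind, n_train) accumulators of per-molecule scores this rep
        acc_r: dict[tuple[str, int], list[float]] = {}
        acc_z: dict[tuple[str, int], list[float]] = {}
        for test_idx in fold_ids:
            pool = np.setdiff1d(order, test_idx, assume_unique=False)
            test_ids = [source_ratings.molecule_ids[i] for i in test_idx]
            src_test = source_ratings.subset_molecules(test_ids)
            tgt_test = target_ratings.subset_molecules(test_ids)
            for nt in n_train_grid:
                train_idx = rng.choice(pool, size=nt, replace=False)
                train_ids = [source_ratings.molecule_ids[i] for i in train_idx]
                tgt_train = target_ratings.subset_molecules(train_ids)
                baseline_vec = compute_baseline(tgt_train if nt > 0 else None, lexicon)
                no_baseline = nt == 0
                base_tbl = RatingsTable(
                    src_test.molecule_ids,
                    lexicon,
                    np.tile(baseline_vec, (len(test_ids), 1)),
                    scale=scale,
                    check_bounds=False,
                )
                preds: dict[str, RatingsTable] = {}
                if "baseline" in kinds:
                    preds["baseline"] = base_tbl
                if "dirsem" in kinds or "mixed" in kinds:
                    assert S is not None
                    sem_vals = S.predict(src_test.values) + baseline_vec
                    preds["dirsem"] = RatingsTable(
                        src_test.molecule_ids, lexicon, sem_vals,
                        scale=scale, check_bounds=False,
                    )
                if "dirrat" in kinds or "mixed" in kinds:
                    src_train = source_ratings.subset_molecules(train_ids)
                    R = fit_ratings_transfer(
                        src_train, tgt_train, baseline_vec, config
                    )
                    rat_vals = R.predict(src_test.values) + baseline_vec
                    preds["dirrat"] = RatingsTable(
                        src_test.molecule_ids, lexicon, rat_vals,
                        scale=scale, check_bounds=False,
                    )
                if "mixed" in kinds:
                    preds["mixed"] = RatingsTable(
                        src_test.molecule_ids,
                        lexicon,
                        0.5 * (preds["dirsem"].values + preds["dirrat"].values),
                        scale=scale,
                        check_bounds=False,
                    )
                for kind in kinds:
                    report = evaluate_model(
                        preds[kind],
                        tgt_test,
                        baseline_preds=None if no_baseline else base_tbl,
                        no_baseline=no_baseline,
                    )
                    acc_r.setdefault((kind, nt), []).extend(report.per_molecule_r)
                    acc_z.setdefault((kind, nt), []).extend(report.per_molecule_z)
        for (kind, nt), rs in acc_r.items():
            rows.append(
                {
                    "model": kind,
                    "n_train": nt,
                    "rep": rep,
                    "median_r": _nanmedian(np.asarray(rs)),
                    "median_z": _nanmedian(np.asarray(acc_z[(kind, nt)])),
                }
            )
    return pd.DataFrame(rows)


def curve_points(tidy: pd.DataFrame) -> list[CurvePoint]:
    """Aggregate the tidy cv_curves frame to one point per (model, n_train)."""
    points = []
    for (kind, nt), grp in tidy.groupby(["model", "n_train"]):
        points.append(
            CurvePoint(
                n_train=int(nt),
                model_kind=str(kind),
                median_z=float(grp["median_z"].median()),
                median_r=float(grp["median_r"].median()),
                n_reps=int(grp["rep"].nunique()),
            )
        )
    return sorted(points, key=lambda p: (p.model_kind, p.n_train))


def descriptor_sweep(
    order: Sequence[str],
    space_source: SemanticSpace,
    space_target: SemanticSpace,
    source_ratings: RatingsTable,
    target_ratings: RatingsTable,
    config: ElasticNetConfig | None = None,
    k_grid: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Zero-shot performance as a function of the number of source descriptors.

    ``order`` is a priority ranking of the source descriptors (typically the
    prototype-selection order).  For each prefix size k, the semantic map is
    refit using only the first k source descriptors and scored by
    leave-one-out cross-validation over the shared molecules (the left-out
    molecule's baseline is the mean of the others).  Returns a frame with
    columns ``k, median_r, median_z``.
    """
    order = [str(d) for d in order]
    src_lex = list(source_ratings.lexicon)
    if sorted(order) != sorted(src_lex):
        raise ValueError("order must cover exactly the source lexicon")
    if list(source_ratings.molecule_ids) != list(target_ratings.molecule_ids):
        raise ValueError("ratings tables must be row-aligned")
    config = config or ElasticNetConfig()
    k_grid = list(k_grid) if k_grid is not None else list(range(1, len(order) + 1))
    if any(k < 1 or k > len(order) for k in k_grid):
        raise ValueError("k out of range for the source lexicon")

    n_mol = source_ratings.n_molecules
    lexicon = target_ratings.lexicon
    rows = []
    for k in k_grid:
        chosen = order[:k]
        S_k = _fit_semantic(
            space_source.subset(chosen), space_target, config
        )
        src_vals = source_ratings.subset_descriptors(chosen).values
        rs, zs = [], []
        for i in range(n_mol):
            others = [j for j in range(n_mol) if j != i]
            baseline_vec = target_ratings.values[others].mean(axis=0)
            pred = S_k.predict(src_vals[i][None, :])[0] + baseline_vec
            g = target_ratings.values[i]
            r = _safe_corr(pred, g)
            rs.append(r)
            rb = _safe_corr(g, baseline_vec)
            rm = _safe_corr(pred, baseline_vec)
            if np.isfinite(r) and np.isfinite(rb) and np.isfinite(rm):
                try:
                    zs.append(
                        0.0
                        if r == rb
                        else dependent_z(
                            _clip_r(r), _clip_r(rb), _clip_r(rm), len(lexicon)
                        )
                    )
                except ValueError:
                    zs.append(float("nan"))
            else:
                zs.append(float("nan"))
        rows.append(
            {
                "k": k,
                "median_r": _nanmedian(np.asarray(rs)),
                "median_z": _nanmedian(np.asarray(zs)),
            }
        )
    return pd.DataFrame(rows)


def auc_paradigm(scores: np.ndarray, positives: Sequence[int]) -> float:
    """Rank-based ROC AUC with midrank tie handling.

    ``positives`` indexes the descriptors that appear in the molecule's
    paradigm-odor notes; higher scores should rank them above the rest.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    pos = np.zeros(scores.size, dtype=bool)
    pos_idx = np.asarray(list(positives), dtype=int)
    if pos_idx.size == 0:
        raise ValueError("need at least one positive")
    pos[pos_idx] = True
    n_pos = int(pos.sum())
    n_neg = scores.size - n_pos
    if n_neg == 0:
        raise ValueError("need at least one negative")
    ranks = stats.rankdata(scores, method="average")
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def paradigm_family_test(scores: np.ndarray, positives: Sequence[int]) -> float:
    """One-sided two-sample t test: are paradigm descriptors scored higher?

    Returns the p-value for the alternative "positives have the larger
    mean".  Identical positive and negative distributions give the boundary
    p = 0.5; zero variance in both groups with equal means is degenerate and
    raises.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    pos = np.zeros(scores.size, dtype=bool)
    pos[np.asarray(list(positives), dtype=int)] = True
    a, b = scores[pos], scores[~pos]
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 scores per group")
    if np.std(a) == 0.0 and np.std(b) == 0.0:
        raise ValueError("degenerate variance in both groups")
    res = stats.ttest_ind(a, b, alternative="greater")
    return float(res.pvalue)


def ks_uniformity(pvalues: Sequence[float]) -> float:
    """One-sample Kolmogorov-Smirnov test of the p-values against Uniform(0,1)."""
    pvalues = np.asarray(list(pvalues), dtype=float)
    if pvalues.size < 5:
        raise ValueError("need at least 5 p-values")
    if np.any((pvalues < 0) | (pvalues > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return float(stats.kstest(pvalues, "uniform").pvalue)
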