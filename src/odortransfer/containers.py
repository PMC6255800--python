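"""Core data containers.

The package moves four kinds of objects between its stages:

* :class:`DescriptorLexicon` -- an ordered set of perceptual descriptor words
  (e.g. the 19 general descriptors of a source study, or the ~131 fine-grained
  descriptors of a target study).  Descriptor order is significant: it fixes
  column order in every matrix downstream.
* :class:`SemanticSpace` -- one embedding vector per descriptor, taken from a
  pre-trained distributional semantic model (300-dimensional by convention).
* :class:`RatingsTable` -- molecules x descriptors perceptual ratings on a
  bounded scale (0-100 for the source study, 0-5 for the target study).
* :class:`ChemFeatureTable` -- molecules x physicochemical features, the input
  of the chemoinformatics-to-perception map.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DescriptorLexicon",
    "SemanticSpace",
    "RatingsTable",
    "ChemFeatureTable",
]


def _normalize_descriptor(name: str) -> str:
    return " ".join(str(name).strip().lower().split())


@dataclass(frozen=True)
class DescriptorLexicon:
    """Ordered, duplicate-free list of lowercased descriptor strings."""

    names: tuple[str, ...]

    def __init__(self, names: Iterable[str]):
        norm = tuple(_normalize_descriptor(n) for n in names)
        if any(not n for n in norm):
            raise ValueError("empty descriptor string in lexicon")
        seen: set[str] = set()
        dups = [n for n in norm if n in seen or seen.add(n)]  # type: ignore[func-returns-value]
        if dups:
            raise ValueError(f"duplicate descriptors in lexicon: {sorted(set(dups))}")
        object.__setattr__(self, "names", norm)

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self) -> Iterator[str]:
        return iter(self.names)

    def __getitem__(self, i: int) -> str:
        return self.names[i]

    def __contains__(self, name: str) -> bool:
        return _normalize_descriptor(name) in self.names

    def index(self, name: str) -> int:
        return self.names.index(_normalize_descriptor(name))

    def subset(self, names: Sequence[str]) -> "DescriptorLexicon":
        """A new lexicon restricted to ``names``, keeping the given order."""
        return DescriptorLexicon(names)


@dataclass(frozen=True)
class SemanticSpace:
    """Embedding vectors for every descriptor of a lexicon.

    ``missing`` records descriptors of the *requested* lexicon that had no
    vector in the source file; together with ``lexicon`` they partition the
    requested lexicon (nothing is ever silently dropped).
    """

    lexicon: DescriptorLexicon
    vectors: np.ndarray
    missing: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        vectors = np.asarray(self.vectors, dtype=float)
        if vectors.ndim != 2:
            raise ValueError("vectors must be a 2-D array [n_descriptors x dim]")
        if vectors.shape[0] != len(self.lexicon):
            raise ValueError(
                f"lexicon has {len(self.lexicon)} descriptors but vectors has "
                f"{vectors.shape[0]} rows"
            )
        if vectors.shape[0] and np.any(np.all(np.isnan(vectors), axis=1)):
            raise ValueError("all-NaN embedding row")
        object.__setattr__(self, "vectors", vectors)
        object.__setattr__(self, "missing", tuple(self.missing))

    @property
    def dim(self) -> int:
        return int(self.vectors.shape[1])

    def vector(self, name: str) -> np.ndarray:
        return self.vectors[self.lexicon.index(name)]

    def subset(self, names: Sequence[str]) -> "SemanticSpace":
        idx = [self.lexicon.index(n) for n in names]
        return SemanticSpace(self.lexicon.subset(names), self.vectors[idx], ())


def _check_unique_ids(ids: Sequence[str]) -> tuple[str, ...]:
    ids = tuple(str(i) for i in ids)
    if len(set(ids)) != len(ids):
        raise ValueError("molecule_ids must be unique")
    return ids


@dataclass(frozen=True)
class RatingsTable:
    """Molecules x descriptors ratings matrix with scale bounds.

    ``scale`` is the (lo, hi) range of the rating instrument.  Observed data
    must lie within it; model *predictions* may exceed it, so construct those
    with ``check_bounds=False`` (the default for tables built by the
    prediction code).
    """

    molecule_ids: tuple[str, ...]
    lexicon: DescriptorLexicon
    values: np.ndarray
    scale: tuple[float, float] | None = None
    check_bounds: bool = field(default=True, compare=False)

    def __post_init__(self) -> None:
        ids = _check_unique_ids(self.molecule_ids)
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(ids), len(self.lexicon)):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"({len(ids)} molecules, {len(self.lexicon)} descriptors)"
            )
        if self.scale is not None:
            lo, hi = (float(self.scale[0]), float(self.scale[1]))
            if not lo < hi:
                raise ValueError("scale must satisfy lo < hi")
            object.__setattr__(self, "scale", (lo, hi))
            if self.check_bounds and values.size:
                finite = values[np.isfinite(values)]
                if finite.size and (finite.min() < lo or finite.max() > hi):
                    raise ValueError(
                        f"observed ratings outside scale [{lo}, {hi}]: "
                        f"range [{finite.min()}, {finite.max()}]"
                    )
        object.__setattr__(self, "molecule_ids", ids)
        object.__setattr__(self, "values", values)

    @property
    def n_molecules(self) -> int:
        return len(self.molecule_ids)

    @property
    def n_descriptors(self) -> int:
        return len(self.lexicon)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.molecule_ids), columns=list(self.lexicon)
        )

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        scale: tuple[float, float] | None = None,
        check_bounds: bool = True,
    ) -> "RatingsTable":
        return cls(
            tuple(str(i) for i in frame.index),
            DescriptorLexicon(frame.columns),
            frame.to_numpy(dtype=float),
            scale,
            check_bounds,
        )

    def subset_molecules(self, ids: Sequence[str]) -> "RatingsTable":
        pos = {m: i for i, m in enumerate(self.molecule_ids)}
        idx = [pos[str(i)] for i in ids]
        return replace(
            self, molecule_ids=tuple(str(i) for i in ids), values=self.values[idx]
        )

    def subset_descriptors(self, names: Sequence[str]) -> "RatingsTable":
        idx = [self.lexicon.index(n) for n in names]
        return replace(
            self, lexicon=self.lexicon.subset(names), values=self.values[:, idx]
        )


@dataclass(frozen=True)
class ChemFeatureTable:
    """Molecules x numeric molecular features (e.g. physicochemical descriptors)."""

    molecule_ids: tuple[str, ...]
    feature_names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        ids = _check_unique_ids(self.molecule_ids)
        names = tuple(str(n) for n in self.feature_names)
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(ids), len(names)):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"({len(ids)} molecules, {len(names)} features)"
            )
        object.__setattr__(self, "molecule_ids", ids)
        object.__setattr__(self, "feature_names", names)
        object.__setattr__(self, "values", values)

    @property
    def n_molecules(self) -> int:
        return len(self.molecule_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.molecule_ids), columns=list(self.feature_names)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ChemFeatureTable":
        return cls(
            tuple(str(i) for i in frame.index),
            tuple(str(c) for c in frame.columns),
            frame.to_numpy(dtype=float),
        )

    def subset_molecules(self, ids: Sequence[str]) -> "ChemFeatureTable":
        pos = {m: i for i, m in enumerate(self.molecule_ids)}
        idx = [pos[str(i)] for i in ids]
        return ChemFeatureTable(
            tuple(str(i) for i in ids), self.feature_names, self.values[idx]
        )

    def impute_median(
        self, medians: np.ndarray | None = None
    ) -> tuple["ChemFeatureTable", np.ndarray]:
        """Replace NaN entries by per-feature medians.

        Medians are computed on this table unless provided (pass the training
        table's medians when imputing a held-out table, so no information
        leaks from test molecules).  Features that are all-NaN fall back to 0.
        Returns the imputed table and the medians used.
        """
        values = self.values.copy()
        if medians is None:
            with np.errstate(all="ignore"):
                medians = np.nanmedian(values, axis=0)
            medians = np.where(np.isfinite(medians), medians, 0.0)
        medians = np.asarray(medians, dtype=float)
        nan_mask = ~np.isfinite(values)
        if nan_mask.any():
            values[nan_mask] = np.broadcast_to(medians, values.shape)[nan_mask]
        return (
            ChemFeatureTable(self.molecule_ids, self.feature_names, values),
            medians,
        )
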