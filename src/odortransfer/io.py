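"""Readers and writers for the standard on-disk formats.

* word-vector text format (the word2vec / fastText ``.vec`` dialect): an
  optional ``"vocab_size dim"`` header line followed by one
  ``token v1 ... v_dim`` line per word;
* CSV ratings / feature matrices: first column molecule id, remaining
  columns descriptors or feature names;
* plain-text lexicons: one descriptor per line, ``#`` comments allowed.

All reader/writer pairs round-trip to better than 1e-12 (CSV floats are
written with full ``repr`` precision, so numeric round-trips are exact).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import TypeVar

import numpy as np
import pandas as pd

from .containers import (
    ChemFeatureTable,
    DescriptorLexicon,
    RatingsTable,
    SemanticSpace,
    _normalize_descriptor,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_lexicon",
    "write_lexicon",
    "read_word_vectors",
    "read_ratings_csv",
    "write_predictions",
    "write_ratings_csv",
    "read_features_csv",
    "write_features_csv",
    "align_tables",
]


class WordVectorParseError(ValueError):
    """A malformed line in a word-vector text file."""


def read_lexicon(path: str | Path) -> DescriptorLexicon:
    names = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            names.append(line)
    return DescriptorLexicon(names)


def write_lexicon(lexicon: DescriptorLexicon, path: str | Path) -> None:
    Path(path).write_text("\n".join(lexicon.names) + "\n", encoding="utf-8")


def _detect_header(first_line: str) -> tuple[int, int] | None:
    parts = first_line.split()
    if len(parts) == 2:
        try:
            n, dim = int(parts[0]), int(parts[1])
        except ValueError:
            return None
        if n > 0 and dim > 0:
            return n, dim
    return None


def read_word_vectors(
    path: str | Path,
    lexicon: DescriptorLexicon,
    match_policy: str = "exact",
) -> SemanticSpace:
    """Look up the embedding vector of every descriptor in ``lexicon``.

    ``match_policy='exact'`` matches the lowercased descriptor against the
    file's tokens; a multiword descriptor (contains whitespace) can never
    match and is reported as missing -- this mirrors the convention of
    dropping out-of-vocabulary descriptors such as "burnt rubber".
    ``match_policy='subword_mean'`` instead represents a multiword descriptor
    by the mean of its constituent words' vectors when all of them are
    present.

    Descriptors without a vector are collected in ``SemanticSpace.missing``
    and logged, never silently dropped.  The returned space's lexicon is the
    requested lexicon minus the missing descriptors, in the original order.
    """
    if match_policy not in ("exact", "subword_mean"):
        raise ValueError(f"unknown match_policy: {match_policy!r}")

    wanted: set[str] = set()
    for name in lexicon:
        wanted.add(name)
        if match_policy == "subword_mean":
            wanted.update(name.split())

    found: dict[str, np.ndarray] = {}
    dim: int | None = None
    with open(path, encoding="utf-8", errors="replace") as fh:
        first = fh.readline()
        if not first:
            raise WordVectorParseError(f"{path}: empty file")
        header = _detect_header(first)
        lineno = 1
        if header is not None:
            dim = header[1]
        else:
            dim, lineno = _parse_vector_line(first, 1, dim, wanted, found, path)
        for line in fh:
            lineno += 1
            if not line.strip():
                continue
            dim, _ = _parse_vector_line(line, lineno, dim, wanted, found, path)

    rows: list[np.ndarray] = []
    matched: list[str] = []
    missing: list[str] = []
    for name in lexicon:
        vec = _lookup(name, found, match_policy)
        if vec is None:
            missing.append(name)
        else:
            matched.append(name)
            rows.append(vec)
    if not matched:
        raise ValueError(
            f"{path}: no descriptor of the requested lexicon has a word vector"
        )
    if missing:
        logger.warning(
            "%d of %d descriptors have no word vector and were dropped: %s",
            len(missing), len(lexicon), missing,
        )
    vectors = np.vstack(rows) if rows else np.empty((0, dim or 0))
    return SemanticSpace(lexicon.subset(matched), vectors, tuple(missing))


def _parse_vector_line(
    line: str,
    lineno: int,
    dim: int | None,
    wanted: set[str],
    found: dict[str, np.ndarray],
    path: str | Path,
) -> tuple[int, int]:
    parts = line.rstrip("\n").split(" ")
    # trailing space before newline is common in .vec files
    if parts and parts[-1] == "":
        parts = parts[:-1]
    if len(parts) < 2:
        raise WordVectorParseError(f"{path}, line {lineno}: too few fields")
    token, comps = parts[0], parts[1:]
    if dim is None:
        dim = len(comps)
    if len(comps) != dim:
        raise WordVectorParseError(
            f"{path}, line {lineno}: expected {dim} vector components, "
            f"got {len(comps)}"
        )
    key = _normalize_descriptor(token)
    if key in wanted and key not in found:
        try:
            found[key] = np.asarray([float(c) for c in comps])
        except ValueError as exc:
            raise WordVectorParseError(
                f"{path}, line {lineno}: non-numeric vector component"
            ) from exc
    return dim, lineno


def _lookup(
    name: str, found: dict[str, np.ndarray], match_policy: str
) -> np.ndarray | None:
    words = name.split()
    if len(words) == 1:
        return found.get(name)
    if match_policy == "exact":
        return None  # multiword descriptors never match exactly
    parts = [found.get(w) for w in words]
    if any(p is None for p in parts):
        return None
    return np.mean(np.vstack(parts), axis=0)  # type: ignore[arg-type]


def read_ratings_csv(
    path: str | Path,
    scale: tuple[float, float] | None = None,
    check_bounds: bool = True,
) -> RatingsTable:
    frame = pd.read_csv(path, index_col=0)
    frame.index = frame.index.astype(str)
    return RatingsTable.from_frame(frame, scale=scale, check_bounds=check_bounds)


def write_ratings_csv(table: RatingsTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index_label="molecule")


# predictions are written with the same dialect as observed ratings
write_predictions = write_ratings_csv


def read_features_csv(path: str | Path) -> ChemFeatureTable:
    frame = pd.read_csv(path, index_col=0)
    frame.index = frame.index.astype(str)
    return ChemFeatureTable.from_frame(frame)


def write_features_csv(table: ChemFeatureTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index_label="molecule")


T = TypeVar("T", RatingsTable, ChemFeatureTable)


def align_tables(a: T, b: RatingsTable) -> tuple[list[str], T, RatingsTable]:
    """Row-align two tables on their shared molecules.

    Returns the shared ids (in ``a``'s order) and both tables restricted and
    reordered to those ids.  Aligning already-aligned tables is a no-op.
    """
    b_ids = set(b.molecule_ids)
    shared = [m for m in a.molecule_ids if m in b_ids]
    if not shared:
        raise ValueError("tables have no molecules in common")
    return shared, a.subset_molecules(shared), b.subset_molecules(shared)
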