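"""Cells-by-features count matrices and ortholog maps."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import PipelineError


@dataclass
class CountMatrix:
    """A cells x features matrix of non-negative integer counts.

    ``normalized`` (optional) is the depth-scaled log1p transform used
    everywhere downstream: ``log1p(count / cell_depth * scale)``.
    """

    cell_ids: list[str]
    feature_ids: list[str]
    counts: np.ndarray
    normalized: np.ndarray | None = None
    _feature_index: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.cell_ids), len(self.feature_ids)):
            raise PipelineError(
                "matrix-shape",
                f"counts {self.counts.shape} vs {len(self.cell_ids)} cells x "
                f"{len(self.feature_ids)} features",
            )
        if np.any(self.counts < 0):
            raise PipelineError("mtx-negative", "negative counts")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise PipelineError("dup-cell-id", "duplicate cell ids")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise PipelineError("dup-feature-id", "duplicate feature ids")
        self._feature_index = {f: i for i, f in enumerate(self.feature_ids)}

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def feature_idx(self, feature_id: str) -> int:
        return self._feature_index[feature_id]

    def depths(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def require_normalized(self) -> np.ndarray:
        if self.normalized is None:
            raise PipelineError("not-normalized", "call normalize_counts first")
        return self.normalized

    def subset_cells(self, mask_or_ids) -> "CountMatrix":
        if isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype == bool:
            idx = np.flatnonzero(mask_or_ids)
        else:
            pos = {c: i for i, c in enumerate(self.cell_ids)}
            idx = np.array([pos[c] for c in mask_or_ids], dtype=int)
        return CountMatrix(
            [self.cell_ids[i] for i in idx],
            list(self.feature_ids),
            self.counts[idx],
            None if self.normalized is None else self.normalized[idx],
        )


def normalize_counts(m: CountMatrix, scale: float = 10_000.0) -> CountMatrix:
    """Fill ``normalized`` with log1p(count / depth * scale).

    Depth-invariant: doubling every count of a cell leaves its normalized
    vector unchanged. Raises ``zero-depth`` for empty cells.
    """
    depths = m.depths().astype(float)
    if np.any(depths <= 0):
        bad = [m.cell_ids[i] for i in np.flatnonzero(depths <= 0)][:5]
        raise PipelineError("zero-depth", f"cells with zero total count: {bad}")
    norm = np.log1p(m.counts / depths[:, None] * scale)
    return CountMatrix(list(m.cell_ids), list(m.feature_ids), m.counts, norm)


@dataclass
class OrthologyMap:
    """(gene_a, gene_b) ortholog pairs; many a -> one b is allowed."""

    pairs: list[tuple[str, str]]

    def __post_init__(self):
        if len(set(self.pairs)) != len(self.pairs):
            raise PipelineError("dup-ortholog-row", "duplicate (gene_a, gene_b) rows")

    def a_to_b(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for a, b in self.pairs:
            if a in out and out[a] != b:
                raise PipelineError("ambiguous-ortholog", f"{a} maps to {out[a]} and {b}")
            out[a] = b
        return out

    def one_to_one(self) -> list[tuple[str, str]]:
        """Pairs whose b-side gene appears exactly once."""
        from collections import Counter

        counts = Counter(b for _, b in self.pairs)
        return [(a, b) for a, b in self.pairs if counts[b] == 1]
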