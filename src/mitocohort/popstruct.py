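"""PCA on haplogroup-frequency profiles across populations.

Populations are rows, haplogroups columns, entries frequencies in [0, 1]
(rows renormalized to unit sum when slightly off, with a log entry).  The
default mode is covariance PCA on raw frequencies — the usual practice for
haplogroup-frequency ordination — with a correlation mode available.  Sign
convention: each loading vector's largest-magnitude entry is made positive,
so orientations are reproducible across platforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SkPCA

logger = logging.getLogger(__name__)


@dataclass
class FrequencyMatrix:
    values: pd.DataFrame  # populations x haplogroups

    def __post_init__(self) -> None:
        vals = self.values
        if ((vals < 0) | (vals > 1)).any().any():
            raise ValueError("frequencies must lie in [0, 1]")
        sums = vals.sum(axis=1)
        off = sums[(sums - 1.0).abs() > 1e-6]
        if not off.empty:
            logger.info("renormalizing %d population row(s) whose "
                        "frequencies did not sum to 1", len(off))
            self.values = vals.div(sums, axis=0)

    @classmethod
    def from_csv(cls, path) -> "FrequencyMatrix":
        return cls(pd.read_csv(path, index_col=0))

    @property
    def populations(self) -> list[str]:
        return list(self.values.index)

    @property
    def haplogroups(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class PCAResult:
    scores: pd.DataFrame            # populations x PCs
    loadings: pd.DataFrame          # haplogroups x PCs
    variance_explained: np.ndarray  # fraction of total variance per PC
    degenerate: bool = False


def pca(fm: FrequencyMatrix, n_components: int,
        mode: str = "covariance") -> PCAResult:
    """Principal component analysis of the frequency matrix.

    ``variance_explained`` entries are fractions of the total variance,
    ordered decreasingly.  An all-identical-rows input has zero total
    variance and is returned flagged degenerate with zero scores.
    """
    X = fm.values.to_numpy(dtype=float)
    n_pops, n_haps = X.shape
    if n_pops < 2:
        raise ValueError("PCA needs at least 2 populations")
    if not 1 <= n_components <= min(n_pops - 1, n_haps):
        raise ValueError("n_components must lie in [1, min(rows-1, cols)]")
    if mode not in ("covariance", "correlation"):
        raise ValueError("mode must be 'covariance' or 'correlation'")
    if mode == "correlation":
        sd = X.std(axis=0, ddof=1)
        if (sd == 0).any():
            raise ValueError("correlation mode undefined for zero-variance "
                             "haplogroup columns")
        X = (X - X.mean(axis=0)) / sd

    centered = X - X.mean(axis=0)
    total_var = (centered ** 2).sum() / (n_pops - 1)
    pcs = [f"PC{i + 1}" for i in range(n_components)]
    if total_var == 0:
        logger.warning("degenerate PCA input: all populations identical")
        return PCAResult(
            scores=pd.DataFrame(0.0, index=fm.values.index, columns=pcs),
            loadings=pd.DataFrame(0.0, index=fm.values.columns, columns=pcs),
            variance_explained=np.zeros(n_components),
            degenerate=True,
        )

    model = _SkPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    loadings = model.components_.T  # haplogroups x PCs
    # orient each component so its largest-magnitude loading is positive
    for j in range(n_components):
        k = np.argmax(np.abs(loadings[:, j]))
        if loadings[k, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return PCAResult(
        scores=pd.DataFrame(scores, index=fm.values.index, columns=pcs),
        loadings=pd.DataFrame(loadings, index=fm.values.columns, columns=pcs),
        variance_explained=model.explained_variance_ratio_.copy(),
    )


def nearest_populations(scores: pd.DataFrame, query: str) -> pd.DataFrame:
    """Rank the other populations by Euclidean distance to ``query`` in PC
    space; ties break lexicographically."""
    if query not in scores.index:
        raise KeyError(f"unknown population {query!r}")
    q = scores.loc[query].to_numpy(dtype=float)
    others = scores.drop(index=query)
    dist = np.sqrt(((others.to_numpy(dtype=float) - q) ** 2).sum(axis=1))
    out = pd.DataFrame({"population": others.index, "distance": dist})
    out = out.sort_values(["distance", "population"], kind="mergesort")
    return out.reset_index(drop=True)
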