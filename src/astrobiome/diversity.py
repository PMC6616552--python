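"""Alpha diversity, rarefied richness, Bray-Curtis distances and PCoA.

Shannon diversity is reported in nats (natural log).  Rarefied richness is
the exact expectation of the number of taxa observed in a without-
replacement subsample of fixed depth (the hypergeometric / Hurlbert
formula), evaluated in log-space for numerical stability.  Bray-Curtis
comes in a weighted flavor (on relative abundances) and an unweighted
flavor (on presence/absence).  PCoA is classical metric scaling of the
double-centered squared distance matrix; coordinates are returned only on
positive eigen-axes, negative eigenvalues are reported, and each axis is
sign-fixed so its largest-magnitude coordinate is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.special import gammaln

from .io import OtuTable, RelAbundanceTable


def shannon(counts: np.ndarray) -> float:
    """Shannon index H = -sum p ln p (nats) of one sample's counts."""
    x = np.asarray(counts, dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be nonnegative")
    total = x.sum()
    if total <= 0:
        raise ValueError("cannot compute Shannon diversity of a zero-sum sample")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def observed_richness(counts: np.ndarray) -> int:
    return int((np.asarray(counts) > 0).sum())


def rarefied_richness(counts: np.ndarray, depth: int) -> float:
    """Expected number of taxa in a without-replacement subsample of size depth.

    E[S_n] = sum_i [1 - C(N - N_i, n) / C(N, n)] with N the total reads.
    """
    x = np.asarray(counts, dtype=np.int64)
    x = x[x > 0]
    n_total = int(x.sum())
    if depth > n_total:
        raise ValueError(f"depth {depth} exceeds sample total {n_total}")
    if depth < 0:
        raise ValueError("depth must be nonnegative")

    def log_comb(n: np.ndarray, k: int) -> np.ndarray:
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    rest = n_total - x
    with np.errstate(invalid="ignore"):
        log_ratio = np.where(
            rest >= depth,
            log_comb(rest.astype(float), depth) - log_comb(float(n_total), depth),
            -np.inf,
        )
    return float(np.sum(1.0 - np.exp(log_ratio)))


def alpha_diversity_table(table: OtuTable, depth: int | None = None) -> pd.DataFrame:
    """Per-sample Shannon, observed and rarefied richness.

    ``depth`` defaults to the minimum library size of the table (recorded in
    the ``rarefaction_depth`` column so runs are reproducible).
    """
    sums = table.counts.sum(axis=0)
    if (sums == 0).any():
        raise ValueError(f"zero-read samples: {list(sums.index[sums == 0])}")
    if depth is None:
        depth = int(sums.min())
    rows = []
    for s in table.sample_ids:
        col = table.counts[s].to_numpy()
        rows.append({
            "sample_id": s,
            "shannon": shannon(col),
            "richness_observed": observed_richness(col),
            "richness_rarefied": rarefied_richness(col, depth),
            "rarefaction_depth": depth,
        })
    return pd.DataFrame(rows).set_index("sample_id")


def bray_curtis(a: np.ndarray, b: np.ndarray, flavor: str = "weighted") -> float:
    """Bray-Curtis dissimilarity between two taxon vectors.

    weighted: sum |a - b| / sum (a + b); unweighted: (A + B - 2J)/(A + B)
    with A, B the two richness values and J the number of shared taxa.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must share the taxon axis")
    if flavor == "unweighted":
        a = (a > 0).astype(float)
        b = (b > 0).astype(float)
    elif flavor != "weighted":
        raise ValueError(f"unknown flavor {flavor!r}")
    denom = (a + b).sum()
    if denom == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(np.abs(a - b).sum() / denom)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with sample labels."""

    sample_ids: list[str]
    values: np.ndarray
    flavor: str = "weighted"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if v.shape[0] != len(self.sample_ids):
            raise ValueError("label/matrix size mismatch")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have a zero diagonal")
        self.values = v

    def get(self, i: str, j: str) -> float:
        a, b = self.sample_ids.index(i), self.sample_ids.index(j)
        return float(self.values[a, b])

    def subset(self, ids: list[str]) -> "DistanceMatrix":
        idx = [self.sample_ids.index(i) for i in ids]
        return DistanceMatrix(list(ids), self.values[np.ix_(idx, idx)], self.flavor)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.sample_ids)


def distance_matrix(
    table: OtuTable | RelAbundanceTable, flavor: str = "weighted"
) -> DistanceMatrix:
    """All pairwise Bray-Curtis distances of a table's samples.

    Weighted distances are computed on relative abundances (counts are
    normalized per sample first); unweighted distances use the presence
    pattern (count > 0) of the table as given.
    """
    if isinstance(table, RelAbundanceTable):
        mat = table.values.to_numpy(dtype=float).T
    else:
        sums = table.counts.sum(axis=0).to_numpy(dtype=float)
        if (sums == 0).any():
            raise ValueError("zero-read sample in distance computation")
        mat = (table.counts.to_numpy(dtype=float) / sums).T
    if flavor == "unweighted":
        mat = (mat > 0).astype(float)
    elif flavor != "weighted":
        raise ValueError(f"unknown flavor {flavor!r}")
    dm = squareform(pdist(mat, metric="braycurtis"))
    ids = (table.sample_ids if isinstance(table, OtuTable)
           else list(table.values.columns))
    return DistanceMatrix(list(ids), dm, flavor)


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    """Serialize as a labeled square TSV (PHYLIP-like)."""
    df = dm.to_frame()
    df.index.name = f"# flavor={dm.flavor}"
    df.to_csv(path, sep="\t")


def read_distance_matrix(path, flavor: str = "weighted") -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(list(df.columns), df.to_numpy(dtype=float), flavor)


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame  # samples x positive axes
    eigenvalues: np.ndarray    # all eigenvalues, descending (negatives included)

    @property
    def proportion_explained(self) -> np.ndarray:
        pos = self.eigenvalues[self.eigenvalues > 0]
        return pos / pos.sum()


def pcoa(dm: DistanceMatrix) -> PcoaResult:
    """Classical scaling: eigendecompose -1/2 J D^2 J.

    Coordinates are returned on positive axes only (eigenvalue > 1e-10 x
    the largest), ordered by eigenvalue; each axis is sign-fixed so its
    largest-magnitude coordinate is positive.  Negative eigenvalues (from
    non-Euclidean distances) are reported in ``eigenvalues``.
    """
    d = dm.values
    n = d.shape[0]
    if n < 2:
        raise ValueError("PCoA requires at least 2 samples")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = 1e-10 * max(abs(evals[0]), 1.0)
    pos = evals > tol
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    for k in range(coords.shape[1]):
        i = np.argmax(np.abs(coords[:, k]))
        if coords[i, k] < 0:
            coords[:, k] = -coords[:, k]
    frame = pd.DataFrame(
        coords, index=dm.sample_ids,
        columns=[f"PCo{k + 1}" for k in range(coords.shape[1])],
    )
    return PcoaResult(frame, evals)
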