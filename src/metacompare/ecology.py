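"""Normalization, rarefaction, richness/diversity and ordination.

The analysis workflow is: build a raw feature x sample count matrix,
normalize it by a two-step rule (per-sample relative abundance scaled back
to the mean sequencing depth), log10(x+1)-transform for ordination, rarefy
raw counts to a common depth before computing richness, Chao1 and
Gini-Simpson diversity, and ordinate Bray-Curtis distances by PCoA or NMDS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.special import gammaln

logger = logging.getLogger("metacompare")


@dataclass
class AbundanceMatrix:
    """Feature x sample abundance matrix with sample group labels.

    ``raw=True`` marks integer read counts, the only state in which
    rarefaction is meaningful; normalized or transformed matrices carry
    ``raw=False``.
    """

    data: pd.DataFrame
    groups: pd.Series
    raw: bool = True

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        if (self.data.values < 0).any():
            raise ValueError("abundance matrix has negative entries")
        missing = [s for s in self.data.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without group label: {missing}")
        self.groups = self.groups.loc[list(self.data.columns)]

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def features(self) -> list[str]:
        return list(self.data.index)

    def group_names(self) -> list[str]:
        return sorted(self.groups.unique())

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.samples if self.groups[s] == group]

    def copy_with(self, data: pd.DataFrame, raw: bool) -> "AbundanceMatrix":
        return AbundanceMatrix(data, self.groups.copy(), raw=raw)


@dataclass(frozen=True)
class DiversitySummary:
    """Per-sample richness, Chao1 estimate and Gini-Simpson diversity."""

    richness: int
    chao1: float
    simpson: float


def normalize(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Two-step depth normalization.

    Each feature value is divided by its sample's total, and the resulting
    fractions are multiplied by the mean total over all samples, so every
    column sums to the same depth-like quantity while between-sample depth
    differences are removed.
    """
    if not matrix.raw:
        logger.warning("normalizing a matrix not flagged as raw counts")
    totals = matrix.data.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero-total sample: {zero.index[0]}")
    scaled = matrix.data.div(totals, axis=1) * totals.mean()
    return matrix.copy_with(scaled, raw=False)


def log_transform(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """x -> log10(x + 1); zero maps to zero, so absent features stay finite."""
    if (matrix.data.values < 0).any():
        raise ValueError("log transform requires non-negative values")
    return matrix.copy_with(np.log10(matrix.data + 1.0), raw=False)


def rarefy(counts: Sequence[float] | pd.Series, depth: int, seed: int | np.random.Generator = 0):
    """Subsample one sample's counts to ``depth`` reads without replacement.

    Draws from the multivariate hypergeometric distribution, i.e. the reads
    themselves are subsampled, not resampled.  Returns counts of the same
    shape summing exactly to ``depth``.
    """
    arr = np.asarray(counts)
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("rarefaction requires integer raw counts")
    arr = np.round(arr).astype(np.int64)
    total = int(arr.sum())
    if depth > total:
        raise ValueError(f"rarefaction depth {depth} exceeds sample total {total}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sub = rng.multivariate_hypergeometric(arr, depth)
    if isinstance(counts, pd.Series):
        return pd.Series(sub, index=counts.index)
    return sub


def expected_richness(counts: Sequence[float], depth: int) -> float:
    """Expected number of features observed in a depth-``depth`` subsample.

    Closed form for sampling without replacement: each feature with count
    N_i survives with probability 1 - C(N - N_i, n) / C(N, n), where N is
    the sample total and n the depth; the expectation is the sum over
    features.
    """
    arr = np.round(np.asarray(counts, dtype=float)).astype(np.int64)
    arr = arr[arr > 0]
    total = int(arr.sum())
    if depth > total:
        raise ValueError(f"depth {depth} exceeds sample total {total}")
    if depth == 0:
        return 0.0

    def log_comb(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    rest = total - arr
    prob_absent = np.zeros(len(arr))
    feasible = rest >= depth
    prob_absent[feasible] = np.exp(log_comb(rest[feasible], depth) - log_comb(total, depth))
    return float(np.sum(1.0 - prob_absent))


def rarefaction_curve(
    matrix: AbundanceMatrix,
    depths: Sequence[int] | None = None,
    n_reps: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Monte-Carlo rarefaction curves (depth, sample, mean richness, sd).

    Samples whose total is below a depth are dropped from that depth with a
    warning rather than erroring, so one shallow library does not abort a
    whole-study curve.
    """
    if not matrix.raw:
        raise ValueError("rarefaction curves require raw counts")
    totals = matrix.data.sum(axis=0)
    if depths is None:
        top = int(totals.min())
        depths = np.unique(np.linspace(1, top, 8, dtype=int))
    rng = np.random.default_rng(seed)
    rows = []
    for depth in depths:
        for sample in matrix.samples:
            if totals[sample] < depth:
                logger.warning("sample %s total %d < depth %d; dropped", sample, totals[sample], depth)
                continue
            rich = [
                int(np.count_nonzero(rarefy(matrix.data[sample], int(depth), rng)))
                for _ in range(n_reps)
            ]
            rows.append(
                {
                    "depth": int(depth),
                    "sample": sample,
                    "mean_richness": float(np.mean(rich)),
                    "sd_richness": float(np.std(rich, ddof=1)) if n_reps > 1 else 0.0,
                }
            )
    return pd.DataFrame(rows)


def diversity_metrics(counts: Sequence[float] | pd.Series) -> DiversitySummary:
    """Observed richness, Chao1 and Gini-Simpson diversity of one sample.

    Chao1 = S + F1^2 / (2 F2) with F1 singletons and F2 doubletons; when no
    doubletons exist the bias-corrected form S + F1 (F1 - 1) / 2 avoids the
    division by zero.  Simpson is reported in the Gini-Simpson form
    1 - sum(p_i^2) so that larger values mean a more even community.
    """
    arr = np.round(np.asarray(counts, dtype=float)).astype(np.int64)
    arr = arr[arr > 0]
    if arr.size == 0:
        raise ValueError("all-zero sample has undefined diversity")
    s = int(arr.size)
    f1 = int(np.sum(arr == 1))
    f2 = int(np.sum(arr == 2))
    if f2 > 0:
        chao1 = s + f1 * f1 / (2.0 * f2)
    else:
        chao1 = s + f1 * (f1 - 1) / 2.0
    p = arr / arr.sum()
    simpson = float(1.0 - np.sum(p * p))
    return DiversitySummary(richness=s, chao1=float(chao1), simpson=simpson)


def diversity_table(matrix: AbundanceMatrix) -> pd.DataFrame:
    """Per-sample diversity summaries as a frame (sample, richness, chao1, simpson)."""
    rows = []
    for sample in matrix.samples:
        d = diversity_metrics(matrix.data[sample])
        rows.append({"sample": sample, "group": matrix.groups[sample],
                     "richness": d.richness, "chao1": d.chao1, "simpson": d.simpson})
    return pd.DataFrame(rows).set_index("sample")


def bray_curtis(matrix: AbundanceMatrix) -> pd.DataFrame:
    """Sample x sample Bray-Curtis dissimilarity, d = sum|u-v| / sum(u+v)."""
    X = matrix.data.T.values
    zero = np.where(X.sum(axis=1) == 0)[0]
    if len(zero) >= 2:
        names = [matrix.samples[i] for i in zero]
        raise ValueError(f"Bray-Curtis undefined between all-zero samples: {names}")
    d = squareform(pdist(X, metric="braycurtis"))
    return pd.DataFrame(d, index=matrix.samples, columns=matrix.samples)


@dataclass
class OrdinationResult:
    method: str
    coordinates: pd.DataFrame
    eigenvalues: np.ndarray | None = None
    stress: float | None = None


def ordinate(
    dist: pd.DataFrame,
    method: str = "pcoa",
    k: int = 2,
    seed: int = 0,
) -> OrdinationResult:
    """Ordinate a distance matrix by PCoA (metric) or NMDS (non-metric).

    PCoA eigendecomposes the double-centered squared-distance matrix; axes
    are ordered by eigenvalue and negative eigenvalues are reported rather
    than silently dropped.  NMDS minimizes Kruskal stress-1 starting from
    the PCoA configuration, which makes it deterministic.
    """
    n = dist.shape[0]
    if dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dist.values, dist.values.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of samples ({n})")

    from skbio import DistanceMatrix
    from skbio.stats.ordination import pcoa as skbio_pcoa

    dm = DistanceMatrix(dist.values, ids=[str(s) for s in dist.index])
    res = skbio_pcoa(dm, method="eigh")
    eigvals = res.eigvals.values
    coords = res.samples.iloc[:, :k].copy()
    coords.index = dist.index
    coords.columns = [f"axis{i + 1}" for i in range(k)]

    if method.lower() == "pcoa":
        return OrdinationResult("pcoa", coords, eigenvalues=eigvals)
    if method.lower() != "nmds":
        raise ValueError(f"unknown ordination method {method!r}")

    from sklearn.manifold import MDS

    mds = MDS(
        n_components=k,
        metric_mds=False,
        metric="precomputed",
        n_init=1,
        init="classical_mds",
        random_state=seed,
        normalized_stress=True,
        max_iter=500,
        eps=1e-9,
    )
    init = coords.values
    emb = mds.fit_transform(dist.values, init=init)
    nm = pd.DataFrame(emb, index=dist.index, columns=[f"axis{i + 1}" for i in range(k)])
    return OrdinationResult("nmds", nm, stress=float(mds.stress_))


def group_separation(dist: pd.DataFrame, groups: pd.Series) -> dict:
    """Mean between-group vs within-group distance (ordination sanity check)."""
    samples = list(dist.index)
    within, between = [], []
    for i, a in enumerate(samples):
        for b in samples[i + 1 :]:
            (within if groups[a] == groups[b] else between).append(dist.loc[a, b])
    return {
        "mean_within": float(np.mean(within)) if within else float("nan"),
        "mean_between": float(np.mean(between)) if between else float("nan"),
    }
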