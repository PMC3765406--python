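"""Admixture stratification via IBS distances and classical MDS.

Pairwise identity-by-state (IBS) allele sharing over mutually called SNPs
gives a sample-by-sample distance matrix; classical (Torgerson)
multidimensional scaling embeds it, and a composite score over the leading
axes dichotomizes the cohort into the half closer to, and the half farther
from, a reference ancestry direction. The cross-population frequency
comparison is then re-run independently within each half (halved sample
sizes widen the intervals, so stratified calls are more conservative).

Eigen-signs are fixed by forcing each axis's largest-magnitude loading
positive, so results are deterministic for a fixed input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_comparison import ComparisonConfig, compare_cohorts, summarize_differences
from .genio import MISSING_CODE, GenotypeTable
from .paf_estimation import estimate_cohort


@dataclass
class StratificationResult:
    """MDS coordinates, composite scores and subgroup labels for one cohort."""

    sample_ids: list
    coordinates: np.ndarray  # samples x k
    eigenvalues: np.ndarray
    composite_scores: np.ndarray
    labels: list  # "closer" / "farther" per sample
    per_subgroup: dict  # label -> (greater, less, either) proportions, when computed

    def to_frame(self) -> pd.DataFrame:
        k = self.coordinates.shape[1]
        frame = pd.DataFrame(
            self.coordinates, index=self.sample_ids,
            columns=[f"axis{i + 1}" for i in range(k)],
        )
        frame["composite_score"] = self.composite_scores
        frame["subgroup"] = self.labels
        return frame


def ibs_distance_matrix(genotypes: GenotypeTable) -> np.ndarray:
    """1 - mean IBS allele sharing over mutually called SNPs, per sample pair.

    Sharing for one SNP is (2 - |g_i - g_j|) / 2 on copy codes. Raises when
    a pair has no mutually called SNP.
    """
    codes = genotypes.codes.astype(np.float64)
    called = codes != MISSING_CODE
    called_f = called.astype(np.float64)
    # pairwise sum over mutually called SNPs of |g_i - g_j|, via the identity
    # |a-b| expansion is not linear, so compute per-dosage indicator products
    n = codes.shape[0]
    indicators = [((codes == d) & called).astype(np.float64) for d in (0, 1, 2)]
    mutual = called_f @ called_f.T
    if (mutual[~np.eye(n, dtype=bool)] == 0).any():
        raise ValueError("a sample pair shares no mutually called SNPs")
    absdiff = np.zeros((n, n))
    for a in range(3):
        for b in range(3):
            if a == b:
                continue
            absdiff += abs(a - b) * (indicators[a] @ indicators[b].T)
    distance = absdiff / (2.0 * mutual)
    np.fill_diagonal(distance, 0.0)
    return (distance + distance.T) / 2.0


def classical_mds(distances: np.ndarray, k: int = 3) -> tuple:
    """Classical MDS: eigendecomposition of the double-centered Gram matrix.

    Returns (coordinates scaled by sqrt(eigenvalue), eigenvalues) for the
    top-k positive eigenvalues; requests beyond the positive spectrum are
    truncated with a warning.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    gram = -0.5 * j @ (d ** 2) @ j
    eigvals, eigvecs = np.linalg.eigh(gram)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    positive = eigvals > max(1e-12, 1e-12 * abs(eigvals[0]))
    n_pos = int(positive.sum())
    if n_pos < k:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; returning {n_pos} axes instead of {k}",
            stacklevel=2,
        )
        k = n_pos
    eigvals, eigvecs = eigvals[:k], eigvecs[:, :k]
    # sign convention: largest-magnitude loading positive per axis
    for axis in range(k):
        col = eigvecs[:, axis]
        if col[np.argmax(np.abs(col))] < 0:
            eigvecs[:, axis] = -col
    coordinates = eigvecs * np.sqrt(eigvals)
    return coordinates, eigvals


def dichotomize(
    coordinates: np.ndarray,
    reference_direction: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> tuple:
    """Median split of a composite ancestry score into closer/farther halves.

    The composite score is a weighted sum of the axes (default: axis 1
    alone), sign-aligned so that larger means closer to the reference
    direction. With an odd sample count the larger half is "closer".
    Returns (labels, composite_scores).
    """
    coords = np.asarray(coordinates, dtype=float)
    n, k = coords.shape
    if weights is None:
        weights = np.zeros(k)
        weights[0] = 1.0
    weights = np.asarray(weights, dtype=float)
    scores = coords @ weights
    if reference_direction is not None:
        ref = np.asarray(reference_direction, dtype=float)
        alignment = float(ref[: k] @ weights[: ref.shape[0]]) if ref.ndim == 1 else 1.0
        if alignment < 0:
            scores = -scores
    median = np.median(scores)
    # stable split into halves: rank by (score, index), top half "closer"
    order = np.lexsort((np.arange(n), -scores))
    labels = np.empty(n, dtype=object)
    n_closer = (n + 1) // 2
    labels[order[:n_closer]] = "closer"
    labels[order[n_closer:]] = "farther"
    return list(labels), scores


def stratified_comparison(
    labels,
    genotypes: GenotypeTable,
    study_records: dict,
    reference_frame: pd.DataFrame,
    config: ComparisonConfig | None = None,
) -> dict:
    """Re-run PAF estimation and CI-overlap calls within each subgroup.

    Returns label -> {"summary": (greater, less, either), "calls": [...]}.
    """
    config = config or ComparisonConfig()
    labels = list(labels)
    if len(labels) != genotypes.n_samples:
        raise ValueError("one label per sample required")
    out = {}
    counted = {s: r.counted_allele for s, r in study_records.items()}
    for label in sorted(set(labels)):
        members = [s for s, l in zip(genotypes.sample_ids, labels) if l == label]
        if len(members) < 2:
            raise ValueError(f"subgroup {label!r} has fewer than 2 samples")
        sub = genotypes.subset_samples(members)
        estimates = estimate_cohort(sub, counted, config.z_quantile)
        calls = compare_cohorts(estimates, study_records, reference_frame, config)
        out[label] = {"summary": summarize_differences(calls), "calls": calls}
    return out


def stratify_cohort(
    genotypes: GenotypeTable,
    k: int = 3,
    reference_direction: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> StratificationResult:
    """IBS distances -> classical MDS -> composite-score dichotomization."""
    distances = ibs_distance_matrix(genotypes)
    coordinates, eigenvalues = classical_mds(distances, k)
    labels, scores = dichotomize(coordinates, reference_direction, weights)
    return StratificationResult(
        list(genotypes.sample_ids), coordinates, eigenvalues, scores, labels, {}
    )
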