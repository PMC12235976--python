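"""Individual-based clustering: DAPC and Evanno delta-K.

DAPC (discriminant analysis of principal components) one-hot expands the
genotype matrix into individual x allele counts (0/1/2), mean-imputes missing
cells, centers, reduces by PCA, and runs linear discriminant analysis with
pooled within-group covariance on the retained scores. Membership
probabilities are the Gaussian class posteriors. Evanno's delta-K scores a
table of clustering log-likelihoods per K from any admixture program.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .io import AlleleLabel, GenotypeMatrix

logger = logging.getLogger("gbas")


# ---------------------------------------------------------------------------
# allele design matrix
# ---------------------------------------------------------------------------


def allele_design_matrix(
    m: GenotypeMatrix,
) -> tuple[np.ndarray, list[tuple[str, AlleleLabel]]]:
    """Individuals x alleles count matrix (0/1/2) with column-mean imputation
    of missing cells. Column order: loci in matrix order, alleles sorted."""
    columns: list[tuple[str, AlleleLabel]] = []
    for locus in m.loci:
        alleles = sorted(
            {a for (s, l), pair in m.calls.items() if l == locus for a in pair}
        )
        columns.extend((locus, a) for a in alleles)
    col_idx = {key: j for j, key in enumerate(columns)}
    locus_cols: dict[str, list[int]] = {}
    for (locus, _), j in col_idx.items():
        locus_cols.setdefault(locus, []).append(j)
    X = np.full((len(m.individuals), len(columns)), np.nan)
    for i, (sample, _) in enumerate(m.individuals):
        for locus in m.loci:
            pair = m.get(sample, locus)
            if pair is None:
                continue
            for j in locus_cols.get(locus, ()):
                X[i, j] = 0.0
            for a in pair:
                X[i, col_idx[(locus, a)]] += 1.0
    col_means = np.nanmean(X, axis=0)
    col_means = np.where(np.isnan(col_means), 0.0, col_means)
    nan_mask = np.isnan(X)
    X[nan_mask] = np.take(col_means, np.nonzero(nan_mask)[1])
    return X, columns


# ---------------------------------------------------------------------------
# DAPC
# ---------------------------------------------------------------------------


@dataclass
class DapcModel:
    sample_ids: list[str]
    groups: list[str]
    group_labels: list[str]  # per individual
    centering: np.ndarray
    pca_loadings: np.ndarray  # features x n_pca
    pca_scores: np.ndarray  # individuals x n_pca
    da_coords: np.ndarray  # individuals x n_da
    memberships: np.ndarray  # individuals x groups, rows sum to 1
    n_pca: int
    n_da: int
    columns: list[tuple[str, AlleleLabel]] = field(repr=False, default_factory=list)

    def assignments(self) -> list[str]:
        return [self.groups[int(i)] for i in np.argmax(self.memberships, axis=1)]

    def accuracy(self) -> float:
        """Fraction of individuals whose highest membership matches their
        prior group."""
        correct = sum(
            a == g for a, g in zip(self.assignments(), self.group_labels)
        )
        return correct / len(self.group_labels)


def _fix_axis_signs(loadings: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # make the largest-magnitude loading on each axis positive (reproducible
    # orientation; axes are otherwise sign-indeterminate)
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return loadings, scores


def dapc_fit(
    m: GenotypeMatrix,
    groups: Mapping[str, str] | None = None,
    n_pca: int = 4,
    n_da: int = 4,
) -> DapcModel:
    """Fit DAPC on a genotype matrix.

    ``groups`` maps sample_id to a prior group; population tags are used when
    omitted. Retains ``n_pca`` principal axes (reduced with a warning when the
    centered design has lower rank) and at most min(n_groups - 1, n_pca)
    discriminant axes. Deterministic up to the fixed axis-sign convention.
    """
    X, columns = allele_design_matrix(m)
    sample_ids = m.sample_ids
    labels = [
        (groups[s] if groups is not None else m.population_of(s)) for s in sample_ids
    ]
    uniq = sorted(set(labels))
    if len(uniq) < 2:
        raise ValueError("DAPC needs at least two groups")
    centering = X.mean(axis=0)
    Xc = X - centering
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int((S > 1e-9 * max(1.0, S[0] if S.size else 0.0)).sum())
    if rank == 0:
        raise ValueError("degenerate design: all individuals identical")
    if n_pca > rank:
        logger.warning("n_pca reduced from %d to matrix rank %d", n_pca, rank)
        n_pca = rank
    loadings = Vt[:n_pca].T.copy()
    scores = Xc @ loadings
    loadings, scores = _fix_axis_signs(loadings, scores)

    n_da = min(n_da, len(uniq) - 1, n_pca)
    label_arr = np.asarray(labels)
    pooled_within = np.zeros(n_pca)
    for g in uniq:
        member = scores[label_arr == g]
        if len(member) > 1:
            pooled_within += member.var(axis=0) * len(member)
    if pooled_within.max() < 1e-12:
        # zero within-group scatter (e.g. fully separated synthetic
        # clusters): LDA covariance is singular; assign by nearest group
        # centroid with hard memberships
        logger.warning("zero within-group variance; using centroid assignment")
        centroids = np.stack([scores[label_arr == g].mean(axis=0) for g in uniq])
        d2 = ((scores[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        memberships = np.zeros((len(scores), len(uniq)))
        memberships[np.arange(len(scores)), np.argmin(d2, axis=1)] = 1.0
        coords = scores[:, :n_da].copy()
    else:
        lda = LinearDiscriminantAnalysis(n_components=n_da, solver="svd")
        lda.fit(scores, labels)
        coords = lda.transform(scores)
        memberships = lda.predict_proba(scores)
        # reorder posterior columns to sorted group order (sklearn sorts
        # classes_ already, but be explicit)
        order = [list(lda.classes_).index(g) for g in uniq]
        memberships = memberships[:, order]
        da_loadings = lda.scalings_[:, :n_da].copy()
        da_loadings, coords = _fix_axis_signs(da_loadings, coords.copy())
    return DapcModel(
        sample_ids=sample_ids,
        groups=uniq,
        group_labels=labels,
        centering=centering,
        pca_loadings=loadings,
        pca_scores=scores,
        da_coords=coords,
        memberships=memberships,
        n_pca=n_pca,
        n_da=n_da,
        columns=columns,
    )


def dapc_downsample(
    m: GenotypeMatrix,
    groups: Mapping[str, str] | None = None,
    n_per_group: int = 5,
    seed: int = 0,
    n_pca: int = 4,
    n_da: int = 4,
) -> tuple[DapcModel, list[str]]:
    """Randomly downsample every group with more than ``n_per_group``
    individuals to ``n_per_group`` (seeded, without replacement), then fit
    DAPC. Groups at or below the target are kept whole. Returns the model
    and the retained sample ids."""
    rng = np.random.default_rng(seed)
    labels = {
        s: (groups[s] if groups is not None else m.population_of(s))
        for s in m.sample_ids
    }
    kept: list[str] = []
    for g in sorted(set(labels.values())):
        members = [s for s in m.sample_ids if labels[s] == g]
        if len(members) > n_per_group:
            members = list(rng.choice(members, size=n_per_group, replace=False))
        else:
            logger.warning("group %s has %d <= %d individuals; kept whole", g, len(members), n_per_group)
        kept.extend(members)
    sub = m.subset(samples=kept)
    model = dapc_fit(sub, groups, n_pca=n_pca, n_da=n_da)
    return model, kept


# ---------------------------------------------------------------------------
# Evanno delta-K
# ---------------------------------------------------------------------------


@dataclass
class DeltaKTable:
    ks: list[int]
    mean_l: dict[int, float]
    sd_l: dict[int, float]
    delta_k: dict[int, float | None]  # None where undefined (edge or sd == 0)

    @property
    def best_k(self) -> int:
        defined = {k: v for k, v in self.delta_k.items() if v is not None}
        if not defined:
            raise ValueError("delta K undefined at every interior K")
        return max(defined, key=lambda k: defined[k])


def evanno_delta_k(runs: Mapping[int, Sequence[float]]) -> DeltaKTable:
    """Evanno's delta K from per-K clustering log-likelihoods.

    delta K(K) = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd(L(K)),
    defined at interior K with positive run-to-run standard deviation.
    Requires at least three consecutive K values and two runs per K.
    """
    ks = sorted(runs)
    if len(ks) < 3:
        raise ValueError("need at least three K values")
    if any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("K values must be consecutive")
    for k in ks:
        if len(runs[k]) < 2:
            raise ValueError(f"K={k}: need at least two runs to compute sd")
    mean_l = {k: float(np.mean(runs[k])) for k in ks}
    sd_l = {k: float(np.std(runs[k], ddof=1)) for k in ks}
    delta: dict[int, float | None] = {}
    for k in ks[1:-1]:
        if sd_l[k] > 0:
            delta[k] = abs(mean_l[k + 1] - 2 * mean_l[k] + mean_l[k - 1]) / sd_l[k]
        else:
            delta[k] = None
    return DeltaKTable(ks, mean_l, sd_l, delta)
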