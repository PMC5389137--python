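"""Procrustes form-space PCA and the associated size statistics.

Form space augments the flattened Procrustes shape coordinates with the
natural logarithm of centroid size (lnCS), so a covariance-matrix PCA of
the reference sample captures overall size, allometry and shape together.
Unknown specimens are never part of the decomposition; they are centred by
the reference mean and projected onto the reference eigenvectors.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin


def form_matrix(shapes: np.ndarray, centroid_sizes: np.ndarray) -> np.ndarray:
    """Stack flattened shape coordinates with a trailing lnCS column."""
    arr = np.asarray(shapes, dtype=float)
    cs = np.asarray(centroid_sizes, dtype=float)
    if arr.ndim != 3:
        raise ValueError("expected shapes of shape (N, K, 3)")
    if np.any(cs <= 0):
        raise ValueError("centroid sizes must be positive")
    flat = arr.reshape(arr.shape[0], -1)
    return np.column_stack([flat, np.log(cs)])


class FormSpacePCA(BaseEstimator, TransformerMixin):
    """Covariance-matrix PCA of [shape coordinates | lnCS] form vectors.

    Parameters
    ----------
    n_components :
        Number of PCs kept; ``None`` keeps every component up to the data
        rank.  No variable weighting is applied between the shape block
        and the lnCS column.

    Attributes
    ----------
    mean_ : (p,) reference mean form vector.
    components_ : (m, p) orthonormal eigenvector rows, eigenvalue-ordered.
    explained_variance_ : (m,) descending eigenvalues of the covariance.
    scores_ : (N, m) centred reference data projected on the eigenvectors.
    lncs_index_ : column index of the lnCS variable (p - 1).
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X, y=None) -> "FormSpacePCA":
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        if n < 3:
            raise ValueError("form-space PCA needs at least 3 reference specimens")
        self.mean_ = X.mean(axis=0)
        centered = X - self.mean_
        u, s, vt = np.linalg.svd(centered, full_matrices=False)
        m = min(n - 1, p)
        if self.n_components is not None:
            m = min(m, self.n_components)
        self.components_ = vt[:m]
        self.explained_variance_ = (s[:m] ** 2) / (n - 1)
        self.scores_ = centered @ self.components_.T
        self.lncs_index_ = p - 1
        self.n_samples_ = n
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.mean_.shape[0]:
            raise ValueError(
                f"form vectors have {X.shape[-1]} variables, "
                f"expected {self.mean_.shape[0]}"
            )
        return (X - self.mean_) @ self.components_.T

    def variance_ratio(self) -> np.ndarray:
        return self.explained_variance_ / self.explained_variance_.sum()

    def positive_eigenvalues(self, rtol: float = 1e-9) -> np.ndarray:
        """Eigenvalues above numerical rank cut-off (for sphericity testing)."""
        lam = self.explained_variance_
        return lam[lam > rtol * lam[0]]


def build_form_space(
    shapes: np.ndarray,
    centroid_sizes: np.ndarray,
    n_components: int | None = None,
) -> FormSpacePCA:
    """Fit a :class:`FormSpacePCA` on reference shapes + centroid sizes."""
    return FormSpacePCA(n_components=n_components).fit(
        form_matrix(shapes, centroid_sizes)
    )


def project(space: FormSpacePCA, shapes: np.ndarray, centroid_sizes: np.ndarray) -> np.ndarray:
    """Project superimposed specimens into an existing form space."""
    return space.transform(form_matrix(shapes, centroid_sizes))


# ---------------------------------------------------------------------------
# PC retention: sphericity of trailing eigenvalue blocks

def anderson_retained_pcs(
    eigenvalues: np.ndarray, n: int, alpha: float = 0.05
) -> int:
    """Number of leading PCs to retain by the trailing-eigenvalue sphericity test.

    For a trailing block of the q smallest eigenvalues the likelihood-ratio
    statistic

        n' * [ q * ln(mean of block) - sum of ln(eigenvalues in block) ]

    with Lawley's small-sample multiplier n' = n - k - (2q^2 + q + 2)/(6q)
    (k leading PCs excluded) is referred to a chi-square with
    q(q+1)/2 - 1 degrees of freedom.  Blocks are grown from the smallest
    trailing pair upward, each block tested at the Bonferroni-corrected
    level ``alpha / (p - 1)`` so that the family-wise chance of retaining
    any PC on truly spherical data stays below ``alpha``; the largest
    block not rejected is deemed isotropic noise and every PC before it
    is retained.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    p = len(lam)
    if p < 2:
        return 0
    if np.any(np.diff(lam) > 1e-12 * max(lam[0], 1.0)):
        raise ValueError("eigenvalues must be sorted in descending order")
    level = alpha / (p - 1)
    largest_equal = 1
    for q in range(2, p + 1):
        block = lam[p - q:]
        if np.any(block <= 0):
            raise ValueError("non-positive eigenvalue in tested block")
        n_eff = n - (p - q) - (2 * q * q + q + 2) / (6.0 * q)
        statistic = n_eff * (q * np.log(block.mean()) - np.sum(np.log(block)))
        df = q * (q + 1) / 2 - 1
        if stats.chi2.sf(statistic, df) >= level:
            largest_equal = q
        else:
            break
    return p - largest_equal


# ---------------------------------------------------------------------------
# Permutation tests on size

class PermutationTestResult:
    def __init__(self, statistic: float, p: float, n_perm: int, seed: int):
        self.statistic = statistic
        self.p = p
        self.n_perm = n_perm
        self.seed = seed

    def __repr__(self) -> str:
        return (
            f"PermutationTestResult(statistic={self.statistic:.6g}, "
            f"p={self.p:.6g}, n_perm={self.n_perm})"
        )


def permutation_test(
    values: np.ndarray,
    labels: np.ndarray,
    statistic: str = "mean_difference",
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationTestResult:
    """Two-sided two-group permutation test on per-specimen scalars.

    ``statistic`` is either ``mean_difference`` or ``variance_difference``
    (unbiased variances).  The p-value uses the add-one convention
    ``(1 + #{|perm| >= |obs|}) / (n_perm + 1)`` so it can never be zero.
    """
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    names = np.unique(lab)
    if len(names) != 2:
        raise ValueError("permutation test needs exactly two groups")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    mask = lab == names[0]
    if mask.all() or (~mask).all():
        raise ValueError("both groups must be non-empty")

    if statistic == "mean_difference":
        def stat(m): return v[m].mean() - v[~m].mean()
    elif statistic == "variance_difference":
        if np.ptp(v) == 0:
            raise ValueError("variance statistic undefined for constant values")
        def stat(m): return v[m].var(ddof=1) - v[~m].var(ddof=1)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")

    observed = stat(mask)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(mask)
        if abs(stat(perm)) >= abs(observed) - 1e-12:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return PermutationTestResult(float(observed), float(p), n_perm, seed)


# ---------------------------------------------------------------------------
# PC-extreme shapes

def pc_extreme_shape(
    space: FormSpacePCA,
    pc: int,
    magnitude: float,
    sign: int = 1,
) -> tuple[np.ndarray, float]:
    """Landmark configuration at an extreme of one form-space PC.

    The shape block of the consensus is displaced by ``sign * magnitude``
    times the shape part of the eigenvector; the result is then uniformly
    scaled by ``exp(sign * magnitude * lnCS loading)`` so the size content
    of the PC is rendered as actual scale.  Returns (K x 3 coordinates,
    scale factor).
    """
    if not 0 <= pc < len(space.components_):
        raise IndexError(f"PC index {pc} out of range")
    if sign not in (-1, 1):
        raise ValueError("sign must be +1 or -1")
    vec = space.components_[pc]
    i = space.lncs_index_
    shape_mean = space.mean_[:i].reshape(-1, 3)
    delta = (sign * magnitude * vec[:i]).reshape(-1, 3)
    scale = float(np.exp(sign * magnitude * vec[i]))
    return (shape_mean + delta) * scale, scale


def allometry_correlations(space: FormSpacePCA, lncs: np.ndarray, n_pcs: int = 3) -> np.ndarray:
    """Pearson correlation of each leading PC's reference scores with lnCS."""
    lncs = np.asarray(lncs, dtype=float)
    out = []
    for j in range(min(n_pcs, space.scores_.shape[1])):
        out.append(float(np.corrcoef(space.scores_[:, j], lncs)[0, 1]))
    return np.array(out)
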