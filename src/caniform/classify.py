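"""Quadratic discriminant classification of canid skulls with resampling.

The reference sample is heavily unbalanced (far more wolves than dogs),
so classification proceeds by balanced resampling: in each of ``n_iter``
iterations a without-replacement wolf subsample of the dog sample size is
drawn, the form space is rebuilt on the balanced sample, the number of
retained PCs is chosen by the trailing-eigenvalue sphericity test, a QDA
with equal priors is fitted, and every unknown specimen is scored.  A
specimen is assigned to a group only when its posterior probability
exceeds a threshold (0.90 by default); otherwise it is undetermined.
Typicality probabilities — chi-square tail probabilities of the squared
Mahalanobis distance under the pooled covariance — flag specimens that
fit neither reference group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin

from .formspace import FormSpacePCA, anderson_retained_pcs

UNDETERMINED = "undetermined"


# ---------------------------------------------------------------------------
# Gaussian group models

def _fit_gaussian(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = x.mean(axis=0)
    cov = np.cov(x, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "singular group covariance; retain fewer PCs or add specimens"
        )
    return mean, cov


def _log_gaussian(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Log density of rows of x under N(mean, cov)."""
    d = x - mean
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        raise np.linalg.LinAlgError("covariance not positive definite")
    maha = np.einsum("ij,ij->i", d, np.linalg.solve(cov, d.T).T)
    k = cov.shape[0]
    return -0.5 * (k * np.log(2 * np.pi) + logdet + maha)


class ThresholdQDA(BaseEstimator, ClassifierMixin):
    """Two-group QDA with a posterior-probability acceptance threshold.

    Group means and unbiased covariance matrices are estimated per class;
    posteriors are prior-weighted Gaussian densities normalised to sum
    to 1.  ``predict`` returns the maximum-posterior class only when that
    posterior strictly exceeds ``threshold`` and returns
    ``"undetermined"`` otherwise (an exact tie is never above threshold).

    Parameters
    ----------
    priors : per-class prior probabilities in class sort order
        (default equal priors).
    threshold : posterior needed for a determinate call; 0.90 follows the
        convention that posteriors are forced to sum to 1 over the two
        reference groups, so an unknown must be allowed to match neither.
    """

    def __init__(self, priors: np.ndarray | None = None, threshold: float = 0.90):
        self.priors = priors
        self.threshold = threshold

    def fit(self, X, y) -> "ThresholdQDA":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        k = X.shape[1]
        if self.priors is None:
            priors = np.full(len(self.classes_), 1.0 / len(self.classes_))
        else:
            priors = np.asarray(self.priors, dtype=float)
            if not np.isclose(priors.sum(), 1.0):
                raise ValueError("priors must sum to 1")
        self.priors_ = priors
        self.means_ = []
        self.covariances_ = []
        for c in self.classes_:
            xc = X[y == c]
            if len(xc) <= k:
                raise ValueError(
                    f"group {c!r} has {len(xc)} specimens for {k} variables; "
                    "covariance would be singular — retain fewer PCs"
                )
            m, s = _fit_gaussian(xc)
            self.means_.append(m)
            self.covariances_.append(s)
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        logp = np.column_stack(
            [
                _log_gaussian(X, m, s) + np.log(pr)
                for m, s, pr in zip(self.means_, self.covariances_, self.priors_)
            ]
        )
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        best = np.argmax(proba, axis=1)
        calls = self.classes_[best].astype(object)
        calls[proba[np.arange(len(calls)), best] <= self.threshold] = UNDETERMINED
        return calls


def fit_qda(scores: np.ndarray, labels: np.ndarray, priors=None) -> ThresholdQDA:
    return ThresholdQDA(priors=priors).fit(scores, labels)


def posterior(model: ThresholdQDA, x: np.ndarray) -> np.ndarray:
    return model.predict_proba(np.atleast_2d(x))[0]


def classify_threshold(
    posteriors: np.ndarray, classes: np.ndarray, threshold: float = 0.90
) -> str:
    """Maximum-posterior class if it strictly exceeds the threshold, else undetermined."""
    posteriors = np.asarray(posteriors, dtype=float)
    best = int(np.argmax(posteriors))
    if posteriors[best] > threshold:
        return str(classes[best])
    return UNDETERMINED


# ---------------------------------------------------------------------------
# Separation statistics

def klecka_tau(confusion: np.ndarray, priors: np.ndarray, group_sizes: np.ndarray) -> float:
    """Proportional reduction in classification error over prior-based chance.

    tau = (n_correct - sum_g prior_g * n_g) / (N - sum_g prior_g * n_g)
    """
    confusion = np.asarray(confusion, dtype=float)
    n_correct = np.trace(confusion)
    n_g = np.asarray(group_sizes, dtype=float)
    chance = float(np.sum(np.asarray(priors) * n_g))
    total = float(n_g.sum())
    if np.isclose(total, chance):
        raise ZeroDivisionError("tau undefined: chance equals the sample size")
    return float((n_correct - chance) / (total - chance))


def wilks_lambda(scores: np.ndarray, labels: np.ndarray) -> float:
    """det(within-group SSCP) / det(total SSCP); small values mean separation."""
    x = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least two groups")
    grand = x.mean(axis=0)
    t = (x - grand).T @ (x - grand)
    w = np.zeros_like(t)
    for c in classes:
        xc = x[y == c]
        d = xc - xc.mean(axis=0)
        w += d.T @ d
    sign_t, logdet_t = np.linalg.slogdet(t)
    sign_w, logdet_w = np.linalg.slogdet(w)
    if sign_t <= 0:
        raise np.linalg.LinAlgError("singular total SSCP")
    return float(np.exp(logdet_w - logdet_t))


def box_m(scores: np.ndarray, labels: np.ndarray) -> tuple[float, int, float]:
    """Box's M test of equality of group covariance matrices.

    Returns (chi-square approximation of M with the standard scaling
    correction, degrees of freedom (g-1)*k*(k+1)/2, upper-tail p).
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    g = len(classes)
    n_total, k = x.shape
    covs, ns = [], []
    for c in classes:
        xc = x[y == c]
        if len(xc) <= k:
            raise ValueError(f"group {c!r} too small for {k} variables")
        covs.append(np.atleast_2d(np.cov(xc, rowvar=False, ddof=1)))
        ns.append(len(xc))
    ns = np.asarray(ns)
    pooled = sum((n - 1) * s for n, s in zip(ns, covs)) / (n_total - g)
    sign, logdet_p = np.linalg.slogdet(pooled)
    if sign <= 0:
        raise np.linalg.LinAlgError("singular pooled covariance")
    m = (n_total - g) * logdet_p
    for n, s in zip(ns, covs):
        sign, logdet = np.linalg.slogdet(np.atleast_2d(s))
        if sign <= 0:
            raise np.linalg.LinAlgError("singular group covariance")
        m -= (n - 1) * logdet
    c = (np.sum(1.0 / (ns - 1)) - 1.0 / (n_total - g)) * (
        2 * k**2 + 3 * k - 1
    ) / (6.0 * (k + 1) * (g - 1))
    chi2_stat = float(m * (1 - c))
    df = int((g - 1) * k * (k + 1) / 2)
    p = float(stats.chi2.sf(chi2_stat, df))
    return chi2_stat, df, p


def typicality(
    pooled_cov: np.ndarray,
    group_mean: np.ndarray,
    x: np.ndarray,
    df: int,
    method: str = "chi2",
    n: int | None = None,
) -> float:
    """Tail probability of membership in a group (Typ.P).

    The squared Mahalanobis distance of ``x`` from the group mean under
    the pooled within-group covariance is referred to the chi-square
    distribution with ``df`` = number of retained PCs (default), or —
    with ``method='f'`` and the pooled sample size ``n`` — to the
    small-sample F reference for an external observation.  Typ.P <= 0.05
    means the specimen is atypical of the group and its posterior should
    be disregarded.
    """
    d = np.asarray(x, dtype=float) - np.asarray(group_mean, dtype=float)
    d2 = float(d @ np.linalg.solve(np.atleast_2d(pooled_cov), d))
    if method == "chi2":
        return float(stats.chi2.sf(d2, df))
    if method == "f":
        if n is None or n <= df + 1:
            raise ValueError("F-based typicality needs the pooled sample size n > df + 1")
        f_stat = d2 * n * (n - df) / (df * (n - 1) * (n + 1))
        return float(stats.f.sf(f_stat, df, n - df))
    raise ValueError(f"unknown typicality method {method!r}")


# ---------------------------------------------------------------------------
# Leave-one-out cross-validated summary

@dataclass
class DiscriminationSummary:
    percent_correct: float
    tau: float
    wilks_lambda: float
    box_m: tuple[float, int, float]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        m, df, p = self.box_m
        return (
            f"{self.percent_correct:.1f}% correctly classified "
            f"(Tau = {self.tau:.3f}, Wilks' lambda = {self.wilks_lambda:.3f}, "
            f"Mbox = {m:.2f}, df = {df}, p = {p:.3g})"
        )


def _loo_posteriors(
    x: np.ndarray, y: np.ndarray, classes: np.ndarray, priors: np.ndarray
) -> np.ndarray:
    """Leave-one-out posterior matrix via rank-one mean/covariance downdates."""
    n, k = x.shape
    stats_by_class = {}
    for c in classes:
        xc = x[y == c]
        m = xc.mean(axis=0)
        s = (xc - m).T @ (xc - m)  # SSCP
        stats_by_class[c] = (len(xc), m, s)
    out = np.empty((n, len(classes)))
    for i in range(n):
        logp = np.empty(len(classes))
        for j, c in enumerate(classes):
            nc, m, s = stats_by_class[c]
            if y[i] == c:
                d = x[i] - m
                m_i = (nc * m - x[i]) / (nc - 1)
                s_i = s - (nc / (nc - 1)) * np.outer(d, d)
                cov = s_i / (nc - 2)
            else:
                cov = s / (nc - 1)
                m_i = m
            logp[j] = _log_gaussian(x[i][None, :], m_i, cov)[0] + np.log(priors[j])
        logp -= logp.max()
        p = np.exp(logp)
        out[i] = p / p.sum()
    return out


def loocv_summary(
    scores: np.ndarray,
    labels: np.ndarray,
    priors: np.ndarray | None = None,
    threshold: float = 0.90,
) -> DiscriminationSummary:
    """Leave-one-out cross-validated discrimination of the reference groups.

    A specimen counts as correct only when its true group is called at the
    posterior threshold; undetermined calls count as misclassifications.
    Tau, Wilks' lambda and Box's M are computed on the same scores.
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if priors is None:
        priors = np.full(len(classes), 1.0 / len(classes))
    priors = np.asarray(priors, dtype=float)
    proba = _loo_posteriors(x, y, classes, priors)
    best = np.argmax(proba, axis=1)
    called = proba[np.arange(len(x)), best] > threshold
    confusion = np.zeros((len(classes), len(classes)))
    class_index = {c: j for j, c in enumerate(classes)}
    for i in range(len(x)):
        if called[i]:
            confusion[class_index[y[i]], best[i]] += 1
    n_g = np.array([np.sum(y == c) for c in classes])
    pct = 100.0 * np.trace(confusion) / len(x)
    tau = klecka_tau(confusion, priors, n_g)
    return DiscriminationSummary(
        percent_correct=float(pct),
        tau=tau,
        wilks_lambda=wilks_lambda(x, y),
        box_m=box_m(x, y),
    )


# ---------------------------------------------------------------------------
# Balanced-resampling classification

@dataclass
class SpecimenCall:
    """Aggregated resampling outcome for one unknown specimen (one Table row)."""

    specimen_id: str
    mean_posterior: dict[str, float]
    percent_calls: dict[str, float]          # group name / "undetermined" -> %
    final_call: str                          # "Dog" / "Wolf" / "Ind" style
    percent_atypical: float                  # % iterations with called Typ.P <= 0.05
    typicality_group: str


@dataclass
class ClassificationReport:
    calls: list[SpecimenCall]
    n_iter: int
    seed: int
    retained_pcs: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.calls:
            row = {"specimen": c.specimen_id}
            for g, v in c.mean_posterior.items():
                row[f"avg_Ppost_{g}"] = round(v, 4)
            for g, v in c.percent_calls.items():
                row[f"pct_{g}"] = round(v, 1)
            row["qda_result"] = c.final_call
            row["pct_TypP_le_0.05"] = round(c.percent_atypical, 1)
            row["typicality_group"] = c.typicality_group
            rows.append(row)
        return pd.DataFrame(rows)


def _pretty(group: str) -> str:
    return {"dog": "Dog", "wolf": "Wolf"}.get(group, group.capitalize())


class ResampledQDA(BaseEstimator):
    """Balanced-resampling cross-validated QDA over rebuilt form spaces.

    ``fit`` stores the reference form vectors (flattened symmetric shape
    coordinates + lnCS) and two-group labels; ``predict`` runs the
    resampling loop and aggregates each unknown's outcomes into a
    Table-1-style report.

    Per iteration ``i`` (pseudo-random stream derived from
    ``(random_state, i)`` so runs are reproducible and restartable):

    1. draw a without-replacement wolf subsample of the dog sample size;
    2. refit the form-space PCA on the balanced sample;
    3. choose the retained PC count by the trailing-eigenvalue sphericity
       test at ``alpha`` (capped so group covariances stay invertible);
    4. fit QDA with priors ``priors`` on the retained scores;
    5. score each projected unknown at ``threshold`` and compute its
       typicality against both groups under the pooled covariance.

    The final call for an unknown is the group winning at least
    ``call_fraction`` of iterations, otherwise indeterminate ("Ind").
    """

    def __init__(
        self,
        n_iter: int = 1000,
        threshold: float = 0.90,
        call_fraction: float = 0.90,
        priors: tuple[float, float] | None = None,
        alpha: float = 0.05,
        form_rank: int | None = None,
        random_state: int = 0,
    ):
        self.n_iter = n_iter
        self.threshold = threshold
        self.call_fraction = call_fraction
        self.priors = priors
        self.alpha = alpha
        self.form_rank = form_rank
        self.random_state = random_state

    def fit(self, X, y) -> "ResampledQDA":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if set(self.classes_) != {"dog", "wolf"}:
            raise ValueError("reference labels must be 'dog' and 'wolf'")
        n_dog = int(np.sum(y == "dog"))
        n_wolf = int(np.sum(y == "wolf"))
        if n_dog > n_wolf:
            raise ValueError(
                "balanced resampling expects at least as many wolves as dogs"
            )
        self.X_, self.y_ = X, y
        self.n_dog_, self.n_wolf_ = n_dog, n_wolf
        return self

    def predict(
        self, X_unknown: np.ndarray, ids: list[str] | None = None
    ) -> tuple[ClassificationReport, DiscriminationSummary]:
        xu = np.atleast_2d(np.asarray(X_unknown, dtype=float))
        n_unknown = len(xu)
        if ids is None:
            ids = [f"unknown_{i + 1}" for i in range(n_unknown)]
        priors = (
            np.full(2, 0.5) if self.priors is None else np.asarray(self.priors)
        )
        dogs = self.X_[self.y_ == "dog"]
        wolves = self.X_[self.y_ == "wolf"]

        n_classes = 2
        post_sum = np.zeros((n_unknown, n_classes))
        call_count = np.zeros((n_unknown, 3), dtype=int)  # dog, wolf, undet
        atypical_count = np.zeros(n_unknown, dtype=int)
        typ_group_count = np.zeros((n_unknown, n_classes), dtype=int)
        retained = np.empty(self.n_iter, dtype=int)
        pct_correct = np.empty(self.n_iter)
        taus = np.empty(self.n_iter)
        wilks = np.empty(self.n_iter)
        box_stats = np.empty(self.n_iter)
        box_df = 0

        class_names = np.array(["dog", "wolf"])
        for i in range(self.n_iter):
            rng = np.random.default_rng([self.random_state, i])
            pick = rng.choice(self.n_wolf_, size=self.n_dog_, replace=False)
            xb = np.vstack([dogs, wolves[pick]])
            yb = np.array(["dog"] * self.n_dog_ + ["wolf"] * self.n_dog_)

            space = FormSpacePCA().fit(xb)
            # Procrustes data are rank-deficient: superimposition (and the
            # symmetric component) suppresses several directions to near
            # zero without zeroing them exactly; the known form-space rank
            # keeps those leakage eigenvalues out of the sphericity blocks.
            if self.form_rank is not None:
                lam = space.explained_variance_[: self.form_rank]
            else:
                lam = space.positive_eigenvalues()
            k = anderson_retained_pcs(lam, n=len(xb), alpha=self.alpha)
            k = int(np.clip(k, 1, self.n_dog_ - 2))
            retained[i] = k
            sb = space.scores_[:, :k]
            su = space.transform(xu)[:, :k]

            model = ThresholdQDA(priors=priors, threshold=self.threshold)
            model.fit(sb, yb)
            proba = model.predict_proba(su)
            post_sum += proba
            best = np.argmax(proba, axis=1)
            for j in range(n_unknown):
                if proba[j, best[j]] > self.threshold:
                    call_count[j, best[j]] += 1
                else:
                    call_count[j, 2] += 1

            pooled = 0.5 * (model.covariances_[0] + model.covariances_[1])
            for j in range(n_unknown):
                typ = np.array(
                    [
                        typicality(pooled, model.means_[g], su[j], df=k)
                        for g in range(n_classes)
                    ]
                )
                tg = int(np.argmax(typ))
                typ_group_count[j, tg] += 1
                if typ[tg] <= 0.05:
                    atypical_count[j] += 1

            summary = loocv_summary(sb, yb, priors=priors, threshold=self.threshold)
            pct_correct[i] = summary.percent_correct
            taus[i] = summary.tau
            wilks[i] = summary.wilks_lambda
            box_stats[i] = summary.box_m[0]
            box_df = summary.box_m[1]

        calls = []
        for j in range(n_unknown):
            pct = 100.0 * call_count[j] / self.n_iter
            winner = int(np.argmax(pct[:2]))
            if pct[winner] >= 100.0 * self.call_fraction:
                final = _pretty(class_names[winner])
            else:
                final = "Ind"
            calls.append(
                SpecimenCall(
                    specimen_id=ids[j],
                    mean_posterior={
                        c: float(post_sum[j, g] / self.n_iter)
                        for g, c in enumerate(class_names)
                    },
                    percent_calls={
                        "dog": float(pct[0]),
                        "wolf": float(pct[1]),
                        UNDETERMINED: float(pct[2]),
                    },
                    final_call=final,
                    percent_atypical=float(100.0 * atypical_count[j] / self.n_iter),
                    typicality_group=_pretty(
                        class_names[int(np.argmax(typ_group_count[j]))]
                    ),
                )
            )
        mean_box = float(box_stats.mean())
        report = ClassificationReport(
            calls=calls,
            n_iter=self.n_iter,
            seed=self.random_state,
            retained_pcs=retained,
        )
        summary = DiscriminationSummary(
            percent_correct=float(pct_correct.mean()),
            tau=float(taus.mean()),
            wilks_lambda=float(wilks.mean()),
            box_m=(mean_box, box_df, float(stats.chi2.sf(mean_box, box_df))),
        )
        return report, summary


def resampled_classification(
    reference_forms: np.ndarray,
    reference_labels: np.ndarray,
    unknown_forms: np.ndarray,
    unknown_ids: list[str] | None = None,
    n_iter: int = 1000,
    threshold: float = 0.90,
    call_fraction: float = 0.90,
    priors=None,
    alpha: float = 0.05,
    form_rank: int | None = None,
    seed: int = 0,
) -> tuple[ClassificationReport, DiscriminationSummary]:
    """Functional wrapper over :class:`ResampledQDA`."""
    model = ResampledQDA(
        n_iter=n_iter,
        threshold=threshold,
        call_fraction=call_fraction,
        priors=priors,
        alpha=alpha,
        form_rank=form_rank,
        random_state=seed,
    )
    model.fit(reference_forms, reference_labels)
    return model.predict(unknown_forms, ids=unknown_ids)
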