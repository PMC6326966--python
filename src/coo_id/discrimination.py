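"""Individual distinctiveness: PCA reduction, DFA classification, LOOCV.

The pipeline standardizes the 14 acoustic parameters, eigendecomposes their
correlation matrix, retains components with eigenvalue > 0.6 (a relaxed
Kaiser criterion), varimax-rotates the retained loadings, and computes
component scores by the regression method.  A linear discriminant analysis on
those scores — pooled within-class covariance, priors matching the observed
group sizes — yields canonical functions, a resubstitution confusion matrix,
and a leave-one-out cross-validated one.  Accuracy is compared against the
1/k chance level with a one-sided exact binomial test.

Standardization and PCA are fitted once on the full data set; the
leave-one-out loop refits only the discriminant stage, mirroring the common
two-step practice (PCA first, LOOCV inside the DFA).  A fully nested variant
that re-standardizes per fold is available via ``loocv(..., nested=True)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats as sps

from .features import PARAMETERS

PRIOR_MODES = ("observed", "uniform")


class DiscriminationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# PCA with eigenvalue retention and varimax rotation


def varimax(loadings: np.ndarray, tol: float = 1e-8, max_sweeps: int = 500) -> np.ndarray:
    """Orthogonal varimax rotation of a loading matrix.

    Iterative pairwise plane rotations (the classic Kaiser algorithm, closed
    form for the optimal angle of each column pair) until the varimax
    criterion improves by less than ``tol`` over a full sweep.  With a single
    column the rotation is the identity.  Communalities (row sums of squared
    loadings) are preserved exactly, as for any orthogonal rotation.
    """
    L = np.array(loadings, dtype=float)
    p, m = L.shape
    if m < 2:
        return L

    def criterion(A):
        sq = A**2
        return float(np.sum(sq**2) - np.sum(sq.sum(axis=0) ** 2) / p)

    last = criterion(L)
    for _ in range(max_sweeps):
        for j in range(m - 1):
            for k in range(j + 1, m):
                x, y = L[:, j], L[:, k]
                u = x**2 - y**2
                v = 2.0 * x * y
                A, B = u.sum(), v.sum()
                num = 2.0 * (np.dot(u, v) - A * B / p)
                den = np.dot(u, u) - np.dot(v, v) - (A**2 - B**2) / p
                phi = 0.25 * np.arctan2(num, den)
                if abs(phi) < 1e-12:
                    continue
                c, s = np.cos(phi), np.sin(phi)
                L[:, j], L[:, k] = c * x + s * y, -s * x + c * y
        now = criterion(L)
        if now - last < tol:
            break
        last = now
    # sign convention: each factor's largest-|loading| entry is positive
    signs = np.sign(L[np.argmax(np.abs(L), axis=0), np.arange(m)])
    signs[signs == 0] = 1.0
    return L * signs


@dataclass
class PCAModel:
    """Standardization constants, eigenstructure, and rotated loadings."""

    parameters: list[str]
    means: np.ndarray
    sds: np.ndarray
    eigenvalues: np.ndarray          # all p, descending
    retained: int
    loadings: np.ndarray             # p × retained, unrotated (eigvec·√λ)
    rotated_loadings: np.ndarray     # p × retained, after varimax
    correlation: np.ndarray
    cumulative_variance_pct: float

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        """Component scores by the regression method: Z · R⁺ · Λ_rot.

        The pseudo-inverse handles the exact linear dependence among the
        parameters (range f0 is max f0 minus min f0 by construction, so the
        correlation matrix is singular by one rank).
        """
        Z = (table[self.parameters].to_numpy(dtype=float) - self.means) / self.sds
        weights = np.linalg.pinv(self.correlation, rcond=1e-10) @ self.rotated_loadings
        return Z @ weights


def fit_pca(
    table: pd.DataFrame,
    eigen_threshold: float = 0.6,
    parameters=PARAMETERS,
    matrix: str = "correlation",
) -> PCAModel:
    """Standardized PCA keeping components with eigenvalue > threshold.

    The default operates on the correlation matrix (z-scored variables, the
    appropriate choice for mixed-unit acoustic parameters); ``matrix=
    'covariance'`` is available for same-unit data.  Retained loadings are
    varimax-rotated.
    """
    X = table[list(parameters)].to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        raise DiscriminationError(f"PCA needs more calls ({n}) than parameters ({p})")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    if np.any(sds == 0):
        bad = [parameters[i] for i in np.flatnonzero(sds == 0)]
        raise DiscriminationError(f"constant parameter column(s): {bad}")
    if matrix == "correlation":
        Z = (X - means) / sds
        S = np.corrcoef(X, rowvar=False)
    elif matrix == "covariance":
        Z = X - means
        S = np.cov(X, rowvar=False)
    else:
        raise ValueError("matrix must be 'correlation' or 'covariance'")
    eigvals, eigvecs = np.linalg.eigh(S)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    eigvals = np.maximum(eigvals, 0.0)
    retained = int(np.sum(eigvals > eigen_threshold))
    if retained == 0:
        raise DiscriminationError(
            f"no eigenvalue exceeds the retention threshold {eigen_threshold}"
        )
    loadings = eigvecs[:, :retained] * np.sqrt(eigvals[:retained])
    rotated = varimax(loadings) if retained >= 2 else loadings.copy()
    cum_pct = 100.0 * float(eigvals[:retained].sum() / eigvals.sum())
    return PCAModel(
        parameters=list(parameters), means=means, sds=sds,
        eigenvalues=eigvals, retained=retained, loadings=loadings,
        rotated_loadings=rotated, correlation=S if matrix == "correlation"
        else np.corrcoef(X, rowvar=False),
        cumulative_variance_pct=cum_pct,
    )


def ks_normality(scores: np.ndarray) -> np.ndarray:
    """One-sample KS p-value per component against N(sample mean, sample SD).

    Reported for inspection only — the discriminant stage is run regardless.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[0] < 5:
        raise ValueError("KS normality check needs >= 5 scores per component")
    ps = []
    for j in range(scores.shape[1]):
        s = scores[:, j]
        ps.append(sps.kstest(s, "norm", args=(s.mean(), s.std(ddof=1))).pvalue)
    return np.asarray(ps)


# ---------------------------------------------------------------------------
# Linear discriminant analysis with canonical functions


@dataclass
class DFAModel:
    classes: list[str]
    class_means: np.ndarray          # k × p
    pooled_cov: np.ndarray           # p × p, ridge-regularized
    priors: np.ndarray               # k
    eigenvalues: np.ndarray          # canonical, descending
    pct_variance: np.ndarray         # per canonical function
    coefficients: np.ndarray         # p × n_functions (canonical weights)

    @property
    def n_functions(self) -> int:
        return self.eigenvalues.size


def fit_dfa(
    scores: np.ndarray,
    labels,
    priors: str = "observed",
    ridge: float = 1e-8,
) -> DFAModel:
    """Linear DFA on component scores with group-size-adjusted priors.

    Pooled within-class covariance (with a small ridge, λ = ridge × mean
    diagonal, so near-singular folds stay invertible); canonical functions
    from the generalized eigenproblem of the between- versus within-class
    scatter; ``min(k-1, p)`` functions with their eigenvalues and percentage
    of between-class variance.
    """
    fixed_priors = None
    if not isinstance(priors, str):
        fixed_priors = np.asarray(priors, dtype=float)
    elif priors not in PRIOR_MODES:
        raise ValueError(f"priors must be one of {PRIOR_MODES}")
    X = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    classes = sorted(set(y.tolist()))
    k, (n, p) = len(classes), X.shape
    if k < 2:
        raise DiscriminationError("DFA needs at least two classes")
    counts = np.array([np.sum(y == c) for c in classes])
    if np.any(counts < 2):
        raise DiscriminationError("every class needs at least two samples")
    mu = np.stack([X[y == c].mean(axis=0) for c in classes])
    Sw = np.zeros((p, p))
    for i, c in enumerate(classes):
        d = X[y == c] - mu[i]
        Sw += d.T @ d
    grand = X.mean(axis=0)
    Sb = (counts[:, None] * (mu - grand)).T @ (mu - grand)
    pooled = Sw / (n - k)
    lam = ridge * np.trace(pooled) / p
    pooled = pooled + lam * np.eye(p)
    try:
        eigvals, eigvecs = sla.eigh(Sb, Sw + (n - k) * lam * np.eye(p))
    except sla.LinAlgError as e:  # pragma: no cover
        raise DiscriminationError(f"singular pooled covariance: {e}") from e
    order = np.argsort(eigvals)[::-1]
    n_fun = min(k - 1, p)
    eigvals = np.maximum(eigvals[order][:n_fun], 0.0)
    coeffs = eigvecs[:, order][:, :n_fun]
    total = eigvals.sum()
    pct = 100.0 * eigvals / total if total > 0 else np.zeros_like(eigvals)
    if fixed_priors is not None:
        if fixed_priors.size != k:
            raise ValueError("explicit priors must have one entry per class")
        pri = fixed_priors / fixed_priors.sum()
    elif priors == "observed":
        pri = counts / n
    else:
        pri = np.full(k, 1.0 / k)
    return DFAModel(
        classes=classes, class_means=mu, pooled_cov=pooled, priors=pri,
        eigenvalues=eigvals, pct_variance=pct, coefficients=coeffs,
    )


def _predict(model: DFAModel, X: np.ndarray) -> np.ndarray:
    """Maximum-posterior class indices (ties broken by class order)."""
    Sinv_mu = sla.solve(model.pooled_cov, model.class_means.T, assume_a="pos")
    scores = X @ Sinv_mu - 0.5 * np.sum(model.class_means * Sinv_mu.T, axis=1)
    scores = scores + np.log(model.priors)
    return np.argmax(scores, axis=1)


@dataclass
class ConfusionMatrix:
    """Counts with rows = true individual, columns = predicted."""

    labels: list[str]
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.labels)
        if self.counts.shape != (k, k) or np.any(self.counts < 0):
            raise ValueError("counts must be a k × k non-negative matrix")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)


def _confusion(classes, y_true_idx, y_pred_idx) -> ConfusionMatrix:
    k = len(classes)
    counts = np.zeros((k, k), dtype=int)
    np.add.at(counts, (y_true_idx, y_pred_idx), 1)
    return ConfusionMatrix(labels=list(classes), counts=counts)


def classify(model: DFAModel, scores: np.ndarray, labels) -> ConfusionMatrix:
    """Resubstitution confusion matrix of the fitted model."""
    y = np.asarray(labels)
    idx = {c: i for i, c in enumerate(model.classes)}
    true_idx = np.array([idx[c] for c in y])
    return _confusion(model.classes, true_idx, _predict(model, np.asarray(scores, float)))


def loocv(scores: np.ndarray, labels, priors: str = "observed") -> ConfusionMatrix:
    """Leave-one-out confusion matrix: refit the discriminant per held-out call.

    Class priors are computed once from the full sample (the group-size
    adjustment of the original procedure) and held fixed across folds; only
    the class means and pooled covariance are re-estimated per fold.
    """
    X = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    classes = sorted(set(y.tolist()))
    idx = {c: i for i, c in enumerate(classes)}
    counts = np.array([np.sum(y == c) for c in classes], dtype=float)
    if isinstance(priors, str):
        if priors not in PRIOR_MODES:
            raise ValueError(f"priors must be one of {PRIOR_MODES}")
        fold_priors = counts / counts.sum() if priors == "observed" \
            else np.full(len(classes), 1.0 / len(classes))
    else:
        fold_priors = np.asarray(priors, dtype=float)
    true_idx, pred_idx = [], []
    for i in range(X.shape[0]):
        mask = np.ones(X.shape[0], dtype=bool)
        mask[i] = False
        y_tr = y[mask]
        if np.sum(y_tr == y[i]) == 0:
            warnings.warn(
                f"LOOCV fold {i} empties class {y[i]!r}; fold skipped", stacklevel=2
            )
            continue
        fold = fit_dfa(X[mask], y_tr, priors=fold_priors)
        p_local = _predict(fold, X[i : i + 1])[0]
        true_idx.append(idx[y[i]])
        pred_idx.append(idx[fold.classes[p_local]])
    return _confusion(classes, np.array(true_idx), np.array(pred_idx))


def accuracy(cm: ConfusionMatrix) -> float:
    """Percent of calls on the confusion-matrix diagonal."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * float(np.trace(cm.counts)) / cm.total


def chance_level(k: int) -> float:
    """Chance classification rate 100/k percent for k individuals."""
    if k < 2:
        raise ValueError("chance level needs k >= 2 individuals")
    return 100.0 / k


def binomial_vs_chance(correct: int, total: int, p0: float) -> float:
    """One-sided exact binomial tail P[X >= correct] under chance rate p0."""
    if not 0 <= correct <= total:
        raise ValueError("need 0 <= correct <= total")
    if not 0 < p0 < 1:
        raise ValueError("need 0 < p0 < 1")
    return float(sps.binomtest(correct, total, p0, alternative="greater").pvalue)


# ---------------------------------------------------------------------------
# End-to-end convenience


@dataclass
class DFAResult:
    """Everything the discrimination stage reports for one feature table."""

    pca: PCAModel
    ks_p_values: np.ndarray
    dfa: DFAModel
    confusion_resub: ConfusionMatrix
    confusion_loocv: ConfusionMatrix
    resub_accuracy: float
    loocv_accuracy: float
    chance_pct: float
    binomial_p: float
    scores: np.ndarray = field(repr=False, default=None)


def run_discrimination(
    table: pd.DataFrame,
    eigen_threshold: float = 0.6,
    priors: str = "observed",
    parameters=PARAMETERS,
) -> DFAResult:
    """Full PCA → DFA → LOOCV analysis of a feature table."""
    pca = fit_pca(table, eigen_threshold=eigen_threshold, parameters=parameters)
    scores = pca.transform(table)
    ks_p = ks_normality(scores)
    labels = table["individual_id"].to_numpy()
    model = fit_dfa(scores, labels, priors=priors)
    cm_resub = classify(model, scores, labels)
    cm_loo = loocv(scores, labels, priors=priors)
    k = len(model.classes)
    acc_r, acc_l = accuracy(cm_resub), accuracy(cm_loo)
    p = binomial_vs_chance(int(np.trace(cm_loo.counts)), cm_loo.total, 1.0 / k)
    return DFAResult(
        pca=pca, ks_p_values=ks_p, dfa=model,
        confusion_resub=cm_resub, confusion_loocv=cm_loo,
        resub_accuracy=acc_r, loocv_accuracy=acc_l,
        chance_pct=chance_level(k), binomial_p=p, scores=scores,
    )
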