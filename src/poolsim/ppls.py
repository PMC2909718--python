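"""Powered partial least squares discriminant analysis (PPLS-DA).

PPLS-DA extracts latent components from a (samples x features) matrix
against a two-class response and classifies with Fisher linear
discriminant analysis (FLDA) on the component scores.

The loading weight of feature *g* for one component is a power-tempered
compromise between its standard deviation ``s_g`` and its correlation
``rho_g`` with the class-coded response.  With ``S_g = s_g / max(s)``
and ``C_g = |rho_g| / max|rho|``, the weight at trade-off parameter
``gamma`` in [0, 1] is

    w_g(gamma) = sign(rho_g) * S_g^((1-gamma)/gamma) * C_g^(gamma/(1-gamma))

At ``gamma = 0.5`` both exponents are one and the weights are
proportional to the feature–response covariances — classical PLS.
Towards the end points the weights concentrate on the features with the
largest standard deviation (``gamma -> 0``) or the largest absolute
correlation (``gamma -> 1``), so components can be driven by few
features.  Per component, ``gamma`` is optimised over a fixed grid in
the configured bounds by maximising the squared correlation between the
candidate score vector ``t = X w`` and the response, after which the
predictor matrix is deflated and the next component is extracted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.utils import check_random_state
from sklearn.utils.validation import check_is_fitted, check_X_y, check_array


def powered_weights(corr: np.ndarray, sd: np.ndarray, gamma: float) -> np.ndarray:
    """Loading-weight vector at trade-off ``gamma`` (not normalised)."""
    corr = np.asarray(corr, dtype=float)
    sd = np.asarray(sd, dtype=float)
    sign = np.sign(corr)
    amax = np.max(np.abs(corr))
    smax = np.max(sd)
    if smax <= 0:
        raise ValueError("zero-variance predictor set")
    if gamma <= 0.0:
        # pure standard-deviation criterion: truncate to the max-sd feature(s)
        return np.where(sd == smax, np.where(sign == 0, 1.0, sign), 0.0)
    if gamma >= 1.0:
        if amax <= 0:
            return np.zeros_like(corr)
        return np.where(np.abs(corr) == amax, sign, 0.0)
    if amax <= 0:
        return np.zeros_like(corr)
    S = sd / smax
    C = np.abs(corr) / amax
    return sign * S ** ((1.0 - gamma) / gamma) * C ** (gamma / (1.0 - gamma))


@dataclass
class PPLSFit:
    """Fitted PPLS decomposition (weights, loadings, scores, powers)."""

    x_mean: np.ndarray
    weights: np.ndarray      # (n_features, n_components)
    loadings: np.ndarray     # (n_features, n_components)
    scores: np.ndarray       # (n_samples, n_components)
    powers: np.ndarray       # chosen gamma per component

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    def rotations(self, n_comp: int | None = None) -> np.ndarray:
        """Projection matrix R with scores(Xnew) = (Xnew - mean) @ R."""
        a = self.n_components if n_comp is None else n_comp
        W = self.weights[:, :a]
        P = self.loadings[:, :a]
        return W @ np.linalg.pinv(P.T @ W)

    def transform(self, X: np.ndarray, n_comp: int | None = None) -> np.ndarray:
        return (np.asarray(X) - self.x_mean) @ self.rotations(n_comp)


def fit_ppls_components(
    X: np.ndarray,
    y: np.ndarray,
    n_comp: int,
    power_bounds: tuple[float, float] = (0.0, 1.0),
    n_power: int = 21,
) -> PPLSFit:
    """Sequentially extract ``n_comp`` powered-PLS components.

    ``y`` is the class coding (any two-valued numeric vector); it is
    centred internally.  Components are extracted greedily: per
    component the power parameter maximising the squared correlation
    between score and response over a ``n_power``-point grid in
    ``power_bounds`` is chosen, then the predictor matrix is deflated.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n_comp < 1 or n_comp > n - 1:
        raise ValueError(f"n_comp must be in [1, {n - 1}]")
    x_mean = X.mean(axis=0)
    E = X - x_mean
    yc = y - y.mean()
    sy = yc.std(ddof=1)
    if sy == 0:
        raise ValueError("response has a single class")
    if not np.any(E.std(axis=0) > 0):
        raise ValueError("zero-variance predictor set")
    lo, hi = power_bounds
    grid = np.linspace(lo, hi, n_power)

    W = np.zeros((p, n_comp))
    P = np.zeros((p, n_comp))
    T = np.zeros((n, n_comp))
    powers = np.zeros(n_comp)
    extracted = 0
    for a in range(n_comp):
        sd = E.std(axis=0, ddof=1)
        cov = E.T @ yc / (n - 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.where(sd > 0, cov / (sd * sy), 0.0)
        # evaluate the whole gamma grid with one matrix product; interior
        # gammas via exp(log) so the powers vectorise across the grid
        Wg = np.empty((p, len(grid)))
        smax = np.max(sd)
        amax = np.max(np.abs(corr))
        interior = (grid > 0.0) & (grid < 1.0)
        if smax > 0 and amax > 0 and np.any(interior):
            with np.errstate(divide="ignore"):
                log_s = np.log(sd / smax)
                log_c = np.log(np.abs(corr) / amax)
            g = grid[interior]
            expo = np.outer(log_s, (1.0 - g) / g) + np.outer(log_c, g / (1.0 - g))
            Wg[:, interior] = np.sign(corr)[:, None] * np.exp(expo)
        for gi in np.flatnonzero(~interior if (smax > 0 and amax > 0) else
                                 np.ones(len(grid), dtype=bool)):
            Wg[:, gi] = powered_weights(corr, sd, grid[gi])
        norms = np.linalg.norm(Wg, axis=0)
        ok = norms > 0
        Wg[:, ok] /= norms[ok]
        Tg = E @ Wg
        ss = np.einsum("ij,ij->j", Tg, Tg)
        with np.errstate(invalid="ignore", divide="ignore"):
            obj = np.where(ok & (ss > 0), (yc @ Tg) ** 2 / ss, -np.inf)
        if not np.any(np.isfinite(obj)):
            break  # nothing left to extract
        best = int(np.argmax(obj))  # first maximum = smallest gamma on ties
        gamma, w, t = grid[best], Wg[:, best], Tg[:, best]
        if t.std(ddof=1) <= 0:
            break
        pa = E.T @ t / (t @ t)
        E = E - np.outer(t, pa)
        W[:, a], P[:, a], T[:, a], powers[a] = w, pa, t, gamma
        extracted += 1
    if extracted == 0:
        raise ValueError("no PPLS component could be extracted")
    return PPLSFit(
        x_mean=x_mean,
        weights=W[:, :extracted],
        loadings=P[:, :extracted],
        scores=T[:, :extracted],
        powers=powers[:extracted],
    )


@dataclass
class FisherLDA:
    """Two-class Fisher discriminant with midpoint threshold."""

    direction: np.ndarray
    threshold: float

    def decision(self, T: np.ndarray) -> np.ndarray:
        return np.atleast_2d(T) @ self.direction - self.threshold


def fit_flda(T: np.ndarray, y01: np.ndarray) -> FisherLDA:
    """Fit a two-class Fisher discriminant on score vectors ``T``.

    The direction is ``Sw^+ (m1 - m0)`` with ``Sw`` the pooled
    within-class covariance (pseudo-inverse for degenerate scatter); the
    threshold is the midpoint of the projected class means, so class 1
    is predicted for positive decision values.
    """
    T = np.atleast_2d(np.asarray(T, dtype=float))
    y01 = np.asarray(y01)
    t0, t1 = T[y01 == 0], T[y01 == 1]
    if len(t0) < 1 or len(t1) < 1 or len(T) < 3:
        raise ValueError("FLDA needs at least two samples in total per class")
    m0, m1 = t0.mean(axis=0), t1.mean(axis=0)
    c0 = t0 - m0
    c1 = t1 - m1
    sw = (c0.T @ c0 + c1.T @ c1) / (len(T) - 2)
    direction = np.linalg.pinv(sw) @ (m1 - m0)
    threshold = float(direction @ (m0 + m1) / 2.0)
    return FisherLDA(direction=direction, threshold=threshold)


class PPLSDAClassifier(ClassifierMixin, BaseEstimator):
    """Powered-PLS discriminant analysis for two classes.

    Parameters
    ----------
    n_components : int or None
        Fixed number of latent components; ``None`` selects it by
        stratified inner cross-validation minimising the
        misclassification count (ties go to fewer components).
    max_components : int
        Cap on the number of components considered.
    power_bounds : (float, float)
        Search interval for the power parameter gamma, default [0, 1].
    n_power : int
        Grid resolution for the gamma search.
    cv : int
        Inner cross-validation folds (reduced to the smallest class
        size when necessary).
    random_state : int, Generator or None
        Seeds the inner-CV fold shuffling.

    Attributes
    ----------
    n_components_ : selected number of components.
    powers_ : chosen gamma per component.
    ppls_ : the fitted :class:`PPLSFit` decomposition.
    cv_errors_ : per-component-count CV misclassification counts
        (present when the inner CV ran).
    """

    def __init__(
        self,
        n_components: int | None = None,
        max_components: int = 10,
        power_bounds: tuple[float, float] = (0.0, 1.0),
        n_power: int = 21,
        cv: int = 10,
        random_state=None,
    ):
        self.n_components = n_components
        self.max_components = max_components
        self.power_bounds = power_bounds
        self.n_power = n_power
        self.cv = cv
        self.random_state = random_state

    def _cap(self, n_samples: int) -> int:
        return max(1, min(self.max_components, n_samples - 2))

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        self.classes_, y01 = np.unique(y, return_inverse=True)
        if len(self.classes_) != 2:
            raise ValueError("PPLS-DA is a two-class method")
        counts = np.bincount(y01)
        if counts.min() < 2:
            raise ValueError("need at least two samples per class")
        cap = self._cap(len(y01))
        if self.n_components is not None:
            a = min(self.n_components, cap)
        else:
            a = self._select_n_components(X, y01, cap)
        self.ppls_ = fit_ppls_components(
            X, y01, a, power_bounds=self.power_bounds, n_power=self.n_power
        )
        a = self.ppls_.n_components  # extraction may stop early
        self.n_components_ = a
        self.powers_ = self.ppls_.powers
        self.flda_ = fit_flda(self.ppls_.scores[:, :a], y01)
        return self

    def _select_n_components(self, X, y01, cap: int) -> int:
        rs = check_random_state(self.random_state)
        n_splits = int(min(self.cv, np.bincount(y01).min()))
        n_splits = max(2, n_splits)
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=rs)
        a_max = cap
        for train, _ in skf.split(X, y01):
            a_max = min(a_max, self._cap(len(train)))
        errors = np.zeros(a_max)
        for train, val in skf.split(X, y01):
            fit = fit_ppls_components(
                X[train], y01[train], a_max,
                power_bounds=self.power_bounds, n_power=self.n_power,
            )
            fold_err = np.zeros(a_max)
            for a in range(1, fit.n_components + 1):
                flda = fit_flda(fit.scores[:, :a], y01[train])
                pred = (flda.decision(fit.transform(X[val], a)) > 0).astype(int)
                fold_err[a - 1] = np.sum(pred != y01[val])
            # component counts beyond what could be extracted behave like the last
            fold_err[fit.n_components:] = fold_err[fit.n_components - 1]
            errors += fold_err
        self.cv_errors_ = errors
        return int(np.argmin(errors)) + 1  # argmin takes the first (fewest) on ties

    def decision_function(self, X):
        check_is_fitted(self, "ppls_")
        X = check_array(X, dtype=float, ensure_min_samples=0)
        if X.shape[1] != self.ppls_.x_mean.shape[0]:
            raise ValueError("feature count differs from the training matrix")
        return self.flda_.decision(self.ppls_.transform(X, self.n_components_))

    def predict(self, X):
        d = self.decision_function(X)
        return self.classes_[(d > 0).astype(int)]
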