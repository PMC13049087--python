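"""Nonlinear effective connectivity via a neural-network MVAR (nCREANN).

A single-hidden-layer feedforward network implements a nonlinear multivariate
autoregressive model x(n) = f(x_p) + noise: the input is the vector of p past
samples of all M regions, the output the current sample of every region.
Hidden units are tanh with a trainable per-unit scaling, so the network's
first-order Taylor expansion at the origin separates f into a linear and a
nonlinear part:

* directed linear connectivity LC_{i->j} aggregates (L2 norm over lags) the
  first-order coefficients from region i's lags to output j, obtained by
  multiplying the network weights with the hidden scaling parameters;
* directed nonlinear connectivity NC_{i->j} = ln(mse_lin_i / mse_full): the
  log ratio of the prediction error for x_j when region i acts only through
  its linearized (first-order) pathway versus the full network.

Training is incremental (per-sample) gradient descent with momentum and an
adaptive learning rate, early stopping on a validation split, and a fivefold
permuted 80/10/10 cross-validation; connectivity is averaged over folds and
fit quality reported as test-set R^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from ._utils import as_rng

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard dependency
    def njit(*a, **k):
        def deco(f):
            return f
        return deco if not (len(a) == 1 and callable(a[0])) else a[0]

__all__ = ["NCREANNetwork", "NCREANN", "select_model_order", "train",
           "linear_connectivity", "nonlinear_connectivity", "compare_directed",
           "build_lagged"]


@dataclass
class NCREANNetwork:
    """Network parameters. Hidden unit h computes tanh(lam_h * (w_h @ u + b_h))."""

    W: np.ndarray      # (H, M*p) input weights
    lam: np.ndarray    # (H,) hidden scaling parameters
    b: np.ndarray      # (H,) hidden biases
    V: np.ndarray      # (M, H) output weights
    c: np.ndarray      # (M,) output biases
    n_regions: int
    order: int

    def forward(self, U):
        """Predict current samples from lagged inputs U of shape (n, M*p)."""
        A = np.tanh(self.lam[None, :] * (U @ self.W.T + self.b[None, :]))
        return A @ self.V.T + self.c[None, :]

    def copy(self):
        return NCREANNetwork(self.W.copy(), self.lam.copy(), self.b.copy(),
                             self.V.copy(), self.c.copy(),
                             self.n_regions, self.order)

    def linear_coefficients(self):
        """First-order Taylor coefficients at the origin.

        Returns (M, M, p): entry [j, i, l] is the linear coefficient from
        region i at lag l+1 onto output j,
        sum_h V[j,h] * tanh'(lam_h b_h) * lam_h * W[h, (i,l)].
        """
        M, p = self.n_regions, self.order
        gprime = 1.0 - np.tanh(self.lam * self.b) ** 2          # (H,)
        C = np.einsum("jh,h,hk->jk", self.V, gprime * self.lam, self.W)
        return C.reshape(M, M, p)


def build_lagged(series_list, p):
    """Lagged design from one or more contiguous segments.

    ``series_list`` is a list of (n_samples, M) arrays (e.g. concatenated
    -0.5..0.5 s epochs). Targets never straddle a segment seam: each segment
    contributes its samples from index p on. Input layout: column i*p + l
    holds x_i(t - l - 1).

    Returns (U, Y) with shapes (n, M*p) and (n, M).
    """
    Us, Ys = [], []
    for seg in series_list:
        seg = np.asarray(seg, dtype=float)
        if seg.ndim != 2:
            raise ValueError("each segment must be (n_samples, M)")
        n, M = seg.shape
        if n <= p:
            continue
        t = np.arange(p, n)
        U = np.empty((t.size, M * p))
        for i in range(M):
            for lag in range(1, p + 1):
                U[:, i * p + lag - 1] = seg[t - lag, i]
        Us.append(U)
        Ys.append(seg[t])
    if not Us:
        raise ValueError(f"no segment longer than the model order p={p}")
    return np.concatenate(Us), np.concatenate(Ys)


# ---------------------------------------------------------------------------
# Model order selection
# ---------------------------------------------------------------------------

def select_model_order(series, candidates=range(1, 13)):
    """Pick the MVAR order by the Schwartz (BIC) criterion, AIC reported too.

    A least-squares linear MVAR is fit per candidate order on a common
    effective sample; ties go to the smaller order. Ill-conditioned designs
    fall back to a small ridge.

    Returns (p, info) where ``info`` maps order -> {"aic": ..., "bic": ...}.
    """
    series = np.asarray(series, dtype=float)
    if series.shape[0] > series.shape[1]:
        raise ValueError("series must be (M, n_samples) with n >> M")
    x = series.T
    candidates = sorted(int(p) for p in candidates)
    pmax = candidates[-1]
    n_eff = x.shape[0] - pmax
    if n_eff < 10 * pmax:
        raise ValueError("series too short for the largest candidate order")
    info = {}
    for p in candidates:
        U, Y = build_lagged([x], p)
        U, Y = U[-n_eff:], Y[-n_eff:]
        X = np.column_stack([np.ones(n_eff), U])
        gram = X.T @ X
        if np.linalg.cond(gram) > 1e12:
            gram = gram + 1e-6 * np.trace(gram) / gram.shape[0] * np.eye(gram.shape[0])
        B = np.linalg.solve(gram, X.T @ Y)
        resid = Y - X @ B
        Sigma = resid.T @ resid / n_eff
        _, logdet = np.linalg.slogdet(Sigma)
        k = p * series.shape[0] ** 2
        info[p] = {"aic": logdet + 2.0 * k / n_eff,
                   "bic": logdet + math.log(n_eff) * k / n_eff}
    best = min(candidates, key=lambda p: (info[p]["bic"], p))
    return best, info


# ---------------------------------------------------------------------------
# Incremental EBP training (numba kernel)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _epoch_update(W, lam, b, V, c, vW, vlam, vb, vV, vc, U, Y, order, eta, mom):
    n, d = U.shape
    H = W.shape[0]
    M = V.shape[0]
    s = np.empty(H)
    a = np.empty(H)
    e = np.empty(M)
    da = np.empty(H)
    for ii in range(n):
        t = order[ii]
        u = U[t]
        y = Y[t]
        for h in range(H):
            acc = b[h]
            for k in range(d):
                acc += W[h, k] * u[k]
            s[h] = acc
            a[h] = math.tanh(lam[h] * acc)
        for j in range(M):
            acc = c[j]
            for h in range(H):
                acc += V[j, h] * a[h]
            e[j] = acc - y[j]
        for h in range(H):
            acc = 0.0
            for j in range(M):
                acc += V[j, h] * e[j]
            da[h] = acc
        for j in range(M):
            vc[j] = mom * vc[j] - eta * e[j]
            c[j] += vc[j]
            for h in range(H):
                vV[j, h] = mom * vV[j, h] - eta * e[j] * a[h]
                V[j, h] += vV[j, h]
        for h in range(H):
            g = da[h] * (1.0 - a[h] * a[h])
            vlam[h] = mom * vlam[h] - eta * g * s[h]
            vb[h] = mom * vb[h] - eta * g * lam[h]
            coef = g * lam[h]
            for k in range(d):
                vW[h, k] = mom * vW[h, k] - eta * coef * u[k]
                W[h, k] += vW[h, k]
            lam[h] += vlam[h]
            b[h] += vb[h]


def _mse(net, U, Y):
    return np.mean((net.forward(U) - Y) ** 2, axis=0)


def _train_single(U, Y, n_hidden, rng, momentum, eta0, eta_up, eta_down,
                  reject_ratio, patience, max_epochs, init_scale):
    n, d = U.shape
    M = Y.shape[1]
    net = NCREANNetwork(
        W=rng.uniform(-init_scale, init_scale, size=(n_hidden, d)),
        lam=rng.uniform(-init_scale, init_scale, size=n_hidden),
        b=rng.uniform(-init_scale, init_scale, size=n_hidden),
        V=rng.uniform(-init_scale, init_scale, size=(M, n_hidden)),
        c=rng.uniform(-init_scale, init_scale, size=M),
        n_regions=M, order=d // M)
    vel = [np.zeros_like(p) for p in (net.W, net.lam, net.b, net.V, net.c)]

    n_val = max(1, int(round(0.111 * n)))      # 10 % of the full series
    idx = rng.permutation(n)
    val_idx, tr_idx = idx[:n_val], idx[n_val:]
    Utr, Ytr = U[tr_idx], Y[tr_idx]
    Uval, Yval = U[val_idx], Y[val_idx]

    eta = eta0
    prev = float(_mse(net, Utr, Ytr).mean())
    initial = prev
    worse_than_initial = 0
    best = net.copy()
    best_val = float(_mse(net, Uval, Yval).mean())
    since_best = 0
    for _ in range(max_epochs):
        snapshot = net.copy()
        vel_snapshot = [v.copy() for v in vel]
        order = rng.permutation(Utr.shape[0])
        _epoch_update(net.W, net.lam, net.b, net.V, net.c, *vel,
                      Utr, Ytr, order, eta, momentum)
        cur = float(_mse(net, Utr, Ytr).mean())
        if not np.isfinite(cur) or cur > prev * reject_ratio:
            net = snapshot
            vel = vel_snapshot
            eta *= eta_down
            if eta < 1e-10:
                raise RuntimeError(
                    f"nCREANN training diverged: learning rate collapsed "
                    f"(train MSE {cur:.3g}, initial {initial:.3g})")
            continue
        if cur < prev:
            eta *= eta_up
        prev = cur
        if cur > initial:
            worse_than_initial += 1
            if worse_than_initial >= 5:
                eta *= 0.5
                worse_than_initial = 0
                if eta < 1e-10:
                    raise RuntimeError("nCREANN training diverged: error never "
                                       "dropped below its initial value")
        else:
            worse_than_initial = 0
        val = float(_mse(net, Uval, Yval).mean())
        if val < best_val:
            best_val = val
            best = net.copy()
            since_best = 0
        else:
            since_best += 1
            if since_best >= patience:
                break
    return best


def linear_connectivity(net: NCREANNetwork, lag_norm="l2"):
    """Directed linear connectivity LC[i, j] (source i -> target j).

    The first-order Taylor coefficients over region i's lags into output j are
    aggregated with the L2 norm (or the sum of absolute values with
    ``lag_norm="abs_sum"``).
    """
    C = net.linear_coefficients()          # (j, i, lag)
    if lag_norm == "l2":
        lc = np.sqrt((C ** 2).sum(axis=2))
    elif lag_norm == "abs_sum":
        lc = np.abs(C).sum(axis=2)
    else:
        raise ValueError(f"unknown lag_norm {lag_norm!r}")
    return lc.T                            # (source, target)


def nonlinear_connectivity(net: NCREANNetwork, U, Y, mode="linearize"):
    """Directed nonlinear connectivity NC[i, j] = ln(mse_num_j / mse_full_j).

    The denominator is the full network's mean squared prediction error for
    x_j. For the numerator, region i's input pathway is replaced:

    * ``mode="linearize"`` (default): i contributes only through the network's
      first-order term in its lags (all cross-terms involving i removed),
      other regions act through the full network;
    * ``mode="ablate"``: region i's inputs are removed altogether.
    """
    M, p = net.n_regions, net.order
    full_mse = _mse(net, U, Y)
    if np.any(full_mse <= 0):
        raise ZeroDivisionError("full-network prediction error is zero")
    lin = net.linear_coefficients()        # (j, i, lag)
    nc = np.zeros((M, M))
    for i in range(M):
        cols = slice(i * p, (i + 1) * p)
        U_wo = U.copy()
        U_wo[:, cols] = 0.0
        pred = net.forward(U_wo)
        if mode == "linearize":
            pred = pred + U[:, cols] @ lin[:, i, :].T
        elif mode != "ablate":
            raise ValueError(f"unknown mode {mode!r}")
        num_mse = np.mean((pred - Y) ** 2, axis=0)
        nc[i] = np.log(num_mse / full_mse)
    return nc


def train(series, order=9, n_hidden=6, folds=5, momentum=0.9, eta0=0.01,
          eta_up=1.05, eta_down=0.7, reject_ratio=1.04, patience=10,
          max_epochs=500, init_scale=0.5, nc_mode="linearize", lag_norm="l2",
          zscore=True, seed=None):
    """Convenience wrapper: fit an :class:`NCREANN` estimator and return it."""
    est = NCREANN(order=order, n_hidden=n_hidden, folds=folds, momentum=momentum,
                  eta0=eta0, eta_up=eta_up, eta_down=eta_down,
                  reject_ratio=reject_ratio, patience=patience,
                  max_epochs=max_epochs, init_scale=init_scale,
                  nc_mode=nc_mode, lag_norm=lag_norm, zscore=zscore,
                  random_state=seed)
    return est.fit(series)


class NCREANN(BaseEstimator):
    """Nonlinear MVAR network estimator of directed connectivity.

    Parameters
    ----------
    order : MVAR model order p (number of past samples per region).
    n_hidden : hidden units (tanh with trainable per-unit scaling).
    folds : permuted cross-validation folds; each fold uses an 80/10/10
        train/validation/test split of the time-indexed samples.
    momentum, eta0, eta_up, eta_down, reject_ratio : incremental EBP
        hyperparameters — classic momentum, initial learning rate, the
        multiplicative increase after an improving epoch, the decrease (with
        epoch rejection) when the training error grows beyond
        ``reject_ratio``.
    patience, max_epochs : early stopping on validation MSE.
    init_scale : parameters initialized uniformly on [-init_scale, init_scale].
    nc_mode : "linearize" (default) or "ablate" numerator for NC.
    zscore : z-score each region before fitting (recommended; the Taylor
        expansion point is the origin).
    r2_floor : mean test R^2 below this flags the fit as poor quality.

    Attributes
    ----------
    lc_, nc_ : (M, M) directed linear / nonlinear connectivity,
        entry [i, j] = i -> j, averaged over folds.
    r2_test_ : (M,) per-region test R^2 averaged over folds; ``r2_mean_``.
    networks_ : per-fold :class:`NCREANNetwork`.
    poor_fit_ : True when ``r2_mean_ < r2_floor``.
    """

    def __init__(self, order=9, n_hidden=6, folds=5, momentum=0.9, eta0=0.01,
                 eta_up=1.05, eta_down=0.7, reject_ratio=1.04, patience=10,
                 max_epochs=500, init_scale=0.5, nc_mode="linearize",
                 lag_norm="l2", zscore=True, r2_floor=0.5, random_state=None):
        self.order = order
        self.n_hidden = n_hidden
        self.folds = folds
        self.momentum = momentum
        self.eta0 = eta0
        self.eta_up = eta_up
        self.eta_down = eta_down
        self.reject_ratio = reject_ratio
        self.patience = patience
        self.max_epochs = max_epochs
        self.init_scale = init_scale
        self.nc_mode = nc_mode
        self.lag_norm = lag_norm
        self.zscore = zscore
        self.r2_floor = r2_floor
        self.random_state = random_state

    def _prepare(self, X):
        if isinstance(X, (list, tuple)):
            segments = [np.asarray(s, dtype=float) for s in X]
        else:
            segments = [np.asarray(X, dtype=float)]
        if self.zscore:
            cat = np.concatenate(segments)
            mu, sd = cat.mean(axis=0), cat.std(axis=0)
            sd[sd == 0] = 1.0
            segments = [(s - mu) / sd for s in segments]
        return build_lagged(segments, self.order)

    def fit(self, X, y=None):
        """Fit on a (n_samples, M) series or a list of contiguous segments."""
        U, Y = self._prepare(X)
        n, M = Y.shape
        if n <= 20 * self.order:
            raise ValueError("series too short: need n > 20 * order samples")
        rng = as_rng(self.random_state)

        n_test = max(1, int(round(0.1 * n)))
        lcs, ncs, r2s, nets = [], [], [], []
        for _ in range(self.folds):
            perm = rng.permutation(n)
            test_idx, fit_idx = perm[:n_test], perm[n_test:]
            net = _train_single(U[fit_idx], Y[fit_idx], self.n_hidden, rng,
                                self.momentum, self.eta0, self.eta_up,
                                self.eta_down, self.reject_ratio, self.patience,
                                self.max_epochs, self.init_scale)
            mse = _mse(net, U[test_idx], Y[test_idx])
            var = Y[test_idx].var(axis=0)
            r2s.append(1.0 - mse / np.where(var > 0, var, np.nan))
            lcs.append(linear_connectivity(net, self.lag_norm))
            ncs.append(nonlinear_connectivity(net, U[test_idx], Y[test_idx],
                                              mode=self.nc_mode))
            nets.append(net)
        self.networks_ = nets
        self.fold_lc_ = np.stack(lcs)
        self.fold_nc_ = np.stack(ncs)
        self.fold_r2_ = np.stack(r2s)
        self.lc_ = self.fold_lc_.mean(axis=0)
        self.nc_ = self.fold_nc_.mean(axis=0)
        self.r2_test_ = np.nanmean(self.fold_r2_, axis=0)
        self.r2_mean_ = float(np.nanmean(self.r2_test_))
        self.poor_fit_ = bool(self.r2_mean_ < self.r2_floor)
        self.n_features_in_ = M
        return self

    def predict(self, X):
        """One-step-ahead prediction (fold-averaged networks) for a series."""
        U, _ = self._prepare(X)
        preds = np.stack([net.forward(U) for net in self.networks_])
        return preds.mean(axis=0)


def compare_directed(estimates, pair):
    """Paired two-tailed t-test of direction a->b versus b->a across subjects.

    ``estimates`` is a sequence of (M, M) matrices (entry [i, j] = i -> j);
    ``pair`` is (a, b). Returns (t, p, df).
    """
    a, b = pair
    fwd = np.array([e[a, b] for e in estimates])
    rev = np.array([e[b, a] for e in estimates])
    if fwd.size < 3:
        raise ValueError("need at least 3 subjects")
    if np.allclose(fwd, rev):
        return 0.0, 1.0, fwd.size - 1
    t, p = stats.ttest_rel(fwd, rev)
    return float(t), float(p), fwd.size - 1
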