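"""Internal Newton-Raphson maximum-likelihood fitters.

Minimal dense-matrix routines for weighted logistic, multinomial-logistic
and Cox proportional-hazards fits.  The pipeline re-fits every model inside
each bootstrap replicate, so per-fit overhead dominates total runtime; these
routines avoid the construction cost of general-purpose model classes.
Coefficient estimates are cross-checked against statsmodels and lifelines in
the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit


class ConvergenceError(RuntimeError):
    """Raised when a Newton iteration fails to reach the gradient tolerance."""


@dataclass
class FitResult:
    params: np.ndarray
    loglik: float
    n_iter: int
    grad_norm: float
    converged: bool


def _step_converged(beta, step):
    return np.max(np.abs(step)) < 1e-10 * (1.0 + np.max(np.abs(beta)))


def _halving_update(beta, step, loglik_fn, ll_current, max_halvings=30):
    # step-halving keeps the Newton update inside the concave region;
    # the tolerance allows for rounding noise in large log-likelihoods
    noise = 1e-11 * (1.0 + abs(ll_current))
    for _ in range(max_halvings):
        cand = beta + step
        ll = loglik_fn(cand)
        if np.isfinite(ll) and ll >= ll_current - noise:
            return cand, ll
        step = step / 2.0
    raise ConvergenceError("step-halving failed to increase the log-likelihood")


def fit_logistic(X, y, weights=None, max_iter=60, tol=1e-10):
    """Weighted binary logistic regression; X must include the intercept column."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    scale = max(1.0, w.sum())

    def loglik(beta):
        eta = X @ beta
        # log(expit) written via logaddexp for numerical range
        return float(np.sum(w * (y * eta - np.logaddexp(0.0, eta))))

    beta = np.zeros(p)
    ll = loglik(beta)
    for it in range(max_iter):
        prob = expit(X @ beta)
        grad = X.T @ (w * (y - prob))
        gnorm = float(np.max(np.abs(grad)))
        if gnorm < tol * scale:
            return FitResult(beta, ll, it, gnorm, True)
        info = X.T @ (X * (w * prob * (1.0 - prob))[:, None])
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("singular information matrix in logistic fit") from exc
        if _step_converged(beta, step):
            beta = beta + step
            return FitResult(beta, loglik(beta), it + 1, gnorm, True)
        beta, ll = _halving_update(beta, step, loglik, ll)
    raise ConvergenceError(
        f"logistic fit did not converge in {max_iter} iterations (|grad|={gnorm:.3g})"
    )


def predict_logistic(X, beta):
    return expit(np.asarray(X, dtype=float) @ beta)


def fit_multinomial(X, y, n_classes, weights=None, max_iter=60, tol=1e-10):
    """Weighted multinomial logit with class 0 as the reference.

    Returns a FitResult whose ``params`` has shape (n_classes - 1, p).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n, p = X.shape
    K = int(n_classes)
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    scale = max(1.0, w.sum())
    Y = np.zeros((n, K))
    Y[np.arange(n), y] = 1.0

    def probs(B):
        z = np.concatenate([np.zeros((n, 1)), X @ B.T], axis=1)
        z -= z.max(axis=1, keepdims=True)
        P = np.exp(z)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def loglik(Bflat):
        P = probs(Bflat.reshape(K - 1, p))
        return float(np.sum(w * np.log(np.clip(P[np.arange(n), y], 1e-300, None))))

    B = np.zeros((K - 1, p))
    ll = loglik(B.ravel())
    for it in range(max_iter):
        P = probs(B)
        grad = np.concatenate([X.T @ (w * (Y[:, k] - P[:, k])) for k in range(1, K)])
        gnorm = float(np.max(np.abs(grad)))
        if gnorm < tol * scale:
            return FitResult(B, ll, it, gnorm, True)
        info = np.zeros(((K - 1) * p, (K - 1) * p))
        for k in range(1, K):
            for l in range(k, K):
                d = w * P[:, k] * ((1.0 if k == l else 0.0) - P[:, l])
                block = X.T @ (X * d[:, None])
                info[(k - 1) * p:k * p, (l - 1) * p:l * p] = block
                if l != k:
                    info[(l - 1) * p:l * p, (k - 1) * p:k * p] = block
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("singular information matrix in multinomial fit") from exc
        if _step_converged(B.ravel(), step):
            B = (B.ravel() + step).reshape(K - 1, p)
            return FitResult(B, loglik(B.ravel()), it + 1, gnorm, True)
        flat, ll = _halving_update(B.ravel(), step, loglik, ll)
        B = flat.reshape(K - 1, p)
    raise ConvergenceError(
        f"multinomial fit did not converge in {max_iter} iterations (|grad|={gnorm:.3g})"
    )


def predict_multinomial(X, B):
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    z = np.concatenate([np.zeros((n, 1)), X @ np.asarray(B).T], axis=1)
    z -= z.max(axis=1, keepdims=True)
    P = np.exp(z)
    P /= P.sum(axis=1, keepdims=True)
    return P


def fit_cox(time, event, X, weights=None, ties="efron", max_iter=60, tol=1e-10):
    """Weighted Cox partial-likelihood fit (Efron or Breslow tie handling).

    With Breslow ties, an observation with integer weight k contributes
    exactly as k duplicated rows would, which the test suite exploits as an
    oracle.  Event times are continuous in the intended analyses, so the two
    tie methods coincide there.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie method: {ties!r}")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if not event.any():
        raise ValueError("no events in the data; the partial likelihood is undefined")

    order = np.argsort(time, kind="stable")
    t = time[order]
    e = event[order]
    Xs = X[order]
    ws = w[order]
    # index of the first row sharing each row's time: risk-set start
    ridx = np.searchsorted(t, t, side="left")
    ev = np.flatnonzero(e)
    k_ev = ridx[ev]
    wev = ws[ev]
    Xev = Xs[ev]
    scale = max(1.0, wev.sum())

    # tie groups among event rows (same event time); Efron corrections are
    # evaluated in vectorized form over all tied groups at once
    _, grp_inv, grp_count = np.unique(t[ev], return_inverse=True, return_counts=True)
    multi = grp_count > 1
    has_ties = ties == "efron" and bool(multi.any())
    if has_ties:
        in_tie = multi[grp_inv]                      # mask over event rows
        gid = (np.cumsum(multi) - 1)[grp_inv][in_tie]  # compact tied-group id
        Gm = int(multi.sum())
        d_g = grp_count[multi].astype(float)
        ev_t = ev[in_tie]
        i0_g = np.zeros(Gm, dtype=int)
        i0_g[gid[::-1]] = ridx[ev_t[::-1]]           # first risk index per group
        W_g = np.bincount(gid, weights=ws[ev_t], minlength=Gm)
        wbar_g = W_g / d_g
        X_t = Xs[ev_t]
        XX_t = np.einsum("ij,ik->ijk", X_t, X_t)
        # expansion over l = 0 .. d-1 within each group
        rep_g = np.repeat(np.arange(Gm), d_g.astype(int))
        l_idx = np.arange(len(rep_g)) - np.repeat(
            np.concatenate([[0], np.cumsum(d_g.astype(int))[:-1]]), d_g.astype(int))
        f_l = l_idx / d_g[rep_g]
        wbar_rep = wbar_g[rep_g]

    def _tie_sums(r):
        r_t = r[ev_t]
        s0D = np.bincount(gid, weights=r_t, minlength=Gm)
        s1D = np.column_stack([
            np.bincount(gid, weights=X_t[:, j] * r_t, minlength=Gm) for j in range(p)
        ])
        return s0D, s1D, r_t

    def loglik(beta):
        eta = Xs @ beta
        r = ws * np.exp(eta)
        S0 = np.cumsum(r[::-1])[::-1]
        ll = float(np.sum(wev * (eta[ev] - np.log(S0[k_ev]))))
        if has_ties:
            s0D, _, _ = _tie_sums(r)
            phi = S0[i0_g][rep_g] - f_l * s0D[rep_g]
            ll += float(np.sum(W_g * np.log(S0[i0_g]))
                        - np.sum(wbar_rep * np.log(phi)))
        return ll

    beta = np.zeros(p)
    ll = loglik(beta)
    for it in range(max_iter):
        eta = Xs @ beta
        r = ws * np.exp(eta)
        S0 = np.cumsum(r[::-1])[::-1]
        S1 = np.cumsum((Xs * r[:, None])[::-1], axis=0)[::-1]
        S2 = np.cumsum(np.einsum("ij,ik->ijk", Xs, Xs * r[:, None])[::-1], axis=0)[::-1]
        s0 = S0[k_ev]
        mu = S1[k_ev] / s0[:, None]
        grad = (wev[:, None] * (Xev - mu)).sum(axis=0)
        H = np.einsum("i,ijk->jk", wev, S2[k_ev] / s0[:, None, None]) - np.einsum(
            "i,ij,ik->jk", wev, mu, mu
        )
        if has_ties:
            s0D, s1D, r_t = _tie_sums(r)
            s2D = np.einsum("ijk,i->ijk", XX_t, r_t)
            s2D_g = np.zeros((Gm, p, p))
            np.add.at(s2D_g, gid, s2D)
            gs0, gs1, gs2 = S0[i0_g], S1[i0_g], S2[i0_g]
            mug = gs1 / gs0[:, None]
            # remove the groups' Breslow terms (the sum_i w_i x_i part is shared)
            grad += (W_g[:, None] * mug).sum(axis=0)
            H -= np.einsum("g,gjk->jk", W_g, gs2 / gs0[:, None, None])
            H += np.einsum("g,gj,gk->jk", W_g, mug, mug)
            # add the Efron terms over the l-expansion
            phi = gs0[rep_g] - f_l * s0D[rep_g]
            m_l = (gs1[rep_g] - f_l[:, None] * s1D[rep_g]) / phi[:, None]
            grad -= (wbar_rep[:, None] * m_l).sum(axis=0)
            num2 = gs2[rep_g] - f_l[:, None, None] * s2D_g[rep_g]
            H += np.einsum("l,ljk->jk", wbar_rep / phi, num2)
            H -= np.einsum("l,lj,lk->jk", wbar_rep, m_l, m_l)
        gnorm = float(np.max(np.abs(grad)))
        if gnorm < tol * scale:
            return FitResult(beta, ll, it, gnorm, True)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("singular information matrix in Cox fit") from exc
        if _step_converged(beta, step):
            beta = beta + step
            return FitResult(beta, loglik(beta), it + 1, gnorm, True)
        beta, ll = _halving_update(beta, step, loglik, ll)
    raise ConvergenceError(
        f"Cox fit did not converge in {max_iter} iterations (|grad|={gnorm:.3g})"
    )
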