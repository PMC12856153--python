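"""Cox partial-likelihood internals.

:class:`PartialLikelihood` presorts the data once and evaluates the log
partial likelihood, gradient, and Hessian with vectorised Breslow
accumulation (suffix cumulative sums over time-sorted risk sets) plus a
vectorised Efron correction applied only at tied event times, so
repeated evaluations inside Newton iterations and smoothing-parameter
searches are cheap.  Case weights and delayed entry / counting-process
rows ((entry, stop] risk sets) are supported under Breslow ties, which
is what the Fine-Gray weighted fit needs.  An optional quadratic penalty
``-0.5 * lam * beta' P beta`` serves the penalised-spline models.

The Newton maximiser uses step-halving, so the (penalised) objective is
nondecreasing across iterations; the trajectory is returned.
"""

from __future__ import annotations

import numpy as np

from .errors import ConvergenceError, DesignMatrixError

_ETA_CLIP = 200.0


def _suffix_cumsum(a: np.ndarray) -> np.ndarray:
    return np.cumsum(a[::-1], axis=0)[::-1]


class PartialLikelihood:
    """Reusable (ll, grad, hess) evaluator for one survival dataset."""

    def __init__(
        self,
        X: np.ndarray,
        time: np.ndarray,
        event: np.ndarray,
        weights: np.ndarray | None = None,
        entry: np.ndarray | None = None,
        ties: str = "efron",
    ):
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=bool)
        w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
        if ties not in ("efron", "breslow"):
            raise ValueError(f"unknown ties method {ties!r}")
        if ties == "efron" and (entry is not None or not np.allclose(w, 1.0)):
            # the Efron correction below assumes unit weights, no entry
            ties = "breslow"
        self.ties = ties
        self.n, self.p = n, p

        order = np.argsort(time, kind="stable")
        self.t = time[order]
        self.d = event[order]
        self.X = X[order]
        self.w = w[order]

        te = self.t[self.d]
        if te.size == 0:
            raise DesignMatrixError("no events in dataset")
        self.ut, self.grp_start, counts = np.unique(
            te, return_index=True, return_counts=True
        )
        self.counts = counts.astype(int)
        self.idx_risk = np.searchsorted(self.t, self.ut, side="left")
        self.n_events = int(self.d.sum())

        if entry is not None:
            en = np.asarray(entry, dtype=float)[order]
            self.eorder = np.argsort(en, kind="stable")
            es = en[self.eorder]
            self.k_entry = np.searchsorted(es, self.ut, side="left")
        else:
            self.eorder = None

        # Efron tie expansion: one row per (tied group, within-tie index)
        if ties == "efron":
            tied = np.flatnonzero(self.counts >= 2)
            self.tied = tied
            if tied.size:
                reps = self.counts[tied]
                self.tie_grp = np.repeat(np.arange(tied.size), reps)
                self.tie_f = (
                    np.concatenate([np.arange(c) for c in reps]).astype(float)
                    / np.repeat(reps, reps)
                )
            else:
                self.tie_grp = np.empty(0, dtype=int)
                self.tie_f = np.empty(0)
        else:
            self.tied = np.empty(0, dtype=int)

    def __call__(self, beta, penalty=None):
        """Return (ll, grad, hess); ``penalty=(lam, P)`` optional."""
        t, d, Xs, ws = self.t, self.d, self.X, self.w
        eta = Xs @ beta
        if not np.all(np.isfinite(eta)):
            raise FloatingPointError("non-finite linear predictor")
        eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
        r = ws * np.exp(eta)

        rX = r[:, None] * Xs
        rXX = rX[:, :, None] * Xs[:, None, :]
        S0 = _suffix_cumsum(r)
        S1 = _suffix_cumsum(rX)
        S2 = _suffix_cumsum(rXX)

        idx = self.idx_risk
        S0g = S0[idx].copy()
        S1g = S1[idx].copy()
        S2g = S2[idx].copy()
        if self.eorder is not None:
            k = self.k_entry
            E0 = np.concatenate([_suffix_cumsum(r[self.eorder]), [0.0]])
            E1 = np.vstack([_suffix_cumsum(rX[self.eorder]), np.zeros((1, self.p))])
            E2 = np.concatenate(
                [_suffix_cumsum(rXX[self.eorder]), np.zeros((1, self.p, self.p))],
                axis=0,
            )
            S0g -= E0[k]
            S1g -= E1[k]
            S2g -= E2[k]
        if np.any(S0g <= 0):
            raise FloatingPointError("empty or negative risk set at an event time")

        w_ev = ws[d]
        eta_ev = eta[d]
        X_ev = Xs[d]
        gs = self.grp_start
        Dw = np.add.reduceat(w_ev, gs)
        sum_eta = np.add.reduceat(w_ev * eta_ev, gs)
        SX = np.add.reduceat(w_ev[:, None] * X_ev, gs, axis=0)

        m = S1g / S0g[:, None]
        ll = float(sum_eta.sum() - (Dw * np.log(S0g)).sum())
        grad = SX.sum(axis=0) - (Dw[:, None] * m).sum(axis=0)
        hess = -(
            np.einsum("g,gij->ij", Dw / S0g, S2g)
            - np.einsum("g,gi,gj->ij", Dw, m, m)
        )

        if self.ties == "efron" and self.tied.size:
            tg = self.tied
            r_ev = np.exp(eta_ev)
            s0D = np.add.reduceat(r_ev, gs)[tg]
            s1D = np.add.reduceat(r_ev[:, None] * X_ev, gs, axis=0)[tg]
            s2D = np.add.reduceat(
                r_ev[:, None, None] * (X_ev[:, :, None] * X_ev[:, None, :]),
                gs,
                axis=0,
            )[tg]
            cnt = self.counts[tg].astype(float)
            S0t, S1t, S2t, mt = S0g[tg], S1g[tg], S2g[tg], m[tg]
            # remove the Breslow contribution of the tied groups
            ll += float((cnt * np.log(S0t)).sum())
            grad += (cnt[:, None] * mt).sum(axis=0)
            hess += np.einsum("g,gij->ij", cnt / S0t, S2t) - np.einsum(
                "g,gi,gj->ij", cnt, mt, mt
            )
            # add the Efron terms, one row per within-tie position
            gr, f = self.tie_grp, self.tie_f
            phi = S0t[gr] - f * s0D[gr]
            num1 = S1t[gr] - f[:, None] * s1D[gr]
            sv = num1 / phi[:, None]
            ll -= float(np.log(phi).sum())
            grad -= sv.sum(axis=0)
            hess -= np.einsum(
                "r,rij->ij", 1.0 / phi, S2t[gr] - f[:, None, None] * s2D[gr]
            ) - np.einsum("ri,rj->ij", sv, sv)

        if penalty is not None:
            lam, P = penalty
            ll -= 0.5 * lam * float(beta @ P @ beta)
            grad = grad - lam * (P @ beta)
            hess = hess - lam * P

        return ll, grad, hess


def cox_loglik(
    beta,
    X,
    time,
    event,
    weights=None,
    entry=None,
    ties: str = "efron",
    penalty=None,
):
    """One-shot evaluation (convenience wrapper over PartialLikelihood)."""
    pl = PartialLikelihood(X, time, event, weights=weights, entry=entry, ties=ties)
    return pl(np.asarray(beta, dtype=float), penalty=penalty)


def newton_maximize(
    fun,
    beta0: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 50,
    max_halvings: int = 30,
):
    """Maximise a concave objective by damped Newton iterations.

    ``fun(beta) -> (ll, grad, hess)``.  Returns
    ``(beta, ll, grad, hess, ll_path, converged)``; step-halving keeps
    the objective path nondecreasing.
    """
    beta = np.asarray(beta0, dtype=float).copy()
    ll, g, H = fun(beta)
    path = [ll]
    converged = False
    for _ in range(max_iter):
        if np.max(np.abs(g)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(-H, g)
        except np.linalg.LinAlgError as exc:
            raise DesignMatrixError(
                "singular information matrix (rank-deficient design?)"
            ) from exc
        alpha = 1.0
        accepted = False
        for _ in range(max_halvings):
            cand = beta + alpha * step
            try:
                ll2, g2, H2 = fun(cand)
            except FloatingPointError:
                alpha /= 2.0
                continue
            if np.isfinite(ll2) and ll2 >= ll - 1e-12:
                accepted = True
                break
            alpha /= 2.0
        if not accepted:
            break
        improvement = ll2 - ll
        beta, ll, g, H = cand, ll2, g2, H2
        path.append(ll)
        if np.max(np.abs(beta)) > 100.0:
            raise ConvergenceError(
                "estimates diverging (monotone likelihood / separation?)"
            )
        # objective plateau: quadratic convergence means a vanishing ll
        # change implies a (numerically) vanishing gradient even when
        # round-off in a large penalty keeps the max-norm test from firing
        if improvement < 1e-10 * (1.0 + abs(ll)):
            converged = True
            break
    return beta, ll, g, H, path, converged


def check_design(X: np.ndarray, names=None) -> None:
    """Reject constant columns and rank-deficient designs."""
    X = np.asarray(X, dtype=float)
    names = list(names) if names is not None else [f"x{j}" for j in range(X.shape[1])]
    sd = X.std(axis=0)
    bad = [names[j] for j in np.flatnonzero(sd == 0)]
    if bad:
        raise DesignMatrixError(f"constant covariate column(s): {bad}")
    centered = X - X.mean(axis=0)
    if np.linalg.matrix_rank(centered) < X.shape[1]:
        raise DesignMatrixError("design matrix is rank deficient")
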