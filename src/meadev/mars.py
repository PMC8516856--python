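"""Multivariate adaptive regression splines (MARS).

Forward stagewise selection of mirrored hinge-basis pairs
``parent * max(0, x_v - t)`` / ``parent * max(0, t - x_v)`` up to a maximum
term count and interaction degree, followed by backward pruning by
generalized cross-validation (GCV).  Candidate knots are quantiles of the
predictor within the parent basis' support.  The forward search scores each
candidate pair by the exact least-squares fit, computed incrementally by
projecting the new columns onto the orthogonal complement of the current
basis, so the pass stays fast on small tables.
"""

from __future__ import annotations

import dataclasses

import numpy as np

_EPS = 1e-10


@dataclasses.dataclass(frozen=True)
class _Hinge:
    var: int
    knot: float
    sign: int  # +1: max(0, x - t); -1: max(0, t - x)

    def __call__(self, X: np.ndarray) -> np.ndarray:
        z = self.sign * (X[:, self.var] - self.knot)
        return np.maximum(0.0, z)


class MARSRegressor:
    """MARS with GCV-pruned hinge bases.

    Parameters
    ----------
    max_terms : int
        Maximum number of basis functions (including the intercept) built by
        the forward pass.
    max_degree : int
        Maximum interaction degree (number of hinge factors per term).
    penalty : float
        GCV complexity charge per knot (Friedman's ``d``; 3 is customary when
        interactions are allowed).
    n_knots : int
        Maximum candidate knots per (parent, variable) pair, taken as
        quantiles of the predictor over the parent's support.
    """

    def __init__(
        self,
        max_terms: int = 35,
        max_degree: int = 5,
        penalty: float = 3.0,
        n_knots: int = 12,
    ):
        self.max_terms = max_terms
        self.max_degree = max_degree
        self.penalty = penalty
        self.n_knots = n_knots

    # each basis term is a tuple of _Hinge factors; () is the intercept
    def _eval_term(self, term: tuple[_Hinge, ...], X: np.ndarray) -> np.ndarray:
        out = np.ones(X.shape[0])
        for h in term:
            out *= h(X)
        return out

    def _basis_matrix(self, terms, X: np.ndarray) -> np.ndarray:
        return np.column_stack([self._eval_term(t, X) for t in terms])

    def _gcv(self, sse: float, n: int, m: int) -> float:
        c = m + self.penalty * (m - 1) / 2.0
        if c >= n:
            return np.inf
        return (sse / n) / (1.0 - c / n) ** 2

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MARSRegressor":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        terms: list[tuple[_Hinge, ...]] = [()]
        B = np.ones((n, 1))
        Q, _ = np.linalg.qr(B)
        resid = y - Q @ (Q.T @ y)
        sse = float(resid @ resid)

        # ---- forward pass -------------------------------------------------
        while len(terms) + 2 <= self.max_terms and sse > _EPS * max(1.0, y @ y):
            best = None  # (sse_new, parent_idx, hinges, cols)
            for pi, parent in enumerate(terms):
                if len(parent) >= self.max_degree:
                    continue
                pcol = B[:, pi]
                support = pcol > 0
                if support.sum() < 2:
                    continue
                used_vars = {h.var for h in parent}
                for v in range(p):
                    if v in used_vars:
                        continue
                    xv = X[support, v]
                    qs = np.unique(
                        np.quantile(xv, np.linspace(0.05, 0.95, self.n_knots))
                    )
                    for t in qs:
                        h_pos = _Hinge(v, float(t), +1)
                        h_neg = _Hinge(v, float(t), -1)
                        c1 = pcol * h_pos(X)
                        c2 = pcol * h_neg(X)
                        cols = np.column_stack([c1, c2])
                        # orthogonalize against current basis
                        co = cols - Q @ (Q.T @ cols)
                        sse_new = sse
                        r = resid.copy()
                        for ci in range(co.shape[1]):
                            u = co[:, ci]
                            nrm = np.linalg.norm(u)
                            if nrm < 1e-8 * (np.linalg.norm(cols[:, ci]) + 1.0):
                                continue
                            u = u / nrm
                            proj = float(u @ r)
                            sse_new -= proj**2
                            r = r - proj * u
                            co = co - np.outer(u, u @ co)
                        if best is None or sse_new < best[0] - _EPS:
                            best = (sse_new, pi, (h_pos, h_neg), cols)
            if best is None or best[0] > sse - _EPS * max(1.0, y @ y):
                break
            sse_new, pi, (h_pos, h_neg), cols = best
            parent = terms[pi]
            terms.append(parent + (h_pos,))
            terms.append(parent + (h_neg,))
            B = np.column_stack([B, cols])
            Q, _ = np.linalg.qr(B)
            resid = y - Q @ (Q.T @ y)
            sse = float(resid @ resid)

        # ---- backward pruning by GCV -------------------------------------
        def fit_subset(idx: list[int]) -> tuple[np.ndarray, float]:
            Bs = B[:, idx]
            coef, *_ = np.linalg.lstsq(Bs, y, rcond=None)
            r = y - Bs @ coef
            return coef, float(r @ r)

        current = list(range(len(terms)))
        _, sse_cur = fit_subset(current)
        best_idx = list(current)
        best_gcv = self._gcv(sse_cur, n, len(current))
        while len(current) > 1:
            best_drop = None
            for j in current[1:]:  # never drop the intercept
                trial = [i for i in current if i != j]
                _, sse_t = fit_subset(trial)
                g = self._gcv(sse_t, n, len(trial))
                if best_drop is None or g < best_drop[0]:
                    best_drop = (g, trial)
            current = best_drop[1]
            if best_drop[0] < best_gcv:
                best_gcv = best_drop[0]
                best_idx = list(current)

        self.terms_ = [terms[i] for i in best_idx]
        self.coef_, _ = fit_subset(best_idx)
        self.gcv_ = best_gcv
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self._basis_matrix(self.terms_, X) @ self.coef_
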