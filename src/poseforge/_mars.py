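"""Multivariate adaptive regression splines (Friedman-style).

Forward pass: starting from the intercept, repeatedly add the mirrored
hinge pair b(x)·max(0, x_v − t), b(x)·max(0, t − x_v) that most reduces the
residual sum of squares, where the parent basis b is the intercept (additive
model, degree 1) or any existing term with fewer than ``degree`` factors.
Knot candidates are quantiles of the variable over the parent's support.
The final number of terms is selected automatically by the backward pass:
terms are deleted one at a time, keeping the subset with the lowest
generalized cross-validation score

    GCV(M) = RSS/n / (1 − C(M)/n)^2,   C(M) = M + penalty·(M − 1)/2,

with ``penalty`` the knot-cost parameter. Deterministic: no randomness,
ties broken by (parent, variable, knot) order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MarsRegressor"]

# a factor is (variable index, sign, knot); sign +1 -> max(0, x-t), -1 -> max(0, t-x)
Factor = tuple[int, int, float]


def _eval_factors(factors: tuple[Factor, ...], X: np.ndarray) -> np.ndarray:
    out = np.ones(X.shape[0])
    for var, sign, knot in factors:
        out = out * np.maximum(0.0, sign * (X[:, var] - knot))
    return out


@dataclass
class _Candidate:
    reduction: float
    parent: int
    var: int
    knot: float


class MarsRegressor:
    """Friedman MARS with hinge basis functions and GCV backward pruning.

    Parameters
    ----------
    degree : maximum number of hinge factors per term (1 = additive).
    penalty : GCV cost per knot (the d of C(M) = M + d(M-1)/2).
    max_terms : cap on basis terms including the intercept; the effective
        term count is chosen by GCV, this only bounds the forward pass.
    n_knot_candidates : quantile knots examined per (parent, variable).
    """

    def __init__(
        self,
        degree: int = 1,
        penalty: float = 3.0,
        max_terms: int = 21,
        n_knot_candidates: int = 16,
    ):
        if degree < 1:
            raise ValueError("degree must be >= 1")
        self.degree = int(degree)
        self.penalty = float(penalty)
        self.max_terms = int(max_terms)
        self.n_knot_candidates = int(n_knot_candidates)

    # -- scikit-learn estimator protocol -------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            "degree": self.degree,
            "penalty": self.penalty,
            "max_terms": self.max_terms,
            "n_knot_candidates": self.n_knot_candidates,
        }

    def set_params(self, **params) -> "MarsRegressor":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    # -- fitting --------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray) -> "MarsRegressor":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64).ravel()
        n, p = X.shape
        if n != y.shape[0]:
            raise ValueError("X and y have inconsistent lengths")

        terms: list[tuple[Factor, ...]] = [()]  # intercept
        B = np.ones((n, 1))
        rss0 = float(np.sum((y - y.mean()) ** 2)) or 1.0

        while len(terms) + 2 <= self.max_terms:
            cand = self._best_candidate(B, terms, X, y)
            if cand is None or cand.reduction <= 1e-10 * rss0:
                break
            parent_factors = terms[cand.parent]
            pb = B[:, cand.parent]
            for sign in (1, -1):
                factors = parent_factors + ((cand.var, sign, cand.knot),)
                terms.append(factors)
                col = pb * np.maximum(0.0, sign * (X[:, cand.var] - cand.knot))
                B = np.column_stack([B, col])

        keep = self._backward_prune(B, y)
        self.terms_ = [terms[i] for i in keep]
        Bk = B[:, keep]
        coef, *_ = np.linalg.lstsq(Bk, y, rcond=None)
        self.coef_ = coef
        resid = y - Bk @ coef
        self.rss_ = float(resid @ resid)
        self.gcv_ = _gcv(self.rss_, len(keep), n, self.penalty)
        self.n_features_in_ = p
        return self

    def _best_candidate(
        self, B: np.ndarray, terms: list, X: np.ndarray, y: np.ndarray
    ) -> _Candidate | None:
        n, p = X.shape
        Q, _ = np.linalg.qr(B)
        r = y - Q @ (Q.T @ y)
        best: _Candidate | None = None
        for parent_idx, parent in enumerate(terms):
            if len(parent) >= self.degree:
                continue
            used_vars = {f[0] for f in parent}
            pb = B[:, parent_idx]
            support = pb > 0
            if support.sum() < 4:
                continue
            for var in range(p):
                if var in used_vars:
                    continue
                xv = X[support, var]
                knots = np.unique(
                    np.quantile(xv, np.linspace(0.05, 0.95, self.n_knot_candidates))
                )
                if knots.size == 0:
                    continue
                # both hinges for every knot, parent-weighted
                diffs = X[:, var][:, None] - knots[None, :]
                H = np.empty((n, 2 * knots.size))
                H[:, 0::2] = pb[:, None] * np.maximum(0.0, diffs)
                H[:, 1::2] = pb[:, None] * np.maximum(0.0, -diffs)
                Hp = H - Q @ (Q.T @ H)
                for j, knot in enumerate(knots):
                    C = Hp[:, 2 * j : 2 * j + 2]
                    G = C.T @ C
                    b = C.T @ r
                    try:
                        sol = np.linalg.solve(G + 1e-10 * np.eye(2), b)
                    except np.linalg.LinAlgError:  # pragma: no cover
                        continue
                    reduction = float(b @ sol)
                    if best is None or reduction > best.reduction + 1e-12:
                        best = _Candidate(reduction, parent_idx, var, float(knot))
        return best

    def _backward_prune(self, B: np.ndarray, y: np.ndarray) -> list[int]:
        n = B.shape[0]

        def rss_of(cols: list[int]) -> float:
            coef, *_ = np.linalg.lstsq(B[:, cols], y, rcond=None)
            resid = y - B[:, cols] @ coef
            return float(resid @ resid)

        current = list(range(B.shape[1]))
        best_cols = list(current)
        best_gcv = _gcv(rss_of(current), len(current), n, self.penalty)
        while len(current) > 1:
            scored = []
            for drop in current[1:]:  # never drop the intercept
                cols = [c for c in current if c != drop]
                scored.append((_gcv(rss_of(cols), len(cols), n, self.penalty), drop))
            gcv_val, drop = min(scored)
            current = [c for c in current if c != drop]
            if gcv_val < best_gcv:
                best_gcv, best_cols = gcv_val, list(current)
        return best_cols

    # -- prediction ------------------------------------------------------
    def _basis(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        return np.column_stack([_eval_factors(t, X) for t in self.terms_])

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "coef_"):
            raise RuntimeError("MarsRegressor is not fitted")
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, model was fitted with {self.n_features_in_}"
            )
        return self._basis(X) @ self.coef_

    @property
    def max_degree_(self) -> int:
        """Largest number of hinge factors in any retained term."""
        return max((len(t) for t in self.terms_), default=0)


def _gcv(rss: float, m: int, n: int, penalty: float) -> float:
    c = m + penalty * (m - 1) / 2.0
    denom = 1.0 - c / n
    if denom <= 0:
        return np.inf
    return rss / n / denom**2
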