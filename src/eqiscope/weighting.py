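"""PCA-based indicator weighting.

Indicator weights are derived objectively from the data rather than from
expert scoring: the correlation matrix R of the standardized IRD
observations is eigendecomposed; components are retained until their
cumulative contribution rate (eigenvalue share of total variance) reaches a
threshold rho (default 0.85); each indicator's importance is the
contribution-rate-weighted mean of its absolute loadings on the retained
components; and the importances are normalized to weights summing to 1.
Per-year weights are averaged arithmetically across epochs to give one
weight set for the whole assessment.

Absolute loadings are used because signed loadings can produce negative
importances, which the weight contract (nonnegative, summing to one)
forbids; a signed variant is available for sensitivity analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "PCAResult",
    "WeightSet",
    "correlation_matrix",
    "pca_weights",
    "average_weights",
]


@dataclass
class PCAResult:
    """Full audit trail of one PCA weighting run."""

    correlation: np.ndarray        # R, n x n
    eigenvalues: np.ndarray        # alpha, descending
    loadings: np.ndarray           # C, columns are component loading vectors
    contribution_rates: np.ndarray  # e_i = alpha_i / sum(alpha)
    rho: float
    n_retained: int                # p: smallest count with cumulative e >= rho
    importances: np.ndarray        # gamma per indicator
    loading_scale: str = "unit"

    def to_dict(self) -> dict:
        return {
            "correlation": self.correlation.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "loadings": self.loadings.tolist(),
            "contribution_rates": self.contribution_rates.tolist(),
            "rho": self.rho,
            "n_retained": self.n_retained,
            "importances": self.importances.tolist(),
            "loading_scale": self.loading_scale,
        }


@dataclass
class WeightSet:
    """Named indicator weights with provenance.

    Invariants: weights nonnegative and summing to 1 (tolerance 1e-10).
    """

    names: tuple[str, ...]
    weights: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if len(self.names) != self.weights.size:
            raise ValueError("one weight per indicator name required")
        if np.any(self.weights < 0):
            raise ValueError(f"weights must be nonnegative, got {self.weights}")
        if abs(float(self.weights.sum()) - 1.0) > 1e-10:
            raise ValueError(f"weights must sum to 1, got sum {self.weights.sum()!r}")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.weights)))

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"weights": self.as_dict(), "provenance": self.provenance}, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "WeightSet":
        d = json.loads(Path(path).read_text())
        names = tuple(d["weights"])
        return cls(names=names, weights=np.array([d["weights"][n] for n in names]),
                   provenance=d.get("provenance", {}))


def correlation_matrix(X: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of an m x n observation matrix.

    For z-scored columns this coincides with the sample covariance matrix:
    r_ij = sum_k x_ki * x_kj / (m - 1) after centering and unit-scaling.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("observation matrix must be 2-D (pixels x indicators)")
    m, n = X.shape
    if m < n + 1:
        raise ValueError(f"need at least n+1={n + 1} observations, got {m}")
    if not np.all(np.isfinite(X)):
        raise ValueError("observation matrix contains non-finite entries")
    sd = X.std(axis=0)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        raise ValueError(f"constant columns have undefined correlation: {constant.tolist()}")
    return np.corrcoef(X, rowvar=False)


def _sorted_eigh(R: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric eigendecomposition, eigenvalues descending, sign-fixed.

    Each eigenvector is scaled so its largest-magnitude element is positive,
    removing the +/-beta ambiguity.  Exactly tied eigenvalues keep a
    deterministic order via the first differing loading.
    """
    alpha, C = np.linalg.eigh(R)
    order = np.argsort(-alpha, kind="stable")
    alpha, C = alpha[order], C[:, order]
    for j in range(C.shape[1]):
        i = int(np.argmax(np.abs(C[:, j])))
        if C[i, j] < 0:
            C[:, j] = -C[:, j]
    # deterministic order within exactly tied eigenvalue blocks
    for start in range(len(alpha) - 1):
        if alpha[start] == alpha[start + 1]:
            block = np.flatnonzero(alpha == alpha[start])
            sub = C[:, block]
            key = np.lexsort(sub[::-1])  # order by first differing loading
            C[:, block] = sub[:, key]
    return alpha, C


def pca_weights(X: np.ndarray, rho: float = 0.85, *, names: tuple[str, ...] | None = None,
                loading_scale: str = "unit", signed: bool = False,
                R: np.ndarray | None = None) -> tuple[WeightSet, PCAResult]:
    """Derive indicator weights from standardized observations by PCA.

    Parameters
    ----------
    X : (m, n) array
        Standardized IRD observations (complete-case pixels x indicators).
    rho : float in (0, 1]
        Cumulative contribution-rate threshold for retaining components.
    loading_scale : {"unit", "sqrt_eigenvalue"}
        Whether importances use raw unit eigenvectors or component loadings
        scaled by sqrt(eigenvalue).
    signed : bool
        Use signed instead of absolute loadings (sensitivity analysis only;
        can raise if it yields a negative importance).
    R : optional precomputed correlation matrix
        Bypasses ``correlation_matrix(X)``; X may then be None.
    """
    if not (0 < rho <= 1):
        raise ValueError(f"rho must be in (0, 1], got {rho}")
    if loading_scale not in {"unit", "sqrt_eigenvalue"}:
        raise ValueError(f"unknown loading_scale {loading_scale!r}")
    if R is None:
        R = correlation_matrix(X)
    R = np.asarray(R, dtype=np.float64)
    if not np.all(np.isfinite(R)):
        raise ValueError("correlation matrix contains non-finite entries")
    n = R.shape[0]
    names = tuple(names) if names is not None else tuple(f"x{i + 1}" for i in range(n))

    alpha, C = _sorted_eigh(R)
    alpha = np.clip(alpha, 0.0, None)  # numerical negatives of a PSD matrix
    e = alpha / alpha.sum()
    p = int(np.searchsorted(np.cumsum(e), rho) + 1)
    p = min(p, n)

    load = C[:, :p] * (np.sqrt(alpha[:p]) if loading_scale == "sqrt_eigenvalue" else 1.0)
    if not signed:
        load = np.abs(load)
    gamma = load @ e[:p] / e[:p].sum()
    if np.any(gamma < 0):
        raise ValueError("signed loadings produced a negative importance; "
                         "use absolute loadings for weighting")
    omega = gamma / gamma.sum()

    result = PCAResult(correlation=R, eigenvalues=alpha, loadings=C,
                       contribution_rates=e, rho=rho, n_retained=p,
                       importances=gamma, loading_scale=loading_scale)
    ws = WeightSet(names=names, weights=omega,
                   provenance={"method": "pca", "rho": rho, "n_retained": p,
                               "loading_scale": loading_scale, "signed": signed,
                               "n_observations": None if X is None else int(np.asarray(X).shape[0])})
    return ws, result


def average_weights(per_year: list[WeightSet]) -> WeightSet:
    """Arithmetic mean of per-year weight sets, renormalized to sum to 1."""
    if not per_year:
        raise ValueError("need at least one weight set")
    names = per_year[0].names
    for ws in per_year[1:]:
        if ws.names != names:
            raise ValueError(f"indicator names differ: {ws.names} vs {names}")
    mean = np.mean([ws.weights for ws in per_year], axis=0)
    mean = mean / mean.sum()
    years = [ws.provenance.get("year") for ws in per_year]
    return WeightSet(names=names, weights=mean,
                     provenance={"method": "average", "years": years,
                                 "components": [ws.as_dict() for ws in per_year]})
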