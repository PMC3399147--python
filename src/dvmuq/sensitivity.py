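"""Correlation-based global sensitivity statistics for the ensemble.

The parameter-importance measure is the partial rank correlation
coefficient (PRCC): inputs and output are rank-transformed, then for each
input x_j the linear effects of the remaining inputs are regressed out of
both x_j and y (each regression with an intercept) and the ordinary
correlation of the two residual vectors is reported.  PRCC is invariant
under strictly monotone transforms of any variable and is a robust
importance measure when inputs are (near-)independent, as they are for a
Latin hypercube sample.

Parameters are ranked by |PRCC| descending; a positive PRCC means the
parameter exerts positive control on the response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .parameter_space import SampleMatrix


class UndefinedCorrelationError(ValueError):
    """Correlation requested for a zero-variance variable."""


class SingularDesignError(np.linalg.LinAlgError):
    """Rank-deficient design matrix in the partial-correlation regression."""


@dataclass(frozen=True)
class PRCCResult:
    """PRCC of every parameter for one scalar model output."""

    param_names: tuple[str, ...]
    prcc: np.ndarray                 # NaN marks parameters with constant input
    n: int
    output_name: str = ""

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.param_names, self.prcc))


@dataclass(frozen=True)
class ImportanceTable:
    """Parameters ordered by |PRCC| descending (rank 1 = most important)."""

    rows: tuple[tuple[int, str, float], ...]  # (rank, parameter, prcc)

    def parameters(self) -> list[str]:
        return [r[1] for r in self.rows]


def correlation_coefficient(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation cov(x, y) / sqrt(var(x) var(y))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("correlation needs at least 3 points")
    xc = x - x.mean()
    yc = y - y.mean()
    vx = np.dot(xc, xc)
    vy = np.dot(yc, yc)
    if vx == 0 or vy == 0:
        raise UndefinedCorrelationError("zero variance in an input to CC")
    return float(np.dot(xc, yc) / np.sqrt(vx * vy))


def _residual(design: np.ndarray, target: np.ndarray, allow_pinv: bool) -> np.ndarray:
    """Residual of target regressed (with intercept) on the design columns."""
    A = np.column_stack([np.ones(design.shape[0]), design])
    if np.linalg.matrix_rank(A) < A.shape[1]:
        if not allow_pinv:
            raise SingularDesignError(
                "rank-deficient design in partial correlation "
                "(set allow_pinv=True for a pseudo-inverse fallback)"
            )
        coef = np.linalg.pinv(A) @ target
    else:
        coef, *_ = np.linalg.lstsq(A, target, rcond=None)
    return target - A @ coef


def partial_corr(
    X: np.ndarray, j: int, y: np.ndarray, allow_pinv: bool = False
) -> float:
    """Partial correlation of column j of X with y, controlling the rest.

    Both x_j and y are regressed (with intercept) on the remaining columns;
    the partial correlation is the ordinary correlation of the residuals.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if n <= k + 1:
        raise ValueError(f"need n > k + 1 samples (n={n}, k={k})")
    others = np.delete(X, j, axis=1)
    rx = _residual(others, X[:, j], allow_pinv)
    ry = _residual(others, y, allow_pinv)
    return correlation_coefficient(rx, ry)


def prcc(
    X: np.ndarray | SampleMatrix,
    y: np.ndarray,
    param_names: list[str] | None = None,
    output_name: str = "",
    allow_pinv: bool = False,
) -> PRCCResult:
    """PRCC of every column of X for the output y.

    All columns and y are rank-transformed (average ranks on ties) before
    the residual regressions.  A constant column yields NaN for that
    parameter (reported as missing); the rest of the vector is computed.
    """
    if isinstance(X, SampleMatrix):
        param_names = list(X.param_names)
        X = X.values
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if param_names is None:
        param_names = [f"x{j}" for j in range(k)]
    Xr = np.column_stack([rankdata(X[:, j]) for j in range(k)])
    yr = rankdata(y)
    values = np.full(k, np.nan)
    # constant inputs carry no information; they get NaN and are dropped
    # from the control design so the remaining regressions stay full rank
    varying = [j for j in range(k) if np.ptp(Xr[:, j]) > 0]
    Xv = Xr[:, varying]
    for jj, j in enumerate(varying):
        try:
            values[j] = partial_corr(Xv, jj, yr, allow_pinv=allow_pinv)
        except UndefinedCorrelationError:
            continue
    return PRCCResult(
        param_names=tuple(param_names), prcc=values, n=n, output_name=output_name
    )


def rank_importance(result: PRCCResult) -> ImportanceTable:
    """Order parameters by |PRCC| descending.

    Ties on |PRCC| are broken by sign (positive first) and then by input
    order; parameters with undefined (NaN) PRCC sort last.
    """
    def key(j: int):
        v = result.prcc[j]
        if np.isnan(v):
            return (np.inf, 1, j)
        return (-abs(v), 0 if v > 0 else 1, j)

    order = sorted(range(len(result.param_names)), key=key)
    rows = tuple(
        (rank + 1, result.param_names[j], float(result.prcc[j]))
        for rank, j in enumerate(order)
    )
    return ImportanceTable(rows=rows)


def prcc_map(
    ensemble_fpc: np.ndarray,
    samples: SampleMatrix,
    output_name: str = "",
    allow_pinv: bool = False,
) -> np.ndarray:
    """Per-cell PRCC of each parameter for a (cell, sample) mean-FPC matrix.

    Cells where the PFT never appears in any ensemble member (all-zero
    response) are masked as NaN rather than reported as zero.  Returns a
    (cell, parameter) array aligned with ``samples.param_names``.
    """
    ensemble_fpc = np.asarray(ensemble_fpc, dtype=float)
    n_cells, n_samples = ensemble_fpc.shape
    if n_samples != samples.n_samples:
        raise ValueError(
            f"ensemble has {n_samples} samples but matrix has {samples.n_samples}"
        )
    k = len(samples.param_names)
    out = np.full((n_cells, k), np.nan)
    never_present = ~np.any(ensemble_fpc > 0, axis=1)
    if never_present.all():
        import warnings

        warnings.warn("PFT never appears in any cell: PRCC map is empty", UserWarning)
        return out
    for c in range(n_cells):
        if never_present[c]:
            continue
        yc = ensemble_fpc[c]
        if np.ptp(yc) == 0:
            continue  # present but invariant: partial correlation undefined
        out[c] = prcc(
            samples.values, yc, list(samples.param_names),
            output_name=output_name, allow_pinv=allow_pinv,
        ).prcc
    return out
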