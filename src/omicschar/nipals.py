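"""NIPALS principal-component extraction tolerating missing entries.

NIPALS (nonlinear iterative partial least squares) extracts principal
components one at a time by alternating least-squares updates of a score
vector t and a loading vector p.  Because each update is a collection of
simple regressions, missing cells can simply be skipped, which makes the
method the standard choice for PCA of incomplete data — no imputation is
performed.  On complete data the result coincides with classical SVD-based
PCA up to component signs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from omicschar.errors import OmicsCharError


@dataclass
class NipalsResult:
    """Fitted NIPALS decomposition.

    scores:      (n_obs, k) component scores.
    loadings:    (n_var, k) unit-norm loadings; per component the
                 largest-magnitude loading is positive (sign convention).
    var_fraction: per-component percentage of the total centered observed
                 sum of squares.
    center:      per-variable means used for centering.
    """

    scores: np.ndarray
    loadings: np.ndarray
    var_fraction: np.ndarray
    center: np.ndarray
    converged: list[bool]
    iterations: list[int]

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def nipals_fit(
    data: np.ndarray,
    n_components: int = 2,
    *,
    tol: float = 1e-9,
    eig_tol: float = 1e-10,
    max_iter: int = 5000,
    center: bool = True,
) -> NipalsResult:
    """Fit a NIPALS PCA on an observation × variable grid with missing cells.

    Parameters
    ----------
    data:
        2-D float array, NaN marking missing cells.
    n_components:
        Number of components to extract sequentially (with deflation).
    tol:
        Convergence threshold on the relative change of the score vector.
    eig_tol:
        Secondary criterion: relative stall of the component sum of squares
        (the quantity the variance fractions report), which converges at
        twice the exponential rate of the score direction; whichever
        criterion is met first stops the iteration.
    max_iter:
        Iteration cap per component; non-convergence is flagged, not raised.
    center:
        Mean-center each variable over its observed entries (default).  The
        variance fractions always refer to the centered sum of squares.
    """
    X = np.array(data, dtype=float)
    if X.ndim != 2:
        raise OmicsCharError("data must be 2-dimensional")
    n_obs, n_var = X.shape
    if n_components < 1:
        raise OmicsCharError("n_components must be >= 1")
    mask = ~np.isnan(X)
    obs_per_var = mask.sum(axis=0)
    if (obs_per_var == 0).any():
        bad = int(np.argmin(obs_per_var))
        raise OmicsCharError(f"variable {bad} has no observed values")

    if center:
        mu = np.nansum(X, axis=0) / obs_per_var
    else:
        mu = np.zeros(n_var)
    R = X - mu  # NaN preserved at missing cells
    R0 = np.nan_to_num(R, nan=0.0)
    total_ss = float(np.sum(R0**2))

    scores = np.zeros((n_obs, n_components))
    loadings = np.zeros((n_var, n_components))
    var_fraction = np.zeros(n_components)
    converged: list[bool] = []
    iterations: list[int] = []

    for comp in range(n_components):
        var_of_vars = np.nansum(R0**2, axis=0)
        t = R0[:, int(np.argmax(var_of_vars))].copy()
        if not np.any(t):
            # residual exhausted; component is null
            converged.append(True)
            iterations.append(0)
            continue
        p = np.zeros(n_var)
        it = 0
        ok = False
        ss_old = float("inf")
        for it in range(1, max_iter + 1):
            # loading update: per-variable regression of residual on t
            tw = mask * t[:, None]
            denom = np.sum(tw * t[:, None], axis=0)
            p = np.where(denom > 0, R0.T @ t / np.maximum(denom, 1e-300), 0.0)
            norm = np.linalg.norm(p)
            if norm == 0:
                break
            p /= norm
            # score update: per-observation regression of residual on p
            pw = mask * p[None, :]
            denom_t = np.sum(pw * p[None, :], axis=1)
            t_new = np.where(denom_t > 0, R0 @ p / np.maximum(denom_t, 1e-300), 0.0)
            delta = np.linalg.norm(t_new - t)
            t = t_new
            # component sum of squares over observed cells: the quantity the
            # variance fractions report, and (unlike ||t||, which can drift
            # under structured missingness) monotone-bounded during the
            # alternating least-squares updates
            ss = float((t**2) @ denom_t)
            if delta <= tol * max(np.linalg.norm(t), 1e-300) or (
                ss > 0 and abs(ss - ss_old) <= eig_tol * ss
            ):
                ok = True
                break
            ss_old = ss
        # sign convention: largest-magnitude loading positive
        flip = np.sign(p[int(np.argmax(np.abs(p)))]) or 1.0
        p *= flip
        t *= flip
        scores[:, comp] = t
        loadings[:, comp] = p
        fitted = np.outer(t, p)
        var_fraction[comp] = (
            100.0 * float(np.sum((fitted * mask) ** 2)) / total_ss if total_ss > 0 else 0.0
        )
        R0 = R0 - fitted * mask
        converged.append(ok)
        iterations.append(it)

    return NipalsResult(
        scores=scores,
        loadings=loadings,
        var_fraction=var_fraction,
        center=mu,
        converged=converged,
        iterations=iterations,
    )


def project(result: NipalsResult, row: np.ndarray) -> np.ndarray:
    """Project one observation (with possible NaNs) onto fitted components.

    Mirrors the NIPALS score update: per component, regress the observed
    residual entries on the loading, then deflate.
    """
    z = np.asarray(row, dtype=float) - result.center
    obs = ~np.isnan(z)
    z0 = np.nan_to_num(z, nan=0.0)
    coords = np.zeros(result.n_components)
    for comp in range(result.n_components):
        p = result.loadings[:, comp]
        denom = float(np.sum(p[obs] ** 2))
        t = float(z0 @ p) / denom if denom > 0 else 0.0
        coords[comp] = t
        z0 = z0 - t * p * obs
    return coords
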