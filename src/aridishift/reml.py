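"""REML machinery for linear models with crossed random intercepts.

The marginal model is ``y = X beta + e`` with
``Var(y) = sigma^2 (I + sum_k gamma_k Z_k Z_k')`` where each ``Z_k`` is the
one-hot indicator matrix of a grouping factor and ``gamma_k`` the ratio of
that factor's intercept variance to the residual variance.  beta and sigma^2
are profiled out analytically; the low-dimensional gamma vector is optimized
numerically.  All W-inverse quadratic forms use the Woodbury identity through
the (small) q x q factor-level space, which also enables a fully vectorized
bootstrap refit with gamma held fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

__all__ = ["RandomStructure", "REMLResult", "reml_fit", "batched_gls", "encode_groups"]

_LOG2PI = np.log(2.0 * np.pi)


def encode_groups(labels) -> np.ndarray:
    """One-hot (n x q) indicator matrix for a vector of group labels."""
    labels = np.asarray(labels)
    levels, idx = np.unique(labels, return_inverse=True)
    Z = np.zeros((len(labels), len(levels)))
    Z[np.arange(len(labels)), idx] = 1.0
    return Z


@dataclass
class RandomStructure:
    """Concatenated one-hot blocks of the random factors."""

    Z: np.ndarray  # n x q, all blocks side by side
    block_sizes: list[int]
    names: list[str]

    @classmethod
    def from_labels(cls, factors: dict) -> "RandomStructure":
        blocks = [encode_groups(v) for v in factors.values()]
        if not blocks:
            return cls(np.zeros((0, 0)), [], [])
        return cls(
            np.hstack(blocks),
            [b.shape[1] for b in blocks],
            list(factors.keys()),
        )

    def expand(self, gammas: np.ndarray) -> np.ndarray:
        """Per-column gamma vector (length q) from per-factor gammas."""
        return np.repeat(np.asarray(gammas, dtype=float), self.block_sizes)


@dataclass
class REMLResult:
    beta: np.ndarray
    cov_beta: np.ndarray  # sigma^2 (X' W^-1 X)^-1
    sigma2: float
    gammas: np.ndarray  # per retained factor, variance ratio
    variances: dict  # factor name -> intercept variance (all factors)
    factor_names: list[str]
    dropped: list[str]
    singular: bool
    reml_criterion: float
    n: int
    p: int
    XtWiX: np.ndarray
    converged: bool = True

    @property
    def variance_components(self) -> dict:
        out = dict(self.variances)
        out["residual"] = self.sigma2
        return out


def _crossprods(X, y, Z):
    return {
        "XtX": X.T @ X,
        "Xty": X.T @ y,
        "yty": float(y @ y),
        "ZtX": Z.T @ X,
        "Zty": Z.T @ y,
        "ZtZ": Z.T @ Z,
    }


def _w_quantities(cp, g):
    """Return (XtWiX, XtWiy, ytWiy, logdetW) for W = I + Z diag(g) Z'."""
    if g.size == 0 or np.all(g == 0):
        return cp["XtX"], cp["Xty"], cp["yty"], 0.0
    sg = np.sqrt(g)
    M = np.eye(len(g)) + sg[:, None] * cp["ZtZ"] * sg[None, :]
    c, low = cho_factor(M, lower=True)
    logdetW = 2.0 * float(np.sum(np.log(np.diag(c))))
    SX = sg[:, None] * cp["ZtX"]
    Sy = sg * cp["Zty"]
    MiSX = cho_solve((c, low), SX)
    MiSy = cho_solve((c, low), Sy)
    XtWiX = cp["XtX"] - SX.T @ MiSX
    XtWiy = cp["Xty"] - SX.T @ MiSy
    ytWiy = cp["yty"] - float(Sy @ MiSy)
    return XtWiX, XtWiy, ytWiy, logdetW


def _profiled_criterion(cp, struct, gammas, n, p):
    """-2 restricted loglik with beta and sigma^2 profiled out."""
    g = struct.expand(gammas)
    XtWiX, XtWiy, ytWiy, logdetW = _w_quantities(cp, g)
    try:
        beta = np.linalg.solve(XtWiX, XtWiy)
        sign, logdetX = np.linalg.slogdet(XtWiX)
        if sign <= 0:
            return np.inf, None, None
    except np.linalg.LinAlgError:
        return np.inf, None, None
    rWr = max(ytWiy - float(beta @ XtWiy), 1e-300)
    sigma2 = rWr / (n - p)
    crit = (
        (n - p) * (np.log(sigma2) + 1.0 + _LOG2PI) + logdetW + logdetX
    )
    return crit, beta, sigma2


def reml_criterion_at(cp, struct, theta, n, p):
    """-2 restricted loglik at explicit theta = (sigma2, var_1, ..., var_K).

    Used for the numeric Hessian of the Satterthwaite approximation.
    """
    sigma2 = theta[0]
    if sigma2 <= 0 or np.any(np.asarray(theta[1:]) < 0):
        return np.inf
    gammas = np.asarray(theta[1:]) / sigma2
    g = struct.expand(gammas)
    XtWiX, XtWiy, ytWiy, logdetW = _w_quantities(cp, g)
    try:
        beta = np.linalg.solve(XtWiX, XtWiy)
        sign, logdetX = np.linalg.slogdet(XtWiX)
        if sign <= 0:
            return np.inf
    except np.linalg.LinAlgError:
        return np.inf
    rWr = max(ytWiy - float(beta @ XtWiy), 1e-300)
    return (
        (n - p) * _LOG2PI
        + (n - p) * np.log(sigma2)
        + logdetW
        + logdetX
        + rWr / sigma2
    )


def cov_beta_at(cp, struct, theta):
    """sigma^2 (X' W^-1 X)^-1 at explicit theta, for Satterthwaite gradients."""
    sigma2 = theta[0]
    gammas = np.clip(np.asarray(theta[1:]) / sigma2, 0.0, None)
    g = struct.expand(gammas)
    XtWiX, *_ = _w_quantities(cp, g)
    return sigma2 * np.linalg.inv(XtWiX)


def reml_fit(
    X: np.ndarray,
    y: np.ndarray,
    factors: dict,
    singular_tol: float = 1e-8,
    drop_singular: bool = True,
) -> REMLResult:
    """REML fit of the crossed random-intercept model.

    ``factors`` maps factor names to label vectors.  Factors whose fitted
    intercept variance falls below ``singular_tol`` are flagged singular and
    (when ``drop_singular``) removed, with the model refit on the remainder;
    with no factors left the fit reduces to OLS.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("more parameters than observations")

    active = {
        k: v for k, v in factors.items() if len(np.unique(np.asarray(v))) >= 2
    }
    pre_dropped = [k for k in factors if k not in active]

    def _fit(current: dict):
        struct = RandomStructure.from_labels(current)
        Z = struct.Z if struct.Z.size else np.zeros((n, 0))
        cp = _crossprods(X, y, Z)
        K = len(struct.block_sizes)
        if K == 0:
            crit, beta, sigma2 = _profiled_criterion(cp, struct, np.empty(0), n, p)
            return struct, cp, np.empty(0), crit, beta, sigma2, True

        def objective(log_g):
            crit, *_ = _profiled_criterion(cp, struct, np.exp(log_g), n, p)
            return crit

        best = None
        converged = False
        for start in ([np.log(0.05)] * K, [np.log(1.0)] * K):
            res = optimize.minimize(
                objective,
                np.asarray(start),
                method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 400},
            )
            if best is None or res.fun < best.fun:
                best = res
                converged = bool(res.success) or converged
        gam = np.exp(best.x)
        gam = np.where(gam < 1e-10, 0.0, gam)
        best_crit = _profiled_criterion(cp, struct, gam, n, p)[0]
        # boundary refinement: REML solutions frequently sit at gamma_k = 0,
        # which a log-scale search can only approach; test each zero pattern
        # with the remaining components re-optimized
        import itertools

        for mask in itertools.product([0.0, 1.0], repeat=K):
            mask = np.asarray(mask)
            if mask.all():
                continue
            free = np.flatnonzero(mask)

            def masked_obj(log_g_free):
                g_full = np.zeros(K)
                g_full[free] = np.exp(log_g_free)
                return _profiled_criterion(cp, struct, g_full, n, p)[0]

            if free.size == 0:
                cand = np.zeros(K)
                crit_cand = _profiled_criterion(cp, struct, cand, n, p)[0]
            else:
                sub = optimize.minimize(
                    masked_obj, np.log(np.maximum(gam[free], 0.05)),
                    method="Nelder-Mead",
                    options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 200},
                )
                cand = np.zeros(K)
                cand[free] = np.exp(sub.x)
                crit_cand = sub.fun
            better = crit_cand < best_crit - 1e-9
            tie_simpler = (
                abs(crit_cand - best_crit) <= 1e-9
                and (cand == 0).sum() > (gam == 0).sum()
            )
            if better or tie_simpler:
                gam, best_crit = cand, min(crit_cand, best_crit)
        crit, beta, sigma2 = _profiled_criterion(cp, struct, gam, n, p)
        return struct, cp, gam, crit, beta, sigma2, converged

    struct, cp, gammas, crit, beta, sigma2, converged = _fit(active)
    if beta is None:
        raise np.linalg.LinAlgError("REML fit failed: singular design")
    variances = {
        name: float(g * sigma2) for name, g in zip(struct.names, gammas)
    }
    singular_factors = [
        name for name, v in variances.items() if v < singular_tol
    ]
    singular = bool(singular_factors or pre_dropped)
    dropped = list(pre_dropped)
    if drop_singular and singular_factors:
        dropped += singular_factors
        kept = {k: v for k, v in active.items() if k not in singular_factors}
        struct, cp, gammas, crit, beta, sigma2, converged = _fit(kept)
        for name in singular_factors:
            variances[name] = 0.0
        variances.update(
            {name: float(g * sigma2) for name, g in zip(struct.names, gammas)}
        )
    for name in pre_dropped:
        variances[name] = 0.0

    g = struct.expand(gammas) if gammas.size else np.empty(0)
    XtWiX, *_ = _w_quantities(cp, g)
    cov_beta = sigma2 * np.linalg.inv(XtWiX)
    return REMLResult(
        beta=beta,
        cov_beta=cov_beta,
        sigma2=float(sigma2),
        gammas=gammas,
        variances=variances,
        factor_names=list(struct.names),
        dropped=dropped,
        singular=singular,
        reml_criterion=float(crit),
        n=n,
        p=p,
        XtWiX=XtWiX,
        converged=converged,
    )


def batched_gls(
    Xb: np.ndarray, yb: np.ndarray, Zb: np.ndarray | None, g: np.ndarray
) -> np.ndarray:
    """GLS coefficients for a batch of resampled designs, gamma held fixed.

    ``Xb`` is (B, n, p), ``yb`` (B, n), ``Zb`` (B, n, q) the resampled random-
    factor indicators, ``g`` the per-column variance ratios.  Returns (B, p)
    coefficients; rows where the normal equations are singular come back as
    NaN for the caller to count as failures.
    """
    B, n, p = Xb.shape
    XtX = np.einsum("bni,bnj->bij", Xb, Xb)
    Xty = np.einsum("bni,bn->bi", Xb, yb)
    if Zb is not None and g.size and np.any(g > 0):
        sg = np.sqrt(g)
        ZtX = np.einsum("bnq,bnp->bqp", Zb, Xb)
        Zty = np.einsum("bnq,bn->bq", Zb, yb)
        ZtZ = np.einsum("bnq,bnr->bqr", Zb, Zb)
        M = np.eye(len(g))[None] + sg[None, :, None] * ZtZ * sg[None, None, :]
        SX = sg[None, :, None] * ZtX
        Sy = sg[None, :] * Zty
        try:
            MiSX = np.linalg.solve(M, SX)
            MiSy = np.linalg.solve(M, Sy[..., None])[..., 0]
        except np.linalg.LinAlgError:
            M = M + 1e-10 * np.eye(len(g))[None]
            MiSX = np.linalg.solve(M, SX)
            MiSy = np.linalg.solve(M, Sy[..., None])[..., 0]
        XtX = XtX - np.einsum("bqi,bqj->bij", SX, MiSX)
        Xty = Xty - np.einsum("bqi,bq->bi", SX, MiSy)
    out = np.full((B, p), np.nan)
    try:
        out = np.linalg.solve(XtX, Xty[..., None])[..., 0]
    except np.linalg.LinAlgError:
        for b in range(B):
            try:
                out[b] = np.linalg.solve(XtX[b], Xty[b])
            except np.linalg.LinAlgError:
                out[b] = np.nan
    return out
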