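"""Moving-window bootstrap of standardized mixed-model coefficients.

Sites are sorted by aridity and the simplified multifunctionality model is
refit in overlapping windows of 60 consecutive sites (one-site steps).
Within each window the standardized coefficients of every fixed term are
bootstrapped by resampling sites with replacement; each window's summaries
are indexed by the window's mean aridity.  Per-term trajectories are smoothed
with a penalized-spline GAM and screened for change points with the same
threshold-detection protocol used for raw gradients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mixed import ModelSpec, build_design, prepare_analysis_table
from .reml import RandomStructure, batched_gls, reml_fit
from .thresholds import ThresholdDecision, detect_threshold
from .smoothing import PSplineGAM

__all__ = [
    "WindowSet",
    "BootstrapCoefficients",
    "Trajectory",
    "make_windows",
    "window_bootstrap",
    "assemble_trajectory",
    "trajectory_threshold",
    "moving_window_analysis",
]


@dataclass
class WindowSet:
    windows: list[np.ndarray]  # positional indices into the sorted table
    w: int
    table: pd.DataFrame  # sorted by aridity (ties broken by site_id)

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def n_shifts(self) -> int:
        """One-site shifts performed after the initial window."""
        return len(self.windows) - 1


@dataclass
class BootstrapCoefficients:
    window_id: int
    window_mean_aridity: float
    terms: list[str]
    matrix: np.ndarray  # B x terms
    median: np.ndarray
    lo: np.ndarray  # 2.5 percentile
    hi: np.ndarray  # 97.5 percentile
    significant: np.ndarray  # one-sided sign-consistency flag per term
    point_estimate: np.ndarray
    usable: bool = True
    n_failed: int = 0
    dropped_random_terms: list[str] = field(default_factory=list)


@dataclass
class Trajectory:
    term: str
    frame: pd.DataFrame  # window_id, mean_aridity, median, lo, hi, significant
    smoother: PSplineGAM | None = None
    decision: ThresholdDecision | None = None


def make_windows(table: pd.DataFrame, w: int = 60) -> WindowSet:
    """Overlapping windows of ``w`` consecutive sites along the gradient."""
    n = len(table)
    if n < w:
        raise ValueError(f"need at least w={w} sites, got {n}")
    if w < 10:
        raise ValueError("window size too small for the window model")
    sort_cols = ["aridity"] + (["site_id"] if "site_id" in table.columns else [])
    ordered = table.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)
    windows = [np.arange(k, k + w) for k in range(n - w + 1)]
    return WindowSet(windows=windows, w=w, table=ordered)


def window_bootstrap(
    window_table: pd.DataFrame,
    spec: ModelSpec | None = None,
    B: int = 500,
    seed: int = 0,
    window_id: int = 0,
    max_fail_frac: float = 0.2,
    alpha: float = 0.05,
) -> BootstrapCoefficients:
    """Bootstrap the standardized coefficients within one window.

    The window model is fit once by REML (singular random terms dropped);
    each of the ``B`` site resamples is then refit by GLS with the window's
    variance ratios, which keeps the bootstrap deterministic, stable, and
    vectorized.  A term is flagged significant when the bootstrap tail
    probability of a sign flip relative to the median is at most ``alpha``
    (one-sided).
    """
    spec = spec or ModelSpec(variant="simplified")
    design = build_design(window_table, spec)
    X, y = design.X, design.y
    n = design.n
    res = reml_fit(X, y, design.random_factors)
    kept = {
        k: v for k, v in design.random_factors.items() if k not in res.dropped
    }
    struct = RandomStructure.from_labels(kept)
    g = struct.expand(res.gammas) if res.gammas.size else np.empty(0)
    Zfull = struct.Z if struct.Z.size else None

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    Xb = X[idx]
    yb = y[idx]
    Zb = Zfull[idx] if Zfull is not None else None
    coefs = batched_gls(Xb, yb, Zb, g)

    ok = np.all(np.isfinite(coefs), axis=1)
    n_failed = int(B - ok.sum())
    usable = n_failed <= max_fail_frac * B
    good = coefs[ok][:, 1:]  # drop intercept
    terms = design.terms
    if good.shape[0] == 0:
        nan = np.full(len(terms), np.nan)
        return BootstrapCoefficients(
            window_id, float(window_table["aridity"].mean()), list(terms),
            coefs[:, 1:], nan, nan, nan,
            np.zeros(len(terms), bool), res.beta[1:],
            usable=False, n_failed=n_failed,
            dropped_random_terms=list(res.dropped),
        )
    median = np.median(good, axis=0)
    lo = np.percentile(good, 2.5, axis=0)
    hi = np.percentile(good, 97.5, axis=0)
    sign = np.where(median >= 0, 1.0, -1.0)
    tail = (good * sign[None, :] <= 0).mean(axis=0)
    significant = tail <= alpha
    return BootstrapCoefficients(
        window_id=window_id,
        window_mean_aridity=float(window_table["aridity"].mean()),
        terms=list(terms),
        matrix=coefs[:, 1:],
        median=median, lo=lo, hi=hi, significant=significant,
        point_estimate=res.beta[1:],
        usable=usable, n_failed=n_failed,
        dropped_random_terms=list(res.dropped),
    )


def assemble_trajectory(
    results: list[BootstrapCoefficients], term: str, smooth: bool = True
) -> Trajectory:
    """Ordered per-window summaries of one term, with a GAM smooth."""
    usable = [r for r in results if r.usable]
    if len(usable) < 10:
        raise ValueError(f"only {len(usable)} usable windows (< 10)")
    if term not in usable[0].terms:
        raise KeyError(f"term {term!r} not in the window model")
    j = usable[0].terms.index(term)
    frame = pd.DataFrame(
        {
            "window_id": [r.window_id for r in usable],
            "mean_aridity": [r.window_mean_aridity for r in usable],
            "median": [r.median[j] for r in usable],
            "lo": [r.lo[j] for r in usable],
            "hi": [r.hi[j] for r in usable],
            "significant": [bool(r.significant[j]) for r in usable],
            "point_estimate": [r.point_estimate[j] for r in usable],
        }
    ).sort_values("mean_aridity", kind="mergesort").reset_index(drop=True)
    smoother = None
    if smooth:
        smoother = PSplineGAM().fit(
            frame["mean_aridity"].to_numpy(), frame["median"].to_numpy()
        )
    return Trajectory(term=term, frame=frame, smoother=smoother)


def trajectory_threshold(
    trajectory: Trajectory, B: int = 500, seed: int = 0
) -> ThresholdDecision:
    """Change-point screen on a coefficient trajectory (bootstrap medians)."""
    x = trajectory.frame["mean_aridity"].to_numpy()
    y = trajectory.frame["median"].to_numpy()
    decision = detect_threshold(x, y, B=B, seed=seed)
    trajectory.decision = decision
    return decision


def moving_window_analysis(
    table: pd.DataFrame,
    w: int = 60,
    B: int = 500,
    seed: int = 0,
    spec: ModelSpec | None = None,
    detect: bool = True,
) -> dict:
    """End-to-end moving-window pipeline on a site table.

    Returns window results, per-term trajectories (with change-point
    decisions when ``detect``), and a long-format trajectory frame.
    Per-window bootstrap seeds are split deterministically from ``seed``.
    """
    spec = spec or ModelSpec(variant="simplified")
    prepared = prepare_analysis_table(table)
    ws = make_windows(prepared, w=w)
    seeds = np.random.SeedSequence(seed).spawn(len(ws))
    results = []
    for k, win in enumerate(ws.windows):
        sub = ws.table.iloc[win]
        results.append(
            window_bootstrap(
                sub, spec=spec, B=B,
                seed=int(seeds[k].generate_state(1)[0] % (2**31)),
                window_id=k,
            )
        )
    terms = results[0].terms
    trajectories = {}
    long_rows = []
    for term in terms:
        traj = assemble_trajectory(results, term)
        if detect:
            trajectory_threshold(traj, B=B, seed=seed)
        trajectories[term] = traj
        f = traj.frame.copy()
        f.insert(0, "term", term)
        long_rows.append(f)
    return {
        "windows": ws,
        "results": results,
        "trajectories": trajectories,
        "long_frame": pd.concat(long_rows, ignore_index=True),
    }
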