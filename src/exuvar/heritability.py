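"""Broad-sense heritability from a one-way random-effects model.

For each feature, replicate-level relative abundances y_ij are modeled as

    y_ij = mu + a_i + e_ij,   a_i ~ N(0, V_B),  e_ij ~ N(0, V_E),

where i indexes accessions (inbred lines) and j replicates. V_B is the
among-accession (genotypic) variance, V_E the within-accession residual.
Broad-sense heritability is H2 = V_B / (V_B + V_E).

Variance components are estimated by restricted maximum likelihood (REML),
profiled down to a one-dimensional search over the ratio lambda = V_B/V_E
on a log scale. Because the one-way REML criterion depends on the data only
through per-group replicate counts, sums and sums of squares, the search is
vectorized over many datasets at once — which makes the accession-level
bootstrap (resampling whole accessions with all their replicates) cheap.

Uncertainty: percentile bootstrap CI over accessions; a feature is called
significantly heritable when the 95% CI excludes zero.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .feature_table import AbundanceTable

__all__ = [
    "HeritabilityResult",
    "reml_one_way",
    "h2_bootstrap",
    "heritability_screen",
]

_LOG_RATIO_BOUNDS = (-12.0, 12.0)
_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


@dataclasses.dataclass
class HeritabilityResult:
    feature_id: str
    v_b: float
    v_e: float
    h2: float
    ci_low: float
    ci_high: float
    n_boot: int
    significant: bool
    n_degenerate_redraws: int = 0


def _group_stats(y: np.ndarray, groups: np.ndarray):
    """Per-group (n_i, sum_i, sumsq_i) sufficient statistics."""
    labels, idx = np.unique(groups, return_inverse=True)
    g = len(labels)
    n = np.bincount(idx, minlength=g).astype(float)
    s = np.bincount(idx, weights=y, minlength=g)
    ss = np.bincount(idx, weights=y * y, minlength=g)
    return n, s, ss


def _reml_criterion(loglam: np.ndarray, n, s, ss):
    """-2 REML log-likelihood (up to a constant) at log(V_B/V_E).

    ``n, s, ss`` have shape (..., G); ``loglam`` broadcasts over the
    leading axes. Returns (criterion, yPy) where yPy is the residual
    quadratic form giving V_E = yPy / (N - 1).
    """
    lam = np.exp(loglam)[..., None]
    denom = 1.0 + lam * n
    ywy = np.sum(ss - lam / denom * s * s, axis=-1)
    xwx = np.sum(n / denom, axis=-1)
    xwy = np.sum(s / denom, axis=-1)
    ntot = np.sum(n, axis=-1)
    ypy = ywy - xwy * xwy / xwx
    ypy = np.maximum(ypy, 1e-300)
    crit = (
        np.sum(np.log(denom), axis=-1)
        + np.log(xwx)
        + (ntot - 1.0) * np.log(ypy)
    )
    return crit, ypy


def _profile_reml(n, s, ss, iters: int = 90):
    """Vectorized golden-section REML over log(V_B/V_E) in [-12, 12].

    Accepts stats of shape (G,) or (B, G); returns arrays (v_b, v_e, h2)
    of the leading shape. Handles the boundary/degenerate cases:
    zero total variance -> (0, 0, 0); zero within-group variance with
    between-group spread -> (var, 0, 1); left-boundary optimum -> V_B = 0.
    """
    n = np.atleast_2d(n)
    s = np.atleast_2d(s)
    ss = np.atleast_2d(ss)
    B = n.shape[0]
    ntot = n.sum(axis=-1)
    mean = s.sum(axis=-1) / ntot
    sst = ss.sum(axis=-1) - ntot * mean**2  # total SS about grand mean
    ssw = np.sum(ss - s * s / np.maximum(n, 1.0), axis=-1)  # within-group SS
    scale = np.maximum(sst, 1e-300)

    lo = np.full(B, _LOG_RATIO_BOUNDS[0])
    hi = np.full(B, _LOG_RATIO_BOUNDS[1])
    for _ in range(iters):
        x1 = hi - _GOLDEN * (hi - lo)
        x2 = lo + _GOLDEN * (hi - lo)
        f1, _ = _reml_criterion(x1, n, s, ss)
        f2, _ = _reml_criterion(x2, n, s, ss)
        move_right = f1 > f2
        lo = np.where(move_right, x1, lo)
        hi = np.where(move_right, hi, x2)
    xopt = 0.5 * (lo + hi)
    crit_opt, ypy = _reml_criterion(xopt, n, s, ss)
    crit_left, ypy_left = _reml_criterion(np.full(B, _LOG_RATIO_BOUNDS[0]), n, s, ss)

    lam = np.exp(xopt)
    v_e = ypy / (ntot - 1.0)
    v_b = lam * v_e
    h2 = lam / (1.0 + lam)

    # left-boundary optimum => V_B truncated at zero
    at_left = (xopt <= _LOG_RATIO_BOUNDS[0] + 0.05) | (crit_left <= crit_opt)
    v_e = np.where(at_left, ypy_left / (ntot - 1.0), v_e)
    v_b = np.where(at_left, 0.0, v_b)
    h2 = np.where(at_left, 0.0, h2)

    # no residual variance but real between-group spread => H2 = 1
    pure_between = (ssw <= 1e-12 * scale) & (sst > 1e-300)
    v_e = np.where(pure_between, 0.0, v_e)
    v_b = np.where(pure_between, sst / np.maximum(ntot - 1.0, 1.0), v_b)
    h2 = np.where(pure_between, 1.0, h2)

    # zero total variance => (0, 0) with H2 = 0 by convention
    flat = sst <= 1e-300
    v_b = np.where(flat, 0.0, v_b)
    v_e = np.where(flat, 0.0, v_e)
    h2 = np.where(flat, 0.0, h2)
    return v_b, v_e, h2


def reml_one_way(y, groups) -> tuple[float, float]:
    """REML variance components (V_B, V_E) of a one-way random-effects fit.

    Raises if every group is a singleton (V_E unidentifiable); emits a
    warning and returns (0, 0) when the response has zero variance.
    """
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    if y.shape != groups.shape:
        raise ValueError("y and groups must have equal length")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite response values")
    n, s, ss = _group_stats(y - y.mean(), groups)  # centering aids conditioning
    if len(n) < 2:
        raise ValueError("need >= 2 groups")
    if n.max() < 2:
        raise ValueError("all groups are singletons: V_E is unidentifiable")
    v_b, v_e, _ = _profile_reml(n, s, ss)
    if v_b[0] == 0.0 and v_e[0] == 0.0:
        warnings.warn("zero total variance; returning (0, 0)")
    return float(v_b[0]), float(v_e[0])


def _h2_from_stats(n, s, ss):
    return _profile_reml(n, s, ss)[2]


def h2_bootstrap(
    y,
    groups,
    n_boot: int = 1000,
    seed: int | np.random.Generator | None = 0,
    feature_id: str = "",
) -> HeritabilityResult:
    """H2 with a 95% accession-level percentile bootstrap CI.

    Accessions (groups) are resampled with replacement, each drawn
    accession carrying all its replicates; H2 is re-estimated by REML on
    each resample. A resample collapsing to a single unique accession is
    redrawn (and counted). ``significant`` means the CI excludes zero.
    """
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} < 100: bootstrap CI will be unstable")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    n, s, ss = _group_stats(y - y.mean(), groups)
    if len(n) < 2:
        raise ValueError("need >= 2 groups")
    if n.max() < 2:
        raise ValueError("all groups are singletons: V_E is unidentifiable")
    v_b, v_e, h2 = (float(a[0]) for a in _profile_reml(n, s, ss))

    g = len(n)
    idx = rng.integers(0, g, size=(n_boot, g))
    n_redraw = 0
    # redraw resamples in which a single accession was drawn g times
    degenerate = (idx == idx[:, :1]).all(axis=1)
    while degenerate.any():
        n_redraw += int(degenerate.sum())
        idx[degenerate] = rng.integers(0, g, size=(int(degenerate.sum()), g))
        degenerate = (idx == idx[:, :1]).all(axis=1)
    h2_boot = _h2_from_stats(n[idx], s[idx], ss[idx])
    ci_low, ci_high = np.quantile(h2_boot, [0.025, 0.975])
    return HeritabilityResult(
        feature_id=feature_id,
        v_b=v_b,
        v_e=v_e,
        h2=h2,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_boot=n_boot,
        significant=bool(ci_low > 0.0),
        n_degenerate_redraws=n_redraw,
    )


def heritability_screen(
    a: AbundanceTable, n_boot: int = 1000, seed: int = 0
) -> pd.DataFrame:
    """Per-feature heritability over an (already filtered) abundance table.

    Returns a DataFrame with columns V_B, V_E, H2, ci_low, ci_high,
    n_boot, significant, indexed by feature_id. Features whose fit fails
    are flagged in an ``error`` column rather than aborting the screen.
    """
    rng = np.random.default_rng(seed)
    groups = a.sample_meta["accession_id"].to_numpy()
    rows = []
    for fid in a.rel_abundance.columns:
        col = a.rel_abundance[fid].to_numpy()
        ok = np.isfinite(col)
        try:
            res = h2_bootstrap(
                col[ok], groups[ok], n_boot=n_boot, seed=rng, feature_id=str(fid),
            )
            rows.append(
                dict(
                    feature_id=str(fid), V_B=res.v_b, V_E=res.v_e, H2=res.h2,
                    ci_low=res.ci_low, ci_high=res.ci_high, n_boot=res.n_boot,
                    significant=res.significant, error="",
                )
            )
        except ValueError as exc:  # flagged, not fatal
            rows.append(
                dict(
                    feature_id=str(fid), V_B=np.nan, V_E=np.nan, H2=np.nan,
                    ci_low=np.nan, ci_high=np.nan, n_boot=0,
                    significant=False, error=str(exc),
                )
            )
    if not rows:
        return pd.DataFrame(
            columns=["V_B", "V_E", "H2", "ci_low", "ci_high", "n_boot",
                     "significant", "error"]
        ).rename_axis("feature_id")
    return pd.DataFrame(rows).set_index("feature_id")
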