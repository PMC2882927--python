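"""Maximum-entropy habitat-suitability modeling with logistic output.

A convex maxent fit with linear + quadratic features standardized on the
training background, an L1 (lasso) regularization multiplier β, the
entropy-calibrated logistic transform LV = e^H q / (1 + e^H q), binomial
threshold tests, rank-based ROC/AUC, projection to alternate climate
stacks, and suitable-area summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .io import ClimateStack, Raster

__all__ = [
    "NicheModel", "fit_maxent", "predict_logistic", "binomial_threshold_test",
    "auc", "suitable_area", "compare_gap_suitability", "DEFAULT_THRESHOLDS",
]

#: ten commonly used logistic presence thresholds
DEFAULT_THRESHOLDS = (0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.40, 0.50, 0.60, 0.70)


@dataclass
class NicheModel:
    variables: list[str]
    #: coefficients over [linear..., quadratic...] standardized features
    lam: np.ndarray
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    log_z: float              # log normalizer over the training background
    entropy: float            # entropy H of the fitted distribution
    beta: float
    n_background: int
    converged: bool
    #: training-background range of each standardized variable, for clamping
    z_range: tuple[np.ndarray, np.ndarray] | None = None

    def features(self, env: np.ndarray, clamp: bool = False) -> np.ndarray:
        """Standardized linear + quadratic features for raw env rows.

        With ``clamp`` the standardized variables are clipped to the
        training-background range before the quadratic expansion, limiting
        extrapolation when projecting to a novel climate.
        """
        z = (env - self.feature_mean) / self.feature_sd
        if clamp and self.z_range is not None:
            z = np.clip(z, self.z_range[0], self.z_range[1])
        return np.hstack([z, z ** 2])


def _stack_env(stack: ClimateStack, variables: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """(valid_mask, env rows for valid cells) over the stack's grid."""
    missing = [v for v in variables if v not in stack]
    if missing:
        raise ValueError(f"climate stack lacks variables {missing}")
    layers = [stack[v] for v in variables]
    valid = ~layers[0].nodata_mask()
    for r in layers[1:]:
        valid &= ~r.nodata_mask()
    env = np.column_stack([r.values[valid] for r in layers])
    return valid, env


def _cells_env(stack: ClimateStack, cells, variables: list[str]) -> np.ndarray:
    rows = np.array([c[0] for c in cells])
    cols = np.array([c[1] for c in cells])
    return np.column_stack([stack[v].values[rows, cols] for v in variables])


def fit_maxent(presences, stack: ClimateStack, background=None,
               beta: float = 1.0, variables: list[str] | None = None,
               max_iter: int = 500, tol: float = 1e-5) -> NicheModel:
    """Fit the maxent model by convex optimization.

    Maximizes mean over presences of λ·f − log Z(λ) − β·Σ_j r_j·|λ_j| where
    Z normalizes e^{λ·f} over the background (all valid cells by default)
    and r_j = 1/√m (m presences) is the sample-size regularization scale on
    the standardized features, so the penalty shrinks as evidence grows.
    The L1 penalty is handled by splitting λ into positive and negative
    parts and bounding both at zero (so the objective stays smooth).
    """
    if variables is None:
        variables = stack.variable_names()
    if len(presences) < 5:
        raise ValueError("need at least 5 presence cells")
    valid, bg_env = _stack_env(stack, variables)
    if background is not None:
        bg_env = _cells_env(stack, background, variables)
    mean = bg_env.mean(axis=0)
    sd = bg_env.std(axis=0)
    sd[sd == 0] = 1.0
    zbg = np.hstack([(bg_env - mean) / sd, ((bg_env - mean) / sd) ** 2])
    pr_env = _cells_env(stack, presences, variables)
    zpr = np.hstack([(pr_env - mean) / sd, ((pr_env - mean) / sd) ** 2])
    target = zpr.mean(axis=0)
    nf = zbg.shape[1]
    reg = beta / np.sqrt(len(presences))

    def negobj(uv: np.ndarray) -> tuple[float, np.ndarray]:
        lam = uv[:nf] - uv[nf:]
        s = zbg @ lam
        smax = s.max()
        logz = smax + np.log(np.exp(s - smax).mean())
        q = np.exp(s - logz) / zbg.shape[0]
        eq = (q[:, None] * zbg).sum(axis=0)
        gain = target @ lam - logz - reg * uv.sum()
        grad_lam = target - eq
        grad = np.concatenate([grad_lam - reg, -grad_lam - reg])
        return -gain, -grad

    res = optimize.minimize(
        negobj, np.zeros(2 * nf), jac=True, method="L-BFGS-B",
        bounds=[(0, None)] * (2 * nf),
        options={"maxiter": max_iter, "ftol": tol * 1e-4, "gtol": tol})
    if not res.success and res.nit >= max_iter:
        raise RuntimeError(
            f"maxent failed to converge after {max_iter} iterations: "
            f"{res.message}")
    lam = res.x[:nf] - res.x[nf:]
    s = zbg @ lam
    smax = s.max()
    logz = smax + np.log(np.exp(s - smax).sum())   # Z as a sum over cells
    q = np.exp(s - logz)
    ent = float(-(q * np.log(np.maximum(q, 1e-300))).sum())
    zlin = (bg_env - mean) / sd
    return NicheModel(list(variables), lam, mean, sd, float(logz), ent,
                      beta, zbg.shape[0], bool(res.success),
                      (zlin.min(axis=0), zlin.max(axis=0)))


def predict_logistic(model: NicheModel, stack: ClimateStack,
                     clamp: bool = False) -> Raster:
    """Logistic suitability LV = e^H q / (1 + e^H q) on a climate stack.

    Projection to a non-training stack (e.g. the LGM scenario) reuses the
    training normalizer Z and entropy H, so current and past maps share one
    calibration.  ``clamp`` clips variables to the training range first
    (off by default).
    """
    valid, env = _stack_env(stack, model.variables)
    f = model.features(env, clamp=clamp)
    s = f @ model.lam
    logq = s - model.log_z
    # LV = 1 / (1 + exp(-(H + log q)))
    lv = 1.0 / (1.0 + np.exp(-(model.entropy + logq)))
    ref = stack.ref
    out = np.full((ref.nrows, ref.ncols), ref.nodata_value, dtype=float)
    out[valid] = lv
    return ref.like(out)


def binomial_threshold_test(suitability: Raster, test_presences,
                            threshold: float) -> float:
    """One-sided binomial P that test presences fall in predicted-suitable
    cells more often than a random model with the same suitable fraction."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    if len(test_presences) == 0:
        raise ValueError("no test presences")
    vals = suitability.data_values()
    a = float((vals >= threshold).mean())
    rows = np.array([c[0] for c in test_presences])
    cols = np.array([c[1] for c in test_presences])
    lv = suitability.values[rows, cols]
    k = int((lv >= threshold).sum())
    n = len(test_presences)
    return float(stats.binom.sf(k - 1, n, a))


def auc(suitability: Raster, presences, background=None) -> float:
    """Rank-based (Mann–Whitney) AUC of presence vs background logistic
    values; ties count half."""
    rows = np.array([c[0] for c in presences])
    cols = np.array([c[1] for c in presences])
    pos = suitability.values[rows, cols]
    if background is None:
        neg = suitability.data_values()
    else:
        rows = np.array([c[0] for c in background])
        cols = np.array([c[1] for c in background])
        neg = suitability.values[rows, cols]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need non-empty presence and background sets")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def suitable_area(suitability: Raster, threshold: float = 0.1,
                  cell_area_km2: float = 100.0,
                  mask: np.ndarray | None = None) -> float:
    """Total area (km²) of valid cells with LV ≥ threshold, optionally
    restricted to a boolean mask."""
    if cell_area_km2 <= 0:
        raise ValueError("cell area must be positive")
    ok = ~suitability.nodata_mask()
    if mask is not None:
        ok &= mask
    return float((suitability.values[ok] >= threshold).sum() * cell_area_km2)


def compare_gap_suitability(raster_a: Raster, raster_b: Raster,
                            gap_mask: np.ndarray) -> tuple[float, float]:
    """Paired t-test of logistic values over overlapping gap pixels.

    Returns (t, P).  Identical rasters give (0.0, 1.0) by convention.
    """
    if not raster_a.same_header(raster_b):
        raise ValueError("rasters must share one grid header")
    ok = gap_mask & ~raster_a.nodata_mask() & ~raster_b.nodata_mask()
    a = raster_a.values[ok]
    b = raster_b.values[ok]
    if a.size < 2:
        raise ValueError("need at least 2 paired gap pixels")
    diff = a - b
    if np.allclose(diff, 0.0):
        return 0.0, 1.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)
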