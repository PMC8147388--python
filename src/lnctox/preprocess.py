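"""Microarray preprocessing chain.

Order of operations (matching common two-color array practice): log2
transform of foreground intensities, background-based probe filtering
against negative-control probes, quantile normalization, then
empirical-Bayes batch adjustment (ComBat, parametric priors) run
sequentially over the ordered list of batch variables while preserving
the exposure-group covariate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, LnctoxError

log = logging.getLogger(__name__)


def log2_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2 of raw intensities; every value must be strictly positive."""
    if m.scale != "raw":
        raise LnctoxError("log2_transform expects a raw-scale matrix")
    vals = m.values.to_numpy()
    if (vals <= 0).any():
        i, j = np.argwhere(vals <= 0)[0]
        raise LnctoxError(
            f"nonpositive intensity at probe {m.values.index[i]!r}, "
            f"sample {m.values.columns[j]!r}"
        )
    return m.with_values(np.log2(m.values), scale="log2")


@dataclass(frozen=True)
class BackgroundRule:
    """Per-sample background threshold from negative-control intensities.

    ``mean_sd`` uses mean + k*SD of the negative-control probes in each
    sample (default k=2); ``quantile`` uses the q-th empirical quantile.
    """

    method: str = "mean_sd"
    k: float = 2.0
    q: float = 0.95

    def threshold(self, neg: np.ndarray) -> np.ndarray:
        if self.method == "mean_sd":
            return neg.mean(axis=0) + self.k * neg.std(axis=0, ddof=1)
        if self.method == "quantile":
            return np.quantile(neg, self.q, axis=0)
        raise LnctoxError(f"unknown background rule {self.method!r}")


def background_filter(
    m: ExpressionMatrix, rule: BackgroundRule = BackgroundRule()
) -> ExpressionMatrix:
    """Retain probes exceeding per-sample background in at least half the samples.

    The threshold per sample comes from that sample's negative-control
    probes; a probe is kept iff its intensity is strictly above threshold
    in >= ceil(n_samples / 2) samples. Negative-control probes are
    removed from the output.
    """
    if m.scale != "log2":
        raise LnctoxError("background_filter expects a log2-scale matrix")
    neg_ids = m.probes_of_biotype("negative_control")
    if len(neg_ids) == 0:
        raise LnctoxError("no negative-control probes: cannot define background")
    neg = m.values.loc[neg_ids].to_numpy()
    thr = rule.threshold(neg)  # one threshold per sample
    n_samples = m.values.shape[1]
    need = math.ceil(n_samples / 2)
    above = (m.values.to_numpy() > thr[None, :]).sum(axis=1)
    keep = (above >= need) & (m.biotype.to_numpy() != "negative_control")
    kept = m.values.index[keep]
    log.info(
        "background filter: retained %d / %d non-control probes",
        len(kept),
        int((m.biotype.to_numpy() != "negative_control").sum()),
    )
    return m.subset_probes(kept)


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common rank-mean distribution.

    The reference vector is the row-wise mean of the sorted columns; ties
    within a column receive the mean of the quantile values they span
    (deterministic and order-independent).
    """
    if m.scale != "log2":
        raise LnctoxError("quantile_normalize expects a log2-scale matrix")
    if m.values.shape[1] < 2:
        raise LnctoxError("quantile normalization needs >=2 samples")
    X = m.values.to_numpy()
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(col)
        assigned[order] = ref
        # ties: average the reference values over each tied block
        s = pd.Series(assigned)
        out[:, j] = s.groupby(pd.Series(col)).transform("mean").to_numpy()
    return m.with_values(
        pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    )


# --- ComBat: parametric empirical-Bayes batch adjustment ---------------


@dataclass
class BatchModel:
    """Fitted location/scale batch model for one batch variable.

    gamma_star / delta_star are (probes x batch levels) shrunken
    location shifts and scale factors on standardized data;
    hyperparameters hold the normal prior (gamma_bar, tau2) and
    inverse-gamma prior (a_prior, b_prior) per batch level.
    """

    batch_var: str
    levels: list[str]
    gamma_star: pd.DataFrame
    delta_star: pd.DataFrame
    hyperparameters: pd.DataFrame


def _check_confounding(design: pd.DataFrame, batch_var: str, preserve: str) -> None:
    tab = design.groupby([preserve, batch_var]).size().unstack(fill_value=0)
    # confounded when every preserved level sits entirely in one batch level
    if ((tab > 0).sum(axis=1) == 1).all() and tab.shape[1] > 1:
        raise LnctoxError(
            f"batch variable {batch_var!r} is confounded 1:1 with {preserve!r}"
        )


def _aprior(d: np.ndarray) -> float:
    m, s2 = d.mean(), d.var(ddof=1)
    return (2 * s2 + m**2) / s2

def _bprior(d: np.ndarray) -> float:
    m, s2 = d.mean(), d.var(ddof=1)
    return (m * s2 + m**3) / s2


def _it_sol(z, g_hat, d_hat, g_bar, t2, a, b, conv=1e-8, max_iter=2000):
    """Iterative joint posterior solve for one batch (sva's it.sol)."""
    n = z.shape[1]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = (t2 * n * g_hat + d_old * g_bar) / (t2 * n + d_old)
        sum2 = ((z - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (0.5 * sum2 + b) / (n / 2 + a - 1)
        change = max(
            np.abs((g_new - g_old) / np.where(g_old == 0, 1, g_old)).max(),
            np.abs((d_new - d_old) / d_old).max(),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def adjust_batch(
    m: ExpressionMatrix,
    design: pd.DataFrame,
    batch_var: str,
    preserve: str = "group",
    return_model: bool = False,
):
    """Remove one batch variable's location/scale effects (parametric ComBat).

    The preserved covariate's fitted group means are removed before
    estimating per-probe, per-batch location (gamma) and scale (delta)
    parameters, which are shrunk toward batch-level priors (normal for
    gamma, inverse-gamma for delta) and then subtracted/divided out.
    A single batch level means there is nothing to adjust: the input is
    returned unchanged.
    """
    if m.scale != "log2":
        raise LnctoxError("adjust_batch expects a log2-scale matrix")
    design = design.set_index("sample_id").loc[list(m.values.columns)].reset_index()
    batches = design[batch_var].astype(str)
    levels = list(dict.fromkeys(batches))
    counts = batches.value_counts()
    if (counts < 2).any():
        lvl = counts[counts < 2].index[0]
        raise LnctoxError(f"batch level {lvl!r} has a single sample")
    if len(levels) == 1:
        if return_model:
            model = BatchModel(batch_var, levels, pd.DataFrame(), pd.DataFrame(), pd.DataFrame())
            return m.with_values(m.values.copy()), model
        return m.with_values(m.values.copy())
    _check_confounding(design, batch_var, preserve)

    X = m.values.to_numpy(dtype=float)
    n_probes, n_samples = X.shape

    batch_dummies = pd.get_dummies(batches, dtype=float)[levels].to_numpy()
    group = design[preserve].astype(str)
    glevels = list(dict.fromkeys(group))
    cov = pd.get_dummies(group, dtype=float)[glevels].to_numpy()[:, 1:]  # drop reference
    D = np.hstack([batch_dummies, cov])
    B_hat, *_ = np.linalg.lstsq(D, X.T, rcond=None)  # (n_params, n_probes)

    n_batches = len(levels)
    batch_sizes = batch_dummies.sum(axis=0)
    grand_mean = (batch_sizes / n_samples) @ B_hat[:n_batches]
    fitted = D @ B_hat
    var_pooled = ((X.T - fitted) ** 2).mean(axis=0)
    if (var_pooled <= 0).any():
        var_pooled = np.where(var_pooled <= 0, var_pooled[var_pooled > 0].min(), var_pooled)

    stand_mean = grand_mean[None, :] + cov @ B_hat[n_batches:]
    Z = (X.T - stand_mean) / np.sqrt(var_pooled)[None, :]  # samples x probes

    gamma_star = np.empty((n_probes, n_batches))
    delta_star = np.empty((n_probes, n_batches))
    hyper = []
    for bi, lvl in enumerate(levels):
        idx = (batches == lvl).to_numpy()
        Zb = Z[idx].T  # probes x batch samples
        g_hat = Zb.mean(axis=1)
        d_hat = Zb.var(axis=1, ddof=1)
        g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1)
        a, b = _aprior(d_hat), _bprior(d_hat)
        g_star, d_star = _it_sol(Zb, g_hat, d_hat, g_bar, t2, a, b)
        gamma_star[:, bi] = g_star
        delta_star[:, bi] = d_star
        hyper.append({"level": lvl, "gamma_bar": g_bar, "tau2": t2, "a_prior": a, "b_prior": b})

    adj = Z.copy()
    for bi, lvl in enumerate(levels):
        idx = (batches == lvl).to_numpy()
        adj[idx] = (Z[idx] - gamma_star[:, bi][None, :]) / np.sqrt(delta_star[:, bi])[None, :]
    adj = adj * np.sqrt(var_pooled)[None, :] + stand_mean

    out = m.with_values(
        pd.DataFrame(adj.T, index=m.values.index, columns=m.values.columns)
    )
    if return_model:
        model = BatchModel(
            batch_var=batch_var,
            levels=levels,
            gamma_star=pd.DataFrame(gamma_star, index=m.values.index, columns=levels),
            delta_star=pd.DataFrame(delta_star, index=m.values.index, columns=levels),
            hyperparameters=pd.DataFrame(hyper).set_index("level"),
        )
        return out, model
    return out


def preprocess_chain(
    m: ExpressionMatrix,
    design: pd.DataFrame,
    rule: BackgroundRule = BackgroundRule(),
    batch_vars: tuple[str, ...] = ("batch_label", "batch_array"),
    preserve: str = "group",
) -> ExpressionMatrix:
    """Full chain: log2 -> background filter -> quantile norm -> sequential ComBat."""
    m = log2_transform(m)
    m = background_filter(m, rule)
    m = quantile_normalize(m)
    for bv in batch_vars:
        m = adjust_batch(m, design, bv, preserve=preserve)
    return m
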