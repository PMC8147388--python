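"""Moderated two-group differential expression with FDR and fold-change gates.

Per exposure group, every probe gets an ordinary two-group linear-model
fit (exposed vs dispersant-matched control); residual variances are
shrunk toward a common prior by empirical Bayes — an inverse-chi-square
prior whose degrees of freedom d0 and location s0^2 are estimated by
method of moments on the log residual variances. The moderated t is the
log2 fold change over the posterior standard error, on d0 + d_residual
degrees of freedom. P-values are Benjamini-Hochberg adjusted within each
contrast across all retained probes (both biotypes jointly); biotype
partitioning happens after gating.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .core import (
    ExpressionMatrix,
    LnctoxError,
    control_group_for,
    exposure_groups,
    samples_of_group,
)


@dataclass(frozen=True)
class DEGates:
    """Significance gates: |log2FC| >= 0.58 (1.5-fold) and BH q <= 0.05."""

    min_abs_log2fc: float = 0.58
    max_q: float = 0.05

    def __post_init__(self) -> None:
        if self.min_abs_log2fc <= 0 or self.max_q <= 0:
            raise LnctoxError("DE gates must be positive")


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} ( m * p_(j) / j ), clipped at 1; order-preserving
    in p.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise LnctoxError("bh_adjust expects a 1-d vector")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise LnctoxError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration on 1/trigamma)."""
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y
    for _ in range(100):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def squeeze_var(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the inverse-chi-square variance prior.

    Returns (d0, s0sq): prior degrees of freedom (may be inf when the
    observed log-variances are under-dispersed relative to chi-square
    sampling noise) and prior variance.
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2[s2 > 0]
    if len(pos) == 0:
        raise LnctoxError("all residual variances are zero; cannot fit variance prior")
    z = np.log(pos)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) if len(e) > 1 else 0.0
    evar_resid = evar - special.polygamma(1, df / 2.0)
    if evar_resid > 0:
        d0 = 2.0 * trigamma_inverse(evar_resid)
        s0sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # under-dispersed log-variances: infinite prior df, and the prior
        # variance reduces to the arithmetic mean of the observed variances
        d0 = np.inf
        s0sq = float(pos.mean())
    return d0, s0sq


def moderated_de(
    m: ExpressionMatrix,
    design: pd.DataFrame,
    group: str,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """One exposed-vs-control contrast with empirical-Bayes moderated t.

    Parameters
    ----------
    group
        Exposed group label; its control is the dispersant-matched
        control group from the design table.
    prior_df
        Override the estimated prior degrees of freedom. ``0`` disables
        shrinkage (ordinary two-sample t on the pooled variance);
        ``None`` (default) estimates d0 from the data.

    Returns a DataFrame indexed by probe_id with columns accession,
    biotype, log2fc, t_mod, p, q (BH within this contrast).
    """
    if m.scale != "log2":
        raise LnctoxError("moderated_de expects a log2-scale matrix")
    ctrl = control_group_for(design, group)
    exp_ids = samples_of_group(design, group)
    ctrl_ids = samples_of_group(design, ctrl)
    if len(exp_ids) < 2 or len(ctrl_ids) < 2:
        raise LnctoxError(
            f"contrast {group!r} vs {ctrl!r} needs >=2 replicates per side "
            f"(got {len(exp_ids)} vs {len(ctrl_ids)})"
        )
    A = m.values[exp_ids].to_numpy(dtype=float)
    B = m.values[ctrl_ids].to_numpy(dtype=float)
    n1, n2 = A.shape[1], B.shape[1]
    lfc = A.mean(axis=1) - B.mean(axis=1)
    d = n1 + n2 - 2
    s2 = (A.var(axis=1, ddof=1) * (n1 - 1) + B.var(axis=1, ddof=1) * (n2 - 1)) / d

    if prior_df is None:
        d0, s0sq = squeeze_var(s2, d)
    elif prior_df == 0:
        d0, s0sq = 0.0, 0.0
    else:
        d0 = float(prior_df)
        _, s0sq = squeeze_var(s2, d)

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0sq + d * s2) / (d0 + d)
        df_total = d0 + d

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), np.where(lfc == 0, 0.0, np.inf * np.sign(lfc)))
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    q = bh_adjust(p)
    return pd.DataFrame(
        {
            "accession": m.accession.to_numpy(),
            "biotype": m.biotype.to_numpy(),
            "log2fc": lfc,
            "t_mod": t,
            "p": p,
            "q": q,
        },
        index=m.values.index.rename("probe_id"),
    )


def gate_de(result: pd.DataFrame, gates: DEGates = DEGates()) -> tuple[set, set]:
    """Partition gate-passing probes by biotype.

    A probe passes iff |log2FC| >= min gate AND q <= max gate (both
    bounds inclusive). Returns (DE lncRNA probe ids, DE mRNA probe ids).
    """
    passed = result[
        (result["log2fc"].abs() >= gates.min_abs_log2fc) & (result["q"] <= gates.max_q)
    ]
    de_lnc = set(passed.index[passed["biotype"] == "lncRNA"])
    de_mrna = set(passed.index[passed["biotype"] == "mRNA"])
    return de_lnc, de_mrna


def run_contrasts(
    m: ExpressionMatrix, design: pd.DataFrame, prior_df: float | None = None
) -> dict[str, pd.DataFrame]:
    """Moderated DE for every exposed group in the design."""
    return {g: moderated_de(m, design, g, prior_df=prior_df) for g in exposure_groups(design)}


def de_count_table(gated: dict[str, tuple[set, set]]) -> pd.DataFrame:
    """Per-group counts of gate-passing lncRNA and mRNA probes."""
    rows = [
        {"group": g, "n_lnc": len(lnc), "n_mrna": len(mrna)}
        for g, (lnc, mrna) in gated.items()
    ]
    return pd.DataFrame(rows, columns=["group", "n_lnc", "n_mrna"]).set_index("group")


def collapse_to_transcripts(result: pd.DataFrame) -> pd.DataFrame:
    """Collapse multiple probes per accession to the probe with max |t_mod|.

    Used when reporting unique-transcript counts; with a one-probe-per
    -accession platform this is the identity.
    """
    order = result["t_mod"].abs().sort_values(ascending=False).index
    dedup = result.loc[order].groupby("accession", sort=False).head(1)
    return dedup.sort_index()
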