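"""Quantile normalization and empirical-Bayes (ComBat-style) batch correction.

Input matrices are assumed to be already background-corrected and
log2-summarized.  ``quantile_normalize`` equalizes the per-sample intensity
distributions; ``combat_correct`` removes a known additive and multiplicative
batch effect per probe by shrinking per-batch location/scale estimates
towards a pooled prior (Johnson-style empirical Bayes), while preserving
biological group differences supplied through the sample design.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .io_model import ExpressionMatrix, SampleDesign, ValidationError

log = logging.getLogger(__name__)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the across-sample mean distribution.

    Each column is replaced by the mean of the order statistics across
    columns, assigned back by rank; ties receive the mean of the reference
    values over the tied ranks (dense midrank policy).
    """
    if matrix.n_samples < 2:
        raise ValidationError("quantile normalization needs >= 2 samples")
    values = matrix.values
    order = np.sort(values, axis=0)
    reference = order.mean(axis=1)  # mean of k-th order statistics
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        ranks = rankdata(values[:, j], method="average")  # 1-based, midrank ties
        # integer ranks index the reference directly; fractional (tied) ranks
        # take the midpoint of the two neighbouring order statistics
        lo = np.floor(ranks).astype(int) - 1
        hi = np.ceil(ranks).astype(int) - 1
        out[:, j] = 0.5 * (reference[lo] + reference[hi])
    return ExpressionMatrix(list(matrix.probe_ids), list(matrix.sample_ids), out)


# ---------------------------------------------------------------------------
# ComBat
# ---------------------------------------------------------------------------


@dataclass
class BatchModel:
    """Estimated batch parameters: per-probe additive shift (log2) and
    multiplicative scale per batch, plus the standardization terms."""

    batches: list[str]
    gamma_star: np.ndarray  # (n_batch, n_probe) additive effects
    delta_star: np.ndarray  # (n_batch, n_probe) multiplicative effects (variances)
    grand_mean: np.ndarray  # (n_probe,)
    var_pooled: np.ndarray  # (n_probe,)


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum_sq, n, a, b):
    return (0.5 * sum_sq + b) / (n / 2.0 + a - 1.0)


def _aprior(delta_hat):
    m, s2 = delta_hat.mean(), delta_hat.var()
    return (2 * s2 + m**2) / s2


def _bprior(delta_hat):
    m, s2 = delta_hat.mean(), delta_hat.var()
    return (m * s2 + m**3) / s2


def _it_sol(sdat, g_hat, d_hat, g_bar, t2, a, b, conv=1e-4):
    """Parametric EB iteration for one batch (normal / inverse-gamma priors)."""
    n = sdat.shape[1]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    change = 1.0
    while change > conv:
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        sum_sq = ((sdat - g_new[:, None]) ** 2).sum(axis=1)
        d_new = _postvar(sum_sq, n, a, b)
        change = max(
            np.abs(g_new - g_old).max() / np.abs(g_old).max()
            if np.abs(g_old).max() > 0
            else 0.0,
            np.abs(d_new - d_old).max() / d_old.max(),
        )
        g_old, d_old = g_new, d_new
    return g_old, d_old


def _int_eprior(sdat, g_hat, d_hat):
    """Nonparametric (Monte Carlo integration) posterior for one batch.

    For each probe the posterior is the likelihood-weighted average of every
    other probe's method-of-moments estimates.
    """
    n_probe = sdat.shape[0]
    g_star = np.empty(n_probe)
    d_star = np.empty(n_probe)
    for i in range(n_probe):
        others = np.arange(n_probe) != i
        g, d = g_hat[others], d_hat[others]
        x = sdat[i]  # (n_samples,)
        resid2 = (x[None, :] - g[:, None]) ** 2  # (n_probe-1, n_samples)
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            ll = (-0.5 * resid2 / d[:, None]).sum(axis=1) - 0.5 * len(x) * np.log(
                2 * np.pi * d
            )
        ll -= ll.max()
        w = np.exp(ll)
        wsum = w.sum()
        if wsum == 0 or not np.isfinite(wsum):
            g_star[i], d_star[i] = g_hat[i], d_hat[i]
        else:
            g_star[i] = (w * g).sum() / wsum
            d_star[i] = (w * d).sum() / wsum
    return g_star, d_star


def combat_correct(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    mode: str = "nonparametric",
    return_model: bool = False,
):
    """Remove per-batch additive and multiplicative effects, preserving
    biological group differences.

    Probes are standardized against least-squares batch + group means, batch
    location/scale estimates are shrunk by empirical Bayes (``mode`` selects
    the nonparametric kernel-weighted posterior or the parametric
    normal/inverse-gamma solution), the batch effect is removed by
    subtracting the additive term and dividing by the multiplicative term,
    and the grand mean and treatment effects are added back.
    """
    if mode not in ("nonparametric", "parametric"):
        raise ValidationError(f"unknown ComBat mode {mode!r}")
    design.validate_against(matrix)
    mat = matrix.subset_samples(design.sample_ids)
    Y = mat.values  # (G, n)
    n_probe, n_sample = Y.shape

    batch_of = dict(
        zip(design.table["sample_id"].astype(str), design.table["batch"].astype(str))
    )
    batch_labels = [batch_of[s] for s in mat.sample_ids]
    batches = sorted(set(batch_labels))
    if len(batches) < 2:
        log.info("single batch: no batch effect to estimate, returning input")
        out = matrix.copy()
        return (out, None) if return_model else out
    groups = design.group_labels().reindex(mat.sample_ids).astype(str).to_numpy()

    batch_idx = {b: [j for j, lb in enumerate(batch_labels) if lb == b] for b in batches}
    for b, idx in batch_idx.items():
        if len(idx) < 2:
            raise ValidationError(f"batch {b!r} has fewer than 2 samples")

    # confounding check: every group must span >= 2 batches or be absent;
    # a batch whose samples all share one group unique to it is unidentifiable
    group_names = sorted(set(groups))
    B = np.zeros((n_sample, len(batches)))
    for k, b in enumerate(batches):
        B[batch_idx[b], k] = 1.0
    G_dummies = np.zeros((n_sample, max(len(group_names) - 1, 0)))
    for k, g in enumerate(group_names[1:]):
        G_dummies[groups == g, k] = 1.0
    X = np.hstack([B, G_dummies])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError(
            "batch is confounded with a biological group: effects unidentifiable"
        )

    # least-squares batch + group means
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)  # (p, G)
    n_b = np.array([len(batch_idx[b]) for b in batches], dtype=float)
    grand_mean = (n_b / n_sample) @ beta[: len(batches)]  # (G,)
    resid = Y - (X @ beta).T
    var_pooled = (resid**2).mean(axis=1)  # (G,)

    zero_var = var_pooled <= 0
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} probe(s) with zero residual variance "
            "passed through uncorrected"
        )
        var_pooled = np.where(zero_var, 1.0, var_pooled)

    stand_mean = grand_mean[:, None] + (G_dummies @ beta[len(batches):]).T
    Z = (Y - stand_mean) / np.sqrt(var_pooled)[:, None]

    gamma_hat = np.empty((len(batches), n_probe))
    delta_hat = np.empty((len(batches), n_probe))
    for k, b in enumerate(batches):
        sub = Z[:, batch_idx[b]]
        gamma_hat[k] = sub.mean(axis=1)
        delta_hat[k] = sub.var(axis=1, ddof=1)
    delta_hat = np.maximum(delta_hat, 1e-12)

    gamma_star = np.empty_like(gamma_hat)
    delta_star = np.empty_like(delta_hat)
    for k, b in enumerate(batches):
        sub = Z[:, batch_idx[b]]
        if mode == "parametric":
            g_bar, t2 = gamma_hat[k].mean(), gamma_hat[k].var()
            a, bb = _aprior(delta_hat[k]), _bprior(delta_hat[k])
            gamma_star[k], delta_star[k] = _it_sol(
                sub, gamma_hat[k], delta_hat[k], g_bar, t2, a, bb
            )
        else:
            gamma_star[k], delta_star[k] = _int_eprior(
                sub, gamma_hat[k], delta_hat[k]
            )
    delta_star = np.maximum(delta_star, 1e-12)

    corrected = Z.copy()
    for k, b in enumerate(batches):
        idx = batch_idx[b]
        corrected[:, idx] = (corrected[:, idx] - gamma_star[k][:, None]) / np.sqrt(
            delta_star[k]
        )[:, None]
    corrected = corrected * np.sqrt(var_pooled)[:, None] + stand_mean
    corrected[zero_var, :] = Y[zero_var, :]

    out_frame = mat.to_frame()
    out_frame.loc[:, :] = corrected
    designed = set(mat.sample_ids)
    ordered = [s for s in matrix.sample_ids if s in designed]
    out = ExpressionMatrix.from_frame(out_frame[ordered])
    if return_model:
        model = BatchModel(
            batches=batches,
            gamma_star=gamma_star,
            delta_star=delta_star,
            grand_mean=grand_mean,
            var_pooled=var_pooled,
        )
        return out, model
    return out
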