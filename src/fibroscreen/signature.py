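"""Disease-signature analysis: batch correction, moderated DE, retention.

This module implements the transcriptomic arm of the pipeline on log2
expression matrices (probes x samples):

* :func:`batch_correct` — parametric empirical-Bayes location/scale batch
  adjustment (the ComBat algorithm of Johnson, Li & Rabinovic 2007),
  preserving the disease covariate.
* :func:`moderated_de` — per-probe linear model with empirical-Bayes
  variance shrinkage, moderated t, Benjamini-Hochberg FDR and the log-odds
  (B) statistic (the limma framework of Smyth 2004), in unpaired two-group
  or paired (one-sample on within-donor differences) form.
* :func:`select_degs` — the composite significance rule: lods > 0,
  |fold change| > 1.5, BH q < 0.01, and average log2 intensity > 4.
* :func:`compare_signatures` — overlap, retention percentage and
  fold-change correlation between a baseline and a follow-up DEG set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests


class DesignError(ValueError):
    """Raised for unusable sample designs (confounding, too few samples)."""


@dataclass(frozen=True)
class DEThresholds:
    """Gates of the composite significance rule (all strict inequalities)."""

    min_fold_change: float = 1.5
    max_q: float = 0.01
    min_lods: float = 0.0
    min_avg_expr: float = 4.0

    @property
    def min_abs_log2fc(self) -> float:
        return float(np.log2(self.min_fold_change))


@dataclass(frozen=True)
class EBHyper:
    """Hyperparameters of the inverse-chi-square prior on probe variances.

    ``d0`` (prior degrees of freedom) may be +inf when the observed
    variances are homogeneous; ``s0_sq`` is the prior variance.
    """

    d0: float
    s0_sq: float


@dataclass
class BatchParams:
    """Fitted batch-adjustment parameters (per probe x batch)."""

    batches: list
    gamma_hat: np.ndarray
    delta_hat_sq: np.ndarray
    gamma_star: np.ndarray
    delta_star_sq: np.ndarray
    grand_mean: np.ndarray
    pooled_var: np.ndarray


# ---------------------------------------------------------------------------
# ComBat-style empirical-Bayes batch correction
# ---------------------------------------------------------------------------

def _design_matrix(meta: pd.DataFrame, covariate: str, batch_col: str):
    batches = sorted(meta[batch_col].unique())
    if len(batches) < 2:
        return None, batches
    batch_dummies = np.column_stack(
        [(meta[batch_col] == b).to_numpy(float) for b in batches]
    )
    cov_levels = sorted(meta[covariate].astype(str).unique())
    cov_cols = [
        (meta[covariate].astype(str) == lv).to_numpy(float)
        for lv in cov_levels[1:]  # drop reference level
    ]
    X = np.column_stack([batch_dummies] + cov_cols) if cov_cols else batch_dummies
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError(
            f"covariate {covariate!r} is confounded with batch; "
            "batch effect not estimable"
        )
    return X, batches


def batch_correct(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    covariate: str = "disease",
    batch_col: str = "batch",
) -> tuple[pd.DataFrame, BatchParams | None]:
    """Parametric empirical-Bayes location/scale batch adjustment.

    Fits, per probe, a linear model with batch indicators and the biological
    covariate; standardises the data; estimates per-(probe, batch) location
    (gamma) and scale (delta^2) of the standardised residuals; shrinks them
    with moment-matched parametric priors (normal on gamma, inverse-gamma on
    delta^2) via the iterative posterior solution; and removes the shrunken
    batch terms, restoring the covariate effects.  With a single batch the
    input is returned unchanged.
    """
    if list(matrix.columns) != list(meta["sample_id"]):
        meta = meta.set_index("sample_id").loc[list(matrix.columns)].reset_index()
    Y = matrix.to_numpy(dtype=float)
    if not np.all(np.isfinite(Y)):
        raise DesignError("expression matrix contains non-finite values")

    X, batches = _design_matrix(meta, covariate, batch_col)
    if X is None:  # single batch: no-op
        return matrix.copy(), None
    n_batches = len(batches)
    batch_idx = [np.flatnonzero((meta[batch_col] == b).to_numpy()) for b in batches]
    n_per_batch = np.array([len(ix) for ix in batch_idx])
    if np.any(n_per_batch < 2):
        raise DesignError("each batch needs >= 2 samples")
    n_samples = Y.shape[1]

    # per-probe OLS fit: batch means + covariate effects
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    # grand mean: batch coefficients weighted by batch size
    w = n_per_batch / n_samples
    grand_mean = w @ beta[:n_batches]
    fitted = (X @ beta).T
    resid = Y - fitted
    pooled_var = (resid ** 2).mean(axis=1)
    pooled_var = np.maximum(pooled_var, 1e-12)

    # covariate contribution (everything except batch terms)
    cov_part = (X[:, n_batches:] @ beta[n_batches:]).T if X.shape[1] > n_batches else 0.0
    stand_mean = grand_mean[:, None] + cov_part
    sd = np.sqrt(pooled_var)[:, None]
    Z = (Y - stand_mean) / sd

    n_probes = Y.shape[0]
    gamma_hat = np.empty((n_probes, n_batches))
    delta_hat_sq = np.empty((n_probes, n_batches))
    for j, ix in enumerate(batch_idx):
        gamma_hat[:, j] = Z[:, ix].mean(axis=1)
        delta_hat_sq[:, j] = Z[:, ix].var(axis=1, ddof=1)
    delta_hat_sq = np.maximum(delta_hat_sq, 1e-12)

    gamma_star = np.empty_like(gamma_hat)
    delta_star_sq = np.empty_like(delta_hat_sq)
    for j, ix in enumerate(batch_idx):
        g = gamma_hat[:, j]
        d2 = delta_hat_sq[:, j]
        gamma_bar, tau_sq = g.mean(), g.var(ddof=1)
        # inverse-gamma prior on delta^2 by moment matching
        m, s2 = d2.mean(), d2.var(ddof=1)
        lam = (2.0 * s2 + m ** 2) / s2
        theta = (m * s2 + m ** 3) / s2
        n_j = len(ix)
        g_star = g.copy()
        d2_star = d2.copy()
        Zj = Z[:, ix]
        for _ in range(200):
            g_new = (n_j * tau_sq * g + d2_star * gamma_bar) / (n_j * tau_sq + d2_star)
            ssr = ((Zj - g_new[:, None]) ** 2).sum(axis=1)
            d2_new = (theta + 0.5 * ssr) / (n_j / 2.0 + lam - 1.0)
            change = max(
                np.max(np.abs(g_new - g_star)), np.max(np.abs(d2_new - d2_star))
            )
            g_star, d2_star = g_new, d2_new
            if change < 1e-8:
                break
        gamma_star[:, j] = g_star
        delta_star_sq[:, j] = d2_star

    Z_adj = Z.copy()
    for j, ix in enumerate(batch_idx):
        Z_adj[:, ix] = (Z[:, ix] - gamma_star[:, j][:, None]) / np.sqrt(
            delta_star_sq[:, j]
        )[:, None]
    Y_adj = Z_adj * sd + stand_mean

    corrected = pd.DataFrame(Y_adj, index=matrix.index, columns=matrix.columns)
    params = BatchParams(
        batches=batches, gamma_hat=gamma_hat, delta_hat_sq=delta_hat_sq,
        gamma_star=gamma_star, delta_star_sq=delta_star_sq,
        grand_mean=grand_mean, pooled_var=pooled_var,
    )
    return corrected, params


# ---------------------------------------------------------------------------
# moderated differential expression
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: np.ndarray) -> np.ndarray:
    """Solve trigamma(y) = x for y (Newton iteration on 1/trigamma)."""
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if np.max(np.abs(dif) / np.maximum(y, 1e-8)) < 1e-8:
            break
    return y


def fit_variance_prior(s_sq: np.ndarray, df: float) -> EBHyper:
    """Moment-match the scaled inverse-chi-square prior on probe variances.

    Works on log sample variances: with z = log(s^2), E[z] and Var[z] under
    the hierarchical model identify (d0, s0^2) through digamma/trigamma
    moments.  Returns d0 = +inf (complete pooling) when the observed spread
    of log variances is no larger than the chi-square sampling spread.
    """
    s_sq = np.asarray(s_sq, dtype=float)
    ok = s_sq > 0
    if ok.sum() < 2:
        # (near-)all-constant data: complete pooling on a floor prior so the
        # shrunken variances stay positive
        return EBHyper(d0=np.inf, s0_sq=max(float(s_sq.mean()), 1e-10))
    z = np.log(s_sq[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    n = len(e)
    e_var = (e - e_mean) @ (e - e_mean) / (n - 1)
    excess = e_var - special.polygamma(1, df / 2.0)
    if excess <= 0:
        return EBHyper(d0=np.inf, s0_sq=float(np.exp(e_mean)))
    d0 = 2.0 * float(_trigamma_inverse(np.array([excess]))[0])
    s0_sq = float(
        np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    )
    return EBHyper(d0=d0, s0_sq=s0_sq)


def _tmixture(
    tstat: np.ndarray, stdev_unscaled: np.ndarray, df: float,
    proportion: float, v0_lim: tuple[float, float],
) -> float:
    """Estimate the prior variance of the coefficient from the top |t| genes."""
    ngenes = len(tstat)
    ntarget = int(np.ceil(proportion / 2.0 * ngenes))
    if ntarget < 1:
        return v0_lim[0]
    p = max(ntarget / ngenes, proportion)
    at = np.abs(tstat)
    order = np.argsort(-at)[:ntarget]
    tt = at[order]
    v1 = stdev_unscaled[order] ** 2
    r = np.arange(1, ntarget + 1)
    p0 = 2.0 * stats.t.sf(tt, df)
    ptarget = ((r - 0.5) / ngenes - (1.0 - p) * p0) / p
    v0 = np.zeros(ntarget)
    pos = ptarget > p0
    if np.any(pos):
        qtarget = stats.t.ppf(ptarget[pos] / 2.0, df)  # negative
        v0[pos] = v1[pos] * ((tt[pos] / qtarget) ** 2 - 1.0)
    v0 = np.clip(v0, v0_lim[0], v0_lim[1])
    return float(v0.mean())


def moderated_de(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    contrast: tuple[str, str] = ("SSc", "healthy"),
    group_col: str = "disease",
    paired: bool = False,
    pair_col: str = "donor",
    prior_proportion: float = 0.01,
    thresholds: DEThresholds = DEThresholds(),
) -> pd.DataFrame:
    """Two-group moderated-t differential expression with lods and BH q.

    Unpaired mode fits, per probe, the two-group difference
    ``mean(contrast[0]) - mean(contrast[1])``; paired mode forms within-pair
    differences (keyed by ``pair_col``) and fits a one-sample mean.  Probe
    variances are shrunk toward an empirical-Bayes prior fitted by moment
    matching on log variances; the moderated t has ``d0 + df_residual``
    degrees of freedom.  lods is the log posterior odds of differential
    expression with prior DE proportion ``prior_proportion``.

    Returns a DataFrame indexed by probe with columns ``log2fc, t, p, q,
    lods, avg_expr, significant`` where ``significant`` applies the
    composite rule in ``thresholds``.
    """
    if list(matrix.columns) != list(meta["sample_id"]):
        meta = meta.set_index("sample_id").loc[list(matrix.columns)].reset_index()
    Y = matrix.to_numpy(dtype=float)
    groups = meta[group_col].astype(str).to_numpy()
    g1, g2 = contrast
    i1 = np.flatnonzero(groups == g1)
    i2 = np.flatnonzero(groups == g2)

    if paired:
        m1 = meta.iloc[i1].set_index(pair_col)["sample_id"]
        m2 = meta.iloc[i2].set_index(pair_col)["sample_id"]
        common = m1.index.intersection(m2.index)
        if len(common) < 2:
            raise DesignError("paired mode needs >= 2 complete pairs")
        d = (
            matrix[m1.loc[common].to_numpy()].to_numpy()
            - matrix[m2.loc[common].to_numpy()].to_numpy()
        )
        n = d.shape[1]
        coef = d.mean(axis=1)
        df_resid = n - 1
        s_sq = d.var(axis=1, ddof=1)
        stdev_unscaled = 1.0 / np.sqrt(n)
    else:
        if len(i1) < 2 or len(i2) < 2:
            raise DesignError("each group needs >= 2 samples")
        n1, n2 = len(i1), len(i2)
        y1, y2 = Y[:, i1], Y[:, i2]
        coef = y1.mean(axis=1) - y2.mean(axis=1)
        df_resid = n1 + n2 - 2
        s_sq = (
            y1.var(axis=1, ddof=1) * (n1 - 1) + y2.var(axis=1, ddof=1) * (n2 - 1)
        ) / df_resid
        stdev_unscaled = np.sqrt(1.0 / n1 + 1.0 / n2)
    if df_resid < 1:
        raise DesignError("zero residual degrees of freedom")

    hyper = fit_variance_prior(s_sq, df=float(df_resid))
    if np.isinf(hyper.d0):
        s_tilde_sq = np.full_like(s_sq, hyper.s0_sq)
        df_total = np.inf
    else:
        s_tilde_sq = (hyper.d0 * hyper.s0_sq + df_resid * s_sq) / (
            hyper.d0 + df_resid
        )
        df_total = hyper.d0 + df_resid

    tstat = coef / (np.sqrt(s_tilde_sq) * stdev_unscaled)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(tstat))
    else:
        p = 2.0 * stats.t.sf(np.abs(tstat), df_total)
    q = multipletests(p, method="fdr_bh")[1]

    # lods (B statistic): posterior log odds of differential expression
    su = np.full_like(coef, stdev_unscaled) if np.isscalar(stdev_unscaled) else stdev_unscaled
    df_mix = 1e6 if np.isinf(df_total) else df_total
    # prior coefficient variance, bounded so the prior sd of the coefficient
    # stays within (0.1, 4) residual-sd units
    v0_lim = (0.1 ** 2 / hyper.s0_sq, 4.0 ** 2 / hyper.s0_sq)
    v0 = _tmixture(tstat, su, df_mix, prior_proportion, v0_lim)
    r = (su ** 2 + v0) / su ** 2
    t2 = tstat ** 2
    if np.isinf(df_total) or df_total > 1e6:
        kernel = t2 * (1.0 - 1.0 / r) / 2.0
    else:
        kernel = (1.0 + df_total) / 2.0 * np.log(
            (t2 + df_total) / (t2 / r + df_total)
        )
    lods = (
        np.log(prior_proportion / (1.0 - prior_proportion))
        - 0.5 * np.log(r) + kernel
    )

    avg_expr = Y.mean(axis=1)
    res = pd.DataFrame(
        {
            "log2fc": coef, "t": tstat, "p": p, "q": q,
            "lods": lods, "avg_expr": avg_expr,
        },
        index=matrix.index,
    )
    res.index.name = "probe"
    res["significant"] = _composite_rule(res, thresholds)
    res.attrs["eb_hyper"] = hyper
    res.attrs["v0"] = v0
    return res


def _composite_rule(res: pd.DataFrame, thr: DEThresholds) -> np.ndarray:
    return (
        (np.abs(res["log2fc"].to_numpy()) > thr.min_abs_log2fc)
        & (res["q"].to_numpy() < thr.max_q)
        & (res["lods"].to_numpy() > thr.min_lods)
        & (res["avg_expr"].to_numpy() > thr.min_avg_expr)
    )


def select_degs(
    results: pd.DataFrame, thresholds: DEThresholds = DEThresholds()
) -> pd.DataFrame:
    """Apply the composite rule; returns selected probes with signed direction."""
    if results.empty:
        return pd.DataFrame(columns=["log2fc", "direction"])
    keep = _composite_rule(results, thresholds)
    out = results.loc[keep, ["log2fc"]].copy()
    out["direction"] = np.sign(out["log2fc"]).astype(int)
    return out


@dataclass(frozen=True)
class SignatureComparison:
    n_base: int
    n_follow: int
    n_overlap: int
    retention_pct: float
    pearson_r: float

    @property
    def retention_pct_rounded(self) -> int:
        return int(round(self.retention_pct))


def compare_signatures(
    deg_base: pd.DataFrame,
    deg_follow: pd.DataFrame,
    lfc_base: pd.Series | None = None,
    lfc_follow: pd.Series | None = None,
) -> SignatureComparison:
    """Overlap, retention and fold-change correlation of two DEG sets.

    ``deg_base``/``deg_follow`` are :func:`select_degs` outputs (indexed by
    probe, with ``log2fc``).  Retention is 100 * |overlap| / |baseline|.
    The Pearson correlation is computed between the two log2FC vectors over
    the union of the DEG sets; fold changes for probes selected in only one
    set are taken from the full per-analysis results if ``lfc_base`` /
    ``lfc_follow`` are given, otherwise the union is restricted to probes
    with fold changes available in both inputs.
    """
    if len(deg_base) == 0:
        raise DesignError("baseline DEG set is empty; retention undefined")
    base_ids = set(deg_base.index)
    follow_ids = set(deg_follow.index)
    n_overlap = len(base_ids & follow_ids)
    retention = 100.0 * n_overlap / len(base_ids)

    union = sorted(base_ids | follow_ids)
    fb = lfc_base if lfc_base is not None else deg_base["log2fc"]
    ff = lfc_follow if lfc_follow is not None else deg_follow["log2fc"]
    both = [u for u in union if u in fb.index and u in ff.index]
    if len(both) >= 2 and fb.loc[both].nunique() > 1 and ff.loc[both].nunique() > 1:
        r = float(stats.pearsonr(fb.loc[both], ff.loc[both])[0])
    else:
        r = float("nan")  # degenerate: too few points or constant fold changes
    return SignatureComparison(
        n_base=len(base_ids), n_follow=len(follow_ids), n_overlap=n_overlap,
        retention_pct=retention, pearson_r=r,
    )


def retention_from_counts(n_base: int, n_overlap: int) -> int:
    """Integer retention percent from reported DEG counts (e.g. 926, 717 -> 77)."""
    if n_base <= 0:
        raise DesignError("baseline count must be positive")
    if not 0 <= n_overlap <= n_base:
        raise DesignError("overlap must be between 0 and the baseline count")
    return int(round(100.0 * n_overlap / n_base))


def collapse_probes_to_genes(
    results: pd.DataFrame, probe_to_gene: pd.Series
) -> pd.DataFrame:
    """Collapse probe-level results to genes, keeping the max-|log2fc| probe."""
    joined = results.join(probe_to_gene.rename("gene"), how="inner")
    idx = (
        joined.assign(_a=np.abs(joined["log2fc"]))
        .sort_values(["gene", "_a"], ascending=[True, False], kind="mergesort")
        .drop_duplicates("gene")
        .index
    )
    out = joined.loc[idx].drop(columns=[]).copy()
    return out.set_index("gene", drop=True).sort_index()
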