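"""Control-based assay statistics for plate-level screen QC.

Implements the standard screening-quality statistics computed from
negative-control (non-targeting shRNA) and positive-control (ACTA2 shRNA)
wells: the Z'-factor (Zhang et al. 1999), the assay window (fold ratio of
control means), control-normalised percent inhibition, knockdown-panel
summaries, and simple endpoint group comparisons.  Sample standard
deviations use the n-1 denominator throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .synthgen import ROLE_NEG, ROLE_POS


class StatError(ValueError):
    """Raised for degenerate statistical inputs."""


@dataclass(frozen=True)
class QCGates:
    """Pass/fail gates for plate QC (defaults: Z' >= 0.3, window >= 2-fold)."""

    min_zprime: float = 0.3
    min_window: float = 2.0


@dataclass(frozen=True)
class QCReport:
    donor: str
    z_prime: float
    window: float
    n_neg: int
    n_pos: int
    passed: bool


def _as_vector(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float).ravel()
    if v.size == 0:
        raise StatError(f"{name} is empty")
    if not np.all(np.isfinite(v)):
        raise StatError(f"{name} contains non-finite values")
    return v


def zprime(neg_scores, pos_scores) -> float:
    """Z'-factor: 1 - 3*(sd_neg + sd_pos) / |mean_neg - mean_pos|.

    The screening-assay quality statistic of Zhang et al. (1999); 1 in the
    noiseless limit, >= 0.5 is conventionally an excellent assay.  Requires
    at least two wells per arm and distinct arm means.
    """
    neg = _as_vector(neg_scores, "neg_scores")
    pos = _as_vector(pos_scores, "pos_scores")
    if neg.size < 2 or pos.size < 2:
        raise StatError("each control arm needs >= 2 wells")
    mu_n, mu_p = neg.mean(), pos.mean()
    if mu_n == mu_p:
        raise StatError("control arms have identical means; separation undefined")
    return float(1.0 - 3.0 * (neg.std(ddof=1) + pos.std(ddof=1)) / abs(mu_n - mu_p))


def assay_window(neg_scores, pos_scores) -> float:
    """Assay window: ratio of negative- to positive-control mean score.

    The fold reduction of the ASMA score achieved by the positive-control
    shRNA; larger is more dynamic range.
    """
    neg = _as_vector(neg_scores, "neg_scores")
    pos = _as_vector(pos_scores, "pos_scores")
    mu_p = pos.mean()
    if mu_p <= 0:
        raise StatError(f"positive-control mean must be > 0, got {mu_p}")
    return float(neg.mean() / mu_p)


def pct_inhibition(test_scores, ctrl_scores, use_median: bool = False) -> float:
    """Percent inhibition of the test condition vs the negative control.

    100 * (1 - mean(test)/mean(ctrl)); negative values indicate enhancement.
    ``use_median`` switches both sides to medians.
    """
    test = _as_vector(test_scores, "test_scores")
    ctrl = _as_vector(ctrl_scores, "ctrl_scores")
    agg = np.median if use_median else np.mean
    c = agg(ctrl)
    if c <= 0:
        raise StatError(f"control aggregate must be > 0, got {c}")
    return float(100.0 * (1.0 - agg(test) / c))


def knockdown_pct(relative_expression: float) -> float:
    """Knockdown percentage from relative target expression.

    100 * (1 - relative_expression); values above 1 (upregulation) give
    negative knockdown, which is allowed.
    """
    rel = np.asarray(relative_expression, dtype=float)
    if np.any(rel < 0):
        raise StatError("relative expression must be >= 0")
    out = 100.0 * (1.0 - rel)
    return float(out) if out.ndim == 0 else out


def summarize_knockdown(
    panel: pd.DataFrame, thresholds=(60.0, 75.0)
) -> pd.DataFrame:
    """Fraction of shRNAs exceeding each knockdown threshold, per donor and pooled.

    ``panel`` needs columns ``shrna_id, donor, knockdown_pct``.  For each
    threshold t, reports the fraction of shRNAs with knockdown strictly
    greater than t ("more than t%"), for each donor separately and pooled
    over all (shrna, donor) measurements.
    """
    if panel.empty:
        raise StatError("empty knockdown panel")
    for col in ("shrna_id", "donor", "knockdown_pct"):
        if col not in panel.columns:
            raise StatError(f"panel missing column {col!r}")
    thresholds = [float(t) for t in thresholds]
    for t in thresholds:
        if not 0.0 <= t <= 100.0:
            raise StatError(f"threshold {t} outside [0, 100]")

    rows = []
    groups = [("pooled", panel)] + [
        (donor, g) for donor, g in panel.groupby("donor", sort=True)
    ]
    for label, g in groups:
        kd = g["knockdown_pct"].to_numpy(dtype=float)
        for t in thresholds:
            rows.append(
                dict(
                    donor=label, threshold=t,
                    fraction=float((kd > t).mean()), n=len(kd),
                )
            )
    return pd.DataFrame(rows)


def group_difference(scores_a, scores_b) -> tuple[float, float]:
    """Difference of group means with a two-tailed Welch t-test p-value.

    Returns ``(mean(a) - mean(b), p)``.  When both groups are constant and
    equal, the difference is 0 and p = 1 (documented degenerate behaviour).
    """
    a = _as_vector(scores_a, "scores_a")
    b = _as_vector(scores_b, "scores_b")
    if a.size < 2 or b.size < 2:
        raise StatError("each group needs >= 2 values")
    diff = float(a.mean() - b.mean())
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return diff, 1.0 if diff == 0 else 0.0
    res = sps.ttest_ind(a, b, equal_var=False)
    return diff, float(res.pvalue)


# ---------------------------------------------------------------------------
# table-level drivers
# ---------------------------------------------------------------------------

def qc_screen(
    plate_map: pd.DataFrame,
    well_table: pd.DataFrame,
    gates: QCGates = QCGates(),
) -> pd.DataFrame:
    """Per-donor plate QC from control wells.

    Joins the plate map onto the well table, computes Z' and assay window
    per donor from the negative/positive control wells, and applies the
    gates.  Returns one row per donor: ``donor, z_prime, window, n_neg,
    n_pos, passed``.
    """
    merged = well_table.merge(
        plate_map[["plate", "well", "shrna_id", "gene", "role"]],
        on=["plate", "well"], how="left", validate="one_to_one",
    )
    if merged["role"].isna().any():
        raise StatError("well table contains wells absent from the plate map")
    reports = []
    for donor, g in merged.groupby("donor", sort=True):
        neg = g.loc[g["role"] == ROLE_NEG, "score"].to_numpy()
        pos = g.loc[g["role"] == ROLE_POS, "score"].to_numpy()
        zp = zprime(neg, pos)
        win = assay_window(neg, pos)
        reports.append(
            QCReport(
                donor=donor, z_prime=zp, window=win,
                n_neg=len(neg), n_pos=len(pos),
                passed=bool(zp >= gates.min_zprime and win >= gates.min_window),
            )
        )
    return pd.DataFrame([r.__dict__ for r in reports])


def inhibition_table(
    plate_map: pd.DataFrame, well_table: pd.DataFrame, use_median: bool = False
) -> pd.DataFrame:
    """Per-(shRNA, donor) percent inhibition vs the negative control.

    Each test shRNA's well scores are compared against the same donor's
    negative-control wells.  Returns ``shrna_id, gene, donor,
    pct_inhibition``.
    """
    merged = well_table.merge(
        plate_map[["plate", "well", "shrna_id", "gene", "role"]],
        on=["plate", "well"], how="left", validate="one_to_one",
    )
    rows = []
    for donor, g in merged.groupby("donor", sort=True):
        ctrl = g.loc[g["role"] == ROLE_NEG, "score"].to_numpy()
        tests = g[g["role"] == "test"]
        for (sid, gene), tg in tests.groupby(["shrna_id", "gene"], sort=True):
            rows.append(
                dict(
                    shrna_id=sid, gene=gene, donor=donor,
                    pct_inhibition=pct_inhibition(
                        tg["score"].to_numpy(), ctrl, use_median=use_median
                    ),
                )
            )
    return pd.DataFrame(rows)
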