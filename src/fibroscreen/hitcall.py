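"""Cross-donor aggregation, ranking and tiered hit classification.

A gene's evidence is the vector of its shRNAs' percent-inhibition values,
each averaged across donors.  Tiers count shRNAs crossing inhibition
thresholds:

* very_strong — at least ``n_very_strong`` shRNAs with more than ``t_hi``%
  inhibition (the MKL1-like phenotype);
* strong — at least ``n_strong`` shRNAs with more than ``t_hi``%;
* moderate — at least one shRNA above ``t_hi``% plus at least one in the
  open interval (``t_lo``, ``t_mid``)%;
* weak — at least ``n_weak`` shRNAs in the open interval (``t_lo``,
  ``t_hi``)%;
* none — otherwise.

Tiers are evaluated in that order of precedence so a gene receives its
best-supported label.  "More than" is a strict inequality throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


class HitCallError(ValueError):
    pass


TIER_ORDER = ["very_strong", "strong", "moderate", "weak", "none"]
_TIER_RANK = {t: i for i, t in enumerate(TIER_ORDER)}


@dataclass(frozen=True)
class TierRules:
    t_hi: float = 35.0
    t_mid: float = 30.0
    t_lo: float = 25.0
    n_strong: int = 2
    n_weak: int = 3
    n_very_strong: int = 8

    def validate(self) -> None:
        if not self.t_lo < self.t_mid < self.t_hi:
            raise HitCallError("thresholds must satisfy t_lo < t_mid < t_hi")
        if min(self.n_strong, self.n_weak, self.n_very_strong) < 1:
            raise HitCallError("tier counts must be >= 1")


@dataclass(frozen=True)
class HitCall:
    gene: str
    tier: str
    n_gt_hi: int
    n_in_lo_mid: int
    n_in_lo_hi: int
    best_mean: float


def aggregate_inhibition(records: pd.DataFrame) -> pd.DataFrame:
    """Average per-shRNA inhibition over donors and rank descending.

    ``records`` has columns ``shrna_id, gene, donor, pct_inhibition`` with
    one row per (shrna, donor).  The cross-donor mean is unweighted; ties in
    the ranking are broken by shrna_id lexicographic order.  shRNAs with no
    finite measurement in any donor are dropped with a warning.
    """
    if records.empty:
        raise HitCallError("empty inhibition record table")
    for col in ("shrna_id", "gene", "donor", "pct_inhibition"):
        if col not in records.columns:
            raise HitCallError(f"records missing column {col!r}")
    dup = records.duplicated(["shrna_id", "donor"])
    if dup.any():
        raise HitCallError("more than one record per (shrna, donor)")

    vals = pd.to_numeric(records["pct_inhibition"], errors="coerce")
    usable = records.assign(pct_inhibition=vals)
    dead = usable.groupby("shrna_id")["pct_inhibition"].apply(
        lambda s: s.isna().all()
    )
    if dead.any():
        warnings.warn(
            f"dropping {int(dead.sum())} shRNA(s) with no usable measurement",
            stacklevel=2,
        )
        usable = usable[~usable["shrna_id"].isin(dead[dead].index)]
    if usable.empty:
        raise HitCallError("no usable inhibition records")

    agg = (
        usable.groupby(["shrna_id", "gene"], sort=False)["pct_inhibition"]
        .agg(mean_inhibition="mean", n_donors="count")
        .reset_index()
        .sort_values(
            ["mean_inhibition", "shrna_id"], ascending=[False, True],
            kind="mergesort",
        )
        .reset_index(drop=True)
    )
    agg["rank"] = np.arange(1, len(agg) + 1)
    return agg


def classify_gene(shrna_means, rules: TierRules = TierRules()) -> HitCall:
    """Classify one gene from its per-shRNA mean-inhibition vector."""
    rules.validate()
    v = np.asarray(shrna_means, dtype=float).ravel()
    if v.size == 0:
        raise HitCallError("empty shRNA vector")
    if not np.all(np.isfinite(v)):
        raise HitCallError("non-finite inhibition values")

    n_gt_hi = int((v > rules.t_hi).sum())
    n_in_lo_mid = int(((v > rules.t_lo) & (v < rules.t_mid)).sum())
    n_in_lo_hi = int(((v > rules.t_lo) & (v < rules.t_hi)).sum())

    if n_gt_hi >= rules.n_very_strong:
        tier = "very_strong"
    elif n_gt_hi >= rules.n_strong:
        tier = "strong"
    elif n_gt_hi >= 1 and n_in_lo_mid >= 1:
        tier = "moderate"
    elif n_in_lo_hi >= rules.n_weak:
        tier = "weak"
    else:
        tier = "none"

    return HitCall(
        gene="", tier=tier, n_gt_hi=n_gt_hi, n_in_lo_mid=n_in_lo_mid,
        n_in_lo_hi=n_in_lo_hi, best_mean=float(v.max()),
    )


def call_hits(
    records: pd.DataFrame, rules: TierRules = TierRules()
) -> pd.DataFrame:
    """Aggregate, classify and rank all genes in an inhibition record table.

    Returns one row per gene (``gene, tier, n_gt_hi, n_in_lo_mid,
    n_in_lo_hi, best_mean, rank``), sorted by tier precedence then by best
    shRNA mean inhibition descending.
    """
    agg = aggregate_inhibition(records)
    rows = []
    for gene, g in agg.groupby("gene", sort=True):
        call = classify_gene(g["mean_inhibition"].to_numpy(), rules)
        rows.append(
            dict(
                gene=gene, tier=call.tier, n_gt_hi=call.n_gt_hi,
                n_in_lo_mid=call.n_in_lo_mid, n_in_lo_hi=call.n_in_lo_hi,
                best_mean=call.best_mean,
            )
        )
    out = pd.DataFrame(rows)
    out["_tier_rank"] = out["tier"].map(_TIER_RANK)
    out = (
        out.sort_values(
            ["_tier_rank", "best_mean", "gene"],
            ascending=[True, False, True], kind="mergesort",
        )
        .drop(columns="_tier_rank")
        .reset_index(drop=True)
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return out
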