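"""Downsampling power analysis for the pooled screen.

Estimates how many barcoded replicates per genotype are needed to detect a
growth difference: repeatedly sample n unique barcodes per genotype from the
no-drug final-time-point frame, rerun the genotype contrast analysis (one
model per downsample, BH over that downsample's own contrast family), and
count how often the target pair — all-yeast (YYY) versus all-null (NNN) —
passes the detection rule (adjusted p < alpha and |effect size| > floor).
Detection frequencies get exact Clopper-Pearson binomial intervals.

Reproducibility: one master seed; each (concentration, n, replicate) gets
its own seeded substream, so results do not depend on execution order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .barcode import BarcodeError
from .growth import GenotypeContrastModel, bh_adjust

__all__ = [
    "DetectionRule",
    "clopper_pearson",
    "downsample_once",
    "power_curve",
    "sampling_frame_from_counts",
]


@dataclass(frozen=True)
class DetectionRule:
    """What counts as a detection for the target genotype pair."""

    alpha: float = 0.05
    es_min: float = 0.2
    pair: tuple[str, str] = ("YYY", "NNN")

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1) or self.es_min < 0:
            raise BarcodeError("invalid detection thresholds")


def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval for k successes in n trials.

    low = Beta^{-1}(alpha/2; k, n-k+1) (0 when k=0);
    high = Beta^{-1}(1-alpha/2; k+1, n-k) (1 when k=n).
    """
    if n < 1 or not 0 <= k <= n:
        raise BarcodeError(f"invalid Clopper-Pearson input k={k}, n={n}")
    a = 1.0 - level
    low = 0.0 if k == 0 else float(stats.beta.ppf(a / 2, k, n - k + 1))
    high = 1.0 if k == n else float(stats.beta.ppf(1 - a / 2, k + 1, n - k))
    return low, high


def _frame_from_table(norm: pd.DataFrame) -> dict[str, np.ndarray]:
    return {
        g: sub["barcode"].unique() for g, sub in norm.groupby("genotype", sort=True)
    }


def downsample_once(
    norm: pd.DataFrame,
    n: int,
    rule: DetectionRule,
    rng: np.random.Generator,
    frame: dict[str, np.ndarray] | None = None,
    log2: bool = True,
) -> bool:
    """One downsampling replicate at one condition.

    ``norm`` is the normalized table restricted to a single (time,
    concentration); ``frame`` maps genotype to the barcodes eligible for
    sampling (the no-drug final-time-point occupants; defaults to the
    barcodes present in ``norm``).  Samples n unique barcodes per genotype,
    refits the genotype model on the sampled barcodes, BH-adjusts within
    this downsample's own contrast family, and reports whether the target
    pair passes the rule.  A pair genotype dropping below two sampled values
    is a non-detection, not an error.
    """
    if frame is None:
        frame = _frame_from_table(norm)
    sampled: list[np.ndarray] = []
    for g in sorted(frame):
        pool = np.asarray(frame[g])
        if len(pool) < n:
            raise BarcodeError(
                f"genotype {g} has only {len(pool)} eligible barcodes, need {n}"
            )
        sampled.append(rng.choice(pool, size=n, replace=False))
    chosen = set(np.concatenate(sampled))
    sub = norm[norm["barcode"].isin(chosen)]
    a, b = rule.pair
    try:
        res = GenotypeContrastModel(
            sub["value"].to_numpy(), sub["genotype"].to_numpy(), log2=log2
        ).fit()
    except BarcodeError:
        return False
    if a not in res.means.index or b not in res.means.index:
        return False
    contrasts = bh_adjust(res.contrasts())
    row = contrasts[
        (contrasts["genotype_a"] == a) & (contrasts["genotype_b"] == b)
        | (contrasts["genotype_a"] == b) & (contrasts["genotype_b"] == a)
    ].iloc[0]
    return bool(
        row["p_adjusted"] < rule.alpha and abs(row["effect_size"]) > rule.es_min
    )


def power_curve(
    norm: pd.DataFrame,
    n_values: list[int],
    replicates: int = 500,
    rule: DetectionRule | None = None,
    seed: int = 0,
    frame: dict[str, np.ndarray] | None = None,
    log2: bool = True,
) -> pd.DataFrame:
    """Detection power versus barcodes-per-genotype, per concentration.

    ``norm`` may span several concentrations at the final time point (if a
    ``time_h`` column is present only the latest time is used).  Power at
    (n, concentration) is the detection fraction over ``replicates``
    independent downsamples, with a 95% Clopper-Pearson interval.
    """
    rule = rule or DetectionRule()
    if replicates < 1:
        raise BarcodeError("replicates must be >= 1")
    if any(n < 2 for n in n_values):
        raise BarcodeError("n_values must be >= 2 barcodes per genotype")
    if "time_h" in norm.columns and norm["time_h"].nunique() > 1:
        norm = norm[norm["time_h"] == norm["time_h"].max()]
    if "mms_pct" in norm.columns:
        conditions = [c for c in sorted(norm["mms_pct"].unique()) if c > 0]
        subsets = {c: norm[norm["mms_pct"] == c] for c in conditions}
    else:
        conditions = [np.nan]
        subsets = {np.nan: norm}
    rows = []
    for c in conditions:
        sub = subsets[c]
        c_key = 0 if np.isnan(c) else int(round(c * 1e6))
        for n in n_values:
            detections = 0
            for rep in range(replicates):
                ss = np.random.SeedSequence(seed, spawn_key=(c_key, int(n), rep))
                rng = np.random.default_rng(ss)
                if downsample_once(sub, n, rule, rng, frame=frame, log2=log2):
                    detections += 1
            power = detections / replicates
            lo, hi = clopper_pearson(detections, replicates)
            rows.append(
                {
                    "n_barcodes": n,
                    "mms_pct": c,
                    "detections": detections,
                    "replicates": replicates,
                    "power": power,
                    "ci_low": lo,
                    "ci_high": hi,
                }
            )
    return pd.DataFrame(rows)


def sampling_frame_from_counts(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    time_h: float | None = None,
) -> dict[str, np.ndarray]:
    """Eligible barcodes per genotype: present in the 0-MMS sample at the
    final (or given) time point, the downsampling frame of the analysis."""
    t = time_h if time_h is not None else meta["time_h"].max()
    ref = meta[(meta["time_h"] == t) & (meta["mms_pct"] == 0)]
    if ref.empty:
        raise BarcodeError(f"no 0-MMS sample at time point {t} h")
    sid = ref["sample_id"].iloc[0]
    present = counts[counts[sid] > 0]
    return {
        g: sub.index.to_numpy() for g, sub in present.groupby("genotype", sort=True)
    }
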