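"""Normalized growth analysis and genotype contrasts.

The analysis follows the screen's two-step normalization: each barcode's
read count becomes a within-sample frequency, which is then divided by the
same barcode's frequency at the same time point without drug.  On the
analysis scale (log2 by default — the values are multiplicative ratios), a
one-way linear model of normalized abundance on genotype is fitted per
(time, concentration) condition, with barcodes as replicates.  Genotype
means are the model's marginal means; all pairwise contrasts are tested
with the pooled residual variance (two-sided t on the residual df), BH FDR
is applied across the full family from all conditions, and significance
requires both adjusted p < alpha and |effect size| > a floor, where effect
size is the contrast estimate divided by the model's residual SD.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .barcode import BarcodeError

__all__ = [
    "relative_freq",
    "mms_normalize",
    "GenotypeContrastModel",
    "GenotypeContrastResults",
    "fit_and_contrast",
    "bh_adjust",
    "significant_pairs",
    "analyze_screen",
]

CONTRAST_COLUMNS = [
    "genotype_a",
    "genotype_b",
    "time_h",
    "mms_pct",
    "estimate",
    "se",
    "df",
    "t",
    "p_value",
    "p_adjusted",
    "effect_size",
]


def relative_freq(counts: pd.Series) -> pd.Series:
    """Within-sample barcode frequencies (counts / total)."""
    total = counts.sum()
    if total <= 0:
        raise BarcodeError("sample has no reads")
    return counts / total


def mms_normalize(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    include_reference: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Normalize barcode frequencies to the matched no-drug sample.

    ``counts`` is the barcode x sample matrix with a leading ``genotype``
    column; ``meta`` has sample_id, time_h, mms_pct.  For every sample with
    mms_pct > 0 there must be a 0-MMS sample at the same time point; the
    normalized value of barcode b is freq(b, c, t) / freq(b, 0, t).
    Barcodes with zero frequency in the reference (or target) sample are
    dropped from that condition and tallied.

    Returns a long table (barcode, genotype, time_h, mms_pct, value) and a
    dict of drop counts keyed by (time_h, mms_pct, reason).
    """
    meta = meta.reset_index(drop=True)
    genotype = counts["genotype"]
    sample_cols = [c for c in counts.columns if c != "genotype"]
    missing = set(meta["sample_id"]) - set(sample_cols)
    if missing:
        raise BarcodeError(f"count matrix lacks samples: {sorted(missing)}")

    ref_by_time: dict[float, str] = {}
    for _, row in meta.iterrows():
        if row["mms_pct"] == 0:
            ref_by_time[row["time_h"]] = row["sample_id"]

    freqs = {sid: relative_freq(counts[sid]) for sid in meta["sample_id"]}
    records = []
    drops: dict = {}
    for _, row in meta.iterrows():
        t, c, sid = row["time_h"], row["mms_pct"], row["sample_id"]
        if c == 0 and not include_reference:
            continue
        if t not in ref_by_time:
            raise BarcodeError(f"no 0-MMS sample at time point {t} h")
        ref = freqs[ref_by_time[t]]
        f = freqs[sid]
        ok_ref = ref > 0
        ok_target = f > 0
        keep = ok_ref & ok_target
        drops[(t, c, "zero_at_reference")] = int((~ok_ref).sum())
        drops[(t, c, "zero_at_target")] = int((ok_ref & ~ok_target).sum())
        value = (f[keep] / ref[keep]).to_numpy()
        records.append(
            pd.DataFrame(
                {
                    "barcode": counts.index[keep],
                    "genotype": genotype[keep].to_numpy(),
                    "time_h": t,
                    "mms_pct": c,
                    "value": value,
                }
            )
        )
    if records:
        table = pd.concat(records, ignore_index=True)
    else:
        table = pd.DataFrame(columns=["barcode", "genotype", "time_h", "mms_pct", "value"])
    return table, drops


@dataclass
class GenotypeContrastResults:
    """Fit of a one-way genotype model at one condition.

    ``means`` are the genotype marginal means on the analysis scale;
    ``resid_sd`` the pooled residual SD; contrasts are differences of means
    tested against t(df_resid).
    """

    means: pd.Series
    nobs: pd.Series
    resid_sd: float
    df_resid: int
    scale: str
    excluded: list = field(default_factory=list)

    @property
    def genotypes(self) -> list[str]:
        return list(self.means.index)

    def contrasts(self, pairs: list[tuple[str, str]] | None = None) -> pd.DataFrame:
        """Pairwise genotype contrasts (all pairs by default).

        estimate = mean_a - mean_b; se uses the pooled residual variance;
        effect_size = estimate / residual SD (0 where both are 0).
        """
        if pairs is None:
            pairs = list(itertools.combinations(self.genotypes, 2))
        rows = []
        for a, b in pairs:
            if a not in self.means.index or b not in self.means.index:
                raise BarcodeError(f"genotype pair ({a}, {b}) not in the fitted model")
            est = self.means[a] - self.means[b]
            se = self.resid_sd * np.sqrt(1.0 / self.nobs[a] + 1.0 / self.nobs[b])
            if se > 0:
                tval = est / se
                p = 2.0 * stats.t.sf(abs(tval), self.df_resid)
                es = est / self.resid_sd
            elif est == 0:  # degenerate: no residual variation, no difference
                tval, p, es = 0.0, 1.0, 0.0
            else:
                tval = np.inf if est > 0 else -np.inf
                p, es = 0.0, np.sign(est) * np.inf
            rows.append(
                {
                    "genotype_a": a,
                    "genotype_b": b,
                    "estimate": est,
                    "se": se,
                    "df": self.df_resid,
                    "t": tval,
                    "p_value": p,
                    "p_adjusted": np.nan,
                    "effect_size": es,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "One-way genotype model of normalized abundance",
            f"scale: {self.scale}   groups: {len(self.means)}   "
            f"obs: {int(self.nobs.sum())}   residual SD: {self.resid_sd:.4g}   "
            f"df: {self.df_resid}",
        ]
        if self.excluded:
            lines.append(f"excluded (<2 barcodes): {', '.join(self.excluded)}")
        lines.append(f"{'genotype':>10} {'n':>6} {'mean':>12}")
        for g in self.genotypes:
            lines.append(f"{g:>10} {int(self.nobs[g]):>6} {self.means[g]:>12.5f}")
        return "\n".join(lines)


class GenotypeContrastModel:
    """One-way linear model of normalized barcode abundance on genotype.

    Values are log2-transformed by default (ratios are multiplicative and
    the transform stabilizes variance); barcodes are the replicates.
    Genotypes with fewer than two barcodes cannot contribute a variance and
    are excluded from the fit (recorded on the results).
    """

    def __init__(self, values, genotypes, log2: bool = True):
        values = np.asarray(values, dtype=float)
        genotypes = np.asarray(genotypes, dtype=object)
        if values.shape != genotypes.shape:
            raise BarcodeError("values and genotypes must have equal length")
        if log2:
            if (values <= 0).any():
                raise BarcodeError("log2 scale requires strictly positive values")
            values = np.log2(values)
        self.endog = values
        self.groups = genotypes
        self.scale = "log2" if log2 else "identity"

    @classmethod
    def from_table(
        cls,
        norm: pd.DataFrame,
        time_h: float | None = None,
        mms_pct: float | None = None,
        log2: bool = True,
    ) -> "GenotypeContrastModel":
        sub = norm
        if time_h is not None:
            sub = sub[sub["time_h"] == time_h]
        if mms_pct is not None:
            sub = sub[sub["mms_pct"] == mms_pct]
        return cls(sub["value"].to_numpy(), sub["genotype"].to_numpy(), log2=log2)

    def fit(self) -> GenotypeContrastResults:
        labels, inverse = np.unique(self.groups, return_inverse=True)
        counts = np.bincount(inverse)
        keep = counts >= 2
        excluded = [str(l) for l in labels[~keep]]
        labels_kept = labels[keep]
        if len(labels_kept) < 2:
            raise BarcodeError("need >= 2 genotypes with >= 2 barcodes each")
        mask = keep[inverse]
        y = self.endog[mask]
        _, inv = np.unique(self.groups[mask], return_inverse=True)
        n_g = np.bincount(inv)
        sums = np.bincount(inv, weights=y)
        means = sums / n_g
        rss = float(((y - means[inv]) ** 2).sum())
        df = int(len(y) - len(labels_kept))
        resid_sd = float(np.sqrt(rss / df)) if df > 0 else 0.0
        return GenotypeContrastResults(
            means=pd.Series(means, index=labels_kept),
            nobs=pd.Series(n_g, index=labels_kept),
            resid_sd=resid_sd,
            df_resid=df,
            scale=self.scale,
            excluded=excluded,
        )


def fit_and_contrast(
    norm: pd.DataFrame,
    pairs: list[tuple[str, str]] | None = None,
    log2: bool = True,
) -> pd.DataFrame:
    """Fit the genotype model and emit pairwise contrasts per condition.

    ``norm`` is the long normalized table; one model is fitted for every
    (time_h, mms_pct) present and the contrast frames are concatenated with
    those labels attached.  ``p_adjusted`` is NaN until :func:`bh_adjust`.
    """
    frames = []
    for (t, c), sub in norm.groupby(["time_h", "mms_pct"], sort=True):
        res = GenotypeContrastModel.from_table(sub, log2=log2).fit()
        frame = res.contrasts(pairs=pairs)
        frame.insert(2, "time_h", t)
        frame.insert(3, "mms_pct", c)
        frames.append(frame)
    if not frames:
        return pd.DataFrame(columns=CONTRAST_COLUMNS)
    return pd.concat(frames, ignore_index=True)[CONTRAST_COLUMNS]


def bh_adjust(results: pd.DataFrame) -> pd.DataFrame:
    """Benjamini-Hochberg step-up over the pooled contrast family.

    Adjusts across every row — all pairs, time points and concentrations
    together — as one family.
    """
    out = results.copy()
    if len(out):
        out["p_adjusted"] = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
    return out


def significant_pairs(
    results: pd.DataFrame, alpha: float = 0.05, es_min: float = 0.2
) -> pd.DataFrame:
    """Keep contrasts with adjusted p < ``alpha`` and |effect size| > ``es_min``."""
    if results["p_adjusted"].isna().any():
        raise BarcodeError("run bh_adjust before filtering for significance")
    keep = (results["p_adjusted"] < alpha) & (results["effect_size"].abs() > es_min)
    return results[keep].reset_index(drop=True)


def analyze_screen(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    alpha: float = 0.05,
    es_min: float = 0.2,
    log2: bool = True,
) -> dict:
    """Full per-condition analysis: normalize, fit, adjust, filter.

    Returns ``normalized`` (long table), ``contrasts`` (BH-adjusted, all
    conditions pooled), ``significant`` (filtered), and ``drops``.
    """
    norm, drops = mms_normalize(counts, meta)
    contrasts = bh_adjust(fit_and_contrast(norm, log2=log2))
    sig = significant_pairs(contrasts, alpha=alpha, es_min=es_min)
    return {
        "normalized": norm,
        "contrasts": contrasts,
        "significant": sig,
        "drops": drops,
    }
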