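"""Two-state conformational entropy and the Region x Group factorial model.

Entropy: per-residue RMSF values are binned into two conformational states
(ordered iff RMSF < threshold, default 3 Å) and S = -sum_i p_i ln p_i over
the state probabilities, so 0 <= S <= ln 2 nats.

Energetics inference: long-format pairing-energy observations (Energy,
Region, Group, replicate, time) are fitted with the full-interaction OLS
model Energy ~ Region + Group + Region:Group, and each region's
low-minus-high group difference is tested as a linear contrast against the
full-model residual variance.  On balanced data the contrast estimate
equals the raw cell-mean difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf

__all__ = [
    "EntropyConfig",
    "EntropyResult",
    "ContrastResult",
    "ZeroVarianceError",
    "conformational_entropy",
    "validate_energy_table",
    "fit_factorial_model",
    "contrast_test",
    "delta_energy",
    "two_sample_t",
    "paired_t",
    "simple_regression",
    "table1_summary",
]

REGION_LEVELS = ("Region1", "Region2", "Region3")
GROUP_LEVELS = ("low", "high")


class ZeroVarianceError(ValueError):
    """A t statistic is undefined because the sample variance is zero."""


@dataclass(frozen=True)
class EntropyConfig:
    """Ordered/disordered binning rule (natural log)."""

    threshold_A: float = 3.0

    def __post_init__(self):
        if self.threshold_A <= 0:
            raise ValueError("entropy threshold must be positive")


@dataclass(frozen=True)
class EntropyResult:
    p_ordered: float
    p_disordered: float
    S: float  # nats
    n_ordered: int
    n_disordered: int


@dataclass(frozen=True)
class ContrastResult:
    region: str
    delta_e: float  # mean(low) - mean(high), kcal/mol
    se: float
    t: float
    p: float
    df: int


def conformational_entropy(rmsf_values: np.ndarray,
                           config: EntropyConfig = EntropyConfig(),
                           ) -> EntropyResult:
    """Two-state entropy of an RMSF profile (ordered iff rmsf < threshold)."""
    vals = np.asarray(rmsf_values, dtype=float)
    if vals.size == 0:
        raise ValueError("empty RMSF profile")
    n_dis = int(np.sum(vals >= config.threshold_A))
    n_ord = int(vals.size - n_dis)
    p_ord = n_ord / vals.size
    p_dis = n_dis / vals.size
    S = 0.0
    for p in (p_ord, p_dis):
        if p > 0:
            S -= p * np.log(p)
    return EntropyResult(p_ord, p_dis, float(S), n_ord, n_dis)


# ---------------------------------------------------------------------------
# Factorial model and contrasts
# ---------------------------------------------------------------------------

def validate_energy_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format 3x2 design: all six cells populated, no NaNs."""
    need = {"energy", "region", "group"}
    missing = need - set(table.columns)
    if missing:
        raise ValueError(f"energy table missing columns: {sorted(missing)}")
    if table["energy"].isna().any():
        raise ValueError("energy table contains missing energies")
    for region in REGION_LEVELS:
        for group in GROUP_LEVELS:
            n = int(((table["region"] == region)
                     & (table["group"] == group)).sum())
            if n == 0:
                raise ValueError(f"empty design cell ({region}, {group})")
    return table


def fit_factorial_model(table: pd.DataFrame):
    """OLS fit of Energy ~ Region * Group with treatment coding.

    Reference levels are (Region1, high); the returned statsmodels results
    object exposes coefficients, residual variance and cell-mean predictions
    (via ``predict``).
    """
    validate_energy_table(table)
    formula = ('energy ~ C(region, Treatment("Region1")) '
               '* C(group, Treatment("high"))')
    return smf.ols(formula, data=table).fit()


def _contrast_vector(fit, region: str) -> np.ndarray:
    """L such that L @ beta = mean(region, low) - mean(region, high)."""
    names = list(fit.params.index)
    L = np.zeros(len(names))
    group_term = 'C(group, Treatment("high"))[T.low]'
    if group_term not in names:
        raise ValueError("fit lacks the group main effect; wrong model?")
    L[names.index(group_term)] = 1.0
    inter = (f'C(region, Treatment("Region1"))[T.{region}]'
             f':C(group, Treatment("high"))[T.low]')
    if inter in names:
        L[names.index(inter)] = 1.0
    elif region != "Region1":
        raise ValueError(f"region {region!r} is not a level of the fit")
    return L


def contrast_test(fit, region: str) -> ContrastResult:
    """Low-minus-high contrast for one region under the full linear model.

    Estimate L·β̂, SE from the full-model residual variance, two-sided t
    test with df = n - 6.
    """
    L = _contrast_vector(fit, region)
    res = fit.t_test(L)
    return ContrastResult(
        region=region,
        delta_e=float(np.ravel(res.effect)[0]),
        se=float(np.ravel(res.sd)[0]),
        t=float(np.ravel(res.tvalue)[0]),
        p=float(np.ravel(res.pvalue)[0]),
        df=int(res.df_denom),
    )


def delta_energy(mean_low: float, mean_high: float) -> float:
    """Energy difference from the low- to the high-ion system (kcal/mol)."""
    if not (np.isfinite(mean_low) and np.isfinite(mean_high)):
        raise ValueError("means must be finite")
    return mean_low - mean_high


def two_sample_t(x, y, variant: str = "welch") -> tuple[float, float, float]:
    """Two-sample t test; Welch by default, 'pooled' for equal variances."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    if variant not in ("welch", "pooled"):
        raise ValueError(f"unknown variant {variant!r}")
    res = scipy.stats.ttest_ind(x, y, equal_var=(variant == "pooled"))
    return float(res.statistic), float(res.df), float(res.pvalue)


def paired_t(differences, alternative: str = "two-sided"
             ) -> tuple[float, int, float]:
    """One-sample t of paired differences against zero.

    'greater' tests whether the differences exceed zero.  Zero-variance
    differences leave t undefined and raise :class:`ZeroVarianceError`.
    """
    d = np.asarray(differences, dtype=float)
    if d.size < 2:
        raise ValueError("paired t needs n >= 2 differences")
    if np.ptp(d) == 0:
        if d[0] != 0:
            raise ZeroVarianceError(
                "all paired differences identical and nonzero: t is infinite"
            )
        # all differences exactly zero: t = 0 by convention
        return 0.0, int(d.size - 1), 1.0
    res = scipy.stats.ttest_1samp(d, 0.0, alternative=alternative)
    return float(res.statistic), int(d.size - 1), float(res.pvalue)


def simple_regression(x, y) -> tuple[float, float, float]:
    """Least-squares line y ~ x; returns (slope, intercept, r_squared).

    A constant response has, by convention, slope 0 and R² = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("regression needs n >= 3 paired points")
    if np.ptp(y) == 0:
        return 0.0, float(y.mean()), 0.0
    res = scipy.stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)


def table1_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Region-level summary: cell means/SDs, low-minus-high ΔE, contrast p.

    One row per region plus a whole-duplex row whose ΔE is tested with a
    two-sample (Welch) t test on the per-observation whole-duplex means —
    mirroring the table layout of the factorial analysis.
    """
    fit = fit_factorial_model(table)
    rows = []
    for region in REGION_LEVELS:
        sub = table[table["region"] == region]
        low = sub.loc[sub["group"] == "low", "energy"]
        high = sub.loc[sub["group"] == "high", "energy"]
        ct = contrast_test(fit, region)
        rows.append((region, low.mean(), low.std(ddof=1), high.mean(),
                     high.std(ddof=1), ct.delta_e, ct.p))
    low_all = table.loc[table["group"] == "low", "energy"]
    high_all = table.loc[table["group"] == "high", "energy"]
    t, df, p = two_sample_t(low_all, high_all)
    rows.append(("whole", low_all.mean(), low_all.std(ddof=1),
                 high_all.mean(), high_all.std(ddof=1),
                 delta_energy(low_all.mean(), high_all.mean()), p))
    return pd.DataFrame(rows, columns=[
        "region", "mean_low", "sd_low", "mean_high", "sd_high",
        "delta_e", "p_value",
    ])
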