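"""Statistical layer: regression models, group tests, and normalization.

Per-sample structure-function relationships are tested by ordinary least
squares with an F-test against the intercept-only model. Relaxation time is
additionally modelled without intercept as

    TTR = b1 * dTT + b2 * (NCX1 * dTT),

reported in the factored form TTR = b1 * (dTT - r * NCX1 * dTT) with
r = -b2/b1, and compared against the nested dTT-only model by a Gaussian
likelihood-ratio test, LR = n * ln(RSS_reduced / RSS_full) ~ chi2(df).
Group comparisons use the unpaired two-tailed Student t-test with
Holm-Bonferroni correction across frequencies. Immunoblot densitometry is
normalized to the geometric mean of Ponceau and GAPDH loading signals and
then to a per-gel reference lane.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from dataclasses import dataclass, field
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .core import InvalidSpecError

__all__ = [
    "RegressionFit",
    "linear_fit",
    "interaction_fit",
    "likelihood_ratio_test",
    "t_test_unpaired",
    "holm_bonferroni",
    "dichotomize_by_dtt",
    "normalize_densitometry",
    "frequency_group_comparison",
    "DTT_SEVERE_THRESHOLD_UM",
]

#: dTT dichotomization boundary: >= is the severe-remodeling group.
DTT_SEVERE_THRESHOLD_UM = 1.05


@dataclass
class RegressionFit:
    """OLS fit summary with a pointwise 95% CI band for the mean response."""

    params: np.ndarray
    bse: np.ndarray
    names: tuple[str, ...]
    with_intercept: bool
    r2: float
    r2_kind: str  # "centered" or "uncentered"
    f_stat: float
    p_value: float
    rss: float
    n: int
    df_model: int
    reparam: dict | None = None
    _result: object = field(default=None, repr=False)

    def conf_band(self, exog_new: np.ndarray, alpha: float = 0.05) -> np.ndarray:
        """Pointwise CI for the mean response at new design rows."""
        pred = self._result.get_prediction(np.asarray(exog_new))
        return pred.conf_int(alpha=alpha)


def _wrap(result, names: tuple[str, ...], with_intercept: bool) -> RegressionFit:
    f_stat = float(result.fvalue) if np.ndim(result.fvalue) == 0 else float(np.squeeze(result.fvalue))
    return RegressionFit(
        params=np.asarray(result.params, dtype=float),
        bse=np.asarray(result.bse, dtype=float),
        names=names,
        with_intercept=with_intercept,
        r2=float(result.rsquared),
        r2_kind="centered" if with_intercept else "uncentered",
        f_stat=f_stat,
        p_value=float(result.f_pvalue),
        rss=float(result.ssr),
        n=int(result.nobs),
        df_model=int(result.df_model),
        _result=result,
    )


def linear_fit(x: np.ndarray, y: np.ndarray, with_intercept: bool = True) -> RegressionFit:
    """Univariate least-squares regression of y on x.

    Returns slope/intercept estimates, R^2, and the F statistic (with
    p-value) of the model against the corresponding constant model.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidSpecError("x and y must be matching 1D arrays")
    if x.size < 3:
        raise InvalidSpecError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise InvalidSpecError("constant predictor: degenerate design")
    exog = sm.add_constant(x) if with_intercept else x[:, None]
    names = ("intercept", "slope") if with_intercept else ("slope",)
    result = sm.OLS(y, exog).fit()
    fit = _wrap(result, names, with_intercept)
    # a flat response has F = 0, p = 1 (guard statsmodels returning NaN)
    if not np.isfinite(fit.f_stat):
        fit.f_stat, fit.p_value = 0.0, 1.0
    return fit


def interaction_fit(delta_tt: np.ndarray, ncx1: np.ndarray, ttr: np.ndarray) -> RegressionFit:
    """No-intercept fit of TTR on dTT and the dTT x NCX1 interaction.

    Model: TTR = b1 * dTT + b2 * (NCX1 * dTT). The printed factored form
    TTR = b1 * (dTT - r * NCX1 * dTT) is reported in ``reparam`` with
    r = -b2/b1. R^2 uses the uncentered total sum of squares (no-intercept
    convention), recorded in ``r2_kind``.
    """
    d = np.asarray(delta_tt, dtype=float)
    x = np.asarray(ncx1, dtype=float)
    y = np.asarray(ttr, dtype=float)
    if not (d.shape == x.shape == y.shape) or d.ndim != 1:
        raise InvalidSpecError("inputs must be matching 1D arrays")
    if d.size < 4:
        raise InvalidSpecError("need at least 4 observations")
    if np.all(d == 0):
        raise InvalidSpecError("dTT identically zero: degenerate design")
    exog = np.column_stack([d, x * d])
    rank = np.linalg.matrix_rank(exog)
    if rank < 2 and not np.all(x == 0):
        raise InvalidSpecError("collinear predictors")
    if np.all(x == 0):
        exog = exog[:, :1]  # nested: reduces to the dTT-only model
        result = sm.OLS(y, exog).fit()
        fit = _wrap(result, ("delta_tt",), with_intercept=False)
        fit.reparam = {"b1": float(fit.params[0]), "interaction_ratio": 0.0}
        return fit
    result = sm.OLS(y, exog).fit()
    fit = _wrap(result, ("delta_tt", "delta_tt:ncx1"), with_intercept=False)
    b1, b2 = fit.params
    fit.reparam = {"b1": float(b1), "interaction_ratio": float(-b2 / b1)}
    return fit


def likelihood_ratio_test(full: RegressionFit, reduced: RegressionFit) -> tuple[float, float]:
    """Gaussian LRT of nested least-squares models.

    Statistic LR = n * ln(RSS_reduced / RSS_full), referred to a chi-square
    with df equal to the difference in coefficient count. Returns (LR, p).
    """
    if full.n != reduced.n:
        raise InvalidSpecError("models must be fitted to the same observations")
    df = (full.df_model + int(full.with_intercept)) - (
        reduced.df_model + int(reduced.with_intercept)
    )
    if df == 0 and np.isclose(full.rss, reduced.rss):
        return 0.0, 1.0  # identical models carry no evidence
    if df <= 0:
        raise InvalidSpecError("full model must have more coefficients than the reduced one")
    if full.rss > reduced.rss * (1 + 1e-10):
        raise InvalidSpecError(
            "full-model RSS exceeds reduced-model RSS: models are not nested least squares"
        )
    if full.rss <= 0:
        return float("inf"), 0.0
    lr = full.n * np.log(reduced.rss / full.rss)
    lr = max(lr, 0.0)
    return float(lr), float(sps.chi2.sf(lr, df))


def t_test_unpaired(group_a, group_b, welch: bool = False) -> tuple[float, float]:
    """Two-tailed unpaired t-test; classic Student by default. Returns (t, p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidSpecError("each group needs at least 2 observations")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return (0.0, 1.0) if a.mean() == b.mean() else (float("inf"), 0.0)
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def holm_bonferroni(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values, in the original order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InvalidSpecError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def dichotomize_by_dtt(
    records: pd.DataFrame,
    threshold_um: float = DTT_SEVERE_THRESHOLD_UM,
    column: str = "delta_tt_um",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split samples into low (< threshold) and severe (>= threshold) remodeling."""
    dtt = records[column]
    if dtt.isna().any():
        raise InvalidSpecError("dTT must be defined for every record")
    low = records[dtt < threshold_um]
    high = records[dtt >= threshold_um]
    return low, high


def normalize_densitometry(raw, ponceau, gapdh, reference=1.0):
    """Immunoblot band normalization.

    value = raw / sqrt(ponceau * gapdh) / reference, where ``reference`` is
    the same-gel reference lane's own loading-normalized value. Scaling all
    lanes of a gel by a common exposure factor leaves the output unchanged.
    """
    raw = np.asarray(raw, dtype=float)
    ponceau = np.asarray(ponceau, dtype=float)
    gapdh = np.asarray(gapdh, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if np.any(raw <= 0) or np.any(ponceau <= 0) or np.any(gapdh <= 0) or np.any(reference <= 0):
        raise InvalidSpecError("densitometry inputs must be positive")
    out = raw / np.sqrt(ponceau * gapdh) / reference
    return float(out) if out.ndim == 0 else out


def frequency_group_comparison(
    records: pd.DataFrame,
    frequencies_hz: tuple[float, ...] = (0.2, 0.5, 1.0, 2.0),
    threshold_um: float = DTT_SEVERE_THRESHOLD_UM,
    tension_columns: dict[float, str] | None = None,
) -> pd.DataFrame:
    """Per-frequency wall-tension comparison between dTT groups.

    Splits the cohort at ``threshold_um``, t-tests the groups' tensions at
    each pacing frequency and Holm-adjusts the p-values across frequencies.
    Returns a tidy table with group means +- SEM and raw/adjusted p.
    """
    if tension_columns is None:
        tension_columns = {
            0.2: "tension_0p2_mN_mm2",
            0.5: "tension_0p5_mN_mm2",
            1.0: "tension_1_mN_mm2",
            2.0: "tension_2_mN_mm2",
        }
    low, high = dichotomize_by_dtt(records, threshold_um)
    if low.empty or high.empty:
        raise InvalidSpecError("both dTT groups must be non-empty")
    rows = []
    for f_hz in frequencies_hz:
        col = tension_columns[f_hz]
        a, b = low[col].to_numpy(), high[col].to_numpy()
        t, p = t_test_unpaired(a, b)
        rows.append(
            {
                "frequency_hz": f_hz,
                "mean_low": a.mean(),
                "sem_low": sps.sem(a),
                "mean_high": b.mean(),
                "sem_high": sps.sem(b),
                "t_stat": t,
                "p_raw": p,
            }
        )
    out = pd.DataFrame(rows)
    out["p_holm"] = holm_bonferroni(out["p_raw"].to_numpy())
    return out
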