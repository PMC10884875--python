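"""Linking reliability maps to signal properties and task effects.

Three analyses: parcel-wise simple OLS between two maps (optionally
excluding low-reliability networks such as the limbic group), network-wise
standardized betas from within-network OLS, and a per-parcel random-intercept
linear mixed model

    reliability ~ tMean + tSD + PE + (1 | participant)

fitted by REML across subjects and states, with all predictors standardized
globally and PEs fixed at zero for rest observations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)

__all__ = [
    "RegressionSummary",
    "parcelwise_ols",
    "networkwise_betas",
    "MixedModelSummary",
    "fit_mixed_model",
    "monotone_trend",
    "bh_fdr",
]


@dataclass
class RegressionSummary:
    """Simple-OLS summary: y on x across included parcels."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    standardized_beta: float
    n: int
    excluded_networks: tuple[str, ...] = ()


def _resolve_inclusion(
    n: int,
    exclude: Sequence[str],
    network_labels: np.ndarray | None,
    network_names: Mapping[int, str] | None,
) -> np.ndarray:
    mask = np.ones(n, dtype=bool)
    if exclude:
        if network_labels is None or network_names is None:
            raise ValueError("network exclusion requires labels and names")
        excluded_ids = {i for i, name in network_names.items() if name in set(exclude)}
        mask &= ~np.isin(np.asarray(network_labels), list(excluded_ids))
    return mask


def parcelwise_ols(
    x: np.ndarray,
    y: np.ndarray,
    exclude: Sequence[str] = (),
    network_labels: np.ndarray | None = None,
    network_names: Mapping[int, str] | None = None,
) -> RegressionSummary:
    """OLS of map ``y`` on map ``x`` across parcels.

    ``exclude`` names networks to drop (resolved through ``network_labels``
    -- per-parcel network ids -- and ``network_names``).  The standardized
    beta equals the Pearson correlation in this simple regression, so
    ``standardized_beta**2 == r_squared``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must align parcel-wise")
    mask = _resolve_inclusion(x.size, exclude, network_labels, network_names)
    mask &= np.isfinite(x) & np.isfinite(y)
    if mask.sum() < 3:
        raise ValueError(f"only {int(mask.sum())} parcels included; need >= 3")
    xs, ys = x[mask], y[mask]
    if xs.std() == 0:
        raise ValueError("x is constant over included parcels; slope undefined")
    res = sstats.linregress(xs, ys)
    return RegressionSummary(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        standardized_beta=float(res.rvalue),
        n=int(mask.sum()),
        excluded_networks=tuple(exclude),
    )


def networkwise_betas(
    x: np.ndarray,
    y: np.ndarray,
    network_labels: np.ndarray,
    network_names: Mapping[int, str],
    exclude: Sequence[str] = (),
    min_parcels: int = 3,
) -> pd.DataFrame:
    """Standardized beta of y on x within each (non-excluded) network.

    Networks with fewer than ``min_parcels`` finite parcel pairs are skipped
    with a log message.  Rows are ordered by network id.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    labels = np.asarray(network_labels)
    excluded = set(exclude)
    rows = []
    for nid in sorted(network_names):
        name = network_names[nid]
        if name in excluded:
            continue
        m = (labels == nid) & np.isfinite(x) & np.isfinite(y)
        if m.sum() < min_parcels:
            logger.info("network %s skipped (%d parcels < %d)", name, m.sum(), min_parcels)
            continue
        if x[m].std() == 0:
            logger.info("network %s skipped (constant x)", name)
            continue
        res = sstats.linregress(x[m], y[m])
        rows.append((nid, name, float(res.rvalue), float(res.pvalue), int(m.sum())))
    return pd.DataFrame(rows, columns=["network_id", "network", "standardized_beta",
                                       "p_value", "n_parcels"])


@dataclass
class MixedModelSummary:
    """Per-parcel mixed-model results plus convenience aggregates."""

    fixed_effects: pd.DataFrame  # parcel x (beta_tmean, beta_tsd, beta_pe, se_*, ...)
    random_intercept_var: np.ndarray  # per parcel
    singular: np.ndarray  # per-parcel flag
    predictors: tuple[str, ...] = ("tmean", "tsd", "pe")
    scaling: dict = field(default_factory=dict)

    def mean_betas(self) -> pd.Series:
        return self.fixed_effects[[f"beta_{p}" for p in self.predictors]].mean()

    def summary(self) -> str:
        lines = ["Per-parcel mixed model: reliability ~ tmean + tsd + pe + (1 | subject)"]
        lines.append(f"parcels fit: {len(self.fixed_effects)}"
                     f" (singular: {int(self.singular.sum())})")
        for p in self.predictors:
            b = self.fixed_effects[f"beta_{p}"]
            lines.append(f"  beta_{p}: mean {b.mean():+.4f}  sd {b.std():.4f}")
        lines.append(f"  random-intercept var: mean {np.nanmean(self.random_intercept_var):.4g}")
        return "\n".join(lines)


def fit_mixed_model(table: pd.DataFrame, reml: bool = True) -> MixedModelSummary:
    """Per-parcel random-intercept mixed model of reliability on signal terms.

    ``table`` is long format with columns ``parcel``, ``subject``, ``state``,
    ``reliability``, ``tmean``, ``tsd``, ``pe``.  PEs are forced to zero for
    rest rows, then all three predictors are standardized globally (mean 0,
    SD 1 across the whole table).  One model is fitted per parcel with
    subjects as the random-intercept grouping; singular fits are flagged, not
    fatal.
    """
    required = {"parcel", "subject", "state", "reliability", "tmean", "tsd", "pe"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table missing columns {sorted(missing)}")
    df = table.copy()
    if df["subject"].nunique() < 2 or df["state"].nunique() < 2:
        raise ValueError("need >= 2 subjects and >= 2 states")
    df.loc[df["state"] == "rest", "pe"] = 0.0
    scaling = {}
    for col in ("tmean", "tsd", "pe"):
        mu, sd = df[col].mean(), df[col].std(ddof=0)
        if sd == 0:
            raise ValueError(f"predictor {col!r} is constant; cannot standardize")
        df[col] = (df[col] - mu) / sd
        scaling[col] = (float(mu), float(sd))

    parcels = np.sort(df["parcel"].unique())
    rows = []
    re_var = np.full(parcels.size, np.nan)
    singular = np.zeros(parcels.size, dtype=bool)
    for i, p in enumerate(parcels):
        sub = df[df["parcel"] == p]
        fit = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for method in ("lbfgs", "powell"):
                try:
                    model = smf.mixedlm("reliability ~ tmean + tsd + pe", sub,
                                        groups=sub["subject"])
                    fit = model.fit(reml=reml, method=method)
                    break
                except Exception as exc:
                    logger.info("parcel %s mixed model (%s) failed: %s", p, method, exc)
        if fit is not None:
            params = fit.params
            bse = fit.bse
            re_var[i] = float(fit.cov_re.iloc[0, 0])
            singular[i] = bool(re_var[i] < 1e-10 or not fit.converged)
            rows.append(
                (p, params["tmean"], params["tsd"], params["pe"],
                 bse["tmean"], bse["tsd"], bse["pe"], params["Intercept"])
            )
        else:
            # boundary case (e.g. no between-subject variance): fall back to
            # the fixed-effects-only fit with a zero random-intercept variance
            logger.warning("parcel %s mixed model singular; OLS fallback", p)
            ols = smf.ols("reliability ~ tmean + tsd + pe", sub).fit()
            re_var[i] = 0.0
            singular[i] = True
            rows.append(
                (p, ols.params["tmean"], ols.params["tsd"], ols.params["pe"],
                 ols.bse["tmean"], ols.bse["tsd"], ols.bse["pe"],
                 ols.params["Intercept"])
            )
    fe = pd.DataFrame(
        rows,
        columns=["parcel", "beta_tmean", "beta_tsd", "beta_pe",
                 "se_tmean", "se_tsd", "se_pe", "intercept"],
    ).set_index("parcel")
    return MixedModelSummary(fixed_effects=fe, random_intercept_var=re_var,
                             singular=singular, scaling=scaling)


def monotone_trend(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation and p-value.

    A programmatic stand-in for visually gauging a nonlinear, monotone
    association (e.g. tSNR vs reliability), provided in addition to the
    linear fits.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    rho, p = sstats.spearmanr(x[ok], y[ok])
    return float(rho), float(p)


def bh_fdr(p_values: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg rejection mask (off by default in all reports)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    ok = np.isfinite(p)
    out = np.zeros(p.size, dtype=bool)
    if ok.any():
        out[ok] = multipletests(p[ok], alpha=alpha, method="fdr_bh")[0]
    return out
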