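"""Differential-consistency gene selection.

Each gene's Local Moran's I profile across samples is regressed against
the clinical outcome through a generalized linear model

    E(y | LMI, confounders) = g^{-1}(alpha * LMI + sum_m beta_m * confounder_m)

with the family chosen by outcome type: ordinary least squares for a
continuous outcome (t statistic for alpha), logistic regression for a
binary outcome (Wald z), and a Cox proportional-hazards model with the
Efron tie correction for survival outcomes (Wald z).  The per-gene Wald
statistics are then pooled and modelled as a two-component mixture

    f(t) = pi0 * f0(t) + (1 - pi0) * f1(t)

with an empirical null f0 = Normal(delta0, sigma0) fitted by central
matching: the marginal density f is estimated by Poisson regression of
histogram counts on a B-spline basis of the bin midpoints, a quadratic
is fitted to log f over the central half of the distribution, and
(delta0, sigma0, pi0) are read off the quadratic.  The local false
discovery rate of a statistic t is lfdr(t) = clip(pi0 f0(t) / f(t), 0, 1),
and genes with lfdr at or below the threshold (default 0.2) are called
differentially consistent (DC).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from scipy.interpolate import BSpline
from scipy.stats import norm
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .io import ClinicalTable

logger = logging.getLogger("dnlc")

DEFAULT_LFDR_THRESHOLD = 0.2
MIN_STATISTICS = 200


class UntestableGene(Exception):
    """A gene whose association model cannot be fitted.

    Carries a short ``reason`` code (``zero_variance``, ``non_convergence``,
    ``non_finite_statistic``).  Untestable genes are excluded from the
    lfdr fit and reported in a sidecar table, never silently dropped.
    """

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


# ---------------------------------------------------------------------------
# Per-gene association models
# ---------------------------------------------------------------------------


def _design_matrix(lmi_row: np.ndarray, confounders: pd.DataFrame) -> np.ndarray:
    """Intercept + LMI + one-hot-encoded confounders (first level reference)."""
    cols = [np.ones_like(lmi_row), lmi_row]
    if confounders is not None and confounders.shape[1] > 0:
        encoded = pd.get_dummies(confounders, drop_first=True, dtype=float)
        cols.extend(encoded[c].to_numpy(dtype=float) for c in encoded.columns)
    return np.column_stack(cols)


def fit_association(
    lmi_row: np.ndarray,
    clin: ClinicalTable,
    outcome_type: str | None = None,
) -> tuple[float, float]:
    """Fit the per-gene outcome model and return ``(estimate, statistic)``.

    ``estimate`` is the coefficient alpha on the LMI score and
    ``statistic`` its Wald statistic (t for the linear model, z for
    logistic and Cox).  Confounders from ``clin`` are always included.

    Raises
    ------
    UntestableGene
        If the LMI row has zero variance or the model does not converge
        (e.g. complete separation or monotone likelihood).
    """
    outcome_type = outcome_type or clin.outcome_type
    lmi_row = np.asarray(lmi_row, dtype=float)
    if np.ptp(lmi_row) == 0:
        raise UntestableGene("zero_variance")

    if outcome_type == "survival":
        return _fit_cox(lmi_row, clin)

    X = _design_matrix(lmi_row, clin.confounders)
    y = clin.outcome
    try:
        if outcome_type == "continuous":
            res = sm.OLS(y, X).fit()
        elif outcome_type == "binary":
            from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                warnings.simplefilter("error", PerfectSeparationWarning)
                res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            if not res.mle_retvals.get("converged", False):
                raise UntestableGene("non_convergence")
        else:
            raise ValueError(f"unknown outcome type {outcome_type!r}")
    except UntestableGene:
        raise
    except ValueError:
        raise
    except Exception as exc:  # separation, singular design, ...
        raise UntestableGene("non_convergence") from exc
    estimate = float(res.params[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        statistic = float(res.params[1] / res.bse[1])
    if np.isnan(statistic):
        raise UntestableGene("non_finite_statistic")
    return estimate, statistic


def _fit_cox(lmi_row: np.ndarray, clin: ClinicalTable) -> tuple[float, float]:
    frame = pd.DataFrame({"time": clin.outcome[:, 0], "event": clin.outcome[:, 1]})
    frame["lmi"] = lmi_row
    if clin.confounders.shape[1] > 0:
        encoded = pd.get_dummies(clin.confounders, drop_first=True, dtype=float)
        for c in encoded.columns:
            frame[str(c)] = encoded[c].to_numpy(dtype=float)
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(frame, duration_col="time", event_col="event")
    except (ConvergenceError, Exception) as exc:
        if isinstance(exc, KeyboardInterrupt):
            raise
        raise UntestableGene("non_convergence") from exc
    estimate = float(cph.params_["lmi"])
    statistic = float(cph.summary.loc["lmi", "z"])
    if not np.isfinite(statistic):
        raise UntestableGene("non_finite_statistic")
    return estimate, statistic


# ---------------------------------------------------------------------------
# Empirical-null local false discovery rate
# ---------------------------------------------------------------------------


@dataclass
class LfdrFit:
    """Two-component mixture fit over a family of Wald statistics.

    Attributes
    ----------
    pi0 : float
        Estimated proportion of null genes, in (0, 1].
    null_mean, null_sd : float
        Parameters (delta0, sigma0) of the empirical null Normal density.
    grid : ndarray
        Histogram bin midpoints on which densities were evaluated.
    marginal_density : ndarray
        Spline-smoothed marginal density f on ``grid``.
    null_density : ndarray
        pi0 * f0 on ``grid``.
    lfdr : ndarray
        Per-input-statistic lfdr values, clipped to [0, 1].
    n : int
        Number of statistics used in the fit.
    """

    pi0: float
    null_mean: float
    null_sd: float
    grid: np.ndarray
    marginal_density: np.ndarray
    null_density: np.ndarray
    lfdr: np.ndarray
    n: int

    def evaluate(self, statistics: np.ndarray) -> np.ndarray:
        """lfdr at arbitrary statistic values (interpolating log f on the grid)."""
        t = np.asarray(statistics, dtype=float)
        log_f = np.interp(t, self.grid, np.log(self.marginal_density))
        f0 = norm.pdf(t, self.null_mean, self.null_sd)
        with np.errstate(over="ignore"):
            raw = self.pi0 * f0 / np.exp(log_f)
        return np.clip(raw, 0.0, 1.0)

    def to_dict(self) -> dict:
        return {
            "pi0": self.pi0,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "n": self.n,
            "grid": self.grid.tolist(),
            "marginal_density": self.marginal_density.tolist(),
            "null_density": self.null_density.tolist(),
        }


def _bspline_basis(x: np.ndarray, lo: float, hi: float, df: int, degree: int = 3) -> np.ndarray:
    """B-spline design matrix with ``df`` basis functions on [lo, hi]."""
    n_internal = df - degree - 1
    if n_internal > 0:
        internal = np.quantile(x, np.linspace(0, 1, n_internal + 2)[1:-1])
    else:
        internal = np.array([])
    eps = 1e-9 * max(1.0, abs(hi - lo))
    knots = np.concatenate(
        [[lo - eps] * (degree + 1), internal, [hi + eps] * (degree + 1)]
    )
    return BSpline.design_matrix(x, knots, degree, extrapolate=False).toarray()


def estimate_lfdr(
    statistics: np.ndarray,
    *,
    bins: int = 120,
    spline_df: int = 7,
    center_quantiles: tuple[float, float] = (0.25, 0.75),
    min_statistics: int = MIN_STATISTICS,
) -> LfdrFit:
    """Empirical-null lfdr over a vector of per-gene statistics.

    The marginal density is estimated by Poisson regression of histogram
    counts (default 120 bins spanning the data) on a B-spline basis of
    the bin midpoints (default 7 degrees of freedom).  The empirical
    null Normal(delta0, sigma0) is fitted by central matching — a
    quadratic fit to the log marginal density over the central half of
    the distribution — and pi0 is the ratio of null to marginal mass at
    the null mode, clipped to (0, 1].

    Raises
    ------
    ValueError
        If fewer than ``min_statistics`` finite statistics are supplied
        (lfdr estimation is unreliable on tiny panels) or the histogram
        is degenerate (all mass in <= 3 bins).
    """
    t = np.asarray(statistics, dtype=float)
    t = t[np.isfinite(t)]
    if t.size < min_statistics:
        raise ValueError(
            f"lfdr estimation needs at least {min_statistics} finite statistics, "
            f"got {t.size}; lfdr is not advisable on tiny gene panels"
        )
    lo, hi = float(t.min()), float(t.max())
    counts, edges = np.histogram(t, bins=bins, range=(lo, hi))
    if np.count_nonzero(counts) <= 3:
        raise ValueError("degenerate statistic histogram (all mass in <= 3 bins)")
    mids = 0.5 * (edges[:-1] + edges[1:])
    width = edges[1] - edges[0]

    basis = _bspline_basis(mids, lo, hi, spline_df)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pois = sm.GLM(counts, basis, family=sm.families.Poisson()).fit(maxiter=200)
    fitted = np.asarray(pois.mu, dtype=float)
    fitted = np.maximum(fitted, 1e-300)
    density = fitted / (t.size * width)

    # central matching: quadratic fit to log f on the central quantile window
    q_lo, q_hi = np.quantile(t, center_quantiles)
    central = (mids >= q_lo) & (mids <= q_hi)
    if central.sum() < 5:
        central = np.argsort(np.abs(mids - np.median(t)))[:5]
    coeffs = np.polyfit(mids[central], np.log(density[central]), 2)
    c2, c1, _ = coeffs
    if c2 < 0:
        null_sd = float(np.sqrt(-1.0 / (2.0 * c2)))
        null_mean = float(-c1 / (2.0 * c2))
        log_f_at_mode = float(np.polyval(coeffs, null_mean))
        pi0 = float(np.exp(log_f_at_mode) * null_sd * np.sqrt(2.0 * np.pi))
    else:
        # The log marginal density is not concave near the center, which
        # happens when the non-null fraction is large enough to make the
        # statistic distribution multimodal — outside the sparse-signal
        # regime the empirical null assumes.  Fall back to the theoretical
        # N(0, 1) null (Wald statistics are asymptotically standard normal
        # under the per-gene null) with pi0 matched to the marginal at 0.
        logger.warning(
            "central matching found a non-concave log density; "
            "falling back to the theoretical N(0, 1) null"
        )
        null_mean, null_sd = 0.0, 1.0
        log_f_at_zero = float(np.interp(0.0, mids, np.log(density)))
        pi0 = float(np.exp(log_f_at_zero) * np.sqrt(2.0 * np.pi))
    pi0 = float(np.clip(pi0, 1e-12, 1.0))

    fit = LfdrFit(
        pi0=pi0,
        null_mean=null_mean,
        null_sd=null_sd,
        grid=mids,
        marginal_density=density,
        null_density=pi0 * norm.pdf(mids, null_mean, null_sd),
        lfdr=np.empty(0),
        n=int(t.size),
    )
    fit.lfdr = fit.evaluate(t)
    return fit


def select_dc_genes(fit: LfdrFit, threshold: float = DEFAULT_LFDR_THRESHOLD) -> np.ndarray:
    """Boolean DC mask over the statistics used in ``fit`` (lfdr <= threshold)."""
    if not 0 < threshold < 1:
        raise ValueError("lfdr threshold must be in (0, 1)")
    return fit.lfdr <= threshold


def bh_qvalues(statistics: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted two-sided normal p-values (comparison only)."""
    from statsmodels.stats.multitest import multipletests

    p = 2 * norm.sf(np.abs(np.asarray(statistics, dtype=float)))
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Whole-panel association
# ---------------------------------------------------------------------------


def associate_genes(
    lmi: pd.DataFrame,
    clin: ClinicalTable,
    *,
    isolated: np.ndarray | None = None,
    lfdr_threshold: float = DEFAULT_LFDR_THRESHOLD,
    bins: int = 120,
    spline_df: int = 7,
    center_quantiles: tuple[float, float] = (0.25, 0.75),
    min_statistics: int = MIN_STATISTICS,
) -> tuple[pd.DataFrame, LfdrFit, pd.DataFrame]:
    """Associate every gene's LMI profile with the outcome and call DC genes.

    Parameters
    ----------
    lmi : DataFrame
        Genes x samples LMI matrix; columns must match ``clin.sample_ids``.
    clin : ClinicalTable
        Outcome and confounders.
    isolated : boolean array, optional
        Genes with no in-radius network neighbor; these are excluded from
        testing (their LMI is identically zero, an undefined rather than a
        null signal).

    Returns
    -------
    table : DataFrame
        Columns gene_id, estimate, statistic, lfdr, is_dc — one row per
        testable gene.
    fit : LfdrFit
        The mixture fit over the pooled statistics.
    untestable : DataFrame
        Columns gene_id, reason for genes that could not be tested.
    """
    if list(lmi.columns) != list(clin.sample_ids):
        raise ValueError("LMI sample ids do not match clinical sample ids")
    gene_ids = list(lmi.index)
    values = lmi.to_numpy(dtype=float)
    if isolated is None:
        isolated = np.zeros(len(gene_ids), dtype=bool)

    kept_genes: list[str] = []
    estimates: list[float] = []
    statistics: list[float] = []
    untestable: list[tuple[str, str]] = []
    for i, gene in enumerate(gene_ids):
        if isolated[i]:
            untestable.append((gene, "isolated"))
            continue
        try:
            est, stat = fit_association(values[i], clin)
        except UntestableGene as exc:
            untestable.append((gene, exc.reason))
            continue
        if not np.isfinite(stat):
            untestable.append((gene, "non_finite_statistic"))
            continue
        kept_genes.append(gene)
        estimates.append(est)
        statistics.append(stat)

    if untestable:
        logger.info("%d gene(s) untestable and excluded from the lfdr fit", len(untestable))
    fit = estimate_lfdr(
        np.asarray(statistics),
        bins=bins,
        spline_df=spline_df,
        center_quantiles=center_quantiles,
        min_statistics=min_statistics,
    )
    is_dc = select_dc_genes(fit, lfdr_threshold)
    if not is_dc.any():
        logger.warning("no DC genes at lfdr threshold %.3g", lfdr_threshold)
    table = pd.DataFrame(
        {
            "gene_id": kept_genes,
            "estimate": estimates,
            "statistic": statistics,
            "lfdr": fit.lfdr,
            "is_dc": is_dc,
        }
    )
    untestable_df = pd.DataFrame(untestable, columns=["gene_id", "reason"])
    return table, fit, untestable_df


class DifferentialConsistencySelector(SelectorMixin, BaseEstimator):
    """Select genes whose Local Moran's I associates with the outcome.

    A feature selector in the sklearn sense: ``X`` is a samples x genes
    matrix of LMI scores (e.g. the output of
    :class:`~dnlc.lmi.LocalMoranTransformer`), ``y`` the clinical
    outcome.  Per gene a GLM Wald statistic for the LMI coefficient is
    computed, the pooled statistics get an empirical-null lfdr, and the
    support mask keeps genes with ``lfdr <= lfdr_threshold``.

    Parameters
    ----------
    outcome_type : {"continuous", "binary", "survival"}, default="binary"
        Regression family.  For survival, ``y`` must be an ``(N, 2)``
        array of (time, event) pairs.
    lfdr_threshold : float, default=0.2
        DC call threshold on the local false discovery rate.
    bins, spline_df, center_quantiles : lfdr fit controls
        Histogram bin count, spline degrees of freedom and central
        quantile window of the empirical-null fit.

    Attributes
    ----------
    estimate_ : ndarray
        Per-gene LMI coefficient (NaN where untestable).
    statistic_ : ndarray
        Per-gene Wald statistic (NaN where untestable).
    lfdr_ : ndarray
        Per-gene lfdr (NaN where untestable).
    support_ : ndarray of bool
        DC mask: testable and lfdr <= threshold.
    lfdr_fit_ : LfdrFit
        Mixture-fit parameters (pi0, empirical null, density grid).
    untestable_reasons_ : dict
        ``{column index: reason}`` for untestable genes.
    """

    def __init__(
        self,
        outcome_type: str = "binary",
        lfdr_threshold: float = DEFAULT_LFDR_THRESHOLD,
        bins: int = 120,
        spline_df: int = 7,
        center_quantiles: tuple[float, float] = (0.25, 0.75),
        min_statistics: int = MIN_STATISTICS,
    ):
        self.outcome_type = outcome_type
        self.lfdr_threshold = lfdr_threshold
        self.bins = bins
        self.spline_df = spline_df
        self.center_quantiles = center_quantiles
        self.min_statistics = min_statistics

    def fit(self, X, y, confounders: pd.DataFrame | None = None):
        feature_names = (
            [str(c) for c in X.columns] if isinstance(X, pd.DataFrame) else None
        )
        X = check_array(X, dtype=float)
        n = X.shape[0]
        y = np.asarray(y, dtype=float)
        conf = confounders if confounders is not None else pd.DataFrame(index=range(n))
        clin = ClinicalTable(
            sample_ids=[str(i) for i in range(n)],
            outcome_type=self.outcome_type,
            outcome=y,
            confounders=conf.reset_index(drop=True),
        )
        genes = feature_names or [f"x{j}" for j in range(X.shape[1])]
        lmi_frame = pd.DataFrame(X.T, index=genes, columns=clin.sample_ids)
        table, fit, untestable = associate_genes(
            lmi_frame,
            clin,
            lfdr_threshold=self.lfdr_threshold,
            bins=self.bins,
            spline_df=self.spline_df,
            center_quantiles=self.center_quantiles,
            min_statistics=self.min_statistics,
        )
        p = X.shape[1]
        index = {g: j for j, g in enumerate(genes)}
        self.estimate_ = np.full(p, np.nan)
        self.statistic_ = np.full(p, np.nan)
        self.lfdr_ = np.full(p, np.nan)
        self.support_ = np.zeros(p, dtype=bool)
        for row in table.itertuples(index=False):
            j = index[row.gene_id]
            self.estimate_[j] = row.estimate
            self.statistic_[j] = row.statistic
            self.lfdr_[j] = row.lfdr
            self.support_[j] = row.is_dc
        self.untestable_reasons_ = {
            index[g]: r for g, r in untestable.itertuples(index=False)
        }
        self.lfdr_fit_ = fit
        self.n_features_in_ = p
        if feature_names is not None:
            self.feature_names_in_ = np.asarray(feature_names, dtype=object)
        return self

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_
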