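"""Within-consultation time trends and between-measure correlations.

Two questions are answered here.  First, does a face-gaze measure change
over the course of a consultation?  This is estimated with a linear mixed
model of the per-decile measure value on the decile index (1–10), with a
random intercept per consultation; the fixed slope is the change per decile.
Second, how are the three measures related across consultations?  Pairwise
Pearson correlations among duration, frequency and dwell are tested at a
Bonferroni-corrected level of 0.05/3, and correlations of each measure with
patient satisfaction and consultation length are reported uncorrected (with
family-corrected p-values alongside).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import SingularFitError
from .measures import MEASURE_NAMES, DecileProfile

__all__ = [
    "DecileTrendModel",
    "DecileTrendResults",
    "fit_decile_trend",
    "CorrelationResult",
    "pairwise_correlations",
    "outcome_correlations",
    "PAIRWISE_ALPHA",
]

log = logging.getLogger(__name__)

PAIRWISE_FAMILY_SIZE = 3
PAIRWISE_ALPHA = 0.05 / PAIRWISE_FAMILY_SIZE  # printed as 0.017

_DECILE_CENTER = 5.5  # centering for numerical stability; slope unchanged


# ---------------------------------------------------------------------------
# decile trend


@dataclass(frozen=True)
class DecileTrendResults:
    """Fixed slope of a measure over consultation deciles.

    ``beta`` is in measure units per decile increment; ``random_intercept_sd``
    is the between-consultation spread of overall level.
    """

    measure_name: str
    beta: float
    beta_se: float
    p_value: float
    intercept: float
    random_intercept_sd: float
    residual_sd: float
    n_consultations: int
    n_obs: int
    method: str
    converged: bool

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        z = stats.norm.ppf(1 - alpha / 2)
        return self.beta - z * self.beta_se, self.beta + z * self.beta_se

    def summary(self) -> str:
        lo, hi = self.conf_int()
        lines = [
            f"Decile trend for {self.measure_name} ({self.method} fit)",
            f"  consultations: {self.n_consultations}   observations: {self.n_obs}",
            f"  slope per decile (beta): {self.beta:+.4f}  "
            f"[95% CI {lo:+.4f}, {hi:+.4f}]   p = {self.p_value:.3g}",
            f"  level at mid-consultation: {self.intercept:.3f}",
            f"  random intercept sd: {self.random_intercept_sd:.4f}   "
            f"residual sd: {self.residual_sd:.4f}",
        ]
        return "\n".join(lines)


class DecileTrendModel:
    """Mixed-effects trend of one measure across consultation deciles.

    Parameters
    ----------
    data
        Either a list of :class:`~facegaze.measures.DecileProfile` for one
        measure, or a long DataFrame with columns ``consultation_id``,
        ``decile`` (1–10) and the measure value.
    measure_name
        Which measure the values represent (``duration``, ``frequency`` or
        ``dwell``); used to pick the value column from a DataFrame.
    """

    def __init__(
        self,
        data: Iterable[DecileProfile] | pd.DataFrame,
        measure_name: str | None = None,
    ):
        if isinstance(data, pd.DataFrame):
            if measure_name is None:
                raise ValueError("measure_name is required with a DataFrame")
            col = measure_name if measure_name in data.columns else "value"
            df = data.loc[:, ["consultation_id", "decile", col]].rename(
                columns={col: "value"}
            )
        else:
            profiles = list(data)
            if not profiles:
                raise ValueError("no profiles supplied")
            names = {p.measure_name for p in profiles}
            if len(names) > 1:
                raise ValueError(f"profiles mix measures: {sorted(names)}")
            measure_name = measure_name or profiles[0].measure_name
            df = pd.DataFrame(
                {
                    "consultation_id": np.repeat(
                        [p.consultation_id for p in profiles], 10
                    ),
                    "decile": np.tile(np.arange(1, 11), len(profiles)),
                    "value": np.concatenate([p.values for p in profiles]),
                }
            )
        if measure_name not in MEASURE_NAMES:
            raise ValueError(f"unknown measure {measure_name!r}")
        self.measure_name = measure_name

        n_missing = int(df["value"].isna().sum())
        if n_missing:
            log.info(
                "decile trend (%s): dropping %d missing bin value(s)",
                measure_name,
                n_missing,
            )
            df = df.dropna(subset=["value"])
        self.data = df.reset_index(drop=True)
        if self.data["consultation_id"].nunique() < 2:
            raise ValueError("at least 2 consultations are required")

    def fit(self, method: str = "mixed") -> DecileTrendResults:
        """Fit the trend.

        ``method='mixed'`` fits value ~ decile with a random intercept per
        consultation (the default); ``method='aggregate'`` first averages
        the profiles across consultations and fits ordinary least squares on
        the 10 decile means.  In a balanced design both give the same slope.
        """
        if method == "aggregate":
            return self._fit_aggregate()
        if method != "mixed":
            raise ValueError(f"unknown method {method!r}")
        return self._fit_mixed()

    # -- internals ---------------------------------------------------------

    def _fit_aggregate(self) -> DecileTrendResults:
        import statsmodels.api as sm

        means = self.data.groupby("decile")["value"].mean()
        x = means.index.to_numpy(dtype=float) - _DECILE_CENTER
        y = means.to_numpy(dtype=float)
        if np.allclose(y, y[0], atol=0, rtol=0) and np.ptp(y) == 0:
            beta, se, p = 0.0, 0.0, 1.0
            intercept = float(y[0])
        else:
            res = sm.OLS(y, sm.add_constant(x)).fit()
            beta, se, p = res.params[1], res.bse[1], res.pvalues[1]
            intercept = res.params[0]
        return DecileTrendResults(
            measure_name=self.measure_name,
            beta=float(beta),
            beta_se=float(se),
            p_value=float(p),
            intercept=float(intercept),
            random_intercept_sd=math.nan,
            residual_sd=math.nan,
            n_consultations=int(self.data["consultation_id"].nunique()),
            n_obs=len(means),
            method="aggregate",
            converged=True,
        )

    def _within_stats(self) -> tuple[float, float, float]:
        """Within-consultation slope and residual/level variation.

        Returns the pooled least-squares slope after removing consultation
        means, its residual sum of squares, and the variance of the
        consultation means — used to detect degenerate (noise-free) inputs.
        """
        df = self.data
        x = df["decile"].to_numpy(dtype=float) - _DECILE_CENTER
        y = df["value"].to_numpy(dtype=float)
        g = df["consultation_id"].to_numpy()
        gm_y = pd.Series(y).groupby(g).transform("mean").to_numpy()
        gm_x = pd.Series(x).groupby(g).transform("mean").to_numpy()
        xd, yd = x - gm_x, y - gm_y
        sxx = float(xd @ xd)
        slope = float(xd @ yd) / sxx if sxx > 0 else 0.0
        rss = float(((yd - slope * xd) ** 2).sum())
        level_var = float(np.var(pd.Series(y).groupby(g).mean().to_numpy()))
        return slope, rss, level_var

    def _fit_mixed(self) -> DecileTrendResults:
        import statsmodels.api as sm

        df = self.data
        y = df["value"].to_numpy(dtype=float)
        slope, rss, level_var = self._within_stats()
        scale = max(float(np.var(y)), 1.0)
        if rss <= 1e-16 * scale * len(df):
            # Deterministic within-consultation structure: every profile is
            # an exact line (possibly flat) around its own level.  The slope
            # is exact; there is no residual noise to test against.
            if level_var <= 1e-16 * scale and abs(slope) <= 1e-12:
                raise SingularFitError(
                    "all profiles are constant and identical; the trend "
                    "model is singular"
                )
            return DecileTrendResults(
                measure_name=self.measure_name,
                beta=slope,
                beta_se=0.0,
                p_value=0.0 if abs(slope) > 1e-12 else 1.0,
                intercept=float(np.mean(y)),
                random_intercept_sd=math.sqrt(max(level_var, 0.0)),
                residual_sd=0.0,
                n_consultations=int(df["consultation_id"].nunique()),
                n_obs=len(df),
                method="mixed (deterministic)",
                converged=True,
            )

        x = df["decile"].to_numpy(dtype=float) - _DECILE_CENTER
        exog = sm.add_constant(x)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, exog, groups=df["consultation_id"].to_numpy())
            try:
                res = model.fit(reml=True)
            except Exception as exc:  # singular / non-convergent fits
                raise SingularFitError(f"mixed trend fit failed: {exc}") from exc
        re_var = float(np.asarray(res.cov_re)[0, 0])
        return DecileTrendResults(
            measure_name=self.measure_name,
            beta=float(res.params[1]),
            beta_se=float(res.bse[1]),
            p_value=float(res.pvalues[1]),
            intercept=float(res.params[0]),
            random_intercept_sd=math.sqrt(max(re_var, 0.0)),
            residual_sd=math.sqrt(max(float(res.scale), 0.0)),
            n_consultations=int(df["consultation_id"].nunique()),
            n_obs=len(df),
            method="mixed",
            converged=bool(getattr(res, "converged", True)),
        )


def fit_decile_trend(
    profiles: Iterable[DecileProfile] | pd.DataFrame,
    measure_name: str | None = None,
    method: str = "mixed",
) -> DecileTrendResults:
    """Convenience wrapper: build a :class:`DecileTrendModel` and fit it."""
    return DecileTrendModel(profiles, measure_name=measure_name).fit(method=method)


# ---------------------------------------------------------------------------
# correlations


@dataclass(frozen=True)
class CorrelationResult:
    """One Pearson correlation with its applied significance level."""

    pair: str
    r: float
    p_value: float
    n: int
    alpha_applied: float
    p_value_family: float

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha_applied

    def __str__(self) -> str:
        star = " *" if self.significant else ""
        return (
            f"{self.pair}: r = {self.r:.3f}, p = {self.p_value:.3g} "
            f"(n = {self.n}, alpha = {self.alpha_applied:.3f}){star}"
        )


def _pearson(x: np.ndarray, y: np.ndarray, pair: str) -> tuple[float, float, int]:
    mask = np.isfinite(x) & np.isfinite(y)
    dropped = int((~mask).sum())
    if dropped:
        log.info("correlation %s: dropping %d incomplete pair(s)", pair, dropped)
    x, y = x[mask], y[mask]
    if x.size < 4:
        raise ValueError(f"correlation {pair}: fewer than 4 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise SingularFitError(
            f"correlation {pair}: a variable has zero variance"
        )
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), int(x.size)


def pairwise_correlations(
    measures: pd.DataFrame, alpha: float = 0.05
) -> list[CorrelationResult]:
    """Pearson correlations among duration, frequency and dwell.

    One row per consultation; rows with undefined dwell are dropped listwise
    per pair.  The applied per-test level is ``alpha / 3`` (Bonferroni over
    the three-test family).
    """
    alpha_applied = alpha / PAIRWISE_FAMILY_SIZE
    cols = {
        "duration": "duration_per_min",
        "frequency": "frequency_per_min",
        "dwell": "mean_dwell_s",
    }
    pairs = [("duration", "frequency"), ("duration", "dwell"), ("frequency", "dwell")]
    out = []
    for a, b in pairs:
        pair = f"{a}-{b}"
        r, p, n = _pearson(
            measures[cols[a]].to_numpy(dtype=float),
            measures[cols[b]].to_numpy(dtype=float),
            pair,
        )
        out.append(
            CorrelationResult(
                pair=pair,
                r=r,
                p_value=p,
                n=n,
                alpha_applied=alpha_applied,
                p_value_family=min(1.0, p * PAIRWISE_FAMILY_SIZE),
            )
        )
    return out


def outcome_correlations(
    measures: pd.DataFrame,
    cohort: pd.DataFrame,
    outcomes: Sequence[str] = ("satisfaction", "minutes"),
    alpha: float = 0.05,
) -> list[CorrelationResult]:
    """Correlate each measure with consultation-level outcomes.

    Outcomes default to patient satisfaction (from the cohort table) and
    total analysed consultation minutes (from the measures table).  Reported
    at the uncorrected level, with Bonferroni family-corrected p-values in
    ``p_value_family`` for the conservative reader.
    """
    df = measures
    if "satisfaction" not in df.columns:
        df = df.merge(
            cohort[["consultation_id", "satisfaction"]],
            on="consultation_id",
            how="left",
        )
    cols = {
        "duration": "duration_per_min",
        "frequency": "frequency_per_min",
        "dwell": "mean_dwell_s",
    }
    family = len(cols) * len(outcomes)
    out = []
    for m, col in cols.items():
        for outcome in outcomes:
            pair = f"{m}-{outcome}"
            r, p, n = _pearson(
                df[col].to_numpy(dtype=float),
                df[outcome].to_numpy(dtype=float),
                pair,
            )
            out.append(
                CorrelationResult(
                    pair=pair,
                    r=r,
                    p_value=p,
                    n=n,
                    alpha_applied=alpha,
                    p_value_family=min(1.0, p * family),
                )
            )
    return out


def correlations_frame(results: Iterable[CorrelationResult]) -> pd.DataFrame:
    """Tidy CSV-ready table of correlation results."""
    return pd.DataFrame(
        [
            {
                "pair": c.pair,
                "r": c.r,
                "p_value": c.p_value,
                "n": c.n,
                "alpha_applied": c.alpha_applied,
                "p_value_family": c.p_value_family,
                "significant": c.significant,
            }
            for c in results
        ]
    )
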