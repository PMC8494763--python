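"""Thin-slice prediction of face gaze.

Does gaze behaviour in the first 30, 60 or 120 s of a consultation predict
gaze behaviour over the rest of it?  Each consultation is split into an
initial slice of valid frames and the remainder; for a chosen measure the
remainder value is regressed on the slice value with total consultation
length (analysed minutes) as a confounder:

    remainder ~ intercept + slice + total_minutes

Because each physician sees several patients, the same model can be refit
with a per-physician random intercept; a likelihood-ratio comparison (on
maximum-likelihood refits, with the boundary-corrected halved p-value)
reports whether the random effect improves fit.  The mixed variant reports
the marginal (fixed-effects) R^2 so both variants are comparable.
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
from .measures import MEASURE_NAMES, GazeMeasures, _RunIndex
from .stream import GazeStream

__all__ = [
    "SliceSplit",
    "split_slice",
    "ThinSliceModel",
    "ThinSliceResults",
    "fit_slice_model",
    "slice_length_sweep",
    "DEFAULT_SLICE_SECONDS",
]

log = logging.getLogger(__name__)

DEFAULT_SLICE_SECONDS = (30.0, 60.0, 120.0)


@dataclass(frozen=True)
class SliceSplit:
    """Measures on the initial slice and on the remainder of one stream."""

    consultation_id: str
    physician_id: str
    slice_seconds: float
    slice_measures: GazeMeasures
    remainder_measures: GazeMeasures
    total_minutes: float


def split_slice(
    stream: GazeStream,
    slice_seconds: float,
    min_instance_frames: int = 1,
    bridge_invalid_frames: int = 0,
) -> SliceSplit | None:
    """Split a stream into its first ``slice_seconds`` of valid time and the rest.

    The slice holds the first ``round(slice_seconds / frame_interval)`` valid
    frames, so gap-masked stretches do not eat into it.  Runs crossing the
    split are truncated at it for duration and counted as an instance on the
    side of their onset.  Returns ``None`` (with a log record) when the
    stream has no valid frames beyond the slice; such consultations are
    excluded from slice models.
    """
    n_slice = round(float(slice_seconds) / stream.frame_interval_s)
    if n_slice < 1:
        raise ValueError("slice_seconds must cover at least one frame")
    n_valid = stream.n_valid
    if n_valid <= n_slice:
        log.info(
            "thin slice: excluding %r (%.1f s valid <= %.0f s slice)",
            stream.consultation_id,
            n_valid * stream.frame_interval_s,
            slice_seconds,
        )
        return None
    vpos = np.flatnonzero(stream.valid)
    boundary = int(vpos[n_slice])  # frame index of the first remainder frame
    idx = _RunIndex(stream, min_instance_frames, bridge_invalid_frames)
    return SliceSplit(
        consultation_id=stream.consultation_id,
        physician_id=stream.physician_id,
        slice_seconds=float(slice_seconds),
        slice_measures=idx.segment_measures((0, boundary)),
        remainder_measures=idx.segment_measures((boundary, stream.n_frames)),
        total_minutes=stream.minutes,
    )


# ---------------------------------------------------------------------------
# model


@dataclass(frozen=True)
class ThinSliceResults:
    """Fit of remainder ~ slice + total minutes for one measure/slice length."""

    measure_name: str
    slice_seconds: float
    intercept: float
    slice_coefficient: float
    duration_covariate_coefficient: float
    p_values: dict[str, float]
    r_squared: float
    n: int
    random_effect_sd: float | None
    fit_improved_by_random_effect: bool | None
    lrt_statistic: float | None
    lrt_p_value: float | None
    aic_fixed: float
    aic_mixed: float | None

    @staticmethod
    def _stars(p: float) -> str:
        if p < 0.001:
            return "***"
        if p < 0.01:
            return "**"
        if p < 0.05:
            return "*"
        return "(NS)"

    def summary(self) -> str:
        s = self._stars
        p = self.p_values
        lines = [
            f"Thin-slice model: {self.measure_name}, slice {self.slice_seconds:.0f} s "
            f"(n = {self.n})",
            f"  intercept:          {self.intercept:+.3f} {s(p['intercept'])}",
            f"  slice measure:      {self.slice_coefficient:+.3f} {s(p['slice'])}",
            f"  total minutes:      {self.duration_covariate_coefficient:+.3f} "
            f"{s(p['minutes'])}",
            f"  R^2:                {self.r_squared:.3f} "
            f"({100 * self.r_squared:.0f}%)",
        ]
        if self.random_effect_sd is not None:
            verdict = "improves" if self.fit_improved_by_random_effect else (
                "does not improve"
            )
            lines.append(
                f"  physician random intercept sd: {self.random_effect_sd:.3f}; "
                f"LRT = {self.lrt_statistic:.3f}, p = {self.lrt_p_value:.3g} "
                f"-> random effect {verdict} fit"
            )
        return "\n".join(lines)


class ThinSliceModel:
    """Regression of remainder gaze on initial-slice gaze.

    Parameters
    ----------
    splits
        :class:`SliceSplit` records for one slice length, or a DataFrame with
        columns ``consultation_id``, ``physician_id``, ``slice_value``,
        ``remainder_value``, ``total_minutes``.
    measure_name
        Which measure to model when ``splits`` are SliceSplit records.
    """

    def __init__(
        self,
        splits: Iterable[SliceSplit] | pd.DataFrame,
        measure_name: str,
        slice_seconds: float | None = None,
    ):
        if measure_name not in MEASURE_NAMES:
            raise ValueError(f"unknown measure {measure_name!r}")
        self.measure_name = measure_name
        if isinstance(splits, pd.DataFrame):
            df = splits.copy()
            if slice_seconds is None:
                raise ValueError("slice_seconds is required with a DataFrame")
            self.slice_seconds = float(slice_seconds)
        else:
            splits = list(splits)
            if not splits:
                raise ValueError("no slice splits supplied")
            lengths = {s.slice_seconds for s in splits}
            if len(lengths) > 1:
                raise ValueError(f"splits mix slice lengths: {sorted(lengths)}")
            self.slice_seconds = float(slice_seconds or splits[0].slice_seconds)
            df = pd.DataFrame(
                {
                    "consultation_id": [s.consultation_id for s in splits],
                    "physician_id": [s.physician_id for s in splits],
                    "slice_value": [
                        s.slice_measures.value(measure_name) for s in splits
                    ],
                    "remainder_value": [
                        s.remainder_measures.value(measure_name) for s in splits
                    ],
                    "total_minutes": [s.total_minutes for s in splits],
                }
            )
        complete = (
            df[["slice_value", "remainder_value", "total_minutes"]]
            .notna()
            .all(axis=1)
        )
        dropped = int((~complete).sum())
        if dropped:
            log.info(
                "thin-slice model (%s, %.0f s): dropping %d row(s) with "
                "undefined measures",
                measure_name,
                self.slice_seconds,
                dropped,
            )
        self.data = df.loc[complete].reset_index(drop=True)
        if len(self.data) < 10:
            raise ValueError(
                f"at least 10 complete consultations are required, have "
                f"{len(self.data)}"
            )

    # -- fitting -----------------------------------------------------------

    def _design(self) -> tuple[np.ndarray, np.ndarray]:
        y = self.data["remainder_value"].to_numpy(dtype=float)
        X = np.column_stack(
            [
                np.ones(len(self.data)),
                self.data["slice_value"].to_numpy(dtype=float),
                self.data["total_minutes"].to_numpy(dtype=float),
            ]
        )
        for j, name in ((1, "slice_value"), (2, "total_minutes")):
            if np.ptp(X[:, j]) == 0:
                raise SingularFitError(f"predictor {name} has zero variance")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise SingularFitError("collinear predictors in thin-slice design")
        return y, X

    def fit(self, physician_effect: bool = False) -> ThinSliceResults:
        """Fit by OLS; optionally compare against a per-physician random
        intercept refit via a boundary-corrected likelihood-ratio test."""
        import statsmodels.api as sm

        y, X = self._design()
        ols = sm.OLS(y, X).fit()
        p_values = {
            "intercept": float(ols.pvalues[0]),
            "slice": float(ols.pvalues[1]),
            "minutes": float(ols.pvalues[2]),
        }
        result = dict(
            measure_name=self.measure_name,
            slice_seconds=self.slice_seconds,
            intercept=float(ols.params[0]),
            slice_coefficient=float(ols.params[1]),
            duration_covariate_coefficient=float(ols.params[2]),
            p_values=p_values,
            r_squared=float(ols.rsquared),
            n=int(len(y)),
            random_effect_sd=None,
            fit_improved_by_random_effect=None,
            lrt_statistic=None,
            lrt_p_value=None,
            aic_fixed=float(ols.aic),
            aic_mixed=None,
        )

        if physician_effect:
            groups = self.data["physician_id"].to_numpy()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mixed = sm.MixedLM(y, X, groups=groups)
                try:
                    mres = mixed.fit(reml=False)
                except Exception as exc:
                    raise SingularFitError(
                        f"mixed thin-slice fit failed: {exc}"
                    ) from exc
            re_var = float(np.asarray(mres.cov_re)[0, 0])
            resid_var = float(mres.scale)
            # marginal R^2: fixed-effects variance over total variance
            fitted_fixed = X @ np.asarray(mres.fe_params)
            var_f = float(np.var(fitted_fixed))
            marginal_r2 = var_f / (var_f + re_var + resid_var)
            lrt = max(0.0, 2.0 * (float(mres.llf) - float(ols.llf)))
            # variance parameter tested on its boundary: halve the chi2(1) tail
            lrt_p = 0.5 * float(stats.chi2.sf(lrt, df=1))
            p_mixed = np.asarray(mres.pvalues, dtype=float)
            result.update(
                intercept=float(mres.fe_params[0]),
                slice_coefficient=float(mres.fe_params[1]),
                duration_covariate_coefficient=float(mres.fe_params[2]),
                p_values={
                    "intercept": float(p_mixed[0]),
                    "slice": float(p_mixed[1]),
                    "minutes": float(p_mixed[2]),
                },
                r_squared=float(marginal_r2),
                random_effect_sd=math.sqrt(max(re_var, 0.0)),
                fit_improved_by_random_effect=bool(lrt_p < 0.05),
                lrt_statistic=lrt,
                lrt_p_value=lrt_p,
                aic_mixed=float(mres.aic),
            )
        return ThinSliceResults(**result)


def fit_slice_model(
    splits: Iterable[SliceSplit] | pd.DataFrame,
    measure_name: str,
    with_physician_effect: bool = False,
    slice_seconds: float | None = None,
) -> ThinSliceResults:
    """Convenience wrapper: build a :class:`ThinSliceModel` and fit it."""
    model = ThinSliceModel(splits, measure_name, slice_seconds=slice_seconds)
    return model.fit(physician_effect=with_physician_effect)


def slice_length_sweep(
    streams: Sequence[GazeStream],
    slice_seconds: Sequence[float] = DEFAULT_SLICE_SECONDS,
    measures: Sequence[str] = MEASURE_NAMES,
    with_physician_effect: bool = False,
    min_instance_frames: int = 1,
    bridge_invalid_frames: int = 0,
) -> pd.DataFrame:
    """Fit one thin-slice model per (measure, slice length).

    Returns a table shaped like the classic slice-model summary: one row per
    combination with intercept, slice coefficient, total-minutes coefficient
    (each with significance stars), and R^2 both as a proportion and as a
    percentage.
    """
    rows = []
    for s_len in slice_seconds:
        splits = []
        for stream in streams:
            sp = split_slice(
                stream,
                s_len,
                min_instance_frames=min_instance_frames,
                bridge_invalid_frames=bridge_invalid_frames,
            )
            if sp is not None:
                splits.append(sp)
        for m in measures:
            res = fit_slice_model(
                splits, m, with_physician_effect=with_physician_effect
            )
            stars = ThinSliceResults._stars
            row = {
                "measure": m,
                "slice_seconds": s_len,
                "n": res.n,
                "intercept": res.intercept,
                "intercept_sig": stars(res.p_values["intercept"]),
                "slice_coefficient": res.slice_coefficient,
                "slice_sig": stars(res.p_values["slice"]),
                "minutes_coefficient": res.duration_covariate_coefficient,
                "minutes_sig": stars(res.p_values["minutes"]),
                "r_squared": res.r_squared,
                "r_squared_pct": 100.0 * res.r_squared,
            }
            if with_physician_effect:
                row.update(
                    random_effect_sd=res.random_effect_sd,
                    lrt_p_value=res.lrt_p_value,
                    fit_improved_by_random_effect=res.fit_improved_by_random_effect,
                )
            rows.append(row)
    return pd.DataFrame(rows)
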