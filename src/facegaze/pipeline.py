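"""One-command analysis pipeline.

Runs the full chain — (optionally) simulate, per-consultation measures,
decile profiles, decile trends, correlations, thin-slice models — and
writes tidy CSV outputs plus a run log:

* ``measures.csv`` — whole-consultation duration/frequency/dwell,
* ``deciles.csv`` — per-consultation per-decile values,
* ``figure_deciles.csv`` — cross-consultation mean and SE per decile
  (the data behind the usual time-course figures),
* ``trend.csv`` — mixed-model slope per decile for each measure,
* ``correlations.csv`` — pairwise and outcome Pearson correlations,
* ``table2.csv`` — thin-slice model grid (3 measures x slice lengths).
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as fio
from .exceptions import ConfigError, FaceGazeError, SingularFitError
from .measures import MEASURE_NAMES, decile_table, measures_table
from .stream import GazeStream
from .synthetic import SyntheticConfig, sample_cohort
from .thinslice import DEFAULT_SLICE_SECONDS, slice_length_sweep
from .trend import (
    DecileTrendModel,
    correlations_frame,
    outcome_correlations,
    pairwise_correlations,
)

__all__ = ["PipelineConfig", "run_pipeline", "render_decile_figure_data"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """What to analyse and where to put the results.

    Exactly one of ``input_dir`` (a directory of stream CSVs plus
    ``cohort.csv``) and ``synthetic`` (a generator configuration) must be
    given.
    """

    out_dir: str
    input_dir: str | None = None
    synthetic: SyntheticConfig | None = None
    seed: int | None = None
    slice_seconds: Sequence[float] = DEFAULT_SLICE_SECONDS
    measures: Sequence[str] = MEASURE_NAMES
    with_physician_effect: bool = False
    min_instance_frames: int = 1
    bridge_invalid_frames: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.input_dir is None) == (self.synthetic is None):
            raise ConfigError(
                "specify exactly one input source: input_dir or synthetic"
            )
        s = [float(v) for v in self.slice_seconds]
        if not s or any(v <= 0 for v in s) or any(
            b <= a for a, b in zip(s, s[1:])
        ):
            raise ConfigError("slice lengths must be positive, strictly increasing")
        self.slice_seconds = tuple(s)
        bad = [m for m in self.measures if m not in MEASURE_NAMES]
        if bad:
            raise ConfigError(f"unknown measure(s): {bad}")


def render_decile_figure_data(deciles: pd.DataFrame) -> pd.DataFrame:
    """Cross-consultation mean and standard error per decile and measure.

    Input is the tidy ``deciles.csv`` table; output has one row per
    (measure, decile) with the mean, the SE of the mean across
    consultations, and the contributing n.  With a single consultation the
    SE is reported as NaN.
    """
    if deciles.empty:
        raise FaceGazeError("decile table is empty")
    long = deciles.melt(
        id_vars=["consultation_id", "decile"],
        value_vars=[m for m in MEASURE_NAMES if m in deciles.columns],
        var_name="measure",
        value_name="value",
    ).dropna(subset=["value"])
    g = long.groupby(["measure", "decile"])["value"]
    out = g.agg(mean="mean", sd="std", n="count").reset_index()
    out["se"] = out["sd"] / np.sqrt(out["n"])
    return out[["measure", "decile", "mean", "se", "n"]]


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Run the full analysis and write all outputs under ``config.out_dir``.

    Returns a mapping of output name to file path.  Any stage error is
    re-raised annotated with the stage name.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    run_log: dict[str, object] = {"stages": []}

    def _stage(name: str):
        run_log["stages"].append(name)
        log.info("pipeline stage: %s", name)

    # -- load or simulate --------------------------------------------------
    if config.synthetic is not None:
        _stage("simulate")
        seed = config.seed if config.seed is not None else config.synthetic.seed
        streams, cohort = sample_cohort(config.synthetic, seed=seed)
        run_log["seed"] = seed
    else:
        _stage("load")
        cohort = fio.read_cohort(os.path.join(config.input_dir, "cohort.csv"))
        streams = fio.read_stream_dir(config.input_dir, cohort=cohort)
        run_log["seed"] = config.seed
    run_log["n_consultations"] = len(streams)
    run_log["n_physicians"] = int(cohort["physician_id"].nunique())

    kw = dict(
        min_instance_frames=config.min_instance_frames,
        bridge_invalid_frames=config.bridge_invalid_frames,
    )
    paths: dict[str, str] = {}

    def _write(name: str, df: pd.DataFrame) -> None:
        path = os.path.join(config.out_dir, f"{name}.csv")
        df.to_csv(path, index=False)
        paths[name] = path

    _stage("measures")
    meas = measures_table(streams, **kw)
    meas["satisfaction"] = meas["consultation_id"].map(
        dict(zip(cohort["consultation_id"], cohort["satisfaction"]))
    )
    _write("measures", meas)

    _stage("deciles")
    too_short = [s.consultation_id for s in streams if s.n_valid < 10]
    if too_short:
        log.warning("deciles: excluding %d too-short stream(s)", len(too_short))
    run_log["decile_exclusions"] = too_short
    dec = decile_table([s for s in streams if s.n_valid >= 10], **kw)
    _write("deciles", dec)
    _write("figure_deciles", render_decile_figure_data(dec))

    _stage("trend")
    trend_rows = []
    for m in config.measures:
        try:
            res = DecileTrendModel(dec, measure_name=m).fit()
        except SingularFitError as exc:
            raise SingularFitError(f"trend stage, measure {m}: {exc}") from exc
        trend_rows.append(
            {
                "measure": m,
                "beta_per_decile": res.beta,
                "beta_se": res.beta_se,
                "p_value": res.p_value,
                "intercept_mid": res.intercept,
                "random_intercept_sd": res.random_intercept_sd,
                "residual_sd": res.residual_sd,
                "n_consultations": res.n_consultations,
            }
        )
    _write("trend", pd.DataFrame(trend_rows))

    _stage("correlate")
    results = pairwise_correlations(meas) + outcome_correlations(meas, cohort)
    _write("correlations", correlations_frame(results))

    _stage("thinslice")
    longest = max(config.slice_seconds)
    excluded = [
        s.consultation_id
        for s in streams
        if s.n_valid * s.frame_interval_s <= longest
    ]
    run_log["thinslice_exclusions"] = excluded
    if excluded:
        log.warning(
            "thin slice: %d consultation(s) shorter than the longest slice",
            len(excluded),
        )
    table2 = slice_length_sweep(
        streams,
        slice_seconds=config.slice_seconds,
        measures=config.measures,
        with_physician_effect=config.with_physician_effect,
        **kw,
    )
    _write("table2", table2)

    _stage("log")
    log_path = os.path.join(config.out_dir, "run_log.json")
    import facegaze

    run_log["facegaze_version"] = facegaze.__version__
    with open(log_path, "w") as fh:
        json.dump(run_log, fh, indent=2)
    paths["run_log"] = log_path
    return paths
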