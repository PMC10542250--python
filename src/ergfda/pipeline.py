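"""End-to-end orchestration: cohort -> landmarks -> registration ->
summaries -> comparison -> CSVs + figures + run manifest."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compare import compare_groups
from .io import Cohort, TimeWindow, read_cohort, restrict_to_window
from .landmarks import (
    DEFAULT_A_SEARCH,
    DEFAULT_B_SEARCH,
    landmark_cohort,
    landmarks_table,
)
from .registration import DEFAULT_GRID_POINTS, register_cohort
from .summaries import BootstrapSpec, summary_bundle
from .simulate import SimulationConfig, simulate_cohort

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

_ESTIMATORS = ("mean", "median", "sd", "mad")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one run needs; YAML-loadable, CLI flags override keys."""

    waveform_file: str | None = None
    metadata_file: str | None = None
    simulation: SimulationConfig | None = None
    display_window: tuple[float, float] = (9.55, 34.9)
    a_search: tuple[float, float] = (DEFAULT_A_SEARCH.start, DEFAULT_A_SEARCH.end)
    b_search: tuple[float, float] = (DEFAULT_B_SEARCH.start, DEFAULT_B_SEARCH.end)
    grid_points: int = DEFAULT_GRID_POINTS
    estimators: tuple[str, ...] = ("mean", "median", "sd", "mad")
    alpha: float = 0.05
    n_boot: int = 1000
    seed: int = 42
    group_a: str | None = None
    group_b: str | None = None
    make_plots: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        bad = [e for e in self.estimators if e not in _ESTIMATORS]
        if bad:
            raise ValueError(f"unknown estimator(s) {bad}; choose from {_ESTIMATORS}")
        if self.grid_points < 2:
            raise ValueError("grid_points must be >= 2")
        if self.waveform_file is None and self.simulation is None:
            raise ValueError("provide either waveform/metadata files or a simulation config")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        d = dict(raw)
        if d.get("simulation") is not None and not isinstance(
            d["simulation"], SimulationConfig
        ):
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        for key in ("display_window", "a_search", "b_search", "estimators"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _write_summary_csvs(bundle, label: str, axis: str, out: Path) -> None:
    for est in ("mean", "median", "sd", "mad"):
        c = bundle[est]
        pd.DataFrame(
            {
                "grid": c.grid,
                "estimate": c.estimate,
                "ci_low": c.ci_low,
                "ci_high": c.ci_high,
                "n": c.n,
            }
        ).to_csv(out / f"summary_{axis}_{label}_{est}.csv", index=False)
    bx = bundle.boxplots
    pd.DataFrame(
        {
            "grid": bx.grid,
            "median": bx.median,
            "q1": bx.q1,
            "q3": bx.q3,
            "whisker_low": bx.whisker_low,
            "whisker_high": bx.whisker_high,
            "n_outliers": [len(o) for o in bx.outliers],
        }
    ).to_csv(out / f"boxplot_{axis}_{label}.csv", index=False)


def run_pipeline(cfg: PipelineConfig, out_dir) -> dict:
    """Run the whole analysis and write its artifact directory.

    Returns the manifest dictionary (also written as ``manifest.json``).
    Any stage failure is logged with the stage name and re-raised.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        if cfg.simulation is not None:
            cohort = simulate_cohort(cfg.simulation)
            logger.info("simulated cohort: %d waveforms", len(cohort))
        else:
            cohort = read_cohort(cfg.waveform_file, cfg.metadata_file)
            logger.info("read cohort: %d waveforms", len(cohort))

        labels = cohort.group_labels
        group_a = cfg.group_a or labels[0]
        group_b = cfg.group_b or (labels[1] if len(labels) > 1 else labels[0])
        for g in (group_a, group_b):
            if g not in labels:
                raise ValueError(f"group {g!r} not in cohort groups {labels}")

        stage = "window"
        display = restrict_to_window(
            cohort, TimeWindow(*cfg.display_window)
        )

        stage = "landmark"
        lm = landmark_cohort(
            cohort, TimeWindow(*cfg.a_search), TimeWindow(*cfg.b_search)
        )
        landmarks_table(lm).to_csv(out / "landmarks.csv", index=False)

        stage = "register"
        ens = register_cohort(lm.usable_segments, cfg.grid_points)
        ens.to_frame().to_csv(out / "registered.csv", index=False)

        stage = "summarize"
        boot = BootstrapSpec(cfg.n_boot, cfg.seed)
        raw_grid, _ = display.matrix()
        bundles_raw, bundles_reg, raw_mats = {}, {}, {}
        for g in dict.fromkeys((group_a, group_b)):
            _, mat = display.by_group(g).matrix()
            raw_mats[g] = mat
            bundles_raw[g] = summary_bundle(
                mat, raw_grid, display.by_group(g).waveform_ids,
                cfg.alpha, boot, axis="raw",
            )
            _write_summary_csvs(bundles_raw[g], g, "raw", out)
            regmat = ens.group_matrix(g)
            bundles_reg[g] = summary_bundle(
                regmat, ens.grid, None, cfg.alpha, boot, axis="registered"
            )
            _write_summary_csvs(bundles_reg[g], g, "registered", out)

        stage = "compare"
        comparisons = {}
        for axis, grid, mats in (
            ("raw", raw_grid, raw_mats),
            ("registered", ens.grid, {g: ens.group_matrix(g) for g in raw_mats}),
        ):
            for est in cfg.estimators:
                res = compare_groups(
                    mats[group_a], mats[group_b], grid, est,
                    cfg.alpha, boot, axis, labels=(group_a, group_b),
                )
                comparisons[(axis, est)] = res
                res.to_frame().to_csv(out / f"comparison_{axis}_{est}.csv", index=False)
                res.intervals_frame().to_csv(
                    out / f"intervals_{axis}_{est}.csv", index=False
                )

        figures: list[str] = []
        if cfg.make_plots:
            stage = "plot"
            from . import plots  # deferred: matplotlib import is slow

            figures += [
                str(p)
                for p in plots.save_figure(
                    plots.pointwise_boxplot_figure(
                        {g: bundles_raw[g].boxplots for g in bundles_raw}
                    ),
                    out / "fig1_boxplots_raw",
                )
            ]
            reg_trajs = {
                g: (ens.grid, ens.group_matrix(g)) for g in bundles_reg
            }
            raw_trajs = {
                g: (raw_grid, raw_mats[g]) for g in raw_mats
            }
            figures += [
                str(p)
                for p in plots.save_figure(
                    plots.group_summary_figure(
                        raw_trajs,
                        {g: bundles_raw[g].mean for g in bundles_raw},
                        {g: bundles_raw[g].sd for g in bundles_raw},
                        axis="raw",
                    ),
                    out / "fig2_raw_summary",
                )
            ]
            figures += [
                str(p)
                for p in plots.save_figure(
                    plots.group_summary_figure(
                        reg_trajs,
                        {g: bundles_reg[g].mean for g in bundles_reg},
                        {g: bundles_reg[g].sd for g in bundles_reg},
                        axis="registered",
                    ),
                    out / "fig3_registered_summary",
                )
            ]
            for (axis, est), res in comparisons.items():
                if est == "mean":
                    figures += [
                        str(p)
                        for p in plots.save_figure(
                            plots.comparison_figure(res, axis=axis),
                            out / f"comparison_{axis}_{est}",
                        )
                    ]
    except Exception:
        logger.exception("pipeline stage %r failed", stage)
        raise

    manifest = {
        "package": "ergfda",
        "version": __version__,
        "numpy": np.__version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "groups": [group_a, group_b],
        "n_waveforms": len(cohort),
        "landmark_failures": lm.failures,
        "degenerate_waveforms": lm.degenerate_ids,
        "figures": figures,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
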