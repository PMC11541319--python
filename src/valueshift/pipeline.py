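"""End-to-end orchestration: obtain data (file or simulation), QC,
fit, reweight, summarize, and write a reproducible artifact bundle.

A run writes to its output directory:

- ``filter_report.json``   -- respondent exclusion audit
- ``draws.csv``            -- flat posterior draws table
- ``diagnostics.json``     -- per-block acceptance rates and R-hat table
- ``valueset.csv``         -- original/updated/difference summary
- ``manifest.json``        -- config echo, master seed, versions, status

Convergence is advisory: R-hat above the threshold flags the run
(``converged = False`` in the manifest and a warning exit status from
the CLI) but the outputs are still written.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import (
    DemographicWeights,
    ValuationDataset,
    load_reference_weights,
    read_tto_table,
    read_weights,
    write_draws_table,
    write_valueset,
)
from .mcmc import MCMCConfig, PosteriorDraws, fit, rhat_table
from .monitor import monitor_valuesets, summarize
from .qc import FilterReport, run_qc
from .synth import TruthScenario, default_truth, simulate_study

RHAT_WARN = 1.05


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    weights_original: str  # path to a weights CSV or a packaged label
    weights_updated: str
    outdir: str
    data_path: str | None = None
    column_map: str | dict | None = None
    scenario: str | dict | None = None  # country style or scenario overrides
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    min_obs: int = 10
    verbosity: int = 1

    def __post_init__(self) -> None:
        if (self.data_path is None) == (self.scenario is None):
            raise ValueError("exactly one of data_path or scenario must be set")
        if self.weights_original == self.weights_updated is None:
            raise ValueError("two weightings are required")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        mcmc = MCMCConfig(**raw.pop("mcmc", {}))
        return cls(mcmc=mcmc, **raw)


def _resolve_weights(spec: str) -> DemographicWeights:
    if isinstance(spec, str) and not Path(spec).exists():
        try:
            return load_reference_weights(spec)
        except ValueError:
            raise FileNotFoundError(
                f"weights {spec!r}: no such file and not a packaged label"
            ) from None
    return read_weights(spec)


def _resolve_scenario(scenario, seed: int) -> TruthScenario:
    if isinstance(scenario, str):
        return default_truth(scenario, seed=seed)
    opts = dict(scenario)
    style = opts.pop("country_style")
    truth = default_truth(style, seed=seed, **{
        k: opts.pop(k) for k in ("n_respondents", "contaminate") if k in opts
    })
    if opts:
        raise ValueError(f"unknown scenario options: {sorted(opts)}")
    return truth


@dataclass
class PipelineResult:
    outdir: Path
    filter_report: FilterReport
    draws: PosteriorDraws
    summary: pd.DataFrame
    rhats: dict[str, float]
    converged: bool
    manifest: dict


def run_pipeline(config: RunConfig) -> PipelineResult:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = print if config.verbosity > 0 else (lambda *a, **k: None)
    manifest: dict = {
        "valueshift_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": config.mcmc.seed,
        "mcmc": {
            "n_chains": config.mcmc.n_chains,
            "n_burnin": config.mcmc.n_burnin,
            "n_total": config.mcmc.n_total,
            "thin": config.mcmc.thin,
            "antithetic": config.mcmc.antithetic,
        },
        "weights_original": config.weights_original,
        "weights_updated": config.weights_updated,
        "stages": {},
    }

    def stage(name):
        manifest["stages"][name] = "ok"

    try:
        w_orig = _resolve_weights(config.weights_original)
        w_upd = _resolve_weights(config.weights_updated)
    except Exception as exc:
        raise RuntimeError(f"stage 'weights' failed: {exc}") from exc
    stage("weights")

    try:
        if config.data_path is not None:
            if not Path(config.data_path).exists():
                raise FileNotFoundError(f"no such data file: {config.data_path}")
            dataset = read_tto_table(
                config.data_path, column_map=config.column_map, max_value=None
            )
            manifest["input"] = {"data_path": str(config.data_path)}
        else:
            truth = _resolve_scenario(config.scenario, seed=config.mcmc.seed)
            dataset = simulate_study(truth)
            manifest["input"] = {
                "scenario": config.scenario
                if isinstance(config.scenario, (str, dict))
                else repr(config.scenario),
                "n_respondents": truth.n_respondents,
            }
        log(f"input: {dataset.n_respondents} respondents, "
            f"{dataset.n_observations} observations")
    except Exception as exc:
        raise RuntimeError(f"stage 'input' failed: {exc}") from exc
    stage("input")

    try:
        kept, report = run_qc(dataset, min_obs=config.min_obs)
        report.to_json(outdir / "filter_report.json")
        log(f"qc: retained {report.n_retained}/{report.n_input} "
            f"(min-obs {report.n_excluded_min_obs}, "
            f"positive-slope {report.n_excluded_positive_slope})")
    except Exception as exc:
        raise RuntimeError(f"stage 'qc' failed: {exc}") from exc
    stage("qc")

    try:
        draws = fit(kept, config.mcmc)
        write_draws_table(draws.to_flat_table(), outdir / "draws.csv")
        rhats = rhat_table(draws)
        diagnostics = {
            "rhat": rhats,
            "acceptance_rates": draws.accept_rates,
            "step_sizes": draws.step_sizes,
        }
        with open(outdir / "diagnostics.json", "w") as fh:
            json.dump(diagnostics, fh, indent=2, default=float)
        finite = [v for v in rhats.values() if np.isfinite(v)]
        max_rhat = max(finite) if finite else float("nan")
        log(f"fit: {draws.n_chains} chains x {draws.n_draws} draws, "
            f"max R-hat {max_rhat:.4f}")
    except Exception as exc:
        raise RuntimeError(f"stage 'fit' failed: {exc}") from exc
    stage("fit")

    try:
        vs = monitor_valuesets(draws, w_orig, w_upd)
        summary = summarize(vs)
        write_valueset(summary, outdir / "valueset.csv")
    except Exception as exc:
        raise RuntimeError(f"stage 'reweight' failed: {exc}") from exc
    stage("reweight")

    converged = bool(np.isfinite(max_rhat) and max_rhat <= RHAT_WARN)
    manifest["max_rhat"] = float(max_rhat)
    manifest["converged"] = converged
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    if not converged:
        log(f"warning: max R-hat {max_rhat:.4f} > {RHAT_WARN}; "
            "inspect chains before trusting the summaries")
    return PipelineResult(outdir, report, draws, summary, rhats, converged, manifest)


def _fmt(x: float) -> str:
    # two decimals, banker's (half-even) rounding as used by format()
    return f"{x:.2f}"


def report(bundle) -> str:
    """Human-readable per-decrement table ``mean (lo - hi)`` for the
    original and updated value sets and their difference; a star marks
    difference intervals excluding 0."""
    if isinstance(bundle, PipelineResult):
        summary = bundle.summary
    elif isinstance(bundle, (str, Path)):
        path = Path(bundle) / "valueset.csv"
        missing = [
            p for p in ("valueset.csv", "filter_report.json", "manifest.json")
            if not (Path(bundle) / p).exists()
        ]
        if missing:
            raise ValueError(f"incomplete bundle {bundle}: missing {missing}")
        summary = pd.read_csv(path)
    else:
        summary = bundle
    lines = [
        f"{'':6s}{'original':>22s}{'updated':>22s}{'difference':>24s}",
    ]
    for _, row in summary.iterrows():
        cells = []
        for stem in ("original", "updated", "diff"):
            cells.append(
                f"{_fmt(row[f'{stem}_mean'])} "
                f"({_fmt(row[f'{stem}_lo'])} - {_fmt(row[f'{stem}_hi'])})"
            )
        star = " *" if row.get("diff_significant", False) else ""
        lines.append(
            f"{row['label']:6s}{cells[0]:>22s}{cells[1]:>22s}{cells[2]:>24s}{star}"
        )
    return "\n".join(lines)
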