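"""Declarative experiment drivers for the four benchmark families:
discriminability sweeps, threshold/topology analysis, rms-error sweeps, and
Potts-vs-Ising comparisons.

Each driver takes an :class:`ExperimentConfig`, runs the full
generate -> sample -> score -> evaluate pipeline with explicit seeds, and
returns an :class:`ExperimentResult` whose records are bit-reproducible for
a fixed config. Shipped presets carry the published parameter choices
(n, mean degree, K, temperature grids) plus scaled-down twins for quick runs.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluation import (
    auc,
    false_positive_topology,
    rmse_report,
    threshold_by_closest_to_ideal,
)
from .graph_ensemble import CouplingMatrix, GraphSpec, generate_er_couplings, pair_topology
from .inference import (
    estimate_moments,
    global_scores,
    local_scores,
    mean_field_inversion,
)
from .mean_field import critical_temperature, ising_order_parameter, potts_order_parameter
from .spin_sampler import SpinModel, sample_gibbs, sample_ising_exact

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "PRESETS",
    "get_preset",
    "run_discriminability",
    "run_threshold_topology",
    "run_rmse_sweep",
    "run_potts_comparison",
    "run_experiment",
]


@dataclass
class ExperimentConfig:
    """Declarative description of one experiment family run."""

    kind: str  # discriminability | threshold_topology | rmse | potts
    n: int
    mean_degree: float
    graph_seed: int = 0
    q: int | tuple = 2
    temperatures: tuple = (0.5, 0.7, 0.85, 1.0, 1.25, 1.5)
    temperatures_in_tc_units: bool = True
    sample_sizes: tuple = (10_000,)
    sampler: str = "gibbs"
    burn_in: int = 1_000
    thinning: int = 10
    ridge: float | None = None
    threshold_mode: str = "validated"
    validation_fraction: float = 0.2
    lp: float = 2.0
    replicate_seeds: tuple = (0,)
    fresh_graph_per_replicate: bool = False

    def __post_init__(self):
        if not self.temperatures:
            raise ValueError("temperature grid must be nonempty")
        self.temperatures = tuple(float(t) for t in self.temperatures)
        self.sample_sizes = tuple(int(k) for k in self.sample_sizes)
        self.replicate_seeds = tuple(int(s) for s in self.replicate_seeds)
        if isinstance(self.q, (list, tuple)):
            self.q = tuple(int(x) for x in self.q)
        else:
            self.q = int(self.q)

    def scaled(self, factor: float) -> "ExperimentConfig":
        """Shrink n and K by ``factor`` (runtime knob; >= 1 shrinks).

        n never drops below twice the mean degree, keeping the edge
        probability lambda/n <= 1/2 (so both edge classes stay populated).
        """
        floor = max(8, int(np.ceil(2 * self.mean_degree)))
        return dataclasses.replace(
            self,
            n=max(floor, int(self.n / factor)),
            sample_sizes=tuple(max(100, int(k / factor)) for k in self.sample_sizes),
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        data = dict(data)
        data.pop("schema_version", None)
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class ExperimentResult:
    config: dict
    records: pd.DataFrame
    extras: dict = field(default_factory=dict)
    version: str = __version__
    warnings_seen: list = field(default_factory=list)

    def save(self, out_dir, force: bool = False) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        meta_path = out / "metadata.json"
        if meta_path.exists() and not force:
            raise FileExistsError(
                f"{meta_path} exists; results are append-only (pass force=True)"
            )
        with open(meta_path, "w") as fh:
            json.dump(
                {
                    "config": self.config,
                    "version": self.version,
                    "warnings": self.warnings_seen,
                    "extras": self.extras,
                },
                fh,
                indent=2,
                default=str,
            )
        self.records.to_csv(out / "records.tsv", sep="\t", index=False)


def _seed_for(base: int, *indices: int) -> int:
    return int(np.random.SeedSequence([base, *indices]).generate_state(1)[0] % 2**31)


def _graph_for(config: ExperimentConfig, replicate_seed: int) -> CouplingMatrix:
    seed = (
        _seed_for(replicate_seed, 9999)
        if config.fresh_graph_per_replicate
        else config.graph_seed
    )
    return generate_er_couplings(GraphSpec(config.n, config.mean_degree, seed))


def _absolute_temperature(config: ExperimentConfig, t: float, q: int) -> float:
    if config.temperatures_in_tc_units:
        return t * critical_temperature(config.mean_degree, q)
    return t


def _draw_samples(config: ExperimentConfig, J, T: float, q: int, K: int, seed: int):
    model = SpinModel(couplings=J, temperature=T, num_states=q)
    if config.sampler == "cftp":
        if q != 2:
            raise ValueError("the exact CFTP sampler only supports q = 2")
        return sample_ising_exact(model, K, seed)
    return sample_gibbs(model, K, seed, burn_in=config.burn_in, thinning=config.thinning)


def _score_both(config, J, samples, T):
    moments = estimate_moments(samples)
    local = local_scores(moments, truth=J)
    inferred = mean_field_inversion(moments, temperature=T, ridge=config.ridge)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate marginals recorded upstream
        glob = global_scores(inferred, moments, truth=J)
    return moments, local, inferred, glob


def run_discriminability(config: ExperimentConfig) -> ExperimentResult:
    """Local vs global AUC over (temperature, sample size, replicate)."""
    q = config.q if isinstance(config.q, int) else config.q[0]
    rows = []
    for rep, rep_seed in enumerate(config.replicate_seeds):
        J = _graph_for(config, rep_seed)
        for ti, t in enumerate(config.temperatures):
            T = _absolute_temperature(config, t, q)
            for ki, K in enumerate(config.sample_sizes):
                seed = _seed_for(rep_seed, ti, ki)
                samples = _draw_samples(config, J, T, q, K, seed)
                _, local, _, glob = _score_both(config, J, samples, T)
                for scored in (local, glob):
                    rows.append(
                        {
                            "replicate": rep,
                            "seed": seed,
                            "T": T,
                            "T_over_Tc": t if config.temperatures_in_tc_units else np.nan,
                            "K": K,
                            "method": scored.method,
                            "auc": auc(scored),
                        }
                    )
    return ExperimentResult(config=config.to_dict(), records=pd.DataFrame(rows))


def run_threshold_topology(config: ExperimentConfig) -> ExperimentResult:
    """Validation/test thresholding, rates, and distance-2 FP histograms."""
    q = config.q if isinstance(config.q, int) else config.q[0]
    rows = []
    histograms = {}
    for rep, rep_seed in enumerate(config.replicate_seeds):
        J = _graph_for(config, rep_seed)
        topo = pair_topology(J)
        for ti, t in enumerate(config.temperatures):
            T = _absolute_temperature(config, t, q)
            K = config.sample_sizes[0]
            seed = _seed_for(rep_seed, ti, 0)
            samples = _draw_samples(config, J, T, q, K, seed)
            _, local, _, glob = _score_both(config, J, samples, T)
            split_seed = _seed_for(rep_seed, ti, 777)
            for scored in (local, glob):
                val, test = scored.split(config.validation_fraction, split_seed)
                report = threshold_by_closest_to_ideal(val, test, p=config.lp)
                fp_topo = false_positive_topology(report, topo)
                key = f"rep{rep}_T{t:g}_{scored.method}"
                histograms[key] = {
                    "fp": fp_topo.fp_counts,
                    "baseline": fp_topo.baseline_counts,
                }
                rows.append(
                    {
                        "replicate": rep,
                        "seed": seed,
                        "T": T,
                        "T_over_Tc": t if config.temperatures_in_tc_units else np.nan,
                        "K": K,
                        "method": scored.method,
                        "threshold": report.threshold,
                        "tpr": report.tpr,
                        "fpr": report.fpr,
                        "positive_rate": report.positive_rate,
                        "overprediction": report.overprediction,
                        "histogram_key": key,
                    }
                )
    return ExperimentResult(
        config=config.to_dict(),
        records=pd.DataFrame(rows),
        extras={"fp_histograms": histograms},
    )


def run_rmse_sweep(config: ExperimentConfig) -> ExperimentResult:
    """Rms error of the de-dimensionalized couplings per (T, K, replicate)."""
    rows = []
    for rep, rep_seed in enumerate(config.replicate_seeds):
        J = _graph_for(config, rep_seed)
        for ti, t in enumerate(config.temperatures):
            T = _absolute_temperature(config, t, 2)
            for ki, K in enumerate(config.sample_sizes):
                seed = _seed_for(rep_seed, ti, ki)
                samples = _draw_samples(config, J, T, 2, K, seed)
                moments = estimate_moments(samples)
                inferred = mean_field_inversion(moments, temperature=T, ridge=config.ridge)
                rep_out = rmse_report(inferred, J)
                rows.append(
                    {
                        "replicate": rep,
                        "seed": seed,
                        "T": T,
                        "T_over_Tc": t if config.temperatures_in_tc_units else np.nan,
                        "K": K,
                        "rmse": rep_out.rmse,
                        "mean_class0": rep_out.bias_by_class[0.0],
                        "mean_class1": rep_out.bias_by_class[1.0],
                        "var_class0": rep_out.variance_by_class[0.0],
                        "var_class1": rep_out.variance_by_class[1.0],
                    }
                )
    return ExperimentResult(config=config.to_dict(), records=pd.DataFrame(rows))


def run_potts_comparison(config: ExperimentConfig) -> ExperimentResult:
    """AUC vs temperature and vs mean-field order parameter across q.

    The same interaction graph backs every q; temperatures are interpreted in
    units of each q's own critical temperature when the config says so.
    """
    qs = config.q if isinstance(config.q, tuple) else (config.q,)
    if any(q not in (2, 3, 4) for q in qs):
        raise ValueError("Potts comparison presets cover q in {2, 3, 4}")
    J = generate_er_couplings(GraphSpec(config.n, config.mean_degree, config.graph_seed))
    rows = []
    for qi, q in enumerate(qs):
        for rep, rep_seed in enumerate(config.replicate_seeds):
            for ti, t in enumerate(config.temperatures):
                T = _absolute_temperature(config, t, q)
                delta = (
                    ising_order_parameter(T, config.mean_degree)
                    if q == 2
                    else potts_order_parameter(T, config.mean_degree, q)
                )
                for ki, K in enumerate(config.sample_sizes):
                    seed = _seed_for(rep_seed, qi, ti, ki)
                    samples = _draw_samples(config, J, T, q, K, seed)
                    _, local, _, glob = _score_both(config, J, samples, T)
                    for scored in (local, glob):
                        rows.append(
                            {
                                "replicate": rep,
                                "seed": seed,
                                "q": q,
                                "T": T,
                                "T_over_Tc": t
                                if config.temperatures_in_tc_units
                                else np.nan,
                                "mean_field_delta": delta,
                                "K": K,
                                "method": scored.method,
                                "auc": auc(scored),
                            }
                        )
    return ExperimentResult(config=config.to_dict(), records=pd.DataFrame(rows))


_RUNNERS = {
    "discriminability": run_discriminability,
    "threshold_topology": run_threshold_topology,
    "rmse": run_rmse_sweep,
    "potts": run_potts_comparison,
}


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    try:
        runner = _RUNNERS[config.kind]
    except KeyError:
        raise ValueError(
            f"unknown experiment kind {config.kind!r}; choose from {sorted(_RUNNERS)}"
        ) from None
    return runner(config)


# -- shipped presets ---------------------------------------------------------
# published parameter choices, each with a scaled-down twin for quick runs

PRESETS: dict[str, ExperimentConfig] = {
    "fig2": ExperimentConfig(
        kind="discriminability",
        n=50,
        mean_degree=20,
        temperatures=(0.7, 1.0, 1.5),
        sample_sizes=(5_000,),
    ),
    "fig3a": ExperimentConfig(
        kind="discriminability", n=400, mean_degree=40, sample_sizes=(2_000,)
    ),
    "fig3b": ExperimentConfig(
        kind="discriminability", n=400, mean_degree=40, sample_sizes=(10_000,)
    ),
    "fig4": ExperimentConfig(
        kind="threshold_topology", n=400, mean_degree=40, sample_sizes=(10_000,)
    ),
    "fig5": ExperimentConfig(
        kind="rmse", n=400, mean_degree=40, sample_sizes=(2_000, 10_000)
    ),
    "fig7": ExperimentConfig(
        kind="potts",
        n=400,
        mean_degree=40,
        q=(2, 3, 4),
        sample_sizes=(2_000, 10_000),
    ),
}
PRESETS.update(
    {f"{name}_small": cfg.scaled(4.0) for name, cfg in PRESETS.items()}
)


def get_preset(name: str) -> ExperimentConfig:
    try:
        return dataclasses.replace(PRESETS[name])
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
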