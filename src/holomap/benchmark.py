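"""End-to-end benchmark driver: accuracy versus simulated stimulation time.

Simulates a continuous mapping experiment, demixes it (optionally), and fits
each requested method on growing trial prefixes, reporting the R^2 between
true and estimated weights plus precision/recall at each time point —
the accuracy-versus-time comparison used to quantify how quickly each
inference method converges.
"""

from __future__ import annotations

import time as _time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import baselines, caviar
from .nwd import demix as nwd_demix
from .nwd import integrate_charge
from .postprocess import compare_maps
from .simulate import (
    NoiseConfig,
    SimConfig,
    StimulusDesign,
    design_stimulus,
    sample_ground_truth,
    simulate_continuous,
)


@dataclass
class BenchmarkConfig:
    """Study conditions for one accuracy-vs-time benchmark."""

    n_neurons: int = 300
    connect_rate: float = 0.1
    ensemble_size: int = 20
    stim_rate: float = 50.0
    spont_rate: float = 1.0
    duration_s: float = 30.0
    n_replicates: int = 3
    prefix_fractions: tuple = (0.25, 0.5, 0.75, 1.0)
    methods: tuple = ("caviar", "cosamp", "cavi-sns")
    use_nwd: bool = True
    seed: int = 0
    sim: SimConfig = None
    noise: NoiseConfig = None
    hyper: caviar.ModelHyperparams = None

    def resolve(self):
        sim = self.sim or SimConfig(n_neurons=self.n_neurons, connect_rate=self.connect_rate)
        sim.n_neurons = self.n_neurons
        sim.connect_rate = self.connect_rate
        noise = self.noise or NoiseConfig()
        noise.spont_rate = self.spont_rate
        hyper = self.hyper or caviar.ModelHyperparams()
        return sim, noise, hyper


def _prefix_design(design: StimulusDesign, k: int) -> StimulusDesign:
    return StimulusDesign(
        design.powers[:, :k],
        design.power_set,
        design.holograms,
        design.trial_hologram[:k],
        design.sweep[:k],
        design.stim_rate,
    )


def fit_method(method, y, design, traces, truth, hyper, rng):
    """Dispatch one inference method; returns the estimated weight vector."""
    if method == "caviar":
        res = caviar.fit(y, design, hyper, rng, traces=traces)
        return res.weights, res
    if method == "cavi-sns":
        res = baselines.cavi_sns(y, design, hyper, rng)
        return res.weights, res
    if method == "cosamp":
        sparsity = int(truth.connected.sum())
        res = baselines.cosamp(y, (design.powers > 0).astype(float), sparsity)
        return res.weights, res
    raise ValueError(f"unknown method {method!r}")


def run_benchmark(
    config: BenchmarkConfig, model=None, verbose: bool = False
) -> pd.DataFrame:
    """Run the benchmark; returns one row per
    (method, replicate, prefix) with accuracy metrics and wall-clock cost.

    ``model`` is a trained demixing network; required when ``use_nwd``.
    Trial prefixes follow presentation order, so a prefix of the trials is
    exactly the experiment had it been stopped early.
    """
    sim_cfg, noise_cfg, hyper = config.resolve()
    if config.use_nwd and model is None:
        raise ValueError("use_nwd=True requires a trained demixing network")
    n_trials_total = int(config.duration_s * config.stim_rate)
    n_sweeps = int(np.ceil(n_trials_total / np.ceil(config.n_neurons / config.ensemble_size)))
    rows = []
    for rep in range(config.n_replicates):
        rng = np.random.default_rng([config.seed, rep])
        truth = sample_ground_truth(sim_cfg, rng)
        design = design_stimulus(
            config.n_neurons, config.ensemble_size, n_sweeps,
            stim_rate=config.stim_rate, rng=rng,
        )
        design = _prefix_design(design, n_trials_total)
        record = simulate_continuous(truth, design, noise_cfg, rng)
        if config.use_nwd:
            traces = nwd_demix(model, record.traces)
        else:
            traces = record.traces
        charges = integrate_charge(traces)
        for frac in config.prefix_fractions:
            k = max(1, int(round(frac * design.n_trials)))
            sub = _prefix_design(design, k)
            t_stim = k / config.stim_rate
            for method in config.methods:
                t0 = _time.perf_counter()
                method_id = {"caviar": 0, "cosamp": 1, "cavi-sns": 2}.get(method, 9)
                w_est, _ = fit_method(
                    method, charges[:k], sub, traces[:k], truth, hyper,
                    np.random.default_rng([config.seed, rep, method_id]),
                )
                wall = _time.perf_counter() - t0
                cmp = compare_maps(truth.weights, w_est)
                rows.append(
                    {
                        "method": method,
                        "nwd": config.use_nwd,
                        "replicate": rep,
                        "n_trials": k,
                        "stim_time_s": t_stim,
                        "r2": cmp.r2,
                        "precision": cmp.precision,
                        "recall": cmp.recall,
                        "wall_time_s": wall,
                    }
                )
                if verbose:
                    print(f"[benchmark] rep={rep} t={t_stim:.1f}s {method}: "
                          f"R2={cmp.r2:.3f} P={cmp.precision:.2f} R={cmp.recall:.2f}")
    return pd.DataFrame(rows)


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- s.d. over replicates for each method and time point."""
    g = table.groupby(["method", "nwd", "stim_time_s"])
    out = g[["r2", "precision", "recall"]].agg(["mean", "std"])
    out.columns = ["_".join(c) for c in out.columns]
    return out.reset_index()
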