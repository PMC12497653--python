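"""HDF5 containers for experiments and inference results.

An experiment file stores the trial traces, the stimulus design (powers,
power set, ragged hologram target lists via index arrays), optional latent
ground truth and spontaneous-event log, and — once demixing has run — the
demixed traces and integrated charges.  Round-trips are lossless.
"""

from __future__ import annotations

import numpy as np

try:
    import h5py
except ImportError as exc:  # pragma: no cover
    raise ImportError("holomap.io requires h5py") from exc

from .caviar import CaviarResult
from .simulate import ExperimentRecord, GroundTruth, SimConfig, StimulusDesign

SCHEMA_VERSION = 1


class SchemaError(ValueError):
    pass


def write_experiment(record: ExperimentRecord, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["sampling_rate_hz"] = record.fs
        f.attrs["stim_onset_sample"] = record.stim_onset
        f.attrs["mode"] = record.mode
        f.create_dataset("traces", data=record.traces.astype(np.float32))
        d = record.design
        f.create_dataset("powers", data=d.powers.astype(np.float32))
        f.create_dataset("power_set", data=np.asarray(d.power_set, dtype=np.float64))
        # ragged hologram target lists as flat values + offsets
        flat = np.concatenate([np.asarray(h) for h in d.holograms]) if d.holograms else np.empty(0, int)
        offsets = np.cumsum([0] + [len(h) for h in d.holograms])
        f.create_dataset("hologram_targets", data=flat.astype(np.int64))
        f.create_dataset("hologram_offsets", data=offsets.astype(np.int64))
        f.create_dataset("trial_hologram", data=d.trial_hologram.astype(np.int64))
        f.create_dataset("sweep", data=d.sweep.astype(np.int64))
        f.attrs["stim_rate_hz"] = d.stim_rate
        if record.truth is not None:
            g = f.create_group("truth")
            t = record.truth
            g.create_dataset("weights", data=t.weights)
            g.create_dataset("connected", data=t.connected)
            g.create_dataset("strong", data=t.strong)
            g.create_dataset("phi", data=t.phi)
            g.create_dataset("tau_r", data=t.tau_r)
            g.create_dataset("tau_d", data=t.tau_d)
        if record.spikes is not None:
            f.create_dataset("spikes", data=record.spikes.astype(np.int8))
        if record.latencies is not None:
            f.create_dataset("latencies", data=record.latencies)
        if record.target_traces is not None:
            f.create_dataset("target_traces", data=record.target_traces.astype(np.float32))
        if record.demixed is not None:
            f.create_dataset("traces_demixed", data=record.demixed.astype(np.float32))
        if record.charges is not None:
            f.create_dataset("charges", data=record.charges)
        g = f.create_group("spont")
        g.create_dataset("times_ms", data=record.spont_times)
        g.create_dataset("amplitudes", data=record.spont_amps)


def read_experiment(path) -> ExperimentRecord:
    with h5py.File(path, "r") as f:
        version = f.attrs.get("schema_version")
        if version != SCHEMA_VERSION:
            raise SchemaError(f"unsupported schema version {version!r}")
        for req in ("traces", "powers", "power_set"):
            if req not in f:
                raise SchemaError(f"missing required dataset {req!r}")
        traces = f["traces"][...].astype(float)
        powers = f["powers"][...].astype(float)
        if traces.shape[0] != powers.shape[1]:
            raise SchemaError("traces and powers disagree on trial count")
        flat = f["hologram_targets"][...]
        offsets = f["hologram_offsets"][...]
        holograms = [flat[offsets[i]: offsets[i + 1]] for i in range(len(offsets) - 1)]
        design = StimulusDesign(
            powers=powers,
            power_set=f["power_set"][...],
            holograms=holograms,
            trial_hologram=f["trial_hologram"][...],
            sweep=f["sweep"][...],
            stim_rate=float(f.attrs["stim_rate_hz"]),
        )
        truth = None
        if "truth" in f:
            g = f["truth"]
            truth = GroundTruth(
                weights=g["weights"][...],
                connected=g["connected"][...].astype(bool),
                strong=g["strong"][...].astype(bool),
                phi=g["phi"][...],
                tau_r=g["tau_r"][...],
                tau_d=g["tau_d"][...],
                config=SimConfig(n_neurons=powers.shape[0]),
            )
        record = ExperimentRecord(
            traces=traces,
            design=design,
            truth=truth,
            spikes=f["spikes"][...] if "spikes" in f else None,
            latencies=f["latencies"][...] if "latencies" in f else None,
            target_traces=f["target_traces"][...].astype(float) if "target_traces" in f else None,
            spont_times=f["spont/times_ms"][...],
            spont_amps=f["spont/amplitudes"][...],
            mode=str(f.attrs["mode"]),
            fs=float(f.attrs["sampling_rate_hz"]),
            stim_onset=int(f.attrs["stim_onset_sample"]),
        )
        if "traces_demixed" in f:
            record.demixed = f["traces_demixed"][...].astype(float)
        if "charges" in f:
            record.charges = f["charges"][...]
        return record


def write_result(result: CaviarResult, path, config_echo: dict | None = None) -> None:
    """Persist a CAVIaR fit: posterior summaries, power curves, diagnostics."""
    import json

    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        st = result.state
        f.create_dataset("mu", data=st.mu)
        f.create_dataset("Omega_diag", data=np.diag(st.Omega))
        f.create_dataset("lambda", data=st.lam)
        f.create_dataset("z", data=st.z)
        f.create_dataset("connected_mask", data=result.connected)
        f.attrs["lambda_spont"] = st.lam_spont
        f.attrs["theta_sh"] = st.theta_sh
        f.attrs["theta_ra"] = st.theta_ra
        f.attrs["converged"] = result.converged
        f.attrs["n_iter"] = result.n_iter
        g = f.create_group("power_curves")
        for n_ix, curve in enumerate(result.curves):
            if curve is None:
                continue
            gg = g.create_group(str(n_ix))
            gg.create_dataset("powers", data=curve.powers)
            gg.create_dataset("mean_rates", data=curve.mean_rates)
            gg.create_dataset("fitted", data=curve.fitted)
            gg.create_dataset("counts", data=curve.counts)
        if config_echo is not None:
            f.attrs["config_echo"] = json.dumps(config_echo, default=str)


def connectivity_table(result: CaviarResult):
    """Connectivity summary as a pandas DataFrame (one row per neuron)."""
    import pandas as pd

    st = result.state
    fmax = [c.at_max_power() if c is not None else 0.0 for c in result.curves]
    return pd.DataFrame(
        {
            "neuron": np.arange(st.mu.size),
            "weight": st.mu,
            "weight_sd": np.sqrt(np.clip(np.diag(st.Omega), 0, None)),
            "spike_rate_at_max_power": fmax,
            "connected": result.connected,
        }
    )
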