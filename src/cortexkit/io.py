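"""Tab-separated readers/writers for the package's external formats."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .network import Connectome, Network, SpikeRecording
from .synapses import TMSynapseParams


def write_spike_table(recording: SpikeRecording, path) -> None:
    pd.DataFrame({"neuron_id": recording.neuron_ids,
                  "time_ms": recording.times_ms}).to_csv(path, sep="\t",
                                                         index=False)


def read_spike_table(path, duration: float, pop_index: np.ndarray,
                     pop_labels: list[str]) -> SpikeRecording:
    df = pd.read_csv(path, sep="\t")
    return SpikeRecording(neuron_ids=df["neuron_id"].to_numpy(np.int64),
                          times_ms=df["time_ms"].to_numpy(float),
                          duration=duration, pop_index=pop_index,
                          pop_labels=pop_labels)


def write_edge_list(conn: Connectome, path) -> None:
    pd.DataFrame({
        "pre_id": conn.pre, "post_id": conn.post, "nsyn": conn.nsyn,
        "delay_ms": conn.delay_ms,
        "pathway": [conn.pathway_labels[k] for k in conn.pathway],
    }).to_csv(path, sep="\t", index=False)


def read_edge_list(path, pathway_params: dict[str, TMSynapseParams],
                   n_neurons: int) -> Connectome:
    df = pd.read_csv(path, sep="\t")
    labels = sorted(df["pathway"].unique())
    lab_index = {lab: k for k, lab in enumerate(labels)}
    return Connectome(
        pre=df["pre_id"].to_numpy(np.int64),
        post=df["post_id"].to_numpy(np.int64),
        nsyn=df["nsyn"].to_numpy(np.int64),
        delay_ms=df["delay_ms"].to_numpy(float),
        pathway=df["pathway"].map(lab_index).to_numpy(np.int64),
        pathway_labels=labels, pathway_params=pathway_params,
        n_neurons=n_neurons)


def write_rate_vector(populations: list[str], rates: np.ndarray, path) -> None:
    pd.DataFrame({"population": populations, "rate_Hz": rates}).to_csv(
        path, sep="\t", index=False)


def read_rate_vector(path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    return df["population"].tolist(), df["rate_Hz"].to_numpy(float)


def read_psth_table(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    return df["time_ms"].to_numpy(float), df["rate_Hz"].to_numpy(float)


def write_psth_table(time_ms: np.ndarray, rate_hz: np.ndarray, path) -> None:
    pd.DataFrame({"time_ms": time_ms, "rate_Hz": rate_hz}).to_csv(
        path, sep="\t", index=False)
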