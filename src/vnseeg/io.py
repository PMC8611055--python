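"""HDF5 / TSV / JSON serialization of the pipeline's data products."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .cluster_stats import ClusterTestResult
from .cnmf import Decomposition
from .epochs import TrialTensor
from .preprocess import AmplitudeSeries, BandSpec, RawRecording


def _write_strings(group: h5py.Group, name: str, items) -> None:
    group.create_dataset(name, data=np.array(list(items), dtype=h5py.string_dtype()))


def _read_strings(group: h5py.Group, name: str) -> list[str]:
    return [s.decode() if isinstance(s, bytes) else str(s) for s in group[name][()]]


def write_recording(path, rec: RawRecording) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("signal", data=rec.signal, compression="gzip")
        f.create_dataset("aux", data=rec.aux, compression="gzip")
        f.attrs["sampling_rate"] = rec.sampling_rate
        _write_strings(f, "channel_ids", rec.channel_ids)
        _write_strings(f, "roi_labels", rec.roi_labels)
        _write_strings(f, "bad_channels", sorted(rec.bad_channels))
        g = f.create_group("ictal_intervals")
        for ch, ivs in rec.ictal_intervals.items():
            g.create_dataset(ch, data=np.asarray(ivs, dtype=np.int64))


def read_recording(path) -> RawRecording:
    with h5py.File(path, "r") as f:
        return RawRecording(
            signal=f["signal"][()],
            sampling_rate=float(f.attrs["sampling_rate"]),
            aux=f["aux"][()],
            channel_ids=_read_strings(f, "channel_ids"),
            roi_labels=_read_strings(f, "roi_labels"),
            bad_channels=set(_read_strings(f, "bad_channels")),
            ictal_intervals={
                ch: [tuple(iv) for iv in f["ictal_intervals"][ch][()]]
                for ch in f["ictal_intervals"]
            },
        )


def write_events(path, events: pd.DataFrame) -> None:
    cols = [
        c for c in ("onset_sample", "onset_s", "modality", "frequency_level",
                    "amplitude_level", "frequency_hz", "amplitude_ma")
        if c in events.columns
    ]
    events[cols].to_csv(path, sep="\t", index=False)


def read_events(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_amplitude(path, amp: AmplitudeSeries) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=amp.values, compression="gzip")
        f.attrs["sampling_rate"] = amp.sampling_rate
        f.attrs["band_name"] = amp.band.name
        f.attrs["band_lo"] = amp.band.f_lo
        f.attrs["band_hi"] = amp.band.f_hi
        _write_strings(f, "channel_ids", amp.channel_ids)
        _write_strings(f, "roi_labels", amp.roi_labels)


def read_amplitude(path) -> AmplitudeSeries:
    with h5py.File(path, "r") as f:
        return AmplitudeSeries(
            values=f["values"][()],
            sampling_rate=float(f.attrs["sampling_rate"]),
            band=BandSpec(str(f.attrs["band_name"]), float(f.attrs["band_lo"]),
                          float(f.attrs["band_hi"])),
            channel_ids=_read_strings(f, "channel_ids"),
            roi_labels=_read_strings(f, "roi_labels"),
        )


def write_tensor(path, tensor: TrialTensor) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("z", data=tensor.z, compression="gzip")
        f.create_dataset("time_axis", data=tensor.time_axis)
        f.attrs["band_name"] = tensor.band.name
        f.attrs["band_lo"] = tensor.band.f_lo
        f.attrs["band_hi"] = tensor.band.f_hi
        f.attrs["modality"] = tensor.modality
        _write_strings(f, "channel_ids", tensor.channel_ids)
        _write_strings(f, "frequency_level", tensor.condition.frequency_level)
        _write_strings(f, "amplitude_level", tensor.condition.amplitude_level)


def read_tensor(path) -> TrialTensor:
    with h5py.File(path, "r") as f:
        condition = pd.DataFrame(
            {
                "frequency_level": _read_strings(f, "frequency_level"),
                "amplitude_level": _read_strings(f, "amplitude_level"),
            }
        )
        return TrialTensor(
            z=f["z"][()],
            time_axis=f["time_axis"][()],
            condition=condition,
            band=BandSpec(str(f.attrs["band_name"]), float(f.attrs["band_lo"]),
                          float(f.attrs["band_hi"])),
            modality=str(f.attrs["modality"]),
            channel_ids=_read_strings(f, "channel_ids"),
        )


def write_decomposition(path, dec: Decomposition, channel_ids=None) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("W", data=dec.W)
        f.create_dataset("G", data=dec.G)
        f.create_dataset("F", data=dec.F)
        f.create_dataset("assignments", data=dec.assignments)
        f.create_dataset("error_trace", data=dec.error_trace)
        f.attrs["rank"] = dec.rank
        f.attrs["reconstruction_error"] = dec.reconstruction_error
        f.attrs["n_restarts"] = dec.n_restarts
        if dec.seed is not None:
            f.attrs["seed"] = dec.seed
    if channel_ids is not None:
        pd.DataFrame(
            {"channel": channel_ids, "cluster": dec.assignments}
        ).to_csv(path.with_suffix(".tsv"), sep="\t", index=False)


def read_decomposition(path) -> Decomposition:
    with h5py.File(path, "r") as f:
        return Decomposition(
            W=f["W"][()], G=f["G"][()], F=f["F"][()],
            rank=int(f.attrs["rank"]),
            assignments=f["assignments"][()],
            reconstruction_error=float(f.attrs["reconstruction_error"]),
            error_trace=f["error_trace"][()],
            seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
            n_restarts=int(f.attrs["n_restarts"]),
        )


def cluster_result_to_dict(result: ClusterTestResult, time_axis=None) -> dict:
    clusters = []
    for c in result.clusters:
        entry = {"cluster_sum": c.cluster_sum, "p_value": c.p_value}
        if c.mask.ndim == 1 and time_axis is not None:
            idx = np.flatnonzero(c.mask)
            entry["time_range_s"] = [float(time_axis[idx[0]]), float(time_axis[idx[-1]])]
        entry.update({k: v for k, v in c.extra.items()})
        clusters.append(entry)
    return {
        "critical_value": result.critical_value,
        "n_permutations": result.n_permutations,
        "seed": result.seed,
        "clusters": clusters,
    }


def write_cluster_result(path, result: ClusterTestResult, time_axis=None) -> None:
    with open(path, "w") as f:
        json.dump(cluster_result_to_dict(result, time_axis), f, indent=2)
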