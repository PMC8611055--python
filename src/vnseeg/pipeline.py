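"""End-to-end orchestration: simulate -> preprocess -> epoch -> CBPT -> cNMF.

``run_pipeline`` executes the full analysis for one or more stimulation
modalities on synthetic recordings, writing every intermediate product
(band tensors, cluster-test JSON, decompositions, window statistics) and a
manifest with per-file SHA-256 hashes.  Rerunning with the same master seed
reproduces byte-identical outputs; per-stage seeds are derived by hashing
(master seed, stage name) so permutation nulls are independent across
bands and stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .cluster_stats import cbpt, cbpt_2d_baseline, group_factorial
from .cnmf import adjusted_rand_index, impute_tensor, project_weights, select_rank
from .epochs import (
    BASELINE_WINDOWS,
    EPOCH_WINDOWS,
    TARGET_WINDOWS,
    TrialTensor,
    condition_average_concat,
    epoch,
    normalize_single_trial,
    sliding_window_proportions,
    window_average,
)
from .preprocess import BandSpec, preprocess_recording
from .synthetic import StimProtocol, SynthConfig, generate_recording

logger = logging.getLogger(__name__)

CANONICAL_BANDS = ("delta", "theta", "alpha")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31 - 1)


@dataclass
class PipelineConfig:
    """Configuration of a full synthetic-data analysis run."""

    modalities: tuple[str, ...] = ("iVNS",)
    bands: tuple[str, ...] = CANONICAL_BANDS
    master_seed: int = 0
    output_dir: str = "vnseeg_out"
    n_channels: int = 24
    sampling_rate: float = 4000.0
    n_trials_per_condition: int = 30
    n_permutations: int = 1000
    alpha: float = 0.05
    statistic: str = "anova_frequency"
    candidate_ranks: tuple[int, ...] = (2, 3, 4, 5, 6)
    n_restarts: int = 10
    #: electrodes for the 2-D spectro-temporal CBPT against baseline
    #: (40-band spectrogram of the high-frequency/high-amplitude trials)
    spectrogram_electrodes: tuple[int, ...] = ()
    synth_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for b in self.bands:
            if b not in CANONICAL_BANDS:
                raise ValueError(
                    f"unknown band {b!r}; expected one of {CANONICAL_BANDS}"
                )
        for m in self.modalities:
            if m not in EPOCH_WINDOWS:
                raise ValueError(f"unknown modality {m!r}")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as f:
            raw = json.load(f)
        for key in ("modalities", "bands", "candidate_ranks",
                    "spectrogram_electrodes"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class RunManifest:
    config: dict
    version: str
    outputs: dict[str, str]  # relative path -> sha256
    warnings: list[str]
    started: float
    finished: float

    def save(self, path) -> None:
        with open(path, "w") as f:
            json.dump(asdict(self), f, indent=2)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _protocol_for(modality: str) -> StimProtocol:
    if modality == "iVNS":
        return StimProtocol.ivns()
    if modality == "taVNS-matched":
        return StimProtocol.tavns_matched()
    return StimProtocol.tavns_short()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full analysis; returns the manifest (also written)."""
    from . import __version__

    started = time.time()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    warns: list[str] = []

    def register(path: Path) -> None:
        outputs[str(path.relative_to(out_dir))] = _sha256(path)

    all_window_rows = []
    decompositions = {}
    for modality in config.modalities:
        protocol = _protocol_for(modality)
        epoch_win = EPOCH_WINDOWS[modality]
        base_win = BASELINE_WINDOWS[modality]
        target_win = TARGET_WINDOWS[modality]
        synth = SynthConfig(
            n_channels=config.n_channels,
            sampling_rate=config.sampling_rate,
            n_trials_per_condition=config.n_trials_per_condition,
            seed=stage_seed(config.master_seed, f"simulate:{modality}"),
            epoch_window=epoch_win,
            **config.synth_overrides,
        )
        rec, truth = generate_recording(synth, protocol)
        rec_path = out_dir / f"{modality}_recording.h5"
        io.write_recording(rec_path, rec)
        register(rec_path)
        ev_path = out_dir / f"{modality}_events.tsv"
        io.write_events(ev_path, truth.events)
        register(ev_path)

        good = rec.good_channel_indices()
        if len(good) < rec.n_channels:
            warns.append(
                f"{modality}: {rec.n_channels - len(good)} bad channel(s) excluded"
            )
        onsets_100 = np.round(
            truth.event_onsets / rec.sampling_rate * 100.0
        ).astype(int)
        for band_name in config.bands:
            band = BandSpec.canonical(band_name)
            amp = preprocess_recording(
                rec, band,
                expected_frequency=protocol.pulse_frequency,
                train_duration=protocol.train_duration,
                ramp_duration=protocol.ramp_duration,
            )
            trials, kept = epoch(amp, onsets_100, epoch_win)
            if len(kept) < len(onsets_100):
                warns.append(
                    f"{modality}/{band_name}: dropped "
                    f"{len(onsets_100) - len(kept)} edge trial(s)"
                )
            t0, t1 = epoch_win
            time_axis = t0 + np.arange(trials.shape[1]) / 100.0
            z = normalize_single_trial(trials, time_axis, base_win)
            tensor = TrialTensor(
                z=z[good],
                time_axis=time_axis,
                condition=truth.events.iloc[kept][
                    ["frequency_level", "amplitude_level"]
                ].reset_index(drop=True),
                band=band,
                modality=modality,
                channel_ids=[rec.channel_ids[i] for i in good],
            )
            tensor_path = out_dir / f"{modality}_{band_name}_tensor.h5"
            io.write_tensor(tensor_path, tensor)
            register(tensor_path)

            # cNMF on the condition-averaged matrix, then per-cluster CBPT
            cmat = condition_average_concat(tensor)
            report = select_rank(
                cmat,
                candidate_ranks=config.candidate_ranks,
                seed=stage_seed(config.master_seed, f"cnmf:{modality}:{band_name}"),
                n_restarts=config.n_restarts,
            )
            dec = report.decompositions[report.chosen_rank]
            dec_path = out_dir / f"{modality}_{band_name}_decomposition.h5"
            io.write_decomposition(dec_path, dec, channel_ids=tensor.channel_ids)
            register(dec_path)
            register(dec_path.with_suffix(".tsv"))
            if band_name == "theta":
                decompositions[modality] = dec

            projected = project_weights(dec.W, impute_tensor(tensor.z))
            for c in range(dec.rank):
                result = cbpt(
                    projected[c],
                    labels=tensor.condition,
                    statistic=config.statistic,
                    n_permutations=config.n_permutations,
                    alpha=config.alpha,
                    seed=stage_seed(
                        config.master_seed, f"cbpt:{modality}:{band_name}:{c}"
                    ),
                )
                res_path = out_dir / f"{modality}_{band_name}_sc{c + 1}_cbpt.json"
                io.write_cluster_result(res_path, result, tensor.time_axis)
                register(res_path)

            if tensor.z.shape[2] >= 4 * 5:
                sw = sliding_window_proportions(tensor)
                sw_path = out_dir / f"{modality}_{band_name}_sliding_windows.tsv"
                sw.to_csv(sw_path, sep="\t", index=False)
                register(sw_path)

            ws = window_average(
                projected, target_win, time_axis=tensor.time_axis,
                condition=tensor.condition,
                unit_ids=[f"SC{c + 1}" for c in range(dec.rank)],
            )
            frame = ws.to_frame().assign(modality=modality, band=band_name)
            ws_path = out_dir / f"{modality}_{band_name}_window_stats.tsv"
            frame.to_csv(ws_path, sep="\t", index=False)
            register(ws_path)
            all_window_rows.append(frame)

        if config.spectrogram_electrodes:
            _spectrogram_cbpt(
                config, rec, truth, good, onsets_100, epoch_win, base_win,
                protocol, modality, out_dir, register,
            )

    window_table = pd.concat(all_window_rows, ignore_index=True)
    try:
        group = group_factorial(window_table)
        group_path = out_dir / "group_factorial.tsv"
        group.to_csv(group_path, sep="\t")
        register(group_path)
    except ValueError as exc:
        warns.append(f"group factorial model skipped: {exc}")

    if len(decompositions) > 1:
        comp = compare_modalities(decompositions)
        comp_path = out_dir / "modality_comparison.tsv"
        comp.to_csv(comp_path, sep="\t", index=False)
        register(comp_path)

    manifest = RunManifest(
        config=asdict(config), version=__version__, outputs=outputs,
        warnings=warns, started=started, finished=time.time(),
    )
    manifest.save(out_dir / "manifest.json")
    return manifest


def _spectrogram_cbpt(config, rec, truth, good, onsets_100, epoch_win,
                      base_win, protocol, modality, out_dir, register):
    """2-D (40-band x time) CBPT against baseline per requested electrode,
    on the high-frequency / high-amplitude trials."""
    from .preprocess import (
        broadband_filter,
        detect_pulses,
        interpolate_artifacts,
        notch_filters,
        resample_signal,
        spectrogram_amplitude,
    )

    fs = rec.sampling_rate
    pulses = detect_pulses(
        rec.aux, fs, protocol.pulse_frequency,
        train_duration=protocol.train_duration,
        ramp_duration=protocol.ramp_duration,
    )
    picks = [good[i] for i in config.spectrogram_electrodes]
    x = rec.signal[picks]
    if fs < 20000.0:
        x = notch_filters(x, fs)
        x = interpolate_artifacts(x, fs, pulses)
        x = broadband_filter(x, fs)
    else:
        x = interpolate_artifacts(x, fs, pulses)
        x = broadband_filter(x, fs)
        x = notch_filters(x, fs)
    x = resample_signal(x, fs, 512.0)
    amp, centers = spectrogram_amplitude(x, 512.0)  # picks x 40 x samples
    hh = truth.events.index[
        (truth.events.frequency_level == "high")
        & (truth.events.amplitude_level == "high")
    ].to_numpy()
    for e_i, e in enumerate(config.spectrogram_electrodes):
        trials, kept = epoch(amp[e_i], onsets_100[hh], epoch_win,
                             sampling_rate=100.0)
        t0 = epoch_win[0]
        taxis = t0 + np.arange(trials.shape[1]) / 100.0
        z = normalize_single_trial(trials, taxis, base_win)
        res = cbpt_2d_baseline(
            z, n_permutations=config.n_permutations, alpha=config.alpha,
            seed=stage_seed(config.master_seed, f"cbpt2d:{modality}:{e}"),
            band_centers=centers, time_axis=taxis,
        )
        path = out_dir / f"{modality}_e{e}_spectrogram_cbpt.json"
        io.write_cluster_result(path, res)
        register(path)


def compare_modalities(decompositions: dict) -> pd.DataFrame:
    """Pairwise ARI and percent agreement of electrode partitions."""
    names = sorted(decompositions)
    sizes = {m: len(decompositions[m].assignments) for m in names}
    if len(set(sizes.values())) > 1:
        raise ValueError(f"electrode sets differ between modalities: {sizes}")
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            ari, agree = adjusted_rand_index(
                decompositions[a].assignments, decompositions[b].assignments
            )
            rows.append(
                {"modality_a": a, "modality_b": b, "ari": ari,
                 "percent_agreement": agree}
            )
    return pd.DataFrame(rows)
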