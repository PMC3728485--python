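"""Readers, writers, configuration and the end-to-end pipeline runner.

EEG travels as a delimited numeric matrix (channels x samples TSV) with a
JSON sidecar (sampling rate, channel names, units), or as EDF (read via mne
when installed); events as BIDS-style ``events.tsv`` (onset, duration,
trial_type in {B, DB}, response_time); volumes as NIfTI-1 through nibabel.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .fmri import BinaryMask, SpatialMap, Volume4D

__all__ = [
    "read_eeg", "write_eeg", "read_events", "write_events",
    "read_nifti", "write_nifti", "write_mask",
    "PipelineConfig", "run_pipeline",
]

log = logging.getLogger("icdecode")


# ----------------------------------------------------------------------
# EEG matrix dialect

def write_eeg(data, sampling_rate: float, path, channel_names=None) -> None:
    """Write channels x samples (uV) as TSV plus a JSON sidecar."""
    data = np.asarray(data, dtype=float)
    path = Path(path)
    np.savetxt(path, data, delimiter="\t")
    names = channel_names or [f"E{i + 1}" for i in range(data.shape[0])]
    sidecar = {"sampling_rate_hz": sampling_rate, "channel_names": list(names),
               "units": "uV"}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_eeg(path) -> tuple[np.ndarray, float, list[str]]:
    """Read EEG as (channels x samples, sampling rate, channel names).

    ``.edf`` files go through mne; anything else is the matrix + sidecar
    dialect.
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        import mne  # optional dependency, EDF only

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        return raw.get_data() * 1e6, float(raw.info["sfreq"]), raw.ch_names
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    try:
        rate = float(sidecar["sampling_rate_hz"])
        names = list(sidecar["channel_names"])
    except KeyError as e:
        raise ValueError(f"malformed sidecar {sidecar_path}: missing {e}")
    data = np.loadtxt(path, delimiter="\t", ndmin=2)
    if data.shape[0] != len(names):
        raise ValueError(
            f"sidecar lists {len(names)} channels but matrix has "
            f"{data.shape[0]} rows"
        )
    return data, rate, names


def write_events(events: pd.DataFrame, path) -> None:
    events.to_csv(path, sep="\t", index=False)


def read_events(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing events file {path}")
    df = pd.read_csv(path, sep="\t")
    required = {"onset", "trial_type"}
    if not required <= set(df.columns):
        raise ValueError(f"{path} lacks required columns {required}")
    return df


# ----------------------------------------------------------------------
# NIfTI

def write_nifti(obj, path) -> None:
    """Write a Volume4D, SpatialMap or raw array as NIfTI-1."""
    if isinstance(obj, Volume4D):
        img = nib.Nifti1Image(obj.values.astype(np.float32), obj.affine)
        img.header["pixdim"][4] = obj.TR
    elif isinstance(obj, SpatialMap):
        img = nib.Nifti1Image(obj.values.astype(np.float32), np.eye(4))
    else:
        img = nib.Nifti1Image(np.asarray(obj, dtype=np.float32), np.eye(4))
    nib.save(img, str(path))


def write_mask(mask: BinaryMask, path) -> None:
    img = nib.Nifti1Image(mask.values.astype(np.uint8), np.eye(4))
    nib.save(img, str(path))


def read_nifti(path, TR: float | None = None) -> Volume4D | SpatialMap:
    """Read a NIfTI file: 4D gives a Volume4D (TR from header unless
    overridden, with a logged warning), 3D gives a SpatialMap."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 4:
        header_tr = float(img.header["pixdim"][4])
        if TR is not None and header_tr > 0 and abs(TR - header_tr) > 1e-6:
            log.warning("overriding header TR %.3f s with configured %.3f s",
                        header_tr, TR)
        tr = TR if TR is not None else header_tr
        if tr <= 0:
            raise ValueError("TR missing from header; pass it explicitly")
        return Volume4D(values=data, TR=tr, affine=np.asarray(img.affine))
    if data.ndim == 3:
        return SpatialMap(values=data, kind="IC", map_id=Path(path).stem)
    raise ValueError(f"expected 3D or 4D NIfTI, got {data.ndim}D")


# ----------------------------------------------------------------------
# configuration

_SCHEMA: dict[str, set[str]] = {
    "run": {"modality", "seed", "out"},
    "data": {"synthetic", "eeg_path", "events_path", "volume_path", "tr"},
    "eeg": {"bands", "n_components", "envelope_method", "lo_hz", "hi_hz",
            "notch_hz"},
    "fmri": {"k", "z_thresh", "n_keep"},
    "wavelet": {"width_cycles", "freq_step"},
    "cv": {"outer_folds", "inner_folds", "stratified"},
    "classifier": {"family"},
    "tree": {"min_instances_per_leaf", "pruning_fraction"},
}


@dataclasses.dataclass
class PipelineConfig:
    modality: str = "eeg"
    seed: int = 0
    out: str = "icdecode_run"
    synthetic: bool = True
    eeg_path: str | None = None
    events_path: str | None = None
    volume_path: str | None = None
    tr: float | None = None
    bands: tuple[str, ...] = ("gamma",)
    n_components: int | None = None
    envelope_method: str = "hilbert"
    k: int = 6
    z_thresh: float = 2.3
    n_keep: int = 6
    width_cycles: float = 6.0
    freq_step: float = 1.0
    outer_folds: int = 10
    inner_folds: int = 10
    stratified: bool = True
    family: str = "decision_tree"
    min_instances_per_leaf: int = 40
    pruning_fraction: float = 1 / 3

    def __post_init__(self):
        if self.modality not in ("eeg", "fmri"):
            raise ValueError("modality must be 'eeg' or 'fmri'")

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        raw = tomllib.loads(Path(path).read_text())
        kwargs: dict = {}
        for section, table in raw.items():
            if section not in _SCHEMA:
                raise ValueError(f"unknown config section [{section}]")
            if not isinstance(table, dict):
                raise ValueError(f"[{section}] must be a table")
            for key, value in table.items():
                if key not in _SCHEMA[section]:
                    raise ValueError(f"unknown key {key!r} in [{section}]")
                kwargs[key] = tuple(value) if isinstance(value, list) else value
        return cls(**kwargs)

    def hash(self) -> str:
        """Hash of the scientific configuration (output path excluded)."""
        fields = dataclasses.asdict(self)
        fields.pop("out", None)
        blob = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ----------------------------------------------------------------------

def _leaf_floor(config: PipelineConfig, report, n_exemplars: int) -> int:
    """Leaf-size floor for the interpretation tree: the leaf size the nested
    CV chose most often when the decoder was a tree, otherwise the configured
    default, capped so a split is possible on the available exemplars."""
    floor = config.min_instances_per_leaf
    if config.family == "decision_tree" and report.chosen_params:
        sizes = [p.get("min_samples_leaf", floor) for p in report.chosen_params]
        floor = max(set(sizes), key=sizes.count)
    return max(2, min(floor, n_exemplars // 4))


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured modality's full chain and write a run directory.

    simulate-or-read -> preprocess/flag -> per-fold ICA + time-point
    selection -> features -> nested CV -> interpretable tree (plus IC/GLM
    overlap for fMRI).  Outputs: report.json, tree.json, tree.txt,
    overlap.tsv (fMRI), run.log; every artifact embeds the config hash and
    seed.
    """
    from .decode import CVSpec, ClassifierSpec, run_nested_cv
    from .interpret import render_tree, tree_node_overlap_table
    from .pipeline import EEGICBuilder, FMRIICBuilder
    from .tree import PrunedDecisionTree
    from .eeg import WaveletParams, detect_artifacts
    from . import synth
    from . import fmri as fmrimod

    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    stamp = {"config_hash": config.hash(), "seed": config.seed}

    try:
        cv = CVSpec(outer_folds=config.outer_folds,
                    inner_folds=config.inner_folds, seed=config.seed,
                    stratified=config.stratified)
        clf = ClassifierSpec(family=config.family)
        wavelet = WaveletParams(width_cycles=config.width_cycles,
                                freq_step=config.freq_step)

        if config.modality == "eeg":
            stage = "load"
            if config.synthetic:
                cfg = synth.EEGSimConfig(seed=config.seed)
                epochs, _ = synth.simulate_eeg(cfg)
            else:
                from .eeg import preprocess_continuous, segment_epochs, baseline_correct
                data, rate, names = read_eeg(config.eeg_path)
                events = read_events(config.events_path)
                stage = "preprocess"
                filtered = preprocess_continuous(data, rate)
                epochs = baseline_correct(
                    segment_epochs(filtered, rate, events, channel_ids=names))
            stage = "artifacts"
            epochs, art_report = detect_artifacts(epochs)
            keep = np.ones(epochs.n_trials, dtype=bool)
            if epochs.bad_trial_mask is not None:
                keep &= ~epochs.bad_trial_mask
            log.info("stage=artifacts excluded_trials=%d",
                     int((~keep).sum()))
            from .eeg import EpochSet
            epochs = EpochSet(data=epochs.data[keep],
                              labels=epochs.labels[keep],
                              sampling_rate=epochs.sampling_rate,
                              t0_offset=epochs.t0_offset,
                              channel_ids=epochs.channel_ids)
            stage = "decode"
            builder = EEGICBuilder(epochs, bands=list(config.bands),
                                   wavelet=wavelet,
                                   n_components=config.n_components,
                                   seed=config.seed,
                                   envelope_method=config.envelope_method)
            report = run_nested_cv(builder, clf, cv)
            stage = "interpret"
            builder.fit(np.arange(epochs.n_trials))
            X = builder.features(np.arange(epochs.n_trials))
            tree = PrunedDecisionTree(
                min_samples_leaf=_leaf_floor(config, report, epochs.n_trials),
                pruning_fraction=config.pruning_fraction,
                random_state=config.seed).fit(X, epochs.labels)
            meta = builder.feature_meta()
            (out / "tree.txt").write_text(render_tree(tree, meta))
            (out / "tree.json").write_text(
                json.dumps({**stamp, **tree.to_dict()}, indent=2))
        else:
            stage = "load"
            if config.synthetic:
                cfg = fmri_cfg = synth.FMRISimConfig(seed=config.seed)
                volvals, truth = synth.simulate_fmri(cfg)
                vol = Volume4D(values=volvals, TR=cfg.TR)
                events = truth.event_table
            else:
                vol = read_nifti(config.volume_path, TR=config.tr)
                events = read_events(config.events_path)
            stage = "decode"
            builder = FMRIICBuilder(vol, events, K=config.k,
                                    seed=config.seed,
                                    z_thresh=config.z_thresh,
                                    n_keep=config.n_keep)
            report = run_nested_cv(builder, clf, cv)
            stage = "interpret"
            builder.fit(np.arange(len(builder.labels)))
            X = builder.features(np.arange(len(builder.labels)))
            tree = PrunedDecisionTree(
                min_samples_leaf=_leaf_floor(config, report, len(builder.labels)),
                pruning_fraction=config.pruning_fraction,
                random_state=config.seed).fit(X, builder.labels)
            meta = [{"source": f"IC{k}", "label": f"IC{k}_peak"}
                    for k in builder.kept_components_]
            (out / "tree.txt").write_text(render_tree(tree, meta))
            (out / "tree.json").write_text(
                json.dumps({**stamp, **tree.to_dict()}, indent=2))
            glm_b = fmrimod.glm_zstat(vol, builder.events, contrast="B-DB")
            glm_db = fmrimod.glm_zstat(vol, builder.events, contrast="DB-B")
            kept_maps = [builder.maps_[k] for k in builder.kept_components_]
            tab = tree_node_overlap_table(tree, meta, kept_maps,
                                          [glm_b, glm_db],
                                          z_thresh=config.z_thresh)
            tab.to_csv(out / "overlap.tsv", sep="\t", index=False)

        payload = json.loads(report.to_json())
        payload.update(stamp)
        (out / "report.json").write_text(json.dumps(payload, indent=2))
        log.info("stage=done mean_accuracy=%.3f", report.mean_accuracy)
        return out
    except Exception as e:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {e}") from e
    finally:
        log.removeHandler(handler)
        handler.close()
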