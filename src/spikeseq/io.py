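"""Result export: spike records, weight snapshots, trial logs, run manifests.

Spikes and accuracy tables go to CSV; weight matrices (optionally per trial
index) to HDF5; every experiment directory gets a manifest recording the
full configuration, its hash, the master seed and the package version, so
any output can be regenerated bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from spikeseq.config import ExperimentConfig, save_config
from spikeseq.network import Network

__all__ = [
    "export_weights_hdf5",
    "load_weights_hdf5",
    "export_trials_csv",
    "write_manifest",
]


def export_weights_hdf5(net: Network, path: str | Path, trial_index: int | None = None) -> None:
    """Dump every synapse group's weight matrix to an HDF5 file.

    Datasets are named ``<pre>__<post>[/trial<k>]``; group attributes carry
    the plasticity mode.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    mode = "a" if trial_index is not None and path.exists() else "w"
    with h5py.File(path, mode) as fh:
        for p in net.projections:
            g = p.group
            name = f"{g.pre_pop}__{g.post_pop}"
            if trial_index is not None:
                name = f"{name}/trial{trial_index}"
            if name in fh:
                del fh[name]
            ds = fh.create_dataset(name, data=g.w, compression="gzip")
            ds.attrs["mode"] = g.mode


def load_weights_hdf5(path: str | Path) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    with h5py.File(path, "r") as fh:
        def visit(name, obj):
            if isinstance(obj, h5py.Dataset):
                out[name] = obj[()]
        fh.visititems(visit)
    return out


def export_trials_csv(trials, path: str | Path) -> None:
    """Trial log with input/target/output sequences and reward outcomes."""
    rows = []
    for k, t in enumerate(trials):
        rows.append(
            {
                "trial_idx": k,
                "rule": t.rule,
                "input_seq": "".join(map(str, t.input_seq)),
                "target_seq": "".join(map(str, t.target_seq)),
                "output_seq": "".join(map(str, t.output_seq)),
                "correct": t.correct,
                "reward": t.reward_given,
            }
        )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False)


def config_hash(config: ExperimentConfig) -> str:
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_manifest(config: ExperimentConfig, outdir: str | Path, extra: dict | None = None) -> Path:
    from spikeseq import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_config(config, outdir / "config.yaml")
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_sha256": config_hash(config),
    }
    if extra:
        manifest.update(extra)
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
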