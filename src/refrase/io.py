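"""NIfTI and config I/O.

Volumes travel as NIfTI (phase/magnitude pairs per echo rather than
complex images, for wider tool compatibility); phase is stored in radians
and normalized into (-pi, pi] on load, honouring any scl_slope/scl_inter
rescaling declared in the header.  Run configuration round-trips through a
single YAML document so every artifact on disk is reproducible from the
emitted config plus its seed.
"""

from __future__ import annotations

import dataclasses
import json
import os
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import yaml

from .fieldmap import EchoSeries, wrap_phase
from .phantom import GroundTruth, PhantomSpec

__all__ = ["save_volume", "load_volume", "save_echo_series", "load_echo_series",
           "save_phantom", "spec_to_yaml", "spec_from_yaml"]

_IDENT = np.eye(4)


def save_volume(path, data, affine=None, dtype=np.float32):
    img = nib.Nifti1Image(np.asarray(data).astype(dtype), _IDENT if affine is None else affine)
    nib.save(img, str(path))


def load_volume(path):
    if not os.path.exists(path):
        raise FileNotFoundError(f"volume not found: {path}")
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=float), img.affine


def save_echo_series(series: EchoSeries, out_dir, prefix: str = "echo"):
    """Write one phase/magnitude NIfTI pair per echo plus a TE sidecar."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {"phase": [], "magnitude": []}
    for e in range(series.n_echoes):
        pp = os.path.join(out_dir, f"{prefix}{e + 1:02d}_phase.nii.gz")
        mp = os.path.join(out_dir, f"{prefix}{e + 1:02d}_mag.nii.gz")
        save_volume(pp, series.phase[e])
        save_volume(mp, series.magnitude[e])
        paths["phase"].append(pp)
        paths["magnitude"].append(mp)
    with open(os.path.join(out_dir, f"{prefix}_tes.json"), "w") as fh:
        json.dump({"tes_s": series.tes.tolist(),
                   "voxel_size_mm": list(series.voxel_size)}, fh, indent=1)
    return paths


def load_echo_series(phase_paths: Sequence, magnitude_paths: Sequence,
                     tes: Optional[Sequence[float]] = None,
                     sidecar: Optional[str] = None) -> EchoSeries:
    """Load phase/magnitude NIfTI pairs into an echo series.

    Phase volumes are rescaled through the NIfTI header scaling (nibabel's
    ``get_fdata`` applies scl_slope/scl_inter) and wrapped into (-pi, pi];
    echo times come from ``tes`` (seconds) or the JSON sidecar.
    """
    if tes is None:
        if sidecar is None:
            raise ValueError("supply echo times or a sidecar path")
        with open(sidecar) as fh:
            tes = json.load(fh)["tes_s"]
    if len(phase_paths) != len(magnitude_paths) or len(phase_paths) != len(tes):
        raise ValueError("need matching phase, magnitude and TE counts")
    phases, mags = [], []
    shape = None
    for pp, mp in zip(phase_paths, magnitude_paths):
        p, _ = load_volume(pp)
        m, _ = load_volume(mp)
        if shape is None:
            shape = p.shape
        if p.shape != shape or m.shape != shape:
            raise ValueError(f"volume shape mismatch at {pp}")
        phases.append(wrap_phase(p))
        mags.append(np.abs(m))
    return EchoSeries(phase=np.stack(phases), magnitude=np.stack(mags),
                      tes=np.asarray(tes, dtype=float))


def spec_to_yaml(spec: PhantomSpec, path=None) -> str:
    doc = yaml.safe_dump(_to_plain(dataclasses.asdict(spec)), sort_keys=False)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(doc)
    return doc


def spec_from_yaml(src) -> PhantomSpec:
    if os.path.exists(str(src)):
        with open(src) as fh:
            data = yaml.safe_load(fh)
    else:
        data = yaml.safe_load(src)
    known = {f.name for f in dataclasses.fields(PhantomSpec)}
    data = {k: _retuple(v) for k, v in data.items() if k in known}
    return PhantomSpec(**data)


def save_phantom(series: EchoSeries, gt: GroundTruth, out_dir):
    """Write signal, ground truth and labels plus the resolved spec YAML."""
    os.makedirs(out_dir, exist_ok=True)
    save_echo_series(series, out_dir)
    save_volume(os.path.join(out_dir, "chi_true.nii.gz"), gt.chi)
    save_volume(os.path.join(out_dir, "b_true_hz.nii.gz"), gt.b)
    save_volume(os.path.join(out_dir, "b_ssh_hz.nii.gz"), gt.b_ssh)
    save_volume(os.path.join(out_dir, "labels.nii.gz"), gt.labels.labels, dtype=np.uint8)
    save_volume(os.path.join(out_dir, "m_max.nii.gz"), gt.labels.m_max, dtype=np.uint8)
    spec_to_yaml(gt.labels.spec, os.path.join(out_dir, "phantom_spec.yaml"))


def _to_plain(obj):
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def _retuple(v):
    if isinstance(v, list):
        return tuple(_retuple(x) for x in v)
    return v
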