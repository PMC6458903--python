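"""Serialization: HDF5 cross-spectra and posteriors, YAML presets, EDF/text.

Cross-spectral data and subject posteriors are stored in HDF5 (complex
matrices split into real/imaginary parts); model parameterizations travel
as field-for-field YAML mappings; sensor time series can be exported as
delimited text and read back from EDF recordings via MNE.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from .cmc import CMCParameters, CrossSpectralData
from .inversion import SubjectPosterior

__all__ = [
    "save_csd",
    "load_csd",
    "save_posterior",
    "load_posterior",
    "parameters_to_yaml",
    "parameters_from_yaml",
    "load_preset",
    "write_timeseries_text",
    "read_edf_epochs",
    "save_scalp_map",
    "config_digest",
]

_PRESET_DIR = Path(__file__).parent / "presets"


def save_csd(path, data: CrossSpectralData) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("freqs", data=data.freqs)
        f.create_dataset("csd_real", data=data.csd.real)
        f.create_dataset("csd_imag", data=data.csd.imag)
        f.attrs["n_eigenmodes"] = data.n_eigenmodes


def load_csd(path) -> CrossSpectralData:
    with h5py.File(path, "r") as f:
        return CrossSpectralData(
            freqs=f["freqs"][()],
            csd=f["csd_real"][()] + 1j * f["csd_imag"][()],
            n_eigenmodes=int(f.attrs["n_eigenmodes"]))


def save_posterior(path, post: SubjectPosterior, digest: str = "") -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("mean", data=post.mean)
        f.create_dataset("covariance", data=post.covariance)
        f.attrs["free_energy"] = post.free_energy
        f.attrs["converged"] = post.converged
        f.attrs["config_digest"] = digest
        f.attrs["names"] = json.dumps(post.names)
        diag = f.create_group("diagnostics")
        for k, v in post.fit_diagnostics.items():
            if isinstance(v, np.ndarray):
                diag.create_dataset(k, data=v)
            else:
                diag.attrs[k] = v


def load_posterior(path) -> SubjectPosterior:
    with h5py.File(path, "r") as f:
        diag = {k: v[()] for k, v in f["diagnostics"].items()}
        diag.update(dict(f["diagnostics"].attrs))
        return SubjectPosterior(
            mean=f["mean"][()], covariance=f["covariance"][()],
            free_energy=float(f.attrs["free_energy"]),
            converged=bool(f.attrs["converged"]),
            names=json.loads(f.attrs["names"]),
            fit_diagnostics=diag)


def parameters_to_yaml(params: CMCParameters, path=None) -> str:
    doc = {
        "tau": params.tau.tolist(),
        "g1": params.g1.tolist(),
        "g2": params.g2.tolist(),
        "g3": params.g3.tolist(),
        "s": float(params.s),
        "a_fwd": params.a_fwd.tolist(),
        "a_bwd": params.a_bwd.tolist(),
        "a_lat": params.a_lat.tolist(),
        "noise_alpha_u": float(params.noise_alpha_u),
        "noise_beta_u": float(params.noise_beta_u),
        "noise_alpha_n": float(params.noise_alpha_n),
        "noise_beta_n": float(params.noise_beta_n),
        "L": params.L.tolist(),
    }
    text = yaml.safe_dump(doc, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def parameters_from_yaml(source) -> CMCParameters:
    """Load a parameterization from a YAML string or file path."""
    p = Path(str(source))
    text = p.read_text() if p.exists() else str(source)
    doc = yaml.safe_load(text)
    return CMCParameters(**doc)


def load_preset(name: str = "alpha_network") -> CMCParameters:
    """Bundled presets; ``alpha_network`` is the alpha-tuned prior mean."""
    path = _PRESET_DIR / f"{name}.yaml"
    if not path.exists():
        raise FileNotFoundError(f"no preset named {name!r}")
    return parameters_from_yaml(path)


def write_timeseries_text(path, Y: np.ndarray, fs: float,
                          channel_names=None) -> None:
    """Tab-delimited export: one column per channel, header with fs."""
    names = channel_names or [f"ch{i}" for i in range(Y.shape[0])]
    header = f"# fs_hz={fs:g}\n" + "\t".join(names)
    np.savetxt(path, np.asarray(Y).T, delimiter="\t", header=header,
               comments="")


def read_edf_epochs(path, epoch_seconds: float = 2.0):
    """Read an EDF recording and segment it into fixed-length epochs.

    Returns (epochs array (n_epochs, n_channels, n_times), fs, channel
    names).
    """
    import mne
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    X = raw.get_data()
    n_t = int(round(epoch_seconds * fs))
    n_ep = X.shape[1] // n_t
    epochs = X[:, :n_ep * n_t].reshape(X.shape[0], n_ep, n_t)
    return epochs.transpose(1, 0, 2), fs, list(raw.ch_names)


def save_scalp_map(path_prefix, smap, title: str = "") -> None:
    """Export a scalp map as delimited text and a PNG image.

    Writes ``<prefix>.tsv`` (64x64 grid, NaN outside the head) and
    ``<prefix>.png``.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    grid = np.where(smap.mask, smap.grid, np.nan)
    np.savetxt(f"{path_prefix}.tsv", grid, delimiter="\t")
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(grid, origin="lower", extent=(-1.05, 1.05, -1.05, 1.05),
                   cmap="RdBu_r")
    if len(smap.positions):
        ax.plot(smap.positions[:, 0], smap.positions[:, 1], "k.", ms=2)
    ax.set_title(title)
    ax.set_axis_off()
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.savefig(f"{path_prefix}.png", dpi=120, bbox_inches="tight")
    plt.close(fig)


def config_digest(obj) -> str:
    """Stable short digest of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
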