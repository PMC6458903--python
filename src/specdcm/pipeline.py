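"""End-to-end pipeline: simulate -> spectra -> invert -> peb -> compare -> report.

A single configuration drives all stages; per-stage seeds are derived from
the master seed with numpy's SeedSequence spawning (stage k gets the k-th
child), so stages are individually reproducible.  Each stage writes its
outputs and a line in the run manifest; a stage whose upstream outputs are
missing aborts with the missing path named, leaving completed outputs
intact.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohorts, io, spectral
from .cmc import default_freqs, default_network, alpha_prior_parameters
from .errors import SpecDCMError
from .inversion import InversionConfig, default_prior_covariance, variational_laplace
from .peb import (ModelSpace, build_design_matrix, compare_model_space,
                  extract_effects, peb_fit)

__all__ = ["RunConfig", "run_pipeline", "STAGES"]

STAGES = ("simulate", "spectra", "invert", "peb", "compare", "report")

log = logging.getLogger("specdcm")


@dataclass
class RunConfig:
    """Configuration for a pipeline run."""

    outdir: str = "specdcm_run"
    seed: int = 1
    stages: tuple = STAGES
    n_subjects: int = 36
    effect_size: float = 0.4
    noise_level: float = 0.05
    target_classes: tuple = ("intrinsic",)
    n_eigenmodes: int = 8
    fmin: float = 1.0
    fmax: float = 30.0
    df: float = 0.5
    max_iterations: int = 64
    sensor_subjects: int = 0      # 0: skip sensor simulation/spectra
    epochs_per_subject: int = 20
    n_permutations: int = 1000

    def __post_init__(self):
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stage(s) {unknown}; valid: {STAGES}")
        # keep topological order regardless of the order given
        self.stages = tuple(s for s in STAGES if s in self.stages)

    def freqs(self):
        return default_freqs(self.fmin, self.fmax, self.df)

    def inversion_config(self) -> InversionConfig:
        return InversionConfig(n_eigenmodes=self.n_eigenmodes, fmin=self.fmin,
                               fmax=self.fmax, df=self.df,
                               max_iterations=self.max_iterations)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        doc = yaml.safe_load(Path(path).read_text()) or {}
        valid = cls.__dataclass_fields__
        unknown = [k for k in doc if k not in valid]
        if unknown:
            raise ValueError(f"unknown config key(s): {unknown}")
        for k in ("stages", "target_classes"):
            if k in doc:
                doc[k] = tuple(doc[k])
        return cls(**doc)


def _stage_seeds(seed: int) -> dict:
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {s: int(c.generate_state(1)[0] % (2 ** 31)) for s, c in
            zip(STAGES, children)}


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise SpecDCMError(
            f"stage {stage!r}: missing upstream output {path}; "
            "run the producing stage first")
    return path


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the requested stages; returns the run manifest."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(cfg.seed)
    manifest = {"seed": cfg.seed, "stage_seeds": seeds,
                "config": asdict(cfg), "config_digest": io.config_digest(asdict(cfg)),
                "stages_run": []}
    net = default_network()
    base = alpha_prior_parameters()
    prior_cov = default_prior_covariance()
    freqs = cfg.freqs()

    if "simulate" in cfg.stages:
        log.info(json.dumps({"stage": "simulate", "seed": seeds["simulate"]}))
        models, csds, cov, z, _, _ = cohorts.construct_validity_cohort(
            seed=seeds["simulate"], n_subjects=cfg.n_subjects,
            effect_size=cfg.effect_size, noise_level=cfg.noise_level,
            n_eigenmodes=cfg.n_eigenmodes, freqs=freqs,
            target_classes=cfg.target_classes)
        (out / "csds").mkdir(exist_ok=True)
        for i, d in enumerate(csds):
            io.save_csd(out / "csds" / f"subject_{i:03d}.h5", d)
        cov.to_csv(out / "covariates.csv", index=False)
        np.savetxt(out / "regressor.txt", z)
        if cfg.sensor_subjects > 0:
            spec = cohorts.CohortSpec(n_subjects=cfg.sensor_subjects)
            epochs, scov, sz = cohorts.generate_sensor_cohort(
                spec, seed=seeds["simulate"] + 1,
                epochs_per_subject=cfg.epochs_per_subject)
            np.savez_compressed(out / "sensor_cohort.npz",
                                **{f"s{i:03d}": e for i, e in enumerate(epochs)})
            scov.to_csv(out / "sensor_covariates.csv", index=False)
        manifest["stages_run"].append("simulate")

    if "spectra" in cfg.stages and cfg.sensor_subjects > 0:
        npz = _require(out / "sensor_cohort.npz", "spectra")
        scov = pd.read_csv(_require(out / "sensor_covariates.csv", "spectra"))
        data = np.load(npz)
        chans = spectral.usable_channels()
        rows = []
        band_powers = []
        for i in range(len(data.files)):
            ep = data[f"s{i:03d}"]
            ps = spectral.multitaper_psd(ep)
            spectra = {c: spectral.PowerSpectrum(ps.freqs, ps.power[j], c)
                       for j, c in enumerate(chans)}
            reg = spectral.regional_average(spectra)
            pk = spectral.alpha_peak(reg["frontal"])
            rows.append({"subject": i, "frontal_peak_amp": pk.amplitude,
                         "frontal_peak_freq": pk.frequency})
            lo, hi = spectral.THETA_ALPHA_BAND
            sel = (ps.freqs >= lo) & (ps.freqs <= hi)
            band_powers.append(ps.power[:, sel].mean(axis=1))
        df_pk = pd.DataFrame(rows)
        slope, t, p, dof = spectral.covariate_regression(
            df_pk["frontal_peak_amp"], scov["kbit_raw"])
        df_pk.to_csv(out / "alpha_peaks.csv", index=False)

        # pixel-wise theta-alpha power maps regressed on the score
        pos = spectral.channel_positions_2d(chans)
        maps = np.stack([
            spectral.build_scalp_map(bp, pos).grid for bp in band_powers])
        spm = spectral.spm_regression(
            maps, scov["kbit_raw"].to_numpy(), alpha=0.05,
            n_permutations=cfg.n_permutations, seed=seeds["spectra"])
        tmap = spectral.ScalpMap(grid=np.where(spm.mask, spm.tmap, np.nan),
                                 mask=spm.mask, positions=pos)
        io.save_scalp_map(out / "theta_alpha_tmap", tmap,
                          title="theta-alpha power ~ score (t)")
        (out / "spectra_stats.json").write_text(json.dumps(
            {"frontal_amp_vs_score": {"slope": slope, "t": t, "p": p,
                                      "df": dof},
             "spm": {"threshold": spm.threshold,
                     "n_clusters": spm.n_clusters,
                     "n_significant_pixels": int(spm.significant.sum())}},
            indent=2))
        manifest["stages_run"].append("spectra")

    if "invert" in cfg.stages:
        csd_dir = _require(out / "csds", "invert")
        cfg_inv = cfg.inversion_config()
        (out / "posteriors").mkdir(exist_ok=True)
        digest = io.config_digest(asdict(cfg))
        for f in sorted(csd_dir.glob("subject_*.h5")):
            d = io.load_csd(f)
            post = variational_laplace(d, base, prior_cov, net, cfg_inv)
            io.save_posterior(out / "posteriors" / f.name, post, digest)
            log.info(json.dumps({"stage": "invert", "subject": f.stem,
                                 "free_energy": post.free_energy,
                                 "converged": post.converged}))
        manifest["stages_run"].append("invert")

    peb = None
    if "peb" in cfg.stages or "compare" in cfg.stages or "report" in cfg.stages:
        post_dir = _require(out / "posteriors", "peb")
        posts = [io.load_posterior(f)
                 for f in sorted(post_dir.glob("subject_*.h5"))]
        cov = pd.read_csv(_require(out / "covariates.csv", "peb"))
        design = build_design_matrix(cov)
        peb = peb_fit(posts, design, base, prior_cov)
        manifest["stages_run"].append("peb")

    if "compare" in cfg.stages or "report" in cfg.stages:
        peb = compare_model_space(peb, ModelSpace())
        (out / "model_space.json").write_text(json.dumps({
            "free_energies": peb.model_free_energies,
            "posterior_probabilities": {
                k: v["probability"] for k, v in peb.model_posteriors.items()},
        }, indent=2))
        manifest["stages_run"].append("compare")

    if "report" in cfg.stages:
        eff = extract_effects(peb, "kbit")
        eff["effects"].to_csv(out / "effects_kbit.csv", index=False)
        winner = max(peb.model_posteriors,
                     key=lambda k: peb.model_posteriors[k]["probability"])
        report = {
            "winner": winner,
            "winner_probability": peb.model_posteriors[winner]["probability"],
            "free_energies": peb.model_free_energies,
            "gamma": peb.gamma,
        }
        (out / "report.json").write_text(json.dumps(report, indent=2))
        manifest["stages_run"].append("report")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
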