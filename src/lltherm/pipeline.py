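"""End-to-end orchestration: simulate → reconstruct → calibrate → map
temperature → validate, from a single declarative configuration.

The configuration fixes every physical and processing choice (sequence
timing, averaging constraints, phantom temperatures and noise, seeds,
processing switches) so a run is reproducible bit for bit; a manifest JSON
records the configuration hash, the seeds and the artifact paths.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import datasets, io
from .phantom import (
    default_geometry,
    gaussian_line_mask,
    make_flip_angle_map,
    make_vial_phantom,
    simulate_acquisition,
)
from .recon import fit_t1star, reconstruct_series, t1_map
from .schedule import AveragingSchedule, build_schedule
from .signal_model import SequenceParams
from .thermometry import fit_K, temperature_map
from .validation import accuracy_precision, bland_altman

__all__ = ["RunConfig", "run_pipeline", "STAGES"]

STAGES = ("simulate", "recon", "calibrate", "thermo", "validate")


@dataclass
class RunConfig:
    """Declarative description of a full synthetic thermometry run."""

    # sequence
    alpha_nominal: float = 5.0
    TR_alpha: float = 25.0
    TE: float = 4.0
    TR_max: float = 2000.0
    n_slices: int = 1
    sat_angle: float = 90.0
    # schedule constraints
    n_points_max: int = 79
    budget: int = 948
    head_points: int = 5
    head_na: int = 42
    tail_points: int = 20
    tail_na: int = 3
    # phantom
    n_vials: int = 5
    reference_temp: float = 24.3
    target_temp: float = 41.7
    grid_nx: int = 64
    grid_ny: int = 35
    # acquisition
    n_keep_lines: int = 24
    mask_width: float | None = None
    noise_sd: float = 0.0
    b1_mean: float = 4.8
    b1_sd: float = 0.6
    seed: int = 0
    # processing switches
    apodize: bool = True
    zero_fill_shape: tuple[int, int] | None = None
    weight_by_na: bool = False
    clip_negatives: bool = True
    K: float = datasets.SENSITIVITY_COEFFICIENT_K

    def sequence(self) -> SequenceParams:
        return SequenceParams(
            alpha_nominal=self.alpha_nominal, TR_alpha=self.TR_alpha, TE=self.TE,
            TR_max=self.TR_max, n_slices=self.n_slices,
            t_sat=self.TR_alpha / 3.0, t_line=self.TR_alpha / 3.0,
            sat_angle=self.sat_angle,
        )

    def schedule(self) -> AveragingSchedule:
        return build_schedule(
            n_points_max=self.n_points_max, budget=self.budget,
            head_points=self.head_points, head_na=self.head_na,
            tail_points=self.tail_points, tail_na=self.tail_na,
            TR_alpha=self.TR_alpha,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["zero_fill_shape"] is not None:
            d["zero_fill_shape"] = list(d["zero_fill_shape"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("zero_fill_shape") is not None:
            d["zero_fill_shape"] = tuple(d["zero_fill_shape"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(io.load_config(path))

    def to_yaml(self, path) -> None:
        io.save_config(path, self.to_dict())

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _simulate_one(config: RunConfig, temperature: float, seed: int, out: Path, tag: str):
    calib = datasets.load_calibration(n_samples=config.n_vials)
    phantom = make_vial_phantom(
        geometry=default_geometry(config.n_vials, (config.grid_nx, config.grid_ny)),
        temperature=temperature, calibration=calib,
    )
    b1 = make_flip_angle_map(
        (config.grid_nx, config.grid_ny), mean=config.b1_mean, sd=config.b1_sd,
        seed=seed + 101,
    )
    mask = gaussian_line_mask(
        config.grid_ny, config.n_keep_lines, width=config.mask_width, seed=seed + 202
    )
    ks = simulate_acquisition(
        phantom, b1, config.schedule(), config.sequence(),
        mask=mask, noise_sd=config.noise_sd, seed=seed,
    )
    path = out / f"kspace_{tag}.h5"
    io.save_kspace(path, ks)
    io.save_map(out / f"b1_{tag}.nii", b1.angles[None], units="deg")
    io.save_map(out / f"labels_{tag}.nii", phantom.label_grid[None].astype(float), units="label")
    return {"kspace": str(path), "b1": str(out / f"b1_{tag}.nii"),
            "labels": str(out / f"labels_{tag}.nii")}


def _recon_one(config: RunConfig, out: Path, tag: str, artifacts: dict):
    ks = io.load_kspace(artifacts[f"simulate_{tag}"]["kspace"])
    b1_values, _ = io.load_map(artifacts[f"simulate_{tag}"]["b1"])
    from .phantom import FlipAngleMap

    out_shape = tuple(config.zero_fill_shape) if config.zero_fill_shape else None
    series = reconstruct_series(ks, out_shape=out_shape, apodize=config.apodize,
                                clip_negative=config.clip_negatives)
    if out_shape and out_shape != (config.grid_nx, config.grid_ny):
        from skimage.transform import resize

        b1_grid = resize(b1_values[0], out_shape, order=1, mode="edge")
    else:
        b1_grid = b1_values[0]
    tsmap = fit_t1star(series, ks.seq, weight_by_na=config.weight_by_na)
    tmap = t1_map(tsmap, FlipAngleMap(angles=b1_grid), config.TR_alpha)
    t1_path = out / f"t1_{tag}.nii"
    io.save_map(t1_path, tmap.t1, units="ms", valid=tmap.valid)
    io.save_map(out / f"t1star_{tag}.nii", tsmap.t1star, units="ms", valid=tsmap.valid)
    return {"t1": str(t1_path), "t1star": str(out / f"t1star_{tag}.nii")}


def run_pipeline(config: RunConfig, stages=STAGES, out_dir="lltherm_run") -> dict:
    """Execute the requested pipeline stages; returns the manifest dict.

    Stage dependencies are explicit: ``recon`` needs ``simulate`` artifacts,
    ``thermo`` needs both reconstructed T1 maps, ``validate`` needs the
    temperature map.  Missing upstream artifacts raise with the artifact
    named.  Rerunning an identical configuration reproduces an identical
    manifest hash.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    artifacts: dict = {}
    if manifest_path.exists():
        artifacts = json.loads(manifest_path.read_text()).get("artifacts", {})

    stages = tuple(stages)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")

    if "simulate" in stages:
        artifacts["simulate_ref"] = _simulate_one(
            config, config.reference_temp, config.seed, out, "ref")
        artifacts["simulate_hot"] = _simulate_one(
            config, config.target_temp, config.seed + 1, out, "hot")

    if "recon" in stages:
        for tag in ("ref", "hot"):
            if f"simulate_{tag}" not in artifacts:
                raise RuntimeError(f"recon requires missing artifact simulate_{tag} (kspace)")
            artifacts[f"recon_{tag}"] = _recon_one(config, out, tag, artifacts)

    if "calibrate" in stages:
        calib = datasets.load_calibration()
        model = fit_K(calib)
        path = out / "sensitivity.json"
        path.write_text(json.dumps(
            {"K": model.K, "stderr": model.stderr, "method": model.method}, indent=2))
        artifacts["calibrate"] = {"sensitivity": str(path)}

    if "thermo" in stages:
        for tag in ("ref", "hot"):
            if f"recon_{tag}" not in artifacts:
                raise RuntimeError(f"thermo requires missing artifact recon_{tag} (t1 map)")
        from .recon import T1Map

        t1a, va = io.load_map(artifacts["recon_ref"]["t1"])
        t1b, vb = io.load_map(artifacts["recon_hot"]["t1"])
        tm = temperature_map(T1Map(t1=t1b, valid=vb), T1Map(t1=t1a, valid=va),
                             Ta=config.reference_temp, model=config.K)
        path = out / "temperature.nii"
        io.save_map(path, tm.temperature, units="degC", valid=tm.valid)
        artifacts["thermo"] = {"temperature": str(path)}

    if "validate" in stages:
        if "thermo" not in artifacts:
            raise RuntimeError("validate requires missing artifact thermo (temperature map)")
        temp, valid = io.load_map(artifacts["thermo"]["temperature"])
        labels, _ = io.load_map(artifacts["simulate_hot"]["labels"])
        labels = labels[0].astype(int)
        if temp.shape[-2:] != labels.shape:
            from skimage.transform import resize

            labels = resize(labels.astype(float), temp.shape[-2:], order=0,
                            preserve_range=True).astype(int)
        rows = []
        for lab in sorted(set(labels.ravel()) - {0, 1}):
            sel = (labels == lab)[None] & valid
            if sel.any():
                rows.append({
                    "label": int(lab),
                    "mean_temp": float(temp[sel].mean()),
                    "sd_temp": float(temp[sel].std(ddof=1)) if sel.sum() > 1 else 0.0,
                })
        means = [r["mean_temp"] for r in rows]
        sds = [r["sd_temp"] for r in rows]
        truth = [config.target_temp] * len(rows)
        report = {"per_vial": rows}
        if rows:
            acc, acc_sd, prec, prec_sd = accuracy_precision(
                np.array(means) + 273.15, np.array(sds), np.array(truth) + 273.15)
            ba = bland_altman(means, truth)
            report.update({
                "accuracy_pct": acc, "precision_pct": prec,
                "bias_degC": ba.bias, "sd_degC": ba.sd,
            })
        path = out / "validation.json"
        path.write_text(json.dumps(report, indent=2))
        artifacts["validate"] = {"report": str(path)}

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "stages": list(stages),
        "artifacts": artifacts,
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
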