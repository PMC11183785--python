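"""Pipeline orchestration: phantom -> preprocess -> pcmra -> segment ->
metrics -> flowquant, with a reproducibility manifest.

Stage outputs are plain files (HDF5 / NIfTI / CSV / JSON), never in-memory
handoffs, so every stage can be re-run independently.  The manifest records
each stage's parameter block and a SHA-256 hash of every written file;
re-running with the same configuration and seed reproduces all
deterministic artifacts bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import flow as flow_mod
from . import metrics as metrics_mod
from .io import (
    FlowVolume4D,
    load_flow_dataset,
    load_mask,
    save_flow_dataset,
    save_mask,
)
from .pcmra import compute_pcmra
from .phantom import (
    TubeSpec,
    make_bifurcation_phantom,
    make_tube_phantom,
    raised_cosine_waveform,
)
from .preprocess import (
    apply_noise_mask,
    compute_noise_mask,
    eddy_current_correct,
    static_tissue_mask,
)

__all__ = ["PipelineConfig", "run_pipeline", "make_preset"]

_STAGES = ("phantom", "preprocess", "pcmra", "segment", "metrics", "flowquant")


@dataclasses.dataclass
class PipelineConfig:
    preset: str = "bifurcation"  # tube | stenosis | bifurcation
    shape: tuple[int, int, int] = (48, 64, 64)
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    n_phases: int = 5
    snr: float = float("inf")
    seed: int = 0
    out_dir: str = "pipeline_out"
    stages: tuple[str, ...] = _STAGES
    noise_quantile: float = 0.35
    eddy_poly_order: int = 2
    pcmra_variant: str = "printed"
    plane_spacing_mm: float = 0.25
    exclusion_mm: float = 2.0
    model_path: str | None = None  # trained segmentation model (.npz); None
    # uses the phantom truth mask as reference segmentation

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        cfg = cls(**data)
        return cfg

    def validate(self) -> None:
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.model_path is not None and not Path(self.model_path).exists():
            raise FileNotFoundError(
                f"segmentation model not found: {self.model_path}"
            )
        if "segment" in self.stages and self.model_path is None and "phantom" not in self.stages:
            raise ValueError(
                "segment stage needs a model_path when no phantom truth is generated"
            )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def make_preset(cfg: PipelineConfig):
    """Instantiate the named phantom preset at the configured grid."""
    shape = tuple(cfg.shape)
    spacing = np.asarray(cfg.spacing, dtype=float)
    ext = (np.asarray(shape) - 1) * spacing
    mid = ext / 2.0
    waveform = raised_cosine_waveform(cfg.n_phases)
    if cfg.preset in ("tube", "stenosis"):
        grade = 0.7 if cfg.preset == "stenosis" else 0.0
        spec = TubeSpec(
            start=[mid[0], mid[1], 2.5],
            end=[mid[0], mid[1], ext[2] - 2.5],
            radius_mm=2.0,
            v_max=0.5,
            stenosis_grade=grade,
            label="tube",
        )
        return make_tube_phantom(
            spec, shape, spacing, waveform=waveform, snr=cfg.snr, seed=cfg.seed
        )
    if cfg.preset == "bifurcation":
        junction = np.array([mid[0], mid[1], ext[2] * 0.5])
        parent = TubeSpec(
            start=[mid[0], mid[1], 3.0], end=junction, radius_mm=2.0,
            v_max=0.5, label="ICA",
        )
        d1 = TubeSpec(
            start=junction, end=[mid[0], ext[1] * 0.85, ext[2] * 0.85],
            radius_mm=1.6, label="MCA",
        )
        d2 = TubeSpec(
            start=junction, end=[mid[0], ext[1] * 0.15, ext[2] * 0.85],
            radius_mm=1.6, label="ACA",
        )
        return make_bifurcation_phantom(
            parent, (d1, d2), split=0.6, shape=shape, spacing=spacing,
            waveform=waveform, snr=cfg.snr, seed=cfg.seed,
        )
    raise ValueError(f"unknown preset {cfg.preset!r}")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the enabled stages in order; returns the manifest dict.

    A stage failure aborts the run with the stage name and cause; artifacts
    of completed stages are retained on disk.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(cfg), "stages": []}
    truth = None
    vol: FlowVolume4D | None = None
    mask = None

    def record(name: str, params: dict, outputs: list[Path], t0: float) -> None:
        manifest["stages"].append(
            {
                "stage": name,
                "params": params,
                "outputs": {str(p): _sha256(p) for p in outputs},
                "wall_s": round(time.time() - t0, 3),
            }
        )

    try:
        if "phantom" in cfg.stages:
            t0 = time.time()
            vol, truth = make_preset(cfg)
            bundle = out / "flow.h5"
            save_flow_dataset(vol, bundle)
            truth_mask_path = out / "truth_mask.nii.gz"
            save_mask(truth.mask, truth_mask_path)
            rows = [
                {"vessel": lab, "analytic_flow_mls": q}
                for lab, q in truth.flows_mls.items()
            ]
            truth_csv = out / "truth_flows.csv"
            pd.DataFrame(rows).to_csv(truth_csv, index=False)
            record(
                "phantom",
                {"preset": cfg.preset, "shape": list(cfg.shape),
                 "spacing": list(cfg.spacing), "snr": str(cfg.snr),
                 "seed": cfg.seed, "n_phases": cfg.n_phases},
                [bundle, truth_mask_path, truth_csv],
                t0,
            )
            mask = truth.mask
        else:
            vol = load_flow_dataset(out / "flow.h5")

        if "preprocess" in cfg.stages:
            t0 = time.time()
            nm = compute_noise_mask(vol, cfg.noise_quantile)
            vol = apply_noise_mask(vol, nm)
            static = static_tissue_mask(vol, nm)
            vol = eddy_current_correct(vol, static, cfg.eddy_poly_order)
            corr = out / "flow_corrected.h5"
            save_flow_dataset(vol, corr)
            record(
                "preprocess",
                {"noise_quantile": cfg.noise_quantile,
                 "eddy_poly_order": cfg.eddy_poly_order},
                [corr],
                t0,
            )

        pcmra_vol = None
        if "pcmra" in cfg.stages:
            t0 = time.time()
            pcmra_vol = compute_pcmra(vol, variant=cfg.pcmra_variant)
            pcmra_path = out / "pcmra.npy"
            np.save(pcmra_path, pcmra_vol.intensity)
            record("pcmra", {"variant": cfg.pcmra_variant}, [pcmra_path], t0)

        if "segment" in cfg.stages:
            t0 = time.time()
            if cfg.model_path is not None:
                from .net import load_model, predict_mask

                model = load_model(cfg.model_path)
                mask = predict_mask(model, pcmra_vol)
                source = f"model:{cfg.model_path}"
            else:
                mask = truth.mask  # reference segmentation from the phantom
                source = "phantom-truth"
            seg_path = out / "segmentation.nii.gz"
            save_mask(mask, seg_path)
            record("segment", {"source": source}, [seg_path], t0)

        if "metrics" in cfg.stages:
            t0 = time.time()
            ref = truth.mask if truth is not None else load_mask(out / "truth_mask.nii.gz")
            rep = metrics_mod.agreement_report(mask, ref, spacing=vol.spacing)
            metrics_path = out / "metrics.json"
            metrics_path.write_text(
                json.dumps(dataclasses.asdict(rep), indent=2, sort_keys=True),
                encoding="utf-8",
            )
            record("metrics", {}, [metrics_path], t0)

        if "flowquant" in cfg.stages:
            t0 = time.time()
            summaries, _ = flow_mod.quantify_vessels(
                vol, mask, cfg.plane_spacing_mm, cfg.exclusion_mm
            )
            rows = [dataclasses.asdict(s) for s in summaries]
            df = pd.DataFrame(rows)
            report_path = out / "flow_report.csv"
            df.to_csv(report_path, index=False)
            params = {
                "plane_spacing_mm": cfg.plane_spacing_mm,
                "exclusion_mm": cfg.exclusion_mm,
            }
            outputs = [report_path]
            if len(summaries) >= 3:
                # inflow = largest-lumen vessel, outflows = the rest
                by_area = sorted(summaries, key=lambda s: -s.median_area_mm2)
                fce = flow_mod.flow_conservation_error(
                    [by_area[0].median_mean_flow_mls],
                    [s.median_mean_flow_mls for s in by_area[1:]],
                )
                fce_path = out / "fce.json"
                fce_path.write_text(
                    json.dumps({"fce": fce, "inflow_vessel": by_area[0].label},
                               indent=2),
                    encoding="utf-8",
                )
                outputs.append(fce_path)
                manifest["fce"] = fce
            record("flowquant", params, outputs, t0)
    except Exception as exc:
        stage = manifest["stages"][-1]["stage"] if manifest["stages"] else "setup"
        raise RuntimeError(
            f"pipeline aborted after stage {stage!r}: {exc}"
        ) from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
    )
    return manifest
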