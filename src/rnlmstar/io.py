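"""Image I/O, run configurations, and the reproducible command dispatcher.

Images are carried internally as float64 arrays on the [0,1] scale.
Readers map PNG (8-bit) and TIFF (8/16-bit) integers linearly to [0,1]
and accept raw ``.npy`` float arrays; multi-channel inputs are collapsed
by luminance average (logged). Writers quantize to the container depth
and clip out-of-range values with a warning.

``run_config`` executes a structured command description and writes a
manifest (config echo + package version) next to the primary output, so
any run can be replayed bit-identically from its manifest.
"""

from __future__ import annotations

import glob as _glob
import json
import logging
import math
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from ._version import __version__
from . import phantoms as _ph
from .metrics import metric_report
from .nlm import FilterParams, compute_weight_field, nlm_filter, rnlm_filter, rnlm_star_filter
from .noise import NoiseSpec, apply_noise, estimate_sigma_background
from .optimize import ParamRanges, optimize
from .robustness import (
    NamedFilter,
    average_denoiser,
    median_denoiser,
    nlm_denoiser,
    noise_sweep,
    rnlm_denoiser,
    rnlm_star_denoiser,
)
from .segmentation import segmentation_sweep
from . import baselines

logger = logging.getLogger("rnlmstar")

__all__ = ["read_image", "write_image", "run_config", "parse_filter"]

_INT_DEPTH = {"uint8": 255.0, "uint16": 65535.0}


def read_image(path) -> np.ndarray:
    """Read a PNG/TIFF/npy image as a float64 array normalized to [0,1]."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(str(p))
    suffix = p.suffix.lower()
    if suffix == ".npy":
        arr = np.load(p)
    elif suffix in (".png", ".tif", ".tiff"):
        arr = iio.imread(p)
    else:
        raise ValueError(f"unsupported image format {suffix!r}")
    if arr.dtype.name in _INT_DEPTH:
        out = arr.astype(float) / _INT_DEPTH[arr.dtype.name]
    elif np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"unsupported integer depth {arr.dtype}")
    else:
        out = arr.astype(float)
    if out.ndim == 3:
        logger.info("collapsing %d-channel image %s by luminance average", out.shape[-1], p)
        out = out.mean(axis=-1)
    if out.ndim != 2:
        raise ValueError(f"image is not 2-D after conversion: shape {out.shape}")
    if not np.all(np.isfinite(out)):
        raise ValueError("image contains non-finite values")
    return out


def write_image(img, path, depth: int | None = None) -> Path:
    """Write a [0,1] image; depth 8/16 for PNG/TIFF, float for .npy.

    Values outside [0,1] are clipped with a logged warning.
    """
    p = Path(path)
    arr = np.asarray(img, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite values")
    if arr.min() < 0 or arr.max() > 1:
        logger.warning(
            "clipping image values [%g, %g] to [0, 1] for %s", arr.min(), arr.max(), p
        )
        arr = np.clip(arr, 0.0, 1.0)
    suffix = p.suffix.lower()
    p.parent.mkdir(parents=True, exist_ok=True)
    if suffix == ".npy":
        np.save(p, arr)
        return p
    if suffix == ".png":
        depth = depth or 8
        if depth != 8:
            raise ValueError("PNG output supports 8-bit depth only")
        iio.imwrite(p, np.round(arr * 255.0).astype(np.uint8))
        return p
    if suffix in (".tif", ".tiff"):
        depth = depth or 16
        if depth == 8:
            iio.imwrite(p, np.round(arr * 255.0).astype(np.uint8))
        elif depth == 16:
            iio.imwrite(p, np.round(arr * 65535.0).astype(np.uint16))
        else:
            raise ValueError(f"unsupported TIFF depth {depth}")
        return p
    raise ValueError(f"unsupported image format {suffix!r}")


# ---------------------------------------------------------------------------
# filter bank parsing shared by CLI commands
# ---------------------------------------------------------------------------

def _params_from(d: dict) -> FilterParams:
    allowed = {"h", "radp", "rads", "degc", "omega", "a", "patch_dialect"}
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown filter parameter field(s): {sorted(unknown)}")
    if "a" in d and d["a"] in ("inf", None):
        d = {**d, "a": math.inf}
    return FilterParams(**d)


def parse_filter(name: str, params: dict | None = None, sigma="level") -> NamedFilter:
    """Build a NamedFilter from a CLI-style name.

    Names: ``nlm``, ``rnlm``, ``rnlm-star``, ``identity``, ``average-K``,
    ``median-K`` (K the odd kernel size).
    """
    params = dict(params or {})
    if name in ("nlm", "rnlm", "rnlm-star", "rnlm_star"):
        fp = _params_from(params)
        if name == "nlm":
            return nlm_denoiser(fp)
        if name == "rnlm":
            return rnlm_denoiser(fp, sigma=sigma)
        return rnlm_star_denoiser(fp, sigma=sigma)
    if name == "identity":
        from .robustness import identity_filter

        return identity_filter()
    for prefix, builder in (("average", average_denoiser), ("median", median_denoiser)):
        if name.startswith(prefix):
            tail = name[len(prefix):].lstrip("-_")
            if not tail.isdigit():
                raise ValueError(f"cannot parse kernel size from {name!r}")
            return builder(int(tail))
    raise ValueError(f"unknown filter name {name!r}")


# ---------------------------------------------------------------------------
# run-config dispatcher
# ---------------------------------------------------------------------------

_SCHEMAS: dict[str, dict[str, set]] = {
    "phantom": {
        "required": {"out"},
        "optional": {
            "size", "bands", "particles", "radius", "contrast", "blur",
            "seed", "band_levels", "depth",
        },
    },
    "add_noise": {
        "required": {"family", "intensity", "input", "output"},
        "optional": {"seed", "depth"},
    },
    "denoise": {
        "required": {"method", "input", "output"},
        "optional": {
            "params", "kernel", "sigma", "auto_sigma", "bg_rows", "no_sqrt",
            "depth", "dump_weights",
        },
    },
    "metrics": {
        "required": {"reference", "image"},
        "optional": {"out"},
    },
    "optimize": {
        "required": {"images", "n", "out"},
        "optional": {"seed", "sigmas", "ranges", "trials_csv"},
    },
    "sweep": {
        "required": {"family", "filter", "images", "out"},
        "optional": {"levels", "seed", "params", "sigma"},
    },
    "segment_eval": {
        "required": {"family", "filters", "images", "out"},
        "optional": {"levels", "seed", "classes", "params", "diff_out", "sigma"},
    },
}


def _validate_config(cfg: dict) -> str:
    if "command" not in cfg:
        raise ValueError("config missing required field: command")
    command = cfg["command"]
    if command not in _SCHEMAS:
        raise ValueError(f"unknown command {command!r}")
    schema = _SCHEMAS[command]
    fields = set(cfg) - {"command"}
    missing = schema["required"] - fields
    if missing:
        raise ValueError(f"{command}: missing required field(s): {sorted(missing)}")
    unknown = fields - schema["required"] - schema["optional"]
    if unknown:
        raise ValueError(f"{command}: unknown field(s): {sorted(unknown)}")
    return command


def _expand_images(spec) -> list[np.ndarray]:
    if isinstance(spec, str):
        paths = sorted(_glob.glob(spec))
    else:
        paths = list(spec)
    if not paths:
        raise ValueError(f"no images match {spec!r}")
    return [read_image(p) for p in paths]


def _write_manifest(cfg: dict, primary_out) -> Path:
    mpath = Path(str(primary_out) + ".manifest.json")
    payload = {"config": cfg, "version": __version__}
    mpath.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return mpath


def run_config(cfg: dict) -> dict:
    """Validate and execute a command config; returns artifact paths.

    Every invocation writes a ``<output>.manifest.json`` capturing the
    full config and version: re-running the manifest reproduces the
    outputs bit-identically.
    """
    command = _validate_config(cfg)
    artifacts: dict[str, str] = {}

    if command == "phantom":
        size = tuple(cfg.get("size", (64, 64)))
        spec = _ph.PhantomSpec(
            size=size,
            n_bands=cfg.get("bands", 4),
            n_particles=cfg.get("particles", 6),
            particle_radius_px=cfg.get("radius", 2),
            particle_contrast=cfg.get("contrast", 0.5),
            edge_blur_sigma=cfg.get("blur", 0.6),
            seed=cfg.get("seed", 0),
            band_levels=(tuple(cfg["band_levels"]) if cfg.get("band_levels") else None),
        )
        img = _ph.make_phantom(spec)
        out = write_image(img, cfg["out"], depth=cfg.get("depth"))
        artifacts["out"] = str(out)

    elif command == "add_noise":
        img = read_image(cfg["input"])
        spec = NoiseSpec(cfg["family"], float(cfg["intensity"]), int(cfg.get("seed", 0)))
        noisy = apply_noise(img, spec)
        out = write_image(noisy, cfg["output"], depth=cfg.get("depth"))
        artifacts["output"] = str(out)

    elif command == "denoise":
        img = read_image(cfg["input"])
        method = cfg["method"]
        if method in ("average", "median"):
            k = int(cfg.get("kernel", 5))
            fn = baselines.average_filter if method == "average" else baselines.median_filter
            result = fn(img, k)
        else:
            fp = _params_from(dict(cfg.get("params", {})))
            if cfg.get("auto_sigma"):
                rows = int(cfg.get("bg_rows", 4))
                mask = np.zeros(img.shape, dtype=bool)
                mask[:rows, :] = True
                sigma = estimate_sigma_background(img, mask)
            else:
                sigma = float(cfg.get("sigma", 0.0))
            no_sqrt = bool(cfg.get("no_sqrt", False))
            if method == "nlm":
                result = nlm_filter(img, fp)
            elif method == "rnlm":
                result = rnlm_filter(img, fp, sigma, no_sqrt=no_sqrt)
            elif method in ("rnlm-star", "rnlm_star"):
                result = rnlm_star_filter(img, fp, sigma, no_sqrt=no_sqrt)
            else:
                raise ValueError(f"unknown denoise method {method!r}")
            if cfg.get("dump_weights"):
                dw = cfg["dump_weights"]
                field = compute_weight_field(
                    img,
                    (int(dw["row"]), int(dw["col"])),
                    fp,
                    variant="rnlm_star" if "star" in method else "nlm",
                )
                pd.DataFrame(field.weights).to_csv(dw["file"], index=False)
                artifacts["weights"] = str(dw["file"])
        out = write_image(result, cfg["output"], depth=cfg.get("depth"))
        artifacts["output"] = str(out)

    elif command == "metrics":
        ref = read_image(cfg["reference"])
        img = read_image(cfg["image"])
        rep = metric_report(ref, img)
        payload = json.dumps(rep.to_dict(), indent=2, sort_keys=True) + "\n"
        if cfg.get("out"):
            Path(cfg["out"]).write_text(payload)
            artifacts["out"] = str(cfg["out"])
        artifacts["report"] = payload

    elif command == "optimize":
        images = _expand_images(cfg["images"])
        sigmas = [float(s) for s in cfg.get("sigmas", (0.05, 0.1, 0.15, 0.2, 0.3))]
        ranges_kw = dict(cfg.get("ranges", {}))
        for key in ("h", "degc"):
            if key in ranges_kw:
                ranges_kw[key] = tuple(ranges_kw[key])
        for key in ("radp", "omega"):
            if key in ranges_kw:
                ranges_kw[key] = tuple(int(v) for v in ranges_kw[key])
        ranges = ParamRanges(**ranges_kw)
        res = optimize(ranges, images, sigmas, int(cfg["n"]), int(cfg.get("seed", 0)))
        best = res.best
        payload = {
            "best": {
                "h": best.h, "degc": best.degc, "radp": best.radp,
                "omega": best.omega, "rads": best.rads,
            },
            "best_mse": res.best_mse,
            "n": res.n,
            "seed": res.seed,
        }
        Path(cfg["out"]).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        artifacts["out"] = str(cfg["out"])
        if cfg.get("trials_csv"):
            res.trials_dataframe().to_csv(cfg["trials_csv"], index=False)
            artifacts["trials_csv"] = str(cfg["trials_csv"])

    elif command == "sweep":
        images = _expand_images(cfg["images"])
        filt = parse_filter(
            cfg["filter"], cfg.get("params"), sigma=cfg.get("sigma", "level")
        )
        levels = cfg.get("levels", [round(0.1 * k, 10) for k in range(1, 10)])
        curve = noise_sweep(images, cfg["family"], levels, filt, int(cfg.get("seed", 0)))
        curve.table.to_csv(cfg["out"], index=False)
        artifacts["out"] = str(cfg["out"])

    elif command == "segment_eval":
        images = _expand_images(cfg["images"])
        bank = [
            parse_filter(name, cfg.get("params"), sigma=cfg.get("sigma", "level"))
            for name in cfg["filters"]
        ]
        levels = cfg.get("levels", [round(0.1 * k, 10) for k in range(1, 10)])
        classes = [int(c) for c in cfg.get("classes", (3, 8))]
        curves, diffs = segmentation_sweep(
            images, cfg["family"], levels, bank, classes, int(cfg.get("seed", 0))
        )
        curves.to_csv(cfg["out"], index=False)
        artifacts["out"] = str(cfg["out"])
        if cfg.get("diff_out"):
            diffs.to_csv(cfg["diff_out"], index=False)
            artifacts["diff_out"] = str(cfg["diff_out"])

    primary = (
        artifacts.get("out")
        or artifacts.get("output")
        or cfg.get("out")
        or cfg.get("output")
    )
    if primary:
        artifacts["manifest"] = str(_write_manifest(cfg, primary))
    return artifacts
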