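"""File I/O: PNG images, manifest / feature / report tables.

All tabular artifacts are plain CSV written through pandas; images are
8-bit RGB PNG. The manifest schema is
``filename, concentration_uM, group_index, replicate_index, seed``.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .calibration import EvaluationReport, LODResult, RecoveryRow
from .features import FEATURE_NAMES
from .synthetic import SyntheticDataset, WellImage, _image_seed

__all__ = [
    "save_dataset", "load_image", "load_manifest_images",
    "write_feature_table", "write_audit_csv", "write_evaluation_csv",
    "write_trace_csv", "write_predictions_csv", "write_recovery_csv",
]


def save_dataset(ds: SyntheticDataset, outdir: str | Path) -> Path:
    """Write all images as PNG plus the manifest CSV; returns manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    k = 0
    for gi, c in enumerate(ds.concentrations):
        for ri in range(ds.n_per_group):
            im = ds.images[k]
            fname = f"well_g{gi:02d}_r{ri:03d}.png"
            iio.imwrite(outdir / fname, np.asarray(im.pixels, dtype=np.uint8))
            rows.append({
                "filename": fname,
                "concentration_uM": c,
                "group_index": gi,
                "replicate_index": ri,
                "seed": _image_seed(ds.master_seed, gi, ri),
            })
            k += 1
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_image(path: str | Path, true_conc: float | None = None) -> WellImage:
    """Read an 8-bit RGB PNG/JPEG as a WellImage (alpha dropped if present)."""
    px = np.asarray(iio.imread(path))
    if px.ndim == 2:
        px = np.stack([px] * 3, axis=-1)
    if px.shape[2] == 4:
        px = px[..., :3]
    return WellImage(pixels=px, true_conc=true_conc, seed_tag=str(path))


def load_manifest_images(manifest: str | Path) -> tuple[list[WellImage], pd.DataFrame]:
    """Load every image listed in a manifest CSV, labels attached."""
    manifest = Path(manifest)
    table = pd.read_csv(manifest)
    images = [
        load_image(manifest.parent / row.filename,
                   true_conc=float(row.concentration_uM))
        for row in table.itertuples()
    ]
    return images, table


def write_feature_table(
    path: str | Path, X: np.ndarray,
    filenames=None, concentrations=None,
) -> None:
    df = pd.DataFrame(np.asarray(X), columns=list(FEATURE_NAMES))
    if concentrations is not None:
        df.insert(0, "concentration_uM", np.asarray(concentrations))
    if filenames is not None:
        df.insert(0, "filename", list(filenames))
    df.to_csv(path, index=False)


def write_audit_csv(path: str | Path, detections, filenames=None) -> None:
    df = pd.DataFrame(
        [{"cx": d.cx, "cy": d.cy, "r": d.r, "score": d.score} for d in detections]
    )
    if filenames is not None:
        df.insert(0, "filename", list(filenames))
    df.to_csv(path, index=False)


def write_evaluation_csv(path: str | Path, reports: dict[str, EvaluationReport]) -> None:
    pd.DataFrame(
        [{"split": name, "r2": r.r2, "mse": r.mse, "slope": r.slope,
          "intercept": r.intercept, "n": r.n} for name, r in reports.items()]
    ).to_csv(path, index=False)


def write_trace_csv(path: str | Path, trace) -> None:
    pd.DataFrame(
        {"epoch": np.arange(1, len(trace.mse) + 1), "train_mse_uM2": trace.mse}
    ).to_csv(path, index=False)


def write_predictions_csv(
    path: str | Path, predicted, truth=None, filenames=None, status=None,
) -> None:
    df = pd.DataFrame({"predicted_uM": np.asarray(predicted, dtype=float)})
    if truth is not None:
        df.insert(0, "concentration_uM", np.asarray(truth))
    if filenames is not None:
        df.insert(0, "filename", list(filenames))
    if status is not None:
        df["status"] = list(status)
    df.to_csv(path, index=False)


def write_recovery_csv(path: str | Path, rows: list[RecoveryRow],
                       lod: LODResult | None = None) -> None:
    df = pd.DataFrame(
        [{"spiked_uM": r.spiked_conc, "measured_mean_uM": r.measured_mean,
          "recovery_pct": r.recovery, "rsd_pct": r.rsd,
          "n_replicates": r.n_replicates} for r in rows]
    )
    df.to_csv(path, index=False)
    if lod is not None:
        Path(path).with_suffix(".lod.txt").write_text(
            f"LOD = {lod.lod:.4f} uM (k={lod.k_factor:g}, "
            f"blank SD={lod.blank_sd:.4f}, slope={lod.slope:.4f})\n"
        )
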