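"""End-to-end calibration workflow.

Ties the generator, preprocessing, feature extraction, network training
and evaluation together into the single run the assay calibration
consists of: render the 12-level × 100-replicate dataset, segment and
crop every image, extract the 9 color moments, split 3:1 stratified by
level, train the 9-18-1 network and evaluate both splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import bpann, calibration, features, preprocess, synthetic

__all__ = ["CalibrationRun", "extract_features", "run_calibration",
           "matrix_shifted_images", "predict_images"]


@dataclass
class CalibrationRun:
    """Everything a default calibration run produces."""

    dataset: synthetic.SyntheticDataset
    X: np.ndarray                    # n × 9 color moments
    y: np.ndarray                    # n true concentrations, µM
    train_idx: np.ndarray
    test_idx: np.ndarray
    state: bpann.NetworkState
    trace: bpann.TrainingTrace
    train_report: calibration.EvaluationReport
    test_report: calibration.EvaluationReport
    detections: list = field(default_factory=list)

    @property
    def train_pred(self) -> np.ndarray:
        return bpann.predict_batch(self.state, self.X[self.train_idx])

    @property
    def test_pred(self) -> np.ndarray:
        return bpann.predict_batch(self.state, self.X[self.test_idx])


def extract_features(
    images,
    cfg: preprocess.PreprocessConfig = preprocess.PreprocessConfig(),
) -> tuple[np.ndarray, list]:
    """Preprocess each image and extract its color moments.

    Returns the n×9 feature matrix and the circle detections for audit.
    Segmentation failures propagate: a calibration image that cannot be
    segmented is a data defect, not something to silently drop.
    """
    rows, dets = [], []
    for im in images:
        crop, det = preprocess.preprocess(im, cfg)
        rows.append(features.color_moments(crop))
        dets.append(det)
    return np.array(rows, dtype=float), dets


def run_calibration(
    master_seed: int = 0,
    concentrations=synthetic.DEFAULT_CONCENTRATIONS,
    n_per_group: int = synthetic.DEFAULT_N_PER_GROUP,
    dose: synthetic.DoseResponseParams = synthetic.DoseResponseParams(),
    colors: synthetic.ColorModel = synthetic.ColorModel(),
    render: synthetic.RenderParams = synthetic.RenderParams(),
    pre_cfg: preprocess.PreprocessConfig = preprocess.PreprocessConfig(),
    net_cfg: bpann.NetworkConfig | None = None,
    split: calibration.SplitSpec | None = None,
) -> CalibrationRun:
    """Run the full calibration workflow from a single master seed.

    The network seed and split seed are derived from ``master_seed`` so
    the whole run is reproducible from one integer.
    """
    sub = np.random.SeedSequence(master_seed).generate_state(3)
    if net_cfg is None:
        net_cfg = bpann.NetworkConfig(seed=int(sub[1] % 2**31))
    if split is None:
        split = calibration.SplitSpec(seed=int(sub[2] % 2**31))

    ds = synthetic.generate_dataset(
        concentrations, n_per_group, dose=dose, colors=colors,
        render=render, master_seed=master_seed,
    )
    X, dets = extract_features(ds.images, pre_cfg)
    y = ds.labels()

    train_idx, test_idx = calibration.split_dataset(y, split)
    state = bpann.init_network(net_cfg)
    state, trace = bpann.train(state, X[train_idx], y[train_idx], net_cfg)

    train_report = calibration.evaluate(
        bpann.predict_batch(state, X[train_idx]), y[train_idx]
    )
    test_report = calibration.evaluate(
        bpann.predict_batch(state, X[test_idx]), y[test_idx]
    )
    return CalibrationRun(
        dataset=ds, X=X, y=y, train_idx=train_idx, test_idx=test_idx,
        state=state, trace=trace,
        train_report=train_report, test_report=test_report, detections=dets,
    )


def matrix_shifted_images(
    spiked_concs,
    n_replicates: int = 3,
    rgb_offset: tuple[float, float, float] = (-4.0, -2.0, 3.0),
    dose: synthetic.DoseResponseParams = synthetic.DoseResponseParams(),
    colors: synthetic.ColorModel = synthetic.ColorModel(),
    render: synthetic.RenderParams = synthetic.RenderParams(),
    master_seed: int = 12345,
) -> list[synthetic.WellImage]:
    """Spiked-sample surrogates: assay images with a constant color offset.

    The offset stands in for a sample-matrix effect (e.g. residual milk
    components shifting the solution color) so recovery/RSD can be
    exercised on images the calibration model has not seen.
    """
    out = []
    for gi, c in enumerate(spiked_concs):
        base = synthetic.solution_color(synthetic.aggregation_fraction(c, dose), colors)
        shifted = np.clip(base + np.asarray(rgb_offset, dtype=float), 0, 255)
        for ri in range(n_replicates):
            seed = synthetic._image_seed(master_seed, gi, ri)
            out.append(
                synthetic.render_well_image(shifted, render, seed=seed, true_conc=c)
            )
    return out


def predict_images(
    state: bpann.NetworkState,
    images,
    pre_cfg: preprocess.PreprocessConfig = preprocess.PreprocessConfig(),
) -> np.ndarray:
    """Predicted concentration (µM) for each image."""
    X, _ = extract_features(images, pre_cfg)
    return bpann.predict_batch(state, X)
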