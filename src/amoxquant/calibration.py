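"""Assay calibration statistics: splitting, fit evaluation, LOD, recovery.

Covers the statistics an analytical-chemistry validation reports:
stratified 3:1 train/test splitting, R²/MSE/slope/intercept of predicted
vs true concentration, the IUPAC limit of detection (k·σ_blank / slope,
k = 3 by default), and spike recovery with relative standard deviation.

R² is computed against the identity line (1 − SS_res/SS_tot with
residuals taken about truth, not about the OLS fit), i.e. as prediction
accuracy; the slope/intercept reported alongside come from the ordinary
least-squares line of predictions on truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SplitSpec",
    "EvaluationReport",
    "LODResult",
    "RecoveryRow",
    "split_dataset",
    "evaluate",
    "lod_iupac",
    "recovery_rsd",
]


@dataclass(frozen=True)
class SplitSpec:
    """Train/test split specification (default 3:1, stratified by level)."""

    train_fraction: float = 0.75
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass(frozen=True)
class EvaluationReport:
    r2: float          # identity-line convention
    mse: float         # µM²
    slope: float       # OLS of pred on truth
    intercept: float   # µM
    n: int


@dataclass(frozen=True)
class LODResult:
    lod: float       # µM
    blank_sd: float  # response units
    slope: float     # response per µM
    k_factor: float


@dataclass(frozen=True)
class RecoveryRow:
    spiked_conc: float    # µM
    measured_mean: float  # µM
    recovery: float       # %
    rsd: float            # %
    n_replicates: int


def split_dataset(
    labels: np.ndarray, spec: SplitSpec = SplitSpec()
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded train/test partition of sample indices.

    With ``stratified`` (the default) each concentration group is split
    train_fraction : 1 − train_fraction separately, so every level appears
    in both sets. Returns sorted (train_idx, test_idx); their union is all
    indices and their intersection empty.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    rng = np.random.default_rng(spec.seed)

    groups = [np.nonzero(labels == lvl)[0] for lvl in np.unique(labels)] \
        if spec.stratified else [np.arange(n)]
    train_parts, test_parts = [], []
    for idx in groups:
        if spec.stratified and len(idx) < 2:
            raise ValueError(
                f"stratified split impossible: group {labels[idx[0]]!r} has "
                f"{len(idx)} member(s)"
            )
        perm = rng.permutation(idx)
        n_train = int(round(spec.train_fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train_parts.append(perm[:n_train])
        test_parts.append(perm[n_train:])
    return np.sort(np.concatenate(train_parts)), np.sort(np.concatenate(test_parts))


def evaluate(pred: np.ndarray, truth: np.ndarray) -> EvaluationReport:
    """Fit-quality report of predicted vs true concentrations.

    mse = mean((pred − truth)²); r2 = 1 − Σ(pred−truth)² / Σ(truth−mean)²;
    slope/intercept from least squares of pred on truth.
    """
    pred = np.asarray(pred, dtype=float).ravel()
    truth = np.asarray(truth, dtype=float).ravel()
    if pred.shape != truth.shape or len(pred) == 0:
        raise ValueError("pred and truth must be non-empty and equal-length")
    ss_tot = float(np.sum((truth - truth.mean()) ** 2))
    if ss_tot <= 0:
        raise ValueError("truth variance is zero; r2 and slope undefined")
    resid = pred - truth
    mse = float(np.mean(resid ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot
    slope, intercept = np.polyfit(truth, pred, 1)
    return EvaluationReport(
        r2=r2, mse=mse, slope=float(slope), intercept=float(intercept), n=len(pred)
    )


def lod_iupac(
    blank_responses: np.ndarray, slope: float, k: float = 3.0
) -> LODResult:
    """IUPAC limit of detection: LOD = k · sd(blanks) / slope.

    ``blank_responses`` are replicate responses of the zero-concentration
    assay (here typically pipeline-predicted concentrations of blank
    images); sample standard deviation (n−1) is used. k = 3 classic, 3.3
    supported.
    """
    blanks = np.asarray(blank_responses, dtype=float).ravel()
    if len(blanks) < 3:
        raise ValueError("need at least 3 blank replicates")
    if slope <= 0:
        raise ValueError("calibration slope must be positive")
    sd = float(np.std(blanks, ddof=1))
    return LODResult(lod=k * sd / slope, blank_sd=sd, slope=float(slope), k_factor=k)


def recovery_rsd(spiked_conc: float, measured: np.ndarray) -> RecoveryRow:
    """Spike recovery (%) and RSD (%) from replicate measured concentrations."""
    if spiked_conc <= 0:
        raise ValueError("spiked concentration must be > 0")
    measured = np.asarray(measured, dtype=float).ravel()
    if len(measured) < 2:
        raise ValueError("need at least 2 replicates")
    mean = float(measured.mean())
    if mean == 0:
        raise ValueError("zero mean measured concentration; RSD undefined")
    sd = float(np.std(measured, ddof=1))
    return RecoveryRow(
        spiked_conc=float(spiked_conc),
        measured_mean=mean,
        recovery=100.0 * mean / spiked_conc,
        rsd=100.0 * sd / mean,
        n_replicates=len(measured),
    )
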