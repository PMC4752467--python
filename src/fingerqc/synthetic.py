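"""Seeded generator of multi-batch, multi-wavelength fingerprint datasets
with known ground truth.

The generative model for peak areas is

    area[b, j] = base[j] * scale[b] * fold[b, j] * exp(noise)

where ``scale`` is a per-batch log-normal global content factor,
``fold`` carries planted composition-shifted outlier batches (peaks are
labelled by chemical class; an outlier multiplies each class by its own
fold change), and the noise is multiplicative log-normal per peak.

Activity data are generated from the 1st channel's areas through a known
linear coefficient vector (response = 1/IC50), together with matching
off-line absorbance series and on-line reaction-channel traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .antioxidant import coil_delay
from .errors import ValidationError
from .io_model import FingerprintMatrix

DEFAULT_CHANNELS: tuple[tuple[int, int], ...] = (
    (260, 49), (265, 46), (330, 38), (335, 39), (350, 33),
)
PEAK_CLASSES = ("nucleoside", "phenolic", "flavonoid", "other")

# Composition shift of the planted outlier batches: phenolic-class peaks
# depressed, flavonoid-class peaks elevated, one nucleoside nearly absent.
DEFAULT_OUTLIER_FOLDS: dict[str, float] = {
    "nucleoside": 0.02,
    "phenolic": 0.3,
    "flavonoid": 1.9,
    "other": 1.0,
}


@dataclass
class SyntheticSpec:
    n_batches: int = 23
    channels: tuple[tuple[int, int], ...] = DEFAULT_CHANNELS
    content_scale_sd: float = 0.08  # relative SD of per-batch global scaling
    peak_noise_cv: float = 0.03  # relative SD of per-peak multiplicative noise
    outliers: dict[int, dict[str, float]] = field(default_factory=dict)
    activity_beta: np.ndarray | None = None  # per-peak coefficients, 1st channel
    activity_noise_sd: float = 0.0  # response units (1/IC50)
    outlier_activity_bias: float = -0.02  # extra response shift of outlier batches
    seed: int = 0

    def validate(self) -> None:
        if self.n_batches < 1 or not self.channels:
            raise ValidationError("need n_batches >= 1 and at least one channel")
        if any(n < 2 for _, n in self.channels):
            raise ValidationError("every channel needs at least 2 peaks")
        for b in self.outliers:
            if not (0 <= b < self.n_batches):
                raise ValidationError(f"outlier batch index {b} out of range")
        if self.content_scale_sd < 0 or self.peak_noise_cv < 0:
            raise ValidationError("noise parameters must be non-negative")


def default_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """The study-shaped default: 23 batches, 5 channels, two planted
    composition-shifted outliers at the 3rd- and 1st-from-last batches
    (indices 20 and 22 at the default size)."""
    n = overrides.get("n_batches", 23)
    if "outliers" not in overrides:
        overrides["outliers"] = {
            n - 3: dict(DEFAULT_OUTLIER_FOLDS),
            n - 1: dict(DEFAULT_OUTLIER_FOLDS),
        }
    return replace(SyntheticSpec(seed=seed), **overrides)


@dataclass
class GroundTruth:
    seed: int
    batch_scales: np.ndarray  # (B,)
    peak_classes: dict[int, np.ndarray]  # wavelength -> per-peak class labels
    base_profiles: dict[int, np.ndarray]  # wavelength -> base areas
    fold_grids: dict[int, np.ndarray]  # wavelength -> B x n fold-change grid
    activity_beta: np.ndarray | None = None
    activity_intercept: float | None = None
    inv_ic50: np.ndarray | None = None  # (B,) noiseless + noise = truth used
    delay: float | None = None

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "batch_scales": self.batch_scales.tolist(),
            "peak_classes": {str(w): c.tolist() for w, c in self.peak_classes.items()},
            "base_profiles": {str(w): p.tolist() for w, p in self.base_profiles.items()},
            "activity_beta": None if self.activity_beta is None else self.activity_beta.tolist(),
            "activity_intercept": self.activity_intercept,
            "inv_ic50": None if self.inv_ic50 is None else self.inv_ic50.tolist(),
            "delay": self.delay,
        }


def _assign_classes(base: np.ndarray) -> np.ndarray:
    """Class labels tied to abundance rank: the dominant peaks are the
    flavonoid and phenolic markers, the smallest are nucleosides, the rest
    unassigned — mimicking a marker-bearing composition profile."""
    n_peaks = base.size
    classes = np.array(["other"] * n_peaks, dtype=object)
    k = max(2, n_peaks // 8)
    order = np.argsort(base)[::-1]
    classes[order[:k]] = "flavonoid"
    classes[order[k:3 * k]] = "phenolic"
    classes[order[-k:]] = "nucleoside"
    return classes


def generate_fingerprints(spec: SyntheticSpec) -> tuple[dict[int, FingerprintMatrix], GroundTruth]:
    """Generate one aligned fingerprint matrix per channel plus ground truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    B = spec.n_batches
    scales = np.exp(rng.normal(0.0, spec.content_scale_sd, size=B))

    matrices: dict[int, FingerprintMatrix] = {}
    classes_by_wl: dict[int, np.ndarray] = {}
    base_by_wl: dict[int, np.ndarray] = {}
    folds_by_wl: dict[int, np.ndarray] = {}
    for wavelength, n_peaks in spec.channels:
        base = np.exp(rng.normal(np.log(300.0), 1.0, size=n_peaks))
        rts = np.sort(rng.uniform(3.0, 57.0, size=n_peaks))
        # enforce a minimum gap so synthetic tables re-cluster cleanly
        for j in range(1, n_peaks):
            rts[j] = max(rts[j], rts[j - 1] + 0.6)
        classes = _assign_classes(base)
        folds = np.ones((B, n_peaks))
        for b, class_folds in spec.outliers.items():
            for cls, fold in class_folds.items():
                folds[b, classes == cls] = fold
        noise = np.exp(rng.normal(0.0, spec.peak_noise_cv, size=(B, n_peaks)))
        areas = base[None, :] * scales[:, None] * folds * noise
        matrices[wavelength] = FingerprintMatrix(
            wavelength=wavelength,
            batch_ids=[f"S{b + 1}" for b in range(B)],
            peak_ids=[f"P{j + 1:02d}" for j in range(n_peaks)],
            areas=areas,
            retention_times=rts,
        )
        classes_by_wl[wavelength] = classes
        base_by_wl[wavelength] = base
        folds_by_wl[wavelength] = folds

    truth = GroundTruth(seed=spec.seed, batch_scales=scales,
                        peak_classes=classes_by_wl, base_profiles=base_by_wl,
                        fold_grids=folds_by_wl)
    return matrices, truth


def default_activity_beta(truth: GroundTruth, wavelength: int) -> np.ndarray:
    """Class-structured coefficients: phenolics strongly positive, flavonoids
    weakly positive, nucleosides inactive, the rest small either-sign."""
    classes = truth.peak_classes[wavelength]
    base = truth.base_profiles[wavelength]
    rng = np.random.default_rng(truth.seed + 1)
    beta = np.zeros(classes.size)
    beta[classes == "phenolic"] = rng.uniform(0.8, 1.2, (classes == "phenolic").sum())
    beta[classes == "flavonoid"] = rng.uniform(0.1, 0.3, (classes == "flavonoid").sum())
    other = classes == "other"
    beta[other] = rng.uniform(-0.1, 0.15, other.sum())
    # normalize so a typical batch lands near 1/IC50 ~ 0.23 (mL/mg)
    ref = float(base @ np.abs(beta))
    return beta / ref * 0.18


def generate_activity(spec: SyntheticSpec,
                      matrices: dict[int, FingerprintMatrix],
                      truth: GroundTruth,
                      concentrations=(1.0, 2.0, 3.0, 4.0, 5.0, 6.0),
                      a_control: float = 0.80,
                      delay: float | None = None):
    """Per-batch activity dataset tied to the first channel's areas.

    Returns ``(inv_ic50, dpph_frame, traces)`` where ``inv_ic50`` is the
    ground-truth response vector, ``dpph_frame`` an off-line absorbance
    table that the off-line pipeline inverts back to the same IC50s, and
    ``traces`` per-batch reaction-channel traces whose negative peaks sit
    at parent retention time + delay with depth proportional to each
    positive coefficient's contribution.
    """
    wavelength = spec.channels[0][0]
    fp = matrices[wavelength]
    rng = np.random.default_rng(spec.seed + 2)
    beta = spec.activity_beta
    if beta is None:
        beta = default_activity_beta(truth, wavelength)
    beta = np.asarray(beta, dtype=float)
    if beta.shape[0] != fp.n_peaks:
        raise ValidationError("activity_beta length must match the first channel")
    intercept = 0.05
    inv_ic50 = intercept + fp.areas @ beta
    inv_ic50 = inv_ic50 + rng.normal(0.0, spec.activity_noise_sd, size=inv_ic50.shape)
    # composition-shifted batches respond below the linear model (matrix
    # effects), mirroring their depressed measured activity
    for b in spec.outliers:
        inv_ic50[b] += spec.outlier_activity_bias
    if np.any(inv_ic50 <= 0):
        raise ValidationError("spec implies non-positive 1/IC50; reduce noise or raise beta")

    conc = np.asarray(concentrations, dtype=float)
    rows = []
    for b, batch in enumerate(fp.batch_ids):
        slope = 50.0 * inv_ic50[b]  # %inhibition per (mg/mL): IC50 = 50/slope
        for c in conc:
            inh = slope * c
            rows.append({
                "batch_id": batch,
                "concentration_mg_ml": c,
                "a_control": a_control,
                "a_sample": a_control * (1.0 - inh / 100.0),
            })
    dpph = pd.DataFrame(rows)

    if delay is None:
        delay = coil_delay()
    t = np.arange(0.0, 60.0, 0.01)
    traces: dict[str, pd.DataFrame] = {}
    width = 0.08  # minutes, gaussian sigma
    for b, batch in enumerate(fp.batch_ids):
        y = np.full_like(t, 100.0)
        for j in range(fp.n_peaks):
            if beta[j] <= 0:
                continue  # inactive components leave no negative peak
            depth = 2000.0 * beta[j] * fp.areas[b, j]
            apex = fp.retention_times[j] + delay
            y -= depth * np.exp(-0.5 * ((t - apex) / width) ** 2)
        traces[batch] = pd.DataFrame({"time_min": t, "intensity": y})

    truth.activity_beta = beta
    truth.activity_intercept = intercept
    truth.inv_ic50 = inv_ic50
    truth.delay = float(delay)
    return inv_ic50, dpph, traces
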