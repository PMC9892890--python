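"""Decision-threshold gating, ROC analysis, mixtures, enumeration, LoD.

Rare-cell counting cannot tolerate the ~1% false-positive rate of a
plain argmax classifier: with thousands of background WBCs per mL each
percent becomes tens of phantom tumor cells.  Raising the decision
threshold alpha far above 0.5 (here up to 1 - 1e-7) trades a modest
loss of sensitivity for orders of magnitude fewer false positives.
The limit of detection of the final assay is defined from
negative-control runs as LoD = mu_NC + 2 sigma_NC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .config import FlowConfig, OpticalConfig
from .snet import ClassScore, confusion

__all__ = [
    "DEFAULT_ALPHA_GRID",
    "ROCCurve",
    "MixtureSpec",
    "EnumerationResult",
    "roc",
    "select_alpha",
    "make_mixture",
    "imaged_volume_ml",
    "frame_geometric_volume_ml",
    "enumerate_detections",
    "limit_of_detection",
    "lod_from_stats",
]

# decade steps toward 1, spanning 0.5 .. 1 - 1e-7
DEFAULT_ALPHA_GRID = (0.5, 0.9, 0.99, 0.999, 0.9999, 0.99999, 0.999999, 0.9999999)


def _scores_array(scores) -> np.ndarray:
    return np.asarray(
        [s.p_tumor if isinstance(s, ClassScore) else float(s) for s in scores]
    )


@dataclass
class ROCCurve:
    """TPR/FPR over a descending threshold grid."""

    thresholds: np.ndarray  # descending
    tpr: np.ndarray
    fpr: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.thresholds) > 0):
            raise ValueError("thresholds must be descending")


@dataclass(frozen=True)
class MixtureSpec:
    """An in-silico mixture: n_tumor tumor crops + n_wbc WBC crops."""

    n_tumor: int
    n_wbc: int
    no_overlap: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tumor < 0 or self.n_wbc < 0:
            raise ValueError("counts must be >= 0")


@dataclass
class EnumerationResult:
    """Final assay output for one run."""

    detected_count: int
    imaged_volume_ml: float
    concentration_per_ml: float
    alpha_used: float
    negative_control_mean: float | None = None
    negative_control_sd: float | None = None
    lod_per_ml: float | None = None

    def to_dict(self) -> dict:
        return {
            "detected_count": self.detected_count,
            "imaged_volume_ml": self.imaged_volume_ml,
            "concentration_per_ml": self.concentration_per_ml,
            "alpha_used": self.alpha_used,
            "negative_control_mean": self.negative_control_mean,
            "negative_control_sd": self.negative_control_sd,
            "lod_per_ml": self.lod_per_ml,
        }


def roc(
    scores,
    labels: Sequence[int],
    thresholds: Sequence[float] = DEFAULT_ALPHA_GRID,
) -> ROCCurve:
    """TPR and FPR at each gating threshold (via the confusion counts).

    Requires both classes present; thresholds are reported in
    descending order.
    """
    p = _scores_array(scores)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC needs both classes present")
    thr = np.sort(np.asarray(thresholds, dtype=float))[::-1]
    tpr = np.empty(len(thr))
    fpr = np.empty(len(thr))
    for i, a in enumerate(thr):
        cm = confusion(p, y, alpha=a)
        tpr[i] = cm.sensitivity
        fpr[i] = cm.fpr
    return ROCCurve(thresholds=thr, tpr=tpr, fpr=fpr)


def select_alpha(curve: ROCCurve) -> float:
    """Smallest threshold attaining the minimum FPR on the grid.

    Raising the threshold beyond the returned value does not lower the
    FPR any further.
    """
    if len(curve.thresholds) == 0:
        raise ValueError("empty ROC curve")
    fpr_min = curve.fpr.min()
    attaining = curve.thresholds[curve.fpr == fpr_min]
    return float(attaining.min())


def make_mixture(
    pool_tumor: np.ndarray,
    pool_wbc: np.ndarray,
    spec: MixtureSpec,
    used_tumor: set[int] | None = None,
    used_wbc: set[int] | None = None,
):
    """Sample an in-silico mixed dataset from pure-population crop pools.

    Returns (crops, labels, tumor_ids, wbc_ids).  When
    ``spec.no_overlap`` and the ``used_*`` sets are supplied, sampling
    avoids previously used pool indices and the sets are updated in
    place, so several mixtures drawn from one pool are disjoint.
    Raises ValueError when a pool is exhausted.
    """
    rng = np.random.default_rng(spec.seed)
    ids = []
    for pool, want, used in (
        (pool_tumor, spec.n_tumor, used_tumor),
        (pool_wbc, spec.n_wbc, used_wbc),
    ):
        avail = np.arange(len(pool))
        if spec.no_overlap and used is not None:
            avail = np.asarray([i for i in avail if i not in used])
        if want > len(avail):
            raise ValueError("crop pool exhausted")
        chosen = rng.choice(avail, size=want, replace=False)
        if spec.no_overlap and used is not None:
            used.update(int(i) for i in chosen)
        ids.append(np.sort(chosen))
    tumor_ids, wbc_ids = ids
    crops = np.concatenate([pool_tumor[tumor_ids], pool_wbc[wbc_ids]], axis=0)
    labels = np.concatenate(
        [np.ones(len(tumor_ids), dtype=int), np.zeros(len(wbc_ids), dtype=int)]
    )
    return crops, labels, tumor_ids, wbc_ids


def imaged_volume_ml(n_frames: int, flow: FlowConfig) -> float:
    """Sample volume imaged during an acquisition (time-based accounting).

    volume = acquisition time x sample flow rate
           = n_frames / frame_rate x Q_sample.
    10 100 frames at 420 fps with 2.5 mL/min give ~1 mL.
    """
    if n_frames < 0:
        raise ValueError("n_frames must be >= 0")
    return n_frames / flow.frame_rate_fps * flow.sample_flow_rate_ml_min / 60.0


def frame_geometric_volume_ml(optics: OpticalConfig) -> float:
    """Geometric sample volume of a single hologram:
    streamwise FOV x sample-core width x channel height (~0.13 uL for
    the default geometry).  At 420 fps the stream is under-sampled, so
    the time-based accounting of :func:`imaged_volume_ml` is canonical;
    this one is reported for reference."""
    fov_x_um = optics.fov_px[1] * optics.pixel_pitch_um
    vol_um3 = fov_x_um * optics.sample_core_width_um * optics.channel_height_um
    return vol_um3 / 1e12  # um^3 -> mL


def enumerate_detections(
    p_tumor,
    alpha: float,
    n_frames: int,
    flow: FlowConfig,
    negative_control_counts: Sequence[float] | None = None,
) -> EnumerationResult:
    """Gate per-cell tumor probabilities and convert counts to cells/mL.

    ``p_tumor`` holds one (deduplicated) score per cell.  When
    negative-control counts are supplied, their statistics and the
    resulting LoD are attached to the result.
    """
    p = _scores_array(p_tumor)
    count = int(np.sum(p > alpha))
    vol = imaged_volume_ml(n_frames, flow)
    conc = count / vol if vol > 0 else float("nan")
    result = EnumerationResult(
        detected_count=count,
        imaged_volume_ml=vol,
        concentration_per_ml=conc,
        alpha_used=alpha,
    )
    if negative_control_counts is not None:
        mu, sd, lod = limit_of_detection(negative_control_counts)
        result.negative_control_mean = mu
        result.negative_control_sd = sd
        result.lod_per_ml = lod
    return result


def limit_of_detection(
    negative_control_counts: Sequence[float],
) -> tuple[float, float, float]:
    """(mu_NC, sigma_NC, LoD) from negative-control concentrations.

    sigma uses the sample standard deviation (n - 1 denominator);
    LoD = mu + 2 sigma.  Requires at least two trials.
    """
    counts = np.asarray(negative_control_counts, dtype=float)
    if counts.size < 2:
        raise ValueError("limit of detection needs >= 2 negative-control trials")
    mu = float(counts.mean())
    sd = float(counts.std(ddof=1))
    return mu, sd, lod_from_stats(mu, sd)


def lod_from_stats(mu_nc: float, sigma_nc: float) -> float:
    """LoD = mu_NC + 2 sigma_NC."""
    return mu_nc + 2.0 * sigma_nc
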