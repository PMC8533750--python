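"""Generalized (Rényi) dimension spectrum of the tracer mass distribution.

For each box edge s the thresholded concentration field is reduced to
normalized box masses p_i (box mass over total mass), and the partition sum
Z(q, s) = sum_i p_i^q is formed over occupied boxes only.  The moment of
order q is the scaling exponent

    D_q = slope of [ln Z(q, s) / (q - 1)] versus ln s       (q != 1)
    D_1 = slope of [sum_i p_i ln p_i] versus ln s           (entropy limit)

Negative q accentuate the faintest local concentrations (possible tiny
metastases), positive q the hotspots (large lesions and tracer-avid
organs).  D_0 is the box-counting dimension of the occupied set.

Two cohort-level summaries are built from the spectrum: the averaged
multifractal index <MFS>_j (mean of D_q over the 21 integer orders
q = -10..10 at study stage j) and the cumulative longitudinal measure
dD(j) = mean over those q of [D_q(j) - D_q(baseline)], which by linearity
equals <MFS>_j - <MFS>_baseline and is identically 0 at baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy.special import logsumexp
from skimage.measure import block_reduce

from ._fitutil import linear_fit
from .boxcount import size_schedule, _validate_sizes
from .errors import AnalysisError
from .volume import TracerVolume

__all__ = [
    "MomentSpectrum",
    "LongitudinalMeasures",
    "SUMMARY_Q",
    "box_masses",
    "partition_sum",
    "dq_spectrum",
    "mean_mfs",
    "delta_d",
]

#: The 21 integer moment orders averaged into <MFS> and dD(j).
SUMMARY_Q: tuple[int, ...] = tuple(range(-10, 11))


@dataclass(frozen=True)
class MomentSpectrum:
    """q -> D_q table for one study, with per-q fit diagnostics."""

    q: tuple[int, ...]
    dq: tuple[float, ...]
    r2: tuple[float, ...]
    stderr: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.q) == len(self.dq) == len(self.r2) == len(self.stderr)):
            raise ValueError("q, dq and diagnostics must have equal length")
        if any(b <= a for a, b in zip(self.q, self.q[1:])):
            raise ValueError("q must be strictly increasing")

    def value(self, q: int) -> float:
        try:
            return self.dq[self.q.index(q)]
        except ValueError:
            raise KeyError(f"moment order q={q} not in spectrum") from None

    def as_dict(self) -> dict:
        return {
            "q": list(self.q),
            "dq": list(self.dq),
            "r2": list(self.r2),
            "stderr": list(self.stderr),
        }


@dataclass(frozen=True)
class LongitudinalMeasures:
    """Per-stage heterogeneity measures for one subject.

    Maps stage j (1 = baseline, 2 = interim, 3 = final) to the fitted
    fractal dimension, the averaged multifractal index and the cumulative
    measure dD(j) relative to baseline.
    """

    subject_id: str | None
    df: dict[int, float]
    mfs: dict[int, float]
    delta_d: dict[int, float]


def box_masses(volume: TracerVolume, s: int, w: float = 1.0) -> np.ndarray:
    """Normalized masses p_i of the occupied s x s x s boxes.

    Voxels below the threshold w contribute no mass; masses are normalized
    by the total thresholded mass so they sum to 1.  Only occupied boxes
    (p_i > 0) are returned, which keeps negative-q partition sums finite.
    """
    if int(s) != s or s <= 0:
        raise ValueError(f"box size must be a positive integer, got {s!r}")
    s = int(s)
    data = np.where(volume.data >= w, volume.data, 0.0)
    total = data.sum()
    if total <= 0:
        raise AnalysisError(f"no tracer mass above threshold w={w:g}")
    if s == 1:
        masses = data.ravel()
    else:
        masses = block_reduce(data, (s, s, s), np.sum, cval=0.0).ravel()
    masses = masses[masses > 0]
    return masses / total


def partition_sum(masses: Iterable[float], q: float) -> float:
    """Z(q, s) = sum_i p_i^q over occupied boxes.

    Z(0, s) is the occupied-box count and Z(1, s) = 1 by normalization.
    """
    p = np.asarray(list(masses) if not isinstance(masses, np.ndarray) else masses,
                   dtype=float)
    if p.size == 0:
        raise ValueError("empty mass list")
    if np.any(p <= 0):
        raise ValueError("all box masses must be > 0 (occupied boxes only)")
    return float(np.exp(logsumexp(q * np.log(p))))


def dq_spectrum(
    volume: TracerVolume,
    w: float = 1.0,
    sizes=None,
    q_list: Iterable[int] = SUMMARY_Q,
) -> MomentSpectrum:
    """Estimate D_q for each requested moment order.

    One shared scale schedule is used for every q (default: the box-counting
    schedule).  Partition sums are evaluated in log space, so deep cascades
    and strongly negative q do not overflow.
    """
    shape = volume.shape
    sizes = _validate_sizes(sizes if sizes is not None else size_schedule(shape), shape)
    if len(sizes) < 3:
        raise AnalysisError(f"need >= 3 scales for the spectrum, got {len(sizes)}")
    q_list = sorted(int(q) for q in set(q_list))

    log_s = np.log(np.array(sizes, dtype=float))
    log_p_by_scale = [np.log(box_masses(volume, s, w)) for s in sizes]

    dq, r2, stderr = [], [], []
    for q in q_list:
        if q == 1:
            y = np.array([float(np.sum(np.exp(lp) * lp)) for lp in log_p_by_scale])
        else:
            y = np.array([logsumexp(q * lp) for lp in log_p_by_scale]) / (q - 1)
        fit = linear_fit(log_s, y)
        dq.append(fit.slope)
        r2.append(fit.r2)
        stderr.append(fit.stderr)
    return MomentSpectrum(tuple(q_list), tuple(dq), tuple(r2), tuple(stderr))


def mean_mfs(spectrum: MomentSpectrum) -> float:
    """Averaged multifractal index: mean of D_q over q = -10..10 (21 orders)."""
    missing = [q for q in SUMMARY_Q if q not in spectrum.q]
    if missing:
        raise ValueError(f"spectrum is missing moment orders {missing}")
    return float(np.mean([spectrum.value(q) for q in SUMMARY_Q]))


def delta_d(
    by_stage: Mapping[int, MomentSpectrum] | Mapping[int, float],
) -> dict[int, float]:
    """Cumulative longitudinal measure dD(j) for each available stage.

    Accepts either per-stage spectra or per-stage <MFS> values; stage 1
    (baseline) must be present.  dD(j) is the mean over q = -10..10 of
    [D_q(j) - D_q(1)], i.e. <MFS>_j - <MFS>_1, and dD(1) = 0 exactly.
    """
    if 1 not in by_stage:
        raise AnalysisError("baseline stage (j=1) is required to compute dD(j)")
    mfs = {
        int(j): (mean_mfs(v) if isinstance(v, MomentSpectrum) else float(v))
        for j, v in by_stage.items()
    }
    out = {j: mfs[j] - mfs[1] for j in sorted(mfs)}
    out[1] = 0.0
    return out
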