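"""Post-division crescent persistence and normalized amplitude dynamics.

After an asymmetric division the polarity crescent inherited by the larger
daughter fades over tens of minutes to hours.  A trace starts at
cytokinesis (frame 0, the first frame with a visible cell plate, supplied
as an annotation) and carries one fitted polarity record per frame.
Persistence is the time of the first frame at which the crescent is no
longer detectable; "detectable" is operationalised as a two-criterion rule
on the fitted peak (contrast A/b and signal-to-residual A/rmse), a
reproducible surrogate for the by-eye call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .polarity import PolarityRecord

DETECT_CONTRAST_DEFAULT = 0.2  # minimum fitted amplitude / baseline
DETECT_SNR_DEFAULT = 2.0       # minimum fitted amplitude / residual RMSE


@dataclass
class PersistenceTrace:
    """One cell's per-frame polarity records, timed from cytokinesis."""

    cell_id: int
    frame_times: np.ndarray           # minutes since cytokinesis, [0] == 0
    records: list[PolarityRecord]

    def __post_init__(self):
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if len(self.frame_times) != len(self.records):
            raise ValueError("frame_times and records must align")
        if len(self.frame_times) < 2:
            raise ValueError("need at least 2 frames")
        if self.frame_times[0] != 0:
            raise ValueError("frame_times[0] must be 0 (cytokinesis)")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must be strictly increasing")

    def amplitudes(self) -> np.ndarray:
        return np.array([r.fit.amplitude for r in self.records])


@dataclass
class PersistenceResult:
    cell_id: int
    persistence_minutes: float
    end_frame: int
    censored: bool              # crescent still detectable at the last frame
    n_frames: int
    warning: str | None = None  # e.g. first frame already undetectable


def _detectable(record: PolarityRecord, contrast: float, snr: float) -> bool:
    # effective (peak-to-trough) quantities, so a near-constant wide bump --
    # degenerate with the baseline -- does not count as a visible crescent
    a = record.fit.effective_amplitude
    b = record.fit.effective_baseline
    rmse = record.fit.residual_rmse
    if a <= 0:
        return False
    contrast_ok = a >= contrast * b if b > 0 else True
    snr_ok = a >= snr * rmse if rmse > 0 else True
    return contrast_ok and snr_ok


def measure_persistence(
    trace: PersistenceTrace,
    detect_contrast: float = DETECT_CONTRAST_DEFAULT,
    detect_snr: float = DETECT_SNR_DEFAULT,
) -> PersistenceResult:
    """Time from cytokinesis to the first frame with no detectable crescent.

    If the crescent is still detectable at the last frame the result is
    censored at that frame's time.  If even frame 0 is undetectable a
    zero-persistence result with a warning is returned.
    """
    flags = [_detectable(r, detect_contrast, detect_snr) for r in trace.records]
    n = len(flags)
    if not flags[0]:
        return PersistenceResult(trace.cell_id, 0.0, 0, censored=False, n_frames=n,
                                 warning="crescent undetectable at cytokinesis frame")
    for i in range(1, n):
        if not flags[i]:
            return PersistenceResult(trace.cell_id, float(trace.frame_times[i]), i,
                                     censored=False, n_frames=n)
    return PersistenceResult(trace.cell_id, float(trace.frame_times[-1]), n - 1,
                             censored=True, n_frames=n)


def normalized_amplitude_curve(trace: PersistenceTrace) -> np.ndarray:
    """Per-frame fitted amplitude divided by the amplitude at frame 0."""
    amps = trace.amplitudes()
    if amps[0] <= 0:
        raise ValueError("amplitude at cytokinesis frame is 0; normalization undefined")
    return amps / amps[0]


@dataclass
class GroupComparison:
    mean_difference: float  # mean(group B) - mean(group A), minutes
    p_value: float          # two-sided rank-sum test on uncensored values
    n_a: int
    n_b: int
    n_censored_a: int = 0
    n_censored_b: int = 0


def compare_persistence_groups(
    group_a: list[PersistenceResult],
    group_b: list[PersistenceResult],
) -> GroupComparison:
    """Mean persistence difference (B - A) and a two-sided rank-sum p-value.

    Censored traces are excluded from both statistics and their counts
    reported; each group needs at least 3 uncensored results.
    """
    a = np.array([r.persistence_minutes for r in group_a if not r.censored])
    b = np.array([r.persistence_minutes for r in group_b if not r.censored])
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need >= 3 uncensored results per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        p = 1.0  # identical constant groups: no rank information
    else:
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return GroupComparison(
        mean_difference=float(b.mean() - a.mean()),
        p_value=p,
        n_a=len(a),
        n_b=len(b),
        n_censored_a=sum(r.censored for r in group_a),
        n_censored_b=sum(r.censored for r in group_b),
    )
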