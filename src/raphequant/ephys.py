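"""Light-evoked EPSC analysis for optogenetic circuit mapping.

Cells are voltage clamped at -70 mV, so evoked EPSCs are inward (negative)
currents; reported amplitudes are magnitudes.  Per the study's procedure, the
first 10 sweeps are averaged, the peak of the baseline-subtracted negative
deflection is measured in the 50 ms window after the light pulse, and cells
whose peak does not exceed the 10 pA baseline-noise criterion are classified
as non-responders.  ``drug_block`` compares paired baseline / antagonist
(CNQX) amplitudes with a paired t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import stats as rqstats

logger = logging.getLogger(__name__)

__all__ = [
    "SweepSet",
    "EPSCResult",
    "DrugBlockResult",
    "average_sweeps",
    "baseline_stats",
    "peak_epsc",
    "classify_responder",
    "responder_fraction",
    "analyze_sweepset",
    "drug_block",
]

NOISE_FLOOR_PA = 10.0  # fixed absolute responder criterion


@dataclass
class SweepSet:
    """Per-cell collection of equal-length current traces (pA)."""

    cell_id: str
    condition: str                 # e.g. "baseline" / "post"
    sweeps: np.ndarray             # (n_sweeps, n_samples)
    sampling_rate_hz: float = 10_000.0
    stim_onset_s: float = 0.2
    pulse_dur_s: float = 0.005
    holding_mv: float = -70.0

    def __post_init__(self) -> None:
        self.sweeps = np.atleast_2d(np.asarray(self.sweeps, dtype=float))
        if self.sweeps.shape[0] < 1:
            raise ValueError("need at least one sweep")
        dur = self.sweeps.shape[1] / self.sampling_rate_hz
        if not 0 <= self.stim_onset_s < dur:
            raise ValueError("stimulus onset lies outside the trace")


@dataclass
class EPSCResult:
    cell_id: str
    condition: str
    baseline_mean_pa: float
    baseline_noise_pa: float
    amplitude_pa: float        # magnitude of the inward deflection, >= 0
    latency_s: float           # time from stimulus onset to peak
    responder: bool = False

    def __post_init__(self) -> None:
        if self.amplitude_pa < 0:
            raise ValueError("amplitude is a magnitude, must be >= 0")


@dataclass
class DrugBlockResult:
    cell_ids: list[str]
    pre_amps_pa: np.ndarray
    post_amps_pa: np.ndarray
    pre_mean_pa: float
    pre_sem_pa: float
    post_mean_pa: float
    post_sem_pa: float
    test: "rqstats.TestResult"


def average_sweeps(sweepset: SweepSet, k: int = 10) -> np.ndarray:
    """Pointwise mean of the first k sweeps (all of them, logged, if fewer)."""
    n = sweepset.sweeps.shape[0]
    if k > n:
        logger.info("cell %s: only %d sweeps available (requested %d); using all",
                    sweepset.cell_id, n, k)
        k = n
    return sweepset.sweeps[:k].mean(axis=0)


def baseline_stats(trace: np.ndarray, sampling_rate_hz: float, stim_onset_s: float,
                   window_s: float = 0.050, gap_s: float = 0.001
                   ) -> tuple[float, float]:
    """(mean, sd) over a pre-stimulus window ending ``gap_s`` before onset."""
    end = int(round((stim_onset_s - gap_s) * sampling_rate_hz))
    start = end - int(round(window_s * sampling_rate_hz))
    if start < 0 or end <= start or end > len(trace):
        raise ValueError("baseline window falls outside the trace")
    seg = np.asarray(trace, dtype=float)[start:end]
    return float(seg.mean()), float(seg.std(ddof=1))


def peak_epsc(trace: np.ndarray, sampling_rate_hz: float, stim_onset_s: float,
              window_s: float = 0.050, cell_id: str = "", condition: str = "",
              blank_artifact_s: float = 0.0) -> EPSCResult:
    """Peak inward deflection in the (onset, onset + window] interval.

    The trace is baseline-subtracted with the pre-stimulus mean; amplitude is
    the largest negative-going deflection magnitude (0 if the trace never
    dips below baseline), with ties broken to the earliest sample.  The 5 ms
    light pulse lies inside the window; optional stimulus-artifact blanking
    of the first ``blank_artifact_s`` seconds is off by default.
    """
    trace = np.asarray(trace, dtype=float)
    b_mean, b_sd = baseline_stats(trace, sampling_rate_hz, stim_onset_s)
    i0 = int(np.floor(stim_onset_s * sampling_rate_hz)) + 1  # open at onset
    if blank_artifact_s > 0:
        i0 = max(i0, int(np.ceil((stim_onset_s + blank_artifact_s) * sampling_rate_hz)))
    i1 = int(round((stim_onset_s + window_s) * sampling_rate_hz)) + 1  # closed
    i1 = min(i1, len(trace))
    if i1 <= i0:
        raise ValueError("response window falls outside the trace")
    deflection = b_mean - trace[i0:i1]  # positive = inward
    j = int(np.argmax(deflection))      # argmax returns the earliest maximum
    amp = float(max(deflection[j], 0.0))
    latency = (i0 + j) / sampling_rate_hz - stim_onset_s
    return EPSCResult(cell_id=cell_id, condition=condition,
                      baseline_mean_pa=b_mean, baseline_noise_pa=b_sd,
                      amplitude_pa=amp, latency_s=float(latency))


def classify_responder(result: EPSCResult,
                       noise_floor_pa: float = NOISE_FLOOR_PA) -> EPSCResult:
    """Responder iff the peak strictly exceeds the absolute noise floor."""
    result.responder = result.amplitude_pa > noise_floor_pa
    return result


def responder_fraction(results: list[EPSCResult]) -> tuple[float, int, int]:
    """(percent, n_responders, n_total); 0/0 is an error upstream."""
    if not results:
        raise ValueError("no cells to summarize")
    n_resp = sum(r.responder for r in results)
    n = len(results)
    return 100.0 * n_resp / n, n_resp, n


def analyze_sweepset(sweepset: SweepSet, k: int = 10, window_s: float = 0.050,
                     noise_floor_pa: float = NOISE_FLOOR_PA) -> EPSCResult:
    """Average -> baseline-subtract -> window peak -> responder flag."""
    trace = average_sweeps(sweepset, k)
    res = peak_epsc(trace, sweepset.sampling_rate_hz, sweepset.stim_onset_s,
                    window_s=window_s, cell_id=sweepset.cell_id,
                    condition=sweepset.condition)
    return classify_responder(res, noise_floor_pa)


def drug_block(pre: list[EPSCResult], post: list[EPSCResult]) -> DrugBlockResult:
    """Paired baseline-vs-antagonist comparison on matching cell ids."""
    pre_by_id = {r.cell_id: r for r in pre}
    post_by_id = {r.cell_id: r for r in post}
    if set(pre_by_id) != set(post_by_id):
        raise ValueError("pre and post conditions must cover the same cells")
    ids = sorted(pre_by_id)
    x = np.array([pre_by_id[i].amplitude_pa for i in ids])
    y = np.array([post_by_id[i].amplitude_pa for i in ids])
    n = len(ids)
    test = rqstats.paired_t(x, y)
    sem = lambda v: float(v.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return DrugBlockResult(cell_ids=ids, pre_amps_pa=x, post_amps_pa=y,
                           pre_mean_pa=float(x.mean()), pre_sem_pa=sem(x),
                           post_mean_pa=float(y.mean()), post_sem_pa=sem(y),
                           test=test)
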