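"""Operational taxonomy of calcium traces.

A post-transient trace is labelled one of

``steady``
    residual variation below ``epsilon_ss`` (or fewer than three peaks in
    the analysis window);
``periodic``
    repeating single-mode oscillations (one peak-amplitude class);
``mmo``
    mixed-mode oscillations: a repeating pattern mixing two or more
    amplitude classes (large spikes with sub-threshold oscillations);
``aberrant``
    sustained but non-periodic oscillations over the 100–200 s analysis
    window — the disease-relevant irregular signal.

Peaks are detected by prominence, their amplitudes clustered with a
deterministic one-dimensional gap method, and periodicity scored as the
best lag-wise agreement of the (amplitude class, inter-peak interval)
cycle sequence — a normalised autocorrelation of the symbol sequence.
Every threshold is configurable; classification is deterministic and
invariant to uniform amplitude rescaling and time shifts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .model import ModelConfig, Trace, simulate
from .params import ModelParams

LABELS = ("steady", "periodic", "mmo", "aberrant")


@dataclass
class ClassifyOptions:
    transient_fraction: float = 0.4   # discarded head of the trace
    transient_time: float | None = None  # overrides the fraction if set
    window: float = 200.0             # s, analysis window length
    epsilon_ss: float = 0.005         # µM, steady-state amplitude bound
    epsilon_peak: float = 0.01        # µM, absolute prominence floor
    smooth_time: float = 0.25         # s, moving-average width before peaks
    rel_prominence: float = 0.05      # fraction of post-transient range
    delta_amp: float = 0.20           # amplitude-class gap, rel. to range
    theta: float = 0.9                # periodicity-score threshold
    min_peaks_oscillatory: int = 5    # peaks needed to call "aberrant"
    interval_rtol: float = 0.08       # rel. tolerance matching intervals


@dataclass
class TraceClassification:
    label: str
    transient_cutoff: float
    peak_times: np.ndarray
    peak_amplitudes: np.ndarray
    amplitude_classes: np.ndarray     # class index per peak
    n_amplitude_classes: int
    period: float | None
    periodicity_score: float
    amplitude: float                  # post-transient max - min

    def to_record(self) -> dict:
        return {
            "label": self.label,
            "transient_cutoff": float(self.transient_cutoff),
            "n_peaks": int(self.peak_times.size),
            "n_amplitude_classes": int(self.n_amplitude_classes),
            "period": None if self.period is None else float(self.period),
            "periodicity_score": float(self.periodicity_score),
            "amplitude": float(self.amplitude),
        }


def _gap_classes(amps: np.ndarray, delta: float) -> np.ndarray:
    """Deterministic 1-D clustering: a sorted gap larger than ``delta``
    starts a new class.  Returns a class index per peak (0 = smallest)."""
    order = np.argsort(amps)
    sorted_amps = amps[order]
    cls_sorted = np.zeros(amps.size, dtype=int)
    for i in range(1, amps.size):
        cls_sorted[i] = cls_sorted[i - 1] + (
            1 if sorted_amps[i] - sorted_amps[i - 1] > delta else 0)
    out = np.empty(amps.size, dtype=int)
    out[order] = cls_sorted
    return out


def _periodicity_score(classes: np.ndarray, intervals: np.ndarray,
                       rtol: float) -> tuple[float, int]:
    """Best lag-wise agreement of the cycle symbol sequence.

    For each candidate lag L the score is the fraction of positions whose
    amplitude class matches at lag L and whose inter-peak interval agrees
    within ``rtol`` (relative to the median interval).  Returns
    (max score over L, best L).
    """
    n = intervals.size               # classes has n+1 entries (peaks)
    if n < 2:
        return 0.0, 0
    med = np.median(intervals)
    atol = max(rtol * med, 1e-9)
    best, best_lag = 0.0, 0
    for lag in range(1, n // 2 + 1):
        cls_match = classes[:-lag][: n + 1 - lag] == classes[lag:][: n + 1 - lag]
        int_match = np.abs(intervals[:-lag] - intervals[lag:]) <= atol
        k = min(cls_match.size, int_match.size)
        score = 0.5 * (np.mean(cls_match[:k]) + np.mean(int_match[:k]))
        if score > best + 1e-12:
            best, best_lag = float(score), lag
    return best, best_lag


def classify_trace(t: np.ndarray | Trace, c: np.ndarray | None = None,
                   options: ClassifyOptions | None = None
                   ) -> TraceClassification:
    """Label a cytosolic-calcium trace as steady/periodic/mmo/aberrant.

    Accepts a :class:`~amyca.model.Trace` or plain ``(t, c)`` arrays with
    uniform sampling.  Raises ``ValueError`` if the trace is shorter than
    the transient cutoff plus the analysis window, or too coarsely
    sampled to resolve oscillations.
    """
    opts = options or ClassifyOptions()
    if isinstance(t, Trace):
        c = t["c"]
        t = t.t
    t = np.asarray(t, dtype=float)
    c = np.asarray(c, dtype=float)
    if t.size != c.size or t.size < 10:
        raise ValueError("need matching t/c arrays with at least 10 samples")
    dt = np.diff(t)
    if np.max(dt) - np.min(dt) > 1e-6 * np.median(dt):
        raise ValueError("classification requires uniform sampling")

    cutoff = (opts.transient_time if opts.transient_time is not None
              else t[0] + opts.transient_fraction * (t[-1] - t[0]))
    need = cutoff + opts.window
    if t[-1] + 1e-9 < need:
        raise ValueError(
            f"trace too short: ends at {t[-1]:.1f}s but needs "
            f"{need:.1f}s (transient {cutoff:.1f}s + {opts.window:.0f}s "
            f"analysis window)")
    mask = (t >= cutoff) & (t <= cutoff + opts.window)
    tw, cw = t[mask], c[mask]
    # light moving-average smoothing so measurement noise cannot seed
    # spurious peaks; the window is far narrower than any calcium event
    k = int(round(opts.smooth_time / np.median(dt)))
    if k > 1:
        kernel = np.ones(k) / k
        cw = np.convolve(cw, kernel, mode="same")
        cw[:k] = cw[k]
        cw[-k:] = cw[-k - 1]
    amp = float(cw.max() - cw.min())

    if amp < opts.epsilon_ss:
        return TraceClassification("steady", cutoff, np.array([]),
                                   np.array([]), np.array([], dtype=int), 0,
                                   None, 0.0, amp)

    prom = max(opts.epsilon_peak, opts.rel_prominence * amp)
    idx, _ = find_peaks(cw, prominence=prom)
    peak_t, peak_a = tw[idx], cw[idx] - cw.min()
    if idx.size < 3:
        # a decaying transient or sub-resolution ripple: effectively steady
        return TraceClassification("steady", cutoff, peak_t, peak_a,
                                   np.zeros(idx.size, dtype=int),
                                   min(idx.size, 1), None, 0.0, amp)

    classes = _gap_classes(peak_a, opts.delta_amp * peak_a.max())
    n_classes = int(classes.max()) + 1
    intervals = np.diff(peak_t)
    score, lag = _periodicity_score(classes, intervals, opts.interval_rtol)
    period = float(lag * np.mean(intervals)) if lag else None

    if score >= opts.theta:
        label = "mmo" if n_classes >= 2 else "periodic"
    elif idx.size >= opts.min_peaks_oscillatory:
        label = "aberrant"
    else:
        label = "periodic" if n_classes == 1 else "mmo"
    return TraceClassification(label, cutoff, peak_t, peak_a, classes,
                               n_classes, period, score, amp)


def classify_parameter_grid(parameter: str, values, params: ModelParams,
                            config: ModelConfig,
                            options: ClassifyOptions | None = None,
                            t_end: float | None = None) -> list[dict]:
    """Simulate and classify over a parameter grid.

    Returns one record per grid point (parameter value, label, statistics);
    simulation failures are recorded as ``label="unresolved"`` rather than
    dropped.  Contiguous runs of identical labels can be read off directly.
    """
    from .equilibria import _with_param
    opts = options or ClassifyOptions()
    out: list[dict] = []
    for v in values:
        pa, cf = _with_param(params, config, parameter, float(v))
        if t_end is not None:
            cf = ModelConfig(variant=cf.variant, p_fixed=cf.p_fixed, a=cf.a,
                             p_s=cf.p_s, stimulus=cf.stimulus, t_end=t_end,
                             output_dt=cf.output_dt, rtol=cf.rtol,
                             atol=cf.atol, method=cf.method)
        try:
            tr = simulate(cf, pa)
            rec = classify_trace(tr, options=opts).to_record()
        except Exception as exc:   # noqa: BLE001 - keep the grid complete
            rec = {"label": "unresolved", "error": str(exc)}
        rec[parameter] = float(v)
        out.append(rec)
    return out


def mmo_intervals(grid_records: list[dict], parameter: str
                  ) -> list[tuple[float, float]]:
    """Contiguous parameter intervals labelled mmo in a grid result."""
    spans: list[tuple[float, float]] = []
    start = None
    for rec in grid_records:
        if rec["label"] == "mmo":
            if start is None:
                start = rec[parameter]
            end = rec[parameter]
        else:
            if start is not None:
                spans.append((start, end))
                start = None
    if start is not None:
        spans.append((start, end))
    return spans
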