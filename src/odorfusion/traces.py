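"""Calcium-imaging response extraction.

Recordings are 20 s fluorescence traces at 4 Hz (80 frames) with two
stimulus injections whose effective onsets, after delivery delay, are
6.75 s and 9.75 s.  The pipeline is:

1. dF/F: 100 * (F_i - F0) / F0, F0 = mean of the 5 s before stimulus onset;
2. bleach correction: an exponential decay A*exp(-t/B) + C is removed.
   The decay rate B is estimated once per animal from the framewise median
   solvent-control trace; A and C are then refitted per trace with B held
   fixed.  The fit ignores the first 750 ms and everything within 11 s
   after each onset (those frames may contain responses), and weights the
   pre-stimulus frames 100-fold;
3. response magnitude: mean over the 5 s after onset minus the mean over
   the 2.5 s before it;
4. drift correction: a line is fitted to the reference-odorant responses
   against measurement index within each animal, and every response is
   scaled by L(t1)/L(t) so the session is expressed relative to the first
   reference presentation.

Frame convention: frame i (1-based) spans [(i-1)/rate, i/rate) seconds and
a window [t1, t2) contains the frames whose start time lies in it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize


@dataclass
class StimulusProtocol:
    """Timing and weighting conventions of one recording."""

    frame_rate: float = 4.0
    duration: float = 20.0
    onsets: tuple[float, ...] = (6.75, 9.75)
    response_window: float = 5.0  # s after onset
    baseline_window: float = 2.5  # s before onset
    f0_window: float = 5.0  # s before first onset
    fit_exclusion_start: float = 0.75  # s at trace start
    fit_exclusion_post: float = 11.0  # s after each onset
    prestim_weight: float = 100.0

    @classmethod
    def from_file(cls, path) -> "StimulusProtocol":
        """Read a key=value protocol file; onsets are comma-separated."""
        kwargs: dict = {}
        floats = {
            "frame_rate", "duration", "response_window", "baseline_window",
            "f0_window", "fit_exclusion_start", "fit_exclusion_post",
            "prestim_weight",
        }
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, value = line.partition("=")
                key = key.strip()
                value = value.strip()
                if key == "onsets":
                    kwargs["onsets"] = tuple(float(v) for v in value.split(","))
                elif key in floats:
                    kwargs[key] = float(value)
                else:
                    raise KeyError(f"unknown protocol key: {key}")
        return cls(**kwargs)

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))

    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    def window_frames(self, t1: float, t2: float) -> np.ndarray:
        t = self.frame_times()
        return np.flatnonzero((t >= t1) & (t < t2))

    def fit_weights(self) -> np.ndarray:
        """Per-frame weights for the decay fit (0 = excluded)."""
        t = self.frame_times()
        w = np.ones(self.n_frames)
        w[t < self.onsets[0]] = self.prestim_weight
        w[t < self.fit_exclusion_start] = 0.0
        for onset in self.onsets:
            w[(t >= onset) & (t <= onset + self.fit_exclusion_post + 1e-9)] = 0.0
        return w


@dataclass
class ImagingTrace:
    """One stimulus presentation: raw or dF/F fluorescence per frame."""

    values: np.ndarray
    animal_id: str = ""
    stimulus_id: str = ""
    is_solvent_control: bool = False
    is_reference: bool = False
    protocol: StimulusProtocol = field(default_factory=StimulusProtocol)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != self.protocol.n_frames:
            raise ValueError(
                f"expected {self.protocol.n_frames} frames, got {self.values.size}"
            )


@dataclass
class DecayModel:
    """Exponential photobleaching model A * exp(-x/B) + C."""

    A: float
    B: float
    C: float

    def __post_init__(self) -> None:
        if self.B <= 0:
            raise ValueError("decay time constant B must be positive")

    def __call__(self, t) -> np.ndarray:
        return self.A * np.exp(-np.asarray(t, dtype=float) / self.B) + self.C


def delta_f_over_f(trace: ImagingTrace) -> ImagingTrace:
    """Relative percentage fluorescence change, 100 * (F - F0) / F0."""
    proto = trace.protocol
    onset = proto.onsets[0]
    idx = proto.window_frames(onset - proto.f0_window, onset)
    f0 = float(np.mean(trace.values[idx]))
    if f0 <= 0:
        raise ValueError(f"non-positive baseline fluorescence F0={f0:.6g}")
    return replace(trace, values=100.0 * (trace.values - f0) / f0)


def estimate_decay(
    control_traces: list[ImagingTrace],
    protocol: StimulusProtocol | None = None,
) -> DecayModel:
    """Fit the decay model to the framewise median solvent-control trace.

    Responses to odorants may not return to baseline within a recording,
    so B is estimated from solvent controls only and reused for every
    trace of the same animal.
    """
    if not control_traces:
        raise ValueError("need at least one solvent-control trace")
    proto = protocol or control_traces[0].protocol
    median = np.median(np.vstack([tr.values for tr in control_traces]), axis=0)
    t = proto.frame_times()
    w = proto.fit_weights()
    mask = w > 0
    sw = np.sqrt(w[mask])

    def resid(p):
        a, logb, c = p
        return sw * (a * np.exp(-t[mask] / np.exp(logb)) + c - median[mask])

    span = float(np.ptp(median[mask])) or 1.0
    best, best_sse = None, np.inf
    for a0 in (span, -span, 0.1 * span):
        for b0 in (2.0, 8.0, 30.0):
            sol = optimize.least_squares(
                resid, [a0, np.log(b0), float(np.median(median[mask]))],
                method="lm", max_nfev=2000,
            )
            if not sol.success or not np.all(np.isfinite(sol.x)):
                continue
            sse = float(np.sum(sol.fun**2))
            if sse < best_sse - 1e-15:
                best, best_sse = sol.x, sse
    if best is None:
        raise RuntimeError(
            "decay fit did not converge on the median control trace "
            f"(n={len(control_traces)} controls, residual floor unreachable)"
        )
    a, logb, c = best
    return DecayModel(A=float(a), B=float(np.exp(logb)), C=float(c))


def bleach_correct(
    trace: ImagingTrace,
    b_fixed: float,
    protocol: StimulusProtocol | None = None,
) -> tuple[ImagingTrace, DecayModel | None]:
    """Remove the bleaching decay from one trace.

    With B fixed, A*exp(-t/B) + C is linear in (A, C) and solved by
    weighted least squares on the non-excluded frames.  If the fitted
    amplitude is not distinguishable from 0 (|A| <= 2 SE), the trace is
    left untouched (degenerate flat control); the returned model is None
    in that case.
    """
    if b_fixed <= 0:
        raise ValueError("B must be positive")
    proto = protocol or trace.protocol
    t = proto.frame_times()
    w = proto.fit_weights()
    mask = w > 0
    if mask.sum() < 3:
        raise ValueError("too few non-excluded frames for the decay fit")
    sw = np.sqrt(w[mask])
    design = np.column_stack([np.exp(-t[mask] / b_fixed), np.ones(mask.sum())])
    coef, res, *_ = np.linalg.lstsq(design * sw[:, None], trace.values[mask] * sw, rcond=None)
    a, c = float(coef[0]), float(coef[1])
    dof = mask.sum() - 2
    if dof > 0:
        resid = (design @ coef - trace.values[mask]) * sw
        sigma2 = float(resid @ resid) / dof
        cov = sigma2 * np.linalg.inv((design * sw[:, None]).T @ (design * sw[:, None]))
        se_a = float(np.sqrt(cov[0, 0]))
        if se_a > 0 and abs(a) <= 2 * se_a:
            return replace(trace, values=trace.values.copy()), None
    model = DecayModel(A=a, B=b_fixed, C=c)
    return replace(trace, values=trace.values - model(t)), model


def response_magnitude(
    trace: ImagingTrace,
    protocol: StimulusProtocol | None = None,
    onset_index: int = 1,
) -> float:
    """Mean of the 5 s post-onset window minus the 2.5 s baseline before it."""
    proto = protocol or trace.protocol
    onset = proto.onsets[onset_index - 1]
    post = proto.window_frames(onset, onset + proto.response_window)
    base = proto.window_frames(onset - proto.baseline_window, onset)
    return float(np.mean(trace.values[post]) - np.mean(trace.values[base]))


class DriftModelError(ValueError):
    """The reference regression crosses zero inside the session."""


def drift_correct(
    responses: pd.Series,
    reference_responses: pd.Series,
) -> pd.Series:
    """Scale a session's responses for slow signal decline.

    Both series are indexed by measurement index (time order within one
    animal).  A line L(t) is fitted to the reference-odorant responses;
    each response at index t is multiplied by L(t1)/L(t), t1 being the
    first reference presentation, so all responses are expressed on the
    scale of the session start.
    """
    ref = reference_responses.dropna().astype(float)
    if ref.size < 2:
        raise ValueError("need at least 2 reference measurements")
    tt = ref.index.to_numpy(dtype=float)
    slope, intercept = np.polyfit(tt, ref.to_numpy(), 1)

    def line(t):
        return slope * np.asarray(t, dtype=float) + intercept

    t_all = responses.index.to_numpy(dtype=float)
    t_session = np.unique(np.concatenate([t_all, tt]))
    if np.any(line(t_session) <= 0):
        raise DriftModelError("drift model invalid: regression line reaches zero")
    factors = line(tt[0]) / line(t_all)
    return responses.astype(float) * factors


def process_animal(
    traces: list[ImagingTrace],
    protocol: StimulusProtocol | None = None,
    drift: bool = True,
) -> pd.DataFrame:
    """Full pipeline for one animal's session, traces in measurement order.

    Returns one row per non-control trace: stimulus, measurement index and
    the drift-corrected response magnitude.
    """
    if not traces:
        raise ValueError("no traces")
    proto = protocol or traces[0].protocol
    dff = [delta_f_over_f(tr) for tr in traces]
    controls = [tr for tr in dff if tr.is_solvent_control]
    if controls:
        decay = estimate_decay(controls, proto)
        corrected = [bleach_correct(tr, decay.B, proto)[0] for tr in dff]
    else:
        corrected = dff
    mags = pd.Series(
        [response_magnitude(tr, proto) for tr in corrected],
        index=np.arange(len(corrected), dtype=float),
    )
    ref_idx = [i for i, tr in enumerate(corrected) if tr.is_reference]
    if drift and len(ref_idx) >= 2:
        mags = drift_correct(mags, mags.iloc[ref_idx])
    rows = []
    for i, tr in enumerate(corrected):
        if tr.is_solvent_control or tr.is_reference:
            continue
        rows.append(
            {
                "animal_id": tr.animal_id,
                "stimulus_id": tr.stimulus_id,
                "measurement_index": i,
                "response": float(mags.iloc[i]),
            }
        )
    return pd.DataFrame(rows, columns=["animal_id", "stimulus_id", "measurement_index", "response"])


def load_traces(path, protocol: StimulusProtocol | None = None) -> list[ImagingTrace]:
    """Read a traces file: animal_id, stimulus_id, role, then frame columns."""
    proto = protocol or StimulusProtocol()
    table = pd.read_csv(path, sep="\t")
    frame_cols = [c for c in table.columns if c.startswith("f")]
    traces = []
    for _, row in table.iterrows():
        traces.append(
            ImagingTrace(
                values=row[frame_cols].to_numpy(dtype=float),
                animal_id=str(row["animal_id"]),
                stimulus_id=str(row["stimulus_id"]),
                is_solvent_control=row["role"] == "solvent",
                is_reference=row["role"] == "reference",
                protocol=proto,
            )
        )
    return traces


def write_traces(traces: list[ImagingTrace], path) -> None:
    n = traces[0].protocol.n_frames
    cols = [f"f{i+1}" for i in range(n)]
    rows = []
    for tr in traces:
        role = (
            "solvent"
            if tr.is_solvent_control
            else "reference" if tr.is_reference else "test"
        )
        rows.append(
            [tr.animal_id, tr.stimulus_id, role] + [f"{v:.6g}" for v in tr.values]
        )
    pd.DataFrame(rows, columns=["animal_id", "stimulus_id", "role"] + cols).to_csv(
        path, sep="\t", index=False
    )
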