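"""Seeded generators for synthetic multi-study data and imaging traces.

The merge machinery assumes that the studies measuring one responding unit
are monotone distortions of a common latent response profile, observed on
partially overlapping odorant panels with additive noise.  The generators
here emulate exactly that: a latent [0, 1] ground-truth profile per unit,
per-study monotone transforms drawn from the five model families, Gaussian
noise on the transformed scale, configurable odorant overlap, and optional
spontaneous-rate offsets.  All generators are pure functions of their
configuration (seeded); the returned metadata records every transform and
subset, so expected values downstream can be computed without re-deriving
anything by hand.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curves import predict
from .datasets import StudyDataset
from .identifiers import SFR_KEY, validate_inchikey
from .traces import ImagingTrace, StimulusProtocol

TUNING_SHAPES = ("uniform", "exponential", "one-hot")


@dataclass
class SimulationConfig:
    """Study-generation conditions.

    Defaults are the conditions the merge engine is validated under:
    3 studies of a 60-odorant panel with 60% per-study coverage, monotone
    distortions from random model families and noise sd 0.05 on the [0, 1]
    response scale.
    """

    n_odorants: int = 60
    n_studies: int = 3
    overlap_fraction: float = 0.6
    transform_family: str = "random"  # one of the 5 families or "random"
    noise_sd: float = 0.05
    sfr_offset: float = 0.0
    tuning_shape: str = "uniform"
    seed: int = 0


def synthetic_inchikey(i: int) -> str:
    """Deterministic syntactically valid InChIKey for odorant index ``i``.

    The second block spells SYNTHETICD so synthetic keys cannot be
    mistaken for real compounds.
    """
    letters = string.ascii_uppercase
    digits = []
    v = i
    for _ in range(14):
        digits.append(letters[v % 26])
        v //= 26
    first = "".join(reversed(digits))
    key = f"{first}-SYNTHETICD-N"
    assert validate_inchikey(key)
    return key


def simulate_ground_truth(config: SimulationConfig) -> pd.Series:
    """Latent [0, 1] response profile of one responding unit.

    ``tuning_shape`` sets the kurtosis regime: ``one-hot`` mimics a
    narrowly tuned unit (single strong ligand), ``exponential`` a skewed
    realistic profile, ``uniform`` a broadly tuned unit.
    """
    if config.n_odorants < 5:
        raise ValueError("need at least 5 odorants")
    if config.tuning_shape not in TUNING_SHAPES:
        raise ValueError(f"unknown tuning shape: {config.tuning_shape}")
    rng = np.random.default_rng(config.seed)
    n = config.n_odorants
    if config.tuning_shape == "one-hot":
        values = np.zeros(n)
        values[int(rng.integers(n))] = 1.0
    elif config.tuning_shape == "uniform":
        values = rng.uniform(0.0, 1.0, size=n)
        values = (values - values.min()) / (values.max() - values.min())
    else:
        values = rng.exponential(scale=0.25, size=n)
        values = (values - values.min()) / (values.max() - values.min())
    keys = [synthetic_inchikey(i) for i in range(n)]
    return pd.Series(values, index=keys, name="truth")


def _random_transform(family: str, rng: np.random.Generator):
    """Monotone-increasing transform parameters on [0, 1] for a family."""
    if family == "identity":
        return np.array([0.0, 1.0])
    if family == "linear":
        return np.array([rng.uniform(0.0, 0.2), rng.uniform(0.5, 1.5)])
    if family == "exponential":
        # a e^{bx} + c with a, b > 0 is increasing
        return np.array([rng.uniform(0.1, 0.5), rng.uniform(0.5, 2.5), rng.uniform(-0.2, 0.2)])
    if family == "sigmoid":
        return np.array([0.0, rng.uniform(0.8, 1.2), rng.uniform(0.3, 0.7), rng.uniform(0.1, 0.25)])
    if family == "asymptotic":
        return np.array([rng.uniform(0.8, 1.3), rng.uniform(0.0, 1.2)])
    if family == "asymptotic-offset":
        return np.array([rng.uniform(0.8, 1.3), rng.uniform(0.0, 1.0), rng.uniform(-0.2, 0.0)])
    raise KeyError(family)


FAMILIES = ("linear", "exponential", "sigmoid", "asymptotic", "asymptotic-offset")


def simulate_studies(
    truth: pd.Series, config: SimulationConfig
) -> tuple[list[StudyDataset], dict]:
    """Generate per-study monotone-distorted noisy observations of a truth.

    Each study observes a random subset of round(overlap_fraction * n)
    odorants, transformed by its own monotone function plus Gaussian noise
    (and an SFR offset when configured).  Returns the datasets and a
    metadata dict with the exact transform, subset and noise draws per
    study, plus the realized pairwise overlap counts.
    """
    rng = np.random.default_rng(config.seed + 1)
    n = len(truth)
    k = int(round(config.overlap_fraction * n))
    k = max(k, 1)
    datasets: list[StudyDataset] = []
    meta: dict = {"studies": {}, "pairwise_overlap": {}, "low_overlap_warning": False}
    for j in range(config.n_studies):
        study_id = f"study{j+1:02d}"
        family = (
            config.transform_family
            if config.transform_family != "random"
            else FAMILIES[int(rng.integers(len(FAMILIES)))]
        )
        params = _random_transform(family, rng)
        subset = np.sort(rng.choice(n, size=k, replace=False))
        keys = truth.index[subset]
        if family == "identity":
            clean = truth.iloc[subset].to_numpy().copy()
        else:
            # normalize the transform to unit output range over the [0, 1]
            # truth domain, so noise_sd is on the same scale as the responses
            f0 = float(predict(family, params, 0.0))
            f1 = float(predict(family, params, 1.0))
            clean = (predict(family, params, truth.iloc[subset].to_numpy()) - f0) / (f1 - f0)
        noise = rng.normal(0.0, config.noise_sd, size=k)
        values = clean + noise + config.sfr_offset
        sfr_reported = config.sfr_offset != 0.0
        responses = pd.Series(values, index=keys)
        if sfr_reported:
            # baseline = the (normalized) transform of a zero response + offset
            responses[SFR_KEY] = config.sfr_offset
        datasets.append(
            StudyDataset(
                study_id=study_id,
                unit_id="synthetic-unit",
                responses=responses,
                sfr_reported=sfr_reported,
                technique="synthetic",
            )
        )
        meta["studies"][study_id] = {
            "family": family,
            "params": params,
            "odorants": list(keys),
            "noise": noise,
        }
    for i in range(config.n_studies):
        for j in range(i + 1, config.n_studies):
            a = set(meta["studies"][f"study{i+1:02d}"]["odorants"])
            b = set(meta["studies"][f"study{j+1:02d}"]["odorants"])
            meta["pairwise_overlap"][(f"study{i+1:02d}", f"study{j+1:02d}")] = len(a & b)
    if meta["pairwise_overlap"] and max(meta["pairwise_overlap"].values()) < 5:
        meta["low_overlap_warning"] = True
    return datasets, meta


@dataclass
class TraceSimulationConfig:
    """Conditions for synthetic imaging traces.

    Decay amplitudes/time constants and the noise level follow the scale
    of dF/F recordings: responses of a few to a few tens of percent over a
    bleaching decay with a time constant of several seconds.
    """

    magnitudes: tuple[float, ...] = (0.0, 5.0, 10.0, 20.0)  # % dF/F
    n_repeats: int = 1
    decay_amplitude: float = 10.0  # % dF/F lost to bleaching
    decay_tau: float = 8.0
    offset: float = 0.0
    noise_sd: float = 0.5  # % dF/F
    n_controls: int = 3
    f_base: float = 100.0  # raw fluorescence units at rest
    seed: int = 0
    protocol: StimulusProtocol = field(default_factory=StimulusProtocol)


def _boxcar(proto: StimulusProtocol, magnitude: float) -> np.ndarray:
    out = np.zeros(proto.n_frames)
    for onset in proto.onsets:
        out[proto.window_frames(onset, onset + proto.response_window)] = magnitude
    return out


def simulate_traces(
    config: TraceSimulationConfig,
) -> tuple[list[ImagingTrace], pd.Series]:
    """Synthetic raw-fluorescence traces with bleaching and responses.

    The percent-scale model signal is decay + boxcar responses at the
    protocol onsets + Gaussian noise; it modulates a resting fluorescence
    of ``f_base``, so the emitted traces are raw and the pipeline's dF/F
    conversion applies.  Returns the traces (solvent controls first) and
    the injected response magnitude per test trace, keyed by stimulus id.
    """
    rng = np.random.default_rng(config.seed)
    proto = config.protocol
    t = proto.frame_times()
    decay = config.decay_amplitude * np.exp(-t / config.decay_tau) + config.offset

    def raw(percent_signal):
        return config.f_base * (1.0 + percent_signal / 100.0)

    traces: list[ImagingTrace] = []
    for c in range(config.n_controls):
        values = raw(decay + rng.normal(0.0, config.noise_sd, size=proto.n_frames))
        traces.append(
            ImagingTrace(
                values=values,
                animal_id="sim",
                stimulus_id=f"solvent{c+1}",
                is_solvent_control=True,
                protocol=proto,
            )
        )
    truth = {}
    for rep in range(config.n_repeats):
        for m, mag in enumerate(config.magnitudes):
            sid = f"odorant{m+1:02d}_r{rep+1}"
            values = raw(
                decay
                + _boxcar(proto, mag)
                + rng.normal(0.0, config.noise_sd, size=proto.n_frames)
            )
            traces.append(
                ImagingTrace(
                    values=values, animal_id="sim", stimulus_id=sid, protocol=proto
                )
            )
            truth[sid] = mag
    return traces, pd.Series(truth, name="injected_magnitude")


def write_simulated_studies(datasets: list[StudyDataset], truth: pd.Series, out_dir) -> None:
    """Emit dataset files plus truth.tsv in the standard dataset format."""
    import os

    from .datasets import write_dataset, write_dataset_info

    os.makedirs(out_dir, exist_ok=True)
    for ds in datasets:
        write_dataset(ds, os.path.join(out_dir, f"{ds.study_id}_{ds.unit_id}.tsv"))
    write_dataset_info(datasets, os.path.join(out_dir, "dataset.info"))
    truth_df = pd.DataFrame({"InChIKey": truth.index, "Response": [f"{v:.6g}" for v in truth]})
    truth_df.to_csv(os.path.join(out_dir, "truth.tsv"), sep="\t", index=False)
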