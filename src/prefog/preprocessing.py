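"""Gait-cycle preprocessing and matched-dataset assembly.

Raw variable-length cycles are low-pass filtered (zero-phase 4th-order
Butterworth, 7 Hz cut-off at the 100 Hz native rate), linearly resampled to
101 samples (one per percent of the gait cycle), and each channel is affinely
rescaled to [-1, 1] per cycle. Pre-FOG cycles are then paired with functional
gait cycles (FGC): one from the same subject (condition-matched where
possible) and one from a NoLab-freezer subject, mirroring the class-balance
protocol of the study design. Unpaired FGCs stay in the training set but are
flagged for exclusion from attribution analysis.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, freqz

from .synthetic import CLASS_FGC, CLASS_PREFOG, RawGaitCycle

N_SAMPLES = 101
#: one-hot column order: (FGC, pre-FOG); the second column is 1 for pre-FOG
CLASS_ORDER = (CLASS_FGC, CLASS_PREFOG)


class SignalTooShortError(ValueError):
    """Raised when a signal is too short for zero-phase filtering."""


def lowpass_filter(signal, fs: float = 100.0, cutoff: float = 7.0, order: int = 4):
    """Zero-phase (forward-backward) Butterworth low-pass filter.

    The input is one gait cycle, so boundaries are handled cyclically: the
    straight line joining the first and last samples is removed, the residual
    is filtered under a periodic extension (applying the squared Butterworth
    magnitude, i.e. the exact forward-backward response, to its discrete
    spectrum), and the line is restored. This keeps the filter strictly
    zero-phase, makes a DC signal an exact fixed point, and avoids the edge
    transients that padded filtering introduces on short cycles.

    Output has the same length as the input. Signals too short to represent
    a cycle at the given order are rejected.
    """
    x = np.asarray(signal, dtype=float)
    if fs <= 2 * cutoff:
        raise ValueError(f"sampling rate {fs} must exceed twice the cut-off {cutoff}")
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    n = x.shape[0]
    if n <= 3 * (order + 1):
        raise SignalTooShortError(
            f"signal of length {n} too short for an order-{order} zero-phase "
            f"filter (needs more than {3 * (order + 1)} samples)"
        )
    b, a = butter(order, cutoff, btype="low", fs=fs)
    t = np.linspace(0.0, 1.0, n)[:, None]
    trend = x[0] + (x[-1] - x[0]) * t
    resid = (x - trend)[:-1]  # one period; endpoints coincide after detrending
    m = n - 1
    freqs = np.fft.rfftfreq(m, d=1.0 / fs)
    _, h = freqz(b, a, worN=2.0 * np.pi * freqs / fs)
    gain = np.abs(h) ** 2  # forward-backward magnitude response
    y = np.fft.irfft(np.fft.rfft(resid, axis=0) * gain[:, None], n=m, axis=0)
    out = np.concatenate([y, y[:1]]) + trend
    return out[:, 0] if squeeze else out


def time_normalize(cycle):
    """Resample a (T, C) cycle onto 101 evenly spaced points (0-100% of cycle).

    Cubic-spline interpolation for T >= 4 (linear below); the output grid
    spans the original support, so the first and last rows equal the input's
    first and last rows, and an input already on the 101-point grid passes
    through unchanged.
    """
    x = np.atleast_2d(np.asarray(cycle, dtype=float))
    if x.shape[0] < 2:
        raise ValueError("time_normalize requires at least 2 samples")
    src = np.linspace(0.0, 1.0, x.shape[0])
    dst = np.linspace(0.0, 1.0, N_SAMPLES)
    if x.shape[0] < 4:
        return np.column_stack(
            [np.interp(dst, src, x[:, c]) for c in range(x.shape[1])]
        )
    return CubicSpline(src, x, axis=0)(dst)


def rescale_unit(channel):
    """Affinely map a vector so min -> -1 and max -> +1.

    A constant channel has no range to normalize and maps to all zeros
    (the interval midpoint).
    """
    x = np.asarray(channel, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x)
    return 2.0 * (x - lo) / (hi - lo) - 1.0


@dataclass(frozen=True)
class GaitCycle:
    """Preprocessed 101x3 network input in [-1, 1] with carried metadata."""

    values: np.ndarray  # (101, 3), columns hip, knee, ankle
    subject_id: str
    label: str
    condition: str
    cycle_id: str
    matched: bool = False

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_SAMPLES, 3):
            raise ValueError(f"expected a ({N_SAMPLES}, 3) matrix, got {v.shape}")
        object.__setattr__(self, "values", v)


def preprocess_cycle(raw: RawGaitCycle) -> GaitCycle:
    """Filter, time-normalize and rescale one raw cycle; metadata carried through."""
    filtered = lowpass_filter(raw.angles, fs=raw.sampling_rate)
    resampled = time_normalize(filtered)
    values = np.column_stack([rescale_unit(resampled[:, c]) for c in range(3)])
    return GaitCycle(
        values=values,
        subject_id=raw.subject_id,
        label=raw.label,
        condition=raw.condition,
        cycle_id=raw.cycle_id,
    )


def one_hot(labels):
    """One-hot encode class labels with fixed column order (FGC, pre-FOG)."""
    labels = list(labels)
    unknown = sorted({l for l in labels if l not in CLASS_ORDER})
    if unknown:
        raise ValueError(f"unknown class labels {unknown}; expected {CLASS_ORDER}")
    Y = np.zeros((len(labels), 2), dtype=int)
    for i, lab in enumerate(labels):
        Y[i, CLASS_ORDER.index(lab)] = 1
    return Y


@dataclass(frozen=True)
class MatchTriple:
    prefog_id: str
    same_subject_fgc_id: str | None
    other_subject_fgc_id: str | None


@dataclass
class MatchedDataset:
    """Cycles plus the pre-FOG/FGC pairing manifest.

    ``triples`` pairs every pre-FOG cycle with (at most) one same-subject FGC
    and one NoLab-freezer FGC; FGC cycles not drawn into any triple are listed
    in ``unmatched_fgc_ids`` and carry ``matched=False`` (excluded from
    attribution analysis, retained for training).
    """

    cycles: list
    triples: list
    unmatched_fgc_ids: list

    def cycle(self, cycle_id: str) -> GaitCycle:
        return self._index[cycle_id]

    def __post_init__(self):
        self._index = {c.cycle_id: c for c in self.cycles}

    def matched_cycles(self) -> list:
        return [c for c in self.cycles if c.matched or c.label == CLASS_PREFOG]

    def to_manifest(self) -> dict:
        return {
            "triples": [
                {
                    "prefog": t.prefog_id,
                    "same_subject_fgc": t.same_subject_fgc_id,
                    "other_subject_fgc": t.other_subject_fgc_id,
                }
                for t in self.triples
            ],
            "unmatched_fgc_ids": list(self.unmatched_fgc_ids),
        }

    def write_manifest(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_manifest(), indent=2))


def match_and_balance(prefog, fgc_pool, roster, seed: int = 0) -> MatchedDataset:
    """Pair each pre-FOG cycle with a same-subject FGC and a NoLab-freezer FGC.

    Preference order for the same-subject pair: same condition tag, then any
    same-subject FGC, else none (logged). The other-subject pair is drawn from
    a seeded-random NoLab-freezer subject (freezer-group subjects contributing
    no pre-FOG cycles), condition-matched when possible. No FGC is reused
    across triples.
    """
    prefog = sorted(prefog, key=lambda c: c.cycle_id)
    fgc_pool = sorted(fgc_pool, key=lambda c: c.cycle_id)
    if not fgc_pool:
        raise ValueError("fgc_pool is empty")
    if any(c.label != CLASS_PREFOG for c in prefog):
        raise ValueError("prefog collection contains non-pre-FOG cycles")
    if any(c.label != CLASS_FGC for c in fgc_pool):
        raise ValueError("fgc_pool contains non-FGC cycles")

    prefog_subjects = {c.subject_id for c in prefog}
    nolab_subjects = sorted(
        s for s, info in roster.items()
        if info["group"] in ("freezer", "nolab_freezer") and s not in prefog_subjects
    )
    if not nolab_subjects:
        warnings.warn(
            "no NoLab-freezer subjects in roster; triples will hold only "
            "same-subject matches",
            stacklevel=2,
        )

    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([int(seed), 23])))
    available = {c.cycle_id for c in fgc_pool}
    by_id = {c.cycle_id: c for c in fgc_pool}

    def take(candidates):
        ids = [c.cycle_id for c in candidates if c.cycle_id in available]
        if not ids:
            return None
        pick = ids[int(rng.integers(len(ids)))]
        available.discard(pick)
        return pick

    triples = []
    for p in prefog:
        same = [c for c in fgc_pool if c.subject_id == p.subject_id]
        same_cond = [c for c in same if c.condition == p.condition]
        same_id = take(same_cond) or take(same)
        if same_id is None and same == []:
            warnings.warn(
                f"pre-FOG cycle {p.cycle_id}: subject {p.subject_id} has no own FGC; "
                "triple holds only the other-subject match",
                stacklevel=2,
            )
        other_id = None
        if nolab_subjects:
            donor = nolab_subjects[int(rng.integers(len(nolab_subjects)))]
            donor_fgc = [c for c in fgc_pool if c.subject_id == donor]
            donor_cond = [c for c in donor_fgc if c.condition == p.condition]
            other_id = take(donor_cond) or take(donor_fgc)
            if other_id is None:
                # the drawn donor ran dry; fall back over remaining NoLab pool
                pool = [c for c in fgc_pool if c.subject_id in nolab_subjects]
                other_id = take([c for c in pool if c.condition == p.condition]) or take(pool)
        triples.append(MatchTriple(p.cycle_id, same_id, other_id))

    matched_ids = {p.prefog_id for p in triples}
    for t in triples:
        matched_ids |= {i for i in (t.same_subject_fgc_id, t.other_subject_fgc_id) if i}
    cycles = [replace(c, matched=True) for c in prefog]
    unmatched = []
    for c in fgc_pool:
        flag = c.cycle_id in matched_ids
        cycles.append(replace(c, matched=flag))
        if not flag:
            unmatched.append(c.cycle_id)
    return MatchedDataset(cycles=cycles, triples=triples, unmatched_fgc_ids=unmatched)


def dataset_arrays(cycles):
    """Stack cycles into (X, y, subjects) arrays for model fitting.

    X is (N, 101, 3); y is 1 for pre-FOG, 0 for FGC (the one-hot pre-FOG
    column); subjects is an object array of subject IDs.
    """
    cycles = list(cycles)
    X = np.stack([c.values for c in cycles])
    y = np.array([1 if c.label == CLASS_PREFOG else 0 for c in cycles], dtype=int)
    subjects = np.array([c.subject_id for c in cycles], dtype=object)
    return X, y, subjects
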