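"""Synthetic gait-cycle cohort generator.

Produces cohorts of sagittal-plane joint-angle cycles (hip, knee, ankle; degrees;
100 Hz) with the statistical structure a pre-freezing-of-gait (pre-FOG) analysis
assumes: per-subject template trajectories, a pre-FOG signature of reduced range
of motion (reduced knee swing-peak flexion, flattened ankle dorsiflexion during
swing, reduced hip excursion), subject heterogeneity including a severely flexed
"stooped" archetype, variable cycle durations, and additive measurement noise.

Templates are truncated Fourier series (six harmonics) fit to normative
sagittal-plane gait shapes; the harmonic coefficients below are the generator's
defaults. Subject-level random effects perturb per-joint amplitude, phase and
offset within +/-15% of the defaults.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

JOINTS = ("hip", "knee", "ankle")
CLASS_PREFOG = "pre-FOG"
CLASS_FGC = "FGC"
GROUPS = ("freezer", "nolab_freezer", "nonfreezer", "control")
ARCHETYPES = ("typical", "stooped")

#: protocol conditions: turning direction/amplitude x cognitive load
CONDITIONS = tuple(
    f"{walk}/{task}"
    for walk in ("180L", "180R", "360L", "360R", "straight")
    for task in ("single", "dual")
)

# Fourier coefficients [a0, a1, b1, ..., a6, b6] for angle(t) =
# a0 + sum_k a_k cos(2 pi k t) + b_k sin(2 pi k t), t in [0, 1), degrees.
# Fit to normative sagittal gait key points with a ridge penalty that
# suppresses harmonics 5-6 (keeps the curves band-limited well below the
# 7 Hz preprocessing cut-off at physiological cadences).
_TEMPLATE_COEF = {
    "hip": np.array(
        [12.7540, 20.6500, -4.3281, -2.6749, -1.9785, -0.54181, 0.51091,
         -0.0072876, 0.033358, -0.00083029, 0.0024679, 0.00013709, 0.000099479]
    ),
    "knee": np.array(
        [21.689, -0.094199, -19.010, -14.899, 5.4201, -0.36796, 3.8310,
         0.025314, -0.034057, -0.012258, -0.0018901, -0.00064851, 0.00025322]
    ),
    "ankle": np.array(
        [0.62599, -1.24673, 4.59330, 0.60818, -6.85955, -2.16038, 0.64285,
         0.137303, -0.0345702, -0.00085917, -0.00374001, 0.00034547, -0.0000015425]
    ),
}

#: constant flexion offsets (degrees) added by the stooped archetype
STOOPED_OFFSETS = {"hip": 20.0, "knee": 15.0, "ankle": 0.0}

#: swing phase of the gait cycle as a fraction of the stride (standard convention)
SWING_WINDOW = (0.60, 1.00)
#: logistic onset of the pre-FOG swing perturbation: center and width (cycle fraction)
_SWING_ONSET_CENTER = 0.63
_SWING_ONSET_SCALE = 0.018

SAMPLING_RATE_HZ = 100.0


class UnknownArchetypeError(ValueError):
    """Raised for archetype tags other than 'typical' or 'stooped'."""


class CohortConfigError(ValueError):
    """Raised when a cohort configuration violates its invariants."""


def _fourier_eval(coef: np.ndarray, t: np.ndarray) -> np.ndarray:
    out = np.full_like(t, coef[0], dtype=float)
    n_harm = (len(coef) - 1) // 2
    for k in range(1, n_harm + 1):
        w = 2.0 * np.pi * k * t
        out += coef[2 * k - 1] * np.cos(w) + coef[2 * k] * np.sin(w)
    return out


@dataclass(frozen=True)
class JointTemplates:
    """Noiseless per-joint angle curves over one normalized gait cycle.

    Parameters are per-joint: a multiplicative amplitude scale applied to the
    deviation from the curve mean, a phase shift (cycle fraction) and an
    additive offset (degrees). ``archetype`` tags the subject morphology.
    """

    archetype: str
    amp_scale: dict
    phase_shift: dict
    offset: dict

    def evaluate(self, joint: str, phase: np.ndarray) -> np.ndarray:
        """Evaluate one joint's template at phase values (cycle fractions)."""
        coef = _TEMPLATE_COEF[joint]
        base = _fourier_eval(coef, np.asarray(phase, dtype=float) + self.phase_shift[joint])
        curve = coef[0] + self.amp_scale[joint] * (base - coef[0]) + self.offset[joint]
        if self.archetype == "stooped":
            curve = curve + STOOPED_OFFSETS[joint]
        return curve

    def curves(self, n: int = 101) -> np.ndarray:
        """Sampled (n, 3) template matrix over one cycle, columns hip/knee/ankle."""
        t = np.linspace(0.0, 1.0, n)
        return np.column_stack([self.evaluate(j, t) for j in JOINTS])


@dataclass(frozen=True)
class RawGaitCycle:
    """One variable-length 3-channel joint-angle time series plus metadata."""

    angles: np.ndarray  # (T, 3) degrees, columns hip, knee, ankle
    sampling_rate: float
    subject_id: str
    label: str  # CLASS_PREFOG or CLASS_FGC
    condition: str
    cycle_id: str

    def __post_init__(self):
        a = np.asarray(self.angles, dtype=float)
        if a.ndim != 2 or a.shape[1] != 3:
            raise ValueError("angles must be a (T, 3) matrix ordered hip, knee, ankle")
        object.__setattr__(self, "angles", a)


@dataclass
class CohortConfig:
    """Study-design parameters of a synthetic cohort.

    Defaults mirror the reference study's design at desk scale: seven
    freezer subjects contributing eight pre-FOG cycles each (56 pre-FOG cycles
    total), seven NoLab freezers (freezer-group subjects who contribute only
    functional cycles), non-freezer and control groups contributing only
    functional gait, one stooped subject among the seven freezers, an effect
    size delta = 0.5 (mid-range of the 31-61.5% range-of-motion reductions
    reported before freezing), 2 degrees of measurement noise, and stride
    durations of 0.8-1.3 s at 100 Hz.
    """

    n_freezers: int = 7
    n_nolab_freezers: int = 7
    n_nonfreezers: int = 7
    n_controls: int = 7
    prefog_per_freezer: int = 8
    fgc_per_subject: int = 8
    delta: float = 0.5
    noise_sd: float = 2.0
    duration_range: tuple = (80, 130)
    stooped_fraction: float = 1.0 / 7.0
    seed: int = 0

    def validate(self) -> None:
        errors = []
        if not (0.0 <= self.delta <= 1.0):
            errors.append(f"delta={self.delta} outside [0, 1]")
        for name in ("n_freezers", "n_nolab_freezers", "n_nonfreezers", "n_controls",
                     "prefog_per_freezer", "fgc_per_subject"):
            if getattr(self, name) < 0:
                errors.append(f"{name} negative")
        lo, hi = self.duration_range
        if not (50 <= lo <= hi <= 200):
            errors.append(f"duration_range={self.duration_range} outside [50, 200]")
        if not (0.0 <= self.stooped_fraction <= 1.0):
            errors.append(f"stooped_fraction={self.stooped_fraction} outside [0, 1]")
        if self.noise_sd < 0:
            errors.append("noise_sd negative")
        if (self.n_freezers + self.n_nolab_freezers + self.n_nonfreezers
                + self.n_controls) == 0:
            errors.append("cohort has zero subjects in every group")
        if errors:
            raise CohortConfigError("; ".join(errors))


def make_joint_templates(archetype: str, subject_seed: int) -> JointTemplates:
    """Draw one subject's joint templates.

    Deterministic in ``(archetype, subject_seed)``. Random effects stay within
    +/-12% amplitude, +/-2% cycle phase and +/-1 degree offset, which bounds
    the typical knee swing-phase peak inside [50, 70] degrees by construction.
    """
    if archetype not in ARCHETYPES:
        raise UnknownArchetypeError(f"unknown archetype {archetype!r}; expected one of {ARCHETYPES}")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([7, int(subject_seed)])))
    amp = {j: float(rng.uniform(0.88, 1.12)) for j in JOINTS}
    phase = {j: float(rng.uniform(-0.02, 0.02)) for j in JOINTS}
    offset = {j: float(rng.uniform(-1.0, 1.0)) for j in JOINTS}
    return JointTemplates(archetype=archetype, amp_scale=amp, phase_shift=phase, offset=offset)


def _swing_weight(t: np.ndarray) -> np.ndarray:
    """Smooth indicator of the swing window.

    A logistic onset centered just after toe-off (63% of the cycle) that is
    effectively 0 through stance and 1 from the swing knee peak (~73%) to the
    end of the cycle; its smoothness keeps the perturbed curves free of sharp
    spectral content.
    """
    return 1.0 / (1.0 + np.exp(-(t - _SWING_ONSET_CENTER) / _SWING_ONSET_SCALE))


def _prefog_curves(templates: JointTemplates, phase: np.ndarray, delta: float) -> np.ndarray:
    """Apply the pre-FOG range-of-motion signature to the noiseless templates.

    Knee: swing excursion above the swing minimum scaled by (1 - delta).
    Ankle: swing trajectory pulled toward its swing mean by a factor delta
    (emulating fixed dorsiflexion). Hip: whole-cycle excursion about the mean
    scaled by (1 - delta/2).
    """
    w = _swing_weight(phase)
    fine = np.linspace(SWING_WINDOW[0], SWING_WINDOW[1], 201)
    hip = templates.evaluate("hip", phase)
    knee = templates.evaluate("knee", phase)
    ankle = templates.evaluate("ankle", phase)

    knee_swing_min = templates.evaluate("knee", fine).min()
    knee = knee - w * delta * (knee - knee_swing_min)

    ankle_swing_mean = templates.evaluate("ankle", fine).mean()
    ankle = ankle - w * delta * (ankle - ankle_swing_mean)

    hip_mean = templates.evaluate("hip", np.linspace(0, 1, 201)).mean()
    hip = hip_mean + (1.0 - delta / 2.0) * (hip - hip_mean)
    return np.column_stack([hip, knee, ankle])


def synthesize_cycle(
    templates: JointTemplates,
    label: str,
    delta: float,
    noise_sd: float,
    duration: int,
    seed: int,
    *,
    subject_id: str = "S0",
    condition: str = "straight/single",
    cycle_id: str = "c0",
) -> RawGaitCycle:
    """Render one gait cycle from subject templates.

    Functional cycles (FGC) are the templates resampled to ``duration`` samples
    plus i.i.d. Gaussian noise; pre-FOG cycles first receive the reduced
    range-of-motion signature of strength ``delta``.
    """
    if not (0.0 <= delta <= 1.0):
        raise ValueError(f"delta={delta} outside [0, 1]")
    if label not in (CLASS_PREFOG, CLASS_FGC):
        raise ValueError(f"unknown class label {label!r}")
    phase = np.linspace(0.0, 1.0, int(duration))
    if label == CLASS_PREFOG:
        clean = _prefog_curves(templates, phase, delta)
    else:
        clean = np.column_stack([templates.evaluate(j, phase) for j in JOINTS])
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([11, int(seed)])))
    angles = clean + rng.normal(0.0, noise_sd, size=clean.shape)
    return RawGaitCycle(
        angles=angles,
        sampling_rate=SAMPLING_RATE_HZ,
        subject_id=subject_id,
        label=label,
        condition=condition,
        cycle_id=cycle_id,
    )


@dataclass
class Cohort:
    """Generated cohort: cycles plus the subject roster (id -> group, archetype)."""

    cycles: list
    roster: dict
    config: CohortConfig

    def by_label(self, label: str) -> list:
        return [c for c in self.cycles if c.label == label]

    def subjects_in_group(self, group: str) -> list:
        return sorted(s for s, info in self.roster.items() if info["group"] == group)


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a full cohort reproducibly from the master seed.

    Freezer subjects contribute both pre-FOG and functional cycles; NoLab
    freezers, non-freezers and controls contribute only functional cycles.
    Protocol-condition tags are drawn per cycle from the ten turning/dual-task
    conditions.
    """
    config.validate()
    master = int(config.seed)
    roster: dict = {}
    cycles: list = []

    group_plan = [
        ("freezer", "F", config.n_freezers),
        ("nolab_freezer", "NL", config.n_nolab_freezers),
        ("nonfreezer", "NF", config.n_nonfreezers),
        ("control", "HC", config.n_controls),
    ]
    n_stooped = int(round(config.stooped_fraction * config.n_freezers))
    subject_index = 0
    for group, prefix, count in group_plan:
        for k in range(count):
            sid = f"{prefix}{k + 1:02d}"
            archetype = "stooped" if (group == "freezer" and k < n_stooped) else "typical"
            templates = make_joint_templates(
                archetype, subject_seed=master * 10007 + subject_index
            )
            rng = np.random.Generator(
                np.random.PCG64(np.random.SeedSequence([master, 101, subject_index]))
            )
            roster[sid] = {"group": group, "archetype": archetype}
            plan = [(CLASS_FGC, config.fgc_per_subject)]
            if group == "freezer":
                plan.append((CLASS_PREFOG, config.prefog_per_freezer))
            cyc_num = 0
            for label, n_cycles in plan:
                for _ in range(n_cycles):
                    duration = int(rng.integers(config.duration_range[0],
                                                config.duration_range[1] + 1))
                    condition = CONDITIONS[int(rng.integers(len(CONDITIONS)))]
                    cycle_seed = int(rng.integers(2**31 - 1))
                    cycles.append(
                        synthesize_cycle(
                            templates,
                            label,
                            config.delta,
                            config.noise_sd,
                            duration,
                            cycle_seed,
                            subject_id=sid,
                            condition=condition,
                            cycle_id=f"{sid}_{cyc_num:03d}",
                        )
                    )
                    cyc_num += 1
            subject_index += 1
    return Cohort(cycles=cycles, roster=roster, config=config)


# ---------------------------------------------------------------------------
# long-format CSV / JSON serialization


def cohort_to_frame(cohort: Cohort) -> pd.DataFrame:
    """Long-format table: one row per (cycle, sample)."""
    rows = []
    for c in cohort.cycles:
        t = np.arange(c.angles.shape[0])
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": c.subject_id,
                    "cycle_id": c.cycle_id,
                    "class": c.label,
                    "condition": c.condition,
                    "sample_index": t,
                    "hip_deg": c.angles[:, 0],
                    "knee_deg": c.angles[:, 1],
                    "ankle_deg": c.angles[:, 2],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


REQUIRED_COHORT_COLUMNS = (
    "subject_id", "cycle_id", "class", "condition",
    "sample_index", "hip_deg", "knee_deg", "ankle_deg",
)


def write_cohort(cohort: Cohort, csv_path, roster_path=None) -> None:
    cohort_to_frame(cohort).to_csv(csv_path, index=False)
    if roster_path is not None:
        payload = {"roster": cohort.roster, "config": asdict(cohort.config)}
        payload["config"]["duration_range"] = list(cohort.config.duration_range)
        Path(roster_path).write_text(json.dumps(payload, indent=2))


def frame_to_cycles(frame: pd.DataFrame) -> list:
    """Parse a long-format cohort table back into RawGaitCycle objects."""
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"cohort table missing required columns: {missing}")
    cycles = []
    for cycle_id, g in frame.groupby("cycle_id", sort=True):
        g = g.sort_values("sample_index")
        cycles.append(
            RawGaitCycle(
                angles=g[["hip_deg", "knee_deg", "ankle_deg"]].to_numpy(float),
                sampling_rate=SAMPLING_RATE_HZ,
                subject_id=str(g["subject_id"].iloc[0]),
                label=str(g["class"].iloc[0]),
                condition=str(g["condition"].iloc[0]),
                cycle_id=str(cycle_id),
            )
        )
    return cycles


def read_cohort(csv_path, roster_path=None):
    """Read a cohort CSV (and optional roster JSON) back into objects.

    Returns ``(cycles, roster)``; roster is None when no roster path is given.
    """
    frame = pd.read_csv(csv_path)
    cycles = frame_to_cycles(frame)
    roster = None
    if roster_path is not None:
        roster = json.loads(Path(roster_path).read_text())["roster"]
    return cycles, roster
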