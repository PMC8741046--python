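"""Seeded synthetic ERP cohorts for the two cognitive tasks.

Generates subject-level epoched EEG for an auditory Oddball task (AOB: 400
tones, 80% Frequent / 10% Target / 10% Novel) and a visual Go/No-Go task
(VGNG: 400 letters, 80% Go / 20% No-Go, plus response-locked Go epochs),
together with clinical covariates (group, sex, age, motor UPDRS, levodopa
equivalent daily dose).

Each trial is a sum of spatiotemporal component "bumps": separable Gaussian
in time and in montage distance, multiplied by a carrier sinusoid at the
center of the component's frequency band, plus additive white noise. The
carrier guarantees that each planted component survives band-pass filtering
into its own band and is recoverable by peak detection. Between-subject
variability enters through per-subject draws of component latency, amplitude
and scalp location; within-subject (trial-to-trial) variability comes from
the additive noise and, for components targeted by a topographic-jitter
effect, from per-trial displacement of the component's scalp center.

Early-stage patients carry a latent positive `severity` scalar that scales
every group effect and linearly co-determines the motor UPDRS score, so a
severity-score correlation exists by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .containers import EpochSet, WINDOWS
from .montage import Montage, build_montage

ConditionKey = tuple[str, str, str]  # (task, condition, lock)

#: The six epoch sets produced per subject.
CONDITIONS: tuple[ConditionKey, ...] = (
    ("AOB", "Frequent", "stimulus"),
    ("AOB", "Target", "stimulus"),
    ("AOB", "Novel", "stimulus"),
    ("VGNG", "Go", "stimulus"),
    ("VGNG", "NoGo", "stimulus"),
    ("VGNG", "Go", "response"),
)

RESPONSE_REQUIRED = {("AOB", "Target"), ("VGNG", "Go")}

#: Band-center carrier frequencies (Hz); must stay consistent with
#: :data:`erpmarker.processing.BANDS`.
#: Carriers sit well inside each band so a component's spectrum stays clear
#: of the neighboring overlapping band's passband.
CARRIER_HZ = {"delta": 2.5, "theta": 5.5, "alpha": 10.0, "beta": 21.0}


@dataclass(frozen=True)
class ComponentSpec:
    """One planted ERP component.

    Latencies in ms relative to the lock event; amplitude is the unsigned
    peak magnitude in microvolts (sign supplied by `polarity`); widths are
    the Gaussian SDs in ms (time) and montage units (space); `latency_sd`
    and `amplitude_sd` are between-subject SDs.
    """

    label: str
    polarity: int
    latency_mean: float
    latency_sd: float
    amplitude_mean: float
    amplitude_sd: float
    topo_center: tuple[float, float]  # (lr, pa)
    spatial_width: float
    temporal_width: float
    carrier_band: str
    conditions: tuple[ConditionKey, ...]

    def __post_init__(self) -> None:
        if self.temporal_width <= 0 or self.spatial_width <= 0:
            raise ValueError("component widths must be positive")
        for key in self.conditions:
            win = WINDOWS[(key[0], key[2])]
            if not (win.start <= self.latency_mean < win.end):
                raise ValueError(
                    f"component {self.label}: latency {self.latency_mean} ms "
                    f"outside epoch window [{win.start}, {win.end}) of {key}"
                )


@dataclass(frozen=True)
class GroupEffect:
    """A patient-group shift of one component attribute in one condition.

    attribute: 'amplitude' (microvolts, added to the unsigned magnitude),
    'latency' (ms, added), or 'topographic_jitter' (montage units, SD of a
    per-trial displacement of the component's scalp center). The delta is
    scaled by each patient's latent severity (mean 1 in the early group).
    """

    component: str
    condition: ConditionKey
    attribute: str
    delta: float

    def __post_init__(self) -> None:
        if self.attribute not in ("amplitude", "latency", "topographic_jitter"):
            raise ValueError(f"unknown effect attribute {self.attribute!r}")


@dataclass(frozen=True)
class SubjectRecord:
    id: str
    group: str  # HC | ESPD | establishedPD
    sex: str  # M | F
    age: float
    mupdrs: int | None = None
    ledd: float | None = None
    severity: float = 0.0  # latent; 0 for HC

    def __post_init__(self) -> None:
        if self.group == "HC" and self.mupdrs is not None:
            raise ValueError("mUPDRS must be absent for healthy controls")
        if self.ledd is not None and self.ledd < 0:
            raise ValueError("LEDD must be non-negative")


def default_components() -> tuple[ComponentSpec, ...]:
    """The planted component inventory (all stimulus conditions unless noted).

    Carrier bands are spread over the band table so that components sharing a
    band are far enough apart in time to be resolvable given the band's
    time-bandwidth limit: the fast P50 rides a beta carrier; N100, P200 and N2
    sit 150 and 50 ms apart in alpha, phase-coherent on the 10 Hz carrier grid
    (crests at 50 + k*100 ms, troughs at 100 + k*100 ms), so their ringing
    superposition reinforces every planted peak instead of displacing it; and
    P300 is the lone delta component of any condition.
    """
    stim = tuple(k for k in CONDITIONS if k[2] == "stimulus")
    return (
        # topographic centers coincide with electrode positions (Fz, Cz, Pz,
        # C3) so the detected peak channel is stable across subjects
        ComponentSpec("P50", +1, 50.0, 6.0, 4.0, 0.9, (0.0, 0.5), 0.50, 18.0,
                      "beta", stim),
        ComponentSpec("N100", -1, 100.0, 8.0, 5.0, 1.0, (0.0, 0.0), 0.50, 30.0,
                      "alpha", stim),
        ComponentSpec("P200", +1, 250.0, 10.0, 5.0, 1.0, (0.0, 0.0), 0.50, 40.0,
                      "alpha", stim),
        ComponentSpec("N2", -1, 300.0, 12.0, 5.0, 1.0, (0.0, 0.5), 0.50, 40.0,
                      "alpha",
                      (("AOB", "Novel", "stimulus"), ("VGNG", "NoGo", "stimulus"))),
        ComponentSpec("P300", +1, 400.0, 12.0, 6.0, 1.2, (0.0, -0.5), 0.60, 110.0,
                      "delta",
                      (("AOB", "Target", "stimulus"), ("AOB", "Novel", "stimulus"),
                       ("VGNG", "Go", "stimulus"), ("VGNG", "NoGo", "stimulus"))),
        # motor preparation over the left motor cortex (right-hand response)
        ComponentSpec("P-200", +1, -200.0, 10.0, 4.0, 0.9, (-0.45, 0.0), 0.50,
                      35.0, "alpha", (("VGNG", "Go", "response"),)),
    )


def default_effects() -> tuple[GroupEffect, ...]:
    """Five patient-vs-control contrasts: higher No-Go P50 amplitude, slower
    Novel N100, lower Frequent P200 amplitude, and noisier topography (hence
    lower topographic similarity) for Novel P200 and response-locked P-200."""
    return (
        GroupEffect("P50", ("VGNG", "NoGo", "stimulus"), "amplitude", +1.2),
        GroupEffect("N100", ("AOB", "Novel", "stimulus"), "latency", +16.0),
        GroupEffect("P200", ("AOB", "Frequent", "stimulus"), "amplitude", -1.2),
        GroupEffect("P200", ("AOB", "Novel", "stimulus"), "topographic_jitter", 0.50),
        GroupEffect("P-200", ("VGNG", "Go", "response"), "topographic_jitter", 0.50),
    )


@dataclass(frozen=True)
class CohortDesign:
    """Task design + generator dials. Defaults are the study conditions."""

    n_trials_aob: int = 400
    n_trials_vgng: int = 400
    aob_proportions: tuple[float, float, float] = (0.8, 0.1, 0.1)  # Freq/Target/Novel
    vgng_go_proportion: float = 0.8
    components: tuple[ComponentSpec, ...] = field(default_factory=default_components)
    effects: tuple[GroupEffect, ...] = field(default_factory=default_effects)
    noise_sd: float = 6.0  # microvolts, white, per sample
    topo_subject_sd: float = 0.05  # between-subject scalp-center scatter
    mastoid_gain: float = 0.05  # component signal leaking into mastoids
    #: scales the patient-vs-control behavioral accuracy gap; 0 makes task
    #: behavior (and hence correct-trial counts) exchangeable across groups,
    #: which the zero-effect null design requires
    behavior_group_gap: float = 1.0
    male_proportion: dict[str, float] = field(
        default_factory=lambda: {"HC": 0.5, "ESPD": 0.84, "establishedPD": 0.75}
    )
    sex_rounding: str = "fixed"  # 'fixed' -> exact per-group male counts
    severity_coupling: float = 20.0  # mUPDRS points per unit severity
    mupdrs_noise_sd: float = 6.0

    def trial_counts(self) -> dict[ConditionKey, int]:
        p_f, p_t, p_n = self.aob_proportions
        n_f = int(round(self.n_trials_aob * p_f))
        n_t = int(round(self.n_trials_aob * p_t))
        n_go = int(round(self.n_trials_vgng * self.vgng_go_proportion))
        return {
            ("AOB", "Frequent", "stimulus"): n_f,
            ("AOB", "Target", "stimulus"): n_t,
            ("AOB", "Novel", "stimulus"): self.n_trials_aob - n_f - n_t,
            ("VGNG", "Go", "stimulus"): n_go,
            ("VGNG", "NoGo", "stimulus"): self.n_trials_vgng - n_go,
        }

    def scaled(self, factor: float) -> "CohortDesign":
        """Same design at reduced trial counts (proportions preserved)."""
        return replace(
            self,
            n_trials_aob=max(20, int(round(self.n_trials_aob * factor))),
            n_trials_vgng=max(20, int(round(self.n_trials_vgng * factor))),
        )


# Behavioral accuracy/RT parameters per group kind (healthy vs patient);
# values follow the reported task-performance table (group differences in
# accuracy, none in RT).
_BEHAVIOR = {
    "go_accuracy": {"HC": 0.95, "PD": 0.92},
    "nogo_commission": {"HC": 0.16, "PD": 0.21},
    "target_hit": {"HC": 0.97, "PD": 0.965},
    "oddball_commission": {"HC": 0.006, "PD": 0.003},
    "go_rt_median": 420.0,
    "target_rt_median": 490.0,
    "rt_sigma": 0.21,  # lognormal shape
}


def _group_prob(table: dict[str, float], group: str, gap: float) -> float:
    """Patient probability interpolated toward the control value by `gap`."""
    if group == "HC":
        return table["HC"]
    return table["HC"] + gap * (table["PD"] - table["HC"])


def _behavior_for(key: ConditionKey, group: str, n: int,
                  rng: np.random.Generator, gap: float = 1.0):
    """Per-trial correctness and RT for one condition."""
    task, cond, _ = key
    rt = np.full(n, np.nan)
    if (task, cond) in RESPONSE_REQUIRED:
        p = _group_prob(_BEHAVIOR["go_accuracy"] if cond == "Go"
                        else _BEHAVIOR["target_hit"], group, gap)
        correct = rng.random(n) < p
        med = (_BEHAVIOR["go_rt_median"] if cond == "Go"
               else _BEHAVIOR["target_rt_median"])
        rt[correct] = med * np.exp(rng.normal(0.0, _BEHAVIOR["rt_sigma"],
                                              int(correct.sum())))
    else:
        p_resp = _group_prob(_BEHAVIOR["nogo_commission"] if cond == "NoGo"
                             else _BEHAVIOR["oddball_commission"], group, gap)
        responded = rng.random(n) < p_resp
        correct = ~responded
        rt[responded] = 450.0 * np.exp(rng.normal(0.0, 0.3, int(responded.sum())))
    return correct, rt


def _effects_for(effects, component: str, key: ConditionKey):
    return [e for e in effects if e.component == component and e.condition == key]


def simulate_subject_epochs(
    profile: SubjectRecord,
    components: tuple[ComponentSpec, ...] | None = None,
    effects: tuple[GroupEffect, ...] | None = None,
    noise_sd: float | None = None,
    seed: int | np.random.SeedSequence = 0,
    design: CohortDesign | None = None,
    montage: Montage | None = None,
) -> list[EpochSet]:
    """Simulate the six epoch sets (one per task/condition/lock) of one subject.

    `seed` fully determines the output: the same seed yields bit-identical
    epochs. Group effects are applied scaled by ``profile.severity`` (zero for
    healthy controls, so effects never touch them).
    """
    design = design or CohortDesign()
    components = design.components if components is None else components
    effects = design.effects if effects is None else effects
    noise_sd = design.noise_sd if noise_sd is None else noise_sd
    montage = montage or build_montage()

    rng = np.random.default_rng(seed)
    pos = montage.positions()  # (n_ch, 2)
    ch_gain = np.where(montage.scalp_mask, 1.0, design.mastoid_gain)
    counts = design.trial_counts()

    # Per-subject component parameters, drawn once so a component keeps a
    # coherent identity across the conditions it appears in.
    subj_params = {}
    for comp in components:
        subj_params[comp.label] = {
            "latency": rng.normal(comp.latency_mean, comp.latency_sd),
            "amplitude": max(0.2, rng.normal(comp.amplitude_mean, comp.amplitude_sd)),
            "center": (np.asarray(comp.topo_center)
                       + rng.normal(0.0, design.topo_subject_sd, 2)),
        }

    sev = profile.severity
    out: list[EpochSet] = []
    for key in CONDITIONS:
        task, cond, lock = key
        win = WINDOWS[(task, lock)]
        t = win.times()  # ms
        if lock == "response":
            # response-locked Go: one epoch per correct Go response
            go = next(e for e in out
                      if e.task == "VGNG" and e.condition == "Go"
                      and e.lock == "stimulus")
            n = int(go.correct.sum())
            correct = np.ones(n, dtype=bool)
            rt = np.sort(go.rt[go.correct & ~np.isnan(go.rt)])
        else:
            n = counts[key]
            correct, rt = _behavior_for(key, profile.group, n, rng,
                                        design.behavior_group_gap)

        data = np.zeros((n, montage.n_channels, win.n_samples), dtype=np.float32)
        for comp in components:
            if key not in comp.conditions:
                continue
            base = subj_params[comp.label]
            lat = base["latency"]
            amp = base["amplitude"]
            center = base["center"]
            jitter_sd = 0.0
            for eff in _effects_for(effects, comp.label, key):
                if eff.attribute == "latency":
                    lat = lat + eff.delta * sev
                elif eff.attribute == "amplitude":
                    amp = max(0.0, amp + eff.delta * sev)
                else:
                    jitter_sd = jitter_sd + eff.delta * sev
            fc = CARRIER_HZ[comp.carrier_band]
            envelope = (np.exp(-0.5 * ((t - lat) / comp.temporal_width) ** 2)
                        * np.cos(2e-3 * np.pi * fc * (t - lat)))  # (n_t,)
            if jitter_sd > 0:
                centers = center + rng.normal(0.0, jitter_sd, (n, 2))
                d2 = ((pos[None, :, :] - centers[:, None, :]) ** 2).sum(-1)
                spatial = np.exp(-0.5 * d2 / comp.spatial_width ** 2) * ch_gain
                data += (comp.polarity * amp
                         * spatial[:, :, None] * envelope[None, None, :]
                         ).astype(np.float32)
            else:
                d2 = ((pos - center) ** 2).sum(-1)
                spatial = np.exp(-0.5 * d2 / comp.spatial_width ** 2) * ch_gain
                data += (comp.polarity * amp
                         * np.outer(spatial, envelope)[None, :, :]
                         ).astype(np.float32)
        if noise_sd > 0:
            data += noise_sd * rng.standard_normal(data.shape, dtype=np.float32)
        out.append(EpochSet(subject_id=profile.id, task=task, condition=cond,
                            lock=lock, data=data, correct=correct, rt=rt))
    return out


def _draw_sexes(n: int, p_male: float, mode: str, rng: np.random.Generator):
    if mode == "fixed":
        n_male = int(round(n * p_male))
        sexes = np.array(["M"] * n_male + ["F"] * (n - n_male))
        rng.shuffle(sexes)
        return sexes
    return np.where(rng.random(n) < p_male, "M", "F")


def _make_record(i: int, group: str, design: CohortDesign,
                 sex: str, rng: np.random.Generator) -> SubjectRecord:
    age_mu, age_sd = {"HC": (64.4, 6.2), "ESPD": (63.7, 7.8),
                      "establishedPD": (66.0, 7.0)}[group]
    age = float(np.clip(np.round(rng.normal(age_mu, age_sd), 1), 40.0, 80.0))
    if group == "HC":
        return SubjectRecord(f"HC{i:03d}", group, sex, age)
    sev_mu, sev_sd = (1.0, 0.3) if group == "ESPD" else (1.35, 0.45)
    sev = float(max(0.2, rng.normal(sev_mu, sev_sd)))
    mupdrs = int(np.clip(round(20.0 + design.severity_coupling * (sev - 1.0)
                               + rng.normal(0.0, design.mupdrs_noise_sd)), 1, 70))
    ledd_med = 240.0 if group == "ESPD" else 600.0
    ledd = float(np.round(ledd_med * np.exp(rng.normal(0.0, 0.45)), 1))
    prefix = "PD" if group == "ESPD" else "EPD"
    return SubjectRecord(f"{prefix}{i:03d}", group, sex, age,
                         mupdrs=mupdrs, ledd=ledd, severity=sev)


def simulate_cohort_records(
    n_hc: int, n_espd: int, n_established: int,
    design: CohortDesign | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> list[SubjectRecord]:
    """Draw the subject metadata table (no epochs)."""
    design = design or CohortDesign()
    rng = np.random.default_rng(
        seed if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed).spawn(1)[0])
    records = []
    for group, n in (("HC", n_hc), ("ESPD", n_espd),
                     ("establishedPD", n_established)):
        if n < 0:
            raise ValueError("cohort sizes must be non-negative")
        sexes = _draw_sexes(n, design.male_proportion[group],
                            design.sex_rounding, rng)
        for i in range(n):
            records.append(_make_record(i, group, design, str(sexes[i]), rng))
    return records


def iter_cohort(
    n_hc: int, n_espd: int, n_established: int,
    design: CohortDesign | None = None,
    seed: int = 0,
    montage: Montage | None = None,
):
    """Yield (SubjectRecord, list[EpochSet]) one subject at a time.

    Streaming access: epochs for a full-design subject are ~100 MB, so the
    pipeline consumes each subject's epochs and discards them before the next.
    """
    design = design or CohortDesign()
    montage = montage or build_montage()
    root = np.random.SeedSequence(seed)
    rec_seed, *subj_seeds = root.spawn(1 + n_hc + n_espd + n_established)
    records = simulate_cohort_records(n_hc, n_espd, n_established, design,
                                      rec_seed)
    for record, sseq in zip(records, subj_seeds):
        yield record, simulate_subject_epochs(
            record, design=design, seed=sseq, montage=montage)


def simulate_cohort(
    n_hc: int, n_espd: int, n_established: int = 0,
    design: CohortDesign | None = None,
    seed: int = 0,
    montage: Montage | None = None,
) -> tuple[list[SubjectRecord], dict[str, list[EpochSet]]]:
    """Materialize a whole cohort in memory (use `iter_cohort` at full scale)."""
    records, epochs = [], {}
    for record, sets in iter_cohort(n_hc, n_espd, n_established, design, seed,
                                    montage):
        records.append(record)
        epochs[record.id] = sets
    return records, epochs


def summarize_behavior(epochs: EpochSet) -> dict[str, float]:
    """Behavior summary: median/SD of correct RTs, accuracy, omission, commission.

    Omission applies to response-required conditions (Go, Target); commission
    to response-forbidden ones (No-Go, Frequent, Novel); the inapplicable one
    is NaN.
    """
    if epochs.n_trials == 0:
        raise ValueError("cannot summarize an empty epoch set")
    required = (epochs.task, epochs.condition) in RESPONSE_REQUIRED
    responded = ~np.isnan(epochs.rt)
    correct_rts = epochs.rt[epochs.correct & responded]
    accuracy = 100.0 * epochs.correct.mean()
    omission = 100.0 * (~responded).mean() if required else float("nan")
    commission = 100.0 * responded.mean() if not required else float("nan")
    return {
        "median_rt_ms": float(np.median(correct_rts)) if correct_rts.size else float("nan"),
        "rt_sd_ms": float(np.std(correct_rts, ddof=1)) if correct_rts.size > 1 else float("nan"),
        "accuracy_pct": float(accuracy),
        "omission_pct": float(omission),
        "commission_pct": float(commission),
    }
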