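"""Spatiotemporal ERP parcels (STEPs): extraction, group clustering, matching,
topographic similarity and the trial-to-trial ERP variability statistic.

A STEP is a local spatiotemporal extremum of a band-filtered ERP, described
by its amplitude, latency, scalp location (left-right and posterior-anterior,
each on a [-1, 1] scale) and a surrounding spatiotemporal patch. Subject
STEPs are clustered across a reference group; clusters common to at least
70% of the group become group STEPs whose mean patch serves as a template.
Individual subjects are then matched against the templates and scored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from numba import njit
from scipy import signal
from scipy.cluster.hierarchy import fcluster, linkage

from .containers import ERP, EpochSet
from .montage import Montage
from .processing import BANDS, BandDef, bandpass_filter

logger = logging.getLogger(__name__)

PATCH_HALF_MS = 100.0  # patch extends +-100 ms around the peak

#: Distance normalization for clustering and matching: 50 ms of latency
#: difference counts as much as 0.3 montage units of spatial difference.
TIME_SCALE_MS = 50.0
SPACE_SCALE = 0.3


@dataclass(frozen=True)
class Step:
    """One subject-level spatiotemporal parcel."""

    subject_id: str
    band: str
    task: str
    condition: str
    lock: str
    peak_time: float  # ms from lock event
    peak_channel: str
    amplitude: float  # signed, microvolts
    lr: float
    pa: float
    polarity: int
    patch: np.ndarray  # (n_scalp_channels, n_patch_samples)

    @property
    def condition_key(self) -> tuple[str, str, str]:
        return (self.task, self.condition, self.lock)


@dataclass(frozen=True)
class GroupStep:
    """A clustered group template: the mean of its member STEPs."""

    id: str
    band: str
    task: str
    condition: str
    lock: str
    polarity: int
    template_time: float
    template_lr: float
    template_pa: float
    template_patch: np.ndarray
    member_fraction: float
    template_amplitude: float = 0.0  # mean member peak amplitude, signed
    canonical_label: str = ""

    @property
    def condition_key(self) -> tuple[str, str, str]:
        return (self.task, self.condition, self.lock)

    @property
    def label(self) -> str:
        return self.canonical_label or self.id


def _extract_patch(data: np.ndarray, t_idx: int, half: int) -> np.ndarray:
    """Channel x time patch centered on t_idx, zero-padded at window edges."""
    n_ch, n_t = data.shape
    patch = np.zeros((n_ch, 2 * half + 1))
    lo, hi = t_idx - half, t_idx + half + 1
    src_lo, src_hi = max(lo, 0), min(hi, n_t)
    patch[:, src_lo - lo:src_hi - lo] = data[:, src_lo:src_hi]
    return patch


def extract_steps(
    erp: ERP,
    montage: Montage,
    min_prominence: float = 0.5,
    suppress_time_ms: float = 60.0,
    suppress_space: float = 1.2,
) -> list[Step]:
    """Detect local spatiotemporal extrema (both polarities) of a band ERP.

    Per-channel temporal peaks with prominence >= `min_prominence` are
    candidates; non-maximum suppression then keeps, among same-polarity
    candidates close in both time and montage distance, only the one with the
    largest absolute amplitude (ties broken by earlier latency, then by the
    more posterior channel). Mastoid channels are excluded.
    """
    scalp = np.flatnonzero(montage.scalp_mask)
    data = erp.data[scalp]
    times = erp.times()
    pos = montage.positions()[scalp]
    half = int(round(PATCH_HALF_MS * erp.sample_rate / 1000.0))

    # one find_peaks call per polarity over all channels: channels are
    # concatenated with single huge separator samples, which act as higher
    # neighboring peaks, so every prominence base stays within its channel —
    # identical to calling find_peaks per channel
    n_rows, n_t = data.shape
    stacked = np.full((n_rows, n_t + 1), 1e30)
    cands: list[tuple[int, int, float, int]] = []  # (scalp_row, t_idx, amp, pol)
    for pol in (+1, -1):
        stacked[:, :n_t] = pol * data
        flat = stacked.ravel()[:-1]
        peaks, _ = signal.find_peaks(flat, prominence=min_prominence)
        rows_p, t_p = np.divmod(peaks, n_t + 1)
        keep = t_p < n_t  # drop the separator spikes themselves
        for row, t_idx in zip(rows_p[keep], t_p[keep]):
            cands.append((int(row), int(t_idx), float(data[row, t_idx]), pol))

    if not cands:
        return []
    # strongest first; deterministic tie-breaks: earlier latency, more posterior
    rows = np.array([c[0] for c in cands], dtype=np.int64)
    t_arr = np.array([c[1] for c in cands], dtype=np.float64)
    amps = np.array([c[2] for c in cands])
    pols = np.array([c[3] for c in cands], dtype=np.int64)
    order = np.lexsort((pos[rows, 1], t_arr, -np.abs(amps)))
    dt_max = suppress_time_ms * erp.sample_rate / 1000.0
    keep = _greedy_nms(order, rows, t_arr, pols, np.ascontiguousarray(pos),
                       dt_max, suppress_space ** 2)
    accepted = [cands[i] for i in order[keep]]

    accepted.sort(key=lambda c: (c[1], c[0]))
    steps = []
    for row, t_idx, amp, pol in accepted:
        steps.append(Step(
            subject_id=erp.subject_id, band=erp.band, task=erp.task,
            condition=erp.condition, lock=erp.lock,
            peak_time=float(times[t_idx]),
            peak_channel=montage.channel_names[scalp[row]],
            amplitude=amp, lr=float(pos[row, 0]), pa=float(pos[row, 1]),
            polarity=pol, patch=_extract_patch(data, t_idx, half),
        ))
    return steps


@njit(cache=False)
def _greedy_nms(order, rows, t_arr, pols, pos, dt_max, space2):
    """Sequential non-maximum suppression over amplitude-ordered candidates."""
    n = len(order)
    keep = np.zeros(n, dtype=np.bool_)
    acc = np.empty((n, 4))  # t, x, y, pol
    n_acc = 0
    for k in range(n):
        i = order[k]
        ti = t_arr[i]
        x, y = pos[rows[i], 0], pos[rows[i], 1]
        p = pols[i]
        ok = True
        for j in range(n_acc):
            if acc[j, 3] == p and abs(acc[j, 0] - ti) <= dt_max and \
                    (acc[j, 1] - x) ** 2 + (acc[j, 2] - y) ** 2 <= space2:
                ok = False
                break
        if ok:
            keep[k] = True
            acc[n_acc, 0] = ti
            acc[n_acc, 1] = x
            acc[n_acc, 2] = y
            acc[n_acc, 3] = p
            n_acc += 1
    return keep


def _step_coords(step: Step) -> np.ndarray:
    return np.array([step.peak_time / TIME_SCALE_MS,
                     step.lr / SPACE_SCALE, step.pa / SPACE_SCALE])


def cluster_group_steps(
    steps_by_subject: dict[str, list[Step]],
    min_fraction: float = 0.7,
    cluster_cutoff: float = 1.5,
) -> list[GroupStep]:
    """Cluster subject STEPs into group templates.

    STEPs compatible in (band, task, condition, lock, polarity) are
    agglomeratively clustered (average linkage) in normalized
    (time, lr, pa) space; a cluster is retained iff the fraction of distinct
    subjects contributing is >= `min_fraction`, keeping at most one STEP per
    subject (the one closest to the cluster mean). Templates are member means.
    """
    n_subjects = len(steps_by_subject)
    if n_subjects < 2:
        raise ValueError("group clustering requires at least 2 subjects")

    by_kind: dict[tuple, list[tuple[str, Step]]] = {}
    for sid, steps in steps_by_subject.items():
        for step in steps:
            kind = (step.band, step.task, step.condition, step.lock, step.polarity)
            by_kind.setdefault(kind, []).append((sid, step))

    group_steps: list[GroupStep] = []
    for kind in sorted(by_kind):
        members = by_kind[kind]
        coords = np.array([_step_coords(s) for _, s in members])
        if len(members) == 1:
            assignments = np.array([1])
        else:
            z = linkage(coords, method="average")
            assignments = fcluster(z, t=cluster_cutoff, criterion="distance")
        for cid in np.unique(assignments):
            idx = np.flatnonzero(assignments == cid)
            # one member per subject: keep the STEP closest to the cluster mean
            center = coords[idx].mean(axis=0)
            best: dict[str, int] = {}
            for i in idx:
                sid = members[i][0]
                d = float(np.linalg.norm(coords[i] - center))
                if sid not in best or d < float(
                        np.linalg.norm(coords[best[sid]] - center)):
                    best[sid] = i
            chosen = sorted(best.values())
            fraction = len(chosen) / n_subjects
            if fraction < min_fraction:
                continue
            sel = [members[i][1] for i in chosen]
            band, task, cond, lock, pol = kind
            t0 = float(np.mean([s.peak_time for s in sel]))
            group_steps.append(GroupStep(
                id="", band=band, task=task, condition=cond, lock=lock,
                polarity=pol, template_time=t0,
                template_lr=float(np.mean([s.lr for s in sel])),
                template_pa=float(np.mean([s.pa for s in sel])),
                template_patch=np.mean([s.patch for s in sel], axis=0),
                member_fraction=fraction,
                template_amplitude=float(np.mean([s.amplitude for s in sel])),
            ))

    group_steps.sort(key=lambda g: (g.task, g.condition, g.lock, g.band,
                                    g.template_time))
    return [replace(g, id=f"gs{i:03d}") for i, g in enumerate(group_steps)]


def match_subject_steps(
    subject_steps: list[Step],
    group_steps: list[GroupStep],
    max_time_gap: float = 80.0,
    max_space_gap: float = 0.6,
) -> dict[str, Step | None]:
    """One-to-one matching of subject STEPs to group templates.

    Candidate pairs must agree on (band, task, condition, lock, polarity) and
    lie within the time/space gates; assignment is greedy by ascending
    normalized distance, so each subject STEP serves at most one template.
    Templates with no admissible STEP map to None (missing, never forced).
    """
    by_kind: dict[tuple, list[int]] = {}
    for si, step in enumerate(subject_steps):
        by_kind.setdefault((step.band, step.condition_key, step.polarity),
                           []).append(si)
    pairs = []
    for gi, gs in enumerate(group_steps):
        idx = by_kind.get((gs.band, gs.condition_key, gs.polarity))
        if not idx:
            continue
        t = np.array([subject_steps[si].peak_time for si in idx])
        lr = np.array([subject_steps[si].lr for si in idx])
        pa = np.array([subject_steps[si].pa for si in idx])
        dt = t - gs.template_time
        dlr = lr - gs.template_lr
        dpa = pa - gs.template_pa
        ok = (np.abs(dt) <= max_time_gap) \
            & (np.hypot(dlr, dpa) <= max_space_gap)
        dist = np.sqrt((dt / TIME_SCALE_MS) ** 2 + (dlr / SPACE_SCALE) ** 2
                       + (dpa / SPACE_SCALE) ** 2)
        pairs.extend((float(dist[j]), gi, idx[j])
                     for j in np.flatnonzero(ok))
    pairs.sort()
    matches: dict[str, Step | None] = {gs.id: None for gs in group_steps}
    used_steps: set[int] = set()
    matched_groups: set[int] = set()
    for _d, gi, si in pairs:
        if gi in matched_groups or si in used_steps:
            continue
        matches[group_steps[gi].id] = subject_steps[si]
        matched_groups.add(gi)
        used_steps.add(si)
    return matches


def topographic_similarity(
    step: Step, group_step: GroupStep, montage: Montage
) -> float | None:
    """Pearson correlation of the subject patch with the template patch after
    aligning peaks in time and space.

    Both patches are already centered on their own peak samples, which aligns
    time. Spatial alignment translates the subject patch by the peak-location
    offset: each template channel reads the subject channel nearest to its own
    position shifted by (subject peak - template peak). Returns None (missing)
    for a zero-variance patch.
    """
    pos = montage.positions()[montage.scalp_mask]
    offset = np.array([step.lr - group_step.template_lr,
                       step.pa - group_step.template_pa])
    # template channel at position p reads the subject channel nearest to
    # p + (subject peak - template peak)
    shifted = pos + offset[None, :]
    nearest = np.argmin(
        ((pos[None, :, :] - shifted[:, None, :]) ** 2).sum(-1), axis=1)
    aligned = step.patch[nearest]
    a = aligned.ravel()
    b = group_step.template_patch.ravel()
    if np.std(a) == 0 or np.std(b) == 0:
        logger.warning("topographic similarity undefined for constant patch")
        return None
    return float(np.clip(np.corrcoef(a, b)[0, 1], -1.0, 1.0))


def erp_variability(
    epochs: EpochSet,
    regions: dict[str, list[str]],
    montage: Montage,
    band: BandDef | None = BANDS["broadband"],
) -> dict[str, float]:
    """Across-trial ERP variability score per scalp region (microvolts).

    Per electrode, the across-trial standard error of the (broadband-filtered)
    single-trial waveforms at each time point, averaged over the epoch; the
    region score is the mean over the region's electrodes. Only correct trials
    are used. `band=None` skips filtering (raw-trial variability).
    """
    mask = epochs.correct
    n = int(mask.sum())
    if n < 2:
        raise ValueError("ERP variability requires at least 2 correct trials")
    data = np.asarray(epochs.data[mask], dtype=float)
    if band is not None:
        data = bandpass_filter(data, band, epochs.sample_rate, order=2)
    se = data.std(axis=0, ddof=1) / np.sqrt(n)  # (n_channels, n_times)
    per_channel = se.mean(axis=1)
    return {
        region: float(np.mean([per_channel[montage.index(ch)] for ch in chans]))
        for region, chans in regions.items()
    }


#: Canonical component label table: (label, polarity, window lo..hi ms, lock).
#: Windows are half-open [lo, hi) and may not overlap within a
#: (polarity, lock) pair.
DEFAULT_COMPONENT_WINDOWS: tuple[tuple[str, int, float, float, str], ...] = (
    ("P50", +1, 30.0, 80.0, "stimulus"),
    ("N100", -1, 80.0, 150.0, "stimulus"),
    ("P200", +1, 150.0, 275.0, "stimulus"),
    ("N2", -1, 200.0, 350.0, "stimulus"),
    ("P300", +1, 275.0, 600.0, "stimulus"),
    ("P-200", +1, -250.0, -150.0, "response"),
)


def _validate_windows(table) -> None:
    by_key: dict[tuple[int, str], list[tuple[float, float, str]]] = {}
    for label, pol, lo, hi, lock in table:
        if not lo < hi:
            raise ValueError(f"label window {label}: lo must be < hi")
        by_key.setdefault((pol, lock), []).append((lo, hi, label))
    for windows in by_key.values():
        windows.sort()
        for (lo1, hi1, l1), (lo2, hi2, l2) in zip(windows, windows[1:]):
            if lo2 < hi1:
                raise ValueError(
                    f"component label windows {l1!r} and {l2!r} overlap")


def assign_component_labels(
    group_steps: list[GroupStep],
    table: tuple[tuple[str, int, float, float, str], ...] = DEFAULT_COMPONENT_WINDOWS,
) -> list[GroupStep]:
    """Attach canonical component names by (polarity, latency window, lock).

    A template whose latency falls in no window keeps its systematic id.
    When several templates of the same (band, condition) fall in one label
    window, the plain label goes to the one with the largest absolute
    template amplitude — the conventional reading of "the" P200 etc. of a
    band ERP — and the rest are disambiguated by descending amplitude:
    P200, P200_2, ...
    """
    _validate_windows(table)
    candidates: dict[tuple, list[int]] = {}
    names = [""] * len(group_steps)
    for i, gs in enumerate(group_steps):
        for label, pol, lo, hi, lock in table:
            if gs.polarity == pol and gs.lock == lock and \
                    lo <= gs.template_time < hi:
                candidates.setdefault((gs.band, gs.condition_key, label),
                                      []).append(i)
                break
    for (_band, _key, label), idx in candidates.items():
        idx.sort(key=lambda i: (-abs(group_steps[i].template_amplitude),
                                group_steps[i].template_time))
        for rank, i in enumerate(idx):
            names[i] = label if rank == 0 else f"{label}_{rank + 1}"
    return [replace(gs, canonical_label=names[i])
            for i, gs in enumerate(group_steps)]
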