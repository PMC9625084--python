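"""Link per-frame detections into trajectories and analyze trophic events.

Frame-to-frame linking solves the assignment problem optimally per frame
pair (particle counts are small), with a cost that combines 3D distance
(axial term down-weighted, since z estimates are noisier than lateral ones)
and relative dry-mass change — the mass estimate is what keeps identities
straight when cells cross.  Tracks tolerate short detection gaps.

On top of the tracks sit the two mass-budget analyses: feeding events
(a predator-prey contact where the prey track terminates and the predator's
dry mass steps up by the prey's mass) and division events (one track ends,
two begin, and the daughters' dry masses should sum to the parent's).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import pearsonr

from .detect import Detection, crop_track_sequences
from .wacnet import MassSeries, predict_mass_radius

logger = logging.getLogger(__name__)

__all__ = [
    "Track",
    "LinkParams",
    "FeedingParams",
    "DivisionParams",
    "FeedingEvent",
    "DivisionEvent",
    "link_tracks",
    "mass_time_series",
    "detect_feeding_events",
    "detect_division_events",
    "regress_event_pairs",
]

_GATE = 1e9  # cost placeholder for disallowed assignments


@dataclass
class Track:
    """One linked identity: detections over (possibly gappy) frames."""

    id: int
    detections: list[Detection] = field(default_factory=list)
    mass_series: np.ndarray | None = None  # refined masses, aligned to mass_frames
    radius_series: np.ndarray | None = None
    mass_frames: np.ndarray | None = None
    window: int | None = None

    @property
    def frames(self) -> np.ndarray:
        return np.array([d.frame_index for d in self.detections])

    @property
    def birth(self) -> int:
        return self.detections[0].frame_index

    @property
    def death(self) -> int:
        return self.detections[-1].frame_index

    def positions_um(self, pitch: float) -> np.ndarray:
        return np.array(
            [[d.x_px * pitch, d.y_px * pitch, d.z_um] for d in self.detections]
        )

    def position_at(self, frame: int, pitch: float) -> np.ndarray | None:
        """(x, y, z) µm at a frame, linearly interpolated inside gaps."""
        frames = self.frames
        if frame < frames[0] or frame > frames[-1]:
            return None
        pos = self.positions_um(pitch)
        return np.array(
            [np.interp(frame, frames, pos[:, k]) for k in range(3)]
        )

    def mass_at(self, frame: int) -> float | None:
        if self.mass_frames is None:
            return None
        if frame < self.mass_frames[0] or frame > self.mass_frames[-1]:
            return None
        return float(np.interp(frame, self.mass_frames, self.mass_series))


@dataclass(frozen=True)
class LinkParams:
    """Linking cost: sqrt(Δx² + Δy² + (w_z Δz)²) + λ_m |Δm|/m, gated at
    max_step_um per elapsed frame; gaps up to max_gap frames are bridged."""

    max_step_um: float = 50.0
    w_z: float = 0.3
    lambda_mass_um: float = 10.0  # µm of cost per unit relative mass change
    max_gap: int = 3


def _link_cost(
    prev: Detection, new: Detection, pitch: float, p: LinkParams
) -> tuple[float, float]:
    """(gating distance µm, total cost) between consecutive detections."""
    dx = (new.x_px - prev.x_px) * pitch
    dy = (new.y_px - prev.y_px) * pitch
    dz = (new.z_um - prev.z_um) * p.w_z
    dist = float(np.sqrt(dx * dx + dy * dy + dz * dz))
    m_ref = max(abs(prev.mass_pg), 1e-9)
    mass_cost = p.lambda_mass_um * abs(new.mass_pg - prev.mass_pg) / m_ref
    return dist, dist + mass_cost


def link_tracks(
    per_frame_detections: list[list[Detection]],
    pitch_um: float,
    params: LinkParams | None = None,
) -> list[Track]:
    """Link detections (list indexed by frame) into tracks.

    Per frame pair the assignment is solved optimally (Hungarian method);
    unassigned detections start new tracks; a track stays linkable while
    its gap is at most ``max_gap`` frames.
    """
    p = params or LinkParams()
    tracks: list[Track] = []
    active: list[Track] = []
    next_id = 0
    for frame, dets in enumerate(per_frame_detections):
        active = [t for t in active if frame - t.death - 1 <= p.max_gap]
        assigned_det: set[int] = set()
        if active and dets:
            cost = np.full((len(active), len(dets)), _GATE)
            for i, tr in enumerate(active):
                prev = tr.detections[-1]
                steps = frame - prev.frame_index
                gate = p.max_step_um * steps
                for j, d in enumerate(dets):
                    dist, c = _link_cost(prev, d, pitch_um, p)
                    if dist <= gate:
                        cost[i, j] = c
            rows, cols = linear_sum_assignment(cost)
            for i, j in zip(rows, cols):
                if cost[i, j] < _GATE:
                    active[i].detections.append(dets[j])
                    assigned_det.add(j)
        for j, d in enumerate(dets):
            if j not in assigned_det:
                tr = Track(id=next_id, detections=[d])
                next_id += 1
                tracks.append(tr)
                active.append(tr)
    return tracks


def mass_time_series(
    track: Track,
    wacnet_model,
    frames: np.ndarray,
    window: int,
    pitch_um: float,
    codec=None,
    dn_dc: float | None = None,
    crop_size: int | None = None,
) -> Track:
    """Annotate a track with a sliding-window refined mass series.

    Crops are re-centered on the track position each frame (interpolated
    inside gaps); estimate i is aligned to the center of its window.
    """
    from .optics import DEFAULT_DN_DC

    if crop_size is None:
        crop_size = getattr(
            getattr(wacnet_model, "config", None), "crop_size", 64
        )
    span = np.arange(track.birth, track.death + 1)
    if len(span) < window:
        raise ValueError(
            f"track {track.id} spans {len(span)} frames < window {window}"
        )
    positions = np.array(
        [track.position_at(f, pitch_um)[:2] / pitch_um for f in span]
    )
    crops, _ = crop_track_sequences(frames[span[0] : span[-1] + 1], positions, crop_size)
    series = predict_mass_radius(
        wacnet_model,
        crops,
        window=window,
        codec=codec,
        dn_dc=DEFAULT_DN_DC if dn_dc is None else dn_dc,
    )
    track.mass_series = series.mass_pg
    track.radius_series = series.radius_um
    track.mass_frames = span[: len(series.mass_pg)] + window // 2
    track.window = window
    return track


# ---------------------------------------------------------------------------
# feeding events
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FeedingParams:
    contact_radius_um: float = 20.0
    w_z: float = 0.3  # axial down-weight in the contact distance
    pre_frames: int = 100
    post_frames: int = 100
    min_frames: int = 10  # usable frames required on each side


@dataclass
class FeedingEvent:
    predator_track: int
    prey_track: int
    contact_interval: tuple[int, int]
    pre_stats: tuple[float, float, int]  # (mean pg, SEM pg, n)
    post_stats: tuple[float, float, int]
    increment_pg: float
    prey_mass_pg: float
    prey_mass_sem_pg: float


def _stats(values: np.ndarray) -> tuple[float, float, int]:
    n = len(values)
    mean = float(np.mean(values))
    sem = float(np.std(values, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return mean, sem, n


def detect_feeding_events(
    tracks: list[Track],
    pitch_um: float,
    params: FeedingParams | None = None,
) -> list[FeedingEvent]:
    """Find predator-prey contacts where the smaller cell's track terminates.

    The predator's dry mass is averaged over up to ``pre_frames`` before
    first contact and ``post_frames`` after last contact (windows truncated,
    never extended, at track boundaries); the increment must exceed twice
    the pooled SEM to count as an event.
    """
    p = params or FeedingParams()
    events: list[FeedingEvent] = []
    annotated = [t for t in tracks if t.mass_frames is not None]
    for i, ta in enumerate(annotated):
        for tb in annotated[i + 1 :]:
            lo = max(ta.birth, tb.birth)
            hi = min(ta.death, tb.death)
            if lo > hi:
                continue
            contact_frames = []
            for f in range(lo, hi + 1):
                pa = ta.position_at(f, pitch_um)
                pb = tb.position_at(f, pitch_um)
                d = pa - pb
                dist = np.sqrt(d[0] ** 2 + d[1] ** 2 + (p.w_z * d[2]) ** 2)
                if dist <= p.contact_radius_um:
                    contact_frames.append(f)
            if not contact_frames:
                continue
            c0, c1 = contact_frames[0], contact_frames[-1]
            ma = np.nanmean(ta.mass_series)
            mb = np.nanmean(tb.mass_series)
            pred, prey = (ta, tb) if ma >= mb else (tb, ta)
            # the prey must disappear during (or right at the end of) contact
            if not (c0 <= prey.death <= c1 + 1):
                continue
            pf = pred.mass_frames
            pre_sel = (pf >= c0 - p.pre_frames) & (pf < c0)
            post_sel = (pf > c1) & (pf <= c1 + p.post_frames)
            if pre_sel.sum() < p.min_frames or post_sel.sum() < p.min_frames:
                continue
            pre = _stats(pred.mass_series[pre_sel])
            post = _stats(pred.mass_series[post_sel])
            increment = post[0] - pre[0]
            pooled_sem = float(np.hypot(pre[1], post[1]))
            if abs(increment) < 2.0 * pooled_sem:
                continue
            prey_sel = (prey.mass_frames >= c0 - p.pre_frames) & (
                prey.mass_frames < c0
            )
            prey_vals = (
                prey.mass_series[prey_sel] if prey_sel.any() else prey.mass_series
            )
            prey_mean, prey_sem, _ = _stats(np.asarray(prey_vals))
            events.append(
                FeedingEvent(
                    predator_track=pred.id,
                    prey_track=prey.id,
                    contact_interval=(c0, c1),
                    pre_stats=pre,
                    post_stats=post,
                    increment_pg=increment,
                    prey_mass_pg=prey_mean,
                    prey_mass_sem_pg=prey_sem,
                )
            )
    return events


def regress_event_pairs(pairs) -> tuple[float, float]:
    """Least-squares slope (with intercept) and Pearson correlation of
    (prey mass, predator increment) pairs."""
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[0] < 2 or pairs.shape[1] != 2:
        raise ValueError("need at least 2 (prey_mass, increment) pairs")
    x, y = pairs[:, 0], pairs[:, 1]
    slope, _ = np.polyfit(x, y, 1)
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        rho = np.nan
    else:
        rho = pearsonr(x, y).statistic
    return float(slope), float(rho)


# ---------------------------------------------------------------------------
# division events
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DivisionParams:
    split_radius_um: float = 30.0
    max_gap: int = 3
    isolation_radius_um: float = 144.0  # 40 px at 3.6 µm pitch
    sem_halfwidth: int = 5  # mass averaged over ±5 frames


@dataclass
class DivisionEvent:
    parent_track: int
    daughter_tracks: tuple[int, int]
    measurement_frames: tuple[int, int, int]  # parent, daughter1, daughter2
    parent_mass: tuple[float, float]  # (mean pg, SEM pg)
    daughter_masses: tuple[tuple[float, float], tuple[float, float]]
    conservation_ratio: float


def _nearest_neighbor_distance(
    track: Track, frame: int, tracks: list[Track], pitch: float
) -> float:
    pos = track.position_at(frame, pitch)
    best = np.inf
    for other in tracks:
        if other.id == track.id:
            continue
        q = other.position_at(frame, pitch)
        if q is None:
            continue
        best = min(best, float(np.hypot(pos[0] - q[0], pos[1] - q[1])))
    return best


def _isolated_mass(
    track: Track,
    tracks: list[Track],
    pitch: float,
    p: DivisionParams,
    search_frames,
) -> tuple[float, float, int] | None:
    """Mass mean ± SEM over ±sem_halfwidth around the first isolation-
    satisfying frame among ``search_frames``."""
    for f in search_frames:
        if track.mass_at(f) is None:
            continue
        if _nearest_neighbor_distance(track, f, tracks, pitch) >= p.isolation_radius_um:
            sel = (track.mass_frames >= f - p.sem_halfwidth) & (
                track.mass_frames <= f + p.sem_halfwidth
            )
            if sel.sum() == 0:
                continue
            mean, sem, _ = _stats(track.mass_series[sel])
            return mean, sem, f
    return None


def detect_division_events(
    tracks: list[Track],
    pitch_um: float,
    params: DivisionParams | None = None,
) -> list[DivisionEvent]:
    """Find track splits (one ends, exactly two begin nearby) and compute
    the mass-conservation ratio (Σ daughters)/parent.

    Masses are measured only at isolation-satisfying frames — the first
    frames where the cell has at least ``isolation_radius_um`` of empty
    space around it — as mean ± SEM over ±``sem_halfwidth`` frames.
    Three-way splits are flagged and skipped.
    """
    p = params or DivisionParams()
    events: list[DivisionEvent] = []
    annotated = [t for t in tracks if t.mass_frames is not None]
    for parent in annotated:
        end_pos = parent.position_at(parent.death, pitch_um)
        candidates = []
        for t in annotated:
            if t.id == parent.id:
                continue
            if not (parent.death < t.birth <= parent.death + 1 + p.max_gap):
                continue
            q = t.position_at(t.birth, pitch_um)
            if np.hypot(q[0] - end_pos[0], q[1] - end_pos[1]) <= p.split_radius_um:
                candidates.append(t)
        if len(candidates) < 2:
            continue
        if len(candidates) > 2:
            logger.warning(
                "track %d: %d-way split at frame %d skipped",
                parent.id,
                len(candidates),
                parent.death,
            )
            continue
        d1, d2 = candidates
        pm = _isolated_mass(
            parent, annotated, pitch_um, p, range(parent.death, parent.birth - 1, -1)
        )
        m1 = _isolated_mass(d1, annotated, pitch_um, p, range(d1.birth, d1.death + 1))
        m2 = _isolated_mass(d2, annotated, pitch_um, p, range(d2.birth, d2.death + 1))
        if pm is None or m1 is None or m2 is None:
            continue
        ratio = (m1[0] + m2[0]) / pm[0]
        events.append(
            DivisionEvent(
                parent_track=parent.id,
                daughter_tracks=(d1.id, d2.id),
                measurement_frames=(pm[2], m1[2], m2[2]),
                parent_mass=(pm[0], pm[1]),
                daughter_masses=((m1[0], m1[1]), (m2[0], m2[1])),
                conservation_ratio=float(ratio),
            )
        )
    return events
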