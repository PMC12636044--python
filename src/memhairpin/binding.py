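"""Protein–membrane contact statistics, binding kinetics and occupancy.

A contact is a (protein heavy atom, membrane heavy atom) pair within a
0.4 nm cutoff, with minimum-image wrapping in x,y (membranes are
z-oriented slabs, so z stays unwrapped).  Binding is operationally
defined as a sustained-contact event: ≥5 contacts maintained for ≥5 ns;
unbinding as <5 contacts for ≥0.5 ns, only after a binding event.  Those
thresholds deliberately ignore transient touches.

Per-residue fractional occupancy is the fraction of frames in which a
residue has at least one membrane contact; replicas are averaged and the
confidence interval comes from a BCa bootstrap over replica values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .io import Trajectory

__all__ = [
    "ContactConfig",
    "ContactSeries",
    "KineticsConfig",
    "StateSeries",
    "OccupancyProfile",
    "count_contacts",
    "count_contacts_bruteforce",
    "contact_series",
    "classify_states",
    "first_binding_cdf",
    "residue_occupancy",
    "bca_bootstrap",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContactConfig:
    """Contact definition: heavy-atom pair cutoff and x,y periodicity."""

    cutoff: float = 0.4  # nm
    pbc_xy: bool = True

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


def _wrapped_coords(coords: np.ndarray, box: np.ndarray | None, pbc_xy: bool,
                    ) -> tuple[np.ndarray, np.ndarray | None]:
    """Shift/wrap coordinates into a KD-tree-compatible periodic box.

    Returns (coords, boxsize) where boxsize is None for the non-periodic
    case.  Only x,y are treated as periodic; z is made non-periodic by
    embedding it in a slot much larger than the z extent.
    """
    if not pbc_xy:
        return coords, None
    if box is None:
        raise ValueError("pbc_xy requires a box")
    out = coords.copy()
    out[:, 0] %= box[0]
    out[:, 1] %= box[1]
    zmin = out[:, 2].min()
    out[:, 2] -= zmin
    z_slot = out[:, 2].max() * 2.0 + 10.0
    return out, np.array([box[0], box[1], z_slot])


def count_contacts(coordinates: np.ndarray, box: np.ndarray | None,
                   protein_idx: np.ndarray, membrane_idx: np.ndarray,
                   residue_of: np.ndarray, residues: np.ndarray,
                   config: ContactConfig = ContactConfig(),
                   ) -> tuple[int, np.ndarray, float]:
    """Count heavy-atom contact pairs in one frame.

    Returns ``(pair_count, residue_contact, min_distance)`` where
    ``residue_contact[r]`` is True iff any atom of ``residues[r]``
    participates in at least one pair.  ``residue_of`` gives the residue
    index of each protein-selection atom.  Pairs at exactly the cutoff
    count (closed boundary).
    """
    protein_idx = np.asarray(protein_idx)
    membrane_idx = np.asarray(membrane_idx)
    if protein_idx.size == 0 or membrane_idx.size == 0:
        raise ValueError("empty atom selection")
    all_coords = np.vstack([coordinates[protein_idx], coordinates[membrane_idx]])
    wrapped, boxsize = _wrapped_coords(all_coords, box, config.pbc_xy)
    n_p = protein_idx.size
    p_coords, m_coords = wrapped[:n_p], wrapped[n_p:]
    tree = cKDTree(m_coords, boxsize=boxsize)
    neighbors = tree.query_ball_point(p_coords, r=config.cutoff)
    pair_count = sum(len(nb) for nb in neighbors)
    atom_in_contact = np.array([len(nb) > 0 for nb in neighbors])
    residue_contact = np.zeros(len(residues), dtype=bool)
    res_pos = {r: i for i, r in enumerate(residues)}
    for atom_res in np.asarray(residue_of)[atom_in_contact]:
        residue_contact[res_pos[atom_res]] = True
    dmin, _ = tree.query(p_coords, k=1)
    return int(pair_count), residue_contact, float(np.min(dmin))


def count_contacts_bruteforce(coordinates: np.ndarray, box: np.ndarray | None,
                              protein_idx: np.ndarray, membrane_idx: np.ndarray,
                              config: ContactConfig = ContactConfig()) -> int:
    """All-pairs O(N·M) contact count; independent check of the tree path."""
    p = coordinates[np.asarray(protein_idx)]
    m = coordinates[np.asarray(membrane_idx)]
    d = p[:, None, :] - m[None, :, :]
    if config.pbc_xy:
        if box is None:
            raise ValueError("pbc_xy requires a box")
        for k in (0, 1):
            d[..., k] -= box[k] * np.round(d[..., k] / box[k])
    dist = np.sqrt((d**2).sum(axis=-1))
    return int(np.sum(dist <= config.cutoff))


@dataclass
class ContactSeries:
    """Per-frame contact statistics for one replica."""

    times: np.ndarray          # ns
    pair_count: np.ndarray     # int per frame
    residue_contact: np.ndarray  # bool (n_frames, n_residues)
    residues: np.ndarray       # residue indices (author numbering)
    min_distance: np.ndarray | None = None
    replica_id: int = 0
    condition: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.pair_count = np.asarray(self.pair_count)
        self.residue_contact = np.asarray(self.residue_contact, dtype=bool)
        if np.any(self.pair_count < 0):
            raise ValueError("contact counts must be ≥ 0")
        if self.residue_contact.shape[0] != self.times.size:
            raise ValueError("residue_contact rows must match frame count")

    @property
    def dt(self) -> float:
        if self.times.size < 2:
            raise ValueError("dt undefined for <2 frames")
        return float(np.median(np.diff(self.times)))


def contact_series(traj: Trajectory, config: ContactConfig = ContactConfig(),
                   ) -> ContactSeries:
    """Evaluate count_contacts on every frame of a trajectory."""
    protein_idx = np.array([a.index for a in traj.atoms
                            if a.group == "protein" and a.is_heavy])
    membrane_idx = np.array([a.index for a in traj.atoms
                             if a.group == "membrane" and a.is_heavy])
    residue_of = np.array([traj.atoms[i].residue_index for i in protein_idx])
    residues = np.unique(residue_of)
    counts = np.zeros(traj.n_frames, dtype=int)
    res_mat = np.zeros((traj.n_frames, residues.size), dtype=bool)
    dmin = np.zeros(traj.n_frames)
    for i, frame in enumerate(traj.frames):
        counts[i], res_mat[i], dmin[i] = count_contacts(
            frame.coordinates, frame.box, protein_idx, membrane_idx,
            residue_of, residues, config)
    return ContactSeries(times=traj.times, pair_count=counts,
                         residue_contact=res_mat, residues=residues,
                         min_distance=dmin, replica_id=traj.replica_id,
                         condition=traj.condition)


@dataclass(frozen=True)
class KineticsConfig:
    """Sustained-contact thresholds for the bound/unbound state machine."""

    min_contacts: int = 5
    bind_dwell: float = 5.0    # ns
    unbind_dwell: float = 0.5  # ns

    def __post_init__(self) -> None:
        if self.min_contacts <= 0 or self.bind_dwell <= 0 or self.unbind_dwell <= 0:
            raise ValueError("all kinetics thresholds must be positive")


@dataclass
class StateSeries:
    """Bound/unbound label per frame plus the event decomposition."""

    times: np.ndarray
    labels: np.ndarray                 # "unbound" / "bound" per frame
    first_binding_time: float | None   # ns, None if never bound
    events: list[tuple[str, float, float]]  # (state, start, end) partition
    replica_id: int = 0
    condition: str = ""

    @property
    def bound_fraction(self) -> float:
        return float(np.mean(self.labels == "bound"))


def classify_states(series: ContactSeries,
                    config: KineticsConfig = KineticsConfig()) -> StateSeries:
    """Apply the sustained-contact binding/unbinding criteria.

    A run of k consecutive frames with ``pair_count ≥ min_contacts`` and
    duration k·dt ≥ bind_dwell switches the state to bound at the run's
    first frame; after that, a run with ``pair_count < min_contacts`` of
    duration ≥ unbind_dwell switches to unbound at its first frame.  The
    trajectory starts unbound and unbinding can only follow a binding
    event.
    """
    dt = series.dt
    counts = series.pair_count
    n = counts.size
    high = counts >= config.min_contacts
    need_bind = int(np.ceil(config.bind_dwell / dt - 1e-12))
    need_unbind = int(np.ceil(config.unbind_dwell / dt - 1e-12))

    labels = np.empty(n, dtype=object)
    state = "unbound"
    first_binding: float | None = None
    i = 0
    while i < n:
        # length of the current homogeneous run
        j = i
        while j < n and high[j] == high[i]:
            j += 1
        run_len = j - i
        if state == "unbound":
            if high[i] and run_len >= need_bind:
                state = "bound"
                if first_binding is None:
                    first_binding = float(series.times[i])
                labels[i:j] = "bound"
            else:
                labels[i:j] = "unbound"
        else:  # bound
            if (not high[i]) and run_len >= need_unbind:
                state = "unbound"
                labels[i:j] = "unbound"
            else:
                labels[i:j] = "bound"
        i = j

    events: list[tuple[str, float, float]] = []
    start = 0
    for i in range(1, n + 1):
        if i == n or labels[i] != labels[start]:
            t_end = series.times[i - 1] + dt if i == n else series.times[i]
            events.append((str(labels[start]), float(series.times[start]),
                           float(t_end)))
            start = i
    return StateSeries(times=series.times, labels=labels.astype(str),
                       first_binding_time=first_binding, events=events,
                       replica_id=series.replica_id, condition=series.condition)


def first_binding_cdf(state_series: list[StateSeries], n_replicas: int,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative count of replicas that have bound by each event time.

    Returns ``(times, counts)`` defining a right-continuous step function
    that plateaus at the number of replicas that ever bind (≤ n_replicas).
    """
    binding_times = sorted(s.first_binding_time for s in state_series
                           if s.first_binding_time is not None)
    if len(binding_times) > n_replicas:
        raise ValueError("more binding events than replicas")
    times = np.asarray(binding_times, dtype=float)
    counts = np.arange(1, times.size + 1, dtype=int)
    return times, counts


@dataclass
class OccupancyProfile:
    """Per-residue membrane-contact probability with bootstrap CIs."""

    residues: np.ndarray
    p_contact: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_replicas: int
    n_resamples: int = 1000
    level: float = 0.95


def residue_occupancy(series_list: list[ContactSeries],
                      n_resamples: int = 1000, level: float = 0.95,
                      seed: int = 0, pooled: bool = False) -> OccupancyProfile:
    """Fractional occupancy per residue, averaged over replicas, with BCa CIs.

    Per replica, a residue's occupancy is (frames with ≥1 contact)/(total
    frames).  With ``pooled=True`` frames are pooled across replicas
    before dividing instead; CIs are bootstrap-over-replica either way.
    """
    if not series_list:
        raise ValueError("need at least one contact series")
    residues = series_list[0].residues
    for s in series_list:
        if s.residue_contact.shape[0] == 0:
            raise ValueError("contact series with zero frames")
        if not np.array_equal(s.residues, residues):
            raise ValueError("all series must share residue indexing")
    per_rep = np.array([s.residue_contact.mean(axis=0) for s in series_list])
    if pooled:
        tot_frames = sum(s.residue_contact.shape[0] for s in series_list)
        p = np.vstack([s.residue_contact.sum(axis=0) for s in series_list]
                      ).sum(axis=0) / tot_frames
    else:
        p = per_rep.mean(axis=0)
    n_rep = len(series_list)
    lo = np.empty(residues.size)
    hi = np.empty(residues.size)
    if n_rep >= 2:
        rng = np.random.default_rng(seed)
        for r in range(residues.size):
            lo[r], hi[r] = bca_bootstrap(per_rep[:, r], n_resamples=n_resamples,
                                         level=level,
                                         seed=int(rng.integers(2**31)))
    else:
        lo[:] = p
        hi[:] = p
    return OccupancyProfile(residues=residues, p_contact=p, ci_low=lo,
                            ci_high=hi, n_replicas=n_rep,
                            n_resamples=n_resamples, level=level)


def bca_bootstrap(values, n_resamples: int = 1000, level: float = 0.95,
                  seed: int = 0, statistic=np.mean) -> tuple[float, float]:
    """Bias-corrected accelerated bootstrap CI of a statistic.

    Wraps the SciPy BCa bootstrap; degenerate inputs (all values equal)
    give a zero-width interval at that value, and an undefined
    acceleration (all jackknife values equal) falls back to the plain
    percentile interval with a logged notice.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least two values to bootstrap")
    if np.allclose(values, values[0]):
        v = float(statistic(values))
        return v, v
    rng = np.random.default_rng(seed)
    try:
        res = stats.bootstrap((values,), statistic, n_resamples=n_resamples,
                              confidence_level=level, method="BCa", rng=rng)
        lo, hi = float(res.confidence_interval.low), float(res.confidence_interval.high)
        if np.isnan(lo) or np.isnan(hi):
            raise ValueError("BCa produced NaN endpoints")
    except ValueError:
        logger.info("BCa acceleration undefined; falling back to percentile CI")
        res = stats.bootstrap((values,), statistic, n_resamples=n_resamples,
                              confidence_level=level, method="percentile",
                              rng=np.random.default_rng(seed))
        lo, hi = float(res.confidence_interval.low), float(res.confidence_interval.high)
    return lo, hi
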