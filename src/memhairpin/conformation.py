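"""Conformational analysis: superposition, essential-dynamics PCA,
Kabsch–Sander helix assignment, Shrake–Rupley SASA and state-conditioned
distribution summaries.

PCA follows essential-dynamics practice: backbone atoms of the analysed
residue span (the mobile C-terminal tail is excluded), frames fitted
iteratively to the running mean structure, covariance of the 3N fitted
coordinates diagonalized.  Helicity is the Kabsch–Sander α class: a
backbone hydrogen bond CO(i)→NH(j) exists when the electrostatic energy
E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol (distances in
Å) is below −0.5 kcal/mol, and a residue is α-helical inside a stretch
supported by two consecutive i→i+4 bonds.  SASA rolls a 0.14 nm probe
over Bondi van-der-Waals spheres using a Fibonacci point lattice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import gaussian_kde

from .io import FragmentSpec, Structure, Trajectory

__all__ = [
    "PCAModel",
    "SSConfig",
    "SASAConfig",
    "SummaryConfig",
    "ConditionalSplit",
    "kabsch_superpose",
    "fit_pca",
    "project_pca",
    "assign_secondary_structure",
    "shrake_rupley_sasa",
    "conditional_distributions",
]


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     weights: np.ndarray | None = None,
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimises the (weighted) RMSD.
    The rotation is always proper: a reflection in the SVD solution is
    corrected by flipping the smallest singular direction.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    if mobile.shape[0] < 3:
        raise ValueError("need at least 3 points")
    w = np.ones(mobile.shape[0]) if weights is None else np.asarray(weights, float)
    w = w / w.sum()
    mc = (w[:, None] * mobile).sum(axis=0)
    rc = (w[:, None] * reference).sum(axis=0)
    x = mobile - mc
    y = reference - rc
    h = (w[:, None] * x).T @ y
    if np.linalg.matrix_rank(h, tol=1e-10) < 2:
        raise ValueError("degenerate (rank-deficient) point configuration")
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = rc - rot @ mc
    aligned = x @ rot.T
    rmsd = float(np.sqrt((w * ((aligned - y) ** 2).sum(axis=1)).sum()))
    return rot, trans, rmsd


# ---------------------------------------------------------------------------
# essential-dynamics PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    """Backbone PCA: mean structure, eigenvectors, eigenvalues (nm²)."""

    atom_indices: np.ndarray      # indices into the trajectory atom table
    mean: np.ndarray              # (n_atoms, 3) fitted mean structure
    eigenvectors: np.ndarray      # (3N, n_modes), columns orthonormal
    eigenvalues: np.ndarray       # nm², descending
    degenerate: bool = False      # True when total variance ≈ 0

    @property
    def variance_fractions(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        if total <= 0:
            return np.zeros_like(self.eigenvalues)
        return self.eigenvalues / total


def _backbone_subset(traj: Trajectory, fragment: FragmentSpec) -> np.ndarray:
    lo, hi = fragment.first_residue, fragment.pca_last_residue
    idx = [a.index for a in traj.atoms
           if a.group == "protein" and a.name in ("N", "CA", "C", "O")
           and lo <= a.residue_index <= hi]
    return np.asarray(idx)


def _fit_frames(coords: np.ndarray, reference: np.ndarray) -> np.ndarray:
    out = np.empty_like(coords)
    for i, frame in enumerate(coords):
        rot, trans, _ = kabsch_superpose(frame, reference)
        out[i] = frame @ rot.T + trans
    return out


def fit_pca(trajectories: list[Trajectory], fragment: FragmentSpec = FragmentSpec(),
            fit_mode: str = "iterative", tol: float = 1e-6,
            max_iter: int = 50) -> PCAModel:
    """Fit backbone PCA on the concatenated, superposed frames.

    ``fit_mode="iterative"`` refines the reference to the running mean
    structure until it moves by less than ``tol`` nm RMSD;
    ``"first_frame"`` is the single-pass alternative.
    """
    idx = _backbone_subset(trajectories[0], fragment)
    if idx.size == 0:
        raise ValueError("no backbone atoms in the analysed residue span")
    frames = np.concatenate([t.coordinates[:, idx, :] for t in trajectories])
    if frames.shape[0] < 2:
        raise ValueError("PCA needs at least two frames")

    reference = frames[0]
    fitted = _fit_frames(frames, reference)
    if fit_mode == "iterative":
        for _ in range(max_iter):
            mean = fitted.mean(axis=0)
            rmsd_change = float(np.sqrt(((mean - reference) ** 2).sum(axis=1).mean()))
            reference = mean
            fitted = _fit_frames(frames, reference)
            if rmsd_change < tol:
                break
    elif fit_mode != "first_frame":
        raise ValueError(f"unknown fit_mode {fit_mode!r}")

    mean = fitted.mean(axis=0)
    flat = fitted.reshape(fitted.shape[0], -1)
    centered = flat - flat.mean(axis=0)
    cov = centered.T @ centered / centered.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # sign convention: make the largest-magnitude component positive
    for k in range(evecs.shape[1]):
        j = np.argmax(np.abs(evecs[:, k]))
        if evecs[j, k] < 0:
            evecs[:, k] = -evecs[:, k]
    degenerate = bool(evals.sum() <= 1e-15)
    return PCAModel(atom_indices=idx, mean=mean, eigenvectors=evecs,
                    eigenvalues=evals, degenerate=degenerate)


def project_pca(traj: Trajectory, model: PCAModel, k: int = 1) -> np.ndarray:
    """Project a trajectory onto principal component ``k`` (1-based), in nm.

    Each frame is superposed on the model mean before centring and
    projecting, so projections are comparable across trajectories.
    """
    if model.degenerate:
        raise ValueError("projection undefined: model has zero variance")
    coords = traj.coordinates[:, model.atom_indices, :]
    if coords.shape[1] != model.mean.shape[0]:
        raise ValueError("trajectory atom subset incompatible with model")
    v = model.eigenvectors[:, k - 1]
    mean_flat = model.mean.reshape(-1)
    out = np.empty(coords.shape[0])
    for i, frame in enumerate(coords):
        rot, trans, _ = kabsch_superpose(frame, model.mean)
        fitted = frame @ rot.T + trans
        out[i] = (fitted.reshape(-1) - mean_flat) @ v
    return out


# ---------------------------------------------------------------------------
# Kabsch–Sander helix assignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SSConfig:
    """Hydrogen-bond energetics and which helix classes count as helical."""

    hbond_constant: float = 0.084 * 332.0  # kcal·Å/mol
    energy_cutoff: float = -0.5            # kcal/mol
    include_310: bool = False
    include_pi: bool = False

    def __post_init__(self) -> None:
        if self.energy_cutoff >= 0:
            raise ValueError("energy cutoff must be negative")


def _residue_table(structure: Structure) -> tuple[list[int], list[dict]]:
    table: dict[int, dict] = {}
    names: dict[int, str] = {}
    for a, xyz in zip(structure.atoms, structure.coordinates):
        table.setdefault(a.residue_index, {})[a.name] = np.asarray(xyz)
        names[a.residue_index] = a.residue_name
    resids = sorted(table)
    rows = []
    for j, r in enumerate(resids):
        d = dict(table[r])
        d["resname"] = names[r]
        # reconstruct the amide H when absent: 1.0 Å from N along prev O→C
        if "H" not in d and j > 0:
            prev = table[resids[j - 1]]
            if "C" in prev and "O" in prev and "N" in d:
                vec = prev["C"] - prev["O"]
                d["H"] = d["N"] + 0.1 * vec / np.linalg.norm(vec)
        rows.append(d)
    return resids, rows


def _hbond_energy(acceptor: dict, donor: dict, config: SSConfig) -> float:
    """Kabsch–Sander CO(acceptor)→NH(donor) energy in kcal/mol."""
    if donor.get("resname") == "PRO" or "H" not in donor:
        return 0.0  # prolines and N-termini never donate
    needed = ("C", "O")
    if any(k not in acceptor for k in needed) or "N" not in donor:
        return 0.0
    # distances in Å (coordinates are nm)
    r_on = np.linalg.norm(acceptor["O"] - donor["N"]) * 10.0
    r_ch = np.linalg.norm(acceptor["C"] - donor["H"]) * 10.0
    r_oh = np.linalg.norm(acceptor["O"] - donor["H"]) * 10.0
    r_cn = np.linalg.norm(acceptor["C"] - donor["N"]) * 10.0
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:  # DSSP's clash guard
        return -9.9
    return config.hbond_constant * (1.0 / r_on + 1.0 / r_ch
                                    - 1.0 / r_oh - 1.0 / r_cn)


def assign_secondary_structure(structure: Structure,
                               config: SSConfig = SSConfig(),
                               ) -> tuple[dict[int, str], int]:
    """Per-residue helix label ("H" or "-") and the helical residue count.

    Residue i is α-helical when it lies in a stretch supported by two
    consecutive i→i+4 hydrogen bonds (turns at i−1 and i span residues
    i..i+3).  3₁₀ (i→i+3) and π (i→i+5) classes can be switched on.
    """
    resids, rows = _residue_table(structure)
    n = len(resids)
    missing = [resids[j] for j, d in enumerate(rows)
               if any(k not in d for k in ("N", "CA", "C", "O"))]
    if missing:
        warnings.warn(f"residues missing backbone atoms, excluded: {missing}",
                      stacklevel=2)

    def turn(stride: int) -> np.ndarray:
        t = np.zeros(n, dtype=bool)
        for i in range(n - stride):
            e = _hbond_energy(rows[i], rows[i + stride], config)
            t[i] = e < config.energy_cutoff
        return t

    labels = {r: "-" for r in resids}
    strides = [4] + ([3] if config.include_310 else []) + \
        ([5] if config.include_pi else [])
    for stride in strides:
        t = turn(stride)
        for i in range(1, n - stride):
            if t[i - 1] and t[i]:
                for j in range(i, i + stride):
                    labels[resids[j]] = "H"
    count = sum(1 for v in labels.values() if v == "H")
    return labels, count


# ---------------------------------------------------------------------------
# Shrake–Rupley SASA
# ---------------------------------------------------------------------------

#: Bondi van der Waals radii, nm
BONDI_RADII = {"C": 0.170, "N": 0.155, "O": 0.152, "S": 0.180, "H": 0.120,
               "P": 0.180}


@dataclass(frozen=True)
class SASAConfig:
    probe_radius: float = 0.14   # nm
    n_points: int = 960
    radii: dict = field(default_factory=lambda: dict(BONDI_RADII))

    def __post_init__(self) -> None:
        if self.probe_radius <= 0:
            raise ValueError("probe radius must be positive")
        if self.n_points < 32:
            raise ValueError("need at least 32 sphere points")


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere points by the golden-angle lattice."""
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z**2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley_sasa(structure: Structure,
                       config: SASAConfig = SASAConfig(),
                       per_residue: bool = False):
    """Solvent-accessible surface area in nm² (total, optionally per residue).

    For every atom, the fraction of probe-expanded sphere points not
    buried inside any neighbour's expanded sphere is multiplied by that
    sphere's area.  Neighbour search is KD-tree accelerated.
    """
    coords = structure.coordinates
    radii = np.empty(len(structure.atoms))
    for i, a in enumerate(structure.atoms):
        key = a.element.capitalize()
        if key not in config.radii and key.upper() not in config.radii:
            raise ValueError(f"no van der Waals radius for element {a.element!r}")
        radii[i] = config.radii.get(key, config.radii.get(key.upper()))
    expanded = radii + config.probe_radius
    sphere = _fibonacci_sphere(config.n_points)
    tree = cKDTree(coords)
    rmax = expanded.max()
    areas = np.zeros(len(structure.atoms))
    for i in range(len(structure.atoms)):
        pts = coords[i] + expanded[i] * sphere
        neighbors = [j for j in tree.query_ball_point(coords[i], expanded[i] + rmax)
                     if j != i]
        accessible = np.ones(config.n_points, dtype=bool)
        for j in neighbors:
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            accessible &= d2 > expanded[j] ** 2
        areas[i] = accessible.mean() * 4.0 * np.pi * expanded[i] ** 2
    total = float(areas.sum())
    if not per_residue:
        return total
    per_res: dict[int, float] = {}
    for a, area in zip(structure.atoms, areas):
        per_res[a.residue_index] = per_res.get(a.residue_index, 0.0) + float(area)
    return total, per_res


# ---------------------------------------------------------------------------
# state-conditioned distribution summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SummaryConfig:
    """KDE settings: Scott's rule, with an optional bandwidth multiplier
    (the helicity violin uses ×2)."""

    bandwidth_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.bandwidth_multiplier <= 0:
            raise ValueError("bandwidth multiplier must be positive")


@dataclass
class ConditionalSplit:
    """Per-state value splits with Gaussian KDEs (None when a state is empty)."""

    bound_values: np.ndarray
    unbound_values: np.ndarray
    bound_kde: gaussian_kde | None
    unbound_kde: gaussian_kde | None

    @property
    def bound_empty(self) -> bool:
        return self.bound_values.size == 0

    @property
    def unbound_empty(self) -> bool:
        return self.unbound_values.size == 0


def _make_kde(values: np.ndarray, mult: float) -> gaussian_kde | None:
    if values.size < 2 or np.allclose(values, values[0]):
        return None
    kde = gaussian_kde(values, bw_method="scott")
    if mult != 1.0:
        kde.set_bandwidth(kde.factor * mult)
    return kde


def conditional_distributions(values, states,
                              config: SummaryConfig = SummaryConfig(),
                              ) -> ConditionalSplit:
    """Split a per-frame observable by bound/unbound state and fit KDEs.

    ``states`` is a StateSeries or any array of "bound"/"unbound" labels
    on the same time axis as ``values``.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(getattr(states, "labels", states))
    if labels.shape[0] != values.shape[0]:
        raise ValueError("values and state labels must share the time axis")
    bound = values[labels == "bound"]
    unbound = values[labels == "unbound"]
    return ConditionalSplit(
        bound_values=bound, unbound_values=unbound,
        bound_kde=_make_kde(bound, config.bandwidth_multiplier),
        unbound_kde=_make_kde(unbound, config.bandwidth_multiplier),
    )
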