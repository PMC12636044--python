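"""Synthetic structures, trajectories and binding curves with known truth.

Every generator here is a pure function of its spec and seed.  The
trajectory emulator is deliberately not molecular dynamics: a rigid
peptide performs overdamped Brownian motion along z above a static
coarse lipid slab, with a surface attraction whose depth scales with the
anionic (PG) lipid fraction.  That is the simplest dynamics that yields
trajectories with controllable contact statistics, binding kinetics and
PG-dependent attraction, which is all the downstream analysis needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Atom, Frame, Structure, Trajectory

__all__ = [
    "HelixBuildSpec",
    "MembraneSlabSpec",
    "BindingSimSpec",
    "ContactSeriesSimSpec",
    "CurveSimSpec",
    "build_ideal_helix",
    "build_hairpin",
    "build_membrane_slab",
    "simulate_binding_trajectory",
    "generate_contact_series",
    "generate_binding_curve",
    "backbone_dihedrals",
    "dihedral",
]

# standard backbone geometry (nm / degrees)
R_N_CA = 0.1458
R_CA_C = 0.1525
R_C_N = 0.1329
R_C_O = 0.1231
R_N_H = 0.100
ANG_N_CA_C = 111.2
ANG_CA_C_N = 116.2
ANG_C_N_CA = 121.7
ANG_CA_C_O = 120.8


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length vector")
    return v / n


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, IUPAC sign convention."""
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1u = _unit(b1)
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    x = np.dot(v, w)
    y = np.dot(np.cross(b1u, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d with |c-d| = bond, angle(b,c,d) and dihedral(a,b,c,d)."""
    theta = np.radians(angle_deg)
    chi = np.radians(torsion_deg)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = bond * np.array([
        -np.cos(theta),
        np.sin(theta) * np.cos(chi),
        np.sin(theta) * np.sin(chi),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


@dataclass(frozen=True)
class HelixBuildSpec:
    """Backbone dihedrals and residue count for an ideal helix fixture."""

    n_residues: int
    phi: float = -57.0
    psi: float = -47.0
    omega: float = 180.0

    def __post_init__(self) -> None:
        if self.n_residues < 2:
            raise ValueError("need at least 2 residues")
        for name in ("phi", "psi", "omega"):
            v = getattr(self, name)
            if not (-180.0 < v <= 180.0):
                raise ValueError(f"{name} must lie in (-180, 180]")


def build_ideal_helix(spec: HelixBuildSpec, first_index: int = 1,
                      residue_name: str = "ALA") -> Structure:
    """Build an ideal poly-alanine backbone by internal-coordinate chaining.

    Atoms per residue: N, (H from residue 2 on), CA, C, O.  The amide H
    is placed 0.1 nm from N along the preceding residue's O→C direction,
    which is what Kabsch–Sander hydrogen-bond detection needs.
    """
    n = spec.n_residues
    N = np.zeros((n, 3))
    CA = np.zeros((n, 3))
    C = np.zeros((n, 3))
    O = np.zeros((n, 3))

    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (R_N_CA, 0.0, 0.0)
    # first C placed in the xy-plane at the N-CA-C angle
    theta = np.radians(ANG_N_CA_C)
    C[0] = CA[0] + R_CA_C * np.array([-np.cos(theta), np.sin(theta), 0.0])
    for i in range(1, n):
        N[i] = _place(N[i - 1], CA[i - 1], C[i - 1], R_C_N, ANG_CA_C_N, spec.psi)
        CA[i] = _place(CA[i - 1], C[i - 1], N[i], R_N_CA, ANG_C_N_CA, spec.omega)
        C[i] = _place(C[i - 1], N[i], CA[i], R_CA_C, ANG_N_CA_C, spec.phi)
    for i in range(n):
        # carbonyl O anti to the next amide N: torsion N-CA-C-O = psi + 180
        O[i] = _place(N[i], CA[i], C[i], R_C_O, ANG_CA_C_O, spec.psi + 180.0)

    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    k = 0
    for i in range(n):
        resid = first_index + i
        rows = [("N", "N", N[i])]
        if i > 0:
            h = N[i] + R_N_H * _unit(C[i - 1] - O[i - 1])
            rows.append(("H", "H", h))
        rows += [("CA", "C", CA[i]), ("C", "C", C[i]), ("O", "O", O[i])]
        for name, elem, xyz in rows:
            atoms.append(Atom(index=k, name=name, element=elem,
                              residue_index=resid, residue_name=residue_name,
                              group="protein"))
            coords.append(xyz)
            k += 1
    return Structure(atoms=atoms, coordinates=np.array(coords))


def backbone_dihedrals(structure: Structure) -> pd.DataFrame:
    """Recompute φ/ψ per residue from coordinates (NaN where undefined)."""
    by_res: dict[int, dict[str, np.ndarray]] = {}
    for a, xyz in zip(structure.atoms, structure.coordinates):
        by_res.setdefault(a.residue_index, {})[a.name] = xyz
    resids = sorted(by_res)
    rows = []
    for j, r in enumerate(resids):
        cur = by_res[r]
        phi = psi = np.nan
        if j > 0 and "C" in by_res[resids[j - 1]]:
            phi = dihedral(by_res[resids[j - 1]]["C"], cur["N"], cur["CA"], cur["C"])
        if j < len(resids) - 1 and "N" in by_res[resids[j + 1]]:
            psi = dihedral(cur["N"], cur["CA"], cur["C"], by_res[resids[j + 1]]["N"])
        rows.append({"residue": r, "phi": phi, "psi": psi})
    return pd.DataFrame(rows)


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation matrix sending unit vector a to unit vector b."""
    a, b = _unit(a), _unit(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.isclose(c, 1.0):
        return np.eye(3)
    if np.isclose(c, -1.0):
        # pick any perpendicular axis for the 180° flip
        axis = _unit(np.cross(a, [1.0, 0.0, 0.0] if abs(a[0]) < 0.9 else [0.0, 1.0, 0.0]))
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def _helix_axis(structure: Structure) -> np.ndarray:
    ca = np.array([xyz for a, xyz in zip(structure.atoms, structure.coordinates)
                   if a.name == "CA"])
    centered = ca - ca.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    # orient from first to last residue
    if np.dot(axis, ca[-1] - ca[0]) < 0:
        axis = -axis
    return axis


def build_hairpin(n1: int, loop: int, n2: int, first_index: int = 26,
                  separation: float = 1.0) -> Structure:
    """Two antiparallel ideal helices joined by an extended loop.

    Helix 1 runs along +z, helix 2 along −z at a lateral offset of
    ``separation`` nm; loop backbones are laid out along the straight
    line between the helix termini.  Residues are numbered continuously
    from ``first_index``; atom order follows the chain.
    """
    if n1 < 4 or n2 < 4:
        raise ValueError("each helix needs at least 4 residues")

    h1 = build_ideal_helix(HelixBuildSpec(n1), first_index=first_index)
    r1 = _rotation_between(_helix_axis(h1), np.array([0.0, 0.0, 1.0]))
    c1 = h1.coordinates @ r1.T
    c1 -= c1.min(axis=0)

    h2 = build_ideal_helix(HelixBuildSpec(n2),
                           first_index=first_index + n1 + loop)
    r2 = _rotation_between(_helix_axis(h2), np.array([0.0, 0.0, -1.0]))
    c2 = h2.coordinates @ r2.T
    c2 += np.array([separation, 0.0, c1[:, 2].max()]) - \
        np.array([c2[:, 0].min(), c2[:, 1].mean(), c2[:, 2].max()])

    atoms = list(h1.atoms)
    coords = [c1]
    # loop: plain backbone beads on the chord between the helix termini
    start = c1[-2]  # last C of helix 1
    end = c2[0]     # first N of helix 2
    step = (end - start) / (loop + 1)
    perp = _unit(np.cross(step, [0.0, 0.0, 1.0])
                 if np.linalg.norm(np.cross(step, [0.0, 0.0, 1.0])) > 1e-9
                 else np.cross(step, [0.0, 1.0, 0.0]))
    k = len(atoms)
    loop_coords = []
    for j in range(loop):
        resid = first_index + n1 + j
        center = start + (j + 1) * step
        offs = {"N": -0.12 * _unit(step), "CA": 0.0 * step,
                "C": 0.12 * _unit(step), "O": 0.12 * _unit(step) + 0.12 * perp}
        for name in ("N", "CA", "C", "O"):
            atoms.append(Atom(index=k, name=name, element=name[0],
                              residue_index=resid, residue_name="GLY",
                              group="protein"))
            loop_coords.append(center + offs[name])
            k += 1
    if loop_coords:
        coords.append(np.array(loop_coords))
    for a in h2.atoms:
        atoms.append(Atom(index=k, name=a.name, element=a.element,
                          residue_index=a.residue_index, residue_name=a.residue_name,
                          group="protein"))
        k += 1
    coords.append(c2)
    return Structure(atoms=atoms, coordinates=np.vstack(coords))


@dataclass(frozen=True)
class MembraneSlabSpec:
    """Coarse PC/PG slab: lipids on a jittered square lattice."""

    nx: int = 16
    ny: int = 16
    area_per_lipid: float = 0.75  # nm² per head group
    pg_fraction: float = 0.5
    beads_per_lipid: int = 4
    z_head: float = 3.0  # nm

    def __post_init__(self) -> None:
        if self.nx * self.ny < 1:
            raise ValueError("need at least one lipid")
        if not 0.0 <= self.pg_fraction <= 1.0:
            raise ValueError("pg_fraction must lie in [0, 1]")
        if self.beads_per_lipid < 1 or self.area_per_lipid <= 0:
            raise ValueError("invalid slab geometry")

    @property
    def n_lipids(self) -> int:
        return self.nx * self.ny

    @property
    def total_area(self) -> float:
        return self.n_lipids * self.area_per_lipid


# bead names within one lipid: three head-group beads at z_head, tails below
_HEAD_BEADS = 3
_TAIL_SPACING = 0.3  # nm


def build_membrane_slab(spec: MembraneSlabSpec, seed: int = 0) -> Structure:
    """Lay out a flat slab of pseudo-lipids; PG lipids assigned by seeded shuffle."""
    rng = np.random.default_rng(seed)
    a = float(np.sqrt(spec.area_per_lipid))
    n = spec.n_lipids
    n_pg = int(round(spec.pg_fraction * n))
    labels = np.array(["DOPG"] * n_pg + ["DOPC"] * (n - n_pg))
    rng.shuffle(labels)

    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    k = 0
    lipid = 0
    for ix in range(spec.nx):
        for iy in range(spec.ny):
            x0 = (ix + 0.5) * a + rng.uniform(-0.1 * a, 0.1 * a)
            y0 = (iy + 0.5) * a + rng.uniform(-0.1 * a, 0.1 * a)
            resname = str(labels[lipid])
            for b in range(spec.beads_per_lipid):
                if b < _HEAD_BEADS:
                    name, elem = ("P", "P") if b == 0 else (f"O{b}", "O")
                    dx = rng.uniform(-0.2, 0.2, size=2) if b else np.zeros(2)
                    xyz = np.array([x0 + dx[0], y0 + dx[1], spec.z_head])
                else:
                    name, elem = f"C{b}", "C"
                    xyz = np.array([x0, y0,
                                    spec.z_head - (b - _HEAD_BEADS + 1) * _TAIL_SPACING])
                atoms.append(Atom(index=k, name=name, element=elem,
                                  residue_index=lipid + 1, residue_name=resname,
                                  group="membrane"))
                coords.append(xyz)
                k += 1
            lipid += 1
    box = np.array([spec.nx * a, spec.ny * a, spec.z_head + 12.0])
    return Structure(atoms=atoms, coordinates=np.array(coords), box=box)


def pg_fraction_of(membrane: Structure) -> float:
    """PG mole fraction of a slab, read back from its residue labels."""
    resnames = {a.residue_index: a.residue_name for a in membrane.atoms}
    vals = list(resnames.values())
    return sum(r == "DOPG" for r in vals) / len(vals)


@dataclass(frozen=True)
class BindingSimSpec:
    """Overdamped 1-D Brownian binding emulator parameters.

    ``well_depth`` (kT) is the surface attraction at full PG; the
    effective depth is ``well_depth × pg_fraction`` of the slab.  The
    well is a flat-bottomed super-Gaussian, U(g) = −depth·exp(−((g−c)/w)⁴),
    centred ``well_center`` nm above the head-group plane with half-width
    ``well_width``: inside the well the peptide diffuses freely within
    contact range, and leaving costs the full depth.
    """

    well_depth: float = 5.0       # kT at pg_fraction 1
    diffusion_z: float = 0.05     # nm²/ns
    wobble_amplitude: float = 0.02  # nm per-atom jitter
    start_height: float = 2.0     # nm above the head groups
    dt: float = 0.1               # ns
    n_frames: int = 2000
    seed: int = 0
    well_center: float = 0.08     # nm
    well_width: float = 0.10      # nm
    top_height: float = 2.2       # reflective ceiling, nm above head groups
    n_substeps: int = 50          # integrator substeps per saved frame

    def __post_init__(self) -> None:
        for name in ("diffusion_z", "wobble_amplitude", "start_height", "dt",
                     "well_center", "well_width", "top_height"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.well_depth < 0 or self.n_frames < 1 or self.n_substeps < 1:
            raise ValueError("well_depth must be ≥0, n_frames and n_substeps ≥1")

    @property
    def length_ns(self) -> float:
        return self.dt * self.n_frames


def _orient_flat(coords: np.ndarray) -> np.ndarray:
    """Rotate so the principal axis lies in the xy-plane (along x)."""
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    rot = _rotation_between(vt[0], np.array([1.0, 0.0, 0.0]))
    return centered @ rot.T


def simulate_binding_trajectory(peptide: Structure, membrane: Structure,
                                spec: BindingSimSpec, replica_id: int = 0,
                                condition: str | None = None) -> Trajectory:
    """Rigid-peptide Brownian binding trajectory above a static slab.

    The peptide is laid flat (principal axis in the membrane plane),
    centred in x,y, and released ``start_height`` nm above the head
    groups; its height then follows overdamped Langevin dynamics in the
    Gaussian surface well, with reflecting walls at the head-group plane
    and the box ceiling.  A per-atom Gaussian wobble is added on top of
    the rigid-body motion.  Identical seeds give identical coordinates.
    """
    if membrane.box is None:
        raise ValueError("membrane must carry a box")
    rng = np.random.default_rng(spec.seed)
    z_head = membrane.coordinates[:, 2].max()
    pg = pg_fraction_of(membrane)
    depth = spec.well_depth * pg

    pep = _orient_flat(peptide.coordinates)
    box = membrane.box.copy()
    box[2] = z_head + spec.top_height + (pep[:, 2].max() - pep[:, 2].min()) + 0.5
    pep[:, 0] += box[0] / 2.0
    pep[:, 1] += box[1] / 2.0
    pep[:, 2] -= pep[:, 2].min()  # peptide bottom at z = 0 + gap

    if spec.start_height <= 0:
        raise ValueError("peptide must start above the membrane")

    g = spec.start_height  # gap between peptide bottom and head groups
    g_min, g_max = 0.05, spec.top_height
    dcoef = spec.diffusion_z
    h = spec.dt / spec.n_substeps
    sig = spec.well_width
    g_c = spec.well_center
    noise_scale = np.sqrt(2.0 * dcoef * h)

    atoms = list(peptide.atoms) + [
        Atom(index=len(peptide.atoms) + a.index, name=a.name, element=a.element,
             residue_index=a.residue_index, residue_name=a.residue_name,
             group=a.group)
        for a in membrane.atoms
    ]
    n_pep = len(peptide.atoms)
    frames: list[Frame] = []
    for i in range(spec.n_frames):
        wobble = rng.normal(0.0, spec.wobble_amplitude, size=(n_pep, 3))
        pep_now = pep + wobble
        pep_now[:, 2] += z_head + g
        frames.append(Frame(time=i * spec.dt,
                            coordinates=np.vstack([pep_now, membrane.coordinates]),
                            box=box))
        for _ in range(spec.n_substeps):
            # overdamped step: drift = D·F/kT, F = −dU/dg of the flat-bottom well
            u = (g - g_c) / sig
            force = -depth * 4.0 * u**3 / sig * np.exp(-(u**4))
            g = g + dcoef * force * h + noise_scale * rng.normal()
            # reflecting walls
            if g < g_min:
                g = 2.0 * g_min - g
            if g > g_max:
                g = 2.0 * g_max - g
    cond = condition if condition is not None else f"pg{pg:.2f}"
    return Trajectory(atoms=atoms, frames=frames, replica_id=replica_id,
                      condition=cond)


@dataclass(frozen=True)
class ContactSeriesSimSpec:
    """Two-state Markov contact-count generator (ground truth for kinetics)."""

    k_on: float = 0.02    # 1/ns
    k_off: float = 0.005  # 1/ns
    mu_bound: float = 20.0
    mu_unbound: float = 0.5
    dt: float = 0.1       # ns
    n_frames: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_on < 0 or self.k_off < 0:
            raise ValueError("rates must be ≥ 0")
        if self.mu_bound < 0 or self.mu_unbound < 0:
            raise ValueError("means must be ≥ 0")
        if self.dt <= 0 or self.n_frames < 1:
            raise ValueError("dt must be > 0 and n_frames ≥ 1")


def generate_contact_series(spec: ContactSeriesSimSpec
                            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample (times, counts, latent_states); states are 0=unbound, 1=bound.

    The latent chain starts unbound, switches with per-step probabilities
    1−exp(−k·dt), and counts are Poisson with the state's mean.
    """
    rng = np.random.default_rng(spec.seed)
    p_on = 1.0 - np.exp(-spec.k_on * spec.dt)
    p_off = 1.0 - np.exp(-spec.k_off * spec.dt)
    states = np.zeros(spec.n_frames, dtype=int)
    s = 0
    u = rng.random(spec.n_frames)
    for i in range(spec.n_frames):
        states[i] = s
        if s == 0 and u[i] < p_on:
            s = 1
        elif s == 1 and u[i] < p_off:
            s = 0
    mus = np.where(states == 1, spec.mu_bound, spec.mu_unbound)
    counts = rng.poisson(mus)
    times = np.arange(spec.n_frames) * spec.dt
    return times, counts, states


_DEFAULT_CONCS = tuple(0.125 * 2.0 ** k for k in range(8))  # 0.125 … 16 μM


@dataclass(frozen=True)
class CurveSimSpec:
    """Hill-shaped Laurdan-GP binding curve with additive Gaussian noise."""

    gp0: float = 0.05
    delta_gp: float = 0.30
    kd: float = 2.0        # μM
    n_hill: float = 1.5
    concentrations: tuple[float, ...] = _DEFAULT_CONCS
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kd <= 0 or self.n_hill <= 0:
            raise ValueError("kd and n_hill must be positive")
        if any(c <= 0 for c in self.concentrations):
            raise ValueError("concentrations must be strictly positive")


def generate_binding_curve(spec: CurveSimSpec) -> pd.DataFrame:
    """Tabulate (concentration_uM, gp) from the Hill model plus noise."""
    rng = np.random.default_rng(spec.seed)
    c = np.asarray(spec.concentrations, dtype=float)
    gp = spec.gp0 + spec.delta_gp * c**spec.n_hill / (spec.kd**spec.n_hill
                                                      + c**spec.n_hill)
    if spec.noise_sd > 0:
        gp = gp + rng.normal(0.0, spec.noise_sd, size=c.shape)
    return pd.DataFrame({"concentration_uM": c, "gp": gp})
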