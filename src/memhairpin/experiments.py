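"""End-to-end study-condition runs over the synthetic generators.

These functions wire the generators to the analysis stages the way the
underlying study was organised: replicas of a hairpin peptide released
2 nm above PC/PG slabs of varying PG fraction, contact series and
sustained-contact kinetics per replica, occupancy over replicas, and
conformational observables conditioned on binding state.  The problem
sizes default to desk-scale replicas (a 28-residue hairpin over a 12×12
slab, 200 ns at 0.1 ns frames) so a full multi-condition sweep runs in
about a minute.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import binding, conformation, synth
from .io import FragmentSpec, Trajectory

__all__ = [
    "default_peptide",
    "default_membrane",
    "run_replica",
    "binding_kinetics_sweep",
    "occupancy_experiment",
    "conformation_experiment",
]

#: desk-scale defaults used across the analysis scripts
N1, LOOP, N2 = 14, 4, 14
SLAB_NX = SLAB_NY = 12
N_FRAMES = 2000
DT = 0.1  # ns


def default_peptide():
    """The hairpin fixture shared by all trajectory experiments."""
    return synth.build_hairpin(N1, LOOP, N2, first_index=26)


def default_membrane(pg_fraction: float, seed: int = 1):
    return synth.build_membrane_slab(
        synth.MembraneSlabSpec(nx=SLAB_NX, ny=SLAB_NY, pg_fraction=pg_fraction),
        seed=seed)


def run_replica(peptide, membrane, well_depth: float, seed: int,
                n_frames: int = N_FRAMES) -> Trajectory:
    spec = synth.BindingSimSpec(well_depth=well_depth, n_frames=n_frames,
                                seed=seed)
    return synth.simulate_binding_trajectory(peptide, membrane, spec,
                                             replica_id=seed)


def binding_kinetics_sweep(well_depths=(0.0, 2.0, 5.0), n_replicas: int = 20,
                           seed: int = 0, n_frames: int = N_FRAMES,
                           pg_fraction: float = 1.0) -> pd.DataFrame:
    """First-binding time per replica across surface-attraction strengths.

    Emulates the PG-fraction dependence of association kinetics: each well
    depth plays the role of one membrane composition.  Returns one row per
    (depth, replica) with the first-binding time (NaN if never bound).
    """
    peptide = default_peptide()
    membrane = default_membrane(pg_fraction, seed=1)
    rows = []
    rng = np.random.default_rng(seed)
    for depth in well_depths:
        rep_seeds = rng.integers(2**31, size=n_replicas)
        for rep, s in enumerate(rep_seeds):
            traj = run_replica(peptide, membrane, depth, int(s), n_frames)
            series = binding.contact_series(traj)
            state = binding.classify_states(series)
            rows.append({
                "well_depth_kT": depth,
                "replica": rep,
                "first_binding_ns": (np.nan if state.first_binding_time is None
                                     else state.first_binding_time),
                "bound_fraction": state.bound_fraction,
                "median_contacts": float(np.median(series.pair_count)),
            })
    return pd.DataFrame(rows)


def occupancy_experiment(n_replicas: int = 8, well_depth: float = 5.0,
                         seed: int = 0, n_frames: int = 1000,
                         n_resamples: int = 1000):
    """Per-residue occupancy with BCa CIs over independent replicas."""
    peptide = default_peptide()
    membrane = default_membrane(1.0, seed=1)
    rng = np.random.default_rng(seed)
    series = []
    for s in rng.integers(2**31, size=n_replicas):
        traj = run_replica(peptide, membrane, well_depth, int(s), n_frames)
        series.append(binding.contact_series(traj))
    profile = binding.residue_occupancy(series, n_resamples=n_resamples,
                                        seed=seed)
    return profile, series


def conformation_experiment(n_replicas: int = 4, well_depth: float = 5.0,
                            seed: int = 0, n_frames: int = 600):
    """PCA + helicity + SASA conditioned on binding state, desk scale.

    Returns a dict with the fitted PCA model, per-frame PC1 projections,
    helical counts and SASA split by state for the first replica.
    """
    peptide = default_peptide()
    membrane = default_membrane(1.0, seed=1)
    resids = sorted({a.residue_index for a in peptide.atoms})
    fragment = FragmentSpec(first_residue=resids[0], last_residue=resids[-1],
                            pca_last_residue=resids[-1] - 5,
                            trp_residue=resids[0] + 5)
    rng = np.random.default_rng(seed)
    trajs, states = [], []
    for s in rng.integers(2**31, size=n_replicas):
        traj = run_replica(peptide, membrane, well_depth, int(s), n_frames)
        trajs.append(traj)
        states.append(binding.classify_states(binding.contact_series(traj)))
    model = conformation.fit_pca(trajs, fragment)
    proj = conformation.project_pca(trajs[0], model, 1)
    split = conformation.conditional_distributions(proj, states[0])
    n_pep = len(peptide.atoms)
    from .io import Structure
    helic = []
    sasa_trp = []
    stride = max(1, n_frames // 50)  # subsample frames for the slow observables
    for frame in trajs[0].frames[::stride]:
        s = Structure(atoms=peptide.atoms, coordinates=frame.coordinates[:n_pep])
        helic.append(conformation.assign_secondary_structure(s)[1])
        total, per_res = conformation.shrake_rupley_sasa(
            s, conformation.SASAConfig(n_points=96), per_residue=True)
        sasa_trp.append(per_res[fragment.trp_residue])
    return {
        "model": model,
        "pc1_projection": proj,
        "pc1_split": split,
        "helical_counts": np.array(helic),
        "trp_sasa": np.array(sasa_trp),
        "states": states,
        "fragment": fragment,
    }
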