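"""End-to-end validation benchmarks with analytic or exhaustive ground truth.

Each function runs one slice of the pipeline at a fixed, documented
problem size and returns the measured quality metrics.  They power both
the acceptance-style tests and ``scripts/acceptance.py``; all randomness
derives from the ``seed`` argument.

Problem sizes (chosen so the full set runs in minutes on one CPU):
umbrella sampling 5 windows x 1e5 samples; metadynamics 1.5e6 steps;
geometric detectors 100 random complexes; coevolution calibration 2500
null pairs + 2000 fresh pairs; power 25 replicates of a 3x3 interface
scan on a 64-leaf tree.
"""

from __future__ import annotations

import itertools

import numpy as np

from .constants import KB
from .phylo.coev import PairPruner
from .phylo.pruning import ColumnModel, pruning_loglik_column, symmetric_transition_factors
from .phylo.tree import PhyloTree
from .phylo.fit import CoevPairModel
from .pipeline.scan import CoevolutionScan, null_delta_aic_distribution, pair_delta_aic
from .simulate import (
    DoubleWell2D,
    Harmonic1D,
    SimulationConfig,
    generate_toy_complex,
    generate_yule_tree,
    run_wt_metadynamics,
    sample_umbrella_windows,
    simulate_alignment_coev,
    simulate_alignment_independent,
)
from .simulate.msa import COMPENSATORY_PROFILE, COMPENSATORY_STATES
from .structure.core import Structure
from .structure.geometry import detect_hbonds, detect_ion_pairs, interface_contacts
from .structure.sasa import sasa_quadrature_tolerance, shrake_rupley_sasa

# ----------------------------------------------------------------- WHAM ----

def wham_benchmark(seed: int = 0) -> dict:
    """Recover the PMF of an analytic harmonic potential from 5 umbrella
    windows (spring 2500 kJ/mol/nm^2, 1e5 samples each)."""
    from .freenergy.wham import WHAM

    kappa = 200.0
    pot = Harmonic1D(kappa=kappa)
    centers = np.array([-0.2, -0.1, 0.0, 0.1, 0.2])
    spring = 2500.0
    cfg = SimulationConfig(seed=seed, n_steps=100_000)
    windows = sample_umbrella_windows(pot, centers, spring, cfg)
    res = WHAM(windows, n_bins=100).fit()

    kT = res.fes.kT
    x = res.fes.axes[0]
    F = res.fes.values
    # coverage range of the window design: restrained means +- 3 sigma
    sigma = np.sqrt(kT / (spring + kappa))
    means = spring * centers / (spring + kappa)
    mask = np.isfinite(F) & (x >= means.min() - 3 * sigma) & (x <= means.max() + 3 * sigma)
    diff = F[mask] - pot.value(x[mask])
    diff -= diff.mean()  # free energies are defined up to a constant
    rms = float(np.sqrt(np.mean(diff**2)))
    return {
        "pmf_rms_error_kT": rms / kT,
        "n_samples_per_window": cfg.n_steps,
        "n_windows": len(centers),
        "converged": float(res.converged),
    }


# -------------------------------------------------------- metadynamics ----

def metadynamics_benchmark(seed: int = 0) -> dict:
    """Reconstruct the analytic double-well barrier with well-tempered
    metadynamics (gamma 15, hills 0.1 kJ/mol x 0.04 nm)."""
    from .freenergy.metad import metad_bias_to_fes, project_fes
    from .freenergy.surface import average_fes_blocks

    pot = DoubleWell2D()  # barrier = 7.5 kJ/mol along x by construction
    cfg = SimulationConfig(seed=seed, n_steps=1_500_000, deposition_stride=250)
    run = run_wt_metadynamics(pot, cfg, n_snapshots=15)
    profiles = [
        project_fes(metad_bias_to_fes(snap), axis=0) for snap in run.snapshots[7:]
    ]
    avg = average_fes_blocks(profiles)
    xs, F = avg.axes[0], avg.values
    saddle = float(F[np.argmin(np.abs(xs))])
    barrier = saddle - float(F[np.isfinite(F)].min())
    kT = cfg.langevin_kT
    left = float(np.mean(run.cvs[:, 0] < -0.05))
    right = float(np.mean(run.cvs[:, 0] > 0.05))
    return {
        "barrier_kJmol": barrier,
        "true_barrier_kJmol": pot.barrier_height,
        "barrier_error_kT": abs(barrier - pot.barrier_height) / kT,
        "fraction_left_well": left,
        "fraction_right_well": right,
        "n_steps": cfg.n_steps,
    }


# ---------------------------------------------------- state populations ----

def _population_surface(n: int):
    from .freenergy.surface import FreeEnergySurface

    step = 1.6 / n
    axis = np.linspace(0.3 + step / 2, 1.9 - step / 2, n)

    def analytic(x, y):
        return 8.0 * ((x - 0.45) * (x - 0.9)) ** 2 + 6.0 * ((y - 0.42) * (y - 1.1)) ** 2

    return FreeEnergySurface((axis, axis), analytic(axis[:, None], axis[None, :])), axis


def populations_benchmark(seed: int = 0) -> dict:
    """Four-state quadrant integration vs refined-grid Riemann sums and
    Monte Carlo draws from the same Boltzmann density."""
    from scipy.stats import chisquare

    from .freenergy.surface import classify_state, fes_to_probability, integrate_state_populations

    coarse, axis = _population_surface(40)
    fine, fine_axis = _population_surface(160)
    pops = integrate_state_populations(coarse, 0.5)
    refined = integrate_state_populations(fine, 0.5)
    max_dev = max(abs(pops[k] - refined[k]) for k in pops)

    p = fes_to_probability(fine).ravel()
    rng = np.random.default_rng(seed)
    n_draws = 20_000
    draws = rng.choice(len(p), p=p, size=n_draws)
    d1 = fine_axis[draws // len(fine_axis)]
    d2 = fine_axis[draws % len(fine_axis)]
    labels = [classify_state(a, b, 0.5) for a, b in zip(d1, d2)]
    observed = np.array([labels.count(k) for k in refined])
    expected = np.array([refined[k] * n_draws for k in refined])
    keep = expected > 5
    pvalue = float(
        chisquare(
            observed[keep],
            expected[keep] * observed[keep].sum() / expected[keep].sum(),
        ).pvalue
    )
    return {
        "population_refined_grid_max_dev": float(max_dev),
        "population_chi2_pvalue": pvalue,
        "n_monte_carlo_draws": n_draws,
    }


# ------------------------------------------------------------ detectors ----

def _brute_contacts(s: Structure, cutoff=0.5):
    pairs = {}
    for i in range(s.n_atoms):
        if s.chain_ids[i] != "A" or str(s.elements[i]).upper() == "H":
            continue
        for j in range(s.n_atoms):
            if s.chain_ids[j] != "B" or str(s.elements[j]).upper() == "H":
                continue
            if np.linalg.norm(s.coords[i] - s.coords[j]) < cutoff:
                key = (
                    (str(s.chain_ids[i]), int(s.res_ids[i]), str(s.res_names[i])),
                    (str(s.chain_ids[j]), int(s.res_ids[j]), str(s.res_names[j])),
                )
                pairs[key] = pairs.get(key, 0) + 1
    return pairs


def _brute_ion_pairs(s: Structure, cutoff=0.5):
    from .constants import ATOMIC_MASSES, CHARGED_GROUPS

    groups = []
    seen = set()
    for idx in range(s.n_atoms):
        key = (str(s.chain_ids[idx]), int(s.res_ids[idx]))
        if key in seen:
            continue
        seen.add(key)
        res_name = str(s.res_names[idx])
        if res_name not in CHARGED_GROUPS:
            continue
        sign, names = CHARGED_GROUPS[res_name]
        rows = [
            i for i in range(s.n_atoms)
            if (str(s.chain_ids[i]), int(s.res_ids[i])) == key
            and str(s.atom_names[i]) in names
        ]
        if len(rows) != len(names):
            continue
        masses = np.array(
            [ATOMIC_MASSES.get(str(s.elements[i]).upper(), 12.011) for i in rows]
        )
        com = (s.coords[rows] * masses[:, None]).sum(axis=0) / masses.sum()
        groups.append((sign, (*key, res_name), com))
    found = set()
    for i, (si, ki, ci) in enumerate(groups):
        for sj, kj, cj in groups[i + 1:]:
            if si * sj < 0 and np.linalg.norm(ci - cj) < cutoff:
                found.add(frozenset((ki, kj)))
    return found


def _brute_hbonds(s: Structure, d_cut=0.35, a_cut=30.0):
    found = set()
    els = [str(e).upper() for e in s.elements]
    for d in range(s.n_atoms):
        if els[d] not in ("N", "O", "S"):
            continue
        hyd = [
            h for h in range(s.n_atoms)
            if els[h] == "H"
            and s.chain_ids[h] == s.chain_ids[d]
            and s.res_ids[h] == s.res_ids[d]
            and np.linalg.norm(s.coords[h] - s.coords[d]) < 0.12
        ]
        if not hyd:
            continue
        for a in range(s.n_atoms):
            if a == d or els[a] not in ("N", "O"):
                continue
            if s.chain_ids[a] == s.chain_ids[d] and s.res_ids[a] == s.res_ids[d]:
                continue
            v = s.coords[a] - s.coords[d]
            if not np.linalg.norm(v) < d_cut:
                continue
            for h in hyd:
                u = s.coords[h] - s.coords[d]
                ang = np.degrees(
                    np.arccos(
                        np.clip(
                            v @ u / (np.linalg.norm(v) * np.linalg.norm(u)), -1, 1
                        )
                    )
                )
                if ang < a_cut:
                    found.add(
                        (
                            (str(s.chain_ids[d]), int(s.res_ids[d])),
                            (str(s.chain_ids[a]), int(s.res_ids[a])),
                        )
                    )
                    break
    return found


def _brute_sasa(s: Structure, n_points=240):
    """Naive Shrake-Rupley without neighbour prefilter."""
    from .constants import DEFAULT_VDW_RADIUS_NM, PROBE_RADIUS_NM, VDW_RADII_NM
    from .structure.sasa import sphere_points

    grid = sphere_points(n_points)
    r = np.array(
        [VDW_RADII_NM.get(str(e).upper(), DEFAULT_VDW_RADIUS_NM) for e in s.elements]
    ) + PROBE_RADIUS_NM
    out = np.empty(s.n_atoms)
    for i in range(s.n_atoms):
        pts = s.coords[i] + r[i] * grid
        ok = np.ones(n_points, dtype=bool)
        for j in range(s.n_atoms):
            if j == i:
                continue
            ok &= np.linalg.norm(pts - s.coords[j], axis=1) >= r[j]
        out[i] = ok.mean() * 4 * np.pi * r[i] ** 2
    return out


def detectors_benchmark(seed: int = 0, n_complexes: int = 100) -> dict:
    """All geometric detectors vs naive exhaustive oracles on random
    synthetic complexes."""
    mismatches = 0
    max_sasa_dev = 0.0
    rng = np.random.default_rng(seed)
    for k in range(n_complexes):
        sub_seed = int(rng.integers(2**31))
        n_res = 4 + k % 5
        separation = 10.0 if k % 7 == 0 else 0.0
        s, truth = generate_toy_complex(n_res, sub_seed, separation=separation)

        rep = interface_contacts(s, "A", "B")
        if {(ra, rb): n for ra, rb, n in rep.residue_pairs} != _brute_contacts(s):
            mismatches += 1
        if rep.residue_pairs != truth.planted_contacts:
            mismatches += 1

        ours_ion = {frozenset((p.positive, p.negative)) for p in detect_ion_pairs(s)}
        if ours_ion != _brute_ion_pairs(s):
            mismatches += 1

        ours_hb = {(b.donor[:2], b.acceptor[:2]) for b in detect_hbonds(s)}
        if ours_hb != _brute_hbonds(s):
            mismatches += 1

        if k % 10 == 0:  # SASA oracle is expensive; spot-check every 10th
            ours = shrake_rupley_sasa(s, n_points=240)
            brute = _brute_sasa(s, n_points=240)
            max_sasa_dev = max(max_sasa_dev, float(np.abs(ours - brute).max()))
    return {
        "n_complexes": n_complexes,
        "detector_mismatches": mismatches,
        "sasa_max_dev_nm2": max_sasa_dev,
    }


# ---------------------------------------------------------- likelihoods ----

def likelihood_benchmark(seed: int = 0) -> dict:
    """Pruning vs exhaustive enumeration; coevolution chain at s = d vs
    the independent-product factorization."""
    tree = PhyloTree.from_newick("((A:0.3,B:0.5):0.2,(C:0.1,D:0.7):0.4);")

    def transition(n, rate, t):
        ps, pd = symmetric_transition_factors(n, rate, t)
        M = np.full((n, n), pd)
        np.fill_diagonal(M, ps)
        return M

    def brute(column, model):
        n = model.n
        idx = {s: i for i, s in enumerate(model.states)}
        internals = [nd for nd in tree.postorder() if not nd.is_leaf]
        total = 0.0
        for assignment in itertools.product(range(n), repeat=len(internals)):
            state = dict(zip(internals, assignment))
            p = 1.0 / n
            for nd in tree.postorder():
                if nd.parent is None:
                    continue
                P = transition(n, model.rate, nd.length)
                target = idx[column[nd.name]] if nd.is_leaf else state[nd]
                p *= P[state[nd.parent], target]
            total += p
        return np.log(total)

    rng = np.random.default_rng(seed)
    states = ("A", "C", "D", "E")
    max_dev_pruning = 0.0
    for _ in range(5):
        column = {leaf: states[rng.integers(4)] for leaf in "ABCD"}
        model = ColumnModel(states, rate=float(rng.uniform(0.2, 2.0)))
        dev = abs(pruning_loglik_column(tree, column, model) - brute(column, model))
        max_dev_pruning = max(max_dev_pruning, float(dev))

    tree12 = generate_yule_tree(12, 2.0, seed + 1)
    max_dev_factor = 0.0
    done = rep = 0
    while done < 5:
        aln = simulate_alignment_independent(tree12, 2, [0.5, 0.5], seed + 10 + rep)
        rep += 1
        col_a, col_b = aln.column(0), aln.column(1)
        if len(set(col_a.values())) < 2 or len(set(col_b.values())) < 2:
            continue  # invariant column: the factorization check needs 2+ states
        done += 1
        pruner = PairPruner(tree12, col_a, col_b)
        alpha = float(rng.uniform(0.1, 1.0))
        ll = pruner.loglik(alpha, alpha)
        prod = pruning_loglik_column(
            tree12, col_a, ColumnModel(pruner.states_a, (pruner.na - 1) * alpha)
        ) + pruning_loglik_column(
            tree12, col_b, ColumnModel(pruner.states_b, (pruner.nb - 1) * alpha)
        )
        max_dev_factor = max(max_dev_factor, float(abs(ll - prod)))
    return {
        "pruning_enumeration_max_abs_dev": max_dev_pruning,
        "coev_factorization_max_abs_dev": max_dev_factor,
    }


# ----------------------------------------------- coevolution statistics ----

#: study conditions of the coevolution benchmarks (see docs/methods.md)
STUDY_TREE = dict(n_taxa=64, birth_rate=4.0, seed=1)
NULL_COLUMN_RATE = 0.25
PLANTED = {
    5: dict(s=5 * 0.286, d=0.286),
    10: dict(s=10 * 0.25, d=0.25),
}


def study_tree() -> PhyloTree:
    return generate_yule_tree(**STUDY_TREE)


def calibration_benchmark(
    seed: int = 0, n_calibration: int = 2500, n_fresh: int = 2000
) -> dict:
    """Type-I error of the simulation-calibrated 99th-percentile dAIC
    threshold on fresh independent pairs."""
    tree = study_tree()
    null_values = null_delta_aic_distribution(
        tree, 2, n_calibration, seed=seed, col_rate=NULL_COLUMN_RATE
    )
    threshold = float(np.percentile(null_values, 99.0))
    fresh_seed = seed + n_calibration + 1
    called = 0
    for rep in range(n_fresh):
        aln = simulate_alignment_independent(
            tree, 2, [NULL_COLUMN_RATE] * 2, seed=fresh_seed + rep
        )
        row = pair_delta_aic(tree, aln.column(0), aln.column(1))
        called += row["dAIC"] >= threshold
    rate = called / n_fresh
    se = np.sqrt(0.01 * 0.99 / n_fresh)
    return {
        "daic_threshold": threshold,
        "null_call_rate": rate,
        "null_call_rate_expected": 0.01,
        "binomial_se": float(se),
        "n_calibration_pairs": n_calibration,
        "n_fresh_pairs": n_fresh,
    }


def planted_interface_alignment(tree, ratio: int, seed: int):
    """3x3 interface scan alignment: planted pair + 2 independent columns
    per side, divergence-typical for an ortholog family."""
    from .phylo.alignment import Alignment, ColumnInfo
    from .pipeline.pairing import PairedAlignment

    params = PLANTED[ratio]
    coev = simulate_alignment_coev(
        tree, set(COMPENSATORY_PROFILE), params["s"], params["d"], 1, seed,
        states_a=COMPENSATORY_STATES, states_b=COMPENSATORY_STATES,
    )
    indep = simulate_alignment_independent(
        tree, 4, [NULL_COLUMN_RATE] * 4, seed + 100_000
    )
    ids = coev.ids
    seqs = []
    for rid in ids:
        c = coev.sequence(rid)
        n = indep.sequence(rid)
        seqs.append(c[0] + n[0] + n[1] + c[1] + n[2] + n[3])
    cols = [ColumnInfo("A", 1), ColumnInfo("A", 2), ColumnInfo("A", 3),
            ColumnInfo("B", 1), ColumnInfo("B", 2), ColumnInfo("B", 3)]
    return PairedAlignment(Alignment(ids, seqs, cols), block_boundary=3)


def power_benchmark(
    seed: int = 0,
    ratio: int = 5,
    n_replicates: int = 25,
    threshold: float = None,
    n_calibration: int = 600,
) -> dict:
    """Detection power for one planted coevolving pair among independent
    interface columns, against the simulation-calibrated threshold."""
    tree = study_tree()
    if threshold is None:
        null_values = null_delta_aic_distribution(
            tree, 2, n_calibration, seed=seed + 500_000, col_rate=NULL_COLUMN_RATE
        )
        threshold = float(np.percentile(null_values, 99.0))
    top = called = 0
    ratios = []
    for rep in range(n_replicates):
        paired = planted_interface_alignment(tree, ratio, seed + rep)
        scan = CoevolutionScan(tree, paired, [1, 2, 3], [4, 5, 6]).fit()
        best = scan.top_pair()
        row = scan.table[(scan.table.col_a == 1) & (scan.table.col_b == 4)].iloc[0]
        top += best == (1, 4)
        called += row["dAIC"] >= threshold
        fit = CoevPairModel(
            tree, paired.column(1), paired.column(4), profile=COMPENSATORY_PROFILE
        ).fit()
        ratios.append(fit.params["s"] / max(fit.params["d"], 1e-12))
    return {
        "daic_threshold": float(threshold),
        "top_pair_fraction": top / n_replicates,
        "called_fraction": called / n_replicates,
        "recovered_ratio_median": float(np.median(ratios)),
        "true_ratio": float(ratio),
        "n_replicates": n_replicates,
    }
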