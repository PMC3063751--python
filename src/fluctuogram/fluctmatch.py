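"""Fluctuation matching: invert bond fluctuations into force constants.

Given per-bond fluctuation statistics measured over a trajectory window,
the matcher adjusts the force constants of an elastic network until the
network's normal-mode prediction of every bond's fluctuation agrees with
the measured value.  Bond fluctuations are treated in the Gaussian
approximation throughout: the observable is the variance of the bond
elongation projected on the mean bond direction, for which the harmonic
prediction is exact (the scalar-distance variance acquires an anharmonic
transverse contribution and is available as an alternative mode).

The default update rule moves each force constant along the difference of
inverse variances,

    k <- max(0, k + alpha * k_B*T * (1/var_MD - 1/var_ENM)),

whose fixed point is exactly var_ENM = var_MD and which solves an isolated
bond in closed form (var = k_B*T/k).  Iteration stops when the RMS change
of the force constants between steps drops below the tolerance
(0.005 kcal/mol/A^2 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cg import CGTrajectory, ElasticNetwork, predict_bond_variances
from .constants import DEFAULT_TEMPERATURE, thermal_energy
from .errors import ZeroVarianceError

_RULES = ("inverse_variance", "variance_difference")


@dataclass
class TargetStatistics:
    """Per-bond mean length and fluctuation variance over one window."""

    bond_indices: np.ndarray     # (n_bonds, 2)
    mean_lengths: np.ndarray     # (n_bonds,) Angstrom
    variances: np.ndarray        # (n_bonds,) A^2, > 0
    mean_structure: np.ndarray   # (n_sites, 3): rest geometry for the network

    def __post_init__(self) -> None:
        self.bond_indices = np.asarray(self.bond_indices, dtype=int)
        self.mean_lengths = np.asarray(self.mean_lengths, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        self.mean_structure = np.asarray(self.mean_structure, dtype=float)
        if (self.mean_lengths <= 0).any():
            raise ValueError("mean bond lengths must be positive")
        if (self.variances <= 0).any():
            raise ValueError("target variances must be positive")


@dataclass
class FluctMatchConfig:
    """Tunable settings of the matcher; defaults follow standard practice."""

    alpha: float = 0.5
    rule: str = "inverse_variance"
    tolerance: float = 0.005          # kcal/mol/A^2, RMS force-constant change
    max_iterations: int = 1000
    temperature: float = DEFAULT_TEMPERATURE
    seed: int | None = None           # reserved; the matcher is deterministic

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.rule not in _RULES:
            raise ValueError(f"rule must be one of {_RULES}")


@dataclass
class ConvergenceTrace:
    """Per-iteration RMS force-constant change and variance mismatch."""

    rms_dk: np.ndarray = field(default_factory=lambda: np.empty(0))
    rms_dvar: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_iterations: int = 0
    converged: bool = False


def measure_targets(
    traj: CGTrajectory,
    bonds: np.ndarray,
    mode: str = "projected",
) -> TargetStatistics:
    """Bond statistics of a trajectory window.

    The mean length is the frame average of the scalar distance.  The
    fluctuation variance is, in the default ``projected`` mode, the
    population variance of the bond-vector component along the mean bond
    direction (the Gaussian-approximation observable the matcher predicts);
    ``mode="distance"`` uses the variance of the scalar distance instead.
    """
    if traj.n_frames < 2:
        raise ValueError("window needs at least two frames")
    bonds = np.asarray(bonds, dtype=int)
    i, j = bonds.T
    rel = traj.coordinates[:, j] - traj.coordinates[:, i]       # (F, B, 3)
    dist = np.linalg.norm(rel, axis=2)
    mean_lengths = dist.mean(axis=0)
    mean_structure = traj.coordinates.mean(axis=0)
    if mode == "projected":
        mvec = mean_structure[j] - mean_structure[i]
        e = mvec / np.linalg.norm(mvec, axis=1)[:, None]
        proj = np.einsum("fbk,bk->fb", rel, e)
        var = proj.var(axis=0)
    elif mode == "distance":
        var = dist.var(axis=0)
    else:
        raise ValueError("mode must be 'projected' or 'distance'")
    if (var <= 0).any():
        bad = bonds[var <= 0][0]
        raise ZeroVarianceError(
            f"bond ({bad[0]}, {bad[1]}) shows zero fluctuation; "
            "force-constant inversion is undefined")
    return TargetStatistics(bonds, mean_lengths, var, mean_structure)


def initialize_force_constants(
    targets: TargetStatistics,
    temperature: float = DEFAULT_TEMPERATURE,
) -> np.ndarray:
    """Initial guess ``k0 = k_B*T / var_MD`` (exact for an isolated bond)."""
    return thermal_energy(temperature) / targets.variances


def fluctuation_match(
    targets: TargetStatistics,
    config: FluctMatchConfig | None = None,
    initial_k: np.ndarray | None = None,
) -> tuple[ElasticNetwork, ConvergenceTrace]:
    """Iteratively match predicted to measured bond fluctuations.

    Returns the matched network (rest lengths = target means, rest geometry
    = window mean structure, all force constants clamped non-negative) and
    the convergence trace.  Non-convergence within ``max_iterations`` is
    flagged on the trace, not raised; a disconnected network (all force
    constants across a cut driven to zero) raises.
    """
    config = config or FluctMatchConfig()
    kT = thermal_energy(config.temperature)
    k = (initialize_force_constants(targets, config.temperature)
         if initial_k is None else np.asarray(initial_k, dtype=float).copy())
    network = ElasticNetwork(
        coordinates=targets.mean_structure,
        bond_indices=targets.bond_indices,
        rest_lengths=targets.mean_lengths,
        force_constants=k,
        temperature=config.temperature,
    )
    rms_dk, rms_dvar = [], []
    converged = False
    v_md = targets.variances
    for _ in range(config.max_iterations):
        v_enm = predict_bond_variances(network)
        if config.rule == "inverse_variance":
            step = config.alpha * kT * (1.0 / v_md - 1.0 / v_enm)
        else:  # variance_difference: same fixed point, linearized step scale
            step = config.alpha * kT / v_md ** 2 * (v_enm - v_md)
        k_new = np.maximum(0.0, network.force_constants + step)
        dk = np.sqrt(((k_new - network.force_constants) ** 2).mean())
        rms_dk.append(dk)
        rms_dvar.append(np.sqrt(((v_enm - v_md) ** 2).mean()))
        network.force_constants = k_new
        if dk < config.tolerance:
            converged = True
            break
    trace = ConvergenceTrace(
        rms_dk=np.array(rms_dk),
        rms_dvar=np.array(rms_dvar),
        n_iterations=len(rms_dk),
        converged=converged,
    )
    return network, trace
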