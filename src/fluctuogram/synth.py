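"""Synthetic data generators.

These generators produce the inputs the analysis pipeline consumes, with
known ground truth so every downstream module can be tested against the
quantity it is supposed to recover:

* toy elastic networks (a self-avoiding chain plus random long-range
  contacts) with known force constants;
* Gaussian-sampled trajectories whose coordinate covariance is exactly
  the network's thermal ensemble — the independent Monte-Carlo oracle for
  the normal-mode variance prediction and the recovery target for
  fluctuation matching;
* two-state trajectories concatenating segments from two networks, with
  recorded change points;
* alignments with planted co-evolving sectors for the SCA arm.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cg import CGTrajectory, ElasticNetwork, normal_modes
from .constants import DEFAULT_TEMPERATURE, thermal_energy
from .errors import RosterMismatchError
from .sca import AA_BACKGROUND, GAP, MultipleAlignment

AMINO_ACIDS = np.array(sorted(AA_BACKGROUND))
_AA_PROBS = np.array([AA_BACKGROUND[a] for a in AMINO_ACIDS])
_AA_PROBS = _AA_PROBS / _AA_PROBS.sum()

#: Default frame spacing, ns (4000 frames then span 100 ns).
DEFAULT_FRAME_SPACING = 0.025


def _self_avoiding_chain(n_sites: int, rng: np.random.Generator,
                         bond_lengths: np.ndarray, min_separation: float,
                         max_restarts: int = 200) -> np.ndarray:
    """Embed a chain in 3-D with excluded volume between non-bonded sites."""
    for _ in range(max_restarts):
        coords = np.zeros((n_sites, 3))
        ok = True
        for i in range(1, n_sites):
            placed = False
            for _ in range(200):
                v = rng.normal(size=3)
                v /= np.linalg.norm(v)
                cand = coords[i - 1] + bond_lengths[i - 1] * v
                if i < 2 or (np.linalg.norm(coords[:i - 1] - cand, axis=1)
                             > min_separation).all():
                    coords[i] = cand
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return coords
    raise RuntimeError("could not embed a self-avoiding chain; relax the geometry")


def make_toy_network(
    n_sites: int = 20,
    n_extra_contacts: int = 8,
    k_range: tuple[float, float] = (1.0, 20.0),
    b_range: tuple[float, float] = (3.6, 4.0),
    seed: int = 0,
    temperature: float = DEFAULT_TEMPERATURE,
    min_separation: float = 3.4,
    max_condition_retries: int = 20,
) -> ElasticNetwork:
    """Random connected elastic network with a realizable 3-D geometry.

    The backbone is a self-avoiding chain with bond lengths drawn from
    ``b_range``; ``n_extra_contacts`` long-range bonds are added between
    random site pairs at sequence separation >= 2, with rest lengths set by
    the embedded geometry.  Force constants are uniform in ``k_range``.

    Generated networks are kept inside the small-fluctuation regime an
    elastic network assumes: a candidate whose softest internal mode has a
    thermal RMS amplitude exceeding its shortest rest length (a nearly
    unbraced collective motion) is discarded and regenerated from a
    deterministically derived seed.
    """
    if n_sites < 2:
        raise ValueError("need at least two sites")
    kT = thermal_energy(temperature)
    for attempt in range(max_condition_retries):
        rng = np.random.default_rng(seed + 1_000_003 * attempt)
        blen = rng.uniform(*b_range, size=n_sites - 1)
        coords = _self_avoiding_chain(n_sites, rng, blen, min_separation)
        bonds = [(i, i + 1) for i in range(n_sites - 1)]
        candidates = [(i, j) for i in range(n_sites) for j in range(i + 2, n_sites)]
        rng.shuffle(candidates)
        bonds.extend(candidates[:n_extra_contacts])
        bonds = np.array(sorted(set(bonds)), dtype=int)
        i, j = bonds.T
        rest = np.linalg.norm(coords[j] - coords[i], axis=1)
        k = rng.uniform(*k_range, size=len(bonds))
        network = ElasticNetwork(coords, bonds, rest, k, temperature=temperature)
        w, _, nonzero = normal_modes(network)
        softest_variance = kT / w[nonzero].min()
        if softest_variance <= rest.min() ** 2:
            return network
    raise RuntimeError(
        "could not generate a well-conditioned network; relax the topology")


def sample_from_network(
    network: ElasticNetwork,
    n_frames: int,
    seed: int = 0,
    frame_spacing: float = DEFAULT_FRAME_SPACING,
    rigid_motion: bool = False,
    start_time: float = 0.0,
) -> CGTrajectory:
    """Draw frames from the network's thermal (Gaussian) ensemble.

    Coordinates are sampled from the multivariate normal with mean equal
    to the rest geometry and covariance ``k_B*T`` times the Hessian
    pseudoinverse; rigid-body (and any floppy) zero modes carry zero
    amplitude, so internal statistics are exact without superposition.
    With ``rigid_motion`` a random rotation and translation is applied per
    frame to exercise superposition-dependent code paths.
    """
    w, V, nonzero = normal_modes(network)
    kT = thermal_energy(network.temperature)
    rng = np.random.default_rng(seed)
    amplitudes = np.sqrt(kT / w[nonzero])
    z = rng.standard_normal((n_frames, int(nonzero.sum())))
    disp = (z * amplitudes) @ V[:, nonzero].T
    coords = network.coordinates[None, :, :] + disp.reshape(n_frames, -1, 3)
    if rigid_motion:
        from scipy.spatial.transform import Rotation

        for f in range(n_frames):
            R = Rotation.random(random_state=np.random.RandomState(
                rng.integers(2 ** 31))).as_matrix()
            center = coords[f].mean(axis=0)
            coords[f] = (coords[f] - center) @ R.T + center + rng.normal(scale=5.0, size=3)
    times = start_time + frame_spacing * np.arange(n_frames)
    return CGTrajectory(times, coords)


def two_state_trajectory(
    network_a: ElasticNetwork,
    network_b: ElasticNetwork,
    frames_per_segment: int,
    seed: int = 0,
    n_segments: int = 2,
    frame_spacing: float = DEFAULT_FRAME_SPACING,
) -> tuple[CGTrajectory, np.ndarray]:
    """Alternating Gaussian segments from two networks (A, B, A, ...).

    Returns the concatenated trajectory and the change-point frame indices
    (the first frame of each new segment after the first).
    """
    if network_a.n_sites != network_b.n_sites:
        raise RosterMismatchError("the two networks must share a site roster")
    rng = np.random.default_rng(seed)
    segments = []
    for s in range(n_segments):
        net = network_a if s % 2 == 0 else network_b
        segments.append(sample_from_network(
            net, frames_per_segment, seed=int(rng.integers(2 ** 31)),
            frame_spacing=frame_spacing,
            start_time=s * frames_per_segment * frame_spacing))
    coords = np.concatenate([s.coordinates for s in segments])
    times = np.concatenate([s.times for s in segments])
    change_points = frames_per_segment * np.arange(1, n_segments)
    return CGTrajectory(times, coords), change_points


@dataclass
class AlignmentSpec:
    """Parameters of the planted-sector alignment generator.

    Sectors are disjoint sets of 1-based column positions.  Per sequence a
    latent activity state is drawn for each sector; sector columns emit
    their consensus residue with probability ``f_active`` when the sector
    is active and ``f_inactive`` otherwise, which makes the columns of a
    sector co-vary.  Background columns emit their consensus independently
    with probability ``f_background``; non-consensus residues come from
    the database background distribution.

    ``sector_mode`` controls the latent structure.  The default,
    ``exclusive``, activates exactly one sector per sequence (clade-like):
    the coupling matrix then shows one collective mode over all sector
    positions followed by contrast modes that spread the sectors at
    distinct angles in the plane of the 2nd and 3rd eigenvectors — the
    canonical sector geometry.  ``independent`` draws each sector's state
    as Bernoulli(``p_active``); each sector then claims its own
    eigenvector.
    """

    n_sequences: int = 3200
    n_positions: int = 100
    sectors: tuple[tuple[int, ...], ...] = ()
    p_active: float = 0.5
    f_active: float = 0.95
    f_inactive: float = 0.4
    f_background: float = 0.6
    sector_mode: str = "exclusive"
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_active, self.f_active, self.f_inactive, self.f_background):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.sector_mode not in ("exclusive", "independent"):
            raise ValueError("sector_mode must be 'exclusive' or 'independent'")
        flat = [p for s in self.sectors for p in s]
        if len(flat) != len(set(flat)):
            raise ValueError("sector position sets must be disjoint")


def default_sector_layout(n_positions: int = 100,
                          n_per_sector: int = 20) -> tuple[tuple[int, ...], ...]:
    """Three disjoint sector position sets interleaved across the alignment.

    The default (3 x 20 positions of 100) mirrors the roughly 30% sector
    occupancy seen in real protein families while leaving enough neutral
    columns to probe false selection.
    """
    pos = np.linspace(1, n_positions, 3 * n_per_sector).round().astype(int)
    pos = np.unique(pos)
    if len(pos) != 3 * n_per_sector:
        raise ValueError("sector layout does not fit: positions collide")
    return tuple(tuple(int(v) for v in pos[i::3]) for i in range(3))


def synth_alignment(spec: AlignmentSpec) -> MultipleAlignment:
    """Generate a gapless alignment with planted co-evolving sectors."""
    rng = np.random.default_rng(spec.seed)
    S, P = spec.n_sequences, spec.n_positions
    n_sec = len(spec.sectors)
    consensus_idx = rng.choice(len(AMINO_ACIDS), size=P, p=_AA_PROBS)
    sector_of_col = np.full(P, -1, dtype=int)
    for s, cols in enumerate(spec.sectors):
        sector_of_col[np.asarray(cols, dtype=int) - 1] = s

    if n_sec and spec.sector_mode == "exclusive":
        group = rng.integers(0, n_sec, size=S)
        active = group[:, None] == np.arange(n_sec)[None, :]
    elif n_sec:
        active = rng.random((S, n_sec)) < spec.p_active
    else:
        active = np.zeros((S, 0), dtype=bool)

    seqs = np.empty((S, P), dtype="<U1")
    for c in range(P):
        sec = sector_of_col[c]
        if sec < 0:
            p_cons = np.full(S, spec.f_background)
        else:
            p_cons = np.where(active[:, sec], spec.f_active, spec.f_inactive)
        is_cons = rng.random(S) < p_cons
        seqs[is_cons, c] = AMINO_ACIDS[consensus_idx[c]]
        n_alt = int((~is_cons).sum())
        if n_alt:
            probs = _AA_PROBS.copy()
            probs[consensus_idx[c]] = 0.0
            probs /= probs.sum()
            seqs[~is_cons, c] = AMINO_ACIDS[rng.choice(len(AMINO_ACIDS),
                                                       size=n_alt, p=probs)]
    ids = [f"synth{n:05d}" for n in range(S)]
    return MultipleAlignment(ids, seqs, np.arange(P) + 1)
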