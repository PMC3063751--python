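"""Coarse-grained elastic network models of proteins.

A protein is reduced to a two-site-per-residue representation: a backbone
site pinned to the C-alpha position and a sidechain site at the sidechain
center of mass (glycine keeps a single site; a single-atom ligand such as a
bound ion becomes one site).  The reduced structure is modelled as an
elastic network: a set of harmonic bonds with rest lengths ``b_ij`` and
force constants ``k_ij``,

    E = sum_bonds 1/2 * k_ij * (d_ij - b_ij)**2.

Normal-mode analysis of that potential yields the thermal ensemble of the
model.  Because the potential is harmonic in the bond strains, the
equal-time positional covariance is ``k_B*T * H^+`` where ``H`` is the
second-derivative (Hessian) matrix evaluated at the rest geometry and
``H^+`` its pseudoinverse over the non-zero modes; site masses drop out of
equal-time statistics by equipartition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .constants import DEFAULT_TEMPERATURE, thermal_energy
from .errors import (
    DisconnectedNetworkError,
    GeometryError,
    RosterMismatchError,
    StructureError,
)

#: Atom names treated as backbone; everything else in a residue is sidechain.
BACKBONE_ATOM_NAMES = frozenset(
    {"N", "CA", "C", "O", "OXT", "H", "HN", "HA", "HA1", "HA2", "HA3",
     "H1", "H2", "H3", "HT1", "HT2", "HT3", "OT1", "OT2"}
)

#: Ratio below the largest Hessian eigenvalue under which a mode counts as zero.
ZERO_MODE_RTOL = 1e-8

_STANDARD_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS HSD HSE HSP ILE LEU LYS MET PHE "
    "PRO SER THR TRP TYR VAL".split()
)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class AtomicStructure:
    """Atomic coordinates plus the metadata needed for coarse-graining.

    Atoms are stored in file order, which must be grouped by residue
    (residue indices non-decreasing).
    """

    atom_names: list[str]
    residue_indices: np.ndarray  # 1-based, non-decreasing
    residue_names: list[str]
    masses: np.ndarray           # amu, > 0
    coordinates: np.ndarray      # (n_atoms, 3) Angstrom

    def __post_init__(self) -> None:
        self.residue_indices = np.asarray(self.residue_indices, dtype=int)
        self.masses = np.asarray(self.masses, dtype=float)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        n = len(self.atom_names)
        if not (len(self.residue_indices) == len(self.residue_names)
                == len(self.masses) == len(self.coordinates) == n):
            raise StructureError("atom field lengths disagree")
        if not np.isfinite(self.coordinates).all():
            raise StructureError("non-finite coordinates")
        if (self.masses <= 0).any():
            raise StructureError("non-positive atom mass")
        if (np.diff(self.residue_indices) < 0).any():
            raise StructureError("residue indices must be non-decreasing")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)


@dataclass
class CGSite:
    site_id: int
    residue_index: int
    kind: str                    # backbone | sidechain | ligand
    member_atom_ids: np.ndarray
    mass: float
    ca_atom_id: int | None = None  # set for backbone sites: coordinate anchor


@dataclass
class CGMapping:
    """Assignment of atoms to coarse-grained sites, ordered by residue."""

    sites: list[CGSite]
    n_atoms: int

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def residue_of_site(self) -> np.ndarray:
        return np.array([s.residue_index for s in self.sites], dtype=int)

    @property
    def site_masses(self) -> np.ndarray:
        return np.array([s.mass for s in self.sites], dtype=float)


@dataclass
class CGTrajectory:
    """Mapped frames: times in ns (strictly increasing), coords in Angstrom."""

    times: np.ndarray            # (n_frames,)
    coordinates: np.ndarray      # (n_frames, n_sites, 3)
    mapping: CGMapping | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (frames, sites, 3)")
        if len(self.times) != len(self.coordinates):
            raise ValueError("times and coordinates disagree on frame count")
        if len(self.times) > 1 and (np.diff(self.times) <= 0).any():
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_sites(self) -> int:
        return self.coordinates.shape[1]

    def window(self, start: int, n_frames: int) -> "CGTrajectory":
        """Return the sub-trajectory of ``n_frames`` frames starting at ``start``."""
        sl = slice(start, start + n_frames)
        return CGTrajectory(self.times[sl], self.coordinates[sl], self.mapping)


@dataclass
class ElasticNetwork:
    """One mechanical coupling network: sites, bonds and a temperature.

    ``coordinates`` is the rest geometry used for normal-mode analysis;
    bond directions are evaluated there, where the harmonic expansion of
    the pair potential reduces to the longitudinal term.
    """

    coordinates: np.ndarray          # (n_sites, 3) rest geometry
    bond_indices: np.ndarray         # (n_bonds, 2) with i < j
    rest_lengths: np.ndarray         # (n_bonds,) Angstrom, > 0
    force_constants: np.ndarray      # (n_bonds,) kcal/mol/A^2, >= 0
    temperature: float = DEFAULT_TEMPERATURE
    masses: np.ndarray | None = None  # amu; irrelevant to equal-time statistics

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.bond_indices = np.asarray(self.bond_indices, dtype=int)
        self.rest_lengths = np.asarray(self.rest_lengths, dtype=float)
        self.force_constants = np.asarray(self.force_constants, dtype=float)
        if self.bond_indices.ndim != 2 or self.bond_indices.shape[1] != 2:
            raise ValueError("bond_indices must have shape (n_bonds, 2)")
        i, j = self.bond_indices.T if len(self.bond_indices) else (np.array([]),) * 2
        if len(self.bond_indices):
            if (i >= j).any():
                raise ValueError("bonds must satisfy i < j")
            pairs = {tuple(p) for p in self.bond_indices}
            if len(pairs) != len(self.bond_indices):
                raise ValueError("duplicate bonds")
        if (self.rest_lengths <= 0).any():
            raise ValueError("rest lengths must be positive")
        if (self.force_constants < 0).any():
            raise ValueError("force constants must be non-negative")
        if self.masses is None:
            self.masses = np.ones(self.n_sites)

    @property
    def n_sites(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_bonds(self) -> int:
        return self.bond_indices.shape[0]

    def bond_unit_vectors(self) -> np.ndarray:
        """Unit vectors along each bond in the rest geometry."""
        i, j = self.bond_indices.T
        vec = self.coordinates[j] - self.coordinates[i]
        norms = np.linalg.norm(vec, axis=1)
        if (norms == 0).any():
            raise GeometryError("coincident bonded sites")
        return vec / norms[:, None]


# ---------------------------------------------------------------------------
# coarse graining
# ---------------------------------------------------------------------------

def build_cg_mapping(
    structure: AtomicStructure,
    backbone_atom_names: Iterable[str] = BACKBONE_ATOM_NAMES,
    sidechain_heavy_only: bool = False,
) -> CGMapping:
    """Assign atoms to backbone/sidechain/ligand sites.

    Every non-glycine amino acid yields a backbone site (anchored to its
    C-alpha, mass of all backbone atoms) and a sidechain site (center of
    mass of the sidechain atoms).  Glycine, which has no sidechain heavy
    atoms, yields a single site.  A single-atom residue (a bound ion or
    similar ligand) yields one ligand site.

    Parameters
    ----------
    sidechain_heavy_only:
        If true, hydrogens are dropped from sidechain sites; by default all
        atoms present in the input contribute.
    """
    backbone_atom_names = frozenset(backbone_atom_names)
    sites: list[CGSite] = []
    # split atoms into residue blocks, preserving order
    order = np.arange(structure.n_atoms)
    blocks: list[list[int]] = []
    prev = None
    for a in order:
        key = (structure.residue_indices[a], structure.residue_names[a])
        if key != prev:
            blocks.append([])
            prev = key
        blocks[-1].append(int(a))

    for atoms in blocks:
        atoms = np.array(atoms)
        res_idx = int(structure.residue_indices[atoms[0]])
        res_name = structure.residue_names[atoms[0]].strip()
        names = [structure.atom_names[a].strip() for a in atoms]
        if len(atoms) == 1:
            sites.append(CGSite(len(sites), res_idx, "ligand", atoms,
                                float(structure.masses[atoms].sum())))
            continue
        if res_name not in _STANDARD_RESIDUES:
            warnings.warn(
                f"unknown residue name {res_name!r} at residue {res_idx}; "
                "partitioning by atom name")
        if "CA" not in names:
            raise StructureError(f"residue {res_idx} ({res_name}) lacks a CA atom")
        ca = int(atoms[names.index("CA")])
        is_bb = np.array([n in backbone_atom_names for n in names])
        sc = atoms[~is_bb]
        if sidechain_heavy_only:
            sc = np.array([a for a in sc
                           if not structure.atom_names[a].strip().startswith("H")],
                          dtype=int)
        if res_name == "GLY" or len(sc) == 0:
            if res_name != "GLY" and len(sc) == 0:
                warnings.warn(f"residue {res_idx} ({res_name}) has no sidechain "
                              "atoms; mapped to a single site")
            sites.append(CGSite(len(sites), res_idx, "backbone", atoms,
                                float(structure.masses[atoms].sum()), ca_atom_id=ca))
            continue
        bb = atoms[is_bb]
        sites.append(CGSite(len(sites), res_idx, "backbone", bb,
                            float(structure.masses[bb].sum()), ca_atom_id=ca))
        sites.append(CGSite(len(sites), res_idx, "sidechain", sc,
                            float(structure.masses[sc].sum())))
    return CGMapping(sites, structure.n_atoms)


def map_structure(structure: AtomicStructure, mapping: CGMapping) -> np.ndarray:
    """Map one atomic frame to site coordinates (backbone site = CA exactly)."""
    if structure.n_atoms != mapping.n_atoms:
        raise RosterMismatchError(
            f"frame has {structure.n_atoms} atoms, mapping expects {mapping.n_atoms}")
    out = np.empty((mapping.n_sites, 3))
    for s in mapping.sites:
        if s.ca_atom_id is not None:
            out[s.site_id] = structure.coordinates[s.ca_atom_id]
        else:
            m = structure.masses[s.member_atom_ids]
            out[s.site_id] = (m[:, None] * structure.coordinates[s.member_atom_ids]
                              ).sum(axis=0) / m.sum()
    return out


def map_trajectory(
    frames: Sequence[AtomicStructure],
    mapping: CGMapping,
    times: np.ndarray | None = None,
) -> CGTrajectory:
    """Map a sequence of atomic frames onto the coarse-grained sites."""
    coords = np.empty((len(frames), mapping.n_sites, 3))
    for f, frame in enumerate(frames):
        try:
            coords[f] = map_structure(frame, mapping)
        except RosterMismatchError as exc:
            raise RosterMismatchError(f"frame {f}: {exc}") from None
    if times is None:
        times = np.arange(len(frames), dtype=float)
    return CGTrajectory(np.asarray(times, dtype=float), coords, mapping)


# ---------------------------------------------------------------------------
# bond pool
# ---------------------------------------------------------------------------

def init_bond_pool(traj: CGTrajectory, cutoff: float = 10.0) -> np.ndarray:
    """All site pairs whose distance drops to ``cutoff`` or below in any frame.

    Returns an (n_bonds, 2) integer array with i < j, lexicographically
    sorted.  The pool is monotone in the cutoff: enlarging ``cutoff`` can
    only add pairs.
    """
    if traj.n_frames < 1:
        raise ValueError("need at least one frame")
    n = traj.n_sites
    dmin = np.full(n * (n - 1) // 2, np.inf)
    for frame in traj.coordinates:
        np.minimum(dmin, pdist(frame), out=dmin)
    mask = squareform(dmin <= cutoff)
    i, j = np.nonzero(np.triu(mask, k=1))
    return np.stack([i, j], axis=1)


# ---------------------------------------------------------------------------
# energetics and normal modes
# ---------------------------------------------------------------------------

def network_energy(network: ElasticNetwork, coordinates: np.ndarray) -> float:
    """Harmonic energy of a configuration, kcal/mol."""
    coordinates = np.asarray(coordinates, dtype=float)
    if coordinates.shape != (network.n_sites, 3):
        raise ValueError(
            f"coordinates shape {coordinates.shape} does not cover "
            f"{network.n_sites} sites")
    i, j = network.bond_indices.T
    d = np.linalg.norm(coordinates[j] - coordinates[i], axis=1)
    return float(0.5 * np.sum(network.force_constants * (d - network.rest_lengths) ** 2))


def _connected_components(n_sites: int, bonds: np.ndarray) -> list[set[int]]:
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    if len(bonds) == 0:
        return [{s} for s in range(n_sites)]
    i, j = bonds.T
    adj = coo_matrix((np.ones(len(bonds)), (i, j)), shape=(n_sites, n_sites))
    n_comp, labels = connected_components(adj, directed=False)
    return [set(np.nonzero(labels == c)[0].tolist()) for c in range(n_comp)]


def hessian(network: ElasticNetwork) -> np.ndarray:
    """Second-derivative matrix of the network energy at the rest geometry.

    At the rest geometry every bond sits at its rest length, so the
    tangential curvature term vanishes and each off-diagonal 3x3 block is
    ``-k_ij * e_ij e_ij^T`` with ``e_ij`` the bond unit vector; diagonal
    blocks carry minus the row sums.
    """
    n = network.n_sites
    H = np.zeros((3 * n, 3 * n))
    units = network.bond_unit_vectors()
    for (i, j), k, e in zip(network.bond_indices, network.force_constants, units):
        if k == 0.0:
            continue
        B = k * np.outer(e, e)
        H[3 * i:3 * i + 3, 3 * i:3 * i + 3] += B
        H[3 * j:3 * j + 3, 3 * j:3 * j + 3] += B
        H[3 * i:3 * i + 3, 3 * j:3 * j + 3] -= B
        H[3 * j:3 * j + 3, 3 * i:3 * i + 3] -= B
    return H


def normal_modes(network: ElasticNetwork) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Eigendecomposition of the Hessian with zero-mode classification.

    Returns ``(eigenvalues, eigenvectors, nonzero_mask)``.  Eigenvalues of
    magnitude below ``ZERO_MODE_RTOL`` times the largest are classed as
    zero.  The rigid-body minimum is six zero modes (five for a collinear
    geometry, whose rotation about its own axis is null); a connected
    network may carry more (under-braced, i.e. floppy, internal motions),
    which are excluded from the thermal ensemble alongside the rigid-body
    modes.  Raises :class:`DisconnectedNetworkError` if the ``k > 0`` bond
    graph is disconnected and :class:`GeometryError` if fewer zero modes
    than rigid-body motions are found.
    """
    active = network.bond_indices[network.force_constants > 0]
    comps = _connected_components(network.n_sites, active)
    if len(comps) > 1:
        raise DisconnectedNetworkError(comps)
    H = hessian(network)
    w, V = np.linalg.eigh(H)
    scale = max(w[-1], 0.0)
    if scale == 0.0:
        raise GeometryError("all-zero Hessian")
    nonzero = np.abs(w) > ZERO_MODE_RTOL * scale
    n_zero = int((~nonzero).sum())
    centered = network.coordinates - network.coordinates.mean(axis=0)
    rank = np.linalg.matrix_rank(centered, tol=1e-10)
    n_rigid = 3 + min(rank, 2) + (1 if rank >= 2 else 0)  # 5 collinear, 6 else
    if n_zero < n_rigid:
        raise GeometryError(
            f"only {n_zero} zero modes where {n_rigid} rigid-body modes are "
            "expected (degenerate geometry)")
    return w, V, nonzero


def positional_covariance(network: ElasticNetwork) -> np.ndarray:
    """Equal-time covariance ``k_B*T * H^+`` over the non-zero modes (A^2)."""
    w, V, nonzero = normal_modes(network)
    Vnz = V[:, nonzero]
    return thermal_energy(network.temperature) * (Vnz / w[nonzero]) @ Vnz.T


def predict_bond_variances(network: ElasticNetwork) -> np.ndarray:
    """Predicted thermal variance of each bond length, A^2.

    The bond-length fluctuation is treated in the Gaussian approximation:
    ``delta d = e_ij . (delta r_j - delta r_i)`` with the unit vector taken
    at the rest geometry, hence ``sigma^2 = e^T (C_ii + C_jj - 2 C_ij) e``
    with ``C`` the positional covariance.
    """
    C = positional_covariance(network)
    units = network.bond_unit_vectors()
    out = np.empty(network.n_bonds)
    for b, ((i, j), e) in enumerate(zip(network.bond_indices, units)):
        S = (C[3 * i:3 * i + 3, 3 * i:3 * i + 3]
             + C[3 * j:3 * j + 3, 3 * j:3 * j + 3]
             - 2 * C[3 * i:3 * i + 3, 3 * j:3 * j + 3])
        out[b] = e @ S @ e
    if (out <= 0).any():
        bad = network.bond_indices[out <= 0]
        raise GeometryError(f"non-positive predicted variance for bonds {bad.tolist()}")
    return out


def predicted_bond_variance_se(network: ElasticNetwork, n_frames: int) -> np.ndarray:
    """Monte-Carlo standard error of the windowed bond-variance estimator.

    The window estimator projects each frame's bond vector onto the
    *estimated* mean bond direction, so its sampling error has two parts:
    the chi-square noise of a variance estimate, ``2 sigma^4 / n``, and the
    noise of the direction itself, which couples the transverse
    fluctuations in: ``4 (P_perp S e)^T S (P_perp S e) / b^2 / n`` with
    ``S`` the 3x3 relative-displacement covariance of the bond, ``e`` its
    unit vector and ``P_perp = I - e e^T``.  Both terms are evaluated from
    the network's predicted covariance.
    """
    C = positional_covariance(network)
    units = network.bond_unit_vectors()
    out = np.empty(network.n_bonds)
    for b, ((i, j), e, rest) in enumerate(zip(network.bond_indices, units,
                                              network.rest_lengths)):
        S = (C[3 * i:3 * i + 3, 3 * i:3 * i + 3]
             + C[3 * j:3 * j + 3, 3 * j:3 * j + 3]
             - 2 * C[3 * i:3 * i + 3, 3 * j:3 * j + 3])
        sigma_par = e @ S @ e
        a = (np.eye(3) - np.outer(e, e)) @ S @ e
        out[b] = np.sqrt((2 * sigma_par ** 2 + 4 * (a @ S @ a) / rest ** 2)
                         / n_frames)
    return out


# ---------------------------------------------------------------------------
# superposition, RMSF, RMSD
# ---------------------------------------------------------------------------

def kabsch_superpose(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Least-squares rigid fit of ``mobile`` onto ``target`` (both (n, 3))."""
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    P, Q = mobile - mc, target - tc
    U, _, Vt = np.linalg.svd(P.T @ Q)
    sign = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, sign])
    R = U @ D @ Vt
    return P @ R + tc


def compute_rmsf(
    traj: CGTrajectory,
    site_filter: np.ndarray | None = None,
    n_mean_iterations: int = 5,
) -> np.ndarray:
    """Per-site RMSF after least-squares superposition onto the mean structure.

    The mean structure is refined iteratively (align, re-average) so rigid
    drift and rotation do not inflate the fluctuation estimate.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least two frames")
    coords = traj.coordinates
    if site_filter is not None:
        coords = coords[:, np.asarray(site_filter)]
    centered = coords[0] - coords[0].mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-10) < 2:
        warnings.warn("degenerate (collinear) structure; superposition ill-conditioned")
    mean = coords[0]
    aligned = coords
    for _ in range(n_mean_iterations):
        aligned = np.array([kabsch_superpose(f, mean) for f in coords])
        new_mean = aligned.mean(axis=0)
        if np.allclose(new_mean, mean, atol=1e-12):
            mean = new_mean
            break
        mean = new_mean
    dev = aligned - mean
    return np.sqrt((dev ** 2).sum(axis=2).mean(axis=0))


def compute_rmsd(traj: CGTrajectory, reference: np.ndarray) -> np.ndarray:
    """Per-frame RMSD to ``reference`` after least-squares superposition."""
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (traj.n_sites, 3):
        raise ValueError("reference does not match the trajectory site count")
    out = np.empty(traj.n_frames)
    for f, frame in enumerate(traj.coordinates):
        aligned = kabsch_superpose(frame, reference)
        out[f] = np.sqrt(((aligned - reference) ** 2).sum(axis=1).mean())
    return out
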