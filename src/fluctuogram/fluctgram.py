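"""The fluctuogram: per-window networks and residue-level variation metrics.

A trajectory is cut into half-overlapping windows; each window is
fluctuation-matched into its own elastic network on a shared bond pool.
The time-ordered sequence of networks — the fluctuogram — is then reduced
to residue-level series:

* ``k_IJ(t)``: mechanical coupling between residues I and J, the sum of
  force constants of bonds connecting their sites; ``k_I = sum_{J!=I} k_IJ``.
* ``delta k_I(t)`` between two states (e.g. ligand-bound vs apo), with
  per-residue classification by the time average of ``|delta k_I|``.
* ``delta k_I(t)`` between consecutive windows.
* ``delta b_I(t)``: summed absolute bond-length change of the bonds of I
  that carry a non-zero force constant in either window.
* ``psi_I(t)``: mean relative force-constant change of the bonds of I,
  normalized per bond by the larger of the two window values, hence
  bounded in [-1, 1] (+1: all bonds newly appear; -1: all vanish).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cg import CGMapping, CGTrajectory, ElasticNetwork
from .errors import FluctuogramError, RosterMismatchError
from .fluctmatch import (
    ConvergenceTrace,
    FluctMatchConfig,
    fluctuation_match,
    measure_targets,
)

#: Classification thresholds on the time-averaged |delta k_I| (kcal/mol/A^2).
DELTA_K_LARGE = 20.0
DELTA_K_SIGNIFICANT = 10.0


@dataclass
class WindowingScheme:
    """Half-overlapping sliding windows over a frame range.

    ``window_frames`` must be even and at least 4; the stride defaults to
    half the window so consecutive windows share exactly half their frames.
    """

    n_frames: int
    window_frames: int
    stride: int | None = None

    def __post_init__(self) -> None:
        if self.window_frames % 2 != 0:
            raise ValueError("window length must be an even number of frames")
        if self.window_frames < 4:
            raise ValueError("window length must be at least 4 frames")
        if self.n_frames < self.window_frames:
            raise ValueError("trajectory shorter than one window")
        if self.stride is None:
            self.stride = self.window_frames // 2
        if self.stride < 1:
            raise ValueError("stride must be positive")

    @property
    def n_windows(self) -> int:
        return (self.n_frames - self.window_frames) // self.stride + 1

    @property
    def starts(self) -> np.ndarray:
        return np.arange(self.n_windows) * self.stride

    def midpoint_times(self, times: np.ndarray) -> np.ndarray:
        """Window midpoint times for a vector of frame times (ns)."""
        times = np.asarray(times, dtype=float)
        lo = times[self.starts]
        hi = times[self.starts + self.window_frames - 1]
        return 0.5 * (lo + hi)


def make_windows(n_frames: int, window_frames: int,
                 stride: int | None = None) -> WindowingScheme:
    """Build the half-overlapping windowing scheme (see :class:`WindowingScheme`)."""
    return WindowingScheme(n_frames, window_frames, stride)


@dataclass
class Fluctuogram:
    """Time-ordered fluctuation-matched networks on a shared bond pool."""

    pool: np.ndarray                      # (n_bonds, 2)
    times: np.ndarray                     # window midpoints, ns
    networks: list[ElasticNetwork]
    traces: list[ConvergenceTrace]
    scheme: WindowingScheme | None = None
    mapping: CGMapping | None = None

    @property
    def n_windows(self) -> int:
        return len(self.networks)

    def site_residues(self) -> np.ndarray:
        """Residue index of each site (identity when no mapping is attached)."""
        if self.mapping is None:
            return np.arange(self.networks[0].n_sites) + 1
        return self.mapping.residue_of_site


def compute_fluctuogram(
    traj: CGTrajectory,
    scheme: WindowingScheme,
    pool: np.ndarray,
    config: FluctMatchConfig | None = None,
    mode: str = "projected",
) -> Fluctuogram:
    """Fluctuation-match every window of the trajectory on a shared pool.

    Windows are independent; evaluation order does not affect the result.
    Matcher errors are re-raised with the window index attached.
    """
    config = config or FluctMatchConfig()
    networks, traces = [], []
    for w, start in enumerate(scheme.starts):
        window = traj.window(int(start), scheme.window_frames)
        try:
            targets = measure_targets(window, pool, mode=mode)
            net, trace = fluctuation_match(targets, config)
        except FluctuogramError as exc:
            raise type(exc)(f"window {w}: {exc}") from None
        networks.append(net)
        traces.append(trace)
    return Fluctuogram(
        pool=np.asarray(pool, dtype=int),
        times=scheme.midpoint_times(traj.times),
        networks=networks,
        traces=traces,
        scheme=scheme,
        mapping=traj.mapping,
    )


# ---------------------------------------------------------------------------
# residue-level reductions
# ---------------------------------------------------------------------------

@dataclass
class ResidueCouplingSeries:
    """Per-window residue coupling: k_IJ matrices and k_I vectors."""

    residues: np.ndarray     # sorted 1-based residue indices, length R
    times: np.ndarray        # (W,)
    k_ij: np.ndarray         # (W, R, R) symmetric, diagonal = intra-residue
    k_i: np.ndarray          # (W, R) = sum over J != I of k_IJ

    @property
    def n_windows(self) -> int:
        return self.k_ij.shape[0]


def residue_coupling(
    network: ElasticNetwork,
    site_residues: np.ndarray,
    min_separation: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Aggregate site-level force constants into residue coupling.

    Returns ``(residues, k_IJ, k_I)``.  ``k_IJ`` sums the force constants
    of all bonds between sites of residues I and J; intra-residue
    (backbone-sidechain) bonds land on the diagonal and are excluded from
    ``k_I``.  ``min_separation`` optionally drops near-sequence neighbours
    (``|I-J| < min_separation``) from ``k_I``; by default all partners count.
    """
    site_residues = np.asarray(site_residues, dtype=int)
    residues, inverse = np.unique(site_residues, return_inverse=True)
    R = len(residues)
    k_ij = np.zeros((R, R))
    bi, bj = network.bond_indices.T
    ri, rj = inverse[bi], inverse[bj]
    np.add.at(k_ij, (ri, rj), network.force_constants)
    np.add.at(k_ij, (rj, ri), network.force_constants)
    # the double np.add.at doubles the diagonal (intra-residue) entries
    k_ij[np.diag_indices(R)] /= 2.0
    off = k_ij.copy()
    np.fill_diagonal(off, 0.0)
    if min_separation > 0:
        sep = np.abs(residues[:, None] - residues[None, :])
        off = np.where(sep >= min_separation, off, 0.0)
    return residues, k_ij, off.sum(axis=1)


def coupling_series(
    fluct: Fluctuogram,
    min_separation: int = 0,
) -> ResidueCouplingSeries:
    """Residue coupling of every window of a fluctuogram."""
    site_res = fluct.site_residues()
    mats, vecs = [], []
    residues = None
    for net in fluct.networks:
        residues, k_ij, k_i = residue_coupling(net, site_res, min_separation)
        mats.append(k_ij)
        vecs.append(k_i)
    return ResidueCouplingSeries(
        residues=residues,
        times=np.asarray(fluct.times, dtype=float),
        k_ij=np.array(mats),
        k_i=np.array(vecs),
    )


@dataclass
class TwoStateComparison:
    """delta k_I(t) between two states plus the per-residue classification."""

    residues: np.ndarray
    times: np.ndarray
    delta_k: np.ndarray          # (W, R) = k_I^A - k_I^B
    mean_abs: np.ndarray         # (R,) time average of |delta k_I|
    classes: np.ndarray          # (R,) 'large' | 'significant' | 'weak'
    top_decile: np.ndarray       # residues in the top 10% of mean_abs


def delta_k_two_states(
    series_a: ResidueCouplingSeries,
    series_b: ResidueCouplingSeries,
    large: float = DELTA_K_LARGE,
    significant: float = DELTA_K_SIGNIFICANT,
) -> TwoStateComparison:
    """Difference of per-residue coupling between two matched fluctuograms.

    Residues are classed by the time average of ``|delta k_I|``: above
    ``large`` (20 kcal/mol/A^2) -> 'large'; between ``significant`` and
    ``large`` -> 'significant'; below -> 'weak'.  The top decile of
    residues by that average is returned alongside.
    """
    if series_a.n_windows != series_b.n_windows:
        raise RosterMismatchError("window counts differ between states")
    if not np.array_equal(series_a.residues, series_b.residues):
        raise RosterMismatchError("residue rosters differ between states")
    delta = series_a.k_i - series_b.k_i
    mean_abs = np.abs(delta).mean(axis=0)
    classes = np.where(mean_abs > large, "large",
                       np.where(mean_abs >= significant, "significant", "weak"))
    n_top = max(1, int(np.ceil(0.10 * len(series_a.residues))))
    order = np.argsort(mean_abs)[::-1]
    return TwoStateComparison(
        residues=series_a.residues,
        times=series_a.times,
        delta_k=delta,
        mean_abs=mean_abs,
        classes=classes,
        top_decile=np.sort(series_a.residues[order[:n_top]]),
    )


def delta_k_consecutive(series: ResidueCouplingSeries) -> np.ndarray:
    """``k_I(t) - k_I(t-1)`` on consecutive windows; shape (W-1, R).

    A single-window series yields an empty (0, R) array.
    """
    return np.diff(series.k_i, axis=0)


def _bonds_touching(fluct: Fluctuogram, inter_residue_only: bool):
    """Per-bond residue memberships: (residues, bond->residue rows list)."""
    site_res = fluct.site_residues()
    residues = np.unique(site_res)
    index = {r: n for n, r in enumerate(residues)}
    members = []
    for i, j in fluct.pool:
        ri, rj = site_res[i], site_res[j]
        if ri == rj:
            members.append(() if inter_residue_only else (index[ri],))
        else:
            members.append((index[ri], index[rj]))
    return residues, members


def conformational_change(fluct: Fluctuogram) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue summed |bond-length change| between consecutive windows.

    Only bonds carrying a non-zero force constant in either of the two
    windows contribute.  Returns ``(residues, delta_b)`` with ``delta_b``
    of shape (W-1, R).
    """
    if fluct.n_windows < 2:
        raise ValueError("need at least two windows")
    residues, members = _bonds_touching(fluct, inter_residue_only=False)
    W, R = fluct.n_windows, len(residues)
    out = np.zeros((W - 1, R))
    for t in range(1, W):
        prev, curr = fluct.networks[t - 1], fluct.networks[t]
        db = np.abs(curr.rest_lengths - prev.rest_lengths)
        live = (curr.force_constants > 0) | (prev.force_constants > 0)
        for b in np.nonzero(live)[0]:
            for r in members[b]:
                out[t - 1, r] += db[b]
    return residues, out


def psi(fluct: Fluctuogram) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean relative force-constant change per residue between windows.

    For every bond of residue I with ``max(k(t), k(t-1)) > 0`` the term
    ``(k(t) - k(t-1)) / max(k(t), k(t-1))`` is accumulated; psi_I is the
    mean over those N_I bonds, hence in [-1, 1].  Intra-residue bonds are
    excluded.  Residues with N_I = 0 carry NaN (undefined, not zero).
    Returns ``(residues, psi, n_bonds)`` with shapes (R,), (W-1, R), (W-1, R).
    """
    if fluct.n_windows < 2:
        raise ValueError("need at least two windows")
    residues, members = _bonds_touching(fluct, inter_residue_only=True)
    W, R = fluct.n_windows, len(residues)
    val = np.zeros((W - 1, R))
    count = np.zeros((W - 1, R), dtype=int)
    for t in range(1, W):
        k0 = fluct.networks[t - 1].force_constants
        k1 = fluct.networks[t].force_constants
        denom = np.maximum(k0, k1)
        live = denom > 0
        terms = np.zeros_like(denom)
        terms[live] = (k1[live] - k0[live]) / denom[live]
        for b in np.nonzero(live)[0]:
            for r in members[b]:
                val[t - 1, r] += terms[b]
                count[t - 1, r] += 1
    with np.errstate(invalid="ignore"):
        out = np.where(count > 0, val / np.maximum(count, 1), np.nan)
    return residues, out, count
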