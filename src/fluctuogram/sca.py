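"""Statistical coupling analysis (SCA) of a multiple sequence alignment.

The alignment is filtered (overall and loop-specific gap limits), purged
of redundant sequences, and reduced to a binary matrix: position i of
sequence s is 1 when it carries the column's most prevalent residue.  Each
column's conservation is the relative entropy (nats)

    D_i = f' ln(f'/q) + (1-f') ln((1-f')/(1-q)),

between the regularized consensus frequency f' and the background
frequency q of that residue; the coupling matrix weights the absolute
binary covariance of two columns by the conservation gradient
``phi_i = |dD/df| = |ln(f'(1-q)/(q(1-f')))|``:

    C_ij = phi_i * phi_j * |<x_i x_j> - <x_i><x_j>|.

Groups of co-evolving positions ("sectors") are read off the 2nd and 3rd
eigenvectors of that matrix: positions far enough from the origin in the
(v2, v3) plane are selected and clustered by their angle.  Statistical
significance of eigenvalues is calibrated by independently permuting each
column across sequences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.vq import kmeans2

from .errors import FluctuogramError

#: Database amino-acid background frequencies (Swiss-Prot composition).
AA_BACKGROUND = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0137,
    "Q": 0.0393, "E": 0.0675, "G": 0.0707, "H": 0.0227, "I": 0.0596,
    "L": 0.0966, "K": 0.0584, "M": 0.0242, "F": 0.0386, "P": 0.0470,
    "S": 0.0656, "T": 0.0534, "W": 0.0108, "Y": 0.0292, "V": 0.0687,
}

#: Pseudocount mixed toward background so consensus frequencies stay in (0, 1).
DEFAULT_PSEUDOCOUNT = 0.01

GAP = "-"

_SECTOR_NAMES = ("blue", "red", "green")


@dataclass
class MultipleAlignment:
    """Rectangular alignment with a column -> reference-residue map."""

    ids: list[str]
    sequences: np.ndarray        # (n_seq, n_col) array of single characters
    column_ref: np.ndarray       # 1-based reference residue per column

    def __post_init__(self) -> None:
        self.sequences = np.asarray(self.sequences)
        self.column_ref = np.asarray(self.column_ref, dtype=int)
        if self.sequences.ndim != 2:
            raise ValueError("alignment must be rectangular")
        if len(self.ids) != self.sequences.shape[0]:
            raise ValueError("id/sequence count mismatch")
        if self.sequences.shape[1] != len(self.column_ref):
            raise ValueError("column map length mismatch")
        if len(self.column_ref) > 1 and (np.diff(self.column_ref) <= 0).any():
            raise ValueError("column map must be strictly increasing")

    @property
    def n_sequences(self) -> int:
        return self.sequences.shape[0]

    @property
    def n_columns(self) -> int:
        return self.sequences.shape[1]

    def subset(self, keep: np.ndarray) -> "MultipleAlignment":
        keep = np.asarray(keep)
        return MultipleAlignment(
            [self.ids[i] for i in np.nonzero(keep)[0]] if keep.dtype == bool
            else [self.ids[i] for i in keep],
            self.sequences[keep],
            self.column_ref,
        )


@dataclass
class ConservationProfile:
    """Per-column consensus residue, frequency, background and relative entropy."""

    consensus: np.ndarray        # most prevalent residue per column
    frequency: np.ndarray        # raw consensus frequency f in [0, 1]
    reg_frequency: np.ndarray    # pseudocount-regularized f'
    background: np.ndarray       # q of the consensus residue
    entropy: np.ndarray          # D_i, nats, >= 0
    pseudocount: float


@dataclass
class SCAMatrix:
    """Conservation-weighted coupling matrix with its eigendecomposition."""

    matrix: np.ndarray           # (P, P) symmetric, entrywise >= 0
    eigenvalues: np.ndarray      # descending
    eigenvectors: np.ndarray     # columns matching eigenvalues
    positions: np.ndarray        # 1-based reference residue per row/column


@dataclass
class SectorAssignment:
    """Positions on the (v2, v3) plane with distance-based sector labels."""

    positions: np.ndarray
    v2: np.ndarray
    v3: np.ndarray
    distance: np.ndarray
    labels: np.ndarray           # 'none' or a sector name, size-ordered
    cutoff: float

    @property
    def selected(self) -> np.ndarray:
        return self.positions[self.labels != "none"]


@dataclass
class EigenSignificance:
    """Permutation-null calibration of the coupling-matrix spectrum."""

    threshold: float                 # 95th percentile of null max eigenvalues
    null_max_eigenvalues: np.ndarray
    significant: list[int]           # 0-based indices with eigenvalue > threshold
    significant_beyond_first: list[int]


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def filter_alignment(
    aln: MultipleAlignment,
    max_gaps: int = 100,
    loop_positions: np.ndarray | None = None,
    max_loop_gaps: int = 1,
) -> MultipleAlignment:
    """Drop sequences with too many gaps overall or inside a key loop.

    ``loop_positions`` are reference residue numbers (e.g. the 75-79
    ligand-binding loop); sequences with more than ``max_loop_gaps`` gaps
    there are removed regardless of their overall gap count.
    """
    gaps = aln.sequences == GAP
    keep = gaps.sum(axis=1) <= max_gaps
    if loop_positions is not None:
        cols = np.isin(aln.column_ref, np.asarray(loop_positions, dtype=int))
        if not cols.any():
            raise ValueError("loop positions not present in the column map")
        keep &= gaps[:, cols].sum(axis=1) <= max_loop_gaps
    if not keep.any():
        raise FluctuogramError("gap filtering removed every sequence")
    return aln.subset(keep)


def pairwise_identity(a: np.ndarray, b: np.ndarray,
                      min_coverage: float = 0.5) -> float:
    """Fractional identity over mutually non-gap columns.

    Pairs sharing fewer than ``min_coverage`` of the columns are scored 0
    (treated as non-redundant).
    """
    both = (a != GAP) & (b != GAP)
    if both.sum() < min_coverage * len(a):
        return 0.0
    return float((a[both] == b[both]).mean())


def remove_redundant(aln: MultipleAlignment, identity: float = 0.95) -> MultipleAlignment:
    """Greedy single-linkage redundancy removal at an identity threshold.

    Sequences at or above ``identity`` over mutually non-gap columns are
    linked; the first-seen sequence of each cluster is kept, in original
    order.
    """
    n = aln.n_sequences
    if n == 0:
        raise ValueError("empty alignment")
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    seqs = aln.sequences
    nongap = seqs != GAP
    min_cols = 0.5 * aln.n_columns
    for i in range(n):
        for j in range(i + 1, n):
            both = nongap[i] & nongap[j]
            cols = both.sum()
            if cols < min_cols:
                continue
            if (seqs[i][both] == seqs[j][both]).mean() >= identity:
                parent[find(j)] = find(i)
    seen: set[int] = set()
    keep = []
    for i in range(n):
        root = find(i)
        if root not in seen:
            seen.add(root)
            keep.append(i)
    return aln.subset(np.array(keep, dtype=int))


# ---------------------------------------------------------------------------
# conservation and coupling
# ---------------------------------------------------------------------------

def binarize(
    aln: MultipleAlignment,
    background: dict[str, float] | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> tuple[np.ndarray, ConservationProfile]:
    """Binary consensus matrix and the conservation profile.

    Per column the most prevalent non-gap residue is the consensus (ties
    break to the alphabetically lowest); entries are 1 where a sequence
    carries it, 0 otherwise (gaps count 0).  Frequencies are mixed with the
    background by the pseudocount before entropies and weights are formed,
    so fully conserved or absent consensus residues stay finite.
    """
    background = background or AA_BACKGROUND
    S, P = aln.sequences.shape
    consensus = np.empty(P, dtype="<U1")
    freq = np.empty(P)
    q = np.empty(P)
    x = np.zeros((S, P), dtype=np.uint8)
    for c in range(P):
        col = aln.sequences[:, c]
        letters, counts = np.unique(col[col != GAP], return_counts=True)
        if len(letters) == 0:
            warnings.warn(f"column {c} is all gaps")
            consensus[c], freq[c], q[c] = "X", 0.0, 0.05
            continue
        best = sorted(letters[counts == counts.max()])[0]  # lowest-alphabetical tie-break
        consensus[c] = best
        x[:, c] = col == best
        freq[c] = x[:, c].mean()
        q[c] = background.get(str(best), 0.05)
    f_reg = (1.0 - pseudocount) * freq + pseudocount * q
    entropy = (f_reg * np.log(f_reg / q)
               + (1.0 - f_reg) * np.log((1.0 - f_reg) / (1.0 - q)))
    profile = ConservationProfile(consensus, freq, f_reg, q, entropy, pseudocount)
    return x, profile


def conservation_weights(profile: ConservationProfile) -> np.ndarray:
    """Gradient weights ``phi_i = |ln(f'(1-q) / (q(1-f')))|``.

    Kept as a single substitution point: this is the one place where the
    entropy-gradient weighting convention enters the coupling matrix.
    """
    f, q = profile.reg_frequency, profile.background
    return np.abs(np.log(f * (1.0 - q) / (q * (1.0 - f))))


def sca_matrix(
    x: np.ndarray,
    profile: ConservationProfile,
    positions: np.ndarray | None = None,
) -> SCAMatrix:
    """Conservation-weighted absolute covariance matrix of the binary alignment."""
    x = np.asarray(x, dtype=float)
    S, P = x.shape
    if ((profile.frequency == 0) | (profile.frequency == 1)).any():
        warnings.warn("constant columns present; pseudocount regularization applies")
    cov = x.T @ x / S - np.outer(x.mean(axis=0), x.mean(axis=0))
    phi = conservation_weights(profile)
    mat = np.outer(phi, phi) * np.abs(cov)
    w, V = np.linalg.eigh(mat)
    order = np.argsort(w)[::-1]
    if positions is None:
        positions = np.arange(P) + 1
    return SCAMatrix(mat, w[order], V[:, order], np.asarray(positions, dtype=int))


def eigen_significance(
    sca: SCAMatrix,
    x: np.ndarray,
    profile: ConservationProfile,
    n_randomizations: int = 100,
    seed: int = 0,
    percentile: float = 95.0,
) -> EigenSignificance:
    """Permutation-null significance of the coupling-matrix eigenvalues.

    Each randomization permutes every column of the binary matrix
    independently across sequences (killing inter-column correlation while
    preserving conservation), rebuilds the matrix and records its largest
    eigenvalue.  Eigenvalues above the ``percentile`` of those null maxima
    are significant.  The leading eigenvector is conservation-dominated
    and reported separately from the sector-relevant remainder.
    """
    if n_randomizations < 10:
        raise ValueError("need at least 10 randomizations")
    rng = np.random.default_rng(seed)
    x = np.asarray(x, dtype=float)
    S, P = x.shape
    phi = conservation_weights(profile)
    null_max = np.empty(n_randomizations)
    for r in range(n_randomizations):
        xr = np.empty_like(x)
        for c in range(P):
            xr[:, c] = x[rng.permutation(S), c]
        cov = xr.T @ xr / S - np.outer(xr.mean(axis=0), xr.mean(axis=0))
        mat = np.outer(phi, phi) * np.abs(cov)
        null_max[r] = np.linalg.eigvalsh(mat)[-1]
    threshold = float(np.percentile(null_max, percentile))
    significant = [int(k) for k in np.nonzero(sca.eigenvalues > threshold)[0]]
    return EigenSignificance(
        threshold=threshold,
        null_max_eigenvalues=null_max,
        significant=significant,
        significant_beyond_first=[k for k in significant if k > 0],
    )


# ---------------------------------------------------------------------------
# sectors
# ---------------------------------------------------------------------------

def select_sectors(
    sca: SCAMatrix,
    cutoff: float = 0.07,
    n_sectors: int = 3,
    seed: int = 0,
) -> SectorAssignment:
    """Select and cluster co-evolving positions on the (v2, v3) plane.

    Positions whose distance from the origin on eigenvectors 2 and 3
    reaches ``cutoff`` are selected and partitioned into ``n_sectors``
    clusters by k-means on their angular coordinate (as unit vectors, so
    the circular topology is respected).  Labels are ordered by cluster
    size.
    """
    if sca.eigenvectors.shape[1] < 3:
        raise ValueError("need at least three eigenvectors")
    v2, v3 = sca.eigenvectors[:, 1], sca.eigenvectors[:, 2]
    distance = np.hypot(v2, v3)
    selected = distance >= cutoff
    n_sel = int(selected.sum())
    labels = np.full(len(distance), "none", dtype="<U16")
    if n_sel > 0:
        if n_sel < n_sectors:
            raise FluctuogramError(
                f"only {n_sel} positions beyond cutoff {cutoff}; "
                f"cannot form {n_sectors} sectors")
        ang = np.stack([v2[selected], v3[selected]], axis=1)
        ang = ang / np.linalg.norm(ang, axis=1)[:, None]
        _, assign = kmeans2(ang, n_sectors, minit="++",
                            seed=np.random.default_rng(seed))
        sizes = np.bincount(assign, minlength=n_sectors)
        order = np.argsort(sizes)[::-1]
        names = [_SECTOR_NAMES[r] if r < len(_SECTOR_NAMES) else f"sector{r + 1}"
                 for r in range(n_sectors)]
        rank_of = np.empty(n_sectors, dtype=int)
        rank_of[order] = np.arange(n_sectors)
        labels[selected] = [names[rank_of[a]] for a in assign]
    return SectorAssignment(sca.positions, v2, v3, distance, labels, cutoff)


def clean_matrix(
    sca: SCAMatrix,
    assignment: SectorAssignment,
    eigen_indices: tuple[int, ...] = (1, 2, 3),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Low-rank reconstruction restricted to the sector positions.

    Sums ``lambda_k v_k v_k^T`` over ``eigen_indices`` (0-based; the
    default keeps eigenvectors 2-4), restricted to the selected positions,
    with rows grouped by sector and ordered by distance to origin within
    each sector.  Returns ``(matrix, positions, labels)`` in that order.
    """
    for k in eigen_indices:
        if not 0 <= k < len(sca.eigenvalues):
            raise ValueError(f"eigenvector index {k} out of range")
    sel = assignment.labels != "none"
    sector_names = [n for n in _SECTOR_NAMES if n in assignment.labels]
    sector_names += sorted(set(assignment.labels[sel]) - set(sector_names) - {"none"})
    order: list[int] = []
    for name in sector_names:
        idx = np.nonzero(assignment.labels == name)[0]
        order.extend(idx[np.argsort(assignment.distance[idx])[::-1]])
    order = np.array(order, dtype=int)
    recon = np.zeros_like(sca.matrix)
    for k in eigen_indices:
        v = sca.eigenvectors[:, k]
        recon += sca.eigenvalues[k] * np.outer(v, v)
    sub = recon[np.ix_(order, order)]
    return sub, sca.positions[order], assignment.labels[order]
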