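"""File formats: PDB, the XYZT trajectory dialect, TSV tables, FASTA.

Conventions: all tables are tab-separated with ``#``-prefixed header
comments; reals are serialized with ``repr`` precision so round trips are
bit-faithful; residue numbering is 1-based everywhere user-facing, site
ids are 0-based internals (this module is the boundary).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np

from .cg import AtomicStructure, CGMapping, CGTrajectory, ElasticNetwork
from .errors import FormatError
from .fluctgram import Fluctuogram, WindowingScheme
from .fluctmatch import ConvergenceTrace
from .sca import MultipleAlignment

_G = "%.17g"


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def read_pdb(path: str | Path, model: int | None = None) -> list[AtomicStructure]:
    """Read a (possibly multi-model) PDB file into atomic structures.

    Returns one :class:`AtomicStructure` per model; pass ``model`` to keep
    a single one.  Masses come from the element assignment.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure("input", str(path))
    except Exception as exc:  # Bio.PDB raises assorted exceptions on bad input
        raise FormatError(f"cannot parse PDB file {path}: {exc}") from None
    frames = []
    for mdl in structure:
        names, res_idx, res_names, masses, coords = [], [], [], [], []
        for chain in mdl:
            for residue in chain:
                for atom in residue:
                    names.append(atom.get_name())
                    res_idx.append(residue.get_id()[1])
                    res_names.append(residue.get_resname())
                    mass = atom.mass
                    if mass is None or not np.isfinite(mass) or mass <= 0:
                        warnings.warn(f"no mass for atom {atom.get_name()}; using 12.0")
                        mass = 12.0
                    masses.append(mass)
                    coords.append(atom.get_coord())
        frames.append(AtomicStructure(names, np.array(res_idx), res_names,
                                      np.array(masses), np.array(coords)))
    if not frames:
        raise FormatError(f"no models found in {path}")
    if model is not None:
        return [frames[model]]
    return frames


# ---------------------------------------------------------------------------
# XYZT trajectory dialect
# ---------------------------------------------------------------------------

def write_xyzt(traj: CGTrajectory, path: str | Path) -> None:
    """Write the plain-text XYZT dialect: header ``nsites nframes``, then
    per frame one line with the time (ns) followed by one ``x y z`` line
    per site, full double precision."""
    with open(path, "w") as fh:
        fh.write(f"{traj.n_sites} {traj.n_frames}\n")
        for t, frame in zip(traj.times, traj.coordinates):
            fh.write(_G % t + "\n")
            for x, y, z in frame:
                fh.write(f"{_G % x} {_G % y} {_G % z}\n")


def read_xyzt(path: str | Path) -> CGTrajectory:
    """Read the XYZT dialect written by :func:`write_xyzt`."""
    with open(path) as fh:
        tokens = fh.read().split()
    try:
        n_sites, n_frames = int(tokens[0]), int(tokens[1])
        body = np.array(tokens[2:], dtype=float)
    except (IndexError, ValueError) as exc:
        raise FormatError(f"malformed XYZT file {path}: {exc}") from None
    per_frame = 1 + 3 * n_sites
    if len(body) != n_frames * per_frame:
        raise FormatError(
            f"XYZT file {path}: expected {n_frames * per_frame} values, "
            f"found {len(body)}")
    body = body.reshape(n_frames, per_frame)
    times = body[:, 0]
    coords = body[:, 1:].reshape(n_frames, n_sites, 3)
    return CGTrajectory(times, coords)


# ---------------------------------------------------------------------------
# elastic network TSV
# ---------------------------------------------------------------------------

def write_network(network: ElasticNetwork, path: str | Path) -> None:
    """Serialize a network as TSV: ``i j b_ij k_ij`` rows.

    The temperature and the rest geometry (needed to rebuild the normal
    modes) travel in ``#`` comment lines.
    """
    with open(path, "w") as fh:
        fh.write(f"# T={_G % network.temperature}\n")
        for s, (xyz, m) in enumerate(zip(network.coordinates, network.masses)):
            fh.write("# site\t%d\t%s\t%s\t%s\t%s\n"
                     % (s, _G % xyz[0], _G % xyz[1], _G % xyz[2], _G % m))
        fh.write("# i\tj\tb_ij\tk_ij\n")
        for (i, j), b, k in zip(network.bond_indices, network.rest_lengths,
                                network.force_constants):
            fh.write(f"{i}\t{j}\t{_G % b}\t{_G % k}\n")


def read_network(path: str | Path) -> ElasticNetwork:
    """Read a network TSV written by :func:`write_network`."""
    temperature = None
    sites: list[tuple[float, float, float, float]] = []
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("T="):
                    temperature = float(body[2:])
                elif body.startswith("site"):
                    parts = body.split("\t")
                    sites.append(tuple(float(v) for v in parts[2:6]))
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(f"malformed network row in {path}: {line!r}")
            rows.append((int(parts[0]), int(parts[1]),
                         float(parts[2]), float(parts[3])))
    if temperature is None or not sites or not rows:
        raise FormatError(f"incomplete network file {path}")
    coords = np.array([s[:3] for s in sites])
    masses = np.array([s[3] for s in sites])
    bonds = np.array([(r[0], r[1]) for r in rows], dtype=int)
    return ElasticNetwork(coords, bonds,
                          np.array([r[2] for r in rows]),
                          np.array([r[3] for r in rows]),
                          temperature=temperature, masses=masses)


def write_trace(trace: ConvergenceTrace, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# converged={int(trace.converged)} iterations={trace.n_iterations}\n")
        fh.write("# iter\trms_dk\trms_dvar\n")
        for m, (dk, dv) in enumerate(zip(trace.rms_dk, trace.rms_dvar)):
            fh.write(f"{m}\t{_G % dk}\t{_G % dv}\n")


def read_trace(path: str | Path) -> ConvergenceTrace:
    converged = False
    dk, dv = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("# converged="):
                converged = line.split("=")[1].split()[0] == "1"
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            dk.append(float(parts[1]))
            dv.append(float(parts[2]))
    return ConvergenceTrace(np.array(dk), np.array(dv), len(dk), converged)


# ---------------------------------------------------------------------------
# fluctuogram run directory
# ---------------------------------------------------------------------------

def write_fluctuogram(fluct: Fluctuogram, directory: str | Path) -> None:
    """Write one directory per run: ``windows.tsv`` plus per-window network
    and convergence-trace files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scheme = fluct.scheme
    with open(directory / "windows.tsv", "w") as fh:
        fh.write("# window\tstart_frame\tmidpoint_ns\n")
        for w in range(fluct.n_windows):
            start = int(scheme.starts[w]) if scheme is not None else -1
            fh.write(f"{w}\t{start}\t{_G % fluct.times[w]}\n")
    np.savetxt(directory / "pool.tsv", fluct.pool, fmt="%d", delimiter="\t",
               header="i\tj")
    for w, (net, trace) in enumerate(zip(fluct.networks, fluct.traces)):
        write_network(net, directory / f"window_{w:04d}.network.tsv")
        write_trace(trace, directory / f"window_{w:04d}.trace.tsv")


def read_fluctuogram(directory: str | Path) -> Fluctuogram:
    directory = Path(directory)
    windows = []
    with open(directory / "windows.tsv") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            w, start, mid = line.split("\t")
            windows.append((int(w), int(start), float(mid)))
    if not windows:
        raise FormatError(f"empty windows.tsv in {directory}")
    pool = np.loadtxt(directory / "pool.tsv", dtype=int, ndmin=2)
    networks, traces = [], []
    for w, _, _ in windows:
        networks.append(read_network(directory / f"window_{w:04d}.network.tsv"))
        traces.append(read_trace(directory / f"window_{w:04d}.trace.tsv"))
    return Fluctuogram(
        pool=pool,
        times=np.array([m for _, _, m in windows]),
        networks=networks,
        traces=traces,
    )


def write_metrics(residues: np.ndarray, windows: np.ndarray, metric: str,
                  values: np.ndarray, fh) -> None:
    """Append a (window x residue) metric block in long format."""
    for w_i, w in enumerate(windows):
        for r_i, r in enumerate(residues):
            v = values[w_i, r_i]
            fh.write(f"{r}\t{w}\t{metric}\t{_G % v if np.isfinite(v) else 'NA'}\n")


# ---------------------------------------------------------------------------
# mapping table
# ---------------------------------------------------------------------------

def write_mapping(mapping: CGMapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# site\tresidue\tkind\tmass\tatoms\n")
        for s in mapping.sites:
            atoms = ",".join(str(a) for a in s.member_atom_ids)
            fh.write(f"{s.site_id}\t{s.residue_index}\t{s.kind}\t"
                     f"{_G % s.mass}\t{atoms}\n")


# ---------------------------------------------------------------------------
# alignment FASTA
# ---------------------------------------------------------------------------

def read_fasta_alignment(path: str | Path) -> MultipleAlignment:
    """Read an aligned FASTA file (all records equal length)."""
    from Bio import SeqIO

    ids, rows = [], []
    for record in SeqIO.parse(str(path), "fasta"):
        ids.append(record.id)
        rows.append(list(str(record.seq).upper()))
    if not rows:
        raise FormatError(f"no sequences in {path}")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise FormatError(f"alignment {path} is not rectangular: lengths {lengths}")
    seqs = np.array(rows)
    return MultipleAlignment(ids, seqs, np.arange(seqs.shape[1]) + 1)


def write_fasta_alignment(aln: MultipleAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, row in zip(aln.ids, aln.sequences):
            fh.write(f">{sid}\n{''.join(row)}\n")


# ---------------------------------------------------------------------------
# residue lists and reports
# ---------------------------------------------------------------------------

def read_residue_list(path: str | Path) -> np.ndarray:
    """Plain text, one 1-based residue number per line; ``#`` comments allowed."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#")[0].strip()
            if not line:
                continue
            try:
                out.append(int(line))
            except ValueError:
                raise FormatError(f"bad residue number {line!r} in {path}") from None
    return np.array(sorted(set(out)), dtype=int)


def write_residue_list(residues: np.ndarray, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in residues:
            fh.write(f"{int(r)}\n")


def write_json(payload: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
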