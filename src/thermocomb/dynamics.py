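"""Coordinate-ensemble analysis: RMSF, Rg, and dynamics cross-correlation.

The dynamics cross-correlation matrix (DCCM) over an aligned ensemble is

    C_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2> <|dr_j|^2>),   dr_i = r_i - <r_i>

computed on a selection (conventionally the C-alpha atoms), with entries in
[-1, 1]: positive for residues moving together, negative for anticorrelated
motion.  Replicate trajectories are combined by element-wise averaging of the
per-replicate correlation matrices.  All fluctuation analysis requires prior
rigid-body superposition (Kabsch) onto the ensemble mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


class DynamicsError(ValueError):
    pass


@dataclass
class Ensemble:
    """F frames of N selected atoms, coordinates in Angstrom."""

    coords: np.ndarray                      # (F, N, 3)
    residue_ids: np.ndarray | None = None   # (N,), 1-based
    superposed: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise DynamicsError(f"coords must be (F, N, 3), got {self.coords.shape}")
        if self.coords.shape[0] < 2:
            raise DynamicsError("an ensemble needs at least 2 frames")
        if not np.all(np.isfinite(self.coords)):
            raise DynamicsError("non-finite coordinates")
        if self.residue_ids is None:
            self.residue_ids = np.arange(1, self.coords.shape[1] + 1)
        else:
            self.residue_ids = np.asarray(self.residue_ids)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


def _kabsch(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Optimal rotation aligning centered P onto centered Q."""
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def superpose(e: Ensemble, reference: str | np.ndarray = "mean") -> Ensemble:
    """Rigid-body align every frame (rotation + translation) onto a reference.

    ``reference="mean"`` runs the standard two-pass scheme: align to frame 0,
    recompute the mean structure, realign to it.  Per-frame RMSD after
    alignment never exceeds the RMSD before.
    """
    if e.n_atoms < 3:
        raise DynamicsError("superposition needs at least 3 atoms")

    def align_to(coords, ref):
        ref_c = ref - ref.mean(axis=0)
        out = np.empty_like(coords)
        for f in range(coords.shape[0]):
            frame = coords[f] - coords[f].mean(axis=0)
            Rmat = _kabsch(frame, ref_c)
            out[f] = frame @ Rmat.T
        return out

    if isinstance(reference, str):
        if reference != "mean":
            raise DynamicsError(f"unknown reference {reference!r}")
        pass1 = align_to(e.coords, e.coords[0])
        mean = pass1.mean(axis=0)
        aligned = align_to(pass1, mean)
    else:
        aligned = align_to(e.coords, np.asarray(reference, dtype=float))
    return Ensemble(aligned, residue_ids=e.residue_ids, superposed=True)


def _require_superposed(e: Ensemble, what: str) -> None:
    if not e.superposed:
        warnings.warn(
            f"{what} on an ensemble not marked superposed; "
            "rigid-body motion will inflate fluctuations",
            stacklevel=3,
        )


def rmsf(e: Ensemble) -> np.ndarray:
    """Per-atom root mean square fluctuation about the ensemble mean (Angstrom)."""
    _require_superposed(e, "RMSF")
    mean = e.coords.mean(axis=0)
    d2 = np.sum((e.coords - mean) ** 2, axis=2)   # (F, N)
    return np.sqrt(d2.mean(axis=0))


def radius_of_gyration(e: Ensemble, masses: np.ndarray | None = None) -> np.ndarray:
    """Per-frame radius of gyration (Angstrom); uniform masses by default."""
    if masses is None:
        w = np.full(e.n_atoms, 1.0 / e.n_atoms)
    else:
        masses = np.asarray(masses, dtype=float)
        w = masses / masses.sum()
    com = np.einsum("fnc,n->fc", e.coords, w)
    d2 = np.sum((e.coords - com[:, None, :]) ** 2, axis=2)
    return np.sqrt(np.einsum("fn,n->f", d2, w))


@dataclass
class DCCMatrix:
    """N x N displacement correlation coefficients, replicate-averaged."""

    matrix: np.ndarray
    n_replicates: int = 1
    flagged: np.ndarray | None = None   # True where variance was zero

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.flagged is None:
            self.flagged = np.zeros(self.matrix.shape, dtype=bool)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def plot(self, ax=None):  # pragma: no cover - thin matplotlib wrapper
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(self.matrix, vmin=-1, vmax=1, cmap="RdBu_r",
                       origin="lower", extent=(1, self.n, 1, self.n))
        ax.set_xlabel("residue")
        ax.set_ylabel("residue")
        plt.colorbar(im, ax=ax, label="C_ij")
        return ax


def _dccm_single(e: Ensemble) -> tuple[np.ndarray, np.ndarray]:
    _require_superposed(e, "DCCM")
    d = e.coords - e.coords.mean(axis=0)              # (F, N, 3)
    cov = np.einsum("fic,fjc->ij", d, d) / e.n_frames  # <dr_i . dr_j>
    var = np.diag(cov).copy()
    zero = var <= 0
    var[zero] = 1.0
    denom = np.sqrt(np.outer(var, var))
    C = cov / denom
    flagged = np.zeros_like(C, dtype=bool)
    if zero.any():
        flagged[zero, :] = True
        flagged[:, zero] = True
        C[flagged] = np.nan
    np.fill_diagonal(C, np.where(zero, np.nan, 1.0))
    return C, flagged


def dccm(replicates: Ensemble | Sequence[Ensemble]) -> DCCMatrix:
    """Cross-correlation matrix, element-wise averaged over replicate ensembles."""
    if isinstance(replicates, Ensemble):
        replicates = [replicates]
    if not replicates:
        raise DynamicsError("no ensembles supplied")
    n = replicates[0].n_atoms
    mats, flags = [], []
    for e in replicates:
        if e.n_atoms != n:
            raise DynamicsError("replicates differ in selection size")
        C, fl = _dccm_single(e)
        mats.append(C)
        flags.append(fl)
    avg = np.mean(mats, axis=0)
    flagged = np.any(flags, axis=0)
    return DCCMatrix(matrix=avg, n_replicates=len(mats), flagged=flagged)


def region_correlation(m: DCCMatrix, region_a: tuple[int, int],
                       region_b: tuple[int, int]) -> dict:
    """Summary statistics of the C_ij cross-block between two residue ranges.

    Ranges are 1-based inclusive (``(220, 237)`` means residues 220-237).
    """
    def _slice(region):
        lo, hi = region
        if not (1 <= lo <= hi <= m.n):
            raise DynamicsError(f"region {region} outside 1..{m.n}")
        return slice(lo - 1, hi)

    block = m.matrix[_slice(region_a), _slice(region_b)]
    vals = block[np.isfinite(block)]
    if vals.size == 0:
        raise DynamicsError("region cross-block contains no finite entries")
    return {
        "mean": float(vals.mean()),
        "min": float(vals.min()),
        "max": float(vals.max()),
        "n_pairs": int(vals.size),
    }


def delta_rmsf(variant_profile: np.ndarray, wt_profile: np.ndarray,
               normalize: bool = True) -> np.ndarray:
    """Per-residue RMSF change of a variant relative to the wild type.

    Sign convention: negative means the variant is locally stabilized.  With
    ``normalize=True`` the difference is divided by the wild-type RMSF
    (dimensionless fractional change); otherwise the plain difference in
    Angstrom is returned.
    """
    v = np.asarray(variant_profile, dtype=float)
    w = np.asarray(wt_profile, dtype=float)
    if v.shape != w.shape:
        raise DynamicsError("profiles have different residue counts")
    diff = v - w
    if not normalize:
        return diff
    if np.any(w <= 0):
        raise DynamicsError("wild-type RMSF must be positive for normalization")
    return diff / w


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_pdb_ensemble(path, selection: str = "CA") -> Ensemble:
    """Read a multi-model PDB (MODEL/ENDMDL) into an ensemble of one selection."""
    import biotite.structure.io.pdb as pdb

    stack = pdb.PDBFile.read(str(path)).get_structure(model=None)
    if selection:
        mask = stack.atom_name == selection
        if not mask.any():
            raise DynamicsError(f"no atoms named {selection!r} in {path}")
        stack = stack[:, mask]
    return Ensemble(
        coords=np.asarray(stack.coord, dtype=float),
        residue_ids=np.asarray(stack.res_id[0] if stack.res_id.ndim > 1 else stack.res_id),
    )


def read_xyz_ensemble(path) -> Ensemble:
    """Read a multi-frame XYZ trajectory (atom count, comment, N coordinate lines)."""
    frames = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                break
            n = int(header)
            fh.readline()  # comment
            coords = np.empty((n, 3))
            for i in range(n):
                parts = fh.readline().split()
                coords[i] = [float(x) for x in parts[1:4]]
            frames.append(coords)
    if len(frames) < 2:
        raise DynamicsError(f"{path} holds fewer than 2 frames")
    return Ensemble(np.stack(frames))


def write_xyz_ensemble(path, e: Ensemble, element: str = "C") -> None:
    with open(path, "w") as fh:
        for f in range(e.n_frames):
            fh.write(f"{e.n_atoms}\nframe {f}\n")
            for x, y, z in e.coords[f]:
                fh.write(f"{element} {x:.6f} {y:.6f} {z:.6f}\n")


def dccm_to_csv(m: DCCMatrix, path) -> None:
    np.savetxt(path, m.matrix, delimiter=",", fmt="%.6f")


def profiles_to_csv(path, rmsf_values=None, rg_values=None) -> None:
    import pandas as pd

    if rmsf_values is not None:
        pd.DataFrame({
            "residue": np.arange(1, len(rmsf_values) + 1),
            "rmsf_angstrom": rmsf_values,
        }).to_csv(path, index=False)
    elif rg_values is not None:
        pd.DataFrame({
            "frame": np.arange(len(rg_values)),
            "rg_angstrom": rg_values,
        }).to_csv(path, index=False)
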