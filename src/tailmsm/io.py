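"""File I/O: multi-model PDB coordinates, feature/discrete trajectories as
CSV and HDF5, and tICA model serialization.

HDF5 layout for trajectories: one dataset per trajectory under the group
``/trajectories`` (``frames x features`` floats, or 1D ints for discrete
state sequences), with the frame spacing stored as the dataset attribute
``lag_unit_ns`` and feature labels as the attribute ``labels``.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .featurization import FeatureTrajectory


# --------------------------------------------------------------------------
# multi-model PDB (CA-only bead chains)
# --------------------------------------------------------------------------

def write_pdb(path, coords: np.ndarray) -> None:
    """Write (frames, n_beads, 3) coordinates (Angstrom) as a multi-model
    PDB of CA atoms (one GLY residue per bead, MODEL/ENDMDL per frame)."""
    import mdtraj as md

    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    n_beads = coords.shape[1]
    top = md.Topology()
    ch = top.add_chain()
    carbon = md.element.carbon
    prev = None
    for i in range(n_beads):
        res = top.add_residue("GLY", ch)
        atom = top.add_atom("CA", carbon, res)
        if prev is not None:
            top.add_bond(prev, atom)
        prev = atom
    traj = md.Trajectory(coords / 10.0, top)  # A -> nm
    traj.save_pdb(str(path))


def read_pdb(path) -> np.ndarray:
    """Read a multi-model PDB into (frames, n_atoms, 3) coordinates in A."""
    import mdtraj as md

    traj = md.load_pdb(str(path))
    return np.asarray(traj.xyz, dtype=float) * 10.0  # nm -> A


# --------------------------------------------------------------------------
# feature trajectories
# --------------------------------------------------------------------------

def write_features_csv(path, ftraj: FeatureTrajectory) -> None:
    df = pd.DataFrame(ftraj.values, columns=ftraj.labels)
    df.insert(0, "frame", np.arange(ftraj.n_frames))
    df.to_csv(path, index=False)


def read_features_csv(path, dt_ns: float = 1.0,
                      traj_id: str | None = None) -> FeatureTrajectory:
    df = pd.read_csv(path)
    if "frame" in df.columns:
        df = df.drop(columns=["frame"])
    return FeatureTrajectory(df.to_numpy(dtype=float), list(df.columns), dt_ns,
                             traj_id or Path(path).stem)


def write_features_h5(path, ftrajs: list[FeatureTrajectory]) -> None:
    with h5py.File(path, "w") as fh:
        grp = fh.create_group("trajectories")
        for f in ftrajs:
            ds = grp.create_dataset(f.traj_id, data=f.values, track_times=False)
            ds.attrs["lag_unit_ns"] = f.dt_ns
            ds.attrs["labels"] = [s.encode() for s in f.labels]


def read_features_h5(path) -> list[FeatureTrajectory]:
    out = []
    with h5py.File(path, "r") as fh:
        for name, ds in fh["trajectories"].items():
            labels = [s.decode() if isinstance(s, bytes) else str(s)
                      for s in ds.attrs.get("labels", [])]
            out.append(FeatureTrajectory(ds[()], labels,
                                         float(ds.attrs["lag_unit_ns"]), name))
    return sorted(out, key=lambda f: f.traj_id)


# --------------------------------------------------------------------------
# discrete trajectories
# --------------------------------------------------------------------------

def write_dtraj_csv(path, dtraj: np.ndarray) -> None:
    pd.DataFrame({"state": np.asarray(dtraj, dtype=np.int64)}).to_csv(
        path, index=False)


def read_dtraj_csv(path) -> np.ndarray:
    return pd.read_csv(path)["state"].to_numpy(dtype=np.int64)


def write_dtrajs_h5(path, dtrajs: dict[str, np.ndarray],
                    lag_unit_ns: float = 1.0) -> None:
    with h5py.File(path, "w") as fh:
        grp = fh.create_group("dtrajs")
        for name, d in dtrajs.items():
            ds = grp.create_dataset(name, data=np.asarray(d, dtype=np.int64),
                                    track_times=False)
            ds.attrs["lag_unit_ns"] = lag_unit_ns


def read_dtrajs_h5(path) -> dict[str, np.ndarray]:
    with h5py.File(path, "r") as fh:
        return {name: ds[()].astype(np.int64)
                for name, ds in fh["dtrajs"].items()}


# --------------------------------------------------------------------------
# tICA model serialization
# --------------------------------------------------------------------------

def write_tica_h5(path, results) -> None:
    """Persist TICAResults: covariances, spectrum, projection, metadata."""
    with h5py.File(path, "w") as fh:
        grp = fh.create_group("tica")
        for name in ("mean", "c0", "ctau", "eigenvalues", "projection"):
            grp.create_dataset(name, data=getattr(results, name),
                               track_times=False)
        grp.attrs["lag"] = results.lag
        grp.attrs["dt_ns"] = results.dt_ns
        grp.attrs["n_components"] = results.n_components


def read_tica_h5(path):
    from .tica import TICAResults

    with h5py.File(path, "r") as fh:
        grp = fh["tica"]
        return TICAResults(
            lag=int(grp.attrs["lag"]), dt_ns=float(grp.attrs["dt_ns"]),
            mean=grp["mean"][()], c0=grp["c0"][()], ctau=grp["ctau"][()],
            eigenvalues=grp["eigenvalues"][()], projection=grp["projection"][()],
            n_components=int(grp.attrs["n_components"]),
        )


# --------------------------------------------------------------------------
# free-energy surface
# --------------------------------------------------------------------------

def write_fes_csv(path, fes) -> None:
    """Free-energy surface as a tidy CSV grid (bin centers, P, Delta G)."""
    xc = 0.5 * (fes.x_edges[:-1] + fes.x_edges[1:])
    yc = 0.5 * (fes.y_edges[:-1] + fes.y_edges[1:])
    X, Y = np.meshgrid(xc, yc, indexing="ij")
    pd.DataFrame({
        "ic1": X.ravel(), "ic2": Y.ravel(),
        "probability": fes.probability.ravel(),
        "delta_g_kcal_mol": fes.delta_g.ravel(),
    }).to_csv(path, index=False)
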