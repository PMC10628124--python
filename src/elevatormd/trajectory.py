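"""Topology/trajectory handling and elevator-geometry metrics.

The elevator mechanism of SLC26-family transporters is quantified here by
rigid-body observables of the transport domain relative to the scaffold
domain of the same protomer: the vertical (z) offset of their centers of
geometry, the angle subtended at the hinge by the bottom halves of the two
domains, and landmark Calpha-Calpha distances that report on lateral
expansion of the transmembrane domain (TMD).

Residue-range domain definitions follow the 7LGU author numbering.  All
geometry uses raw (wrapped) coordinates and assumes the protein is whole and
centered in the box; see :func:`assert_whole`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MolecularSystem",
    "TrajectoryFrame",
    "DomainSpec",
    "load_system",
    "iter_frames",
    "resolve_selection",
    "center_of_geometry",
    "td_sd_zshift",
    "td_sd_rotation",
    "landmark_distance",
    "assert_whole",
]


@dataclass
class MolecularSystem:
    """Static per-atom description of a simulation system.

    Charges are in elementary charge units (e), masses in amu.  Atom order
    is the file/topology order; indices used throughout the package are
    0-based positions into these arrays.
    """

    names: np.ndarray
    resids: np.ndarray
    resnames: np.ndarray
    chains: np.ndarray
    charges: np.ndarray
    masses: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.names)
        for attr in ("resids", "resnames", "chains", "charges", "masses"):
            if len(getattr(self, attr)) != n:
                raise ValueError(f"{attr} length does not match atom count {n}")
        if not np.all(np.isfinite(self.charges)):
            raise ValueError("non-finite charges")
        if not np.all(np.isfinite(self.masses)):
            raise ValueError("non-finite masses")

    @property
    def n_atoms(self) -> int:
        return len(self.names)


@dataclass
class TrajectoryFrame:
    """One snapshot: coordinates (Angstrom), orthorhombic box, time (ps).

    ``z_unwrapped`` is populated by :func:`elevatormd.electrostatics.unwrap_z`
    and is required for displacement-charge evaluation.
    """

    xyz: np.ndarray
    box: np.ndarray
    time: float = 0.0
    z_unwrapped: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError("xyz must be (n_atoms, 3)")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive lengths")


# Default domain ranges (author numbering of the 7LGU model).  The hinge is
# the upper half of the scaffold domain.
_DEFAULT_RANGES: dict[str, tuple[tuple[int, int], ...]] = {
    "transport": ((76, 151), (173, 196), (332, 436)),
    "scaffold": ((207, 305), (436, 507)),
    "transport_bottom": ((76, 93), (117, 137), (185, 196), (351, 380)),
    "scaffold_bottom": ((207, 216), (272, 292), (449, 507)),
    "hinge": ((217, 271), (293, 305), (437, 448)),
    "tmd": ((76, 505),),
}


@dataclass
class DomainSpec:
    """Named residue-range selections for the elevator-domain metrics."""

    ranges: dict[str, tuple[tuple[int, int], ...]] = field(
        default_factory=lambda: dict(_DEFAULT_RANGES)
    )

    def __post_init__(self) -> None:
        for name, rngs in self.ranges.items():
            if not rngs:
                raise ValueError(f"domain {name!r} has no ranges")
            for lo, hi in rngs:
                if hi < lo:
                    raise ValueError(f"domain {name!r}: bad range {(lo, hi)}")
        if "hinge" in self.ranges and "scaffold" in self.ranges:
            hinge = self.residue_set("hinge")
            scaffold = self.residue_set("scaffold")
            if not hinge <= scaffold:
                raise ValueError("hinge residues must be a subset of the scaffold")

    def residue_set(self, name: str) -> set[int]:
        return {
            r for lo, hi in self.ranges[name] for r in range(lo, hi + 1)
        }


def load_system(
    topology_path: str | Path,
    charge_table_path: str | Path | None = None,
) -> MolecularSystem:
    """Read a PDB topology plus an optional charge/mass table.

    PDB files carry no partial charges; a delimited table with columns
    ``atom_index`` (0-based topology order), ``charge_e`` and ``mass_amu``
    supplies them.  Atoms absent from the table keep charge 0 (a warning is
    emitted if no table is given) and an element-guessed mass.
    """
    import MDAnalysis as mda

    u = mda.Universe(str(topology_path))
    atoms = u.atoms
    n = atoms.n_atoms
    try:
        chains = atoms.chainIDs.astype(str)
    except AttributeError:
        chains = atoms.segids.astype(str)

    charges = np.zeros(n)
    try:
        masses = atoms.masses.astype(float)
    except Exception:  # pragma: no cover - mass guessing rarely fails on PDB
        masses = np.zeros(n)

    if charge_table_path is None:
        warnings.warn(
            "no charge table supplied; all partial charges default to 0 e",
            stacklevel=2,
        )
    else:
        table = pd.read_csv(charge_table_path)
        idx = table["atom_index"].to_numpy(dtype=int)
        if len(np.unique(idx)) != len(idx):
            raise ValueError("duplicate atom indices in charge table")
        if idx.min() < 0 or idx.max() >= n:
            raise ValueError(
                f"charge table refers to atom index {idx.max()} outside 0..{n - 1}"
            )
        charges[idx] = table["charge_e"].to_numpy(dtype=float)
        if "mass_amu" in table.columns:
            masses[idx] = table["mass_amu"].to_numpy(dtype=float)

    return MolecularSystem(
        names=atoms.names.astype(str),
        resids=atoms.resids.astype(int),
        resnames=atoms.resnames.astype(str),
        chains=chains,
        charges=charges,
        masses=masses,
    )


def iter_frames(
    trajectory_path: str | Path,
    system: MolecularSystem,
    topology_path: str | Path | None = None,
) -> Iterator[TrajectoryFrame]:
    """Stream frames of an XTC/DCD/TRR trajectory in file order.

    The trajectory atom count must match ``system``.  A truncated file
    raises an error naming the last frame read successfully.
    """
    import MDAnalysis as mda

    if topology_path is not None:
        u = mda.Universe(str(topology_path), str(trajectory_path))
    else:
        n = system.n_atoms
        u = mda.Universe.empty(n, trajectory=True)
        u.load_new(str(trajectory_path))
    if u.atoms.n_atoms != system.n_atoms:
        raise ValueError(
            f"trajectory has {u.atoms.n_atoms} atoms but system has "
            f"{system.n_atoms}"
        )
    last_good = -1
    try:
        for ts in u.trajectory:
            frame = TrajectoryFrame(
                xyz=ts.positions.astype(float).copy(),
                box=ts.dimensions[:3].astype(float).copy(),
                time=float(ts.time),
            )
            last_good = ts.frame
            yield frame
    except (OSError, EOFError, RuntimeError) as exc:
        raise IOError(
            f"trajectory read failed after frame {last_good}: {exc}"
        ) from exc


def resolve_selection(
    system: MolecularSystem,
    residue_ranges: Iterable[tuple[int, int]],
    atom_names: Sequence[str] | None = None,
    chain: str | None = None,
) -> np.ndarray:
    """Atom indices whose residue id falls in any of the given ranges.

    Optionally restricted to a chain and to atom names (e.g. ``["CA"]`` or
    the backbone triple ``["N", "CA", "C"]``).  An empty result raises, to
    guard against silent mis-selection.
    """
    mask = np.zeros(system.n_atoms, dtype=bool)
    for lo, hi in residue_ranges:
        mask |= (system.resids >= lo) & (system.resids <= hi)
    if atom_names is not None:
        mask &= np.isin(system.names, list(atom_names))
    if chain is not None:
        mask &= system.chains == chain
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError(
            f"selection is empty (ranges={list(residue_ranges)}, "
            f"names={atom_names}, chain={chain})"
        )
    return idx


def center_of_geometry(frame: TrajectoryFrame, selection: np.ndarray) -> np.ndarray:
    """Unweighted mean position of the selected atoms (Angstrom)."""
    selection = np.asarray(selection)
    if selection.size == 0:
        raise ValueError("empty selection")
    return frame.xyz[selection].mean(axis=0)


def _domain_cog(
    frame: TrajectoryFrame,
    system: MolecularSystem,
    domains: DomainSpec,
    name: str,
    chain: str | None,
) -> np.ndarray:
    if name not in domains.ranges:
        raise KeyError(f"domain {name!r} not defined")
    sel = resolve_selection(system, domains.ranges[name], chain=chain)
    return center_of_geometry(frame, sel)


def td_sd_zshift(
    frame: TrajectoryFrame,
    system: MolecularSystem,
    domains: DomainSpec | None = None,
    chain: str | None = None,
) -> float:
    """z offset of transport-domain COG relative to the scaffold-domain COG.

    Negative values indicate a transport domain sitting below the scaffold
    along the membrane normal; the compact-to-expanded transition of an
    elevator transporter shows up as a downward (more negative) shift.
    """
    domains = domains or DomainSpec()
    z_t = _domain_cog(frame, system, domains, "transport", chain)[2]
    z_s = _domain_cog(frame, system, domains, "scaffold", chain)[2]
    return float(z_t - z_s)


def td_sd_rotation(
    frame: TrajectoryFrame,
    system: MolecularSystem,
    domains: DomainSpec | None = None,
    chain: str | None = None,
) -> float:
    """Transport-scaffold angle at the hinge, in degrees within [0, 180].

    The angle between (COG of the transport-domain bottom half - COG of the
    hinge) and (COG of the scaffold-domain bottom half - COG of the hinge);
    the hinge is the upper half of the scaffold domain.
    """
    domains = domains or DomainSpec()
    hinge = _domain_cog(frame, system, domains, "hinge", chain)
    tb = _domain_cog(frame, system, domains, "transport_bottom", chain)
    sb = _domain_cog(frame, system, domains, "scaffold_bottom", chain)
    v_t = tb - hinge
    v_s = sb - hinge
    nt, ns = np.linalg.norm(v_t), np.linalg.norm(v_s)
    if nt == 0 or ns == 0:
        raise ValueError("zero-length domain vector; degenerate geometry")
    cosang = np.clip(np.dot(v_t, v_s) / (nt * ns), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def landmark_distance(
    frame: TrajectoryFrame,
    system: MolecularSystem,
    residue_a: int,
    residue_b: int,
    atom_name: str = "CA",
    chain: str | None = None,
) -> float:
    """Euclidean distance between one named atom of two residues (Angstrom).

    Intra-protein, so no periodic imaging is applied.
    """
    pos = []
    for resid in (residue_a, residue_b):
        mask = (system.resids == resid) & (system.names == atom_name)
        if chain is not None:
            mask &= system.chains == chain
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise ValueError(
                f"atom {atom_name!r} of residue {resid} not found"
                + (f" in chain {chain!r}" if chain else "")
            )
        pos.append(frame.xyz[idx[0]])
    return float(np.linalg.norm(pos[0] - pos[1]))


def assert_whole(
    frame: TrajectoryFrame,
    system: MolecularSystem,
    selection: np.ndarray,
    max_extent: float | None = None,
) -> None:
    """Error if a selection appears broken across the periodic boundary.

    Geometry metrics here use wrapped coordinates; a protein split by the
    box would corrupt them silently.  The proxy check is that the
    selection's extent stays below ``max_extent`` (default: half the
    smallest box side).
    """
    xyz = frame.xyz[np.asarray(selection)]
    extent = xyz.max(axis=0) - xyz.min(axis=0)
    limit = max_extent if max_extent is not None else float(frame.box.min()) / 2
    if np.any(extent > limit):
        raise ValueError(
            f"selection extent {extent} exceeds {limit:.1f} A; the molecule "
            "appears broken across the periodic boundary"
        )


def geometry_table(
    frames: Iterable[TrajectoryFrame],
    system: MolecularSystem,
    domains: DomainSpec | None = None,
    chains: Sequence[str] = ("A",),
    landmark: tuple[int, int] = (82, 505),
) -> pd.DataFrame:
    """Per-frame, per-protomer table of the three elevator observables."""
    domains = domains or DomainSpec()
    rows = []
    for i, frame in enumerate(frames):
        for ch in chains:
            rows.append(
                {
                    "frame": i,
                    "time_ps": frame.time,
                    "chain": ch,
                    "zshift_A": td_sd_zshift(frame, system, domains, ch),
                    "rotation_deg": td_sd_rotation(frame, system, domains, ch),
                    "landmark_A": landmark_distance(
                        frame, system, *landmark, chain=ch
                    ),
                }
            )
    return pd.DataFrame(rows)
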