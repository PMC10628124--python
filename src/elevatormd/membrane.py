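"""Excluded-lipid cross-sectional area per leaflet.

The protein-occupied membrane area is inferred without any protein surface
construction: the bulk area-per-lipid (APL) measured far from the protein
gives the theoretical lipid count the leaflet would hold if it were pure
bilayer, and the shortfall of actual lipids times the APL is the
"excluded-lipid area".  Computed per frame and per leaflet, since the two
leaflets of an elevator transporter need not (and do not) expand together.

Distances are lateral (xy) with periodic minimum imaging; the "protein
center" is the xy centroid of the protein atoms in the frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .trajectory import MolecularSystem, TrajectoryFrame

__all__ = [
    "LeafletAssignment",
    "LeafletAreaRecord",
    "assign_leaflets",
    "bulk_apl",
    "excluded_lipid_area",
    "area_table",
]


@dataclass
class LeafletAssignment:
    """Leaflet membership of each lipid, by reference-atom z vs midplane."""

    lipid_atoms: np.ndarray  # indices of the reference atom of each lipid
    leaflet: np.ndarray  # 'intra' (below midplane) or 'extra' per lipid
    reference_atom: str
    midplane_z: float

    def atoms_in(self, leaflet: str) -> np.ndarray:
        return self.lipid_atoms[self.leaflet == leaflet]


@dataclass
class LeafletAreaRecord:
    """Per-frame, per-leaflet area bookkeeping (Angstrom^2)."""

    frame: int
    leaflet: str
    apl: float
    n_bulk: int
    n_actual: int
    n_theoretical: float
    excluded_area: float


def assign_leaflets(
    frame: TrajectoryFrame,
    system: MolecularSystem,
    lipid_reference_atom: str = "P",
) -> LeafletAssignment:
    """Split lipids into leaflets by reference-atom z against the midplane.

    The midplane is the mean reference-atom z; the lower leaflet is taken
    as intracellular.  A degenerate flat system (all lipids at one z) is
    assigned to a single leaflet with a warning.
    """
    atoms = np.flatnonzero(system.names == lipid_reference_atom)
    if atoms.size == 0:
        raise ValueError(f"no lipids: no atoms named {lipid_reference_atom!r}")
    z = frame.xyz[atoms, 2]
    mid = float(z.mean())
    leaflet = np.where(z < mid, "intra", "extra")
    if len(set(leaflet)) == 1:
        warnings.warn(
            "all lipid reference atoms on one side of the midplane; "
            "single-leaflet assignment",
            stacklevel=2,
        )
    return LeafletAssignment(
        lipid_atoms=atoms,
        leaflet=leaflet,
        reference_atom=lipid_reference_atom,
        midplane_z=mid,
    )


def _lateral_minimage_dist(
    xy: np.ndarray, center: np.ndarray, box_xy: np.ndarray
) -> np.ndarray:
    d = xy - center
    d -= box_xy * np.round(d / box_xy)
    return np.linalg.norm(d, axis=1)


def _clipped_disk_area(radius: float, lx: float, ly: float) -> float:
    """Area of {min-image lateral distance < radius} in an Lx x Ly cell."""
    if radius <= min(lx, ly) / 2:
        return np.pi * radius**2

    def seg(half: float) -> float:
        if radius <= half:
            return 0.0
        return radius**2 * np.arccos(half / radius) - half * np.sqrt(
            radius**2 - half**2
        )

    if radius**2 > (lx / 2) ** 2 + (ly / 2) ** 2:
        return lx * ly  # disk covers the whole cell
    # corner regions are not double-subtracted below this radius
    return np.pi * radius**2 - 2 * seg(lx / 2) - 2 * seg(ly / 2)


def protein_center_xy(
    frame: TrajectoryFrame, protein_atoms: np.ndarray
) -> np.ndarray:
    """xy centroid of the protein atoms in this frame."""
    return frame.xyz[np.asarray(protein_atoms), :2].mean(axis=0)


def bulk_apl(
    frame: TrajectoryFrame,
    leaflet_lipid_atoms: np.ndarray,
    center_xy: np.ndarray,
    cutoff: float = 70.0,
    subtract_exclusion_disk: bool = True,
) -> tuple[float, int]:
    """Bulk area-per-lipid of one leaflet (Angstrom^2) and the bulk count.

    Bulk lipids lie laterally farther than ``cutoff`` from the protein
    center.  The bulk area is the box xy area minus the (box-clipped)
    exclusion disk; dividing the total box area by the bulk count instead
    (``subtract_exclusion_disk=False``) biases APL upward by construction
    and is kept only for sensitivity checks.
    """
    atoms = np.asarray(leaflet_lipid_atoms)
    if atoms.size == 0:
        raise ValueError("leaflet has no lipids")
    box_xy = frame.box[:2]
    dist = _lateral_minimage_dist(frame.xyz[atoms, :2], center_xy, box_xy)
    bulk = dist > cutoff
    n_bulk = int(bulk.sum())
    if n_bulk == 0:
        raise ValueError(
            f"no bulk lipids beyond {cutoff} A; use a smaller cutoff for "
            "this box size"
        )
    area = box_xy[0] * box_xy[1]
    if subtract_exclusion_disk:
        area -= _clipped_disk_area(cutoff, box_xy[0], box_xy[1])
    return area / n_bulk, n_bulk


def excluded_lipid_area(
    frame: TrajectoryFrame,
    leaflet_lipid_atoms: np.ndarray,
    center_xy: np.ndarray,
    cutoff: float = 70.0,
    frame_id: int = 0,
    leaflet: str = "",
    subtract_exclusion_disk: bool = True,
) -> LeafletAreaRecord:
    """Excluded-lipid area of one leaflet in one frame.

    excluded = box_area - N_actual * APL = (N_theoretical - N_actual) * APL
    where N_theoretical = box_area / APL.
    """
    apl, n_bulk = bulk_apl(
        frame, leaflet_lipid_atoms, center_xy, cutoff, subtract_exclusion_disk
    )
    box_area = float(frame.box[0] * frame.box[1])
    n_actual = int(np.asarray(leaflet_lipid_atoms).size)
    n_theoretical = box_area / apl
    return LeafletAreaRecord(
        frame=frame_id,
        leaflet=leaflet,
        apl=apl,
        n_bulk=n_bulk,
        n_actual=n_actual,
        n_theoretical=n_theoretical,
        excluded_area=box_area - n_actual * apl,
    )


def area_table(
    frames: Iterable[TrajectoryFrame],
    system: MolecularSystem,
    protein_atoms: np.ndarray,
    cutoff: float = 70.0,
    leaflets: Sequence[str] = ("intra", "extra"),
    lipid_reference_atom: str = "P",
) -> pd.DataFrame:
    """Per-frame, per-leaflet excluded-area table over a trajectory."""
    rows = []
    for i, frame in enumerate(frames):
        assignment = assign_leaflets(frame, system, lipid_reference_atom)
        center = protein_center_xy(frame, protein_atoms)
        for leaflet in leaflets:
            rec = excluded_lipid_area(
                frame,
                assignment.atoms_in(leaflet),
                center,
                cutoff=cutoff,
                frame_id=i,
                leaflet=leaflet,
            )
            rows.append(
                {
                    "frame": i,
                    "time_ps": frame.time,
                    "leaflet": leaflet,
                    "apl_A2": rec.apl,
                    "n_bulk": rec.n_bulk,
                    "n_actual": rec.n_actual,
                    "excluded_A2": rec.excluded_area,
                }
            )
    return pd.DataFrame(rows)
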