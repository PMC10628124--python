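"""History-labeled water accessibility and chloride binding states.

Waters are labeled by the last bulk phase they visited (intracellular or
extracellular slab beyond the phosphate planes plus a margin), so that a
water found near a residue can be attributed to the side of the membrane
it came from -- the in-silico analogue of substituted-cysteine
accessibility experiments.  Chloride ions are classified against the
anion-binding pocket by Calpha-distance criteria.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .trajectory import MolecularSystem, TrajectoryFrame

__all__ = [
    "WaterHistory",
    "ChlorideState",
    "track_water_history",
    "residue_water_counts",
    "aggregate_accessibility",
    "chloride_bound_state",
]

INTRA, EXTRA = 0, 1

WATER_OXYGEN_NAMES = ("OW", "OH2", "O")
WATER_RESNAMES = ("HOH", "TIP3", "SOL", "WAT")


@dataclass
class WaterHistory:
    """Per-water, per-frame origin labels (0=intra, 1=extra).

    ``provisional`` marks waters that have not yet visited either bulk
    slab; they carry their initial side-of-midplane label.  Labels change
    only in frames where the water occupies a bulk slab.
    """

    water_atoms: np.ndarray  # oxygen atom indices
    labels: np.ndarray  # (n_frames, n_waters) int8
    provisional: np.ndarray  # (n_frames, n_waters) bool
    slab_margin: float
    phosphate_planes: np.ndarray  # (n_frames, 2) lower/upper plane z


def _water_oxygens(system: MolecularSystem) -> np.ndarray:
    idx = np.flatnonzero(
        np.isin(system.resnames, WATER_RESNAMES)
        & np.isin(system.names, WATER_OXYGEN_NAMES)
    )
    if idx.size == 0:
        raise ValueError("no water oxygens found")
    return idx


def track_water_history(
    frames: Sequence[TrajectoryFrame],
    system: MolecularSystem,
    slab_margin: float = 5.0,
    phosphate_name: str = "P",
) -> WaterHistory:
    """Label every water by the last bulk phase it visited.

    Bulk slabs are z above (upper phosphate plane + margin) for the
    extracellular side and below (lower plane - margin) for the
    intracellular side.  Waters that have never reached a slab carry their
    frame-0 side-of-midplane label, flagged provisional.
    """
    phos = np.flatnonzero(system.names == phosphate_name)
    if phos.size == 0:
        raise ValueError("no phosphate atoms: membrane slab is undefined")
    waters = _water_oxygens(system)
    n_frames, n_w = len(frames), waters.size
    labels = np.empty((n_frames, n_w), dtype=np.int8)
    prov = np.empty((n_frames, n_w), dtype=bool)
    planes = np.empty((n_frames, 2))

    state = None
    provisional = None
    for i, frame in enumerate(frames):
        pz = frame.xyz[phos, 2]
        mid = pz.mean()
        lower = pz[pz < mid].mean() if np.any(pz < mid) else mid
        upper = pz[pz >= mid].mean() if np.any(pz >= mid) else mid
        planes[i] = (lower, upper)
        z = frame.xyz[waters, 2]
        in_intra = z < lower - slab_margin
        in_extra = z > upper + slab_margin
        if state is None:
            state = np.where(z > mid, EXTRA, INTRA).astype(np.int8)
            provisional = np.ones(n_w, dtype=bool)
        state = np.where(in_extra, EXTRA, np.where(in_intra, INTRA, state)).astype(
            np.int8
        )
        provisional = provisional & ~(in_intra | in_extra)
        labels[i] = state
        prov[i] = provisional
    return WaterHistory(
        water_atoms=waters,
        labels=labels,
        provisional=prov,
        slab_margin=slab_margin,
        phosphate_planes=planes,
    )


def _minimage_dists(
    a: np.ndarray, b: np.ndarray, box: np.ndarray
) -> np.ndarray:
    """(len(a), len(b)) distance matrix with 3-D periodic minimum imaging."""
    d = a[:, None, :] - b[None, :, :]
    d -= box * np.round(d / box)
    return np.sqrt((d**2).sum(axis=-1))


def residue_water_counts(
    frame: TrajectoryFrame,
    system: MolecularSystem,
    residues: Sequence[int],
    labels_this_frame: np.ndarray,
    water_atoms: np.ndarray,
    cutoff: float = 5.0,
    chain: str | None = None,
    exclude_provisional: np.ndarray | None = None,
) -> pd.DataFrame:
    """Waters within ``cutoff`` of each residue's backbone, by origin.

    A water counts once per residue if its oxygen lies within the cutoff
    (inclusive, <=) of ANY of the residue's N/CA/C atoms; it is attributed
    to its current history label.  Periodic minimum imaging in all three
    dimensions.
    """
    rows = []
    wxyz = frame.xyz[water_atoms]
    keep = (
        ~exclude_provisional
        if exclude_provisional is not None
        else np.ones(len(water_atoms), dtype=bool)
    )
    for resid in residues:
        mask = (system.resids == resid) & np.isin(system.names, ["N", "CA", "C"])
        if chain is not None:
            mask &= system.chains == chain
        backbone = np.flatnonzero(mask)
        if backbone.size == 0:
            raise ValueError(f"residue {resid} has no backbone atoms")
        dmat = _minimage_dists(wxyz, frame.xyz[backbone], frame.box)
        near = (dmat <= cutoff).any(axis=1) & keep
        rows.append(
            {
                "residue": resid,
                "intra": int(np.sum(near & (labels_this_frame == INTRA))),
                "extra": int(np.sum(near & (labels_this_frame == EXTRA))),
            }
        )
    return pd.DataFrame(rows)


def accessibility_counts(
    frames: Sequence[TrajectoryFrame],
    system: MolecularSystem,
    residues: Sequence[int],
    history: WaterHistory,
    cutoff: float = 5.0,
    chain: str | None = None,
) -> pd.DataFrame:
    """Per-frame, per-residue water counts over a trajectory."""
    tables = []
    for i, frame in enumerate(frames):
        df = residue_water_counts(
            frame,
            system,
            residues,
            history.labels[i],
            history.water_atoms,
            cutoff=cutoff,
            chain=chain,
        )
        df.insert(0, "frame", i)
        tables.append(df)
    return pd.concat(tables, ignore_index=True)


def aggregate_accessibility(
    counts: pd.DataFrame, cluster_labels: np.ndarray
) -> pd.DataFrame:
    """Mean/SD water counts per (residue, cluster), split by origin.

    ``counts`` must have columns frame/residue/intra/extra;
    ``cluster_labels`` assigns each frame a cluster id (-1 = unassigned
    frames are kept under their own id).  Totals over member frames are
    also emitted alongside the per-frame means.
    """
    labels = np.asarray(cluster_labels)
    df = counts.copy()
    df["cluster"] = labels[df["frame"].to_numpy()]
    grouped = df.groupby(["residue", "cluster"])
    out = grouped.agg(
        intra_mean=("intra", "mean"),
        intra_sd=("intra", lambda s: s.std(ddof=0)),
        intra_total=("intra", "sum"),
        extra_mean=("extra", "mean"),
        extra_sd=("extra", lambda s: s.std(ddof=0)),
        extra_total=("extra", "sum"),
        n_frames=("frame", "nunique"),
    ).reset_index()
    if (out["n_frames"] == 0).any():  # pragma: no cover - groupby can't
        raise ValueError("empty cluster")
    return out


@dataclass
class ChlorideState:
    """Per-chloride binding classification for one frame.

    2 = bound (within cutoff of the Calpha of all three pocket residues),
    1 = partially bound (within cutoff of the two serine Calphas only),
    0 = unbound.  ``pocket_state`` is the max over chlorides; the mean is
    the per-frame average bound state.
    """

    frame: int
    chloride_atoms: np.ndarray
    states: np.ndarray

    @property
    def pocket_state(self) -> int:
        return int(self.states.max()) if self.states.size else 0

    @property
    def mean_state(self) -> float:
        return float(self.states.mean()) if self.states.size else 0.0


def chloride_bound_state(
    frame: TrajectoryFrame,
    system: MolecularSystem,
    cutoff: float = 7.0,
    pocket: tuple[int, int, int] = (137, 396, 398),
    chain: str | None = "A",
    chloride_resnames: Sequence[str] = ("CLA", "CL", "CLM"),
    frame_id: int = 0,
) -> ChlorideState:
    """Classify every chloride against the anion-binding pocket.

    The pocket is defined by the Calphas of (F137, S396, S398); a
    chloride within ``cutoff`` of all three is bound (2), within the
    cutoff of S396 and S398 but not F137 partially bound (1), otherwise
    unbound (0).  Distances use 3-D periodic minimum imaging.
    """
    f137, s396, s398 = pocket
    cas = []
    for resid in pocket:
        mask = (system.resids == resid) & (system.names == "CA")
        if chain is not None:
            mask &= system.chains == chain
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise ValueError(f"pocket residue {resid} CA not found")
        cas.append(idx[0])
    cl = np.flatnonzero(np.isin(system.resnames, list(chloride_resnames)))
    if cl.size == 0:
        return ChlorideState(
            frame=frame_id, chloride_atoms=cl, states=np.empty(0, dtype=np.int8)
        )
    d = _minimage_dists(frame.xyz[cl], frame.xyz[cas], frame.box)
    near = d <= cutoff  # columns: F137, S396, S398
    states = np.zeros(cl.size, dtype=np.int8)
    partial = near[:, 1] & near[:, 2]
    states[partial] = 1
    states[partial & near[:, 0]] = 2
    return ChlorideState(frame=frame_id, chloride_atoms=cl, states=states)
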