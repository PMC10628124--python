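"""Ground-truthed synthetic data for the whole analysis pipeline.

Two generators are provided:

* :func:`make_elevator_trajectory` builds a kinematic two-state "elevator"
  dimer embedded in a lattice bilayer: a static scaffold domain, a transport
  domain that rigidly translates along z and twists about the hinge between
  the compact (CS) and expanded (ES) states, lipids on a square lattice with
  a state-dependent protein footprint, waters performing reflected random
  walks between labeled intra/extracellular bulk slabs (with an
  intracellular vestibule that is open only in ES), scripted chloride ions,
  and partial charges that ride with the transport domain.  Every quantity a
  downstream analysis estimates is recorded as ground truth.

* :func:`make_cefield_system` emulates constant-electric-field recordings of
  two fixed conformations differing by one charge displaced along z, from
  which the gating charge can be recovered by the Q-route.

* ``make_nlc_recording`` / ``make_vcf_recording`` / ``make_qv_step_recording``
  generate electrophysiology/fluorometry tables from two-state Boltzmann
  models with noise, photobleaching and ohmic leak.

Trajectories are kinematic, not physical: no force field, no energies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .trajectory import DomainSpec, MolecularSystem, TrajectoryFrame

__all__ = [
    "ElevatorParams",
    "SyntheticTrajectory",
    "EphysTruth",
    "CEFieldRecordings",
    "make_elevator_trajectory",
    "make_cefield_system",
    "make_nlc_recording",
    "make_vcf_recording",
    "make_qv_step_recording",
    "boltzmann_occupancy",
]

# Leaflet phosphate planes sit at +/- this distance from the bilayer
# midplane (Angstrom); together with the bulk margin it defines the
# labeled bulk slabs of the water-history model.
SLAB_HALF_THICKNESS = 17.0

#: residues whose Calpha anchors the anion-binding pocket
POCKET_RESIDUES = {"F137": 137, "S396": 396, "S398": 398}


def boltzmann_occupancy(v: np.ndarray, v_half: float, alpha: float) -> np.ndarray:
    """Two-state Boltzmann open probability 1/(1+exp(-(V-V1/2)/alpha))."""
    v = np.asarray(v, dtype=float)
    return 1.0 / (1.0 + np.exp(-(v - v_half) / alpha))


# ---------------------------------------------------------------------------
# elevator trajectory
# ---------------------------------------------------------------------------


@dataclass
class ElevatorParams:
    """Parameters of the synthetic elevator-dimer trajectory.

    Footprint radii are per intracellular leaflet; the extracellular
    leaflet uses the state-independent ``footprint_radius_extra`` (defaults
    to the CS radius), reflecting the asymmetry in which only the
    intracellular cross-section changes between states.  Defaults emulate a
    transporter whose intracellular footprint area grows by 5.4% upon the
    CS->ES transition, with a 1.5 A downward translation and a 7 degree
    twist of the transport domain.
    """

    dz_shift: float = 1.5
    rot_deg: float = 7.0
    footprint_radius_cs: float = 34.0
    footprint_radius_es: float | None = None  # default: 5.4% area increase
    footprint_radius_extra: float | None = None  # default: = CS radius
    box: tuple[float, float, float] = (129.0, 129.0, 90.0)
    apl_true: float = 65.0
    n_waters: int = 400
    n_pathway_waters: int = 8  # scripted vestibule visitors (ES frames)
    n_chloride: int = 2
    n_frames: int = 500
    state_sequence: np.ndarray | None = None
    switching_rate: float = 0.02
    dt_frame: float = 100.0  # ps
    noise_sd: float = 0.1  # A, thermal jitter on protein atoms
    water_step: float = 3.0  # A per frame
    vestibule_radius: float = 6.0
    bulk_margin: float = 5.0
    area_increase: float = 0.054  # used when footprint_radius_es is None
    seed: int = 0

    def __post_init__(self) -> None:
        # when the ES radius is not given explicitly, the generator grows
        # the ES footprint by whole lattice sites closest to area_increase
        self._es_radius_derived = self.footprint_radius_es is None
        if self.footprint_radius_es is None:
            self.footprint_radius_es = self.footprint_radius_cs * float(
                np.sqrt(1.0 + self.area_increase)
            )
        if self.footprint_radius_extra is None:
            self.footprint_radius_extra = self.footprint_radius_cs
        if self.dz_shift < 0:
            raise ValueError("dz_shift must be >= 0")
        for r in (
            self.footprint_radius_cs,
            self.footprint_radius_es,
            self.footprint_radius_extra,
        ):
            if not 0 < r < min(self.box[0], self.box[1]) / 2:
                raise ValueError(
                    f"footprint radius {r} A does not fit in box "
                    f"{self.box[:2]} (must be < half the smaller xy side)"
                )
        for count in (self.n_waters, self.n_chloride, self.n_frames):
            if count < 0:
                raise ValueError("counts must be >= 0")
        if self.state_sequence is not None:
            seq = np.asarray(self.state_sequence)
            if not set(np.unique(seq)) <= {"CS", "ES"}:
                raise ValueError("state labels must be 'CS' or 'ES'")
            self.state_sequence = seq
            self.n_frames = len(seq)


@dataclass
class SyntheticTrajectory:
    """Frames plus topology, per-atom metadata and per-frame ground truth."""

    system: MolecularSystem
    frames: list[TrajectoryFrame]
    domain_tag: np.ndarray  # per atom: transport/scaffold/other/lipid/...
    leaflet_tag: np.ndarray  # per atom: 'intra'/'extra' for lipids, '' else
    truth: dict
    params: ElevatorParams

    def __post_init__(self) -> None:
        n = self.system.n_atoms
        for fr in self.frames:
            if fr.xyz.shape[0] != n:
                raise ValueError("frame atom count differs from topology")
        for key in ("state", "qd"):
            if len(self.truth[key]) != len(self.frames):
                raise ValueError(f"truth[{key!r}] does not align with frames")

    # -- writers (text PDB topology, XTC frames, CSV tables) --------------

    def write_pdb(self, path: str | Path) -> None:
        u = self._as_universe()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u.atoms.write(str(path))

    def write_xtc(self, path: str | Path) -> None:
        import MDAnalysis as mda

        u = self._as_universe()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with mda.Writer(str(path), n_atoms=u.atoms.n_atoms) as w:
                for i, fr in enumerate(self.frames):
                    u.atoms.positions = fr.xyz
                    u.trajectory.ts.dimensions = [*fr.box, 90.0, 90.0, 90.0]
                    u.trajectory.ts.time = fr.time
                    u.trajectory.ts.frame = i
                    w.write(u.atoms)

    def write_charge_table(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "atom_index": np.arange(self.system.n_atoms),
                "charge_e": self.system.charges,
                "mass_amu": self.system.masses,
            }
        ).to_csv(path, index=False)

    def write_truth(self, path: str | Path) -> None:
        t = self.truth
        df = pd.DataFrame(
            {
                "frame": np.arange(len(self.frames)),
                "state": t["state"],
                "excluded_intra_A2": t["excluded_area"]["intra"],
                "excluded_extra_A2": t["excluded_area"]["extra"],
                "qd_e": t["qd"],
                "chloride_pocket_state": t["chloride_state"].max(axis=1)
                if t["chloride_state"].size
                else 0,
            }
        )
        df.to_csv(path, index=False)

    def _as_universe(self):
        import MDAnalysis as mda

        sys_ = self.system
        n = sys_.n_atoms
        # one residue per unique (chain, resid) run, in atom order
        resindex = np.zeros(n, dtype=int)
        res_keys: list[tuple[str, int]] = []
        for i in range(n):
            key = (sys_.chains[i], int(sys_.resids[i]))
            if not res_keys or res_keys[-1] != key:
                res_keys.append(key)
            resindex[i] = len(res_keys) - 1
        n_res = len(res_keys)
        u = mda.Universe.empty(
            n,
            n_residues=n_res,
            atom_resindex=resindex,
            residue_segindex=np.zeros(n_res, dtype=int),
            trajectory=True,
        )
        u.add_TopologyAttr("names", sys_.names)
        u.add_TopologyAttr("resids", [r for _, r in res_keys])
        first_atom = np.searchsorted(resindex, np.arange(n_res))
        u.add_TopologyAttr("resnames", sys_.resnames[first_atom])
        u.add_TopologyAttr("chainIDs", sys_.chains)
        u.add_TopologyAttr("masses", sys_.masses)
        u.atoms.positions = self.frames[0].xyz
        u.trajectory.ts.dimensions = [*self.frames[0].box, 90.0, 90.0, 90.0]
        return u


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold positions into [lo, hi] by mirror reflection."""
    span = hi - lo
    y = np.mod(x - lo, 2 * span)
    y = np.where(y > span, 2 * span - y, y)
    return y + lo


def _scatter_disc(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    """n deterministic points roughly uniform in a disc of given radius."""
    r = radius * np.sqrt(rng.uniform(0.05, 1.0, n))
    th = rng.uniform(0, 2 * np.pi, n)
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


def _build_protein_template(
    params: ElevatorParams, rng: np.random.Generator
) -> tuple[np.ndarray, list[dict], np.ndarray]:
    """CS-state coordinates and atom records for the two protomers.

    Returns (coords, atom_records, mover_mask).  Chain-local geometry puts
    the hinge COG, the transport-bottom COG and the scaffold-bottom COG in
    one horizontal plane so that the hinge-angle metric responds one-to-one
    to the applied twist about the vertical hinge axis, and translation
    along z perturbs it only to second order.
    """
    domains = DomainSpec()
    cx, cy = params.box[0] / 2, params.box[1] / 2
    zmid = params.box[2] / 2
    tb_set = domains.residue_set("transport_bottom")
    sb_set = domains.residue_set("scaffold_bottom")
    hinge_set = domains.residue_set("hinge")
    transport_set = domains.residue_set("transport")

    # charged residues: +1 e on CA of six transport residues, -1 e on CA of
    # four scaffold residues; everything else neutral
    charged_pos = {100, 130, 150, 340, 360, 400}
    charged_neg = {220, 280, 460, 490}

    # xy group centers (chain-local) and z bands (relative to membrane mid)
    lever = 18.0
    groups = {
        "tb": (np.array([lever, 0.0]), (-16.0, -8.0)),
        "sb": (lever * np.array([np.cos(np.radians(100)), np.sin(np.radians(100))]),
               (-16.0, -8.0)),
        "hinge": (np.array([0.0, 0.0]), (-16.0, -8.0)),
        "t_other": (np.array([10.0, -6.0]), (-6.0, 14.0)),
        "other": (np.array([-6.0, -10.0]), (-6.0, 14.0)),
    }
    pocket_xy_local = np.array([6.0, 0.0])
    pocket_z = -2.0  # relative to membrane midplane

    coords: list[np.ndarray] = []
    records: list[dict] = []
    mover: list[bool] = []
    residues = sorted(set(range(76, 508)))
    # chain-local atom layout, built once; protomer B is the C2 copy of A
    # (local xy negated), so lateral displacements of the two transport
    # domains cancel and the dimer centroid stays put during the transition
    local: list[tuple[np.ndarray, ...]] = []
    for resid in residues:
        if resid in tb_set:
            g = "tb"
        elif resid in sb_set:
            g = "sb"
        elif resid in hinge_set:
            g = "hinge"
        elif resid in transport_set:
            g = "t_other"
        else:
            g = "other"
        center, zband = groups[g]
        if resid == POCKET_RESIDUES["F137"]:
            ca_xy = pocket_xy_local + np.array([0.0, 4.0])
            ca_z = zmid + pocket_z
        elif resid == POCKET_RESIDUES["S396"]:
            ca_xy = pocket_xy_local + np.array([-1.5, 0.0])
            ca_z = zmid + pocket_z
        elif resid == POCKET_RESIDUES["S398"]:
            ca_xy = pocket_xy_local + np.array([1.5, 0.0])
            ca_z = zmid + pocket_z
        else:
            ca_xy = center + _scatter_disc(rng, 1, 5.0)[0]
            ca_z = zmid + rng.uniform(*zband)
        n_off = rng.normal(0, 0.4, 3) + np.array([-1.3, 0.2, 0.1])
        c_off = rng.normal(0, 0.4, 3) + np.array([1.3, -0.2, -0.1])
        local.append((ca_xy, ca_z, n_off, c_off))

    for chain, xoff, flip in (("A", -8.0, 1.0), ("B", 8.0, -1.0)):
        origin = np.array([cx + xoff, cy])
        for resid, (ca_xy, ca_z, n_off, c_off) in zip(residues, local):
            xy = origin + flip * ca_xy  # flip = C2 copy for protomer B
            ca = np.array([xy[0], xy[1], ca_z])
            n_off_c = n_off * np.array([flip, flip, 1.0])
            c_off_c = c_off * np.array([flip, flip, 1.0])
            if resid == 137:
                resname = "PHE"
            elif resid in (396, 398):
                resname = "SER"
            elif resid in charged_pos:
                resname = "ARG"
            elif resid in charged_neg:
                resname = "GLU"
            else:
                resname = "GLY"
            in_transport = resid in transport_set
            tag = "transport" if in_transport else (
                "scaffold" if resid in domains.residue_set("scaffold") else "other"
            )
            for name, pos, mass in (
                ("N", ca + n_off_c, 14.007),
                ("CA", ca, 12.011),
                ("C", ca + c_off_c, 12.011),
            ):
                charge = 0.0
                if name == "CA" and resid in charged_pos:
                    charge = 1.0
                elif name == "CA" and resid in charged_neg:
                    charge = -1.0
                coords.append(pos)
                records.append(
                    dict(
                        name=name,
                        resid=resid,
                        resname=resname,
                        chain=chain,
                        charge=charge,
                        mass=mass,
                        tag=tag,
                    )
                )
                mover.append(in_transport)
    return np.array(coords), records, np.array(mover, dtype=bool)


def _lattice_sites(params: ElevatorParams) -> tuple[np.ndarray, float]:
    """Square lipid lattice over the xy box; returns sites and cell area."""
    bx, by = params.box[0], params.box[1]
    a = float(np.sqrt(params.apl_true))
    nx, ny = max(1, round(bx / a)), max(1, round(by / a))
    ax, ay = bx / nx, by / ny
    # the irrational-fraction offset breaks the shell degeneracy a lattice
    # centered on the protein axis would have, so hole counts grow smoothly
    # with the footprint radius
    xs = np.mod((np.arange(nx) + 0.5 + 0.2832) * ax, bx)
    ys = np.mod((np.arange(ny) + 0.5 + 0.1317) * ay, by)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel()]), ax * ay


def _min_image_dist_xy(
    pts: np.ndarray, center: np.ndarray, box_xy: np.ndarray
) -> np.ndarray:
    d = pts - center
    d -= box_xy * np.round(d / box_xy)
    return np.linalg.norm(d, axis=1)


def make_elevator_trajectory(params: ElevatorParams) -> SyntheticTrajectory:
    """Generate the two-state elevator-dimer trajectory with full truth.

    Deterministic for a fixed seed.  Scaffold pseudo-atoms are static up to
    thermal jitter; transport pseudo-atoms are rigidly twisted by
    ``rot_deg`` about the vertical axis through their chain's hinge COG and
    shifted down by ``dz_shift`` in ES frames.  Lipids sit on a square
    lattice with a hole of the state's footprint radius; lipids whose site
    is swallowed by the expanding footprint are displaced to interstitial
    positions in the far bulk, emulating the bulk compression an expanding
    inclusion causes at fixed box area and lipid number.
    """
    rng = np.random.default_rng(params.seed)
    box = np.asarray(params.box, dtype=float)
    zmid = box[2] / 2

    # ----- states ---------------------------------------------------------
    if params.state_sequence is not None:
        states = np.asarray(params.state_sequence)
    else:
        seq = []
        s = "CS"
        for _ in range(params.n_frames):
            seq.append(s)
            if rng.random() < params.switching_rate:
                s = "ES" if s == "CS" else "CS"
        states = np.array(seq)
    n_frames = len(states)

    # ----- protein templates ---------------------------------------------
    prot_cs, records, mover = _build_protein_template(params, rng)
    domains = DomainSpec()
    prot_es = prot_cs.copy()
    phi = np.radians(params.rot_deg)
    rot = np.array(
        [[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]]
    )
    chains_arr = np.array([r["chain"] for r in records])
    resids_arr = np.array([r["resid"] for r in records])
    hinge_set = domains.residue_set("hinge")
    for chain in ("A", "B"):
        cmask = chains_arr == chain
        hmask = cmask & np.isin(resids_arr, list(hinge_set))
        hinge_cog = prot_cs[hmask].mean(axis=0)
        m = cmask & mover
        xy = prot_es[m, :2] - hinge_cog[:2]
        prot_es[m, :2] = xy @ rot.T + hinge_cog[:2]
        prot_es[m, 2] -= params.dz_shift

    # pocket CA positions per state (chain A), used for chloride scripting
    def pocket_cas(template: np.ndarray) -> dict[str, np.ndarray]:
        out = {}
        for key, resid in POCKET_RESIDUES.items():
            idx = np.flatnonzero(
                (chains_arr == "A") & (resids_arr == resid)
                & (np.array([r["name"] for r in records]) == "CA")
            )[0]
            out[key] = template[idx]
        return out

    pocket = {"CS": pocket_cas(prot_cs), "ES": pocket_cas(prot_es)}
    vest_xy = pocket["CS"]["S396"][:2] / 2 + pocket["CS"]["S398"][:2] / 2

    # ----- lipids ---------------------------------------------------------
    sites, cell_area = _lattice_sites(params)
    center_xy = box[:2] / 2
    dist = _min_image_dist_xy(sites, center_xy, box[:2])
    leaflet_radii = {
        "intra": {"CS": params.footprint_radius_cs, "ES": params.footprint_radius_es},
        "extra": {
            "CS": params.footprint_radius_extra,
            "ES": params.footprint_radius_extra,
        },
    }
    if params._es_radius_derived:
        # grow the ES hole by whole sites, as close to the requested
        # fractional area increase as lattice quantization allows
        n_cs = int(np.sum(dist < params.footprint_radius_cs))
        n_es = n_cs + max(1, round(n_cs * params.area_increase))
        order = np.sort(dist)
        leaflet_radii["intra"]["ES"] = float((order[n_es - 1] + order[n_es]) / 2)
    lipid_xy: dict[str, dict[str, np.ndarray]] = {}
    truth_area: dict[str, dict[str, float]] = {}
    for leaflet, radii in leaflet_radii.items():
        r_small = min(radii.values())
        keep = dist >= r_small  # atom slots, fixed across frames
        slot_xy = sites[keep]
        slot_dist = dist[keep]
        per_state = {}
        for state, r in radii.items():
            xy = slot_xy.copy()
            displaced = np.flatnonzero(slot_dist < r)
            if displaced.size:
                far = np.argsort(slot_dist)[::-1][: displaced.size]
                xy[displaced] = slot_xy[far] + np.array(
                    [np.sqrt(cell_area) / 2, np.sqrt(cell_area) / 2]
                )
            per_state[state] = xy
        lipid_xy[leaflet] = per_state
        truth_area[leaflet] = {
            s: float(np.sum(dist < r) * cell_area) for s, r in radii.items()
        }
    n_lipids = {lf: lipid_xy[lf]["CS"].shape[0] for lf in lipid_xy}
    lipid_z = {"intra": zmid - SLAB_HALF_THICKNESS, "extra": zmid + SLAB_HALF_THICKNESS}

    # ----- assemble topology ---------------------------------------------
    names = [r["name"] for r in records]
    resids = [r["resid"] for r in records]
    resnames = [r["resname"] for r in records]
    chains = [r["chain"] for r in records]
    charges = [r["charge"] for r in records]
    masses = [r["mass"] for r in records]
    tags = [r["tag"] for r in records]
    leaflet_tag = [""] * len(records)

    for leaflet in ("intra", "extra"):
        for j in range(n_lipids[leaflet]):
            names.append("P")
            resids.append(j + 1)
            resnames.append("POPC")
            chains.append("L" if leaflet == "intra" else "M")
            charges.append(0.0)
            masses.append(30.974)
            tags.append("lipid")
            leaflet_tag.append(leaflet)
    for j in range(params.n_waters):
        names.append("OW")
        resids.append(j + 1)
        resnames.append("HOH")
        chains.append("W")
        charges.append(0.0)
        masses.append(18.015)
        tags.append("water")
        leaflet_tag.append("")
    for j in range(params.n_chloride):
        names.append("CLA")
        resids.append(j + 1)
        resnames.append("CLA")
        chains.append("I")
        charges.append(-1.0)
        masses.append(35.45)
        tags.append("ion")
        leaflet_tag.append("")
    # gate particle: blocks the intracellular vestibule in CS frames
    names.append("GAT")
    resids.append(1)
    resnames.append("GAT")
    chains.append("G")
    charges.append(0.0)
    masses.append(10.0)
    tags.append("gate")
    leaflet_tag.append("")

    system = MolecularSystem(
        names=np.array(names),
        resids=np.array(resids),
        resnames=np.array(resnames),
        chains=np.array(chains),
        charges=np.array(charges),
        masses=np.array(masses),
    )
    n_prot = len(records)
    lip_slice = slice(n_prot, n_prot + n_lipids["intra"] + n_lipids["extra"])
    wat_slice = slice(lip_slice.stop, lip_slice.stop + params.n_waters)
    ion_slice = slice(wat_slice.stop, wat_slice.stop + params.n_chloride)
    gate_idx = ion_slice.stop

    # ----- water initial positions ----------------------------------------
    slab_lo, slab_hi = zmid - SLAB_HALF_THICKNESS, zmid + SLAB_HALF_THICKNESS
    wat = np.empty((params.n_waters, 3))
    half = params.n_waters // 2
    wat[:, 0] = rng.uniform(0, box[0], params.n_waters)
    wat[:, 1] = rng.uniform(0, box[1], params.n_waters)
    wat[:half, 2] = rng.uniform(1.0, slab_lo - 1.0, half)
    wat[half:, 2] = rng.uniform(slab_hi + 1.0, box[2] - 1.0, params.n_waters - half)

    bulk_lo = slab_lo - params.bulk_margin
    bulk_hi = slab_hi + params.bulk_margin
    origin = np.where(wat[:, 2] > zmid, 1, 0).astype(np.int8)  # 1=extra, 0=intra
    provisional = ~((wat[:, 2] < bulk_lo) | (wat[:, 2] > bulk_hi))

    pocket_top = zmid + (-2.0) + 2.0  # vestibule reaches just above pocket

    def water_allowed(pos: np.ndarray, state: str) -> np.ndarray:
        z = pos[:, 2]
        outside_slab = (z <= slab_lo) | (z >= slab_hi)
        if state != "ES":
            return outside_slab
        dxy = pos[:, :2] - vest_xy
        dxy -= box[:2] * np.round(dxy / box[:2])
        in_vest = (np.linalg.norm(dxy, axis=1) <= params.vestibule_radius) & (
            z < pocket_top
        )
        return outside_slab | in_vest

    # ----- per-state template assembly ------------------------------------
    def template(state: str) -> np.ndarray:
        xyz = np.empty((system.n_atoms, 3))
        xyz[:n_prot] = prot_cs if state == "CS" else prot_es
        row = n_prot
        for leaflet in ("intra", "extra"):
            nl = n_lipids[leaflet]
            xyz[row : row + nl, :2] = lipid_xy[leaflet][state]
            xyz[row : row + nl, 2] = lipid_z[leaflet]
            row += nl
        # waters/ions/gate filled per frame
        xyz[wat_slice] = 0.0
        xyz[ion_slice] = 0.0
        p = pocket[state]
        if state == "CS":
            xyz[gate_idx] = [vest_xy[0], vest_xy[1], zmid - 10.0]
        else:
            xyz[gate_idx] = [5.0, 5.0, 5.0]
        return xyz

    templates = {s: template(s) for s in ("CS", "ES")}

    # chloride scripted positions per state (ion 0 tracks the pocket)
    def chloride_positions(state: str) -> tuple[np.ndarray, np.ndarray]:
        pos = np.empty((params.n_chloride, 3))
        cl_states = np.zeros(params.n_chloride, dtype=np.int8)
        p = pocket[state]
        park = np.array([center_xy[0] + 40.0, center_xy[1] + 40.0, zmid - 30.0])
        for j in range(params.n_chloride):
            pos[j] = park + [4.0 * j, 0.0, 0.0]
        if params.n_chloride:
            if state == "CS":  # fully bound in the compact state
                pos[0] = (p["F137"] + p["S396"] + p["S398"]) / 3.0
                cl_states[0] = 2
            else:  # partially bound in the expanded state
                mid = (p["S396"] + p["S398"]) / 2.0
                pos[0] = mid + np.array([0.0, -5.0, 0.0])
                cl_states[0] = 1
        return pos, cl_states

    cl_pos = {s: chloride_positions(s) for s in ("CS", "ES")}

    # truth displacement charge of the noiseless template (waters/ions at
    # their scripted/current positions contribute; waters are neutral)
    def template_qd(state: str) -> float:
        xyz = templates[state].copy()
        xyz[ion_slice] = cl_pos[state][0]
        return float(np.sum(system.charges * xyz[:, 2]) / box[2])

    truth_qd_state = {s: template_qd(s) for s in ("CS", "ES")}

    # ----- frame loop ------------------------------------------------------
    frames: list[TrajectoryFrame] = []
    water_labels = np.empty((n_frames, params.n_waters), dtype=np.int8)
    water_prov = np.empty((n_frames, params.n_waters), dtype=bool)
    cl_state_truth = np.empty((n_frames, params.n_chloride), dtype=np.int8)
    excl_truth = {
        "intra": np.empty(n_frames),
        "extra": np.empty(n_frames),
    }
    qd_truth = np.empty(n_frames)

    for i, state in enumerate(states):
        xyz = templates[state].copy()
        xyz[:n_prot] += rng.normal(0, params.noise_sd, (n_prot, 3))
        # lipids: tiny in-plane jitter, never enough to change lattice counts
        nl_total = n_lipids["intra"] + n_lipids["extra"]
        xyz[lip_slice, :2] += rng.normal(0, 0.05, (nl_total, 2))

        # waters: one reflected-random-walk step
        prop = wat + rng.normal(0, params.water_step, wat.shape)
        for d in range(3):
            prop[:, d] = _reflect(prop[:, d], 0.0, box[d])
        ok = water_allowed(prop, state)
        wat = np.where(ok[:, None], prop, wat)
        if state == "CS":
            # the closing gate expels any water still inside the vestibule
            # back into the intracellular side
            stuck = ~water_allowed(wat, "CS")
            if stuck.any():
                wat[stuck, 2] = slab_lo - rng.uniform(1.0, 3.0, int(stuck.sum()))
        # pathway waters: a scripted cohort shuttling between the
        # intracellular bulk (CS) and the open vestibule near the pocket
        # (ES), realizing conformation-dependent intracellular access with
        # unambiguous history labels
        n_path = min(params.n_pathway_waters, params.n_waters)
        if n_path:
            off = _scatter_disc(rng, n_path, max(params.vestibule_radius - 2, 1.0))
            if state == "ES":
                wat[:n_path, 0] = vest_xy[0] + off[:, 0]
                wat[:n_path, 1] = vest_xy[1] + off[:, 1]
                wat[:n_path, 2] = zmid + rng.uniform(-5.0, 0.0, n_path)
            else:
                wat[:n_path, 0] = vest_xy[0] + 2.5 * off[:, 0]
                wat[:n_path, 1] = vest_xy[1] + 2.5 * off[:, 1]
                wat[:n_path, 2] = slab_lo - rng.uniform(
                    params.bulk_margin + 1, params.bulk_margin + 6, n_path
                )
        # history labels: last visited bulk slab
        in_extra = wat[:, 2] > bulk_hi
        in_intra = wat[:, 2] < bulk_lo
        origin = np.where(in_extra, 1, np.where(in_intra, 0, origin)).astype(np.int8)
        provisional = provisional & ~(in_extra | in_intra)
        xyz[wat_slice] = wat
        water_labels[i] = origin
        water_prov[i] = provisional

        pos, cl_states = cl_pos[state]
        xyz[ion_slice] = pos + rng.normal(0, 0.15, pos.shape)
        cl_state_truth[i] = cl_states

        frames.append(
            TrajectoryFrame(xyz=xyz, box=box.copy(), time=i * params.dt_frame)
        )
        excl_truth["intra"][i] = truth_area["intra"][state]
        excl_truth["extra"][i] = truth_area["extra"][state]
        qd_truth[i] = truth_qd_state[state]

    truth = {
        "state": states,
        "excluded_area": excl_truth,
        "excluded_area_by_state": truth_area,
        "apl_eff": cell_area,
        "water_origin": water_labels,
        "water_provisional": water_prov,
        "chloride_state": cl_state_truth,
        "qd": qd_truth,
        "qd_by_state": truth_qd_state,
        "bulk_margin": params.bulk_margin,
        "slab_half_thickness": SLAB_HALF_THICKNESS,
        "pocket_xy": vest_xy,
    }
    return SyntheticTrajectory(
        system=system,
        frames=frames,
        domain_tag=np.array(tags),
        leaflet_tag=np.array(leaflet_tag),
        truth=truth,
        params=params,
    )


# ---------------------------------------------------------------------------
# constant-electric-field system
# ---------------------------------------------------------------------------


@dataclass
class CEFieldRecordings:
    """Per-state, per-voltage frame sets of a minimal charge-displacement rig."""

    system: MolecularSystem
    frames: dict[tuple[str, float], list[TrajectoryFrame]]
    truth_qg: float
    voltages: tuple[float, ...]


def make_cefield_system(
    q_move: float = 0.62,
    dz: float | None = None,
    box_z: float = 90.0,
    capacitance_slope: float = 1.0e-4,
    voltages: tuple[float, ...] = (-200.0, 0.0, 200.0),
    noise_sd: float = 0.02,
    n_frames: int = 75,
    seed: int = 0,
) -> CEFieldRecordings:
    """Two fixed conformations differing by one charge displaced along z.

    The per-frame displacement charge of the generated frames is
    ``state offset + capacitance_slope*V + N(0, noise_sd)`` by construction;
    the ground-truth gating charge is ``q_move*dz/box_z`` (CS minus ES at
    zero voltage).  ``dz`` defaults to the full box height, so ``q_move``
    is itself the truth.  Voltage enters through a unit probe charge whose
    height encodes the capacitive response; noise through a unit charge
    with Gaussian z jitter.
    """
    if dz is None:
        dz = box_z
    if dz > box_z:
        raise ValueError("dz cannot exceed box_z")
    rng = np.random.default_rng(seed)
    box = np.array([50.0, 50.0, box_z])
    system = MolecularSystem(
        names=np.array(["QMV", "QVP", "QNS", "BG"]),
        resids=np.array([1, 2, 3, 4]),
        resnames=np.array(["MOV", "PRB", "NSE", "BGD"]),
        chains=np.array(["X", "X", "X", "X"]),
        charges=np.array([q_move, 1.0, 1.0, -1.0]),
        masses=np.array([10.0, 10.0, 10.0, 10.0]),
    )
    z0 = 10.0
    frames: dict[tuple[str, float], list[TrajectoryFrame]] = {}
    for state, z_move in (("CS", z0 + dz), ("ES", z0)):
        for v in voltages:
            fl = []
            for k in range(n_frames):
                z_noise = rng.normal(0.0, noise_sd * box_z) if noise_sd > 0 else 0.0
                xyz = np.array(
                    [
                        [25.0, 25.0, z_move],
                        [25.0, 25.0, capacitance_slope * v * box_z],
                        [25.0, 25.0, z_noise],
                        [25.0, 25.0, 0.0],
                    ]
                )
                fl.append(TrajectoryFrame(xyz=xyz, box=box.copy(), time=k * 1000.0))
            frames[(state, v)] = fl
    return CEFieldRecordings(
        system=system,
        frames=frames,
        truth_qg=q_move * dz / box_z,
        voltages=tuple(voltages),
    )


# ---------------------------------------------------------------------------
# electrophysiology recordings
# ---------------------------------------------------------------------------


@dataclass
class EphysTruth:
    """Ground-truth parameters for synthetic NLC / Q-V / VCF recordings.

    Units: capacitance pF, charge fC, voltage mV, time ms, conductance nS.
    ``f_delta`` is the relative fluorescence change at full sensor
    saturation.  The bleach envelope is multiplicative:
    ``(1-a1-a2) + a1*exp(-t/tau1) + a2*exp(-t/tau2)``.
    """

    c_lin: float = 12.0
    q_max: float = 344.0
    v_half: float = -137.0
    alpha: float = 43.0
    bleach_amp1: float = 0.15
    bleach_tau1: float = 2000.0
    bleach_amp2: float = 0.10
    bleach_tau2: float = 20000.0
    leak_conductance: float = 2.0
    noise_sd: float = 0.05
    f_delta: float = 0.05
    v_hold: float = -60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.bleach_tau1 <= 0 or self.bleach_tau2 <= 0:
            raise ValueError("bleach time constants must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.bleach_amp1 + self.bleach_amp2 >= 1.0:
            raise ValueError("bleach amplitudes must sum to < 1")


def make_nlc_recording(truth: EphysTruth, v_grid: np.ndarray) -> pd.DataFrame:
    """Membrane-capacitance trace C_M(V) on a voltage grid, with noise.

    The generating model is the bell-shaped derivative of a first-order
    Boltzmann charge-voltage relation:
    ``C_M = C_lin + (Q_max/alpha) * e^-u / (1+e^-u)^2``, u=(V-V1/2)/alpha,
    whose peak height above C_lin is Q_max/(4*alpha).
    """
    from .ephys import nlc_model

    rng = np.random.default_rng(truth.seed)
    v = np.asarray(v_grid, dtype=float)
    c = nlc_model(v, truth.c_lin, truth.q_max, truth.v_half, truth.alpha)
    if truth.noise_sd > 0:
        c = c + rng.normal(0, truth.noise_sd, v.shape)
    return pd.DataFrame({"v_mV": v, "c_pF": c})


def _normalize_protocol(
    protocol: list[tuple], pre_ms: float, inter_ms: float
) -> list[tuple[float, float, float]]:
    """Return [(onset, v, dur)]; validates overlap for explicit onsets."""
    steps = []
    if protocol and len(protocol[0]) == 3:
        for onset, v, dur in protocol:
            if dur <= 0:
                raise ValueError("step duration must be > 0")
            steps.append((float(onset), float(v), float(dur)))
        steps.sort()
        for (o1, _, d1), (o2, _, _) in zip(steps, steps[1:]):
            if o2 < o1 + d1:
                raise ValueError("overlapping voltage steps in protocol")
    else:
        t = pre_ms
        for v, dur in protocol:
            if dur <= 0:
                raise ValueError("step duration must be > 0")
            steps.append((t, float(v), float(dur)))
            t += dur + inter_ms
    return steps


def make_vcf_recording(
    truth: EphysTruth,
    protocol: list[tuple],
    sample_rate_hz: float = 10_000.0,
    pre_ms: float = 500.0,
    inter_ms: float = 500.0,
    post_ms: float = 500.0,
) -> pd.DataFrame:
    """Fluorescence trace for a family of voltage steps.

    ``protocol`` is a list of (level mV, duration ms) applied sequentially
    from the holding potential, or (onset ms, level mV, duration ms) with
    explicit onsets.  F(t) is the Boltzmann F-V response multiplied by the
    double-exponential bleach envelope, plus Gaussian noise.
    """
    rng = np.random.default_rng(truth.seed)
    steps = _normalize_protocol(protocol, pre_ms, inter_ms)
    t_end = max(o + d for o, _, d in steps) + post_ms if steps else pre_ms + post_ms
    dt = 1000.0 / sample_rate_hz
    t = np.arange(0.0, t_end, dt)
    v = np.full_like(t, truth.v_hold)
    for onset, lvl, dur in steps:
        v[(t >= onset) & (t < onset + dur)] = lvl

    b = boltzmann_occupancy(v, truth.v_half, truth.alpha)
    b0 = boltzmann_occupancy(np.array([truth.v_hold]), truth.v_half, truth.alpha)[0]
    signal = 1.0 + truth.f_delta * (b - b0)
    c0 = 1.0 - truth.bleach_amp1 - truth.bleach_amp2
    env = (
        c0
        + truth.bleach_amp1 * np.exp(-t / truth.bleach_tau1)
        + truth.bleach_amp2 * np.exp(-t / truth.bleach_tau2)
    )
    f = signal * env
    if truth.noise_sd > 0:
        f = f + rng.normal(0, truth.noise_sd * truth.f_delta * 0.1, t.shape)
    return pd.DataFrame({"t_ms": t, "v_mV": v, "F": f})


@dataclass
class StepSweep:
    """One voltage-step current sweep: command level and sampled current."""

    v_step: float
    t_ms: np.ndarray
    i_pA: np.ndarray


@dataclass
class QVRecording:
    """Main-pulse sweeps with their P/N leak-subtraction subpulse sweeps."""

    sweeps: list[StepSweep]
    subpulses: list[list[StepSweep]]
    truth_q: pd.DataFrame  # per main step: v_mV, q_fC (nonlinear charge)
    v_hold: float
    subpulse_n: int


def make_qv_step_recording(
    truth: EphysTruth,
    v_steps: np.ndarray,
    subpulse_n: int = 8,
    dur_ms: float = 20.0,
    sample_rate_hz: float = 50_000.0,
    tau_ms: float = 0.5,
) -> QVRecording:
    """Capacitive step transients with ohmic leak and P/-n subpulses.

    Each main step evokes an exponentially decaying transient whose
    integral is the linear charge C_lin*dV plus the nonlinear sensor charge
    Q(V)-Q(hold) from the generating Boltzmann, on top of ohmic leak g*V.
    Subpulses of amplitude -dV/n evoke only the linear components, the
    idealization under which P/-n subtraction is exact (experimentally the
    subpulse range is chosen where sensor charge is immobile).
    """
    rng = np.random.default_rng(truth.seed)
    dt = 1000.0 / sample_rate_hz
    t = np.arange(0.0, dur_ms, dt)
    kernel = np.exp(-t / tau_ms) / tau_ms  # unit-charge transient, 1/ms

    def sweep(v_level: float, q_extra: float) -> StepSweep:
        dv = v_level - truth.v_hold
        i = (truth.c_lin * dv + q_extra) * kernel + truth.leak_conductance * v_level
        if truth.noise_sd > 0:
            i = i + rng.normal(0, truth.noise_sd, t.shape)
        return StepSweep(v_step=v_level, t_ms=t.copy(), i_pA=i)

    b0 = boltzmann_occupancy(np.array([truth.v_hold]), truth.v_half, truth.alpha)[0]
    sweeps, subs, rows = [], [], []
    for v in np.asarray(v_steps, dtype=float):
        q_nl = truth.q_max * (
            boltzmann_occupancy(np.array([v]), truth.v_half, truth.alpha)[0] - b0
        )
        sweeps.append(sweep(v, q_nl))
        dv = v - truth.v_hold
        sub_level = truth.v_hold - dv / subpulse_n
        subs.append([sweep(sub_level, 0.0) for _ in range(subpulse_n)])
        rows.append({"v_mV": v, "q_fC": q_nl})
    return QVRecording(
        sweeps=sweeps,
        subpulses=subs,
        truth_q=pd.DataFrame(rows),
        v_hold=truth.v_hold,
        subpulse_n=subpulse_n,
    )
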