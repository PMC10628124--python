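"""Center-of-charge profiles and Q-route gating-charge computation.

The charge-center offset CZ = CC_TMD - MC_MEM locates the absolute-charge-
weighted center of the charged TMD residues relative to the phosphate mass
center of the membrane, per frame.  The gating charge Q_g is obtained by
the Q-route: the displacement charge Q_d = sum_i q_i z_i^u / L_z (unwrapped
z) varies linearly with voltage as <Q_d>_{s,0} + C V for each conformational
state s, with C the state-independent system capacitance; Q_g is the
offset between the two state lines at V = 0,

    Q_g = <Q_d>_{CS,0} - <Q_d>_{ES,0}.

Block averaging over the production tail of each trajectory provides the
spread from which the Q_g standard deviation is propagated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .trajectory import (
    DomainSpec,
    MolecularSystem,
    TrajectoryFrame,
    resolve_selection,
)

__all__ = [
    "ChargeProfile",
    "GatingChargeEstimate",
    "charged_residue_selection",
    "tmd_center_of_charge",
    "membrane_mass_center",
    "charge_center_offset",
    "unwrap_z",
    "displacement_charge",
    "block_means",
    "gating_charge",
]

CHARGED_RESNAMES = ("ASP", "GLU", "ARG", "LYS")


@dataclass
class ChargeProfile:
    """Charge-center bookkeeping for one frame (z in Angstrom)."""

    frame: int
    cc_tmd: float
    mc_mem: float

    @property
    def cz(self) -> float:
        return self.cc_tmd - self.mc_mem


def charged_residue_selection(
    system: MolecularSystem,
    domains: DomainSpec | None = None,
    chain: str | None = None,
    resnames: Sequence[str] = CHARGED_RESNAMES,
) -> np.ndarray:
    """Atoms of charged residues within the TMD range.

    Default charged set: Asp/Glu/Arg/Lys.  The returned atoms feed the
    absolute-charge-weighted center (only atoms with nonzero |q| actually
    contribute).
    """
    domains = domains or DomainSpec()
    idx = resolve_selection(system, domains.ranges["tmd"], chain=chain)
    mask = np.isin(system.resnames[idx], list(resnames))
    if not mask.any():
        raise ValueError("no charged residues in the TMD selection")
    return idx[mask]


def tmd_center_of_charge(
    frame: TrajectoryFrame, system: MolecularSystem, selection: np.ndarray
) -> float:
    """Absolute-charge-weighted mean z: sum(|q_i| z_i) / sum(|q_i|)."""
    sel = np.asarray(selection)
    if sel.size == 0:
        raise ValueError("empty selection")
    w = np.abs(system.charges[sel])
    total = w.sum()
    if total == 0:
        raise ValueError("selection carries zero total |charge|")
    return float(np.dot(w, frame.xyz[sel, 2]) / total)


def membrane_mass_center(
    frame: TrajectoryFrame, system: MolecularSystem, selection: np.ndarray
) -> float:
    """Mass-weighted mean z of the phosphate selection."""
    sel = np.asarray(selection)
    if sel.size == 0:
        raise ValueError("empty selection")
    w = system.masses[sel]
    total = w.sum()
    if total == 0:
        raise ValueError("selection carries zero total mass")
    return float(np.dot(w, frame.xyz[sel, 2]) / total)


def charge_center_offset(
    frame: TrajectoryFrame,
    system: MolecularSystem,
    tmd_charged: np.ndarray,
    phosphates: np.ndarray,
    frame_id: int = 0,
) -> ChargeProfile:
    """CZ = CC_TMD - MC_MEM for one frame.

    Negative CZ means the TMD charge center sits below the membrane mass
    center (deeper toward the intracellular side).
    """
    return ChargeProfile(
        frame=frame_id,
        cc_tmd=tmd_center_of_charge(frame, system, tmd_charged),
        mc_mem=membrane_mass_center(frame, system, phosphates),
    )


def unwrap_z(frames: Sequence[TrajectoryFrame]) -> Sequence[TrajectoryFrame]:
    """Populate continuity-unwrapped z on every frame (in place).

    z^u(t) is chosen so each atom's step from the previous frame is the
    minimum image: |z^u(t) - z^u(t-1)| <= L_z/2.  Atoms moving close to
    half a box per step make the unwrapping ambiguous and trigger a
    warning naming them.
    """
    prev = None
    for frame in frames:
        lz = frame.box[2]
        z = frame.xyz[:, 2]
        if prev is None:
            frame.z_unwrapped = z.copy()
        else:
            delta = z - (prev % lz)
            delta -= lz * np.round(delta / lz)
            suspicious = np.flatnonzero(np.abs(delta) > 0.45 * lz)
            if suspicious.size:
                warnings.warn(
                    f"atoms {suspicious[:10].tolist()} moved nearly half the "
                    "box along z in one step; unwrapping may be ambiguous",
                    stacklevel=2,
                )
            frame.z_unwrapped = prev + delta
        prev = frame.z_unwrapped
    return frames


def displacement_charge(
    frame: TrajectoryFrame,
    system: MolecularSystem,
    selection: np.ndarray | None = None,
) -> float:
    """Q_d = sum_i q_i z_i^u / L_z over the configured atom set (default all).

    Requires unwrapped z (see :func:`unwrap_z`).  The Q-route works at the
    system level, so by default every atom contributes.
    """
    if frame.z_unwrapped is None:
        raise ValueError("frame has no unwrapped z; run unwrap_z first")
    q = system.charges
    zu = frame.z_unwrapped
    if selection is not None:
        sel = np.asarray(selection)
        q, zu = q[sel], zu[sel]
    return float(np.dot(q, zu) / frame.box[2])


def block_means(
    values: np.ndarray,
    n_blocks: int = 3,
    times: np.ndarray | None = None,
    equilibration_cut: float = 0.0,
) -> np.ndarray:
    """Contiguous-block means of a series after an equilibration cut.

    The post-cut series is partitioned into ``n_blocks`` equal contiguous
    blocks (a remainder shorter than a block is dropped from the front so
    the production tail is kept intact).
    """
    v = np.asarray(values, dtype=float)
    if times is not None:
        v = v[np.asarray(times) >= equilibration_cut]
    elif equilibration_cut:
        v = v[int(equilibration_cut):]
    if n_blocks < 1 or v.size < n_blocks:
        raise ValueError(
            f"series of length {v.size} cannot form {n_blocks} blocks"
        )
    per = v.size // n_blocks
    v = v[v.size - per * n_blocks:]
    return v.reshape(n_blocks, per).mean(axis=1)


@dataclass
class GatingChargeEstimate:
    """Q-route gating charge with per-state linear fits over block means.

    ``qg`` is the difference of the zero-voltage intercepts (CS - ES); the
    SD comes from re-fitting with one block per voltage at a time.  The
    fitted slopes estimate the system capacitance and should agree between
    states.
    """

    qg: float
    sd: float
    intercepts: dict[str, float]
    slopes: dict[str, float]
    slope_se: dict[str, float]
    per_block_qg: np.ndarray
    n_blocks: int


def _linfit(v: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line y = a + b v; returns (a, b, se_b)."""
    if np.unique(v).size < 2:
        raise ValueError("need at least two distinct voltages per state")
    if len(v) > 3:
        coeffs, cov = np.polyfit(v, y, 1, cov=True)
        se_b = float(np.sqrt(cov[0, 0]))
    else:
        coeffs = np.polyfit(v, y, 1)
        se_b = float("nan")
    b, a = float(coeffs[0]), float(coeffs[1])
    return a, b, se_b


def gating_charge(
    blocks_by_state_and_voltage: Mapping[str, Mapping[float, np.ndarray]],
    state_a: str = "CS",
    state_b: str = "ES",
) -> GatingChargeEstimate:
    """Gating charge from per-state linear fits of <Q_d> vs voltage.

    Input: ``{state: {voltage_mV: array of block-mean Q_d}}``.  The main
    estimate pools all block means into one fit per state; the SD is the
    spread of Q_g over fits that use the k-th block of every voltage
    (block-wise replicates, matching block-averaged error propagation).
    """
    fits = {}
    for state in (state_a, state_b):
        vmap = blocks_by_state_and_voltage[state]
        v = np.concatenate(
            [np.full(len(np.atleast_1d(m)), volt) for volt, m in vmap.items()]
        )
        y = np.concatenate([np.atleast_1d(m) for m in vmap.values()])
        fits[state] = _linfit(v, y)

    qg = fits[state_a][0] - fits[state_b][0]
    n_blocks = min(
        len(np.atleast_1d(m))
        for state in (state_a, state_b)
        for m in blocks_by_state_and_voltage[state].values()
    )
    per_block = []
    for k in range(n_blocks):
        intercepts = {}
        for state in (state_a, state_b):
            vmap = blocks_by_state_and_voltage[state]
            v = np.array(list(vmap.keys()), dtype=float)
            y = np.array([np.atleast_1d(m)[k] for m in vmap.values()])
            intercepts[state] = _linfit(v, y)[0]
        per_block.append(intercepts[state_a] - intercepts[state_b])
    per_block = np.array(per_block)
    sd = float(per_block.std(ddof=1)) if n_blocks > 1 else 0.0
    return GatingChargeEstimate(
        qg=float(qg),
        sd=sd,
        intercepts={s: fits[s][0] for s in fits},
        slopes={s: fits[s][1] for s in fits},
        slope_se={s: fits[s][2] for s in fits},
        per_block_qg=per_block,
        n_blocks=n_blocks,
    )
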