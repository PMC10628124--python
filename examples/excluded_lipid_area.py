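"""Per-leaflet excluded-lipid area: the membrane's view of protein expansion.

The bulk area-per-lipid far from the protein gives the lipid count the
leaflet would hold without an inclusion; the shortfall of actual lipids
times the APL is the protein-occupied ("excluded-lipid") area, computed
independently for the intra- and extracellular leaflets.
"""

import numpy as np

from elevatormd import ElevatorParams, make_elevator_trajectory
from elevatormd import membrane as M

seq = np.array((["CS"] * 25 + ["ES"] * 25) * 2)
traj = make_elevator_trajectory(ElevatorParams(state_sequence=seq, seed=5))
protein = np.flatnonzero(
    np.isin(traj.domain_tag, ["transport", "scaffold", "other"])
)

table = M.area_table(traj.frames, traj.system, protein, cutoff=40.0)
table["state"] = traj.truth["state"][table.frame.to_numpy()]
summary = table.groupby(["leaflet", "state"])[["apl_A2", "excluded_A2"]].mean()
print(summary.round(1))

intra = summary.loc["intra", "excluded_A2"]
extra = summary.loc["extra", "excluded_A2"]
print(
    "\nCS -> ES change: intracellular %+.1f%%, extracellular %+.1f%%"
    % (
        100 * (intra["ES"] / intra["CS"] - 1),
        100 * (extra["ES"] / extra["CS"] - 1),
    )
)
# The generator expands the intracellular footprint by ~5.4% (about three
# lipids) while the extracellular leaflet is unchanged -- the asymmetric
# area change the method is designed to resolve.
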