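"""Electrophysiology curve analyses: NLC, step-evoked Q-V, and VCF F-V.

Synthetic recordings generated from known Boltzmann parameters (with noise,
ohmic leak and photobleaching) are pushed through the full analysis chain:
bell-shaped Boltzmann-derivative fit for NLC, P/-8 leak subtraction plus
transient integration for Q-V, and double-exponential bleach correction
plus late-window averaging for F-V.
"""

import numpy as np

from elevatormd import (
    EphysTruth,
    make_nlc_recording,
    make_qv_step_recording,
    make_vcf_recording,
)
from elevatormd import ephys as F

# --- nonlinear capacitance -------------------------------------------------
nlc_truth = EphysTruth(
    c_lin=12.0, q_max=344.0, v_half=-137.0, alpha=43.0, noise_sd=0.05, seed=1
)
rec = make_nlc_recording(nlc_truth, np.arange(-250.0, 101.0, 2.0))
fit = F.fit_nlc(rec.v_mV, rec.c_pF)
print(
    "NLC: V1/2 %.1f mV, alpha %.1f mV, C_lin %.2f pF, NLC_max %.2f pF"
    % (fit.v_half, fit.alpha, fit.c_lin, fit.nlc_max)
)

# --- charge movement from voltage steps (P/-8) ------------------------------
qv_truth = EphysTruth(
    v_half=93.1, alpha=57.5, leak_conductance=5.0, noise_sd=0.05, seed=2
)
qv = make_qv_step_recording(qv_truth, np.arange(-120.0, 201.0, 10.0))
table = F.qv_table(qv)
qfit = F.fit_boltzmann(table.v_mV, table.q_fC)
print(
    "Q-V: V1/2 %.1f mV, alpha %.1f mV, Q_max %.0f fC"
    % (qfit.v_half, qfit.alpha, qfit.amplitude)
)

# --- voltage-clamp fluorometry ----------------------------------------------
fv_truth = EphysTruth(v_half=93.1, alpha=57.5, noise_sd=0.05, seed=3)
protocol = [(v, 100.0) for v in np.arange(-120.0, 201.0, 10.0)]
trace = make_vcf_recording(fv_truth, protocol)
corrected, info = F.correct_bleaching(trace)
fv = F.fv_from_steps(corrected, window_ms=10.0)
bfit = F.fit_boltzmann(fv.v_mV, fv.F)
print("F-V: V1/2 %.1f mV, alpha %.1f mV" % (bfit.v_half, bfit.alpha))

smoothed = F.boxcar_smooth(
    corrected.F_corrected.to_numpy(), width_ms=1.5, dt_ms=0.1
)
print(
    "display trace smoothed with a 1.5 ms boxcar (%d samples)" % len(smoothed)
)
# Each fit recovers its generator's V1/2 and alpha; NLC_max equals
# Q_max/(4 alpha) by the analytic property of the Boltzmann derivative.
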