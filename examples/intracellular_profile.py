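"""Extract an intrinsic-property profile from a synthetic late-spiking cell.

Generates a current-clamp sweep set for a neurogliaform-like (LS) cell —
hyperpolarizing step, subthreshold step, rheobase sweeps, and trains at
1.3x and 2x rheobase — then runs the full extraction: input resistance,
membrane tau, rheobase, first-spike latency, adaptation index, ISI
regularity and the LS/IS/BS classification.
"""
from id2phys import intracell, synth

sweeps, truth = synth.gen_intracellular_cell(synth.default_phenotype("LS"), seed=1)
profile = intracell.profile_cell(sweeps)

print(f"firing class          : {profile.firing_class} (planted {truth['firing_class']})")
print(f"rheobase              : {profile.rheobase_pA:.0f} pA (planted {truth['rheobase_planted_pA']:.0f}, 10 pA grid)")
print(f"input resistance      : {profile.input_resistance_MOhm:.0f} MOhm (planted {truth['rin_MOhm']:.0f})")
print(f"membrane tau          : {profile.tau_ms:.1f} ms (planted {truth['tau_ms']:.0f})")
print(f"first-spike latency   : {profile.first_ap_latency_ms:.0f} ms")
print(f"latency / tau         : {profile.latency_over_tau:.1f}")
print(f"adaptation index (2x) : {profile.ai_2x:.2f} (planted {truth['ai_2x']})")
print(f"ISI CV (2x rheobase)  : {profile.cv_isi_2x:.3f} (planted {truth['cv_2x']})")
print(f"firing rate (2x)      : {profile.firing_rate_2x_Hz:.0f} Hz")
print(f"AP half-width         : {profile.ap.halfwidth_ms:.2f} ms, AHP {profile.ap.ahp_mV:.1f} mV")
print()
print("A late-spiking profile: a single AP after a >500 ms depolarizing ramp")
print("at rheobase, regular firing (low CV), and mild adaptation (AI < 1).")
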