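"""Identify light-responsive units with the three-criterion opto-tag test.

Builds a synthetic session in which the Id2-class units fire reliably
~5 ms after each 100 ms light pulse, then tests every unit: (1) response
> 2 s.d. of the pulse-shuffle null, (2) Poisson modulation p < 1e-3,
(3) significant difference from 500 shuffled-pulse replicates.
"""
from id2phys import invivo, synth

bundle = synth.gen_session(synth.SessionSpec(seed=5))
pulses = bundle.events["pulse"]

tagged, by_class = [], {}
for i, (unit, info) in enumerate(zip(bundle.units, bundle.ground_truth["units"])):
    # pulses are delivered in waking blocks, so the null jitters pulse
    # times locally (state-matched) instead of over the whole session
    r = invivo.optotag_test(unit, pulses, bundle.duration_s, seed=100 + i,
                            null_jitter_s=5.0)
    by_class.setdefault(info["cls"], []).append(r.tagged)
    if r.tagged:
        tagged.append((unit.unit_id, info["cls"], r.response_z, r.p_shuffle))

print(f"{len(pulses)} pulses; {len(bundle.units)} units tested")
for cls, flags in sorted(by_class.items()):
    print(f"  {cls:4s}: {sum(flags)}/{len(flags)} tagged")
print()
print("tagged units (id, class, z vs null, shuffle p):")
for uid, cls, z, p in tagged[:5]:
    print(f"  {uid}  {cls}  z={z:.1f}  p={p:.4f}")
print()
print("The planted light-followers (Id2 class) all pass the three criteria;")
print("a planted slowly light-facilitated interneuron can occasionally pass")
print("too. The shuffle p floors at 1/501 with 500 replicates.")
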