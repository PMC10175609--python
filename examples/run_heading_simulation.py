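"""Round-trip heading simulation with bridge-end wrap.

Simulates forward motion interrupted by a right turn and an equal left
turn; the bump crosses from L8 to R8 and back, returning to its
starting column — direction information integrates correctly over time.
"""

from cxcompass import (
    build_mask,
    default_trajectory,
    gen_trajectory,
    make_targets,
    net_displacement,
    optimize_maintenance,
    optimize_modulations,
    simulate,
)

targets = make_targets()
model = optimize_maintenance(build_mask("default"), targets)
mods = optimize_modulations(model, targets)
commands = gen_trajectory(default_trajectory(forward_steps=4, turn_steps=8))
sim = simulate(model, mods, commands, start_column="L4")

print("commands:  " + " ".join(c.replace("turn_", "") for c in commands))
print("bump:      " + " ".join(sim.bump_trace))
print(f"net circular displacement: {net_displacement(sim)} columns "
      f"(equal turn blocks close the loop)")
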