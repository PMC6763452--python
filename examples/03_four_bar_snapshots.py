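"""Boundary coevolution from the four-bar start.

The lattice is split into four vertical bars (C, D, C, D); the two left
bars start with the minimum learning ability 0.1, the two right bars with
the maximum 1.0.  Under rule II only cooperators coevolve w: bulk
cooperators sink to w = 0.1 (their payoff ties the neighbourhood average)
while defectors keep their initial w unchanged — and the eager w = 1
defectors of the right half are steadily absorbed by their conservative
cooperator neighbours.
"""

from pathlib import Path

from coevolearn import (
    GameParams,
    RuleVariant,
    cooperation_density,
    export_snapshot,
    four_bar_initial,
    learning_ability_stats,
)
from coevolearn.observables import advance, replicate_seed

params = GameParams(b=1.02, d=0.05, rule=RuleVariant.RULE_II).validate()
world = four_bar_initial(L=60)
out = Path("scratch/four_bar")

times = [0, 10, 100, 1000]
t_now = 0
for si, t in enumerate(times):
    if t > t_now:
        advance(world, params, t - t_now, seed=replicate_seed(3, si))
        t_now = t
    export_snapshot(world, out / f"snap_t{t:05d}")
    stats = learning_ability_stats(world)
    line = f"t = {t:5d}  f_C = {cooperation_density(world):.3f}"
    for s in ("C", "D"):
        if s in stats:
            line += (
                f"  mean w_{s} = {stats[s]['mean_w']:.3f}"
                f" (boundary {stats[s]['boundary_mean_w']:.3f})"
            )
    print(line)

print(f"\nStrategy and w heat-map matrices written under {out}/")
print("Cooperators hold a lower mean w than defectors at every stage: they")
print("imitate rarely while the eager w = 1 defectors of the right half keep")
print("copying their successful cooperator neighbours — rule II's promotion")
print("mechanism through enhanced network reciprocity.")
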