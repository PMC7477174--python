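"""Generate the synthetic motor and startle cohorts used by the analyses.

Motor: 10 subjects x 10 blocks (30 s walk / 30 s rest), a canonical
cortical activation (peak +1 uM O2Hb, -0.3 uM HHb) confined to the lower
layer, no superficial signal.  Startle: 10 subjects x 5 blocks (30 s
baseline / 3 s stimulus / 60 s reaction) with a 70/30 flight/freezing mix.
Writes pipeline-ready CSV inputs under scratch/cohorts/ (bulky, not part
of the deliverable tree).
"""

import argparse
from pathlib import Path

from ovifnirs.simulate import generate_cohort, write_cohort

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=11)
args = parser.parse_args()

OUT = Path(__file__).resolve().parents[1] / "scratch" / "cohorts"

motor = generate_cohort(n_subjects=10, task="motor", seed=args.seed)
cfg_m = write_cohort(motor, OUT / "motor")
print(f"motor cohort: {len(motor.subjects())} subjects, "
      f"{len(motor.schedules[motor.subjects()[0]].block_starts)} blocks each "
      f"-> {cfg_m}")

startle = generate_cohort(
    n_subjects=10, task="startle", seed=args.seed + 1,
    behavior_mix={"flight": 0.7, "freezing": 0.3})
cfg_s = write_cohort(startle, OUT / "startle")
n_flight = sum(1 for a in startle.annotations if a.behavior == "flight")
n_freeze = sum(1 for a in startle.annotations if a.behavior == "freezing")
print(f"startle cohort: {len(startle.subjects())} subjects, "
      f"{n_flight} flight / {n_freeze} freezing blocks -> {cfg_s}")
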