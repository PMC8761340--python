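"""Train the multi-view CNN on phantoms and segment a held-out case.

A compact version of the full study: an 8-phantom cohort, class-rebalanced
voxel sampling (50% tumor / 1% healthy), 3 epochs of soft-dice training, and
masked full-volume inference on two held-out cases.  Prints the loss history,
the held-out Dice scores and the predicted vs reference volumes.
"""

import numpy as np

from mvseg import (
    ModelConfig,
    PhantomConfig,
    TrainConfig,
    build_template,
    dsc,
    generate_cohort,
    predicted_volume_cm3,
    segment_volume,
    train_fold,
)

base = PhantomConfig(misalign_mm=0, misalign_deg=0)
cases, manifest = generate_cohort(8, seed=3, base_config=base)
tpl = build_template([c.t1 for c, _ in cases], 0.30)

held = [c for c, _ in cases][-2:]
train_cases = [c for c, _ in cases][:-2]
print(f"training on {len(train_cases)} phantoms, holding out "
      f"{[c.case_id for c in held]}")

model, history = train_fold(
    train_cases, TrainConfig(epochs=3, seed=3), ModelConfig(), tpl.occupancy_mask)
print("epoch mean soft-dice loss:", [round(h, 3) for h in history])

for case in held:
    pred = segment_volume(model, case, tpl.occupancy_mask, batch_size=1024)
    print(f"{case.case_id}: DSC {dsc(pred, case.reference):.3f}   "
          f"predicted {predicted_volume_cm3(pred):5.1f} cm^3 vs "
          f"reference {predicted_volume_cm3(case.reference):5.1f} cm^3")
print("A falling loss and held-out DSC well above chance show the network "
      "recovered the tumor contrast pattern rather than memorizing voxels.")
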