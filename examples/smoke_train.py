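"""Train a width-scaled variant of the detector for a few dozen SGD steps
on synthetic scenes and print the smoothed loss trajectory.

A falling smoothed loss shows the assembled network, the assignment, the
distribution-focal box loss and the backward pass all cooperate; it makes
no claim about benchmark accuracy.
"""

from yolowl import smoke_train

res = smoke_train(steps=60, n_scenes=16, image_size=128, batch_size=4,
                  width_mult=0.25, seed=0, progress=True)
s = res.smoothed
print(f"\nsmoothed loss: {s[0]:.3f} -> {s[-1]:.3f} "
      f"({'decreased' if res.decreased() else 'did not decrease'}) "
      f"over {len(res.losses)} steps")
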