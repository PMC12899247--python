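"""Recover the context-stage (C2f-MSDDSC) wiring from parameter counts.

The published table pins each context stage's parameter budget but not
the block's internal wiring. This script enumerates the bounded design
space (~1M configurations, a few seconds) and prints the configuration
whose built blocks reproduce all four printed rows exactly.
"""

from yolowl import load_default_manifest, search_msddsc_config

manifest = load_default_manifest()
targets = [(r.args[0], r.args[1], r.args[2], r.expected_params)
           for r in manifest.rows if r.module == "C2f-MSDDSC"]

result = search_msddsc_config(targets)
print(f"searched {result.n_searched} configurations")
print(f"total |deviation| over the four rows: {result.total_deviation}")
for (ci, co, n, exp), dev in zip(targets, result.deviations):
    print(f"  C2f-MSDDSC[{ci},{co},{n}] expected {exp:>7}  delta {dev:+d}")
print("\nresolved configuration:")
for k, v in result.as_dict()["config"].items():
    print(f"  {k}: {v}")
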