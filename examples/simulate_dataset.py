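"""Generate a synthetic drug-repositioning benchmark and write it to disk.

The generator plants disease clusters that share pathogenic genes and
pathways, therapeutic drugs whose target sets overlap their disease's
genes, and reveals only a fraction of the true associations as "known";
the rest form the held-out recovery truth.
"""

import tempfile
from pathlib import Path

from ddcm import SyntheticConfig, generate
from ddcm.synthetic import write_dataset

config = SyntheticConfig(seed=42)  # defaults: 20 diseases, 100 drugs, 4 clusters
synth = generate(config)

print(f"diseases: {len(synth.dataset.diseases)}  drugs: {len(synth.dataset.drugs)}")
print(f"true associations: {len(synth.truth)}")
print(f"known (training) associations: {len(synth.dataset.associations)}")
print(f"held-out associations: {len(synth.holdout)}")

with tempfile.TemporaryDirectory() as tmp:
    manifest = write_dataset(synth, Path(tmp))
    files = sorted(p.name for p in Path(tmp).iterdir())
    print("files written:", ", ".join(files))
    print("dataset manifest:", manifest.name)

print(
    "\nknown + held-out partition the truth; truth/holdout files are for "
    "evaluation only and are never referenced by the dataset manifest."
)
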