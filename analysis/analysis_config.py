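"""Shared configuration for the numbered analysis drivers.

All drivers operate on the same output directory and the same run
configuration, so completed stages are reused (see the manifest written by
``unidims.pipeline.run_all``).  The world is the standard aligned simulation:
6 networks x 3 layers x 60 channels mixing 3 universal and 6 idiosyncratic
latents, 600 fit / 200 evaluation stimuli, and 4 brain subjects that share the
universal latents.
"""

from unidims import WorldConfig
from unidims.pipeline import RunConfig

OUT_DIR = "results/analysis"

CONFIG = RunConfig(
    world=WorldConfig(),
    n_perm=199,
    ks=(10, 5),
    out_dir=OUT_DIR,
    seed=0,
)
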