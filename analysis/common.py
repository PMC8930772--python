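"""Shared run configuration for the analysis scripts.

A desk-scale version of the study design: two strains (wild-type-like
and seipin-null-like droplet phenotypes), three independent
experiments, three fields per strain per experiment, ~40 cells per
field.  All scripts read and write under results/run.
"""

from dropseg.pipeline import RunConfig


def demo_config() -> RunConfig:
    return RunConfig(
        seed=20260920,
        out_dir="results/run",
        archetypes=["wt_like", "null_like"],
        n_experiments=3,
        fields_per_strain=3,
        n_cells=40,
        image_shape=(256, 256),
        segmentation="network",
        train_steps=500,
        metric="pct_cells_supersized",
        pairs=[("wt_like", "null_like")],
    )
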