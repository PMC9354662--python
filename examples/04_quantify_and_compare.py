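"""Quantify annotations across a two-group study and screen for enrichment.

Sixteen synthetic samples in two diet-like groups, one EC planted threefold
enriched in the second group.  Family copy numbers are normalized to copies
per million small-protein copies, restricted to ECs present in every sample,
and screened by one-way ANOVA with Benjamini-Hochberg correction."""

import tempfile
from pathlib import Path

from smorfscape import (
    EmbedderSpec,
    PipelineConfig,
    SynthConfig,
    build_db,
    make_annotation_source,
    make_community,
    run_study,
)

config = SynthConfig(
    seed=99, n_families=8, family_size=(4, 7), n_samples=16,
    groups=tuple(["normal"] * 8 + ["highfat"] * 8),
    enriched_ec="1.11.1.6", enriched_group="highfat", enrichment_factor=3.0,
    n_long_proteins=2, n_singletons=4,
)

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    manifest, _, truth = make_community(config, outdir=tmp / "data")
    source, _ = make_annotation_source(config)
    db = build_db(source, EmbedderSpec(dimension=32))
    results = run_study(
        manifest, PipelineConfig(outdir=tmp / "out",
                                 embedder=EmbedderSpec(dimension=32)), db=db
    )

table = results["shared"]
print(f"abundance table: {table.shape[0]} shared ECs x {table.shape[1]} samples")
print("top hits by raw p (copies per million, group means):")
for c in results["comparisons"][:3]:
    means = ", ".join(f"{g}={m:,.0f}" for g, m in sorted(c.group_means.items()))
    print(f"  {c.rank}. EC {c.annotation}: F={c.f_statistic:.1f} "
          f"p={c.p_value:.2e} q={c.q_value:.2e} ({means})")
print(f"planted enriched EC: {config.enriched_ec} "
      f"(x{config.enrichment_factor} in group '{config.enriched_group}')")
print("A small raw p with a large q is the expected pattern when few "
      "features are tested but the signal survives here by design.")
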