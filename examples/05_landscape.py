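"""Fit the 2-D PCA landscape of an embedded small-protein database and
overlay sample families on it.

The landscape is the mean-centered principal-component projection of all
database vectors; sample family representatives are embedded with the same
embedder and projected with the fitted model."""

from smorfscape import (
    EmbedderSpec,
    SynthConfig,
    build_db,
    call_families,
    cluster_linear,
    embed_batch,
    fit_landscape,
    make_annotation_source,
    make_community,
    project_landscape,
)
from smorfscape.embedding import EmbeddingMatrix

spec = EmbedderSpec(dimension=64)
config = SynthConfig(seed=5, n_families=12, db_entries_per_family=4)

source, _ = make_annotation_source(config)
db = build_db(source, spec)
db_matrix = EmbeddingMatrix(ids=[e.id for e in db.entries],
                            vectors=db.vectors, embedder=spec)
model = fit_landscape(db_matrix)
total_var = db_matrix.vectors.var(axis=0, ddof=1).sum()
pc1, pc2 = model.explained_variance
print(f"database landscape over {len(db.entries)} entries")
print(f"explained variance: PC1 {pc1 / total_var:.1%}, PC2 {pc2 / total_var:.1%}")

_, samples, _ = make_community(config)
records = samples["s00"]
families = call_families(cluster_linear(records), records)
overlay = embed_batch([f.representative for f in families], spec)
coords = project_landscape(model, overlay)
print(f"overlaid {len(coords)} family representatives from sample s00:")
for fid, x, y in coords[:5]:
    print(f"  {fid}: ({x:+.3f}, {y:+.3f})")
print("Families land near their source database entries because both are "
      "near-copies of the same ancestors in embedding space.")
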