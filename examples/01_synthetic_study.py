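"""Generate the default two-species synthetic multiome and inspect it.

The generator plants a known regulatory structure: five cone-promoting TFs
(two of them species-a specific), signed TF -> peak -> target regulons,
footprint-protected binding sites, histone-consistent element classes and
conserved promoter pairs.
"""

from conegrn.config import PipelineConfig
from conegrn.synthetic import generate_dataset

ds = generate_dataset(PipelineConfig(seed=1), seed=1)

for sp, data in ds.species.items():
    print(f"species {sp}: {data.rna.n_cells} cells, {data.rna.n_features} genes, "
          f"{len(data.peaks)} peaks")
print(f"planted regulons: a={len(ds.truth.planted_regulons['a'])}, "
      f"b={len(ds.truth.planted_regulons['b'])}")
print(f"planted cone-promoting TFs: {ds.truth.cone_tfs}")
print(f"conserved promoter pairs: {len(ds.truth.conserved_pairs)}")

# Species b lacks the regulons of the two species-a-specific cone TFs, so
# the cross-species comparison has a known, planted direction.
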