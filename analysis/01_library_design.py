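#!/usr/bin/env python
"""Build the two synthetic sgRNA libraries and summarise their composition.

Emulates a medium-scale pilot library (12,100 targeting sgRNAs over 2,269
genes + 250 non-targeting controls) and a large custom library (19,760
targeting sgRNAs over 3,744 genes + 490 NTCs = 20,250 elements, ~2.5% NTC),
then writes the manifests and composition tables under results/.
"""

from pathlib import Path

from sortscreen import composition_summary, write_manifest
from sortscreen.simulate import synthetic_manifest

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def build(name, n_genes, n_ntc, per_gene_counts, seed):
    m = synthetic_manifest(n_genes, 5, n_ntc, seed=seed,
                           per_gene_counts=per_gene_counts, name=name)
    s = composition_summary(m)
    write_manifest(m, OUT / f"{name}_manifest.tsv")
    s.to_frame().to_csv(OUT / f"{name}_composition.tsv", sep="\t", index=False)
    print(f"{name}: {s.n_total} elements = {s.n_targeting} targeting over "
          f"{s.n_genes} genes + {s.n_ntc} NTC ({100 * s.ntc_fraction:.2f}%); "
          f"guides/gene histogram {s.per_gene_histogram}")
    return m


# pilot: 12,100 guides over 2,269 genes (755 genes carry a 6th guide)
base, extra = divmod(12100, 2269)
pilot_counts = [base + 1] * extra + [base] * (2269 - extra)
build("pilot_library", 2269, 250, pilot_counts, seed=11)

# custom: 19,760 guides over 3,744 genes (1,040 genes carry a 6th guide)
custom_counts = [6] * 1040 + [5] * (3744 - 1040)
build("custom_library", 3744, 490, custom_counts, seed=12)
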