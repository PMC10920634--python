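#!/usr/bin/env python
"""Simulate a small cohort of archaeological items with known truth.

Builds the 11-group reference panel on a synthetic cacao genome, fabricates
four cacao-bearing items with different ancestries (one single-source, one
two-group hybrid, one sparse low-input item and one heavily contaminated
item), two negative-control items whose DNA comes entirely from non-target
taxa, plus a 326-item methylxanthine table with a 40% true-positive rate.

Writes FASTQ pairs, truth tables and the panel under results/sim/.
"""

import json
from pathlib import Path

import numpy as np

from paleocacao import simulate as sim

OUT = Path("results/sim")
SEED = 20260925

rng = np.random.default_rng(SEED)
OUT.mkdir(parents=True, exist_ok=True)

focal = {"chr1": sim.synthetic_genome(20000, gc=0.38, seed=rng)}
taxa = {
    "Theobroma_cacao": focal,
    "Herrania": {"h1": sim.related_genome(focal["chr1"], 0.05, seed=rng)},
    "Zea_mays": {"z1": sim.synthetic_genome(6000, gc=0.45, seed=rng)},
    "Musa": {"m1": sim.synthetic_genome(6000, gc=0.40, seed=rng)},
}
with open(OUT / "taxa.fasta", "w") as fh:
    for taxon, genome in taxa.items():
        for chrom, seq in genome.items():
            fh.write(f">{taxon}:{chrom} taxon={taxon}\n{seq}\n")

panel = sim.build_panel(n_groups=11, n_loci=300, divergence=0.15, seed=rng, genome=focal)
panel.to_tsv(OUT / "panel.tsv")

model = sim.DamageModel()  # delta0 0.05, mean length 81.65 bp

items = {
    "item_criollo": dict(q=np.eye(11)[0], n_pairs=800, contamination=0.2),
    "item_hybrid": dict(q=(np.eye(11)[4] + np.eye(11)[9]) / 2, n_pairs=800, contamination=0.2),
    "item_sparse": dict(q=np.eye(11)[2], n_pairs=120, contamination=0.2),
    "item_dirty": dict(q=np.eye(11)[6], n_pairs=800, contamination=0.6),
    "control_soil": dict(q=None, n_pairs=400, contamination=0.0, target="Zea_mays"),
    "control_musa": dict(q=None, n_pairs=400, contamination=0.0, target="Musa"),
}

manifest = {}
for name, spec in items.items():
    genotype = None
    if spec["q"] is not None:
        genotype = sim.sample_admixed_genotype(panel, spec["q"], seed=rng)
        np.savetxt(OUT / f"{name}_genotype_truth.tsv", genotype, fmt="%d")
    m = sim.DamageModel(contamination_fraction=spec["contamination"])
    cfg = sim.ItemConfig(
        name,
        spec["n_pairs"],
        genotype=genotype,
        target_taxon=spec.get("target", "Theobroma_cacao"),
        contaminant_taxa=("Zea_mays", "Musa"),
    )
    lib = sim.simulate_library(panel, taxa, m, cfg, seed=rng, out_dir=OUT)
    manifest[name] = {
        "n_pairs": spec["n_pairs"],
        "contamination": spec["contamination"],
        "target": spec.get("target", "Theobroma_cacao"),
        "true_q": None if spec["q"] is None else list(np.round(spec["q"], 3)),
        "n_target_reads": int((lib.truth.taxon == cfg.target_taxon).sum()),
    }
    print(f"{name}: {spec['n_pairs']} pairs, "
          f"{manifest[name]['n_target_reads']} from {cfg.target_taxon}")

chem_table = sim.simulate_methylxanthine(326, positive_fraction=0.4, seed=rng)
chem_table.to_csv(OUT / "methylxanthines.tsv", sep="\t", index=False)
print(f"methylxanthines: 326 items, {int(chem_table.true_positive.sum())} true positives")

with open(OUT / "manifest.json", "w") as fh:
    json.dump(manifest, fh, indent=2)
print(f"wrote {OUT}/")
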