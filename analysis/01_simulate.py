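"""Generate the synthetic study inputs with planted truth.

Emulates the study design: one stably male-flowering target cultivar plus
14 predominantly female-producing pool cultivars, buds at two branch
positions, 50-bp single-end mRNA-Seq reads at 30x over a 20-transcript
reference carrying planted target-specific polymorphisms (two foreign
transcripts, one 38-bp insertion, one SNP), a 600-gene negative-binomial
count matrix with planted DE genes and three correlated modules, and
bisulfite amplicon reads at CG/CHG/CHH methylation probabilities
0.628/0.594/0.05.

Writes everything under results/data/.
"""

import json
from pathlib import Path

from kskpipe import pipeline, simulate
from kskpipe.io import write_fasta, write_fastq

SEED = 0
OUT = Path("results/data")
READS = Path("scratch/data")  # bulky raw reads stay out of results/


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    READS.mkdir(parents=True, exist_ok=True)
    cfg = pipeline.RunConfig(seed=SEED)
    sim = cfg.sim_config()

    transcriptome = simulate.generate_transcriptome(sim)
    variants = simulate.plant_default_variants(transcriptome, sim)
    write_fasta(sorted(transcriptome.items()), OUT / "transcriptome.fasta")
    (OUT / "planted_variants.json").write_text(simulate.variants_to_json(variants))
    write_fastq(
        simulate.generate_reads(transcriptome, sim, variants, True, "target"),
        READS / "reads_target.fastq",
    )
    for i in range(sim.n_pool_samples):
        label = f"pool{i + 1:02d}"
        write_fastq(
            simulate.generate_reads(transcriptome, sim, target=False, sample_label=label),
            READS / f"reads_{label}.fastq",
        )

    genes = [f"g{i + 1:04d}" for i in range(cfg.n_count_genes)]
    truth = simulate.default_count_truth(genes, seed=SEED)
    counts, meta, lengths = simulate.generate_counts(cfg.count_config(), truth, genes=genes)
    counts.to_csv(OUT / "counts.tsv", sep="\t")
    meta.to_csv(OUT / "samples.tsv", sep="\t", index=False)
    lengths.to_frame().to_csv(OUT / "gene_lengths.tsv", sep="\t")
    (OUT / "count_truth.json").write_text(simulate.count_truth_to_json(truth))

    amplicon = simulate.random_amplicon(cfg.amplicon_length, seed=SEED)
    bs_truth = simulate.BisulfiteSimTruth(
        "amplicon", amplicon, cfg.p_cg, cfg.p_chg, cfg.p_chh,
        cfg.conversion_efficiency, cfg.bs_depth_per_strand,
    )
    reads, _ = simulate.generate_bisulfite_reads(bs_truth, seed=SEED)
    write_fasta([("amplicon", amplicon)], OUT / "amplicon.fasta")
    write_fastq(reads, READS / "bisulfite_reads.fastq")
    (OUT / "bisulfite_truth.json").write_text(simulate.bisulfite_truth_to_json(bs_truth))

    (OUT / "config.json").write_text(
        json.dumps({"seed": SEED, "n_pool_samples": sim.n_pool_samples,
                    "read_length": sim.read_length, "depth": sim.depth}, indent=1)
    )
    print(f"simulated {len(transcriptome)} transcripts, {sim.n_pool_samples} pool cultivars,")
    print(f"{counts.shape[0]} x {counts.shape[1]} count matrix, {len(reads)} bisulfite reads")
    print(f"planted variants: {[v.variant_id for v in variants]}")


if __name__ == "__main__":
    main()
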