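"""Catalog anchored 35-mers, subtract the pool, assemble target-specific contigs.

The subtraction step asks a simple question: which 35-bp subsequences
(anchored at an 'A') occur in the target cultivar's reads but never — zero
counts — in the pooled reads of the 14 background cultivars? Reads carrying
such k-mers (KSK) are recruited and greedily assembled; contigs with fewer
than 10 distinct KSK are discarded as minor polymorphisms or noise; the
survivors are ranked in a report, flagging contigs with more than 80 KSK.

Reads results/data/, writes results/ksk/.
"""

from pathlib import Path

from kskpipe import assembly, kmers
from kskpipe.io import iter_reads, write_fasta

DATA = Path("results/data")
READS = Path("scratch/data")
OUT = Path("results/ksk")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    target_reads = list(iter_reads(READS / "reads_target.fastq"))
    target_cat = kmers.build_catalog(target_reads, sample_label="target")
    pool_cats = []
    for fq in sorted(READS.glob("reads_pool*.fastq")):
        pool_cats.append(
            kmers.build_catalog(iter_reads(fq), sample_label=fq.stem.replace("reads_", ""))
        )
    pooled = kmers.merge_catalogs(pool_cats)
    ksk = kmers.specific_kmers(target_cat, pooled)
    kmers.save_ksk(ksk, OUT / "ksk.txt")
    print(f"target catalog: {len(target_cat.counts)} distinct anchored 35-mers")
    print(f"pooled catalog: {len(pooled.counts)} distinct ({len(pool_cats)} cultivars)")
    print(f"target-specific k-mers (KSK): {len(ksk)}")

    recruited = assembly.recruit_reads(target_reads, ksk)
    contigs = assembly.remap_ksk(assembly.assemble(recruited), ksk)
    retained = assembly.filter_contigs(contigs, min_ksk=10)
    write_fasta([(c.contig_id, c.sequence) for c in retained], OUT / "contigs_retained.fasta")
    report = assembly.report_contigs(retained, highlight_threshold=80)
    report.to_csv(OUT / "contig_report.tsv", sep="\t", index=False)
    print(f"recruited {len(recruited)} reads -> {len(contigs)} contigs, "
          f"{len(retained)} retained at >= 10 KSK")
    print(report.to_string(index=False))


if __name__ == "__main__":
    main()
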