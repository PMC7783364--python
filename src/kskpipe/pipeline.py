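"""End-to-end orchestration: simulate -> catalog -> assemble -> profile.

A single :class:`RunConfig` carries every stage parameter with defaults
equal to the analysis parameters of the study design this package models
(k=35, anchor 'A', min KSK 10, RPKM > 1, bias > 2, FDR < 0.01, per-cultivar
alphas 0.1/0.05, signed beta 5, edge weight > 0.43, hubs > 50 connections,
minimum module size 30). A run writes every artefact as plain text with
fixed float formatting and records a JSON manifest of parameters, a
filter-chain survivor table and SHA-256 digests of every output, so a rerun
with the same config and seed reproduces identical digests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import assembly, expression, kmers, methylation, network, simulate
from .io import write_fasta, write_fastq

FLOAT_FMT = "%.6g"


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "results/run"
    # stage toggles
    run_kmer: bool = True
    run_expression: bool = True
    run_network: bool = True
    run_methylation: bool = True
    # read simulation
    n_transcripts: int = 20
    gene_length_range: tuple[int, int] = (500, 1500)
    read_length: int = 50
    depth: float = 30.0
    error_rate: float = 0.0
    n_pool_samples: int = 14
    n_positions: int = 2
    # cataloging / assembly
    k: int = 35
    anchor: str = "A"
    min_target_count: int = 1
    min_overlap: int = 25
    min_ksk: int = 10
    highlight_threshold: int = 80
    # expression
    n_count_genes: int = 600
    n_de_up: int = 30
    n_de_down: int = 30
    log2_effect: float = 3.0
    module_sizes: tuple[int, ...] = (60, 40, 40)
    module_eigen_correlation: float = 0.8
    nb_dispersion: float = 0.05
    biological_sigma: float = 0.3
    module_sigma: float = 1.0
    rpkm_min: float = 1.0
    bias_min: float = 2.0
    fdr: float = 0.01
    lenient_cultivars: tuple[str, ...] = ("pool01", "pool02")
    # network
    beta: float = 5.0
    weight_min: float = 0.43
    min_connections: int = 50
    min_module_size: int = 30
    cut_height: float = 0.8
    # methylation
    amplicon_length: int = 400
    p_cg: float = 0.628
    p_chg: float = 0.594
    p_chh: float = 0.05
    conversion_efficiency: float = 1.0
    bs_depth_per_strand: int = 500

    def sim_config(self) -> simulate.SimulationConfig:
        return simulate.SimulationConfig(
            seed=self.seed,
            n_pool_samples=self.n_pool_samples,
            n_positions=self.n_positions,
            n_genes=self.n_transcripts,
            gene_length_range=self.gene_length_range,
            read_length=self.read_length,
            depth=self.depth,
            error_rate=self.error_rate,
            kmer_k=self.k,
        )

    def count_config(self) -> simulate.SimulationConfig:
        cfg = self.sim_config()
        return dataclasses.replace(cfg, n_genes=self.n_count_genes)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def variant_novel_kmers(
    transcriptome: dict[str, str],
    variants: list[simulate.PlantedVariantTruth],
    k: int = 35,
    anchor: str = "A",
) -> dict[str, set[str]]:
    """Anchored k-mers diagnostic of each planted variant.

    A variant's novel k-mers are the anchored k-mers of its variant-applied
    sequence that occur nowhere in the reference transcript set — exactly
    the k-mers the subtraction stage can recover when pool reads are
    error-free draws from the reference.
    """
    ref_kmers: set[str] = set()
    for seq in transcriptome.values():
        ref_kmers.update(kmers.extract_anchored_kmers(seq, k, anchor))
    novel: dict[str, set[str]] = {}
    for v in variants:
        if v.kind == "foreign_transcript":
            applied = v.alt
        else:
            applied = simulate.apply_variants(transcriptome, [v])[v.host_gene]
        novel[v.variant_id] = (
            set(kmers.extract_anchored_kmers(applied, k, anchor)) - ref_kmers
        )
    return novel


@dataclass
class RunResult:
    config: RunConfig
    manifest: dict
    out_dir: Path
    # in-memory handles for downstream inspection
    transcriptome: dict[str, str] = field(default_factory=dict)
    variants: list = field(default_factory=list)
    ksk: kmers.KskSet | None = None
    contigs_retained: list = field(default_factory=list)
    counts: pd.DataFrame | None = None
    meta: pd.DataFrame | None = None
    gene_lengths: pd.Series | None = None
    count_truth: simulate.CountSimTruth | None = None
    deg1: expression.DegResult | None = None
    deg2: expression.DegResult | None = None
    net: network.CoexpressionNetwork | None = None
    modules: network.ModuleAssignment | None = None
    enrichment: list = field(default_factory=list)
    meth_levels: dict = field(default_factory=dict)
    meth_truth: simulate.BisulfiteSimTruth | None = None
    meth_compare_p: float | None = None


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the enabled stages in dependency order; write the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    survivors: dict[str, int | float] = {}
    result = RunResult(config=config, manifest={}, out_dir=out)

    # config echo normalises out_dir so digests are location-independent
    (out / "config.json").write_text(
        json.dumps(
            dataclasses.asdict(config) | {"out_dir": "."},
            indent=1,
            sort_keys=True,
            default=list,
        )
    )

    if config.run_kmer:
        sim = config.sim_config()
        transcriptome = simulate.generate_transcriptome(sim)
        variants = simulate.plant_default_variants(transcriptome, sim)
        result.transcriptome, result.variants = transcriptome, variants
        write_fasta(sorted(transcriptome.items()), out / "transcriptome.fasta")
        (out / "planted_variants.json").write_text(simulate.variants_to_json(variants))
        target_reads = simulate.generate_reads(
            transcriptome, sim, variants, target=True, sample_label="target"
        )
        write_fastq(target_reads, out / "reads_target.fastq")
        survivors["target_reads"] = len(target_reads)
        target_cat = kmers.build_catalog(
            target_reads, config.k, config.anchor, sample_label="target"
        )
        pool_cats = []
        n_pool_reads = 0
        for i in range(config.n_pool_samples):
            label = f"pool{i + 1:02d}"
            pool_reads = simulate.generate_reads(
                transcriptome, sim, target=False, sample_label=label
            )
            n_pool_reads += len(pool_reads)
            write_fastq(pool_reads, out / f"reads_{label}.fastq")
            pool_cats.append(
                kmers.build_catalog(pool_reads, config.k, config.anchor, sample_label=label)
            )
        pooled = kmers.merge_catalogs(pool_cats)
        survivors["pool_reads"] = n_pool_reads
        survivors["target_kmers"] = len(target_cat.counts)
        survivors["pool_kmers"] = len(pooled.counts)
        ksk = kmers.specific_kmers(target_cat, pooled, config.min_target_count)
        result.ksk = ksk
        kmers.save_ksk(ksk, out / "ksk.txt")
        survivors["ksk"] = len(ksk)
        if len(ksk) > 0:
            recruited = assembly.recruit_reads(target_reads, ksk)
            contigs = assembly.assemble(recruited, config.min_overlap)
            contigs = assembly.remap_ksk(contigs, ksk)
            retained = assembly.filter_contigs(contigs, config.min_ksk)
        else:  # nothing target-specific: empty chain, not an error
            recruited, contigs, retained = [], [], []
        survivors["recruited_reads"] = len(recruited)
        survivors["contigs"] = len(contigs)
        survivors["contigs_retained"] = len(retained)
        result.contigs_retained = retained
        write_fasta(
            [(c.contig_id, c.sequence) for c in retained], out / "contigs_retained.fasta"
        )
        _write_tsv(
            assembly.report_contigs(retained, config.highlight_threshold),
            out / "contig_report.tsv",
        )

    if config.run_expression or config.run_network:
        ccfg = config.count_config()
        genes = [f"g{i + 1:04d}" for i in range(config.n_count_genes)]
        count_truth = simulate.default_count_truth(
            genes,
            n_de_up=config.n_de_up,
            n_de_down=config.n_de_down,
            log2_effect=config.log2_effect,
            module_sizes=config.module_sizes,
            module_eigen_correlation=config.module_eigen_correlation,
            nb_dispersion=config.nb_dispersion,
            seed=config.seed,
        )
        counts, meta, lengths = simulate.generate_counts(
            ccfg,
            count_truth,
            genes=genes,
            biological_sigma=config.biological_sigma,
            module_sigma=config.module_sigma,
        )
        result.counts, result.meta, result.gene_lengths = counts, meta, lengths
        result.count_truth = count_truth
        _write_tsv(counts, out / "counts.tsv", index=True)
        _write_tsv(meta, out / "samples.tsv")
        _write_tsv(lengths.to_frame(), out / "gene_lengths.tsv", index=True)
        (out / "count_truth.json").write_text(simulate.count_truth_to_json(count_truth))

    if config.run_expression:
        rp = expression.rpkm(result.counts, result.gene_lengths)
        _write_tsv(rp, out / "rpkm.tsv", index=True)
        deg1 = expression.comparison_one(
            result.counts,
            result.gene_lengths,
            result.meta,
            fdr_threshold=config.fdr,
            rpkm_min=config.rpkm_min,
            bias_min=config.bias_min,
        )
        deg2, ptable, _ = expression.comparison_two(
            result.counts,
            result.gene_lengths,
            result.meta,
            rpkm_min=config.rpkm_min,
            lenient=config.lenient_cultivars,
        )
        result.deg1, result.deg2 = deg1, deg2
        _write_tsv(deg1.table, out / "deg_comparison1.tsv")
        _write_tsv(ptable, out / "deg_comparison2_pvalues.tsv", index=True)
        for name, genes_set in (
            ("deg1_up", deg1.up),
            ("deg1_down", deg1.down),
            ("deg2_up", deg2.up),
            ("deg2_down", deg2.down),
        ):
            (out / f"{name}.txt").write_text("".join(f"{g}\n" for g in sorted(genes_set)))
            survivors[name] = len(genes_set)

    if config.run_network:
        if not config.run_expression:
            raise RuntimeError(
                "network stage requires the expression stage (DEG sets for "
                "module enrichment): missing artifact 'deg_comparison1.tsv'"
            )
        rp = expression.rpkm(result.counts, result.gene_lengths)
        expr = np.log2(rp + 1.0)
        expr = expr[expr.var(axis=1) > 0]
        net = network.signed_adjacency(expr, beta=config.beta)
        result.net = net
        r2, mean_k = network.scale_free_fit(net)
        (out / "scale_free.json").write_text(
            json.dumps({"beta": config.beta, "r2": round(r2, 6), "mean_k": round(mean_k, 6)})
        )
        modules = network.detect_modules(
            net, min_module_size=config.min_module_size, cut_height=config.cut_height
        )
        result.modules = modules
        mod_tab = pd.DataFrame(
            {"gene": list(modules.assignments), "module": list(modules.assignments.values())}
        )
        _write_tsv(mod_tab, out / "modules.tsv")
        survivors["modules"] = modules.n_modules()
        edges = network.edge_list(net, weight_min=config.weight_min)
        _write_tsv(edges, out / "edges.tsv")
        survivors["edges"] = len(edges)
        hubs = network.hub_genes(edges, min_connections=config.min_connections)
        (out / "hubs.txt").write_text("".join(f"{g}\n" for g in hubs))
        survivors["hubs"] = len(hubs)
        if result.deg1 is not None:
            universe = set(result.counts.index)
            enr_rows = []
            result.enrichment = []
            for deg_name, deg_res in (("comparison1", result.deg1), ("comparison2", result.deg2)):
                deg_set = deg_res.up | deg_res.down
                for mid in sorted({m for m in modules.assignments.values() if m > 0}):
                    e = network.module_enrichment(
                        modules.module_genes(mid), deg_set, universe, module_id=mid
                    )
                    result.enrichment.append((deg_name, e))
                    enr_rows.append({"deg_set": deg_name} | dataclasses.asdict(e))
            _write_tsv(pd.DataFrame(enr_rows), out / "enrichment.tsv")

    if config.run_methylation:
        amplicon = simulate.random_amplicon(config.amplicon_length, seed=config.seed)
        truth = simulate.BisulfiteSimTruth(
            "amplicon",
            amplicon,
            config.p_cg,
            config.p_chg,
            config.p_chh,
            config.conversion_efficiency,
            config.bs_depth_per_strand,
        )
        result.meth_truth = truth
        write_fasta([("amplicon", amplicon)], out / "amplicon.fasta")
        reads_a, _ = simulate.generate_bisulfite_reads(truth, seed=config.seed)
        reads_b, _ = simulate.generate_bisulfite_reads(truth, seed=config.seed + 1)
        write_fastq(reads_a, out / "bisulfite_reads.fastq")
        ctx = methylation.classify_contexts(amplicon)
        asn_a, _ = methylation.align_bisulfite(reads_a, amplicon)
        asn_b, _ = methylation.align_bisulfite(reads_b, amplicon)
        prof_a = methylation.call_methylation(asn_a, amplicon, ctx)
        prof_b = methylation.call_methylation(asn_b, amplicon, ctx)
        levels = methylation.context_levels(prof_a)
        result.meth_levels = levels
        _write_tsv(methylation.profile_table(prof_a), out / "methylation_profile.tsv")
        (out / "methylation_levels.json").write_text(
            json.dumps({c: round(v, 4) for c, v in sorted(levels.items())})
        )
        _, agg_p = methylation.compare_patterns(prof_a, prof_b)
        result.meth_compare_p = agg_p
        (out / "methylation_compare.json").write_text(
            json.dumps({"aggregate_p": round(agg_p, 6), "test": "paired Wilcoxon on per-site fractions (declared convention)"})
        )

    digests = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "package": "kskpipe",
        "parameters": dataclasses.asdict(config) | {"out_dir": "."},
        "survivors": survivors,
        "outputs": digests,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True, default=list))
    result.manifest = manifest
    return result


def validate_against_truth(result: RunResult) -> dict:
    """Precision/recall of every stage against its planted truth."""
    report: dict = {}
    if result.contigs_retained or result.ksk is not None:
        novel = variant_novel_kmers(
            result.transcriptome, result.variants, result.config.k, result.config.anchor
        )
        classes: dict[str, dict[str, float]] = {}
        covered_contigs: set[str] = set()
        for kind in sorted({v.kind for v in result.variants}):
            kind_variants = [v for v in result.variants if v.kind == kind and v.expected_specific]
            if not kind_variants:
                continue
            hit = 0
            for v in kind_variants:
                vk = novel[v.variant_id]
                for c in result.contigs_retained:
                    windows = set(
                        kmers.extract_anchored_kmers(
                            c.sequence, result.config.k, result.config.anchor
                        )
                    )
                    if windows & vk:
                        hit += 1
                        covered_contigs.add(c.contig_id)
                        break
            classes[kind] = {"recall": hit / len(kind_variants), "n": len(kind_variants)}
        # precision: retained contigs covering >= 1 planted variant of any class
        n_cover = 0
        for c in result.contigs_retained:
            windows = set(
                kmers.extract_anchored_kmers(c.sequence, result.config.k, result.config.anchor)
            )
            if any(windows & novel[v.variant_id] for v in result.variants):
                n_cover += 1
        precision = n_cover / len(result.contigs_retained) if result.contigs_retained else 0.0
        report["variants"] = {"classes": classes, "contig_precision": precision}
    if result.deg1 is not None and result.count_truth is not None:
        truth_up = set(result.count_truth.de_genes_up)
        truth_down = set(result.count_truth.de_genes_down)
        for name, res in (("comparison1", result.deg1), ("comparison2", result.deg2)):
            if res is None:
                continue
            called = res.up | res.down
            truth_all = truth_up | truth_down
            tp = len((res.up & truth_up) | (res.down & truth_down))
            report[name] = {
                "recall": tp / len(truth_all) if truth_all else float("nan"),
                "precision": tp / len(called) if called else float("nan"),
                "n_called": len(called),
            }
    if result.modules is not None and result.count_truth is not None:
        genes = list(result.counts.index)
        truth_labels = [result.count_truth.module_assignments_true.get(g, 0) for g in genes]
        pred_labels = [result.modules.assignments.get(g, 0) for g in genes]
        module_genes = [i for i, t in enumerate(truth_labels) if t > 0]
        report["modules"] = {
            "adjusted_rand_all": float(adjusted_rand_score(truth_labels, pred_labels)),
            "adjusted_rand_module_genes": float(
                adjusted_rand_score(
                    [truth_labels[i] for i in module_genes],
                    [pred_labels[i] for i in module_genes],
                )
            ),
            "n_modules_found": result.modules.n_modules(),
        }
    if result.meth_truth is not None and result.meth_levels:
        planted = {"CG": result.meth_truth.p_cg, "CHG": result.meth_truth.p_chg, "CHH": result.meth_truth.p_chh}
        report["methylation"] = {
            ctx: {
                "planted_percent": 100.0 * planted[ctx],
                "estimated_percent": result.meth_levels.get(ctx),
            }
            for ctx in sorted(result.meth_levels)
        }
        report["methylation_compare_p"] = result.meth_compare_p
    return report
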