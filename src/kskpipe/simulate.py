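"""Synthetic data generators with planted, serialisable ground truth.

The generators emulate the study design every downstream stage expects:
one target cultivar plus a pool of predominantly female-producing cultivars
(14 by default), buds sampled at two branch positions, short single-end
reads (SR50), target-specific planted polymorphisms (SNPs, indels, foreign
transcripts), negative-binomial count matrices with planted differentially
expressed genes and correlated gene modules, and bisulfite amplicon reads
with per-context methylation probabilities.

All generators are pure functions of (config, seed): the same inputs give
byte-identical output files. Read sampling is uniform along transcripts with
a constant quality character; qualities are unused downstream.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import revcomp
from .methylation import classify_contexts

BASES = np.array(list("ACGT"))


def _rng_for(seed: int, label: str) -> np.random.Generator:
    """Independent, label-stable stream derived from the master seed."""
    return np.random.default_rng([seed, zlib.crc32(label.encode())])


@dataclass
class SimulationConfig:
    seed: int = 0
    n_pool_samples: int = 14
    n_positions: int = 2  # branch positions "#1" (medial) and "#2" (top)
    n_genes: int = 20
    gene_length_range: tuple[int, int] = (500, 2000)
    read_length: int = 50
    depth: float = 30.0  # mean per-base coverage per transcript per sample
    error_rate: float = 0.0
    kmer_k: int = 35  # downstream cataloging k; reads must be at least this long

    def __post_init__(self) -> None:
        lo, hi = self.gene_length_range
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if lo <= 0 or hi < lo:
            raise ValueError(f"invalid gene_length_range {self.gene_length_range}")
        if self.read_length < self.kmer_k:
            raise ValueError(
                f"read_length {self.read_length} shorter than cataloging k {self.kmer_k}"
            )
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        if self.n_pool_samples < 1 or self.n_positions < 1:
            raise ValueError("need at least one pool sample and one position")


@dataclass
class PlantedVariantTruth:
    """A polymorphism planted in the target cultivar only."""

    variant_id: str
    kind: str  # snp | insertion | deletion | foreign_transcript
    host_gene: str | None
    position: int  # 0-based on the host transcript; 0 for foreign transcripts
    alt: str  # substituted base, inserted sequence, or the full foreign sequence
    del_length: int = 0
    expected_specific: bool = True

    def __post_init__(self) -> None:
        if self.kind not in {"snp", "insertion", "deletion", "foreign_transcript"}:
            raise ValueError(f"unknown variant kind {self.kind!r}")


@dataclass
class CountSimTruth:
    """Planted truth for the expression and co-expression stages."""

    de_genes_up: dict[str, float] = field(default_factory=dict)  # gene -> log2 effect
    de_genes_down: dict[str, float] = field(default_factory=dict)
    module_assignments_true: dict[str, int] = field(default_factory=dict)  # 0 = none
    module_eigen_correlation: float = 0.8
    nb_dispersion: float = 0.05

    def __post_init__(self) -> None:
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if not 0.0 <= self.module_eigen_correlation <= 1.0:
            raise ValueError("module_eigen_correlation must be in [0, 1]")


@dataclass
class BisulfiteSimTruth:
    amplicon_id: str
    sequence: str
    p_cg: float
    p_chg: float
    p_chh: float
    conversion_efficiency: float = 1.0
    depth_per_strand: int = 500

    def __post_init__(self) -> None:
        for name in ("p_cg", "p_chg", "p_chh", "conversion_efficiency"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        present = {s.context for s in classify_contexts(self.sequence)}
        for ctx in ("CG", "CHG", "CHH"):
            if ctx not in present:
                raise ValueError(f"amplicon contains no cytosine in {ctx} context")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))


def generate_transcriptome(config: SimulationConfig) -> dict[str, str]:
    """Random reference transcript set; insertion order is the gene order."""
    rng = _rng_for(config.seed, "transcriptome")
    lo, hi = config.gene_length_range
    width = len(str(config.n_genes))
    transcripts = {}
    for i in range(config.n_genes):
        length = int(rng.integers(lo, hi + 1))
        transcripts[f"gene{i + 1:0{width}d}"] = _random_seq(rng, length)
    return transcripts


def plant_default_variants(
    transcriptome: dict[str, str],
    config: SimulationConfig,
    n_foreign: int = 2,
    foreign_length: int = 1000,
    insertion_length: int = 38,
    n_snp: int = 1,
) -> list[PlantedVariantTruth]:
    """Default planted truth: foreign transcripts, one structural insertion,
    and SNP noise variants (which yield too few specific k-mers to survive
    the contig filter, mimicking minor polymorphisms).

    Foreign transcripts are drawn as random trinucleotide strings, a
    composition distinct from the uniform-base reference, guaranteeing novel
    k-mers against it.
    """
    rng = _rng_for(config.seed, "variants")
    genes = sorted(transcriptome)
    variants: list[PlantedVariantTruth] = []
    codons = ["".join(c) for c in np.stack(np.meshgrid(BASES, BASES, BASES), -1).reshape(-1, 3)]
    for i in range(n_foreign):
        n_cod = foreign_length // 3
        seq = "".join(rng.choice(codons, size=n_cod))
        variants.append(
            PlantedVariantTruth(f"foreign{i + 1}", "foreign_transcript", None, 0, seq)
        )
    hosts = list(rng.choice(genes, size=1 + n_snp, replace=False))
    ins_host = hosts[0]
    ins_pos = int(rng.integers(100, len(transcriptome[ins_host]) - 100))
    variants.append(
        PlantedVariantTruth(
            "ins1", "insertion", ins_host, ins_pos, _random_seq(rng, insertion_length)
        )
    )
    for j, host in enumerate(hosts[1:]):
        pos = int(rng.integers(100, len(transcriptome[host]) - 100))
        ref_base = transcriptome[host][pos]
        alt = str(rng.choice([b for b in "ACGT" if b != ref_base]))
        variants.append(PlantedVariantTruth(f"snp{j + 1}", "snp", host, pos, alt))
    return variants


def apply_variants(
    transcriptome: dict[str, str], truth: list[PlantedVariantTruth]
) -> dict[str, str]:
    """Target-cultivar transcript set: host genes mutated, foreign added."""
    modified = dict(transcriptome)
    for v in truth:
        if v.kind == "foreign_transcript":
            modified[v.variant_id] = v.alt
            continue
        if v.host_gene not in modified:
            raise ValueError(f"variant {v.variant_id}: unknown host gene {v.host_gene}")
        seq = modified[v.host_gene]
        if not 0 <= v.position < len(seq):
            raise ValueError(f"variant {v.variant_id}: position outside transcript")
        if v.kind == "snp":
            seq = seq[: v.position] + v.alt + seq[v.position + 1 :]
        elif v.kind == "insertion":
            seq = seq[: v.position] + v.alt + seq[v.position :]
        elif v.kind == "deletion":
            if v.position + v.del_length > len(seq):
                raise ValueError(f"variant {v.variant_id}: deletion past transcript end")
            seq = seq[: v.position] + seq[v.position + v.del_length :]
        modified[v.host_gene] = seq
    return modified


def generate_reads(
    transcriptome: dict[str, str],
    config: SimulationConfig,
    truth: list[PlantedVariantTruth] | None = None,
    target: bool = False,
    sample_label: str = "sample",
) -> list[tuple[str, str]]:
    """Uniform single-end reads at the configured mean coverage.

    Target samples draw reads from the variant-applied transcript set; pool
    samples draw from the reference, so with ``error_rate=0`` no pool read can
    contain a planted target-specific sequence. The number of reads per
    transcript is ``round(depth * length / read_length)``.
    """
    source = apply_variants(transcriptome, truth or []) if target else dict(transcriptome)
    rng = _rng_for(config.seed, f"reads:{sample_label}")
    rl = config.read_length
    reads: list[tuple[str, str]] = []
    for gene in sorted(source):
        seq = source[gene]
        if len(seq) < rl:
            raise ValueError(f"transcript {gene} shorter than read length after variants")
        n_reads = max(1, round(config.depth * len(seq) / rl))
        starts = rng.integers(0, len(seq) - rl + 1, size=n_reads)
        for j, start in enumerate(starts):
            read = seq[start : start + rl]
            if config.error_rate > 0:
                arr = np.frombuffer(read.encode(), dtype=np.uint8).copy()
                hits = np.nonzero(rng.random(rl) < config.error_rate)[0]
                for h in hits:
                    choices = [b for b in b"ACGT" if b != arr[h]]
                    arr[h] = choices[rng.integers(0, 3)]
                read = arr.tobytes().decode()
            reads.append((f"{sample_label}:{gene}:{j}", read))
    return reads


def sample_sheet(config: SimulationConfig) -> pd.DataFrame:
    """Metadata for the (1 + n_pool) cultivars x n_positions design."""
    rows = []
    cultivars = ["target"] + [f"pool{i + 1:02d}" for i in range(config.n_pool_samples)]
    for cv in cultivars:
        for p in range(config.n_positions):
            rows.append(
                {
                    "sample": f"{cv}_#{p + 1}",
                    "cultivar": cv,
                    "position": f"#{p + 1}",
                    "group": "target" if cv == "target" else "pool",
                }
            )
    return pd.DataFrame(rows)


def default_count_truth(
    genes: list[str],
    n_de_up: int = 30,
    n_de_down: int = 30,
    log2_effect: float = 3.0,
    module_sizes: tuple[int, ...] = (60, 40, 40),
    module_eigen_correlation: float = 0.8,
    nb_dispersion: float = 0.05,
    seed: int = 0,
) -> CountSimTruth:
    """Planted DE genes and correlated modules over a gene list.

    Module 1 is the largest by default, and up-regulated DE genes are drawn
    from it preferentially so the enrichment and hub stages have signal;
    remaining genes are unassigned background.
    """
    rng = _rng_for(seed, "count-truth")
    if sum(module_sizes) + n_de_up + n_de_down > len(genes):
        raise ValueError("not enough genes for the requested modules and DE sets")
    order = list(rng.permutation(genes))
    modules: dict[str, int] = {}
    idx = 0
    for m, size in enumerate(module_sizes, start=1):
        for g in order[idx : idx + size]:
            modules[g] = m
        idx += size
    # Half of the up-regulated genes sit inside module 1 (the target-induced
    # program, giving the enrichment stage real overlap); the other half and
    # all down-regulated genes are quiet background genes, where a per-gene
    # test has power.
    module1 = [g for g, m in modules.items() if m == 1]
    background = [g for g in order if modules.get(g, 0) == 0]
    up = {g: log2_effect for g in module1[: min(n_de_up // 2, len(module1))]}
    for g in background[: n_de_up - len(up)]:
        up[g] = log2_effect
    down = {g: log2_effect for g in background[len(up) : len(up) + n_de_down] if g not in up}
    return CountSimTruth(up, down, modules, module_eigen_correlation, nb_dispersion)


def generate_counts(
    config: SimulationConfig,
    truth: CountSimTruth,
    genes: list[str] | None = None,
    gene_lengths: dict[str, int] | None = None,
    base_mean: float = 50.0,
    position_effect_sd: float = 0.0,
    biological_sigma: float = 0.3,
    module_sigma: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Negative-binomial count matrix for the full cultivar x position design.

    Background genes vary idiosyncratically with log-sd ``biological_sigma``
    around a shared mean. Genes of module m follow a strong shared latent
    program: their log mean is
    ``log mu_g + de_shift(g, s) + module_sigma * (sqrt(rho) z_m[s] + sqrt(1-rho) e_gs)``
    with rho = module_eigen_correlation, so module genes correlate at about
    rho on the log scale. Counts are NB with variance ``mu + dispersion *
    mu^2``. DE shifts apply to target samples only.

    Returns (counts genes x samples, sample sheet, gene lengths in bp).
    """
    if genes is None:
        genes = [f"g{i + 1:04d}" for i in range(config.n_genes)]
    unknown = (set(truth.de_genes_up) | set(truth.de_genes_down)) - set(genes)
    if unknown:
        raise ValueError(f"effect size given for unknown gene(s): {sorted(unknown)[:3]}")
    unknown_m = set(truth.module_assignments_true) - set(genes)
    if unknown_m:
        raise ValueError(f"module assignment for unknown gene(s): {sorted(unknown_m)[:3]}")
    meta = sample_sheet(config)
    samples = list(meta["sample"])
    rng = _rng_for(config.seed, "counts")
    n_g, n_s = len(genes), len(samples)
    if gene_lengths is None:
        lengths = pd.Series(
            rng.integers(*config.gene_length_range, size=n_g), index=genes, name="length"
        )
    else:
        lengths = pd.Series({g: gene_lengths[g] for g in genes}, name="length")
    mu_g = rng.lognormal(mean=np.log(base_mean), sigma=1.0, size=n_g)
    module_ids = sorted({m for m in truth.module_assignments_true.values() if m > 0})
    z = {m: rng.normal(size=n_s) for m in module_ids}
    rho = truth.module_eigen_correlation
    is_target = (meta["group"] == "target").to_numpy()
    pos_shift = (
        rng.normal(scale=position_effect_sd, size=n_s) if position_effect_sd > 0 else np.zeros(n_s)
    )
    log_mu = np.empty((n_g, n_s))
    for i, g in enumerate(genes):
        m = truth.module_assignments_true.get(g, 0)
        noise = rng.normal(size=n_s)
        if m > 0:
            wobble = module_sigma * (np.sqrt(rho) * z[m] + np.sqrt(1.0 - rho) * noise)
        else:
            wobble = biological_sigma * noise
        log_mu[i] = np.log(mu_g[i]) + wobble + pos_shift
        if g in truth.de_genes_up:
            log_mu[i, is_target] += np.log(2.0) * truth.de_genes_up[g]
        elif g in truth.de_genes_down:
            log_mu[i, is_target] -= np.log(2.0) * truth.de_genes_down[g]
    mu = np.exp(log_mu)
    r = 1.0 / truth.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    return pd.DataFrame(counts, index=genes, columns=samples), meta, lengths


def random_amplicon(length: int = 400, seed: int = 0, amplicon_id: str = "amplicon") -> str:
    """Random amplicon guaranteed to carry all three cytosine contexts."""
    rng = _rng_for(seed, f"amplicon:{amplicon_id}")
    while True:
        seq = _random_seq(rng, length)
        present = {s.context for s in classify_contexts(seq)}
        if {"CG", "CHG", "CHH"} <= present:
            return seq


def generate_bisulfite_reads(
    truth: BisulfiteSimTruth, seed: int
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Full-length bisulfite amplicon reads for both strands.

    Per read, each cytosine (on the read's own strand) is methylated with the
    context probability and then survives as C; unmethylated cytosines are
    converted to T with probability ``conversion_efficiency``. Bottom-strand
    reads are emitted in bottom-strand orientation, so relative to the
    reference they carry G->A conversions. Returns the reads and a truth
    table of (read_id, strand).
    """
    rng = _rng_for(seed, f"bisulfite:{truth.amplicon_id}")
    ref = truth.sequence.upper()
    p_by_ctx = {"CG": truth.p_cg, "CHG": truth.p_chg, "CHH": truth.p_chh}
    sites = classify_contexts(ref)
    plus_sites = [(s.position, p_by_ctx[s.context]) for s in sites if s.strand == "+" and s.context != "NA"]
    minus_sites = [(s.position, p_by_ctx[s.context]) for s in sites if s.strand == "-" and s.context != "NA"]
    # NA-context cytosines at the ends are still subject to conversion; treat
    # them as unmethylated (they are excluded from level summaries anyway).
    plus_na = [s.position for s in sites if s.strand == "+" and s.context == "NA"]
    minus_na = [s.position for s in sites if s.strand == "-" and s.context == "NA"]
    reads: list[tuple[str, str]] = []
    rows = []
    for i in range(truth.depth_per_strand):
        arr = list(ref)
        for pos, p in plus_sites:
            if rng.random() >= p and rng.random() < truth.conversion_efficiency:
                arr[pos] = "T"
        for pos in plus_na:
            if rng.random() < truth.conversion_efficiency:
                arr[pos] = "T"
        rid = f"{truth.amplicon_id}:plus:{i}"
        reads.append((rid, "".join(arr)))
        rows.append({"read_id": rid, "strand": "+", "offset": 0})
    for i in range(truth.depth_per_strand):
        arr = list(ref)
        for pos, p in minus_sites:
            if rng.random() >= p and rng.random() < truth.conversion_efficiency:
                arr[pos] = "A"  # bottom-strand C->T appears as G->A on the top strand
        for pos in minus_na:
            if rng.random() < truth.conversion_efficiency:
                arr[pos] = "A"
        rid = f"{truth.amplicon_id}:minus:{i}"
        reads.append((rid, revcomp("".join(arr))))
        rows.append({"read_id": rid, "strand": "-", "offset": 0})
    return reads, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# truth (de)serialisation — JSON round-trips


def variants_to_json(truth: list[PlantedVariantTruth]) -> str:
    return json.dumps([dataclasses.asdict(v) for v in truth], indent=1, sort_keys=True)


def variants_from_json(text: str) -> list[PlantedVariantTruth]:
    return [PlantedVariantTruth(**d) for d in json.loads(text)]


def count_truth_to_json(truth: CountSimTruth) -> str:
    return json.dumps(dataclasses.asdict(truth), indent=1, sort_keys=True)


def count_truth_from_json(text: str) -> CountSimTruth:
    return CountSimTruth(**json.loads(text))


def bisulfite_truth_to_json(truth: BisulfiteSimTruth) -> str:
    return json.dumps(dataclasses.asdict(truth), indent=1, sort_keys=True)


def bisulfite_truth_from_json(text: str) -> BisulfiteSimTruth:
    return BisulfiteSimTruth(**json.loads(text))
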