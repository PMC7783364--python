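"""Read counting, RPKM normalisation and the two DEG-selection procedures.

Comparison I contrasts the target cultivar against the pooled background
cultivars as two groups, then filters on FDR (Benjamini-Hochberg), group
RPKM and fold bias. Comparison II runs one position-paired contrast of the
target against each background cultivar separately and intersects: a gene is
called only if it is significant, in the same direction, in every one of the
cultivar-wise comparisons (raw per-cultivar p thresholds, by design two
lenient cultivars at alpha=0.1 and the rest at 0.05), and passes the RPKM
floor.

The per-gene test engines are simple, well-defined stand-ins — a
pooled-variance Student t on log2(RPKM+1) for the group contrast, and an
exact conditional binomial (gene count versus library-size ratio) for the
paired contrast. The contract of this module is the filtering and
intersection logic, not the numerics of any particular DE package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_LENIENT_ALPHA = 0.1
DEFAULT_ALPHA = 0.05


@dataclass
class DegResult:
    comparison_id: str
    table: pd.DataFrame  # per-gene statistics
    up: set[str] = field(default_factory=set)
    down: set[str] = field(default_factory=set)


# ---------------------------------------------------------------------------
# counting


def count_reads_exact(
    reads_by_sample: dict[str, list[tuple[str, str]]], transcriptome: dict[str, str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count reads by unique exact match against the transcript set.

    A naive counter for error-free synthetic reads: each read is assigned to
    the single transcript containing it as an exact substring; reads matching
    zero or more than one transcript are discarded and tallied in the log.
    All reads must share one length.
    """
    lengths = {len(seq) for reads in reads_by_sample.values() for _, seq in reads}
    if len(lengths) != 1:
        raise ValueError("exact matcher requires uniform read length")
    (read_len,) = lengths
    index: dict[str, str | None] = {}
    for gene, seq in transcriptome.items():
        for p in range(len(seq) - read_len + 1):
            window = seq[p : p + read_len]
            prev = index.get(window)
            if prev is None:
                index[window] = gene
            elif prev != gene:
                index[window] = "*"  # ambiguous across genes
    genes = sorted(transcriptome)
    counts = pd.DataFrame(0, index=genes, columns=sorted(reads_by_sample))
    log_rows = []
    for sample, reads in reads_by_sample.items():
        unmapped = ambiguous = 0
        for _, seq in reads:
            hit = index.get(seq)
            if hit is None:
                unmapped += 1
            elif hit == "*":
                ambiguous += 1
            else:
                counts.loc[hit, sample] += 1
        log_rows.append({"sample": sample, "unmapped": unmapped, "ambiguous": ambiguous})
    return counts, pd.DataFrame(log_rows)


def count_reads_sam(
    sam_paths: dict[str, str], transcriptome: dict[str, str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count primary mapped alignments per reference transcript from SAM."""
    genes = sorted(transcriptome)
    counts = pd.DataFrame(0, index=genes, columns=sorted(sam_paths))
    log_rows = []
    for sample, path in sam_paths.items():
        with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
            refs = set(sam.references)
            missing = refs - set(transcriptome)
            if missing:
                raise ValueError(
                    f"SAM references absent from transcriptome: {sorted(missing)[:3]}"
                )
            unmapped = 0
            for rec in sam:
                if rec.is_unmapped:
                    unmapped += 1
                    continue
                if rec.is_secondary or rec.is_supplementary:
                    continue
                counts.loc[rec.reference_name, sample] += 1
        log_rows.append({"sample": sample, "unmapped": unmapped, "ambiguous": 0})
    return counts, pd.DataFrame(log_rows)


# ---------------------------------------------------------------------------
# normalisation and filters


def rpkm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Reads per kilobase of transcript per million counted reads.

    rpkm[g, s] = count[g, s] * 1e9 / (length_bp[g] * library_size[s]).
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every gene needs a positive length")
    libs = counts.sum(axis=0)
    if (libs <= 0).any():
        bad = list(libs.index[libs <= 0])
        raise ValueError(f"zero library size for sample(s) {bad}")
    return counts.mul(1e9, axis=0).div(lengths, axis=0).div(libs, axis=1)


def bias(mean_a: float, mean_b: float, pseudocount: float = 0.1) -> float:
    """Fold ratio between two group means, larger over smaller.

    The pseudocount keeps the ratio finite when one mean is zero.
    """
    hi, lo = max(mean_a, mean_b), min(mean_a, mean_b)
    return (hi + pseudocount) / (lo + pseudocount)


# ---------------------------------------------------------------------------
# comparison I: pooled group contrast


def comparison_one(
    counts: pd.DataFrame,
    lengths: pd.Series,
    meta: pd.DataFrame,
    fdr_threshold: float = 0.01,
    rpkm_min: float = 1.0,
    bias_min: float = 2.0,
    pseudocount: float = 0.1,
) -> DegResult:
    """Target-vs-pool group DEG call with FDR, RPKM and bias filters.

    Pooled-variance Student t on log2(RPKM+1) per gene (the small target
    group leaves a Welch test with ~1 degree of freedom and no power, so the
    stand-in borrows the pooled degrees of freedom instead), then
    Benjamini-Hochberg over all tested genes; a gene passes if FDR <=
    threshold, the larger group-mean RPKM exceeds ``rpkm_min`` and the bias
    (larger/smaller group mean, with pseudocount) exceeds ``bias_min``;
    strict inequalities on RPKM and bias.
    """
    tgt = meta.loc[meta["group"] == "target", "sample"].tolist()
    pool = meta.loc[meta["group"] == "pool", "sample"].tolist()
    if len(tgt) < 2 or len(pool) < 2:
        raise ValueError("need >= 2 samples in each group")
    expr = np.log2(rpkm(counts, lengths) + 1.0)
    a = expr[tgt].to_numpy()
    b = expr[pool].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat, pvals = stats.ttest_ind(a, b, axis=1, equal_var=True)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
    rp = rpkm(counts, lengths)
    mean_t = rp[tgt].mean(axis=1)
    mean_p = rp[pool].mean(axis=1)
    biases = np.array([bias(x, y, pseudocount) for x, y in zip(mean_t, mean_p)])
    table = pd.DataFrame(
        {
            "gene": counts.index,
            "p": pvals,
            "fdr": fdr,
            "mean_rpkm_target": mean_t.to_numpy(),
            "mean_rpkm_pool": mean_p.to_numpy(),
            "bias": biases,
            "direction": np.where(mean_t.to_numpy() >= mean_p.to_numpy(), "up", "down"),
        }
    )
    passing = (
        (table["fdr"] <= fdr_threshold)
        & (np.maximum(table["mean_rpkm_target"], table["mean_rpkm_pool"]) > rpkm_min)
        & (table["bias"] > bias_min)
    )
    up = set(table.loc[passing & (table["direction"] == "up"), "gene"])
    down = set(table.loc[passing & (table["direction"] == "down"), "gene"])
    return DegResult("comparison_I", table, up, down)


# ---------------------------------------------------------------------------
# comparison II: paired per-cultivar contrasts intersected over all cultivars


def default_alphas(cultivars: list[str], lenient: tuple[str, ...] = ()) -> dict[str, float]:
    """Per-cultivar raw p thresholds: 0.1 for the designated lenient
    cultivars, 0.05 for the rest."""
    return {c: (DEFAULT_LENIENT_ALPHA if c in lenient else DEFAULT_ALPHA) for c in cultivars}


def _binom_two_sided(x: np.ndarray, n: np.ndarray, p0: float) -> np.ndarray:
    """Two-sided exact binomial p as twice the smaller tail, capped at 1."""
    lower = stats.binom.cdf(x, n, p0)
    upper = stats.binom.sf(x - 1, n, p0)
    p = 2.0 * np.minimum(lower, upper)
    return np.clip(np.where(n > 0, p, 1.0), 0.0, 1.0)


def comparison_two(
    counts: pd.DataFrame,
    lengths: pd.Series,
    meta: pd.DataFrame,
    alphas: dict[str, float] | None = None,
    rpkm_min: float = 1.0,
    lenient: tuple[str, ...] = (),
) -> tuple[DegResult, pd.DataFrame, pd.DataFrame]:
    """Intersection of position-paired target-vs-cultivar DEG calls.

    For each background cultivar, matched-position counts of target and
    cultivar are pooled and compared by an exact conditional binomial: under
    the null the target's share of a gene's reads follows its share of the
    combined library. A gene is returned only if it is significant at the
    cultivar's alpha with the same direction in all comparisons and the
    larger group-mean RPKM exceeds ``rpkm_min``.

    Returns the intersected result, the per-cultivar p-value table and the
    per-cultivar direction table (+1 up in target, -1 down).
    """
    meta = meta.set_index("sample")
    tgt_samples = meta.index[meta["group"] == "target"].tolist()
    cultivars = sorted(meta.loc[meta["group"] == "pool", "cultivar"].unique())
    if not tgt_samples or not cultivars:
        raise ValueError("need a target cultivar and >= 1 pool cultivar")
    if alphas is None:
        alphas = default_alphas(cultivars, lenient)
    missing_alpha = [c for c in cultivars if c not in alphas]
    if missing_alpha:
        raise ValueError(f"no alpha for cultivar(s) {missing_alpha}")
    tgt_positions = set(meta.loc[tgt_samples, "position"])
    rp = rpkm(counts, lengths)
    libs = counts.sum(axis=0)
    genes = counts.index
    per_cv_p: dict[str, np.ndarray] = {}
    per_cv_dir: dict[str, np.ndarray] = {}
    sig_all = np.ones(len(genes), dtype=bool)
    same_dir = None
    for cv in cultivars:
        cv_samples = meta.index[(meta["cultivar"] == cv)].tolist()
        cv_positions = set(meta.loc[cv_samples, "position"])
        if cv_positions != tgt_positions:
            raise ValueError(f"cultivar {cv} lacks matched branch positions")
        x = counts[tgt_samples].sum(axis=1).to_numpy()
        y = counts[cv_samples].sum(axis=1).to_numpy()
        n_t = libs[tgt_samples].sum()
        n_c = libs[cv_samples].sum()
        p0 = n_t / (n_t + n_c)
        pvals = _binom_two_sided(x, x + y, p0)
        # direction: target rate vs cultivar rate
        direction = np.where(x / n_t >= y / n_c, 1, -1)
        per_cv_p[cv] = pvals
        per_cv_dir[cv] = direction
        sig_all &= pvals < alphas[cv]
        same_dir = direction if same_dir is None else np.where(same_dir == direction, same_dir, 0)
    mean_t = rp[tgt_samples].mean(axis=1).to_numpy()
    pool_samples = meta.index[meta["group"] == "pool"].tolist()
    mean_p = rp[pool_samples].mean(axis=1).to_numpy()
    rpkm_ok = np.maximum(mean_t, mean_p) > rpkm_min
    keep = sig_all & (same_dir != 0) & rpkm_ok
    up = set(genes[keep & (same_dir == 1)])
    down = set(genes[keep & (same_dir == -1)])
    ptable = pd.DataFrame(per_cv_p, index=genes)
    dirtable = pd.DataFrame(per_cv_dir, index=genes)
    table = pd.DataFrame(
        {
            "gene": genes,
            "n_significant": sum((per_cv_p[cv] < alphas[cv]) for cv in cultivars),
            "direction_consistent": same_dir != 0,
            "mean_rpkm_target": mean_t,
            "mean_rpkm_pool": mean_p,
        }
    )
    return DegResult("comparison_II", table, up, down), ptable, dirtable
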