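"""Bisulfite amplicon methylation profiling.

Bisulfite treatment deaminates unmethylated cytosine to uracil (sequenced as
T) while 5-methylcytosine stays C. Given amplicon reads and the amplicon
reference, this module classifies every cytosine by its sequence context
(CG, CHG, CHH with H in {A, C, T}), matches each read ungapped to the
reference in a conversion-aware way (C->T collapsed for top-strand reads,
G->A for bottom-strand reads), tallies methylated/unmethylated calls per
cytosine, summarises per-context methylation levels, and compares two
profiles site by site.

Alignment is deliberately ungapped: amplicon sequencing targets a known short
region, so reads failing a 90% collapsed identity are dropped rather than
clipped or gap-aligned.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import revcomp

CONTEXTS = ("CG", "CHG", "CHH")

_NON_ACGT = re.compile(r"[^ACGT]")


@dataclass
class SiteContext:
    position: int  # 0-based on the + strand of the reference
    strand: str  # '+' (reference C) or '-' (reference G, C on the bottom strand)
    context: str  # CG, CHG, CHH, or NA when truncated by the amplicon end


@dataclass
class MethylationProfile:
    """Per-cytosine methylated/unmethylated read counts for one amplicon."""

    amplicon_id: str
    records: pd.DataFrame  # columns: position, strand, context, methylated, unmethylated
    discarded_reads: list[str] = field(default_factory=list)

    def coverage(self) -> pd.Series:
        return self.records["methylated"] + self.records["unmethylated"]


def classify_contexts(reference: str) -> list[SiteContext]:
    """Classify every cytosine on both strands of ``reference``.

    Positions whose context is truncated by the amplicon end (fewer than two
    downstream bases on the cytosine's own strand, unless the immediate next
    base already makes it CG) are reported with context ``"NA"`` and are
    excluded from level summaries.
    """
    reference = reference.upper()
    if _NON_ACGT.search(reference):
        raise ValueError("reference contains non-ACGT symbols")
    n = len(reference)
    sites: list[SiteContext] = []
    for i, base in enumerate(reference):
        if base == "C":
            if i + 1 < n and reference[i + 1] == "G":
                ctx = "CG"
            elif i + 2 < n:
                ctx = "CHG" if reference[i + 2] == "G" else "CHH"
            else:
                ctx = "NA"
            sites.append(SiteContext(i, "+", ctx))
        elif base == "G":
            # C on the bottom strand; downstream on that strand is leftwards.
            if i - 1 >= 0 and reference[i - 1] == "C":
                ctx = "CG"
            elif i - 2 >= 0:
                ctx = "CHG" if reference[i - 2] == "C" else "CHH"
            else:
                ctx = "NA"
            sites.append(SiteContext(i, "-", ctx))
    return sites


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _best_offset(read_collapsed: np.ndarray, ref_collapsed: np.ndarray) -> tuple[int, int]:
    """Return (offset, mismatches) of the best ungapped placement."""
    m, n = len(read_collapsed), len(ref_collapsed)
    best_off, best_mm = 0, m + 1
    for off in range(n - m + 1):
        mm = int(np.count_nonzero(ref_collapsed[off : off + m] != read_collapsed))
        if mm < best_mm:
            best_off, best_mm = off, mm
            if mm == 0:
                break
    return best_off, best_mm


@dataclass
class ReadAssignment:
    read_id: str
    offset: int
    strand: str
    oriented_seq: str  # read in reference (+) orientation
    mismatches: int


def align_bisulfite(
    reads: list[tuple[str, str]], reference: str, min_identity: float = 0.9
) -> tuple[list[ReadAssignment], list[str]]:
    """Match reads ungapped to an amplicon reference, conversion-aware.

    Top-strand placement scores mismatches after C->T collapsing of both read
    and reference; bottom-strand placement reverse-complements the read and
    scores after G->A collapsing. The better strand wins; reads below
    ``min_identity`` collapsed identity are discarded and returned separately.
    """
    reference = reference.upper()
    ref_ct = _encode(reference.replace("C", "T"))
    ref_ga = _encode(reference.replace("G", "A"))
    assignments: list[ReadAssignment] = []
    discarded: list[str] = []
    for read_id, seq in reads:
        seq = seq.upper()
        if len(seq) > len(reference):
            raise ValueError(f"reference shorter than read {read_id!r}")
        fwd = seq
        rev = revcomp(seq)
        off_f, mm_f = _best_offset(_encode(fwd.replace("C", "T")), ref_ct)
        off_r, mm_r = _best_offset(_encode(rev.replace("G", "A")), ref_ga)
        if mm_f <= mm_r:
            off, mm, strand, oriented = off_f, mm_f, "+", fwd
        else:
            off, mm, strand, oriented = off_r, mm_r, "-", rev
        if 1.0 - mm / len(seq) < min_identity:
            discarded.append(read_id)
        else:
            assignments.append(ReadAssignment(read_id, off, strand, oriented, mm))
    return assignments, discarded


def call_methylation(
    assignments: list[ReadAssignment],
    reference: str,
    context_map: list[SiteContext] | None = None,
    amplicon_id: str = "amplicon",
) -> MethylationProfile:
    """Tally methylated/unmethylated calls at each strand-matched cytosine.

    At a + strand site (reference C), a C in a top-strand read counts as
    methylated and a T as unmethylated; bottom-strand sites (reference G) use
    G/A symmetrically. Any other base is ignored.
    """
    reference = reference.upper()
    if context_map is None:
        context_map = classify_contexts(reference)
    meth = {(s.position, s.strand): 0 for s in context_map}
    unmeth = {(s.position, s.strand): 0 for s in context_map}
    ctx = {(s.position, s.strand): s.context for s in context_map}
    for asn in assignments:
        lo, hi = asn.offset, asn.offset + len(asn.oriented_seq)
        for (pos, strand), _ in ctx.items():
            if strand != asn.strand or not (lo <= pos < hi):
                continue
            base = asn.oriented_seq[pos - lo]
            if strand == "+":
                if base == "C":
                    meth[(pos, strand)] += 1
                elif base == "T":
                    unmeth[(pos, strand)] += 1
            else:
                if base == "G":
                    meth[(pos, strand)] += 1
                elif base == "A":
                    unmeth[(pos, strand)] += 1
    records = pd.DataFrame(
        {
            "position": [p for p, _ in ctx],
            "strand": [s for _, s in ctx],
            "context": [ctx[k] for k in ctx],
            "methylated": [meth[k] for k in ctx],
            "unmethylated": [unmeth[k] for k in ctx],
        }
    ).sort_values(["position", "strand"], ignore_index=True)
    return MethylationProfile(amplicon_id, records)


def context_levels(profile: MethylationProfile) -> dict[str, float]:
    """Percent methylation per context, pooling counts over sites.

    Contexts with zero coverage are omitted (missing, not zero); ``"NA"``
    sites near the amplicon end never contribute.
    """
    if profile.records.empty:
        raise ValueError("empty methylation profile")
    levels: dict[str, float] = {}
    for context in CONTEXTS:
        sub = profile.records[profile.records["context"] == context]
        m = int(sub["methylated"].sum())
        u = int(sub["unmethylated"].sum())
        if m + u > 0:
            levels[context] = 100.0 * m / (m + u)
    return levels


def compare_patterns(
    profile_a: MethylationProfile, profile_b: MethylationProfile, min_shared: int = 5
) -> tuple[pd.DataFrame, float]:
    """Site-by-site and aggregate comparison of two methylation profiles.

    Per shared covered site a two-sided Fisher exact test on the 2x2
    methylated/unmethylated table; the aggregate statistic is a paired
    Wilcoxon signed-rank on per-site methylation fractions (a declared
    convention — the choice of aggregate test is a design decision of this
    package). Identical profiles, where every per-site difference is zero,
    return aggregate p = 1.0 by convention.
    """
    a = profile_a.records.set_index(["position", "strand"])
    b = profile_b.records.set_index(["position", "strand"])
    shared = [
        k
        for k in a.index.intersection(b.index)
        if a.loc[k, "methylated"] + a.loc[k, "unmethylated"] > 0
        and b.loc[k, "methylated"] + b.loc[k, "unmethylated"] > 0
    ]
    if len(shared) < min_shared:
        raise ValueError(f"fewer than {min_shared} shared covered sites")
    rows = []
    fracs_a, fracs_b = [], []
    for pos, strand in shared:
        ma, ua = int(a.loc[(pos, strand), "methylated"]), int(a.loc[(pos, strand), "unmethylated"])
        mb, ub = int(b.loc[(pos, strand), "methylated"]), int(b.loc[(pos, strand), "unmethylated"])
        _, p = stats.fisher_exact([[ma, ua], [mb, ub]])
        fa, fb = ma / (ma + ua), mb / (mb + ub)
        fracs_a.append(fa)
        fracs_b.append(fb)
        rows.append(
            {
                "position": pos,
                "strand": strand,
                "context": a.loc[(pos, strand), "context"],
                "fraction_a": fa,
                "fraction_b": fb,
                "p_site": p,
            }
        )
    diffs = np.asarray(fracs_a) - np.asarray(fracs_b)
    if np.allclose(diffs, 0.0):
        aggregate_p = 1.0
    else:
        aggregate_p = float(stats.wilcoxon(fracs_a, fracs_b).pvalue)
    return pd.DataFrame(rows), aggregate_p


def profile_table(profile: MethylationProfile) -> pd.DataFrame:
    """Per-site TSV-ready table with methylation fractions."""
    tab = profile.records.copy()
    cov = tab["methylated"] + tab["unmethylated"]
    tab["fraction"] = np.where(cov > 0, tab["methylated"] / cov.replace(0, 1), np.nan)
    return tab
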