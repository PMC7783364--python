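"""Anchored k-mer cataloging and target-specific subtraction.

A catalog holds the counts of every fixed-length subsequence that starts
with a designated anchor nucleotide ('A', k=35 by default), scanned along
reads exactly as sequenced — no reverse-complement canonicalisation unless
requested, since the specificity logic depends on the stranded scan
semantics. Subtracting a pooled background catalog from the target catalog
yields the target-specific k-mer set (KSK): k-mers seen in the target and
with strictly zero counts in the pool.

Windows containing any non-ACGT symbol are dropped rather than expanded;
ambiguity codes would fabricate specificity. Counting is in-memory and
intended for desk scale (up to ~1e8 k-mers); no disk-backed counting.
"""

from __future__ import annotations

import gzip
import json
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .io import revcomp

DEFAULT_K = 35
DEFAULT_ANCHOR = "A"

_NON_ACGT = re.compile(r"[^ACGT]")


@dataclass
class KmerCatalog:
    k: int = DEFAULT_K
    anchor: str = DEFAULT_ANCHOR
    counts: Counter = field(default_factory=Counter)
    sample_label: str = ""

    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class KskSet:
    """Target-specific anchored k-mers with their extraction provenance."""

    kmers: frozenset
    k: int
    anchor: str
    min_target_count: int
    target_label: str
    pool_labels: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.kmers)


def extract_anchored_kmers(
    sequence: str, k: int = DEFAULT_K, anchor: str = DEFAULT_ANCHOR
) -> list[str]:
    """All k-windows starting with ``anchor``, in position order.

    Duplicates are preserved; windows containing non-ACGT symbols are
    skipped. Reads shorter than k yield an empty list.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(anchor) != 1:
        raise ValueError("anchor must be a single nucleotide")
    sequence = sequence.upper()
    out: list[str] = []
    limit = len(sequence) - k
    i = sequence.find(anchor)
    while 0 <= i <= limit:
        window = sequence[i : i + k]
        if not _NON_ACGT.search(window):
            out.append(window)
        i = sequence.find(anchor, i + 1)
    return out


def build_catalog(
    reads: Iterable[str | tuple[str, str]],
    k: int = DEFAULT_K,
    anchor: str = DEFAULT_ANCHOR,
    sample_label: str = "",
    canonical: bool = False,
) -> KmerCatalog:
    """Count anchored k-mers over a read set.

    ``canonical=True`` additionally scans the reverse complement of every
    read (off by default; changes results and is not the reference
    behaviour).
    """
    counts: Counter = Counter()
    for read in reads:
        seq = read[1] if isinstance(read, tuple) else read
        counts.update(extract_anchored_kmers(seq, k, anchor))
        if canonical:
            counts.update(extract_anchored_kmers(revcomp(seq), k, anchor))
    return KmerCatalog(k, anchor, counts, sample_label)


def merge_catalogs(catalogs: Iterable[KmerCatalog]) -> KmerCatalog:
    """Pool catalogs by element-wise count summation."""
    catalogs = list(catalogs)
    if not catalogs:
        raise ValueError("no catalogs to merge")
    k, anchor = catalogs[0].k, catalogs[0].anchor
    merged: Counter = Counter()
    labels = []
    for cat in catalogs:
        if cat.k != k or cat.anchor != anchor:
            raise ValueError(
                f"cannot merge catalogs with mismatched parameters "
                f"(k={cat.k}/{k}, anchor={cat.anchor}/{anchor})"
            )
        merged.update(cat.counts)
        if cat.sample_label:
            labels.append(cat.sample_label)
    return KmerCatalog(k, anchor, merged, "+".join(labels))


def specific_kmers(
    target: KmerCatalog, pool: KmerCatalog, min_target_count: int = 1
) -> KskSet:
    """Target k-mers with zero counts in the pooled background.

    The pool criterion is strict zero membership; ``min_target_count``
    (default 1) additionally requires the target count to reach a floor —
    noise is otherwise filtered later at the contig level.
    """
    if target.k != pool.k or target.anchor != pool.anchor:
        raise ValueError("target and pool catalogs use different k or anchor")
    pool_keys = pool.counts
    kmers = frozenset(
        m for m, c in target.counts.items() if c >= min_target_count and m not in pool_keys
    )
    return KskSet(
        kmers,
        target.k,
        target.anchor,
        min_target_count,
        target.sample_label,
        tuple(pool.sample_label.split("+")) if pool.sample_label else (),
    )


# ---------------------------------------------------------------------------
# persistence: sorted kmer\tcount text (gzip) + JSON header sidecar


def save_catalog(catalog: KmerCatalog, path: str | Path) -> None:
    path = Path(path)
    with gzip.open(path, "wt") as fh:
        for kmer in sorted(catalog.counts):
            fh.write(f"{kmer}\t{catalog.counts[kmer]}\n")
    sidecar = {"k": catalog.k, "anchor": catalog.anchor, "sample_label": catalog.sample_label}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def load_catalog(path: str | Path) -> KmerCatalog:
    path = Path(path)
    meta = json.loads(Path(str(path) + ".json").read_text())
    counts: Counter = Counter()
    with gzip.open(path, "rt") as fh:
        for line in fh:
            kmer, count = line.split("\t")
            counts[kmer] = int(count)
    return KmerCatalog(meta["k"], meta["anchor"], counts, meta["sample_label"])


def save_ksk(ksk: KskSet, path: str | Path) -> None:
    path = Path(path)
    path.write_text("".join(f"{m}\n" for m in sorted(ksk.kmers)))
    sidecar = {
        "k": ksk.k,
        "anchor": ksk.anchor,
        "min_target_count": ksk.min_target_count,
        "target_label": ksk.target_label,
        "pool_labels": list(ksk.pool_labels),
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def load_ksk(path: str | Path) -> KskSet:
    path = Path(path)
    meta = json.loads(Path(str(path) + ".json").read_text())
    kmers = frozenset(line.strip() for line in path.read_text().splitlines() if line.strip())
    return KskSet(
        kmers,
        meta["k"],
        meta["anchor"],
        meta["min_target_count"],
        meta["target_label"],
        tuple(meta["pool_labels"]),
    )
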