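"""KSK read recruitment, greedy overlap assembly, remapping and filtering.

Reads carrying at least one target-specific k-mer (KSK) as an exact
forward-orientation substring are recruited and assembled by a deterministic
greedy overlap-layout procedure: repeatedly merge the pair of sequences with
the longest exact suffix-prefix overlap (>= ``min_overlap``), absorbing
sequences exactly contained in another. Distinct KSK are then remapped onto
each contig, and contigs with fewer than ``min_ksk`` distinct KSK are
discarded as minor polymorphisms or sequencing noise.

The assembler trades sophistication for determinism: same input, same
output, byte for byte. Tie-breaking when several pairs share the longest
overlap: prefer the longer resulting contig, then the lexicographically
smaller resulting sequence. It is intended for transcript/amplicon-scale
problems (thousands of reads), not genome assembly.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, replace

import pandas as pd

from .kmers import KskSet, extract_anchored_kmers


@dataclass(frozen=True)
class Contig:
    contig_id: str
    sequence: str
    supporting_read_ids: tuple[str, ...]
    ksk_count: int | None = None  # filled by remap_ksk

    @property
    def length(self) -> int:
        return len(self.sequence)


def recruit_reads(
    reads: list[tuple[str, str]], ksk: KskSet
) -> list[tuple[str, str]]:
    """Exactly the reads containing >= 1 KSK member as a forward substring.

    Because every KSK starts with the anchor nucleotide, scanning the
    anchored windows of each read is equivalent to a full substring search
    over all KSK members.
    """
    if len(ksk.kmers) == 0:
        raise ValueError("empty KSK set: nothing to recruit")
    recruited = []
    members = ksk.kmers
    for rid, seq in reads:
        for window in extract_anchored_kmers(seq, ksk.k, ksk.anchor):
            if window in members:
                recruited.append((rid, seq))
                break
    return recruited


class _Greedy:
    """Deterministic greedy exact suffix-prefix overlap merger."""

    def __init__(self, min_overlap: int):
        self.w = min_overlap
        self.seqs: dict[int, str] = {}
        self.support: dict[int, set[str]] = {}
        self.alive: set[int] = set()
        self.prefix_index: dict[str, set[int]] = {}
        self.substr_index: dict[str, list[tuple[int, int]]] = {}
        self.heap: list[tuple[int, int, str, int, int]] = []
        self._next = 0

    # -- index plumbing ----------------------------------------------------
    def _contained_in_alive(self, seq: str) -> int | None:
        for cid, pos in self.substr_index.get(seq[: self.w], ()):
            if cid in self.alive and self.seqs[cid][pos : pos + len(seq)] == seq:
                return cid
        return None

    def _absorb_contained(self, nid: int) -> None:
        seq = self.seqs[nid]
        for p in range(len(seq) - self.w + 1):
            for cid in list(self.prefix_index.get(seq[p : p + self.w], ())):
                if cid == nid or cid not in self.alive:
                    continue
                # candidate's full sequence must match at this window start
                if seq[p : p + len(self.seqs[cid])] == self.seqs[cid]:
                    self.alive.discard(cid)
                    self.support[nid] |= self.support[cid]

    def _register(self, nid: int) -> None:
        seq = self.seqs[nid]
        self.prefix_index.setdefault(seq[: self.w], set()).add(nid)
        for p in range(len(seq) - self.w + 1):
            self.substr_index.setdefault(seq[p : p + self.w], []).append((nid, p))

    def _push_overlaps(self, nid: int) -> None:
        seq = self.seqs[nid]
        n = len(seq)
        # nid as the left partner: suffix of nid == prefix of other
        best: dict[int, int] = {}
        for s in range(1, n - self.w + 1):  # overlap o = n - s, descending
            o = n - s
            for other in self.prefix_index.get(seq[s : s + self.w], ()):
                if other == nid or other not in self.alive or other in best:
                    continue
                oseq = self.seqs[other]
                if o <= len(oseq) and seq[s:] == oseq[:o]:
                    best[other] = o
        for other, o in best.items():
            self._push_pair(nid, other, o)
        # nid as the right partner: suffix of other == prefix of nid
        best_left: dict[int, int] = {}
        for other, pos in self.substr_index.get(seq[: self.w], ()):
            if other == nid or other not in self.alive or pos < 1:
                continue
            oseq = self.seqs[other]
            o = len(oseq) - pos
            if o < self.w or o > n:
                continue
            if oseq[pos:] == seq[:o] and o > best_left.get(other, 0):
                best_left[other] = o
        for other, o in best_left.items():
            self._push_pair(other, nid, o)

    def _push_pair(self, a: int, b: int, o: int) -> None:
        res = self.seqs[a] + self.seqs[b][o:]
        heapq.heappush(self.heap, (-o, -len(res), res, a, b))

    # -- node lifecycle ----------------------------------------------------
    def add(self, seq: str, support: set[str]) -> None:
        host = self._contained_in_alive(seq)
        if host is not None:
            self.support[host] |= support
            return
        nid = self._next
        self._next += 1
        self.seqs[nid] = seq
        self.support[nid] = support
        self.alive.add(nid)
        self._absorb_contained(nid)
        self._register(nid)
        self._push_overlaps(nid)

    def run(self) -> list[tuple[str, set[str]]]:
        while self.heap:
            no, _, res, a, b = heapq.heappop(self.heap)
            if a not in self.alive or b not in self.alive or a == b:
                continue
            support = self.support[a] | self.support[b]
            self.alive.discard(a)
            self.alive.discard(b)
            self.add(res, support)
        return [(self.seqs[i], self.support[i]) for i in self.alive]


def _assemble_with_mismatches(
    groups: list[tuple[str, set[str]]], min_overlap: int, max_mismatch: int
) -> list[tuple[str, set[str]]]:
    """Quadratic fallback allowing up to ``max_mismatch`` mismatches in the
    overlap; the left partner's bases win in the merged region. Intended for
    small noisy fixtures only."""

    def best_pair(items):
        best = None
        for i, (sa, _) in enumerate(items):
            for j, (sb, _) in enumerate(items):
                if i == j:
                    continue
                for o in range(min(len(sa), len(sb)), min_overlap - 1, -1):
                    mm = sum(x != y for x, y in zip(sa[-o:], sb[:o]))
                    if mm <= max_mismatch:
                        res = sa + sb[o:]
                        key = (-o, -len(res), res)
                        if best is None or key < best[0]:
                            best = (key, i, j, o)
                        break
        return best

    items = list(groups)
    while True:
        hit = best_pair(items)
        if hit is None:
            return items
        (_, _, res), i, j, o = hit
        _, supa = items[i]
        _, supb = items[j]
        merged_seq, merged_sup = res, supa | supb
        rest = [it for idx, it in enumerate(items) if idx not in (i, j)]
        kept = []
        for seq, sup in rest:  # absorb exact containments into the new contig
            if seq in merged_seq:
                merged_sup |= sup
            else:
                kept.append((seq, sup))
        items = kept + [(merged_seq, merged_sup)]


def assemble(
    reads: list[tuple[str, str]], min_overlap: int = 25, max_mismatch: int = 0
) -> list[Contig]:
    """Greedy overlap assembly of recruited reads into contigs.

    Identical reads collapse first; reads exactly contained in another
    sequence are absorbed; unmergeable reads come out as singleton contigs.
    Output is sorted by descending length, then sequence, with stable ids.
    """
    if not reads:
        raise ValueError("no reads to assemble")
    dedup: dict[str, set[str]] = {}
    for rid, seq in reads:
        dedup.setdefault(seq.upper(), set()).add(rid)
    long_items = [(s, ids) for s, ids in sorted(dedup.items()) if len(s) >= min_overlap]
    short_items = [(s, ids) for s, ids in sorted(dedup.items()) if len(s) < min_overlap]
    if max_mismatch > 0:
        final = _assemble_with_mismatches(long_items, min_overlap, max_mismatch)
    else:
        greedy = _Greedy(min_overlap)
        for seq, ids in long_items:
            greedy.add(seq, set(ids))
        final = greedy.run()
    # absorb short sequences contained in a contig; keep the rest as singletons
    leftovers = []
    for seq, ids in short_items:
        for i, (cseq, csup) in enumerate(final):
            if seq in cseq:
                final[i] = (cseq, csup | set(ids))
                break
        else:
            leftovers.append((seq, set(ids)))
    final.extend(leftovers)
    final.sort(key=lambda t: (-len(t[0]), t[0]))
    width = max(4, len(str(len(final))))
    return [
        Contig(f"contig_{i + 1:0{width}d}", seq, tuple(sorted(sup)))
        for i, (seq, sup) in enumerate(final)
    ]


def remap_ksk(contigs: list[Contig], ksk: KskSet) -> list[Contig]:
    """Count the distinct KSK members occurring in each contig (forward)."""
    scored = []
    for contig in contigs:
        windows = set(extract_anchored_kmers(contig.sequence, ksk.k, ksk.anchor))
        scored.append(replace(contig, ksk_count=len(windows & ksk.kmers)))
    return scored


def filter_contigs(contigs: list[Contig], min_ksk: int = 10) -> list[Contig]:
    """Retain contigs with at least ``min_ksk`` distinct KSK, order preserved."""
    for contig in contigs:
        if contig.ksk_count is None:
            raise ValueError(f"contig {contig.contig_id} has no KSK score; run remap_ksk first")
    return [c for c in contigs if c.ksk_count >= min_ksk]


def report_contigs(contigs: list[Contig], highlight_threshold: int = 80) -> pd.DataFrame:
    """Ranked contig table: ksk_count descending, ties by contig_id.

    The annotation column is a placeholder hook for external homology
    searches, which this package does not perform.
    """
    rows = [
        {
            "contig_id": c.contig_id,
            "ksk_count": c.ksk_count if c.ksk_count is not None else 0,
            "length": c.length,
            "annotation": "",
            "highlight": (c.ksk_count or 0) > highlight_threshold,
        }
        for c in contigs
    ]
    tab = pd.DataFrame(rows, columns=["contig_id", "ksk_count", "length", "annotation", "highlight"])
    if not tab.empty:
        tab = tab.sort_values(
            ["ksk_count", "contig_id"], ascending=[False, True], ignore_index=True
        )
    return tab
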