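"""Seed words and their occurrences in 3'UTRs.

The target site of a miRNA is the k-mer in the 3'UTR exactly complementary
(reverse complement, antiparallel) to the miRNA seed — by default positions
2-8 of the mature sequence, a 7-mer.  Matching is exact: no wobble pairs, no
mismatches.  Overlapping occurrences are all counted, and windows containing
N never match and are never counted among the eligible windows.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seqio import MiRNA, UTRRecord

__all__ = ["SeedWord", "SiteList", "seed_word", "find_seed_matches", "total_windows"]

_COMPLEMENT = str.maketrans("ACGU", "TGCA")


@dataclass(frozen=True)
class SeedWord:
    """The DNA word a UTR must contain to pair with a miRNA seed."""

    word: str
    source_mirna: str
    seed_start: int
    seed_len: int

    def __len__(self) -> int:
        return len(self.word)


@dataclass(frozen=True)
class SiteList:
    """Sorted 0-based start positions of a word's occurrences in one UTR."""

    gene_id: str
    word: str
    positions: tuple[int, ...]

    @property
    def count(self) -> int:
        return len(self.positions)


def seed_word(mirna: MiRNA) -> SeedWord:
    """Reverse-complement of the miRNA seed, written in DNA (U -> T).

    The seed is the subsequence at 1-based positions
    [seed_start, seed_start + seed_len - 1] of the mature miRNA.
    """
    start, length = mirna.seed_start, mirna.seed_len
    if start < 1 or start + length - 1 > len(mirna.sequence):
        raise ValueError(
            f"seed window {start}..{start + length - 1} out of range for {mirna.mirna_id!r}"
        )
    seed = mirna.sequence[start - 1 : start - 1 + length]
    word = seed.translate(_COMPLEMENT)[::-1]
    return SeedWord(word=word, source_mirna=mirna.mirna_id, seed_start=start, seed_len=length)


def find_seed_matches(utr: UTRRecord, word: SeedWord | str) -> SiteList:
    """All (including overlapping) exact occurrences of the word in the UTR.

    Windows containing N are excluded: an unknown base cannot support a
    claimed match.
    """
    w = word.word if isinstance(word, SeedWord) else word
    k = len(w)
    seq = utr.sequence
    positions = []
    start = 0
    while True:
        hit = seq.find(w, start)
        if hit == -1:
            break
        positions.append(hit)
        start = hit + 1
    if "N" in w:
        positions = []
    return SiteList(gene_id=utr.gene_id, word=w, positions=tuple(positions))


def total_windows(utr: UTRRecord, k: int) -> int:
    """Number of k-windows in the UTR that contain no N.

    Equals len - k + 1 for an N-free sequence and 0 when the UTR is shorter
    than k.  This is the window universe over which both the total count t
    and the match count c are defined.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    seq = utr.sequence
    n = len(seq)
    if n < k:
        return 0
    if "N" not in seq:
        return n - k + 1
    total = 0
    n_in_window = seq[: k - 1].count("N")
    prev = ""
    for start in range(n - k + 1):
        n_in_window += seq[start + k - 1] == "N"
        if prev == "N":
            n_in_window -= 1
        if n_in_window == 0:
            total += 1
        prev = seq[start]
    return total
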