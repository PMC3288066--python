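"""Over-representation scoring of miRNA-3'UTR interactions.

An interaction is scored by the single-hypothesis P value P_SH: the
probability that a word complementary to the miRNA seed occurs by chance at
least c times among the t eligible k-mer windows of the 3'UTR,

    P_SH = P(X >= c),   X ~ Binomial(t_filter, p),

where p is the word's background probability under a zeroth-order
(mononucleotide) composition model and t_filter / c_filter are the numbers
of all windows, and of seed-match windows, that pass the active filter
(none, accessibility, conservation, or both).  Filtering changes the counts
only — the score and the ranking rule are the same in every configuration.
Lower P_SH means the interaction is less likely to be explained by chance
and hence ranks higher.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .accessibility import PfreeProfile, accessible_window_mask
from .conservation import ColumnMap, ConservationConfig, column_map, conserved_window_mask
from .seedmatch import SeedWord, find_seed_matches, seed_word, total_windows
from .seqio import AlignedUTR, MiRNA, UTRRecord

__all__ = [
    "FilterConfig",
    "InteractionScore",
    "word_probability",
    "filtered_counts",
    "p_sh",
    "score_interaction",
    "rank_predictions",
]

FILTER_MODES = ("none", "access", "cons", "cons+access")


@dataclass(frozen=True)
class FilterConfig:
    """Which filter to apply before counting, and the seed definition.

    mode 'access' requires a PfreeProfile at score time; 'cons' an
    AlignedUTR; 'cons+access' both.  p_cutoff is the inclusive accessibility
    threshold (default 0.2).
    """

    mode: str = "none"
    p_cutoff: float = 0.2
    cons: Optional[ConservationConfig] = None
    seed_start: int = 2
    seed_len: int = 7
    background: str = "per-utr"  # {"per-utr", "global"}
    global_composition: Optional[tuple[float, float, float, float]] = None  # A,C,G,T

    def __post_init__(self) -> None:
        if self.mode not in FILTER_MODES:
            raise ValueError(f"filter mode must be one of {FILTER_MODES}, got {self.mode!r}")
        if not 0.0 <= self.p_cutoff <= 1.0:
            raise ValueError("p_cutoff must lie in [0, 1]")
        if self.mode in ("cons", "cons+access") and self.cons is None:
            raise ValueError(f"mode {self.mode!r} requires a ConservationConfig")
        if self.background not in ("per-utr", "global"):
            raise ValueError("background must be 'per-utr' or 'global'")
        if self.background == "global" and self.global_composition is None:
            raise ValueError("global background requires a composition table")


@dataclass(frozen=True)
class InteractionScore:
    """One ranked miRNA-3'UTR record: filtered counts and P_SH.

    c_filter = 0 marks a non-prediction: no filtered seed match exists, the
    binomial tail is exactly 1, and the record is excluded from ranked
    output.
    """

    mirna_id: str
    gene_id: str
    t_filter: int
    c_filter: int
    p_word: float
    p_sh: float

    @property
    def is_prediction(self) -> bool:
        return self.c_filter > 0

    def __post_init__(self) -> None:
        if not 0 <= self.c_filter <= self.t_filter:
            raise ValueError("need 0 <= c_filter <= t_filter")


def word_probability(utr: UTRRecord, word: SeedWord | str,
                     composition: Optional[tuple[float, float, float, float]] = None) -> float:
    """Background probability of the word under a zeroth-order model.

    Product, over the word's letters, of that letter's mononucleotide
    frequency in the UTR (N excluded from the counts), or of the supplied
    global composition (A, C, G, T).  If a needed letter never occurs the
    probability is 0; observing a match is then inconsistent with the model
    and the caller raises.
    """
    w = word.word if isinstance(word, SeedWord) else word
    if composition is None:
        seq = utr.sequence
        counts = {b: seq.count(b) for b in "ACGT"}
        denom = sum(counts.values())
        if denom == 0:
            raise ValueError(f"UTR {utr.gene_id!r} has no unambiguous bases")
        freq = {b: counts[b] / denom for b in "ACGT"}
    else:
        freq = dict(zip("ACGT", composition))
    p = 1.0
    for ch in w:
        p *= freq[ch]
    return p


def filtered_counts(
    utr: UTRRecord,
    word: SeedWord | str,
    cfg: FilterConfig,
    profile: Optional[PfreeProfile] = None,
    aln: Optional[AlignedUTR] = None,
    cmap: Optional[ColumnMap] = None,
) -> tuple[int, int]:
    """(t_filter, c_filter): windows and seed matches passing the filter.

    t counts every N-free k-window meeting the filter requirement regardless
    of its sequence; c counts the seed-match windows among them, so
    c <= t by construction.
    """
    w = word.word if isinstance(word, SeedWord) else word
    k = len(w)
    matches = find_seed_matches(utr, w).positions
    if cfg.mode == "none":
        return total_windows(utr, k), len(matches)

    n = utr.length
    if n < k:
        return 0, 0
    keep = np.ones(n - k + 1, dtype=bool)
    seq_bytes = np.frombuffer(utr.sequence.encode(), dtype="S1")
    has_n = seq_bytes == b"N"
    if has_n.any():
        keep &= ~np.lib.stride_tricks.sliding_window_view(has_n, k).any(axis=1)

    if cfg.mode in ("access", "cons+access"):
        if profile is None:
            raise ValueError(f"filter mode {cfg.mode!r} requires an accessibility profile")
        if profile.length != n:
            raise ValueError(
                f"profile length {profile.length} != UTR length {n} for {utr.gene_id!r}"
            )
        keep &= accessible_window_mask(profile, k, cfg.p_cutoff)
    if cfg.mode in ("cons", "cons+access"):
        if aln is None:
            raise ValueError(f"filter mode {cfg.mode!r} requires an alignment")
        if cmap is None:
            cmap = column_map(aln)
        keep &= conserved_window_mask(utr.sequence, aln, cmap, k, cfg.cons)

    t = int(keep.sum())
    c = sum(1 for pos in matches if keep[pos])
    return t, c


def p_sh(t: int, c: int, p: float) -> float:
    """Upper-tail binomial probability P(X >= c) with X ~ Binomial(t, p).

    Computed through the regularized incomplete beta function (scipy's
    survival function), which stays accurate down to ~1e-300.  By
    convention P(X >= 0) = 1 exactly.
    """
    if not 0 <= c <= t:
        raise ValueError(f"need 0 <= c <= t, got c={c}, t={t}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    if c == 0:
        return 1.0
    return float(stats.binom.sf(c - 1, t, p))


def score_interaction(
    mirna: MiRNA,
    utr: UTRRecord,
    cfg: FilterConfig,
    profile: Optional[PfreeProfile] = None,
    aln: Optional[AlignedUTR] = None,
    cmap: Optional[ColumnMap] = None,
) -> InteractionScore:
    """Score one miRNA-3'UTR pair: seed word -> filtered counts -> P_SH."""
    word = seed_word(mirna)
    t, c = filtered_counts(utr, word, cfg, profile=profile, aln=aln, cmap=cmap)
    composition = cfg.global_composition if cfg.background == "global" else None
    p = word_probability(utr, word, composition)
    if p == 0.0 and c >= 1:
        raise ValueError(
            f"word {word.word!r} observed {c}x in {utr.gene_id!r} but has zero "
            "probability under the background model"
        )
    return InteractionScore(
        mirna_id=mirna.mirna_id,
        gene_id=utr.gene_id,
        t_filter=t,
        c_filter=c,
        p_word=p,
        p_sh=p_sh(t, c, p),
    )


def rank_predictions(scores: list[InteractionScore]) -> list[InteractionScore]:
    """Ascending P_SH; deterministic tie-breaking; non-predictions dropped.

    Ties are broken by descending c_filter, then gene_id, then mirna_id, so
    rankings are stable and reproducible across runs.
    """
    predictions = [s for s in scores if s.is_prediction]
    return sorted(predictions, key=lambda s: (s.p_sh, -s.c_filter, s.gene_id, s.mirna_id))
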