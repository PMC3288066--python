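"""Cross-species conservation of seed-match windows.

A window of the reference 3'UTR is judged conserved from a multiple
alignment under one of two rules:

* **Any-S** — the site is present (at the orthologous, aligned positions)
  in at least S species, the reference included, regardless of which
  species they are or how distant.
* **Selected-S** — the site is present in every species of a fixed,
  pre-selected list.  The canonical ladder adds species in order of
  increasing distance from human: Selected-2 = {human, chimp}, then
  rhesus, mouse, dog, cow, chicken.

Conservation is positional: the alignment defines the correspondence, and a
species carries the site only if its row, at exactly the columns where the
reference spells the word, is gap-free and spells the same word.  Columns
where the reference itself is gapped (insertions in other species) are
skipped.  An indel inside the window, or a missing species (all-gap row),
means the site is not conserved in that species.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seedmatch import SeedWord
from .seqio import AlignedUTR

__all__ = [
    "SELECTED_SPECIES_LADDER",
    "ConservationConfig",
    "ColumnMap",
    "column_map",
    "species_has_site",
    "is_conserved",
    "conserved_window_total",
    "conserved_window_mask",
]

# Species added in order of increasing distance from the reference (human).
SELECTED_SPECIES_LADDER = ("human", "chimp", "rhesus", "mouse", "dog", "cow", "chicken")


def selected_species(s: int) -> tuple[str, ...]:
    """The Selected-S species list from the canonical ladder (2 <= S <= 7)."""
    if not 2 <= s <= len(SELECTED_SPECIES_LADDER):
        raise ValueError(f"Selected-S supports 2 <= S <= {len(SELECTED_SPECIES_LADDER)}")
    return SELECTED_SPECIES_LADDER[:s]


@dataclass(frozen=True)
class ConservationConfig:
    """Which conservation rule to apply and its stringency."""

    mode: str = "selected"  # {"any", "selected"}
    S: int = 1
    species_list: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.mode not in ("any", "selected"):
            raise ValueError(f"mode must be 'any' or 'selected', got {self.mode!r}")
        if self.mode == "any" and self.S < 1:
            raise ValueError("Any-S requires S >= 1")
        if self.mode == "selected" and not self.species_list:
            raise ValueError("Selected mode requires a non-empty species list")


@dataclass
class ColumnMap:
    """Maps each 0-based ungapped reference position to its alignment column."""

    gene_id: str
    ref_pos_to_col: np.ndarray

    def __post_init__(self) -> None:
        self.ref_pos_to_col = np.asarray(self.ref_pos_to_col, dtype=np.intp)

    def __getitem__(self, pos: int) -> int:
        return int(self.ref_pos_to_col[pos])

    def __len__(self) -> int:
        return self.ref_pos_to_col.size


def column_map(aln: AlignedUTR) -> ColumnMap:
    """Column index of every non-gap reference character, in order."""
    ref = np.frombuffer(aln.ref_row().encode(), dtype="S1")
    cols = np.flatnonzero(ref != b"-")
    return ColumnMap(gene_id=aln.gene_id, ref_pos_to_col=cols)


def _word_of(word: SeedWord | str) -> str:
    w = word.word if isinstance(word, SeedWord) else word
    return w.upper().replace("U", "T")


def species_has_site(
    aln: AlignedUTR, cmap: ColumnMap, species: str, start: int, word: SeedWord | str
) -> bool:
    """Does this species carry the word at the orthologous columns?

    Examines the columns cmap[start] .. cmap[start + k - 1] where the
    reference spells the word (checked); the species row must be gap-free
    and spell exactly the word across them (case-insensitive, U treated as
    T).  A species absent from the alignment counts as all-gap.
    """
    w = _word_of(word)
    k = len(w)
    cols = cmap.ref_pos_to_col[start : start + k]
    if cols.size != k:
        raise ValueError(f"window [{start}, {start + k}) outside the reference UTR")
    ref_row = aln.ref_row()
    ref_word = "".join(ref_row[c] for c in cols).upper().replace("U", "T")
    if ref_word != w:
        raise ValueError(
            f"reference does not carry word {w!r} at position {start} (found {ref_word!r})"
        )
    row = aln.rows.get(species)
    if row is None:
        return False
    site = "".join(row[c] for c in cols)
    if "-" in site:
        return False
    return site.upper().replace("U", "T") == w


def is_conserved(
    aln: AlignedUTR,
    cmap: ColumnMap,
    start: int,
    word: SeedWord | str,
    cfg: ConservationConfig,
) -> bool:
    """Apply the Any-S or Selected rule to one site.

    Any-S: at least S species (the reference included) carry the site.
    Selected: every species in the configured list carries it; a listed
    species missing from the alignment is treated as all-gap, hence false.
    """
    if cfg.mode == "any":
        count = sum(
            species_has_site(aln, cmap, sp, start, word) for sp in aln.rows
        )
        return count >= cfg.S
    return all(species_has_site(aln, cmap, sp, start, word) for sp in cfg.species_list)


def _per_position_match(aln: AlignedUTR, cmap: ColumnMap, species: str) -> np.ndarray:
    """match[p]: species row equals the reference base at ref position p.

    Gap or mismatch at the ref-bearing column, or a species absent from the
    alignment, gives False.
    """
    n = len(cmap)
    row = aln.rows.get(species)
    if row is None:
        return np.zeros(n, dtype=bool)
    cols = cmap.ref_pos_to_col
    sp = np.frombuffer(row.upper().replace("U", "T").encode(), dtype="S1")[cols]
    ref = np.frombuffer(
        aln.ref_row().upper().replace("U", "T").encode(), dtype="S1"
    )[cols]
    return (sp == ref) & (sp != b"-")


def conserved_window_mask(
    utr_sequence: str,
    aln: AlignedUTR,
    cmap: ColumnMap,
    k: int,
    cfg: ConservationConfig,
) -> np.ndarray:
    """Boolean mask over all k-window starts: conserved or not.

    The rule is applied to EVERY window, taking the reference k-mer at that
    window as the word — this is how the filtered total t_cons counts all
    eligible 7-mers, not only seed matches.  Windows containing N in the
    reference are never conserved (they are outside the window universe).
    """
    n = len(utr_sequence)
    if n != len(cmap):
        raise ValueError("UTR length does not match the column map")
    if n < k:
        return np.zeros(0, dtype=bool)
    species = [sp for sp in aln.rows if sp != aln.ref_species]
    if cfg.mode == "selected":
        species_needed = [sp for sp in cfg.species_list if sp != aln.ref_species]
        per_site = np.ones((max(len(species_needed), 1), n), dtype=bool)
        for i, sp in enumerate(species_needed):
            per_site[i] = _per_position_match(aln, cmap, sp)
        window_ok = np.lib.stride_tricks.sliding_window_view(per_site, k, axis=1).all(
            axis=2
        )
        mask = window_ok.all(axis=0) if species_needed else np.ones(n - k + 1, dtype=bool)
    else:
        if not species:
            counts = np.zeros(n - k + 1, dtype=np.intp)
        else:
            per_site = np.stack([_per_position_match(aln, cmap, sp) for sp in species])
            window_ok = np.lib.stride_tricks.sliding_window_view(
                per_site, k, axis=1
            ).all(axis=2)
            counts = window_ok.sum(axis=0)
        mask = counts + 1 >= cfg.S  # +1: the reference always carries its own k-mer
    has_n = np.frombuffer(utr_sequence.encode(), dtype="S1") == b"N"
    if has_n.any():
        n_in_window = np.lib.stride_tricks.sliding_window_view(has_n, k).any(axis=1)
        mask = mask & ~n_in_window
    return mask


def conserved_window_total(
    utr_sequence: str,
    aln: AlignedUTR,
    cmap: ColumnMap,
    k: int,
    cfg: ConservationConfig,
) -> int:
    """Number of k-windows whose reference k-mer satisfies the rule."""
    return int(conserved_window_mask(utr_sequence, aln, cmap, k, cfg).sum())
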