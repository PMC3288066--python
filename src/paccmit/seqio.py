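"""Readers and writers for the standard formats the predictor touches.

FASTA (3'UTRs as DNA, mature miRNAs as RNA), UCSC-dialect MAF multiple
alignments, per-gene pre-stitched alignment FASTA, and the ranked-prediction
TSV.  All coordinates are 0-based half-open internally; MAF's native 0-based
starts are kept as-is.  Alignments are normalized to the reference + strand
at read time, and 3'UTRs are stored as sense-strand mRNA sequence, because
seed matching is defined on the mRNA.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Seq import reverse_complement

__all__ = [
    "UTRRecord",
    "MiRNA",
    "AlignedUTR",
    "MAFBlock",
    "read_fasta",
    "write_fasta",
    "read_maf",
    "write_maf",
    "stitch_aligned_utr",
    "read_alignment_fasta",
    "write_alignment_fasta",
    "write_predictions",
    "read_predictions",
    "dedupe_by_longest",
    "strip_assembly",
]

_DNA_ALPHABET = set("ACGTN")
_RNA_ALPHABET = set("ACGUN")

PREDICTION_COLUMNS = ["mirna_id", "gene_id", "c_filter", "t_filter", "p_word", "p_sh", "rank"]


@dataclass(frozen=True)
class UTRRecord:
    """One gene's 3'UTR: sense-strand mRNA sequence over {A,C,G,T,N}."""

    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.gene_id!r}")
        bad = set(self.sequence) - _DNA_ALPHABET
        if bad:
            raise ValueError(f"illegal DNA characters {sorted(bad)} in {self.gene_id!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MiRNA:
    """A mature miRNA sequence (RNA, 5'->3') with its seed definition.

    The default seed covers positions 2-8 (1-based), the canonical 7-mer
    seed; ``seed_start``/``seed_len`` allow shorter, longer, or shifted
    matches.
    """

    mirna_id: str
    sequence: str
    seed_start: int = 2
    seed_len: int = 7

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.mirna_id!r}")
        bad = set(self.sequence) - _RNA_ALPHABET
        if bad:
            raise ValueError(f"illegal RNA characters {sorted(bad)} in {self.mirna_id!r}")
        if self.seed_start < 1:
            raise ValueError("seed_start must be >= 1")
        if self.seed_start + self.seed_len - 1 > len(self.sequence):
            raise ValueError(
                f"seed window {self.seed_start}..{self.seed_start + self.seed_len - 1} "
                f"exceeds miRNA {self.mirna_id!r} of length {len(self.sequence)}"
            )


@dataclass
class AlignedUTR:
    """Per-species gap-aligned rows over a shared column space.

    Ungapping the reference row reproduces the UTR sequence exactly.
    Species absent from the underlying alignment are represented as all-gap
    rows.
    """

    gene_id: str
    ref_species: str
    rows: dict[str, str]
    n_columns: int = field(default=0)

    def __post_init__(self) -> None:
        if self.ref_species not in self.rows:
            raise ValueError(f"reference species {self.ref_species!r} missing from rows")
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) != 1:
            raise ValueError(f"aligned rows have unequal lengths {sorted(lengths)}")
        (n,) = lengths
        if self.n_columns and self.n_columns != n:
            raise ValueError("n_columns does not match row length")
        self.n_columns = n

    def ref_row(self) -> str:
        return self.rows[self.ref_species]

    def ungapped_ref(self) -> str:
        return self.ref_row().replace("-", "")


@dataclass
class MAFBlock:
    """One MAF alignment block: per-species (start, size, strand, srcSize, text).

    ``srcs`` keeps the full MAF source names ("assembly.chrom"); rows are
    keyed by the species (assembly) part.
    """

    rows: dict[str, tuple[int, int, str, int, str]]
    srcs: dict[str, str] = field(default_factory=dict)

    def species(self) -> list[str]:
        return list(self.rows)


def strip_assembly(src: str) -> str:
    """Map a MAF source name 'assembly.chrom' to its species/assembly key.

    UCSC MAF rows are named "assembly.chrom"; the default rule keeps the text
    before the first dot.
    """
    return src.split(".", 1)[0]


def _normalize(seq: str, alphabet: str) -> str:
    seq = seq.upper()
    if alphabet == "dna":
        return seq.replace("U", "T")
    return seq.replace("T", "U")


def read_fasta(path: str | os.PathLike, alphabet: str = "dna") -> list:
    """Read a FASTA file into UTRRecord (dna) or MiRNA (rna) records.

    Identifiers are truncated at the first whitespace; sequences are
    upper-cased and normalized to the requested alphabet (dna: U->T,
    rna: T->U).  Duplicate identifiers and characters outside
    {A,C,G,T/U,N} are hard errors.
    """
    if alphabet not in ("dna", "rna"):
        raise ValueError(f"alphabet must be 'dna' or 'rna', got {alphabet!r}")
    allowed = _DNA_ALPHABET if alphabet == "dna" else _RNA_ALPHABET
    out: list = []
    seen: set[str] = set()
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        ident = rec.id
        if ident in seen:
            raise ValueError(f"duplicate identifier {ident!r} in {path}")
        seen.add(ident)
        seq = _normalize(str(rec.seq), alphabet)
        for pos, ch in enumerate(seq):
            if ch not in allowed:
                raise ValueError(
                    f"illegal character {ch!r} at position {pos} of record {ident!r}"
                )
        out.append(UTRRecord(ident, seq) if alphabet == "dna" else MiRNA(ident, seq))
    return out


def write_fasta(records, path: str | os.PathLike, width: int = 60) -> None:
    """Write UTRRecord/MiRNA records as wrapped FASTA."""
    with open(path, "w") as fh:
        for rec in records:
            ident = getattr(rec, "gene_id", None) or getattr(rec, "mirna_id")
            fh.write(f">{ident}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def dedupe_by_longest(records: list[UTRRecord]) -> list[UTRRecord]:
    """Keep, for each gene_id, only the record with the longest sequence.

    Mirrors the convention of retaining a single (longest-3'UTR) isoform per
    gene; ties keep the first-seen record.  Input order of the surviving
    ids is preserved.
    """
    best: dict[str, UTRRecord] = {}
    order: list[str] = []
    for rec in records:
        if rec.gene_id not in best:
            best[rec.gene_id] = rec
            order.append(rec.gene_id)
        elif rec.length > best[rec.gene_id].length:
            best[rec.gene_id] = rec
    return [best[g] for g in order]


def read_maf(path: str | os.PathLike, ref_species: str | None = None) -> list[MAFBlock]:
    """Read a UCSC-dialect MAF file into alignment blocks.

    Each block carries per-species (start, size, strand, srcSize, aligned
    text) keyed by the species name (assembly prefix of the source).  Starts
    are MAF-native: 0-based on the given strand.  A block with two rows for
    the same species is a hard error, as is a row-length mismatch.
    """
    blocks: list[MAFBlock] = []
    with open(path) as fh:
        for msa in AlignIO.parse(fh, "maf"):
            rows: dict[str, tuple[int, int, str, int, str]] = {}
            srcs: dict[str, str] = {}
            length = msa.get_alignment_length()
            for rec in msa:
                sp = strip_assembly(rec.id)
                if sp in rows:
                    raise ValueError(f"species {sp!r} appears twice in one MAF block")
                text = str(rec.seq)
                if len(text) != length:
                    raise ValueError(
                        f"row length mismatch in MAF block for {rec.id!r}"
                    )
                strand = "+" if rec.annotations["strand"] == 1 else "-"
                rows[sp] = (
                    int(rec.annotations["start"]),
                    int(rec.annotations["size"]),
                    strand,
                    int(rec.annotations["srcSize"]),
                    text,
                )
                srcs[sp] = rec.id
            blocks.append(MAFBlock(rows, srcs))
    return blocks


def write_maf(blocks: list[MAFBlock], path: str | os.PathLike) -> None:
    """Write blocks in the UCSC MAF dialect ("a"/"s" lines)."""
    with open(path, "w") as fh:
        fh.write("##maf version=1\n")
        for block in blocks:
            fh.write("a\n")
            for sp, (start, size, strand, src_size, text) in block.rows.items():
                src = block.srcs.get(sp, f"{sp}.chr")
                fh.write(f"s {src} {start} {size} {strand} {src_size} {text}\n")
            fh.write("\n")


def _oriented_block(block: MAFBlock, ref: str) -> MAFBlock:
    """Flip a block so the reference row is on the + strand."""
    start, size, strand, src_size, text = block.rows[ref]
    if strand == "+":
        return block
    rows: dict[str, tuple[int, int, str, int, str]] = {}
    for sp, (s, sz, st, ssz, txt) in block.rows.items():
        flipped = "+" if st == "-" else "-"
        rows[sp] = (ssz - s - sz, sz, flipped, ssz, reverse_complement(txt))
    return MAFBlock(rows, dict(block.srcs))


def stitch_aligned_utr(
    blocks: list[MAFBlock],
    gene_id: str,
    ref_interval: tuple[int, int],
    species: list[str],
    ref_species: str | None = None,
    utr_sequence: str | None = None,
) -> AlignedUTR:
    """Assemble a per-gene AlignedUTR from MAF blocks over a reference interval.

    ``ref_interval`` is 0-based half-open on the + strand of the reference.
    Blocks are strand-normalized, their columns restricted to reference
    positions inside the interval, concatenated in reference order, and
    reference positions not covered by any block are emitted as columns in
    which every non-reference species is a gap.  Overlapping blocks on the
    reference are a hard error (input is required to be single-coverage).

    If ``utr_sequence`` is given the uncovered reference positions are filled
    from it (and covered positions are checked against it); otherwise they
    are filled with 'N'.
    """
    if ref_species is None:
        ref_species = species[0]
    lo, hi = ref_interval
    if not 0 <= lo < hi:
        raise ValueError(f"bad ref_interval {ref_interval}")

    # Restrict each block to the interval, keyed by its ref start.
    pieces: list[tuple[int, int, dict[str, str]]] = []  # (ref_lo, ref_hi, columns)
    for raw in blocks:
        if ref_species not in raw.rows:
            continue
        block = _oriented_block(raw, ref_species)
        r_start, r_size, _, _, r_text = block.rows[ref_species]
        b_lo, b_hi = max(r_start, lo), min(r_start + r_size, hi)
        if b_lo >= b_hi:
            continue
        # Column range holding ref positions [b_lo, b_hi).
        cols_of_pos = [i for i, ch in enumerate(r_text) if ch != "-"]
        c_lo = cols_of_pos[b_lo - r_start]
        c_hi = cols_of_pos[b_hi - r_start - 1] + 1
        sub = {
            sp: block.rows[sp][4][c_lo:c_hi] if sp in block.rows else "-" * (c_hi - c_lo)
            for sp in species
        }
        pieces.append((b_lo, b_hi, sub))

    pieces.sort(key=lambda p: p[0])
    for (_, prev_hi, _), (nxt_lo, _, _) in zip(pieces, pieces[1:]):
        if nxt_lo < prev_hi:
            raise ValueError("overlapping MAF blocks on the reference (not single-coverage)")

    parts: dict[str, list[str]] = {sp: [] for sp in species}

    def pad(a: int, b: int) -> None:
        if b <= a:
            return
        if utr_sequence is not None:
            ref_fill = utr_sequence[a - lo : b - lo]
        else:
            ref_fill = "N" * (b - a)
        for sp in species:
            parts[sp].append(ref_fill if sp == ref_species else "-" * (b - a))

    cursor = lo
    for b_lo, b_hi, sub in pieces:
        pad(cursor, b_lo)
        for sp in species:
            parts[sp].append(sub[sp])
        cursor = b_hi
    pad(cursor, hi)

    rows = {sp: "".join(parts[sp]).upper() for sp in species}
    aln = AlignedUTR(gene_id=gene_id, ref_species=ref_species, rows=rows)
    if utr_sequence is not None and aln.ungapped_ref() != utr_sequence.upper():
        raise ValueError(
            f"stitched reference row does not reproduce the UTR sequence for {gene_id!r}"
        )
    return aln


def read_alignment_fasta(path: str | os.PathLike, gene_id: str, ref_species: str) -> AlignedUTR:
    """Read a pre-stitched per-gene alignment FASTA (rows named by species)."""
    rows: dict[str, str] = {}
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        if rec.id in rows:
            raise ValueError(f"duplicate species {rec.id!r} in {path}")
        rows[rec.id] = str(rec.seq).upper()
    return AlignedUTR(gene_id=gene_id, ref_species=ref_species, rows=rows)


def write_alignment_fasta(aln: AlignedUTR, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for sp, row in aln.rows.items():
            fh.write(f">{sp}\n{row}\n")


def write_predictions(scores, path: str | os.PathLike) -> None:
    """Write a ranked prediction list as TSV.

    Columns: mirna_id, gene_id, c_filter, t_filter, p_word, p_sh, rank.
    Floats use scientific notation with 6+ significant digits so a re-read
    reproduces the values to printed precision.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(PREDICTION_COLUMNS) + "\n")
        for rank, s in enumerate(scores, start=1):
            fh.write(
                f"{s.mirna_id}\t{s.gene_id}\t{s.c_filter}\t{s.t_filter}\t"
                f"{s.p_word:.6e}\t{s.p_sh:.6e}\t{rank}\n"
            )


def read_predictions(path: str | os.PathLike) -> pd.DataFrame:
    """Read a prediction TSV back into a DataFrame (columns as written)."""
    df = pd.read_csv(path, sep="\t", dtype={"mirna_id": str, "gene_id": str})
    missing = [c for c in PREDICTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"prediction table missing columns {missing}")
    return df
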