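"""Site-accessibility classification from windowed unpaired probabilities.

A k-mer window of the 3'UTR is catalogued as accessible if it contains at
least one u-mer (u = 4 by default) that is unpaired in the thermodynamic
ensemble with probability P_free >= P_cutoff (default 0.2, inclusive).  The
P_free values are inputs: they come from windowed partition-function folding
(RNAplfold with -u 4, window W = 80, maximum pairing span L = 40) and are
consumed through its ``_lunp`` per-position table dialect.  The partition
function itself is never recomputed here.

``_lunp`` convention: the table row with first column i (1-based) gives, in
the column for stretch length l, the probability that the l-mer ENDING at
position i is fully unpaired.  Hence the u-mer starting at 0-based s ends at
1-based s + u.  "NA" cells are undefined (positions i < u are always NA);
windows whose contained u-mers are all undefined are classified inaccessible.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PfreeProfile",
    "parse_lunp",
    "write_lunp",
    "window_pfree",
    "is_accessible",
    "accessible_window_mask",
]


@dataclass
class PfreeProfile:
    """Per-position unpaired probabilities for u-mers of one gene's UTR.

    ``p_free[i - 1]`` is the probability that the u-mer ending at 1-based
    position i is fully unpaired; NaN marks undefined entries.  W and L
    record the folding window and maximum pairing span used to produce the
    profile.
    """

    gene_id: str
    u: int
    p_free: np.ndarray  # float array, length == UTR length, NaN = undefined
    window_W: int = 80
    span_L: int = 40

    def __post_init__(self) -> None:
        self.p_free = np.asarray(self.p_free, dtype=float)
        defined = self.p_free[~np.isnan(self.p_free)]
        if defined.size and (defined.min() < 0.0 or defined.max() > 1.0):
            raise ValueError(f"p_free values outside [0, 1] for {self.gene_id!r}")

    @property
    def length(self) -> int:
        return self.p_free.size


def parse_lunp(path: str | os.PathLike, u: int = 4, gene_id: str | None = None,
               window_W: int = 80, span_L: int = 40) -> PfreeProfile:
    """Parse an RNAplfold ``_lunp`` unpaired-probability table.

    The file is a whitespace-separated table whose first column is the
    1-based end position i; comment lines start with '#'.  The column for
    stretch length ``u`` (the (u+1)-th column) is required.  "NA" cells map
    to undefined; any numeric value outside [0, 1] is a hard error.
    """
    if gene_id is None:
        gene_id = os.path.basename(os.fspath(path)).removesuffix("_lunp")
    rows: dict[int, float] = {}
    max_i = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < u + 1:
                raise ValueError(
                    f"{path}:{lineno}: no column for stretch length u={u} "
                    f"(row has {len(fields) - 1} probability columns)"
                )
            i = int(fields[0])
            cell = fields[u]
            if cell == "NA":
                value = np.nan
            else:
                value = float(cell)
                if not 0.0 <= value <= 1.0:
                    raise ValueError(f"{path}:{lineno}: P_free={value} outside [0, 1]")
            rows[i] = value
            max_i = max(max_i, i)
    p_free = np.full(max_i, np.nan)
    for i, value in rows.items():
        p_free[i - 1] = value
    return PfreeProfile(gene_id=gene_id, u=u, p_free=p_free,
                        window_W=window_W, span_L=span_L)


def write_lunp(profile: PfreeProfile, path: str | os.PathLike) -> None:
    """Write a profile in the ``_lunp`` dialect that :func:`parse_lunp` reads.

    Columns for stretch lengths below u are emitted as NA so the u-column
    lands at its conventional index.
    """
    u = profile.u
    with open(path, "w") as fh:
        fh.write("#unpaired probabilities\n")
        fh.write(" #i$\tl=" + "\t".join(str(l) for l in range(1, u + 1)) + "\n")
        for i in range(1, profile.length + 1):
            value = profile.p_free[i - 1]
            cell = "NA" if np.isnan(value) else f"{value:.8g}"
            fh.write("\t".join([str(i)] + ["NA"] * (u - 1) + [cell]) + "\n")


def window_pfree(profile: PfreeProfile, start: int, k: int) -> float:
    """Maximum P_free over the k - u + 1 u-mers contained in the window.

    ``start`` is the 0-based window start.  Undefined entries are skipped;
    if every contained entry is undefined the result is NaN.
    """
    u = profile.u
    if k < u:
        raise ValueError(f"window length k={k} shorter than stretch length u={u}")
    if start < 0 or start + k > profile.length:
        raise ValueError(f"window [{start}, {start + k}) outside sequence of "
                         f"length {profile.length}")
    # u-mers starting at s in [start, start + k - u] end at 1-based s + u.
    contained = profile.p_free[start + u - 1 : start + k]
    if np.all(np.isnan(contained)):
        return float("nan")
    return float(np.nanmax(contained))


def is_accessible(profile: PfreeProfile, start: int, k: int, p_cutoff: float = 0.2) -> bool:
    """True iff the window holds at least one u-mer with P_free >= p_cutoff.

    The comparison is inclusive; an all-undefined window is inaccessible
    (no evidence of accessibility).
    """
    best = window_pfree(profile, start, k)
    return bool(best >= p_cutoff) if not np.isnan(best) else False


def accessible_window_mask(profile: PfreeProfile, k: int, p_cutoff: float = 0.2) -> np.ndarray:
    """Boolean mask over all k-window starts: accessible or not.

    Vectorized equivalent of calling :func:`is_accessible` at every start;
    used by the scoring layer to count accessible windows in one pass.
    """
    u = profile.u
    n = profile.length
    if n < k:
        return np.zeros(0, dtype=bool)
    hit = profile.p_free >= p_cutoff  # NaN compares False
    # Window at start w contains u-mer end indices (0-based into p_free)
    # w + u - 1 .. w + k - 1; accessible iff any hit among them.
    m = k - u + 1
    windows = np.lib.stride_tricks.sliding_window_view(hit[u - 1 :], m)
    return windows[: n - k + 1].any(axis=1)
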