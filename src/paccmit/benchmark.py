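"""Evaluation harness for ranked target predictions.

Implements the construction of balanced positive/negative pair sets, the
three-way "small" dataset splits used for error bars, the ranked-list
metrics (targets per miRNA and precision at a prediction depth, true
positives before the k-th false positive, precision-sensitivity curves),
and the binned mean log2 fold-change analysis relating rank to protein
downregulation.  Significance testing is delegated to scipy (one-sided t
test across small-dataset replicates; one-sided Wilcoxon rank-sum between
log2FC samples).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .conservation import column_map
from .scoring import FilterConfig, InteractionScore, rank_predictions, score_interaction

__all__ = [
    "BenchmarkPair",
    "build_negative_set",
    "split_small_datasets",
    "metrics_at_depth",
    "tp_before_kth_fp",
    "rank_bin_means",
    "precision_sensitivity_curve",
    "label_by_log2fc",
    "read_pairs",
    "write_pairs",
    "read_expression",
    "write_expression",
    "small_dataset_ttest",
    "ranksum_downregulation",
]

logger = logging.getLogger(__name__)

FUNCTIONAL = "functional"
NONFUNCTIONAL = "nonfunctional"

# Training convention: a pair is functional when the protein log2 fold
# change after miRNA perturbation is at most this cutoff.
LOG2FC_FUNCTIONAL_CUTOFF = -0.2


@dataclass(frozen=True)
class BenchmarkPair:
    """A labeled miRNA-gene pair used as ground truth for evaluation."""

    mirna_id: str
    gene_id: str
    label: str

    def __post_init__(self) -> None:
        if self.label not in (FUNCTIONAL, NONFUNCTIONAL):
            raise ValueError(f"label must be {FUNCTIONAL!r} or {NONFUNCTIONAL!r}")


def build_negative_set(
    mirnas: Sequence[str], unbound_genes: Sequence[str], N: int, rng_seed: int
) -> list[BenchmarkPair]:
    """Sample N distinct nonfunctional pairs from miRNAs x unbound genes.

    Uniform without replacement over the Cartesian product, reproducible
    under the seed.  The negative set is built the same size as the positive
    set so precision values spread over (0, 1) instead of piling up at an
    extreme.
    """
    universe = len(mirnas) * len(unbound_genes)
    if N > universe:
        raise ValueError(f"cannot draw {N} pairs from a universe of {universe}")
    rng = np.random.default_rng(rng_seed)
    flat = rng.choice(universe, size=N, replace=False)
    n_genes = len(unbound_genes)
    return [
        BenchmarkPair(mirnas[idx // n_genes], unbound_genes[idx % n_genes], NONFUNCTIONAL)
        for idx in sorted(int(i) for i in flat)
    ]


def split_small_datasets(
    mirnas: Sequence[str],
    n_splits: int = 3,
    rng_seed: int = 0,
    pairs: Optional[Iterable[BenchmarkPair]] = None,
) -> list[dict]:
    """Partition miRNAs into n_splits subgroups of near-equal size.

    Subgroup sizes differ by at most one (74 -> 25/25/24, 26 -> 9/9/8).
    Membership is randomized under the seed and recorded; when labeled
    pairs are supplied, each subgroup also carries the pairs induced by its
    miRNAs.
    """
    if len(mirnas) < n_splits:
        raise ValueError("need at least one miRNA per split")
    rng = np.random.default_rng(rng_seed)
    order = list(mirnas)
    rng.shuffle(order)
    base, extra = divmod(len(order), n_splits)
    groups: list[dict] = []
    cursor = 0
    for i in range(n_splits):
        size = base + (1 if i < extra else 0)
        members = sorted(order[cursor : cursor + size])
        cursor += size
        group = {"mirnas": members}
        if pairs is not None:
            member_set = set(members)
            group["pairs"] = [p for p in pairs if p.mirna_id in member_set]
        groups.append(group)
    return groups


def _label_map(pairs: Iterable[BenchmarkPair]) -> dict[tuple[str, str], str]:
    labels: dict[tuple[str, str], str] = {}
    for p in pairs:
        key = (p.mirna_id, p.gene_id)
        if key in labels:
            raise ValueError(f"duplicate labeled pair {key}")
        labels[key] = p.label
    return labels


def _labeled_ranking(
    ranked: Sequence[InteractionScore], pairs: Iterable[BenchmarkPair]
) -> list[bool]:
    """True/False per ranked labeled prediction; unlabeled pairs are ignored."""
    labels = _label_map(pairs)
    out = []
    for s in ranked:
        label = labels.get((s.mirna_id, s.gene_id))
        if label is not None:
            out.append(label == FUNCTIONAL)
    return out


def metrics_at_depth(
    ranked: Sequence[InteractionScore],
    pairs: Iterable[BenchmarkPair],
    depth_per_mirna: float,
    n_mirnas: int,
    per_mirna: bool = False,
) -> tuple[float, Optional[float]]:
    """(targets per miRNA, precision) among the top predictions.

    The depth axis is normalized by the number of miRNAs: the global
    ranking is cut at depth_per_mirna * n_mirnas predictions (the default),
    or, with per_mirna=True, at depth_per_mirna predictions of each miRNA
    separately.  Precision is None when no labeled prediction falls above
    the cut (undefined: no true or false positives yet).
    """
    if per_mirna:
        taken: list[InteractionScore] = []
        seen: dict[str, int] = {}
        for s in ranked:
            if seen.get(s.mirna_id, 0) < depth_per_mirna:
                taken.append(s)
                seen[s.mirna_id] = seen.get(s.mirna_id, 0) + 1
    else:
        taken = list(ranked[: int(round(depth_per_mirna * n_mirnas))])
    flags = _labeled_ranking(taken, pairs)
    tp = sum(flags)
    fp = len(flags) - tp
    precision = tp / (tp + fp) if flags else None
    return tp / n_mirnas, precision


def tp_before_kth_fp(
    ranked: Sequence[InteractionScore], pairs: Iterable[BenchmarkPair], kth: int
) -> int:
    """True positives preceding the kth false positive in the ranking.

    If fewer than kth false positives occur, every true positive counts.
    """
    if kth < 1:
        raise ValueError("kth must be >= 1")
    fp = tp = 0
    for is_tp in _labeled_ranking(ranked, pairs):
        if is_tp:
            tp += 1
        else:
            fp += 1
            if fp == kth:
                break
    return tp


def precision_sensitivity_curve(
    ranked: Sequence[InteractionScore], pairs: Iterable[BenchmarkPair]
) -> list[tuple[float, float]]:
    """(sensitivity, precision) after each labeled prediction in rank order."""
    pairs = list(pairs)
    flags = _labeled_ranking(ranked, pairs)
    n_pos = sum(1 for p in pairs if p.label == FUNCTIONAL)
    if n_pos == 0:
        raise ValueError("need at least one functional pair")
    curve = []
    tp = 0
    for i, is_tp in enumerate(flags, start=1):
        tp += is_tp
        curve.append((tp / n_pos, tp / i))
    return curve


def rank_bin_means(
    ranked: Sequence[InteractionScore],
    expr: pd.DataFrame,
    scheme: str = "doubling",
    first_size: int = 10,
    bin_size: int = 100,
) -> pd.DataFrame:
    """Mean log2 fold change per rank bin of the prediction list.

    Doubling scheme: bins of sizes first_size, 2*first_size, 4*first_size,
    ... (top 10, next 20, next 40, ...); fixed scheme: constant bin_size.
    Predictions that cannot be joined to the expression table are dropped
    (their count is logged).  Returns one row per bin with the mean, the
    standard error of the mean, and n.
    """
    if scheme not in ("doubling", "fixed"):
        raise ValueError("scheme must be 'doubling' or 'fixed'")
    lookup = {
        (str(r.mirna_id), str(r.gene_id)): float(r.log2fc)
        for r in expr.itertuples(index=False)
    }
    values = []
    dropped = 0
    for s in ranked:
        v = lookup.get((s.mirna_id, s.gene_id))
        if v is None:
            dropped += 1
        else:
            values.append(v)
    if dropped:
        logger.info("rank_bin_means: dropped %d predictions absent from expression", dropped)
    if not values:
        raise ValueError("no ranked prediction joins to the expression table")
    rows = []
    start, size = 0, first_size if scheme == "doubling" else bin_size
    j = 1
    while start < len(values):
        chunk = np.asarray(values[start : start + size])
        sem = float(chunk.std(ddof=1) / np.sqrt(chunk.size)) if chunk.size > 1 else 0.0
        rows.append(
            {"bin": f"A{j}", "mean_log2fc": float(chunk.mean()), "sem": sem, "n": chunk.size}
        )
        start += size
        if scheme == "doubling":
            size *= 2
        j += 1
    return pd.DataFrame(rows)


def label_by_log2fc(expr: pd.DataFrame, cutoff: float = LOG2FC_FUNCTIONAL_CUTOFF) -> list[BenchmarkPair]:
    """Label expression rows: log2FC <= cutoff is functional, else not."""
    return [
        BenchmarkPair(
            str(r.mirna_id),
            str(r.gene_id),
            FUNCTIONAL if float(r.log2fc) <= cutoff else NONFUNCTIONAL,
        )
        for r in expr.itertuples(index=False)
    ]


def small_dataset_ttest(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """One-sided paired t test that metric A exceeds metric B across splits."""
    res = stats.ttest_rel(values_a, values_b, alternative="greater")
    return float(res.pvalue)


def ranksum_downregulation(log2fc_a: Sequence[float], log2fc_b: Sequence[float]) -> float:
    """One-sided Wilcoxon rank-sum: sample A more downregulated than B."""
    res = stats.ranksums(log2fc_a, log2fc_b, alternative="less")
    return float(res.pvalue)


def score_labeled_pairs(
    pairs: Iterable[BenchmarkPair],
    mirnas: dict,
    utrs: dict,
    cfg: FilterConfig,
    profiles: Optional[dict] = None,
    alignments: Optional[dict] = None,
) -> list[InteractionScore]:
    """Score every labeled pair under one filter configuration and rank.

    Column maps are computed once per gene; the evaluation restricts itself
    to the labeled universe, mirroring a benchmark on constructed
    positive/negative sets.
    """
    cmaps: dict[str, object] = {}
    scores = []
    for p in pairs:
        utr = utrs[p.gene_id]
        profile = profiles.get(p.gene_id) if profiles else None
        aln = alignments.get(p.gene_id) if alignments else None
        cmap = None
        if aln is not None and cfg.mode in ("cons", "cons+access"):
            cmap = cmaps.get(p.gene_id)
            if cmap is None:
                cmap = cmaps.setdefault(p.gene_id, column_map(aln))
        scores.append(
            score_interaction(mirnas[p.mirna_id], utr, cfg,
                              profile=profile, aln=aln, cmap=cmap)
        )
    return rank_predictions(scores)


def read_pairs(path) -> list[BenchmarkPair]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [BenchmarkPair(r.mirna_id, r.gene_id, r.label) for r in df.itertuples(index=False)]


def write_pairs(pairs: Iterable[BenchmarkPair], path) -> None:
    with open(path, "w") as fh:
        fh.write("mirna_id\tgene_id\tlabel\n")
        for p in pairs:
            fh.write(f"{p.mirna_id}\t{p.gene_id}\t{p.label}\n")


def read_expression(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"mirna_id": str, "gene_id": str})
    if not np.isfinite(df["log2fc"]).all():
        raise ValueError("expression table contains non-finite log2fc values")
    if df.duplicated(["mirna_id", "gene_id"]).any():
        raise ValueError("expression table has duplicate (mirna_id, gene_id) keys")
    return df


def write_expression(expr: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("mirna_id\tgene_id\tlog2fc\n")
        for r in expr.itertuples(index=False):
            fh.write(f"{r.mirna_id}\t{r.gene_id}\t{float(r.log2fc):.6e}\n")
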