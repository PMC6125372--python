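"""Two-condition expression analysis along the genome.

Intensities are quantile-normalized (all samples forced onto the mean
order-statistic distribution), log2-transformed, screened for outlier
samples by 1 - Pearson correlation distance under Ward clustering, tested
per gene with a Welch two-sample t-test, thresholded at p <= 0.05 and
linear fold change >= 1.5 (no multiple-testing correction by default, a
Benjamini-Hochberg option exists), and summarized as counts of up- and
down-regulated genes in sliding windows of 15 consecutive genes along the
reference gene order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform


@dataclass
class ScanConfig:
    window: int = 15
    p_threshold: float = 0.05
    fc_threshold: float = 1.5
    detection_min_fraction: float = 0.5
    pseudocount: float = 1.0
    adjust: str = "none"  # or "bh"
    outlier_k: float = 2.0

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if not (0.0 < self.p_threshold < 1.0):
            raise ValueError("p_threshold must be in (0, 1)")
        if self.fc_threshold < 1.0:
            raise ValueError("fc_threshold must be >= 1 (linear scale)")
        if self.adjust not in ("none", "bh"):
            raise ValueError("adjust must be 'none' or 'bh'")


@dataclass
class ExpressionMatrix:
    """Genes x samples intensities with per-sample condition labels and a
    per-cell detection flag (array 'present' calls)."""

    values: pd.DataFrame          # genes x samples, float
    conditions: dict[str, str]    # sample_id -> "treatment" | "control"
    detected: pd.DataFrame | None = None  # bool, same shape as values

    def __post_init__(self) -> None:
        for s in self.values.columns:
            if s not in self.conditions:
                raise ValueError(f"sample {s!r} has no condition label")
            if self.conditions[s] not in ("treatment", "control"):
                raise ValueError(
                    f"sample {s!r}: bad condition {self.conditions[s]!r}")
        if self.detected is None:
            self.detected = pd.DataFrame(True, index=self.values.index,
                                         columns=self.values.columns)

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.values.columns
                if self.conditions[s] == condition]

    def drop_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        keep = [s for s in self.values.columns if s not in set(sample_ids)]
        return ExpressionMatrix(
            values=self.values[keep],
            conditions={s: self.conditions[s] for s in keep},
            detected=self.detected[keep])


@dataclass
class DEResult:
    gene_id: str
    log2fc: float
    p_value: float
    call: str  # up | down | ns | undetected


@dataclass
class WindowProfile:
    """Per window (indexed by replicon and first rank): counts of up/down
    calls among the ``window`` consecutive genes starting there."""

    window: int
    table: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: replicon, start_rank, up_count, down_count


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Force every sample onto the mean order-statistic distribution.

    After normalization the sorted value vector of every column is
    identical; ranks within columns are preserved.  Ties within a column
    receive the mean of the reference values at the tied ranks.
    """
    arr = values.to_numpy(dtype=float)
    n, m = arr.shape
    order = np.argsort(arr, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(arr, order, axis=0)
    reference = sorted_vals.mean(axis=1)
    out = np.empty_like(arr)
    for j in range(m):
        out[order[:, j], j] = reference
        # tied input values share the mean reference value of their ranks
        col = arr[:, j]
        uniq, inverse, counts = np.unique(col, return_inverse=True,
                                          return_counts=True)
        if (counts > 1).any():
            sums = np.bincount(inverse, weights=out[:, j])
            out[:, j] = sums[inverse] / counts[inverse]
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def log_transform(values: pd.DataFrame, pseudocount: float = 1.0,
                  ) -> pd.DataFrame:
    """log2(value + pseudocount); rejects negative intensities."""
    if (values.to_numpy() < 0).any():
        raise ValueError("negative intensities cannot be log-transformed")
    return np.log2(values + pseudocount)


def detect_outlier_samples(values: pd.DataFrame, k: float = 2.0) -> list[str]:
    """Outlier samples under 1 - Pearson correlation distance with Ward
    linkage.

    A sample is flagged when it sits alone on one side of the top split of
    the Ward dendrogram AND its mean distance to all other samples exceeds
    mean + k*sd of all pairwise distances.  Needs >= 3 samples.
    """
    samples = list(values.columns)
    if len(samples) < 3:
        raise ValueError("outlier detection needs at least 3 samples")
    corr = np.corrcoef(values.to_numpy(dtype=float), rowvar=False)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    condensed = squareform(dist, checks=False)
    if not condensed.any():
        return []
    linkage = hierarchy.linkage(condensed, method="ward")
    top = hierarchy.fcluster(linkage, t=2, criterion="maxclust")
    flagged = []
    for label in (1, 2):
        side = [i for i, c in enumerate(top) if c == label]
        if len(side) != 1:
            continue
        i = side[0]
        others = [j for j in range(len(samples)) if j != i]
        # margin computed over distances among the remaining samples only;
        # the candidate's own distances would otherwise inflate the spread
        rest = dist[np.ix_(others, others)]
        rest_pairs = rest[np.triu_indices(len(others), k=1)]
        mean_i = dist[i, others].mean()
        if mean_i > rest_pairs.mean() + k * rest_pairs.std():
            flagged.append(samples[i])
    return flagged


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    n = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(n)
    running = 1.0
    for idx in range(n - 1, -1, -1):
        i = order[idx]
        running = min(running, pvals[i] * n / (idx + 1))
        adj[i] = running
    return adj


def differential_expression(matrix: ExpressionMatrix,
                            config: ScanConfig | None = None,
                            ) -> list[DEResult]:
    """Per-gene Welch t-test of treatment vs control on log2 values.

    Assumes ``matrix.values`` is already normalized and log2-transformed.
    A gene detected in fewer than ``detection_min_fraction`` of samples in
    both conditions is reported as ``undetected``.  Zero variance in both
    groups yields p = 1 at equal means (p = 0 at different means).
    """
    config = config or ScanConfig()
    treat = matrix.samples_of("treatment")
    ctrl = matrix.samples_of("control")
    if len(treat) < 2 or len(ctrl) < 2:
        raise ValueError("need >= 2 replicates per condition")
    vt = matrix.values[treat].to_numpy(dtype=float)
    vc = matrix.values[ctrl].to_numpy(dtype=float)
    dt = matrix.detected[treat].to_numpy(dtype=bool)
    dc = matrix.detected[ctrl].to_numpy(dtype=bool)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(vt, vc, axis=1, equal_var=False)
    pvals = np.asarray(res.pvalue, dtype=float)
    lfc = vt.mean(axis=1) - vc.mean(axis=1)
    degenerate = np.isnan(pvals)
    equal_means = np.isclose(lfc, 0.0)
    pvals[degenerate & equal_means] = 1.0
    pvals[degenerate & ~equal_means] = 0.0
    if config.adjust == "bh":
        pvals = _bh_adjust(pvals)
    min_lfc = math.log2(config.fc_threshold)
    undetected = (dt.mean(axis=1) < config.detection_min_fraction) & \
                 (dc.mean(axis=1) < config.detection_min_fraction)
    results = []
    for i, gene in enumerate(matrix.values.index):
        if undetected[i]:
            call = "undetected"
        elif pvals[i] <= config.p_threshold and lfc[i] >= min_lfc:
            call = "up"
        elif pvals[i] <= config.p_threshold and lfc[i] <= -min_lfc:
            call = "down"
        else:
            call = "ns"
        results.append(DEResult(gene_id=str(gene), log2fc=float(lfc[i]),
                                p_value=float(pvals[i]), call=call))
    return results


def sliding_window_profile(de_results: Sequence[DEResult],
                           reference_gene_order: Sequence[tuple[str, str]],
                           config: ScanConfig | None = None) -> WindowProfile:
    """Counts of up/down calls in each window of ``config.window``
    consecutive genes along the reference order (step 1).

    ``reference_gene_order`` lists (replicon_id, gene_id) in rank order;
    windows never cross replicon boundaries, and genes without a DE result
    count as no call.  Replicons shorter than the window contribute no
    windows.
    """
    config = config or ScanConfig()
    call_of = {r.gene_id: r.call for r in de_results}
    by_replicon: dict[str, list[str]] = {}
    order: list[str] = []
    for rep, gene in reference_gene_order:
        if rep not in by_replicon:
            by_replicon[rep] = []
            order.append(rep)
        by_replicon[rep].append(gene)
    rows = []
    w = config.window
    for rep in order:
        genes = by_replicon[rep]
        ups = np.array([call_of.get(g) == "up" for g in genes], dtype=int)
        downs = np.array([call_of.get(g) == "down" for g in genes], dtype=int)
        if len(genes) < w:
            continue
        cum_u = np.concatenate([[0], np.cumsum(ups)])
        cum_d = np.concatenate([[0], np.cumsum(downs)])
        for start in range(len(genes) - w + 1):
            rows.append((rep, start,
                         int(cum_u[start + w] - cum_u[start]),
                         int(cum_d[start + w] - cum_d[start])))
    return WindowProfile(window=w, table=pd.DataFrame(
        rows, columns=["replicon", "start_rank", "up_count", "down_count"]))


def category_summary(de_results: Sequence[DEResult],
                     gene_category: dict[str, str]) -> pd.DataFrame:
    """Per functional category: up/down/ns/undetected counts and the
    up-regulated fraction among DE genes.  Genes missing from the mapping
    fall into ``uncategorized``."""
    tallies: dict[str, dict[str, int]] = {}
    for r in de_results:
        cat = gene_category.get(r.gene_id, "uncategorized")
        t = tallies.setdefault(cat, {"up": 0, "down": 0, "ns": 0,
                                     "undetected": 0})
        t[r.call] += 1
    rows = []
    for cat in sorted(tallies):
        t = tallies[cat]
        n_de = t["up"] + t["down"]
        rows.append((cat, t["up"], t["down"], t["ns"], t["undetected"],
                     round(t["up"] / n_de, 4) if n_de else float("nan")))
    return pd.DataFrame(rows, columns=["category", "n_up", "n_down", "n_ns",
                                       "n_undetected", "frac_up_of_de"])


# ---------------------------------------------------------------------------
# TSV round trip

def write_expression_tsv(path, matrix: ExpressionMatrix,
                         detected_path=None) -> None:
    """Gene x sample TSV with a two-row header (sample ids, conditions);
    detection flags optionally to a parallel TSV."""
    with open(path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(matrix.values.columns) + "\n")
        fh.write("condition\t" + "\t".join(
            matrix.conditions[s] for s in matrix.values.columns) + "\n")
        matrix.values.to_csv(fh, sep="\t", header=False)
    if detected_path is not None:
        matrix.detected.astype(int).to_csv(detected_path, sep="\t")


def read_expression_tsv(path, detected_path=None) -> ExpressionMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cond_row = fh.readline().rstrip("\n").split("\t")
        values = pd.read_csv(fh, sep="\t", header=None, index_col=0,
                             names=header)
    values.index.name = None
    samples = header[1:]
    conditions = dict(zip(samples, cond_row[1:]))
    detected = None
    if detected_path is not None:
        detected = pd.read_csv(detected_path, sep="\t", index_col=0) \
            .astype(bool)
        detected.index.name = None
    return ExpressionMatrix(values=values, conditions=conditions,
                            detected=detected)


def de_results_frame(results: Sequence[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.gene_id, round(r.log2fc, 5), r.p_value, r.call)
         for r in results],
        columns=["gene_id", "log2fc", "p_value", "call"])
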