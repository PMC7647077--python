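"""Stage 3: downstream interpretation of the network tensor and components.

Given per-sample component scores, samples are split into high/low regions
(median split or the N highest vs N lowest). Each region's networks are
collapsed into a binary adjacency over the gene universe (an edge exists if
its coefficient is nonzero in at least one of the region's samples), and
genes are ranked by how many of their incident edges differ between the two
regions — the top-ranked genes are the region-specific markers. Around seed
genes (e.g. EMT transcription factors) the regulatory neighbourhood can be
expanded two hops to build target networks.

Edge strength in a given sample is summarized by the regulatory effect
RE_jla = beta_jl(m_a) * x_aj, and its modulator dependence by the regulatory
effect change REC_jl = max_a RE - min_a RE. PCA of the REC matrix restricted
to the marker genes groups markers with shared modulator-dependent targets.
A Pearson chi-squared test relates region membership to tissue of origin.
"""

from __future__ import annotations

from dataclasses import dataclass
from warnings import warn

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import chi2

from .datasets import ExpressionDataset, NetworkTensor
from .exceptions import DegenerateTableError, InvalidArgumentError


@dataclass
class RegionSplit:
    """High/low sample groups defined on one component's scores."""

    mode: str  # "median" or "top_bottom_N"
    high_ids: list[str]
    low_ids: list[str]
    component: int = 0
    N: int | None = None

    def __post_init__(self):
        if set(self.high_ids) & set(self.low_ids):
            raise InvalidArgumentError("high and low sample sets must be disjoint")


@dataclass
class BinaryAdjacency:
    """Directional target x regulator 0/1 matrix embedded in a square gene universe."""

    matrix: pd.DataFrame  # square, index = columns = gene universe
    region: RegionSplit | None = None

    def __post_init__(self):
        if not self.matrix.index.equals(self.matrix.columns):
            raise InvalidArgumentError("adjacency must be square over one gene universe")
        vals = self.matrix.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise InvalidArgumentError("adjacency entries must be 0 or 1")


def split_samples(scores: pd.Series, mode: str = "median", N: int | None = None,
                  component: int = 0) -> RegionSplit:
    """Partition samples by a component score.

    ``median`` puts samples strictly above the median in the high group and
    the rest in the low group. ``top_bottom_N`` takes the N highest and N
    lowest; boundary ties are broken by ascending sample identifier, so the
    split is reproducible.
    """
    scores = scores.sort_index()  # ascending-ID tie-break baseline
    if mode == "median":
        med = float(scores.median())
        high = scores.index[scores > med]
        low = scores.index[scores <= med]
        if len(high) == 0:
            warn("constant (or heavily tied) scores: median split put every "
                 "sample in the low region", stacklevel=2)
        return RegionSplit(mode="median", high_ids=list(high), low_ids=list(low),
                           component=component)
    if mode == "top_bottom_N":
        if N is None or N < 1:
            raise InvalidArgumentError("top_bottom_N mode requires N >= 1")
        if 2 * N > len(scores):
            raise InvalidArgumentError("N exceeds half the sample count")
        order = scores.reset_index()
        order.columns = ["sample", "score"]
        asc = order.sort_values(["score", "sample"], ascending=[True, True])
        low = asc["sample"].iloc[:N].tolist()
        high = asc["sample"].iloc[-N:].tolist()[::-1]
        return RegionSplit(mode="top_bottom_N", high_ids=high, low_ids=low,
                           component=component, N=N)
    raise InvalidArgumentError(f"unknown split mode {mode!r}")


def gene_universe(tensor: NetworkTensor) -> list[str]:
    """Sorted union of the tensor's target and regulator identifiers."""
    return sorted(set(tensor.target_ids) | set(tensor.regulator_ids))


def binary_adjacency(tensor: NetworkTensor, sample_ids,
                     region: RegionSplit | None = None) -> BinaryAdjacency:
    """OR of the nonzero-coefficient patterns over the listed samples.

    Entry (l, j) of the returned square matrix is 1 iff regulator j has a
    nonzero fitted coefficient on target l in at least one listed sample.
    The matrix is directional (rows = targets, columns = regulators) embedded
    in the square universe of all gene identifiers.
    """
    sample_ids = list(sample_ids)
    if not sample_ids:
        raise InvalidArgumentError("sample_ids must be nonempty")
    idx = tensor.sample_index(sample_ids)
    present = (tensor.coefficients[:, :, idx] != 0).any(axis=2)

    universe = gene_universe(tensor)
    A = pd.DataFrame(0, index=universe, columns=universe, dtype=int)
    A.loc[tensor.target_ids, tensor.regulator_ids] = present.astype(int)
    return BinaryAdjacency(matrix=A, region=region)


def differential_edge_score(A_high: BinaryAdjacency, A_low: BinaryAdjacency,
                            aggregation: str = "incident") -> pd.Series:
    """Per-gene count of edges that differ between two region adjacencies.

    D = |A_high - A_low|; a gene's score sums the differing edges incident to
    it — its row (edges onto it as a target) plus its column (edges out of it
    as a regulator), each differing edge counted once. ``aggregation="row"``
    restricts to the row sum.
    """
    if not A_high.matrix.index.equals(A_low.matrix.index):
        raise InvalidArgumentError("adjacencies are over different gene universes")
    D = (A_high.matrix - A_low.matrix).abs()
    if aggregation == "incident":
        diag = pd.Series(np.diag(D.to_numpy()), index=D.index)
        score = D.sum(axis=1) + D.sum(axis=0) - diag
    elif aggregation == "row":
        score = D.sum(axis=1)
    else:
        raise InvalidArgumentError(f"unknown aggregation {aggregation!r}")
    return score.astype(int)


def top_k_markers(scores: pd.Series, k: int = 10) -> list[str]:
    """The k genes with the largest scores, ties broken by ascending gene ID."""
    if k > len(scores):
        raise InvalidArgumentError("k exceeds the number of genes")
    df = scores.rename("score").rename_axis("gene").reset_index()
    df = df.sort_values(["score", "gene"], ascending=[False, True], kind="mergesort")
    return df["gene"].iloc[:k].tolist()


def expand_target_network(seeds, tensor: NetworkTensor, sample_ids,
                          hops: int = 2) -> list[tuple[str, str]]:
    """Breadth-first expansion of the seeds' regulatory targets.

    Hop 1 collects genes targeted by any seed in at least one listed sample;
    hop 2 collects the targets of those genes; and so on. Returns the
    traversed directed (regulator, target) edges.
    """
    seeds = list(seeds)
    if not seeds:
        raise InvalidArgumentError("seed set must be nonempty")
    if hops < 1:
        raise InvalidArgumentError("hops must be >= 1")
    adj = binary_adjacency(tensor, sample_ids).matrix
    unknown = [s for s in seeds if s not in adj.index]
    if unknown:
        raise InvalidArgumentError(f"seed gene {unknown[0]!r} not in the gene universe")

    G = nx.from_pandas_adjacency(adj.T, create_using=nx.DiGraph)  # regulator -> target
    edges: list[tuple[str, str]] = []
    frontier = set(seeds)
    visited = set(seeds)
    for _ in range(hops):
        nxt = set()
        for u in sorted(frontier):
            for v in sorted(G.successors(u)):
                edges.append((u, v))
                if v not in visited:
                    nxt.add(v)
        visited |= nxt
        frontier = nxt
        if not frontier:
            break
    return edges


def regulatory_effect(tensor: NetworkTensor, data: ExpressionDataset) -> np.ndarray:
    """RE_jla = beta_jl(m_a) * x_aj: realized edge effect per sample.

    Returns a targets x regulators x samples array aligned with the tensor.
    """
    if list(data.sample_ids) != list(tensor.sample_ids):
        raise InvalidArgumentError("tensor and expression samples are misaligned")
    missing = [g for g in tensor.regulator_ids if g not in data.values.index]
    if missing:
        raise InvalidArgumentError(f"regulator {missing[0]!r} missing from expression data")
    X = data.values.loc[tensor.regulator_ids].to_numpy()  # regulators x samples
    return tensor.coefficients * X[None, :, :]


def rec(re: np.ndarray) -> np.ndarray:
    """Regulatory effect change: REC_jl = max_a RE_jla - min_a RE_jla."""
    re = np.asarray(re, dtype=float)
    if re.ndim != 3 or re.shape[2] < 1:
        raise InvalidArgumentError("RE array must be targets x regulators x samples")
    return re.max(axis=2) - re.min(axis=2)


def mean_re_summary(re: np.ndarray, tensor: NetworkTensor, sample_ids,
                    prune_zero_mean: bool = True) -> pd.DataFrame:
    """Average RE over the listed samples, optionally dropping exact-zero rows.

    Returns a long-format frame (target, regulator, mean_re); edges whose
    mean is exactly zero over the listed samples are removed when
    ``prune_zero_mean`` is set.
    """
    sample_ids = list(sample_ids)
    if not sample_ids:
        raise InvalidArgumentError("sample_ids must be nonempty")
    idx = tensor.sample_index(sample_ids)
    mean_re = np.asarray(re, dtype=float)[:, :, idx].mean(axis=2)
    df = pd.DataFrame(mean_re, index=tensor.target_ids, columns=tensor.regulator_ids)
    long = df.stack().rename("mean_re").rename_axis(["target", "regulator"]).reset_index()
    if prune_zero_mean:
        long = long[long["mean_re"] != 0.0].reset_index(drop=True)
    return long


def rec_pca(rec_matrix: pd.DataFrame, marker_genes) -> dict:
    """Column-centered PCA of the REC matrix restricted to the marker columns.

    Observations are target genes, features the (<= 10) marker regulators.
    Returns marker loadings and target scores on the first two components
    plus the variance fractions of all components (non-increasing, summing
    to 1). Component signs are fixed so the largest-magnitude loading is
    positive.
    """
    marker_genes = list(marker_genes)
    if len(marker_genes) < 2:
        raise InvalidArgumentError("need at least 2 marker columns for PCA")
    missing = [g for g in marker_genes if g not in rec_matrix.columns]
    if missing:
        raise InvalidArgumentError(f"marker {missing[0]!r} not a column of the REC matrix")
    M = rec_matrix[marker_genes].to_numpy(dtype=float)
    Mc = M - M.mean(axis=0)
    U, s, Vt = np.linalg.svd(Mc, full_matrices=False)
    total = float(np.sum(s**2))
    if total == 0:
        raise InvalidArgumentError("REC matrix is constant; PCA is undefined")
    var = s**2 / total
    scores = U * s
    loadings = Vt.copy()
    for r in range(loadings.shape[0]):
        jmax = int(np.argmax(np.abs(loadings[r])))
        if loadings[r, jmax] < 0:
            loadings[r] *= -1
            scores[:, r] *= -1
    ncomp = min(2, loadings.shape[0])
    return {
        "loadings": pd.DataFrame(
            loadings[:ncomp].T, index=marker_genes,
            columns=[f"PC{i+1}" for i in range(ncomp)],
        ),
        "scores": pd.DataFrame(
            scores[:, :ncomp], index=rec_matrix.index,
            columns=[f"PC{i+1}" for i in range(ncomp)],
        ),
        "variance_explained": var,
    }


def tissue_association_test(tissue_labels: pd.Series, split: RegionSplit,
                            tissue: str, correction: bool = False):
    """Pearson chi-squared test of region membership against one tissue.

    Builds the 2x2 table {in tissue, not in tissue} x {high, low} over the
    split's samples and computes sum (O-E)^2/E (optionally Yates-corrected).
    Returns ``(statistic, p_value, stars)`` where stars marks p < .01, .001,
    .0001 with two, three or four asterisks.
    """
    members = split.high_ids + split.low_ids
    missing = [s for s in members if s not in tissue_labels.index]
    if missing:
        raise InvalidArgumentError(f"sample {missing[0]!r} has no tissue label")
    in_tissue = tissue_labels.loc[members] == tissue
    is_high = pd.Series([s in set(split.high_ids) for s in members], index=members)
    table = np.array(
        [
            [int((in_tissue & is_high).sum()), int((in_tissue & ~is_high).sum())],
            [int((~in_tissue & is_high).sum()), int((~in_tissue & ~is_high).sum())],
        ],
        dtype=float,
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DegenerateTableError("contingency table has an empty margin")
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    diff = np.abs(table - expected)
    if correction:
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float(np.sum(diff**2 / expected))
    p = float(chi2.sf(stat, df=1))
    stars = "****" if p < 1e-4 else "***" if p < 1e-3 else "**" if p < 1e-2 else ""
    return stat, p, stars
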