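"""Exosome subpopulation discovery: SOM quantization + consensus metaclustering.

The single-exosome profiles of all samples are pooled, downsampled to a fixed
number of exosomes per sample, binarized to presence/absence (with ~2.4
proteins per exosome the counts are near-binary anyway), and quantized with a
batch self-organizing map.  The SOM codebook vectors are then metaclustered
into K subpopulations by consensus clustering: repeated subsampled
average-linkage runs build a co-clustering consensus matrix, and the final
partition is an average-linkage cut of 1 - consensus.  Each exosome inherits
the metacluster of its nearest codebook node; per-sample subpopulation
proportions and per-cluster detection-frequency signatures summarize the
result.  A seeded t-SNE embedding is provided for visualization only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats as st
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_samples, silhouette_score

from .expression import bh_adjust
from .readproc import ExosomeProteinMatrix


@dataclass
class FeatureBlock:
    """Pooled exosome x protein features with sample provenance."""

    X: sp.csr_matrix
    exosome_ids: np.ndarray  # unique ids, "<sample>:<tag>"
    sample_ids: np.ndarray  # per-row sample of origin
    protein_names: list[str]
    transform: str = "counts"

    def __post_init__(self) -> None:
        self.X = sp.csr_matrix(self.X)
        self.exosome_ids = np.asarray(self.exosome_ids)
        self.sample_ids = np.asarray(self.sample_ids)
        n = self.X.shape[0]
        if not (len(self.exosome_ids) == len(self.sample_ids) == n):
            raise ValueError("row annotations must match the feature matrix")

    @property
    def n_exosomes(self) -> int:
        return self.X.shape[0]

    def dense(self) -> np.ndarray:
        return np.asarray(self.X.todense(), dtype=np.float32)


@dataclass
class ClusterModel:
    """SOM codebook plus node -> metacluster map defining subpopulations."""

    grid: tuple[int, int]
    codebook: np.ndarray  # (nodes, P)
    node_metacluster: np.ndarray  # (nodes,) int, 1..K
    k: int
    consensus: np.ndarray | None = None
    seed: int | None = None
    selection: dict | None = None  # auto-K diagnostics, if requested

    def __post_init__(self) -> None:
        labels = np.unique(self.node_metacluster)
        if labels.min() < 1 or labels.max() > self.k:
            raise ValueError("node metacluster labels must lie in 1..K")
        if self.consensus is not None:
            c = self.consensus
            if not np.allclose(c, c.T) or not np.allclose(np.diag(c), 1.0):
                raise ValueError("consensus matrix must be symmetric with "
                                 "unit diagonal")


@dataclass
class SubpopulationTable:
    """Per-sample cluster proportions and per-cluster marker signatures."""

    proportions: pd.DataFrame  # samples x clusters, rows sum to 1
    signatures: pd.DataFrame  # clusters x proteins, detection frequencies
    assignments: pd.Series  # exosome id -> cluster label


def pool_matrices(matrices: Sequence[ExosomeProteinMatrix]) -> FeatureBlock:
    """Stack per-sample matrices into one block with qualified exosome ids."""
    X = sp.vstack([m.counts for m in matrices], format="csr")
    ids = np.concatenate([
        np.array([f"{m.sample_id}:{t}" for t in m.exosome_tags])
        for m in matrices
    ])
    samples = np.concatenate([
        np.full(m.n_exosomes, m.sample_id) for m in matrices
    ])
    return FeatureBlock(X, ids, samples, list(matrices[0].protein_names))


def downsample_exosomes(block: FeatureBlock, n: int = 3000,
                        seed: int | None = None) -> FeatureBlock:
    """Uniform without-replacement downsample to ``n`` exosomes per sample.

    Samples with <= n exosomes are kept whole.  Row order within the block is
    preserved; reproducible under ``seed``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    keep_mask = np.zeros(block.n_exosomes, dtype=bool)
    for sample in pd.unique(block.sample_ids):
        idx = np.flatnonzero(block.sample_ids == sample)
        if idx.size <= n:
            keep_mask[idx] = True
        else:
            keep_mask[rng.choice(idx, size=n, replace=False)] = True
    keep = np.flatnonzero(keep_mask)
    return FeatureBlock(block.X[keep], block.exosome_ids[keep],
                        block.sample_ids[keep], block.protein_names,
                        transform=block.transform)


def binarize_features(block: FeatureBlock) -> FeatureBlock:
    """Presence/absence transform: entry = 1 iff count > 0.  Idempotent."""
    X = block.X.copy()
    X.data = (X.data > 0).astype(np.int8)
    X.eliminate_zeros()
    return FeatureBlock(X, block.exosome_ids, block.sample_ids,
                        block.protein_names, transform="binary")


def log1p_features(block: FeatureBlock) -> FeatureBlock:
    """log(1 + count) transform, the offered alternative to binarization."""
    X = block.X.astype(np.float64).copy()
    X.data = np.log1p(X.data)
    return FeatureBlock(X, block.exosome_ids, block.sample_ids,
                        block.protein_names, transform="log1p")


def normalize_rows(block: FeatureBlock) -> FeatureBlock:
    """L2-normalize each exosome's feature vector.

    On presence/absence profiles this makes Euclidean distances equivalent to
    cosine distances, which matters for sparse single-exosome data: without
    it, diffuse low-norm prototypes sit near the origin and spuriously
    attract every single-protein exosome.
    """
    X = block.X.astype(np.float64).tocsr()
    norms = np.sqrt(np.asarray(X.multiply(X).sum(axis=1)).ravel())
    norms[norms == 0] = 1.0
    X = sp.diags(1.0 / norms) @ X
    return FeatureBlock(X.tocsr(), block.exosome_ids, block.sample_ids,
                        block.protein_names,
                        transform=f"{block.transform}-l2")


# -- self-organizing map -------------------------------------------------


def _bmu(X: np.ndarray, codebook: np.ndarray, chunk: int = 65536) -> np.ndarray:
    """Best-matching unit per row: argmin Euclidean distance to codebook."""
    w2 = (codebook ** 2).sum(axis=1)
    out = np.empty(X.shape[0], dtype=np.int64)
    for start in range(0, X.shape[0], chunk):
        block = X[start:start + chunk]
        d = block @ codebook.T
        d *= -2.0
        d += w2[None, :]
        out[start:start + chunk] = np.argmin(d, axis=1)
    return out


def _pca_plane_init(X: np.ndarray, rows: int, cols: int) -> np.ndarray:
    """Initialize the codebook on the plane of the first two principal
    components, spanning +-2 standard deviations (classic SOM linear init)."""
    mu = X.mean(axis=0)
    Xc = X - mu
    cov = (Xc.T @ Xc) / X.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    sd1, sd2 = np.sqrt(np.maximum(evals[-1], 0)), np.sqrt(np.maximum(evals[-2], 0))
    v1, v2 = evecs[:, -1], evecs[:, -2]
    a = np.linspace(-2.0, 2.0, rows)
    b = np.linspace(-2.0, 2.0, cols)
    return np.array([mu + ai * sd1 * v1 + bj * sd2 * v2 for ai in a for bj in b])


def train_som(
    data: FeatureBlock | np.ndarray,
    grid: tuple[int, int] = (10, 10),
    epochs: int = 20,
    seed: int | None = None,
    sigma_start: float = 3.0,
    sigma_end: float = 0.05,
    init: str = "pca",
) -> np.ndarray:
    """Train a batch self-organizing map; returns the (nodes, P) codebook.

    Gaussian neighborhood on the grid with width shrinking linearly from
    ``sigma_start`` to ``sigma_end`` across epochs.  ``init='pca'`` places the
    initial codebook on the plane of the first two principal components
    (deterministic, well-organized maps); ``init='sample'`` draws distinct
    random data rows.
    """
    X = data.dense() if isinstance(data, FeatureBlock) else \
        np.asarray(data, dtype=np.float32)
    rows, cols = grid
    n_nodes = rows * cols
    if X.shape[0] < n_nodes:
        raise ValueError(
            f"{X.shape[0]} exosomes < {n_nodes} SOM nodes; use a smaller grid"
        )
    Xd = X.astype(np.float64)
    rng = np.random.default_rng(seed)
    if init == "pca":
        codebook = _pca_plane_init(Xd, rows, cols)
    elif init == "sample":
        codebook = Xd[rng.choice(X.shape[0], size=n_nodes, replace=False)].copy()
    else:
        raise ValueError(f"unknown SOM init {init!r}")
    pos = np.array([(i, j) for i in range(rows) for j in range(cols)], dtype=float)
    grid_d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(axis=2)
    for epoch in range(epochs):
        frac = epoch / max(epochs - 1, 1)
        sigma = sigma_start + (sigma_end - sigma_start) * frac
        H = np.exp(-grid_d2 / (2.0 * sigma * sigma))
        bmu = _bmu(Xd, codebook)
        onehot = sp.csr_matrix(
            (np.ones(Xd.shape[0]), (bmu, np.arange(Xd.shape[0]))),
            shape=(n_nodes, Xd.shape[0]),
        )
        sums = onehot @ Xd  # (nodes, P)
        counts = np.asarray(onehot.sum(axis=1)).ravel()
        numer = H @ sums
        denom = H @ counts
        nonzero = denom > 0
        codebook[nonzero] = numer[nonzero] / denom[nonzero, None]
    return codebook


def quantization_error(X: np.ndarray, codebook: np.ndarray) -> float:
    """Mean Euclidean distance of each vector to its best-matching node."""
    bmu = _bmu(np.asarray(X, dtype=np.float64), codebook)
    return float(np.linalg.norm(X - codebook[bmu], axis=1).mean())


# -- consensus metaclustering -------------------------------------------


def _consensus_matrices(
    codebook: np.ndarray,
    ks: Sequence[int],
    n_reps: int,
    subsample: float,
    rng: np.random.Generator,
) -> dict[int, np.ndarray]:
    """Consensus matrix per candidate k from shared subsampled linkage reps."""
    n = codebook.shape[0]
    m = max(2, int(round(subsample * n)))
    hits = {k: np.zeros((n, n)) for k in ks}
    cosampled = np.zeros((n, n))
    for _ in range(n_reps):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        Z = linkage(codebook[idx], method="average", metric="euclidean")
        ix = np.ix_(idx, idx)
        cosampled[ix] += 1
        for k in ks:
            labels = fcluster(Z, t=k, criterion="maxclust")
            hits[k][ix] += labels[:, None] == labels[None, :]
    out = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        for k in ks:
            c = np.where(cosampled > 0, hits[k] / np.maximum(cosampled, 1), 0.0)
            np.fill_diagonal(c, 1.0)
            out[k] = (c + c.T) / 2.0
    return out


def _cut_consensus(consensus: np.ndarray, k: int) -> np.ndarray:
    d = 1.0 - consensus
    np.fill_diagonal(d, 0.0)
    Z = linkage(squareform(d, checks=False), method="average")
    return fcluster(Z, t=k, criterion="maxclust")


def _cdf_area(consensus: np.ndarray) -> float:
    """Area under the consensus CDF over off-diagonal entries.

    Equals 1 - mean(consensus) for values in [0, 1].
    """
    iu = np.triu_indices_from(consensus, k=1)
    return float(1.0 - consensus[iu].mean())


def _pac(consensus: np.ndarray, lower: float = 0.1, upper: float = 0.9) -> float:
    """Proportion of ambiguous clustering: off-diagonal mass in (lower, upper]."""
    iu = np.triu_indices_from(consensus, k=1)
    v = consensus[iu]
    return float(((v > lower) & (v <= upper)).mean())


def metacluster_consensus(
    codebook: np.ndarray,
    k: int = 12,
    n_reps: int = 100,
    subsample: float = 0.8,
    k_range: Sequence[int] | None = None,
    auto_k: bool = False,
    criterion: str = "silhouette",
    node_weights: np.ndarray | None = None,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Group SOM nodes into K metaclusters by consensus clustering.

    Returns (node labels 1..K, consensus matrix at the chosen K, diagnostics).
    With ``auto_k`` the number of clusters is selected over ``k_range`` by the
    requested criterion: 'silhouette' (mean silhouette of the consensus
    partition in codebook space, weighted by ``node_weights`` — typically
    node occupancies — when given; maximized), 'pac' (proportion of ambiguous
    clustering; minimized) or 'delta-area' (relative change in consensus-CDF
    area; maximized).
    """
    n = codebook.shape[0]
    if k > n:
        raise ValueError(f"K={k} exceeds the number of SOM nodes ({n})")
    rng = np.random.default_rng(seed)
    ks = sorted(set(k_range)) if (auto_k and k_range is not None) else (
        list(range(2, min(21, n))) if auto_k else [k]
    )
    consensus_by_k = _consensus_matrices(codebook, ks, n_reps, subsample, rng)

    diagnostics: dict = {"k_range": ks}
    if auto_k:
        w = None if node_weights is None else np.asarray(node_weights, float)
        areas = {kk: _cdf_area(consensus_by_k[kk]) for kk in ks}
        pacs = {kk: _pac(consensus_by_k[kk]) for kk in ks}
        sils = {}
        for kk in ks:
            labels_kk = _cut_consensus(consensus_by_k[kk], kk)
            if len(np.unique(labels_kk)) < 2:
                sils[kk] = -1.0
            elif w is None:
                sils[kk] = float(
                    silhouette_score(codebook, labels_kk, metric="euclidean")
                )
            else:
                s = silhouette_samples(codebook, labels_kk, metric="euclidean")
                sils[kk] = float((s * w).sum() / w.sum())
        deltas = {}
        prev = None
        for kk in ks:
            deltas[kk] = areas[kk] if prev is None else (
                (areas[kk] - areas[prev]) / areas[prev] if areas[prev] > 0 else 0.0
            )
            prev = kk
        if criterion == "silhouette":
            k = max(ks, key=lambda kk: (sils[kk], -kk))
        elif criterion == "pac":
            k = min(ks, key=lambda kk: (pacs[kk], kk))
        elif criterion == "delta-area":
            k = max(ks, key=lambda kk: (deltas[kk], -kk))
        else:
            raise ValueError(f"unknown auto-K criterion {criterion!r}")
        diagnostics.update(
            selected_k=int(k),
            criterion=criterion,
            cdf_area=areas,
            delta_area=deltas,
            pac=pacs,
            silhouette=sils,
        )
    consensus = consensus_by_k[k]
    labels = _cut_consensus(consensus, k)
    return labels.astype(np.int32), consensus, diagnostics


def fit_cluster_model(
    block: FeatureBlock,
    grid: tuple[int, int] = (10, 10),
    k: int = 12,
    epochs: int = 20,
    n_reps: int = 100,
    subsample: float = 0.8,
    auto_k: bool = False,
    k_range: Sequence[int] | None = None,
    criterion: str = "silhouette",
    som_init: str = "pca",
    seed: int | None = None,
) -> ClusterModel:
    """Train the SOM and metacluster its codebook in one call.

    Nodes that no exosome maps to after training are dropped before
    metaclustering: they carry no data and would otherwise form phantom
    clusters in low-density regions of the map.
    """
    rng = np.random.default_rng(seed)
    som_seed = int(rng.integers(0, 2**31 - 1))
    cons_seed = int(rng.integers(0, 2**31 - 1))
    codebook = train_som(block, grid=grid, epochs=epochs, seed=som_seed,
                         init=som_init)
    bmu = _bmu(block.dense().astype(np.float64), codebook)
    occupancy = np.bincount(bmu, minlength=codebook.shape[0]).astype(float)
    codebook = codebook[occupancy > 0]
    weights = occupancy[occupancy > 0] if auto_k else None
    labels, consensus, diag = metacluster_consensus(
        codebook, k=k, n_reps=n_reps, subsample=subsample,
        k_range=k_range, auto_k=auto_k, criterion=criterion,
        node_weights=weights, seed=cons_seed,
    )
    k_used = int(diag.get("selected_k", k))
    return ClusterModel(
        grid=grid, codebook=codebook, node_metacluster=labels,
        k=k_used, consensus=consensus, seed=seed,
        selection=diag if auto_k else None,
    )


# -- assignment and summaries -------------------------------------------


def assign_and_summarize(
    block: FeatureBlock, model: ClusterModel
) -> SubpopulationTable:
    """Assign exosomes to metaclusters and summarize proportions/signatures.

    An exosome's cluster is the metacluster of its nearest codebook node.
    Cluster labels are renumbered by decreasing overall abundance (label 1 =
    largest) for stable reporting.
    """
    X = block.dense().astype(np.float64)
    bmu = _bmu(X, model.codebook)
    raw = model.node_metacluster[bmu]

    observed, counts = np.unique(raw, return_counts=True)
    order = observed[np.argsort(-counts, kind="stable")]
    relabel = {old: new + 1 for new, old in enumerate(order)}
    labels = np.array([relabel[v] for v in raw])
    cluster_ids = sorted(relabel.values())

    assignments = pd.Series(labels, index=block.exosome_ids, name="cluster")
    samples = pd.unique(block.sample_ids)
    prop = np.zeros((len(samples), len(cluster_ids)))
    for i, sample in enumerate(samples):
        sel = labels[block.sample_ids == sample]
        for j, c in enumerate(cluster_ids):
            prop[i, j] = (sel == c).mean() if sel.size else 0.0
    proportions = pd.DataFrame(prop, index=samples, columns=cluster_ids)

    sig = np.zeros((len(cluster_ids), X.shape[1]))
    binary = (X > 0).astype(float)
    for j, c in enumerate(cluster_ids):
        members = binary[labels == c]
        sig[j] = members.mean(axis=0) if members.size else 0.0
    signatures = pd.DataFrame(sig, index=cluster_ids, columns=block.protein_names)
    return SubpopulationTable(proportions, signatures, assignments)


def find_cluster_by_markers(
    table: SubpopulationTable, markers: Sequence[str]
) -> int:
    """Cluster whose signature is most enriched for the given marker set."""
    freq = table.signatures[list(markers)].mean(axis=1)
    return int(freq.idxmax())


def diff_abundance(
    table: SubpopulationTable,
    groups: Mapping[str, str],
    group_a: str,
    group_b: str,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-cluster two-sample t test on per-sample proportions, BH-adjusted."""
    g = pd.Series({s: groups[s] for s in table.proportions.index})
    a_mask, b_mask = g == group_a, g == group_b
    if a_mask.sum() < 3 or b_mask.sum() < 3:
        raise ValueError("each group needs at least 3 samples")
    rows = []
    for c in table.proportions.columns:
        a = table.proportions.loc[a_mask, c].to_numpy()
        b = table.proportions.loc[b_mask, c].to_numpy()
        if np.ptp(np.concatenate([a, b])) == 0:
            p = np.nan
        else:
            p = float(st.ttest_ind(b, a, equal_var=equal_var).pvalue)
        rows.append({
            "cluster": c,
            "mean_a": a.mean(),
            "mean_b": b.mean(),
            "difference": b.mean() - a.mean(),
            "p": p,
        })
    out = pd.DataFrame(rows).set_index("cluster")
    out["q"] = bh_adjust(out["p"])
    out["significant"] = (out["q"] < 0.05) & out["q"].notna()
    return out


def embed_2d(
    block: FeatureBlock, seed: int | None = None, perplexity: float = 30.0
) -> np.ndarray:
    """Seeded 2-D t-SNE embedding for visualization only.

    Deterministic under a fixed seed and inputs; no downstream computation
    consumes the coordinates.
    """
    from sklearn.manifold import TSNE

    X = block.dense().astype(np.float64)
    if X.shape[0] < 3:
        # t-SNE degenerates below a handful of points; return zeros
        return np.zeros((X.shape[0], 2))
    perplexity = min(perplexity, (X.shape[0] - 1) / 3.0)
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        init="pca",
        random_state=None if seed is None else int(seed),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return tsne.fit_transform(X)
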