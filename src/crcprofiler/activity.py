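"""Footprint-based pathway / transcription-factor / kinase activity inference.

The core statistic is the normalized weighted mean: for a regulon (the
signed, weighted target set of a source) with weights ``w`` and a per-gene
molecular statistic ``x`` (a differential-expression contrast or a sample's
scaled expression),

    score(source) = sum_t w_t * x_t / sum_t |w_t|

and the normalized enrichment score (NES) is the z-score of that value
against a null built by permuting the gene labels of ``x``:

    NES = (score - mean_null) / sd_null.

|NES| >= 2 is the significance convention. Pathway scoring restricts each
pathway's weight vector to its ``top_n`` most responsive genes (largest
|weight|) before applying the same statistic. Single-sample gene-set
projection (ssGSEA) ranks a sample's z-score-corrected expression and sums
the difference between the |r|^alpha-weighted in-set ECDF and the uniform
out-of-set ECDF along the ranked list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

NETWORK_COLUMNS = ["source", "target", "weight"]


@dataclass(frozen=True)
class SsgseaParams:
    """Projection parameters (rank-weight exponent, correction, permutations)."""

    alpha: float = 0.75
    correction: str = "z.score"
    n_perm: int = 1000
    min_size: int = 10

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


# ---------------------------------------------------------------------------
# Network handling
# ---------------------------------------------------------------------------

def _resource_set(value) -> set[str]:
    if isinstance(value, (set, frozenset, list, tuple)):
        return set(value)
    return {r.strip() for r in str(value).split(";") if r.strip()}


def filter_kinase_network(edges: pd.DataFrame) -> pd.DataFrame:
    """Clean a signed enzyme-substrate network before activity inference.

    Drops edges supported only by ProtMapper (text-mining derived, retained
    when confirmed by any other resource), keeps only phosphorylation /
    dephosphorylation events, and removes duplicate
    (source, target, modification) records.
    """
    for col in ("source", "target", "resources", "modification"):
        if col not in edges.columns:
            raise KeyError(f"network table lacks column {col!r}")
    res = edges["resources"].map(_resource_set)
    protmapper_only = res.map(lambda s: s == {"ProtMapper"})
    keep_mod = edges["modification"].isin(["phosphorylation", "dephosphorylation"])
    out = edges.loc[~protmapper_only & keep_mod]
    out = out.drop_duplicates(subset=["source", "target", "modification"])
    return out.reset_index(drop=True)


def network_to_matrix(network: pd.DataFrame,
                      genes: pd.Index | list[str]) -> pd.DataFrame:
    """Source x gene weight matrix restricted to ``genes`` (absent -> 0)."""
    for col in NETWORK_COLUMNS:
        if col not in network.columns:
            raise KeyError(f"network table lacks column {col!r}")
    net = network.drop_duplicates(subset=["source", "target"])
    W = (net.pivot(index="source", columns="target", values="weight")
         .reindex(columns=list(genes)).fillna(0.0))
    return W


# ---------------------------------------------------------------------------
# Weighted-mean activity
# ---------------------------------------------------------------------------

def wmean(stat: pd.Series, network: pd.DataFrame,
          min_size: int = 5) -> pd.Series:
    """Per-source |w|-normalized weighted mean of the gene statistic."""
    W = network_to_matrix(network, stat.index)
    n_targets = (W.to_numpy() != 0).sum(axis=1)
    keep = n_targets >= min_size
    if not keep.any():
        warnings.warn("no source has enough measured targets; empty result")
        return pd.Series(dtype=float)
    W = W.loc[keep]
    x = stat.to_numpy(dtype=float)
    Wv = W.to_numpy()
    scores = Wv @ x / np.abs(Wv).sum(axis=1)
    return pd.Series(scores, index=W.index, name="score")


def _nes_from_null(scores: np.ndarray, null: np.ndarray) -> tuple[np.ndarray,
                                                                  np.ndarray]:
    """z-score and two-sided empirical p (+1 smoothing) against a null matrix.

    ``null`` has shape (n_perm, n_sources).
    """
    mean = null.mean(axis=0)
    sd = null.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        nes = np.where(sd > 0, (scores - mean) / sd, np.nan)
    dev = np.abs(scores - mean)
    exceed = (np.abs(null - mean) >= dev - 1e-12).sum(axis=0)
    p = (1.0 + exceed) / (null.shape[0] + 1.0)
    return nes, p


def norm_wmean_matrix(stat: pd.Series, W: pd.DataFrame, n_perm: int = 1000,
                      seed: int = 0, min_size: int = 5) -> pd.DataFrame:
    """Normalized weighted mean for a source x gene weight matrix."""
    n_targets = (W.to_numpy() != 0).sum(axis=1)
    keep = n_targets >= min_size
    if not keep.any():
        warnings.warn("no source has enough measured targets; empty result")
        return pd.DataFrame(columns=["source", "score", "nes", "p_perm",
                                     "n_targets_used"])
    W = W.loc[keep]
    Wv = W.to_numpy()
    norm = np.abs(Wv).sum(axis=1)
    x = stat.reindex(W.columns).fillna(0.0).to_numpy(dtype=float)
    scores = Wv @ x / norm
    rng = np.random.default_rng(seed)
    perm = rng.permuted(np.broadcast_to(x, (n_perm, len(x))).copy(), axis=1)
    null = perm @ Wv.T / norm
    nes, p = _nes_from_null(scores, null)
    if np.isnan(nes).any():
        warnings.warn("zero-variance permutation null for some sources; "
                      "NES left unset")
    return pd.DataFrame({"source": W.index, "score": scores, "nes": nes,
                         "p_perm": p,
                         "n_targets_used": n_targets[keep]}
                        ).reset_index(drop=True)


def norm_wmean(stat: pd.Series, network: pd.DataFrame, n_perm: int = 1000,
               seed: int = 0, min_size: int = 5) -> pd.DataFrame:
    """Normalized weighted mean with permutation NES for an edge-list network."""
    W = network_to_matrix(network, stat.index)
    return norm_wmean_matrix(stat, W, n_perm=n_perm, seed=seed,
                             min_size=min_size)


def pathway_scores(stat: pd.Series, weight_matrix: pd.DataFrame,
                   top_n: int = 100, n_perm: int = 1000, seed: int = 0,
                   min_size: int = 5) -> pd.DataFrame:
    """Pathway activities using each pathway's top responsive genes.

    ``weight_matrix`` is a dense pathway x gene table; per pathway only the
    ``top_n`` genes with the largest |weight| keep their weights, all other
    weights are zeroed, then the normalized weighted mean is applied.
    """
    if top_n < min_size:
        raise ValueError("top_n must be >= min_size")
    W = weight_matrix.reindex(columns=stat.index).fillna(0.0).copy()
    Wv = W.to_numpy()
    if top_n < Wv.shape[1]:
        thresh_idx = np.argsort(np.abs(Wv), axis=1)[:, :-top_n]
        np.put_along_axis(Wv, thresh_idx, 0.0, axis=1)
    W = pd.DataFrame(Wv, index=W.index, columns=W.columns)
    return norm_wmean_matrix(stat, W, n_perm=n_perm, seed=seed,
                             min_size=min_size)


def per_sample_activities(expr: pd.DataFrame, network: pd.DataFrame,
                          n_perm: int = 1000, seed: int = 0,
                          min_size: int = 5,
                          nes_threshold: float = 2.0,
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Source x sample NES matrix from per-gene scaled expression.

    Each gene is z-scored across samples (constant genes dropped); each
    sample's z-vector is the statistic fed to the normalized weighted mean.
    Returns (nes_matrix, significance_mask at |NES| >= ``nes_threshold``).
    The same permutation schedule is reused across samples so columns are
    comparable.
    """
    if expr.shape[1] < 3:
        raise ValueError("per-sample activities need >= 3 samples")
    X = expr.to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=0)
    keep = sd > 0
    if (~keep).any():
        warnings.warn(f"dropping {(~keep).sum()} constant gene row(s)")
    X = X[keep]
    genes = expr.index[keep]
    Z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, ddof=0,
                                                    keepdims=True)
    W = network_to_matrix(network, genes)
    n_targets = (W.to_numpy() != 0).sum(axis=1)
    W = W.loc[n_targets >= min_size]
    if W.empty:
        raise ValueError("no source has enough measured targets")
    Wv = W.to_numpy()
    norm = np.abs(Wv).sum(axis=1)
    rng = np.random.default_rng(seed)
    G = Z.shape[0]
    perm_idx = rng.permuted(
        np.broadcast_to(np.arange(G), (n_perm, G)).copy(), axis=1)
    nes_cols = {}
    for j, sample in enumerate(expr.columns):
        z = Z[:, j]
        scores = Wv @ z / norm
        null = z[perm_idx] @ Wv.T / norm
        nes, _ = _nes_from_null(scores, null)
        nes_cols[sample] = nes
    nes_df = pd.DataFrame(nes_cols, index=W.index)
    return nes_df, nes_df.abs() >= nes_threshold


# ---------------------------------------------------------------------------
# ssGSEA projection
# ---------------------------------------------------------------------------

def _es_sum(w_ranked: np.ndarray, mask_ranked: np.ndarray) -> float:
    """Sum-form enrichment score of one ranked sample for one set mask.

    ``w_ranked`` are |r|^alpha rank weights in ranked order; ``mask_ranked``
    flags in-set genes. ES = sum_i [ P_in(i) - P_out(i) ] with P_in the
    weighted in-set ECDF and P_out the uniform out-of-set ECDF.
    """
    w_in = np.where(mask_ranked, w_ranked, 0.0)
    denom_in = w_in.sum()
    n_out = (~mask_ranked).sum()
    if denom_in == 0 or n_out == 0:
        return np.nan
    p_in = np.cumsum(w_in) / denom_in
    p_out = np.cumsum(~mask_ranked) / n_out
    return float((p_in - p_out).sum())


def ssgsea(expr: pd.DataFrame, gene_sets: dict[str, list[str]],
           params: SsgseaParams | None = None, seed: int = 0,
           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single-sample gene-set projection with permutation p-values.

    Expression is z-score corrected per gene across samples, genes are
    ranked per sample by the corrected value (descending) and each set's
    sum-form ES is computed. Sets overlapping fewer than ``min_size`` genes
    or covering the whole matrix (no out-of-set ECDF) are skipped with a
    warning. p-values come from random same-size gene sets (gene-label
    permutation), two-sided with +1 smoothing.

    Returns (scores, p_values), both set x sample.
    """
    params = params or SsgseaParams()
    genes = expr.index
    X = expr.to_numpy(dtype=float)
    if params.correction == "z.score":
        sd = X.std(axis=1, ddof=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    N = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    masks: dict[str, np.ndarray] = {}
    for name, members in gene_sets.items():
        idx = [gene_pos[g] for g in set(members) if g in gene_pos]
        if len(idx) < params.min_size:
            warnings.warn(f"set {name!r}: overlap {len(idx)} < "
                          f"min size {params.min_size}; skipped")
            continue
        if len(idx) == N:
            warnings.warn(f"set {name!r} covers every gene; skipped")
            continue
        m = np.zeros(N, dtype=bool)
        m[idx] = True
        masks[name] = m
    if not masks:
        return (pd.DataFrame(columns=expr.columns),
                pd.DataFrame(columns=expr.columns))

    rng = np.random.default_rng(seed)
    sizes = sorted({int(m.sum()) for m in masks.values()})
    scores = pd.DataFrame(index=list(masks), columns=expr.columns, dtype=float)
    pvals = pd.DataFrame(index=list(masks), columns=expr.columns, dtype=float)
    for j, sample in enumerate(expr.columns):
        order = np.argsort(-X[:, j], kind="stable")
        w = np.abs(X[order, j]) ** params.alpha
        # null ES per set size from random masks, shared across sets of a size
        null_by_size: dict[int, np.ndarray] = {}
        for m_size in sizes:
            sel = np.zeros((params.n_perm, N), dtype=bool)
            picks = rng.random((params.n_perm, N)).argsort(axis=1)[:, :m_size]
            np.put_along_axis(sel, picks, True, axis=1)
            w_in = np.where(sel, w, 0.0)
            p_in = np.cumsum(w_in, axis=1) / w_in.sum(axis=1, keepdims=True)
            p_out = np.cumsum(~sel, axis=1) / float(N - m_size)
            null_by_size[m_size] = (p_in - p_out).sum(axis=1)
        for name, mask in masks.items():
            es = _es_sum(w, mask[order])
            scores.loc[name, sample] = es
            null = null_by_size[int(mask.sum())]
            mu, sdv = null.mean(), null.std(ddof=1)
            dev = abs(es - mu)
            exceed = int((np.abs(null - mu) >= dev - 1e-12).sum())
            pvals.loc[name, sample] = (1 + exceed) / (params.n_perm + 1)
    return scores, pvals


# ---------------------------------------------------------------------------
# Expression preprocessing and contrast statistic
# ---------------------------------------------------------------------------

def filter_normalize(counts: pd.DataFrame, min_count: int = 10,
                     min_samples: int = 5) -> pd.DataFrame:
    """Nonspecific intensity filter + log2 counts-per-million.

    Keeps genes with >= ``min_count`` reads in >= ``min_samples`` samples,
    then normalizes each sample to counts per million and returns
    log2(CPM + 1).
    """
    X = counts.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("counts must be nonnegative")
    lib = X.sum(axis=0)
    if (lib == 0).any():
        bad = list(counts.columns[lib == 0])
        raise ValueError(f"zero library size for sample(s): {bad}")
    keep = (X >= min_count).sum(axis=1) >= min_samples
    cpm = X[keep] / lib * 1e6
    return pd.DataFrame(np.log2(cpm + 1.0), index=counts.index[keep],
                        columns=counts.columns)


def contrast_statistic(expr: pd.DataFrame, groups: pd.Series) -> pd.Series:
    """Per-gene Welch t statistic, group1 minus group2.

    ``groups`` maps sample -> label; exactly two labels are required, each
    with >= 2 samples. Group1 is the lexicographically smaller label.
    """
    groups = pd.Series(groups)
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    s1 = [s for s in expr.columns if groups.get(s) == labels[0]]
    s2 = [s for s in expr.columns if groups.get(s) == labels[1]]
    if len(s1) < 2 or len(s2) < 2:
        raise ValueError("each group needs >= 2 samples")
    X1 = expr[s1].to_numpy(dtype=float)
    X2 = expr[s2].to_numpy(dtype=float)
    m1, m2 = X1.mean(axis=1), X2.mean(axis=1)
    v1, v2 = X1.var(axis=1, ddof=1), X2.var(axis=1, ddof=1)
    se = np.sqrt(v1 / len(s1) + v2 / len(s2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (m1 - m2) / se, 0.0)
    return pd.Series(t, index=expr.index, name="t")
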