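"""Patient stratification and actionability mapping.

Patients are clustered on their activity profiles with the
hierarchical-clustering-on-principal-components recipe: features are
standardized, PCA retains the smallest number of components reaching the
cumulative explained-variance threshold (default 95%), Ward-linkage
hierarchical clustering runs on the component scores, the cluster count in
[2, max_k] is chosen by the largest relative loss of within-cluster inertia
between successive cuts, and the partition is optionally consolidated by
k-means started from the hierarchical cluster centroids.

Actionability: prioritized variants are matched against a knowledgebase,
keeping only oncogenic / likely-oncogenic records (exact protein-change
records take precedence over gene-level ones) and attaching therapeutic
evidence levels (sensitivity 1-4, resistance R1-R2). Genes carrying
actionable variants map patients to interventional baskets (RME, PAM, DDR,
TK, OTH, DEV, CC); the immune-evasion (IE) basket is assigned on MSI status
and/or high tumor mutational burden.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

ONCOGENIC_LABELS = frozenset({"Oncogenic", "Likely Oncogenic"})
BASKETS = ("RME", "PAM", "DDR", "TK", "OTH", "DEV", "CC")
IE = "IE"


@dataclass
class PatientProfile:
    patient_id: str
    msi_status: str
    tmb: float
    cluster_id: int = 0
    mutated_genes: set[str] = field(default_factory=set)
    baskets: set[str] = field(default_factory=set)


def _within_inertia(scores: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for lab in np.unique(labels):
        pts = scores[labels == lab]
        total += ((pts - pts.mean(axis=0)) ** 2).sum()
    return total


def _choose_k(scores: np.ndarray, Z: np.ndarray, max_k: int) -> int:
    """Cluster count by the largest relative within-inertia gain.

    For successive cuts k = 1..max_k+1 the within-cluster inertia W(k)
    decreases; the chosen k maximizes (W(k-1) - W(k)) / (W(k) - W(k+1)),
    i.e. a large drop reaching k followed by a small one — the inertia-gain
    heuristic used by hierarchical-clustering-on-components tools.
    """
    n = scores.shape[0]
    upper = min(max_k, n - 1)
    ks = list(range(1, upper + 2))
    W = {}
    for k in ks:
        labels = fcluster(Z, t=k, criterion="maxclust")
        W[k] = _within_inertia(scores, labels)
    best_k, best_ratio = 2, -np.inf
    for k in range(2, upper + 1):
        drop_in = W[k - 1] - W[k]
        drop_out = W[k] - W[k + 1]
        ratio = drop_in / drop_out if drop_out > 1e-12 else np.inf
        if ratio > best_ratio:
            best_k, best_ratio = k, ratio
    return best_k


def hcpc_cluster(activities: pd.DataFrame, var_threshold: float = 0.95,
                 max_k: int = 10, consolidate: bool = True, seed: int = 0,
                 n_clusters: int | None = None,
                 ) -> tuple[pd.Series, int]:
    """PCA -> Ward clustering -> (optional) k-means consolidation.

    ``activities`` is a patient x feature matrix. Returns (labels indexed by
    patient, number of retained components). ``n_clusters`` overrides the
    automatic inertia-gain choice.
    """
    if activities.shape[0] < 3:
        raise ValueError("clustering needs >= 3 patients")
    X = activities.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=0)
    if (sd == 0).any():
        warnings.warn(f"dropping {(sd == 0).sum()} constant feature(s)")
        X = X[:, sd > 0]
        sd = sd[sd > 0]
    X = (X - X.mean(axis=0)) / sd
    n_comp_max = min(X.shape)
    pca = PCA(n_components=n_comp_max, svd_solver="full")
    scores_full = pca.fit_transform(X)
    cumvar = np.cumsum(pca.explained_variance_ratio_)
    n_comp = int(np.searchsorted(cumvar, var_threshold - 1e-12) + 1)
    n_comp = min(n_comp, n_comp_max)
    scores = scores_full[:, :n_comp]

    Z = linkage(scores, method="ward")
    k = n_clusters if n_clusters is not None else _choose_k(scores, Z, max_k)
    labels = fcluster(Z, t=k, criterion="maxclust")
    if consolidate and k > 1:
        centroids = np.vstack([scores[labels == lab].mean(axis=0)
                               for lab in range(1, k + 1)])
        km = KMeans(n_clusters=k, init=centroids, n_init=1,
                    random_state=seed)
        labels = km.fit_predict(scores) + 1
    return pd.Series(labels, index=activities.index, name="cluster_id"), n_comp


def significance_mask(nes_matrix: pd.DataFrame,
                      threshold: float = 2.0) -> pd.DataFrame:
    """Boolean mask of significant activities: |NES| >= threshold."""
    return nes_matrix.abs() >= threshold


def actionable_filter(variants: pd.DataFrame, kb: pd.DataFrame) -> pd.DataFrame:
    """Keep variants with an oncogenic / likely-oncogenic knowledgebase match.

    ``kb`` columns: gene, alteration (a protein change, or "any" for
    gene-level records), oncogenicity, therapeutic_level. Exact
    protein-change records take precedence over gene-level "any" records.
    Matched variants get ``oncogenicity`` and ``therapeutic_level`` columns.
    """
    if kb.empty:
        raise ValueError("knowledgebase is empty")
    for col in ("gene", "alteration", "oncogenicity", "therapeutic_level"):
        if col not in kb.columns:
            raise KeyError(f"knowledgebase lacks column {col!r}")
    exact = {(r.gene, r.alteration): r for r in kb.itertuples()
             if r.alteration != "any"}
    generic = {r.gene: r for r in kb.itertuples() if r.alteration == "any"}
    rows = []
    for idx, var in variants.iterrows():
        change = var.get("protein_change", None)
        rec = exact.get((var["gene"], change)) or generic.get(var["gene"])
        if rec is None or rec.oncogenicity not in ONCOGENIC_LABELS:
            continue
        row = var.to_dict()
        row["oncogenicity"] = rec.oncogenicity
        row["therapeutic_level"] = rec.therapeutic_level
        rows.append(row)
    cols = list(variants.columns) + ["oncogenicity", "therapeutic_level"]
    return pd.DataFrame(rows, columns=cols)


def assign_baskets(mutated_genes: set[str], basket_map: pd.DataFrame,
                   msi_status: str, tmb: float,
                   tmb_high: float = 10.0) -> set[str]:
    """Interventional basket labels for one patient.

    The union of the basket labels of the patient's actionable mutated genes
    (genes absent from the map are silently unmapped), plus the
    immune-evasion basket iff the tumor is MSI or its TMB reaches
    ``tmb_high`` mutations/Mb. An empty set means unassigned.
    """
    for col in ("gene", "basket"):
        if col not in basket_map.columns:
            raise KeyError(f"basket map lacks column {col!r}")
    gene_to_basket = dict(zip(basket_map["gene"], basket_map["basket"]))
    baskets = {gene_to_basket[g] for g in mutated_genes if g in gene_to_basket}
    if msi_status == "MSI" or tmb >= tmb_high:
        baskets.add(IE)
    return baskets


def patient_report(profile: PatientProfile,
                   actionable: pd.DataFrame,
                   nes: pd.Series | None = None,
                   nes_threshold: float = 2.0) -> str:
    """Plain-text personalized summary of one patient's profile."""
    lines = [f"Patient {profile.patient_id}",
             f"  MSI status : {profile.msi_status}",
             f"  TMB        : {profile.tmb:.2f} mutations/Mb",
             f"  Cluster    : {profile.cluster_id}",
             f"  Baskets    : {', '.join(sorted(profile.baskets)) or 'none'}"]
    mine = actionable.loc[actionable["patient_id"] == profile.patient_id] \
        if len(actionable) else actionable
    if len(mine):
        lines.append("  Actionable variants:")
        for _, v in mine.iterrows():
            change = v.get("protein_change", "")
            lines.append(f"    {v['gene']} {change} "
                         f"[{v['oncogenicity']}, level {v['therapeutic_level']}]")
    else:
        lines.append("  Actionable variants: none")
    if nes is not None:
        sig = nes[nes.abs() >= nes_threshold]
        if len(sig):
            lines.append("  Significant activities (|NES| >= "
                         f"{nes_threshold:g}):")
            for src, val in sig.sort_values(key=lambda s: -s.abs()).items():
                lines.append(f"    {src}: NES {val:+.2f}")
    return "\n".join(lines)
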