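"""Cohort-level characterization: MSI status, TMB, mutation spectra and
differential mutation-frequency / over-representation statistics.

MSI calls follow the MANTIS-score convention (> 0.6 instable, < 0.4 stable,
otherwise undetermined), MSI-L labels are grouped with MSS throughout, and
tumor mutational burden is protein-altering mutations per megabase of
captured exome. Mutation-frequency differences between MSI and MSS tumors
use a two-sided Fisher exact test per gene with Benjamini-Hochberg
adjustment; pathway over-representation uses the hypergeometric upper tail
and reports the rich factor (hit count over annotated set size).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

MSI = "MSI"
MSS = "MSS"
UNDETERMINED = "Undetermined"

#: Variant classes counted as protein-altering for TMB.
PROTEIN_ALTERING = frozenset({"missense", "stop_gained", "splice_site",
                              "frameshift", "inframe_indel", "stop_loss"})

SPECTRUM_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class TmbValue:
    patient_id: str
    n_protein_altering: int
    capture_mb: float

    @property
    def tmb(self) -> float:
        return self.n_protein_altering / self.capture_mb


def classify_msi_mantis(score: float, msi_above: float = 0.6,
                        mss_below: float = 0.4) -> str:
    """MANTIS-score MSI call: > 0.6 MSI, < 0.4 MSS, else Undetermined."""
    if score < 0:
        raise ValueError(f"MANTIS score must be nonnegative, got {score}")
    if score > msi_above:
        return MSI
    if score < mss_below:
        return MSS
    return UNDETERMINED


def group_msi(labels: pd.Series | list[str]) -> pd.Series:
    """Collapse {MSI-H, MSI-L, MSS} labels into the binary {MSI, MSS}."""
    mapping = {"MSI-H": MSI, "MSI": MSI, "MSI-L": MSS, "MSS": MSS}
    ser = pd.Series(labels)
    unknown = set(ser.unique()) - set(mapping)
    if unknown:
        raise ValueError(f"unknown MSI label(s): {sorted(unknown)}")
    return ser.map(mapping)


def compute_tmb(variants: pd.DataFrame, capture_mb: float = 35.0,
                patients: list[str] | None = None) -> pd.DataFrame:
    """Protein-altering mutations per megabase, per patient.

    ``patients`` fixes the output roster (so zero-mutation patients are
    reported); by default the patients present in the table are used.
    """
    if capture_mb <= 0:
        raise ValueError("capture_mb must be positive")
    if "variant_class" not in variants.columns:
        raise KeyError("variant table lacks 'variant_class' column")
    qual = variants.loc[variants["variant_class"].isin(PROTEIN_ALTERING)]
    counts = qual.groupby("patient_id").size()
    roster = patients if patients is not None else sorted(
        variants["patient_id"].unique())
    n = counts.reindex(roster, fill_value=0)
    return pd.DataFrame({"patient_id": roster,
                         "n_protein_altering": n.to_numpy(),
                         "tmb": n.to_numpy() / capture_mb})


def substitution_spectrum(snvs: pd.DataFrame) -> pd.DataFrame:
    """Per-patient proportions of the six pyrimidine-context substitutions.

    Purine-reference substitutions (G>*, A>*) are complemented to their
    pyrimidine equivalent (so G>A counts as C>T). Non-SNV rows are skipped
    with a warning. Patients without SNVs get an all-NaN row.
    """
    needed = {"patient_id", "ref", "alt"}
    if not needed <= set(snvs.columns):
        raise KeyError(f"SNV table lacks column(s): {sorted(needed - set(snvs.columns))}")
    ref = snvs["ref"].astype(str)
    alt = snvs["alt"].astype(str)
    is_snv = (ref.str.len() == 1) & (alt.str.len() == 1) \
        & ref.isin(list("ACGT")) & alt.isin(list("ACGT")) & (ref != alt)
    if (~is_snv).any():
        warnings.warn(f"skipping {(~is_snv).sum()} non-SNV row(s) in spectrum")
    sub = snvs.loc[is_snv, ["patient_id"]].copy()
    r, a = ref[is_snv], alt[is_snv]
    flip = r.isin(["A", "G"])
    r = r.where(~flip, r.map(_COMPLEMENT))
    a = a.where(~flip, a.map(_COMPLEMENT))
    sub["klass"] = r + ">" + a
    counts = (sub.groupby(["patient_id", "klass"]).size()
              .unstack(fill_value=0)
              .reindex(columns=SPECTRUM_CLASSES, fill_value=0))
    props = counts.div(counts.sum(axis=1), axis=0)
    roster = sorted(snvs["patient_id"].unique())
    return props.reindex(roster)


def compare_mutation_freq(matrix: pd.DataFrame, groups: pd.Series,
                          p_adj_max: float = 0.1,
                          min_mutated: int = 4) -> pd.DataFrame:
    """Per-gene two-sided Fisher test of mutation frequency between groups.

    ``matrix`` is a binary gene x patient table; ``groups`` maps patient ->
    {MSI, MSS}. Genes mutated in fewer than ``min_mutated`` samples overall
    are not tested. Benjamini-Hochberg adjustment runs across the tested
    genes; rows with adjusted p <= ``p_adj_max`` are flagged significant and
    the enriched group (by odds ratio direction) is reported.
    """
    groups = pd.Series(groups)
    patients = [p for p in matrix.columns if p in groups.index]
    groups = groups.loc[patients]
    g1 = [p for p in patients if groups[p] == MSI]
    g2 = [p for p in patients if groups[p] == MSS]
    if not g1 or not g2:
        raise ValueError("both MSI and MSS groups must be nonempty")
    m = matrix[patients].astype(bool)
    rows = []
    for gene in m.index:
        v = m.loc[gene]
        a = int(v[g1].sum())          # mutated, MSI
        b = len(g1) - a               # wild-type, MSI
        c = int(v[g2].sum())          # mutated, MSS
        d = len(g2) - c
        if a + c < min_mutated:
            continue
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append(dict(gene=gene, a=a, b=b, c=c, d=d,
                         odds_ratio=odds, p=p))
    result = pd.DataFrame(rows, columns=["gene", "a", "b", "c", "d",
                                         "odds_ratio", "p"])
    if len(result):
        result["p_adj"] = multipletests(result["p"], method="fdr_bh")[1]
        rate1 = result["a"] / (result["a"] + result["b"])
        rate2 = result["c"] / (result["c"] + result["d"])
        result["enriched_in"] = np.where(rate1 >= rate2, MSI, MSS)
        result["significant"] = result["p_adj"] <= p_adj_max
        result = result.sort_values(["p_adj", "p", "gene"]).reset_index(drop=True)
    else:
        result["p_adj"] = []
        result["enriched_in"] = []
        result["significant"] = []
    return result


def ora_hypergeom(hit_genes: set[str], universe: set[str],
                  gene_sets: dict[str, list[str]],
                  p_adj_max: float = 0.1) -> pd.DataFrame:
    """Hypergeometric over-representation of ``hit_genes`` in each gene set.

    Per set: count = |hits ∩ set ∩ universe|, rich factor = count over the
    set's annotated (in-universe) size, p = upper-tail hypergeometric
    probability of at least ``count`` hits, BH-adjusted across sets.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("gene universe is empty")
    hits = set(hit_genes)
    if not hits <= universe:
        raise ValueError("hit genes must be a subset of the universe")
    N, K = len(universe), len(hits)
    rows = []
    for name, members in gene_sets.items():
        annotated = set(members) & universe
        if not annotated:
            continue
        count = len(hits & annotated)
        n = len(annotated)
        p = float(stats.hypergeom.sf(count - 1, N, K, n))
        rows.append(dict(set=name, count=count, set_size=n,
                         rich_factor=count / n, p=p))
    result = pd.DataFrame(rows, columns=["set", "count", "set_size",
                                         "rich_factor", "p"])
    if len(result):
        result["p_adj"] = multipletests(result["p"], method="fdr_bh")[1]
        result["significant"] = result["p_adj"] <= p_adj_max
        result = result.sort_values(["p_adj", "p", "set"]).reset_index(drop=True)
    else:
        result["p_adj"] = []
        result["significant"] = []
    return result
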