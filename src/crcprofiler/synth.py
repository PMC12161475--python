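"""Synthetic cohorts with recorded ground truth.

Every downstream stage of the pipeline can be exercised without any external
download: this module generates (a) MAF-like somatic variant tables for
mixed MSI/MSS cohorts that differ in mutation count and frameshift
fraction, (b) copy-number segment profiles forward-simulated from a known
(tumor cell content, ploidy, allele-specific copy number) truth with
binomially sampled B-allele fractions, (c) negative-binomial expression
count matrices with planted regulon/pathway activities in a designated
patient group, and (d) small self-consistent knowledgebase, basket-map,
driver-list, transcript-map and gene-set fixtures.

Mutation rates default to the cohort medians the generator emulates (about
1250 protein-altering variants per MSI tumor versus about 110 per MSS
tumor), and MSI tumors receive an elevated frameshift fraction. All
generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cnaploidy import expected_baf, expected_log2ratio

# ---------------------------------------------------------------------------
# Gene universe
# ---------------------------------------------------------------------------

#: Curated colorectal-cancer driver genes used for fixtures and variant genes.
DRIVER_GENES = (
    "APC", "TP53", "KRAS", "BRAF", "NRAS", "HRAS", "GNAS", "SMAD2", "SMAD3",
    "SMAD4", "PIK3CA", "PTEN", "TSC2", "AKT1", "MTOR", "ATM", "BRCA1",
    "BRCA2", "RAD50", "CHEK2", "PALB2", "ERBB2", "ERBB3", "EGFR", "NTRK1",
    "RET", "ALK", "FBXW7", "TCF7L2", "SOX9", "ARID1A", "RNF43", "ACVR2A",
    "TGFBR2", "BCL9L", "PTPRC", "MSH3", "MSH6", "MLH1", "POLE", "CTNNB1",
    "KMT2C", "KMT2D", "AMER1", "MAP2K1", "CDKN2A", "CDK4", "CCND1",
)

_BASKET_OF = {
    "KRAS": "RME", "BRAF": "RME", "NRAS": "RME", "HRAS": "RME",
    "MAP2K1": "RME",
    "PIK3CA": "PAM", "PTEN": "PAM", "TSC2": "PAM", "AKT1": "PAM",
    "MTOR": "PAM",
    "ATM": "DDR", "BRCA1": "DDR", "BRCA2": "DDR", "RAD50": "DDR",
    "CHEK2": "DDR", "PALB2": "DDR",
    "ERBB2": "TK", "ERBB3": "TK", "EGFR": "TK", "NTRK1": "TK", "RET": "TK",
    "ALK": "TK",
    "APC": "DEV", "CTNNB1": "DEV", "RNF43": "DEV", "SOX9": "DEV",
    "TCF7L2": "DEV",
    "CDKN2A": "CC", "CDK4": "CC", "CCND1": "CC",
    "GNAS": "OTH", "ARID1A": "OTH", "FBXW7": "OTH",
}

_VARIANT_CLASSES = ("missense", "stop_gained", "splice_site", "frameshift",
                    "inframe_indel", "other")
#: Class frequencies emulating protein-altering calls in MSS tumors
#: (missense-dominated) and the frameshift-enriched MSI phenotype.
_CLASS_P_MSS = (0.845, 0.058, 0.016, 0.069, 0.006, 0.006)
_CLASS_P_MSI = (0.655, 0.055, 0.015, 0.250, 0.015, 0.010)

_CLASS_TO_SO = {"missense": "missense_variant",
                "stop_gained": "stop_gained",
                "splice_site": "splice_acceptor_variant",
                "frameshift": "frameshift_variant",
                "inframe_indel": "inframe_deletion",
                "other": "synonymous_variant"}

_AA = "ACDEFGHIKLMNPQRSTVWY"


def gene_pool(n_genes: int) -> list[str]:
    """Gene universe: curated drivers padded with synthetic gene symbols."""
    pool = list(DRIVER_GENES)
    pool += [f"G{i:04d}" for i in range(1, n_genes - len(pool) + 1)]
    return pool[:n_genes]


@dataclass
class CohortTruth:
    """Per-patient ground truth recorded by the generators."""

    patient_id: str
    msi_status_true: str
    tcc_true: float = 1.0
    ploidy_true: float = 2.0
    planted_activities: dict[str, float] = field(default_factory=dict)
    n_mutations_true: int = 0

    def __post_init__(self):
        if not (0.05 < self.tcc_true <= 1.0):
            raise ValueError("tcc_true must lie in (0.05, 1.0]")
        if not (1.0 <= self.ploidy_true <= 6.5):
            raise ValueError("ploidy_true must lie in [1, 6.5]")


# ---------------------------------------------------------------------------
# Variant tables
# ---------------------------------------------------------------------------

def gen_variant_table(n_patients: int, msi_fraction: float = 0.25,
                      rate_msi: float = 1257.0, rate_mss: float = 108.0,
                      seed: int = 0, n_genes: int = 400,
                      evidence_support_p: float = 0.30,
                      full_support_frac: float = 0.4,
                      beta_params: tuple[float, float] = (8.0, 2.0),
                      confidence_p: tuple[float, ...] = (
                          0.01, 0.01, 0.01, 0.02, 0.02, 0.03, 0.05,
                          0.25, 0.3, 0.3),
                      ) -> tuple[pd.DataFrame, list[CohortTruth]]:
    """MAF-like somatic variant table for a mixed MSI/MSS cohort.

    MSI patients draw Poisson(``rate_msi``) variants with an elevated
    frameshift fraction; MSS patients draw Poisson(``rate_mss``). Each row
    carries a caller confidence (1-10), gene, genomic change, protein
    change, consequence annotation and the four evidence sub-scores (a
    category is supported with probability ``evidence_support_p``; a
    supported category is fully supported (1.0) with probability
    ``full_support_frac``, otherwise Beta(*beta_params*)-distributed).
    """
    if n_patients <= 0:
        raise ValueError("n_patients must be positive")
    if not (0 <= msi_fraction <= 1):
        raise ValueError("msi_fraction must lie in [0, 1]")
    if not (rate_msi > rate_mss > 0):
        raise ValueError("rates must satisfy rate_msi > rate_mss > 0")
    rng = np.random.default_rng(seed)
    patients = [f"P{i + 1:03d}" for i in range(n_patients)]
    n_msi = int(round(n_patients * msi_fraction))
    msi_idx = set(rng.choice(n_patients, size=n_msi, replace=False).tolist())
    genes = gene_pool(n_genes)
    bases = np.array(list("ACGT"))
    rows = []
    truths = []
    for i, pid in enumerate(patients):
        is_msi = i in msi_idx
        n_var = int(rng.poisson(rate_msi if is_msi else rate_mss))
        truths.append(CohortTruth(patient_id=pid,
                                  msi_status_true="MSI" if is_msi else "MSS",
                                  n_mutations_true=n_var))
        if n_var == 0:
            continue
        gidx = rng.integers(0, len(genes), size=n_var)
        klass = rng.choice(_VARIANT_CLASSES, size=n_var,
                           p=_CLASS_P_MSI if is_msi else _CLASS_P_MSS)
        conf = rng.choice(np.arange(1, 11), size=n_var, p=confidence_p)
        refs = bases[rng.integers(0, 4, size=n_var)]
        alts = bases[(rng.integers(1, 4, size=n_var)
                      + np.searchsorted(bases, refs)) % 4]
        pos = rng.integers(1, 2_000_000, size=n_var)
        chrom = rng.integers(1, 23, size=n_var).astype(str)
        aa1 = rng.choice(list(_AA), size=n_var)
        aa2 = rng.choice(list(_AA), size=n_var)
        ppos = rng.integers(1, 1200, size=n_var)
        supported = rng.random((n_var, 4)) < evidence_support_p
        values = np.where(rng.random((n_var, 4)) < full_support_frac, 1.0,
                          rng.beta(*beta_params, size=(n_var, 4)))
        ev = np.where(supported, values, 0.0)
        for k in range(n_var):
            rows.append((pid, genes[gidx[k]], chrom[k], int(pos[k]),
                         refs[k], alts[k], klass[k], int(conf[k]),
                         f"p.{aa1[k]}{ppos[k]}{aa2[k]}",
                         ev[k, 0], ev[k, 1], ev[k, 2], ev[k, 3]))
    df = pd.DataFrame(rows, columns=[
        "patient_id", "gene", "chrom", "pos", "ref", "alt", "variant_class",
        "confidence", "protein_change", "ev_pathogenicity", "ev_cancer",
        "ev_clinical", "ev_expression"])
    return df, truths


# ---------------------------------------------------------------------------
# Segment profiles
# ---------------------------------------------------------------------------

def default_cn_profile(ploidy: float) -> list[tuple[int, int, int]]:
    """A 20-segment (cA, cB, length_bp) profile for a given target ploidy.

    Profiles mix balanced states with strongly imbalanced (LOH) states and
    include odd total copy numbers so that harmonic purity/ploidy
    degeneracies cannot fit the data exactly.
    """
    mb = 1_000_000
    if ploidy <= 2.5:
        states = [(1, 1)] * 9 + [(2, 0)] * 4 + [(3, 0)] * 2 + [(2, 2)] * 3 \
            + [(4, 2)] * 2
        lengths = [15 * mb] * 9 + [6 * mb] * 11
    elif ploidy <= 3.5:
        states = [(2, 2)] * 6 + [(3, 0)] * 4 + [(2, 0)] * 3 + [(4, 2)] * 4 \
            + [(1, 1)] * 2 + [(4, 0)] * 1
        lengths = [12 * mb] * 6 + [7 * mb] * 14
    else:
        states = [(2, 2)] * 8 + [(4, 2)] * 4 + [(3, 0)] * 3 + [(5, 0)] * 2 \
            + [(4, 4)] * 3
        lengths = [12 * mb] * 8 + [7 * mb] * 12
    return [(a, b, ln) for (a, b), ln in zip(states, lengths)]


def gen_segment_profile(tcc: float, ploidy: float,
                        cn_profile: list[tuple[int, int, int]] | None = None,
                        depth: float = 100.0, n_snps_per_segment: int = 30,
                        seed: int = 0, noiseless: bool = False,
                        coverage_noise_sd: float = 0.0,
                        ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Forward-simulate a segment table + SNP table from a known CN profile.

    Per segment the coverage log2 ratio follows the purity/ploidy coverage
    model (plus optional Gaussian noise) and each het SNP draws its tumor
    allele fraction binomially at the expected (unfolded) B-allele
    fraction, the alternative allele landing on the major or minor
    haplotype with equal probability. ``noiseless=True`` emits exact
    expected values. Returns (segments, snps, truth).
    """
    if not (0 < tcc <= 1):
        raise ValueError("tcc must lie in (0, 1]")
    if depth <= 0:
        raise ValueError("depth must be positive")
    cn_profile = cn_profile if cn_profile is not None else default_cn_profile(ploidy)
    for cA, cB, _ in cn_profile:
        if cB < 0 or cA < cB or int(cA) != cA or int(cB) != cB:
            raise ValueError("cn_profile entries need integer cA >= cB >= 0")
    rng = np.random.default_rng(seed)
    seg_rows, snp_rows = [], []
    start = 1  # 1-based inclusive coordinates in emitted tables
    for idx, (cA, cB, length) in enumerate(cn_profile):
        ct = cA + cB
        end = start + length - 1
        l2r = expected_log2ratio(ct, tcc, ploidy)
        if not noiseless and coverage_noise_sd > 0:
            l2r += rng.normal(0.0, coverage_noise_sd)
        seg_rows.append(("1", start, end, l2r))
        positions = np.linspace(start, end, n_snps_per_segment).astype(int)
        on_major = rng.random(n_snps_per_segment) < 0.5
        for j, posn in enumerate(positions):
            c_alt = cA if on_major[j] else cB
            af_exp = (tcc * c_alt + (1 - tcc)) / (tcc * ct + 2 * (1 - tcc))
            if noiseless:
                af_t, af_n = af_exp, 0.5
            else:
                af_t = rng.binomial(int(depth), af_exp) / depth
                af_n = rng.binomial(int(depth), 0.5) / depth
            snp_rows.append(("1", int(posn), af_n, af_t, depth))
        start = end + 1
    segments = pd.DataFrame(seg_rows,
                            columns=["chrom", "start", "end", "log2ratio"])
    snps = pd.DataFrame(snp_rows,
                        columns=["chrom", "pos", "af_normal", "af_tumor",
                                 "depth"])
    truth = {"tcc": tcc, "ploidy": ploidy,
             "segments": [(a, b) for a, b, _ in cn_profile],
             "expected_baf": [expected_baf(a, b, tcc)
                              for a, b, _ in cn_profile]}
    return segments, snps, truth


# ---------------------------------------------------------------------------
# Regulon networks and expression
# ---------------------------------------------------------------------------

def gen_regulon_network(n_sources: int = 15, n_targets: int = 30,
                        genes: list[str] | None = None, n_genes: int = 2000,
                        seed: int = 0, positive_frac: float = 0.8,
                        ) -> pd.DataFrame:
    """Random signed regulon network (source, target, weight +-1, metadata)."""
    rng = np.random.default_rng(seed)
    genes = genes if genes is not None else gene_pool(n_genes)
    resources = np.array(["PhosphoSitePlus", "SIGNOR", "ProtMapper"])
    rows = []
    for s in range(n_sources):
        targets = rng.choice(len(genes), size=n_targets, replace=False)
        signs = np.where(rng.random(n_targets) < positive_frac, 1.0, -1.0)
        for t, w in zip(targets, signs):
            res = ";".join(sorted(rng.choice(
                resources, size=rng.integers(1, 3), replace=False)))
            rows.append((f"TF{s + 1:02d}", genes[t], float(w), res,
                         "phosphorylation"))
    return pd.DataFrame(rows, columns=["source", "target", "weight",
                                       "resources", "modification"])


def gen_expression_matrix(n_patients: int, network: pd.DataFrame,
                          planted: dict[str, float] | None = None,
                          n_genes: int = 2000, seed: int = 0,
                          group: np.ndarray | None = None,
                          dispersion: float = 0.2,
                          ) -> tuple[pd.DataFrame, dict]:
    """Negative-binomial count matrix with planted regulon activities.

    Background: per-gene lognormal means, NB counts at the given
    dispersion. For each planted source with effect ``delta``, the mean of
    every target gene is scaled by ``2 ** (delta * weight)`` in the
    designated patient group (default: the first half of the cohort).
    Returns (gene x sample counts, truth dict).
    """
    planted = planted or {}
    if n_patients <= 0:
        raise ValueError("n_patients must be positive")
    sources = set(network["source"])
    unknown = set(planted) - sources
    if unknown:
        raise ValueError(f"planted source(s) not in network: {sorted(unknown)}")
    genes = gene_pool(n_genes)
    missing = set(network["target"]) - set(genes)
    if missing:
        raise ValueError("n_genes smaller than the network's target space")
    rng = np.random.default_rng(seed)
    samples = [f"P{i + 1:03d}" for i in range(n_patients)]
    if group is None:
        group = np.arange(n_patients) < (n_patients + 1) // 2
    group = np.asarray(group, dtype=bool)
    mu = rng.lognormal(mean=4.0, sigma=1.0, size=n_genes)
    lfc = np.zeros(n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for src, delta in planted.items():
        sub = network.loc[network["source"] == src]
        for t, w in zip(sub["target"], sub["weight"]):
            lfc[gene_pos[t]] += delta * float(w)
    mu_mat = mu[:, None] * np.where(group[None, :], 2.0 ** lfc[:, None], 1.0)
    r = 1.0 / dispersion
    p = r / (r + mu_mat)
    counts = rng.negative_binomial(r, p)
    df = pd.DataFrame(counts, index=genes, columns=samples)
    truth = {"planted": dict(planted), "group": group.copy(),
             "samples": samples}
    return df, truth


def gen_pathway_weights(n_pathways: int = 8, genes: list[str] | None = None,
                        n_genes: int = 2000, seed: int = 0,
                        n_responsive: int = 150) -> pd.DataFrame:
    """Dense pathway x gene weight matrix emulating responsive-gene footprints.

    Each pathway has ``n_responsive`` genes with non-negligible weights
    (decaying magnitudes, mostly positive); all other weights are tiny
    noise, so restricting to the top responsive genes is meaningful.
    """
    rng = np.random.default_rng(seed)
    genes = genes if genes is not None else gene_pool(n_genes)
    W = rng.normal(0.0, 0.01, size=(n_pathways, len(genes)))
    for pth in range(n_pathways):
        idx = rng.choice(len(genes), size=n_responsive, replace=False)
        mags = np.sort(rng.gamma(2.0, 0.5, size=n_responsive))[::-1] + 0.2
        signs = np.where(rng.random(n_responsive) < 0.85, 1.0, -1.0)
        W[pth, idx] = mags * signs
    return pd.DataFrame(W, index=[f"PW{p + 1:02d}" for p in range(n_pathways)],
                        columns=genes)


# ---------------------------------------------------------------------------
# Knowledgebase fixtures
# ---------------------------------------------------------------------------

def gen_fixtures(seed: int = 0, genes: list[str] | None = None,
                 n_sets: int = 15, set_size_range: tuple[int, int] = (10, 40),
                 ) -> dict:
    """Small self-consistent knowledgebase / basket / driver / MANE / GMT
    fixtures over the gene universe.

    Every basket label appears at least once, at least one gene carries the
    oncogenicity label "Unknown" (exercising the actionability exclusion),
    and all gene sets have at least 10 members.
    """
    rng = np.random.default_rng(seed)
    genes = genes if genes is not None else gene_pool(2000)
    levels = ["1", "2", "3", "4", "R1", "R2", "none"]
    onco = ["Oncogenic", "Likely Oncogenic", "Unknown"]
    kb_rows = []
    for i, g in enumerate(DRIVER_GENES):
        label = onco[0] if i % 3 == 0 else (onco[1] if i % 3 == 1 else onco[2])
        level = levels[i % len(levels)]
        kb_rows.append((g, "any", label, level))
    # exact protein-change records with highest evidence
    kb_rows.append(("BRAF", "p.V600E", "Oncogenic", "1"))
    kb_rows.append(("KRAS", "p.G12C", "Oncogenic", "1"))
    kb = pd.DataFrame(kb_rows, columns=["gene", "alteration", "oncogenicity",
                                        "therapeutic_level"])
    basket_map = pd.DataFrame(sorted(_BASKET_OF.items()),
                              columns=["gene", "basket"])
    drivers = sorted(DRIVER_GENES)
    mane_rows = []
    for g in genes[:600]:
        mane_rows.append((g, f"T_{g}.1", int(rng.integers(800, 6000)), True))
        mane_rows.append((g, f"T_{g}.2", int(rng.integers(500, 4000)), False))
    mane = pd.DataFrame(mane_rows, columns=["gene", "transcript",
                                            "length_bp", "mane_select"])
    gene_sets = {}
    for s in range(n_sets):
        size = int(rng.integers(set_size_range[0], set_size_range[1] + 1))
        members = rng.choice(len(genes), size=size, replace=False)
        gene_sets[f"SET_{s + 1:02d}"] = sorted(genes[j] for j in members)
    return {"knowledgebase": kb, "basket_map": basket_map,
            "drivers": drivers, "mane": mane, "gene_sets": gene_sets}


# ---------------------------------------------------------------------------
# Whole-cohort simulation
# ---------------------------------------------------------------------------

def gen_cohort(n_patients: int = 30, msi_fraction: float = 0.25,
               seed: int = 0, n_genes: int = 2000,
               rate_msi: float = 1257.0, rate_mss: float = 108.0,
               planted_delta: float = 2.0,
               n_planted_sources: int = 3) -> dict:
    """Simulate everything one pipeline run needs, with ground truth.

    MSI patients form the perturbed expression group: ``n_planted_sources``
    regulons get a planted activity of ``planted_delta`` in MSI tumors.
    Each patient also receives a purity/ploidy truth, a forward-simulated
    segment profile and a MANTIS-like instability score consistent with the
    MSI truth.
    """
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=6)
    variants, truths = gen_variant_table(
        n_patients, msi_fraction, rate_msi=rate_msi, rate_mss=rate_mss,
        seed=int(sub[0]), n_genes=min(400, n_genes))
    genes = gene_pool(n_genes)
    network = gen_regulon_network(genes=genes, seed=int(sub[1]))
    pathway_w = gen_pathway_weights(genes=genes, seed=int(sub[2]))
    fixtures = gen_fixtures(seed=int(sub[3]), genes=genes)
    is_msi = np.array([t.msi_status_true == "MSI" for t in truths])
    planted = {f"TF{i + 1:02d}": planted_delta
               for i in range(n_planted_sources)}
    counts, expr_truth = gen_expression_matrix(
        n_patients, network, planted=planted, n_genes=n_genes,
        seed=int(sub[4]), group=is_msi)
    # MANTIS-like scores consistent with truth
    mantis = np.where(is_msi, 0.65 + 0.25 * rng.beta(2, 2, n_patients),
                      0.05 + 0.30 * rng.beta(2, 2, n_patients))
    ploidies = np.array([2.0, 3.0, 4.0])
    seg_tables, snp_tables = {}, {}
    for i, t in enumerate(truths):
        t.planted_activities = dict(planted) if is_msi[i] else {}
        t.tcc_true = float(np.round(rng.uniform(0.30, 0.95), 2))
        t.ploidy_true = float(rng.choice(ploidies))
        segs, snps, _ = gen_segment_profile(
            t.tcc_true, t.ploidy_true, seed=int(rng.integers(0, 2**31 - 1)))
        seg_tables[t.patient_id] = segs
        snp_tables[t.patient_id] = snps
    patient_table = pd.DataFrame({
        "patient_id": [t.patient_id for t in truths],
        "mantis_score": np.round(mantis, 4),
        "msi_status_true": [t.msi_status_true for t in truths],
        "tcc_true": [t.tcc_true for t in truths],
        "ploidy_true": [t.ploidy_true for t in truths],
    })
    return {"variants": variants, "truths": truths,
            "patients": patient_table, "counts": counts,
            "network": network, "pathway_weights": pathway_w,
            "fixtures": fixtures, "planted": planted,
            "segments": seg_tables, "snps": snp_tables}
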