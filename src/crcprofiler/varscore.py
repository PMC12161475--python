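"""Evidence-aggregation scoring and prioritization of somatic variants.

Each annotated variant carries four evidence sub-scores in [0, 1]:

* ``ev_pathogenicity`` — variant-effect prediction support,
* ``ev_cancer``        — cancer knowledge-base support,
* ``ev_clinical``      — clinical relevance support,
* ``ev_expression``    — whether the affected gene is expressed in the cohort
  (>= 10 read counts in at least 5 samples -> 1, else 0).

The aggregate score is a weighted arithmetic mean of the four sub-scores
(equal weights by default), so with binary evidence it equals the fraction of
supported categories and the >= 0.5 cutoff keeps exactly the variants with at
least two of four categories supported. Downstream, the affected transcript
is chosen by MANE membership first, then highest predicted consequence
impact, then transcript length, and prioritized genes are intersected with a
curated driver-gene list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

EVIDENCE_COLUMNS = ["ev_pathogenicity", "ev_cancer", "ev_clinical", "ev_expression"]

#: Consequence impact ranking (highest first). Editable: pass a custom
#: ordering to :func:`select_transcript` to change precedence.
SO_IMPACT_ORDER: tuple[str, ...] = (
    "transcript_ablation",
    "stop_gained",
    "frameshift_variant",
    "stop_lost",
    "start_lost",
    "splice_acceptor_variant",
    "splice_donor_variant",
    "splice_site_variant",
    "missense_variant",
    "inframe_insertion",
    "inframe_deletion",
    "protein_altering_variant",
    "splice_region_variant",
    "synonymous_variant",
    "intron_variant",
)


@dataclass(frozen=True)
class EvidenceProfile:
    """The four per-category evidence sub-scores of one variant."""

    pathogenicity: float
    cancer: float
    clinical: float
    expression: float

    def __post_init__(self):
        for name, v in self.as_dict().items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"evidence sub-score {name}={v} outside [0, 1]")

    def as_dict(self) -> dict[str, float]:
        return {
            "pathogenicity": self.pathogenicity,
            "cancer": self.cancer,
            "clinical": self.clinical,
            "expression": self.expression,
        }

    @property
    def categories_supported(self) -> int:
        """Number of categories with any support (sub-score > 0)."""
        return sum(v > 0 for v in self.as_dict().values())


@dataclass(frozen=True)
class SvracasScore:
    value: float
    categories_supported: int


def filter_confidence(variants: pd.DataFrame, min_conf: int = 8) -> pd.DataFrame:
    """Keep variants called with confidence >= ``min_conf`` (of 10)."""
    if "confidence" not in variants.columns:
        raise KeyError("variant table has no 'confidence' column")
    return variants.loc[variants["confidence"] >= min_conf].copy()


def expression_evidence(counts: pd.DataFrame, gene: str,
                        min_count: int = 10, min_samples: int = 5) -> int:
    """1 if ``gene`` has >= ``min_count`` reads in >= ``min_samples`` samples.

    A gene absent from the matrix scores 0 (not expressed as far as the
    cohort shows).
    """
    if gene not in counts.index:
        return 0
    row = counts.loc[gene]
    return int((np.asarray(row) >= min_count).sum() >= min_samples)


def svracas_score(profile: EvidenceProfile,
                  weights: tuple[float, float, float, float] = (1, 1, 1, 1),
                  ) -> SvracasScore:
    """Weighted mean of the four evidence sub-scores, in [0, 1]."""
    w = np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise ValueError("evidence weights must be nonnegative")
    if w.sum() <= 0:
        raise ValueError("evidence weights must not all be zero")
    subs = np.array([profile.pathogenicity, profile.cancer,
                     profile.clinical, profile.expression])
    value = float((w * subs).sum() / w.sum())
    return SvracasScore(value=value,
                        categories_supported=profile.categories_supported)


def score_table(variants: pd.DataFrame,
                weights: tuple[float, float, float, float] = (1, 1, 1, 1),
                ) -> pd.DataFrame:
    """Vectorized scoring: adds ``svracas_score`` and ``n_categories`` columns."""
    missing = [c for c in EVIDENCE_COLUMNS if c not in variants.columns]
    if missing:
        raise KeyError(f"variant table lacks evidence column(s): {missing}")
    w = np.asarray(weights, dtype=float)
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("weights must be nonnegative with positive sum")
    sub = variants[EVIDENCE_COLUMNS].to_numpy(dtype=float)
    if ((sub < 0) | (sub > 1)).any():
        raise ValueError("evidence sub-scores must lie in [0, 1]")
    out = variants.copy()
    out["svracas_score"] = (sub * w).sum(axis=1) / w.sum()
    out["n_categories"] = (sub > 0).sum(axis=1)
    return out


def prioritize(variants: pd.DataFrame, cutoff: float = 0.5) -> pd.DataFrame:
    """Keep variants with aggregate score >= ``cutoff`` (default 0.5)."""
    if "svracas_score" not in variants.columns:
        raise ValueError("variants must be scored before prioritization "
                         "(missing 'svracas_score')")
    if variants["svracas_score"].isna().any():
        raise ValueError("svracas_score is unset on some rows")
    return variants.loc[variants["svracas_score"] >= cutoff].copy()


def select_transcript(consequences: dict[str, str],
                      mane_map: dict[str, str] | None = None,
                      lengths: dict[str, int] | None = None,
                      gene: str | None = None,
                      impact_order: tuple[str, ...] = SO_IMPACT_ORDER,
                      ) -> str:
    """Pick the representative aberrant transcript for a variant.

    Precedence: the gene's MANE Select transcript if it is among the
    annotated transcripts; otherwise the transcript whose consequence term
    has the highest impact, ties broken by the longest transcript, then by
    lexicographic id. Unknown consequence terms are warned about and ranked
    below all known terms.
    """
    if not consequences:
        raise ValueError("consequences mapping is empty")
    if mane_map and gene is not None:
        mane_tx = mane_map.get(gene)
        if mane_tx is not None and mane_tx in consequences:
            return mane_tx
    rank = {term: i for i, term in enumerate(impact_order)}
    worst = len(impact_order)

    def key(tx: str):
        term = consequences[tx]
        r = rank.get(term)
        if r is None:
            warnings.warn(f"unknown consequence term {term!r}; ranking lowest")
            r = worst
        length = (lengths or {}).get(tx, 0)
        return (r, -length, tx)

    return min(consequences, key=key)


def map_drivers(genes: set[str] | list[str],
                driver_list: set[str] | list[str]) -> list[str]:
    """Deterministically sorted intersection with a curated driver-gene list."""
    return sorted(set(genes) & set(driver_list))
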