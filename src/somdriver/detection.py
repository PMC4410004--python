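"""Detection step: score cohort genes against a reference model.

For every cohort gene with at least one non-silent mutation and a model
entry, two upper-tail binomial probabilities are computed on
correction-weighted counts:

* ``pOG`` — probability that at least the observed number of OG mutations
  fall on reference hotspots, given the gene's hotspot density
  ``p_h = n_hotspots / CDS length``;
* ``pTSG`` — probability of at least the observed number of truncating
  mutations among all mutations, given the neutral nonsense probability
  ``p_n = 23/549`` from the genetic-code enumeration.

Each probability list is Benjamini–Hochberg adjusted across the tested
genes; the combined driver statistic is ``qDG = qOG * qTSG`` and a gene
is a putative driver at ``qDG <= alpha``.  Drivers are classified by the
ratiometric 20/20-style scores: TSG when the truncating proportion is
>= 20%, else OG when the hotspot-located proportion is >= 20%, else
unclassified (a truncating signal overrides clustering, since a specific
missense can inactivate a TSG but truncation rarely activates a gene).
"""

from __future__ import annotations

import logging
import warnings
from enum import Enum

import numpy as np
import pandas as pd

from .genetic_code import STANDARD_CODE, CodonMutationTable
from .reference import GeneMutationProfile, ReferenceGene, ReferenceModel, aggregate_profiles
from .stats import bh_adjust, binom_upper_tail

logger = logging.getLogger(__name__)

#: Minimum score (percent) for an OG or TSG classification.
SCORE_THRESHOLD = 20.0

RESULT_COLUMNS = [
    "gene",
    "n_og",
    "n_tsg",
    "k_hog",
    "p_og",
    "p_tsg",
    "q_og",
    "q_tsg",
    "q_dg",
    "og_score",
    "tsg_score",
    "call",
]


class Call(str, Enum):
    OG = "OG"
    TSG = "TSG"
    DRIVER_UNCLASSIFIED = "DRIVER_UNCLASSIFIED"
    NOT_SIGNIFICANT = "NOT_SIGNIFICANT"


def _hotspot_hits(profile: GeneMutationProfile, ref: ReferenceGene) -> int:
    """Raw count of cohort OG mutations located at reference hotspots."""
    positions = ref.hotspot_positions
    return sum(c for pos, c in profile.position_counts.items() if pos in positions)


def compute_p_og(profile: GeneMutationProfile, ref: ReferenceGene) -> tuple[float, int]:
    """Hotspot-clustering probability for one gene.

    Returns ``(p_og, k_hog_raw)`` where ``k_hog_raw`` is the uncorrected
    number of cohort OG mutations at reference hotspot positions.  Both
    the hit count and the total are weighted by ``f_OG`` before the
    binomial tail is taken at ``p_h = n_hotspots / CDS length``.
    """
    k_raw = _hotspot_hits(profile, ref)
    if not ref.hotspots or ref.cds_length <= 0:
        return 1.0, k_raw
    p_h = len(ref.hotspots) / ref.cds_length
    k_corr = k_raw * ref.f_og
    n_corr = profile.n_og * ref.f_og
    if k_corr <= 0:
        return 1.0, k_raw
    return binom_upper_tail(k_corr, n_corr, min(p_h, 1.0)), k_raw


def compute_p_tsg(
    profile: GeneMutationProfile,
    ref: ReferenceGene,
    code: CodonMutationTable = STANDARD_CODE,
) -> float:
    """Truncation-excess probability for one gene.

    Tests the corrected truncating count against the neutral nonsense
    probability ``p_n`` among all (corrected) non-silent mutations.
    """
    k_corr = profile.n_tsg * ref.f_tsg
    n_corr = profile.n_tot * ref.f_tsg
    if k_corr <= 0:
        return 1.0
    return binom_upper_tail(k_corr, n_corr, code.p_nonsense)


def compute_scores(
    profile: GeneMutationProfile,
    ref: ReferenceGene,
    corrected: bool = False,
) -> tuple[float, float]:
    """20/20-style classification scores on a 0–100 percent scale.

    OG score = share of OG mutations located at reference hotspots;
    TSG score = share of truncating mutations among all mutations.  Raw
    counts by default (the ratiometric rule uses observed proportions);
    ``corrected=True`` weighs them by the correction factors instead.
    """
    k_h: float = _hotspot_hits(profile, ref)
    n_og: float = profile.n_og
    n_tsg: float = profile.n_tsg
    if corrected:
        k_h, n_og = k_h * ref.f_og, n_og * ref.f_og
        n_tsg = n_tsg * ref.f_tsg
    n_tot = n_og + n_tsg
    og_score = 100.0 * k_h / n_og if n_og > 0 else 0.0
    tsg_score = 100.0 * n_tsg / n_tot if n_tot > 0 else 0.0
    return og_score, tsg_score


def classify_gene(
    og_score: float,
    tsg_score: float,
    q_dg: float,
    alpha: float = 0.05,
) -> Call:
    """Apply the driver threshold and the 20/20 classification rule."""
    if q_dg > alpha:
        return Call.NOT_SIGNIFICANT
    if tsg_score >= SCORE_THRESHOLD:
        return Call.TSG
    if og_score >= SCORE_THRESHOLD:
        return Call.OG
    return Call.DRIVER_UNCLASSIFIED


def run_detection(
    cohort: pd.DataFrame,
    model: ReferenceModel,
    alpha: float = 0.05,
    code: CodonMutationTable = STANDARD_CODE,
    corrected_scores: bool = False,
) -> pd.DataFrame:
    """Score every testable cohort gene and rank by the driver statistic.

    Parameters
    ----------
    cohort
        Mutation table as returned by :func:`somdriver.io.read_maf`.
    model
        Reference model from the first step.
    alpha
        Driver significance threshold on ``qDG``.

    Returns
    -------
    pandas.DataFrame
        One row per tested gene with columns :data:`RESULT_COLUMNS`,
        sorted by ascending ``q_dg`` (gene symbol breaks ties).

    Raises
    ------
    ValueError
        If no cohort gene has a model entry.
    """
    cds_lengths = {g.gene: g.cds_length for g in model.genes.values()}
    profiles, _ = aggregate_profiles(cohort, cds_lengths)
    if not profiles:
        raise ValueError("no overlap between cohort genes and the reference model")

    rows = []
    for gene in sorted(profiles):
        profile = profiles[gene]
        if profile.n_tot == 0:
            continue  # silent-only genes are not tested
        ref = model.get(gene)
        p_og, k_hog = compute_p_og(profile, ref)
        p_tsg = compute_p_tsg(profile, ref, code)
        og_score, tsg_score = compute_scores(profile, ref, corrected=corrected_scores)
        rows.append(
            {
                "gene": gene,
                "n_og": profile.n_og,
                "n_tsg": profile.n_tsg,
                "k_hog": k_hog,
                "p_og": p_og,
                "p_tsg": p_tsg,
                "og_score": og_score,
                "tsg_score": tsg_score,
            }
        )
    if not rows:
        raise ValueError("cohort contains no genes with non-silent mutations")

    results = pd.DataFrame(rows)
    results["q_og"] = bh_adjust(results["p_og"].to_numpy())
    results["q_tsg"] = bh_adjust(results["p_tsg"].to_numpy())
    results["q_dg"] = results["q_og"] * results["q_tsg"]
    results["call"] = [
        classify_gene(r.og_score, r.tsg_score, r.q_dg, alpha).value
        for r in results.itertuples(index=False)
    ]
    results = results.sort_values(
        ["q_dg", "gene"], ascending=[True, True], kind="mergesort"
    ).reset_index(drop=True)
    return results[RESULT_COLUMNS]


def benchmark_enrichment(
    results: pd.DataFrame,
    benchmark_genes: set[str] | frozenset[str],
    top_k: int,
) -> float:
    """Fraction of the ``top_k`` ranked genes present in a benchmark list.

    ``results`` must be sorted by ascending ``q_dg`` (as returned by
    :func:`run_detection`).  When fewer than ``top_k`` rows exist all rows
    are used and a warning is emitted.
    """
    if not benchmark_genes:
        raise ValueError("benchmark gene set is empty")
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if len(results) < top_k:
        warnings.warn(
            f"only {len(results)} ranked genes available for top_k={top_k}",
            stacklevel=2,
        )
    top = results["gene"].head(top_k)
    if len(top) == 0:
        return 0.0
    return float(np.mean([g in benchmark_genes for g in top]))
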