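"""Reference step: per-gene background correction factors and hotspots.

From a large reference mutation table (COSMIC-like), two things are
learned per gene:

* **Correction factors** ``f_OG`` and ``f_TSG`` in [0, 1] that down-weight
  genes whose silent-mutation load indicates a high background mutation
  rate.  Each factor is ``1 - observed/expected`` silent ratio, where the
  expected silent-to-missense and silent-to-nonsense ratios come from the
  exhaustive enumeration of the genetic code (134/392 and 134/23), clamped
  to zero when negative.
* **Hotspots** — CDS nucleotide positions where missense/in-frame (OG)
  mutations recur across samples more than expected under a uniform
  per-position model, assessed with an upper-tail binomial test at
  ``p_l = 1 / CDS length`` on correction-weighted counts.

The resulting :class:`ReferenceModel` is what the detection step consumes
and is persisted as two plain TSVs plus a metadata header.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .genetic_code import STANDARD_CODE, CodonMutationTable
from .io import Category, atomic_write
from .stats import binom_upper_tail

logger = logging.getLogger(__name__)

#: Minimum raw recurrence for a position to qualify as a hotspot.  A
#: singleton mutation is never "clustering", even when its tail
#: probability dips under alpha at small n.
MIN_CLUSTER_SIZE = 2


@dataclass
class GeneMutationProfile:
    """Per-gene aggregated mutation counts.

    ``position_counts`` maps CDS position -> OG-mutation count and only
    includes records with a parseable, in-range position, so its total can
    be smaller than ``n_og``.
    """

    gene: str
    cds_length: int
    n_sil: int = 0
    n_og: int = 0
    n_tsg: int = 0
    position_counts: dict[int, int] = field(default_factory=dict)

    @property
    def n_tot(self) -> int:
        return self.n_og + self.n_tsg


@dataclass(frozen=True)
class CorrectionFactors:
    """Background-correction weights, both clamped to [0, 1]."""

    f_og: float
    f_tsg: float


@dataclass(frozen=True)
class Hotspot:
    """A significantly recurrent CDS position."""

    cds_pos: int
    raw_count: int
    p_value: float


@dataclass(frozen=True)
class ReferenceGene:
    """Reference-step output for one gene."""

    gene: str
    cds_length: int
    f_og: float
    f_tsg: float
    n_sil: int
    n_og: int
    n_tsg: int
    hotspots: tuple[Hotspot, ...] = ()

    @property
    def hotspot_positions(self) -> frozenset[int]:
        return frozenset(h.cds_pos for h in self.hotspots)


@dataclass
class ReferenceModel:
    """Serializable container of per-gene reference information."""

    genes: dict[str, ReferenceGene]
    alpha: float = 0.05
    metadata: dict[str, str] = field(default_factory=dict)

    def get(self, gene: str) -> ReferenceGene | None:
        return self.genes.get(gene)

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def n_hotspots(self) -> int:
        return sum(len(g.hotspots) for g in self.genes.values())

    def genes_frame(self) -> pd.DataFrame:
        rows = [
            (g.gene, g.cds_length, g.f_og, g.f_tsg, g.n_sil, g.n_og, g.n_tsg)
            for g in sorted(self.genes.values(), key=lambda g: g.gene)
        ]
        return pd.DataFrame(
            rows,
            columns=["gene", "cds_length", "f_og", "f_tsg", "n_sil", "n_og", "n_tsg"],
        )

    def hotspots_frame(self) -> pd.DataFrame:
        rows = [
            (g.gene, h.cds_pos, h.raw_count, h.p_value)
            for g in sorted(self.genes.values(), key=lambda g: g.gene)
            for h in sorted(g.hotspots, key=lambda h: h.cds_pos)
        ]
        return pd.DataFrame(rows, columns=["gene", "cds_pos", "raw_count", "p_value"])

    def save(self, directory: str | Path) -> None:
        """Persist as ``genes.tsv``, ``hotspots.tsv`` and ``metadata.txt``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with atomic_write(directory / "genes.tsv") as handle:
            self.genes_frame().to_csv(handle, sep="\t", index=False)
        with atomic_write(directory / "hotspots.tsv") as handle:
            self.hotspots_frame().to_csv(handle, sep="\t", index=False)
        with atomic_write(directory / "metadata.txt") as handle:
            handle.write(f"format_version\t1\nalpha\t{self.alpha!r}\n")
            for key, value in sorted(self.metadata.items()):
                handle.write(f"{key}\t{value}\n")

    @classmethod
    def load(cls, directory: str | Path) -> "ReferenceModel":
        directory = Path(directory)
        genes_path = directory / "genes.tsv"
        if not genes_path.exists():
            raise FileNotFoundError(f"not a reference model directory: {directory}")
        genes_df = pd.read_csv(genes_path, sep="\t", float_precision="round_trip")
        hs_df = pd.read_csv(
            directory / "hotspots.tsv", sep="\t", float_precision="round_trip"
        )
        metadata: dict[str, str] = {}
        alpha = 0.05
        meta_path = directory / "metadata.txt"
        if meta_path.exists():
            for line in meta_path.read_text().splitlines():
                if "\t" not in line:
                    continue
                key, value = line.split("\t", 1)
                if key == "alpha":
                    alpha = float(value)
                elif key != "format_version":
                    metadata[key] = value
        by_gene: dict[str, list[Hotspot]] = {}
        for row in hs_df.itertuples(index=False):
            by_gene.setdefault(row.gene, []).append(
                Hotspot(int(row.cds_pos), int(row.raw_count), float(row.p_value))
            )
        genes = {
            row.gene: ReferenceGene(
                gene=row.gene,
                cds_length=int(row.cds_length),
                f_og=float(row.f_og),
                f_tsg=float(row.f_tsg),
                n_sil=int(row.n_sil),
                n_og=int(row.n_og),
                n_tsg=int(row.n_tsg),
                hotspots=tuple(by_gene.get(row.gene, ())),
            )
            for row in genes_df.itertuples(index=False)
        }
        return cls(genes=genes, alpha=alpha, metadata=metadata)


def aggregate_profiles(
    mutations: pd.DataFrame,
    cds_lengths: Mapping[str, int],
) -> tuple[dict[str, GeneMutationProfile], int]:
    """Aggregate a mutation table into per-gene profiles.

    Genes without a CDS length are dropped; the count of dropped genes is
    returned alongside the profiles.
    """
    profiles: dict[str, GeneMutationProfile] = {}
    n_dropped = 0
    for gene, sub in mutations.groupby("gene", sort=True):
        length = cds_lengths.get(gene)
        if length is None:
            n_dropped += 1
            continue
        counts = sub["category"].value_counts()
        og_positions = sub.loc[
            (sub["category"] == Category.OG.value) & sub["pos_valid"], "cds_pos"
        ]
        profiles[str(gene)] = GeneMutationProfile(
            gene=str(gene),
            cds_length=int(length),
            n_sil=int(counts.get(Category.SILENT.value, 0)),
            n_og=int(counts.get(Category.OG.value, 0)),
            n_tsg=int(counts.get(Category.TSG.value, 0)),
            position_counts={
                int(pos): int(cnt) for pos, cnt in og_positions.value_counts().items()
            },
        )
    if n_dropped:
        logger.warning("%d gene(s) without a CDS length were dropped", n_dropped)
    return profiles, n_dropped


def _ratio_factor(n_sil: int, n_events: int, expected_ratio: float) -> float:
    # Limits of 1 - (n_sil/n_events)/expected as the observed ratio
    # degenerates: no events and no silent -> no evidence of elevated
    # background (1); silent but no events -> ratio diverges (0).
    if n_events == 0:
        return 1.0 if n_sil == 0 else 0.0
    return max(0.0, 1.0 - (n_sil / n_events) / expected_ratio)


def compute_correction_factors(
    profile: GeneMutationProfile,
    code: CodonMutationTable = STANDARD_CODE,
) -> CorrectionFactors:
    """Background-correction factors from observed vs expected silent ratios."""
    return CorrectionFactors(
        f_og=_ratio_factor(profile.n_sil, profile.n_og, code.expected_sil_to_mis),
        f_tsg=_ratio_factor(profile.n_sil, profile.n_tsg, code.expected_sil_to_non),
    )


def detect_hotspots(
    profile: GeneMutationProfile,
    factors: CorrectionFactors,
    alpha: float = 0.05,
) -> tuple[Hotspot, ...]:
    """Call recurrently mutated CDS positions for one gene.

    A position with raw OG count ``k >= 2`` is a hotspot when
    ``P(X >= k * f_OG) <= alpha`` for
    ``X ~ Binomial(n_OG * f_OG, 1 / CDS length)``.
    """
    if profile.cds_length <= 0:
        logger.warning("gene %s has non-positive CDS length; skipped", profile.gene)
        return ()
    p_l = 1.0 / profile.cds_length
    n_corr = profile.n_og * factors.f_og
    hotspots = []
    for pos in sorted(profile.position_counts):
        raw = profile.position_counts[pos]
        if raw < MIN_CLUSTER_SIZE:
            continue
        k_corr = raw * factors.f_og
        if k_corr <= 0:
            continue
        p_value = binom_upper_tail(k_corr, n_corr, p_l)
        if p_value <= alpha:
            hotspots.append(Hotspot(cds_pos=pos, raw_count=raw, p_value=p_value))
    return tuple(hotspots)


def build_reference(
    mutations: pd.DataFrame,
    cds_lengths: Mapping[str, int],
    alpha: float = 0.05,
    code: CodonMutationTable = STANDARD_CODE,
    source: str = "",
) -> ReferenceModel:
    """Run the full reference step.

    Every gene in ``cds_lengths`` receives a model entry; genes absent
    from the mutation table keep the neutral defaults ``f_OG = f_TSG = 1``
    and an empty hotspot set (absence of reference data is not evidence of
    a high background rate).

    Raises
    ------
    ValueError
        If the mutation table is empty.
    """
    if mutations is None or len(mutations) == 0:
        raise ValueError("reference mutation table is empty")
    profiles, n_dropped = aggregate_profiles(mutations, cds_lengths)
    genes: dict[str, ReferenceGene] = {}
    for gene, length in cds_lengths.items():
        profile = profiles.get(gene, GeneMutationProfile(gene=gene, cds_length=length))
        factors = compute_correction_factors(profile, code)
        hotspots = detect_hotspots(profile, factors, alpha)
        genes[gene] = ReferenceGene(
            gene=gene,
            cds_length=int(length),
            f_og=factors.f_og,
            f_tsg=factors.f_tsg,
            n_sil=profile.n_sil,
            n_og=profile.n_og,
            n_tsg=profile.n_tsg,
            hotspots=hotspots,
        )
    metadata = {
        "source": source,
        "build_date": datetime.date.today().isoformat(),
        "n_records": str(len(mutations)),
        "n_genes_dropped_no_cds_length": str(n_dropped),
    }
    return ReferenceModel(genes=genes, alpha=alpha, metadata=metadata)
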