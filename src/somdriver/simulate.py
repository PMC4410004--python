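"""Synthetic somatic-mutation cohorts with planted driver genes.

Emulates the mutation patterns the method is built to detect:

* **neutral genes** — passenger mutations only; silent : missense :
  nonsense counts follow the neutral codon-space proportions
  134 : 392 : 23 (taken from the genetic-code enumeration, so neutral
  genes have correction factors concentrated near zero) at positions
  uniform over the CDS;
* **planted oncogene-like genes** — few silent mutations, with a stated
  fraction of missense mutations concentrated on a handful of fixed
  hotspot positions;
* **planted tumour-suppressor-like genes** — a stated fraction of
  protein-truncating mutations (nonsense and frameshift) spread
  uniformly along the gene.

Per-gene background mutation rates are drawn from a log-normal
distribution to mimic the wide mutation-rate heterogeneity of real
genomes.  All randomness flows from a single integer seed; the reference
table and the cohort MAF use independent substreams of that seed, so the
two datasets share gene properties (CDS length, rate, hotspot positions)
but have independent mutation draws — exactly the two-step setting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genetic_code import STANDARD_CODE
from .io import atomic_write

_SNV_BASES = np.array(list("ACGT"))

# Variant_Classification strings emitted per simulated consequence.
_CLASS_SILENT = "Silent"
_CLASS_MISSENSE = "Missense_Mutation"
_CLASS_NONSENSE = "Nonsense_Mutation"
_CLASS_FRAMESHIFT = ("Frame_Shift_Del", "Frame_Shift_Ins")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults describe a moderately sized exome screen: 200 neutral genes,
    5 planted oncogene-like and 5 planted tumour-suppressor-like genes,
    100 tumour samples, and per-gene per-nucleotide background rates
    (expected mutations across the whole cohort) drawn log-normally so a
    median-length gene collects a handful of passenger mutations while
    the tail produces a few heavily mutated background genes.
    """

    n_neutral_genes: int = 200
    n_og_genes: int = 5
    n_tsg_genes: int = 5
    n_samples: int = 100
    cds_length_range: tuple[int, int] = (450, 6000)
    #: log-normal parameters of the per-nucleotide cohort-wide rate
    log_rate_mean: float = math.log(5e-3)
    log_rate_sigma: float = 1.0
    #: fraction of a planted OG gene's missense mutations on hotspots
    hotspot_fraction: float = 0.5
    n_hotspots: int = 3
    #: fraction of a planted TSG gene's mutations that are truncating
    truncating_fraction: float = 0.5
    #: silent share in planted driver genes (low: drivers are selected)
    planted_silent_fraction: float = 0.05
    #: nonsense share among a planted OG gene's non-silent mutations
    planted_og_nonsense_fraction: float = 0.03
    #: planted genes carry at least this expected mutation count
    planted_min_expected: float = 40.0
    seed: int = 0
    #: neutral silent/missense/nonsense proportions (codon-space ratios)
    neutral_proportions: tuple[float, float, float] = field(
        default_factory=lambda: (
            STANDARD_CODE.n_silent / STANDARD_CODE.n_total,
            STANDARD_CODE.n_missense / STANDARD_CODE.n_total,
            STANDARD_CODE.n_nonsense / STANDARD_CODE.n_total,
        )
    )

    def validate(self) -> None:
        fractions = {
            "hotspot_fraction": self.hotspot_fraction,
            "truncating_fraction": self.truncating_fraction,
            "planted_silent_fraction": self.planted_silent_fraction,
            "planted_og_nonsense_fraction": self.planted_og_nonsense_fraction,
        }
        for name, value in fractions.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.n_hotspots < 1:
            raise ValueError("n_hotspots must be >= 1")
        lo, hi = self.cds_length_range
        if lo < 3 or hi < lo:
            raise ValueError(f"invalid cds_length_range {self.cds_length_range}")
        if self.n_hotspots > lo:
            raise ValueError("n_hotspots exceeds the minimum CDS length")
        for name in ("n_neutral_genes", "n_og_genes", "n_tsg_genes", "n_samples"):
            if getattr(self, name) < 0 or (name == "n_samples" and self.n_samples < 1):
                raise ValueError(f"{name} out of range")


def plan_genes(config: SimulationConfig) -> pd.DataFrame:
    """Draw the fixed per-gene ground truth shared by reference and cohort.

    Returns a frame with columns ``gene``, ``role`` (neutral/og/tsg),
    ``cds_length``, ``rate`` (per-nucleotide cohort-wide background rate)
    and ``hotspots`` (tuple of planted positions; empty unless og).
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    names: list[str] = []
    roles: list[str] = []
    names += [f"OG{i + 1:02d}" for i in range(config.n_og_genes)]
    roles += ["og"] * config.n_og_genes
    names += [f"TSG{i + 1:02d}" for i in range(config.n_tsg_genes)]
    roles += ["tsg"] * config.n_tsg_genes
    names += [f"NEU{i + 1:04d}" for i in range(config.n_neutral_genes)]
    roles += ["neutral"] * config.n_neutral_genes

    lo, hi = config.cds_length_range
    # CDS lengths in whole codons
    lengths = (rng.integers(lo // 3, hi // 3 + 1, size=len(names)) * 3).astype(int)
    rates = rng.lognormal(config.log_rate_mean, config.log_rate_sigma, size=len(names))
    hotspots = []
    for role, length in zip(roles, lengths):
        if role == "og":
            positions = rng.choice(length, size=config.n_hotspots, replace=False) + 1
            hotspots.append(tuple(int(p) for p in sorted(positions)))
        else:
            hotspots.append(())
    return pd.DataFrame(
        {
            "gene": names,
            "role": roles,
            "cds_length": lengths,
            "rate": rates,
            "hotspots": hotspots,
        }
    )


def _uniform_positions(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    return rng.integers(1, length + 1, size=n)


def _draw_gene_mutations(
    rng: np.random.Generator,
    row,
    config: SimulationConfig,
) -> tuple[np.ndarray, list[str]]:
    """Positions and variant classes for one gene's mutations."""
    mu = row.rate * row.cds_length
    if row.role != "neutral":
        mu = max(mu, config.planted_min_expected)
    n = int(rng.poisson(mu))
    if n == 0:
        return np.empty(0, dtype=int), []

    if row.role == "neutral":
        n_sil, n_mis, n_non = rng.multinomial(n, config.neutral_proportions)
        positions = _uniform_positions(rng, n, row.cds_length)
        classes = (
            [_CLASS_SILENT] * n_sil + [_CLASS_MISSENSE] * n_mis + [_CLASS_NONSENSE] * n_non
        )
        return positions, classes

    if row.role == "og":
        n_sil = int(rng.binomial(n, config.planted_silent_fraction))
        n_rest = n - n_sil
        n_non = int(rng.binomial(n_rest, config.planted_og_nonsense_fraction))
        n_mis = n_rest - n_non
        n_hot = int(rng.binomial(n_mis, config.hotspot_fraction))
        hot_positions = np.array(row.hotspots, dtype=int)
        hot_assign = hot_positions[rng.integers(0, len(hot_positions), size=n_hot)]
        other = _uniform_positions(rng, n - n_hot, row.cds_length)
        positions = np.concatenate([hot_assign, other])
        classes = (
            [_CLASS_MISSENSE] * n_hot
            + [_CLASS_MISSENSE] * (n_mis - n_hot)
            + [_CLASS_SILENT] * n_sil
            + [_CLASS_NONSENSE] * n_non
        )
        return positions, classes

    # tumour-suppressor-like gene
    n_tsg = int(rng.binomial(n, config.truncating_fraction))
    n_fs = int(rng.binomial(n_tsg, 0.5))  # nonsense vs frameshift split
    n_rest = n - n_tsg
    n_sil = int(rng.binomial(n_rest, config.planted_silent_fraction))
    n_mis = n_rest - n_sil
    positions = _uniform_positions(rng, n, row.cds_length)
    fs_classes = [
        _CLASS_FRAMESHIFT[i] for i in rng.integers(0, 2, size=n_fs)
    ]
    classes = (
        [_CLASS_NONSENSE] * (n_tsg - n_fs)
        + fs_classes
        + [_CLASS_SILENT] * n_sil
        + [_CLASS_MISSENSE] * n_mis
    )
    return positions, classes


def _simulate_table(
    truth: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
    sample_prefix: str,
) -> pd.DataFrame:
    """One realization of the generative process as a mutation table."""
    genes: list[str] = []
    samples: list[str] = []
    positions: list[int] = []
    classes: list[str] = []
    for row in truth.itertuples(index=False):
        pos, cls = _draw_gene_mutations(rng, row, config)
        n = len(cls)
        if n == 0:
            continue
        sample_idx = rng.integers(0, config.n_samples, size=n)
        genes += [row.gene] * n
        samples += [f"{sample_prefix}{i + 1:04d}" for i in sample_idx]
        positions += [int(p) for p in pos]
        classes += cls
    df = pd.DataFrame(
        {
            "gene": genes,
            "sample": samples,
            "cds_pos": positions,
            "variant_class": classes,
        }
    )
    # collapse duplicate calls (same gene/sample/position/class), as the
    # readers do, so generator tallies match what a round trip sees
    df = df.drop_duplicates().sort_values(["gene", "sample", "cds_pos"], kind="mergesort")
    return df.reset_index(drop=True)


def simulate_reference(
    config: SimulationConfig,
    truth: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the reference mutation table.

    Returns ``(mutations, truth)`` where ``mutations`` has columns
    ``gene``, ``sample``, ``cds_pos``, ``variant_class`` and ``truth`` is
    the gene plan from :func:`plan_genes`.  Deterministic in the config
    seed.
    """
    if truth is None:
        truth = plan_genes(config)
    rng = np.random.default_rng([config.seed, 1])
    return _simulate_table(truth, config, rng, sample_prefix="REFS"), truth


def simulate_cohort_maf(
    config: SimulationConfig,
    truth: pd.DataFrame,
) -> pd.DataFrame:
    """Simulate a cohort as a syntactically valid MAF frame.

    Re-runs the same generative process with an independent substream of
    the seed and formats the rows with standard MAF columns
    (``Hugo_Symbol``, ``Tumor_Sample_Barcode``, ``Variant_Classification``,
    ``HGVSc`` with HGVS-style ``c.`` positions).
    """
    rng = np.random.default_rng([config.seed, 2])
    table = _simulate_table(truth, config, rng, sample_prefix="TCGA-SIM-")
    n = len(table)
    ref_idx = rng.integers(0, 4, size=n)
    alt_shift = rng.integers(1, 4, size=n)
    ref = _SNV_BASES[ref_idx]
    alt = _SNV_BASES[(ref_idx + alt_shift) % 4]
    hgvsc = []
    for i, row in enumerate(table.itertuples(index=False)):
        if row.variant_class in _CLASS_FRAMESHIFT:
            suffix = "del" if row.variant_class.endswith("Del") else f"dup{ref[i]}"
            hgvsc.append(f"c.{row.cds_pos}{suffix}")
        else:
            hgvsc.append(f"c.{row.cds_pos}{ref[i]}>{alt[i]}")
    return pd.DataFrame(
        {
            "Hugo_Symbol": table["gene"],
            "Chromosome": "1",
            "Start_Position": np.arange(1, n + 1) * 10,
            "Variant_Classification": table["variant_class"],
            "Tumor_Sample_Barcode": table["sample"],
            "HGVSc": hgvsc,
        }
    )


def per_gene_class_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Tally gene x variant-class counts of a simulated table."""
    col = "variant_class" if "variant_class" in table.columns else "Variant_Classification"
    gene_col = "gene" if "gene" in table.columns else "Hugo_Symbol"
    return table.groupby([gene_col, col]).size().unstack(fill_value=0)


def cds_length_table(truth: pd.DataFrame) -> dict[str, int]:
    return {row.gene: int(row.cds_length) for row in truth.itertuples(index=False)}


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    out = truth.copy()
    out["hotspots"] = [";".join(str(p) for p in h) for h in out["hotspots"]]
    with atomic_write(path) as handle:
        out.to_csv(handle, sep="\t", index=False)


def write_maf(maf: pd.DataFrame, path: str | Path) -> None:
    with atomic_write(path) as handle:
        handle.write("#version 2.4\n")
        maf.to_csv(handle, sep="\t", index=False)
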